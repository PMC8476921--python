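"""Generator correctness: phasor mixtures, phantom frames, spectra, cohorts."""

import cmath

import numpy as np
import pytest

from flimspec import (
    CalibrationModel,
    CohortGroup,
    CohortSpec,
    NoiseModel,
    PhantomScene,
    RegionParams,
    alpha_for_apparent_lifetime,
    alpha_to_rsc,
    apparent_lifetime,
    compute_rsc,
    fit_baseline,
    make_phasor_signal,
    mwu_greater,
    reconstruct,
    render_demod_frame,
    rsc_to_alpha,
    synth_cohort,
    synth_spectrum,
)
from flimspec.synthetic_data import TAU_AUTO_NS, TAU_PPIX_NS


def oracle_phasor(alpha, tau_auto_ns, tau_ppix_ns, f_mod_hz):
    """Term-by-term complex-arithmetic phasor sum, independent of the
    vectorized implementation."""
    omega = 2.0 * cmath.pi * f_mod_hz
    total = 0j
    for fraction, tau in ((1.0 - alpha, tau_auto_ns), (alpha, tau_ppix_ns)):
        wt = omega * tau * 1e-9
        m = 1.0 / cmath.sqrt(1.0 + wt**2).real
        phi = cmath.atan(wt).real
        total += fraction * m * cmath.exp(1j * phi)
    return cmath.phase(total), abs(total)


class TestPhasorSignal:
    @pytest.mark.parametrize(
        "alpha,expected_tau", [(0.0, TAU_AUTO_NS), (1.0, TAU_PPIX_NS)]
    )
    def test_single_component_limits(self, alpha, expected_tau):
        assert apparent_lifetime(alpha) == pytest.approx(expected_tau, rel=1e-12)

    def test_mixture_matches_complex_oracle(self):
        for alpha in (0.1, 0.5, 0.9):
            phase, amp = make_phasor_signal(alpha, 1.6, 16.4, 10e6)
            phase_o, amp_o = oracle_phasor(alpha, 1.6, 16.4, 10e6)
            assert phase == pytest.approx(phase_o, rel=1e-12)
            assert amp == pytest.approx(amp_o, rel=1e-12)

    def test_mixture_lifetime_between_components(self):
        tau = apparent_lifetime(0.5)
        assert TAU_AUTO_NS < tau < TAU_PPIX_NS

    def test_strictly_monotone_in_alpha(self):
        taus = apparent_lifetime(np.linspace(0.0, 1.0, 101))
        assert np.all(np.diff(taus) > 0)

    @pytest.mark.parametrize("bad_tau", [0.0, -1.0, np.nan, np.inf])
    def test_invalid_lifetime_rejected(self, bad_tau):
        with pytest.raises(ValueError):
            make_phasor_signal(0.5, bad_tau, 16.4, 10e6)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_phasor_signal(1.5)

    def test_alpha_inversion_round_trip(self):
        for target in (1.6, 2.5, 4.1, 13.0, 16.4):
            alpha = alpha_for_apparent_lifetime(target)
            assert apparent_lifetime(alpha) == pytest.approx(target, abs=1e-9)


class TestRenderFrame:
    def test_noiseless_round_trip(self):
        scene = PhantomScene.uniform((32, 32), RegionParams(alpha_ppix=0.0, tau_auto_ns=2.0))
        frame = render_demod_frame(scene)
        tau_map, _ = reconstruct(frame, CalibrationModel(0.0))
        assert np.allclose(tau_map.tau, 2.0, atol=1e-9)

    def test_determinism_under_seed(self):
        scene = PhantomScene.uniform((32, 32), RegionParams(alpha_ppix=0.3))
        noise = NoiseModel(phase_jitter_scale=0.1, amplitude_noise_sd=1.0, seed=7)
        a = render_demod_frame(scene, noise)
        b = render_demod_frame(scene, noise)
        assert np.array_equal(a.phase, b.phase)
        assert np.array_equal(a.amplitude, b.amplitude)

    def test_noisy_mean_close_to_noiseless(self):
        scene = PhantomScene.uniform(
            (128, 128), RegionParams(alpha_ppix=0.0, tau_auto_ns=2.0, intensity_mv=100.0)
        )
        noise = NoiseModel(amplitude_noise_sd=1.0, seed=5)
        frame = render_demod_frame(scene, noise)
        tau_map, _ = reconstruct(frame, CalibrationModel(0.0))
        assert np.nanmean(tau_map.tau) == pytest.approx(2.0, rel=0.02)

    def test_empty_label_map_rejected(self):
        with pytest.raises(ValueError):
            PhantomScene(label_map=np.zeros((0, 0), dtype=int), region_params={})

    def test_unlabelled_region_rejected(self):
        with pytest.raises(ValueError):
            PhantomScene(label_map=np.ones((4, 4), dtype=int), region_params={0: RegionParams(0.0)})


class TestSynthSpectrum:
    @pytest.mark.parametrize("target", [0.0, 1.0])
    def test_degenerate_targets_round_trip(self, target):
        spectrum = synth_spectrum(target)
        decomp = compute_rsc(spectrum, fit_baseline(spectrum))
        assert decomp.rsc == pytest.approx(target, abs=1e-9)

    def test_intermediate_target_round_trip(self):
        spectrum = synth_spectrum(0.37)
        decomp = compute_rsc(spectrum, fit_baseline(spectrum))
        assert decomp.rsc == pytest.approx(0.37, abs=1e-6)

    def test_sloped_baseline_round_trip(self):
        spectrum = synth_spectrum(0.55, baseline=(900.0, -1.0))
        decomp = compute_rsc(spectrum, fit_baseline(spectrum))
        assert decomp.rsc == pytest.approx(0.55, abs=1e-6)

    def test_grid_covers_band_at_fine_spacing(self):
        spectrum = synth_spectrum(0.5)
        assert spectrum.wavelength[0] <= 590 and spectrum.wavelength[-1] >= 740
        assert np.max(np.diff(spectrum.wavelength)) <= 1.0 + 1e-12

    def test_target_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            synth_spectrum(1.2)

    def test_band_fraction_peak_fraction_link_inverts(self):
        for alpha in (0.0, 0.2, 0.7, 1.0):
            assert rsc_to_alpha(alpha_to_rsc(alpha)) == pytest.approx(alpha, abs=1e-12)

    def test_peak_rsc_exceeds_band_fraction(self):
        # The PpIX peak is narrower than the detection band, so the 635 nm
        # fraction is larger than the band-integrated fraction.
        for alpha in (0.2, 0.5, 0.8):
            assert alpha_to_rsc(alpha) > alpha


class TestSynthCohort:
    def test_control_median_recovered(self):
        spec = CohortSpec(
            groups=[CohortGroup("CTL", "none", "not_visible", 1, 1.6, 0.05)],
            frame_shape=(32, 32),
        )
        cohort = synth_cohort(spec, seed=11)
        frame = cohort.specimens[0].frame
        tau_map, _ = reconstruct(frame, CalibrationModel(0.0))
        # within sampling error of the generator draw around 1.6 ns
        assert np.nanmedian(tau_map.tau) == pytest.approx(1.6, rel=0.2)

    def test_empty_group_omitted_with_warning(self):
        spec = CohortSpec(
            groups=[
                CohortGroup("CTL", "none", "not_visible", 1, 1.6),
                CohortGroup("LGG", "INF", "not_visible", 0, 4.1),
            ],
            frame_shape=(16, 16),
        )
        with pytest.warns(UserWarning, match="0 specimens"):
            cohort = synth_cohort(spec, seed=0)
        assert set(cohort.manifest["entity"]) == {"CTL"}

    def test_separated_groups_reach_small_p(self):
        spec = CohortSpec(
            groups=[
                CohortGroup("CTL", "none", "not_visible", 10, 1.5, 0.05),
                CohortGroup("HGG", "TUM", "visible", 10, 13.0, 0.05),
            ],
            frame_shape=(16, 16),
        )
        cohort = synth_cohort(spec, seed=2)
        by_entity = {"CTL": [], "HGG": []}
        for specimen in cohort.specimens:
            by_entity[specimen.entity].append(specimen.true_lifetime_ns)
        result = mwu_greater(np.array(by_entity["HGG"]), np.array(by_entity["CTL"]))
        assert result.p_value < 0.005

    def test_determinism_and_registration(self):
        spec = CohortSpec(
            groups=[CohortGroup("LGG", "INF", "not_visible", 2, 4.1)],
            frame_shape=(16, 16),
        )
        a = synth_cohort(spec, seed=3)
        b = synth_cohort(spec, seed=3)
        assert a.manifest.equals(b.manifest)
        for sa, sb in zip(a.specimens, b.specimens):
            assert np.array_equal(sa.frame.phase, sb.frame.phase)
            assert sa.roi_coords == sb.roi_coords
            assert len(sa.spectra) == len(sa.roi_coords)
            for pa, pb in zip(sa.spectra, sb.spectra):
                assert np.array_equal(pa.counts, pb.counts)

    def test_cohort_write_layout(self, tmp_path):
        spec = CohortSpec(
            groups=[CohortGroup("MNG", "TUM", "visible", 1, 12.2)],
            frame_shape=(8, 8),
        )
        cohort = synth_cohort(spec, seed=4)
        manifest_path = cohort.write(tmp_path)
        import pandas as pd

        manifest = pd.read_csv(manifest_path)
        assert list(manifest.columns[:6]) == [
            "specimen_id",
            "entity",
            "subgroup",
            "fluorescence_status",
            "frame_path",
            "roi_spectra",
        ]
        for rel in manifest.loc[0, "roi_spectra"].split(";"):
            assert (tmp_path / rel).exists()
        assert (tmp_path / manifest.loc[0, "frame_path"]).exists()
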