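"""Synthetic FD-FLIM phantoms, emission spectra, and labeled cohorts.

The measured fluorescence of 5-ALA-labeled brain tissue is modelled as a
two-component mixture: tissue autofluorescence (mono-exponential, ~0.8-2 ns)
and protoporphyrin IX (PpIX, 16.4 ns in solution, main emission peak at
635 nm).  Under sinusoidal excitation at ``f_mod`` each mono-exponential
component contributes a phasor

    z_i = f_i * m_i * exp(1j * phi_i),   m_i = (1 + (w tau_i)^2)^-1/2,
    phi_i = atan(w tau_i),               w = 2 pi f_mod,

weighted by its steady-state intensity fraction ``f_i``.  The demodulated
signal is the vector sum, so the apparent phase lifetime of a mixture is a
signal-weighted average lying strictly between the component lifetimes.

This module renders demodulated frames for region-labelled phantom scenes,
synthesizes matched 590-740 nm emission spectra with a prescribed relative
PpIX signal contribution (RSC) at 635 nm, and assembles labelled specimen
cohorts so the full reconstruction / decomposition / statistics pipeline can
be exercised without instrument data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .flim_reconstruction import (
    DemodFrame,
    NS_PER_S,
    lifetime_to_phase,
    write_frame,
)
from .spectral_decomposition import EmissionSpectrum

__all__ = [
    "TAU_PPIX_NS",
    "TAU_AUTO_NS",
    "F_MOD_HZ",
    "BAND_NM",
    "FluorophoreComponent",
    "RegionParams",
    "PhantomScene",
    "NoiseModel",
    "CohortGroup",
    "CohortSpec",
    "SyntheticSpecimen",
    "SyntheticCohort",
    "make_phasor_signal",
    "apparent_lifetime",
    "alpha_for_apparent_lifetime",
    "render_demod_frame",
    "ppix_spectrum_shape",
    "synth_spectrum",
    "alpha_to_rsc",
    "rsc_to_alpha",
    "synth_cohort",
    "reference_frame",
]

# Study conditions: PpIX lifetime in solution, typical parenchyma
# autofluorescence lifetime, modulation frequency, and detection band.
TAU_PPIX_NS = 16.4
TAU_AUTO_NS = 1.6
F_MOD_HZ = 10e6
BAND_NM = (590.0, 740.0)

_ANCHOR_LO = (600.0, 610.0)
_ANCHOR_HI = (720.0, 730.0)


# --- component and scene types ----------------------------------------------


@dataclass(frozen=True)
class FluorophoreComponent:
    """A mono-exponential fluorophore with an emission spectrum shape.

    ``spectrum_shape`` maps wavelength (nm) to non-negative relative counts
    with unit peak on the detection band.
    """

    name: str
    lifetime_ns: float
    spectrum_shape: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lifetime_ns) and self.lifetime_ns > 0):
            raise ValueError("lifetime must be finite and positive")
        grid = np.linspace(*BAND_NM, 151)
        values = np.asarray(self.spectrum_shape(grid), dtype=float)
        if (values < 0).any():
            raise ValueError("spectrum_shape must be non-negative")
        if np.trapezoid(values, grid) <= 0:
            raise ValueError("spectrum_shape must have positive band integral")


@dataclass(frozen=True)
class RegionParams:
    """Mixture and signal parameters of one phantom region."""

    alpha_ppix: float
    tau_auto_ns: float = TAU_AUTO_NS
    intensity_mv: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_ppix <= 1.0:
            raise ValueError("alpha_ppix must be in [0, 1]")
        if not self.tau_auto_ns > 0:
            raise ValueError("tau_auto_ns must be positive")
        if self.intensity_mv < 0:
            raise ValueError("intensity_mv must be non-negative")


@dataclass(frozen=True)
class PhantomScene:
    """Region-labelled phantom: every pixel belongs to exactly one region."""

    label_map: np.ndarray
    region_params: dict[int, RegionParams]
    pixel_pitch_um: float = 25.0
    f_mod_hz: float = F_MOD_HZ
    tau_ppix_ns: float = TAU_PPIX_NS

    def __post_init__(self) -> None:
        labels = np.asarray(self.label_map, dtype=int)
        object.__setattr__(self, "label_map", labels)
        if labels.size == 0:
            raise ValueError("empty label map")
        missing = set(np.unique(labels)) - set(self.region_params)
        if missing:
            raise ValueError(f"label(s) {sorted(missing)} have no region parameters")
        if not self.pixel_pitch_um > 0:
            raise ValueError("pixel_pitch_um must be positive")

    @classmethod
    def uniform(
        cls, shape: tuple[int, int], params: RegionParams, **kwargs
    ) -> "PhantomScene":
        return cls(label_map=np.zeros(shape, dtype=int), region_params={0: params}, **kwargs)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise for frames and spectra.

    Frame noise is applied in the in-phase/quadrature (IQ) plane: Gaussian on
    both quadratures with standard deviation
    ``sqrt(amplitude_noise_sd^2 + phase_jitter_scale^2 * R)``, which yields a
    per-pixel phase jitter of about ``phase_jitter_scale / sqrt(R)`` -- the
    amplitude-dependent jitter characteristic of lock-in detection.  Spectra
    receive a dark-count offset and optional Poisson shot noise.
    """

    phase_jitter_scale: float = 0.0  # rad * sqrt(mV_RMS)
    amplitude_noise_sd: float = 0.0  # mV_RMS
    spectrum_dark_offset: float = 0.0  # counts
    spectrum_poisson: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase_jitter_scale < 0 or self.amplitude_noise_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if self.spectrum_dark_offset < 0:
            raise ValueError("spectrum_dark_offset must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @property
    def is_quiet(self) -> bool:
        return self.phase_jitter_scale == 0 and self.amplitude_noise_sd == 0


# --- frequency-domain forward model ------------------------------------------


def _component_phasor(tau_ns, f_mod_hz: float):
    omega_tau = 2.0 * np.pi * f_mod_hz * np.asarray(tau_ns, dtype=float) / NS_PER_S
    return (1.0 + 1j * omega_tau) / (1.0 + omega_tau**2)


def make_phasor_signal(
    alpha_ppix,
    tau_auto_ns: float = TAU_AUTO_NS,
    tau_ppix_ns: float = TAU_PPIX_NS,
    f_mod_hz: float = F_MOD_HZ,
):
    """Demodulated (phase, relative amplitude) of a two-component mixture.

    ``alpha_ppix`` is the PpIX fraction of the total detected steady-state
    signal; the remainder is autofluorescence.  Accepts scalar or array
    ``alpha_ppix``.  Returns phase in rad and amplitude relative to the total
    steady-state intensity (i.e. the effective modulation depth).
    """
    for tau in (tau_auto_ns, tau_ppix_ns):
        if not (np.isfinite(tau) and tau > 0):
            raise ValueError("lifetimes must be finite and positive")
    if not f_mod_hz > 0:
        raise ValueError("f_mod_hz must be positive")
    alpha = np.asarray(alpha_ppix, dtype=float)
    if (alpha < 0).any() or (alpha > 1).any():
        raise ValueError("alpha_ppix must be in [0, 1]")
    z = (1.0 - alpha) * _component_phasor(tau_auto_ns, f_mod_hz) + (
        alpha * _component_phasor(tau_ppix_ns, f_mod_hz)
    )
    phase = np.angle(z)
    amplitude = np.abs(z)
    if phase.ndim == 0:
        return float(phase), float(amplitude)
    return phase, amplitude


def apparent_lifetime(
    alpha_ppix,
    tau_auto_ns: float = TAU_AUTO_NS,
    tau_ppix_ns: float = TAU_PPIX_NS,
    f_mod_hz: float = F_MOD_HZ,
):
    """Apparent phase lifetime (ns) of the two-component mixture."""
    phase, _ = make_phasor_signal(alpha_ppix, tau_auto_ns, tau_ppix_ns, f_mod_hz)
    return np.tan(phase) / (2.0 * np.pi * f_mod_hz) * NS_PER_S


def alpha_for_apparent_lifetime(
    tau_ns: float,
    tau_auto_ns: float = TAU_AUTO_NS,
    tau_ppix_ns: float = TAU_PPIX_NS,
    f_mod_hz: float = F_MOD_HZ,
) -> float:
    """Invert the mixture: PpIX fraction giving a target apparent lifetime.

    The alpha -> lifetime map is strictly increasing for
    ``tau_auto < tau_ppix``, so the root is unique (brentq).
    """
    if not tau_auto_ns <= tau_ns <= tau_ppix_ns:
        raise ValueError(
            f"target lifetime {tau_ns} ns outside [{tau_auto_ns}, {tau_ppix_ns}]"
        )
    if tau_ns == tau_auto_ns:
        return 0.0
    if tau_ns == tau_ppix_ns:
        return 1.0
    return float(
        brentq(
            lambda a: apparent_lifetime(a, tau_auto_ns, tau_ppix_ns, f_mod_hz) - tau_ns,
            0.0,
            1.0,
            xtol=1e-14,
        )
    )


def render_demod_frame(
    scene: PhantomScene,
    noise: NoiseModel | None = None,
    phase_offset: float = 0.0,
) -> DemodFrame:
    """Render a phantom scene into a demodulated (phase, amplitude) frame.

    Each pixel takes the mixture phasor of its region scaled by the region's
    total intensity; ``phase_offset`` emulates the uncalibrated instrument
    delay.  IQ-plane noise is applied per :class:`NoiseModel`; output is
    bit-reproducible for a fixed noise seed.
    """
    noise = noise or NoiseModel()
    labels = scene.label_map
    phase = np.zeros(labels.shape, dtype=float)
    amplitude = np.zeros(labels.shape, dtype=float)
    for label, params in scene.region_params.items():
        sel = labels == label
        if not sel.any():
            continue
        ph, rel_amp = make_phasor_signal(
            params.alpha_ppix, params.tau_auto_ns, scene.tau_ppix_ns, scene.f_mod_hz
        )
        phase[sel] = ph
        amplitude[sel] = params.intensity_mv * rel_amp
    phase = phase + phase_offset

    if not noise.is_quiet:
        rng = noise.rng()
        sd = np.sqrt(
            noise.amplitude_noise_sd**2 + noise.phase_jitter_scale**2 * amplitude
        )
        i_comp = amplitude * np.cos(phase) + rng.normal(0.0, 1.0, labels.shape) * sd
        q_comp = amplitude * np.sin(phase) + rng.normal(0.0, 1.0, labels.shape) * sd
        phase = np.arctan2(q_comp, i_comp)
        amplitude = np.hypot(i_comp, q_comp)

    return DemodFrame(
        phase=phase,
        amplitude=amplitude,
        f_mod_hz=scene.f_mod_hz,
        pixel_pitch_um=scene.pixel_pitch_um,
    )


# --- emission spectra ---------------------------------------------------------


def _cosine_taper(wavelength: np.ndarray, lo: float, lo_full: float,
                  hi_full: float, hi: float) -> np.ndarray:
    """Smooth window: 0 outside [lo, hi], 1 on [lo_full, hi_full]."""
    w = np.zeros_like(wavelength, dtype=float)
    w[(wavelength >= lo_full) & (wavelength <= hi_full)] = 1.0
    rise = (wavelength > lo) & (wavelength < lo_full)
    w[rise] = 0.5 * (1 - np.cos(np.pi * (wavelength[rise] - lo) / (lo_full - lo)))
    fall = (wavelength > hi_full) & (wavelength < hi)
    w[fall] = 0.5 * (1 + np.cos(np.pi * (wavelength[fall] - hi_full) / (hi - hi_full)))
    return w


def ppix_spectrum_shape(
    wavelength,
    main_sigma_nm: float = 10.0,
    satellite_sigma_nm: float = 12.0,
    satellite_height: float = 0.3,
) -> np.ndarray:
    """PpIX emission shape: main peak at 635 nm plus a 705 nm satellite.

    Two Gaussians multiplied by a smooth cosine taper that is identically
    zero inside the baseline anchor windows (600-610 and 720-730 nm), so the
    dual-window baseline sees no PpIX signal at all.  Unit height at 635 nm.
    """
    wavelength = np.asarray(wavelength, dtype=float)
    shape = np.exp(-0.5 * ((wavelength - 635.0) / main_sigma_nm) ** 2)
    shape = shape + satellite_height * np.exp(
        -0.5 * ((wavelength - 705.0) / satellite_sigma_nm) ** 2
    )
    shape = shape * _cosine_taper(wavelength, 612.0, 622.0, 708.0, 718.0)
    peak = np.exp(0.0) + satellite_height * np.exp(-0.5 * (70.0 / satellite_sigma_nm) ** 2)
    return shape / peak


def _default_grid(spacing_nm: float = 1.0) -> np.ndarray:
    n = int(round((BAND_NM[1] - BAND_NM[0]) / spacing_nm)) + 1
    return np.linspace(BAND_NM[0], BAND_NM[1], n)


def synth_spectrum(
    target_rsc: float,
    baseline: tuple[float, float] = (400.0, 0.0),
    noise: NoiseModel | None = None,
    wavelength: np.ndarray | None = None,
    peak_counts: float | None = None,
) -> EmissionSpectrum:
    """Synthesize an emission spectrum with a prescribed noiseless RSC.

    The spectrum is a linear autofluorescence baseline (``intercept, slope``
    in counts and counts/nm) plus the PpIX shape with peak height ``h``
    chosen so that the dual-window baseline decomposition at 635 nm returns
    exactly ``target_rsc`` on the noiseless signal:

        h = target_rsc * baseline(635) / (1 - target_rsc)

    (the PpIX shape vanishes inside both anchor windows, so the fitted
    baseline recovers the true line exactly).  ``target_rsc == 1`` requires a
    vanishing autofluorescence contribution at the peak and is realized with
    a zero baseline.  ``peak_counts`` rescales the spectrum so the total at
    635 nm hits the given count level (useful with Poisson noise).
    """
    if not 0.0 <= target_rsc <= 1.0:
        raise ValueError("target_rsc must be in [0, 1]")
    grid = _default_grid() if wavelength is None else np.asarray(wavelength, float)
    intercept, slope = baseline
    base = intercept + slope * grid
    if (base < 0).any():
        raise ValueError("baseline must be non-negative over the band")
    base_635 = intercept + slope * 635.0

    if target_rsc == 1.0:
        base = np.zeros_like(grid)
        height = base_635 if base_635 > 0 else float(intercept) or 1000.0
    else:
        height = target_rsc * base_635 / (1.0 - target_rsc)
    counts = base + height * ppix_spectrum_shape(grid)

    if peak_counts is not None:
        total_635 = counts[np.argmin(np.abs(grid - 635.0))]
        if total_635 > 0:
            counts = counts * (peak_counts / total_635)

    if noise is not None:
        rng = noise.rng()
        counts = counts + noise.spectrum_dark_offset
        if noise.spectrum_poisson:
            counts = rng.poisson(np.clip(counts, 0, None)).astype(float)
    return EmissionSpectrum(wavelength=grid, counts=counts)


def _band_link_integrals(
    baseline: tuple[float, float], grid: np.ndarray | None = None
) -> tuple[float, float, float]:
    grid = _default_grid() if grid is None else grid
    intercept, slope = baseline
    base = np.clip(intercept + slope * grid, 0, None)
    shape = ppix_spectrum_shape(grid)
    return (
        float(np.trapezoid(shape, grid)),
        float(np.trapezoid(base, grid)),
        float(intercept + slope * 635.0),
    )


def alpha_to_rsc(alpha: float, baseline: tuple[float, float] = (400.0, 0.0)) -> float:
    """Map the band-integrated PpIX signal fraction to the 635 nm RSC.

    ``alpha`` is the PpIX fraction of the total signal integrated over the
    590-740 nm detection band (the quantity entering the phasor mixture);
    the RSC is the PpIX fraction at the 635 nm peak only.  Both are computed
    from the same component shapes, so the two metrics are linked but not
    identical -- the PpIX peak is narrower than the band, making RSC at the
    peak larger than the band fraction.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if alpha == 1.0:
        return 1.0
    shape_int, base_int, base_635 = _band_link_integrals(baseline)
    height = alpha * base_int / ((1.0 - alpha) * shape_int)
    return height / (height + base_635)


def rsc_to_alpha(rsc: float, baseline: tuple[float, float] = (400.0, 0.0)) -> float:
    """Inverse of :func:`alpha_to_rsc`."""
    if not 0.0 <= rsc <= 1.0:
        raise ValueError("rsc must be in [0, 1]")
    if rsc == 1.0:
        return 1.0
    shape_int, base_int, base_635 = _band_link_integrals(baseline)
    height = rsc * base_635 / (1.0 - rsc)
    signal_ppix = height * shape_int
    return signal_ppix / (signal_ppix + base_int)


# --- cohorts ------------------------------------------------------------------


@dataclass(frozen=True)
class CohortGroup:
    """One labelled specimen group of a synthetic cohort.

    Specimen-level apparent lifetimes are drawn log-normally:
    ``ln tau ~ N(ln lifetime_median_ns, lifetime_sigma_log^2)`` (lifetimes
    are positive and right-skewed across specimens).  The PpIX mixture
    fraction per specimen is derived by inverting the phasor mixture for the
    drawn lifetime; ``alpha_jitter_sd`` adds ROI-to-ROI variability.
    """

    entity: str
    subgroup: str = "none"
    fluorescence_status: str = "not_visible"
    n_specimens: int = 3
    lifetime_median_ns: float = TAU_AUTO_NS
    lifetime_sigma_log: float = 0.15
    alpha_jitter_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.n_specimens < 0:
            raise ValueError("n_specimens must be >= 0")
        if not 0 < self.lifetime_median_ns <= 20.0:
            raise ValueError("lifetime_median_ns must lie in (0, 20] ns")
        if self.lifetime_sigma_log < 0 or self.alpha_jitter_sd < 0:
            raise ValueError("spread parameters must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Group structure of a synthetic cohort (entities x subgroups)."""

    groups: Sequence[CohortGroup]
    frame_shape: tuple[int, int] = (64, 64)
    pixel_pitch_um: float = 100.0
    f_mod_hz: float = F_MOD_HZ
    tau_auto_ns: float = TAU_AUTO_NS
    tau_ppix_ns: float = TAU_PPIX_NS
    rois_per_specimen: int = 3
    baseline: tuple[float, float] = (400.0, 0.0)
    instrument_phase_offset: float = 0.0
    noise: NoiseModel = field(
        default_factory=lambda: NoiseModel(
            phase_jitter_scale=0.05, amplitude_noise_sd=0.5, spectrum_poisson=True
        )
    )

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort spec needs at least one group")
        if self.rois_per_specimen < 1:
            raise ValueError("rois_per_specimen must be >= 1")


@dataclass
class SyntheticSpecimen:
    """One generated specimen: frame plus spatially registered ROI spectra."""

    specimen_id: str
    entity: str
    subgroup: str
    fluorescence_status: str
    frame: DemodFrame
    spectra: list[EmissionSpectrum]
    roi_coords: list[tuple[int, int]]
    true_lifetime_ns: float
    true_alpha: float


@dataclass
class SyntheticCohort:
    """Generated cohort: specimens plus a manifest table."""

    specimens: list[SyntheticSpecimen]
    manifest: pd.DataFrame
    seed: int

    def write(self, out_dir) -> Path:
        """Write frames (TIFF+JSON), spectra (CSV) and the manifest CSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for spec in self.specimens:
            frame_path = out_dir / f"{spec.specimen_id}_frame.tif"
            write_frame(spec.frame, frame_path, seed=self.seed)
            spectra_paths = []
            for k, (spectrum, (row, col)) in enumerate(
                zip(spec.spectra, spec.roi_coords)
            ):
                sp_path = out_dir / f"{spec.specimen_id}_roi{k}.csv"
                spectrum.to_csv(sp_path)
                spectra_paths.append(sp_path.name)
            rows.append(
                {
                    "specimen_id": spec.specimen_id,
                    "entity": spec.entity,
                    "subgroup": spec.subgroup,
                    "fluorescence_status": spec.fluorescence_status,
                    "frame_path": frame_path.name,
                    "roi_spectra": ";".join(spectra_paths),
                    "roi_coords": ";".join(
                        f"{r},{c}" for r, c in spec.roi_coords
                    ),
                }
            )
        manifest_path = out_dir / "manifest.csv"
        pd.DataFrame(rows).to_csv(manifest_path, index=False)
        return manifest_path


def reference_frame(
    spec: CohortSpec, tau_ref_ns: float = 2.0, seed: int = 12345
) -> DemodFrame:
    """Calibration reference: uniform mono-exponential sample rendered with
    the same instrument phase offset as the cohort frames."""
    scene = PhantomScene.uniform(
        spec.frame_shape,
        RegionParams(alpha_ppix=0.0, tau_auto_ns=tau_ref_ns),
        pixel_pitch_um=spec.pixel_pitch_um,
        f_mod_hz=spec.f_mod_hz,
        tau_ppix_ns=spec.tau_ppix_ns,
    )
    noise = NoiseModel(
        phase_jitter_scale=spec.noise.phase_jitter_scale,
        amplitude_noise_sd=spec.noise.amplitude_noise_sd,
        seed=seed,
    )
    return render_demod_frame(scene, noise, phase_offset=spec.instrument_phase_offset)


def synth_cohort(spec: CohortSpec, seed: int = 0) -> SyntheticCohort:
    """Generate a labelled synthetic cohort from a group specification.

    For each specimen an apparent lifetime is drawn from its group's
    log-normal distribution, the corresponding PpIX fraction is obtained by
    inverting the phasor mixture, one uniform-region frame is rendered, and
    3-4 spatially registered ROI spectra are synthesized whose 635 nm RSC
    follows from the specimen's band fraction.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    specimens: list[SyntheticSpecimen] = []
    rows = []
    for group in spec.groups:
        if group.n_specimens == 0:
            warnings.warn(
                f"group {group.entity}/{group.subgroup} has 0 specimens; omitted",
                stacklevel=2,
            )
            continue
        for i in range(group.n_specimens):
            sid = f"{group.entity}-{group.subgroup}-{i:03d}"
            tau = float(
                np.exp(rng.normal(np.log(group.lifetime_median_ns), group.lifetime_sigma_log))
            )
            tau = float(np.clip(tau, 0.05, spec.tau_ppix_ns - 1e-6))
            # Draws at or below the autofluorescence base are pure
            # autofluorescence with that lifetime; above it, PpIX admixture.
            if tau <= spec.tau_auto_ns:
                tau_auto, alpha = tau, 0.0
            else:
                tau_auto = spec.tau_auto_ns
                alpha = alpha_for_apparent_lifetime(
                    tau, tau_auto, spec.tau_ppix_ns, spec.f_mod_hz
                )
            noise = NoiseModel(
                phase_jitter_scale=spec.noise.phase_jitter_scale,
                amplitude_noise_sd=spec.noise.amplitude_noise_sd,
                spectrum_dark_offset=spec.noise.spectrum_dark_offset,
                spectrum_poisson=spec.noise.spectrum_poisson,
                seed=int(rng.integers(2**31 - 1)),
            )
            scene = PhantomScene.uniform(
                spec.frame_shape,
                RegionParams(alpha_ppix=alpha, tau_auto_ns=tau_auto),
                pixel_pitch_um=spec.pixel_pitch_um,
                f_mod_hz=spec.f_mod_hz,
                tau_ppix_ns=spec.tau_ppix_ns,
            )
            frame = render_demod_frame(
                scene, noise, phase_offset=spec.instrument_phase_offset
            )

            n_rois = spec.rois_per_specimen + int(rng.integers(0, 2))
            coords = [
                (int(rng.integers(spec.frame_shape[0])), int(rng.integers(spec.frame_shape[1])))
                for _ in range(n_rois)
            ]
            spectra = []
            for _ in range(n_rois):
                a_roi = float(np.clip(alpha + rng.normal(0, group.alpha_jitter_sd), 0, 1))
                roi_noise = NoiseModel(
                    spectrum_dark_offset=spec.noise.spectrum_dark_offset,
                    spectrum_poisson=spec.noise.spectrum_poisson,
                    seed=int(rng.integers(2**31 - 1)),
                )
                spectra.append(
                    synth_spectrum(
                        alpha_to_rsc(a_roi, spec.baseline),
                        baseline=spec.baseline,
                        noise=roi_noise if spec.noise.spectrum_poisson else None,
                        peak_counts=10_000.0 if spec.noise.spectrum_poisson else None,
                    )
                )
            specimens.append(
                SyntheticSpecimen(
                    specimen_id=sid,
                    entity=group.entity,
                    subgroup=group.subgroup,
                    fluorescence_status=group.fluorescence_status,
                    frame=frame,
                    spectra=spectra,
                    roi_coords=coords,
                    true_lifetime_ns=tau,
                    true_alpha=alpha,
                )
            )
            rows.append(
                {
                    "specimen_id": sid,
                    "entity": group.entity,
                    "subgroup": group.subgroup,
                    "fluorescence_status": group.fluorescence_status,
                    "true_lifetime_ns": tau,
                    "true_alpha": alpha,
                }
            )
    manifest = pd.DataFrame(rows)
    return SyntheticCohort(specimens=specimens, manifest=manifest, seed=seed)
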