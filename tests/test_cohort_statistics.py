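"""Pixel subsampling, group summaries, KS shape checks, Mann-Whitney tests."""

import numpy as np
import pytest
from scipy.special import comb

from flimspec import (
    GroupSample,
    LifetimeMap,
    SpecimenRecord,
    build_group_samples,
    ks_shape_check,
    mwu_greater,
    significance_stars,
    subsample_pixels,
    summarize,
)
from flimspec.cohort_statistics import cohort_results_table


def lifetime_map(values):
    return LifetimeMap(tau=np.asarray(values, dtype=float))


def group(values, key=("HGG", "TUM", "visible")):
    values = np.asarray(values, dtype=float)
    return GroupSample(
        key=key, lifetimes_ns=values, specimen_ids=("s0",), n_per_specimen=values.size
    )


class TestSubsample:
    def test_exhaustive_sample_is_permutation(self):
        tau = np.arange(1.0, 26.0).reshape(5, 5)
        sample = subsample_pixels(lifetime_map(tau), 25, seed=0)
        assert np.array_equal(np.sort(sample), np.sort(tau.ravel()))

    def test_uniform_map_yields_constant(self):
        sample = subsample_pixels(lifetime_map(np.full((10, 10), 5.0)), 30, seed=1)
        assert np.all(sample == 5.0)

    def test_two_region_fraction_hypergeometric(self):
        tau = np.concatenate([np.full(10_000, 2.0), np.full(10_000, 12.0)])
        sample = subsample_pixels(lifetime_map(tau.reshape(100, 200)), 10_000, seed=2)
        assert np.mean(sample == 12.0) == pytest.approx(0.5, abs=0.015)

    def test_nan_pixels_excluded_and_reduced_with_warning(self):
        tau = np.full((4, 4), 3.0)
        tau[0, :] = np.nan
        with pytest.warns(UserWarning, match="only 12"):
            sample = subsample_pixels(lifetime_map(tau), 16, seed=0)
        assert sample.size == 12 and np.all(sample == 3.0)

    def test_no_valid_pixels_rejected(self):
        with pytest.raises(ValueError):
            subsample_pixels(lifetime_map(np.full((2, 2), np.nan)), 1, seed=0)

    def test_deterministic_under_seed(self):
        tau = np.random.default_rng(0).uniform(1, 10, (20, 20))
        a = subsample_pixels(lifetime_map(tau), 100, seed=5)
        b = subsample_pixels(lifetime_map(tau), 100, seed=5)
        assert np.array_equal(a, b)


class TestGroupSamples:
    def test_equal_contribution_per_specimen(self, rng):
        records = [
            SpecimenRecord(
                specimen_id=f"s{i}",
                entity="HGG",
                subgroup="TUM",
                fluorescence_status="visible",
                lifetime_map=lifetime_map(rng.uniform(1, 15, (8, 8 + i))),
            )
            for i in range(3)
        ]
        groups = build_group_samples(records, seed=0)
        sample = groups[("HGG", "TUM", "visible")]
        # smallest specimen has 64 valid pixels -> 64 from each of 3 specimens
        assert sample.n_per_specimen == 64
        assert sample.lifetimes_ns.size == 3 * 64

    def test_control_subgroup_vocabulary(self):
        with pytest.raises(ValueError):
            SpecimenRecord("c0", "CTL", "TUM", "not_visible", lifetime_map(np.ones((2, 2))))


class TestSummarize:
    def test_small_sample_quartiles(self):
        summary = summarize(group([1, 2, 3, 4, 5]))
        assert (summary.median, summary.q1, summary.q3, summary.mean) == (3, 2, 4, 3)

    def test_constant_group(self):
        summary = summarize(group([7.0] * 10))
        assert summary.sd == 0.0
        assert summary.q1 == summary.median == summary.q3 == 7.0

    def test_lognormal_median_matches_analytic(self, rng):
        mu, sigma = np.log(4.1), 0.4
        values = np.exp(rng.normal(mu, sigma, 21_733))
        summary = summarize(group(values))
        assert summary.median == pytest.approx(np.exp(mu), rel=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize(group([]))


class TestKsShapeCheck:
    def test_group_against_itself_d_zero(self, rng):
        values = rng.normal(5, 1, 500)
        table = ks_shape_check([group(values, ("HGG", "TUM", "visible")),
                                group(values, ("CTL", "none", "not_visible"))])
        assert table.loc[0, "statistic"] == 0.0
        assert not table.loc[0, "flagged"]

    def test_same_shape_different_location_scale_not_flagged(self, rng):
        a = rng.normal(2, 0.5, 5000)
        b = rng.normal(12, 2.5, 5000)  # same shape, shifted and scaled
        table = ks_shape_check([group(a, ("CTL", "none", "not_visible")),
                                group(b, ("MNG", "TUM", "visible"))])
        assert not table.loc[0, "flagged"]

    def test_different_shapes_flagged(self, rng):
        a = rng.normal(0, 1, 5000)
        b = rng.standard_t(1.5, 5000)  # heavy tails
        table = ks_shape_check([group(a, ("CTL", "none", "not_visible")),
                                group(b, ("HGG", "NEC", "visible"))])
        assert table.loc[0, "flagged"]

    def test_zero_iqr_group_skipped_with_warning(self, rng):
        degenerate = group([3.0] * 100, ("LGG", "REA", "not_visible"))
        healthy = [group(rng.normal(0, 1, 200), ("CTL", "none", "not_visible")),
                   group(rng.normal(5, 2, 200), ("HGG", "TUM", "visible"))]
        with pytest.warns(UserWarning, match="zero spread"):
            table = ks_shape_check([degenerate, *healthy])
        assert len(table) == 1  # only the healthy pair remains

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            ks_shape_check([group(rng.normal(0, 1, 10))])


class TestMannWhitney:
    def test_identical_samples_p_near_half(self, rng):
        values = rng.uniform(1, 10, 200)
        result = mwu_greater(values, values.copy())
        assert result.p_value == pytest.approx(0.5, abs=0.05)
        assert result.stars == ""

    def test_complete_separation_exact_tail(self):
        control = np.arange(1.0, 21.0)
        treated = control + 100.0
        result = mwu_greater(treated, control)
        # extreme one-sided tail of the exact U distribution
        assert result.p_value == pytest.approx(1.0 / comb(40, 20), rel=1e-9)
        assert result.p_value < 1e-6
        assert result.stars == "***"

    def test_rank_invariance_under_monotone_transform(self, rng):
        a = rng.normal(5, 1, 80)
        b = rng.normal(6, 1, 90)
        p_raw = mwu_greater(b, a).p_value
        p_log = mwu_greater(np.exp(b / 3), np.exp(a / 3)).p_value
        assert p_raw == pytest.approx(p_log, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mwu_greater(np.array([]), np.array([1.0]))

    @pytest.mark.parametrize(
        "p,stars", [(0.2, ""), (0.049, "*"), (0.009, "**"), (0.004, "***"), (0.05, "")]
    )
    def test_star_convention(self, p, stars):
        assert significance_stars(p) == stars


class TestResultsTable:
    def test_ordering_and_stars_recovered(self, rng):
        records = []
        for entity, subgroup, status, median in (
            ("CTL", "none", "not_visible", 1.6),
            ("LGG", "INF", "not_visible", 4.1),
            ("HGG", "TUM", "visible", 13.0),
        ):
            for i in range(3):
                tau = np.exp(rng.normal(np.log(median), 0.1, (24, 24)))
                records.append(
                    SpecimenRecord(f"{entity}{i}", entity, subgroup, status,
                                   lifetime_map(tau))
                )
        table = cohort_results_table(build_group_samples(records, seed=0))
        table = table.set_index("entity")
        assert table.loc["CTL", "median"] < table.loc["LGG", "median"] < table.loc["HGG", "median"]
        assert table.loc["LGG", "stars"] == "***"
        assert table.loc["HGG", "stars"] == "***"

    def test_missing_control_rejected(self, rng):
        records = [SpecimenRecord("h0", "HGG", "TUM", "visible",
                                  lifetime_map(rng.uniform(1, 15, (8, 8))))]
        with pytest.raises(ValueError, match="control"):
            cohort_results_table(build_group_samples(records, seed=0))
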