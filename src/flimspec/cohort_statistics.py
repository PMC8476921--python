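"""Cohort-level lifetime statistics across labelled specimen groups.

Specimens contribute equally: the number of evaluated pixels per specimen is
normalized to the smallest specimen by uniform random subsampling without
replacement.  Group summaries report mean, SD, median, and quartiles.  Each
tumor group is tested one-sided (greater) against the non-pathological
control group with a Mann-Whitney U test; comparability of distribution
shapes -- a prerequisite for reading the U test as a median comparison -- is
checked with pairwise two-sample Kolmogorov-Smirnov tests after each group
is standardized by its median and interquartile range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .flim_reconstruction import LifetimeMap

__all__ = [
    "STAR_THRESHOLDS",
    "SpecimenRecord",
    "GroupSample",
    "GroupSummary",
    "TestResult",
    "subsample_pixels",
    "build_group_samples",
    "summarize",
    "ks_shape_check",
    "mwu_greater",
    "significance_stars",
    "cohort_results_table",
]

ENTITIES = ("CTL", "LGG", "HGG", "MNG", "MET")
SUBGROUPS = ("TUM", "INF", "NEC", "REA", "none")
STAR_THRESHOLDS = (0.05, 0.01, 0.005)


@dataclass(frozen=True)
class SpecimenRecord:
    """A labelled specimen and its reconstructed lifetime map."""

    specimen_id: str
    entity: str
    subgroup: str
    fluorescence_status: str
    lifetime_map: LifetimeMap

    def __post_init__(self) -> None:
        if self.entity not in ENTITIES:
            raise ValueError(f"unknown entity {self.entity!r}")
        if self.subgroup not in SUBGROUPS:
            raise ValueError(f"unknown subgroup {self.subgroup!r}")
        if self.entity == "CTL" and self.subgroup != "none":
            raise ValueError("control specimens carry subgroup 'none'")


@dataclass(frozen=True)
class GroupSample:
    """Pooled subsampled pixel lifetimes of one (entity, subgroup, status) group."""

    key: tuple[str, str, str]
    lifetimes_ns: np.ndarray
    specimen_ids: tuple[str, ...]
    n_per_specimen: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "lifetimes_ns", np.asarray(self.lifetimes_ns, dtype=float)
        )


@dataclass(frozen=True)
class GroupSummary:
    median: float
    q1: float
    q3: float
    mean: float
    sd: float
    n_specimens: int
    n_pixels: int

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles out of order")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    alternative: str = "greater"
    stars: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def subsample_pixels(
    lifetime_map: LifetimeMap, n: int, seed: int
) -> np.ndarray:
    """Uniform random sample of ``n`` valid pixel lifetimes, without replacement.

    If fewer than ``n`` valid pixels exist, all of them are returned with a
    warning.  Deterministic for a fixed seed.
    """
    values = lifetime_map.valid_values
    if values.size == 0:
        raise ValueError("lifetime map has no valid pixels")
    if n > values.size:
        warnings.warn(
            f"requested {n} pixels but only {values.size} are valid; using all",
            stacklevel=2,
        )
        n = values.size
    rng = np.random.default_rng(seed)
    idx = rng.choice(values.size, size=n, replace=False)
    return values[idx]


def build_group_samples(
    records: Sequence[SpecimenRecord],
    n_subsample: int | None = None,
    seed: int = 0,
) -> dict[tuple[str, str, str], GroupSample]:
    """Group specimens and pool equal per-specimen pixel subsamples.

    ``n_subsample`` defaults to the smallest valid-pixel count over all
    specimens, so every specimen contributes the same number of pixels.
    Child seeds are derived per specimen for reproducible yet independent
    subsampling.
    """
    if not records:
        raise ValueError("no specimen records")
    valid_counts = [r.lifetime_map.valid_values.size for r in records]
    if min(valid_counts) == 0:
        bad = records[int(np.argmin(valid_counts))].specimen_id
        raise ValueError(f"specimen {bad} has no valid pixels")
    if n_subsample is None:
        n_subsample = min(valid_counts)
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.generate_state(len(records)) % (2**31 - 1)
    groups: dict[tuple[str, str, str], dict] = {}
    for record, child in zip(records, child_seeds):
        key = (record.entity, record.subgroup, record.fluorescence_status)
        sample = subsample_pixels(record.lifetime_map, n_subsample, int(child))
        bucket = groups.setdefault(key, {"values": [], "ids": []})
        bucket["values"].append(sample)
        bucket["ids"].append(record.specimen_id)
    return {
        key: GroupSample(
            key=key,
            lifetimes_ns=np.concatenate(bucket["values"]),
            specimen_ids=tuple(bucket["ids"]),
            n_per_specimen=n_subsample,
        )
        for key, bucket in groups.items()
    }


def summarize(group: GroupSample) -> GroupSummary:
    """Descriptive statistics (linear-interpolation quantiles, sample SD)."""
    values = group.lifetimes_ns
    if values.size == 0:
        raise ValueError("empty group")
    q1, median, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return GroupSummary(
        median=float(median),
        q1=float(q1),
        q3=float(q3),
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
        n_specimens=len(group.specimen_ids),
        n_pixels=int(values.size),
    )


def _standardize(values: np.ndarray) -> np.ndarray | None:
    median = np.median(values)
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    if iqr == 0:
        return None
    return (values - median) / iqr


def ks_shape_check(
    groups: Sequence[GroupSample],
    alpha: float = 0.05,
    normalization: str = "median_iqr",
) -> pd.DataFrame:
    """Pairwise KS tests of distribution shape after location-scale removal.

    Each group is standardized (median/IQR by default, mean/SD with
    ``normalization="zscore"``) so the tests compare shapes only.  Returns a
    table with columns ``group_a, group_b, statistic, p_value, flagged``;
    ``flagged`` marks pairs whose shapes differ at level ``alpha``.  Groups
    with zero spread are skipped with a warning.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    standardized = {}
    for group in groups:
        if normalization == "median_iqr":
            z = _standardize(group.lifetimes_ns)
        elif normalization == "zscore":
            sd = np.std(group.lifetimes_ns, ddof=1)
            z = None if sd == 0 else (group.lifetimes_ns - np.mean(group.lifetimes_ns)) / sd
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        if z is None:
            warnings.warn(
                f"group {group.key} has zero spread; skipped in KS check",
                stacklevel=2,
            )
            continue
        standardized[group.key] = z
    keys = list(standardized)
    rows = []
    for i, key_a in enumerate(keys):
        for key_b in keys[i + 1 :]:
            stat, p = stats.ks_2samp(standardized[key_a], standardized[key_b])
            rows.append(
                {
                    "group_a": "/".join(key_a),
                    "group_b": "/".join(key_b),
                    "statistic": float(stat),
                    "p_value": float(p),
                    "flagged": bool(p < alpha),
                }
            )
    return pd.DataFrame(rows)


def significance_stars(p_value: float) -> str:
    """Asterisk convention: * < 0.05, ** < 0.01, *** < 0.005."""
    if p_value < STAR_THRESHOLDS[2]:
        return "***"
    if p_value < STAR_THRESHOLDS[1]:
        return "**"
    if p_value < STAR_THRESHOLDS[0]:
        return "*"
    return ""


def mwu_greater(group: GroupSample | np.ndarray, control: GroupSample | np.ndarray) -> TestResult:
    """One-sided Mann-Whitney U: group lifetimes greater than control.

    Uses the exact null distribution when both samples have at most 25
    observations and no ties across samples; otherwise the tie-corrected
    normal approximation.
    """
    x = group.lifetimes_ns if isinstance(group, GroupSample) else np.asarray(group, float)
    y = control.lifetimes_ns if isinstance(control, GroupSample) else np.asarray(control, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    small = x.size <= 25 and y.size <= 25
    method = "exact" if small and np.unique(np.concatenate([x, y])).size == x.size + y.size else "asymptotic"
    stat, p = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        alternative="greater",
        stars=significance_stars(float(p)),
    )


def cohort_results_table(
    groups: dict[tuple[str, str, str], GroupSample],
    control_key: tuple[str, str, str] | None = None,
) -> pd.DataFrame:
    """Summaries plus one-sided tests of every group against the control.

    ``control_key`` defaults to the first group with entity ``CTL``.  The
    control row carries no test statistics.
    """
    if control_key is None:
        ctl_keys = [k for k in groups if k[0] == "CTL"]
        if not ctl_keys:
            raise ValueError("no control (CTL) group present")
        control_key = ctl_keys[0]
    control = groups[control_key]
    rows = []
    for key, sample in groups.items():
        summary = summarize(sample)
        row = {
            "entity": key[0],
            "subgroup": key[1],
            "status": key[2],
            "n_specimens": summary.n_specimens,
            "median": summary.median,
            "q1": summary.q1,
            "q3": summary.q3,
            "mean": summary.mean,
            "sd": summary.sd,
        }
        if key == control_key:
            row.update({"U": np.nan, "p": np.nan, "stars": ""})
        else:
            result = mwu_greater(sample, control)
            row.update({"U": result.statistic, "p": result.p_value, "stars": result.stars})
        rows.append(row)
    return pd.DataFrame(rows)
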