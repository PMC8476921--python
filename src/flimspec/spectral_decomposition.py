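"""Emission-spectrum preprocessing and the relative PpIX signal contribution.

PpIX emission in 5-ALA-labelled tissue rides on a broad autofluorescence
background.  The background under the 635 nm PpIX peak is estimated by an
ordinary least-squares line fitted only to two PpIX-free anchor windows
(600-610 nm and 720-730 nm).  At the peak, counts above the line are
attributed to PpIX (S_PpIX) and the line itself to autofluorescence
(S_Autofl), giving the relative PpIX signal contribution

    RSC_PpIX = S_PpIX / (S_Autofl + S_PpIX)  in [0, 1].

No optical-property correction or spectral unmixing of photoproducts is
attempted: the metric deliberately operates on the raw signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "PEAK_NM",
    "ANCHOR_WINDOWS_NM",
    "EmissionSpectrum",
    "BaselineFit",
    "SpectralDecomposition",
    "preprocess_spectrum",
    "fit_baseline",
    "compute_rsc",
]

PEAK_NM = 635.0
ANCHOR_WINDOWS_NM = ((600.0, 610.0), (720.0, 730.0))


@dataclass(frozen=True)
class EmissionSpectrum:
    """Wavelength-resolved photon counts over the detection band."""

    wavelength: np.ndarray  # nm, strictly increasing
    counts: np.ndarray  # non-negative (raw spectra may carry dark offsets)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "counts", counts)
        if wl.ndim != 1 or wl.shape != counts.shape:
            raise ValueError("wavelength and counts must be matching 1-D arrays")
        if wl.size < 2 or (np.diff(wl) <= 0).any():
            raise ValueError("wavelength must be strictly increasing")

    @property
    def spacing_nm(self) -> float:
        return float(np.median(np.diff(self.wavelength)))

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavelength[0] <= lo and self.wavelength[-1] >= hi

    def to_csv(self, path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"wavelength_nm": self.wavelength, "counts": self.counts}
        ).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path) -> "EmissionSpectrum":
        table = pd.read_csv(path)
        return cls(
            wavelength=table["wavelength_nm"].to_numpy(),
            counts=table["counts"].to_numpy(),
        )


@dataclass(frozen=True)
class BaselineFit:
    """OLS line through the pooled anchor-window points."""

    intercept: float
    slope: float
    anchor_windows: tuple[tuple[float, float], ...] = ANCHOR_WINDOWS_NM

    def __call__(self, wavelength) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(wavelength, dtype=float)


@dataclass(frozen=True)
class SpectralDecomposition:
    """PpIX / autofluorescence partition of the signal at the 635 nm peak."""

    s_ppix: float
    s_autofl: float

    def __post_init__(self) -> None:
        if self.s_ppix < 0 or self.s_autofl < 0:
            raise ValueError("signal contributions must be non-negative")

    @property
    def rsc(self) -> float:
        total = self.s_ppix + self.s_autofl
        if total == 0:
            return 0.0
        return self.s_ppix / total


def preprocess_spectrum(
    raw: EmissionSpectrum,
    dark: EmissionSpectrum | float = 0.0,
    smoothing_sigma_nm: float = 2.0,
) -> EmissionSpectrum:
    """Background-correct and Gaussian-smooth a raw spectrum.

    ``dark`` is either a constant count offset or a dark spectrum on the same
    wavelength grid.  Counts are clipped at zero after subtraction, then
    smoothed along wavelength with a Gaussian of ``smoothing_sigma_nm``
    (0 disables smoothing; the filter preserves constants and, away from the
    edges, integrated counts).
    """
    if isinstance(dark, EmissionSpectrum):
        if not np.array_equal(dark.wavelength, raw.wavelength):
            raise ValueError("dark spectrum is on a different wavelength grid")
        dark_counts = dark.counts
    else:
        dark_counts = float(dark)
    counts = np.clip(raw.counts - dark_counts, 0.0, None)
    if smoothing_sigma_nm > 0:
        counts = gaussian_filter1d(
            counts, sigma=smoothing_sigma_nm / raw.spacing_nm, mode="nearest"
        )
    return EmissionSpectrum(wavelength=raw.wavelength, counts=counts)


def fit_baseline(
    spectrum: EmissionSpectrum,
    anchor_windows: tuple[tuple[float, float], ...] = ANCHOR_WINDOWS_NM,
) -> BaselineFit:
    """Fit the autofluorescence baseline line to the anchor-window points."""
    wl = spectrum.wavelength
    sel = np.zeros(wl.shape, dtype=bool)
    for lo, hi in anchor_windows:
        sel |= (wl >= lo) & (wl <= hi)
    if sel.sum() < 2:
        raise ValueError("need at least 2 points inside the anchor windows")
    x = wl[sel]
    if np.ptp(x) == 0:
        raise ValueError("anchor points share a single wavelength")
    slope, intercept = np.polyfit(x, spectrum.counts[sel], 1)
    return BaselineFit(
        intercept=float(intercept), slope=float(slope), anchor_windows=anchor_windows
    )


def _value_at(spectrum: EmissionSpectrum, wavelength_nm: float) -> float:
    wl = spectrum.wavelength
    if not (wl[0] <= wavelength_nm <= wl[-1]):
        raise ValueError(f"{wavelength_nm} nm outside the measured grid")
    return float(np.interp(wavelength_nm, wl, spectrum.counts))


def compute_rsc(
    spectrum: EmissionSpectrum,
    baseline: BaselineFit | None = None,
    band_halfwidth_nm: float | None = None,
) -> SpectralDecomposition:
    """Decompose the signal at the 635 nm PpIX peak against the baseline.

    Point evaluation at 635 nm (linear interpolation between grid points) is
    the default.  ``band_halfwidth_nm`` switches to integrating counts and
    baseline over 635 +/- the half-width instead -- a sensitivity-analysis
    variant, not the primary definition.

    S_Autofl is the baseline value clipped at zero; S_PpIX is counts minus
    baseline clipped at zero; RSC = S_PpIX / (S_Autofl + S_PpIX), defined as
    0 when both vanish.
    """
    if baseline is None:
        baseline = fit_baseline(spectrum)
    if band_halfwidth_nm is None:
        total = _value_at(spectrum, PEAK_NM)
        base = float(baseline(PEAK_NM))
    else:
        lo, hi = PEAK_NM - band_halfwidth_nm, PEAK_NM + band_halfwidth_nm
        if not spectrum.covers(lo, hi):
            raise ValueError("integration band outside the measured grid")
        wl = spectrum.wavelength
        sel = (wl >= lo) & (wl <= hi)
        total = float(np.trapezoid(spectrum.counts[sel], wl[sel]))
        base = float(np.trapezoid(baseline(wl[sel]), wl[sel]))
    s_autofl = max(base, 0.0)
    s_ppix = max(total - base, 0.0)
    return SpectralDecomposition(s_ppix=s_ppix, s_autofl=s_autofl)
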