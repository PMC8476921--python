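"""Lifetime colorization, grayscale intensity rendering, and color blending.

Lifetime maps are color-coded with a jet-style map scaled by the binary
logarithm between fixed limits (1 to 16 ns), so the full dynamic range from
tissue autofluorescence to strong PpIX fluorescence is contrasted
consistently across specimens: parenchyma renders blue, strong PpIX red.

To show tissue structure and lifetime contrast in one image, the color-coded
lifetime is blended onto a high-resolution structural image (fluorescence
intensity or white light):

1. convert both RGB images to HSL;
2. replace hue and saturation of the structure image with those of the
   lifetime image;
3. convert back to RGB, then to YPbPr (BT.601);
4. keep the chrominances Pb/Pr and replace the luminance Y with the Y of the
   original structure image;
5. convert back to RGB and clip to gamut.

The perceived resolution of the blend is dominated by the structural
luminance, quantified with the structural similarity index measure (SSIM).

``ColorImage`` is a plain ``(H, W, 3)`` float array with channels in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.metrics import structural_similarity
from skimage.transform import resize

from .flim_reconstruction import IntensityMap, LifetimeMap

__all__ = [
    "BlendConfig",
    "colorize_lifetime",
    "intensity_grayscale",
    "blend_lifetime_on_intensity",
    "compute_ssim",
    "rgb_to_hsl",
    "hsl_to_rgb",
    "rgb_to_ypbpr",
    "ypbpr_to_rgb",
    "luminance",
]

# BT.601 luma coefficients (standard-definition television primaries).
_KR, _KG, _KB = 0.299, 0.587, 0.114


@dataclass(frozen=True)
class BlendConfig:
    """Colormap limits and rendering options for lifetime visualization."""

    lo_ns: float = 1.0
    hi_ns: float = 16.0
    colormap: str = "jet"
    nan_color: tuple[float, float, float] = (0.0, 0.0, 0.0)
    upsample: str = "nearest"  # or "bilinear"

    def __post_init__(self) -> None:
        if not 0 < self.lo_ns < self.hi_ns:
            raise ValueError("need 0 < lo_ns < hi_ns")
        if self.upsample not in ("nearest", "bilinear"):
            raise ValueError("upsample must be 'nearest' or 'bilinear'")


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if not np.isfinite(image).all():
        raise ValueError("RGB image must be finite")
    return image


def colorize_lifetime(
    lifetime_map: LifetimeMap, cfg: BlendConfig | None = None
) -> np.ndarray:
    """Render a lifetime map through the log2-scaled jet colormap.

    u = clip((log2 tau - log2 lo) / (log2 hi - log2 lo), 0, 1); invalid
    (NaN) pixels take ``cfg.nan_color``.
    """
    cfg = cfg or BlendConfig()
    tau = lifetime_map.tau
    with np.errstate(invalid="ignore", divide="ignore"):
        u = (np.log2(tau) - np.log2(cfg.lo_ns)) / (
            np.log2(cfg.hi_ns) - np.log2(cfg.lo_ns)
        )
    u = np.clip(u, 0.0, 1.0)
    cmap = colormaps[cfg.colormap]
    rgb = cmap(np.nan_to_num(u, nan=0.0))[..., :3]
    rgb[~lifetime_map.mask] = cfg.nan_color
    return rgb


def intensity_grayscale(intensity_map: IntensityMap) -> np.ndarray:
    """Render intensity as grayscale scaled from 0 to the image maximum."""
    values = intensity_map.intensity
    peak = np.nanmax(values)
    gray = np.zeros_like(values, dtype=float) if peak == 0 else values / peak
    gray = np.nan_to_num(np.clip(gray, 0.0, 1.0))
    return np.repeat(gray[..., None], 3, axis=-1)


# --- color-space conversions --------------------------------------------------


def rgb_to_hsl(rgb: np.ndarray) -> np.ndarray:
    """Vectorized RGB -> HSL (hexagonal model); H in [0, 1)."""
    rgb = _check_rgb(rgb)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    c_max = rgb.max(axis=-1)
    c_min = rgb.min(axis=-1)
    chroma = c_max - c_min
    lightness = (c_max + c_min) / 2.0

    hue = np.zeros_like(lightness)
    nz = chroma > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r_max = nz & (c_max == r)
        g_max = nz & ~r_max & (c_max == g)
        b_max = nz & ~r_max & ~g_max
        hue[r_max] = np.mod((g - b)[r_max] / chroma[r_max], 6.0)
        hue[g_max] = (b - r)[g_max] / chroma[g_max] + 2.0
        hue[b_max] = (r - g)[b_max] / chroma[b_max] + 4.0
    hue /= 6.0

    sat = np.zeros_like(lightness)
    denom = 1.0 - np.abs(2.0 * lightness - 1.0)
    ok = nz & (denom > 0)
    sat[ok] = chroma[ok] / denom[ok]
    return np.stack([hue, sat, lightness], axis=-1)


def hsl_to_rgb(hsl: np.ndarray) -> np.ndarray:
    """Vectorized HSL -> RGB inverse of :func:`rgb_to_hsl`."""
    hsl = np.asarray(hsl, dtype=float)
    hue, sat, lightness = hsl[..., 0], hsl[..., 1], hsl[..., 2]
    chroma = (1.0 - np.abs(2.0 * lightness - 1.0)) * sat
    h6 = np.mod(hue, 1.0) * 6.0
    x = chroma * (1.0 - np.abs(np.mod(h6, 2.0) - 1.0))
    zeros = np.zeros_like(chroma)
    sector = np.floor(h6).astype(int) % 6
    r1 = np.choose(sector, [chroma, x, zeros, zeros, x, chroma])
    g1 = np.choose(sector, [x, chroma, chroma, x, zeros, zeros])
    b1 = np.choose(sector, [zeros, zeros, x, chroma, chroma, x])
    m = lightness - chroma / 2.0
    return np.stack([r1 + m, g1 + m, b1 + m], axis=-1)


def luminance(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luma Y of an RGB image."""
    rgb = _check_rgb(rgb)
    return _KR * rgb[..., 0] + _KG * rgb[..., 1] + _KB * rgb[..., 2]


def rgb_to_ypbpr(rgb: np.ndarray) -> np.ndarray:
    rgb = _check_rgb(rgb)
    y = luminance(rgb)
    pb = (rgb[..., 2] - y) / (2.0 * (1.0 - _KB))
    pr = (rgb[..., 0] - y) / (2.0 * (1.0 - _KR))
    return np.stack([y, pb, pr], axis=-1)


def ypbpr_to_rgb(ypbpr: np.ndarray) -> np.ndarray:
    ypbpr = np.asarray(ypbpr, dtype=float)
    y, pb, pr = ypbpr[..., 0], ypbpr[..., 1], ypbpr[..., 2]
    r = y + 2.0 * (1.0 - _KR) * pr
    b = y + 2.0 * (1.0 - _KB) * pb
    g = (y - _KR * r - _KB * b) / _KG
    return np.stack([r, g, b], axis=-1)


# --- blending and similarity --------------------------------------------------


def _upsample_to(image: np.ndarray, shape: tuple[int, int], mode: str) -> np.ndarray:
    if image.shape[:2] == shape:
        return image
    order = 0 if mode == "nearest" else 1
    return resize(
        image,
        (*shape, 3),
        order=order,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )


def blend_lifetime_on_intensity(
    lifetime_rgb: np.ndarray,
    structure_rgb: np.ndarray,
    cfg: BlendConfig | None = None,
    return_gamut_mask: bool = False,
):
    """Blend lifetime color onto structural luminance.

    The lifetime image is upsampled to the structure resolution first
    (nearest-neighbor by default, so no interpolated pseudo-lifetimes are
    introduced).  Hue/saturation come from the lifetime image, luminance from
    the structure image; out-of-gamut values after the final conversion are
    clipped, which can shift the luminance of the affected pixels (a fully
    saturated hue cannot carry an arbitrary luminance).  With
    ``return_gamut_mask=True`` the in-gamut pixel mask -- where luminance is
    preserved exactly -- is returned alongside the image.
    """
    cfg = cfg or BlendConfig()
    structure_rgb = _check_rgb(structure_rgb)
    lifetime_rgb = _check_rgb(lifetime_rgb)
    lifetime_rgb = _upsample_to(lifetime_rgb, structure_rgb.shape[:2], cfg.upsample)
    if lifetime_rgb.shape != structure_rgb.shape:
        raise ValueError("image dimensions do not match after upsampling")

    lifetime_hsl = rgb_to_hsl(lifetime_rgb)
    structure_hsl = rgb_to_hsl(structure_rgb)
    merged_hsl = np.stack(
        [lifetime_hsl[..., 0], lifetime_hsl[..., 1], structure_hsl[..., 2]], axis=-1
    )
    merged_ypbpr = rgb_to_ypbpr(hsl_to_rgb(merged_hsl))
    structure_y = rgb_to_ypbpr(structure_rgb)[..., 0]
    merged_ypbpr[..., 0] = structure_y
    raw = ypbpr_to_rgb(merged_ypbpr)
    blended = np.clip(raw, 0.0, 1.0)
    if return_gamut_mask:
        eps = 1e-9
        in_gamut = ((raw >= -eps) & (raw <= 1.0 + eps)).all(axis=-1)
        return blended, in_gamut
    return blended


def compute_ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean SSIM between two images (11x11 Gaussian window, sigma 1.5).

    RGB inputs are reduced to BT.601 luminance first; grayscale arrays are
    compared directly.  Constants K1=0.01, K2=0.03 on a dynamic range of 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share dimensions")
    if a.ndim == 3:
        a, b = luminance(a), luminance(b)
    return float(
        structural_similarity(
            a,
            b,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
            data_range=1.0,
        )
    )
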