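"""Frequency-domain FLIM reconstruction.

A lock-in amplifier demodulates the fluorescence emitted under sinusoidally
modulated excitation into a per-pixel phase ``theta`` (rad) and amplitude
``R`` (mV_RMS).  After subtracting the instrument phase offset (time of
flight plus electronic delays), the phase lifetime follows from

    tau = tan(phi) / (2 * pi * f_mod)

where ``phi`` is the corrected phase and ``f_mod`` the modulation frequency.
This module converts calibrated demodulated frames into lifetime and
intensity maps, propagating a validity mask for pixels whose corrected phase
falls outside the physical domain [0, pi/2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "DemodFrame",
    "CalibrationModel",
    "LifetimeMap",
    "IntensityMap",
    "calibrate_phase",
    "phase_to_lifetime",
    "lifetime_to_phase",
    "reconstruct",
    "read_frame",
    "write_frame",
    "write_map",
]

NS_PER_S = 1e9


@dataclass(frozen=True)
class DemodFrame:
    """Raw FD-FLIM measurement: demodulated phase and amplitude at ``f_mod``.

    Attributes
    ----------
    phase : ndarray
        Per-pixel demodulated phase theta, rad.
    amplitude : ndarray
        Per-pixel demodulated amplitude R, mV_RMS (non-negative).
    f_mod_hz : float
        Modulation frequency, Hz.
    pixel_pitch_um : float
        Lateral pixel spacing, micrometres.
    """

    phase: np.ndarray
    amplitude: np.ndarray
    f_mod_hz: float
    pixel_pitch_um: float = 25.0

    def __post_init__(self) -> None:
        phase = np.asarray(self.phase, dtype=float)
        amplitude = np.asarray(self.amplitude, dtype=float)
        object.__setattr__(self, "phase", phase)
        object.__setattr__(self, "amplitude", amplitude)
        if phase.shape != amplitude.shape:
            raise ValueError(
                f"phase shape {phase.shape} != amplitude shape {amplitude.shape}"
            )
        if phase.size == 0:
            raise ValueError("empty frame")
        if not self.f_mod_hz > 0:
            raise ValueError("f_mod_hz must be positive")
        if np.nanmin(amplitude) < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.phase.shape


@dataclass(frozen=True)
class CalibrationModel:
    """System phase offset (time-of-flight + electronic delay) at ``f_mod``."""

    phase_offset: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.phase_offset):
            raise ValueError("phase_offset must be finite")


@dataclass(frozen=True)
class LifetimeMap:
    """Per-pixel phase lifetime in ns; NaN marks invalid pixels.

    ``mask`` is True exactly where ``tau`` is valid (finite).
    """

    tau: np.ndarray
    pixel_pitch_um: float = 25.0
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        object.__setattr__(self, "tau", tau)
        mask = self.mask
        if mask is None:
            mask = np.isfinite(tau)
        mask = np.asarray(mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.shape != tau.shape:
            raise ValueError("mask shape mismatch")
        if not np.array_equal(mask, np.isfinite(tau)):
            raise ValueError("mask must be True exactly where tau is finite")
        if tau[mask].size and np.min(tau[mask]) < 0:
            raise ValueError("finite lifetimes must be non-negative")

    @property
    def valid_values(self) -> np.ndarray:
        return self.tau[self.mask]


@dataclass(frozen=True)
class IntensityMap:
    """Per-pixel demodulated fluorescence intensity, mV_RMS."""

    intensity: np.ndarray
    pixel_pitch_um: float = 25.0

    def __post_init__(self) -> None:
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "intensity", intensity)
        if np.nanmin(intensity) < 0:
            raise ValueError("intensity must be non-negative")


def phase_to_lifetime(phase, f_mod_hz: float):
    """Convert corrected phase (rad) to phase lifetime (ns).

    tau = tan(phase) / (2 pi f_mod).  Phases outside [0, pi/2) have no
    mono-exponential interpretation and map to NaN rather than being clamped.
    Accepts scalars or arrays.
    """
    if not f_mod_hz > 0:
        raise ValueError("f_mod_hz must be positive")
    phase = np.asarray(phase, dtype=float)
    valid = (phase >= 0) & (phase < np.pi / 2)
    tau_s = np.where(valid, np.tan(np.where(valid, phase, 0.0)), np.nan)
    tau_ns = tau_s / (2.0 * np.pi * f_mod_hz) * NS_PER_S
    return tau_ns if tau_ns.ndim else float(tau_ns)


def lifetime_to_phase(tau_ns, f_mod_hz: float):
    """Inverse of :func:`phase_to_lifetime`: phase = atan(2 pi f tau)."""
    if not f_mod_hz > 0:
        raise ValueError("f_mod_hz must be positive")
    tau_ns = np.asarray(tau_ns, dtype=float)
    phase = np.arctan(2.0 * np.pi * f_mod_hz * tau_ns / NS_PER_S)
    return phase if phase.ndim else float(phase)


def calibrate_phase(
    reference_frame: DemodFrame, reference_lifetime_ns: float
) -> CalibrationModel:
    """Estimate the system phase offset from a mono-exponential reference.

    The reference sample has a known lifetime (0 ns for a purely scattering
    reference).  The offset is the robust central value (median over pixels)
    of the measured phase minus the phase the reference lifetime implies.
    """
    if reference_lifetime_ns < 0:
        raise ValueError("reference lifetime must be >= 0")
    phase = reference_frame.phase
    if not np.isfinite(phase).any():
        raise ValueError("reference frame has no finite phase values")
    expected = lifetime_to_phase(reference_lifetime_ns, reference_frame.f_mod_hz)
    offset = float(np.nanmedian(phase) - expected)
    return CalibrationModel(phase_offset=offset)


def reconstruct(
    frame: DemodFrame, cal: CalibrationModel
) -> tuple[LifetimeMap, IntensityMap]:
    """Reconstruct lifetime and intensity maps from a demodulated frame.

    Lifetime comes from the offset-corrected phase; intensity is the
    demodulated amplitude unchanged.  No intensity threshold is applied here;
    low-signal masking is a downstream, configurable concern.
    """
    corrected = frame.phase - cal.phase_offset
    tau = phase_to_lifetime(corrected, frame.f_mod_hz)
    tau = np.asarray(tau, dtype=float)
    return (
        LifetimeMap(tau=tau, pixel_pitch_um=frame.pixel_pitch_um),
        IntensityMap(intensity=frame.amplitude, pixel_pitch_um=frame.pixel_pitch_um),
    )


# --- TIFF + JSON sidecar I/O -------------------------------------------------
# Frames are stored as 2-page 32-bit float TIFFs (page 1 phase rad, page 2
# amplitude mV_RMS) with a .json sidecar holding acquisition metadata.


def write_frame(frame: DemodFrame, path, seed: int | None = None) -> Path:
    path = Path(path)
    tifffile.imwrite(
        path,
        np.stack([frame.phase, frame.amplitude]).astype(np.float32),
    )
    meta = {
        "f_mod_hz": frame.f_mod_hz,
        "pixel_pitch_um": frame.pixel_pitch_um,
    }
    if seed is not None:
        meta["seed"] = int(seed)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_frame(path) -> DemodFrame:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] != 2:
        raise ValueError(f"{path}: expected a 2-page (phase, amplitude) TIFF")
    meta = json.loads(path.with_suffix(".json").read_text())
    return DemodFrame(
        phase=pages[0].astype(float),
        amplitude=pages[1].astype(float),
        f_mod_hz=float(meta["f_mod_hz"]),
        pixel_pitch_um=float(meta.get("pixel_pitch_um", 25.0)),
    )


def write_map(array: np.ndarray, path, **metadata) -> Path:
    """Write a lifetime or intensity map as 32-bit float TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    path.with_suffix(".json").write_text(json.dumps(metadata, indent=1))
    return path
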