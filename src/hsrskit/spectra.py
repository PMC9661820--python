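"""Raman/SRS spectra: wavenumber axes, normalization, synthetic references, windows.

An SRS spectrum is a vector of intensities sampled on a strictly increasing
wavenumber axis (cm^-1).  Axes need not be uniformly spaced; every operation
that integrates or selects uses the axis explicitly.  The fingerprint window
(670-900 cm^-1 here) carries the chemically specific bands -- limonene's
signature is the 760 cm^-1 ring/CH2 band -- while the C-H stretching window
(2800-3100 cm^-1) is strong but unspecific.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "SpectralWindow",
    "DEFAULT_WINDOWS",
    "normalize_spectrum",
    "make_synthetic_reference",
    "window_sum",
    "peak_intensity",
    "lorentzian",
    "gaussian",
]


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing, finite wavenumber grid in cm^-1 (length >= 2)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("wavenumber axis must be 1-D with at least 2 points")
        if not np.all(np.isfinite(vals)):
            raise ValueError("wavenumber axis contains non-finite values")
        if not np.all(np.diff(vals) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))

    def nearest_index(self, center: float) -> int:
        """Index of the axis point nearest ``center``; ties go to the lower wavenumber."""
        vals = self.values
        if center < vals[0] or center > vals[-1]:
            raise ValueError(
                f"wavenumber {center} outside axis range [{vals[0]}, {vals[-1]}]"
            )
        dist = np.abs(vals - center)
        # argmin returns the first (lower-wavenumber) index on exact ties
        return int(np.argmin(dist))


@dataclass(frozen=True)
class Spectrum:
    """Intensity samples (arbitrary SRS units) on a :class:`WavenumberAxis`."""

    axis: WavenumberAxis
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity, dtype=float)
        if inten.shape != (len(self.axis),):
            raise ValueError(
                f"intensity length {inten.shape} does not match axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(inten)):
            raise ValueError("spectrum intensity contains non-finite values")
        object.__setattr__(self, "intensity", inten)


@dataclass(frozen=True)
class SpectralWindow:
    """Inclusive wavenumber interval [lo, hi] with a display name."""

    lo: float
    hi: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"window requires lo < hi, got [{self.lo}, {self.hi}]")


#: Default analysis windows: chemically specific fingerprint region and the
#: strong-but-unspecific C-H stretching region.
DEFAULT_WINDOWS: dict[str, SpectralWindow] = {
    "fingerprint": SpectralWindow(670.0, 900.0, "fingerprint"),
    "ch": SpectralWindow(2800.0, 3100.0, "ch"),
}


def normalize_spectrum(s: Spectrum, mode: str = "max") -> Spectrum:
    """Return ``s`` rescaled so its peak (``max``) or trapezoidal area (``area``) is 1.

    ``mode='none'`` returns the spectrum unchanged.  Normalizing an all-zero
    spectrum is degenerate and raises ``ValueError``.
    """
    if mode == "none":
        return s
    if mode == "max":
        scale = float(np.max(np.abs(s.intensity)))
        if scale == 0.0:
            raise ValueError("cannot max-normalize an all-zero spectrum")
    elif mode == "area":
        scale = float(np.trapezoid(s.intensity, s.axis.values))
        if scale == 0.0:
            raise ValueError("cannot area-normalize a spectrum with zero integral")
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return replace(s, intensity=s.intensity / scale)


def lorentzian(x: np.ndarray, center: float, fwhm: float, amplitude: float) -> np.ndarray:
    """Lorentzian profile with unit value ``amplitude`` at its center."""
    hwhm = fwhm / 2.0
    return amplitude * hwhm**2 / ((np.asarray(x, float) - center) ** 2 + hwhm**2)


def gaussian(x: np.ndarray, center: float, fwhm: float, amplitude: float) -> np.ndarray:
    """Gaussian profile parameterized by FWHM, peak value ``amplitude``."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return amplitude * np.exp(-0.5 * ((np.asarray(x, float) - center) / sigma) ** 2)


def make_synthetic_reference(
    peaks: list[tuple[float, float, float]],
    axis: WavenumberAxis,
    baseline: float = 0.0,
    label: str = "",
    shape: str = "lorentzian",
) -> Spectrum:
    """Build a reference spectrum as a sum of line profiles plus a flat baseline.

    Each peak is ``(center_cm1, fwhm_cm1, amplitude)``.  Lorentzian line shapes
    are the default (typical for Raman bands); ``shape='gaussian'`` is available.
    An empty peak list with zero baseline yields an all-zero blank.
    """
    profile = {"lorentzian": lorentzian, "gaussian": gaussian}.get(shape)
    if profile is None:
        raise ValueError(f"unknown line shape {shape!r}")
    y = np.full(len(axis), float(baseline))
    for center, fwhm, amplitude in peaks:
        if fwhm <= 0:
            raise ValueError(f"peak at {center} cm^-1 has non-positive FWHM {fwhm}")
        if amplitude < 0:
            raise ValueError(f"peak at {center} cm^-1 has negative amplitude {amplitude}")
        y = y + profile(axis.values, center, fwhm, amplitude)
    return Spectrum(axis=axis, intensity=y, label=label)


def window_sum(stack, w: SpectralWindow) -> np.ndarray:
    """Per-pixel sum of stack frames whose wavenumber lies in [w.lo, w.hi].

    This is the "spectrally summed" image used for display and as the
    segmentation input.  Bounds are inclusive.
    """
    axis = stack.axis.values
    sel = (axis >= w.lo) & (axis <= w.hi)
    if not np.any(sel):
        raise ValueError(
            f"window [{w.lo}, {w.hi}] contains no frames of axis "
            f"[{axis[0]}, {axis[-1]}]"
        )
    return np.asarray(stack.data[sel].sum(axis=0))


def peak_intensity(stack_or_spectrum, center: float):
    """Intensity at the axis point nearest ``center`` (nearest-neighbor lookup).

    For a :class:`Spectrum` returns a scalar; for a hyperspectral stack returns
    the selected 2-D frame.
    """
    if isinstance(stack_or_spectrum, Spectrum):
        idx = stack_or_spectrum.axis.nearest_index(center)
        return float(stack_or_spectrum.intensity[idx])
    idx = stack_or_spectrum.axis.nearest_index(center)
    return np.asarray(stack_or_spectrum.data[idx])
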