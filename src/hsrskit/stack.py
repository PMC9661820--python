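"""The hyperspectral stack container: a lambda-x-y cube with a wavenumber axis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum, WavenumberAxis

__all__ = ["HyperspectralStack"]


@dataclass(frozen=True)
class HyperspectralStack:
    """SRS intensities indexed (wavenumber, row, column).

    ``data[i]`` is the image acquired at Raman shift ``axis.values[i]``; the
    spectrum of a single pixel is ``data[:, r, c]``.  Pixel size is in um/px
    when known, else ``None``.
    """

    axis: WavenumberAxis
    data: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"stack data must be 3-D (lambda, y, x), got shape {arr.shape}")
        if arr.shape[0] != len(self.axis):
            raise ValueError(
                f"stack has {arr.shape[0]} frames but axis has {len(self.axis)} points"
            )
        object.__setattr__(self, "data", arr)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def pixel_spectrum(self, row: int, col: int, label: str = "") -> Spectrum:
        return Spectrum(axis=self.axis, intensity=self.data[:, row, col], label=label)

    def crop(self, rows: slice, cols: slice) -> "HyperspectralStack":
        """Spatial crop; the spectral axis is untouched."""
        return HyperspectralStack(
            axis=self.axis, data=self.data[:, rows, cols].copy(), pixel_size=self.pixel_size
        )

    def mean_spectrum(self, mask: np.ndarray | None = None, label: str = "") -> Spectrum:
        """Mean spectrum over all pixels, or over ``mask`` (2-D boolean) if given."""
        if mask is None:
            inten = self.data.reshape(self.n_frames, -1).mean(axis=1)
        else:
            mask = np.asarray(mask, bool)
            if mask.shape != self.spatial_shape:
                raise ValueError("mask shape does not match stack spatial shape")
            if not mask.any():
                raise ValueError("mask selects no pixels")
            inten = self.data[:, mask].mean(axis=1)
        return Spectrum(axis=self.axis, intensity=inten, label=label)
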