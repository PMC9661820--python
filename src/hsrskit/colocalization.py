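"""Mander's colocalization of the limonene map with an enzyme-fluorescence channel.

MCC = sum_i Lim_i * [LimSyn_i >= threshold] / sum_i Lim_i over the evaluated
region: the fraction of total limonene intensity that falls on pixels where
the enzyme channel exceeds a threshold.  The comparison is inclusive (>=).
Evaluation defaults to cells-only when a restriction mask is supplied, since
the biological question is intracellular co-occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

__all__ = ["ColocalizationResult", "mcc", "auto_threshold"]


@dataclass(frozen=True)
class ColocalizationResult:
    mcc: float
    threshold_used: float
    n_colocal_pixels: int
    restricted_to: str  # 'whole-image' or 'cells-only'

    def __post_init__(self) -> None:
        if not 0.0 <= self.mcc <= 1.0:
            raise ValueError(f"MCC {self.mcc} outside [0, 1]")


def mcc(
    lim_map: np.ndarray,
    limsyn_map: np.ndarray,
    threshold: float,
    restrict_mask: np.ndarray | None = None,
) -> ColocalizationResult:
    """Mander's coefficient of ``lim_map`` against thresholded ``limsyn_map``.

    ``restrict_mask`` (e.g. the cell footprint) limits the evaluated pixels;
    an all-zero limonene map over the region makes the coefficient undefined
    and raises rather than returning NaN.
    """
    lim = np.asarray(lim_map, float)
    syn = np.asarray(limsyn_map, float)
    if lim.shape != syn.shape:
        raise ValueError("maps are not aligned")
    if restrict_mask is not None:
        region = np.asarray(restrict_mask) > 0
        if region.shape != lim.shape:
            raise ValueError("restriction mask is not aligned with the maps")
        restricted_to = "cells-only"
    else:
        region = np.ones_like(lim, bool)
        restricted_to = "whole-image"
    total = float(lim[region].sum())
    if total == 0.0:
        raise ZeroDivisionError("MCC undefined: limonene map sums to zero over the region")
    colocal = region & (syn >= threshold)
    return ColocalizationResult(
        mcc=float(lim[colocal].sum()) / total,
        threshold_used=float(threshold),
        n_colocal_pixels=int(colocal.sum()),
        restricted_to=restricted_to,
    )


def auto_threshold(
    limsyn_map: np.ndarray,
    method: str = "otsu",
    restrict_mask: np.ndarray | None = None,
) -> float:
    """Scalar threshold for the fluorescence channel.

    ``otsu`` (default) or ``quantile:q`` with q in [0, 1] (linear-interpolation
    quantile of the evaluated values).
    """
    syn = np.asarray(limsyn_map, float)
    values = syn[np.asarray(restrict_mask) > 0] if restrict_mask is not None else syn.ravel()
    if values.size == 0:
        raise ValueError("restriction mask selects no pixels")
    if method == "otsu":
        if np.ptp(values) == 0:
            raise ValueError("constant fluorescence map: Otsu threshold is degenerate")
        return float(threshold_otsu(values))
    if method.startswith("quantile:"):
        q = float(method.split(":", 1)[1])
        if not 0.0 <= q <= 1.0:
            raise ValueError("quantile must be in [0, 1]")
        return float(np.quantile(values, q))
    raise ValueError(f"unknown threshold method {method!r}")
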