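"""Cell and aggregate label masks from images, plus an importer for external masks.

The classical pipeline here (smooth, threshold, fill, optional watershed split,
size filter) is a deterministic stand-in for interactive pixel/object
classification; externally curated masks can be imported and validated so a
hand-corrected segmentation slots into the same downstream quantification.

Conventions: row-major, 0-based pixel indices, pixel centers at integer
coordinates, 8-connectivity for components, label 0 = background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation as skseg
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "CellLabelMask",
    "AggregateLabelMask",
    "segment_cells",
    "segment_aggregates",
    "import_labels",
    "compact_labels",
    "parent_aggregates",
]


@dataclass(frozen=True)
class CellLabelMask:
    """Integer-labeled cells: 0 = background, 1..n consecutive labels."""

    labels: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2 or not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("cell labels must be a 2-D integer image")
        if labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        object.__setattr__(self, "labels", labels)

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class AggregateLabelMask:
    """Integer-labeled aggregates with an aggregate -> parent-cell mapping."""

    labels: np.ndarray
    parent: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2 or not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("aggregate labels must be a 2-D integer image")
        present = set(np.unique(labels)) - {0}
        missing = present - set(self.parent)
        if missing:
            raise ValueError(f"aggregate labels without a parent cell: {sorted(missing)}")
        object.__setattr__(self, "labels", labels)

    @property
    def n_aggregates(self) -> int:
        return int(self.labels.max())


def compact_labels(labels: np.ndarray) -> tuple[np.ndarray, dict[int, int]]:
    """Relabel to consecutive 1..n preserving original label order; returns the
    compacted image and the old -> new mapping."""
    labels = np.asarray(labels)
    old = np.unique(labels)
    old = old[old > 0]
    mapping = {int(o): i + 1 for i, o in enumerate(old)}
    lut = np.zeros(int(labels.max()) + 1, labels.dtype)
    for o, n in mapping.items():
        lut[o] = n
    return lut[labels], mapping



def _drop_small(labels: np.ndarray, min_area_px: int) -> np.ndarray:
    """Zero out labels with fewer than ``min_area_px`` pixels."""
    sizes = np.bincount(labels.ravel())
    small = sizes < min_area_px
    small[0] = False
    out = labels.copy()
    out[small[labels]] = 0
    return out

def segment_cells(
    image: np.ndarray,
    smooth_sigma: float = 1.0,
    threshold_method: str | float = "otsu",
    min_area_px: int = 50,
    split: bool = True,
    split_erosion_px: int = 3,
) -> CellLabelMask:
    """Segment cells from a spectrally summed image.

    Gaussian smooth -> global threshold (Otsu by default, or a numeric value)
    -> hole filling -> optional watershed split of touching cells (markers from
    an eroded foreground, so each rod keeps a single marker) -> size filter ->
    consecutive relabel.  Fully deterministic.
    """
    image = np.asarray(image, float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    smoothed = ndimage.gaussian_filter(image, smooth_sigma) if smooth_sigma > 0 else image
    if threshold_method == "otsu":
        if np.ptp(smoothed) == 0:
            raise ValueError("constant image: Otsu threshold is degenerate")
        thr = threshold_otsu(smoothed)
    else:
        thr = float(threshold_method)
    binary = smoothed > thr
    binary = ndimage.binary_fill_holes(binary)
    if split:
        markers_bin = morphology.erosion(binary, morphology.disk(split_erosion_px))
        markers, _ = ndimage.label(markers_bin, structure=np.ones((3, 3)))
        if markers.max() > 0:
            distance = ndimage.distance_transform_edt(binary)
            labels = skseg.watershed(-distance, markers=markers, mask=binary)
        else:
            labels, _ = ndimage.label(binary, structure=np.ones((3, 3)))
    else:
        labels, _ = ndimage.label(binary, structure=np.ones((3, 3)))
    labels = _drop_small(labels, min_area_px)
    labels, _ = compact_labels(labels)
    return CellLabelMask(labels=labels.astype(np.int32))


def parent_aggregates(
    agg_labels: np.ndarray,
    cells: CellLabelMask,
    on_background: str = "drop",
) -> tuple[np.ndarray, dict[int, int]]:
    """Assign each aggregate to the cell under its centroid (rounded to the
    nearest pixel).  Aggregates whose centroid falls on background are dropped
    with a warning (``on_background='drop'``) or raise (``'error'``)."""
    agg_labels = np.asarray(agg_labels)
    out = agg_labels.copy()
    parent: dict[int, int] = {}
    offenders: list[int] = []
    for region in measure.regionprops(agg_labels):
        r, c = (int(round(x)) for x in region.centroid)
        r = min(max(r, 0), cells.labels.shape[0] - 1)
        c = min(max(c, 0), cells.labels.shape[1] - 1)
        cell = int(cells.labels[r, c])
        if cell == 0:
            offenders.append(region.label)
            out[agg_labels == region.label] = 0
            continue
        parent[region.label] = cell
    if offenders:
        if on_background == "error":
            raise ValueError(f"aggregates with centroid on background: {offenders}")
        logger.warning("dropped %d aggregates with centroid on background: %s",
                       len(offenders), offenders)
    out, mapping = compact_labels(out)
    parent = {mapping[old]: cell for old, cell in parent.items()}
    return out, parent


def segment_aggregates(
    image: np.ndarray,
    cells: CellLabelMask,
    tophat_radius_px: int = 4,
    agg_threshold: float | None = None,
    min_area_px: int = 4,
) -> AggregateLabelMask:
    """Detect bright intracellular spots in a limonene map or summed image.

    White top-hat (disk of ``tophat_radius_px``) isolates compact bright
    features; the threshold defaults to Otsu over in-cell top-hat values.
    Components are restricted to cell pixels, size-filtered, and parented to
    the cell under their centroid.
    """
    image = np.asarray(image, float)
    if image.shape != cells.labels.shape:
        raise ValueError("image and cell mask shapes differ")
    tophat = morphology.white_tophat(image, morphology.disk(tophat_radius_px))
    in_cell = cells.labels > 0
    if agg_threshold is None:
        vals = tophat[in_cell]
        if vals.size == 0 or np.ptp(vals) == 0:
            return AggregateLabelMask(labels=np.zeros_like(cells.labels), parent={})
        agg_threshold = threshold_otsu(vals)
    binary = (tophat > agg_threshold) & in_cell
    labels, _ = ndimage.label(binary, structure=np.ones((3, 3)))
    labels = _drop_small(labels, min_area_px)
    labels, _ = compact_labels(labels)
    labels, parent = parent_aggregates(labels, cells, on_background="drop")
    return AggregateLabelMask(labels=labels.astype(np.int32), parent=parent)


def import_labels(
    path,
    kind: str = "cell",
    cells_for_parenting: CellLabelMask | None = None,
    pixel_size: float | None = None,
):
    """Load an externally produced label mask (e.g. a hand-corrected
    segmentation) from an integer TIFF and validate it.

    Labels are compacted to 1..n preserving order.  For ``kind='aggregate'`` a
    cell mask must be supplied; each aggregate is re-parented to the cell under
    its centroid and an aggregate lying wholly on background is a validation
    error.
    """
    import tifffile

    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D mask, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("mask contains non-integer pixel values")
        arr = np.round(arr).astype(np.int32)
    arr = arr.astype(np.int32)
    if kind == "cell":
        labels, _ = compact_labels(arr)
        return CellLabelMask(labels=labels, pixel_size=pixel_size)
    if kind == "aggregate":
        if cells_for_parenting is None:
            raise ValueError("aggregate import requires a cell mask for parenting")
        wholly_bg = [
            int(region.label)
            for region in measure.regionprops(arr)
            if not (cells_for_parenting.labels[tuple(region.coords.T)] > 0).any()
        ]
        if wholly_bg:
            raise ValueError(f"aggregates lying wholly on background: {wholly_bg}")
        labels, parent = parent_aggregates(arr, cells_for_parenting, on_background="error")
        return AggregateLabelMask(labels=labels, parent=parent)
    raise ValueError(f"unknown mask kind {kind!r}")
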