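"""Single-cell and single-aggregate feature quantification.

Five feature categories per segmented object: cell geometry (area, length),
aggregate geometry, intracellular aggregate location (the d/L polar metric),
raw SRS image features (760 cm^-1 peak, spectrally summed windows), and the
unmixed chemical profile (limonene and cell-body channels).  On top of the
tables: threshold-sweep classification of limonene-rich aggregates against
control populations, population summaries, rank-sum comparisons, and
calibration-curve / limit-of-detection estimation.

The localization metric: for an aggregate-containing cell, L is the length of
the cell's central line (pole to pole) and d the distance along that line from
the aggregate to the furthest pole, so d/L is 0.5 at midcell and 1.0 at a
pole.  Two variants are provided -- ``centroid`` (distance to the projected
aggregate centroid) and ``maxline`` (distance to the maximum-intensity pixel
along the central line).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage import measure
from skimage.morphology import skeletonize

from .segmentation import AggregateLabelMask, CellLabelMask
from .spectra import DEFAULT_WINDOWS, SpectralWindow, peak_intensity, window_sum
from .stack import HyperspectralStack
from .unmixing import ConcentrationMaps

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationFit",
    "CentralLine",
    "central_line",
    "aggregate_location",
    "extract_cell_features",
    "sweep_threshold",
    "population_summaries",
    "fit_calibration",
    "estimate_concentration",
    "compare_populations",
]

LIMONENE_PEAK_CM1 = 760.0


@dataclass(frozen=True)
class CentralLine:
    """Polyline along a cell's major axis from pole to pole.

    ``points`` are (row, col) vertices in image coordinates, ``arclength`` the
    cumulative distance at each vertex, ``length`` the pole-to-pole total.
    """

    points: np.ndarray
    arclength: np.ndarray
    length: float

    def project(self, point: tuple[float, float]) -> float:
        """Arclength coordinate of the vertex nearest to ``point``."""
        diffs = self.points - np.asarray(point, float)
        return float(self.arclength[np.argmin(np.einsum("ij,ij->i", diffs, diffs))])


def _longest_geodesic(coords: np.ndarray) -> list[int]:
    """Indices of the longest geodesic path through an 8-connected pixel set,
    found with two sweeps of Dijkstra (diagonal steps weigh sqrt(2))."""
    index = {tuple(c): i for i, c in enumerate(coords)}
    rows, cols, weights = [], [], []
    for i, (r, c) in enumerate(coords):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None and j > i:
                    w = np.sqrt(2.0) if dr and dc else 1.0
                    rows.append(i)
                    cols.append(j)
                    weights.append(w)
    n = len(coords)
    graph = coo_matrix((weights, (rows, cols)), shape=(n, n))

    def farthest(src: int):
        dist, pred = dijkstra(graph, directed=False, indices=src, return_predecessors=True)
        dist[~np.isfinite(dist)] = -1.0
        return int(np.argmax(dist)), pred

    a, _ = farthest(0)
    b, pred = farthest(a)
    path = [b]
    while path[-1] != a:
        path.append(int(pred[path[-1]]))
    return path[::-1]


def _extend_to_boundary(mask: np.ndarray, end: np.ndarray, inward: np.ndarray) -> np.ndarray:
    """March from a skeleton endpoint away from the path until leaving the
    mask; returns the last in-mask point (the pole)."""
    direction = end - inward
    norm = np.linalg.norm(direction)
    if norm == 0:
        return end.astype(float)
    direction = direction / norm
    pole = end.astype(float)
    pos = end.astype(float)
    for _ in range(400):
        pos = pos + 0.5 * direction
        r, c = int(round(pos[0])), int(round(pos[1]))
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
            break
        pole = pos.copy()
    return pole


def central_line(mask: np.ndarray) -> CentralLine:
    """Central line of a cell mask: skeleton pruned to its longest geodesic
    path, with both endpoints extended along the local direction to the mask
    boundary so the length spans pole to pole.

    Raises for degenerate (near-circular) masks whose skeleton collapses to
    fewer than two pixels.
    """
    mask = np.asarray(mask, bool)
    if mask.sum() < 2:
        raise ValueError("cell mask has fewer than 2 pixels")
    pix = np.argwhere(mask)
    cov = np.cov(pix.T) + 1e-12 * np.eye(2)
    eigvals = np.sort(np.linalg.eigvalsh(cov))
    if np.sqrt(eigvals[1] / eigvals[0]) < 1.3:
        raise ValueError(
            "degenerate (near-circular) cell: major axis undefined"
        )
    skel = skeletonize(mask)
    coords = np.argwhere(skel)
    if len(coords) < 2:
        raise ValueError("degenerate cell: skeleton collapses to a point, major axis undefined")
    path_idx = _longest_geodesic(coords)
    path = coords[path_idx].astype(float)
    k = min(3, len(path) - 1)
    pole_a = _extend_to_boundary(mask, path[0], path[k])
    pole_b = _extend_to_boundary(mask, path[-1], path[-1 - k])
    points = np.vstack([pole_a, path, pole_b])
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arclength = np.concatenate([[0.0], np.cumsum(steps)])
    return CentralLine(points=points, arclength=arclength, length=float(arclength[-1]))


def aggregate_location(
    cell_mask: np.ndarray,
    aggregate: tuple[float, float] | np.ndarray,
    mode: str = "centroid",
    line: CentralLine | None = None,
) -> tuple[float, float, float]:
    """(d, L, d/L) for one aggregate in one cell.

    ``centroid`` mode takes ``aggregate`` as the aggregate centroid (row, col)
    and measures d to the furthest pole from its projection onto the central
    line; ``maxline`` mode takes an intensity image and measures d to the
    maximum-intensity pixel along the central line.
    """
    line = line or central_line(cell_mask)
    if mode == "centroid":
        s = line.project(tuple(np.asarray(aggregate, float)))
    elif mode == "maxline":
        intensity = np.asarray(aggregate, float)
        idx = np.clip(np.round(line.points).astype(int), 0,
                      np.array(intensity.shape) - 1)
        values = intensity[idx[:, 0], idx[:, 1]]
        s = float(line.arclength[int(np.argmax(values))])
    else:
        raise ValueError(f"unknown location mode {mode!r}")
    d = max(s, line.length - s)
    return d, line.length, d / line.length


def _window_features(stack: HyperspectralStack, windows: dict[str, SpectralWindow]):
    """Per-window summed images; windows outside the stack axis give None."""
    images = {}
    for name, w in windows.items():
        try:
            images[name] = window_sum(stack, w)
        except ValueError:
            images[name] = None
    return images


def extract_cell_features(
    stack: HyperspectralStack,
    maps: ConcentrationMaps,
    cells: CellLabelMask,
    aggs: AggregateLabelMask,
    windows: dict[str, SpectralWindow] | None = None,
    fluorescence: np.ndarray | None = None,
    location_mode: str = "centroid",
    rich_threshold: float | None = None,
    control_cellbody_mean: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the per-cell and per-aggregate feature tables.

    Region statistics are taken over exact label supports; "rest of the cell"
    means the cell footprint minus its aggregates.  When ``rich_threshold`` is
    given, an aggregate is flagged limonene-rich if its mean limonene channel,
    normalized by ``control_cellbody_mean``, is >= the threshold.  Both d/L
    variants are recorded; ``location_mode`` selects which fills ``d_px`` /
    ``dl_ratio``.
    """
    windows = windows or DEFAULT_WINDOWS
    H, W = cells.labels.shape
    if maps.maps.shape[1:] != (H, W) or stack.spatial_shape != (H, W):
        raise ValueError("stack, maps and masks are not spatially aligned")
    if aggs.labels.shape != (H, W):
        raise ValueError("aggregate mask misaligned with cell mask")
    lim = maps["limonene"] if "limonene" in maps.names else maps.maps[0]
    cell_body = maps["cell_body"] if "cell_body" in maps.names else None
    win_images = _window_features(stack, windows)
    try:
        peak_img = peak_intensity(stack, LIMONENE_PEAK_CM1)
    except ValueError:
        peak_img = None
    px = cells.pixel_size or stack.pixel_size

    agg_by_cell: dict[int, list[int]] = {}
    for agg_label, cell_label in aggs.parent.items():
        agg_by_cell.setdefault(cell_label, []).append(agg_label)

    lines: dict[int, CentralLine] = {}
    cell_rows = []
    for region in measure.regionprops(cells.labels):
        cid = int(region.label)
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        support = cells.labels == cid
        try:
            sl = region.slice
            offset = np.array([sl[0].start, sl[1].start], float)
            local = central_line(support[sl])
            lines[cid] = CentralLine(
                points=local.points + offset, arclength=local.arclength, length=local.length
            )
            length = local.length
        except ValueError:
            logger.warning("cell %d has a degenerate central line; using ellipse axis", cid)
            length = float(region.axis_major_length)
        rest = support & (aggs.labels == 0)
        row = {
            "cell_id": cid,
            "area_px": int(region.area),
            "area_um2": float(region.area) * px**2 if px else np.nan,
            "major_axis_len_px": length,
            "n_aggregates": len(agg_by_cell.get(cid, [])),
            "mean_limonene": float(lim[rr, cc].mean()),
            "mean_limonene_rest": float(lim[rest].mean()) if rest.any() else np.nan,
        }
        if cell_body is not None:
            row["mean_cellbody"] = float(cell_body[rr, cc].mean())
        for name, img in win_images.items():
            row[f"sum_{name}"] = float(img[rr, cc].sum()) if img is not None else np.nan
        row["peak760"] = float(peak_img[rr, cc].mean()) if peak_img is not None else np.nan
        cell_rows.append(row)
    cell_table = pd.DataFrame(cell_rows)

    agg_rows = []
    for region in measure.regionprops(aggs.labels):
        aid = int(region.label)
        cid = aggs.parent[aid]
        line = lines.get(cid)
        if line is None:
            continue
        cell_support = cells.labels == cid
        d_cen, L, dl_cen = aggregate_location(cell_support, region.centroid,
                                              mode="centroid", line=line)
        d_max, _, dl_max = aggregate_location(cell_support, lim, mode="maxline", line=line)
        if abs(d_cen - d_max) > 2.0:
            logger.info("aggregate %d: centroid and maxline d differ by %.1f px",
                        aid, abs(d_cen - d_max))
        d, dl = (d_cen, dl_cen) if location_mode == "centroid" else (d_max, dl_max)
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        mean_lim = float(lim[rr, cc].mean())
        row = {
            "aggregate_id": aid,
            "cell_id": cid,
            "area_px": int(region.area),
            "major_axis_len_px": float(region.axis_major_length),
            "d_px": d,
            "L_px": L,
            "dl_ratio": dl,
            "dl_ratio_centroid": dl_cen,
            "dl_ratio_maxline": dl_max,
            "mean_limonene": mean_lim,
            "total_limonene": float(lim[rr, cc].sum()),
            "mean_cellbody": float(cell_body[rr, cc].mean()) if cell_body is not None else np.nan,
            "mean_fluorescence": (
                float(fluorescence[rr, cc].mean()) if fluorescence is not None else np.nan
            ),
            "limonene_rich": (
                bool(mean_lim / control_cellbody_mean >= rich_threshold)
                if rich_threshold is not None
                else False
            ),
        }
        agg_rows.append(row)
    agg_table = pd.DataFrame(agg_rows)
    return cell_table, agg_table


def sweep_threshold(
    values_positive: np.ndarray,
    values_control: np.ndarray,
    grid: np.ndarray,
    alpha: float = 0.0,
) -> tuple[float | None, pd.DataFrame]:
    """Choose the limonene-rich intensity threshold against control strains.

    For each grid threshold t the fraction of each population with value >= t
    is recorded; the chosen threshold is the smallest grid value at which the
    control fraction drops to <= ``alpha`` (default: zero control positives).
    Returns (chosen or None, the full sweep curve for plotting).
    """
    pos = np.asarray(values_positive, float)
    ctl = np.asarray(values_control, float)
    if pos.size == 0 or ctl.size == 0:
        raise ValueError("both populations must be nonempty")
    grid = np.asarray(grid, float)
    if grid.ndim != 1 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    frac_pos = (pos[None, :] >= grid[:, None]).mean(axis=1)
    frac_ctl = (ctl[None, :] >= grid[:, None]).mean(axis=1)
    curve = pd.DataFrame(
        {"threshold": grid, "frac_positive": frac_pos, "frac_control": frac_ctl}
    )
    ok = np.flatnonzero(frac_ctl <= alpha)
    if ok.size == 0:
        warnings.warn("no grid threshold meets the control criterion", stacklevel=2)
        return None, curve
    return float(grid[ok[0]]), curve


def population_summaries(cell_table: pd.DataFrame, agg_table: pd.DataFrame) -> dict:
    """Population statistics: aggregate-bearing fraction, limonene-rich
    fraction, aggregate-count histogram, and (area, mean limonene) pairs."""
    if cell_table.empty:
        raise ValueError("empty cell table")
    n_cells = len(cell_table)
    frac_agg = float((cell_table["n_aggregates"] >= 1).mean())
    if not agg_table.empty and "limonene_rich" in agg_table:
        rich_cells = set(agg_table.loc[agg_table["limonene_rich"], "cell_id"])
    else:
        rich_cells = set()
    counts = cell_table["n_aggregates"].value_counts().sort_index()
    scatter = (
        agg_table[["area_px", "mean_limonene"]].to_numpy().tolist()
        if not agg_table.empty
        else []
    )
    return {
        "n_cells": n_cells,
        "n_aggregates": int(len(agg_table)),
        "frac_cells_with_aggregates": frac_agg,
        "frac_cells_limonene_rich": len(rich_cells) / n_cells,
        "aggregate_count_histogram": {int(k): int(v) for k, v in counts.items()},
        "aggregate_area_vs_mean_limonene": scatter,
    }


@dataclass(frozen=True)
class CalibrationFit:
    """Linear calibration of SRS intensity against concentration.

    ``lod_mm`` is the 3*sigma_blank / slope detection limit; a valid
    calibration requires a positive slope.
    """

    slope: float  # a.u. per mM
    intercept: float  # a.u.
    blank_sigma: float  # a.u.
    lod_mm: float  # mM
    r2: float
    slope_stderr: float = float("nan")


def fit_calibration(table: pd.DataFrame) -> CalibrationFit:
    """Ordinary least-squares line through a dilution series.

    Expects columns ``conc_mm`` and ``intensity`` with at least 3 distinct
    concentrations including blank (zero) replicates; the blank standard
    deviation sets the detection limit as 3*sigma/slope.
    """
    conc = np.asarray(table["conc_mm"], float)
    inten = np.asarray(table["intensity"], float)
    if len(np.unique(conc)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    blanks = inten[conc == 0]
    if blanks.size == 0:
        raise ValueError("need blank (conc = 0) replicates to estimate blank sigma")
    res = stats.linregress(conc, inten)
    if res.slope <= 0:
        raise ValueError(f"invalid calibration: non-positive slope {res.slope}")
    blank_sigma = float(np.std(blanks, ddof=1)) if blanks.size > 1 else 0.0
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        blank_sigma=blank_sigma,
        lod_mm=3.0 * blank_sigma / float(res.slope),
        r2=float(res.rvalue) ** 2,
        slope_stderr=float(res.stderr),
    )


def estimate_concentration(
    intensity: float, blank_intensity: float, fit: CalibrationFit
) -> float:
    """Invert the calibration line: (intensity - blank)/slope, floored at 0 mM."""
    if fit.slope <= 0:
        raise ValueError("invalid calibration fit")
    return max(0.0, (float(intensity) - float(blank_intensity)) / fit.slope)


def adjust_pvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjustment for many pairwise comparisons (single
    comparisons are reported unadjusted by default)."""
    return stats.false_discovery_control(np.asarray(pvalues, float), method="bh")


def compare_populations(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison, normal
    approximation with tie correction; returns (U statistic of a, p value)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
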