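"""Ground-truthed synthetic hSRS scenes of limonene-producing rod-shaped bacteria.

The generator emulates the statistical structure the downstream analysis
assumes: a field of non-overlapping 2-D spherocylindrical cells, a minority
subpopulation carrying one or two bright intracellular limonene aggregates
with a polar placement bias, per-pixel spectra that are nonnegative mixtures
of three reference spectra (limonene, cell body, background) plus additive
Gaussian noise, a matched fluorescence channel for the synthase enzyme, and a
dilution calibration series for detection-limit work.  Every output is a
deterministic function of the parameters and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .spectra import Spectrum, WavenumberAxis, make_synthetic_reference
from .stack import HyperspectralStack
from .unmixing import ReferenceSet

__all__ = [
    "SceneParams",
    "CellTruth",
    "AggregateTruth",
    "SceneTruth",
    "PlacementError",
    "default_axis",
    "default_references",
    "generate_scene",
    "render_stack",
    "render_fluorescence",
    "generate_calibration_series",
]


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap; use fewer cells or a
    larger image."""


@dataclass(frozen=True)
class SceneParams:
    """Scene geometry and population statistics.

    Defaults encode the study conditions this simulator emulates: about 19% of
    cells carry aggregates, aggregate positions cluster at 70-90% of the cell
    length (truncated-normal d/L, mean 0.8, sd 0.08), cells are 2-4 um rods of
    0.8 um width imaged at 0.1 um/px.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.1  # um per px
    n_cells: int = 60
    cell_length_range: tuple[float, float] = (2.0, 4.0)  # um, pole to pole
    cell_width: float = 0.8  # um
    aggregate_probability: float = 0.19
    aggregate_count_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.8, 2: 0.2}
    )
    aggregate_radius: float = 0.2  # um
    polar_bias: tuple[float, float] = (0.8, 0.08)  # d/L mean, sd on [0.5, 1]
    limonene_conc_range: tuple[float, float] = (0.5, 1.5)  # coefficient units
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.aggregate_probability <= 1.0:
            raise ValueError("aggregate_probability must be in [0, 1]")
        if self.cell_width <= 0 or self.aggregate_radius <= 0 or self.pixel_size <= 0:
            raise ValueError("geometric sizes must be positive")
        if self.cell_length_range[0] <= self.cell_width:
            raise ValueError("cell length must exceed cell width (rod shape)")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        weights = self.aggregate_count_weights
        if weights and (min(weights) < 1 or abs(sum(weights.values()) - 1.0) > 1e-9):
            raise ValueError("aggregate_count_weights must be a distribution over counts >= 1")


@dataclass(frozen=True)
class CellTruth:
    cell_id: int
    centroid: tuple[float, float]  # (row, col) px
    orientation: float  # radians, axis direction
    length_px: float  # pole-to-pole L
    width_px: float
    pole_a: tuple[float, float]
    pole_b: tuple[float, float]


@dataclass(frozen=True)
class AggregateTruth:
    aggregate_id: int
    cell_id: int
    centroid: tuple[float, float]
    radius_px: float
    dl_ratio: float  # distance to furthest pole / cell length
    concentration: float  # limonene coefficient inside the aggregate


@dataclass(frozen=True)
class SceneTruth:
    """Everything the generator knows: geometry, labels and concentration maps.

    ``concentration_maps`` is (3, H, W) ordered (limonene, cell_body,
    background); limonene is zero outside aggregate footprints.
    """

    params: SceneParams
    cells: tuple[CellTruth, ...]
    aggregates: tuple[AggregateTruth, ...]
    cell_labels: np.ndarray
    aggregate_labels: np.ndarray
    aggregate_parent: dict[int, int]
    concentration_maps: np.ndarray
    channel_names: tuple[str, str, str] = ("limonene", "cell_body", "background")

    @property
    def aggregate_bearing_fraction(self) -> float:
        if not self.cells:
            return 0.0
        bearing = {a.cell_id for a in self.aggregates}
        return len(bearing) / len(self.cells)


def default_axis(lo: float = 670.0, hi: float = 900.0, step: float = 10.0) -> WavenumberAxis:
    """Fingerprint-region acquisition axis (24 frames at 10 cm^-1 by default)."""
    return WavenumberAxis(np.arange(lo, hi + step / 2, step))


def default_references(axis: WavenumberAxis | None = None) -> ReferenceSet:
    """Three synthetic references on the fingerprint axis.

    Limonene: dominant 760 cm^-1 band plus a weaker ring mode; cell body: broad
    unspecific bands as in a wild-type cell spectrum; background: nearly flat
    offset from the medium/coverslip.
    """
    axis = axis or default_axis()
    lim = make_synthetic_reference(
        [(760.0, 18.0, 1.0), (715.0, 25.0, 0.25)], axis, baseline=0.02, label="limonene"
    )
    cell = make_synthetic_reference(
        [(720.0, 60.0, 0.55), (785.0, 45.0, 0.45), (860.0, 55.0, 0.35)],
        axis,
        baseline=0.05,
        label="cell_body",
    )
    bg = make_synthetic_reference(
        [(830.0, 400.0, 0.15)], axis, baseline=0.6, label="background"
    )
    return ReferenceSet(spectra=(lim, cell, bg), names=("limonene", "cell_body", "background"))


def _capsule_mask(
    shape: tuple[int, int],
    center: np.ndarray,
    direction: np.ndarray,
    half_seg: float,
    radius: float,
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Boolean footprint of a capsule (segment of half-length ``half_seg``
    dilated by ``radius``), restricted to a bounding box for speed."""
    extent = half_seg + radius + 1.5
    r0 = max(int(np.floor(center[0] - extent)), 0)
    r1 = min(int(np.ceil(center[0] + extent)) + 1, shape[0])
    c0 = max(int(np.floor(center[1] - extent)), 0)
    c1 = min(int(np.ceil(center[1] + extent)) + 1, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    rel = np.stack([rr - center[0], cc - center[1]], axis=-1)
    t = np.clip(rel @ direction, -half_seg, half_seg)
    closest = t[..., None] * direction
    dist = np.sqrt(((rel - closest) ** 2).sum(axis=-1))
    return dist <= radius, (slice(r0, r1), slice(c0, c1))


def generate_scene(p: SceneParams) -> SceneTruth:
    """Place cells and aggregates and rasterize labels and truth maps.

    Cells are placed by rejection sampling (no overlap, one pixel of clearance);
    aggregate-bearing cells are Bernoulli(aggregate_probability) draws, their
    aggregate count follows ``aggregate_count_weights`` and the axial position
    follows the truncated-normal polar-bias law on d/L in [0.5, 1].
    """
    rng = np.random.default_rng(p.seed)
    H, W = p.image_shape
    px = p.pixel_size
    width_px = p.cell_width / px
    radius = width_px / 2.0
    agg_r = p.aggregate_radius / px
    if agg_r >= radius:
        raise ValueError("aggregate radius must be smaller than the cell half-width")

    cell_labels = np.zeros((H, W), np.int32)
    occupied = np.zeros((H, W), bool)
    cells: list[CellTruth] = []
    max_tries = max(200, 200 * p.n_cells)
    tries = 0
    while len(cells) < p.n_cells:
        if tries >= max_tries:
            raise PlacementError(
                f"placed only {len(cells)}/{p.n_cells} cells after {max_tries} tries; "
                "use fewer cells or a larger image"
            )
        tries += 1
        L_um = rng.uniform(*p.cell_length_range)
        L_px = L_um / px
        theta = rng.uniform(0.0, np.pi)
        u = np.array([np.sin(theta), np.cos(theta)])  # (row, col) direction
        margin = L_px / 2 + 2.0
        if H - margin <= margin or W - margin <= margin:
            raise PlacementError("cells do not fit in the image")
        center = np.array([rng.uniform(margin, H - margin), rng.uniform(margin, W - margin)])
        half_seg = (L_px - width_px) / 2.0
        mask, box = _capsule_mask((H, W), center, u, half_seg, radius)
        # one-pixel clearance so neighbouring cells never touch
        grown, gbox = _capsule_mask((H, W), center, u, half_seg, radius + 1.5)
        if occupied[gbox][grown].any():
            continue
        label = len(cells) + 1
        cell_labels[box][mask] = label
        occupied[box] |= mask
        pole_a = center - u * (L_px / 2.0)
        pole_b = center + u * (L_px / 2.0)
        cells.append(
            CellTruth(
                cell_id=label,
                centroid=(float(center[0]), float(center[1])),
                orientation=float(theta),
                length_px=float(L_px),
                width_px=float(width_px),
                pole_a=(float(pole_a[0]), float(pole_a[1])),
                pole_b=(float(pole_b[0]), float(pole_b[1])),
            )
        )

    # aggregate placement
    mean_dl, sd_dl = p.polar_bias
    lo_t, hi_t = (0.5 - mean_dl) / sd_dl, (1.0 - mean_dl) / sd_dl
    counts = sorted(p.aggregate_count_weights)
    weights = np.array([p.aggregate_count_weights[c] for c in counts], float)
    agg_labels = np.zeros((H, W), np.int32)
    aggregates: list[AggregateTruth] = []
    parent: dict[int, int] = {}
    for cell in cells:
        if rng.random() >= p.aggregate_probability:
            continue
        n_agg = int(rng.choice(counts, p=weights)) if counts else 0
        u = np.array([np.sin(cell.orientation), np.cos(cell.orientation)])
        pole_a = np.array(cell.pole_a)
        L = cell.length_px
        placed_t: list[float] = []
        for _ in range(n_agg):
            for _attempt in range(20):
                f = float(stats.truncnorm.rvs(lo_t, hi_t, loc=mean_dl, scale=sd_dl,
                                              random_state=rng))
                # d/L = f means axial distance (1-f)L from the near pole; keep
                # the whole disk inside the capsule and clear of siblings
                near = rng.integers(2)
                t = (1.0 - f) * L if near == 0 else f * L
                t = float(np.clip(t, agg_r + 0.5, L - agg_r - 0.5))
                if all(abs(t - t0) > 2.5 * agg_r for t0 in placed_t):
                    break
            else:
                continue
            placed_t.append(t)
            center = pole_a + u * t
            dl = max(t, L - t) / L
            label = len(aggregates) + 1
            mask, box = _capsule_mask((H, W), center, u, 0.0, agg_r)
            inside = mask & (cell_labels[box] == cell.cell_id)
            agg_labels[box][inside] = label
            conc = float(rng.uniform(*p.limonene_conc_range))
            aggregates.append(
                AggregateTruth(
                    aggregate_id=label,
                    cell_id=cell.cell_id,
                    centroid=(float(center[0]), float(center[1])),
                    radius_px=float(agg_r),
                    dl_ratio=float(dl),
                    concentration=conc,
                )
            )
            parent[label] = cell.cell_id

    maps = np.zeros((3, H, W))
    for agg in aggregates:
        maps[0][agg_labels == agg.aggregate_id] = agg.concentration
    maps[1][cell_labels > 0] = 1.0
    maps[2][:] = 1.0
    return SceneTruth(
        params=p,
        cells=tuple(cells),
        aggregates=tuple(aggregates),
        cell_labels=cell_labels,
        aggregate_labels=agg_labels,
        aggregate_parent=parent,
        concentration_maps=maps,
    )


def render_stack(
    truth: SceneTruth,
    refs: ReferenceSet | None = None,
    noise_sigma: float | None = None,
    seed: int | None = None,
    blur_sigma: float = 0.0,
    noise_model: str = "gaussian",
) -> tuple[HyperspectralStack, np.ndarray]:
    """Forward model: per-pixel spectrum = c . S plus noise.

    ``refs`` must carry the three channels in truth order (limonene, cell_body,
    background); the mixture uses peak-normalized references so the truth
    coefficients read as fractions of pure-reference peak intensity.  An
    optional Gaussian optical blur is applied to the signal before noise.
    ``noise_model='gaussian'`` adds N(0, noise_sigma) (lock-in detected SRS);
    ``'poisson'`` draws shot noise with gain ``noise_sigma`` (variance
    noise_sigma * signal).  Returns the stack and the pre-noise truth maps
    (3, H, W).
    """
    refs = refs or default_references()
    if refs.k != 3:
        raise ValueError("render_stack needs exactly 3 reference channels")
    p = truth.params
    noise_sigma = p.noise_sigma if noise_sigma is None else noise_sigma
    seed = p.seed if seed is None else seed
    S = refs.matrix("max")  # (3, N)
    maps = truth.concentration_maps
    signal = np.einsum("kn,khw->nhw", S, maps)
    if blur_sigma > 0:
        signal = ndimage.gaussian_filter(signal, sigma=(0.0, blur_sigma, blur_sigma))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        if noise_model == "gaussian":
            signal = signal + rng.normal(0.0, noise_sigma, signal.shape)
        elif noise_model == "poisson":
            signal = rng.poisson(np.maximum(signal, 0.0) / noise_sigma) * noise_sigma
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")
    stack = HyperspectralStack(axis=refs.axis, data=signal, pixel_size=p.pixel_size)
    return stack, maps.copy()


def render_fluorescence(
    truth: SceneTruth,
    psf_sigma: float = 1.0,
    colocal_fraction: float = 1.0,
    noise_sigma: float = 0.005,
    seed: int | None = None,
) -> np.ndarray:
    """Synthetic enzyme-fluorescence channel matched to the scene.

    Aggregates emit in proportion to their limonene content; a
    ``1 - colocal_fraction`` share of the total flux is relocated to random
    in-cell, non-aggregate pixels (imperfect enzyme-product colocalization),
    then PSF blur and additive noise are applied.
    """
    if not 0.0 <= colocal_fraction <= 1.0:
        raise ValueError("colocal_fraction must be in [0, 1]")
    seed = truth.params.seed + 1 if seed is None else seed
    rng = np.random.default_rng(seed)
    emission = truth.concentration_maps[0] * colocal_fraction
    total = float(truth.concentration_maps[0].sum())
    stray = total * (1.0 - colocal_fraction)
    if stray > 0:
        candidates = np.flatnonzero((truth.cell_labels > 0) & (truth.aggregate_labels == 0))
        if candidates.size:
            n_sites = min(candidates.size, max(1, 3 * max(1, len(truth.aggregates))))
            sites = rng.choice(candidates, n_sites, replace=False)
            flat = emission.ravel()
            flat[sites] += stray / n_sites
    if psf_sigma > 0:
        emission = ndimage.gaussian_filter(emission, psf_sigma)
    if noise_sigma > 0:
        emission = emission + rng.normal(0.0, noise_sigma, emission.shape)
    return emission


def generate_calibration_series(
    concentrations: list[float] | None = None,
    slope: float = 2.0,
    blank_sigma: float = 14.0,
    n_replicates: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Dilution series for the 760 cm^-1 calibration: intensity =
    slope * concentration + N(0, blank_sigma) per replicate.

    Defaults span the tens-to-one-hundred mM range relevant for intracellular
    aggregates, with replicated blanks so the blank standard deviation (and
    hence the 3-sigma detection limit) is estimable.
    """
    if concentrations is None:
        concentrations = [0.0, 10.0, 25.0, 50.0, 75.0, 100.0]
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be >= 0")
    if slope <= 0:
        raise ValueError("slope must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for conc in concentrations:
        noise = rng.normal(0.0, blank_sigma, n_replicates) if blank_sigma > 0 else np.zeros(n_replicates)
        for rep in range(n_replicates):
            rows.append({"conc_mm": float(conc), "intensity": slope * conc + float(noise[rep])})
    return pd.DataFrame(rows)
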