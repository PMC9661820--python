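"""Pixel-wise L1-regularized linear spectral unmixing (LASSO).

Model: each pixel's measured spectrum d (length N_lambda) is a linear mixture
of k pure-component reference spectra S (k x N_lambda) plus residual noise,

    d = c S + e,

and the per-pixel concentrations c are estimated by

    c_hat = argmin_c  1/2 ||d - c S||_2^2  +  lambda ||c||_1 .

The L1 penalty encodes the sparsity premise: most pixels are dominated by one
or two components (limonene is confined to intracellular aggregates; the rest
of the cell matches the wild-type cell-body spectrum).  The solver is cyclic
coordinate descent with the exact per-coordinate soft-threshold update, run
simultaneously over all pixels; a nonnegativity constraint (on by default)
clips each coordinate update at zero, since concentrations are physical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from .spectra import Spectrum, WavenumberAxis
from .stack import HyperspectralStack

__all__ = [
    "ReferenceSet",
    "UnmixConfig",
    "ConcentrationMaps",
    "objective",
    "soft_threshold",
    "lasso_unmix_pixel",
    "unmix_stack",
    "estimate_background_spectrum",
    "select_lambda",
    "ConvergenceWarning",
]

DEFAULT_CHANNEL_NAMES = ("limonene", "cell_body", "background")


class ConvergenceWarning(UserWarning):
    """Coordinate descent hit max_iter before the objective stabilized."""


@dataclass(frozen=True)
class ReferenceSet:
    """The unmixing basis S: k spectra on one shared wavenumber axis.

    The canonical basis has three members -- pure limonene, the wild-type
    cell-body spectrum, and the non-cell background of the image stack.
    """

    spectra: tuple[Spectrum, ...]
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        spectra = tuple(self.spectra)
        if len(spectra) < 1:
            raise ValueError("ReferenceSet needs at least one spectrum")
        axis0 = spectra[0].axis
        for s in spectra[1:]:
            if s.axis != axis0:
                raise ValueError("all reference spectra must share one wavenumber axis")
        for i, s in enumerate(spectra):
            if not np.any(s.intensity):
                raise ValueError(f"reference {i} is all-zero")
        names = tuple(self.names) or tuple(
            s.label or f"channel_{i}" for i, s in enumerate(spectra)
        )
        if len(names) != len(spectra):
            raise ValueError("names length must match number of spectra")
        object.__setattr__(self, "spectra", spectra)
        object.__setattr__(self, "names", names)

    @property
    def axis(self) -> WavenumberAxis:
        return self.spectra[0].axis

    @property
    def k(self) -> int:
        return len(self.spectra)

    def matrix(self, normalize: str = "none") -> np.ndarray:
        """Stack references into S (k x N_lambda); ``normalize='max'`` rescales
        each row to unit peak so coefficients read as fractions of the pure
        reference intensity."""
        S = np.stack([s.intensity for s in self.spectra])
        if normalize == "max":
            S = S / np.max(np.abs(S), axis=1, keepdims=True)
        elif normalize != "none":
            raise ValueError(f"unknown reference normalization {normalize!r}")
        return S

    def resample(self, axis: WavenumberAxis) -> "ReferenceSet":
        """Linearly interpolate every reference onto ``axis``."""
        spectra = tuple(
            Spectrum(
                axis=axis,
                intensity=np.interp(axis.values, s.axis.values, s.intensity),
                label=s.label,
            )
            for s in self.spectra
        )
        return ReferenceSet(spectra=spectra, names=self.names)


@dataclass(frozen=True)
class UnmixConfig:
    """Solver settings.

    lam            L1 penalty (>= 0); one value is held fixed across all stacks
                   recorded under the same acquisition conditions.
    nonnegative    clip coordinate updates at zero (concentrations are physical).
    max_iter       maximum full coordinate cycles.
    tol            relative objective-change stopping tolerance.
    normalize_refs 'max' fits against peak-normalized references, 'none' uses
                   raw units.
    resample_refs  allow linear interpolation of references onto the stack axis.
    """

    lam: float = 0.0
    nonnegative: bool = True
    max_iter: int = 1000
    tol: float = 1e-8
    normalize_refs: str = "max"
    resample_refs: bool = False

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class ConcentrationMaps:
    """The unmixing result C: one 2-D coefficient map per reference channel,
    plus the per-pixel residual L2 norm ||d - c S||."""

    maps: np.ndarray  # (k, H, W)
    names: tuple[str, ...]
    residual_norm: np.ndarray  # (H, W)
    lam: float = 0.0
    n_iter: int = 0

    def __post_init__(self) -> None:
        if self.maps.ndim != 3:
            raise ValueError("maps must be (k, H, W)")
        if len(self.names) != self.maps.shape[0]:
            raise ValueError("names length must match channel count")
        if self.residual_norm.shape != self.maps.shape[1:]:
            raise ValueError("residual_norm shape must match map spatial shape")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[self.names.index(name)]

    def crop(self, rows: slice, cols: slice) -> "ConcentrationMaps":
        return ConcentrationMaps(
            maps=self.maps[:, rows, cols].copy(),
            names=self.names,
            residual_norm=self.residual_norm[rows, cols].copy(),
            lam=self.lam,
            n_iter=self.n_iter,
        )


def soft_threshold(x: np.ndarray, lam: float) -> np.ndarray:
    """sign(x) * max(|x| - lam, 0)."""
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


def objective(d: np.ndarray, c: np.ndarray, S: np.ndarray, lam: float) -> float:
    """1/2 ||d - c S||_2^2 + lam ||c||_1 for one pixel."""
    d = np.asarray(d, float)
    c = np.asarray(c, float)
    S = np.asarray(S, float)
    if S.ndim != 2 or d.shape != (S.shape[1],) or c.shape != (S.shape[0],):
        raise ValueError(
            f"dimension mismatch: d {d.shape}, c {c.shape}, S {S.shape}"
        )
    r = d - c @ S
    return 0.5 * float(r @ r) + lam * float(np.abs(c).sum())


def _cd_solve(
    D: np.ndarray, S: np.ndarray, lam: float, nonnegative: bool, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Cyclic coordinate descent on P pixels at once.

    D is (P, N); returns (C (P, k), residual (P, N), cycles used, converged).
    Each pixel warm-starts at 0 and is frozen once its own relative objective
    change drops below tol, so the result is identical to solving pixels one
    at a time.
    """
    P, N = D.shape
    k = S.shape[0]
    G = S @ S.T  # (k, k) Gram matrix
    diag = np.diag(G).copy()
    if np.any(diag <= 0):
        raise ValueError("reference with zero norm cannot be fit")
    B = D @ S.T  # (P, k) correlations s_j . d

    C = np.zeros((P, k))
    half_dd = 0.5 * np.einsum("ij,ij->i", D, D)
    obj = half_dd.copy()  # objective at c = 0
    active = np.ones(P, bool)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Ca = C[idx]
        C_old = Ca.copy()
        Ba = B[idx]
        for j in range(k):
            # rho_j = s_j.d - sum_{l != j} G_jl c_l
            rho = Ba[:, j] - Ca @ G[:, j] + Ca[:, j] * diag[j]
            cj = soft_threshold(rho, lam) / diag[j]
            if nonnegative:
                np.maximum(cj, 0.0, out=cj)
            Ca[:, j] = cj
        C[idx] = Ca
        # objective via the Gram form: 1/2 d.d - c.b + 1/2 c G c + lam |c|
        # (k x k work per pixel instead of re-forming the N-long residual)
        new_obj = (
            half_dd[idx]
            - np.einsum("ij,ij->i", Ca, Ba)
            + 0.5 * np.einsum("ij,ij->i", Ca @ G, Ca)
            + lam * np.abs(Ca).sum(axis=1)
        )
        # converge on the objective AND the iterate: the objective change alone
        # saturates near sqrt(eps) coefficient accuracy because the objective
        # is quadratic around the optimum.  The eps*(1 + d.d) floor is the
        # numerical resolution of the Gram-form objective, so perfect fits
        # terminate instead of chasing rounding noise.
        floor = np.finfo(float).eps * (1.0 + 2.0 * half_dd[idx])
        obj_ok = np.abs(obj[idx] - new_obj) <= np.maximum(tol * obj[idx], floor)
        step = np.abs(Ca - C_old).max(axis=1)
        scale = np.maximum(np.abs(Ca).max(axis=1), 1.0)
        done = obj_ok & (step <= tol * scale)
        obj[idx] = new_obj
        active[idx[done]] = False
    converged = not active.any()
    residual = D - C @ S
    return C, residual, n_iter, converged


def lasso_unmix_pixel(
    d: np.ndarray, refs: ReferenceSet, cfg: UnmixConfig | None = None
) -> np.ndarray:
    """Solve the per-pixel LASSO for one spectrum; returns coefficients (k,)."""
    cfg = cfg or UnmixConfig()
    d = np.asarray(d, float)
    S = refs.matrix(cfg.normalize_refs)
    if d.shape != (S.shape[1],):
        raise ValueError(f"spectrum length {d.shape} does not match references {S.shape}")
    if not np.all(np.isfinite(d)):
        raise ValueError("spectrum contains non-finite values")
    C, _, _, converged = _cd_solve(
        d[None, :], S, cfg.lam, cfg.nonnegative, cfg.max_iter, cfg.tol
    )
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {cfg.max_iter} cycles",
            ConvergenceWarning,
            stacklevel=2,
        )
    return C[0]


def unmix_stack(
    stack: HyperspectralStack, refs: ReferenceSet, cfg: UnmixConfig | None = None
) -> ConcentrationMaps:
    """Apply the per-pixel LASSO independently to every pixel of the stack.

    Pixels are independent, so the decomposition commutes with spatial
    cropping; the computation is vectorized across pixels but numerically
    identical to calling :func:`lasso_unmix_pixel` per pixel.
    """
    cfg = cfg or UnmixConfig()
    if refs.axis != stack.axis:
        if cfg.resample_refs:
            refs = refs.resample(stack.axis)
        else:
            raise ValueError(
                "reference axis does not match stack axis "
                "(set resample_refs=True to interpolate)"
            )
    S = refs.matrix(cfg.normalize_refs)
    H, W = stack.spatial_shape
    D = stack.data.reshape(stack.n_frames, -1).T  # (P, N)
    if not np.all(np.isfinite(D)):
        raise ValueError("stack contains non-finite values")
    C, R, n_iter, converged = _cd_solve(
        D, S, cfg.lam, cfg.nonnegative, cfg.max_iter, cfg.tol
    )
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {cfg.max_iter} cycles "
            "for some pixels",
            ConvergenceWarning,
            stacklevel=2,
        )
    maps = C.T.reshape(refs.k, H, W)
    residual_norm = np.sqrt(np.einsum("ij,ij->i", R, R)).reshape(H, W)
    return ConcentrationMaps(
        maps=maps, names=refs.names, residual_norm=residual_norm,
        lam=cfg.lam, n_iter=n_iter,
    )


def estimate_background_spectrum(
    stack: HyperspectralStack, cell_mask: np.ndarray | None = None
) -> Spectrum:
    """Mean spectrum of the non-cell area, used as the background reference.

    When no cell mask is supplied, non-cell pixels are those below the Otsu
    threshold of the spectrally summed image.
    """
    if cell_mask is None:
        summed = stack.data.sum(axis=0)
        if np.ptp(summed) == 0:
            raise ValueError("constant image: cannot auto-detect non-cell area")
        cell_mask = summed > threshold_otsu(summed)
    else:
        cell_mask = np.asarray(cell_mask) > 0
    outside = ~cell_mask
    if not outside.any():
        raise ValueError("non-cell area is empty")
    return stack.mean_spectrum(mask=outside, label="background")


def select_lambda(
    stack: HyperspectralStack,
    refs: ReferenceSet,
    cell_mask: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    inflation: float = 1.1,
    cfg: UnmixConfig | None = None,
    max_pixels: int = 2000,
    seed: int = 0,
) -> float:
    """Pick the penalty for an acquisition condition.

    Returns the largest grid value for which the mean residual norm on
    non-cell pixels stays within ``inflation`` times its unpenalized value.
    The chosen value is meant to be held fixed for every stack recorded under
    the same imaging and digitizing conditions.
    """
    cfg = cfg or UnmixConfig()
    if grid is None:
        grid = np.concatenate([[0.0], np.geomspace(1e-4, 1.0, 17)])
    grid = np.sort(np.asarray(grid, float))
    if cell_mask is None:
        summed = stack.data.sum(axis=0)
        cell_mask = summed > threshold_otsu(summed)
    outside = ~(np.asarray(cell_mask) > 0)
    if not outside.any():
        raise ValueError("non-cell area is empty")
    D = stack.data[:, outside].T  # (P, N)
    if D.shape[0] > max_pixels:
        rng = np.random.default_rng(seed)
        D = D[rng.choice(D.shape[0], max_pixels, replace=False)]
    S = refs.matrix(cfg.normalize_refs)

    def mean_resid(lam: float) -> float:
        _, R, _, _ = _cd_solve(D, S, lam, cfg.nonnegative, cfg.max_iter, cfg.tol)
        return float(np.sqrt(np.einsum("ij,ij->i", R, R)).mean())

    base = mean_resid(0.0)
    best = 0.0
    for lam in grid:
        if mean_resid(lam) <= inflation * base:
            best = float(lam)
    return best
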