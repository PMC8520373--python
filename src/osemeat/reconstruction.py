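"""MLEM and ordered-subset EM (OSEM) reconstruction.

Both algorithms iterate the multiplicative Poisson-EM update

    g_j  <-  g_j * ( sum_i q_ij * y_i / yhat_i ) / ( sum_i q_ij ),

where ``yhat = A g`` is the current forward projection.  MLEM uses all
rays in every update; OSEM partitions the view angles into L equal-sized
subsets and applies the update once per subset, so each full iteration
refines the image L times and converges roughly L-fold faster.

Subset construction follows two rules: every subset's angles are
uniformly spread over the angular range (stride-L interleave, so the
subsets are balanced and each one samples the object evenly), and the
processing order is chosen so that consecutively processed subsets are
angularly as far apart as possible (greedy farthest-first ordering),
which decorrelates successive updates and speeds early convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .phantom_geometry import ImageGrid
from .projector import Sinogram, SystemMatrix

_STRATEGIES = ("sequential", "optimized")


class PartitionError(ValueError):
    """Raised for invalid subset partitions."""


@dataclass
class SubsetPartition:
    """L disjoint, equal-sized, angularly uniform subsets of view indices."""

    L: int
    subsets: list[list[int]]
    order: list[int]  # processing sequence, 0-based subset indices
    strategy: str

    def __post_init__(self) -> None:
        if self.L != len(self.subsets):
            raise PartitionError("L does not match the number of subsets")
        flat = sorted(i for s in self.subsets for i in s)
        if flat != list(range(len(flat))):
            raise PartitionError("subsets must be disjoint and cover all angles")
        sizes = {len(s) for s in self.subsets}
        if len(sizes) != 1:
            raise PartitionError("subsets must be balanced (equal size)")
        if sorted(self.order) != list(range(self.L)):
            raise PartitionError("order must be a permutation of the subsets")

    @property
    def n_angles(self) -> int:
        return sum(len(s) for s in self.subsets)


@dataclass
class ReconConfig:
    """Iteration settings for the EM loop.

    ``epsilon`` guards divisions by a vanishing forward projection or
    sensitivity; ``seed`` is recorded for provenance only (the core is
    deterministic).
    """

    n_iterations: int = 20
    per_subset: int = 6
    epsilon: float = 1e-12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if not (0.0 < self.epsilon <= 1e-6):
            raise ValueError("epsilon must lie in (0, 1e-6]")


@dataclass
class ReconState:
    """Current estimate g^k plus per-iteration error/likelihood history."""

    image: ImageGrid
    k: int = 0
    sub_iterations_done: int = 0
    error_history: list[float] = field(default_factory=list)
    loglik_history: list[float] = field(default_factory=list)


def init_image(grid: ImageGrid) -> ImageGrid:
    """Uniform all-ones starting image (any positive constant works for EM)."""
    return ImageGrid(np.ones_like(grid.values), pixel_size=grid.pixel_size)


def _circular_set_distance(sa: list[int], sb: list[int], n_angles: int) -> int:
    """Minimum circular distance (in angle-index units) between two angle sets."""
    a = np.asarray(sa)[:, None]
    b = np.asarray(sb)[None, :]
    d = np.abs(a - b) % n_angles
    return int(np.minimum(d, n_angles - d).min())


def partition_subsets(
    n_angles: int, per_subset: int, strategy: str = "optimized"
) -> SubsetPartition:
    """Split ``n_angles`` view indices into L = n_angles/per_subset subsets.

    Subset m holds the stride-L interleave {m, m+L, m+2L, ...}, so each
    subset's angles are uniformly spaced across the angular range.  With
    the ``sequential`` strategy subsets are processed in index order;
    ``optimized`` greedily orders them farthest-first: each successive
    subset maximizes the minimum circular angular distance to all
    previously processed subsets (ties broken by lowest subset index).
    """
    if strategy not in _STRATEGIES:
        raise ValueError(f"strategy must be one of {_STRATEGIES}")
    if per_subset < 1 or n_angles < 1 or n_angles % per_subset != 0:
        raise PartitionError(
            f"per_subset={per_subset} does not divide n_angles={n_angles}"
        )
    L = n_angles // per_subset
    subsets = [list(range(m, n_angles, L)) for m in range(L)]
    if strategy == "sequential" or L == 1:
        order = list(range(L))
    else:
        order = [0]
        remaining = set(range(1, L))
        while remaining:
            best, best_d = None, -1
            for cand in sorted(remaining):
                d = min(
                    _circular_set_distance(subsets[cand], subsets[u], n_angles)
                    for u in order
                )
                if d > best_d:
                    best, best_d = cand, d
            order.append(best)
            remaining.discard(best)
    return SubsetPartition(L=L, subsets=subsets, order=order, strategy=strategy)


def compute_residual(
    observed: np.ndarray, theoretical: np.ndarray, epsilon: float = 1e-12
) -> np.ndarray:
    """Elementwise ratio r_i = y_i / max(yhat_i, epsilon).

    A ray with zero observed and zero predicted counts gets residual 0
    (the guard denominator makes 0/eps = 0), which freezes pixels seen
    only by empty rays at zero — the standard EM treatment.
    """
    obs = np.asarray(observed, dtype=float)
    theo = np.asarray(theoretical, dtype=float)
    if obs.shape != theo.shape:
        raise ValueError("observed and theoretical projections differ in length")
    if np.any(obs < 0):
        raise ValueError("observed projections must be non-negative")
    return obs / np.maximum(theo, epsilon)


def compute_correction(
    A: SystemMatrix,
    residual: np.ndarray,
    subset: list[int],
    epsilon: float = 1e-12,
) -> np.ndarray:
    """Backproject the residual over one subset and normalize by sensitivity.

    c_j = (sum_{i in S} q_ij r_i) / (sum_{i in S} q_ij); pixels with zero
    subset sensitivity receive c_j = 1 (no update).
    """
    if len(subset) == 0:
        raise PartitionError("subset must contain at least one angle")
    rows = A.rays_for_angles(subset)
    sub = A.weights[rows]
    return _correction_kernel(sub, np.asarray(residual, dtype=float))


def _correction_kernel(
    sub: sp.csr_matrix, residual: np.ndarray, sens: np.ndarray | None = None
) -> np.ndarray:
    if sens is None:
        sens = np.asarray(sub.sum(axis=0)).ravel()
    back = sub.T @ residual
    out = np.ones_like(back)
    covered = sens > 0
    out[covered] = back[covered] / sens[covered]
    return out


def apply_update(state: ReconState, correction: np.ndarray) -> ReconState:
    """Multiplicative image update g <- g * c (in place on the state)."""
    c = np.asarray(correction, dtype=float).reshape(state.image.values.shape)
    if np.any(c < 0):
        raise ValueError("correction factors must be non-negative")
    state.image.values *= c
    state.sub_iterations_done += 1
    return state


def reconstruction_error(
    recon: ImageGrid | np.ndarray, truth: ImageGrid | np.ndarray
) -> float:
    """Relative root-mean-square error ||recon - truth||_2 / ||truth||_2."""
    r = recon.values if isinstance(recon, ImageGrid) else np.asarray(recon, float)
    t = truth.values if isinstance(truth, ImageGrid) else np.asarray(truth, float)
    if r.shape != t.shape:
        raise ValueError("shape mismatch between reconstruction and truth")
    denom = np.linalg.norm(t)
    if denom == 0:
        raise ValueError("relative error undefined for an all-zero reference")
    return float(np.linalg.norm(r - t) / denom)


def poisson_log_likelihood(
    y: Sinogram | np.ndarray,
    A: SystemMatrix,
    g: ImageGrid | np.ndarray,
    epsilon: float = 1e-12,
) -> float:
    """Poisson data log-likelihood sum_i [y_i log yhat_i - yhat_i], up to a
    g-independent constant; EM increases this monotonically."""
    yv = y.values if isinstance(y, Sinogram) else np.asarray(y, float)
    gv = g.values if isinstance(g, ImageGrid) else np.asarray(g, float)
    yhat = A.weights @ gv.ravel()
    return float(np.sum(yv * np.log(np.maximum(yhat, epsilon)) - yhat))


def osem_reconstruct(
    y: Sinogram | np.ndarray,
    A: SystemMatrix,
    partition: SubsetPartition,
    config: ReconConfig | None = None,
    truth: ImageGrid | np.ndarray | None = None,
    track_loglik: bool = True,
    initial: ImageGrid | np.ndarray | None = None,
) -> ReconState:
    """Run OSEM for ``config.n_iterations`` full iterations.

    Each full iteration sweeps the subsets in ``partition.order``; per
    subset the loop forward-projects, forms the residual, backprojects
    the sensitivity-normalized correction and multiplies it into the
    image.  When ``truth`` is given, the relative RMSE against it is
    appended to ``error_history`` after every full iteration.
    """
    if config is None:
        config = ReconConfig()
    yv = y.values if isinstance(y, Sinogram) else np.asarray(y, float).ravel()
    if yv.size != A.n_rays:
        raise ValueError("sinogram length does not match the system matrix")
    if np.any(yv < 0):
        raise ValueError("sinogram must be non-negative")
    if partition.n_angles != A.geometry.n_angles:
        raise PartitionError("partition does not cover the geometry's angles")

    nr, nc = A.image_shape
    if initial is None:
        start = np.ones((nr, nc))
    else:
        start = initial.values if isinstance(initial, ImageGrid) else initial
        start = np.array(start, dtype=float)
        if start.shape != (nr, nc):
            raise ValueError("initial image shape mismatch")
        if np.any(start < 0):
            raise ValueError("initial image must be non-negative")
    state = ReconState(image=ImageGrid(start, pixel_size=A.pixel_size))
    g = state.image.values.ravel()

    # cache per-subset row blocks and sensitivities once
    sub_mats, sub_y, sub_sens = [], [], []
    for m in partition.order:
        rows = A.rays_for_angles(partition.subsets[m])
        sub = A.weights[rows]
        sub_mats.append(sub)
        sub_y.append(yv[rows])
        sub_sens.append(np.asarray(sub.sum(axis=0)).ravel())

    eps = config.epsilon
    for _ in range(config.n_iterations):
        for sub, ym, sens in zip(sub_mats, sub_y, sub_sens):
            yhat = sub @ g
            r = ym / np.maximum(yhat, eps)
            c = _correction_kernel(sub, r, sens)
            g *= c
            state.sub_iterations_done += 1
        state.k += 1
        if truth is not None:
            state.error_history.append(reconstruction_error(state.image, truth))
        if track_loglik:
            state.loglik_history.append(
                poisson_log_likelihood(yv, A, g.reshape(nr, nc), eps)
            )
    state.image.values = g.reshape(nr, nc)
    return state


def mlem_reconstruct(
    y: Sinogram | np.ndarray,
    A: SystemMatrix,
    config: ReconConfig | None = None,
    truth: ImageGrid | np.ndarray | None = None,
    track_loglik: bool = True,
    initial: ImageGrid | np.ndarray | None = None,
) -> ReconState:
    """MLEM: OSEM with the single-subset (all views at once) partition."""
    n_angles = A.geometry.n_angles
    partition = partition_subsets(n_angles, n_angles, strategy="sequential")
    return osem_reconstruct(
        y,
        A,
        partition,
        config=config,
        truth=truth,
        track_loglik=track_loglik,
        initial=initial,
    )
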