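"""Self-organizing maps over daily time series, in three variants.

``euclidean``
    The classic Kohonen SOM: best-matching unit (BMU) by Euclidean distance,
    weights nudged toward the input timestamp-by-timestamp.
``dtw_match``
    BMU chosen by DTW distance, but the weight update still uses timestamp
    alignment — the halfway design of earlier DTW-SOM hybrids.
``dtw_full``
    BMU by DTW distance *and* the update applied along the DTW warping path:
    each aligned pair ``(t, t_bar)`` contributes a convex combination of the
    neuron value at ``t`` and the input value at ``t_bar``, placed at a
    pseudo-timestamp between the two, and the resulting irregular point set
    is resampled back onto the integer grid.  This is what lets a trained
    neuron keep a sharp peak that recurs at slightly different clock times
    across days, where timestamp averaging would smear it flat.

All three update rules are convex (effective step ``eps * h`` in [0, 1]), so
weights never leave the data range; the DTW resampling is linear
interpolation, which cannot extrapolate either.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dtwsom.dtw import compute_dtw

__all__ = [
    "SomGrid",
    "TrainConfig",
    "Assignment",
    "init_grid",
    "find_bmu",
    "neighborhood_weight",
    "update_euclidean",
    "update_dtw",
    "aligned_update",
    "train",
]

logger = logging.getLogger(__name__)

VARIANTS = ("euclidean", "dtw_match", "dtw_full")


@dataclass
class SomGrid:
    """An R-by-C lattice of neurons, each holding a length-T weight vector.

    ``weights`` has shape ``(R*C, T)`` in row-major neuron order;
    ``positions`` holds each neuron's (row, col) lattice coordinates.
    """

    rows: int
    cols: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("SomGrid: rows and cols must be positive")
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape[0] != self.rows * self.cols:
            raise ValueError("SomGrid: weights must have rows*cols rows")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("SomGrid: weights must be finite")

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    @property
    def positions(self) -> np.ndarray:
        """(R*C, 2) array of (row, col) per neuron, row-major."""
        r, c = np.divmod(np.arange(self.n_neurons), self.cols)
        return np.column_stack([r, c])

    def position(self, index: int) -> tuple[int, int]:
        return divmod(index, self.cols)


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    ``epsilon_schedule`` and ``sigma_schedule`` are (start, end) pairs decayed
    exponentially over the run; ``sigma_schedule=None`` resolves to
    ``(max(R, C) / 2, 0.2)`` at train time — the kernel starts wide enough to
    order the whole lattice and ends narrow enough that late training is
    effectively winner-only (at sigma 0.2 the kernel weight of even the
    nearest neighbour falls below any practical cutoff), so each neuron's
    weights settle on its own cluster instead of a neighbour-biased blend.  ``kernel_space`` selects whether
    the neighbourhood kernel decays with lattice distance to the BMU
    (standard SOM, preserves 2-D topology) or with DTW distance between the
    neurons' weight vectors.  ``band`` is the Sakoe-Chiba half-width in
    samples for every DTW call; ``None`` disables the constraint.
    """

    variant: str = "dtw_full"
    iterations: int = 3000
    epsilon_schedule: tuple[float, float] = (0.5, 0.01)
    sigma_schedule: tuple[float, float] | None = None
    kernel_space: str = "lattice"
    band: int | None = 60
    init: str = "sample"
    seed: int = 0
    kernel_cutoff: float = 1e-3

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"TrainConfig.variant must be one of {VARIANTS}")
        if self.iterations < 1:
            raise ValueError("TrainConfig.iterations must be >= 1")
        e0, e1 = self.epsilon_schedule
        if not (0 < e1 <= e0 <= 1):
            raise ValueError("TrainConfig.epsilon_schedule needs 0 < end <= start <= 1")
        if self.sigma_schedule is not None:
            s0, s1 = self.sigma_schedule
            if s0 <= 0 or s1 <= 0:
                raise ValueError("TrainConfig.sigma_schedule values must be > 0")
        if self.kernel_space not in ("lattice", "dtw_weightspace"):
            raise ValueError("TrainConfig.kernel_space must be 'lattice' or "
                             "'dtw_weightspace'")
        if self.init not in ("sample", "random"):
            raise ValueError("TrainConfig.init must be 'sample' or 'random'")
        if self.kernel_cutoff <= 0:
            raise ValueError("TrainConfig.kernel_cutoff must be > 0")


@dataclass
class Assignment:
    """Final mapping of every input series to its best-matching neuron."""

    neuron: np.ndarray    # flat row-major neuron index per input
    row: np.ndarray
    col: np.ndarray
    distance: np.ndarray  # distance to the BMU under the training metric

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "day": np.arange(self.neuron.size),
            "neuron": self.neuron,
            "row": self.row,
            "col": self.col,
            "distance": self.distance,
        })


def _as_matrix(dataset) -> np.ndarray:
    X = np.asarray(dataset, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("dataset must be a non-empty (n_series, T) array")
    if not np.all(np.isfinite(X)):
        raise ValueError("dataset must be finite (no missing values)")
    return X


def init_grid(rows: int, cols: int, dataset, config: TrainConfig) -> SomGrid:
    """Seeded weight initialization.

    ``init='sample'`` draws rows*cols distinct input series when possible
    (with replacement, and a logged warning, when the dataset is smaller);
    ``init='random'`` draws i.i.d. Uniform over the dataset's [min, max].
    """
    config.validate()
    X = _as_matrix(dataset)
    rng = np.random.default_rng(config.seed)
    n_neurons = rows * cols
    if config.init == "sample":
        if n_neurons > X.shape[0]:
            logger.warning(
                "init_grid: %d neurons > %d inputs; sampling with replacement",
                n_neurons, X.shape[0])
            idx = rng.integers(0, X.shape[0], size=n_neurons)
        else:
            idx = rng.choice(X.shape[0], size=n_neurons, replace=False)
        weights = X[idx].copy()
    else:
        lo, hi = X.min(), X.max()
        weights = rng.uniform(lo, hi, size=(n_neurons, X.shape[1]))
    return SomGrid(rows=rows, cols=cols, weights=weights)


def find_bmu(grid: SomGrid, x, variant: str = "dtw_full",
             band: int | None = 60) -> tuple[int, float]:
    """Best-matching unit: argmin over neurons of the variant's metric.

    Euclidean for ``variant='euclidean'``, DTW distance otherwise.  Ties go
    to the lowest row-major neuron index.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] != grid.weights.shape[1]:
        raise ValueError("find_bmu: input length does not match neuron weights")
    if variant == "euclidean":
        d = np.linalg.norm(grid.weights - x, axis=1)
    else:
        d = np.array([compute_dtw(w, x, band=band).distance
                      for w in grid.weights])
    best = int(np.argmin(d))
    return best, float(d[best])


def neighborhood_weight(grid: SomGrid, r: int, s: int, sigma: float,
                        kernel_space: str = "lattice",
                        band: int | None = 60) -> float:
    """Gaussian distance-decay kernel ``h = exp(-delta^2 / (2 sigma^2))``.

    ``delta`` is the lattice Euclidean distance between the positions of
    neuron ``r`` and BMU ``s`` (``kernel_space='lattice'``) or the DTW
    distance between their weight vectors (``'dtw_weightspace'``).
    ``h(r=s) = 1`` in either space.
    """
    if sigma <= 0:
        raise ValueError("neighborhood_weight: sigma must be > 0")
    if r == s:
        return 1.0
    if kernel_space == "lattice":
        pr, ps = grid.position(r), grid.position(s)
        delta = float(np.hypot(pr[0] - ps[0], pr[1] - ps[1]))
    else:
        delta = compute_dtw(grid.weights[r], grid.weights[s],
                            band=band).distance
    return float(np.exp(-(delta ** 2) / (2.0 * sigma ** 2)))


def update_euclidean(W, x, epsilon: float, h: float) -> np.ndarray:
    """Timestamp-aligned update ``W + eps*h*(x - W)``."""
    W = np.asarray(W, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if W.shape != x.shape:
        raise ValueError("update_euclidean: length mismatch")
    eh = epsilon * h
    if not 0.0 <= eh <= 1.0:
        raise ValueError("update_euclidean: epsilon*h must lie in [0, 1]")
    return W + eh * (x - W)


def aligned_update(W, x, eps_h: float, path: np.ndarray) -> np.ndarray:
    """DTW-aligned update along a given warping path.

    For each path pair ``(t, t_bar)`` the new value
    ``v = W[t] + eps_h * (x[t_bar] - W[t])`` is placed at the pseudo-timestamp
    ``t_tilde = t + eps_h * (t_bar - t)`` — value and timestamp both move
    toward the aligned input point by the same fraction, so ``eps_h = 0`` is
    the identity and ``eps_h = 1`` reproduces ``x`` exactly.  Many-to-one
    alignments produce duplicate pseudo-timestamps, which are averaged; the
    piecewise-linear curve through the sorted ``(t_tilde, v)`` points is then
    resampled onto the integer grid ``0..T-1`` (the boundary path pairs pin
    ``t_tilde = 0`` and ``T-1``, so this never extrapolates).
    """
    W = np.asarray(W, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if not 0.0 <= eps_h <= 1.0:
        raise ValueError("aligned_update: epsilon*h must lie in [0, 1]")
    t = path[:, 0].astype(np.float64)
    t_bar = path[:, 1].astype(np.float64)
    v = W[path[:, 0]] + eps_h * (x[path[:, 1]] - W[path[:, 0]])
    t_tilde = t + eps_h * (t_bar - t)
    # collapse duplicate pseudo-timestamps (many-to-one alignment) by averaging
    uniq, inverse = np.unique(t_tilde, return_inverse=True)
    sums = np.bincount(inverse, weights=v)
    counts = np.bincount(inverse)
    v_uniq = sums / counts
    return np.interp(np.arange(W.shape[0], dtype=np.float64), uniq, v_uniq)


def update_dtw(W, x, epsilon: float, h: float,
               band: int | None = 60) -> np.ndarray:
    """DTW-aligned update: compute the warping path W->x, then apply
    :func:`aligned_update` along it."""
    W = np.asarray(W, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    eh = epsilon * h
    if not 0.0 <= eh <= 1.0:
        raise ValueError("update_dtw: epsilon*h must lie in [0, 1]")
    result = compute_dtw(W, x, band=band)
    return aligned_update(W, x, eh, result.path)


def _exp_schedule(start: float, end: float, iterations: int) -> np.ndarray:
    if iterations == 1:
        return np.array([start])
    frac = np.arange(iterations) / (iterations - 1)
    return start * (end / start) ** frac


def train(dataset, rows: int, cols: int, config: TrainConfig
          ) -> tuple[SomGrid, Assignment, np.ndarray]:
    """Online competitive training.

    One input per iteration (shuffled cycling through the dataset, seeded);
    find the BMU under the variant's metric; every neuron whose kernel weight
    exceeds ``kernel_cutoff`` is updated — timestamp-aligned for
    ``euclidean``/``dtw_match``, DTW-aligned for ``dtw_full``, each updated
    neuron using its own warping path to the input.  Learning rate and kernel
    width decay exponentially over the run.

    Returns the trained grid, the final assignment (recomputed with the
    trained weights), and a per-iteration trace of the drawn sample's
    Euclidean distance to its BMU (before the update) for convergence checks.
    """
    config.validate()
    X = _as_matrix(dataset)
    n, T = X.shape
    grid = init_grid(rows, cols, X, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    eps = _exp_schedule(*config.epsilon_schedule, config.iterations)
    sigma_schedule = config.sigma_schedule or (max(rows, cols) / 2.0, 0.2)
    sig = _exp_schedule(*sigma_schedule, config.iterations)

    order = np.empty(0, dtype=np.intp)
    trace = np.empty(config.iterations)
    for it in range(config.iterations):
        if it % n == 0:
            order = rng.permutation(n)
        x = X[order[it % n]]
        bmu, _ = find_bmu(grid, x, variant=config.variant, band=config.band)
        trace[it] = float(np.linalg.norm(grid.weights[bmu] - x))
        for r in range(grid.n_neurons):
            h = neighborhood_weight(grid, r, bmu, sig[it],
                                    kernel_space=config.kernel_space,
                                    band=config.band)
            if h < config.kernel_cutoff:
                continue
            if config.variant == "dtw_full":
                grid.weights[r] = update_dtw(grid.weights[r], x, eps[it], h,
                                             band=config.band)
            else:
                grid.weights[r] = update_euclidean(grid.weights[r], x,
                                                   eps[it], h)

    assignment = assign(grid, X, variant=config.variant, band=config.band)
    return grid, assignment, trace


def assign(grid: SomGrid, dataset, variant: str = "dtw_full",
           band: int | None = 60) -> Assignment:
    """Map every input to its BMU under the given metric."""
    X = _as_matrix(dataset)
    neuron = np.empty(X.shape[0], dtype=np.intp)
    dist = np.empty(X.shape[0])
    for i, x in enumerate(X):
        neuron[i], dist[i] = find_bmu(grid, x, variant=variant, band=band)
    row, col = np.divmod(neuron, grid.cols)
    return Assignment(neuron=neuron, row=row, col=col, distance=dist)
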