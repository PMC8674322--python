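"""Comparison metrics for trained maps.

Quantization error, grid-size tuning curve, Moore-neighbour weight distance,
season-stratified cluster entropy, and the per-neuron outcome-fraction
overlay.  Quantization error is always the Euclidean per-series-norm RMS —
regardless of which metric trained the map — so the three training variants
are directly comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dtwsom.som import Assignment, SomGrid, TrainConfig, train

__all__ = [
    "quantization_error",
    "tune_grid_size",
    "moore_neighbor_distance",
    "cluster_entropy",
    "outcome_fraction",
]


def quantization_error(grid: SomGrid, dataset, assignment: Assignment,
                       per_timestamp: bool = False) -> float:
    """Root-mean-square distance from each input to its BMU's weights.

    ``QE = sqrt(mean_i ||x_i - W_bmu(i)||^2)`` with the full-series Euclidean
    norm.  ``per_timestamp=True`` divides each squared norm by the series
    length, giving a per-minute RMSE instead of a per-series norm.
    """
    X = np.asarray(dataset, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("quantization_error: dataset must be non-empty 2-D")
    if assignment.neuron.size != X.shape[0]:
        raise ValueError("quantization_error: assignment does not cover dataset")
    resid = X - grid.weights[assignment.neuron]
    sq = np.sum(resid ** 2, axis=1)
    if per_timestamp:
        sq = sq / X.shape[1]
    return float(np.sqrt(np.mean(sq)))


def tune_grid_size(dataset, sizes, config: TrainConfig) -> pd.DataFrame:
    """Train one map per (rows, cols) size and report the final QE.

    Same seed policy for every size.  The returned curve carries an
    ``elbow`` flag at the maximum-curvature point (discrete second
    difference of QE against neuron count) — a suggestion only; pick the
    inflection by eye for real analyses.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("tune_grid_size: sizes must be non-empty")
    rows = []
    for (r, c) in sizes:
        grid, assignment, _ = train(dataset, r, c, config)
        qe = quantization_error(grid, dataset, assignment)
        rows.append({"rows": r, "cols": c, "n_neurons": r * c, "qe": qe})
    curve = pd.DataFrame(rows).sort_values("n_neurons").reset_index(drop=True)
    curve["elbow"] = False
    if len(curve) >= 3:
        curvature = np.abs(np.diff(curve["qe"].to_numpy(), 2))
        curve.loc[int(np.argmax(curvature)) + 1, "elbow"] = True
    return curve


def moore_neighbor_distance(grid: SomGrid) -> float:
    """Mean Euclidean weight distance between lattice Moore neighbours.

    For each neuron, average the distance to each of its existing eight
    surrounding neighbours (edge neurons have fewer); return the mean over
    neurons.  Lower values indicate smoother topology — neighbouring neurons
    encode more similar diurnal shapes.
    """
    if grid.n_neurons < 2:
        raise ValueError("moore_neighbor_distance: needs at least 2 neurons")
    per_neuron = []
    for idx in range(grid.n_neurons):
        r, c = grid.position(idx)
        dists = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < grid.rows and 0 <= cc < grid.cols:
                    other = rr * grid.cols + cc
                    dists.append(np.linalg.norm(
                        grid.weights[idx] - grid.weights[other]))
        per_neuron.append(np.mean(dists))
    return float(np.mean(per_neuron))


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def cluster_entropy(assignment: Assignment, labels) -> tuple[float, float]:
    """Label purity of the clustering, as Shannon entropy in bits.

    Returns ``(entropy_weighted, entropy_joint)``:

    - weighted: sum over neurons of (occupancy fraction) x (entropy of the
      label distribution within the neuron); 0 when every neuron is pure,
      bounded by log2(#labels).
    - joint: entropy of the joint (neuron, label) distribution, bounded by
      log2(#neurons x #labels).  Reported alongside because purity summaries
      in the literature are sometimes on this scale.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != assignment.neuron.size:
        raise ValueError("cluster_entropy: one label per assigned input required")
    if labels.dtype == object and any(l is None for l in labels):
        raise ValueError("cluster_entropy: missing labels")
    df = pd.DataFrame({"neuron": assignment.neuron, "label": labels})
    M = len(df)
    counts = df.groupby(["neuron", "label"], observed=True).size()
    joint = _entropy_bits(counts.to_numpy() / M)
    weighted = 0.0
    for _, grp in counts.groupby(level="neuron"):
        m = grp.sum()
        weighted += (m / M) * _entropy_bits(grp.to_numpy() / m)
    return weighted, joint


def outcome_fraction(assignment: Assignment, outcomes,
                     n_neurons: int | None = None) -> pd.DataFrame:
    """Per-neuron fraction of outcome-positive days among outcome-known days.

    ``outcomes`` is one entry per assigned input: 0, 1, or missing (NaN /
    pd.NA) when the day had no outcome record.  Per neuron: denominator =
    assigned days with a known outcome, numerator = those with outcome 1;
    the fraction is left missing (not 0) when the denominator is 0.
    """
    outcomes = pd.array(outcomes, dtype="Int64")
    if len(outcomes) != assignment.neuron.size:
        raise ValueError("outcome_fraction: one outcome entry per input required")
    frame = pd.DataFrame({"neuron": assignment.neuron, "outcome": outcomes})
    if n_neurons is None:
        n_neurons = int(assignment.neuron.max()) + 1 if len(frame) else 0
    rows = []
    for n in range(n_neurons):
        grp = frame.loc[frame["neuron"] == n, "outcome"]
        known = grp.dropna()
        den = len(known)
        num = int(known.sum()) if den else 0
        rows.append({
            "neuron": n,
            "numerator": num,
            "denominator": den,
            "fraction": num / den if den else np.nan,
        })
    return pd.DataFrame(rows, columns=["neuron", "numerator", "denominator",
                                       "fraction"])
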