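"""SOM variants: BMU search, kernel, the two update rules, training loop."""

import numpy as np
import pytest

from conftest import warped_impulse_dataset
from dtwsom.evaluate import quantization_error
from dtwsom.som import (
    SomGrid,
    TrainConfig,
    aligned_update,
    find_bmu,
    init_grid,
    neighborhood_weight,
    train,
    update_dtw,
    update_euclidean,
)


def cfg(**kw):
    return TrainConfig(**kw)


class TestInitGrid:
    X = np.arange(20.0).reshape(5, 4)

    def test_seeded_reruns_identical(self):
        g1 = init_grid(2, 2, self.X, cfg(seed=11))
        g2 = init_grid(2, 2, self.X, cfg(seed=11))
        np.testing.assert_array_equal(g1.weights, g2.weights)

    def test_sample_init_draws_distinct_inputs(self):
        g = init_grid(2, 2, self.X, cfg(init="sample", seed=0))
        rows = {tuple(w) for w in g.weights}
        assert len(rows) == 4
        assert rows <= {tuple(x) for x in self.X}

    def test_sample_init_identical_dataset(self):
        X = np.tile([1.0, 2.0, 3.0], (6, 1))
        g = init_grid(2, 2, X, cfg(seed=0))
        np.testing.assert_array_equal(g.weights, np.tile([1.0, 2.0, 3.0], (4, 1)))

    def test_oversized_grid_samples_with_replacement(self, caplog):
        g = init_grid(3, 3, self.X, cfg(seed=0))
        assert g.weights.shape == (9, 4)

    def test_random_init_within_data_range(self):
        g = init_grid(4, 4, self.X, cfg(init="random", seed=2))
        assert g.weights.min() >= self.X.min()
        assert g.weights.max() <= self.X.max()


class TestFindBmu:
    def test_exact_match_distance_zero(self):
        grid = SomGrid(1, 2, np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert find_bmu(grid, [3.0, 4.0], "euclidean") == (1, 0.0)
        assert find_bmu(grid, [3.0, 4.0], "dtw_full", band=None) == (1, 0.0)

    def test_metrics_disagree_on_shifted_impulse(self):
        """DTW sees the shifted impulse as the same shape; Euclidean prefers
        the flat neuron."""
        grid = SomGrid(1, 2, np.array([[0, 1, 0, 0],
                                       [0.25, 0.25, 0.25, 0.25]]))
        x = [0.0, 0.0, 1.0, 0.0]
        n_dtw, d_dtw = find_bmu(grid, x, "dtw_match", band=None)
        n_euc, d_euc = find_bmu(grid, x, "euclidean")
        assert (n_dtw, d_dtw) == (0, 0.0)
        assert n_euc == 1
        assert d_euc == pytest.approx(np.sqrt(3 * 0.25 ** 2 + 0.75 ** 2))

    def test_tie_breaks_to_lowest_index(self):
        grid = SomGrid(1, 2, np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert find_bmu(grid, [0.0, 0.0], "euclidean")[0] == 0

    def test_length_mismatch_rejected(self):
        grid = SomGrid(1, 1, np.zeros((1, 4)))
        with pytest.raises(ValueError, match="length"):
            find_bmu(grid, [1.0, 2.0], "euclidean")


class TestNeighborhoodWeight:
    grid = SomGrid(2, 2, np.zeros((4, 3)))

    def test_bmu_weight_is_one(self):
        assert neighborhood_weight(self.grid, 2, 2, sigma=0.7) == 1.0

    def test_lattice_neighbor_gaussian(self):
        assert neighborhood_weight(self.grid, 0, 1, sigma=1.0) == (
            pytest.approx(np.exp(-0.5)))

    def test_small_sigma_vanishes(self):
        assert neighborhood_weight(self.grid, 0, 3, sigma=1e-4) < 1e-300

    def test_weightspace_kernel_uses_dtw(self):
        grid = SomGrid(1, 2, np.array([[0, 0, 1, 0], [0, 1, 0, 0.0]]))
        # shifted impulses: DTW distance 0 -> kernel weight 1 despite
        # being far apart element-wise
        h = neighborhood_weight(grid, 0, 1, sigma=0.5,
                                kernel_space="dtw_weightspace", band=None)
        assert h == pytest.approx(1.0)


class TestUpdateRules:
    def test_euclidean_formula(self):
        np.testing.assert_allclose(
            update_euclidean([0.0, 0.0], [1.0, 1.0], 0.5, 1.0), [0.5, 0.5])

    def test_zero_step_identity(self):
        W = np.array([0.2, 0.8, 0.1])
        np.testing.assert_array_equal(update_euclidean(W, [1, 1, 1.0], 0.0, 1.0), W)
        np.testing.assert_allclose(update_dtw(W, [1, 1, 1.0], 0.0, 1.0, None), W)

    def test_full_step_reproduces_input(self):
        W = np.array([0.0, 1.0, 0.0, 0.0])
        x = np.array([0.0, 0.0, 1.0, 0.0])
        np.testing.assert_array_equal(update_euclidean(W, x, 1.0, 1.0), x)
        np.testing.assert_allclose(update_dtw(W, x, 1.0, 1.0, None), x)

    def test_dtw_diagonal_path_equals_euclidean(self, rng):
        """With a forced elementwise alignment (band 0) the DTW-aligned
        update degenerates to the timestamp update."""
        for _ in range(20):
            W, x = rng.normal(size=12), rng.normal(size=12)
            np.testing.assert_allclose(
                update_dtw(W, x, 0.4, 0.6, band=0),
                update_euclidean(W, x, 0.4, 0.6), atol=1e-12)

    def test_hand_traced_aligned_update(self):
        """Zero-cost path on the shifted impulse pair: values move halfway
        and land at half-shifted pseudo-timestamps, so the resampled grid
        sees the plateau [0, .5, .5, 0]."""
        W = np.array([0.0, 1.0, 0.0, 0.0])
        x = np.array([0.0, 0.0, 1.0, 0.0])
        path = np.array([[0, 0], [0, 1], [1, 2], [2, 3], [3, 3]])
        np.testing.assert_allclose(aligned_update(W, x, 0.5, path),
                                   [0.0, 0.5, 0.5, 0.0])

    def test_many_to_one_duplicates_averaged(self):
        # full step: t_tilde = t_bar, so both pairs hitting t_bar=1 average
        W = np.array([0.0, 4.0, 2.0])
        x = np.array([0.0, 1.0, 2.0])
        path = np.array([[0, 0], [1, 1], [2, 1], [2, 2]])
        out = aligned_update(W, x, 1.0, path)
        np.testing.assert_allclose(out, x)

    def test_step_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="epsilon"):
            update_euclidean([0.0], [1.0], 2.0, 1.0)
        with pytest.raises(ValueError, match="epsilon"):
            update_dtw([0.0, 1.0], [1.0, 0.0], 2.0, 1.0, None)


class TestTrain:
    def test_identical_series_collapse(self):
        X = np.tile([0.2, 0.5, 0.3], (8, 1))
        for variant in ("euclidean", "dtw_match", "dtw_full"):
            grid, assignment, trace = train(
                X, 1, 1, cfg(variant=variant, iterations=500, band=None, seed=0))
            assert quantization_error(grid, X, assignment) < 1e-3

    def test_two_constant_prototypes_recovered(self):
        X = np.vstack([np.full((10, 20), 0.2), np.full((10, 20), 0.8)])
        grid, assignment, _ = train(
            X, 1, 2, cfg(variant="dtw_full", iterations=500, band=None, seed=3))
        levels = sorted(grid.weights.mean(axis=1))
        assert abs(levels[0] - 0.2) < 0.05
        assert abs(levels[1] - 0.8) < 0.05
        assert set(assignment.neuron) == {0, 1}

    def test_weights_stay_in_data_range(self):
        X, _ = warped_impulse_dataset(seed=5, n_days=15, T=48, warp=6)
        lo, hi = X.min(), X.max()
        for variant in ("euclidean", "dtw_full"):
            grid, _, _ = train(X, 2, 2, cfg(variant=variant, iterations=120,
                                            band=10, seed=1))
            assert grid.weights.min() >= lo - 1e-9
            assert grid.weights.max() <= hi + 1e-9

    def test_band0_dtw_full_equals_euclidean_training(self):
        """When every DTW path is forced diagonal the full DTW variant must
        reproduce Euclidean training exactly (single-neuron grid, so BMU
        choice cannot differ between metrics)."""
        X, _ = warped_impulse_dataset(seed=2, n_days=10, T=32, warp=4)
        g_dtw, _, _ = train(X, 1, 1, cfg(variant="dtw_full", iterations=80,
                                         band=0, seed=7))
        g_euc, _, _ = train(X, 1, 1, cfg(variant="euclidean", iterations=80,
                                         seed=7))
        np.testing.assert_allclose(g_dtw.weights, g_euc.weights, atol=1e-9)

    def test_seeded_training_deterministic(self):
        X, _ = warped_impulse_dataset(seed=3, n_days=10, T=32, warp=4)
        g1, a1, t1 = train(X, 2, 1, cfg(iterations=50, band=8, seed=9))
        g2, a2, t2 = train(X, 2, 1, cfg(iterations=50, band=8, seed=9))
        np.testing.assert_array_equal(g1.weights, g2.weights)
        np.testing.assert_array_equal(a1.neuron, a2.neuron)
        np.testing.assert_array_equal(t1, t2)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            train(np.empty((0, 5)), 1, 1, cfg())

    def test_dtw_full_retains_peak_euclidean_flattens(self):
        """Impulse prototype under random warps: DTW-aligned training keeps
        the peak; timestamp averaging smears it."""
        X, proto = warped_impulse_dataset(seed=0)
        peak = proto.max()
        g_dtw, _, _ = train(X, 1, 1, cfg(variant="dtw_full", iterations=200,
                                         band=20, seed=0))
        g_euc, _, _ = train(X, 1, 1, cfg(variant="euclidean", iterations=200,
                                         seed=0))
        assert g_dtw.weights.max() >= 0.8 * peak
        assert g_euc.weights.max() < 0.8 * peak


@pytest.mark.parametrize("field, value", [
    ("variant", "manhattan"),
    ("iterations", 0),
    ("epsilon_schedule", (0.01, 0.5)),
    ("kernel_space", "spectral"),
    ("kernel_cutoff", 0.0),
])
def test_invalid_train_config(field, value):
    with pytest.raises(ValueError):
        TrainConfig(**{field: value}).validate()
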