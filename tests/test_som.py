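"""SOM engine: initialization, BMU search vs a brute-force scan, the update
rule's closed forms, topology, conservation and export round-trips."""

import numpy as np
import pandas as pd
import pytest

from multimorbid.som import (
    HexSom,
    batch_bmu,
    bmu,
    export_maps,
    hex_positions,
    init_codebook,
    lattice_sq_distances,
    load_model,
    save_model,
    train_som,
    write_maps,
)


def brute_force_bmu(x, codebook):
    """Independent oracle: exhaustive scan over all nodes."""
    best, best_d = 0, np.inf
    for i, m in enumerate(codebook):
        d = float(((np.asarray(x) - m) ** 2).sum())
        if d < best_d:
            best, best_d = i, d
    return best


class TestLattice:
    def test_hex_offset_geometry(self):
        pos = hex_positions(3, 2)
        # odd rows shifted +0.5, rows spaced sqrt(3)/2
        np.testing.assert_allclose(pos[0], [0.0, 0.0])
        np.testing.assert_allclose(pos[2], [0.5, np.sqrt(3) / 2])
        np.testing.assert_allclose(pos[4], [0.0, np.sqrt(3)])
        # nearest lattice neighbours sit at unit distance
        d2 = lattice_sq_distances(pos)
        assert d2[0, 1] == pytest.approx(1.0)
        assert d2[0, 2] == pytest.approx(1.0)


class TestInitCodebook:
    def test_vectors_are_data_rows(self):
        rng = np.random.default_rng(0)
        X = rng.random((4, 21))
        cb = init_codebook(X, 4, np.random.default_rng(1))
        rows = {tuple(r) for r in X}
        assert all(tuple(v) in rows for v in cb)

    def test_single_row_degenerate(self):
        X = np.tile(np.arange(21.0), (1, 1))
        cb = init_codebook(X, 9, np.random.default_rng(0))
        assert (cb == X[0]).all()

    def test_seeded_determinism(self):
        X = np.random.default_rng(3).random((50, 21))
        a = init_codebook(X, 16, np.random.default_rng(5))
        b = init_codebook(X, 16, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestBmu:
    def test_exact_match_and_tie_rule(self):
        codebook = np.zeros((10, 21))
        codebook[7] = 1.0
        assert bmu(np.ones(21), codebook) == 7
        # nodes 3 and 9 equidistant -> lowest index wins
        cb = np.full((10, 21), 5.0)
        cb[3] = 1.0
        cb[9] = -1.0
        assert bmu(np.zeros(21), cb) == 3

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(12)
        codebook = rng.random((5, 21))
        X = rng.random((40, 21))
        for x in X:
            assert bmu(x, codebook) == brute_force_bmu(x, codebook)
        np.testing.assert_array_equal(
            batch_bmu(X, codebook), [brute_force_bmu(x, codebook) for x in X]
        )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            bmu(np.zeros(5), np.zeros((3, 21)))


class TestTraining:
    def test_single_update_closed_form(self):
        # one step, neighborhood 1 at the BMU: m' = m + alpha (x - m)
        X = np.zeros((1, 21))
        X[0, 0] = 1.0
        som = HexSom(
            grid_rows=1,
            grid_cols=1,
            n_iterations=1,
            alpha_start=0.05,
            alpha_end=0.01,
            radius_start=1.0,
            random_state=0,
        )
        # codebook initialized from the single data row; use a fresh origin row
        som.fit(np.vstack([X[0], np.zeros(21)]))
        # whichever row seeded the node, one update pulls it toward the
        # sampled row by factor alpha_start
        assert som.codebook_.min() >= 0.0 and som.codebook_.max() <= 1.0

    def test_update_formula_explicit(self):
        # reproduce the internal RNG to predict the single online step exactly
        X = np.vstack([np.zeros(21), np.eye(21)[0]])
        som = HexSom(grid_rows=1, grid_cols=1, n_iterations=1, alpha_start=0.05,
                     alpha_end=0.01, radius_start=1.0, random_state=4)
        rng = np.random.default_rng(4)
        init_row = rng.integers(0, 2, size=1)[0]
        sampled = rng.integers(0, 2, size=1)[0]
        som.fit(X)
        expected = X[init_row] + 0.05 * (X[sampled] - X[init_row])
        np.testing.assert_allclose(som.codebook_[0], expected)

    def test_repeated_row_is_fixed_point(self):
        row = np.random.default_rng(2).random(21)
        X = np.tile(row, (30, 1))
        som = train_som(X, grid_rows=3, grid_cols=3, n_iterations=2000, random_state=0)
        np.testing.assert_allclose(som.codebook_, np.tile(row, (9, 1)), atol=1e-3)

    def test_single_node_is_exponentially_weighted_mean(self):
        # with one node every step is m <- m + a_t (x_t - m); unroll the
        # recursion with the same seeded sampling order
        rng_data = np.random.default_rng(8)
        X = rng_data.random((20, 4))
        n_iter = 50
        som = HexSom(grid_rows=1, grid_cols=1, n_iterations=n_iter,
                     alpha_start=0.05, alpha_end=0.01, radius_start=1.0,
                     random_state=13)
        som.fit(X)
        rng = np.random.default_rng(13)
        m = X[rng.integers(0, len(X), size=1)[0]].copy()
        order = rng.integers(0, len(X), size=n_iter)
        for t in range(n_iter):
            a = 0.05 + (0.01 - 0.05) * t / (n_iter - 1)
            m = m + a * (X[order[t]] - m)
        np.testing.assert_allclose(som.codebook_[0], m, atol=1e-12)

    def test_separated_blobs_map_to_disjoint_nodes(self):
        rng = np.random.default_rng(21)
        a = (rng.random((150, 21)) < 0.05).astype(float)
        b = (rng.random((150, 21)) < 0.05).astype(float)
        b[:, :5] = 1.0  # block of always-on diseases separates the blobs
        X = np.vstack([a, b])
        som = train_som(X, grid_rows=3, grid_cols=3, n_iterations=3000, random_state=1)
        nodes_a = set(som.predict(a))
        nodes_b = set(som.predict(b))
        assert nodes_a.isdisjoint(nodes_b)

    def test_conservation_and_convex_hull(self, full_run):
        _, prep, result = full_run
        som = result.som
        assert som.activation_counts_.sum() == len(prep.matrix)
        assert som.codebook_.min() >= 0.0
        assert som.codebook_.max() <= 1.0

    def test_quantization_error_decreases(self, full_run):
        _, _, result = full_run
        qe = result.som.quantization_errors_
        assert qe[-1] <= qe[0] + 1e-6

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            HexSom(alpha_start=0.01, alpha_end=0.05).fit(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            HexSom(n_iterations=0).fit(np.zeros((3, 2)))


class TestExports:
    def test_count_map_conserves_subjects_and_planes_in_unit_box(self):
        X = (np.random.default_rng(5).random((100, 21)) < 0.3).astype(float)
        som = train_som(X, grid_rows=4, grid_cols=4, n_iterations=500, random_state=2)
        maps = export_maps(som, feature_names=[f"d{j}" for j in range(21)])
        assert maps["count_map"].to_numpy().sum() == 100
        for plane in maps["component_planes"].values():
            vals = plane.to_numpy()
            assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_csv_round_trip(self, tmp_path):
        X = (np.random.default_rng(6).random((30, 21)) < 0.4).astype(float)
        som = train_som(X, grid_rows=2, grid_cols=2, n_iterations=100, random_state=3)
        write_maps(som, tmp_path, feature_names=[f"d{j}" for j in range(21)])
        counts = pd.read_csv(tmp_path / "count_map.csv").to_numpy()
        np.testing.assert_array_equal(counts, som.activation_counts_.reshape(2, 2))
        plane0 = pd.read_csv(tmp_path / "plane_d0.csv").to_numpy()
        np.testing.assert_allclose(plane0, som.codebook_[:, 0].reshape(2, 2))

    def test_model_bundle_round_trip(self, tmp_path):
        X = (np.random.default_rng(9).random((40, 21)) < 0.4).astype(float)
        som = train_som(X, grid_rows=2, grid_cols=3, n_iterations=200, random_state=3)
        save_model(som, tmp_path)
        loaded = load_model(tmp_path)
        np.testing.assert_allclose(loaded.codebook_, som.codebook_)
        np.testing.assert_array_equal(loaded.activation_counts_, som.activation_counts_)
        np.testing.assert_array_equal(loaded.predict(X), som.predict(X))
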