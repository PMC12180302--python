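"""Hexagonal-lattice self-organizing map (Kohonen network).

Online training: at each iteration one input row is drawn uniformly with
replacement, its best-matching unit (BMU) located by squared Euclidean
distance, and every codebook vector pulled toward the input under a Gaussian
neighborhood on the hexagonal lattice. Learning rate and neighborhood radius
both decay linearly between their start and end values. On binary inputs
every codebook vector is a convex combination of data rows and therefore
stays inside [0, 1]^d.

Defaults follow common practice for survey-scale binary data: a 30×30 grid,
learning rate 0.05 → 0.01 over 20,000 iterations, radius ⅔·max(grid dims)
→ 1.0.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted


def hex_positions(grid_rows: int, grid_cols: int) -> np.ndarray:
    """Node centers of an offset hexagonal lattice (odd rows shifted +0.5,
    row spacing √3/2), as an (n_nodes, 2) array in row-major node order."""
    rows, cols = np.mgrid[0:grid_rows, 0:grid_cols]
    x = cols + 0.5 * (rows % 2)
    y = rows * (np.sqrt(3.0) / 2.0)
    return np.column_stack([x.ravel(), y.ravel()]).astype(float)


def lattice_sq_distances(positions: np.ndarray) -> np.ndarray:
    d = positions[:, None, :] - positions[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


def bmu(x: np.ndarray, codebook: np.ndarray) -> int:
    """Index of the codebook vector nearest to ``x`` (squared Euclidean);
    ties resolve to the lowest node index."""
    x = np.asarray(x, dtype=float)
    if x.shape != (codebook.shape[1],):
        raise ValueError(
            f"input has {x.shape} entries, codebook vectors have {codebook.shape[1]}"
        )
    diff = codebook - x
    return int(np.argmin(np.einsum("ij,ij->i", diff, diff)))


def batch_bmu(X: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    """BMU index per row of ``X`` (first-index tie-break, as in :func:`bmu`)."""
    sq = (
        np.einsum("ij,ij->i", X, X)[:, None]
        - 2.0 * X @ codebook.T
        + np.einsum("ij,ij->i", codebook, codebook)[None, :]
    )
    return np.argmin(sq, axis=1)


def init_codebook(X: np.ndarray, n_nodes: int, rng: np.random.Generator) -> np.ndarray:
    """Seed each node with a data row drawn uniformly with replacement."""
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        raise ValueError("empty data")
    return X[rng.integers(0, len(X), size=n_nodes)].copy()


class HexSom(BaseEstimator, TransformerMixin):
    """Self-organizing map on a hexagonal grid.

    Parameters
    ----------
    grid_rows, grid_cols : int, default 30
        Lattice dimensions; the map has ``grid_rows * grid_cols`` nodes.
    n_iterations : int, default 20_000
        Online training steps (one input presentation each).
    alpha_start, alpha_end : float, defaults 0.05 and 0.01
        Learning rate, linearly interpolated over the iterations.
    radius_start, radius_end : float
        Gaussian neighborhood width σ in lattice units, linearly decayed.
        ``radius_start=None`` uses ⅔·max(grid_rows, grid_cols).
    n_checkpoints : int, default 5
        Number of evenly spaced points (including start and end of training)
        at which the quantization error over the full dataset is recorded.
    random_state : int, default 0
        Seeds codebook initialization and the sampling order.

    Attributes
    ----------
    codebook_ : ndarray of shape (n_nodes, n_features)
    node_positions_ : ndarray of shape (n_nodes, 2)
    activation_counts_ : ndarray of shape (n_nodes,)
        Number of training subjects whose BMU is each node.
    bmu_index_ : ndarray of shape (n_samples,)
        BMU of each training subject (one final pass after training).
    quantization_errors_ : ndarray of shape (n_checkpoints,)
        Mean Euclidean distance of subjects to their BMU at each checkpoint.
    """

    def __init__(
        self,
        grid_rows: int = 30,
        grid_cols: int = 30,
        n_iterations: int = 20_000,
        alpha_start: float = 0.05,
        alpha_end: float = 0.01,
        radius_start: float | None = None,
        radius_end: float = 1.0,
        n_checkpoints: int = 5,
        random_state: int = 0,
    ):
        self.grid_rows = grid_rows
        self.grid_cols = grid_cols
        self.n_iterations = n_iterations
        self.alpha_start = alpha_start
        self.alpha_end = alpha_end
        self.radius_start = radius_start
        self.radius_end = radius_end
        self.n_checkpoints = n_checkpoints
        self.random_state = random_state

    def _validate_params_(self) -> None:
        # a 1×1 map degenerates to an exponentially-weighted running mean;
        # allowed for diagnostics, real maps should be at least 2×2
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be at least 1")
        if not (self.alpha_start > self.alpha_end > 0):
            raise ValueError("need alpha_start > alpha_end > 0")
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be positive")

    def _quantization_error(self, X: np.ndarray) -> float:
        b = batch_bmu(X, self.codebook_)
        return float(np.sqrt(((X - self.codebook_[b]) ** 2).sum(axis=1)).mean())

    def fit(self, X, y=None) -> "HexSom":
        self._validate_params_()
        X = check_array(X, dtype=float)
        rng = np.random.default_rng(self.random_state)
        n_nodes = self.grid_rows * self.grid_cols
        self.node_positions_ = hex_positions(self.grid_rows, self.grid_cols)
        lattice_sq = lattice_sq_distances(self.node_positions_)
        M = init_codebook(X, n_nodes, rng)
        self.codebook_ = M

        n_iter = self.n_iterations
        r0 = (
            (2.0 / 3.0) * max(self.grid_rows, self.grid_cols)
            if self.radius_start is None
            else float(self.radius_start)
        )
        r1 = float(self.radius_end)
        order = rng.integers(0, len(X), size=n_iter)
        # checkpoints are taken during training (the first after ~1/n of the
        # iterations): with codebooks seeded from data rows the pre-training
        # quantization error of binary data is a degenerate near-exact match
        # and not a useful baseline
        n_ck = max(self.n_checkpoints, 2)
        checkpoints = set(np.linspace(0, n_iter, n_ck + 1)[1:-1].astype(int).tolist())
        qe: list[float] = []

        for t in range(n_iter):
            if t in checkpoints:
                qe.append(self._quantization_error(X))
            frac = t / (n_iter - 1) if n_iter > 1 else 1.0
            alpha = self.alpha_start + (self.alpha_end - self.alpha_start) * frac
            sigma = r0 + (r1 - r0) * frac
            x = X[order[t]]
            diff = x - M
            c = np.argmin(np.einsum("ij,ij->i", diff, diff))
            h = np.exp(-lattice_sq[c] / (2.0 * sigma * sigma))
            M += alpha * h[:, None] * diff
        qe.append(self._quantization_error(X))
        self.quantization_errors_ = np.asarray(qe)

        self.bmu_index_ = batch_bmu(X, M)
        self.activation_counts_ = np.bincount(self.bmu_index_, minlength=n_nodes)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """BMU index per row."""
        check_is_fitted(self, "codebook_")
        X = check_array(X, dtype=float)
        return batch_bmu(X, self.codebook_)

    def transform(self, X) -> np.ndarray:
        """Euclidean distances from each row to every codebook vector."""
        check_is_fitted(self, "codebook_")
        X = check_array(X, dtype=float)
        sq = (
            np.einsum("ij,ij->i", X, X)[:, None]
            - 2.0 * X @ self.codebook_.T
            + np.einsum("ij,ij->i", self.codebook_, self.codebook_)[None, :]
        )
        return np.sqrt(np.maximum(sq, 0.0))


def train_som(X, **kwargs) -> HexSom:
    """Convenience wrapper: fit a :class:`HexSom` on a disease matrix."""
    return HexSom(**kwargs).fit(np.asarray(X, dtype=float))


def export_maps(som: HexSom, feature_names=None) -> dict:
    """Grid-shaped exports: node activation counts and one component plane
    (codebook column reshaped onto the grid) per feature."""
    check_is_fitted(som, "codebook_")
    shape = (som.grid_rows, som.grid_cols)
    count_map = pd.DataFrame(som.activation_counts_.reshape(shape))
    if feature_names is None:
        feature_names = [f"feature_{j}" for j in range(som.codebook_.shape[1])]
    planes = {
        name: pd.DataFrame(som.codebook_[:, j].reshape(shape))
        for j, name in enumerate(feature_names)
    }
    return {"count_map": count_map, "component_planes": planes}


def write_maps(som: HexSom, outdir, feature_names=None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    maps = export_maps(som, feature_names)
    maps["count_map"].to_csv(outdir / "count_map.csv", index=False)
    for name, plane in maps["component_planes"].items():
        plane.to_csv(outdir / f"plane_{name}.csv", index=False)


def save_model(som: HexSom, outdir, feature_names=None) -> None:
    """Persist a trained map as a JSON config + CSV arrays bundle."""
    check_is_fitted(som, "codebook_")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.json", "w") as fh:
        json.dump(som.get_params(), fh, indent=2)
    cols = feature_names if feature_names is not None else None
    pd.DataFrame(som.codebook_, columns=cols).to_csv(
        outdir / "codebook.csv", index=False
    )
    pd.DataFrame({"activation_count": som.activation_counts_}).to_csv(
        outdir / "activation_counts.csv", index=False
    )
    pd.DataFrame({"bmu": som.bmu_index_}).to_csv(outdir / "bmu.csv", index=False)


def load_model(outdir) -> HexSom:
    outdir = Path(outdir)
    with open(outdir / "config.json") as fh:
        som = HexSom(**json.load(fh))
    som.codebook_ = pd.read_csv(outdir / "codebook.csv").to_numpy(dtype=float)
    som.activation_counts_ = (
        pd.read_csv(outdir / "activation_counts.csv")["activation_count"]
        .to_numpy(dtype=int)
    )
    som.bmu_index_ = pd.read_csv(outdir / "bmu.csv")["bmu"].to_numpy(dtype=int)
    som.node_positions_ = hex_positions(som.grid_rows, som.grid_cols)
    som.n_features_in_ = som.codebook_.shape[1]
    return som
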