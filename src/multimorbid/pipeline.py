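"""End-to-end two-stage analysis: SOM → activation-weighted k-means.

Convenience layer gluing the modules together for scripts, the CLI and the
acceptance run: generate or load a cohort, preprocess it, train the map,
cluster the codebook with node activation frequencies as weights, assign
subjects through their BMU, and compute the descriptive outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import PreprocessResult, build_matrix
from .som import HexSom
from .synthetic import GeneratorConfig, SyntheticCohort, default_config, generate
from .wkmeans import WeightedKMeans, assign_subjects, elbow_scan


@dataclass
class TwoStageResult:
    som: HexSom
    solution: WeightedKMeans
    assignment: np.ndarray  # cluster per subject
    elbow: pd.DataFrame | None


def two_stage_cluster(
    matrix: pd.DataFrame,
    k: int = 4,
    grid_rows: int = 30,
    grid_cols: int = 30,
    n_iterations: int = 20_000,
    alpha_start: float = 0.05,
    alpha_end: float = 0.01,
    n_restarts: int = 20,
    seed: int = 0,
    scan_k: tuple[int, int] | None = (1, 10),
) -> TwoStageResult:
    """Train the SOM, cluster its codebook with activation weights, and map
    subjects to clusters via their BMU. ``scan_k=(k_min, k_max)`` also emits
    the weighted-WSS elbow table (``None`` skips the scan)."""
    X = matrix.to_numpy(dtype=float)
    som = HexSom(
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        n_iterations=n_iterations,
        alpha_start=alpha_start,
        alpha_end=alpha_end,
        random_state=seed,
    ).fit(X)
    weights = som.activation_counts_.astype(float)
    elbow = None
    if scan_k is not None:
        elbow = elbow_scan(
            som.codebook_, weights, scan_k[0], scan_k[1], seed=seed, n_restarts=n_restarts
        )
    solution = WeightedKMeans(
        n_clusters=k, n_restarts=n_restarts, random_state=seed
    ).fit(som.codebook_, sample_weight=weights)
    assignment = assign_subjects(som, solution)
    return TwoStageResult(som=som, solution=solution, assignment=assignment, elbow=elbow)


def synthetic_study(
    n_subjects: int = 8911,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> tuple[SyntheticCohort, PreprocessResult]:
    """Generate the default planted-cluster cohort and preprocess it."""
    cfg = config or default_config(n_subjects=n_subjects, seed=seed)
    synth = generate(cfg)
    prep = build_matrix(synth.cohort)
    return synth, prep
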