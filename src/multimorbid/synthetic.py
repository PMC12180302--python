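"""Seeded synthetic cohorts with a planted latent-class disease structure.

The generator emulates a community survey of adults aged 60-92 screened for
21 chronic conditions. Subjects belong to one of a small number of latent
clusters; given the cluster, the 21 disease indicators are independent
Bernoulli draws, so every mixture marginal and pairwise co-occurrence rate
is available in closed form for testing. The default configuration plants
four clusters:

1. a hypertension cluster (hypertension probability 1.0, roughly half also
   hyperuricemic),
2. a hypertension+diabetes cluster (both ≈ 0.9966, so their joint rate is
   ≈ 0.9932),
3. a large low-disease ("healthy") cluster, and
4. a hyperuricemia cluster (hyperuricemia probability 1.0).

Serum uric acid is simulated per sex and then reconciled to the drawn
hyperuricemia indicator by sampling from the correct side of the sex
threshold (>420 μmol/L men, >360 μmol/L women), so the preprocessing
threshold rule recovers the indicator exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .diseases import DISEASES, DISEASE_INDEX, N_DISEASES, REPORTED_DISEASES, URIC_ACID_THRESHOLD

AGE_BOUNDS = (60.0, 92.0)
BMI_BOUNDS = (14.0, 45.0)
# uric acid simulation support (μmol/L), per sex, split at the threshold
URIC_BOUNDS = (120.0, 800.0)
URIC_NORMAL = {"male": (360.0, 60.0), "female": (310.0, 55.0)}

EDUCATION_LEVELS = (
    "primary_or_below",
    "junior_high",
    "senior_high",
    "college_or_undergraduate",
    "graduate_or_above",
)
# marginal education / smoking / drinking proportions of the emulated survey
EDUCATION_PROBS = (0.1726, 0.2747, 0.3397, 0.2104, 0.0026)
SMOKE_PROB = 0.2038
DRINK_PROB = 0.1443

# overall per-disease prevalence of the emulated cohort (proportions)
MARGINAL_PREVALENCE: dict[str, float] = {
    "hyperuricemia": 0.4030,
    "chronic_bronchitis": 0.0146,
    "copd": 0.0020,
    "asthma": 0.0046,
    "tuberculosis": 0.0038,
    "hypertension": 0.3601,
    "hyperlipidemia": 0.1132,
    "angina_pectoris": 0.0036,
    "myocardial_infarction": 0.0054,
    "coronary_heart_disease": 0.0555,
    "chronic_hepatitis": 0.0048,
    "nephritis": 0.0038,
    "diabetes": 0.1522,
    "migraine": 0.0061,
    "stroke": 0.0104,
    "alzheimers_disease": 0.0016,
    "parkinsons_disease": 0.0024,
    "depression": 0.0017,
    "osteoporosis": 0.0270,
    "arthritis": 0.0508,
    "tumors": 0.0217,
}

# conditional disease probabilities fixed inside specific clusters
# (cluster index -> disease -> Bernoulli p); the low-disease cluster (2) is
# solved as the residual that reproduces MARGINAL_PREVALENCE.
_CLUSTER_OVERRIDES: dict[int, dict[str, float]] = {
    0: {  # hypertension cluster
        "hypertension": 1.0,
        "hyperuricemia": 0.4832,
        "hyperlipidemia": 0.1514,
        "coronary_heart_disease": 0.0751,
        "arthritis": 0.0593,
        "osteoporosis": 0.0230,
        "tumors": 0.0198,
        "diabetes": 0.01,
    },
    1: {  # hypertension + diabetes cluster
        "hypertension": 0.9966,
        "diabetes": 0.9966,
        "hyperuricemia": 0.4649,
        "hyperlipidemia": 0.3204,
        "coronary_heart_disease": 0.1554,
        "arthritis": 0.0521,
    },
    3: {  # hyperuricemia cluster
        "hyperuricemia": 1.0,
        "hypertension": 0.0,
        "diabetes": 0.1032,
        "hyperlipidemia": 0.0813,
        "coronary_heart_disease": 0.0360,
        "arthritis": 0.0477,
        "osteoporosis": 0.0224,
        "tumors": 0.0156,
        "chronic_bronchitis": 0.0141,
    },
}

_RESIDUAL_CLUSTER = 2  # the low-disease cluster absorbs the marginal residual

# cluster sizes of the emulated four-group solution (of 8,911 subjects)
DEFAULT_CLUSTER_COUNTS = (2477, 736, 3644, 2054)


@dataclass
class ClusterDemographics:
    """Per-cluster demographic sampling parameters."""

    age_mean: float
    age_sd: float
    female_prop: float
    bmi_mean: float
    bmi_sd: float


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    ``per_cluster_disease_probs`` has shape (n_clusters, 21) in the canonical
    disease column order; diseases are conditionally independent given the
    cluster label.
    """

    n_subjects: int
    n_clusters: int
    cluster_weights: np.ndarray
    per_cluster_disease_probs: np.ndarray
    demographics: list[ClusterDemographics]
    uric_normal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(URIC_NORMAL)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.cluster_weights = np.asarray(self.cluster_weights, dtype=float)
        self.per_cluster_disease_probs = np.asarray(
            self.per_cluster_disease_probs, dtype=float
        )
        self.validate()

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.n_clusters <= 0:
            raise ValueError("n_clusters must be positive")
        if self.cluster_weights.shape != (self.n_clusters,):
            raise ValueError("cluster_weights length must equal n_clusters")
        if abs(self.cluster_weights.sum() - 1.0) > 1e-12:
            raise ValueError("cluster_weights must sum to 1 within 1e-12")
        if np.any(self.cluster_weights < 0):
            raise ValueError("cluster_weights must be non-negative")
        p = self.per_cluster_disease_probs
        if p.shape[0] != self.n_clusters:
            raise ValueError("per_cluster_disease_probs rows must equal n_clusters")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("disease probabilities must lie in [0, 1]")
        if len(self.demographics) != self.n_clusters:
            raise ValueError("demographics must have one entry per cluster")

    def mixture_marginals(self) -> np.ndarray:
        """Closed-form marginal disease prevalences implied by the mixture."""
        return self.cluster_weights @ self.per_cluster_disease_probs

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["cluster_weights"] = self.cluster_weights.tolist()
        payload["per_cluster_disease_probs"] = self.per_cluster_disease_probs.tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["demographics"] = [
            ClusterDemographics(**d) for d in payload["demographics"]
        ]
        payload["uric_normal"] = {
            k: tuple(v) for k, v in payload["uric_normal"].items()
        }
        return cls(**payload)


@dataclass
class SyntheticCohort:
    """A generated cohort table plus its ground-truth cluster labels."""

    cohort: pd.DataFrame
    true_labels: np.ndarray
    config: GeneratorConfig


def default_config(n_subjects: int = 8911, seed: int = 0) -> GeneratorConfig:
    """The four-cluster study conditions the package is calibrated to.

    Cluster proportions are (2477, 736, 3644, 2054)/8911. Clusters 1, 2 and 4
    carry fixed conditional disease probabilities (hypertension 1.0 in
    cluster 1, hypertension and diabetes 0.9966 in cluster 2, hyperuricemia
    1.0 in cluster 4, plus the co-occurrence-implied rates for the other
    cardiometabolic conditions); the low-disease cluster 3 receives, per
    disease, the residual probability that makes the mixture marginal equal
    the target overall prevalence, clipped to [0, 1]. Diseases with no
    cluster-specific information get the overall prevalence in every cluster.
    """
    counts = np.asarray(DEFAULT_CLUSTER_COUNTS, dtype=float)
    weights = counts / counts.sum()
    n_clusters = len(counts)

    probs = np.tile(
        np.array([MARGINAL_PREVALENCE[d] for d in DISEASES]), (n_clusters, 1)
    )
    for c, overrides in _CLUSTER_OVERRIDES.items():
        for disease, p in overrides.items():
            probs[c, DISEASE_INDEX[disease]] = p
    # residual calibration of the low-disease cluster
    overridden = {d for ov in _CLUSTER_OVERRIDES.values() for d in ov}
    for disease in overridden:
        j = DISEASE_INDEX[disease]
        target = MARGINAL_PREVALENCE[disease]
        other = sum(
            weights[c] * probs[c, j]
            for c in range(n_clusters)
            if c != _RESIDUAL_CLUSTER
        )
        probs[_RESIDUAL_CLUSTER, j] = float(
            np.clip((target - other) / weights[_RESIDUAL_CLUSTER], 0.0, 1.0)
        )

    demographics = [
        ClusterDemographics(68.51, 5.68, 0.4170, 25.3, 3.1),
        ClusterDemographics(69.11, 5.63, 0.4280, 25.4, 3.2),
        ClusterDemographics(67.07, 5.11, 0.4179, 24.0, 3.0),
        ClusterDemographics(67.41, 5.34, 0.4567, 25.0, 3.1),
    ]
    return GeneratorConfig(
        n_subjects=n_subjects,
        n_clusters=n_clusters,
        cluster_weights=weights,
        per_cluster_disease_probs=probs,
        demographics=demographics,
        seed=seed,
    )


def _truncated_normal(
    rng: np.random.Generator, mean, sd, low: float, high: float, size: int
) -> np.ndarray:
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    sd = np.broadcast_to(np.asarray(sd, dtype=float), (size,))
    a = (low - mean) / sd
    b = (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)


def generate(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a cohort i.i.d. from the latent-class mixture.

    The same config (including seed) always yields a bit-identical cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    labels = rng.choice(config.n_clusters, size=n, p=config.cluster_weights)
    disease = (
        rng.random((n, N_DISEASES)) < config.per_cluster_disease_probs[labels]
    ).astype(np.int8)

    demo = config.demographics
    female_prop = np.array([d.female_prop for d in demo])[labels]
    sex = np.where(rng.random(n) < female_prop, "female", "male")

    age_mean = np.array([d.age_mean for d in demo])[labels]
    age_sd = np.array([d.age_sd for d in demo])[labels]
    age = _truncated_normal(rng, age_mean, age_sd, *AGE_BOUNDS, size=n)

    bmi_mean = np.array([d.bmi_mean for d in demo])[labels]
    bmi_sd = np.array([d.bmi_sd for d in demo])[labels]
    bmi = _truncated_normal(rng, bmi_mean, bmi_sd, *BMI_BOUNDS, size=n)

    # uric acid consistent with the drawn hyperuricemia indicator: sample the
    # per-sex normal truncated to the correct side of the sex threshold
    hua = disease[:, DISEASE_INDEX["hyperuricemia"]].astype(bool)
    uric = np.empty(n)
    for s in ("male", "female"):
        mu, sd = config.uric_normal[s]
        thr = URIC_ACID_THRESHOLD[s]
        is_s = sex == s
        for positive in (True, False):
            m = is_s & (hua == positive)
            if not m.any():
                continue
            low, high = (thr, URIC_BOUNDS[1]) if positive else (URIC_BOUNDS[0], thr)
            uric[m] = _truncated_normal(rng, mu, sd, low, high, size=int(m.sum()))

    education = rng.choice(EDUCATION_LEVELS, size=n, p=EDUCATION_PROBS)
    smoke = (rng.random(n) < SMOKE_PROB).astype(np.int8)
    drink = (rng.random(n) < DRINK_PROB).astype(np.int8)

    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "education": education,
            "smoke": smoke,
            "drink": drink,
            "uric_acid": uric,
        }
    )
    for d in REPORTED_DISEASES:
        cohort[d] = disease[:, DISEASE_INDEX[d]]

    return SyntheticCohort(cohort=cohort, true_labels=labels, config=config)


def write_cohort_csv(synth: SyntheticCohort, path, labels_path=None) -> None:
    synth.cohort.to_csv(path, index=False)
    if labels_path is not None:
        pd.DataFrame(
            {"subject_id": synth.cohort["subject_id"], "true_label": synth.true_labels}
        ).to_csv(labels_path, index=False)
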