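"""Canonical disease vocabulary for the 21-condition multimorbidity matrix.

The column order below is fixed and used everywhere: in generated cohorts,
in the wide binary disease matrix, in SOM codebooks and in every exported
table, so that downstream artefacts are order-stable across runs.
"""

from __future__ import annotations

# 21 chronic conditions screened in older-adult health surveys, in canonical
# column order. Hyperuricemia is derived from serum uric acid, the other 20
# are self-reported.
DISEASES: tuple[str, ...] = (
    "hyperuricemia",
    "chronic_bronchitis",
    "copd",
    "asthma",
    "tuberculosis",
    "hypertension",
    "hyperlipidemia",
    "angina_pectoris",
    "myocardial_infarction",
    "coronary_heart_disease",
    "chronic_hepatitis",
    "nephritis",
    "diabetes",
    "migraine",
    "stroke",
    "alzheimers_disease",
    "parkinsons_disease",
    "depression",
    "osteoporosis",
    "arthritis",
    "tumors",
)

N_DISEASES = len(DISEASES)

#: Diseases whose coexistence (two or more) defines cardiometabolic
#: multimorbidity.
CARDIOMETABOLIC: frozenset[str] = frozenset(
    {"hypertension", "diabetes", "coronary_heart_disease", "stroke", "hyperlipidemia"}
)

#: The 20 self-reported indicators (hyperuricemia excluded: derived from
#: serum uric acid and sex).
REPORTED_DISEASES: tuple[str, ...] = tuple(d for d in DISEASES if d != "hyperuricemia")

#: Serum uric acid thresholds (μmol/L); hyperuricemia is a strictly greater
#: than comparison per sex.
URIC_ACID_THRESHOLD = {"male": 420.0, "female": 360.0}

DISEASE_INDEX = {name: i for i, name in enumerate(DISEASES)}
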