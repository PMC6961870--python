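"""Feature catalog for the memory-clinic cohort.

Defines the fixed inventory of classifier inputs — neuropsychological test
scores, MRI-derived atrophy/lesion markers, APOE ε4 carriership and the three
CSF analytes — together with plausible value ranges used for validation.
Age and sex are demographics (covariates), not classifier features.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf


@dataclass(frozen=True)
class FeatureSpec:
    """Description of one classifier input.

    Parameters
    ----------
    name : str
        Column name in the cohort CSV schema.
    modality : str
        One of ``"NP"`` (neuropsychology), ``"MRI"``, ``"APOE"``, ``"CSF"``.
    kind : str
        ``"continuous"`` or ``"binary"``. Binary features take values {0, 1}
        and are excluded from covariate correction.
    lower, upper : float
        Closed plausible range; values outside are rejected at load time,
        never clamped.
    """

    name: str
    modality: str
    kind: str = "continuous"
    lower: float = -inf
    upper: float = inf

    def __post_init__(self) -> None:
        if self.modality not in {"NP", "MRI", "APOE", "CSF"}:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.kind not in {"continuous", "binary"}:
            raise ValueError(f"unknown kind {self.kind!r}")
        if not self.lower < self.upper:
            raise ValueError(f"empty plausible range for {self.name!r}")

    def in_range(self, value: float) -> bool:
        if self.kind == "binary":
            return value in (0.0, 1.0)
        return self.lower <= value <= self.upper


#: Diagnostic groups in the fixed clinical order used for deterministic
#: tie-breaking (controls first, then by decreasing prevalence).
GROUPS: tuple[str, ...] = ("CONTROL", "AD", "FTD", "VAD")

#: The six canonical pairwise comparisons; the first element is the
#: "positive" group of the pair. Reversed pairs are derived by complement.
CANONICAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("CONTROL", "AD"),
    ("CONTROL", "FTD"),
    ("CONTROL", "VAD"),
    ("AD", "FTD"),
    ("AD", "VAD"),
    ("VAD", "FTD"),
)

DEFAULT_CATALOG: tuple[FeatureSpec, ...] = (
    FeatureSpec("apoe_e4", "APOE", kind="binary"),
    # neuropsychology
    FeatureSpec("mmse", "NP", lower=0, upper=30),
    FeatureSpec("ravlt_learning", "NP", lower=0, upper=75),
    FeatureSpec("ravlt_recall", "NP", lower=0, upper=15),
    FeatureSpec("tmt_a", "NP", lower=0, upper=600),
    FeatureSpec("tmt_b", "NP", lower=0, upper=1200),
    FeatureSpec("animal_fluency", "NP", lower=0, upper=60),
    FeatureSpec("npi_total", "NP", lower=0, upper=144),
    # MRI markers (consumed as precomputed numbers)
    FeatureSpec("cmta_right", "MRI", lower=0, upper=4),
    FeatureSpec("cmta_left", "MRI", lower=0, upper=4),
    FeatureSpec("cgca", "MRI", lower=0, upper=3),
    FeatureSpec("wmh_ml", "MRI", lower=0, upper=250),
    FeatureSpec("ad_similarity", "MRI", lower=0, upper=1),
    FeatureSpec("ap_index", "MRI", lower=-10, upper=10),
    # CSF analytes, pg/ml
    FeatureSpec("ab42", "CSF", lower=0, upper=3000),
    FeatureSpec("total_tau", "CSF", lower=0, upper=3000),
    FeatureSpec("p_tau", "CSF", lower=0, upper=500),
)

#: Names of the three CSF analytes, in schema order.
CSF_FEATURES: tuple[str, ...] = ("ab42", "total_tau", "p_tau")

#: Feature subset used before CSF testing: neuropsychology, MRI and APOE.
NOCSF_SUBSET: frozenset[str] = frozenset(
    s.name for s in DEFAULT_CATALOG if s.modality != "CSF"
)

#: Full subset including the CSF analytes.
CSF_SUBSET: frozenset[str] = frozenset(s.name for s in DEFAULT_CATALOG)

#: Non-feature columns of the cohort CSV schema, in order.
META_COLUMNS: tuple[str, ...] = ("patient_id", "age", "sex", "diagnosis")

#: Full CSV column order.
SCHEMA_COLUMNS: tuple[str, ...] = META_COLUMNS + tuple(
    s.name for s in DEFAULT_CATALOG
)


def catalog_by_name(
    catalog: tuple[FeatureSpec, ...] = DEFAULT_CATALOG,
) -> dict[str, FeatureSpec]:
    """Return a name → spec mapping, checking name uniqueness."""
    out = {s.name: s for s in catalog}
    if len(out) != len(catalog):
        raise ValueError("duplicate feature names in catalog")
    return out
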