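"""Synthetic four-group memory-clinic cohort generator.

Emulates the structure of a pooled three-center cohort of 535 subjects
(139 controls with subjective cognitive decline, 286 AD, 82 FTD, 28 VaD):
per-group feature means and SDs, sex and APOE ε4 carrier frequencies,
realistic missingness (1% for MMSE up to 24% for TMT-B, 12% for APOE, CSF
and MRI always present per the inclusion criterion), and a linear age
effect per feature so the covariate correction has something to remove.

Continuous features are drawn from a Gaussian copula within each modality
(a single within-modality correlation knob) with truncated-normal marginals
on each feature's plausible range. The ``separation_scale`` multiplier
shrinks or expands every between-group difference — feature means, feature
SDs and APOE carrier frequencies — around the size-weighted pooled value,
so a scale of 0 gives a null cohort whose groups share one distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm, truncnorm

from .catalog import DEFAULT_CATALOG, GROUPS, catalog_by_name
from .cohort import Cohort

# Per-group baseline parameters: (CONTROL, AD, FTD, VAD) means and SDs.
_FEATURE_TABLE: dict[str, tuple[tuple[float, float, float, float], tuple[float, float, float, float]]] = {
    "mmse": ((28, 21, 24, 24), (1, 5, 4, 4)),
    "ravlt_learning": ((42, 22, 28, 24), (9, 8, 8, 8)),
    "ravlt_recall": ((9, 2, 4, 4), (3, 2, 3, 3)),
    "tmt_a": ((37, 79, 57, 96), (20, 54, 36, 57)),
    "tmt_b": ((85, 193, 155, 220), (39, 80, 77, 86)),
    "animal_fluency": ((22, 13, 12, 11), (5, 5, 7, 4)),
    "npi_total": ((7, 11, 22, 16), (9, 11, 17, 10)),
    "cmta_right": ((0.3, 1.4, 1.6, 1.5), (0.5, 0.8, 1.2, 1.0)),
    "cmta_left": ((0.3, 1.5, 2.0, 1.5), (0.5, 0.9, 1.4, 1.2)),
    "cgca": ((0.3, 1.2, 1.3, 1.4), (0.5, 0.8, 0.8, 0.7)),
    "wmh_ml": ((2.9, 6.6, 3.6, 44.5), (4.7, 9.9, 7.7, 29.6)),
    "ad_similarity": ((0.4, 0.6, 0.4, 0.6), (0.1, 0.1, 0.1, 0.1)),
    "ap_index": ((0.1, 0.1, -2.1, 0.1), (0.7, 1.2, 1.7, 1.1)),
    "ab42": ((928, 535, 914, 704), (280, 183, 250, 252)),
    "total_tau": ((322, 693, 337, 308), (208, 405, 140, 162)),
    "p_tau": ((52, 86, 45, 43), (24, 39, 18, 18)),
}

#: Direction of the injected age trend (performance declines, pathology
#: accumulates, AB42 falls with age).
_AGE_SLOPE_SIGN: dict[str, float] = {
    "mmse": -1, "ravlt_learning": -1, "ravlt_recall": -1, "animal_fluency": -1,
    "tmt_a": 1, "tmt_b": 1, "npi_total": 1,
    "cmta_right": 1, "cmta_left": 1, "cgca": 1, "wmh_ml": 1,
    "ad_similarity": 1, "ap_index": -1,
    "ab42": -1, "total_tau": 1, "p_tau": 1,
}

_MODALITY_BLOCKS: tuple[tuple[str, ...], ...] = (
    ("mmse", "ravlt_learning", "ravlt_recall", "tmt_a", "tmt_b",
     "animal_fluency", "npi_total"),
    ("cmta_right", "cmta_left", "cgca", "wmh_ml", "ad_similarity", "ap_index"),
    ("ab42", "total_tau", "p_tau"),
)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator (defaults mirror the
    pooled three-center cohort's baseline characteristics)."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"CONTROL": 139, "AD": 286, "FTD": 82, "VAD": 28}
    )
    age_mean: dict[str, float] = field(
        default_factory=lambda: {"CONTROL": 62, "AD": 67, "FTD": 63, "VAD": 70}
    )
    age_sd: dict[str, float] = field(
        default_factory=lambda: {"CONTROL": 8, "AD": 8, "FTD": 6, "VAD": 8}
    )
    age_range: tuple[float, float] = (40.0, 95.0)
    female_freq: dict[str, float] = field(
        default_factory=lambda: {"CONTROL": 0.43, "AD": 0.55, "FTD": 0.44, "VAD": 0.29}
    )
    apoe_freq: dict[str, float] = field(
        default_factory=lambda: {"CONTROL": 0.42, "AD": 0.65, "FTD": 0.34, "VAD": 0.48}
    )
    feature_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            f: dict(zip(GROUPS, means)) for f, (means, _) in _FEATURE_TABLE.items()
        }
    )
    feature_sds: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            f: dict(zip(GROUPS, sds)) for f, (_, sds) in _FEATURE_TABLE.items()
        }
    )
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {
            "mmse": 0.01, "ravlt_learning": 0.05, "ravlt_recall": 0.05,
            "tmt_a": 0.04, "tmt_b": 0.24, "animal_fluency": 0.03,
            "npi_total": 0.17, "apoe_e4": 0.12,
        }
    )
    within_modality_correlation: float = 0.3
    separation_scale: float = 1.0
    #: injected age slope, in feature SDs per year (sign per feature)
    age_slope_sd_per_year: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        if not 0 <= self.within_modality_correlation < 1:
            raise ValueError("within-modality correlation must be in [0, 1)")
        if self.separation_scale < 0:
            raise ValueError("separation_scale must be >= 0")
        for f, r in self.missing_rates.items():
            if not 0 <= r <= 1:
                raise ValueError(f"missing rate for {f} outside [0, 1]")
        for f, sds in self.feature_sds.items():
            if any(s <= 0 for s in sds.values()):
                raise ValueError(f"non-positive SD for {f}")


def default_generator_config(seed: int = 0) -> GeneratorConfig:
    """The default, baseline-table-parameterized configuration."""
    return GeneratorConfig(seed=seed)


def scaled_config(n_total: int, seed: int = 0, **overrides) -> GeneratorConfig:
    """Default config with group sizes rescaled to roughly ``n_total``
    while keeping the prevalence mix."""
    cfg = default_generator_config(seed=seed)
    base = sum(cfg.group_sizes.values())
    cfg.group_sizes = {
        g: max(1, round(n * n_total / base)) for g, n in cfg.group_sizes.items()
    }
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def _interpolate_to_pooled(
    config: GeneratorConfig, per_group: dict[str, float]
) -> dict[str, float]:
    """Shrink per-group values toward their size-weighted pooled mean by
    ``separation_scale`` (0 = identical groups, 1 = table values)."""
    weights = {g: config.group_sizes[g] for g in GROUPS}
    total = sum(weights.values())
    pooled = sum(weights[g] * per_group[g] for g in GROUPS) / total
    return {
        g: pooled + config.separation_scale * (per_group[g] - pooled) for g in GROUPS
    }


def shifted_group_means(config: GeneratorConfig) -> dict[str, dict[str, float]]:
    """Group feature means after applying ``separation_scale``."""
    return {
        f: _interpolate_to_pooled(config, means)
        for f, means in config.feature_means.items()
    }


def shifted_group_sds(config: GeneratorConfig) -> dict[str, dict[str, float]]:
    """Group feature SDs after applying ``separation_scale``.

    SDs are interpolated geometrically (``pooled * (sd/pooled)**scale``) so
    they stay positive for any scale; a scale of 0 removes dispersion
    differences as well — groups then share one distribution.
    """
    weights = {g: config.group_sizes[g] for g in GROUPS}
    total = sum(weights.values())
    out: dict[str, dict[str, float]] = {}
    for f, sds in config.feature_sds.items():
        pooled = sum(weights[g] * sds[g] for g in GROUPS) / total
        out[f] = {
            g: pooled * (sds[g] / pooled) ** config.separation_scale for g in GROUPS
        }
    return out


def shifted_apoe_freq(config: GeneratorConfig) -> dict[str, float]:
    """APOE ε4 carrier frequencies after applying ``separation_scale``."""
    freq = _interpolate_to_pooled(config, config.apoe_freq)
    return {g: min(1.0, max(0.0, p)) for g, p in freq.items()}


def age_slope(config: GeneratorConfig, feature: str, group: str) -> float:
    """Injected per-year age slope of a feature within a group."""
    return (
        _AGE_SLOPE_SIGN[feature]
        * config.age_slope_sd_per_year
        * shifted_group_sds(config)[feature][group]
    )


def pooled_age_mean(config: GeneratorConfig) -> float:
    """Size-weighted mean age; the age trend is anchored here for every
    group, so age/sex correction removes it identically across groups."""
    total = sum(config.group_sizes.values())
    return sum(config.group_sizes[g] * config.age_mean[g] for g in GROUPS) / total


def _block_normals(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    """n x m standard normals with common pairwise correlation rho."""
    z = rng.standard_normal((n, m))
    if m == 1 or rho == 0:
        return z
    shared = rng.standard_normal((n, 1))
    return np.sqrt(rho) * shared + np.sqrt(1 - rho) * z


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw one synthetic cohort; byte-identical under the same seed."""
    rng = np.random.default_rng(config.seed)
    specs = catalog_by_name(DEFAULT_CATALOG)
    means = shifted_group_means(config)
    sds = shifted_group_sds(config)
    apoe_freq = shifted_apoe_freq(config)
    age_ref = pooled_age_mean(config)
    lo_age, hi_age = config.age_range
    frames = []
    counter = 0
    for g in GROUPS:
        n = config.group_sizes[g]
        a_mu, a_sd = config.age_mean[g], config.age_sd[g]
        age = truncnorm.ppf(
            rng.uniform(size=n),
            (lo_age - a_mu) / a_sd,
            (hi_age - a_mu) / a_sd,
            loc=a_mu,
            scale=a_sd,
        )
        sex = np.where(rng.uniform(size=n) < config.female_freq[g], "F", "M")
        apoe = (rng.uniform(size=n) < apoe_freq[g]).astype(float)
        df = pd.DataFrame(
            {
                "patient_id": [f"S{counter + i:05d}" for i in range(n)],
                "age": age,
                "sex": sex,
                "diagnosis": g,
                "apoe_e4": apoe,
            }
        )
        counter += n
        for block in _MODALITY_BLOCKS:
            z = _block_normals(rng, n, len(block), config.within_modality_correlation)
            u = norm.cdf(z)
            for j, f in enumerate(block):
                spec = specs[f]
                sd = sds[f][g]
                loc = means[f][g] + age_slope(config, f, g) * (age - age_ref)
                a = (spec.lower - loc) / sd
                b = (spec.upper - loc) / sd
                # beyond ~37 SDs the normal tail mass underflows entirely
                if np.any(a > 37) or np.any(b < -37):
                    raise ValueError(
                        f"infeasible truncation for {f} in group {g}: mean far "
                        f"outside plausible range"
                    )
                df[f] = truncnorm.ppf(u[:, j], a, b, loc=loc, scale=sd)
        # missingness, completely at random, independent per feature
        for f, rate in config.missing_rates.items():
            if rate > 0 and f in df.columns:
                df.loc[rng.uniform(size=n) < rate, f] = np.nan
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    cols = ["patient_id", "age", "sex", "diagnosis"] + [s.name for s in DEFAULT_CATALOG]
    return Cohort(data=data[cols], catalog=DEFAULT_CATALOG)


# -- config file I/O -------------------------------------------------------


def config_to_yaml(config: GeneratorConfig, path) -> None:
    doc = {
        "group_sizes": config.group_sizes,
        "age_mean": config.age_mean,
        "age_sd": config.age_sd,
        "age_range": list(config.age_range),
        "female_freq": config.female_freq,
        "apoe_freq": config.apoe_freq,
        "feature_means": config.feature_means,
        "feature_sds": config.feature_sds,
        "missing_rates": config.missing_rates,
        "within_modality_correlation": config.within_modality_correlation,
        "separation_scale": config.separation_scale,
        "age_slope_sd_per_year": config.age_slope_sd_per_year,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path) -> GeneratorConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "age_range" in doc:
        doc["age_range"] = tuple(doc["age_range"])
    return GeneratorConfig(**doc)


# -- registered hand fixtures ---------------------------------------------


def _fixture_perfect_separation() -> Cohort:
    """Every group occupies a disjoint value band on every continuous
    feature; classification is unambiguous by construction. Values are on
    the corrected scale (``corrected=True``)."""
    specs = catalog_by_name(DEFAULT_CATALOG)
    n_per = 8
    rows = []
    pid = 0
    for k, g in enumerate(GROUPS):
        for i in range(n_per):
            row = {
                "patient_id": f"PS{pid:03d}",
                "age": 60.0 + i,
                "sex": "F" if i % 2 else "M",
                "diagnosis": g,
                "apoe_e4": 0.0,
            }
            for f, spec in specs.items():
                if spec.kind == "binary":
                    continue
                lo = spec.lower if np.isfinite(spec.lower) else -10.0
                hi = spec.upper if np.isfinite(spec.upper) else 10.0
                width = (hi - lo) / 5.0
                row[f] = lo + width * (k + 0.2 + 0.07 * i)
            rows.append(row)
            pid += 1
    cols = ["patient_id", "age", "sex", "diagnosis"] + [s.name for s in DEFAULT_CATALOG]
    return Cohort(pd.DataFrame(rows)[cols], corrected=True)


def _fixture_null() -> Cohort:
    """Identical distributions across four balanced groups (no signal)."""
    cfg = default_generator_config(seed=97)
    cfg.group_sizes = {g: 100 for g in GROUPS}
    cfg.separation_scale = 0.0
    return generate_cohort(cfg)


_SCENARIO_REF_SEED = 20260317 % (2**31)


def _fixture_scenario_reference() -> Cohort:
    """Reference cohort used to fit the models behind ``scenario_walk``
    (moderate size for fast leave-one-out refits)."""
    cfg = scaled_config(320, seed=_SCENARIO_REF_SEED)
    cfg.group_sizes["VAD"] = max(cfg.group_sizes["VAD"], 20)
    return generate_cohort(cfg)


def _fixture_scenario_walk() -> Cohort:
    """Twelve query patients engineered to exercise all four decision
    groups of the stepwise scenario, selected deterministically from a
    seeded pool classified by models fitted on ``scenario_reference``."""
    from .catalog import CSF_SUBSET, NOCSF_SUBSET
    from .correction import AgeSexCorrector
    from .dsi import fit_dsi_model
    from .pcc import build_pcc_model
    from .scenarios import ScenarioConfig, derive_simulated_csf_profiles, run_scenario

    ref_raw = _fixture_scenario_reference()
    corrector = AgeSexCorrector().fit(ref_raw)
    ref = corrector.transform(ref_raw)
    dsi_nocsf = fit_dsi_model(ref, NOCSF_SUBSET)
    dsi_csf = fit_dsi_model(ref, CSF_SUBSET)
    pcc_nocsf = build_pcc_model(ref, NOCSF_SUBSET)
    pcc_csf = build_pcc_model(ref, CSF_SUBSET)
    profiles = derive_simulated_csf_profiles(ref)

    pool_cfg = scaled_config(400, seed=_SCENARIO_REF_SEED + 1)
    pool_raw = generate_cohort(pool_cfg)
    pool_raw.data["patient_id"] = [f"W{i:05d}" for i in range(pool_raw.n)]
    pool = corrector.transform(pool_raw)

    outcomes = run_scenario(
        pool, dsi_nocsf, dsi_csf, pcc_nocsf, pcc_csf, profiles, ScenarioConfig("A")
    )
    chosen: list[str] = []
    for group in (1, 2, 3, 4):
        ids = [o.patient_id for o in outcomes if o.decision_group == group]
        chosen.extend(ids[:3])
    mask = pool.data["patient_id"].isin(chosen)
    return pool.subset(mask.to_numpy())


_FIXTURES = {
    "perfect_separation": _fixture_perfect_separation,
    "null": _fixture_null,
    "scenario_reference": _fixture_scenario_reference,
    "scenario_walk": _fixture_scenario_walk,
}


def make_fixture(name: str) -> Cohort:
    """Return a registered deterministic test cohort by name."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; registered: {sorted(_FIXTURES)}"
        ) from None
    return builder()
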