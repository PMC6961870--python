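"""Age/sex covariate correction.

Every continuous feature is residualized against age and sex before
classification: a least-squares linear model ``value ~ age + sex`` is fitted
on the control (reference) group's observed values, and each observed value
is replaced by its residual plus the reference-group mean, so corrected
values stay on the original measurement scale. Binary features (APOE) are
left untouched; missingness is preserved.

The transformer follows scikit-learn conventions (`fit`/`transform`,
fitted attributes with trailing underscores) and works on a plain
DataFrame; :func:`fit_covariate_models` / :func:`apply_covariate_correction`
are thin cohort-level wrappers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin

from .catalog import catalog_by_name
from .cohort import Cohort

MIN_REFERENCE_OBS = 10


@dataclass(frozen=True)
class CovariateModel:
    """Linear age/sex model for one continuous feature.

    ``corrected = value - (intercept + age_coefficient*age +
    sex_coefficient*sex) + reference_mean`` with sex coded 0=male, 1=female.
    """

    feature: str
    intercept: float
    age_coefficient: float
    sex_coefficient: float
    reference_mean: float

    def predict(self, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
        return (
            self.intercept
            + self.age_coefficient * np.asarray(age, float)
            + self.sex_coefficient * np.asarray(sex, float)
        )


class AgeSexCorrector(TransformerMixin, BaseEstimator):
    """Residualize continuous features against age and sex.

    Parameters
    ----------
    reference_group : str, default "CONTROL"
        Diagnosis label whose members define the covariate models; the
        control fit avoids absorbing disease effects into the correction.
    min_obs : int, default 10
        Minimum observed reference values required per feature.

    Attributes
    ----------
    models_ : dict[str, CovariateModel]
        One fitted model per continuous feature.
    """

    def __init__(self, reference_group: str = "CONTROL", min_obs: int = MIN_REFERENCE_OBS):
        self.reference_group = reference_group
        self.min_obs = min_obs

    def fit(self, cohort: Cohort, y=None) -> "AgeSexCorrector":
        if cohort.corrected:
            raise ValueError("cohort is already covariate-corrected")
        specs = catalog_by_name(cohort.catalog)
        ref = cohort.data["diagnosis"] == self.reference_group
        if not ref.any():
            raise ValueError(f"no {self.reference_group} members in cohort")
        age = cohort.data.loc[ref, "age"].to_numpy(float)
        sex = cohort.sex_numeric()[ref.to_numpy()]
        models: dict[str, CovariateModel] = {}
        for name, spec in specs.items():
            if spec.kind != "continuous" or name not in cohort.data.columns:
                continue
            vals = cohort.data.loc[ref, name].to_numpy(float)
            obs = ~np.isnan(vals)
            if obs.sum() < self.min_obs:
                raise ValueError(
                    f"feature {name}: only {int(obs.sum())} usable reference "
                    f"observations (< {self.min_obs})"
                )
            X = sm.add_constant(np.column_stack([age[obs], sex[obs]]), has_constant="add")
            fit = sm.OLS(vals[obs], X).fit()
            b0, b_age, b_sex = fit.params
            models[name] = CovariateModel(
                feature=name,
                intercept=float(b0),
                age_coefficient=float(b_age),
                sex_coefficient=float(b_sex),
                reference_mean=float(vals[obs].mean()),
            )
        self.models_ = models
        return self

    def transform(self, cohort: Cohort) -> Cohort:
        if cohort.corrected:
            raise ValueError("cohort is already covariate-corrected")
        df = cohort.data.copy()
        age = df["age"].to_numpy(float)
        sex = cohort.sex_numeric()
        for name, model in self.models_.items():
            if name not in df.columns:
                continue
            vals = df[name].to_numpy(float)
            pred = model.predict(age, sex)
            df[name] = vals - pred + model.reference_mean  # NaN stays NaN
        return replace(cohort, data=df, corrected=True)


def fit_covariate_models(
    cohort: Cohort, reference_group: str = "CONTROL"
) -> dict[str, CovariateModel]:
    """Fit one ``value ~ age + sex`` model per continuous feature on the
    reference group's observed values."""
    return AgeSexCorrector(reference_group=reference_group).fit(cohort).models_


def apply_covariate_correction(
    cohort: Cohort, models: dict[str, CovariateModel]
) -> Cohort:
    """Replace observed continuous values by residual + reference mean."""
    corrector = AgeSexCorrector()
    corrector.models_ = dict(models)
    return corrector.transform(cohort)


def covariate_models_to_json(models: dict[str, CovariateModel], path) -> None:
    with open(path, "w") as fh:
        json.dump({name: asdict(m) for name, m in models.items()}, fh, indent=1)


def covariate_models_from_json(path) -> dict[str, CovariateModel]:
    with open(path) as fh:
        raw = json.load(fh)
    return {name: CovariateModel(**d) for name, d in raw.items()}
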