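"""Covariate adjustment of height and variance explained by genetic scores.

Height is adjusted by ordinary least squares on age, sex (0 = female,
1 = male) and their interaction; the standardized residuals (mean 0, SD 1)
are the outcome for every downstream analysis. Variance explained by a
score is the squared Pearson correlation between residuals and score,
computed overall or within a sex stratum; several scores jointly are
entered as multiple-regression predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .scoring import ScoreSet

log = logging.getLogger(__name__)

STRATA = ("all", "male", "female")


class DegenerateModelError(ValueError):
    """Covariate model cannot be fitted (rank deficiency or zero variance)."""


@dataclass
class PhenotypeModel:
    """Height adjusted for age, sex, and age x sex.

    ``residuals`` are standardized (mean 0, SD 1, ddof=1). ``coefficients``
    indexes intercept/age/sex/age_sex; ``age_slopes`` gives the implied
    per-sex regression slope of height on age (cm/year).
    """

    sample_ids: list[str]
    sex: np.ndarray
    residuals: np.ndarray
    coefficients: pd.Series
    covariate_r2: float
    age_slopes: dict
    residual_scale: float  # SD (cm) removed by standardization

    def stratum_mask(self, stratum: str) -> np.ndarray:
        if stratum == "all":
            return np.ones(len(self.sample_ids), dtype=bool)
        if stratum == "male":
            return self.sex == 1
        if stratum == "female":
            return self.sex == 0
        raise ValueError(f"unknown stratum: {stratum}")


@dataclass
class R2Result:
    r2: float
    n: int
    predictors: list[str]
    stratum: str = "all"


def adjust_phenotype(samples: pd.DataFrame) -> PhenotypeModel:
    """OLS of height on {age, sex, age x sex}; standardize the residuals."""
    needed = ["height", "age", "sex"]
    sub = samples.dropna(subset=needed)
    if len(sub) < len(samples):
        log.info("adjust_phenotype: dropped %d samples with missing data",
                 len(samples) - len(sub))
    if len(sub) < 5:
        raise DegenerateModelError("too few complete samples")
    age = sub["age"].to_numpy(dtype=float)
    sex = sub["sex"].to_numpy(dtype=int)
    y = sub["height"].to_numpy(dtype=float)
    X = pd.DataFrame({"intercept": 1.0, "age": age, "sex": sex,
                      "age_sex": age * sex})
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DegenerateModelError("constant covariate column (rank-deficient design)")
    fit = sm.OLS(y, X).fit()
    resid = np.asarray(fit.resid)
    scale = resid.std(ddof=1)
    if scale < 1e-12:
        raise DegenerateModelError("zero residual variance: height is exactly "
                                   "linear in the covariates")
    coefs = pd.Series(fit.params.values, index=X.columns)
    return PhenotypeModel(
        sample_ids=sub["sample_id"].tolist(),
        sex=sex,
        residuals=(resid - resid.mean()) / scale,
        coefficients=coefs,
        covariate_r2=float(fit.rsquared),
        age_slopes={"female": float(coefs["age"]),
                    "male": float(coefs["age"] + coefs["age_sex"])},
        residual_scale=float(scale),
    )


def _aligned_values(model: PhenotypeModel, score: ScoreSet) -> np.ndarray:
    if list(score.sample_ids) == list(model.sample_ids):
        return score.values
    lookup = dict(zip(score.sample_ids, score.values))
    try:
        return np.array([lookup[s] for s in model.sample_ids])
    except KeyError as exc:
        raise ValueError(f"score lacks sample {exc.args[0]!r}") from exc


def score_r2(model: PhenotypeModel, score: ScoreSet,
             stratum: str = "all") -> R2Result:
    """Squared Pearson correlation between residuals and score in a stratum."""
    mask = model.stratum_mask(stratum)
    if mask.sum() < 3:
        raise ValueError(f"stratum {stratum!r} has fewer than 3 samples")
    s = _aligned_values(model, score)[mask]
    r = model.residuals[mask]
    if s.std() == 0:
        raise ValueError("zero-variance score")
    rho = np.corrcoef(r, s)[0, 1]
    return R2Result(r2=float(rho ** 2), n=int(mask.sum()),
                    predictors=[f"{score.panel_name}:{score.kind}"],
                    stratum=stratum)


def joint_score_r2(model: PhenotypeModel, scores: list[ScoreSet],
                   stratum: str = "all") -> R2Result:
    """r2 of the multiple OLS of residuals on all scores jointly.

    Collinear score columns are tolerated: the least-squares fit uses a
    minimum-norm solution, so a duplicated predictor leaves r2 unchanged
    (a warning notes the rank deficiency).
    """
    if len(scores) < 1:
        raise ValueError("at least one score is required")
    mask = model.stratum_mask(stratum)
    S = np.column_stack([_aligned_values(model, s)[mask] for s in scores])
    y = model.residuals[mask]
    X = np.column_stack([np.ones(mask.sum()), S])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        log.warning("joint_score_r2: %d collinear predictor(s) effectively dropped",
                    X.shape[1] - rank)
    fitted = X @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - fitted) ** 2))
    return R2Result(r2=1.0 - sse / sst, n=int(mask.sum()),
                    predictors=[f"{s.panel_name}:{s.kind}" for s in scores],
                    stratum=stratum)


def r2_table(model: PhenotypeModel, scores: list[ScoreSet],
             strata=STRATA, joint: bool = True) -> pd.DataFrame:
    """One row per (score, stratum), plus joint rows — Table-1-shaped output."""
    rows = []
    for s in scores:
        for st in strata:
            res = score_r2(model, s, st)
            rows.append({"panel": s.panel_name, "kind": s.kind,
                         "stratum": st, "r2": res.r2,
                         "pct_variance_explained": 100 * res.r2, "n": res.n})
    if joint and len(scores) >= 2:
        for st in strata:
            res = joint_score_r2(model, scores, st)
            rows.append({"panel": "+".join(sorted({s.panel_name for s in scores})),
                         "kind": "joint", "stratum": st, "r2": res.r2,
                         "pct_variance_explained": 100 * res.r2, "n": res.n})
    return pd.DataFrame(rows)
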