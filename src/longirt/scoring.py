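"""EORTC-style dimension scores and the linear mixed-model comparator.

The classical analysis route summarises the J items of a dimension at each
visit into a score on the 0-100 scale, ``S_iv = (mean_j y_iv^(j)) * 100 / M``,
and fits a linear mixed model to the scores.  Estimation is plain maximum
likelihood (not REML) so that BIC comparisons between the random-intercept
and random-intercept-plus-slope structures are valid, and BIC uses the
number of subjects as the sample size, matching the IRT fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

from .links import ConfigurationError, DomainError
from .model import ItemBank, ResponseDataset

logger = logging.getLogger("longirt")


@dataclass(frozen=True)
class LmmSpec:
    """Random structure of the comparator LMM: a = 1 intercept only,
    a = 2 independent intercept + time slope."""

    random_structure: int = 1

    def __post_init__(self):
        if self.random_structure not in (1, 2):
            raise ConfigurationError("random_structure must be 1 or 2")


@dataclass
class LmmFitResult:
    """ML estimates of the score LMM with BIC on the subject count."""

    spec: LmmSpec
    beta0: float
    beta1: float
    sigma0_sq: float
    sigma1_sq: float
    sigma_eps_sq: float
    loglik: float
    bic: float
    converged: bool
    n_used: int
    n_params: int


def eortc_score(responses, max_category: int) -> float:
    """Score of one visit: mean item response rescaled to 0-100.

    Undefined (raises) if any item is missing; callers drop such visits.
    """
    y = np.asarray(responses, dtype=float)
    if y.size == 0 or np.any(~np.isfinite(y)):
        raise DomainError("score undefined: missing item response")
    if np.any((y < 0) | (y > max_category)):
        raise DomainError(f"responses must lie in 0..{max_category}")
    return float(y.mean() * 100.0 / max_category)


def score_dataset(data: ResponseDataset, items: ItemBank = None) -> pd.DataFrame:
    """Per-(subject, visit) scores; visits missing any item are dropped
    (complete-case) with a log entry."""
    bank = items if items is not None else data.items
    Ms = {it.max_category for it in bank}
    if len(Ms) != 1:
        raise ConfigurationError(
            "scoring requires identical category counts across items"
        )
    M = Ms.pop()
    df = data.records
    grouped = df.groupby(["subject_id", "time"])["response"]
    counts = grouped.count()
    complete = counts == bank.J
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info("dropping %d visits with incomplete items from scoring", n_drop)
    means = grouped.mean()[complete]
    out = means.reset_index()
    out["score"] = out["response"] * 100.0 / M
    return out[["subject_id", "time", "score"]]


def fit_lmm(scores: pd.DataFrame, spec: LmmSpec = LmmSpec()) -> LmmFitResult:
    """ML fit of the score LMM; a = 2 uses independent intercept and slope."""
    df = scores.dropna(subset=["score"])
    n_subjects = df["subject_id"].nunique()
    dt = df["time"].to_numpy(dtype=float) - float(df["time"].min())
    exog = np.column_stack([np.ones(len(df)), dt])
    a = spec.random_structure
    exog_re = exog if a == 2 else exog[:, :1]
    md = MixedLM(
        df["score"].to_numpy(dtype=float),
        exog,
        groups=df["subject_id"].to_numpy(),
        exog_re=exog_re,
    )
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if a == 2:
                free = MixedLMParams.from_components(
                    fe_params=np.ones(2), cov_re=np.eye(2)
                )
                res = md.fit(reml=False, free=free, method="lbfgs")
            else:
                res = md.fit(reml=False, method="lbfgs")
        converged = bool(res.converged)
    except Exception as exc:   # singular fits, line-search failures
        logger.warning("LMM fit failed: %s", exc)
        return LmmFitResult(
            spec, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            converged=False, n_used=n_subjects, n_params=0,
        )
    sigma0_sq = float(res.cov_re[0, 0])
    sigma1_sq = float(res.cov_re[1, 1]) if a == 2 else 0.0
    n_params = 2 + 1 + (1 if a == 2 else 0) + 1   # beta0, beta1, variances, resid
    ll = float(res.llf)
    bic = -2.0 * ll + n_params * np.log(n_subjects)
    return LmmFitResult(
        spec=spec,
        beta0=float(res.fe_params[0]),
        beta1=float(res.fe_params[1]),
        sigma0_sq=sigma0_sq,
        sigma1_sq=sigma1_sq,
        sigma_eps_sq=float(res.scale),
        loglik=ll,
        bic=float(bic),
        converged=converged,
        n_used=n_subjects,
        n_params=n_params,
    )


def lmm_bic_select(scores: pd.DataFrame) -> tuple:
    """Fit both random structures and select by BIC (ties to M1).

    Returns (choice, fit_m1, fit_m2).
    """
    f1 = fit_lmm(scores, LmmSpec(1))
    f2 = fit_lmm(scores, LmmSpec(2))
    if not (f1.converged and f2.converged):
        raise DomainError("LMM selection requires two converged fits")
    choice = "M2" if f2.bic < f1.bic - 1e-8 else "M1"
    return choice, f1, f2
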