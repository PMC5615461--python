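"""Model specification and predictor assembly.

An IRT mixed model for longitudinal questionnaire data is identified by a
quadruple: the ratio family ``r``, the CdF ``F``, the item parameterisation
``Z_q`` (q = 1: item-specific thresholds, the partial-credit layout; q = 2:
one shared threshold vector plus a per-item shift, the rating-scale layout)
and the random structure ``U_a`` (a = 1: subject intercept; a = 2: intercept
plus time slope).  Discrimination parameters are carried as fixed known
constants (1 by default) so that the predictor remains linear and the model
stays inside the GLMM class.

The latent trait of subject ``i`` at visit ``v`` decomposes linearly as
``theta_iv = x_iv' beta + u_v' xi_i`` with normally distributed subject
random effects ``xi_i``.  Two fixed designs are supported:

* ``time_only``: ``theta_iv = (t_v - t_0) beta_1  [+ xi_i0 + (t_v - t_0) xi_i1]``
  — the simulation design, with no fixed intercept;
* ``group_time_interaction``:
  ``theta_iv = g_i beta_1 + (t_v - t_0) beta_2 + g_i (t_v - t_0) beta_3 + ...``
  — the two-arm trial design (g = 0 control, g = 1 experimental).

Neither design carries a fixed intercept; the baseline latent value with
zero random effects is exactly 0, which is what identifies the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .links import (
    CdfSpec,
    ConfigurationError,
    DomainError,
    RatioFamily,
    category_probs,
)

FIXED_DESIGNS = ("time_only", "group_time_interaction")
RANDOM_COVS = ("independent_diagonal", "unstructured_2x2")


# --------------------------------------------------------------------------
# Items
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Item:
    """A single ordinal item with ``n_categories`` = M + 1 response levels.

    ``thresholds`` are the difficulty parameters ``delta_1..delta_M``;
    ``shift`` is the rating-scale location ``tau_j`` added to every shared
    threshold under q = 2; ``discrimination`` is the fixed slope ``alpha_j``.
    """

    item_id: str
    n_categories: int
    thresholds: tuple
    shift: float = 0.0
    discrimination: float = 1.0

    def __post_init__(self):
        if self.n_categories < 2:
            raise ConfigurationError(
                f"item {self.item_id!r}: need at least 2 categories"
            )
        thr = tuple(float(t) for t in self.thresholds)
        if len(thr) != self.n_categories - 1:
            raise ConfigurationError(
                f"item {self.item_id!r}: expected {self.n_categories - 1} "
                f"thresholds, got {len(thr)}"
            )
        object.__setattr__(self, "thresholds", thr)

    @property
    def max_category(self) -> int:
        return self.n_categories - 1

    def effective_thresholds(self) -> np.ndarray:
        """Thresholds after applying the rating-scale shift."""
        return np.asarray(self.thresholds) + self.shift


@dataclass(frozen=True)
class ItemBank:
    """Ordered collection of items measuring one latent dimension."""

    items: tuple

    def __post_init__(self):
        items = tuple(self.items)
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("item ids must be unique")
        object.__setattr__(self, "items", items)

    @property
    def J(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def ids(self):
        return [it.item_id for it in self.items]


# --------------------------------------------------------------------------
# Model specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """The (ratio, CdF, Z_q, U_a) quadruple plus the fixed design."""

    ratio: RatioFamily
    cdf: CdfSpec
    item_param_kind: int = 1          # q: 1 item-specific, 2 rating scale
    random_structure: int = 1         # a: 1 intercept, 2 intercept + slope
    fixed_design: str = "time_only"
    random_cov: str = "independent_diagonal"

    def __post_init__(self):
        if isinstance(self.ratio, str):
            object.__setattr__(self, "ratio", RatioFamily(self.ratio))
        if isinstance(self.cdf, str):
            object.__setattr__(self, "cdf", CdfSpec(self.cdf))
        if self.item_param_kind not in (1, 2):
            raise ConfigurationError("item_param_kind must be 1 or 2")
        if self.random_structure not in (1, 2):
            raise ConfigurationError("random_structure must be 1 or 2")
        if self.fixed_design not in FIXED_DESIGNS:
            raise ConfigurationError(
                f"fixed_design must be one of {FIXED_DESIGNS}"
            )
        if self.random_cov not in RANDOM_COVS:
            raise ConfigurationError(f"random_cov must be one of {RANDOM_COVS}")
        if self.random_structure == 1 and self.random_cov != "independent_diagonal":
            raise ConfigurationError(
                "a single random intercept has a single variance; "
                "use random_cov='independent_diagonal'"
            )

    @property
    def n_beta(self) -> int:
        return 1 if self.fixed_design == "time_only" else 3

    def with_random_structure(self, a: int) -> "ModelSpec":
        cov = self.random_cov if a == 2 else "independent_diagonal"
        return replace(self, random_structure=a, random_cov=cov)


@dataclass(frozen=True)
class FixedEffects:
    """Fixed coefficients matching a fixed design (no intercept)."""

    beta: tuple
    design: str = "time_only"

    def __post_init__(self):
        beta = tuple(float(b) for b in self.beta)
        expected = 1 if self.design == "time_only" else 3
        if self.design not in FIXED_DESIGNS:
            raise ConfigurationError(f"design must be one of {FIXED_DESIGNS}")
        if len(beta) != expected:
            raise ConfigurationError(
                f"design {self.design!r} needs {expected} coefficients, "
                f"got {len(beta)}"
            )
        object.__setattr__(self, "beta", beta)


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Variances (and optional covariance) of the subject random effects."""

    sigma0_sq: float
    sigma1_sq: float = 0.0
    covariance: float = 0.0

    def __post_init__(self):
        if self.sigma0_sq < 0 or self.sigma1_sq < 0:
            raise ConfigurationError("variances must be non-negative")
        if self.covariance != 0.0:
            det = self.sigma0_sq * self.sigma1_sq - self.covariance**2
            if det < -1e-12:
                raise ConfigurationError(
                    "random-effect covariance matrix is not positive semi-definite"
                )

    def cov_matrix(self, a: int) -> np.ndarray:
        if a == 1:
            return np.array([[self.sigma0_sq]])
        return np.array(
            [[self.sigma0_sq, self.covariance], [self.covariance, self.sigma1_sq]]
        )


# --------------------------------------------------------------------------
# Response data container
# --------------------------------------------------------------------------

REQUIRED_COLUMNS = ("subject_id", "group", "time", "item_id", "response")


@dataclass
class ResponseDataset:
    """Long-format repeated ordinal measurements.

    One row per (subject, visit, item) with columns
    ``subject_id, group, time, item_id, response``.
    """

    records: pd.DataFrame
    items: ItemBank

    def __post_init__(self):
        df = self.records
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise DomainError(f"missing columns: {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)
        dup = df.duplicated(subset=["subject_id", "time", "item_id"])
        if dup.any():
            rows = df.index[dup].tolist()[:5]
            raise DomainError(f"duplicate (subject, visit, item) rows: {rows}")
        if (df["time"] < 0).any():
            raise DomainError("times must be non-negative")
        for it in self.items:
            sel = df.loc[df["item_id"].astype(str) == str(it.item_id), "response"]
            bad = sel[(sel < 0) | (sel > it.max_category) | (sel != sel.astype(int))]
            if len(bad):
                raise DomainError(
                    f"item {it.item_id!r}: responses outside 0..{it.max_category} "
                    f"at rows {bad.index.tolist()[:5]}"
                )
        known = set(map(str, self.items.ids()))
        unknown = set(df["item_id"].astype(str)) - known
        if unknown:
            raise DomainError(f"responses for undeclared items: {sorted(unknown)}")
        self.records = df

    @property
    def n(self) -> int:
        return self.records["subject_id"].nunique()

    @property
    def baseline_time(self) -> float:
        return float(self.records["time"].min())


def reverse_functional_scale(
    dataset: ResponseDataset, items: Optional[ItemBank] = None
) -> ResponseDataset:
    """Reverse the category order of every response: m -> M_j - m.

    Used to put functional-scale items (where a low category means high
    capacity) on the same footing as symptom items.  Applying it twice gives
    back the original data.
    """
    bank = items if items is not None else dataset.items
    df = dataset.records.copy()
    for it in bank:
        mask = df["item_id"].astype(str) == str(it.item_id)
        df.loc[mask, "response"] = it.max_category - df.loc[mask, "response"]
    return ResponseDataset(df, bank)


# --------------------------------------------------------------------------
# Predictor assembly
# --------------------------------------------------------------------------

def linear_predictor(theta: float, item: Item, m: int, q: int = 1) -> float:
    """IRT linear predictor ``alpha_j (theta - delta_jm)`` for threshold m.

    Under q = 2 the item's shift enters: ``alpha_j (theta - (delta_m + tau_j))``.
    """
    if not 1 <= m <= item.max_category:
        raise DomainError(
            f"threshold index {m} out of range 1..{item.max_category}"
        )
    delta = item.thresholds[m - 1] + (item.shift if q == 2 else 0.0)
    return item.discrimination * (theta - delta)


def item_etas(theta, item: Item, q: int = 1) -> np.ndarray:
    """Vector (eta_1..eta_M) for an item; theta may carry leading axes."""
    theta = np.asarray(theta, dtype=float)
    delta = np.asarray(item.thresholds)
    if q == 2:
        delta = delta + item.shift
    return item.discrimination * (theta[..., None] - delta)


def latent_value(covariates: dict, beta: FixedEffects, xi=(0.0, 0.0),
                 design: Optional[str] = None) -> float:
    """Latent trait ``theta_iv`` from covariates, fixed effects and xi.

    ``covariates`` needs ``time`` and ``baseline_time`` (default 0), and
    ``group`` for the trial design.  ``xi`` is ``(xi_0, xi_1)``; a missing
    slope component is treated as zero.
    """
    design = design or beta.design
    if design != beta.design:
        raise ConfigurationError("fixed-effect vector does not match design")
    if "time" not in covariates:
        raise DomainError("covariate record must contain 'time'")
    dt = float(covariates["time"]) - float(covariates.get("baseline_time", 0.0))
    xi = tuple(xi) + (0.0,) * (2 - len(tuple(xi)))
    if design == "time_only":
        fixed = dt * beta.beta[0]
    else:
        if "group" not in covariates:
            raise DomainError("trial design needs a 'group' covariate")
        g = float(covariates["group"])
        b1, b2, b3 = beta.beta
        fixed = g * b1 + dt * b2 + g * dt * b3
    return fixed + xi[0] + dt * xi[1]


def category_probability(theta, item: Item, spec: ModelSpec) -> np.ndarray:
    """Conditional category probabilities for one item at latent value theta."""
    etas = item_etas(theta, item, q=spec.item_param_kind)
    return category_probs(spec.ratio, etas, spec.cdf)
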