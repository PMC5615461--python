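"""Ordinal link mathematics: CdFs, probability-ratio families, category maps.

Regression models for an ordinal response with categories ``0..M`` are built
from two ingredients: a probability *ratio* (cumulative, adjacent or
sequential) that maps the category-probability vector to M quantities in
(0, 1), and a continuous CdF ``F`` that links each quantity to a linear
predictor, ``r_m(pi) = F(eta_m)``.

Everything here follows the descending-order IRT convention: the predictor
for threshold ``m`` is ``eta_m = theta - delta_m`` and the ratios are taken
from the top of the scale, so a larger latent value ``theta`` pushes mass
toward higher categories (for the cumulative and adjacent families).  The
sequential family is written in the ascending form (the one under which
``pi_m / (pi_m + ... + pi_M) = F(eta_m)``); it is not reversible, so no
descending rewrite is attempted.

All ``probs_*`` functions are vectorised: ``etas`` may carry arbitrary
leading axes with the threshold index last, and the result appends the
category axis of length ``M + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy import stats


class ConfigurationError(ValueError):
    """Unknown CdF / ratio-family name or inconsistent model options."""


class DomainError(ValueError):
    """Inputs violate a mathematical precondition (e.g. unordered thresholds)."""


# --------------------------------------------------------------------------
# CdFs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CdfSpec:
    """One of the four supported inverse-link CdFs.

    ``symmetric`` marks CdFs whose density is symmetric about zero
    (logistic, gaussian); only those give models that are invariant under
    reversal of the category order.
    """

    name: str
    symmetric: bool = field(init=False)

    def __post_init__(self):
        if self.name not in _CDF_TABLE:
            raise ConfigurationError(
                f"unknown CdF {self.name!r}; expected one of {sorted(_CDF_TABLE)}"
            )
        object.__setattr__(self, "symmetric", self.name in ("logistic", "gaussian"))

    # Direct special-function implementations (the scipy distribution
    # wrappers carry per-call overhead that dominates the fitter's inner
    # loop on large arrays).

    def cdf(self, eta):
        eta = np.asarray(eta, dtype=float)
        if self.name == "logistic":
            return special.expit(eta)
        if self.name == "gaussian":
            return special.ndtr(eta)
        if self.name == "gumbel_max":
            return np.exp(-np.exp(-eta))
        return -np.expm1(-np.exp(eta))

    def logcdf(self, eta):
        eta = np.asarray(eta, dtype=float)
        if self.name == "logistic":
            return special.log_expit(eta)
        if self.name == "gaussian":
            return special.log_ndtr(eta)
        if self.name == "gumbel_max":
            return -np.exp(-eta)
        with np.errstate(divide="ignore"):
            return np.log(-np.expm1(-np.exp(eta)))

    def logsf(self, eta):
        eta = np.asarray(eta, dtype=float)
        if self.name == "logistic":
            return special.log_expit(-eta)
        if self.name == "gaussian":
            return special.log_ndtr(-eta)
        if self.name == "gumbel_min":
            return -np.exp(eta)
        with np.errstate(divide="ignore"):
            return np.log(-np.expm1(-np.exp(-eta)))

    def pdf(self, eta):
        eta = np.asarray(eta, dtype=float)
        if self.name == "logistic":
            return np.exp(special.log_expit(eta) + special.log_expit(-eta))
        if self.name == "gaussian":
            return np.exp(-0.5 * eta**2) / np.sqrt(2.0 * np.pi)
        if self.name == "gumbel_max":
            return np.exp(-eta - np.exp(-eta))
        return np.exp(eta - np.exp(eta))

    def ppf(self, p):
        p = np.asarray(p, dtype=float)
        if self.name == "logistic":
            return special.logit(p)
        if self.name == "gaussian":
            return special.ndtri(p)
        if self.name == "gumbel_max":
            return -np.log(-np.log(p))
        return np.log(-np.log1p(-p))

    def dpdf(self, eta):
        """Derivative of the density with respect to eta."""
        eta = np.asarray(eta, dtype=float)
        f = self.pdf(eta)
        if self.name == "logistic":
            return f * (1.0 - 2.0 * special.expit(eta))
        if self.name == "gaussian":
            return -eta * f
        if self.name == "gumbel_max":
            return f * (np.exp(-eta) - 1.0)
        # gumbel_min
        return f * (1.0 - np.exp(eta))


_CDF_TABLE = {
    "logistic": stats.logistic,
    "gaussian": stats.norm,
    "gumbel_max": stats.gumbel_r,   # F(eta) = exp(-exp(-eta))
    "gumbel_min": stats.gumbel_l,   # F(eta) = 1 - exp(-exp(eta))
}

CDF_NAMES = tuple(sorted(_CDF_TABLE))


def cdf_eval(F: CdfSpec, eta):
    """Evaluate the CdF; value is in (0, 1) for finite eta."""
    return F.cdf(eta)


# --------------------------------------------------------------------------
# Ratio families
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RatioFamily:
    """One of the three ordinal probability-ratio families."""

    name: str
    reversible: bool = field(init=False)

    def __post_init__(self):
        if self.name not in ("adjacent", "cumulative", "sequential"):
            raise ConfigurationError(
                f"unknown ratio family {self.name!r}; "
                "expected adjacent, cumulative or sequential"
            )
        # Reversing the category order maps a cumulative (adjacent) model to
        # another cumulative (adjacent) model; a sequential model describes a
        # directed process and has no such counterpart.
        object.__setattr__(self, "reversible", self.name != "sequential")


def _check_etas(etas) -> np.ndarray:
    etas = np.asarray(etas, dtype=float)
    if etas.ndim == 0:
        etas = etas[None]
    if etas.shape[-1] < 1:
        raise DomainError("at least one threshold is required")
    if not np.all(np.isfinite(etas)):
        raise DomainError("linear predictors must be finite")
    return etas


def _log_cdf_diff(F: CdfSpec, a, b):
    """log(F(a) - F(b)) computed stably for a >= b.

    Works in whichever tail is better conditioned: ``F(a) - F(b)``
    equals ``SF(b) - SF(a)``, and the log of a difference of two
    log-scale quantities is taken with log1p.
    """
    la, lb = F.logcdf(a), F.logcdf(b)
    sa, sb = F.logsf(a), F.logsf(b)
    with np.errstate(divide="ignore", invalid="ignore"):
        # via the lower tail: log F(a) + log(1 - F(b)/F(a))
        lower = la + np.log1p(-np.exp(np.minimum(lb - la, 0.0)))
        # via the upper tail: log SF(b) + log(1 - SF(a)/SF(b))
        upper = sb + np.log1p(-np.exp(np.minimum(sa - sb, 0.0)))
    use_lower = la < sb
    out = np.where(use_lower, lower, upper)
    return out


def probs_cumulative(etas, F: CdfSpec) -> np.ndarray:
    """Category probabilities of the cumulative (proportional-odds style) model.

    With descending ratios ``Pr(Y >= m) = F(eta_m)``:
    ``pi_0 = 1 - F(eta_1)``, ``pi_m = F(eta_m) - F(eta_{m+1})``,
    ``pi_M = F(eta_M)``.  Requires ``F(eta)`` non-increasing along the
    threshold axis, i.e. strictly increasing thresholds.
    """
    etas = _check_etas(etas)
    diffs = np.diff(etas, axis=-1)
    if np.any(diffs >= 0):
        bad = int(np.argmax(np.any(diffs >= 0, axis=tuple(range(diffs.ndim - 1)))))
        raise DomainError(
            "cumulative model needs strictly decreasing eta along thresholds; "
            f"violated between thresholds {bad + 1} and {bad + 2}"
        )
    tail = F.cdf(etas)                      # Pr(Y >= m), m = 1..M
    shape = etas.shape[:-1] + (etas.shape[-1] + 1,)
    probs = np.empty(shape)
    probs[..., 0] = 1.0 - tail[..., 0]
    probs[..., 1:-1] = tail[..., :-1] - tail[..., 1:]
    probs[..., -1] = tail[..., -1]
    return probs


def probs_adjacent(etas, F: CdfSpec) -> np.ndarray:
    """Category probabilities of the adjacent-ratio model.

    ``pi_m`` is proportional to the product of the odds ``F(eta_k)/(1-F(eta_k))``
    for ``k <= m``; computed in the log domain so large ``|eta|`` cannot
    overflow.  With the logistic CdF this is exactly the partial-credit
    exponential form ``pi_m \\propto exp(sum_{k<=m} eta_k)``.
    """
    etas = _check_etas(etas)
    log_odds = F.logcdf(etas) - F.logsf(etas)
    a = np.concatenate(
        [np.zeros(etas.shape[:-1] + (1,)), np.cumsum(log_odds, axis=-1)], axis=-1
    )
    return np.exp(a - special.logsumexp(a, axis=-1, keepdims=True))


def probs_sequential(etas, F: CdfSpec) -> np.ndarray:
    """Category probabilities of the sequential (continuation-ratio) model.

    Written in the ascending form: ``pi_m / (pi_m + ... + pi_M) = F(eta_m)``
    for ``m`` indexing thresholds 1..M against categories 0..M-1, so
    ``pi_m = F(eta_{m+1}) * prod_{k<=m} (1 - F(eta_k))`` and the top category
    takes the remaining mass.
    """
    etas = _check_etas(etas)
    logF = F.logcdf(etas)
    logS = F.logsf(etas)
    cum_logS = np.cumsum(logS, axis=-1)
    shape = etas.shape[:-1] + (etas.shape[-1] + 1,)
    logp = np.empty(shape)
    logp[..., 0] = logF[..., 0]
    logp[..., 1:-1] = logF[..., 1:] + cum_logS[..., :-1]
    logp[..., -1] = cum_logS[..., -1]
    return np.exp(logp)


_PROB_FUNCS = {
    "cumulative": probs_cumulative,
    "adjacent": probs_adjacent,
    "sequential": probs_sequential,
}


def category_probs(ratio: RatioFamily, etas, F: CdfSpec) -> np.ndarray:
    """Dispatch to the ratio family's probability map."""
    return _PROB_FUNCS[ratio.name](etas, F)


def reverse_coding(probs) -> np.ndarray:
    """Reverse the category order: entry m maps to entry M - m."""
    return np.asarray(probs)[..., ::-1].copy()
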