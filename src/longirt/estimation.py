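"""Marginal maximum-likelihood estimation of longitudinal IRT mixed models.

The marginal likelihood of one subject integrates the conditional multinomial
likelihood of all their (visit, item) responses over the subject's random
effects::

    L_i = \\int \\prod_{v,j} \\pi^{(j)}_{ivm}(\\xi) \\, d\\Phi(\\xi; 0, \\Sigma)

The integral is approximated by (adaptive) Gauss-Hermite quadrature: per
subject the integrand is recentred at its mode and rescaled by the curvature
there, so that few nodes per dimension suffice.  The log-likelihood carries
analytic first derivatives with respect to every free parameter (thresholds,
fixed effects, variance components), which keeps the quasi-Newton fit fast
even for the two-dimensional random structure.

Free-parameter transformations keep the optimiser unconstrained where
possible: cumulative-family thresholds are (delta_1, log-increments) so the
ordering constraint always holds, and variance components are log standard
deviations (Cholesky factor for the unstructured 2x2 case).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .links import CdfSpec, ConfigurationError, DomainError
from .model import (
    FixedEffects,
    Item,
    ItemBank,
    ModelSpec,
    RandomEffectsSpec,
    ResponseDataset,
    category_probability,
    latent_value,
)

logger = logging.getLogger("longirt")

_LOG_SD_BOUNDS = (-9.0, 3.0)
_LOG_INC_BOUNDS = (-10.0, 5.0)
_BOUNDARY_LOG_SD = -8.5    # variance estimates at/under this are reported as 0


@dataclass(frozen=True)
class QuadratureConfig:
    """Gauss-Hermite settings: nodes per random-effect dimension and whether
    to recentre/rescale the nodes per subject at the posterior mode."""

    nodes_per_dim: int = 9
    adaptive: bool = True

    def __post_init__(self):
        if self.nodes_per_dim < 3:
            raise ConfigurationError("nodes_per_dim must be >= 3")

    def total_nodes(self, a: int) -> int:
        return self.nodes_per_dim ** a


@dataclass(frozen=True)
class IrtParameters:
    """Full parameter set of an IRT mixed model on the natural scale."""

    beta: FixedEffects
    thresholds: dict                   # item_id -> tuple of delta
    random: RandomEffectsSpec
    shifts: Optional[dict] = None      # item_id -> tau (rating scale only)


@dataclass
class FitResult:
    """Estimates, uncertainty and fit criteria of one model fit."""

    spec: ModelSpec
    beta_hat: FixedEffects
    thresholds_hat: dict
    random_hat: RandomEffectsSpec
    loglik: float
    bic: float
    se: dict
    wald_p: dict
    converged: bool
    n_used: int
    n_params: int
    boundary: bool = False
    shifts_hat: Optional[dict] = None
    message: str = ""

    def params(self) -> IrtParameters:
        return IrtParameters(
            beta=self.beta_hat,
            thresholds=self.thresholds_hat,
            random=self.random_hat,
            shifts=self.shifts_hat,
        )

    def summary_table(self) -> pd.DataFrame:
        """Coefficient table: estimate, standard error, Wald p-value."""
        rows = []
        names = _beta_names(self.spec.fixed_design)
        for name, est in zip(names, self.beta_hat.beta):
            rows.append(
                {
                    "coefficient": name,
                    "estimate": est,
                    "se": self.se.get(name, np.nan),
                    "p_value": self.wald_p.get(name, np.nan),
                }
            )
        for item_id, deltas in self.thresholds_hat.items():
            for m, d in enumerate(deltas, start=1):
                nm = f"delta[{item_id}][{m}]"
                rows.append(
                    {
                        "coefficient": nm,
                        "estimate": d,
                        "se": self.se.get(nm, np.nan),
                        "p_value": np.nan,
                    }
                )
        for nm, val in (
            ("sigma0_sq", self.random_hat.sigma0_sq),
            ("sigma1_sq", self.random_hat.sigma1_sq),
            ("cov01", self.random_hat.covariance),
        ):
            if nm == "sigma1_sq" and self.spec.random_structure == 1:
                continue
            if nm == "cov01" and self.spec.random_cov != "unstructured_2x2":
                continue
            rows.append(
                {
                    "coefficient": nm,
                    "estimate": val,
                    "se": self.se.get(nm, np.nan),
                    "p_value": np.nan,
                }
            )
        return pd.DataFrame(rows)


def _beta_names(design: str):
    return ("time",) if design == "time_only" else ("group", "time", "group_time")


# ==========================================================================
# Conditional log-likelihood kernels (per ratio family)
#
# Each kernel receives the latent values `theta` (n_obs, K), the effective
# thresholds `delta` (M,) of one item and the observed categories `y`
# (n_obs,), and returns the observation-level log-probability plus the
# requested derivatives with respect to theta and the thresholds.
# ==========================================================================

def _lse(A):
    """logsumexp over the last axis (scipy's adds noticeable overhead)."""
    amax = A.max(axis=-1)
    return amax + np.log(np.sum(np.exp(A - amax[..., None]), axis=-1))


def _kernel_adjacent(F: CdfSpec, theta, delta, y, need_grad, need_curv):
    eta = theta[..., None] - delta                       # (nb, K, M)
    M = delta.size
    logistic = F.name == "logistic"
    if logistic:
        log_odds = eta                                   # exact identity
    else:
        lF, lS = F.logcdf(eta), F.logsf(eta)
        log_odds = lF - lS
    A = np.concatenate(
        [np.zeros(eta.shape[:-1] + (1,)), np.cumsum(log_odds, axis=-1)], axis=-1
    )
    logZ = _lse(A)
    logp = np.take_along_axis(A, y[:, None, None], axis=-1)[..., 0] - logZ
    dtheta = ddelta = d2theta = None
    if need_grad or need_curv:
        pi = np.exp(A - logZ[..., None])                 # (nb, K, M+1)
        if logistic:
            # w = d log-odds / d eta is identically 1
            mvec = np.arange(M + 1, dtype=float)
            EB = pi @ mvec
            dtheta = y[:, None] - EB
            if need_grad:
                tail = 1.0 - np.cumsum(pi, axis=-1)[..., :-1]
                ddelta = tail - (np.arange(1, M + 1) <= y[:, None, None])
            if need_curv:
                d2theta = -(pi @ mvec**2 - EB**2)
            return logp, dtheta, ddelta, d2theta
        logw = np.log(np.maximum(F.pdf(eta), 1e-300)) - lF - lS
        w = np.exp(logw)
        Bfull = np.concatenate(
            [np.zeros(eta.shape[:-1] + (1,)), np.cumsum(w, axis=-1)], axis=-1
        )
        EB = np.einsum("...m,...m->...", pi, Bfull)
        dtheta = (
            np.take_along_axis(Bfull, y[:, None, None], axis=-1)[..., 0] - EB
        )
        if need_grad:
            # tail probability Pr(Y >= l) for l = 1..M
            tail = 1.0 - np.cumsum(pi, axis=-1)[..., :-1]
            ddelta = -w * ((np.arange(1, M + 1) <= y[:, None, None]) - tail)
        if need_curv:
            Fv = F.cdf(eta)
            wprime = w * (F.dpdf(eta) / np.maximum(F.pdf(eta), 1e-300)) - (
                w**2
            ) * (1.0 - 2.0 * Fv)
            Bp = np.concatenate(
                [np.zeros(eta.shape[:-1] + (1,)), np.cumsum(wprime, axis=-1)],
                axis=-1,
            )
            varB = np.einsum("...m,...m->...", pi, Bfull**2) - EB**2
            d2theta = (
                np.take_along_axis(Bp, y[:, None, None], axis=-1)[..., 0]
                - np.einsum("...m,...m->...", pi, Bp)
                - varB
            )
    return logp, dtheta, ddelta, d2theta


def _kernel_cumulative(F: CdfSpec, theta, delta, y, need_grad, need_curv):
    from .links import _log_cdf_diff

    M = delta.size
    nb, K = theta.shape
    logp = np.empty((nb, K))
    dtheta = np.zeros((nb, K)) if (need_grad or need_curv) else None
    ddelta = np.zeros((nb, K, M)) if need_grad else None
    d2theta = np.zeros((nb, K)) if need_curv else None
    for m in range(M + 1):
        sel = y == m
        if not sel.any():
            continue
        th = theta[sel]
        a = th - delta[m - 1] if m >= 1 else None        # upper tail cut
        b = th - delta[m] if m <= M - 1 else None        # next cut
        if m == 0:
            lp = F.logsf(b)
        elif m == M:
            lp = F.logcdf(a)
        else:
            lp = _log_cdf_diff(F, a, b)
        logp[sel] = lp
        if not (need_grad or need_curv):
            continue
        fa = F.pdf(a) if a is not None else 0.0
        fb = F.pdf(b) if b is not None else 0.0
        inv_pi = np.exp(-lp)
        dt = (fa - fb) * inv_pi
        dtheta[sel] = dt
        if need_grad:
            if m >= 1:
                ddelta[sel, :, m - 1] = -fa * inv_pi
            if m <= M - 1:
                ddelta[sel, :, m] = fb * inv_pi
        if need_curv:
            fpa = F.dpdf(a) if a is not None else 0.0
            fpb = F.dpdf(b) if b is not None else 0.0
            d2theta[sel] = (fpa - fpb) * inv_pi - dt**2
    return logp, dtheta, ddelta, d2theta


def _kernel_sequential(F: CdfSpec, theta, delta, y, need_grad, need_curv):
    M = delta.size
    eta = theta[..., None] - delta                       # (nb, K, M)
    logF = F.logcdf(eta)
    logS = F.logsf(eta)
    zero = np.zeros(eta.shape[:-1] + (1,))
    cumS = np.concatenate([zero, np.cumsum(logS, axis=-1)], axis=-1)
    yc = y[:, None, None]
    below = np.take_along_axis(cumS, np.minimum(yc, M), axis=-1)[..., 0]
    at = np.where(
        y[:, None] < M,
        np.take_along_axis(logF, np.minimum(yc, M - 1), axis=-1)[..., 0],
        0.0,
    )
    logp = at + below
    dtheta = ddelta = d2theta = None
    if need_grad or need_curv:
        logpdf = np.log(np.maximum(F.pdf(eta), 1e-300))
        hF = np.exp(logpdf - logF)                       # f / F
        hS = np.exp(logpdf - logS)                       # f / (1 - F)
        cum_hS = np.concatenate([zero, np.cumsum(hS, axis=-1)], axis=-1)
        hF_at = np.where(
            y[:, None] < M,
            np.take_along_axis(hF, np.minimum(yc, M - 1), axis=-1)[..., 0],
            0.0,
        )
        hS_below = np.take_along_axis(cum_hS, np.minimum(yc, M), axis=-1)[..., 0]
        dtheta = hF_at - hS_below
        if need_grad:
            idx = np.arange(1, M + 1)
            ddelta = hS * (idx <= y[:, None, None])
            is_at = idx == (y[:, None, None] + 1)
            ddelta = ddelta - hF * is_at
        if need_curv:
            ratio = F.dpdf(eta) / np.maximum(F.pdf(eta), 1e-300)
            dhF = hF * (ratio - hF)
            dhS = hS * (ratio + hS)
            cum_dhS = np.concatenate([zero, np.cumsum(dhS, axis=-1)], axis=-1)
            dhF_at = np.where(
                y[:, None] < M,
                np.take_along_axis(dhF, np.minimum(yc, M - 1), axis=-1)[..., 0],
                0.0,
            )
            d2theta = dhF_at - np.take_along_axis(
                cum_dhS, np.minimum(yc, M), axis=-1
            )[..., 0]
    return logp, dtheta, ddelta, d2theta


_KERNELS = {
    "adjacent": _kernel_adjacent,
    "cumulative": _kernel_cumulative,
    "sequential": _kernel_sequential,
}


# ==========================================================================
# Parameter layout: natural scale <-> unconstrained optimisation vector
# ==========================================================================

class _ParamLayout:
    """Maps between the unconstrained optimiser vector and natural parameters.

    Vector order: threshold blocks (per item under q=1; shared base followed
    by shifts tau_2..tau_J under q=2), then beta, then the variance block.
    """

    def __init__(self, spec: ModelSpec, bank: ItemBank):
        self.spec = spec
        self.bank = bank
        self.ordered = spec.ratio.name == "cumulative"
        self.q = spec.item_param_kind
        self.a = spec.random_structure
        self.Ms = [it.max_category for it in bank]
        if self.q == 2 and len(set(self.Ms)) != 1:
            raise ConfigurationError(
                "rating-scale parameterisation needs identical category "
                "counts across items"
            )
        pos = 0
        self.thr_slices = []
        if self.q == 1:
            for M in self.Ms:
                self.thr_slices.append(slice(pos, pos + M))
                pos += M
        else:
            M = self.Ms[0]
            self.base_slice = slice(pos, pos + M)
            pos += M
            self.shift_slice = slice(pos, pos + bank.J - 1)
            pos += bank.J - 1
        self.beta_slice = slice(pos, pos + spec.n_beta)
        pos += spec.n_beta
        if self.a == 1:
            nv = 1
        elif spec.random_cov == "independent_diagonal":
            nv = 2
        else:
            nv = 3
        self.var_slice = slice(pos, pos + nv)
        self.size = pos + nv

    # ---- threshold-set transforms ----
    def _set_to_raw(self, delta):
        delta = np.asarray(delta, dtype=float)
        if not self.ordered:
            return delta.copy()
        inc = np.diff(delta)
        if np.any(inc <= 0):
            raise DomainError(
                "cumulative-family thresholds must be strictly increasing"
            )
        return np.concatenate([[delta[0]], np.log(inc)])

    def _raw_to_set(self, raw):
        if not self.ordered:
            return raw.copy()
        return raw[0] + np.concatenate([[0.0], np.cumsum(np.exp(raw[1:]))])

    def _chain_set_grad(self, g_delta, raw):
        """Gradient wrt the raw threshold block from the natural gradient."""
        if not self.ordered:
            return g_delta
        out = np.empty_like(g_delta)
        rev_cum = np.cumsum(g_delta[::-1])[::-1]
        out[0] = rev_cum[0]
        out[1:] = np.exp(raw[1:]) * rev_cum[1:]
        return out

    # ---- full-vector pack/unpack ----
    def pack(self, params: IrtParameters) -> np.ndarray:
        x = np.zeros(self.size)
        if self.q == 1:
            for it, sl in zip(self.bank, self.thr_slices):
                x[sl] = self._set_to_raw(params.thresholds[it.item_id])
        else:
            first = self.bank.items[0]
            x[self.base_slice] = self._set_to_raw(params.thresholds[first.item_id])
            shifts = params.shifts or {}
            x[self.shift_slice] = [
                shifts.get(it.item_id, 0.0) for it in self.bank.items[1:]
            ]
        x[self.beta_slice] = params.beta.beta
        r = params.random
        if self.a == 1:
            x[self.var_slice] = [0.5 * np.log(max(r.sigma0_sq, 1e-14))]
        elif self.spec.random_cov == "independent_diagonal":
            x[self.var_slice] = [
                0.5 * np.log(max(r.sigma0_sq, 1e-14)),
                0.5 * np.log(max(r.sigma1_sq, 1e-14)),
            ]
        else:
            l11 = np.sqrt(max(r.sigma0_sq, 1e-14))
            l21 = r.covariance / l11
            l22 = np.sqrt(max(r.sigma1_sq - l21**2, 1e-14))
            x[self.var_slice] = [np.log(l11), l21, np.log(l22)]
        return x

    def deltas(self, x):
        """Effective per-item threshold vectors at the given vector."""
        if self.q == 1:
            return [self._raw_to_set(x[sl]) for sl in self.thr_slices]
        base = self._raw_to_set(x[self.base_slice])
        shifts = np.concatenate([[0.0], x[self.shift_slice]])
        return [base + tau for tau in shifts]

    def chol(self, x):
        """Cholesky factor L of the random-effect covariance (d x d)."""
        v = x[self.var_slice]
        if self.a == 1:
            return np.array([[np.exp(v[0])]])
        if self.spec.random_cov == "independent_diagonal":
            return np.diag(np.exp(v[:2]))
        return np.array([[np.exp(v[0]), 0.0], [v[1], np.exp(v[2])]])

    def unpack(self, x) -> IrtParameters:
        deltas = self.deltas(x)
        thresholds = {
            it.item_id: tuple(np.round(d, 12))
            for it, d in zip(self.bank, deltas)
        }
        shifts = None
        if self.q == 2:
            sh = np.concatenate([[0.0], x[self.shift_slice]])
            shifts = {it.item_id: float(s) for it, s in zip(self.bank, sh)}
            first = self.bank.items[0].item_id
            thresholds = {it.item_id: thresholds[first] for it in self.bank}
        beta = FixedEffects(tuple(x[self.beta_slice]), self.spec.fixed_design)
        L = self.chol(x)
        S = L @ L.T
        random = RandomEffectsSpec(
            sigma0_sq=float(S[0, 0]),
            sigma1_sq=float(S[1, 1]) if self.a == 2 else 0.0,
            covariance=(
                float(S[1, 0]) if self.spec.random_cov == "unstructured_2x2" else 0.0
            ),
        )
        return IrtParameters(beta, thresholds, random, shifts)

    def bounds(self):
        bounds = [(None, None)] * self.size
        if self.ordered:
            sls = self.thr_slices if self.q == 1 else [self.base_slice]
            for sl in sls:
                for i in range(sl.start + 1, sl.stop):
                    bounds[i] = _LOG_INC_BOUNDS
        v = self.var_slice
        if self.a == 1:
            bounds[v.start] = _LOG_SD_BOUNDS
        elif self.spec.random_cov == "independent_diagonal":
            bounds[v.start] = _LOG_SD_BOUNDS
            bounds[v.start + 1] = _LOG_SD_BOUNDS
        else:
            bounds[v.start] = _LOG_SD_BOUNDS
            bounds[v.start + 2] = _LOG_SD_BOUNDS
        return bounds

    def natural_vector(self, x):
        """Natural-scale parameter values with names, for SE reporting."""
        names, vals = [], []
        for it, d in zip(self.bank, self.deltas(x)):
            for m, dm in enumerate(d, start=1):
                names.append(f"delta[{it.item_id}][{m}]")
                vals.append(dm)
        for nm, b in zip(_beta_names(self.spec.fixed_design), x[self.beta_slice]):
            names.append(nm)
            vals.append(b)
        L = self.chol(x)
        S = L @ L.T
        names.append("sigma0_sq")
        vals.append(S[0, 0])
        if self.a == 2:
            names.append("sigma1_sq")
            vals.append(S[1, 1])
            if self.spec.random_cov == "unstructured_2x2":
                names.append("cov01")
                vals.append(S[1, 0])
        return names, np.array(vals)


# ==========================================================================
# Data packing
# ==========================================================================

class _Packed:
    """Dense arrays extracted from a ResponseDataset, sorted by subject."""

    def __init__(self, data: ResponseDataset, spec: ModelSpec, bank: ItemBank):
        df = data.records.sort_values(
            ["subject_id", "time", "item_id"], kind="stable"
        ).reset_index(drop=True)
        subj, self.sub_idx = np.unique(df["subject_id"].to_numpy(), return_inverse=True)
        # np.unique sorts; re-derive a stable sort of the frame by the codes
        order = np.argsort(self.sub_idx, kind="stable")
        df = df.iloc[order].reset_index(drop=True)
        self.sub_idx = self.sub_idx[order]
        self.subjects = subj
        self.n = subj.size
        t0 = float(df["time"].min())
        self.dt = df["time"].to_numpy(dtype=float) - t0
        self.g = df["group"].to_numpy(dtype=float)
        self.y = df["response"].to_numpy(dtype=np.int64)
        item_ids = [str(i) for i in bank.ids()]
        codes = pd.Categorical(
            df["item_id"].astype(str), categories=item_ids
        ).codes
        self.item_idx = np.asarray(codes)
        self.n_obs = len(df)
        self.starts = np.searchsorted(self.sub_idx, np.arange(self.n))
        if spec.fixed_design == "time_only":
            self.X = self.dt[:, None]
        else:
            self.X = np.column_stack([self.g, self.dt, self.g * self.dt])
        # per-item observation blocks (subject order preserved inside a block)
        self.blocks = []
        for j in range(bank.J):
            idx = np.flatnonzero(self.item_idx == j)
            bstarts = np.searchsorted(self.sub_idx[idx], np.arange(self.n))
            counts = np.diff(np.append(bstarts, idx.size))
            self.blocks.append((idx, bstarts, counts))

    def seg_sum(self, arr):
        """Sum an (n_obs, ...) array within subjects -> (n, ...)."""
        return np.add.reduceat(arr, self.starts, axis=0)

    def block_seg_sum(self, j, arr):
        """Per-subject sums of a per-item-block array, zero-filled for
        subjects without observations of that item."""
        idx, bstarts, counts = self.blocks[j]
        safe = np.minimum(bstarts, max(idx.size - 1, 0))
        out = np.add.reduceat(arr, safe, axis=0)
        out[counts == 0] = 0.0
        return out


# ==========================================================================
# Core evaluation
# ==========================================================================

def _conditional(layout, packed, deltas, beta, xi0, xi1, need_grad, need_curv):
    """Conditional pieces at given random-effect values.

    ``xi0``/``xi1`` have shape (n, K).  Returns per-subject-per-node sums:
    the conditional log-likelihood ``c`` (n, K) and, as requested, the
    derivative aggregates needed for the parameter gradient (d beta,
    d thresholds) or for the posterior curvature (d/d xi and d2/d xi2).
    """
    F = layout.spec.cdf
    kern = _KERNELS[layout.spec.ratio.name]
    K = xi0.shape[1]
    fixed = packed.X @ beta
    theta = fixed[:, None] + xi0[packed.sub_idx]
    if xi1 is not None:
        theta = theta + packed.dt[:, None] * xi1[packed.sub_idx]

    logp_full = np.empty((packed.n_obs, K))
    dtheta_full = np.empty((packed.n_obs, K)) if (need_grad or need_curv) else None
    d2_full = np.empty((packed.n_obs, K)) if need_curv else None
    ddelta_red = [] if need_grad else None

    for j, dvec in enumerate(deltas):
        idx, _, _ = packed.blocks[j]
        lp, dth, dde, d2 = kern(
            F, theta[idx], dvec, packed.y[idx], need_grad, need_curv
        )
        logp_full[idx] = lp
        if dtheta_full is not None:
            dtheta_full[idx] = dth
        if need_curv:
            d2_full[idx] = d2
        if need_grad:
            ddelta_red.append(packed.block_seg_sum(j, dde))

    out = {"c": packed.seg_sum(logp_full)}
    if need_grad:
        out["dbeta"] = np.stack(
            [packed.seg_sum(dtheta_full * packed.X[:, b, None])
             for b in range(packed.X.shape[1])],
            axis=-1,
        )
        out["ddelta"] = ddelta_red
    if need_curv:
        u1 = packed.dt[:, None]
        out["gxi0"] = packed.seg_sum(dtheta_full)
        out["h00"] = packed.seg_sum(d2_full)
        if xi1 is not None:
            out["gxi1"] = packed.seg_sum(dtheta_full * u1)
            out["h01"] = packed.seg_sum(d2_full * u1)
            out["h11"] = packed.seg_sum(d2_full * u1**2)
    return out


def _find_modes(layout, packed, deltas, beta, L, mu0, max_iter=30, tol=1e-6):
    """Per-subject posterior modes and Cholesky factors of the posterior
    covariance, by safeguarded Newton iterations (the conditional
    log-likelihood is log-concave for all supported families)."""
    d = L.shape[0]
    Sinv = np.linalg.inv(L @ L.T)
    mu = mu0.copy()

    def pieces(mu):
        xi0 = mu[:, 0:1]
        xi1 = mu[:, 1:2] if d == 2 else None
        cond = _conditional(
            layout, packed, deltas, beta, xi0, xi1, need_grad=False, need_curv=True
        )
        quad = np.einsum("id,de,ie->i", mu, Sinv, mu)
        h = cond["c"][:, 0] - 0.5 * quad
        g = np.empty((packed.n, d))
        g[:, 0] = cond["gxi0"][:, 0]
        if d == 2:
            g[:, 1] = cond["gxi1"][:, 0]
        g -= mu @ Sinv
        H = np.empty((packed.n, d, d))
        H[:, 0, 0] = cond["h00"][:, 0]
        if d == 2:
            H[:, 0, 1] = H[:, 1, 0] = cond["h01"][:, 0]
            H[:, 1, 1] = cond["h11"][:, 0]
        H -= Sinv
        return h, g, H

    h, g, H = pieces(mu)
    for _ in range(max_iter):
        if np.max(np.abs(g)) < tol:
            break
        step = np.linalg.solve(-H, g[..., None])[..., 0]
        lam = np.ones(packed.n)
        for _ in range(12):
            trial = mu + lam[:, None] * step
            h_new, g_new, H_new = pieces(trial)
            worse = h_new < h - 1e-12
            if not worse.any():
                break
            lam[worse] *= 0.5
        mu, h, g, H = trial, h_new, g_new, H_new
    # Cholesky of the posterior covariance (-H)^-1
    A = -H
    if d == 1:
        B = 1.0 / np.sqrt(np.maximum(A[:, 0, 0], 1e-12))
        B = B[:, None, None]
    else:
        det = np.maximum(A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] ** 2, 1e-12)
        inv = np.empty_like(A)
        inv[:, 0, 0] = A[:, 1, 1] / det
        inv[:, 1, 1] = A[:, 0, 0] / det
        inv[:, 0, 1] = inv[:, 1, 0] = -A[:, 0, 1] / det
        B = np.zeros_like(A)
        B[:, 0, 0] = np.sqrt(np.maximum(inv[:, 0, 0], 1e-12))
        B[:, 1, 0] = inv[:, 1, 0] / B[:, 0, 0]
        B[:, 1, 1] = np.sqrt(
            np.maximum(inv[:, 1, 1] - B[:, 1, 0] ** 2, 1e-12)
        )
    return mu, B


def _gh_nodes(K, d):
    z, w = np.polynomial.hermite.hermgauss(K)
    logw = np.log(w)
    if d == 1:
        return z[:, None], logw
    Z0, Z1 = np.meshgrid(z, z, indexing="ij")
    zz = np.column_stack([Z0.ravel(), Z1.ravel()])
    lw = (logw[:, None] + logw[None, :]).ravel()
    return zz, lw


def _marginal_eval(layout, packed, x, quad, mode_cache=None, need_grad=False):
    """Marginal log-likelihood (and gradient) at optimiser vector ``x``."""
    deltas = layout.deltas(x)
    beta = x[layout.beta_slice]
    L = layout.chol(x)
    d = L.shape[0]
    z, logw = _gh_nodes(quad.nodes_per_dim, d)
    K = z.shape[0]

    if quad.adaptive:
        mu0 = (
            mode_cache.get("mu")
            if mode_cache and mode_cache.get("mu") is not None
            else np.zeros((packed.n, d))
        )
        mu, B = _find_modes(layout, packed, deltas, beta, L, mu0)
        if mode_cache is not None:
            mode_cache["mu"] = mu
    else:
        mu = np.zeros((packed.n, d))
        B = np.broadcast_to(L, (packed.n, d, d)).copy()

    # nodes in random-effect space: xi_ik = mu_i + sqrt(2) B_i z_k
    xi = mu[:, None, :] + np.sqrt(2.0) * np.einsum("ide,ke->ikd", B, z)
    xi0 = xi[..., 0]
    xi1 = xi[..., 1] if d == 2 else None

    cond = _conditional(
        layout, packed, deltas, beta, xi0, xi1, need_grad=need_grad, need_curv=False
    )

    # prior log-density at the nodes
    v0 = xi0 / L[0, 0]
    quad_form = v0**2
    if d == 2:
        v1 = (xi1 - L[1, 0] * v0) / L[1, 1]
        quad_form = quad_form + v1**2
    log_phi = (
        -0.5 * d * np.log(2 * np.pi)
        - np.sum(np.log(np.diag(L)))
        - 0.5 * quad_form
    )

    bracket = logw[None, :] + np.sum(z**2, axis=1)[None, :] + cond["c"] + log_phi
    log_det_B = np.sum(np.log(np.diagonal(B, axis1=1, axis2=2)), axis=1)
    logL_i = 0.5 * d * np.log(2.0) + log_det_B + _lse(bracket)
    ll = float(np.sum(logL_i))

    if not need_grad:
        return ll, None, logL_i

    qw = np.exp(bracket - _lse(bracket)[:, None])
    grad = np.zeros(layout.size)
    # thresholds
    if layout.q == 1:
        for sl, red, raw in zip(
            layout.thr_slices, cond["ddelta"],
            [x[sl] for sl in layout.thr_slices],
        ):
            g_nat = np.einsum("ik,ikm->m", qw, red)
            grad[sl] = layout._chain_set_grad(g_nat, raw)
    else:
        g_base = np.zeros(layout.Ms[0])
        g_shift = []
        for j, red in enumerate(cond["ddelta"]):
            g_nat = np.einsum("ik,ikm->m", qw, red)
            g_base += g_nat
            if j >= 1:
                g_shift.append(np.sum(g_nat))
        grad[layout.base_slice] = layout._chain_set_grad(
            g_base, x[layout.base_slice]
        )
        grad[layout.shift_slice] = g_shift
    # fixed effects
    grad[layout.beta_slice] = np.einsum("ik,ikb->b", qw, cond["dbeta"])
    # variance components (xi nodes held fixed)
    vsl = layout.var_slice
    if layout.a == 1:
        grad[vsl.start] = np.einsum("ik,ik->", qw, v0**2 - 1.0)
    elif layout.spec.random_cov == "independent_diagonal":
        grad[vsl.start] = np.einsum("ik,ik->", qw, v0**2 - 1.0)
        grad[vsl.start + 1] = np.einsum("ik,ik->", qw, v1**2 - 1.0)
    else:
        l21, l22 = L[1, 0], L[1, 1]
        grad[vsl.start] = np.einsum(
            "ik,ik->", qw, v0**2 - 1.0 - v1 * v0 * l21 / l22
        )
        grad[vsl.start + 1] = np.einsum("ik,ik->", qw, v0 * v1 / l22)
        grad[vsl.start + 2] = np.einsum("ik,ik->", qw, v1**2 - 1.0)
    return ll, grad, logL_i


# ==========================================================================
# Public API
# ==========================================================================

def marginal_loglik(
    data: ResponseDataset,
    spec: ModelSpec,
    params: IrtParameters,
    quad: QuadratureConfig = QuadratureConfig(),
) -> float:
    """Marginal log-likelihood at the given parameters.

    Deterministic given the parameters and quadrature settings.  Raises
    :class:`DomainError` if the likelihood is non-finite, naming the first
    offending subject.
    """
    layout = _ParamLayout(spec, data.items)
    packed = _Packed(data, spec, data.items)
    x = layout.pack(params)
    ll, _, logL_i = _marginal_eval(layout, packed, x, quad)
    if not np.isfinite(ll):
        bad = packed.subjects[~np.isfinite(logL_i)]
        raise DomainError(
            f"non-finite likelihood contribution for subject(s) {bad[:5].tolist()}"
        )
    return ll


def _start_values(layout, packed, bank, spec) -> np.ndarray:
    """Heuristic starting vector: thresholds from pooled inverse-CdF of the
    observed category frequencies, beta = 0, sigma0^2 = 1, sigma1^2 = 0.05."""
    F = spec.cdf
    x = np.zeros(layout.size)
    start_sets = []
    for j, it in enumerate(bank):
        idx, _, _ = packed.blocks[j]
        counts = np.bincount(packed.y[idx], minlength=it.n_categories) + 0.5
        M = it.max_category
        if spec.ratio.name == "cumulative":
            tail = np.cumsum(counts[::-1])[::-1]
            p = tail[1:] / tail[0]
            delta = -F.ppf(np.clip(p, 1e-4, 1 - 1e-4))
        elif spec.ratio.name == "adjacent":
            p = counts[1:] / (counts[1:] + counts[:-1])
            delta = -F.ppf(np.clip(p, 1e-4, 1 - 1e-4))
        else:
            tail = np.cumsum(counts[::-1])[::-1]
            p = counts[:-1] / tail[:-1]
            delta = -F.ppf(np.clip(p, 1e-4, 1 - 1e-4))
        # the cumulative transform needs strictly increasing values
        for m in range(1, M):
            if delta[m] <= delta[m - 1] + 1e-3 and layout.ordered:
                delta[m] = delta[m - 1] + 0.05
        start_sets.append(delta)
    if layout.q == 1:
        for sl, delta in zip(layout.thr_slices, start_sets):
            x[sl] = layout._set_to_raw(delta)
    else:
        x[layout.base_slice] = layout._set_to_raw(start_sets[0])
        x[layout.shift_slice] = 0.0
    v = layout.var_slice
    x[v.start] = 0.0                       # sigma0 = 1
    if layout.a == 2:
        if spec.random_cov == "independent_diagonal":
            x[v.start + 1] = 0.5 * np.log(0.05)
        else:
            x[v.start + 1] = 0.0
            x[v.start + 2] = 0.5 * np.log(0.05)
    return x


def _collapse_unobserved(data: ResponseDataset, spec: ModelSpec) -> ResponseDataset:
    """For the cumulative family, merge categories that were never observed
    into their lower neighbour (top/bottom into the adjacent category).  The
    cumulative model is invariant under gathering successive categories, so
    this only removes unidentifiable thresholds."""
    df = data.records
    new_items = []
    changed = False
    df = df.copy()
    for it in data.items:
        mask = df["item_id"].astype(str) == str(it.item_id)
        obs = np.bincount(
            df.loc[mask, "response"].to_numpy(dtype=int), minlength=it.n_categories
        )
        if np.all(obs > 0):
            new_items.append(it)
            continue
        changed = True
        keep = np.flatnonzero(obs > 0)
        if keep.size < 2:
            raise DomainError(
                f"item {it.item_id!r} has fewer than 2 observed categories"
            )
        remap = np.searchsorted(keep, np.arange(it.n_categories), side="right") - 1
        remap = np.maximum(remap, 0)
        df.loc[mask, "response"] = remap[df.loc[mask, "response"].to_numpy(dtype=int)]
        logger.warning(
            "item %s: collapsing unobserved categories %s for the cumulative fit",
            it.item_id,
            np.flatnonzero(obs == 0).tolist(),
        )
        new_items.append(
            Item(
                item_id=it.item_id,
                n_categories=keep.size,
                thresholds=tuple(0.0 for _ in range(keep.size - 1)),
                shift=it.shift,
                discrimination=it.discrimination,
            )
        )
    if not changed:
        return data
    return ResponseDataset(df, ItemBank(tuple(new_items)))


def fit_irt(
    data: ResponseDataset,
    spec: ModelSpec,
    quad: QuadratureConfig = QuadratureConfig(),
    start: Optional[IrtParameters] = None,
    compute_se: bool = True,
    max_restarts: int = 3,
) -> FitResult:
    """Fit an IRT mixed model by maximising the marginal likelihood.

    Non-convergence is flagged on the result, not raised.  ``start`` allows
    warm starts (e.g. the intercept-only fit when adding a random slope).
    """
    if spec.ratio.name == "cumulative":
        data = _collapse_unobserved(data, spec)
    bank = data.items
    layout = _ParamLayout(spec, bank)
    packed = _Packed(data, spec, bank)
    for j, it in enumerate(bank):
        idx = packed.blocks[j][0]
        if np.unique(packed.y[idx]).size < 2:
            raise DomainError(
                f"item {it.item_id!r} has fewer than 2 observed categories"
            )

    x0 = layout.pack(start) if start is not None else _start_values(
        layout, packed, bank, spec
    )
    bounds = layout.bounds()
    cache = {"mu": None}

    def objective(x):
        ll, grad, _ = _marginal_eval(
            layout, packed, x, quad, mode_cache=cache, need_grad=True
        )
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(x)
        return -ll, -grad

    rng = np.random.default_rng(0)
    best = None
    converged = False
    message = ""
    for attempt in range(max_restarts):
        xs = x0 if attempt == 0 else x0 + rng.normal(0.0, 0.1, size=x0.size)
        cache["mu"] = None
        res = optimize.minimize(
            objective,
            xs,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-6},
        )
        ok = res.success or (
            np.isfinite(res.fun) and np.max(np.abs(res.jac)) < 1e-3
        )
        if best is None or res.fun < best.fun:
            best = res
        message = str(res.message)
        if ok:
            converged = True
            best = res if res.fun <= best.fun else best
            break

    x_hat = best.x
    ll = -float(best.fun)
    params = layout.unpack(x_hat)

    # boundary handling for variance components
    boundary = False
    v = layout.var_slice
    random = params.random
    if layout.a == 2:
        s1_idx = v.start + 1 if spec.random_cov == "independent_diagonal" else v.start + 2
        if x_hat[s1_idx] <= _BOUNDARY_LOG_SD:
            boundary = True
            random = RandomEffectsSpec(
                sigma0_sq=random.sigma0_sq, sigma1_sq=0.0, covariance=0.0
            )
    if x_hat[v.start] <= _BOUNDARY_LOG_SD:
        boundary = True
        random = RandomEffectsSpec(
            sigma0_sq=0.0,
            sigma1_sq=random.sigma1_sq,
            covariance=random.covariance,
        )

    n_params = layout.size
    bic = -2.0 * ll + n_params * np.log(packed.n)

    se: dict = {}
    wald: dict = {}
    if compute_se and converged:
        se, wald = _standard_errors(layout, packed, x_hat, quad)

    return FitResult(
        spec=spec,
        beta_hat=params.beta,
        thresholds_hat=params.thresholds,
        random_hat=random,
        loglik=ll,
        bic=float(bic),
        se=se,
        wald_p=wald,
        converged=converged,
        n_used=packed.n,
        n_params=n_params,
        boundary=boundary,
        shifts_hat=params.shifts,
        message=message,
    )


def _standard_errors(layout, packed, x_hat, quad):
    """SEs from the inverse observed information, mapped to the natural
    scale by the delta method (numerical Jacobian of the transform)."""
    p = layout.size
    cache = {"mu": None}

    def grad(x):
        _, g, _ = _marginal_eval(
            layout, packed, x, quad, mode_cache=cache, need_grad=True
        )
        return g

    H = np.zeros((p, p))
    h = 1e-4 * (1.0 + np.abs(x_hat))
    for i in range(p):
        e = np.zeros(p)
        e[i] = h[i]
        H[i] = -(grad(x_hat + e) - grad(x_hat - e)) / (2 * h[i])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    if np.any(np.diag(cov) < 0):
        cov = np.where(np.isfinite(cov), cov, np.nan)

    names, nat = layout.natural_vector(x_hat)

    def nat_fn(x):
        return layout.natural_vector(x)[1]

    J = np.zeros((nat.size, p))
    for i in range(p):
        e = np.zeros(p)
        e[i] = h[i]
        J[:, i] = (nat_fn(x_hat + e) - nat_fn(x_hat - e)) / (2 * h[i])
    cov_nat = J @ cov @ J.T
    with np.errstate(invalid="ignore"):
        ses = np.sqrt(np.diag(cov_nat))
    se = {nm: float(s) for nm, s in zip(names, ses)}
    wald = {}
    for nm in _beta_names(layout.spec.fixed_design):
        est = nat[names.index(nm)]
        s = se.get(nm, np.nan)
        wald[nm] = wald_p(est, s)
    return se, wald


def wald_p(estimate: float, se: float) -> float:
    """Two-sided Wald p-value from the normal approximation."""
    if not np.isfinite(se) or se <= 0:
        return np.nan
    return float(2.0 * stats.norm.sf(abs(estimate) / se))


def wald_test(fit: FitResult, coefficient: str) -> float:
    """Two-sided Wald p-value of a named fixed coefficient."""
    names = _beta_names(fit.spec.fixed_design)
    if coefficient not in names:
        raise ConfigurationError(
            f"unknown coefficient {coefficient!r}; expected one of {names}"
        )
    est = fit.beta_hat.beta[names.index(coefficient)]
    return wald_p(est, fit.se.get(coefficient, np.nan))


def bic_select(fit_m1: FitResult, fit_m2: FitResult) -> str:
    """BIC choice between the intercept-only (M1) and intercept+slope (M2)
    fits of the same data; ties go to the more parsimonious M1."""
    if not (fit_m1.converged and fit_m2.converged):
        raise DomainError("bic_select requires two converged fits")
    if fit_m2.bic < fit_m1.bic - 1e-8:
        return "M2"
    return "M1"


def fit_random_structures(
    data: ResponseDataset,
    spec: ModelSpec,
    quad: QuadratureConfig = QuadratureConfig(),
    compute_se: bool = False,
):
    """Fit M1 and M2 on the same data; the slope fit is warm-started from
    the intercept-only estimates."""
    fit1 = fit_irt(
        data, spec.with_random_structure(1), quad, compute_se=compute_se
    )
    p1 = fit1.params()
    warm = IrtParameters(
        beta=p1.beta,
        thresholds=p1.thresholds,
        random=RandomEffectsSpec(
            sigma0_sq=max(p1.random.sigma0_sq, 1e-4), sigma1_sq=0.05
        ),
        shifts=p1.shifts,
    )
    fit2 = fit_irt(
        data,
        spec.with_random_structure(2),
        quad,
        start=warm,
        compute_se=compute_se,
    )
    return fit1, fit2


def probability_curves(
    fit_or_params,
    item: Item,
    times,
    groups=(0, 1),
    spec: Optional[ModelSpec] = None,
    baseline_time: float = 0.0,
) -> pd.DataFrame:
    """Expected category probabilities over time at zero random effects.

    Returns one row per (time, group, category) with the probability and the
    upper-tail cut-point ``Pr(Y >= category)`` used for stacked-band plots.
    """
    if isinstance(fit_or_params, FitResult):
        spec = fit_or_params.spec
        beta = fit_or_params.beta_hat
    else:
        beta = fit_or_params.beta
        if spec is None:
            raise ConfigurationError("spec is required with raw parameters")
    rows = []
    use_groups = groups if spec.fixed_design == "group_time_interaction" else (0,)
    for t in times:
        for g in use_groups:
            theta = latent_value(
                {"time": t, "baseline_time": baseline_time, "group": g},
                beta,
            )
            probs = category_probability(theta, item, spec)
            tails = np.concatenate([[1.0], np.cumsum(probs[::-1])[::-1][1:]])
            for m, (pi, tail) in enumerate(zip(probs, tails)):
                rows.append(
                    {
                        "time": float(t),
                        "group": int(g),
                        "category": m,
                        "prob": float(pi),
                        "tail_prob": float(tail),
                    }
                )
    return pd.DataFrame(rows)
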