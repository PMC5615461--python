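"""Multinomial simulation of longitudinal ordinal item responses.

The generator draws, per subject, a random intercept ``xi_0 ~ N(0, sigma0^2)``
and (if the slope variance is positive) an independent random slope
``xi_1 ~ N(0, sigma1^2)``, forms the latent trajectory
``theta_iv = (t_v - t_0) beta_1 + xi_0 + (t_v - t_0) xi_1``, and draws one
multinomial response per (subject, visit, item) from the category
probabilities of the chosen (ratio, CdF) pair.

The default preset mirrors a two-item symptom dimension with four response
levels: n = 300 subjects, visits at months (0, 1, 2, 4, 6, 8, 10, 12),
``sigma0^2 = 1.5``, and the "near"/"far" threshold sets below.  An
alternative visit grid (0, 0.5, 1, 2, 4, 6, 8, 10) is available as
``VISITS_ALT``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .links import ConfigurationError
from .model import Item, ItemBank, ModelSpec, ResponseDataset, category_probability

# Threshold sets for the two-item presets.  "near" puts the two upper
# thresholds close together; "far" spreads them out.
DELTA_NEAR = ((-1.6, 1.0, 1.45), (-0.8, 1.15, 1.9))
DELTA_FAR = ((-2.1, 1.0, 2.75), (-1.25, 1.4, 3.3))

VISITS_DEFAULT = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
VISITS_ALT = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)


@dataclass(frozen=True)
class ScenarioPreset:
    """One simulation scenario: generating family, threshold set, effect
    sizes, sample size, visit grid and seed."""

    ratio: str = "adjacent"
    delta_set: str = "near"            # 'near' or 'far'
    beta1: float = 0.3
    sigma0_sq: float = 1.5
    sigma1_sq: float = 0.2             # 0 => generate under M1
    n_subjects: int = 300
    visit_times: tuple = VISITS_DEFAULT
    seed: int = 0
    cdf: str = "logistic"

    def __post_init__(self):
        if self.delta_set not in ("near", "far"):
            raise ConfigurationError("delta_set must be 'near' or 'far'")
        if self.sigma0_sq < 0 or self.sigma1_sq < 0:
            raise ConfigurationError("variances must be non-negative")
        object.__setattr__(self, "visit_times", tuple(float(t) for t in self.visit_times))

    def item_bank(self) -> ItemBank:
        deltas = DELTA_NEAR if self.delta_set == "near" else DELTA_FAR
        return ItemBank(
            tuple(
                Item(item_id=f"item{j + 1}", n_categories=4, thresholds=d)
                for j, d in enumerate(deltas)
            )
        )

    def model_spec(self) -> ModelSpec:
        a = 2 if self.sigma1_sq > 0 else 1
        return ModelSpec(
            ratio=self.ratio,
            cdf=self.cdf,
            item_param_kind=1,
            random_structure=a,
            fixed_design="time_only",
        )


def replicate_seeds(base_seed: int, N: int) -> list:
    """Deterministic, collision-free per-replicate seeds (< 2^31)."""
    if N < 1:
        raise ConfigurationError("N must be >= 1")
    ss = np.random.SeedSequence(int(base_seed))
    state = ss.generate_state(N, dtype=np.uint64)
    seeds = (state % (2**31 - 1)).astype(np.int64)
    # resolve the (practically impossible) collisions deterministically
    seen = set()
    out = []
    for s in seeds:
        s = int(s)
        while s in seen:
            s = (s + 1) % (2**31 - 1)
        seen.add(s)
        out.append(s)
    return out


def simulate_dataset(
    preset: ScenarioPreset, spec: Optional[ModelSpec] = None
) -> ResponseDataset:
    """Draw one longitudinal dataset from the preset's generating model.

    Fully reproducible from ``preset.seed``: random effects are drawn first
    (intercepts then slopes), then one uniform per (subject, visit, item) in
    subject-major order is inverted through the category CdF.
    """
    spec = spec or preset.model_spec()
    bank = preset.item_bank()
    rng = np.random.default_rng(preset.seed)
    n, times = preset.n_subjects, np.asarray(preset.visit_times)
    t0 = times.min()
    xi0 = rng.normal(0.0, np.sqrt(preset.sigma0_sq), size=n)
    if preset.sigma1_sq > 0:
        xi1 = rng.normal(0.0, np.sqrt(preset.sigma1_sq), size=n)
    else:
        xi1 = np.zeros(n)
    dt = times - t0
    theta = dt[None, :] * preset.beta1 + xi0[:, None] + dt[None, :] * xi1[:, None]

    # one uniform per (subject, visit, item), subject-major order
    u = rng.random((n, times.size, bank.J))
    frames = []
    for j, item in enumerate(bank):
        probs = category_probability(theta, item, spec)      # (n, V, M+1)
        cum = np.cumsum(probs, axis=-1)
        cat = np.sum(u[:, :, j, None] > cum[..., :-1], axis=-1)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(np.arange(1, n + 1), times.size),
                    "group": 0,
                    "time": np.tile(times, n),
                    "item_id": item.item_id,
                    "response": cat.ravel(),
                }
            )
        )
    df = (
        pd.concat(frames)
        .sort_values(["subject_id", "time", "item_id"], kind="stable")
        .reset_index(drop=True)
    )
    return ResponseDataset(df, bank)


def simulate_lmm_scores(
    beta0: float,
    beta1: float,
    sigma0_sq: float,
    sigma1_sq: float,
    sigma_eps_sq: float,
    n_subjects: int = 300,
    visit_times: Sequence[float] = VISITS_DEFAULT,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian scores from the linear mixed model
    ``S_iv = beta0 + (t_v - t_0) beta1 + xi_0 + (t_v - t_0) xi_1 + eps``."""
    if min(sigma0_sq, sigma1_sq, sigma_eps_sq) < 0:
        raise ConfigurationError("variances must be non-negative")
    rng = np.random.default_rng(seed)
    times = np.asarray(visit_times, dtype=float)
    dt = times - times.min()
    n = n_subjects
    xi0 = rng.normal(0.0, np.sqrt(sigma0_sq), size=n)
    xi1 = rng.normal(0.0, np.sqrt(sigma1_sq), size=n)
    eps = rng.normal(0.0, np.sqrt(sigma_eps_sq), size=(n, times.size))
    S = beta0 + dt[None, :] * beta1 + xi0[:, None] + dt[None, :] * xi1[:, None] + eps
    return pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(1, n + 1), times.size),
            "time": np.tile(times, n),
            "score": S.ravel(),
        }
    )
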