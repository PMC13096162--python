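"""Synthetic cohort and trial-level behaviour generators.

The cohort generator draws participant profiles matching the study's
demographics: a continuous bilingual-experience score (LSBQ composite,
truncated normal with mean 9.01, SD 2.69 on [5.05, 14.05]), age (33.11 ±
9.57 years on [18, 57]), second-language age of acquisition, ordinal
education, gender, handedness and task-presentation order.

The behaviour generator produces trial-level reaction times for a built
session with a known additive structure: block-wise learning (default −84 ms
from the first to the eighth block), a negative LSBQ offset (more bilingual
experience → faster responses), a positive block × LSBQ interaction at
ambiguity levels ≥ 1 (more experience → flatter learning slopes), a slowing
per ambiguity level, and mean-one log-normal multiplicative noise.
Correctness is Bernoulli with a 0.97 accuracy rate.  Effect magnitudes are
generator configuration — the shapes, not the sizes, are what the
downstream behavioural models are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ambiguity import DEFAULT_MAX_LEVEL
from .session import SessionSpec

__all__ = [
    "CohortConfig",
    "BehaviorParams",
    "sample_cohort",
    "simulate_behavior",
    "N_PARTICIPANTS",
]

#: Final analysed sample size of the emulated study.
N_PARTICIPANTS = 28

TASK_ORDERS = ["ALF", "AFL", "LAF", "LFA", "FAL", "FLA"]  # A=AGL, L=lexical, F=flanker


@dataclass(frozen=True)
class CohortConfig:
    """Population parameters for the synthetic cohort (study demographics)."""

    lsbq_mean: float = 9.01
    lsbq_sd: float = 2.69
    lsbq_bounds: tuple[float, float] = (5.05, 14.05)
    age_mean: float = 33.11
    age_sd: float = 9.57
    age_bounds: tuple[float, float] = (18.0, 57.0)
    l2_aoa_mean: float = 6.25
    l2_aoa_sd: float = 4.63
    l2_aoa_bounds: tuple[float, float] = (0.0, 20.0)
    # ordinal education 1..4 (GCSE/O-level, A-level, degree, postgraduate)
    education_probs: tuple[float, ...] = (1 / 28, 4 / 28, 10 / 28, 13 / 28)
    p_female: float = 21 / 28
    p_left_handed: float = 2 / 28

    def __post_init__(self):
        for lo, hi in (self.lsbq_bounds, self.age_bounds, self.l2_aoa_bounds):
            if not lo < hi:
                raise ValueError(f"invalid bounds ({lo}, {hi})")
        if abs(sum(self.education_probs) - 1.0) > 1e-9:
            raise ValueError("education probabilities must sum to 1")


def _truncnorm(rng, mean, sd, bounds, size):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_cohort(
    n: int,
    seed: int | np.random.SeedSequence,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Draw ``n`` participant profiles; deterministic given the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:03d}" for i in range(n)],
            "lsbq": _truncnorm(rng, cfg.lsbq_mean, cfg.lsbq_sd, cfg.lsbq_bounds, n),
            "age": _truncnorm(rng, cfg.age_mean, cfg.age_sd, cfg.age_bounds, n),
            "l2_aoa": _truncnorm(
                rng, cfg.l2_aoa_mean, cfg.l2_aoa_sd, cfg.l2_aoa_bounds, n
            ),
            "education": rng.choice(
                np.arange(1, len(cfg.education_probs) + 1), size=n, p=cfg.education_probs
            ),
            "gender": np.where(rng.random(n) < cfg.p_female, "female", "male"),
            "handedness": np.where(rng.random(n) < cfg.p_left_handed, "left", "right"),
            "task_order": rng.choice(TASK_ORDERS, size=n),
        }
    )
    return df


@dataclass(frozen=True)
class BehaviorParams:
    """Additive reaction-time model used to simulate trial responses.

    ``block_rt_change_ms`` is the total change from the first to the last of
    the eight blocks (applied linearly); ``lsbq_rt_offset_ms`` is the RT
    shift per LSBQ unit (centred at ``lsbq_center``);
    ``lsbq_slope_flattening_ms`` maps ambiguity level (>= 1) to the block ×
    LSBQ interaction in ms per block step per LSBQ unit (positive values
    flatten the learning slope of more experienced participants);
    ``level_slowing_ms`` adds a penalty per ambiguity level of the trial's
    point (unresolved points count as ``max_level``).
    """

    baseline_rt_ms: float = 520.0
    block_rt_change_ms: float = -84.0
    lsbq_rt_offset_ms: float = -12.0
    lsbq_center: float = 9.01
    lsbq_slope_flattening_ms: dict = field(
        default_factory=lambda: {1: 1.0, 2: 1.5, 3: 2.0, 4: 2.5, 5: 2.5}
    )
    level_slowing_ms: float = 8.0
    noise_sigma: float = 0.12
    accuracy_rate: float = 0.97

    def __post_init__(self):
        if not 0 < self.accuracy_rate <= 1:
            raise ValueError("accuracy_rate must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def simulate_behavior(
    profiles: pd.DataFrame,
    session: SessionSpec,
    params: BehaviorParams | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Simulate trial-level responses for every participant in the cohort.

    Returns one row per participant per trial with the session's annotation
    columns joined, plus ``rt_ms`` and ``correct``.
    """
    params = params or BehaviorParams()
    trials = session.trials
    if "class_at_level_0" not in trials.columns:
        raise ValueError("session has no ambiguity annotations")
    rng = np.random.default_rng(seed)
    n_blocks = trials["block"].nunique()
    block_slope = params.block_rt_change_ms / max(1, n_blocks - 1)

    level = trials["ambiguity_level"].to_numpy(dtype=float, na_value=np.nan)
    status = trials["status"].to_numpy()
    eff_level = np.where(np.isnan(level), 0.0, level)
    eff_level = np.where(status == "unresolved", float(DEFAULT_MAX_LEVEL), eff_level)
    block = trials["block"].to_numpy(dtype=float)
    flatten = np.array(
        [
            params.lsbq_slope_flattening_ms.get(int(l), 0.0) if l >= 1 else 0.0
            for l in eff_level
        ]
    )

    out = []
    for _, prof in profiles.iterrows():
        lsbq_c = prof["lsbq"] - params.lsbq_center
        rt = (
            params.baseline_rt_ms
            + block_slope * block
            + params.lsbq_rt_offset_ms * lsbq_c
            + flatten * lsbq_c * block
            + params.level_slowing_ms * eff_level
        )
        if params.noise_sigma > 0:
            noise = np.exp(
                rng.normal(-0.5 * params.noise_sigma**2, params.noise_sigma, rt.shape)
            )
            rt = rt * noise
        correct = rng.random(rt.shape) < params.accuracy_rate
        df = trials.copy()
        df.insert(0, "participant_id", prof["participant_id"])
        df["lsbq"] = prof["lsbq"]
        df["rt_ms"] = rt
        df["correct"] = correct.astype(int)
        out.append(df)
    return pd.concat(out, ignore_index=True)
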