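"""Rescorla-Wagner model space for self-belief formation (models M1-M5).

All five models share the delta-rule core

    EXP_{t+1} = EXP_t + alpha_valence * PE_t * (1 - w * ND(FB_t))

with PE_t = FB_t - EXP_t, separate learning rates for positive and negative
prediction errors (valence), and a feedback-weight factor ``w`` that damps
updates for feedback near the ends of the percentile scale via the U-shaped
extremity function ``ND``.  Trial indices are always within an experimental
condition: belief formation is specific to each estimation category.

The models differ in how the Interference manipulation enters:

* ``M1_valence`` — baseline, two valence learning rates, no interference term.
* ``M2_interference_valence`` — four rates: valence x (Agent / NoAgent).
* ``M3_interference_weighting`` — two rates plus a weight ``s`` shrinking
  every update in the Agent condition by ``(1 - s)``.
* ``M4_attribution_valence`` — four rates: valence x (internal / external
  trial-by-trial attribution).
* ``M5_attribution_weighting`` — two rates plus ``s`` shrinking the update by
  ``(1 - s)`` only on trials the participant attributed externally.

Trials without an attribution probe (NoAgent condition) are treated as
internally attributed throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .task_engine import Attribution, Interference, TrialRecord

__all__ = [
    "ModelId",
    "ParameterSet",
    "FeedbackWeightFn",
    "Trajectory",
    "nd_weight",
    "update_expectation",
    "simulate_trajectory",
    "pointwise_loglik",
    "group_by_condition",
    "PARAM_NAMES",
]

_LOG_2PI = math.log(2.0 * math.pi)


class ModelId(str, Enum):
    M1_valence = "M1_valence"
    M2_interference_valence = "M2_interference_valence"
    M3_interference_weighting = "M3_interference_weighting"
    M4_attribution_valence = "M4_attribution_valence"
    M5_attribution_weighting = "M5_attribution_weighting"


#: Serialized parameter names per model, in sampling order.
PARAM_NAMES: dict[ModelId, tuple[str, ...]] = {
    ModelId.M1_valence: ("alpha_pos", "alpha_neg", "w", "sigma_obs"),
    ModelId.M2_interference_valence: (
        "alpha_pos",
        "alpha_neg",
        "alpha_pos_agent",
        "alpha_neg_agent",
        "w",
        "sigma_obs",
    ),
    ModelId.M3_interference_weighting: ("alpha_pos", "alpha_neg", "w", "s", "sigma_obs"),
    ModelId.M4_attribution_valence: (
        "alpha_pos",
        "alpha_neg",
        "alpha_pos_ext",
        "alpha_neg_ext",
        "w",
        "sigma_obs",
    ),
    ModelId.M5_attribution_weighting: ("alpha_pos", "alpha_neg", "w", "s", "sigma_obs"),
}

_UNIT = ("alpha_pos", "alpha_neg", "alpha_pos_agent", "alpha_neg_agent",
         "alpha_pos_ext", "alpha_neg_ext", "w", "s")


@dataclass(frozen=True)
class ParameterSet:
    """Parameters of one model instance.

    Fields not used by a model are ignored; ``None`` marks absence.  Learning
    rates, ``w`` and ``s`` live in [0, 1]; ``sigma_obs`` (the rating-noise
    scale, in percentile points) must be positive.
    """

    alpha_pos: float | None = None
    alpha_neg: float | None = None
    alpha_pos_agent: float | None = None
    alpha_neg_agent: float | None = None
    alpha_pos_ext: float | None = None
    alpha_neg_ext: float | None = None
    w: float | None = None
    s: float | None = None
    sigma_obs: float | None = None

    def __post_init__(self) -> None:
        for name in _UNIT:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.sigma_obs is not None and self.sigma_obs <= 0:
            raise ValueError(f"sigma_obs={self.sigma_obs} must be positive")

    def require(self, model: ModelId) -> None:
        for name in PARAM_NAMES[model]:
            if getattr(self, name) is None:
                raise ValueError(f"model {model.value} requires parameter '{name}'")

    def to_dict(self, model: ModelId) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES[model]}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParameterSet":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})

    def with_(self, **kwargs: float) -> "ParameterSet":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FeedbackWeightFn:
    """Feedback-extremity map ND: percentile -> [0, 1].

    Default (``bell=False``): ``ND(f) = 1 - exp(-(f - center)^2 / (2 spread^2))``
    — zero at mid-scale and maximal at the scale limits, so ``w * ND`` damps
    updates for implausibly extreme feedback.  ``bell=True`` exposes the
    literal max-normalized normal density (peaked mid-scale) for sensitivity
    checks.
    """

    center: float = 50.0
    spread: float = 25.0
    bell: bool = False

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValueError("spread must be positive")


def nd_weight(feedback: float | np.ndarray, fn: FeedbackWeightFn) -> float | np.ndarray:
    """Evaluate the feedback-extremity function ND at a feedback percentile."""
    z = (np.asarray(feedback, dtype=float) - fn.center) / fn.spread
    bell = np.exp(-0.5 * z * z)
    out = bell if fn.bell else 1.0 - bell
    return float(out) if np.isscalar(feedback) else out


def _active_alpha(
    model: ModelId,
    params: ParameterSet,
    pe: float,
    interference: Interference,
    attribution: Attribution,
) -> float:
    pos = pe > 0
    if model is ModelId.M2_interference_valence and interference is Interference.AGENT:
        return params.alpha_pos_agent if pos else params.alpha_neg_agent
    if model is ModelId.M4_attribution_valence and attribution is Attribution.EXTERNAL:
        return params.alpha_pos_ext if pos else params.alpha_neg_ext
    return params.alpha_pos if pos else params.alpha_neg


def update_expectation(
    model: ModelId,
    params: ParameterSet,
    exp_t: float,
    feedback: float,
    interference: Interference = Interference.NO_AGENT,
    attribution: Attribution = Attribution.NOT_ASKED,
    fn: FeedbackWeightFn = FeedbackWeightFn(),
    *,
    clip: bool = True,
) -> float:
    """One delta-rule transition EXP_t -> EXP_{t+1} under a given model.

    ``not_asked`` attributions are treated as internal.  The result is
    clipped to [0, 100] unless ``clip=False`` (the likelihood evaluates the
    unclipped mean).
    """
    params.require(model)
    pe = feedback - exp_t
    if pe == 0.0:
        return exp_t
    alpha = _active_alpha(model, params, pe, interference, attribution)
    update = alpha * pe * (1.0 - params.w * nd_weight(feedback, fn))
    if model is ModelId.M3_interference_weighting and interference is Interference.AGENT:
        update *= 1.0 - params.s
    if model is ModelId.M5_attribution_weighting and attribution is Attribution.EXTERNAL:
        update *= 1.0 - params.s
    nxt = exp_t + update
    return min(max(nxt, 0.0), 100.0) if clip else nxt


def group_by_condition(session: list[TrialRecord]) -> dict[int, list[TrialRecord]]:
    """Split a session into per-condition records, in within-condition order."""
    groups: dict[int, list[TrialRecord]] = {}
    for rec in session:
        groups.setdefault(rec.condition.category_id, []).append(rec)
    for recs in groups.values():
        recs.sort(key=lambda r: r.trial_within)
    return groups


@dataclass
class Trajectory:
    """Model-predicted expectation path for one condition."""

    category_id: int
    expectations: np.ndarray  # predicted EXP_t, aligned to the condition's trials
    prediction_errors: np.ndarray  # PE_t = FB_t - predicted EXP_t


def simulate_trajectory(
    model: ModelId,
    params: ParameterSet,
    session: list[TrialRecord],
    fn: FeedbackWeightFn = FeedbackWeightFn(),
    noise_seed: int | None = None,
) -> dict[int, Trajectory]:
    """Forward-simulate predicted expectations through a session.

    Within each condition the trajectory starts at the subject's first
    observed rating (the model explains transitions, not the starting point)
    and then evolves by the model's update rule using the recorded feedback
    and attributions.  With ``noise_seed`` set, Gaussian rating noise of scale
    ``sigma_obs`` is added (clipped to the scale).
    """
    params.require(model)
    rng = np.random.default_rng(noise_seed) if noise_seed is not None else None
    out: dict[int, Trajectory] = {}
    for cid, recs in group_by_condition(session).items():
        if not recs:
            out[cid] = Trajectory(cid, np.empty(0), np.empty(0))
            continue
        exps = np.empty(len(recs))
        pes = np.empty(len(recs))
        e = recs[0].expectation
        for t, rec in enumerate(recs):
            exps[t] = e
            pes[t] = rec.feedback - e
            e = update_expectation(
                model, params, e, rec.feedback,
                rec.condition.interference, rec.attribution, fn,
            )
        if rng is not None:
            exps = np.clip(exps + rng.normal(0.0, params.sigma_obs, size=len(exps)), 0, 100)
        out[cid] = Trajectory(cid, exps, pes)
    return out


def pointwise_loglik(
    model: ModelId,
    params: ParameterSet,
    session: list[TrialRecord],
    fn: FeedbackWeightFn = FeedbackWeightFn(),
) -> np.ndarray:
    """Per-transition Gaussian log density of the observed ratings.

    The latent expectation follows the model's trajectory (seeded at each
    condition's first observed rating); observed ratings at trials 2..T of
    each condition are scored against the *unclipped* predicted mean under
    ``Normal(mean, sigma_obs)``.  Conditions are concatenated in category-id
    order; the sum over entries is the session log-likelihood.
    """
    params.require(model)
    if params.sigma_obs is None or params.sigma_obs <= 0:
        raise ValueError("sigma_obs must be positive")
    sigma = params.sigma_obs
    entries: list[float] = []
    groups = group_by_condition(session)
    for cid in sorted(groups):
        recs = groups[cid]
        e = recs[0].expectation
        for rec, nxt in zip(recs[:-1], recs[1:]):
            mu = update_expectation(
                model, params, e, rec.feedback,
                rec.condition.interference, rec.attribution, fn, clip=False,
            )
            z = (nxt.expectation - mu) / sigma
            entries.append(-0.5 * z * z - math.log(sigma) - 0.5 * _LOG_2PI)
            e = min(max(mu, 0.0), 100.0)
    return np.asarray(entries)
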