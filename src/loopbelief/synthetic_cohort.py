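"""Synthetic participants with known generative parameters.

The human sample this emulates: 64 university students performing the LOOP
task (2x2 design, 20 trials per condition), with subclinical depression
(PHQ-9, 0-27) and self-esteem (SDQ-III general-self scale) scores that are
strongly negatively correlated (Spearman rho around -0.62), a median-negative
valence bias in learning (faster learning from worse-than-expected feedback),
and a self-serving attribution policy (worse-than-expected and more extreme
feedback is more often attributed to the computer agent).

Every agent is generated from one of the belief models (M5, the attribution-
weighting model, by default), so the full pipeline — fitting, model
selection, group statistics — can be validated by parameter and model
recovery against the stored ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .belief_models import ModelId, ParameterSet, FeedbackWeightFn, update_expectation
from .task_engine import (
    Attribution,
    ConditionLabel,
    TaskConfig,
    TrialRecord,
    records_to_frame,
    run_session,
)

__all__ = [
    "AttributionPolicy",
    "AgentProfile",
    "CohortSpec",
    "sample_cohort",
    "attribution_response",
    "ModelAgent",
    "simulate_subject",
    "generate_dataset",
    "cohort_manifest",
]


@dataclass(frozen=True)
class AttributionPolicy:
    """Logistic policy for the internal/external probe on Agent trials.

    P(external) = logistic(b0 + b_neg*1[PE<0] + b_extremity*|FB-50|
                           + b_trait*trait + b_trait_x_neg*trait*1[PE<0])

    ``trait`` is a centered (z-scored) self-esteem-like score; with the
    default coefficients the policy is self-serving (b_neg > 0), sensitive to
    feedback extremity (b_extremity > 0), and participants with higher trait
    scores externalize negative feedback more (b_trait_x_neg > 0).
    """

    b0: float = -1.2
    b_neg: float = 0.9
    b_extremity: float = 0.025
    b_trait: float = 0.0
    b_trait_x_neg: float = 0.35

    def prob_external(self, pe: float, feedback: float, trait: float) -> float:
        neg = 1.0 if pe < 0 else 0.0
        logit = (
            self.b0
            + self.b_neg * neg
            + self.b_extremity * abs(feedback - 50.0)
            + self.b_trait * trait
            + self.b_trait_x_neg * trait * neg
        )
        return 1.0 / (1.0 + math.exp(-logit))


def attribution_response(
    policy: AttributionPolicy,
    pe: float,
    feedback: float,
    trait: float,
    rng: np.random.Generator | int,
) -> Attribution:
    """Sample one internal/external judgement from the policy."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p = policy.prob_external(pe, feedback, trait)
    return Attribution.EXTERNAL if rng.random() < p else Attribution.INTERNAL


@dataclass(frozen=True)
class AgentProfile:
    """Ground truth for one synthetic participant."""

    subject_id: str
    generating_model: ModelId
    params: ParameterSet
    phq9: int
    sdq: int
    trait_z: float  # latent (standardized) self-esteem factor
    policy: AttributionPolicy
    seed: int  # per-subject stream for behavioural noise

    def __post_init__(self) -> None:
        self.params.require(self.generating_model)
        if not 0 <= self.phq9 <= 27:
            raise ValueError("phq9 outside 0-27")


@dataclass(frozen=True)
class CohortSpec:
    """Generative settings for a cohort of synthetic participants.

    Defaults emulate the reference sample: n=64, trait Spearman correlation
    target -0.62, learning rates centered so the cohort medians land near
    alpha_neg ~ 0.24 / alpha_pos ~ 0.11, attribution weight s ~ N(0.51,
    0.17) truncated to (0, 1), and rating noise sigma_obs drawn in [4, 8]
    percentile points.
    """

    n_subjects: int = 64
    trait_correlation_target: float = -0.62
    bias_trait_link: float = 0.25  # slope of learning bias on the trait factor
    bias_mean: float = -0.3
    bias_noise_sd: float = 0.4
    alpha_scale_median: float = 0.175
    alpha_scale_log_sd: float = 0.4
    s_mean: float = 0.51
    s_sd: float = 0.17
    w_beta: tuple[float, float] = (2.0, 6.0)
    sigma_range: tuple[float, float] = (4.0, 8.0)
    s_range: tuple[float, float] | None = None  # overrides the truncated normal
    generating_model: ModelId = ModelId.M5_attribution_weighting
    policy: AttributionPolicy = field(default_factory=AttributionPolicy)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not abs(self.trait_correlation_target) < 1:
            raise ValueError("|trait_correlation_target| must be < 1")
        if self.sigma_range[0] <= 0 or self.sigma_range[0] > self.sigma_range[1]:
            raise ValueError("invalid sigma_range")


def _trait_scores(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Correlated (phq9, sdq) marginals via a Gaussian copula.

    The latent Pearson correlation is chosen so that the copula's population
    Spearman correlation equals the target: r = 2*sin(pi*rho_s/6).
    """
    n = spec.n_subjects
    r = 2.0 * math.sin(math.pi * spec.trait_correlation_target / 6.0)
    z_sdq = rng.standard_normal(n)
    z_phq = r * z_sdq + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    # PHQ-9: right-skewed subclinical distribution (gamma quantile transform)
    u = stats.norm.cdf(z_phq)
    phq = np.clip(np.floor(stats.gamma.ppf(u, a=1.8, scale=3.0) + 0.5), 0, 27)
    # SDQ-III general-self sum: roughly symmetric on its 12-96 range
    sdq = np.clip(np.floor(60.0 + 13.0 * z_sdq + 0.5), 12, 96)
    return phq.astype(int), sdq.astype(int), z_sdq


def sample_cohort(spec: CohortSpec) -> list[AgentProfile]:
    """Draw a cohort of agent profiles; deterministic for a fixed spec/seed.

    Learning-rate asymmetry is tied to the latent trait factor: the per-
    subject learning bias (alpha_pos - alpha_neg)/(alpha_pos + alpha_neg) is
    ``bias_mean + bias_trait_link * trait_z`` plus noise, so higher synthetic
    self-esteem goes with a weaker negativity bias (and, through the trait
    copula, higher depression with a stronger one).
    """
    master = np.random.SeedSequence(spec.seed)
    cohort_rng = np.random.default_rng(master.spawn(1)[0])
    subject_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in master.spawn(spec.n_subjects + 1)[1:]]

    phq, sdq, z = _trait_scores(spec, cohort_rng)
    model = spec.generating_model
    profiles: list[AgentProfile] = []
    for i in range(spec.n_subjects):
        bias = spec.bias_mean + spec.bias_trait_link * z[i] + cohort_rng.normal(0.0, spec.bias_noise_sd)
        bias = float(np.clip(bias, -0.9, 0.9))
        scale = spec.alpha_scale_median * math.exp(cohort_rng.normal(0.0, spec.alpha_scale_log_sd))
        a_pos = float(np.clip(scale * (1.0 + bias), 0.005, 0.95))
        a_neg = float(np.clip(scale * (1.0 - bias), 0.005, 0.95))
        w = float(cohort_rng.beta(*spec.w_beta))
        if spec.s_range is not None:
            s = float(cohort_rng.uniform(*spec.s_range))
        else:
            lo, hi = (0.02 - spec.s_mean) / spec.s_sd, (0.98 - spec.s_mean) / spec.s_sd
            s = float(spec.s_mean + spec.s_sd * stats.truncnorm.rvs(lo, hi, random_state=cohort_rng))
        sigma = float(cohort_rng.uniform(*spec.sigma_range))

        kwargs: dict[str, float] = {
            "alpha_pos": a_pos, "alpha_neg": a_neg, "w": w, "sigma_obs": sigma,
        }
        if model in (ModelId.M3_interference_weighting, ModelId.M5_attribution_weighting):
            kwargs["s"] = s
        elif model is ModelId.M2_interference_valence:
            kwargs["alpha_pos_agent"] = float(np.clip(a_pos * (1.0 - s), 0.005, 0.95))
            kwargs["alpha_neg_agent"] = float(np.clip(a_neg * (1.0 - s), 0.005, 0.95))
        elif model is ModelId.M4_attribution_valence:
            kwargs["alpha_pos_ext"] = float(np.clip(a_pos * (1.0 - s), 0.005, 0.95))
            kwargs["alpha_neg_ext"] = float(np.clip(a_neg * (1.0 - s), 0.005, 0.95))

        profiles.append(
            AgentProfile(
                subject_id=f"s{i + 1:03d}",
                generating_model=model,
                params=ParameterSet(**kwargs),
                phq9=int(phq[i]),
                sdq=int(sdq[i]),
                trait_z=float(z[i]),
                policy=spec.policy,
                seed=subject_seeds[i],
            )
        )
    return profiles


class ModelAgent:
    """Task agent whose behaviour follows its profile's generative model.

    Keeps one latent expectation per condition, initialized near the
    mid-scale prior (individuals hold slightly different prior beliefs about
    a novel ability, so the starting latent is jittered around the task's
    initial belief).  The first rating in each condition reports the latent
    expectation exactly; later ratings add Gaussian noise of scale
    ``sigma_obs`` — matching the likelihood used in fitting, which anchors
    each condition's trajectory at the first observed rating and explains
    transitions.  Attributions on Agent trials are drawn from the profile's
    logistic policy and then fed into the latent update.
    """

    def __init__(
        self,
        profile: AgentProfile,
        config: TaskConfig,
        fn: FeedbackWeightFn | None = None,
        initial_belief_sd: float = 6.0,
    ) -> None:
        self.profile = profile
        self.config = config
        self.fn = fn or FeedbackWeightFn()
        self.initial_belief_sd = initial_belief_sd
        self.rng = np.random.default_rng(profile.seed)
        self._latent: dict[int, float] = {}
        self._pending: dict[int, float] = {}

    def _get_latent(self, cid: int) -> float:
        if cid not in self._latent:
            start = self.config.initial_belief + self.rng.normal(0.0, self.initial_belief_sd)
            self._latent[cid] = float(np.clip(start, 0.0, 100.0))
        return self._latent[cid]

    def expect(self, condition: ConditionLabel, trial_within: int) -> float:
        latent = self._get_latent(condition.category_id)
        if trial_within == 1:
            rating = latent
        else:
            rating = latent + self.rng.normal(0.0, self.profile.params.sigma_obs)
        rating = float(np.clip(rating, 0.0, 100.0))
        self._pending[condition.category_id] = rating
        return rating

    def attribute(
        self, condition: ConditionLabel, trial_within: int, feedback: float, pe: float
    ) -> Attribution:
        return attribution_response(
            self.profile.policy, pe, feedback, self.profile.trait_z, self.rng
        )

    def observe(
        self,
        condition: ConditionLabel,
        trial_within: int,
        feedback: float,
        attribution: Attribution,
    ) -> None:
        cid = condition.category_id
        self._latent[cid] = update_expectation(
            self.profile.generating_model,
            self.profile.params,
            self._get_latent(cid),
            feedback,
            condition.interference,
            attribution,
            self.fn,
        )


def simulate_subject(
    profile: AgentProfile, config: TaskConfig, fn: FeedbackWeightFn | None = None
) -> list[TrialRecord]:
    """Run one synthetic participant through a full task session."""
    agent = ModelAgent(profile, config, fn)
    return run_session(agent, config, subject_id=profile.subject_id)


def generate_dataset(
    cohort: list[AgentProfile],
    task_config: TaskConfig | None = None,
    fn: FeedbackWeightFn | None = None,
) -> pd.DataFrame:
    """Simulate the whole cohort; returns a tidy trial table (CSV schema)."""
    config = task_config or TaskConfig()
    frames = [records_to_frame(simulate_subject(p, config, fn)) for p in cohort]
    return pd.concat(frames, ignore_index=True)


def cohort_manifest(cohort: list[AgentProfile]) -> dict:
    """Recovery ground truth: model, true parameters, traits, policy."""
    return {
        p.subject_id: {
            "generating_model": p.generating_model.value,
            "params": p.params.to_dict(p.generating_model),
            "phq9": p.phq9,
            "sdq": p.sdq,
            "trait_z": p.trait_z,
            "policy": {
                "b0": p.policy.b0,
                "b_neg": p.policy.b_neg,
                "b_extremity": p.policy.b_extremity,
                "b_trait": p.policy.b_trait,
                "b_trait_x_neg": p.policy.b_trait_x_neg,
            },
            "seed": p.seed,
        }
        for p in cohort
    }
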