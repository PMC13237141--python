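"""Structure and feedback logic of the learning-of-own-performance (LOOP) task.

The task lets a participant "learn" an alleged estimation ability from
pre-programmed percentile feedback.  Four estimation categories form a 2x2
within-subject design: Ability (High = mostly better-than-expected feedback,
Low = mostly worse-than-expected) x Interference (Agent = the computer may
have manipulated the feedback and the participant is asked for an
internal/external attribution after each trial, NoAgent = no such cover
story).  Feedback is not a fixed sequence of values: each condition carries a
sequence of *planned prediction errors* which are added to the participant's
rolling ability belief (mean of their last few expectation ratings in that
condition), so realized prediction errors track the planned ones regardless
of where the participant's expectations drift.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Ability",
    "Interference",
    "Attribution",
    "ConditionLabel",
    "PlannedPeSpec",
    "TaskConfig",
    "TrialRecord",
    "SessionAgent",
    "build_planned_pe_sequence",
    "build_trial_order",
    "current_ability_belief",
    "compute_feedback",
    "run_session",
    "records_to_frame",
    "frame_to_records",
    "CONDITIONS",
    "TRIAL_COLUMNS",
]


class Ability(str, Enum):
    HIGH = "High"
    LOW = "Low"


class Interference(str, Enum):
    AGENT = "Agent"
    NO_AGENT = "NoAgent"


class Attribution(str, Enum):
    INTERNAL = "internal"
    EXTERNAL = "external"
    NOT_ASKED = "not_asked"


@dataclass(frozen=True)
class ConditionLabel:
    """One cell of the Ability x Interference design, tied to a category id."""

    ability: Ability
    interference: Interference
    category_id: int

    @property
    def name(self) -> str:
        return f"{self.ability.value}/{self.interference.value}"


#: Canonical category-id assignment for the four design cells.
CONDITIONS: tuple[ConditionLabel, ...] = (
    ConditionLabel(Ability.HIGH, Interference.NO_AGENT, 0),
    ConditionLabel(Ability.HIGH, Interference.AGENT, 1),
    ConditionLabel(Ability.LOW, Interference.NO_AGENT, 2),
    ConditionLabel(Ability.LOW, Interference.AGENT, 3),
)


@dataclass(frozen=True)
class PlannedPeSpec:
    """Distributional constraints for one condition's planned-PE sequence."""

    pe_min: float
    pe_max: float
    frac_positive: float

    def __post_init__(self) -> None:
        if not (self.pe_min < 0 < self.pe_max):
            raise ValueError("pe_min must be negative and pe_max positive")
        if not 0.0 <= self.frac_positive <= 1.0:
            raise ValueError("frac_positive must lie in [0, 1]")


#: High-Ability feedback is drawn from PEs in [-18, 27], 70% positive;
#: Low-Ability from [-27, 18], 30% positive.
HIGH_ABILITY_PE = PlannedPeSpec(pe_min=-18.0, pe_max=27.0, frac_positive=0.7)
LOW_ABILITY_PE = PlannedPeSpec(pe_min=-27.0, pe_max=18.0, frac_positive=0.3)


@dataclass(frozen=True)
class TaskConfig:
    trials_per_condition: int = 20
    scale_min: float = 0.0
    scale_max: float = 100.0
    rolling_window: int = 5
    initial_belief: float = 50.0
    max_run_length: int = 2
    pe_spec_high: PlannedPeSpec = HIGH_ABILITY_PE
    pe_spec_low: PlannedPeSpec = LOW_ABILITY_PE
    integer_feedback: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_condition <= 0:
            raise ValueError("trials_per_condition must be positive")
        if self.scale_min >= self.scale_max:
            raise ValueError("scale_min must be below scale_max")
        if self.rolling_window < 1:
            raise ValueError("rolling_window must be >= 1")
        if self.max_run_length < 1:
            raise ValueError("max_run_length must be >= 1")

    @property
    def n_trials(self) -> int:
        return 4 * self.trials_per_condition

    def pe_spec(self, ability: Ability) -> PlannedPeSpec:
        return self.pe_spec_high if ability is Ability.HIGH else self.pe_spec_low


@dataclass
class TrialRecord:
    """One task trial: what was asked, shown and answered."""

    subject_id: str
    trial_global: int  # 1-based across the session
    trial_within: int  # 1-based within the condition
    condition: ConditionLabel
    expectation: float  # EXP_t, rating in [0, 100]
    planned_pe: float
    belief_basis: float  # rolling-mean belief the feedback was anchored to
    feedback: float  # FB_t, percentile in [scale_min, scale_max]
    realized_pe: float  # PE_t = FB_t - EXP_t
    attribution: Attribution
    clipped: bool = field(default=False)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_planned_pe_sequence(
    spec: PlannedPeSpec, n: int, seed: int, *, integer: bool = False
) -> np.ndarray:
    """Draw an ordered sequence of signed planned prediction errors.

    Exactly ``round(n * frac_positive)`` values are strictly positive (drawn
    uniformly from ``(0, pe_max]``); the rest are strictly negative (from
    ``[pe_min, 0)``).  The order is a seeded permutation, so the same
    (spec, seed) pair always yields the same sequence — the task reuses one
    sequence for every participant.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    exact = n * spec.frac_positive
    n_pos = _round_half_up(exact)
    if abs(exact - round(exact)) > 1e-9:
        warnings.warn(
            f"{n} * {spec.frac_positive} = {exact} is not an integer; "
            f"rounding half-up to {n_pos} positive values",
            stacklevel=2,
        )
    n_neg = n - n_pos
    rng = np.random.default_rng(seed)
    if integer:
        pos = rng.integers(1, int(spec.pe_max), size=n_pos, endpoint=True).astype(float)
        neg = rng.integers(int(spec.pe_min), -1, size=n_neg, endpoint=True).astype(float)
    else:
        # open at 0 in exact arithmetic; a literal 0 draw has probability 0
        pos = rng.uniform(0.0, spec.pe_max, size=n_pos)
        neg = rng.uniform(spec.pe_min, 0.0, size=n_neg)
    seq = np.concatenate([pos, neg])
    rng.shuffle(seq)
    return seq


def build_trial_order(
    config: TaskConfig, seed: int, *, max_retries: int = 1000
) -> list[ConditionLabel]:
    """Interleave the four conditions with a bounded run length.

    Produces a seeded permutation of ``4 * trials_per_condition`` condition
    labels in which no more than ``max_run_length`` consecutive trials share a
    condition.  Rejection-sampled; raises after ``max_retries`` failures.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(4), config.trials_per_condition)
    for _ in range(max_retries):
        perm = rng.permutation(labels)
        run, ok = 1, True
        for a, b in zip(perm[:-1], perm[1:]):
            run = run + 1 if a == b else 1
            if run > config.max_run_length:
                ok = False
                break
        if ok:
            return [CONDITIONS[i] for i in perm]
    raise RuntimeError(
        f"could not satisfy max_run_length={config.max_run_length} "
        f"after {max_retries} shuffles"
    )


def current_ability_belief(history: Sequence[float], config: TaskConfig) -> float:
    """Rolling ability belief: mean of the last ``rolling_window`` ratings.

    Before the first rating in a condition the belief is ``initial_belief``
    (50 by default); with fewer ratings than the window, all are averaged.
    """
    if len(history) == 0:
        return float(config.initial_belief)
    window = list(history)[-config.rolling_window:]
    return float(np.mean(window))


def compute_feedback(
    belief: float, planned_pe: float, config: TaskConfig
) -> tuple[float, bool]:
    """Delivered feedback = belief + planned PE, clamped to the scale.

    Returns the feedback percentile and whether clamping truncated it.
    """
    raw = belief + planned_pe
    fb = min(max(raw, config.scale_min), config.scale_max)
    if config.integer_feedback:
        fb = float(_round_half_up(fb))
    return fb, fb != raw


class SessionAgent(Protocol):
    """Behavioural policy driving one simulated (or replayed) participant."""

    def expect(self, condition: ConditionLabel, trial_within: int) -> float:
        """Expectation rating in [0, 100] before feedback."""
        ...

    def attribute(
        self, condition: ConditionLabel, trial_within: int, feedback: float, pe: float
    ) -> Attribution:
        """Internal/external judgement; only called on Agent trials."""
        ...

    def observe(
        self,
        condition: ConditionLabel,
        trial_within: int,
        feedback: float,
        attribution: Attribution,
    ) -> None:
        """Feedback delivery; lets the agent update its internal state."""
        ...


def run_session(
    agent: SessionAgent,
    config: TaskConfig,
    *,
    subject_id: str = "s01",
    order_seed: int | None = None,
    pe_seed: int | None = None,
) -> list[TrialRecord]:
    """Play one full session of the task against a behavioural agent.

    Trial order and the per-condition planned-PE sequences are functions of
    the config seed (unless overridden), so every participant faces the same
    task structure — only the delivered feedback varies with their ratings.
    """
    order_seed = config.seed if order_seed is None else order_seed
    pe_seed = config.seed if pe_seed is None else pe_seed

    order = build_trial_order(config, order_seed)
    pe_sequences = {
        cond.category_id: build_planned_pe_sequence(
            config.pe_spec(cond.ability),
            config.trials_per_condition,
            # distinct stream per category, identical across subjects
            pe_seed * 7 + cond.category_id,
            integer=config.integer_feedback,
        )
        for cond in CONDITIONS
    }

    histories: dict[int, list[float]] = {c.category_id: [] for c in CONDITIONS}
    counters: dict[int, int] = {c.category_id: 0 for c in CONDITIONS}
    records: list[TrialRecord] = []

    for i, cond in enumerate(order, start=1):
        cid = cond.category_id
        t_within = counters[cid] + 1
        expectation = float(agent.expect(cond, t_within))
        if not (0.0 <= expectation <= 100.0):
            raise ValueError(
                f"agent returned out-of-range rating {expectation!r} on "
                f"global trial {i} ({cond.name}, trial {t_within})"
            )
        belief = current_ability_belief(histories[cid], config)
        planned = float(pe_sequences[cid][t_within - 1])
        feedback, was_clipped = compute_feedback(belief, planned, config)
        realized = feedback - expectation

        if cond.interference is Interference.AGENT:
            attribution = agent.attribute(cond, t_within, feedback, realized)
            if attribution not in (Attribution.INTERNAL, Attribution.EXTERNAL):
                raise ValueError(
                    f"agent must answer internal/external on Agent trials, "
                    f"got {attribution!r} on global trial {i}"
                )
        else:
            attribution = Attribution.NOT_ASKED

        agent.observe(cond, t_within, feedback, attribution)
        histories[cid].append(expectation)
        counters[cid] = t_within
        records.append(
            TrialRecord(
                subject_id=subject_id,
                trial_global=i,
                trial_within=t_within,
                condition=cond,
                expectation=expectation,
                planned_pe=planned,
                belief_basis=belief,
                feedback=feedback,
                realized_pe=realized,
                attribution=attribution,
                clipped=was_clipped,
            )
        )
    return records


#: Canonical trial-table CSV column order.
TRIAL_COLUMNS = [
    "subject_id", "trial_global", "trial_within", "ability", "interference",
    "category_id", "expectation", "planned_pe", "belief_basis", "feedback",
    "realized_pe", "attribution",
]


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records into the canonical trial-table layout.

    Attributions are encoded ``internal``/``external``/``NA`` (NA only on
    NoAgent trials where no probe is shown).
    """
    rows = [
        {
            "subject_id": r.subject_id,
            "trial_global": r.trial_global,
            "trial_within": r.trial_within,
            "ability": r.condition.ability.value,
            "interference": r.condition.interference.value,
            "category_id": r.condition.category_id,
            "expectation": r.expectation,
            "planned_pe": r.planned_pe,
            "belief_basis": r.belief_basis,
            "feedback": r.feedback,
            "realized_pe": r.realized_pe,
            "attribution": (
                "NA" if r.attribution is Attribution.NOT_ASKED else r.attribution.value
            ),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> dict[str, list[TrialRecord]]:
    """Rebuild per-subject trial records from a trial table."""
    by_cell = {(c.ability.value, c.interference.value): c for c in CONDITIONS}
    out: dict[str, list[TrialRecord]] = {}
    for row in frame.itertuples(index=False):
        cond = by_cell[(row.ability, row.interference)]
        att = (
            Attribution.NOT_ASKED
            if (isinstance(row.attribution, float) and math.isnan(row.attribution))
            or row.attribution in ("NA", "", None)
            else Attribution(row.attribution)
        )
        out.setdefault(str(row.subject_id), []).append(
            TrialRecord(
                subject_id=str(row.subject_id),
                trial_global=int(row.trial_global),
                trial_within=int(row.trial_within),
                condition=cond,
                expectation=float(row.expectation),
                planned_pe=float(row.planned_pe),
                belief_basis=float(row.belief_basis),
                feedback=float(row.feedback),
                realized_pe=float(row.realized_pe),
                attribution=att,
            )
        )
    for recs in out.values():
        recs.sort(key=lambda r: r.trial_global)
    return out
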