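"""Simulation engine: single participants, seeded cohorts and stream runs.

A simulated participant carries one independent learner per *option* (four
learners for the default two-pair task).  On each trial the engine reads
the two presented options' expectancies, lets the policy choose, samples
the outcome, and updates **only the chosen option's** learner — the
unchosen option's state is untouched, mirroring a task in which feedback
is experienced only for the stimulus actually selected.

Random-stream contract (per trial, in order): the policy consumes at most
one draw (greedy: one integer draw only on an exact expectancy tie;
softmax: one uniform), then the outcome consumes exactly one uniform.
Cohort participant seeds are derived from the master seed with
``numpy.random.SeedSequence(master_seed).generate_state(n)`` — a
counter-based scheme independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .environments import TaskSchedule, sample_outcome
from .learners import LearnerSpec, make_learner
from .policy import PolicySpec, choose

__all__ = [
    "TrialRecord",
    "ParticipantRun",
    "CohortSpec",
    "run_participant",
    "run_cohort",
    "run_stream_learner",
    "participant_seeds",
    "trials_frame",
]


@dataclass(frozen=True)
class TrialRecord:
    """Everything that happened on one trial of one participant."""

    trial_index: int
    pair_label: str
    phase: str
    evs: Dict[str, float]  # expectancies at decision time, per presented option
    chosen_option: str
    outcome: float
    correct: bool  # chosen option was the currently correct one


@dataclass
class ParticipantRun:
    """One simulated participant's full session."""

    trials: List[TrialRecord]
    histories: Dict[str, List[float]]  # per-option experienced outcomes
    seed: int

    def __len__(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of i.i.d. simulated participants on a common schedule."""

    n_participants: int
    learner: LearnerSpec
    schedule: TaskSchedule
    policy: PolicySpec = field(default_factory=PolicySpec)
    master_seed: int = 0
    win_value: float = 1.0
    loss_value: float = -1.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


def run_participant(
    schedule: TaskSchedule,
    learner_spec: LearnerSpec,
    policy_spec: PolicySpec,
    seed: int,
    win_value: float = 1.0,
    loss_value: float = -1.0,
) -> ParticipantRun:
    """Simulate one participant through a schedule.

    Expectancies are read *before* the trial's outcome is experienced
    (predictive semantics), and only the chosen option's learner and
    history are updated.
    """
    rng = np.random.default_rng(seed)
    learners = {opt: make_learner(learner_spec) for opt in schedule.options}
    histories: Dict[str, List[float]] = {opt: [] for opt in schedule.options}
    trials: List[TrialRecord] = []

    for event in schedule.events:
        opts = event.pair.options
        evs = {o: learners[o].expectancy() for o in opts}
        chosen = choose(evs, policy_spec, rng)
        outcome = sample_outcome(event, chosen, rng, win_value, loss_value)
        learners[chosen].observe(outcome)
        histories[chosen].append(outcome)
        trials.append(
            TrialRecord(
                trial_index=event.trial_index,
                pair_label=event.pair.label,
                phase=event.phase,
                evs=evs,
                chosen_option=chosen,
                outcome=outcome,
                correct=(chosen == event.correct_option),
            )
        )
    return ParticipantRun(trials=trials, histories=histories, seed=seed)


def participant_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-participant seeds derived from a master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n)


def run_cohort(spec: CohortSpec) -> List[ParticipantRun]:
    """Run ``n_participants`` independent sessions with derived seeds."""
    seeds = participant_seeds(spec.master_seed, spec.n_participants)
    return [
        run_participant(
            spec.schedule,
            spec.learner,
            spec.policy,
            int(s),
            spec.win_value,
            spec.loss_value,
        )
        for s in seeds
    ]


def run_stream_learner(
    stream: Sequence[float], learner_spec: LearnerSpec
) -> np.ndarray:
    """Run a single learner over an outcome stream; return predictive EVs.

    Entry ``t`` (0-based) is the expectancy *before* outcome ``t`` is
    observed, i.e. it reflects outcomes ``0..t−1`` only.  For the decay
    learner the returned values are normalised onto the outcome scale.
    """
    stream = np.asarray(stream, dtype=float)
    if stream.size == 0:
        raise ValueError("stream must be non-empty")
    learner = make_learner(learner_spec)
    evs = np.empty(stream.size)
    for t, outcome in enumerate(stream):
        evs[t] = learner.expectancy()
        learner.observe(outcome)
    return evs


def trials_frame(
    runs: Sequence[ParticipantRun], participant_ids: Optional[Sequence[int]] = None
) -> pd.DataFrame:
    """Flatten runs into a tidy per-trial DataFrame (one row per TrialRecord)."""
    if participant_ids is None:
        participant_ids = range(len(runs))
    rows = []
    for pid, run in zip(participant_ids, runs):
        for rec in run.trials:
            row = {
                "participant": pid,
                "seed": run.seed,
                "trial_index": rec.trial_index,
                "pair_label": rec.pair_label,
                "phase": rec.phase,
                "chosen_option": rec.chosen_option,
                "outcome": rec.outcome,
                "correct": rec.correct,
            }
            for opt, ev in rec.evs.items():
                row[f"ev_{opt}"] = ev
            rows.append(row)
    return pd.DataFrame(rows)
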