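"""Seeded outcome-generating processes.

Two task environments:

* a Bernoulli outcome stream whose base rate may shift at a change point
  (used for single-cue expectancy trajectories), and
* a two-alternative probabilistic discrimination schedule with a
  mid-session reversal, in which choosing an option wins points
  (outcome +1) with that option's programmed probability and otherwise
  loses points (outcome −1).

All randomness flows through explicit integer seeds or caller-supplied
``numpy.random.Generator`` objects, so every generated schedule or stream
is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BernoulliStreamSpec",
    "generate_bernoulli_stream",
    "DiscriminationPair",
    "TrialEvent",
    "TaskSchedule",
    "build_schedule",
    "sample_outcome",
    "ACQUISITION",
    "REVERSAL",
]

ACQUISITION = "acquisition"
REVERSAL = "reversal"


@dataclass(frozen=True)
class BernoulliStreamSpec:
    """A change-point Bernoulli outcome stream.

    The first ``n_before`` trials present the outcome with probability
    ``p_before`` and the remaining ``n_after`` with ``p_after``.  Present
    and absent outcomes are coded ``outcome_present``/``outcome_absent``
    (default 1/0).  A stationary stream is the special case
    ``n_after = 0`` (or ``p_after = p_before``).
    """

    p_before: float
    p_after: float
    n_before: int
    n_after: int
    outcome_present: float = 1.0
    outcome_absent: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_before", "p_after"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("n_before", "n_after"):
            n = getattr(self, name)
            if n < 0:
                raise ValueError(f"{name} must be >= 0, got {n}")

    @property
    def n_total(self) -> int:
        return self.n_before + self.n_after

    @property
    def change_trial(self) -> int:
        """1-based index of the first trial drawn at ``p_after``."""
        return self.n_before + 1


def generate_bernoulli_stream(
    spec: BernoulliStreamSpec, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Draw the full outcome stream described by ``spec``.

    Returns an array of length ``n_before + n_after``.  If ``rng`` is not
    given, a fresh generator is built from ``spec.seed``, so identical
    specs yield identical streams.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    p = np.empty(spec.n_total)
    p[: spec.n_before] = spec.p_before
    p[spec.n_before :] = spec.p_after
    present = rng.random(spec.n_total) < p
    return np.where(present, spec.outcome_present, spec.outcome_absent)


@dataclass(frozen=True)
class DiscriminationPair:
    """A stimulus pair with programmed reward probabilities.

    Choosing the currently correct option wins with probability
    ``p_reward_correct``; the incorrect option wins with
    ``p_reward_incorrect``.  The label follows the a:b convention
    (``"80:20"`` means 0.80 vs 0.20).  ``option_a`` is the option that is
    correct during acquisition; at reversal the assignment swaps.
    """

    label: str
    p_reward_correct: float
    p_reward_incorrect: float
    option_a: str = ""
    option_b: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_reward_incorrect <= self.p_reward_correct <= 1.0):
            raise ValueError(
                "need 0 <= p_reward_incorrect <= p_reward_correct <= 1, got "
                f"{self.p_reward_incorrect}, {self.p_reward_correct}"
            )
        if not self.option_a:
            object.__setattr__(self, "option_a", f"{self.label}/A")
        if not self.option_b:
            object.__setattr__(self, "option_b", f"{self.label}/B")
        if self.option_a == self.option_b:
            raise ValueError("pair options must be distinct")

    @classmethod
    def from_label(cls, label: str) -> "DiscriminationPair":
        """Build a pair from an ``"a:b"`` percentage label, e.g. ``"80:20"``."""
        try:
            a, b = (int(part) for part in label.split(":"))
        except ValueError as exc:
            raise ValueError(f"cannot parse discrimination label {label!r}") from exc
        return cls(label=label, p_reward_correct=a / 100.0, p_reward_incorrect=b / 100.0)

    @property
    def options(self) -> tuple[str, str]:
        return (self.option_a, self.option_b)


@dataclass(frozen=True)
class TrialEvent:
    """One scheduled trial: which pair is shown and which option is correct."""

    trial_index: int  # 1-based
    pair: DiscriminationPair
    phase: str  # ACQUISITION or REVERSAL
    correct_option: str

    @property
    def incorrect_option(self) -> str:
        a, b = self.pair.options
        return b if self.correct_option == a else a


@dataclass(frozen=True)
class TaskSchedule:
    """A full session: pairs, trial count, reversal point and trial order.

    ``reversal_trial`` is the 1-based index of the first reversal-phase
    trial; at that trial the correct/incorrect assignment swaps
    simultaneously for every pair.  Presentation order is a seeded random
    interleaving with per-pair balance (pair counts differ by at most 1).
    """

    pairs: tuple[DiscriminationPair, ...]
    total_trials: int
    reversal_trial: int
    seed: int = 0
    presentation_order: str = "interleaved-random"
    events: tuple[TrialEvent, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("schedule needs at least one pair")
        if self.total_trials < 1:
            raise ValueError("total_trials must be >= 1")
        if not (1 <= self.reversal_trial <= self.total_trials):
            raise ValueError(
                f"reversal_trial must be in [1, {self.total_trials}], "
                f"got {self.reversal_trial}"
            )

    @property
    def options(self) -> tuple[str, ...]:
        return tuple(opt for pair in self.pairs for opt in pair.options)


def _phase(trial_index: int, reversal_trial: int) -> str:
    return ACQUISITION if trial_index < reversal_trial else REVERSAL


def build_schedule(
    pairs: Sequence[DiscriminationPair],
    total_trials: int,
    reversal_trial: int,
    seed: int = 0,
) -> TaskSchedule:
    """Build a balanced, seeded-random interleaved trial schedule.

    Each pair appears ``total_trials // len(pairs)`` times (remainder
    trials assigned to the first pairs, so counts differ by at most 1);
    the order is a single seeded shuffle over the whole session.
    """
    pairs = tuple(pairs)
    schedule = TaskSchedule(
        pairs=pairs,
        total_trials=total_trials,
        reversal_trial=reversal_trial,
        seed=seed,
    )
    n_pairs = len(pairs)
    base, extra = divmod(total_trials, n_pairs)
    pair_indices = np.repeat(
        np.arange(n_pairs), [base + (1 if i < extra else 0) for i in range(n_pairs)]
    )
    rng = np.random.default_rng(seed)
    rng.shuffle(pair_indices)

    events = []
    for t, pi in enumerate(pair_indices, start=1):
        pair = pairs[pi]
        phase = _phase(t, reversal_trial)
        correct = pair.option_a if phase == ACQUISITION else pair.option_b
        events.append(
            TrialEvent(trial_index=t, pair=pair, phase=phase, correct_option=correct)
        )
    object.__setattr__(schedule, "events", tuple(events))
    return schedule


def sample_outcome(
    event: TrialEvent,
    chosen_option: str,
    rng: np.random.Generator,
    win_value: float = 1.0,
    loss_value: float = -1.0,
) -> float:
    """Sample the outcome of choosing an option on a scheduled trial.

    Returns ``win_value`` (+1: points won) with the chosen option's
    current reward probability, else ``loss_value`` (−1: points lost).
    Consumes exactly one uniform draw from ``rng``.
    """
    if chosen_option not in event.pair.options:
        raise ValueError(
            f"option {chosen_option!r} is not in pair {event.pair.label!r}"
        )
    if chosen_option == event.correct_option:
        p_win = event.pair.p_reward_correct
    else:
        p_win = event.pair.p_reward_incorrect
    return win_value if rng.random() < p_win else loss_value
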