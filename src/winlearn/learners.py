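"""Trial-level expectancy updaters.

Three associative learners that map an experienced outcome history to an
expectancy (predicted value) for the next outcome of a cue:

* **Window learner** — the expectancy is the arithmetic mean of the last
  ``W`` experienced outcomes.  ``W``, the *learning window width*, plays a
  dual role: a small ``W`` means few outcomes are aggregated and each one
  has a large influence (1/W) on the expectancy; a large ``W`` yields an
  expectancy that is robust to stochastic fluctuation but slow to track a
  genuine change in the outcome base rate.
* **Delta (Rescorla–Wagner) learner** — incremental prediction-error
  update ``ev ← ev + L·(O − ev)`` with learning rate ``L``.
* **Decay learner** — associative-strength accumulator
  ``s ← (1 − D)·(s + O)`` with decay rate ``D``.  Under a constant unit
  outcome the strength asymptotes at ``(1 − D)/D``, so strengths are
  normalised by ``D/(1 − D)`` to put them on the outcome scale.

All three are exposed both as pure functions over explicit state (for
analytic work and oracle tests) and as small stateful classes with a common
``expectancy()`` / ``observe()`` protocol used by the simulation engine.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Protocol, Sequence, Union

__all__ = [
    "WindowSpec",
    "DeltaSpec",
    "DecaySpec",
    "LearnerSpec",
    "window_expectancy",
    "delta_update",
    "decay_update",
    "decay_normalised_ev",
    "Learner",
    "WindowLearner",
    "DeltaLearner",
    "DecayLearner",
    "make_learner",
]


@dataclass(frozen=True)
class WindowSpec:
    """Parameters of the sliding-window learner.

    Parameters
    ----------
    W : int
        Learning window width — the number of most recent experienced
        outcomes averaged to form the expectancy.  Must be >= 1.
    prior_ev : float
        Expectancy returned before any outcome has been experienced.
    """

    W: int
    prior_ev: float = 0.0

    def __post_init__(self) -> None:
        if not isinstance(self.W, int) or isinstance(self.W, bool):
            raise TypeError(f"W must be an integer, got {self.W!r}")
        if self.W < 1:
            raise ValueError(f"W must be >= 1, got {self.W}")
        if not math.isfinite(self.prior_ev):
            raise ValueError("prior_ev must be finite")


@dataclass(frozen=True)
class DeltaSpec:
    """Parameters of the prediction-error (delta-rule) learner.

    ``L`` is the learning rate, in (0, 1]; ``initial_ev`` the expectancy
    before any outcome has been experienced.
    """

    L: float
    initial_ev: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.L <= 1.0):
            raise ValueError(f"L must be in (0, 1], got {self.L}")
        if not math.isfinite(self.initial_ev):
            raise ValueError("initial_ev must be finite")


@dataclass(frozen=True)
class DecaySpec:
    """Parameters of the decay-rule learner.

    ``D`` is the decay rate, in (0, 1) so that the constant-input
    asymptote ``(1 − D)/D`` is finite and positive; ``initial_strength``
    is the stored associative strength before any outcome.
    """

    D: float
    initial_strength: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.D < 1.0):
            raise ValueError(f"D must be in (0, 1), got {self.D}")
        if not math.isfinite(self.initial_strength):
            raise ValueError("initial_strength must be finite")


LearnerSpec = Union[WindowSpec, DeltaSpec, DecaySpec]


def window_expectancy(history: Sequence[float], spec: WindowSpec) -> float:
    """Expectancy of the window learner given an outcome history.

    Returns the arithmetic mean of the last ``min(n, W)`` outcomes where
    ``n = len(history)``; with an empty history, returns ``spec.prior_ev``.
    Averaging the ``n`` available outcomes when ``n < W`` gives a smooth
    cold start without inventing phantom observations.
    """
    n = len(history)
    if n == 0:
        return spec.prior_ev
    k = min(n, spec.W)
    return math.fsum(history[n - k :]) / k


def delta_update(ev: float, outcome: float, spec: DeltaSpec) -> float:
    """One delta-rule step: ``ev + L·(outcome − ev)``."""
    return ev + spec.L * (outcome - ev)


def decay_update(strength: float, outcome: float, spec: DecaySpec) -> float:
    """One decay-rule step: ``(1 − D)·(strength + outcome)``.

    Under a constant outcome of 1 the fixed point is ``(1 − D)/D``.
    """
    return (1.0 - spec.D) * (strength + outcome)


def decay_normalised_ev(strength: float, spec: DecaySpec) -> float:
    """Map a stored strength onto the outcome scale: ``strength · D/(1 − D)``.

    The normaliser sends the constant-unit-input asymptote ``(1 − D)/D``
    to exactly 1, making decay-learner output comparable with the window
    and delta expectancies.
    """
    return strength * spec.D / (1.0 - spec.D)


class Learner(Protocol):
    """Minimal stateful learner protocol used by the engine."""

    def expectancy(self) -> float:
        """Predicted value of the next outcome, before observing it."""
        ...

    def observe(self, outcome: float) -> None:
        """Incorporate an experienced outcome into the learner state."""
        ...


class WindowLearner:
    """Stateful sliding-window learner over a growing outcome history.

    Only the most recent ``W`` outcomes are retained; the expectancy is
    recomputed from the buffer on demand so it agrees with
    :func:`window_expectancy` to the last bit.
    """

    def __init__(self, spec: WindowSpec) -> None:
        self.spec = spec
        self._buf: deque[float] = deque(maxlen=spec.W)
        self.n_observed = 0

    def expectancy(self) -> float:
        if not self._buf:
            return self.spec.prior_ev
        return math.fsum(self._buf) / len(self._buf)

    def observe(self, outcome: float) -> None:
        self._buf.append(float(outcome))
        self.n_observed += 1


class DeltaLearner:
    """Stateful Rescorla–Wagner learner."""

    def __init__(self, spec: DeltaSpec) -> None:
        self.spec = spec
        self.ev = spec.initial_ev
        self.n_observed = 0

    def expectancy(self) -> float:
        return self.ev

    def observe(self, outcome: float) -> None:
        self.ev = delta_update(self.ev, outcome, self.spec)
        self.n_observed += 1


class DecayLearner:
    """Stateful decay-rule learner.

    ``expectancy()`` returns the *normalised* strength (on the outcome
    scale), so the three learner classes are interchangeable behind the
    choice policy; the raw accumulator is available as ``strength``.
    """

    def __init__(self, spec: DecaySpec) -> None:
        self.spec = spec
        self.strength = spec.initial_strength
        self.n_observed = 0

    def expectancy(self) -> float:
        return decay_normalised_ev(self.strength, self.spec)

    def observe(self, outcome: float) -> None:
        self.strength = decay_update(self.strength, outcome, self.spec)
        self.n_observed += 1


def make_learner(spec: LearnerSpec) -> Learner:
    """Instantiate the stateful learner matching a spec."""
    if isinstance(spec, WindowSpec):
        return WindowLearner(spec)
    if isinstance(spec, DeltaSpec):
        return DeltaLearner(spec)
    if isinstance(spec, DecaySpec):
        return DecayLearner(spec)
    raise TypeError(f"unknown learner spec: {spec!r}")
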