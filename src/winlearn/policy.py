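"""Choice policies mapping per-option expectancies to a choice.

Two rules: greedy (argmax, ties broken uniformly at random) and softmax
(Boltzmann choice with temperature τ).  Greedy is the default: an "error"
is then simply a choice of the lower-valued option.  Both consume at most
one random draw per call — greedy draws only on an exact tie, softmax
draws exactly one uniform — which keeps engine random streams easy to
reason about.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

__all__ = ["PolicySpec", "choose"]

_KINDS = ("greedy", "softmax")


@dataclass(frozen=True)
class PolicySpec:
    """Choice rule configuration.

    ``kind`` is ``"greedy"`` or ``"softmax"``; ``temperature`` (τ > 0)
    applies to softmax only.  ``seed`` seeds a private generator when the
    caller does not supply one.
    """

    kind: str = "greedy"
    temperature: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind == "softmax" and not self.temperature > 0.0:
            raise ValueError(f"softmax temperature must be > 0, got {self.temperature}")


def choose(
    evs: Mapping[str, float],
    spec: PolicySpec,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Pick an option given its expectancy map.

    Greedy returns the argmax option, breaking exact ties uniformly at
    random.  Softmax returns option *i* with probability
    ``exp(ev_i/τ) / Σ_j exp(ev_j/τ)`` (computed with the max subtracted
    for numerical stability, which leaves the probabilities unchanged).
    """
    if not evs:
        raise ValueError("cannot choose from an empty option set")
    options = list(evs)
    values = np.asarray([evs[o] for o in options], dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expectancies must be finite")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    if spec.kind == "greedy":
        best = values.max()
        ties = [o for o, v in zip(options, values) if v == best]
        if len(ties) == 1:
            return ties[0]
        return ties[int(rng.integers(len(ties)))]

    z = values / spec.temperature
    z -= z.max()
    w = np.exp(z)
    cum = np.cumsum(w / w.sum())
    idx = int(np.searchsorted(cum, rng.random(), side="right"))
    return options[min(idx, len(options) - 1)]
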