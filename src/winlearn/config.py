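"""YAML/JSON run configuration and provenance-stamped CSV output.

A run config is a plain mapping with up to five blocks::

    learner:  {kind: window, W: 9, prior_ev: 0.0}        # or delta/decay
    stream:   {p_before: 0.25, p_after: 0.75, n_before: 400, n_after: 400, seed: 3}
    schedule: {pairs: ["100:0", "80:20"], total_trials: 270,
               reversal_trial: 136, seed: 7}
    policy:   {kind: greedy}            # or {kind: softmax, temperature: 0.5}
    cohort:   {n_participants: 1000, master_seed: 11}

Pairs may be given as ``"a:b"`` labels or as mappings with explicit
probabilities.  Output CSVs carry ``#``-prefixed header comments with the
config hash and seeds so every file is traceable to the exact settings
that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Union

import pandas as pd
import yaml

from .engine import CohortSpec
from .environments import (
    BernoulliStreamSpec,
    DiscriminationPair,
    TaskSchedule,
    build_schedule,
)
from .learners import DecaySpec, DeltaSpec, LearnerSpec, WindowSpec
from .policy import PolicySpec

__all__ = [
    "load_config",
    "config_hash",
    "learner_from_config",
    "stream_from_config",
    "schedule_from_config",
    "policy_from_config",
    "cohort_from_config",
    "write_csv_with_provenance",
]


def load_config(path: Union[str, Path]) -> dict:
    """Read a YAML (or JSON, a YAML subset) config file into a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    return dict(cfg)


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Short stable hash of a config mapping (canonical-JSON SHA1 prefix)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def learner_from_config(block: Mapping[str, Any]) -> LearnerSpec:
    block = dict(block)
    kind = block.pop("kind", "window")
    if kind == "window":
        return WindowSpec(W=int(block.pop("W")), **block)
    if kind == "delta":
        return DeltaSpec(L=float(block.pop("L")), **block)
    if kind == "decay":
        return DecaySpec(D=float(block.pop("D")), **block)
    raise ValueError(f"unknown learner kind {kind!r}")


def stream_from_config(block: Mapping[str, Any]) -> BernoulliStreamSpec:
    return BernoulliStreamSpec(**block)


def _pair_from_entry(entry: Any) -> DiscriminationPair:
    if isinstance(entry, str):
        return DiscriminationPair.from_label(entry)
    if isinstance(entry, Mapping):
        return DiscriminationPair(**entry)
    raise ValueError(f"cannot build discrimination pair from {entry!r}")


def schedule_from_config(block: Mapping[str, Any]) -> TaskSchedule:
    block = dict(block)
    pairs = [_pair_from_entry(e) for e in block.pop("pairs")]
    return build_schedule(
        pairs,
        total_trials=int(block.pop("total_trials")),
        reversal_trial=int(block.pop("reversal_trial")),
        seed=int(block.pop("seed", 0)),
    )


def policy_from_config(block: Mapping[str, Any]) -> PolicySpec:
    return PolicySpec(**block)


def cohort_from_config(cfg: Mapping[str, Any]) -> CohortSpec:
    """Assemble a full CohortSpec from the learner/schedule/policy/cohort blocks."""
    cohort = dict(cfg.get("cohort", {}))
    return CohortSpec(
        n_participants=int(cohort.get("n_participants", 1)),
        learner=learner_from_config(cfg["learner"]),
        schedule=schedule_from_config(cfg["schedule"]),
        policy=policy_from_config(cfg.get("policy", {})),
        master_seed=int(cohort.get("master_seed", 0)),
        win_value=float(cohort.get("win_value", 1.0)),
        loss_value=float(cohort.get("loss_value", -1.0)),
    )


def write_csv_with_provenance(
    df: pd.DataFrame, path: Union[str, Path], meta: Mapping[str, Any]
) -> None:
    """Write a CSV preceded by ``# key: value`` provenance comment lines.

    Files round-trip with ``pandas.read_csv(path, comment="#")``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)
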