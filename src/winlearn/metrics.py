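"""Errors-to-criterion scoring and cohort summaries.

The headline behavioural statistic of the reversal task: within one phase
(acquisition or reversal) of one discrimination, the number of incorrect
choices made before first achieving ``k`` consecutive correct choices
(default k = 8).  Participants who never reach criterion in a phase are
*censored*: their error count is the total number of errors in the phase
and they are flagged as non-attainers.

Cohort summaries report, per (pair × phase) cell, the mean and SD of
errors to criterion together with attainment counts.  By default the mean
is taken over **all** participants using the censored counts (attainment
rate reported alongside); an attainers-only mode is available, making any
selection explicit rather than silent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import ParticipantRun

__all__ = [
    "CriterionSpec",
    "PhaseResult",
    "errors_to_criterion",
    "phase_results",
    "summarise_cohort",
]


@dataclass(frozen=True)
class CriterionSpec:
    """Learning criterion: ``k_consecutive`` correct choices in a row."""

    k_consecutive: int = 8

    def __post_init__(self) -> None:
        if self.k_consecutive < 1:
            raise ValueError("k_consecutive must be >= 1")


@dataclass(frozen=True)
class PhaseResult:
    """Errors-to-criterion outcome for one (pair, phase) cell of one run."""

    pair_label: str
    phase: str
    errors_to_criterion: int
    attained: bool
    trials_to_criterion: Optional[int]  # 1-based within-phase trial at which the run starts


def _score_correct_sequence(
    correct: Sequence[bool], k: int
) -> tuple[int, bool, Optional[int]]:
    """Score a within-phase correctness sequence against a k-run criterion."""
    run_len = 0
    n_errors = 0
    for i, c in enumerate(correct):
        if c:
            run_len += 1
            if run_len == k:
                start = i - k + 1  # 0-based index of the run's first trial
                errors_before = sum(1 for x in correct[:start] if not x)
                return errors_before, True, start + 1
        else:
            run_len = 0
            n_errors += 1
    return n_errors, False, None


def errors_to_criterion(
    run: ParticipantRun,
    pair_label: str,
    phase: str,
    spec: CriterionSpec = CriterionSpec(),
) -> PhaseResult:
    """Errors before the first k-long correct run for one pair and phase.

    Trials are restricted to the given pair within the given phase, in
    session order; the criterion run may not straddle the phase boundary
    because each phase is scored independently.  If the criterion is
    never met, ``errors_to_criterion`` counts every error in the phase
    and ``trials_to_criterion`` is ``None``.
    """
    correct = [
        rec.correct
        for rec in run.trials
        if rec.pair_label == pair_label and rec.phase == phase
    ]
    if not correct:
        raise KeyError(f"run has no trials for pair {pair_label!r}, phase {phase!r}")
    n_err, attained, start = _score_correct_sequence(correct, spec.k_consecutive)
    return PhaseResult(
        pair_label=pair_label,
        phase=phase,
        errors_to_criterion=n_err,
        attained=attained,
        trials_to_criterion=start,
    )


def phase_results(
    run: ParticipantRun, spec: CriterionSpec = CriterionSpec()
) -> List[PhaseResult]:
    """Score every (pair, phase) cell present in a run, in first-seen order."""
    cells: list[tuple[str, str]] = []
    for rec in run.trials:
        cell = (rec.pair_label, rec.phase)
        if cell not in cells:
            cells.append(cell)
    return [errors_to_criterion(run, pair, ph, spec) for pair, ph in cells]


def summarise_cohort(
    runs: Sequence[ParticipantRun],
    spec: CriterionSpec = CriterionSpec(),
    include_non_attainers: bool = True,
) -> pd.DataFrame:
    """Per-(pair × phase) mean/SD errors to criterion across participants.

    Columns: ``pair_label, phase, mean_errors, sd_errors, n_attained,
    n_total``.  With ``include_non_attainers`` (default) the mean uses
    every participant's censored error count; otherwise only attainers
    enter the mean/SD while ``n_total`` still counts everyone.  SD is the
    sample SD (ddof=1), reported as 0.0 when fewer than two values enter.
    """
    if not runs:
        raise ValueError("need at least one run")
    rows = []
    for pid, run in enumerate(runs):
        for res in phase_results(run, spec):
            rows.append(
                {
                    "participant": pid,
                    "pair_label": res.pair_label,
                    "phase": res.phase,
                    "errors": res.errors_to_criterion,
                    "attained": res.attained,
                }
            )
    df = pd.DataFrame(rows)

    out = []
    for (pair, ph), cell in df.groupby(["pair_label", "phase"], sort=False):
        included = cell if include_non_attainers else cell[cell["attained"]]
        vals = included["errors"].to_numpy(dtype=float)
        out.append(
            {
                "pair_label": pair,
                "phase": ph,
                "mean_errors": float(np.mean(vals)) if vals.size else float("nan"),
                "sd_errors": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                "n_attained": int(cell["attained"].sum()),
                "n_total": int(len(cell)),
            }
        )
    return pd.DataFrame(out)
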