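import pytest
from hypothesis import HealthCheck, settings

import winlearn as wl

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def two_pair_schedule():
    """The default choice task: 100:0 and 80:20 interleaved, 270 trials,
    reversal at trial 136."""
    pairs = [
        wl.DiscriminationPair.from_label("100:0"),
        wl.DiscriminationPair.from_label("80:20"),
    ]
    return wl.build_schedule(pairs, total_trials=270, reversal_trial=136, seed=7)


@pytest.fixture(scope="session")
def reversal_cohort_summaries(two_pair_schedule):
    """Cohort summaries (n=200 participants) for narrow (W=3) and wide (W=9)
    window learners on the two-pair reversal task, under the default greedy
    policy.  Session-scoped: shared by the pattern and acceptance tests."""
    summaries = {}
    for W in (3, 9):
        spec = wl.CohortSpec(
            n_participants=200,
            learner=wl.WindowSpec(W=W),
            schedule=two_pair_schedule,
            policy=wl.PolicySpec(kind="greedy"),
            master_seed=2021,
        )
        runs = wl.run_cohort(spec)
        summaries[W] = wl.summarise_cohort(runs)
    return summaries


def cell(summary, pair_label, phase):
    """Pull one (pair, phase) row from a cohort summary DataFrame."""
    row = summary[(summary.pair_label == pair_label) & (summary.phase == phase)]
    assert len(row) == 1
    return row.iloc[0]
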