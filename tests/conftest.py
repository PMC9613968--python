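import numpy as np
import pytest

from gaitcomplexity import (
    activity_suite,
    analyze_activity,
    generate_benchmark,
)


@pytest.fixture(scope="session")
def lorenz_series():
    """20k samples of the Lorenz x component at dt = 0.01, transient discarded."""
    return generate_benchmark("lorenz", 20000, {"dt": 0.01})


@pytest.fixture(scope="session")
def logistic_series():
    return generate_benchmark("logistic", 10000, {"x0": 0.2, "transient": 100})


@pytest.fixture(scope="session")
def suite_reports():
    """Activity reports for the designed four-activity suite (seed 1)."""
    suite = activity_suite(seed=1, n_trials=2, n_strides=60)
    reports = []
    for label, trials in suite.items():
        reports.append(
            analyze_activity(
                [t for t, _, _ in trials],
                [c for _, c, _ in trials],
                activity_label=label,
            )
        )
    return reports


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
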