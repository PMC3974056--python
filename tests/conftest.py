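import pandas as pd
import pytest

from crticc import ClusterSummarySet, load_study_fixture


@pytest.fixture(scope="session")
def study():
    """The embedded per-cluster summary tables of the 14-hospital trial."""
    return load_study_fixture()


def make_continuous_summary(rows):
    """rows: list of (cluster_id, arm, n, mean, sd)."""
    return ClusterSummarySet(
        "y",
        "continuous",
        pd.DataFrame(rows, columns=["cluster_id", "arm", "n", "mean", "sd"]),
    )


def make_binary_summary(rows):
    """rows: list of (cluster_id, arm, n, events)."""
    return ClusterSummarySet(
        "y",
        "binary",
        pd.DataFrame(rows, columns=["cluster_id", "arm", "n", "events"]),
    )
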