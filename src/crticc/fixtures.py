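"""Embedded per-cluster summary tables from the 14-hospital heart-failure CRT.

The trial randomized 14 Italian community hospitals (7 care-pathway, CP;
7 usual-care, UC; 429 patients, cluster sizes 30-32) and published only
per-cluster summaries: baseline characteristics (age, sex, NYHA class at
admission, hypertension, co-morbidities) and outcomes (length of stay, cost,
NYHA class at discharge, in-hospital mortality, appropriateness of stay,
unscheduled readmission).  Those printed tables ship here as packaged CSVs
and are the only real data this package carries.

Transcription caveats, preserved rather than repaired:

- The first CP cluster's baseline row is incomplete in the source: only its
  NYHA-at-admission percentages are printed.  Its size (30) follows from the
  arm total of 214.  Age, sex, hypertension and co-morbidity analyses of the
  baseline table therefore cover 13 of 14 clusters and are flagged.
- NYHA-at-discharge denominators are not printed and are smaller than the
  admitted n (patients who died were not graded).  They are inferred per
  cluster as the integer in ``[n - deaths - 3, n]`` whose percentage triple
  has the smallest total rounding residual, and flagged as inferred.
- The running text reports a mean age of 81.66 +/- 8.41 while the table's
  total row prints 80.66 +/- 8.41; the per-cluster values stored here are
  the table's and the discrepancy is left as found.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .data import (
    BINARY,
    CONTINUOUS,
    ORDINAL,
    ClusterSummarySet,
    counts_from_percentages,
    infer_denominator,
)
from .exceptions import ConsistencyError

NYHA_CODES = (2, 3, 4)

#: baseline variables (pooled over all 14 clusters; intervention not yet applied)
BASELINE_VARIABLES = ("age", "male", "nyha_admission", "hypertension", "comorbidities")
#: outcome variables (analysed separately per arm)
OUTCOME_VARIABLES = ("los", "cost", "nyha_discharge", "mortality", "aos", "readmission")


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("crticc").joinpath("tables", name).open("r") as fh:
        return pd.read_csv(fh, dtype={"cluster_id": str})


@dataclass
class StudyFixture:
    """The study's Tables 1-2 as :class:`~crticc.data.ClusterSummarySet` maps.

    ``table1`` maps baseline variable names to pooled 14-cluster summaries
    (clusters with unprinted values omitted and recorded in ``incomplete``);
    ``table2`` maps outcome names to 14-cluster summaries carrying an ``arm``
    column, to be split with ``subset_arm`` for per-arm estimation.
    """

    table1: dict[str, ClusterSummarySet]
    table2: dict[str, ClusterSummarySet]
    #: variable -> list of cluster_ids whose printed row lacks that variable
    incomplete: dict[str, list[str]] = field(default_factory=dict)
    #: nyha_discharge: cluster_id -> inferred denominator (not printed)
    inferred_denominators: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = self.table2["los"].rows.set_index("cluster_id")["n"]
        arms = self.table2["los"].rows.set_index("cluster_id")["arm"]
        if len(sizes) != 14:
            raise ConsistencyError("fixture must contain 14 clusters")
        if not set(sizes) <= {30, 31, 32}:
            raise ConsistencyError("cluster sizes must lie in {30, 31, 32}")
        tot = sizes.groupby(arms).sum()
        if int(tot["CP"]) != 214 or int(tot["UC"]) != 215:
            raise ConsistencyError(
                f"arm totals must be CP=214 / UC=215, got {tot.to_dict()}"
            )


def _continuous_rows(df: pd.DataFrame, mean_col: str, sd_col: str) -> pd.DataFrame:
    sub = df.dropna(subset=[mean_col, sd_col])
    return pd.DataFrame(
        {
            "cluster_id": sub["cluster_id"],
            "arm": sub["arm"],
            "n": sub["n"].astype(int),
            "mean": sub[mean_col].astype(float),
            "sd": sub[sd_col].astype(float),
        }
    ).reset_index(drop=True)


def _binary_rows(df: pd.DataFrame, pct_col: str) -> pd.DataFrame:
    sub = df.dropna(subset=[pct_col])
    events = [
        counts_from_percentages(int(n), [float(p)])[0]
        for n, p in zip(sub["n"], sub[pct_col])
    ]
    return pd.DataFrame(
        {
            "cluster_id": sub["cluster_id"],
            "arm": sub["arm"],
            "n": sub["n"].astype(int),
            "events": events,
        }
    ).reset_index(drop=True)


def _ordinal_rows(
    df: pd.DataFrame,
    pct_cols: list[str],
    denominators: dict[str, int] | None = None,
) -> pd.DataFrame:
    rows = []
    for _, r in df.iterrows():
        n = int(r["n"])
        pcts = [float(r[c]) for c in pct_cols]
        denom = denominators.get(r["cluster_id"], n) if denominators else n
        counts = counts_from_percentages(n, pcts, denominator=denom)
        rows.append(
            {
                "cluster_id": r["cluster_id"],
                "arm": r["arm"],
                "n": n,
                "counts": tuple(counts),
            }
        )
    return pd.DataFrame(rows)


def load_study_fixture() -> StudyFixture:
    """Build the :class:`StudyFixture` from the packaged CSV transcriptions."""
    t1 = _read_packaged("table1_baseline.csv")
    t2 = _read_packaged("table2_outcomes.csv")

    incomplete: dict[str, list[str]] = {}
    table1: dict[str, ClusterSummarySet] = {}

    table1["age"] = ClusterSummarySet(
        "age", CONTINUOUS, _continuous_rows(t1, "age_mean", "age_sd")
    )
    for var, col in [
        ("male", "male_pct"),
        ("hypertension", "ht_pct"),
        ("comorbidities", "cm_pct"),
    ]:
        table1[var] = ClusterSummarySet(var, BINARY, _binary_rows(t1, col))
    table1["nyha_admission"] = ClusterSummarySet(
        "nyha_admission",
        ORDINAL,
        _ordinal_rows(t1, ["nyha2_pct", "nyha3_pct", "nyha4_pct"]),
        codes=NYHA_CODES,
    )
    for var in ("age", "male", "hypertension", "comorbidities"):
        missing = sorted(set(t1["cluster_id"]) - set(table1[var].rows["cluster_id"]))
        if missing:
            incomplete[var] = missing

    table2: dict[str, ClusterSummarySet] = {
        "los": ClusterSummarySet("los", CONTINUOUS, _continuous_rows(t2, "los_mean", "los_sd")),
        "cost": ClusterSummarySet("cost", CONTINUOUS, _continuous_rows(t2, "cost_mean", "cost_sd")),
        "mortality": ClusterSummarySet("mortality", BINARY, _binary_rows(t2, "mortality_pct")),
        "aos": ClusterSummarySet("aos", BINARY, _binary_rows(t2, "aos_pct")),
        "readmission": ClusterSummarySet("readmission", BINARY, _binary_rows(t2, "ur_pct")),
    }

    # NYHA at discharge: denominators exclude in-hospital deaths and are
    # recovered from the printed percentages (see module docstring).
    deaths = dict(zip(table2["mortality"].rows["cluster_id"], table2["mortality"].rows["events"]))
    denominators = {
        r["cluster_id"]: infer_denominator(
            int(r["n"]),
            [float(r[c]) for c in ("dnyha2_pct", "dnyha3_pct", "dnyha4_pct")],
            excluded=int(deaths[r["cluster_id"]]),
        )
        for _, r in t2.iterrows()
    }
    table2["nyha_discharge"] = ClusterSummarySet(
        "nyha_discharge",
        ORDINAL,
        _ordinal_rows(t2, ["dnyha2_pct", "dnyha3_pct", "dnyha4_pct"], denominators),
        codes=NYHA_CODES,
    )

    return StudyFixture(
        table1=table1,
        table2=table2,
        incomplete=incomplete,
        inferred_denominators=denominators,
    )
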