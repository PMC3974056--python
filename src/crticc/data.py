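"""Data containers and I/O for two-arm cluster randomized trial (CRT) data.

Two representations are supported and interconvertible in one direction:

``CRTDataset``
    Individual-level long-format records: one row per patient with a cluster
    identifier, a trial arm (``CP`` = care pathway, ``UC`` = usual care), and
    one column per outcome.  Outcomes may be continuous, binary (0/1) or
    ordinal (small integer category codes from a declared ordered code set).

``ClusterSummarySet``
    Per-cluster sufficient statistics for a single outcome: ``(n, mean, sd)``
    for continuous outcomes, ``(n, events)`` for binary outcomes, and
    per-category counts for ordinal outcomes.  Every estimator in this
    package consumes summaries, so published per-cluster tables are as
    usable as raw data.

``summarize`` maps the first representation onto the second; the reverse is
not possible (nor needed) beyond sufficient statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, InputError

logger = logging.getLogger(__name__)

ARMS = ("CP", "UC")

CONTINUOUS = "continuous"
BINARY = "binary"
ORDINAL = "ordinal"
OUTCOME_TYPES = (CONTINUOUS, BINARY, ORDINAL)


@dataclass
class CRTDataset:
    """Individual-level CRT data.

    Parameters
    ----------
    frame : pandas.DataFrame
        Long-format table with columns ``cluster_id``, ``arm`` and one
        column per outcome.  Missing outcome values are allowed (NaN).
    outcome_types : dict
        Maps each outcome column to one of ``continuous``, ``binary``,
        ``ordinal``.
    ordinal_codes : dict
        For each ordinal outcome, the ordered tuple of admissible integer
        category codes (e.g. NYHA class ``(2, 3, 4)``).
    """

    frame: pd.DataFrame
    outcome_types: dict[str, str]
    ordinal_codes: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("cluster_id", "arm"):
            if col not in self.frame.columns:
                raise InputError(f"required column {col!r} missing")
        if not self.outcome_types:
            raise InputError("at least one outcome column is required")
        for name, typ in self.outcome_types.items():
            if name not in self.frame.columns:
                raise InputError(f"outcome column {name!r} missing from frame")
            if typ not in OUTCOME_TYPES:
                raise InputError(f"unknown outcome type {typ!r} for {name!r}")
            if typ == ORDINAL and name not in self.ordinal_codes:
                raise InputError(f"ordinal outcome {name!r} has no declared code set")
        bad_arm = set(self.frame["arm"].unique()) - set(ARMS)
        if bad_arm:
            raise InputError(f"unknown arm labels {sorted(bad_arm)}; expected {ARMS}")
        arms_per_cluster = self.frame.groupby("cluster_id")["arm"].nunique()
        split = arms_per_cluster[arms_per_cluster > 1]
        if len(split):
            raise ConsistencyError(
                f"cluster(s) assigned to more than one arm: {list(split.index)}"
            )
        for name, codes in self.ordinal_codes.items():
            vals = self.frame[name].dropna().unique()
            bad = set(int(v) for v in vals) - set(codes)
            if bad:
                raise InputError(
                    f"ordinal outcome {name!r} contains codes {sorted(bad)} "
                    f"outside the declared set {codes}"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def outcomes(self) -> list[str]:
        return list(self.outcome_types)

    @property
    def k(self) -> int:
        """Number of clusters."""
        return self.frame["cluster_id"].nunique()

    @property
    def n_total(self) -> int:
        """Total number of individuals."""
        return len(self.frame)

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.frame.groupby("cluster_id").size()

    @property
    def cluster_arms(self) -> dict[str, str]:
        return self.frame.groupby("cluster_id")["arm"].first().to_dict()

    def subset_arm(self, arm: str) -> "CRTDataset":
        if arm not in ARMS:
            raise InputError(f"unknown arm {arm!r}")
        sub = self.frame[self.frame["arm"] == arm].reset_index(drop=True)
        return CRTDataset(sub, dict(self.outcome_types), dict(self.ordinal_codes))


@dataclass
class ClusterSummarySet:
    """Per-cluster sufficient statistics for one outcome.

    ``rows`` is a DataFrame with columns ``cluster_id``, ``arm``, ``n`` and,
    depending on ``outcome_type``:

    - continuous: ``mean``, ``sd`` (sample SD, n-1 denominator);
    - binary: ``events``;
    - ordinal: ``counts`` (a tuple of per-category counts aligned with
      ``codes``; the counts may sum to less than ``n`` when the outcome was
      not gradable for every subject).
    """

    outcome: str
    outcome_type: str
    rows: pd.DataFrame
    codes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.outcome_type not in OUTCOME_TYPES:
            raise InputError(f"unknown outcome type {self.outcome_type!r}")
        r = self.rows
        if (r["n"] < 1).any():
            raise InputError("cluster sizes must be >= 1")
        if self.outcome_type == CONTINUOUS:
            if (r["sd"] < 0).any():
                raise InputError("SDs must be >= 0")
        elif self.outcome_type == BINARY:
            if ((r["events"] < 0) | (r["events"] > r["n"])).any():
                raise InputError("event counts must satisfy 0 <= events <= n")
        else:
            if self.codes is None:
                raise InputError("ordinal summaries need a declared code set")
            for counts, n in zip(r["counts"], r["n"]):
                if len(counts) != len(self.codes):
                    raise InputError("counts length must match the code set")
                if any(c < 0 for c in counts):
                    raise InputError("category counts must be >= 0")
                if sum(counts) > n:
                    raise InputError("category counts exceed the cluster size")

    @property
    def k(self) -> int:
        return len(self.rows)

    @property
    def n_total(self) -> int:
        return int(self.rows["n"].sum())

    def subset_arm(self, arm: str) -> "ClusterSummarySet":
        sub = self.rows[self.rows["arm"] == arm].reset_index(drop=True)
        return ClusterSummarySet(self.outcome, self.outcome_type, sub, self.codes)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_outcome_type(series: pd.Series) -> tuple[str, tuple[int, ...] | None]:
    """Column-type inference for :func:`read_long`.

    Rule: values all in {0, 1} -> binary; otherwise all-integer values with
    at most 6 distinct levels -> ordinal (codes = sorted observed values);
    otherwise continuous.
    """
    vals = pd.to_numeric(series, errors="raise").dropna().unique()
    if len(vals) == 0:
        return CONTINUOUS, None
    if set(np.unique(vals)) <= {0, 1, 0.0, 1.0}:
        return BINARY, None
    if all(float(v).is_integer() for v in vals) and len(vals) <= 6:
        return ORDINAL, tuple(sorted(int(v) for v in vals))
    return CONTINUOUS, None


def read_long(
    path,
    outcome_types: dict[str, str] | None = None,
    ordinal_codes: dict[str, tuple[int, ...]] | None = None,
) -> CRTDataset:
    """Read a long-format CRT CSV (columns ``cluster_id``, ``arm``, outcomes).

    Comma-separated, UTF-8, ``.`` decimal.  Arm labels are matched
    case-insensitively against ``CP``/``UC``.  When ``outcome_types`` is not
    supplied the per-column rule of :func:`_infer_outcome_type` applies.
    Row order is preserved.
    """
    df = pd.read_csv(path, dtype={"cluster_id": str})
    for col in ("cluster_id", "arm"):
        if col not in df.columns:
            raise InputError(f"required column {col!r} missing from {path}")
    df["arm"] = df["arm"].astype(str).str.strip().str.upper()
    outcome_cols = [c for c in df.columns if c not in ("cluster_id", "arm")]
    if not outcome_cols:
        raise InputError("no outcome columns found")
    ordinal_codes = dict(ordinal_codes or {})
    if outcome_types is None:
        outcome_types = {}
        for c in outcome_cols:
            typ, codes = _infer_outcome_type(df[c])
            outcome_types[c] = typ
            if codes is not None:
                ordinal_codes.setdefault(c, codes)
    return CRTDataset(df, outcome_types, ordinal_codes)


def write_long(data: CRTDataset, path) -> None:
    """Write a :class:`CRTDataset` back to long-format CSV (lossless for
    :func:`read_long` round-trips)."""
    data.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# summarization
# ---------------------------------------------------------------------------

def summarize(data: CRTDataset, outcome: str) -> ClusterSummarySet:
    """Per-cluster sufficient statistics for one outcome.

    Missing values are dropped per cluster with ``n`` adjusted; clusters in
    which every value is missing are dropped with a logged warning.
    Continuous SDs use the sample (n-1) denominator; a singleton cluster
    reports ``sd = 0``.
    """
    if outcome not in data.outcome_types:
        raise InputError(f"unknown outcome {outcome!r}")
    typ = data.outcome_types[outcome]
    codes = data.ordinal_codes.get(outcome)
    rows = []
    for cid, grp in data.frame.groupby("cluster_id", sort=False):
        vals = grp[outcome].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            logger.warning("cluster %s has no observed %r values; dropped", cid, outcome)
            continue
        row = {"cluster_id": cid, "arm": grp["arm"].iloc[0], "n": len(vals)}
        if typ == CONTINUOUS:
            row["mean"] = float(np.mean(vals))
            row["sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        elif typ == BINARY:
            row["events"] = int(np.sum(vals))
        else:
            row["counts"] = tuple(int(np.sum(vals == c)) for c in codes)
        rows.append(row)
    return ClusterSummarySet(outcome, typ, pd.DataFrame(rows), codes)


# ---------------------------------------------------------------------------
# count reconstruction from printed percentages
# ---------------------------------------------------------------------------

def counts_from_percentages(
    n: int,
    percentages: list[float],
    denominator: int | None = None,
) -> list[int]:
    """Recover integer counts from printed percentages of a denominator.

    Each count is ``round(n * p / 100)`` with ties-to-even.  When the
    percentages describe an exhaustive partition (they sum to ~100, within
    printing error) the counts must sum to the denominator (``denominator``
    if given, else ``n``); any discrepancy left by rounding is repaired
    deterministically by moving the count with the largest rounding residual,
    and the repair is logged.  Non-exhaustive percentage lists (e.g. a single
    event percentage) are rounded without repair.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if any(p < 0 or p > 100 for p in percentages):
        raise InputError("percentages must lie in [0, 100]")
    denom = denominator if denominator is not None else n
    raw = [denom * p / 100.0 for p in percentages]
    counts = [round(x) for x in raw]  # Python round: ties-to-even
    exhaustive = abs(sum(percentages) - 100.0) <= 0.05 * len(percentages) + 0.5
    if denominator is None and not exhaustive:
        return counts
    target = denom
    while sum(counts) != target:
        resid = [x - c for x, c in zip(raw, counts)]
        if sum(counts) < target:
            i = max(range(len(counts)), key=lambda j: resid[j])
            counts[i] += 1
        else:
            i = min(range(len(counts)), key=lambda j: resid[j])
            counts[i] -= 1
            if counts[i] < 0:
                raise InputError(
                    f"percentages {percentages} cannot yield non-negative counts "
                    f"summing to {target}"
                )
        logger.info(
            "counts_from_percentages: largest-remainder repair at index %d "
            "(n=%d, target=%d)", i, n, target,
        )
    return counts


def infer_denominator(
    n: int,
    percentages: list[float],
    max_excluded: int = 3,
    excluded: int = 0,
) -> int:
    """Infer an unprinted denominator behind a percentage partition.

    Searches the integers ``d`` in ``[n - excluded - max_excluded, n]`` and
    returns the one minimizing the total rounding residual
    ``sum_j |d * p_j/100 - round(d * p_j/100)|``; ties resolve to the larger
    ``d``.  ``excluded`` counts subjects known to be ungradable (e.g. deaths
    before a discharge assessment).
    """
    lo = max(1, n - excluded - max_excluded)
    best_d, best_res = None, math.inf
    for d in range(lo, n + 1):
        res = sum(abs(d * p / 100.0 - round(d * p / 100.0)) for p in percentages)
        if res <= best_res:  # ties -> larger d (later in the scan)
            best_d, best_res = d, res
    return best_d
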