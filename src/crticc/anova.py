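"""One-way random-effects ANOVA estimation of the intraclass correlation.

Model
-----
For individual ``j`` in cluster ``i``,

.. math:: y_{ij} = \\mu + b_i + e_{ij}, \\qquad
          b_i \\sim N(0, \\sigma_b^2), \\; e_{ij} \\sim N(0, \\sigma_w^2),

and the intraclass correlation coefficient (ICC) is
:math:`\\rho = \\sigma_b^2 / (\\sigma_b^2 + \\sigma_w^2)`: the fraction of
total outcome variance attributable to between-cluster variation, equally
the correlation between two members of the same cluster.

The moment (Donner-Klar) estimator works from the one-way ANOVA mean
squares.  With cluster sizes :math:`n_i`, :math:`N = \\sum n_i`, ``k``
clusters and the adjusted average cluster size

.. math:: m_0 = \\frac{N - \\sum n_i^2 / N}{k - 1},

the variance components are :math:`\\hat\\sigma_w^2 = MSW` and
:math:`\\hat\\sigma_b^2 = (MSB - MSW)/m_0`, and
:math:`\\hat\\rho = \\hat\\sigma_b^2/(\\hat\\sigma_b^2+\\hat\\sigma_w^2)`.
The raw estimate may be negative; the reported ``icc`` is truncated at
zero, the convention when the estimate feeds a sample-size calculation.

Both mean squares are functions of per-cluster ``(n, mean, sd)`` only, so
the estimator accepts cluster summaries directly; fitting from individual
data is defined as summarize-then-fit and is bit-identical to it.

Standard errors use the Swiger et al. large-sample variance

.. math:: \\mathrm{Var}(\\hat\\rho) =
   \\frac{2 (N-1) (1-\\rho)^2 [1 + (m_0-1)\\rho]^2}{m_0^2 (N-k)(k-1)},

with the 95% interval :math:`\\hat\\rho \\pm 1.96\\,\\mathrm{SE}` clipped to
``[0, 1]``.  Ordinal outcomes enter the same machinery after replacing each
category by its integer code (:func:`ordinal_scores`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CONTINUOUS, ORDINAL, ClusterSummarySet, CRTDataset, summarize
from .exceptions import DegenerateDataError, InputError

Z975 = 1.959963984540054  # scipy.stats.norm.ppf(0.975)


@dataclass
class VarianceComponents:
    """One-way ANOVA decomposition for clustered data.

    Attributes
    ----------
    msb, msw : float
        Between- and within-cluster mean squares.
    sb2, sw2 : float
        Method-of-moments variance components; ``sb2`` may be negative.
    m0 : float
        Adjusted average cluster size ``(N - sum(n_i^2)/N) / (k-1)``.
    k, n_total : int
        Number of clusters and of individuals.
    """

    msb: float
    msw: float
    sb2: float
    sw2: float
    m0: float
    k: int
    n_total: int


def adjusted_cluster_size(sizes) -> float:
    """The ANOVA cluster-size constant ``m0 = (N - sum(n_i^2)/N) / (k-1)``.

    Equals the common size ``m`` for balanced designs and is slightly below
    the arithmetic mean under unbalance.
    """
    n = np.asarray(sizes, dtype=float)
    if len(n) < 2:
        raise InputError("m0 needs at least 2 clusters")
    N = n.sum()
    return float((N - (n**2).sum() / N) / (len(n) - 1))


def anova_components(summary: ClusterSummarySet) -> VarianceComponents:
    """Mean squares and variance components from per-cluster ``(n, mean, sd)``."""
    if summary.outcome_type != CONTINUOUS:
        raise InputError(
            f"anova_components needs a continuous summary, got {summary.outcome_type!r}"
            " (convert ordinal summaries with ordinal_scores first)"
        )
    n = summary.rows["n"].to_numpy(dtype=float)
    means = summary.rows["mean"].to_numpy(dtype=float)
    sds = summary.rows["sd"].to_numpy(dtype=float)
    k = len(n)
    if k < 2:
        raise InputError("ICC estimation needs at least 2 clusters")
    N = n.sum()
    if N - k < 1:
        raise InputError("ICC estimation needs N - k >= 1 within-cluster df")
    grand = float((n * means).sum() / N)
    msb = float((n * (means - grand) ** 2).sum() / (k - 1))
    msw = float(((n - 1) * sds**2).sum() / (N - k))
    if msb == 0.0 and msw == 0.0:
        raise DegenerateDataError(
            "all cluster means equal and all within-cluster SDs zero: "
            "total variance is zero and the ICC is undefined"
        )
    m0 = adjusted_cluster_size(n)
    sb2 = (msb - msw) / m0
    return VarianceComponents(msb=msb, msw=msw, sb2=sb2, sw2=msw, m0=m0, k=k, n_total=int(N))


def swiger_ci(vc: VarianceComponents, rho: float) -> tuple[float, float, float]:
    """Swiger large-sample SE and 95% Wald interval for an ANOVA ICC.

    Returns ``(se, ci_low, ci_high)`` with the interval clipped to [0, 1].
    """
    if not 0.0 <= rho <= 1.0:
        raise InputError("rho must lie in [0, 1]")
    k, N, m0 = vc.k, vc.n_total, vc.m0
    var = (
        2.0 * (N - 1) * (1.0 - rho) ** 2 * (1.0 + (m0 - 1.0) * rho) ** 2
        / (m0**2 * (N - k) * (k - 1))
    )
    se = float(np.sqrt(var))
    return se, float(max(0.0, rho - Z975 * se)), float(min(1.0, rho + Z975 * se))


def ordinal_scores(summary: ClusterSummarySet) -> ClusterSummarySet:
    """Score an ordinal summary onto its integer category codes.

    Each category is replaced by its code (e.g. NYHA II/III/IV -> 2/3/4) and
    per-cluster mean and sample SD are computed from the category counts, so
    the ANOVA machinery for continuous outcomes applies unchanged.  The
    per-cluster ``n`` becomes the number of graded subjects (the count sum),
    which may be below the admitted n.
    """
    if summary.outcome_type != ORDINAL:
        raise InputError("ordinal_scores needs an ordinal summary")
    codes = np.asarray(summary.codes, dtype=float)
    rows = []
    for _, r in summary.rows.iterrows():
        c = np.asarray(r["counts"], dtype=float)
        tot = c.sum()
        if tot < 1:
            raise InputError(f"cluster {r['cluster_id']} has no graded subjects")
        mean = float((c * codes).sum() / tot)
        var = float((c * (codes - mean) ** 2).sum() / (tot - 1)) if tot > 1 else 0.0
        rows.append(
            {
                "cluster_id": r["cluster_id"],
                "arm": r["arm"],
                "n": int(tot),
                "mean": mean,
                "sd": float(np.sqrt(var)),
            }
        )
    return ClusterSummarySet(summary.outcome, CONTINUOUS, pd.DataFrame(rows))


class AnovaICC:
    """One-way random-effects ANOVA ICC model for one clustered outcome.

    Parameters
    ----------
    summary : ClusterSummarySet
        Continuous or ordinal per-cluster summaries (ordinal summaries are
        scored onto their category codes).

    Examples
    --------
    >>> model = AnovaICC(summary)          # doctest: +SKIP
    >>> res = model.fit()                  # doctest: +SKIP
    >>> res.icc, res.conf_int()            # doctest: +SKIP
    """

    def __init__(self, summary: ClusterSummarySet):
        if summary.outcome_type == ORDINAL:
            summary = ordinal_scores(summary)
        self.summary = summary
        self.outcome = summary.outcome

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        outcome: str,
        outcome_type: str = CONTINUOUS,
        codes: tuple[int, ...] | None = None,
    ) -> "AnovaICC":
        """Build from individual-level long data (via :func:`summarize`)."""
        data = CRTDataset(
            frame,
            {outcome: outcome_type},
            {outcome: codes} if codes is not None else {},
        )
        return cls(summarize(data, outcome))

    @classmethod
    def from_dataset(cls, data: CRTDataset, outcome: str) -> "AnovaICC":
        return cls(summarize(data, outcome))

    def fit(self) -> "AnovaICCResults":
        vc = anova_components(self.summary)
        raw = vc.sb2 / (vc.sb2 + vc.sw2)
        icc = max(raw, 0.0)
        se, lo, hi = swiger_ci(vc, icc)
        return AnovaICCResults(self, vc, raw=float(raw), icc=float(icc), se=se, ci=(lo, hi))


class AnovaICCResults:
    """Fit results for :class:`AnovaICC`.

    Attributes
    ----------
    raw : float
        Untruncated moment estimate (may be negative under little or no
        between-cluster variation).
    icc : float
        Point estimate truncated at zero, as used for design effects.
    se : float
        Swiger large-sample standard error, evaluated at the truncated
        estimate.
    components : VarianceComponents
    """

    method = "anova"

    def __init__(self, model, components, raw, icc, se, ci):
        self.model = model
        self.components = components
        self.raw = raw
        self.icc = icc
        self.se = se
        self._ci = ci

    @property
    def k(self) -> int:
        return self.components.k

    @property
    def n_total(self) -> int:
        return self.components.n_total

    @property
    def m0(self) -> float:
        return self.components.m0

    def conf_int(self) -> tuple[float, float]:
        """95% Wald interval ``icc +/- 1.96*se`` clipped to [0, 1]."""
        return self._ci

    def to_dict(self) -> dict:
        lo, hi = self._ci
        return {
            "outcome": self.model.outcome,
            "method": self.method,
            "raw": self.raw,
            "value": self.icc,
            "se": self.se,
            "ci_low": lo,
            "ci_high": hi,
            "k": self.k,
            "N": self.n_total,
            "m0": self.m0,
        }

    def summary(self) -> str:
        vc = self.components
        lo, hi = self._ci
        lines = [
            "One-way random-effects ANOVA ICC",
            "=" * 46,
            f"Outcome:            {self.model.outcome}",
            f"Clusters (k):       {vc.k}",
            f"Individuals (N):    {vc.n_total}",
            f"Adj. mean size m0:  {vc.m0:.4f}",
            "-" * 46,
            f"MSB:                {vc.msb:.6g}",
            f"MSW:                {vc.msw:.6g}",
            f"sigma_b^2:          {vc.sb2:.6g}",
            f"sigma_w^2:          {vc.sw2:.6g}",
            "-" * 46,
            f"ICC (raw):          {self.raw:.6f}",
            f"ICC (truncated):    {self.icc:.6f}",
            f"SE (Swiger):        {self.se:.6f}",
            f"95% CI:             [{lo:.6f}, {hi:.6f}]",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<AnovaICCResults icc={self.icc:.4f} se={self.se:.4f} "
            f"k={self.k} N={self.n_total}>"
        )


def icc_anova(summary: ClusterSummarySet) -> AnovaICCResults:
    """Convenience wrapper: ``AnovaICC(summary).fit()``."""
    return AnovaICC(summary).fit()
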