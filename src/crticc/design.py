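"""Design effects and sample-size inflation for cluster randomized trials.

Randomizing intact clusters instead of individuals inflates the variance of
treatment-effect estimators by the design effect

.. math:: DE = 1 + (m - 1)\\,\\rho,

where ``m`` is the average cluster size and ``rho`` the (non-negative,
truncated) ICC.  A trial powered for ``n`` individuals under simple random
sampling needs ``ceil(n * DE)`` individuals under the clustered design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .anova import adjusted_cluster_size
from .exceptions import InputError


@dataclass(frozen=True)
class DesignEffect:
    """Variance inflation of a clustered design relative to an individually
    randomized one: ``value = 1 + (m - 1) * icc``."""

    icc: float
    m: float
    value: float

    def rounded(self, ndigits: int = 2) -> float:
        return round(self.value, ndigits)


def design_effect(icc: float, m: float) -> DesignEffect:
    """Closed-form design effect ``1 + (m - 1) * icc``.

    ``icc`` must lie in [0, 1] (negative estimates are truncated upstream,
    before any sample-size use); ``m`` is the average cluster size, >= 1
    (``m = 1`` degenerates to an unclustered design with ``DE = 1``).
    """
    if not 0.0 <= icc <= 1.0:
        raise InputError(f"icc must lie in [0, 1], got {icc}")
    if m < 1.0:
        raise InputError(f"mean cluster size must be >= 1, got {m}")
    return DesignEffect(icc=float(icc), m=float(m), value=1.0 + (m - 1.0) * icc)


def inflate_n(n_individual: int, de: DesignEffect) -> int:
    """Clustered sample size: ``ceil(n_individual * de.value)``.

    A 1-ulp guard keeps products that are integers up to binary rounding
    (e.g. 100 x 2.68) from being pushed up a whole subject by float error.
    """
    if n_individual < 1:
        raise InputError("n_individual must be >= 1")
    x = n_individual * de.value
    return math.ceil(x - 1e-9 * max(1.0, abs(x)))


def mean_cluster_size(sizes) -> float:
    """Arithmetic mean cluster size (for planning, use with design_effect).

    The ANOVA companion constant ``m0`` for unbalanced designs is exposed as
    :func:`crticc.anova.adjusted_cluster_size`.
    """
    sizes = list(sizes)
    if not sizes:
        raise InputError("sizes must be nonempty")
    return float(sum(sizes) / len(sizes))


__all__ = [
    "DesignEffect",
    "design_effect",
    "inflate_n",
    "mean_cluster_size",
    "adjusted_cluster_size",
]
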