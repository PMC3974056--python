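"""Synthetic two-arm CRT data with known ground-truth ICC.

Three generative families, all random-intercept models so the target ICC is
exact by construction:

normal
    ``y_ij = mu + b_i + e_ij`` with ``b_i ~ N(0, icc * scale^2)`` and
    ``e_ij ~ N(0, (1 - icc) * scale^2)``; the ICC is the usual variance
    ratio.

binary_logit
    ``y_ij ~ Bernoulli(logit^-1(beta0 + b_i))`` with
    ``sigma_b^2 = icc * (pi^2/3) / (1 - icc)`` so that ``icc`` is exactly
    the latent-scale ICC targeted by the logit-normal estimator.  The
    ``location`` parameter is the *marginal* log-odds; ``beta0`` is solved
    numerically so the population event rate matches it (a Gaussian random
    intercept attenuates the marginal rate relative to the conditional
    intercept).

ordinal_latent
    A latent logistic variable ``b_i + eps_ij`` (``eps`` standard logistic)
    cut at a threshold vector into ordered category codes; the latent ICC is
    again ``sigma_b^2 / (sigma_b^2 + pi^2/3)``.

:func:`simulate_study_like` instantiates the 14-hospital heart-failure
trial's structure — 7 care-pathway + 7 usual-care clusters of 30-32
patients (arm totals forced to 214/215), with length of stay, cost,
mortality, appropriateness of stay, readmission and NYHA class generated at
the arm-specific means, SDs, event rates and ICCs the study reports — so
every estimator in the package can be exercised end-to-end without any
external data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .anova import icc_anova
from .binary import BootstrapConfig, fit_logit_normal, icc_anova_binary
from .data import BINARY, CONTINUOUS, ORDINAL, CRTDataset, summarize
from .exceptions import ConfigError

logger = logging.getLogger(__name__)

LOGISTIC_VARIANCE = math.pi**2 / 3.0

FAMILIES = ("normal", "binary_logit", "ordinal_latent")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for one simulated CRT outcome.

    Parameters
    ----------
    k : int
        Clusters per arm.
    cluster_sizes : int | tuple | list
        Common size, an inclusive ``(min, max)`` range sampled uniformly,
        or an explicit list of ``k * len(arms)`` sizes.
    family : str
        ``normal``, ``binary_logit`` or ``ordinal_latent``.
    true_icc : float
        Ground-truth ICC in [0, 1); variance ratio for ``normal``,
        latent-scale ICC otherwise.
    location : float
        Grand mean (normal) or marginal log-odds (binary); latent shift
        (ordinal, usually 0 with the thresholds doing the work).
    scale : float | tuple
        Total SD for ``normal``; the ordered threshold vector for
        ``ordinal_latent`` (ignored for binary).
    codes : tuple
        Ordinal category codes (must be one longer than the thresholds).
    seed : int
        Seed for the reproducible random stream.
    """

    k: int = 7
    cluster_sizes: int | tuple | list = (30, 32)
    family: str = "normal"
    true_icc: float = 0.05
    location: float = 0.0
    scale: float | tuple = 1.0
    codes: tuple[int, ...] = (2, 3, 4)
    arms: tuple[str, ...] = ("UC",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}")
        if not 0.0 <= self.true_icc < 1.0:
            raise ConfigError(f"true_icc must lie in [0, 1), got {self.true_icc}")
        if self.k < 2:
            raise ConfigError("k must be >= 2")

    @property
    def sigma_b(self) -> float:
        """Between-cluster SD implied by ``true_icc`` for this family."""
        if self.family == "normal":
            return math.sqrt(self.true_icc) * float(self.scale)
        return math.sqrt(self.true_icc * LOGISTIC_VARIANCE / (1.0 - self.true_icc))


def _draw_sizes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    total = config.k * len(config.arms)
    cs = config.cluster_sizes
    if isinstance(cs, int):
        return np.full(total, cs, dtype=int)
    if isinstance(cs, tuple) and len(cs) == 2:
        return rng.integers(cs[0], cs[1] + 1, size=total)
    sizes = np.asarray(list(cs), dtype=int)
    if len(sizes) != total:
        raise ConfigError(f"need {total} cluster sizes, got {len(sizes)}")
    return sizes


def _solve_conditional_intercept(marginal_logodds: float, sigma_b: float) -> float:
    """beta0 such that E[expit(beta0 + sigma_b Z)] = expit(marginal_logodds)."""
    if sigma_b == 0.0:
        return marginal_logodds
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    w = weights / math.sqrt(2.0 * math.pi)
    target = expit(marginal_logodds)

    def marginal(b0):
        return float(np.sum(w * expit(b0 + sigma_b * nodes))) - target

    return float(optimize.brentq(marginal, marginal_logodds - 10, marginal_logodds + 10))


def _solve_thresholds(marginal_probs, sigma_b: float) -> np.ndarray:
    """Latent-logistic cutpoints reproducing marginal category probabilities."""
    cum = np.cumsum(marginal_probs)[:-1]
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    w = weights / math.sqrt(2.0 * math.pi)
    thresholds = []
    for c in cum:
        f = lambda t: float(np.sum(w * expit(t - sigma_b * nodes))) - c
        thresholds.append(optimize.brentq(f, -30, 30))
    return np.asarray(thresholds)


def _gen_outcome(
    config: SimulationConfig, sizes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One outcome column (concatenated over clusters in size order)."""
    k_total = len(sizes)
    N = int(sizes.sum())
    sigma_b = config.sigma_b
    b = rng.normal(0.0, sigma_b, size=k_total) if sigma_b > 0 else np.zeros(k_total)
    b_long = np.repeat(b, sizes)
    if config.family == "normal":
        sigma_w = math.sqrt(1.0 - config.true_icc) * float(config.scale)
        return config.location + b_long + rng.normal(0.0, sigma_w, size=N)
    if config.family == "binary_logit":
        beta0 = _solve_conditional_intercept(config.location, sigma_b)
        return rng.binomial(1, expit(beta0 + b_long)).astype(float)
    # ordinal_latent
    thresholds = np.asarray(config.scale, dtype=float)
    if len(config.codes) != len(thresholds) + 1:
        raise ConfigError("codes must be one longer than the threshold vector")
    latent = config.location + b_long + rng.logistic(0.0, 1.0, size=N)
    idx = np.searchsorted(thresholds, latent)
    return np.asarray(config.codes, dtype=float)[idx]


def simulate(config: SimulationConfig) -> CRTDataset:
    """Draw one CRT dataset (outcome column ``y``) under ``config``.

    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sizes = _draw_sizes(config, rng)
    y = _gen_outcome(config, sizes, rng)
    cluster_ids = [
        f"{arm} {i + 1 + a * config.k}"
        for a, arm in enumerate(config.arms)
        for i in range(config.k)
    ]
    frame = pd.DataFrame(
        {
            "cluster_id": np.repeat(cluster_ids, sizes),
            "arm": np.repeat(
                [arm for arm in config.arms for _ in range(config.k)], sizes
            ),
            "y": y,
        }
    )
    typ = {"normal": CONTINUOUS, "binary_logit": BINARY, "ordinal_latent": ORDINAL}[
        config.family
    ]
    codes = {"y": tuple(config.codes)} if typ == ORDINAL else {}
    return CRTDataset(frame, {"y": typ}, codes)


# ---------------------------------------------------------------------------
# study-like multi-outcome generator
# ---------------------------------------------------------------------------

#: per-arm generative parameters mirroring the trial's reported summaries
#: (means/SDs/rates from the outcome table, ICCs from the estimate tables)
STUDY_PARAMS = {
    "los": {"family": "normal",
            "CP": {"mean": 10.35, "sd": 5.17, "icc": 0.063},
            "UC": {"mean": 11.42, "sd": 6.69, "icc": 0.020}},
    "cost": {"family": "normal",
             "CP": {"mean": 2125.56, "sd": 530.93, "icc": 0.001},
             "UC": {"mean": 2211.21, "sd": 574.76, "icc": 0.046}},
    "mortality": {"family": "binary_logit",
                  "CP": {"rate": 0.056, "icc": 0.001},
                  "UC": {"rate": 0.153, "icc": 0.001}},
    "aos": {"family": "binary_logit",
            "CP": {"rate": 0.762, "icc": 0.069},
            "UC": {"rate": 0.721, "icc": 0.203}},
    "readmission": {"family": "binary_logit",
                    "CP": {"rate": 0.079, "icc": 0.010},
                    "UC": {"rate": 0.140, "icc": 0.004}},
    "nyha_admission": {"family": "ordinal_latent",
                       "CP": {"probs": (0.072, 0.541, 0.387), "icc": 0.046},
                       "UC": {"probs": (0.072, 0.541, 0.387), "icc": 0.046}},
}

_ARM_TOTALS = {"CP": 214, "UC": 215}


def _study_sizes(rng: np.random.Generator, target: int) -> np.ndarray:
    """Seven sizes from {30, 31, 32} forced to sum to the arm total."""
    sizes = rng.integers(30, 33, size=7)
    order = rng.permutation(7)
    j = 0
    while sizes.sum() != target:
        i = order[j % 7]
        if sizes.sum() < target and sizes[i] < 32:
            sizes[i] += 1
        elif sizes.sum() > target and sizes[i] > 30:
            sizes[i] -= 1
        j += 1
    return sizes


def simulate_study_like(seed: int) -> CRTDataset:
    """A synthetic replica of the trial's design: 14 clusters, 429 patients.

    Continuous outcomes are truncated at zero (a patient cannot have a
    negative stay or cost); truncation events are logged.  All generative
    parameters live in :data:`STUDY_PARAMS`.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for a, arm in enumerate(("CP", "UC")):
        sizes = _study_sizes(rng, _ARM_TOTALS[arm])
        N = int(sizes.sum())
        ids = [f"{arm} {i + 1 + 7 * a}" for i in range(7)]
        cols = {
            "cluster_id": np.repeat(ids, sizes),
            "arm": np.repeat(arm, N),
        }
        for name, params in STUDY_PARAMS.items():
            p = params[arm]
            if params["family"] == "normal":
                cfg = SimulationConfig(
                    k=7, family="normal", true_icc=p["icc"],
                    location=p["mean"], scale=p["sd"], arms=(arm,),
                )
                y = _gen_outcome(cfg, sizes, rng)
                n_trunc = int((y < 0).sum())
                if n_trunc:
                    logger.info(
                        "simulate_study_like: %d negative %s values truncated to 0",
                        n_trunc, name,
                    )
                cols[name] = np.maximum(y, 0.0)
            elif params["family"] == "binary_logit":
                cfg = SimulationConfig(
                    k=7, family="binary_logit", true_icc=p["icc"],
                    location=float(np.log(p["rate"] / (1 - p["rate"]))), arms=(arm,),
                )
                cols[name] = _gen_outcome(cfg, sizes, rng)
            else:
                sigma_b = math.sqrt(p["icc"] * LOGISTIC_VARIANCE / (1 - p["icc"]))
                thresholds = tuple(_solve_thresholds(p["probs"], sigma_b))
                cfg = SimulationConfig(
                    k=7, family="ordinal_latent", true_icc=p["icc"],
                    location=0.0, scale=thresholds, codes=(2, 3, 4), arms=(arm,),
                )
                cols[name] = _gen_outcome(cfg, sizes, rng)
        frames.append(pd.DataFrame(cols))
    frame = pd.concat(frames, ignore_index=True)
    outcome_types = {
        name: {"normal": CONTINUOUS, "binary_logit": BINARY, "ordinal_latent": ORDINAL}[
            params["family"]
        ]
        for name, params in STUDY_PARAMS.items()
    }
    return CRTDataset(frame, outcome_types, {"nyha_admission": (2, 3, 4)})


# ---------------------------------------------------------------------------
# recovery experiments
# ---------------------------------------------------------------------------

ESTIMATORS = ("anova", "logit_normal", "anova_binary")

_VALID_PAIRS = {
    "normal": ("anova",),
    "ordinal_latent": ("anova",),
    "binary_logit": ("logit_normal", "anova_binary"),
}


@dataclass
class RecoveryReport:
    """Bias / RMSE / CI-coverage summary of a parameter-recovery run."""

    estimator: str
    family: str
    true_icc: float
    n_reps: int
    bias: float          #: mean(truncated estimate) - truth
    bias_raw: float      #: mean(raw estimate) - truth (anova only; else == bias)
    rmse: float
    coverage: float | None  #: fraction of 95% CIs covering the truth
    estimates: np.ndarray = field(repr=False)
    base_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "family": self.family,
            "true_icc": self.true_icc,
            "n_reps": self.n_reps,
            "bias": self.bias,
            "bias_raw": self.bias_raw,
            "rmse": self.rmse,
            "coverage": self.coverage,
            "base_seed": self.base_seed,
        }


def recovery_experiment(
    config: SimulationConfig,
    n_reps: int,
    estimator: str = "anova",
    boot: BootstrapConfig | None = None,
    compute_ci: bool = True,
) -> RecoveryReport:
    """Repeatedly simulate and re-estimate; report bias, RMSE and coverage.

    Replicate ``r`` uses seed ``config.seed + r`` (recorded in the report),
    so runs are reproducible and extensible.  ``boot`` configures the
    bootstrap CI for the ``logit_normal`` estimator; for ``anova`` the
    Swiger interval is used.  ``compute_ci=False`` skips intervals (and
    coverage) when only point-estimate behaviour is of interest.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    if estimator not in ESTIMATORS:
        raise ConfigError(f"unknown estimator {estimator!r}")
    if estimator not in _VALID_PAIRS[config.family]:
        raise ConfigError(
            f"estimator {estimator!r} does not apply to family {config.family!r}"
        )
    values = np.empty(n_reps)
    raws = np.empty(n_reps)
    covered = np.zeros(n_reps, dtype=bool)
    have_ci = compute_ci
    for r in range(n_reps):
        cfg = replace(config, seed=config.seed + r)
        data = simulate(cfg)
        summary = summarize(data, "y")
        if estimator == "anova":
            res = icc_anova(summary)
            values[r], raws[r] = res.icc, res.raw
            if compute_ci:
                lo, hi = res.conf_int()
                covered[r] = lo <= config.true_icc <= hi
        elif estimator == "anova_binary":
            res = icc_anova_binary(summary)
            values[r], raws[r] = res.icc, res.raw
            if compute_ci:
                lo, hi = res.conf_int()
                covered[r] = lo <= config.true_icc <= hi
        else:
            res = fit_logit_normal(summary)
            values[r] = raws[r] = res.icc
            if compute_ci:
                bc = boot or BootstrapConfig(n_reps=200)
                lo, hi = res.bootstrap_ci(replace(bc, seed=(bc.seed or 0) + r))
                covered[r] = lo <= config.true_icc <= hi
    return RecoveryReport(
        estimator=estimator,
        family=config.family,
        true_icc=config.true_icc,
        n_reps=n_reps,
        bias=float(values.mean() - config.true_icc),
        bias_raw=float(raws.mean() - config.true_icc),
        rmse=float(np.sqrt(np.mean((values - config.true_icc) ** 2))),
        coverage=float(covered.mean()) if have_ci else None,
        estimates=values,
        base_seed=config.seed,
    )
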