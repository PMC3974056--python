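"""ANOVA ICC estimator: components, CIs, ordinal scoring, properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crticc import (
    AnovaICC,
    ClusterSummarySet,
    DegenerateDataError,
    adjusted_cluster_size,
    anova_components,
    icc_anova,
    ordinal_scores,
    summarize,
    swiger_ci,
)
from crticc.simulate import SimulationConfig, simulate

from conftest import make_continuous_summary

UC_SIZES = [30, 30, 32, 31, 30, 30, 32]


def test_perfect_separation_components():
    s = make_continuous_summary(
        [("a", "CP", 2, 0.0, 0.0), ("b", "CP", 2, 1.0, 0.0)]
    )
    vc = anova_components(s)
    assert vc.msw == 0.0
    assert vc.sb2 > 0


def test_adjusted_cluster_size_uc_arm():
    # (215 - 6609/215) / 6 for the usual-care sizes
    assert adjusted_cluster_size(UC_SIZES) == pytest.approx(30.71, abs=0.01)


def test_uc_los_mean_squares(study):
    vc = anova_components(study.table2["los"].subset_arm("UC"))
    assert vc.msb == pytest.approx(71.7, abs=0.1)
    assert vc.msw == pytest.approx(44.0, abs=0.1)
    assert vc.sw2 == vc.msw
    assert vc.sb2 == pytest.approx((vc.msb - vc.msw) / vc.m0, rel=1e-12)


@pytest.mark.parametrize(
    "arm, printed",
    [("UC", 0.020), ("CP", 0.063)],
)
def test_los_icc_matches_published(study, arm, printed):
    res = icc_anova(study.table2["los"].subset_arm(arm))
    assert res.icc == pytest.approx(printed, abs=0.005)


def test_identical_means_truncate_to_zero():
    s = make_continuous_summary(
        [("a", "CP", 10, 5.0, 1.0), ("b", "CP", 10, 5.0, 2.0), ("c", "CP", 10, 5.0, 1.5)]
    )
    res = icc_anova(s)
    assert res.raw <= 0
    assert res.icc == 0.0


def test_degenerate_zero_variance_raises():
    s = make_continuous_summary(
        [("a", "CP", 5, 3.0, 0.0), ("b", "CP", 5, 3.0, 0.0)]
    )
    with pytest.raises(DegenerateDataError):
        anova_components(s)


def test_swiger_se_at_rho_zero_balanced():
    m, k = 30, 10
    N = m * k
    s = make_continuous_summary(
        [(f"c{i}", "CP", m, float(i % 2), 1.0) for i in range(k)]
    )
    vc = anova_components(s)
    se, lo, hi = swiger_ci(vc, 0.0)
    expected = np.sqrt(2.0 * (N - 1) / (m**2 * (N - k) * (k - 1)))
    assert se == pytest.approx(expected, rel=1e-12)
    assert lo == 0.0


def test_uc_los_ci_lower_bound_clips_to_zero(study):
    res = icc_anova(study.table2["los"].subset_arm("UC"))
    lo, hi = res.conf_int()
    assert lo == 0.0
    assert 0 < hi < 1


def test_swiger_se_tracks_jackknife_on_average():
    """The analytic SE agrees with a jackknife-over-clusters SE once both
    are averaged over replicate datasets (a single-dataset jackknife SE
    carries ~10% Monte-Carlo noise of its own at k=50)."""
    sw, jk = [], []
    for r in range(50):
        s = summarize(simulate(SimulationConfig(
            k=50, cluster_sizes=30, family="normal", true_icc=0.05, seed=7 + r)), "y")
        res = icc_anova(s)
        sw.append(res.se)
        loo = []
        for cid in s.rows["cluster_id"]:
            sub = ClusterSummarySet(
                "y", "continuous",
                s.rows[s.rows["cluster_id"] != cid].reset_index(drop=True))
            loo.append(icc_anova(sub).icc)
        loo = np.asarray(loo)
        k = len(loo)
        jk.append(np.sqrt((k - 1) / k * np.sum((loo - loo.mean()) ** 2)))
    assert np.mean(sw) == pytest.approx(np.mean(jk), rel=0.10)


def test_ordinal_scores_from_counts():
    s = ClusterSummarySet(
        "nyha", "ordinal",
        pd.DataFrame({"cluster_id": ["a", "b"], "arm": ["CP", "CP"],
                      "n": [30, 30], "counts": [(2, 12, 16), (0, 30, 0)]}),
        codes=(2, 3, 4),
    )
    scored = ordinal_scores(s)
    row = scored.rows.set_index("cluster_id")
    assert row.loc["a", "mean"] == pytest.approx((2 * 2 + 12 * 3 + 16 * 4) / 30)
    assert row.loc["b", "sd"] == 0.0  # all mass on one category


def test_nyha_admission_icc_matches_published(study):
    res = icc_anova(study.table1["nyha_admission"])
    assert res.icc == pytest.approx(0.046, abs=0.01)


def test_ordinal_summary_accepted_directly(study):
    # AnovaICC scores ordinal input internally; same result as explicit scoring
    direct = AnovaICC(study.table1["nyha_admission"]).fit()
    explicit = icc_anova(ordinal_scores(study.table1["nyha_admission"]))
    assert direct.icc == explicit.icc


@settings(derandomize=True, max_examples=50)
@given(
    a=st.floats(min_value=0.01, max_value=100).filter(lambda x: abs(x) > 1e-6),
    b=st.floats(min_value=-1e3, max_value=1e3),
    flip=st.booleans(),
)
def test_affine_invariance(a, b, flip):
    """The ICC is a variance ratio: y -> a*y + b leaves it unchanged."""
    if flip:
        a = -a
    base = make_continuous_summary(
        [("a", "CP", 10, 1.0, 1.0), ("b", "CP", 12, 2.5, 2.0),
         ("c", "UC", 11, 0.5, 1.5), ("d", "UC", 10, 3.0, 0.8)]
    )
    transformed = ClusterSummarySet(
        "y", "continuous",
        base.rows.assign(mean=a * base.rows["mean"] + b,
                         sd=abs(a) * base.rows["sd"]),
    )
    r0, r1 = icc_anova(base), icc_anova(transformed)
    assert r1.icc == pytest.approx(r0.icc, rel=1e-9, abs=1e-12)


def test_mean_deviation_inflation_monotone():
    """Scaling every cluster mean's deviation from the grand mean upward
    (within-SDs fixed) never decreases the estimate."""
    base = make_continuous_summary(
        [("a", "CP", 10, 1.0, 1.0), ("b", "CP", 10, 2.0, 2.0),
         ("c", "UC", 10, 3.0, 1.5), ("d", "UC", 10, 4.0, 0.8)]
    )
    grand = (base.rows["n"] * base.rows["mean"]).sum() / base.rows["n"].sum()
    last = icc_anova(base).icc
    for factor in (1.2, 1.7, 2.5, 4.0):
        inflated = ClusterSummarySet(
            "y", "continuous",
            base.rows.assign(mean=grand + factor * (base.rows["mean"] - grand)),
        )
        cur = icc_anova(inflated).icc
        assert cur >= last - 1e-12
        last = cur


def test_balanced_total_variance_decomposition():
    """On balanced data sb2 + sw2 recovers the ANOVA's implied total
    variance and the raw estimate respects its algebraic floor."""
    cfg = SimulationConfig(k=20, cluster_sizes=30, family="normal",
                           true_icc=0.1, scale=2.0, seed=21)
    s = summarize(simulate(cfg), "y")
    vc = anova_components(s)
    m = 30
    res = icc_anova(s)
    # algebraic range of the moment estimator on balanced data
    assert -1.0 / (m - 1) < res.raw <= 1.0
    assert vc.sb2 + vc.sw2 == pytest.approx(vc.msw + (vc.msb - vc.msw) / m, rel=1e-10)


def test_parameter_recovery_at_study_size():
    """Mean estimate over 500 replicates of a 14-cluster, m=30 design with a
    true ICC of 0.05 lands within 0.01 of the truth."""
    from crticc import recovery_experiment

    rep = recovery_experiment(
        SimulationConfig(k=14, cluster_sizes=30, family="normal",
                         true_icc=0.05, seed=200),
        500, "anova", compute_ci=False,
    )
    assert abs(rep.bias) < 0.01


def test_results_serialization(study):
    d = icc_anova(study.table2["los"].subset_arm("UC")).to_dict()
    assert d["method"] == "anova"
    assert d["k"] == 7 and d["N"] == 215
    assert 0 <= d["ci_low"] <= d["value"] <= d["ci_high"] <= 1
    text = icc_anova(study.table2["los"].subset_arm("UC")).summary()
    assert "ICC" in text and "Swiger" in text
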