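"""Region aggregation, paired testing, variability, covariates, power,
Wilcoxon."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import twinmeth as tm
from twinmeth import regions as rg


def _counts(records):
    return pd.DataFrame(records,
                        columns=["region_id", "chrom", "pos", "sample",
                                 "meth", "unmeth"])


def _sheet(n, **kw):
    base = dict(sex="female", age=60, packyears=0.0, smoking_status="never",
                histology="adenocarcinoma")
    base.update(kw)
    return pd.DataFrame([{**{"pair_id": f"p{i}", "case_sample": f"c{i}",
                             "control_sample": f"k{i}"}, **base}
                         for i in range(n)])


# ------------------------------------------------------------ aggregation
def test_fraction_and_coverage_arithmetic():
    rc = _counts([("r1", "chr1", 10, "s1", 80, 20),
                  ("r1", "chr1", 20, "s1", 100, 100),
                  ("r1", "chr1", 30, "s1", 150, 150)])
    agg = rg.aggregate_regions(rc)
    assert agg.fractions.loc[("r1", "chr1", 10), "s1"] == pytest.approx(0.80)
    assert agg.mean_coverage["r1"] == pytest.approx(200.0)
    assert agg.region_means.loc["r1", "s1"] == pytest.approx(
        (0.8 + 0.5 + 0.5) / 3)


def test_two_region_toy_means_match_hand_computation():
    rc = _counts([("r1", "chr1", 10, "s1", 50, 50),
                  ("r1", "chr1", 20, "s1", 30, 70),
                  ("r2", "chr2", 5, "s1", 90, 10)])
    agg = rg.aggregate_regions(rc)
    assert agg.region_means.loc["r1", "s1"] == pytest.approx(0.4)
    assert agg.region_means.loc["r2", "s1"] == pytest.approx(0.9)


def test_low_depth_cpgs_become_missing():
    rc = _counts([("r1", "chr1", 10, "s1", 3, 2),       # depth 5 < 10
                  ("r1", "chr1", 20, "s1", 30, 20)])
    agg = rg.aggregate_regions(rc)
    assert math.isnan(agg.fractions.loc[("r1", "chr1", 10), "s1"])
    # all-shallow region: mean missing for that sample
    rc2 = _counts([("r1", "chr1", 10, "s1", 1, 1)])
    assert math.isnan(
        rg.aggregate_regions(rc2).region_means.loc["r1", "s1"])
    with pytest.raises(ValueError):
        rg.aggregate_regions(rc.iloc[:0])


# --------------------------------------------------------- paired testing
def _fractions_from(case_vals, ctrl_vals):
    """One CpG per row; columns c*/k* as in _sheet."""
    n = len(case_vals[0])
    cols = {}
    for i in range(n):
        cols[f"c{i}"] = [row[i] for row in case_vals]
        cols[f"k{i}"] = [row[i] for row in ctrl_vals]
    idx = pd.MultiIndex.from_tuples(
        [("r1", "chr1", 10 * (j + 1)) for j in range(len(case_vals))],
        names=["region_id", "chrom", "pos"])
    return pd.DataFrame(cols, index=idx)


def test_paired_t_matches_closed_form_oracle():
    diffs = np.array([0.02, 0.03, 0.01, 0.04])
    frac = _fractions_from([0.5 + diffs], [np.full(4, 0.5)])
    res = rg.paired_position_tests(frac, _sheet(4))
    m, s = diffs.mean(), diffs.std(ddof=1)
    t_oracle = m / (s / 2.0)
    p_oracle = 2 * stats.t.sf(abs(t_oracle), 3)
    assert res["t"].iloc[0] == pytest.approx(t_oracle, abs=1e-12)
    assert res["p"].iloc[0] == pytest.approx(p_oracle, abs=1e-12)


def test_identical_case_control_and_zero_variance_markers():
    vals = np.array([0.4, 0.5, 0.6, 0.7])
    frac = _fractions_from([vals, vals + 0.01], [vals, vals])
    res = rg.paired_position_tests(frac, _sheet(4))
    assert res["t"].iloc[0] == 0.0 or math.isnan(res["t"].iloc[0])
    # constant nonzero shift has zero difference variance -> undefined
    assert math.isnan(res["p"].iloc[1])


def test_missing_pairs_dropped_per_cpg():
    case = np.array([0.52, 0.55, np.nan, 0.60])
    ctrl = np.array([0.50, 0.50, 0.50, 0.50])
    res = rg.paired_position_tests(_fractions_from([case], [ctrl]),
                                   _sheet(4))
    assert res["n_pairs"].iloc[0] == 3


def test_planted_shifted_region_detected_with_fdr():
    cfg = tm.SimConfig(seed=6, n_regions=6, n_cc_pairs=40,
                       coverage_mean=500, variable_region_index=None,
                       shifted_region_index=3, shifted_effect=0.05)
    rc, sheet = tm.generate_casecontrol_regions(cfg)
    agg = rg.aggregate_regions(rc)
    res = rg.paired_position_tests(agg.fractions, sheet)
    shifted = res.xs("region03", level="region_id")
    others = res.drop("region03", level="region_id")
    assert (shifted["q"] < 0.05).all()
    assert (others["q"] > 0.05).mean() > 0.9


def test_storey_q_bounded_by_bh():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=200) ** 2     # enriched near zero
    from statsmodels.stats.multitest import multipletests
    bh = multipletests(p, method="fdr_bh")[1]
    q = rg.storey_q(p)
    assert (q <= bh + 1e-12).all()
    assert (q <= 1.0).all()


# ------------------------------------------------------------ variability
def test_variability_zero_for_identical_pairs():
    vals = np.array([0.4, 0.5, 0.6, 0.7])
    frac = _fractions_from([vals], [vals])
    out = rg.region_variability(frac, _sheet(4))
    assert out["sd_signed_diff"].iloc[0] == pytest.approx(0.0)
    assert out["mean_abs_diff"].iloc[0] == pytest.approx(0.0)


def test_mean_abs_diff_matches_hand_computation_two_pairs():
    frac = _fractions_from([[0.6, 0.4]], [[0.5, 0.5]])  # diffs +0.1, -0.1
    out = rg.region_variability(frac, _sheet(2))
    assert out["mean_abs_diff"].iloc[0] == pytest.approx(0.1)
    assert out["sd_signed_diff"].iloc[0] == pytest.approx(
        np.std([0.1, -0.1], ddof=1))
    with pytest.raises(ValueError):
        rg.region_variability(frac, _sheet(1))


def test_planted_variable_region_ranked_first_across_seeds():
    for seed in range(1, 11):
        cfg = tm.SimConfig(seed=seed, n_regions=8, n_cc_pairs=30,
                           coverage_mean=300, variable_region_index=5)
        rc, sheet = tm.generate_casecontrol_regions(cfg)
        agg = rg.aggregate_regions(rc)
        out = rg.region_variability(agg.fractions, sheet)
        assert out.index[0] == "region05"
        assert out["variable"].loc["region05"]


# ------------------------------------------------------------- covariates
def test_linear_age_dependence_gives_r_one():
    sheet = _sheet(4)
    sheet["age"] = [40, 50, 60, 70]
    means = pd.DataFrame(
        {f"c{i}": 0.3 + 0.002 * sheet.age[i] for i in range(4)}
        | {f"k{i}": 0.3 + 0.002 * sheet.age[i] for i in range(4)},
        index=pd.Index(["r1"], name="region_id"))
    out = rg.covariate_association(means, sheet)
    assert out.loc["r1", "r_age"] == pytest.approx(1.0)


def test_r2_matches_normal_equations_oracle():
    sheet = _sheet(2)
    sheet.loc[1, "sex"] = "male"
    y = np.array([0.2, 0.5, 0.3, 0.6])   # c0, c1, k0, k1 order built below
    means = pd.DataFrame({"c0": [0.2], "c1": [0.5], "k0": [0.3], "k1": [0.6]},
                         index=pd.Index(["r1"], name="region_id"))
    out = rg.covariate_association(means, sheet)
    x = np.column_stack([np.ones(4), [0, 1, 0, 1]])   # female=0, male=1
    beta = np.linalg.solve(x.T @ x, x.T @ y)
    resid = y - x @ beta
    r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
    assert out.loc["r1", "r2_sex"] == pytest.approx(r2, abs=1e-12)


def test_constant_covariate_gives_nan_marker():
    sheet = _sheet(3)                     # all female, never smokers
    means = pd.DataFrame(
        {s: [v] for s, v in zip(["c0", "c1", "c2", "k0", "k1", "k2"],
                                [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])},
        index=pd.Index(["r1"], name="region_id"))
    out = rg.covariate_association(means, sheet)
    assert math.isnan(out.loc["r1", "r2_sex"])
    assert math.isnan(out.loc["r1", "r_packyears"])


def test_null_regions_show_weak_covariate_relations():
    cfg = tm.SimConfig(seed=8, n_regions=10, n_cc_pairs=109,
                       coverage_mean=400, variable_region_index=None)
    rc, sheet = tm.generate_casecontrol_regions(cfg)
    agg = rg.aggregate_regions(rc)
    out = rg.covariate_association(agg.region_means, sheet)
    # null fluctuations: nearly all regions well below 0.2, none anywhere near
    # a real association
    assert (np.abs(out["r_age"]) < 0.2).mean() >= 0.9
    assert np.nanmax(np.abs(out["r_age"])) < 0.3
    assert np.nanmax(out[["r2_sex", "r2_smoking_status",
                          "r2_case_status"]].to_numpy()) < 0.2


# ------------------------------------------------------------------ power
def _power_oracle(n, delta, sd, alpha):
    """Noncentral-t tails by quadrature over the chi-square mixing density."""
    df = n - 1
    ncp = delta / (sd / math.sqrt(n))
    tcrit = stats.t.ppf(1 - alpha / 2, df)

    def upper(u):
        return stats.norm.sf(tcrit * math.sqrt(u / df) - ncp) \
            * stats.chi2.pdf(u, df)

    def lower(u):
        return stats.norm.cdf(-tcrit * math.sqrt(u / df) - ncp) \
            * stats.chi2.pdf(u, df)

    hi = integrate.quad(upper, 0, np.inf, limit=200)[0]
    lo = integrate.quad(lower, 0, np.inf, limit=200)[0]
    return hi + lo


def test_power_matches_quadrature_oracle_on_grid():
    for n in (10, 50, 109):
        for sd in (0.05, 0.1, 0.2):
            got = rg.paired_power(rg.PowerSpec(n=n, delta=0.05, sd=sd))
            assert got == pytest.approx(_power_oracle(n, 0.05, sd, 0.05),
                                        abs=1e-4)


def test_power_null_equals_alpha_and_monotonicity():
    assert rg.paired_power(rg.PowerSpec(n=30, delta=0.0, sd=0.1)) \
        == pytest.approx(0.05, abs=1e-10)
    p_base = rg.paired_power(rg.PowerSpec(n=30, delta=0.05, sd=0.1))
    assert rg.paired_power(rg.PowerSpec(n=60, delta=0.05, sd=0.1)) > p_base
    assert rg.paired_power(rg.PowerSpec(n=30, delta=0.08, sd=0.1)) > p_base
    assert rg.paired_power(rg.PowerSpec(n=30, delta=0.05, sd=0.2)) < p_base
    with pytest.raises(ValueError):
        rg.paired_power(rg.PowerSpec(n=30, delta=0.05, sd=0.0))


# --------------------------------------------------------------- Wilcoxon
def test_wilcoxon_exact_enumeration_oracle():
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    w, p = rg.wilcoxon_one_sided(x, y, alternative="less")
    assert p == pytest.approx(1 / 20)
    # enumeration: rank-sum of x over all C(6,3) assignments
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    assert w == pytest.approx(w_obs)
    all_sums = [sum(c) for c in itertools.combinations(range(1, 7), 3)]
    assert p == pytest.approx(
        sum(s <= w_obs for s in all_sums) / len(all_sums))


def test_wilcoxon_identical_samples_not_significant():
    x = [1.0, 2.0, 3.0, 4.0]
    w, p = rg.wilcoxon_one_sided(x, x, alternative="less")
    assert p > 0.3
    with pytest.raises(ValueError):
        rg.wilcoxon_one_sided([], x)


def test_wilcoxon_exact_and_normal_branches_agree():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 15)
    y = rng.normal(0.5, 1, 15)
    _, p_exact = rg.wilcoxon_one_sided(x, y, alternative="less")
    res = stats.mannwhitneyu(x, y, alternative="less", method="asymptotic")
    assert abs(p_exact - res.pvalue) < 0.01
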