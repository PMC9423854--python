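"""Region-level analysis of targeted bisulfite count data.

Matched case-control amplicon data enter as per-CpG methylated/unmethylated
read counts.  This module aggregates them to methylation fractions and
region means, runs two-sided paired t-tests per CpG with FDR correction
(BH, or a Storey-style q-value), ranks regions by bidirectional intra-pair
variability, relates region means to clinical covariates, and computes the
power of the paired t-test from the noncentral-t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_MIN_DEPTH = 10


@dataclass
class RegionAggregate:
    fractions: pd.DataFrame       # (region_id, chrom, pos) x samples
    region_means: pd.DataFrame    # region_id x samples (unweighted over CpGs)
    mean_coverage: pd.Series      # region_id -> mean depth across cytosines


def aggregate_regions(rc: pd.DataFrame,
                      min_depth: int = DEFAULT_MIN_DEPTH) -> RegionAggregate:
    """Fractions, unweighted region means and mean coverage.

    The methylation fraction meth/(meth+unmeth) is defined only where depth
    is > 0 and at least ``min_depth``; region means are unweighted means of
    the CpG fractions; mean coverage is the mean read depth across all
    cytosines (and samples) of a region.
    """
    if rc.empty:
        raise ValueError("empty region count table")
    rc = rc.copy()
    depth = rc["meth"] + rc["unmeth"]
    rc["depth"] = depth
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where((depth > 0) & (depth >= min_depth),
                        rc["meth"] / depth, np.nan)
    rc["fraction"] = frac
    fractions = rc.pivot(index=["region_id", "chrom", "pos"],
                         columns="sample", values="fraction")
    region_means = fractions.groupby(level="region_id").mean()
    mean_coverage = rc.groupby("region_id")["depth"].mean()
    return RegionAggregate(fractions=fractions, region_means=region_means,
                           mean_coverage=mean_coverage)


def _paired_diffs(values: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Case-minus-control differences per matched pair (columns = pair ids)."""
    case = values[list(sheet.case_sample)].to_numpy(dtype=float)
    ctrl = values[list(sheet.control_sample)].to_numpy(dtype=float)
    return pd.DataFrame(case - ctrl, index=values.index,
                        columns=list(sheet.pair_id))


def storey_q(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey-style q-values: BH scaled by the null-proportion estimate
    pi0 = #{p > lambda} / ((1 - lambda) m), capped at 1."""
    p = np.asarray(p, dtype=float)
    ok = np.isfinite(p)
    m = ok.sum()
    pi0 = min(1.0, (p[ok] > lam).sum() / ((1.0 - lam) * m)) if m else np.nan
    q = np.full_like(p, np.nan)
    if m:
        q[ok] = np.minimum(1.0, pi0 * multipletests(p[ok], method="fdr_bh")[1])
    return q


def paired_position_tests(fractions: pd.DataFrame, sheet: pd.DataFrame,
                          *, fdr: str = "bh") -> pd.DataFrame:
    """Two-sided paired t-test per CpG with FDR across CpGs.

    The paired test is the one-sample t on case-minus-control differences;
    pairs with a missing value are dropped per CpG.  CpGs with fewer than
    two complete pairs or zero difference variance get NaN markers and are
    excluded from the FDR adjustment.
    """
    diffs = _paired_diffs(fractions, sheet).to_numpy()
    fin = np.isfinite(diffs)
    n = fin.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(fin, diffs, 0.0).sum(axis=1) / n
        ss = np.where(fin, (diffs - mean[:, None]) ** 2, 0.0).sum(axis=1)
        sd = np.sqrt(ss / (n - 1))
        t = mean / (sd / np.sqrt(n))
    bad = (n < 2) | (sd == 0) | ~np.isfinite(sd)
    mean = np.where(n > 0, mean, np.nan)
    t = np.where(bad, np.nan, t)
    p = np.where(bad, np.nan, 2.0 * stats.t.sf(np.abs(t), n - 1))
    if fdr == "bh":
        q = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    elif fdr == "storey":
        q = storey_q(p)
    else:
        raise ValueError(f"unknown fdr method {fdr!r}")
    return pd.DataFrame({"n_pairs": n, "mean_diff": mean, "t": t,
                         "p": p, "q": q}, index=fractions.index)


def region_variability(fractions: pd.DataFrame, sheet: pd.DataFrame,
                       *, top_k: int = 1) -> pd.DataFrame:
    """Rank regions by the SD of signed paired differences.

    The SD of signed case-minus-control differences (pooled over CpGs and
    pairs) captures variability *in both directions*; the report also
    carries the mean absolute paired difference per region and flags the
    ``top_k`` highest-SD regions as variable.
    """
    if len(sheet) < 2:
        raise ValueError("need >=2 matched pairs")
    diffs = _paired_diffs(fractions, sheet)
    grp = diffs.groupby(level="region_id")
    out = pd.DataFrame({
        "mean_abs_diff": grp.apply(
            lambda g: float(np.nanmean(np.abs(g.to_numpy())))),
        "sd_signed_diff": grp.apply(
            lambda g: float(np.nanstd(g.to_numpy(), ddof=1))),
    })
    out["rank"] = out["sd_signed_diff"].rank(ascending=False,
                                             method="first").astype(int)
    out["variable"] = out["rank"] <= top_k
    return out.sort_values("rank")


def _sample_covariates(sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-sample covariate table from the matched pair sheet."""
    rows = []
    for _, r in sheet.iterrows():
        shared = dict(sex=r.sex, age=r.age, packyears=r.packyears,
                      smoking_status=r.smoking_status)
        rows.append(dict(sample=r.case_sample, case_status="case",
                         histology=r.histology, **shared))
        rows.append(dict(sample=r.control_sample, case_status="control",
                         histology=np.nan, **shared))
    return pd.DataFrame(rows).set_index("sample")


def _r2_nominal(y: np.ndarray, labels: pd.Series) -> float:
    """R^2 of OLS on one-hot-encoded levels of a nominal covariate."""
    ok = np.isfinite(y) & labels.notna().to_numpy()
    y = y[ok]
    labels = labels[ok]
    if len(y) < 3 or labels.nunique() < 2:
        return np.nan
    x = pd.get_dummies(labels, drop_first=True).to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(y)), x])
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return np.nan
    return 1.0 - float((resid ** 2).sum()) / ss_tot


def covariate_association(region_means: pd.DataFrame,
                          sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-region association with clinical covariates.

    Pearson r (with two-sided p) against age and packyears; R^2 from OLS on
    one-hot dummies for sex, smoking status, histology and case status.
    Constant or insufficient covariates yield NaN markers.
    """
    cov = _sample_covariates(sheet)
    samples = [s for s in cov.index if s in region_means.columns]
    if len(samples) < 3:
        raise ValueError("need >=3 samples with covariates")
    cov = cov.loc[samples]
    rows = []
    for rid, vals in region_means[samples].iterrows():
        y = vals.to_numpy(dtype=float)
        rec = {"region_id": rid}
        for name in ("age", "packyears"):
            x = cov[name].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rec[f"r_{name}"] = np.nan
                rec[f"p_{name}"] = np.nan
            else:
                r, p = stats.pearsonr(x[ok], y[ok])
                rec[f"r_{name}"] = float(r)
                rec[f"p_{name}"] = float(p)
        for name in ("sex", "smoking_status", "histology", "case_status"):
            rec[f"r2_{name}"] = _r2_nominal(y, cov[name])
        rows.append(rec)
    return pd.DataFrame(rows).set_index("region_id")


@dataclass
class PowerSpec:
    n: int = 109                  # matched pairs (observations per group)
    delta: float = 0.05           # detectable mean paired difference
    sd: float = 0.10              # SD of the paired differences
    alpha: float = 0.05
    sides: int = 2

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")


def paired_power(spec: PowerSpec) -> float:
    """Power of the (two-sided) paired t-test via the noncentral t.

    With df = n - 1 and noncentrality ncp = delta / (sd / sqrt(n)), the
    power is P(T_ncp > t_{1-alpha/2, df}) + P(T_ncp < -t_{1-alpha/2, df}).
    """
    spec.validate()
    df = spec.n - 1
    ncp = spec.delta / (spec.sd / np.sqrt(spec.n))
    if spec.sides == 2:
        tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
        hi = stats.nct.sf(tcrit, df, ncp)
        lo = stats.nct.cdf(-tcrit, df, ncp)
        # the opposite tail underflows for large |ncp|; it is negligible there
        if not np.isfinite(lo):
            lo = 0.0
        return float(min(1.0, hi + lo))
    tcrit = stats.t.ppf(1.0 - spec.alpha, df)
    return float(stats.nct.sf(tcrit, df, ncp))


def wilcoxon_one_sided(x, y, *, alternative: str = "less") -> tuple[float, float]:
    """One-sided unpaired Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank-sum statistic of ``x``.  The p-value
    is exact for small tie-free samples and a tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (not has_ties and x.size + y.size <= 50) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    w = float(res.statistic + x.size * (x.size + 1) / 2.0)
    return w, float(res.pvalue)
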