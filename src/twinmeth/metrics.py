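"""Intra-pair differential methylation and cohort-level summaries.

DM = beta_severe - beta_mild per probe per twin pair; global similarity
statistics (grand mean/SD, t-based 95% CI, per-pair aggregates, correlations
of per-pair mean absolute DM with clinical discordance and age); and
cohort summary tables, including reconstruction of overall aggregates from
per-category summaries alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def compute_pair_dm(beta: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-probe, per-pair differential methylation (severe minus mild).

    Missing if either twin's beta is missing.  Columns are pair ids.
    """
    missing = [s for s in pd.concat([cohort.sample_mild, cohort.sample_severe])
               if s not in beta.columns]
    if missing:
        raise KeyError(f"sample(s) absent from beta matrix: {missing[:5]}")
    sev = beta[list(cohort.sample_severe)].to_numpy()
    mld = beta[list(cohort.sample_mild)].to_numpy()
    return pd.DataFrame(sev - mld, index=beta.index,
                        columns=list(cohort.pair_id))


@dataclass
class GlobalStats:
    global_mean_dm: float
    global_sd_dm: float
    ci95_low: float
    ci95_high: float
    per_pair: pd.DataFrame        # pair_id, mean_dm, mean_abs_dm
    corr_absdiff_delta: dict      # {"r", "r2", "p", "n"}
    corr_absdiff_age: dict


def _corr_report(x, y) -> dict:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return {"r": np.nan, "r2": np.nan, "p": np.nan, "n": int(ok.sum())}
    r, p = stats.pearsonr(x[ok], y[ok])
    return {"r": float(r), "r2": float(r * r), "p": float(p), "n": int(ok.sum())}


def global_similarity(dm: pd.DataFrame, cohort: pd.DataFrame,
                      *, ci_basis: str = "pairs") -> GlobalStats:
    """Cohort-level similarity statistics from the DM matrix.

    The grand mean and SD are over all non-missing probe x pair values. The
    95% CI of the mean is t-based; with ``ci_basis="pairs"`` (default) it is
    computed on per-pair mean DM values (n = pairs, avoiding
    pseudo-replication over probes), with ``"values"`` on every DM value.
    """
    vals = dm.to_numpy(dtype=float)
    if not np.isfinite(vals).any():
        raise ValueError("DM matrix has no non-missing values")
    grand_mean = float(np.nanmean(vals))
    grand_sd = float(np.nanstd(vals, ddof=1))

    per_pair = pd.DataFrame({
        "pair_id": dm.columns,
        "mean_dm": np.nanmean(vals, axis=0),
        "mean_abs_dm": np.nanmean(np.abs(vals), axis=0),
    })
    if ci_basis == "pairs":
        basis = per_pair["mean_dm"].to_numpy()
    elif ci_basis == "values":
        basis = vals[np.isfinite(vals)]
    else:
        raise ValueError(f"unknown ci_basis {ci_basis!r}")
    n = basis.size
    if n < 2:
        raise ValueError("need >=2 non-missing units for a confidence interval")
    m = float(np.mean(basis))
    se = float(np.std(basis, ddof=1) / np.sqrt(n))
    tcrit = float(stats.t.ppf(0.975, n - 1))

    by_pair = cohort.set_index("pair_id").loc[per_pair.pair_id]
    corr_delta = _corr_report(per_pair.mean_abs_dm, by_pair["delta"])
    corr_age = _corr_report(per_pair.mean_abs_dm, by_pair["age"])
    return GlobalStats(
        global_mean_dm=grand_mean, global_sd_dm=grand_sd,
        ci95_low=m - tcrit * se, ci95_high=m + tcrit * se,
        per_pair=per_pair,
        corr_absdiff_delta=corr_delta, corr_absdiff_age=corr_age)


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-category and overall n, age mean +- SD and female/male ratio."""
    if cohort.empty:
        raise ValueError("empty cohort")
    rows = []
    groups = list(cohort.groupby("category", sort=False)) + [("all", cohort)]
    for cat, g in groups:
        n_f = int((g.sex == "female").sum()) * 2  # both twins share sex
        n_m = int((g.sex == "male").sum()) * 2
        rows.append({
            "category": cat,
            "n_individuals": 2 * len(g),
            "mean_age": float(g.age.mean()),
            "sd_age": float(g.age.std(ddof=1)) if len(g) > 1 else np.nan,
            "n_female": n_f, "n_male": n_m,
            "female_male_ratio": n_f / n_m if n_m else np.inf,
        })
    return pd.DataFrame(rows).set_index("category")


def combine_category_summaries(table: pd.DataFrame) -> dict:
    """Overall aggregates from per-category summaries alone.

    ``table`` needs columns ``n_individuals``, ``mean_age`` and
    ``female_male_ratio`` (one row per category).  The overall mean age is the
    size-weighted mean; female/male counts are recovered per category by
    rounding ``n * ratio / (1 + ratio)`` to the nearest integer.
    """
    n = table["n_individuals"].to_numpy(dtype=float)
    mean_age = float(np.average(table["mean_age"].to_numpy(dtype=float),
                                weights=n))
    ratio = table["female_male_ratio"].to_numpy(dtype=float)
    n_female = np.round(n * ratio / (1.0 + ratio)).astype(int)
    n_male = (n - n_female).astype(int)
    return {
        "n_individuals": int(n.sum()),
        "mean_age": mean_age,
        "n_female": int(n_female.sum()),
        "n_male": int(n_male.sum()),
        "female_male_ratio": float(n_female.sum() / n_male.sum()),
        "per_category_female": dict(zip(table.index, n_female)),
        "per_category_male": dict(zip(table.index, n_male)),
    }
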