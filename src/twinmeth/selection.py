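"""Discordance-dependent, direction-consistent iDMP selection.

A probe survives the funnel when

1. it passes probe QC,
2. it is *discordance dependent*: strongly differentially methylated
   (|DM| >= 0.10 by default) in at least ``strong_min_pairs`` discordant or
   unknown-discordance pairs while every concordant pair stays within the
   no-difference cap (|DM| <= 0.05), and
3. it is *one-directional*: the correlation of beta with individual severity
   (DfO), the correlation of DM with intra-pair discordance (Delta) and the
   mean DM agree on hyper- or hypo-methylation in the severe twins.

With DfO oriented so that larger values mean milder disease, hypomethylation
in severe twins shows as corr(beta, DfO) > 0, corr(DM, Delta) < 0 and
mean DM < 0; hypermethylation as the three signs reversed.  Sign
inequalities are strict: exact zeros or undefined correlations carry no
directional evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import QCResult


@dataclass
class SelectionConfig:
    strong_threshold: float = 0.10    # |DM| cutoff in discordant/unknown pairs
    concordant_cap: float = 0.05      # |DM| cap in concordant pairs
    strong_min_pairs: int = 1
    require_all_concordant: bool = True
    dfo_higher_is_milder: bool = True

    def validate(self) -> None:
        if not 0.0 < self.concordant_cap <= self.strong_threshold <= 1.0:
            raise ValueError("need 0 < concordant_cap <= strong_threshold <= 1")
        if self.strong_min_pairs < 1:
            raise ValueError("strong_min_pairs must be >= 1")


@dataclass
class DirectionalityEvidence:
    corr_beta_dfo: float
    corr_dm_delta: float
    mean_dm: float
    direction: str                    # "hyper" | "hypo" | "none"


def pearson(x, y) -> float:
    """Product-moment correlation, computed from its defining sums.

    Missing entries are removed pairwise.  Returns NaN (the undefined
    marker) with fewer than 3 retained points or when either variable has
    zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return math.nan
    xv = x[ok] - x[ok].mean()
    yv = y[ok] - y[ok].mean()
    den = math.sqrt(float(xv @ xv) * float(yv @ yv))
    if den == 0.0:
        return math.nan
    return float(xv @ yv) / den


def pearson_rows(m: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r of a (probes x units) matrix against a unit vector.

    NaNs in either operand are removed pairwise per row; rows with fewer
    than 3 complete points or zero variance give NaN.
    """
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)[None, :]
    ok = np.isfinite(m) & np.isfinite(y)
    n = ok.sum(axis=1)
    mm = np.where(ok, m, 0.0)
    yy = np.where(ok, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = mm.sum(axis=1) / n
        my = yy.sum(axis=1) / n
        dx = np.where(ok, m - mx[:, None], 0.0)
        dy = np.where(ok, y - my[:, None], 0.0)
        num = (dx * dy).sum(axis=1)
        den = np.sqrt((dx * dx).sum(axis=1) * (dy * dy).sum(axis=1))
        r = num / den
    r[(n < 3) | (den == 0)] = np.nan
    return r


def flag_discordance_dependent(dm: pd.DataFrame, cohort: pd.DataFrame,
                               cfg: SelectionConfig | None = None) -> pd.Series:
    """Per-probe boolean for the discordance-dependent criteria.

    True iff at least ``strong_min_pairs`` discordant-or-unknown pairs reach
    ``strong_threshold`` in absolute DM and (with ``require_all_concordant``)
    every concordant pair with non-missing DM stays within ``concordant_cap``.
    Intermediate pairs are unconstrained.
    """
    cfg = cfg or SelectionConfig()
    cfg.validate()
    cat = cohort.set_index("pair_id")["category"]
    strong_pairs = [p for p in dm.columns if cat[p] in ("discordant", "unknown")]
    conc_pairs = [p for p in dm.columns if cat[p] == "concordant"]
    if not strong_pairs or not conc_pairs:
        raise ValueError("need >=1 concordant and >=1 discordant-or-unknown pair")

    absdm = dm.abs()
    n_strong = (absdm[strong_pairs] >= cfg.strong_threshold).sum(axis=1)
    ok = n_strong >= cfg.strong_min_pairs
    if cfg.require_all_concordant:
        conc = absdm[conc_pairs]
        ok &= ((conc <= cfg.concordant_cap) | conc.isna()).all(axis=1)
    return ok


def _directions_from_signs(r_dfo, r_delta, mean_dm,
                           dfo_higher_is_milder: bool = True) -> np.ndarray:
    if not dfo_higher_is_milder:
        r_dfo = -np.asarray(r_dfo, dtype=float)
    hypo = (r_dfo > 0) & (r_delta < 0) & (mean_dm < 0)
    hyper = (r_dfo < 0) & (r_delta > 0) & (mean_dm > 0)
    out = np.full(np.shape(hypo), "none", dtype=object)
    out[np.asarray(hypo, dtype=bool)] = "hypo"
    out[np.asarray(hyper, dtype=bool)] = "hyper"
    return out


def directionality_evidence(beta: pd.DataFrame, dm: pd.DataFrame,
                            cohort: pd.DataFrame,
                            cfg: SelectionConfig | None = None) -> pd.DataFrame:
    """Vectorized directionality evidence for every probe.

    Returns columns corr_beta_dfo, corr_dm_delta, mean_dm, direction.
    Individuals without a DfO score and pairs without a Delta score (the
    unknown-discordance category) are excluded from the respective
    correlation; mean DM is over all pairs with non-missing DM.
    """
    cfg = cfg or SelectionConfig()
    samples, dfo = [], []
    for _, row in cohort.iterrows():
        for s, v in ((row.sample_mild, row.dfo_mild),
                     (row.sample_severe, row.dfo_severe)):
            if np.isfinite(v):
                samples.append(s)
                dfo.append(float(v))
    known = cohort[np.isfinite(cohort["delta"])]
    r_dfo = pearson_rows(beta[samples].to_numpy(), np.array(dfo))
    r_delta = pearson_rows(dm[list(known.pair_id)].to_numpy(),
                           known["delta"].to_numpy(dtype=float))
    mean_dm = np.nanmean(dm.to_numpy(dtype=float), axis=1)
    direction = _directions_from_signs(r_dfo, r_delta, mean_dm,
                                       cfg.dfo_higher_is_milder)
    return pd.DataFrame({
        "corr_beta_dfo": r_dfo, "corr_dm_delta": r_delta,
        "mean_dm": mean_dm, "direction": direction}, index=dm.index)


def assess_directionality(beta: pd.DataFrame, dm: pd.DataFrame,
                          cohort: pd.DataFrame, probe,
                          cfg: SelectionConfig | None = None
                          ) -> DirectionalityEvidence:
    """Directionality evidence for a single probe."""
    row = directionality_evidence(beta.loc[[probe]], dm.loc[[probe]],
                                  cohort, cfg).iloc[0]
    return DirectionalityEvidence(
        corr_beta_dfo=float(row.corr_beta_dfo),
        corr_dm_delta=float(row.corr_dm_delta),
        mean_dm=float(row.mean_dm), direction=str(row.direction))


@dataclass
class SelectionResult:
    probes: pd.DataFrame          # flags + evidence per probe
    funnel: dict                  # stage counts and fractions

    @property
    def selected(self) -> pd.Index:
        return self.probes.index[self.probes["one_directional"]]


def select_idmps(beta: pd.DataFrame, dm: pd.DataFrame, cohort: pd.DataFrame,
                 qc: QCResult, cfg: SelectionConfig | None = None
                 ) -> SelectionResult:
    """Compose QC, discordance dependence and directionality into the funnel."""
    cfg = cfg or SelectionConfig()
    cfg.validate()
    qc_pass = dm.index.isin(qc.retained)
    kept = dm.index[qc_pass]
    dd = pd.Series(False, index=dm.index)
    dd.loc[kept] = flag_discordance_dependent(dm.loc[kept], cohort, cfg)

    cand = dm.index[dd]
    evidence = pd.DataFrame(
        {"corr_beta_dfo": np.nan, "corr_dm_delta": np.nan,
         "mean_dm": np.nan, "direction": "none"}, index=dm.index)
    if len(cand):
        ev = directionality_evidence(beta.loc[cand], dm.loc[cand], cohort, cfg)
        evidence.loc[cand] = ev
    one_dir = dd & (evidence["direction"] != "none")

    probes = pd.DataFrame({
        "qc_pass": qc_pass, "discordance_dependent": dd,
        "one_directional": one_dir}, index=dm.index).join(evidence)
    n_univ, n_qc = len(dm.index), int(qc_pass.sum())
    n_dd, n_od = int(dd.sum()), int(one_dir.sum())
    funnel = {
        "n_universe": n_univ,
        "n_qc_retained": n_qc,
        "frac_qc_retained": n_qc / n_univ if n_univ else np.nan,
        "n_discordance_dependent": n_dd,
        "frac_dd_of_retained": n_dd / n_qc if n_qc else np.nan,
        "n_one_directional": n_od,
        "frac_onedir_of_dd": n_od / n_dd if n_dd else np.nan,
    }
    return SelectionResult(probes=probes, funnel=funnel)
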