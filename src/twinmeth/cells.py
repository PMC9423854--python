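"""Blood cell-type composition: F-test specificity, markers, deconvolution.

Reference-based constrained-projection deconvolution in the Houseman style:
non-negative least squares of a sample's beta profile on the per-cell-type
mean methylomes over a marker probe set, followed by sum-to-one
normalization.  Cell-type-specific positions are flagged by a one-way ANOVA
F-test across cell types with Bonferroni adjustment; iDMPs significant
there are attributed to composition, the remainder are deemed acquired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic import CELL_TYPES, ReferencePanel


def celltype_f_test(panel: ReferencePanel, *, alpha: float = 0.05,
                    method: str = "bonferroni") -> pd.DataFrame:
    """One-way ANOVA F across cell types, per probe.

    Returns columns F, p, p_adj, specific.  Adjustment is Bonferroni
    (``min(1, m*p)``) by default, Benjamini-Hochberg with
    ``method="bh"``.  Probes with no variation at all get p = 1 (no
    evidence); zero within-group variance with real between-group spread
    gives p -> 0.
    """
    groups = [panel.values.loc[:, panel.cell_types == t].to_numpy()
              for t in CELL_TYPES if (panel.cell_types == t).any()]
    if len(groups) < 2 or any(g.shape[1] < 2 for g in groups):
        raise ValueError("need >=2 cell types with >=2 replicates each")
    k = len(groups)
    n = sum(g.shape[1] for g in groups)
    grand = np.hstack(groups).mean(axis=1)
    ss_between = sum(g.shape[1] * (g.mean(axis=1) - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
                    for g in groups)
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
        p = stats.f.sf(f, df_b, df_w)
    # degenerate probes (tolerance absorbs float residue of centering on
    # beta-scale data): no spread anywhere -> no evidence; spread between
    # but none within -> p -> 0
    tol = 1e-20
    allzero = (ss_between < tol) & (ss_within < tol)
    f = np.where(allzero, 0.0, f)
    p = np.where(allzero, 1.0, p)
    p = np.where(np.isinf(f) | ((ss_within < tol) & ~allzero), 0.0, p)
    m = len(p)
    if method == "bonferroni":
        p_adj = np.minimum(1.0, p * m)
    elif method == "bh":
        from statsmodels.stats.multitest import multipletests
        p_adj = multipletests(p, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown adjustment {method!r}")
    return pd.DataFrame({"F": f, "p": p, "p_adj": p_adj,
                         "specific": p_adj < alpha}, index=panel.values.index)


def select_markers(panel: ReferencePanel, m_per_type: int = 50) -> pd.Index:
    """Top discriminating probes per cell type, union over types.

    For each type, the ``m_per_type`` probes maximizing
    |type mean - mean of the other type means|, ties broken by probe id.
    """
    if m_per_type < 1:
        raise ValueError("m_per_type must be >= 1")
    means = panel.type_means()
    if m_per_type > len(means):
        warnings.warn("m_per_type exceeds available probes; capping",
                      stacklevel=2)
        m_per_type = len(means)
    markers: set = set()
    for t in means.columns:
        others = means.drop(columns=t).mean(axis=1)
        contrast = (means[t] - others).abs()
        order = pd.DataFrame({"c": -contrast, "id": means.index}).sort_values(
            ["c", "id"])
        markers.update(order["id"].iloc[:m_per_type])
    return means.index[means.index.isin(markers)]


@dataclass
class CellComposition:
    proportions: pd.Series        # index = cell types, sums to 1
    residual: float               # NNLS residual norm over markers


def deconvolve(beta_sample: pd.Series, panel: ReferencePanel,
               markers) -> CellComposition:
    """Estimate cell-type proportions of one sample by constrained projection.

    Solves ``min_w ||beta - M w||`` over the marker probes subject to
    ``w >= 0``, then normalizes to a partition of unity.
    """
    markers = pd.Index(markers)
    if not len(markers):
        raise ValueError("empty marker set")
    means = panel.type_means().loc[markers]
    y = beta_sample.loc[markers].to_numpy(dtype=float)
    ok = np.isfinite(y)
    if not ok.any():
        raise ValueError("sample is missing at every marker probe")
    w, res = optimize.nnls(means.to_numpy()[ok], y[ok])
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate solution: all proportions zero")
    return CellComposition(
        proportions=pd.Series(w / total, index=means.columns),
        residual=float(res))


def deconvolve_all(beta: pd.DataFrame, panel: ReferencePanel,
                   markers) -> pd.DataFrame:
    """Composition for every sample (samples x cell types)."""
    rows = {s: deconvolve(beta[s], panel, markers).proportions
            for s in beta.columns}
    return pd.DataFrame(rows).T


@dataclass
class AcquiredPartition:
    acquired: set
    celltype_attributable: set
    fraction_celltype: float      # |attributable| / |idmps|; 0 when empty


def filter_acquired(idmps, spec: pd.DataFrame) -> AcquiredPartition:
    """Split iDMPs into acquired vs cell-type-attributable.

    ``spec`` is the :func:`celltype_f_test` output.  Probes absent from the
    panel are treated as not-specific (with a warning).
    """
    idmps = set(idmps)
    absent = idmps - set(spec.index)
    if absent:
        warnings.warn(
            f"{len(absent)} iDMP(s) absent from the specificity table; "
            "treated as not cell-type-specific", stacklevel=2)
    specific = set(spec.index[spec["specific"]])
    attributable = idmps & specific
    acquired = idmps - specific
    frac = len(attributable) / len(idmps) if idmps else 0.0
    return AcquiredPartition(acquired=acquired,
                             celltype_attributable=attributable,
                             fraction_celltype=frac)
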