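"""Candidate prioritization for targeted validation.

Two routes into the candidate set:

* set A, *strong or frequent* in the twin cohort: |DM| >= 10% in more than
  one pair, or |DM| >= 5% in more than four pairs (strict counts; a pair
  clearing 10% also counts toward the 5% tally), and
* set B, *tumor concordant*: tumor-minus-normal mean methylation difference
  of at least 5% in both cancer cohorts, with the sign matching the probe's
  twin-cohort direction in both.

The candidate report is the union with inclusion-exclusion bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import TumorNormalSummary


def flag_strong_frequent(dm_values, *, strong: float = 0.10,
                         frequent: float = 0.05, strong_count: int = 1,
                         frequent_count: int = 4) -> bool:
    """True iff count(|DM| >= strong) > strong_count or
    count(|DM| >= frequent) > frequent_count over non-missing pairs."""
    v = np.abs(np.asarray(dm_values, dtype=float))
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("DM undefined for every pair")
    return bool((v >= strong).sum() > strong_count
                or (v >= frequent).sum() > frequent_count)


def strong_frequent_set(dm: pd.DataFrame, probes=None, **kw) -> set:
    idx = dm.index if probes is None else pd.Index(probes)
    return {p for p in idx if flag_strong_frequent(dm.loc[p], **kw)}


def tumor_concordance(direction: str, tn: TumorNormalSummary, probe,
                      threshold: float = 0.05) -> tuple[bool, str]:
    """Same-direction tumor/normal difference >= threshold in both cohorts.

    Returns (flag, reason).  A probe missing either cohort is inevaluable
    (False, "missing_cohort").
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError("direction must be 'hyper' or 'hypo'")
    sub = tn.table[tn.table["probe_id"] == probe]
    if sub["cohort"].nunique() < 2:
        return False, "missing_cohort"
    d = (sub["mean_tumor"] - sub["mean_normal"]).to_numpy(dtype=float)
    want = 1.0 if direction == "hyper" else -1.0
    # the >= boundary is inclusive; guard it against float representation
    if np.all(np.abs(d) >= threshold - 1e-12) and np.all(np.sign(d) == want):
        return True, "concordant"
    return False, "not_concordant"


def tumor_concordant_set(directions: pd.Series, tn: TumorNormalSummary,
                         threshold: float = 0.05) -> set:
    """Vectorized set B over all probes with a defined direction."""
    piv_t = tn.table.pivot(index="probe_id", columns="cohort",
                           values="mean_tumor")
    piv_n = tn.table.pivot(index="probe_id", columns="cohort",
                           values="mean_normal")
    d = (piv_t - piv_n)
    out = set()
    for p, direction in directions.items():
        if direction not in ("hyper", "hypo") or p not in d.index:
            continue
        row = d.loc[p].to_numpy(dtype=float)
        if np.isnan(row).any() or len(row) < 2:
            continue
        want = 1.0 if direction == "hyper" else -1.0
        if np.all(np.abs(row) >= threshold - 1e-12) \
                and np.all(np.sign(row) == want):
            out.add(p)
    return out


@dataclass
class CandidateReport:
    strong_frequent: set          # set A
    tumor_concordant: set         # set B
    union: set
    reasons: dict                 # probe -> "A" | "B" | "A+B"

    @property
    def n_overlap(self) -> int:
        return len(self.strong_frequent & self.tumor_concordant)


def candidate_union(a, b) -> CandidateReport:
    """Union of the two candidate routes with per-probe reasons."""
    a, b = set(a), set(b)
    reasons = {}
    for p in a | b:
        reasons[p] = "A+B" if p in a and p in b else ("A" if p in a else "B")
    report = CandidateReport(strong_frequent=a, tumor_concordant=b,
                             union=a | b, reasons=reasons)
    assert len(report.union) == len(a) + len(b) - report.n_overlap
    return report
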