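"""Probe-level quality control.

Reduces the probe universe to the analyzable set: probes with missing beta
values, probes overlapping repetitive sequence (``n_bp_repetitive >= 1``),
cross-reactive probes, and probes on a user-supplied unreliable-probe list
are removed, each with a single recorded reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: fixed precedence when a probe matches several removal rules
REASON_ORDER = ("missing_value", "repetitive", "cross_reactive", "unreliable_list")


@dataclass
class QCResult:
    retained: pd.Index            # probe ids kept, in input order
    removed: dict                 # probe_id -> reason (first matching rule)
    fraction_retained: float

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def apply_probe_qc(beta: pd.DataFrame, ann: pd.DataFrame,
                   exclusion_list=(), *, missing_tol: float = 0.0) -> QCResult:
    """Apply the four removal rules and record one reason per removed probe.

    Parameters
    ----------
    beta : probes x samples beta matrix (NaN = missing).
    ann : probe annotation with ``n_bp_repetitive`` and ``cross_reactive``.
    exclusion_list : probe ids deemed unreliable (user-supplied).
    missing_tol : tolerated fraction of missing samples per probe. The
        default 0.0 removes a probe with a missing value in *any* sample.
    """
    unknown = beta.index.difference(ann.index)
    if len(unknown):
        raise KeyError(
            f"probe(s) absent from annotation: {', '.join(map(str, unknown[:5]))}")
    ann = ann.loc[beta.index]
    excl = set(exclusion_list)

    miss_frac = beta.isna().mean(axis=1)
    rules = {
        "missing_value": miss_frac > missing_tol,
        "repetitive": ann["n_bp_repetitive"].to_numpy() >= 1,
        "cross_reactive": ann["cross_reactive"].astype(bool).to_numpy(),
        "unreliable_list": beta.index.isin(excl),
    }
    reason = pd.Series(pd.NA, index=beta.index, dtype="object")
    for name in REASON_ORDER:
        hit = pd.Series(rules[name], index=beta.index).astype(bool)
        reason = reason.where(reason.notna() | ~hit, name)

    removed = reason.dropna().to_dict()
    retained = beta.index[reason.isna()]
    return QCResult(retained=retained, removed=removed,
                    fraction_retained=len(retained) / len(beta.index))


def removal_report(result: QCResult) -> pd.DataFrame:
    """Removal report as a two-column table (probe_id, reason)."""
    return pd.DataFrame(
        {"probe_id": list(result.removed), "reason": list(result.removed.values())}
    )
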