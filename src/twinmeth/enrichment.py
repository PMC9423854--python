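"""Annotation-category and gene-set enrichment of probe sets.

One-sided Fisher's exact test of a foreground probe set against a
background universe, per genomic/functional category (gene association,
promoter/body/UTRs, CGI relation, enhancer, DHS, promoter-associated,
cell-type-specific promoter, subtelomeric, imprinted), and the same
machinery for user-supplied gene -> term mappings with BH FDR.

Coordinate conventions: positions are 1-based; the subtelomeric window is
the terminal 500,000 bases of a chromosome arm (inclusive); the imprinted
window is the closed interval [TSS - 1500, TSS + 1500].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SUBTELOMERIC_BP = 500_000
IMPRINTED_WINDOW_BP = 1_500

CATEGORY_COLUMNS = (
    "gene_associated", "promoter", "body", "utr5", "utr3", "tss",
    "cgi_island", "cgi_shore", "cgi_shelf", "enhancer", "dhs",
    "promoter_assoc", "celltype_promoter", "subtelomeric", "imprinted",
)


def categorize_probes(ann: pd.DataFrame,
                      imprinted_tss: pd.DataFrame | None = None) -> pd.DataFrame:
    """Boolean membership matrix (probes x categories).

    ``imprinted_tss`` (optional) is a table with columns chrom, tss; when
    given, a probe is imprinted iff it lies within +-1500 bp of any listed
    TSS (closed window), otherwise the annotation's ``imprinted`` flag is
    used.  Subtelomeric requires declared arm bounds.
    """
    if ann[["arm_start", "arm_end"]].isna().any().any():
        raise ValueError("missing chromosome-arm bounds; "
                         "subtelomeric categorization undefined")
    pos = ann["pos"].to_numpy(dtype=np.int64)
    arm_start = ann["arm_start"].to_numpy(dtype=np.int64)
    arm_end = ann["arm_end"].to_numpy(dtype=np.int64)
    subtel = ((pos - arm_start + 1 <= SUBTELOMERIC_BP)
              | (arm_end - pos + 1 <= SUBTELOMERIC_BP))

    if imprinted_tss is not None:
        imprint = np.zeros(len(ann), dtype=bool)
        for chrom, g in imprinted_tss.groupby("chrom"):
            on = ann["chrom"].to_numpy() == chrom
            if not on.any():
                continue
            tss = g["tss"].to_numpy(dtype=np.int64)
            d = np.abs(pos[on, None] - tss[None, :]).min(axis=1)
            imprint[on] = d <= IMPRINTED_WINDOW_BP
    else:
        imprint = ann["imprinted"].astype(bool).to_numpy()

    region = ann["gene_region"].astype(str)
    out = pd.DataFrame({
        "gene_associated": ann["gene"].notna().to_numpy(),
        "promoter": (region == "promoter").to_numpy(),
        "body": (region == "body").to_numpy(),
        "utr5": (region == "5utr").to_numpy(),
        "utr3": (region == "3utr").to_numpy(),
        "tss": (region == "tss").to_numpy(),
        "cgi_island": (ann["cgi_relation"] == "island").to_numpy(),
        "cgi_shore": (ann["cgi_relation"] == "shore").to_numpy(),
        "cgi_shelf": (ann["cgi_relation"] == "shelf").to_numpy(),
        "enhancer": ann["enhancer"].astype(bool).to_numpy(),
        "dhs": ann["dhs"].astype(bool).to_numpy(),
        "promoter_assoc": ann["promoter_assoc"].astype(bool).to_numpy(),
        "celltype_promoter": ann["celltype_promoter"].astype(bool).to_numpy(),
        "subtelomeric": subtel,
        "imprinted": imprint,
    }, index=ann.index)
    return out


def categorize_probe(ann_row: pd.Series,
                     imprinted_tss: pd.DataFrame | None = None) -> set:
    """Category membership set for a single annotation row."""
    m = categorize_probes(ann_row.to_frame().T, imprinted_tss).iloc[0]
    return set(m.index[m.astype(bool)])


def _fisher_rows(tables: list[tuple[str, int, int, int, int]]) -> pd.DataFrame:
    rows = []
    for name, a, b, c, d in tables:
        if a + b == 0:          # empty foreground: no evidence of enrichment
            odds, p = np.nan, 1.0
        else:
            odds, p = stats.fisher_exact([[a, b], [c, d]],
                                         alternative="greater")
        rows.append({"category": name, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds, "p_one_sided": p})
    out = pd.DataFrame(rows).set_index("category")
    out["p_adj"] = multipletests(out["p_one_sided"], method="fdr_bh")[1]
    return out


def fisher_enrichment(foreground, background,
                      memberships: pd.DataFrame) -> pd.DataFrame:
    """One-sided Fisher enrichment of foreground vs background per category.

    The 2x2 table per category is (fg in, fg out, (bg \\ fg) in,
    (bg \\ fg) out).  BH adjustment across categories.
    """
    fg = set(foreground)
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    rest = bg - fg
    mem = memberships.loc[memberships.index.isin(bg)]
    tables = []
    for cat in mem.columns:
        in_cat = set(mem.index[mem[cat].astype(bool)])
        a = len(fg & in_cat)
        b = len(fg) - a
        c = len(rest & in_cat)
        d = len(rest) - c
        tables.append((cat, a, b, c, d))
    return _fisher_rows(tables)


def term_enrichment(genes, gene_to_terms: dict,
                    background_genes) -> pd.DataFrame:
    """Fisher one-sided enrichment of a gene set in each term, with BH FDR.

    ``gene_to_terms`` maps gene symbol -> iterable of terms (user-supplied;
    no ontology download or graph propagation).
    """
    genes = set(genes)
    bg = set(background_genes)
    stray = genes - bg
    if stray:
        raise ValueError(
            f"gene(s) not in background: {', '.join(sorted(stray)[:5])}")
    term_members: dict = {}
    for g, terms in gene_to_terms.items():
        if g not in bg:
            continue
        for t in terms:
            term_members.setdefault(t, set()).add(g)
    rest = bg - genes
    tables = []
    for t in sorted(term_members):
        members = term_members[t]
        a = len(genes & members)
        b = len(genes) - a
        c = len(rest & members)
        d = len(rest) - c
        tables.append((t, a, b, c, d))
    if not tables:
        return pd.DataFrame(columns=["a", "b", "c", "d", "odds_ratio",
                                     "p_one_sided", "p_adj"])
    return _fisher_rows(tables)
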