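"""Synthetic twin-methylome cohort generator.

Emulates the statistical structure of a blood 450K-style methylation study of
monozygotic twin pairs discordant for a chronic inflammatory disease:

* a bimodal beta-value baseline (most CpGs either very slightly or very
  highly methylated),
* twins of a pair sharing a per-probe baseline plus small independent noise,
* a subset of "acquired" probes whose severe-twin shift scales with the
  pair's clinical discordance (Delta) and whose baseline covaries with
  individual severity (DfO) in the same direction,
* a subset of probes driven purely by blood cell-type composition, rendered
  as mixtures of a 6-cell-type reference panel with a granulocyte-up /
  NK-down shift in severe twins of discordant pairs,
* tumor/normal mean-methylation summaries for two cancer cohorts with a
  planted same-direction concordant subset, and
* targeted bisulfite amplicon read counts for a matched case-control cohort
  with one designated highly variable (bidirectional) region.

Every generator is fully determined by ``SimConfig.seed``.  Planted effects
are recorded in :class:`TruthLabels` so that downstream selection stages can
be scored for recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_TYPES = ("granulocyte", "monocyte", "cd4t", "cd8t", "bcell", "nk")

CATEGORIES = ("concordant", "intermediate", "discordant", "unknown")

#: whole-blood composition used for every individual (granulocyte-dominated)
BASE_COMPOSITION = {
    "granulocyte": 0.58, "monocyte": 0.07, "cd4t": 0.16,
    "cd8t": 0.09, "bcell": 0.06, "nk": 0.04,
}

#: composition of the *severe* twin in discordant pairs: granulocytes up,
#: natural killer cells down, the remainder rescaled (neutrophilia-like shift)
SEVERE_DISCORDANT_COMPOSITION = {
    "granulocyte": 0.68, "monocyte": 0.056, "cd4t": 0.128,
    "cd8t": 0.072, "bcell": 0.048, "nk": 0.016,
}

# clinical-score distributions per category: (mean, sd) as printed in the
# source cohort table, with Delta truncated to disjoint category bins
_DELTA_PARAMS = {
    "concordant": (80.5, 36.7, 5.0, 130.0),
    "intermediate": (164.0, 31.5, 130.0, 250.0),
    "discordant": (366.2, 36.5, 250.0, 480.0),
    # unknown pairs have missing Delta; a hidden discordance in the
    # discordant range drives their planted effects
    "unknown": (366.2, 36.5, 250.0, 480.0),
}
_DFO_PARAMS = {
    "concordant": (562.3, 235.8),
    "intermediate": (466.8, 133.6),
    "discordant": (466.9, 203.4),
    "unknown": (500.0, 200.0),
}
_AGE_PARAMS = {
    "concordant": (19.3, 9.6),
    "intermediate": (14.6, 7.3),
    "discordant": (17.0, 10.2),
    "unknown": (3.0, 1.2),
}
#: number of female pairs per category (both twins of a pair share sex);
#: chosen to reproduce the cohort table's female/male ratios (2.0, 0.2, 2.0, 3.0)
_FEMALE_PAIRS = {"concordant": 4, "intermediate": 1, "discordant": 4, "unknown": 3}


class ConfigurationError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass
class SimConfig:
    """Study conditions for all four generators.

    Parameters mirror the emulated study: 22 twin pairs in four discordance
    categories, beta noise calibrated so the intra-pair difference SD is
    ~2.7%, planted acquired effects up to 15% scaled by discordance.
    """

    n_pairs_per_category: dict = field(
        default_factory=lambda: {"concordant": 6, "intermediate": 6,
                                 "discordant": 6, "unknown": 4})
    n_probes: int = 20000
    frac_low: float = 0.42          # baseline mode < 0.10
    frac_high: float = 0.40         # baseline mode > 0.85
    noise_sd: float = 0.019         # per-individual beta noise (DM sd ~2.7%)
    n_acquired_truth: int = 50
    n_celltype_truth: int = 200
    effect_max: float = 0.15        # max planted |DM|
    effect_delta_floor: float = 120.0
    effect_delta_ref: float = 380.0
    dfo_coef: float = 2e-5          # baseline-vs-DfO coupling (beta per DfO unit)
    frac_missing_probes: float = 0.05
    frac_repetitive: float = 0.12
    frac_cross_reactive: float = 0.06
    frac_unreliable: float = 0.02
    composition_conc: float = 300.0  # Dirichlet concentration of per-individual mixing
    # reference panel
    n_replicates: int = 6
    panel_noise_sd: float = 0.02
    # tumor/normal summaries
    frac_tumor_concordant: float = 0.4
    tn_noise_sd: float = 0.005
    tn_effect_range: tuple = (0.08, 0.15)
    # case-control amplicon data
    n_regions: int = 20
    n_cc_pairs: int = 109
    coverage_mean: float = 1694.0
    coverage_log_sd: float = 0.55
    coverage_range: tuple = (124.0, 4841.0)
    cc_cpg_sd: float = 0.03         # per-CpG offset of region methylation
    cc_sample_sd: float = 0.015     # per-sample biological jitter
    variable_region_index: int | None = 13   # 1-based; bidirectional per-pair shifts
    variable_effect_range: tuple = (0.10, 0.25)
    shifted_region_index: int | None = None  # uniform case-vs-control shift
    shifted_effect: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if any(v < 0 for v in self.n_pairs_per_category.values()):
            raise ConfigurationError("pair counts must be non-negative")
        if sum(self.n_pairs_per_category.values()) <= 0:
            raise ConfigurationError("need at least one twin pair")
        if self.n_probes <= 0:
            raise ConfigurationError("n_probes must be positive")
        for name in ("frac_low", "frac_high", "frac_missing_probes",
                     "frac_repetitive", "frac_cross_reactive",
                     "frac_unreliable", "frac_tumor_concordant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.frac_low + self.frac_high > 1.0:
            raise ConfigurationError("frac_low + frac_high must be <= 1")
        if self.noise_sd < 0 or self.panel_noise_sd < 0:
            raise ConfigurationError("noise sds must be non-negative")
        if not 0.0 <= self.effect_max <= 1.0:
            raise ConfigurationError("effect_max must be in [0, 1]")
        if self.n_acquired_truth < 0 or self.n_celltype_truth < 0:
            raise ConfigurationError("truth counts must be non-negative")
        if self.n_replicates < 2:
            raise ConfigurationError(
                "need >=2 replicates per cell type (F-test undefined otherwise)")
        if self.coverage_mean <= 0:
            raise ConfigurationError("coverage_mean must be positive")
        if self.n_regions < 1 or self.n_cc_pairs < 1:
            raise ConfigurationError("need >=1 region and >=1 case-control pair")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TruthLabels:
    """Ground-truth bookkeeping for planted effects."""

    acquired_truth: set
    celltype_truth: set
    planted_direction: dict  # probe_id -> "hyper" | "hypo"

    def __post_init__(self):
        assert not self.acquired_truth & self.celltype_truth
        assert set(self.planted_direction) == set(self.acquired_truth)


@dataclass
class ReferencePanel:
    """Reference methylomes: probes x (cell type, replicate) beta values."""

    values: pd.DataFrame          # probes x replicate columns
    cell_types: pd.Series         # column -> cell type

    def type_means(self) -> pd.DataFrame:
        """Per-cell-type mean methylome (probes x 6 types)."""
        return self.values.T.groupby(self.cell_types).mean().T[list(CELL_TYPES)]


@dataclass
class TumorNormalSummary:
    """Per-probe tumor/normal mean methylation for two cancer cohorts.

    ``concordant_truth`` records the probes planted with a >=5% same-direction
    tumor-normal difference in both cohorts (ground truth for recovery tests).
    """

    table: pd.DataFrame   # probe_id, cohort, mean_tumor, mean_normal, n_tumor, n_normal
    concordant_truth: set


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed) % (2**31), stream])


def _baselines(cfg: SimConfig) -> np.ndarray:
    """Bimodal baseline betas: uniform low / high / mid three-way mixture."""
    rng = _rng(cfg, 0)
    u = rng.random(cfg.n_probes)
    out = np.empty(cfg.n_probes)
    low = u < cfg.frac_low
    high = (u >= cfg.frac_low) & (u < cfg.frac_low + cfg.frac_high)
    mid = ~(low | high)
    out[low] = rng.uniform(0.01, 0.09, low.sum())
    out[high] = rng.uniform(0.86, 0.99, high.sum())
    out[mid] = rng.uniform(0.10, 0.85, mid.sum())
    return out


def _probe_ids(cfg: SimConfig) -> pd.Index:
    width = len(str(cfg.n_probes))
    return pd.Index([f"cg{i:0{width}d}" for i in range(cfg.n_probes)],
                    name="probe_id")


def _annotation_flags(cfg: SimConfig):
    """QC-relevant flags; deterministic given the seed."""
    rng = _rng(cfg, 1)
    n = cfg.n_probes
    repetitive = rng.random(n) < cfg.frac_repetitive
    n_bp_rep = np.where(repetitive, rng.poisson(3.0, n) + 1, 0)
    cross = rng.random(n) < cfg.frac_cross_reactive
    unreliable = rng.random(n) < cfg.frac_unreliable
    missing = rng.random(n) < cfg.frac_missing_probes
    return n_bp_rep, cross, unreliable, missing


def _truth_assignment(cfg: SimConfig):
    """Choose planted probe indices among QC-clean probes and their directions."""
    n_bp_rep, cross, unreliable, missing = _annotation_flags(cfg)
    clean = np.flatnonzero((n_bp_rep == 0) & ~cross & ~unreliable & ~missing)
    need = cfg.n_acquired_truth + cfg.n_celltype_truth
    if need > clean.size:
        raise ConfigurationError(
            f"cannot plant {need} truth probes among {clean.size} QC-clean probes")
    rng = _rng(cfg, 3)
    chosen = rng.choice(clean, size=need, replace=False)
    acquired_idx = np.sort(chosen[:cfg.n_acquired_truth])
    celltype_idx = np.sort(chosen[cfg.n_acquired_truth:])
    directions = rng.choice(["hyper", "hypo"], size=cfg.n_acquired_truth)
    return acquired_idx, celltype_idx, directions


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    """Draw from N(mean, sd) by rejection within [lo, hi] (clip as fallback)."""
    x = rng.normal(mean, sd, size)
    bad = (x < lo) | (x > hi)
    for _ in range(50):
        if not np.any(bad):
            break
        x = np.where(bad, rng.normal(mean, sd, size), x)
        bad = (x < lo) | (x > hi)
    return np.clip(x, lo, hi)


def generate_clinical(cfg: SimConfig) -> pd.DataFrame:
    """Twin sample sheet: one row per pair, plus a hidden effect-discordance.

    Unknown-category pairs have missing Delta/DfO but a hidden discordance
    (column ``_delta_effect``, also present for the other categories) that
    scales their planted effects: they participate in the strong-DM criterion
    while contributing nothing to the clinical correlations.
    """
    rng = _rng(cfg, 2)
    rows = []
    k = 0
    for cat in CATEGORIES:
        n_pairs = cfg.n_pairs_per_category.get(cat, 0)
        n_female = min(_FEMALE_PAIRS.get(cat, 0), n_pairs)
        dmean, dsd, dlo, dhi = _DELTA_PARAMS[cat]
        fmean, fsd = _DFO_PARAMS[cat]
        amean, asd = _AGE_PARAMS[cat]
        for j in range(n_pairs):
            k += 1
            delta = float(_truncnorm(rng, dmean, dsd, dlo, dhi))
            center = float(_truncnorm(rng, fmean, fsd,
                                      max(100.0, delta / 2 + 20.0), 1000.0))
            age = float(np.round(_truncnorm(rng, amean, asd, 0.5, 60.0), 1))
            sex = "female" if j < n_female else "male"
            if cat == "unknown":
                rec = dict(delta=np.nan, dfo_mild=np.nan, dfo_severe=np.nan)
            else:
                rec = dict(delta=delta,
                           dfo_mild=center + delta / 2.0,
                           dfo_severe=center - delta / 2.0)
            rows.append(dict(
                pair_id=f"pair{k:02d}", sample_mild=f"P{k:02d}M",
                sample_severe=f"P{k:02d}S", category=cat, age=age, sex=sex,
                _delta_effect=delta, **rec))
    cohort = pd.DataFrame(rows)
    return cohort


def _effect_magnitude(cfg: SimConfig, delta_effect: np.ndarray) -> np.ndarray:
    scale = np.clip((delta_effect - cfg.effect_delta_floor)
                    / (cfg.effect_delta_ref - cfg.effect_delta_floor), 0.0, 1.0)
    return cfg.effect_max * scale


def panel_type_means(cfg: SimConfig) -> pd.DataFrame:
    """Deterministic per-cell-type mean methylomes shared by all generators.

    Non-cell-type probes have one common mean (the baseline); planted
    cell-type probes get one divergent cell type (high-vs-low or low-vs-high).
    """
    base = _baselines(cfg)
    _, celltype_idx, _ = _truth_assignment(cfg)
    rng = _rng(cfg, 5)
    means = np.tile(base[:, None], (1, len(CELL_TYPES)))
    m = celltype_idx.size
    if m:
        which = rng.integers(0, len(CELL_TYPES), m)
        hi_out = rng.random(m) < 0.5
        hi = rng.uniform(0.65, 0.95, m)
        lo = rng.uniform(0.05, 0.30, m)
        for row, t, flip, h, l in zip(celltype_idx, which, hi_out, hi, lo):
            means[row, :] = h if flip else l
            means[row, t] = l if flip else h
    return pd.DataFrame(means, index=_probe_ids(cfg), columns=list(CELL_TYPES))


def generate_twin_cohort(cfg: SimConfig):
    """Generate (BetaMatrix, TwinCohort, ProbeAnnotationTable, TruthLabels).

    The beta matrix is probes x samples with NaN for missing values; the
    cohort is one row per pair; annotation carries QC fields, genomic
    coordinates with declared chromosome-arm bounds, and category flags.
    """
    cfg.validate()
    probes = _probe_ids(cfg)
    base = _baselines(cfg)
    n_bp_rep, cross, unreliable, missing_flag = _annotation_flags(cfg)
    acquired_idx, celltype_idx, directions = _truth_assignment(cfg)
    cohort = generate_clinical(cfg)

    samples = []
    for _, row in cohort.iterrows():
        samples.append(row.sample_mild)
        samples.append(row.sample_severe)
    n_pairs = len(cohort)
    n_samples = 2 * n_pairs

    rng = _rng(cfg, 4)
    beta = np.tile(base[:, None], (1, n_samples))

    # --- planted acquired effects -------------------------------------
    sign = np.where(directions == "hyper", 1.0, -1.0)
    if acquired_idx.size:
        # direction-aware baseline redraw so planted shifts cannot clip
        lo = np.where(sign > 0, 0.10, cfg.effect_max + 0.05)
        hi = np.where(sign > 0, 0.95 - cfg.effect_max - 0.05, 0.90)
        beta[acquired_idx, :] = rng.uniform(lo, hi)[:, None]
    eff = _effect_magnitude(cfg, cohort["_delta_effect"].to_numpy())
    dfo_center = (cohort["dfo_mild"] + cohort["dfo_severe"]) / 2.0
    dfo_mid = float(np.nanmean(dfo_center)) if np.isfinite(dfo_center).any() else 0.0
    for j, row in cohort.iterrows():
        sev = 2 * j + 1
        mld = 2 * j
        if acquired_idx.size:
            beta[acquired_idx, sev] += sign * eff[j]
            # baseline covaries with individual severity (DfO): milder
            # individuals (higher DfO) sit lower for hyper probes
            for col, dfo in ((mld, row.dfo_mild), (sev, row.dfo_severe)):
                if np.isfinite(dfo):
                    beta[acquired_idx, col] += sign * cfg.dfo_coef * (dfo_mid - dfo)

    # --- cell-composition-driven probes -------------------------------
    mu = panel_type_means(cfg).to_numpy()[celltype_idx, :]  # m x 6
    w_base = np.array([BASE_COMPOSITION[t] for t in CELL_TYPES])
    w_sev_disc = np.array([SEVERE_DISCORDANT_COMPOSITION[t] for t in CELL_TYPES])
    for j, row in cohort.iterrows():
        for col, is_severe in ((2 * j, False), (2 * j + 1, True)):
            target = (w_sev_disc if is_severe and row.category == "discordant"
                      else w_base)
            w = rng.dirichlet(target * cfg.composition_conc)
            if celltype_idx.size:
                beta[celltype_idx, col] = mu @ w

    # --- noise, clipping, missingness ----------------------------------
    if cfg.noise_sd > 0:
        beta += rng.normal(0.0, cfg.noise_sd, beta.shape)
    np.clip(beta, 0.0, 1.0, out=beta)
    for row in np.flatnonzero(missing_flag):
        cols = rng.choice(n_samples, size=rng.integers(1, 4), replace=False)
        beta[row, cols] = np.nan

    beta_df = pd.DataFrame(beta, index=probes, columns=samples)
    ann = _annotation_table(cfg, n_bp_rep, cross, unreliable)
    truth = TruthLabels(
        acquired_truth=set(probes[acquired_idx]),
        celltype_truth=set(probes[celltype_idx]),
        planted_direction={probes[i]: d
                           for i, d in zip(acquired_idx, directions)},
    )
    return beta_df, cohort.drop(columns=["_delta_effect"]), ann, truth


#: synthetic genome: 6 chromosomes, 60 Mb each, centromere at 30 Mb
_CHROM_LEN = 60_000_000
_CENTROMERE = 30_000_000
_N_CHROMS = 6


def _annotation_table(cfg, n_bp_rep, cross, unreliable) -> pd.DataFrame:
    rng = _rng(cfg, 9)
    n = cfg.n_probes
    chrom_i = rng.integers(0, _N_CHROMS, n)
    pos = rng.integers(1, _CHROM_LEN + 1, n)
    on_p = pos <= _CENTROMERE
    arm_start = np.where(on_p, 1, _CENTROMERE + 1)
    arm_end = np.where(on_p, _CENTROMERE, _CHROM_LEN)
    gene_pool = np.array([f"GENE{i:04d}" for i in range(2000)])
    has_gene = rng.random(n) < 0.6
    gene = np.where(has_gene, gene_pool[rng.integers(0, gene_pool.size, n)], None)
    region = np.where(
        has_gene,
        rng.choice(["promoter", "body", "5utr", "3utr", "tss"], n,
                   p=[0.30, 0.40, 0.10, 0.10, 0.10]),
        "intergenic")
    cgi = rng.choice(["island", "shore", "shelf", "open_sea"], n,
                     p=[0.30, 0.23, 0.10, 0.37])
    ann = pd.DataFrame({
        "chrom": [f"chr{c + 1}" for c in chrom_i],
        "pos": pos,
        "n_bp_repetitive": n_bp_rep,
        "cross_reactive": cross,
        "unreliable": unreliable,
        "gene": gene,
        "gene_region": region,
        "cgi_relation": cgi,
        "enhancer": rng.random(n) < 0.10,
        "dhs": rng.random(n) < 0.12,
        "promoter_assoc": rng.random(n) < 0.15,
        "celltype_promoter": rng.random(n) < 0.05,
        "imprinted": rng.random(n) < 0.005,
        "arm_start": arm_start,
        "arm_end": arm_end,
    }, index=_probe_ids(cfg))
    return ann


def generate_reference_panel(cfg: SimConfig) -> ReferencePanel:
    """Reference blood-cell methylomes: 6 cell types x n_replicates.

    Planted cell-type probes have large between-type mean differences; all
    other probes share a single mean, so they carry no cell-type signal
    beyond replicate noise.
    """
    cfg.validate()
    means = panel_type_means(cfg)
    rng = _rng(cfg, 6)
    cols, types, blocks = [], [], []
    for t in CELL_TYPES:
        m = means[t].to_numpy()[:, None]
        block = m + rng.normal(0.0, cfg.panel_noise_sd,
                               (cfg.n_probes, cfg.n_replicates))
        blocks.append(np.clip(block, 0.0, 1.0))
        cols.extend(f"{t}_{r + 1}" for r in range(cfg.n_replicates))
        types.extend([t] * cfg.n_replicates)
    values = pd.DataFrame(np.hstack(blocks), index=_probe_ids(cfg), columns=cols)
    return ReferencePanel(values=values, cell_types=pd.Series(types, index=cols))


_TN_COHORTS = (("cohortA", 32, 463), ("cohortB", 43, 361))


def generate_tumor_normal(cfg: SimConfig, truth: TruthLabels) -> TumorNormalSummary:
    """Tumor/normal mean-beta summaries for two cancer cohorts.

    A fraction of the acquired-truth probes is planted with a same-direction
    tumor-normal difference of at least 5% in both cohorts; everything else
    fluctuates around zero difference.
    """
    cfg.validate()
    rng = _rng(cfg, 7)
    probes = _probe_ids(cfg)
    acquired = sorted(truth.acquired_truth)
    n_conc = int(round(cfg.frac_tumor_concordant * len(acquired)))
    conc = set(rng.choice(acquired, size=n_conc, replace=False)) if n_conc else set()
    normal = rng.uniform(0.2, 0.7, cfg.n_probes)
    lo, hi = cfg.tn_effect_range
    rows = []
    for cname, n_norm, n_tum in _TN_COHORTS:
        diff = (rng.normal(0.0, cfg.tn_noise_sd, cfg.n_probes)
                if cfg.tn_noise_sd > 0 else np.zeros(cfg.n_probes))
        for p in conc:
            i = probes.get_loc(p)
            s = 1.0 if truth.planted_direction[p] == "hyper" else -1.0
            diff[i] = s * rng.uniform(lo, hi)
        tumor = np.clip(normal + diff, 0.0, 1.0)
        rows.append(pd.DataFrame({
            "probe_id": probes, "cohort": cname,
            "mean_tumor": tumor, "mean_normal": normal,
            "n_tumor": n_tum, "n_normal": n_norm}))
    return TumorNormalSummary(table=pd.concat(rows, ignore_index=True),
                              concordant_truth=conc)


def generate_casecontrol_regions(cfg: SimConfig):
    """Targeted-bisulfite read counts + matched case-control sheet.

    Returns ``(RegionCounts, CaseControlSheet)``.  RegionCounts is a long
    table (region_id, chrom, pos, sample, meth, unmeth); coverage is Poisson
    around lognormal per-region means clipped to the configured range.  The
    designated variable region receives per-pair case shifts of random sign
    (hyper- and hypo-methylation across the cohort); the optional shifted
    region receives a uniform case-vs-control offset.
    """
    cfg.validate()
    rng = _rng(cfg, 8)
    sheet = _casecontrol_sheet(cfg, rng)

    var_region = (f"region{cfg.variable_region_index:02d}"
                  if cfg.variable_region_index
                  and cfg.variable_region_index <= cfg.n_regions else None)
    shift_region = (f"region{cfg.shifted_region_index:02d}"
                    if cfg.shifted_region_index
                    and cfg.shifted_region_index <= cfg.n_regions else None)

    lo, hi = cfg.variable_effect_range
    pair_shift = rng.uniform(lo, hi, cfg.n_cc_pairs) * rng.choice(
        [-1.0, 1.0], cfg.n_cc_pairs)

    frames = []
    for r in range(1, cfg.n_regions + 1):
        rid = f"region{r:02d}"
        n_cpg = int(rng.integers(4, 13))
        chrom = f"chr{(r - 1) % _N_CHROMS + 1}"
        start = int(rng.integers(1, _CHROM_LEN - 500))
        pos = np.sort(rng.choice(np.arange(start, start + 400), n_cpg,
                                 replace=False))
        cov_mean = float(np.clip(
            rng.lognormal(np.log(cfg.coverage_mean) - cfg.coverage_log_sd**2 / 2,
                          cfg.coverage_log_sd), *cfg.coverage_range))
        p_region = rng.uniform(0.15, 0.85)
        p_cpg = np.clip(p_region + rng.normal(0.0, cfg.cc_cpg_sd, n_cpg),
                        0.02, 0.98)
        for j, row in sheet.iterrows():
            for sample, is_case in ((row.case_sample, True),
                                    (row.control_sample, False)):
                p = p_cpg + (rng.normal(0.0, cfg.cc_sample_sd, n_cpg)
                             if cfg.cc_sample_sd > 0 else 0.0)
                if is_case and rid == var_region:
                    p = p + pair_shift[j]
                if is_case and rid == shift_region:
                    p = p + cfg.shifted_effect
                p = np.clip(p, 0.0, 1.0)
                cov = rng.poisson(cov_mean, n_cpg)
                meth = rng.binomial(cov, p)
                frames.append(pd.DataFrame({
                    "region_id": rid, "chrom": chrom, "pos": pos,
                    "sample": sample, "meth": meth, "unmeth": cov - meth}))
    rc = pd.concat(frames, ignore_index=True)
    return rc, sheet


_HISTOLOGY = (["adenocarcinoma"] * 59 + ["SCC"] * 18 + ["SCLC"] * 14
              + ["LCC"] * 8 + ["carcinoid"] * 6 + ["NSCLC"] * 2 + ["mixed"] * 2)


def _casecontrol_sheet(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_cc_pairs
    # sex / smoking-status margins follow the emulated cohort table
    sexes = np.array(["female"] * round(n * 50 / 109) + ["male"] * n)[:n]
    smoking = np.array(["current"] * round(n * 25 / 109)
                       + ["ex"] * round(n * 17 / 109) + ["never"] * n)[:n]
    rng.shuffle(sexes)
    rng.shuffle(smoking)
    hist = [_HISTOLOGY[rng.integers(0, len(_HISTOLOGY))] for _ in range(n)]
    age = np.round(_truncnorm(rng, 60.6, 10.2, 35, 85, n)).astype(int)
    packyears = np.where(smoking == "never", 0.0,
                         np.round(rng.exponential(39.0, n), 1))
    return pd.DataFrame({
        "pair_id": [f"cc{i + 1:03d}" for i in range(n)],
        "case_sample": [f"cc{i + 1:03d}_case" for i in range(n)],
        "control_sample": [f"cc{i + 1:03d}_ctrl" for i in range(n)],
        "sex": sexes, "age": age, "packyears": packyears,
        "smoking_status": smoking, "histology": hist,
    })
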