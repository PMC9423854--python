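# twinmeth

Analysis pipeline for blood DNA-methylation studies of **monozygotic twin
pairs clinically discordant for a chronic inflammatory disease** (the
motivating setting is cystic fibrosis), together with the downstream steps
that carry candidate positions into a lung-cancer case-control validation:

1. **Probe QC** — remove array probes with missing values, repetitive
   sequence content, cross-reactivity, or membership on an unreliable-probe
   list, with one recorded reason per removed probe.
2. **Intra-pair differential methylation** — `DM = β_severe − β_mild` per
   probe per pair, plus global similarity statistics (grand mean/SD,
   t-based 95% CI, correlations of per-pair mean |DM| with clinical
   discordance Δ and age).
3. **Discordance-dependent, direction-consistent selection** of
   inflammation-related differentially methylated positions (iDMPs): a
   probe qualifies when |DM| ≥ 0.10 in at least one discordant or
   unknown-discordance pair, |DM| ≤ 0.05 in every concordant pair, and
   three pieces of directional evidence agree —

   * r(β, DfO), the correlation of methylation with individual clinical
     severity (DfO = distance from origin; higher = milder),
   * r(DM, Δ), the correlation of pair differences with pair discordance,
   * the mean difference DM̄,

   using `r = Σ(xᵢ−x̄)(yᵢ−ȳ) / √(Σ(xᵢ−x̄)² Σ(yᵢ−ȳ)²)`. A *hyper* call
   requires r(β,DfO) < 0, r(DM,Δ) > 0, DM̄ > 0; *hypo* the reverse.
4. **Cell-type composition** — Houseman-style reference-based
   deconvolution (non-negative least squares on 6 blood-cell reference
   methylomes over marker probes, normalized to a partition of unity), a
   per-probe one-way ANOVA F-test across cell types with Bonferroni
   adjustment, and the split of iDMPs into *cell-type attributable* vs
   *acquired*.
5. **Enrichment** — one-sided Fisher's exact tests of the acquired set
   against genomic/functional categories (CGI relation, regulatory flags,
   subtelomeric = distal 500 kb of a chromosome arm, imprinted = ±1500 bp
   around an imprinted-gene TSS) and user-supplied gene→term maps, BH-FDR
   adjusted.
6. **Prioritization** — *strong or frequent* twin effects (|DM| ≥ 10% more
   than once, or ≥ 5% more than four times) unioned with *tumor
   concordance* (≥ 5% same-direction tumor−normal difference in both of
   two cancer cohorts).
7. **Case-control regions** — targeted-bisulfite count aggregation,
   two-sided paired t-tests per CpG with BH/Storey FDR, region ranking by
   the SD of signed intra-pair differences (bidirectional variability),
   covariate association (Pearson r, one-hot OLS R²), and paired t-test
   power from the noncentral-t distribution.

Because cohorts of this kind are rarely depositable, the package ships a
first-class **synthetic-data generator** (`twinmeth.synthetic`) that
emulates every pipeline input — bimodal beta baselines, intra-pair noise
at the ~2.7% DM scale, discordance-scaled planted effects with ground-truth
labels, cell-composition confounding (granulocytes up / NK cells down in
severe twins of discordant pairs), tumor/normal summaries, and amplicon
read counts with realistic coverage — so every stage can be tested for
truth recovery.

## Worked example

```python
import twinmeth as tm
from twinmeth import metrics as mt, selection as sel, cells

cfg = tm.SimConfig(seed=1)                      # 22 pairs, 20000 probes
beta, cohort, ann, truth = tm.generate_twin_cohort(cfg)
qc = tm.apply_probe_qc(beta, ann, set(ann.index[ann.unreliable]))
dm = mt.compute_pair_dm(beta, cohort)
gs = mt.global_similarity(dm, cohort)
res = sel.select_idmps(beta, dm, cohort, qc)
spec = cells.celltype_f_test(tm.generate_reference_panel(cfg))
part = cells.filter_acquired(res.selected, spec)
```

prints (via the obvious format calls):

```text
global mean DM  +0.012%  (SD 2.68%)
95% CI of mean  [+0.003%, +0.020%]
QC retained     15470/20000 (77.3%)
discordance-dependent  50 (0.32% of retained)
one-directional iDMPs  41 (82.0% of discordance-dependent)
cell-type attributable 3, acquired 38
recovery of planted acquired probes: 60.00%
```

Reading: twins are globally near-identical (mean intra-pair difference
~0.01% with SD 2.7%); the funnel narrows 20000 probes to 41 iDMPs of which
38 are not attributable to blood cell composition. At the default
(realistic) noise level the strict concordant cap sacrifices sensitivity —
60% of planted effects survive; under the quieter recovery conditions used
by the test suite (`noise_sd=0.01`) recovery exceeds 99% with no false
discoveries.

The same objects feed the later stages: `prioritize.strong_frequent_set`
and `prioritize.tumor_concordant_set` produce the candidate union, and
`regions.aggregate_regions` → `paired_position_tests` →
`region_variability` analyse the case-control amplicon data.

A thin CLI mirrors the stages:

```sh
twinmeth simulate --seed 1 --outdir sim/
twinmeth select --beta sim/beta.tsv --cohort sim/cohort.tsv \
    --annotation sim/annotation.tsv --out selection.tsv
twinmeth casecontrol --counts sim/region_counts.tsv \
    --sheet sim/casecontrol_sheet.tsv --outdir cc/
twinmeth power --sd 0.1
```

## Documentation

`docs/methods.md` describes the statistical model, the generator's
assumptions and defaults, numerical choices, and known limitations.
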