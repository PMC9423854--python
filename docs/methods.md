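# Methods

## Setting and model

The pipeline analyses probe-level DNA-methylation fractions
(beta values, β ∈ [0,1]) from whole blood of monozygotic twin pairs in
which the two twins differ in the clinical severity of a chronic
inflammatory disease. Because monozygotic twins share genotype, sex, age
and (largely) environment, a systematic intra-pair methylation difference
that scales with clinical discordance is interpreted as *acquired*,
plausibly inflammation-related, rather than genetic.

Two clinical scores organise the design: **DfO** (distance from origin), a
per-individual composite severity score where larger values mean milder
disease, and **Δ (Delta)**, a per-pair discordance score. Pairs are binned
into concordant / intermediate / discordant categories by Δ, plus an
unknown-discordance category whose scores are missing.

The core quantity is the intra-pair difference **DM = β_severe − β_mild**
per probe per pair. Selection is threshold-based by design (no moderated
statistics): methylation differences below ~5% are at the reliability
limit of orthogonal assays, so the rules are phrased directly in beta
units.

### Selection rules

A QC-retained probe is **discordance dependent** when

* at least `strong_min_pairs` (default 1) discordant-or-unknown pairs have
  |DM| ≥ `strong_threshold` (default 0.10), and
* every concordant pair with non-missing DM has |DM| ≤ `concordant_cap`
  (default 0.05).

Intermediate pairs are unconstrained: the rule set addresses the two ends
of the discordance spectrum, and constraining the middle would make the
criteria brittle without adding discriminating power.

A discordance-dependent probe is **one-directional** when three signs
agree: r(β, DfO) over individuals with known DfO, r(DM, Δ) over pairs with
known Δ, and the mean DM̄ over all pairs. With DfO oriented
higher-is-milder, hypermethylation in severe twins requires
r(β,DfO) < 0, r(DM,Δ) > 0, DM̄ > 0, and hypomethylation the mirror
pattern. Inequalities are strict: an exact zero or an undefined
correlation (fewer than 3 points, zero variance) carries no directional
evidence and yields `none`. The orientation is a config switch
(`dfo_higher_is_milder`) for cohorts whose severity score points the
other way.

The correlation is computed from its defining sums (pairwise-complete,
NaN-safe, vectorised across probes); unknown-category pairs participate in
the strong-DM criterion but are excluded from both correlations because
their clinical scores are missing.

### Cell-type composition

Blood is a cell mixture and inflammation shifts its composition, so an
apparent intra-pair difference can reflect differential cell counts
rather than acquired methylation change. Two complementary devices:

* **Deconvolution** — per-sample proportions of six cell types
  (granulocytes, monocytes, CD4+ T, CD8+ T, B, NK) by non-negative least
  squares of the sample profile on the per-type reference means over a
  marker set, followed by sum-to-one normalization. NNLS followed by
  normalization was chosen over an equality-constrained QP for robustness;
  on noiseless mixtures of the reference means it is exact (residual
  < 1e-8 in the test suite). Markers are the `m_per_type` (default 50)
  probes per type maximizing |type mean − mean of other types|, ties
  broken by probe id.
* **F-test filtering** — per-probe one-way ANOVA across cell types on the
  reference panel (≥2 replicates per type required), Bonferroni-adjusted
  across probes, flagged at adjusted p < 0.05. iDMPs significant here are
  *cell-type attributable*; the rest are *acquired*. Bonferroni is the
  named adjustment; Benjamini-Hochberg is available behind a flag.
  Sums of squares below 1e-20 are treated as exactly zero so that
  constant probes report p = 1 (no evidence) instead of float residue.

### Enrichment, prioritization, case-control validation

Enrichment uses one-sided Fisher's exact tests with the 2×2 table
(foreground-in, foreground-out, rest-of-background-in, rest-out), BH
adjustment across categories/terms. Coordinates are 1-based; windows are
closed intervals: subtelomeric = the terminal 500,000 bases of an arm
(inclusive), imprinted = [TSS − 1500, TSS + 1500]. An empty foreground
returns p = 1 rather than raising.

Prioritization flags a probe as *strong or frequent* when |DM| ≥ 0.10 in
strictly more than one pair or |DM| ≥ 0.05 in strictly more than four
pairs; the thresholds are nested, so a ≥10% pair also counts toward the
≥5% tally. *Tumor concordance* requires |mean_tumor − mean_normal| ≥ 0.05
in both of two cancer cohorts with signs matching the probe's twin-cohort
direction (the directionality-test direction, which coincides with
sign(DM̄) for selected probes by construction). The ≥ boundary is
inclusive and guarded by a 1e-12 epsilon against float representation.

Case-control amplicon analysis aggregates per-CpG methylated/unmethylated
counts to fractions (defined only at depth ≥ `min_depth`, default 10 — a
conservative floor, configurable), takes unweighted region means over
CpGs, and tests case-minus-control differences per CpG with a two-sided
one-sample t (equivalently the paired t), BH FDR by default and a
Storey-style q-value (π₀ = #{p > λ}/((1−λ)m), λ = 0.5, q = π₀·BH, capped
at 1) behind a flag. "Highly variable" regions are ranked by the SD of
*signed* paired differences pooled over CpGs and pairs, which rewards
variability in both directions rather than a uniform shift. Power of the
paired t-test uses the noncentral-t: df = n−1, ncp = δ/(s/√n),
power = P(T' > t₁₋α/₂) + P(T' < −t₁₋α/₂); the opposite tail underflows to
NaN in scipy for large ncp and is set to 0 there (it is < 1e-20 whenever
that happens). The one-sided unpaired Wilcoxon uses the exact null
distribution for tie-free samples up to n₁+n₂ = 50 and a tie-corrected
normal approximation otherwise.

The global 95% CI of the mean DM is t-based on per-pair mean DM values
(n = pairs) to avoid pseudo-replication over probes; computing it over
all probe×pair values is available via `ci_basis="values"`. Correlation
reports carry both r and r² with the two-sided t-transform p.

## Synthetic-data generator

The generator (`twinmeth.synthetic`) defines the study conditions; its
defaults are fixed once and shared by tests and the acceptance script.

* **Cohort structure** — 6/6/6/4 pairs (concordant/intermediate/
  discordant/unknown), 44 individuals; ages per category (means/SDs
  19.3±9.6, 14.6±7.3, 17.0±10.2, 3.0±1.2 years) and female/male pair
  counts chosen to reproduce the emulated cohort table's ratios (2.0,
  0.2, 2.0, 3.0). Δ is drawn per category from the printed means/SDs,
  truncated to disjoint bins (≤130 / 130–250 / 250–480): categories *are*
  discordance bins, and the truncation keeps planted effects consistent
  with the selection assumptions. DfO is split around a pair centre so
  the milder twin scores higher by exactly Δ.
* **Baseline betas** — three-component mixture: uniform low mode on
  (0.01, 0.09) with weight `frac_low` = 0.42, uniform high mode on
  (0.86, 0.99) with weight `frac_high` = 0.40, uniform mid otherwise.
  Uniform components are parameter-transparent: the fraction of baselines
  below 0.10 / above 0.85 equals the configured weights exactly, which
  the tests check empirically.
* **Noise** — additive Gaussian per individual on the beta scale,
  truncated to [0,1], default sd 0.019; two independent draws per pair
  make the intra-pair DM SD ≈ 0.027, matching the ~2.7% global intra-pair
  SD the generator emulates. (Logit-scale noise was rejected to keep the
  DM SD interpretable in beta units.)
* **Planted acquired effects** — `n_acquired_truth` = 50 probes, random
  hyper/hypo direction, severe-twin shift of magnitude
  `effect_max · clip((Δ − 120)/(380 − 120), 0, 1)` (effect_max = 0.15).
  The discordance floor at Δ = 120 means concordant pairs carry no
  planted effect — exactly the no-difference assumption the selection
  encodes — while discordant and (hidden-Δ) unknown pairs reach the full
  effect; a through-origin scaling would bleed ~3% effects into
  concordant pairs and make the concordant cap reject most true probes at
  realistic noise. Baselines of planted probes are redrawn with
  direction-aware headroom so shifts cannot clip at 0/1, and a small
  DfO-coupled term (2e-5 per DfO unit) makes baselines covary with
  individual severity in the planted direction.
* **Cell-composition confounding** — `n_celltype_truth` = 200 probes are
  rendered as mixtures of the reference panel: every individual gets a
  Dirichlet draw around a granulocyte-dominated blood composition
  (concentration 300), and severe twins of discordant pairs get a shifted
  target (granulocytes 0.58→0.68, NK 0.04→0.016, rest rescaled) —
  a neutrophilia-like shift. The reference panel gives these probes one
  divergent cell type (high-vs-low or low-vs-high between U(0.65, 0.95)
  and U(0.05, 0.30)); all other probes share a single mean, so panel
  replicates differ only by noise (sd 0.02).
* **QC structure** — independent per-probe flags: repetitive 12%,
  cross-reactive 6%, unreliable 2%, missing values 5% (1–3 random NaN
  entries per affected probe), giving ~77% retention; truth probes are
  planted only among clean probes.
* **Tumor/normal summaries** — two cohorts with the emulated sample
  counts (32/463 and 43/361); 40% of acquired-truth probes get a planted
  same-direction difference U(0.08, 0.15) in both cohorts, the rest
  N(0, 0.005) around zero.
* **Amplicon counts** — 20 regions × 4–12 CpGs, 109 matched case-control
  pairs with the emulated margins (50F/59M; 25 current / 17 ex / 67 never
  smokers; packyears 0 for never-smokers, exponential otherwise; matched
  covariates equal within a pair by construction). Coverage is Poisson
  around lognormal per-region means (median ~1450, clipped to 124–4841,
  overall mean ≈ 1700×). One designated region (default #13) receives
  per-pair case shifts of random sign and magnitude U(0.10, 0.25) —
  variable in both directions — and an optional second region can receive
  a uniform case shift for FDR power tests.

**What the generator does not emulate:** probe-probe correlation
(neighbouring CpGs are independent here), genotype effects on methylation
(metQTLs), batch/chip structure, age-related drift within the cohort,
bisulfite-conversion failure, and the heavy-tailed error of low-coverage
amplicons. Recovery results on synthetic data therefore demonstrate that
the *rules are implemented correctly and behave as designed under their
own assumptions*, not that the pipeline would achieve the same
sensitivity on a real cohort.

## Problem sizes in the test suite and acceptance script

Unit tests use toy fixtures (≤ 100 probes). Recovery suites use the full
22-pair design with 20,000 probes over seeds 1–20 (selection) and reduced
amplicon cohorts (8 regions × 30–40 pairs, seeds 1–10) for region
ranking; null-calibration suites use 1000 probes/CpGs. The acceptance
script runs the default study once and the recovery conditions over 5
derived seeds. These sizes were chosen so the full pipeline is exercised
end to end while any single suite completes in well under a minute.

## Known limitations

* The unreliable-probe list is user-supplied; the package does not ship
  one (the synthetic annotation carries its own flag).
* The exact one-directional survival fraction reported by any real study
  depends on its non-deposited data; only the machinery, its boundary
  behaviour and truth recovery on synthetic cohorts are contracted here.
* The F-test defaults to testing all panel probes; restricting it to a
  candidate subset changes the Bonferroni family size and is left to the
  caller.
* Fisher's exact test is conservative for small counts; the null
  calibration checks use tables large enough for the attained level to
  approach the nominal one.
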