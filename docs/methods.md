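# Methods

This note documents the statistical model behind each stage of
`qtltriad`, the defaults and why they were chosen, the numerical
choices, and what the synthetic-data generator does and does not
emulate.

## Data model

All stages consume per-variant marginal association records
(variant id, alleles, effect-allele frequency, beta, SE, p, n) for one
trait per dataset.  Disease effects are on the log-odds scale, molecular
effects in SD units.  Coordinates are 1-based; chromosome labels are
normalised by stripping any `chr` prefix.  Rows whose printed P
disagrees with `2·Φ(−|β/se|)` by more than 5% relative — a tolerance
reflecting inputs rounded to 4–5 significant figures — are repaired by
recomputing P from (β, se), with the printed value retained as
`p_reported`; internal consistency is required because every downstream
statistic is built from z-scores.

Allele harmonisation orients each outcome record to the exposure's
effect allele: identical alleles pass through, swapped alleles flip the
beta sign and complement the frequency, and strand complements are
resolved before the same logic.  Palindromic (A/T, C/G) variants are
dropped when either frequency is missing or within ±0.08 of 0.5; outside
that band letters orient first and a side-of-0.5 frequency disagreement
triggers a strand correction.  The MAF filter folds frequency
(`min(eaf, 1−eaf) ≥ 0.005` by default) and *retains* records with
missing frequency under a `maf_unknown` flag — dropping them would
silently shrink meta-analyses whose inputs omit frequencies, while the
palindromic rule still protects the ambiguous cases.

## Meta-analysis

Fixed-effects inverse-variance weighting only: `w_i = 1/se_i²`, pooled
beta `Σw_iβ_i/Σw_i`, pooled SE `(Σw_i)^{-1/2}`.  Cochran's Q and I² are
reported but never gate anything; random-effects and sample-size
weighting are deliberately out of scope.  Genome-wide-significant loci
(p < 5×10⁻⁸) are defined by greedy distance clumping: the smallest-p
unassigned variant indexes a locus and absorbs significant variants
within ±500 kb on its chromosome; ties in minimum p break by
(chromosome, position) for determinism.  Distance clumping rather than
LD clumping keeps locus definition independent of a reference panel;
at the 500-kb scale the two agree for well-separated signals.
Replication concordance harmonises index variants into the discovery
orientation, then asks for sign agreement and nominal p < 0.05; an
exactly zero replication beta is counted inconsistent and flagged
ambiguous.

## Two-sample MR

Instruments are cis variants (within 1 Mb of the TSS) passing BH-FDR
< 0.05 — computed once across the exposure dataset, matching how QTL
consortia publish "significant" associations — and p < 10⁻⁵, greedily
LD-pruned strongest-first at r² < 0.1.  Without an LD panel, pruning
falls back to a 250-kb distance rule; with a panel, distance is ignored.
Variance explained uses `r² = z²/(z²+n−2)` on the observed scale for
both quantitative and case-control traits; for the binary outcome this
is an approximation, acceptable because Steiger filtering only compares
orders of magnitude (molecular r² is typically 100-fold larger).
Steiger passes only when `r²_exposure > r²_outcome`; equality and
missing sample sizes fail conservatively.  A single instrument gives the
Wald ratio with the first-order delta SE
`√(se_y²/β_x² + β_y² se_x²/β_x⁴)`; the second-order term is omitted
because instruments are gated at p < 10⁻⁵, so `|β_x|/se_x > 4.4` and the
term is O(1/z²) relative.  Multiple instruments combine by fixed-effect
IVW of per-instrument ratios with weights `β_x²/se_y²`.  Gene-level FDR
is BH across all genes estimated in one run.

## SMR and HEIDI

The SMR statistic `T = z_x²z_y²/(z_x²+z_y²)` is referred to χ²(1); the
top instrument is the minimum-p cis variant and must reach p < 10⁻⁵ or
the feature is skipped.  `se_smr = |b̂|/√T` diverges as the outcome
z-score vanishes, which is the honest answer for an uninformative
instrument.

HEIDI compares Wald ratios across SNPs in LD with the top QTL.
Eligibility follows the conventions of the originating method:
exposure p < 1.57×10⁻³ (z² > 10), LD r² with the top SNP in
[0.05, 0.9], at most the 20 smallest-p SNPs, at least 3 — all four
config-exposed.  The deviation vector `d_i = b̂_i − b̂_top` has a
first-order delta-method covariance built from
`Cov(β̂_i, β̂_j) = r_ij se_i se_j` within each dataset and independence
across datasets (non-overlapping cohorts).  `T = Σ(d_i/sd_i)²` is
referred to `Σλ_k χ²₁` with λ the eigenvalues of the correlation matrix
of the standardised deviations.

**Tail evaluation.**  The mixture tail is computed by Imhof's
characteristic-function inversion (`scipy.integrate.quad`), which is
essentially exact in the bulk of the distribution; a three-moment
Liu-type chi-square match is the fallback for the far tail (p < 10⁻⁶)
and for integration failures.  The pure moment match was measured
against a 200,000-draw Monte-Carlo oracle during development and showed
absolute errors up to ≈0.03 on small unfavourable spectra — material at
the p > 0.05 gate — while Imhof inversion stays within ≈0.003; the test
suite bounds the shipped path at ±0.02.  Pairs with fewer than three
eligible SNPs carry `p_heidi = None` with a `heidi_untestable` flag and,
by default, *pass* the HEIDI gate with that flag visible (the test
protects against a specific artefact, and its absence is not evidence of
that artefact); `keep_heidi_untestable: false` flips them to exclusion.

## Three-step design and gates

Step 1 tests expression → disease for each gene in the caller-supplied
gene filter; step 2 tests methylation → disease for every probe; step 3
tests methylation → expression only for (probe, gene) pairs significant
in steps 1 and 2 (BH-FDR within each step, over the tests actually
performed in that step) with the probe inside the gene's 1-Mb cis
window.  Probe–gene pairing happens *after* step-1/step-2 significance
rather than restricting the step-2 universe up front; both orderings
give the same candidates when the probe universe is cis-complete, and
the implemented order keeps step 2 a self-contained epigenome scan.
Gates: (1) q < 0.05 three times; (2) top-instrument p < 10⁻⁵ in the
eQTL, the mQTL, and the GWAS (evaluated at the step-1 top SNP for the
GWAS); (3) every computable HEIDI p > 0.05; (4) optionally — on by
default — eQTL-vs-GWAS colocalization PP.H4 > 0.5 over the gene's cis
panel.  Candidates are chains passing all gates; the sign chain
`sign(meth→disease) = sign(meth→expr) × sign(expr→disease)` is reported
per chain with an explicit inconsistency marker.

## Colocalization

Wakefield log-ABFs `½[log(1−r) + r z²]`, `r = W/(se²+W)`, with
effect-size prior SD `√W` of 0.2 for molecular traits and 0.15 for
case-control, and per-SNP priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ — the
originating method's defaults, all config-exposed.  All evidence is
accumulated in log space (`logsumexp`), so |z| up to 50 and beyond
cannot overflow; the H3 term `log(exp(l1+l2) − exp(l12))` clamps tiny
negative differences to −∞ with a warning, which also covers the
single-SNP panel where H3 is structurally impossible.

## Synthetic-data generator

Summary statistics are simulated directly on the standardized scale:
per layer, `z ~ MVN(√n · R b, R)` with `β̂ = z/√n`, `se = 1/√n`, where
`R` is an AR(1) LD matrix (`r_jk = ρ^{|j−k|}`, ρ = 0.6 by default; any
user PSD matrix is accepted) and `b` the causal-effect vector implied by
the scenario.  This is exact for the quantities every stage consumes and
avoids simulating genotypes; the disease layer is treated on the same
linear scale, so liability-threshold case-control artefacts are not
emulated.  Layers are drawn independently (non-overlapping cohorts);
panel metadata (alleles, frequencies) derives from a separate
`panel_seed` so that replicate draws share a reference panel.

Default study conditions: α = 0.15 (SNP→methylation), γ = 0.5
(methylation→expression), c = 0.3 (expression→disease), sample sizes
20k/20k/200k, m = 100 SNPs — QTL z-scores ≈ 21/10.6 and a disease
z ≈ 10 at the causal variant, i.e. a clearly detectable locus of the
kind the pipeline is meant to prioritise.  Scenarios: `mediated` (full
chain), `pleiotropy` (direct SNP→disease effect sized to the mediated
marginal, c = 0), `linkage` (molecular causal SNP and disease causal
SNP adjacent, LD r = ρ; expression effect doubled via a direct δ so the
two signals are individually strong), `null`, and `reverse` (a strong
disease signal echoing into expression at half amplitude, which Steiger
filtering must catch).  One gene and one CpG probe per locus;
multi-feature inputs are composed by concatenating loci with disjoint
panels.

What passing tests show — and do not.  The generator reproduces the LD
structure, noise law and causal topologies the analysis assumes, so the
tests validate the *statistics* (calibration, power, gate logic,
recovery).  It does not emulate realistic MAF/LD drawn from reference
panels, sample overlap between layers, binary-trait scale conversion,
imputation error, or multi-causal architectures; performance on real
cohort data depends on those factors and is not certified by this suite.

## Problem sizes and runtime choices

Batch experiments use 200 replicate loci per scenario (binomial SE
≈ 0.02 on a 0.9 detection rate) and 2,000 replicates for SMR null
calibration (SE ≈ 0.005 on the 0.05 rejection rate); the
Monte-Carlo quadratic-form oracle uses 200,000 draws (SE ≈ 0.001 on
mid-range p).  These sizes make every reported rate's uncertainty small
relative to the decision margins while keeping a full run in minutes on
one core.

## Known limitations

- Single-causal-variant logic throughout: no conditional analysis,
  multi-signal colocalization (SuSiE-style) or multi-SNP SMR.
- HEIDI's delta-method covariance assumes no sample overlap between
  exposure and outcome cohorts.
- The binary-outcome variance-explained approximation understates
  liability-scale r²; Steiger conclusions are robust to this only when
  the exposure/outcome contrast is large, as it is for cis-QTLs.
- Distance-based locus clumping can merge distinct signals closer than
  the window or split one signal spanning more than it.
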