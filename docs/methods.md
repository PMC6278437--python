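# Methods

`methrestore` implements an integrative analysis of DNA methylation and
gene expression for a three-condition design: a control arm (saline,
n = 3), a disease-induction arm (OVA, an ovalbumin-sensitized mouse
asthma model, n = 3) and a treatment arm (DSE, a herbal extract, n = 4).
The scientific object of interest is the *restoration pattern*: a
molecular change induced by disease and reversed by treatment, detected
in both the methylome and the transcriptome and joined through an
inverse methylation–expression correlation.

## Windowed DMR calling

CpG-level methylated/unmethylated read counts (Bismark
cytosine-report-like tables) are filtered to CpGs with read depth ≥ 20
in **every** sample of the contrast (the stricter, per-sample reading of
a minimum-depth rule; a `group_mean` scope is available). The genome is
tiled with 1000-bp windows stepped by 500 bp, so interior bases fall in
exactly two windows; overlapping windows are tested independently and
both may be reported. Strands are not merged by default (destranding is
a config flag).

For each window with ≥ 2 covered CpGs, per-sample counts are summed
over its CpGs and the two groups are compared with a binomial
likelihood-ratio test of the pooled proportions:

G = 2·[ ℓ(β̂_a) + ℓ(β̂_b) − ℓ(β̂_pooled) ],

where ℓ is the binomial log-likelihood over per-sample counts and
β̂_g = Σmeth/Σdepth within group g. This is exactly the
logistic-regression LRT with group as the only covariate (the logistic
MLE under one categorical covariate is the pooled group proportion),
written in closed form so it is exact at complete separation (β = 0 or
1) and needs no iterative solver. Degenerate windows where both groups
share a pooled β of exactly 0 or 1 give G = 0, p = 1.

**Overdispersion.** Replicated bisulfite counts are overdispersed
relative to binomial (between-sample biological variance); referring G
directly to χ²(1) would inflate the false-positive rate roughly by the
dispersion factor. G is therefore divided by a Pearson dispersion
estimate — Σ X² / Σ df of the fitted two-group model — **pooled across
all tested windows of the contrast** and floored at 1. Pooling matters:
a per-window estimate has only (n_samples − 2) df and is far too noisy
to both hold the null calibration and retain power at q < 0.01, while
the pooled estimate over thousands of windows is essentially exact.
Single-window use (`test_window`) falls back to the window's own
estimate. Groups without replicates are compared with Fisher's exact
test on the pooled 2×2 table instead.

Benjamini–Hochberg correction runs over all tested windows of the
contrast (the testable set is contrast-specific because the depth
filter is). A window is a DMR when |Δβ| ≥ 10 percentage points and
q < 0.01; Δβ = 100·(β̂_b − β̂_a), so `hyper` means group b gained
methylation. All tested windows are retained for pattern analysis.
BH replaces the SLIM q-value method sometimes used with this style of
caller because it is deterministic and monotone.

## Feature annotation

Each window receives exactly one of six classes by fixed precedence
promoter > 5′ UTR > 3′ UTR > CDS > intron > intergenic over all
overlapping transcripts (any 1-bp overlap counts). The promoter is
TSS ± 1000 bp; both the span and the precedence are conventions, not
biology, and are configurable. UTRs are derived from the exon/CDS
difference strand-awarely; exons of non-coding transcripts rank at the
3′-UTR level. DMR→transcript links take every transcript whose promoter
or body overlaps the window, otherwise the nearest TSS within
10 kb (ties broken lexicographically, all ties returned).

## Differential expression

Raw transcript counts are normalized to counts-per-million (library
size; TMM-style composition correction is a documented simplification —
a config hook exists for substituting another normalizer). The test is
a negative-binomial Wald test on the log ratio of group means with a
method-of-moments dispersion: tagwise φ̂ from pooled within-group CPM
variance via var = m + φm², clipped at 0, shrunk halfway toward the
common (median over transcripts with mean ≥ 1 CPM) dispersion. The Wald
variance of the log mean difference is (1/m_a + φ)/n_a +
(1/m_b + φ)/n_b with a pseudocount of 0.5 on the means. The statistic
is referred to a **moderated t with 2·(n_a + n_b − 2) df**: the
half-weight shrinkage implies a prior df equal to the residual df, so
the posterior df doubles. On null Poisson simulations of the study's
size (1000 transcripts, 3 vs 3) this keeps the empirical type-I error
at 0.035–0.055 across seeds, where a normal reference is
anti-conservative (0.06–0.10) and an unmoderated t(4) over-corrects
(≈ 0.02).

Fold changes are reported in the signed linear convention (+r for
up-regulation, −1/r for down; a ratio of exactly 1 maps to +1). The
genome-wide DEG screen flags transcripts with |log2 FC| ≥ 1 and raw
p < 0.05 (no FDR at this stage, configurable). This NB test is a
deliberately self-contained desk-scale method; numerical parity with
quantile-adjusted conditional-ML packages is a non-goal, and the test
suite cross-checks the calls against an independent NB implementation
(pyDESeq2) instead of reusing one.

## Restoration patterns and integration

The two ordered contrasts are induction (OVA vs saline) and treatment
(DSE vs OVA). Methylation patterns: `hyper_hypo` requires Δβ₁ ≥ +10,
Δβ₂ ≤ −10, both q < 0.01; `hypo_hyper` mirrors it. Expression
patterns: `down_up` requires fc₁ ≤ −min_fc, fc₂ ≥ +min_fc, both
p < 0.05; `up_down` mirrors it. Pattern A = `hyper_hypo` + `down_up`
at a linked gene; Pattern B is the mirror. The sign conditions make A
and B mutually exclusive for a given (DMR, transcript) pair.

Two expression thresholds coexist deliberately. The genome-wide screen
uses min_fc = 2 (|log2 FC| ≥ 1). The candidate-table roll-up
(`summarize_candidate_table`, and the CLI `fixture-check`) uses
min_fc = 1, i.e. direction + significance: the packaged worked example
contains candidate fold changes with magnitude as low as 1.39, so the
magnitude screen demonstrably did not gate that table, and applying it
would drop 4 of its 18 genes.

For each linked (DMR, transcript) pair with a valid A/B pairing, the
per-sample window β (pooled meth/depth per sample, already in [0, 1])
is correlated with the per-sample CPM min–max scaled to [0, 1], by
Spearman rank correlation across **all 10 samples jointly** (the
all-sample choice maximizes rank resolution). The pair is emitted only
if ρ < 0 (strictly; the cutoff is configurable). A constant vector
scales to all 0.5, leaving ranks degenerate; the correlation is then
undefined and the pair is excluded rather than scored. Gene-level
roll-up: a gene is Pattern A if any of its links is; gene counts are
unique symbols.

## Synthetic data

The generator emulates the study conditions rather than any particular
dataset. Defaults: 3/3/4 samples; a toy genome of two 2-Mb chromosomes
with 10 CpGs/kb (8000 windows — a full run stays well under a minute);
per-CpG depth ~ Poisson(30); background per-CpG methylation drawn from
a bimodal Beta mixture (Beta(2,18)/Beta(18,2), reflecting the bimodal
methylomes of bulk tissue) shared across groups; counts beta-binomial
with precision 30 (moderate overdispersion). Planted windows (20
Pattern A, 5 Pattern B, placed on the 1000-bp tiling grid with ≥ 2-kb
gaps) sit at baseline β 0.4 (A) or 0.6 (B) so a ±30-pp group shift
stays inside (0, 1); OVA is shifted, saline and DSE share the baseline
(clipped to [0.02, 0.98] if needed). Expression: log-normal baseline
(median 200, sd(log) 1.0), NB dispersion 0.1, OVA mean divided
(Pattern A) or multiplied (Pattern B) by a 4-fold change, 500 null
genes. Planted genes' promoters are placed over their planted windows
(TSS at window centre), which couples the two layers through the shared
group means and induces the negative Spearman ρ the integrator
requires. Everything is deterministic under the config seed (the count
draw uses seed + 1 so the two layers are reproducible independently).

What the generator does **not** emulate: CpG clustering/islands,
distance-decay correlation between neighbouring CpGs, sample-level
covariates or batch effects, composition bias in library sizes,
transcript-length effects, and enhancer-mediated (distal) regulation.
Passing recovery tests therefore show the pipeline's logic and
calibration under the stated noise model, not performance on real
tissue data.

## Numerical choices and degenerate inputs

- p-values are two-sided throughout; the DMR q-values are plain BH.
- Dispersion floors: the window-test scaling factor is never < 1; the
  NB tagwise dispersion is never < 0.
- A CpG missing from one sample is depth 0 (fails the depth filter),
  not an error; an empty CpG table is valid input.
- Windows with zero total depth in a group are skipped with a warning;
  transcripts with all-zero counts in a contrast are dropped with a log
  note; links to transcripts absent from the expression table are
  skipped with a warning.
- `dmr_summary` rounds percentages to two decimals; a zero bin total
  raises rather than returning NaN.

## Test problem sizes

The suite's simulations are sized for a desk run: null calibration on
~2000 windows (one 1-Mb chromosome), planted-window recovery on a
260-kb chromosome with 10 planted windows, 50 small replicates for the
fold-change range check, 15 mid-size replicates for the ρ-sign check,
and the full-pipeline recovery at generator defaults. The whole suite
runs in well under a minute on one CPU.

## Known limitations

- The window test conditions on pooled per-group counts; it does not
  model per-CpG effects within a window (no BSmooth-style smoothing,
  no per-base DMC calling).
- CPM normalization is not robust to strong composition shifts; a
  global fold change shared by most of the transcriptome would be
  absorbed into the normalization.
- The expression model supports only a two-group comparison with the
  group factor; no covariate adjustment.
- Promoter span, feature precedence and the linking distance are
  conventions; results at feature boundaries depend on them.
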