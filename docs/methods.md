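# Methods note

## Model and procedure

**Counts model.** miRNA read counts are treated as negative binomial. The
synthetic generator draws gamma–Poisson counts: for feature *g* in sample
*i*, λ_gi = s_i · q_gi · γ_gi with γ_gi ~ Gamma(shape = 1/φ, scale = φ),
log2 q_gi = log2 b_g + β_g·x_i + u_{p(i)} + ε_gi. Here b_g is a lognormal
base abundance rescaled to sum to 10⁶ (so q is on the counts-per-million
scale), β_g is the planted log2 effect (nonzero for a chosen subset, applied
in the interictal and ictal groups), u_p is a per-patient normal random
effect shared by the two samples of self-paired patients, and ε is
N(0, σ_e²) sample noise. The patient effect standard deviation is set as
σ_b = σ_e·√(ρ/(1−ρ)) so that ρ is the intra-patient correlation of the
log-scale noise. Library sizes s_i are uniform on a configured range.

**Normalization.** TMM scaling factors: the reference sample is the one
whose 75th-percentile count fraction is closest to the mean of those
fractions; for each sample, M (log-ratio) and A (log-abundance) values over
features positive in both samples are double-trimmed (30 % of M, 5 % of A,
trim count = ⌊n·trim⌋ + 1 on average ranks) and averaged with
inverse-asymptotic-variance weights; factors are rescaled to geometric
mean 1. Expression is log2 counts-per-million with prior count 0.5 added
after scaling library sizes by the TMM factors.

**Precision weights.** Per-feature residual standard deviations from an OLS
fit of log2-CPM on the design are square-rooted and smoothed against mean
log2-count by lowess (span 0.5); each observation's weight is the
interpolated trend at its fitted log-count raised to the −4 power.

**Moderated test.** Weighted least squares per feature, then
empirical-Bayes variance shrinkage: the prior degrees of freedom d₀ and
prior variance s₀² are estimated by method of moments on log sample
variances (digamma/trigamma; trigamma inverse by Newton iteration), the
posterior variance is s̃² = (d₀s₀² + d·s²)/(d₀ + d), and the moderated t
statistic has d₀ + d degrees of freedom. `prior_df` can be forced to 0
(ordinary t) or ∞ (common variance). The ictal-vs-interictal contrast is
fit as a one-sample moderated t on within-patient differences of log2-CPM,
with per-difference weight 1/(1/w_ictal + 1/w_interictal). This treats the
pairing exactly but discards unpaired samples for that contrast; it is a
deliberate simplification relative to fitting a shared intra-block
correlation across all samples.

**DE filter and ranking.** A feature is DE when |signed FC| > 1.2 **and**
raw p < 0.05, both strict. Signed FC is 2^log2FC for log2FC ≥ 0 and
−2^(−log2FC) otherwise. The adjusted p (Benjamini–Hochberg across all
tested features) is reported but not used for the call. The average rank is
the mean of the fractional rank by |FC| descending and by p ascending, over
either all tested features or the DE subset (`rank_scope`).

**Signed network and node strength.** Interaction records are filtered per
tier — predicted score > 80.0, mirSVR score < −1.2 (both strict), validated
records unfiltered — then deduplicated to one edge per (miRNA, gene) pair
with miRNA identifiers case-normalized on the hsa-/miR-/let- prefixes.
Edges from upregulated miRNAs get weight +1, from downregulated −1; node
strength is the sum over a gene's incident edges, so strength ≡ degree
(mod 2) is an invariant. Positive strength predicts the gene down, negative
up; |strength| > 1 marks genes targeted consistently by several miRNAs.

**Validation.** A gene with nonzero strength and nonzero measured mRNA
log2FC is consistent iff sign(log2FC) = −sign(strength). Strength 0 or
log2FC exactly 0 is counted as not consistent rather than excluded.

**Enrichment.** One-sided hypergeometric tail P(X ≥ k) per term with the
gene universe taken as the genes of the filtered interaction database; BH
FDR across terms; significance at p < 0.01 on the raw hypergeometric p.
The specificity filter keeps terms with annotation frequency strictly
< 0.15; terms lacking a frequency are kept and flagged.

## Tunable parameters

| Parameter | Default | Rationale |
|---|---|---|
| TMM trims (M, A) | 0.30, 0.05 | standard double-trim fractions for composition-robust scaling |
| log-CPM prior count | 0.5 | stabilizes log of low counts without flattening fold changes |
| lowess span | 0.5 | smooth mean–variance trend on a few hundred features |
| FC threshold | 1.2 (strict) | modest effect floor typical of PBMC miRNA studies |
| p threshold | 0.05 raw (strict) | matches the call definition used for the bundled lists |
| score / mirSVR cutoffs | > 80.0 / < −1.2 | high-confidence prediction tiers |
| emphasis cutoff | \|strength\| > 1 | multi-miRNA convergence on a target |
| ORA alpha / frequency cutoff | 0.01 / 0.15 | significant yet specific terms |
| dispersion φ | 0.1 | moderate biological variability |
| pairing correlation ρ | 0.5 | substantial within-patient correlation |
| sample noise σ_e | 0.25 (log2) | per-sample technical/biological noise |
| library size range | 0.8–1.2 M | small RNA-seq depth scale |
| group sizes | 12 / 16 / 8 (healthy / interictal / ictal) | unbalanced design exercising the paired contrast |

The calibration and recovery studies in `scripts/acceptance.py` use fixed
problem sizes chosen by the package, not tuned to outcomes: the null study
runs 50 replicate 8-vs-8 studies of 200 features with no planted effects;
the recovery study plants 30 effects of |log2FC| = 1.5 among 300 miRNAs with
a 1000-gene target universe (30–70 targets per miRNA) and a 0.4 sign-flip
fraction in the mRNA stand-in. All randomness derives from the script's
`--seed` via splittable seed sequences.

## Generator scope

The generator covers what the tests need and no more: negative-binomial
counts with group effects and pairing, threshold-straddling interaction
scores (true edges pass exactly one tier's filter, decoys fail it), an mRNA
log2FC table whose signs oppose the planted strengths except for a
configurable flip fraction (flip 0 ⇒ all consistent, flip 1 ⇒ none, floored
magnitudes so noise never changes a sign), and gene sets with one planted
term below the frequency cutoff and others straddling it. Passing tests
show the pipeline recovers *these* planted structures under *these* noise
models; they do not certify performance on real libraries with adapter
artifacts, isomiR ambiguity, or non-NB overdispersion.

## Numerical and design choices

- Paired contrast by explicit within-patient differences (see above), not a
  shared-correlation mixed model.
- Per-million values are computed once from TMM-scaled library sizes and
  reused for both log-CPM and reporting.
- Average ranks use fractional (mean) ranks, so ties share a rank.
- Deduplication keeps one interaction per (miRNA, gene) pair regardless of
  how many tiers support it; weights are ±1, not confidence-scaled.
- The ORA universe is the filtered interaction-database gene set, not the
  genome, because the query is drawn from that same database.
- `hypergeom.sf(k−1, N, K, n)` gives the inclusive upper tail; BH uses the
  step-up procedure.
- All fitted linear algebra is batched (einsum) over features; no
  per-feature Python loops in the hot path.

## Known limitations

- No multiple-testing control on the DE *call* itself (raw p by design);
  BH-adjusted values are provided for readers who want them.
- Edge signs ignore interaction confidence and expression magnitude.
- Strength-0 genes are unvalidatable by construction; with even degree and
  balanced miRNA directions this can hide real targets.
- The generator's mRNA stand-in bypasses an actual mRNA count model.
- lowess weights assume enough features (≳100) for a stable trend.

## Open questions resolved in code

- Features with zero counts in all samples of a contrast are kept in the
  fit (prior count prevents degeneracy) but effectively never pass the FC
  filter.
- When the DE list for a contrast is empty, downstream stages are skipped
  and flagged in the run manifest rather than erroring.
- Missing genes in the mRNA table simply drop out of the validation
  intersection; counts of predicted, measured and overlapping genes are
  reported so the attrition is visible.
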