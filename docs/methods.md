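# Methods

This note records the models, defaults and numerical choices behind
`lesionlink`, and what the synthetic-data experiments do and do not show.

## Study design and the synthetic generator

The generator emulates a two-laboratory factorial toxicogenomics study:
2 sites × 2 genotypes (wild type, Mgmt-null) × 2 treatments (MAM 20 mg/kg,
vehicle) × 4 timepoints (6, 24, 48, 168 h) × 3 hybridized arrays per cell =
96 arrays, one animal per array. Each animal contributes one brain
expression profile and one lesion measurement per tissue (brain, liver),
mirroring the half-brain split (RNA from one hemisphere, DNA from the
other) that justifies pairing expression with lesion burden at the animal
level. Expression is generated for brain only; liver appears only in the
lesion table.

**Probe-level expression.** Probeset baselines are N(8.5, 1.0) on log2;
each of the 11 probes carries a fixed additive affinity N(0, 0.5) (median
polish needs this probe-level structure); measurement noise is iid
Gaussian per probe, default sd 0.25 log2. Raw intensities are
`2^log2signal` plus an optical background N(100, 20) — exactly the
normal-noise component the RMA background model assumes. A constant
per-site offset (default 0.3 log2) mimics the batch effect that the
model's laboratory term absorbs.

**Planted signals** are disjoint probeset categories recorded in a truth
table: treatment effects (added to all MAM arrays), genotype effects
(added to knockout arrays), interaction effects (added to the MAM×knockout
cell, so the difference-of-differences equals the effect size while main
effects of half the size appear as a side product), laboratory-inconsistent
probesets (a site×treatment interaction of the same magnitude), and
anchored probesets. Default effect size is 1.0 log2 (fold change 2.0,
safely above the 1.3 call gate).

**Anchoring implantation** works on ranks: within each timepoint's
MAM-treated group, observed brain lesion values are rank-transformed to
normal scores (Blom), and the anchored probeset receives
`amplitude · (ρ·z + sqrt(1−ρ²)·ε)` with ρ = `anchor_strength`. Because the
construction is a Gaussian copula on the lesion ranks, `anchor_strength`
maps directly onto the population Spearman correlation (up to the usual
ρ→(6/π)asin(ρ/2) correction, ~1% at ρ = 0.9). The amplitude reuses
`log2_effect_size`; no separate knob is exposed.

**Lesion kinetics.** A single-pulse, first-order-repair surrogate: the
expected burden is `initial · exp(−rate·t)` with genotype-specific rates
(defaults: wild type half-life 24 h; knockout rate 0.001/h, i.e. nearly
persistent) and tissue-specific initial burdens (brain 300, liver 300 000
lesions per 1e8 nucleotides — three orders of magnitude apart).
Measurement error is mean-preserving lognormal with CV 0.20. Observations
below the assay's minimal detectable quantity (MDQ, range 1–2.6 per 1e8)
are reported at the MDQ midpoint (1.8) with a censored flag; vehicle
animals sit at the floor by construction. The surrogate reproduces the
qualitative picture — low/flat wild-type brain, persistently elevated
knockout tissues, declining wild-type liver — but no attempt is made to
model absorption or repair saturation.

**What passing these simulations shows.** Recovery results demonstrate
that the pipeline's statistics behave as designed under the generative
model: Gaussian noise, additive probe affinities, exchangeable arrays,
effects constant across timepoints. Real arrays add heavier-tailed noise,
intensity-dependent variance, probe cross-hybridization and outlier
arrays; the median-polish and rank-based stages are robust to some of
this, but the simulations do not certify behavior under those violations.

## Preprocessing

Background correction estimates the normal+exponential convolution
parameters per array with the classic mode-based heuristic: the noise mean
μ is a two-pass smoothed-histogram density mode (the second pass uses only
data left of the first mode, where the Silverman bandwidth is not inflated
by the signal tail; zero boundary padding keeps the truncation edge from
attracting the argmax), σ comes from the left-of-mode spread (×√2/0.85),
and the exponential rate α from the mean excess above the mode. The
correction applies the exact posterior mean of a positive
exponential signal under Gaussian noise, computed stably through
`erfcx`. The transform is strictly positive and order-preserving; fold
changes at intensities near the background are attenuated (the posterior
mean has a floor), which is the familiar low-intensity compression of this
preprocessing family and is why a few planted 2-fold effects on dim
probesets fall below the 1.3 fold-change gate in the recovery experiments.

Quantile normalization maps every column onto the mean-of-sorted-columns
reference; tied values receive the mean of the reference values at their
tied ranks. With ties present, the "all columns share one sorted vector"
identity can no longer hold exactly (tie patterns differ between columns);
it holds exactly, along with idempotence, on tie-free input.

Median polish runs Tukey's row/column sweeps to convergence (max absolute
effect change < 0.01) or 10 sweeps; the probeset summary is the overall
plus column effects. Column-shift equivariance is exact for additive
blocks and holds to within the convergence tolerance otherwise.

## Factorial models and the consistency filter

Factors are coded ±½ (sum to zero), so every coefficient is directly a
group contrast in log2 units and, on the balanced design, the columns are
orthogonal. "Interactions involving the laboratory" is read per-term: all
three lab-interaction p-values must exceed 0.15 for the probeset to be
*reduced* (lab main effect retained) — the strictest reading consistent
with excluding probes whose effects differ between laboratories. A joint
3-df F variant is available (`joint_lab_test=True`). Under the null this
per-term rule excludes ≈ 1 − 0.85³ ≈ 39% of clean probesets at any single
timepoint; union-over-timepoints significance keeps end-to-end sensitivity
high (a clean probeset is excluded at all four timepoints only ~2% of the
time).

BH is applied within each (timepoint × effect) family over non-excluded
probesets, matching the timepoint-by-timepoint analysis. Fold change is
model-based: signed `2^|estimate|`. The "MAM response within the knockout"
analysis is the contrast `b_trt + ½·b_trt:geno` with variance from the
coefficient covariance; the "genotype difference in response" analysis is
the interaction term. Probeset→gene de-duplication keeps the probeset with
the smallest q-value per gene.

## Anchoring

Spearman ρ (Pearson on mid-ranks, average ranks for ties) between
normalized expression and brain lesion burden over MAM-treated animals of
a timepoint, both genotypes pooled; a candidate is anchored when signed
ρ > 0.70 at ≥ 1 timepoint (`absolute=True` switches to |ρ|). Censored
lesion values enter at the MDQ midpoint, which is rank-safe because all
censored values tie. Timepoints with fewer than 3 matched animals are
skipped. No multiplicity correction is applied — the rule is a fixed
threshold, not a test.

## Rank-based adduct statistics

For the two-group genotype comparison, rank regression with Wilcoxon
scores reduces to the Hodges–Lehmann shift (median of all pairwise
differences). The scale τ uses the Koul–Sievers–McKean window estimator
(δ = 0.80 for n/p > 5, √(n/(n−p−1)) correction). The optional Huber-type
tail inflation is off by default: at the study's group sizes it biases τ
upward and drops the null rejection rate of the approximate F(1, n−2)
test to ~0.03; without it the test sizes at ~0.048 for n = 15 per group.
`SE(shift) = τ·√(1/n₁+1/n₂)`, `TS = (shift/SE)²`. Group medians carry
McKean–Schrader order-statistic standard errors (95% window).

## Enrichment and promoter analysis

Overrepresentation uses the hypergeometric upper tail `P(X ≥ k)` and the
conservative EASE variant (tail at k−1, floored), BH-adjusted across
terms; terms are ranked by ascending EASE p, ties broken by larger overlap
then term id. The default universe is all genes represented on the matrix.

Motif scanning accepts IUPAC consensus strings (degenerate positions as
character classes, overlapping matches counted via lookahead; an N in the
sequence never satisfies a non-N motif position) or probability PWMs
scored as log2-odds against a uniform background with a finite threshold.
Both-strand scanning matches the reverse-complemented motif on the forward
sequence; positions are 0-based, half-open, forward coordinates. The
interaction matrix is binary (≥ 1 hit) over the candidate genes'
promoters, and motifs present in ≤ 5% of those promoters are dropped;
enrichment compares candidate hit frequency against a reference set
(hypergeometric when candidates ⊆ reference, one-sided Fisher when
disjoint). Promoters are taken as given in FASTA — the package does not
extract them from a genome; the synthetic promoter generator uses 2000 bp.

## Problem sizes used in the shipped experiments

The recovery experiments run 1000 probesets × 96 arrays for 20 seeds
(differential expression), 300 probesets × 10 seeds (anchoring), 200
probesets (consistency filter), 2000 replicates (rank-test null), 200
seeds (TRE power), and a 4000-probeset empirical permutation-null check
against the exact 720-permutation n = 6 null. These sizes give binomial
standard errors well below the margins being asserted while keeping the
whole suite inexpensive.

## Known limitations

- The per-term p > 0.15 consistency rule is aggressive under the null; a
  joint test is provided but not the default, to match the published rule.
- Background-correction parameters are heuristic estimates; the mode-based
  μ is biased upward for strongly skewed columns (this mirrors the
  reference heuristic's behavior and mostly cancels in fold changes).
- Censored lesion values are imputed at the MDQ midpoint rather than
  modelled with a censored likelihood.
- Time is a stratification variable, not a continuous covariate; no
  empirical-Bayes variance moderation or random animal effects.
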