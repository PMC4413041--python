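# Methods

## Model and procedure

`coexshift` treats a two-group expression study as two samples of pairwise
coexpression levels. Within each group *g*, the coexpression level of genes
*i* and *j* is the absolute sample Pearson correlation |r| of their
expression profiles across that group's samples. The absolute value is
deliberate: a pair locked in tight negative correlation is as biologically
coupled as a tight positive one, and the method's question is about coupling
strength, not direction. Correlations are computed strictly within group;
pooling samples would mix the two regimes being compared.

Each group's g·(g−1)/2 values are summarised by the empirical survival curve
F(t) = Prob(C ≥ t). The two-sample Kolmogorov–Smirnov statistic
D = max_t |F_d(t) − F_n(t)| measures the largest structural gap between the
groups, and the threshold attaining it is the disease-specific cutoff C. The
supremum over real thresholds is attained on the pooled multiset of observed
values, so that multiset is the evaluation grid. When several grid points
attain D exactly, the smallest is returned — the most inclusive strong
class — and the tie count is recorded in the result and the run log, so a
plateau is visible rather than silent.

Significance uses the classical asymptotic two-sided KS tail
p = 2·Σ (−1)^{k−1} exp(−2k²λ²) with λ = √(nm/(n+m))·D, evaluated by direct
alternating summation truncated when terms fall below 1e-30 and clamped to
[1e-30, 1]. No small-sample correction is applied.

Classification uses *strong iff |r| ≥ C*, the same inequality as the
survival curve. This consistency is what makes the identity
D·n = |#strong_disease − #strong_normal| hold when both groups have the same
pair count, a cross-check asserted in the test suite. The four classes
follow by crossing the per-group labels; disease-specific strong equals
normal-specific weak by construction, and the implementation computes the
four sets independently so the identity is verified rather than assumed.

GO-term mapping pairs each term's annotated genes (restricted to the
analyzed gene universe — only those pairs have coexpression values) and
intersects them with the four classes to form the table [[a, b], [c, d]].
The one-sided Fisher exact test (alternative: *a* enriched) asks whether the
term's pairs shifted toward disease-specific strong coexpression. Bonferroni
correction multiplies by the number of terms actually mapped in the run (not
the annotation file's term count), and the corrected value is reported
uncapped by default because values above 1 carry ranking information; a
`cap_at_1` flag restores convention. Terms in different GO categories
(biological process, cellular component, molecular function) are corrected
independently, each with its own m.

Candidate-term selection reproduces EASE-style enrichment: the one-sided
hypergeometric upper tail computed after removing one gene from the
list-term overlap (an overlap of ≤ 1 scores exactly 1), with
Benjamini–Hochberg FDR across terms and strict < 0.05 thresholds on both.
The background population defaults to all genes in the annotation but should
be supplied explicitly when known, since enrichment p-values are only as
meaningful as the background.

## Statistical assumptions and known limitations

- **Pair dependence.** The n = g·(g−1)/2 coexpression values within a group
  share genes and are not independent observations; the KS test treats them
  as if they were. Simulation shows the practical impact is small at this
  package's scale — under a structureless null with 93 genes and equal group
  sizes the measured false-positive rate at α = 0.05 is ≈ 4–6% and the null
  p-value distribution is close to uniform (Kolmogorov distance ≈ 0.06 over
  200 replicates) — but the approximation is documented, not corrected.
- **Unequal group sizes shift the null.** The sampling distribution of |r|
  under independence depends on the number of samples: fewer samples mean
  larger |r| values by chance. With unequal groups the two survival curves
  therefore differ even when the underlying correlation structure is
  identical; at 93 genes and 9-vs-8 samples a structureless simulation is
  flagged significant in ≈ 98% of runs. A significant D in an unequal design
  conflates structural change with this sample-size artifact, and results
  from such designs should be read accordingly (or calibrated by
  permutation, which this package does not implement).
- **Asymptotic p at small pair counts.** Below a few hundred pairs the
  asymptotic tail is conservative in the mid-range; rejection rates at
  α = 0.05 remain near nominal, but mid-range p-values are biased upward.

## Synthetic data generator

The simulator emulates the target study shape: a candidate gene set of ~93
genes measured in two small groups (defaults 9 disease, 8 normal samples).
Correlated blocks use a single-factor model — within block *b* and group
*g*, x = √ρ·f + √(1−ρ)·ε with f, ε standard normal — so two same-block genes
have population correlation exactly ρ_bg, the block's per-group target. The
loading has closed form √ρ, which is why the factor model was chosen over
sampling from an explicit covariance matrix; targets must lie in [0, 1).
Genes outside every block are independent. A per-gene baseline (default 8,
roughly a log-intensity scale) and a global noise-scale multiplier make the
matrices look like normalized array data but do not affect any correlation.

What the generator does *not* emulate: probe-level effects and probe
multiplicity, batch structure, heavy-tailed or heteroskedastic noise,
mean–variance coupling, and the marginal distributions of any particular
real dataset. Passing tests on synthetic data therefore demonstrate the
statistics and the pipeline plumbing under a correctly specified factor
model, not robustness to real microarray artifacts.

Replicate runs derive child seeds from a base seed via NumPy's SeedSequence
(kept below 2³¹), making every experiment reproducible end to end; identical
configurations produce byte-identical pipeline artifacts (the run log
records versions and thresholds and contains no timestamps).

## Numerical and design choices

- **Probe collapsing** is the per-sample arithmetic mean of all probes
  mapped to a gene; probes without a mapping, or with an ambiguous
  multi-symbol mapping (`///`, `;`, `|` separators), are dropped and
  counted, avoiding double counting. Collapsing an already gene-level matrix
  with the identity map is a no-op.
- **Symbol matching** is case-insensitive exact comparison everywhere; no
  alias resolution, which would drag in an external database dependency.
- **Missing values** are rejected by default; an opt-in policy imputes the
  within-group gene mean (or drops the row). The default is strict because
  silent imputation changes correlations.
- **Zero-variance genes** make |r| undefined; the default is a hard error
  naming the offenders, because substituting 0 would distort the
  distribution the cutoff is extracted from. An `as-zero` flag exists for
  exploratory runs and logs what it did.
- **The strong-proportion test** is an exact one-sided binomial with p₀
  fixed at the normal group's observed strong proportion — the simplest
  reading of a two-group proportion comparison; a pooled two-proportion
  z-test is available as a method flag and agrees at any realistic effect
  size.
- **Fisher, binomial, BH-FDR** computations are delegated to
  scipy/statsmodels; the package's own contributions (survival-curve cutoff
  selection, classification, term-pair mapping, EASE variant, simulator)
  are implemented here and cross-checked in the tests against independent
  brute-force oracles (exhaustive threshold search, fixed-margin
  hypergeometric enumeration, direct PMF summation).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic or
printed-table inputs: exhaustive Fisher enumeration covers all 2×2 tables
with total ≤ 30 and all EASE margins with background ≤ 60; cutoff selection
is cross-validated against brute force on 200 random instances; the null
calibration uses 200 replicates of a 15-gene (105-pair) equal-group design
and the uniformity check 200 replicates at 93 genes; power uses 50
replicates of a 20-gene design with a planted 12-gene block (|r| = 0.8
vs 0.0, 30 samples per group). These sizes were chosen to give stable Monte
Carlo estimates at interactive runtimes.
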