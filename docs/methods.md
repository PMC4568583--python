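# Methods

## The pairwise 8-df chi-square scan

For SNPs stored as genotypes x, y ∈ {0, 1, 2} (additive coding: copies of
the alphabetically larger allele), the pair of a subject is encoded as
c = x + 3·y, a bijection from {0,1,2}² onto {0,…,8}. For each tested pair
of columns a 2 × 9 contingency table counts cases (row 0) and controls
(row 1) per code. Every cell is initialized to a pseudocount (default 1)
before counting, so every expected count is strictly positive; expected
counts are taken from the pseudocounted table's own marginals, and the
Pearson statistic is referred to the chi-square distribution with
(2−1)(9−1) = 8 degrees of freedom. The degrees of freedom are never
reduced when a genotype class happens to be absent — the pseudocounts make
the table non-degenerate by construction, and keeping df fixed keeps every
pair's p-value on the same scale.

Which pairs are tested is controlled by a single integer, the LD width:
pair (i, j) is eligible iff j − i > ldwidth. The default of 100 skips
column-adjacent SNPs, which on genotyping arrays tend to sit in strong
linkage disequilibrium and would otherwise flood the report with
physically linked, biologically redundant pairs. For simulated data with
independent columns the appropriate value is 0 (all pairs).

Significance is declared by Bonferroni correction at level α (default
0.05) over the number of pairs actually tested after the LD exclusion —
a correction should count the tests performed, not the hypothetical
C(m, 2); with ldwidth = 0 the two coincide. A pair is reported iff
p < τ strictly. The "repeatedly extract the minimum p-value until it
exceeds the threshold" formulation is implemented as the equivalent
single pass: filter p < τ, sort ascending (ties by column indices).

### Sensitivity to marginal effects, and the univariate filter

The 9-state table inherits each member SNP's marginal case/control signal:
a pair containing one strongly associated SNP will test significant even
if the second SNP is pure noise. Reported pairs are therefore filtered,
by default, to those whose members are *both* insignificant under the
single-SNP 2-df chi-square test (2 × 3 table, same pseudocount
convention) at the Bonferroni level α / m. The same convention
(pseudocounting the univariate table) is applied for symmetry; it is
configurable. What survives the filter is evidence of association that
exists only jointly.

### Numerics

Chi-square tail probabilities are computed as Q(df/2, x/2), the
regularized upper incomplete gamma function (`scipy.special.gammaincc`),
accurate to well past 10 significant digits down to p ≈ 1e-300. Beyond
the float64 floor p underflows to 0.0; ordering among such extreme pairs
is preserved by ranking on the statistic, which is strictly monotone in p
at fixed df, and `chi2_logsf` provides a finite log-scale tail (switching
to the asymptotic expansion of Q(a, z) once the direct evaluation
underflows) for reporting. The scan visits one reference column at a
time and tallies all of its partner tables in a single vectorized
histogram pass, giving exact agreement with the per-pair construction
(checked against an independent double-loop oracle) at O(n·m) peak memory.

## Input handling and quality control

Numeric GWAS text comes in two dialects — compact (one character per
genotype) and whitespace-separated — with cases stored before controls
and the case count supplied out of band. Two-letter nucleotide genotypes
are converted to 0/1/2 by counting the alphabetically larger of the (at
most two) letters observed per column; a monomorphic column maps to all
zeros, a deterministic convention for SNPs that are uninformative either
way. Optional QC mirrors standard GWAS cleaning: a Hardy–Weinberg 1-df
goodness-of-fit filter computed in controls only (so genuine associations
in cases are not mistaken for genotyping artefacts; default threshold
1e-6, the conventional stringent level), then removal of columns with
more than 1% missing entries. Residual missing genotypes in surviving
columns are imputed to the column mode — the least disruptive
deterministic choice, applied before testing. Both filters are off by
default for simulated data, which is generated clean.

## The simulator

Each replicate dataset has m columns (default 1000; the test suite and
acceptance runs use 200 to keep runtimes in seconds — results at 200
columns exercise the identical code paths, only the multiple-testing
burden is smaller). All non-interacting columns are independent draws
from Hardy–Weinberg proportions ((1−p)², 2p(1−p), p²) at the setting's
allele frequency. One designated pair — the first and last column by
default — is drawn jointly with disease status: genotype pairs (a, b)
are sampled from the HWE product, disease is assigned with probability
penetrance[a][b], and draws are accepted into the case or control stratum
until the requested totals (default balanced) are filled. This rejection
scheme reproduces retrospective case/control ascertainment with exact
class sizes. Replicates are reproducible individually: dataset d uses a
generator seeded by (master seed, d).

Four named penetrance families are built in. `multiplicative` has
pen[a][b] = base·(1+θ)^(a+b) capped at 1; `epistasis_m2` and
`classical_epistasis` share the dominant-threshold default pattern
(risk base + gap iff a ≥ 1 and b ≥ 1) and differ only by which published
benchmark table a user injects via `DiseaseModel`; `xor` elevates risk
iff exactly one locus carries a risk allele. Defaults are base risk 0.05
and gap 0.4 (the worked pattern 0.05/0.45). Away from allele frequency
0.5 all of these patterns induce some marginal effect at the interacting
loci; for the dominant-threshold models the marginal signal is strong
enough that the univariate filter removes the true pair at realistic
sample sizes, and for XOR it crosses the univariate Bonferroni threshold
around 1600 subjects. This is a property of single-gap threshold tables,
faithfully reflected in the evaluation output (the harness also reports
unfiltered power and the minimum-p recovery rate, which measure raw
detection); matching published benchmark power values exactly requires
the original calibrated tables, which the simulator accepts as input.

What the simulator does *not* emulate: linkage disequilibrium among the
null columns, population stratification, genotyping error and
missingness. Passing results therefore demonstrate the statistic's
behaviour under independent-SNP conditions, not robustness to confounded
real data.

## Evaluation

Over the replicates of one setting: power is the fraction of datasets in
which the true pair is reported (significant and filter-surviving);
false-positive rate is the fraction in which at least one reported pair
is not the true one; both are exact fractions of the replicate count.
For ROC curves each dataset is re-thresholded along a fixed descending
ladder of p-value cutoffs (1, 5e-6, 3e-6, 1e-6, 5e-7, 1e-7, 5e-8, 1e-8,
5e-9, 1e-9, 5e-10, 1e-10, 5e-11, 1e-11, 1e-29); the binary
(false-reported, true-detected) flags at each cutoff, anchored at (0,0)
and (1,1), form a polyline whose trapezoidal area is the dataset's AUC,
and the mean over datasets is reported. The univariate filter applies at
every rung of the ladder. An alternative single setting-level ROC built
from the power/FPR curves is available (`setting_auc`) as a cross-check;
the per-dataset construction is the default because the headline
definitions of power and FPR are themselves per-dataset.

A small diagnostic, `pair_label_correlation`, computes the Pearson
correlation between the encoded pair values and the 0 (case) / 1
(control) labels — a quick gauge of whether a statistically significant
pair carries any usable predictive signal; it returns no value when the
encoding is constant.

### Calibration checks

Under a constant-penetrance null the pipeline's false-positive rate at
the Bonferroni threshold stays at or below α; the pseudocounts shrink the
statistic slightly, making the extreme tail conservative. Null p-values
are approximately uniform: the systematic Kolmogorov–Smirnov deviation
from pseudocounting is ≈ 0.017 at 800 subjects. Because the C(m, 2)
pairs of one dataset share only m SNPs, a single dataset's empirical KS
statistic is dominated by dependence noise (measured spread ≈ 0.01–0.11
at m = 100); the uniformity tests therefore pool p-values across
independent replicate datasets, which shrinks the noise without touching
the systematic deviation being measured, and assert KS < 0.05.

## Limitations

* The 8-df test gains power against any joint deviation but pays an
  8-df penalty on pure two-way interactions; dedicated interaction
  statistics can be sharper in specific directions.
* The univariate filter is a hard two-sided gate: a true interacting pair
  whose loci carry even moderate marginal effects is discarded by design.
* Fixed-df testing with pseudocounts is slightly conservative at small n
  and for rare genotype classes.
* The scan is CPU-vectorized; very large studies (hundreds of thousands
  of SNPs) are tractable only because memory stays O(n·m), but wall-clock
  time grows with the full pair count.
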