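# Methods

This note documents the models, estimators and design choices behind
lactopop, and what the synthetic cohort does and does not emulate.

## Diversity statistics

All statistics operate on a haploid genotype matrix (sites × strains, allele
indices with −1 for missing). Nucleotide diversity π is the mean per-pair
count of differing sites divided by the surveyed length L; Watterson's
θ_W = S/(a_n L); Tajima's D uses the standard 1989 variance constants
computed from S and the mean pairwise difference. For n < 4 those constants
vanish identically, so D is reported as 0 when the numerator is exactly zero
and NaN otherwise, with a warning.

Missing-data convention: a site missing in either member of a pair is
skipped for that pair, and the denominator (L, or the genome length for
divergence) is **not** adjusted. This matches a divergence defined as
"differing positions over total genome size" and keeps π, θ_W and the
divergence matrix on one scale. L defaults to the reference genome length
for cohort-level statistics; with dense haploid calls the difference from a
callable-sites denominator is negligible, but heavily missing data will bias
all per-site statistics downward — a deliberate, documented trade-off.

F_ST is Hudson-style 1 − H_w/H_b, with H_w the mean pairwise differing-site
count within populations (the two populations averaged with equal weight)
and H_b the mean over between-population pairs. Negative estimates are
reported unclamped. Note that this pair-based form is not exactly zero for
two samples with identical allele frequencies — within-population pairs
exclude self-comparisons — but it is unbiased around zero for random splits
of a panmictic sample, which is how the tests check it.

## Distance trees

Neighbor joining uses the Q-criterion Q(i,j) = (r−2)d(i,j) − R_i − R_j with
branch lengths l_i = d(i,j)/2 + (R_i−R_j)/(2(r−2)). BioNJ differs only in
the reduction step: the new node's distances use the weight
λ = 1/2 + Σ_k(V_jk − V_ik) / (2(r−2)V_ij) (clamped to [0,1]) that minimizes
the variance of the reduced matrix, with pair variances taken proportional
to distances (the proportionality constant cancels). On an additive matrix
both methods are consistent and identical in topology; on an ultrametric
matrix λ = 1/2 and BioNJ reduces to classic NJ exactly.

Ties in Q are broken by the lexicographically smallest cluster-label pair
(a cluster is labelled by its smallest member leaf), making output
deterministic. Negative branch-length estimates are preserved by default
(`clamp_negative=True` floors them at 0) so tests can see the raw algorithm
output. Two-taxon input yields a single edge, represented as two half-length
edges around the structural seed node.

## Copy-number calling

Per-window depth is normalized by the genome-wide median (robust to the
CNVs themselves; GC correction is out of scope because the synthetic depth
carries no GC trend) and rounded to integer copy number at the baseline
ploidy. Under realistic overdispersion single-window rounding is noisy, so
the default caller stabilizes segmentation morphologically: baseline
interruptions shorter than `min_windows` (default 3) inside a deviating
stretch are closed, deviating blips shorter than `min_windows` are opened
away, and each surviving stretch takes the copy number rounded from its
mean ratio — segment means being far less noisy than windows. A stretch is
split where internal sub-run means still jump by ≥ 1.2 copies with both
sides at least 3 windows; the 1.2-copy threshold keeps selection-biased
sub-run means from splitting homogeneous segments, at the declared cost of
not resolving directly adjacent segments one copy apart. With
`reestimate=False` the caller is the plain round-merge-smooth pipeline.
Calls are invariant to uniform depth scaling by construction.

Segmental duplications are maximal runs (≥ 2 windows) of 10-kb-rebinned
ratio ≥ 1.5 at haploid baseline.

Gene assignment follows the half-overlap rule: a gene keeps the baseline
ploidy unless at least half of its length (inclusive) lies in
deviating-copy-number segments; it then takes the copy number of the single
deviating segment covering the largest fraction of the gene. Equal-coverage
ties resolve to the copy number closer to the ploidy, then to the leftmost
segment — conservative and deterministic. A per-base brute-force oracle of
the same rules verifies the interval implementation exactly on 1,000 random
instances.

The differential screen applies the two-sample Kolmogorov–Smirnov test to
each gene's copy numbers across the two groups and flags p < α (default
0.05, raw p-values; Benjamini–Hochberg adjustment is available but off by
default, matching a raw-p selection followed by manual inspection).

## Nonparametric tests

Both tests are self-contained. D is the supremum gap between the two
empirical CDFs evaluated at every pooled value, so ties are handled exactly.
U counts pairs with x > y plus half the ties. For n1+n2 ≤ 16 (configurable)
p-values are exact by enumerating all C(n1+n2, n1) group labelings — valid
under ties. Beyond that, KS uses the two-sided Kolmogorov series truncated
at terms < 1e-10, evaluated at the standard finite-sample argument
(√n_e + 0.12 + 0.11/√n_e)·D with n_e = n1 n2/(n1+n2); the bare √n_e·D form
is measurably conservative at cohort-scale n (empirical level ~0.035 at
n = 19 vs 22 against ~0.044 for the corrected form, nominal 0.05). MWU uses
a normal approximation with tie-corrected variance and a 0.5 continuity
correction. At n = 8 vs 8 the exact permutation distribution of D is
supported on multiples of 1/8, so mid-range p-values necessarily deviate
from any smooth asymptotic (up to ~0.14); in the decision-relevant tail
(exact p ≤ 0.25) the two modes agree within 0.05.

Significance stars follow the usual convention: * ≤ 0.05, ** ≤ 0.01,
*** ≤ 0.001.

## Growth quantification

OD600 curves are smoothed by LOESS: at each time point a degree-2 polynomial
is fitted by weighted least squares to the nearest ⌈span·N⌉ points with
tricube weights (span 0.45, no robustness iterations). Degree 2 reproduces
quadratic signals exactly and constants trivially. The growth ratio is, in
the default `top-rate-1h` mode, the maximum OD gain over sliding 60-min
windows on the sampling grid (7-point differences at the 10-min default;
windows truncated at the series end are excluded), condition over the
glucose reference; `max-od` instead takes the maximum smoothed OD after
subtracting the first-hour minimum as media baseline (configurable). Both
modes are computed in pipeline outputs because both definitions are in
common use and they answer slightly different questions (rate vs yield).
Both are scale-equivariant, so well-to-well scale factors cancel. Group
differences in the ratio are tested two-sided by Wilcoxon–Mann–Whitney.

## TE copy estimation

Breadth is the fraction of query positions with depth ≥ 5 (min_depth);
status is present at breadth ≥ 0.8, partial at ≥ 0.2, absent below — these
thresholds are declared conventions standing in for the by-eye inspection a
manual coverage review performs, and are configurable. Copies are estimated
as the 5%-per-tail trimmed mean depth over covered positions divided by the
strain's genome median depth; the trim resists pileups at element termini,
and the ratio form makes the estimate invariant to global depth scaling.

## Synthetic cohort

The neutral engine is a Kingman coalescent in units of 2N generations: with
k lineages the next merger is Exponential(k(k−1)/2), merging pairs are
uniform, and mutations fall on branches as a Poisson process of rate
θ_site·L/2 per unit branch length under infinite sites — so E[S] =
θ_site·L·a_n, exactly the scaling Watterson's estimator inverts, and the
generator doubles as the estimators' oracle.

Structure is a star backbone without migration: each clade is an
independent coalescent sample plus clade-private fixed differences drawn
Binomial(L, b_clade) at distinct genome positions. Expected between-clade
divergence is b_i + b_j + θ_i(1−1/n_i) + θ_j(1−1/n_j), the θ terms being
each side's expected lineage-private polymorphism.

Default cohort (41 strains, one 2.4-Mb chromosome, 300 genes of 6 kb on an
8-kb pitch):

| clade | size | θ_site | backbone b | role |
|-------|------|--------|-----------|------|
| dairy | 19 | 6×10⁻⁴ | 0.013 | low-diversity domesticated clade |
| wild1 | 6 | 5×10⁻³ | 0.015 | |
| wild2 | 6 | 5×10⁻³ | 0.018 | |
| asia  | 5 | 5×10⁻³ | 0.040 | one of the two most diverged clades |
| na2   | 5 | 5×10⁻³ | 0.045 | the other |

These place within-clade diversity at ~0.5% for wild clades and ~0.06% for
dairy, every between-clade divergence above 3%, and the asia–na2 pair near
9% with pairwise F_ST ≈ 0.95. Planted gene content: a three-gene presence
cluster carried only by the dairy clade (copy number 0 elsewhere, emulating
an introgressed lactose-utilization cluster) and ten dairy-restricted gene
gains (copy number 2).

Read depth per 1-kb window is gamma-Poisson (negative binomial) with mean
coverage 100 × local copy number and shape 20 (variance m + m²/20),
matching the overdispersion of real short-read depth; shape = ∞ gives the
Poisson limit. Growth curves are logistic, OD(t) = 0.1 + K/(1+e^{−r(t−t0)})
with K = 1, r = 0.004 min⁻¹ (early-phase doubling ≈ 2.9 h, realistic for a
slow-growing yeast in synthetic medium and the reason a 48-h assay is
needed), t0 = 12 h, sampled every 10 min for 48 h (289 points), with
homoscedastic Gaussian noise (sd 0.01 OD), a shared per-strain lognormal
factor on K (sd 0.05; inoculum/well effects that cancel in ratios) and a
per-strain-per-condition lognormal factor (sd 0.1; biological variability in
condition response that does not cancel). Default lactose effects scale
wild-strain (K, r) by (0.90, 1.0), (0.65, 0.9) and (0.40, 0.8) at 2/5/10%
lactose, so the dairy advantage strengthens with concentration. TE coverage
is Poisson with mean genome-median × copies over the covered fraction of
the query and exactly zero elsewhere.

What the generator does **not** emulate: recombination and migration
(within-clade genealogies are single trees; between-clade structure is
strictly tree-like), selection, indels, GC-dependent coverage bias, mapping
artifacts (multi-mapping, edge pileups), plate-reader drift or
heteroscedastic OD noise, and TE sequence divergence (coverage loss is
modelled only through the covered fraction). Passing recovery tests
therefore demonstrate correctness of the estimators and callers under the
stated stochastic models, not robustness to alignment- or
library-preparation artifacts.

## Problem sizes in the verification runs

The test suite and `scripts/acceptance.py` use: 500 coalescent replicates
(n = 20, θ_site = 0.01, L = 10 kb) for estimator recovery; 1,000 random
segment/gene instances for the copy-number rule oracle; 100 random 8-taxon
additive matrices for tree consistency; 2,000 null replicates at n = 19 vs
22 for test calibration; the default 41-strain cohort for structure
recovery and the differential screen; 100 growth simulations (82 curves
each) for the power check and 20 for the dose-response pattern; and 100
replicates per true copy number in {0, 1, 3, 10, 100} for TE estimation.
Planted depth segments in the recovery oracle span 8–12 windows with copy
numbers {0, 2, 3}, the scale of gene-sized and duplication-sized events the
caller is designed for; at the default overdispersion, exact-copy-number
recovery of 6-window events is limited by information (the segment mean's
rounding error), not by the segmentation.

## Known limitations

- Per-site statistics assume a fixed surveyed length; heavy missingness
  biases them downward (see above).
- The CNV caller does not resolve directly adjacent segments that differ by
  a single copy, and its breakpoints are window-resolution only.
- Asymptotic KS p-values are approximate for moderate n; exact mode is
  limited to n1+n2 ≤ 16 by enumeration cost.
- The BioNJ variance model Var ∝ d is the method's original first-order
  model; no higher-order variance tracking is attempted.
- Growth-ratio modes answer different questions (maximum rate vs yield) and
  can rank strains differently; outputs report both.
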