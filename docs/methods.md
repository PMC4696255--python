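# Methods

This note documents the models, conventions and numerical choices behind
`arraycascade`, in the order the pipeline applies them, together with
what the synthetic-data generator does and does not emulate.

## Input model

The unit of analysis is the *probe set* (one spot measuring one
transcript; several probe sets may map to one gene symbol). Input is a
probe × array matrix of raw linear intensities with one categorical
quality flag per value (the "good" code defaults to `G`), a per-probe
control indicator, optional gene symbols, and an array → group map with
exactly two groups for differential expression. Missing tokens
(`""`, `NA`, `NaN`, `null`, configurable) and unparseable numeric cells
both become missing values; the parse log counts them separately and
`rows_in = rows_parsed + rows_rejected` always holds. Probes without a
gene symbol participate in differential expression but are excluded from
enrichment (which operates on symbols).

## QC cascade

Six stages in fixed order; value-level stages mask cells to missing
(later imputed), probe-level stages shrink the matrix:

1. control probes dropped (unit: probe sets);
2. values with flag ≠ good masked (unit: values);
3. remaining negative values masked (a cell that is both poorly flagged
   and negative counts once, as poor — flag precedence);
4. rule A: probe set dropped if **any** group has ≥ 50 % missing values.
   With three arrays per group, a group with two missing values cannot
   support a group mean, which motivates the "any group" reading;
5. rule B (among survivors of A): probe set dropped if **no** group
   simultaneously has ≥ 50 % good-flagged values and ≥ 50 % values
   strictly above the intensity threshold (default 0, i.e. positivity —
   the threshold itself is configurable);
6. outliers: a value x is masked iff x/med > 4 or med/x > 4, where med is
   the probe's within-group median of non-missing values; strict
   inequality, computed on the raw linear scale (the stage precedes the
   log2 transform); groups with fewer than two observed values are
   skipped.

Each ledger row records the rule's unit, count and denominator.
Percentages are reported to one decimal against: raw cells
(probes × arrays before control removal) for stages 2–3; post-control
probes for stages 4–5; post-probe-filter cells for stage 6 and for the
residual-missing summary. These conventions make the standard 35,129 × 6
design print 21.2 % for a 7,177-probe rule-B removal and 0.6 %/0.8 % for
1,300/1,603 masked values, which is how they were chosen; they are
recorded per stage so any run can be audited line by line.

Conservation (`probes_in − controls − ruleA − ruleB = probes_out`) holds
by construction. The cascade is idempotent on its own output *provided
the outlier stage masks nothing new*: because outliers are masked after
the probe-set rules, a masked outlier can push a probe past rule A's
missingness threshold on a second pass. This is inherent to the stage
order, not a defect; a second pass is never part of the pipeline.

## PPCA imputation

Probabilistic PCA models a d-dimensional observation as
`y = Wz + μ + ε`, `z ~ N(0, I_q)`, `ε ~ N(0, σ²I_d)`. The arrays are the
variables (d = number of arrays, typically 6) and the probes the
observations — the transposed orientation would mean six observations of
a ~26k-dimensional variable, which is degenerate. This matches the
common missing-value-imputation convention for expression matrices, so
`W` is d × q and `μ` per-array.

The fit is EM with missing entries treated as latent, grouping rows by
missingness pattern for vectorization. The M-step updates (W, μ) jointly
via an augmented latent [z; 1] and then σ², which preserves the EM
ascent property; the observed-data log-likelihood is recorded each
iteration and asserted non-decreasing to 1e-8. Convergence is declared
when the relative change of the full parameter vector falls below `tol`
(default 1e-6); `max_iter` defaults to 1,000 and exhaustion returns
`converged=False` with a warning rather than an exception. σ² is floored
at 1e-12 of the data variance so that noise-free (e.g. exact rank-1)
inputs remain numerically stable and are completed exactly. W is
initialized from the seeded RNG; the seed is mandatory in the pipeline
config. `n_components` defaults to 2: with six arrays in two groups, one
component captures the shared intensity profile and a second the group
contrast; 2–3 is the feasible range and the value is exposed.

Within the pipeline, the stage order is impute → quantile normalize →
log2. The EM fit and imputation run on log2-transformed intensities —
single-channel intensities are log-normal, so the Gaussian factor model
holds on that scale, and a linear-scale fit could impute negative
intensities that would break the later log2 — and imputed values are
exponentiated back to linear before quantile normalization. Observed
cells are never modified, and the provenance mask marks exactly the
imputed cells.

## Quantile normalization and log2

Classic across-array quantile normalization: sort each column, replace
rank k by the mean of the k-th order statistics across columns, restore
order. Ties receive the mean of their rank-block values, so tied entries
stay tied. Afterwards every column shares an identical sorted vector
(exactly, absent ties). log2 then refuses any non-positive value,
identifying the offending cell — after QC and imputation this signals a
pipeline-order bug, not a data problem.

## Differential expression

Classical pooled-variance two-sample t (the equal-variance Student test;
Welch is available behind a flag), two-sided p from the t distribution
with n₁+n₂−2 df. Zero pooled variance yields t = 0, p = 1 and a
`degenerate` flag rather than NaN. BH step-up FDR is computed across all
tested probes. The fold change is computed from log2 group means,
`FC = 2^Δ` for Δ ≥ 0 and `−2^(−Δ)` otherwise (so |FC| ≥ 2 ⇔ |Δ| ≥ 1),
matching the signed reporting convention of microarray tables. Counts
are per probe set; duplicate probes for one gene are *not* collapsed.

Thresholds are inclusive (q ≤ 0.01, |FC| ≥ 2). The tier labels: L1 when
both hold; the low band is 1.5 < |FC| < 2 and/or 0.01 < q ≤ 0.05; L2
when exactly one of the L1 conditions holds and the other is in the low
band; L3 when both are in the low band. The L2/L3 split is an
interpolation from the two-band caption convention of heat-map figures
in this field; only the L1/low distinction is standard.

**Power at n = 3 per group.** With 4 df the t distribution has heavy
tails: even a true Δ = 2 (fourfold change) at per-value noise
σ = 0.25 log2 units gives a median two-sided p around 6×10⁻⁴, while the
BH threshold at q ≤ 0.01 with a 5 % spiked fraction sits near 5×10⁻⁴
(it scales with the discovered fraction, not the matrix size). Mean
sensitivity under these conditions is therefore ~0.15–0.25, as the
acceptance script reports honestly; only substantially larger effects
(|Δ| ≈ 3, i.e. 8-fold) are recovered near-completely. A known-variance
z-test would have essentially full power here — the gap is entirely the
cost of estimating the variance from six values. False-discovery
control, by contrast, is comfortably met in both the null and spiked
simulations.

## Clustering

Distance d = 1 − Pearson r between profiles (rows are clustered on the
same log2 matrix used for DE; no z-scoring is applied since Pearson
correlation is already location/scale invariant). Zero-variance rows are
rejected with their indices listed. Complete linkage (maximum pairwise
member distance) guarantees monotone merge heights, which is asserted on
every tree. The linkage computation is delegated to scipy and verified
in the test suite against a naive O(n³) agglomerative oracle; tie-breaks
follow scipy's deterministic ordering (oracle comparisons use tie-free
instances, ties having measure zero for continuous data). The heat-map
helper clusters the L1 probes on rows and the arrays on columns and
returns both trees plus the reordered matrix; trees serialize to Newick
with merge heights as branch lengths and parse back to the identical
topology.

## Enrichment and upstream regulators

Overrepresentation is the one-tailed hypergeometric upper tail
P(X ≥ hits) per gene set, with BH across sets. The EASE variant removes
one overlap member (floored at zero) before computing the tail — a
jackknife that can only weaken evidence, so EASE p ≥ Fisher p always.
The default universe is all annotated post-QC genes; symbols are
case-normalized and the query must lie in the universe.

The package ships no ontology or pathway content: users supply GMT gene
sets and a signed regulator→target edge list (licensing and version
drift make bundling third-party databases a liability). Annotation
clustering is deliberately minimal: sets are visited in order of
increasing EASE p, each unassigned set seeds a cluster and absorbs sets
whose query-restricted Jaccard similarity to the seed is ≥ 0.5 (the full
kappa-statistic machinery of annotation tools is out of scope). The
cluster score — the quantity actually tabulated in reports — is exact
given a clustering: the mean of −log10(EASE p) over members, with p
floored at 1e-300.

The upstream score `z = Σ expected·observed / √N` over a regulator's
significantly regulated targets (L1 by default, N ≥ 3 required) is an
intentionally unweighted directional statistic; it reproduces the
activation/inhibition logic of commercial causal-network tools, whose
proprietary edge weights make their published z values numerically
incomparable. Calls: activated at z ≥ 2, inhibited at z ≤ −2 (the
symmetric convention used in result tables in this field).

## qPCR quantification

Technical replicates are averaged per biological replicate first — the
three biological passages carry the degrees of freedom, the technical
duplicates only reduce measurement noise. Per replicate,
ΔCq = Cq(target) − mean(reference-gene Cq means); averaging the two
reference genes' Cq is identical to using the geometric mean of their
quantities (asserted in log space in the tests). ΔΔCq references the
calibrator group's mean ΔCq, so the calibrator's group-level RQ is
exactly 1. RQ = 2^−ΔΔCq; per-replicate RQs feed the SEM (computed over
biological replicates). RQ is invariant to adding a constant to every
Cq on the plate.

Amplification efficiency is estimated by OLS of Cq on log10 quantity
over ≥ 3 dilutions; `E% = 100·(10^(−1/slope) − 1)`, slope ≥ 0 is an
invalid curve. Efficiencies are reported alongside results but not
folded into RQ by default — the plain 2^−ΔΔCq is the method being
mirrored — with an efficiency-corrected mode ((1+E)^−ΔΔCq) behind a
flag. Group comparison is one-way ANOVA on per-replicate ΔCq, which for
two groups equals the two-sample t-test (F = t², asserted to 1e-10);
significance at p ≤ 0.05. Concordance with the array compares
sign(log2 RQ) with the sign of the array's log2 difference per shared
gene symbol.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
35,129 probe sets (1,280 controls) × 6 arrays in two groups of three;
probe baselines drawn from a log2-Gaussian hyperprior (mean 8, sd 1.5 —
typical single-channel dynamic range); per-value log2 noise sd 0.25;
a differential fraction (default 2.5 %) of non-control probes whose
treated-group mean shifts by a signed log2 effect (default: magnitude
1 + Exp(0.7), 30 % up — effects at least twofold, with the down-skew
seen in transfection studies); and per-value corruption at the rates the
QC ledger of the emulated design reports: 0.6 % poor flags, 0.8 %
negative values, 0.8 % missing, 0.3 % outliers (× or ÷ 6, safely beyond
the fourfold rule). When one cell draws several corruptions the
precedence missing > negative > poor > outlier resolves it, keeping the
ground-truth lists disjoint. All draws come from fixed substreams of one
global seed, so identical seeds give bit-identical output.

What it does **not** emulate: spatial/slide artifacts, batch or dye
effects (single-channel, single-batch design), probe-specific variance
heterogeneity, and the *clustering of bad flags on failing probes* —
corruption is i.i.d. across cells, so rule B removes almost nothing on
synthetic data, whereas on real arrays whole probes fail and rule B is
the dominant filter (~21 % of probes in the emulated study). Passing
tests on synthetic data therefore validate the rules' logic and
bookkeeping, not the real-world removal proportions. Likewise the qPCR
generator (Cq = base − log₁₊ₑ(quantity) + Gaussian noise, references at
quantity 1) validates the ΔΔCq arithmetic, not amplification chemistry.

## Degenerate inputs and tie-breaks

Zero pooled variance → p = 1 with a flag; zero-variance rows rejected
before correlation; all-missing rows/columns rejected before EM;
empty matrix after any QC stage aborts with the stage name; BH of an
empty vector is empty; enrichment of an empty query/universe is an
error; a flat standard curve is an invalid-curve error; regulators with
fewer than 3 usable targets are omitted, not scored.

## Known limitations

- Sensitivity at three arrays per group is intrinsically low at q ≤ 0.01
  for effects below ~8-fold (see the power paragraph); the pipeline
  reports what the data support rather than moderating variances
  (no empirical-Bayes shrinkage, by design — the plain Student test is
  the method being mirrored).
- The annotation-cluster step is a minimal overlap clustering, not a
  kappa-statistic reimplementation; scores are comparable only given the
  same clustering.
- The GEO adapter maps any series whose sample tables carry an ID/VALUE/
  flag layout; vendor-specific control-probe annotation must be supplied
  by the caller (control lists differ per platform).
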