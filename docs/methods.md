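# Methods

This note documents the models, parameters and numerical choices behind
`modulome`, what the synthetic world does and does not emulate, and the open
design decisions that were resolved while building the package.

## Preprocessing

The compendium is a log2 gene × sample matrix with five-column sample
metadata (project, condition, reference condition, replicate group). Two
operations precede decomposition:

**Replicate QC.** Within each replicate group of size ≥ 2, a sample is
removed when its *best* Pearson correlation to any other group member is
below `min_corr` (default 0.95, computed over all genes on the log2 scale).
Keying on the best rather than the mean correlation removes only true
outliers: one corrupt sample cannot drag down its intact partners. A group
whose members are all mutually below the cutoff is removed whole, with a
warning. Singleton groups are never touched. The filter runs before
centering; whether to apply it before or after log2 transformation is not
determinable from the workflow it mirrors — here log2 happens at load (via an
explicit flag for raw-intensity input) and QC operates on log2 values.

**Reference centering.** Per project, the mean expression of the project's
reference-condition samples is subtracted from every sample of that project,
gene by gene (arithmetic mean over all reference samples). Activities
downstream are therefore log2 fold changes against each project's control
state. Centering is idempotent in effect; a project whose reference condition
lost all samples in QC is rejected by name. Missing values are a load error,
never imputed — array summaries and the generator both produce complete
matrices.

## Robust ICA

FastICA (log-cosh contrast, full whitening — the scikit-learn implementation)
is run `n_runs = 100` times at convergence tolerance 1e-7 from per-run seeds
derived from one master seed. Genes are the observations and samples the
mixed signals, so the sources are gene-weight vectors, which sparse module
structure makes heavy-tailed and hence identifiable. Each run's weight
columns are rescaled to unit L2 norm (activities inversely, product
unchanged).

A run counts as *failed* only when it raises or returns non-finite output;
more than 50% failures abort. Hitting the iteration cap is recorded but the
solution is kept: at dimensions above the true source count the surplus
directions are Gaussian and have no FastICA fixed point, so every run "fails
to converge" in the library's sense while the signal components are perfectly
usable — the clustering stage exists precisely to discard the wandering
directions.

All run components are clustered with DBSCAN under d = 1 − |ρ| (eps 0.1,
min_samples 50 with 100 runs — a component must recur in at least half the
restarts to be robust; desk-scale runs shrink both numbers together).
Cluster members are sign-aligned to the first member in scan order, averaged,
re-normalized, and oriented so the largest-|weight| gene entry is positive.
Distances are compared with strict `<` inside DBSCAN and cluster order
follows the deterministic scan order, so outputs are bytewise reproducible
under a fixed master seed.

**Centroid activities.** Averaging run activities would mix incompatible
scalings, so A is recomputed in one ordinary least-squares fit of X on the
full centroid weight set. This guarantees X ≈ M·A for the final pair. A
consequence worth knowing: estimation error in M leaks a small fraction of
one component's activity into another's (cross-talk of order 1% here). With
a +20 planted activation this produces systematic offsets ≈ 0.1 activity
units in unshifted components — detectable by a distribution test if left
uncontrolled (see active-TRN below).

**Dimension selection.** The scan (defaults 20–215 step 5) records, per
dimension: robust components, those whose thresholded gene set has more than
one gene, and those reproduced (|ρ| > 0.7) at the largest scanned dimension.
The working dimension is one where the last two counts agree — beyond it,
added dimensions only fragment structure into single-gene components. Among
dimensions satisfying the equality, the one reproducing the *most* final
components wins (ties to the smallest): on compact data a pair of two-module
mixtures can satisfy the equality trivially, since a 50/50 mixture correlates
0.707 with its dominant module. The criterion lives in one function
(`select_dimension`) so it can be swapped.

## iModulon definition

The membership threshold of a component is found by iterative outlier
trimming: remove the largest-|weight| gene, test the remainder with the
D'Agostino–Pearson K² statistic, stop when the statistic falls below a
cutoff (default 50). The threshold is the midpoint between the last removed
and the largest surviving |weight|; if the full vector already passes, it is
max|weight| and the member set is empty — a *Null* iModulon, kept as a
first-class output (its activity can still track conditions). Under the null
the statistic is ~χ²(2), so the cutoff of 50 makes a pure-noise component
essentially never yield members (simulated null membership rate ≪ 10%),
while genuine module weights hold the statistic far above the cutoff until
every member is removed. The procedure is scale-equivariant; a constant
remainder (degenerate single-spike vectors) counts as passing. Vectors
shorter than 20 genes are rejected (the normality test is uncalibrated
below that).

Explained variance of a component subset S is 1 − ‖X − M_S·A_S‖²_F / ‖X‖²_F,
clipped below at zero. Naming is `IM_1..` / `Null_1..`, with a user-supplied
rename map for curated labels.

## Enrichment

For every (iModulon, regulator) pair, the overlap is scored one-sided
hypergeometrically against the gene universe of the expression matrix (not a
genome annotation, keeping results self-contained), with BH correction across
all pairs globally (per-iModulon correction was the alternative; global is
the stricter and simpler choice). Each iModulon's best hit is the
lowest-FDR row, ties broken by larger overlap then regulator name.
RR = |shared|/|regulon| and MR = |shared|/|iModulon| (0 for an empty
iModulon) are binned at threshold 0.6 into: both high → well-matched;
RR low, MR high → regulon subset (the iModulon sits mostly inside the
regulon); RR high, MR low → regulon discovery (the iModulon covers the
regulon plus new genes); both low → poorly-matched. The quadrant→name
mapping follows from the category names; it is a documented decision.
Combination enrichment over regulator pairs is deliberately excluded.

## Differential activity

Between two disjoint sample groups (each ≥ 2), per iModulon: difference of
group means, two-sided Welch t-test, BH across the k iModulons. A call
requires *both* |Δmean| > `activity_threshold` (default 5, in the activity
units fixed by unit-norm weight columns) and FDR < level (0.05 or 0.01).
The threshold applies to the difference of group means — applying it to a
fitted distribution statistic was the unstated alternative. The conjunctive
rule is conservative by construction; identical groups yield p = 1 (the
zero-variance t is mapped to 1).

## Active-TRN

The reference state (e.g. free-living aerobic) is supplied as condition ids,
never hard-coded. Per iModulon, a two-sample Kolmogorov–Smirnov test compares
reference and target activity values; selection requires p < alpha (default
0.05) *and* a higher target mean — KS is location-agnostic, so the mean
conjunct operationalizes "increase". An optional switch (`ks_fdr`) applies
BH across the iModulons before thresholding; the uncorrected rule is the
default. The end-to-end analyses here enable the switch: with ~20 parallel
screens and exact edge-set recovery demanded, the OLS cross-talk offsets
described above occasionally reach the borderline exact-KS quantile
(6 vs 6 samples, D = 5/6, p = 0.026) and multiplicity control is the
statistically appropriate remedy.

An edge (R → g) of the draft TRN enters the active network iff the *target*
g belongs to an activated iModulon; regulator membership is not required
(regulators appear as inactive "grey" nodes when only their targets are
active). iModulon genes are regulated targets by construction, which is why
inclusion keys on targets; whether edges should also follow activated
regulators is not determinable from the source workflow and is deliberately
not done. Nodes and edges are emitted in sorted order; the edge set is
monotone in the activated set.

## Synthetic world

`generate_compendium` emulates what the decomposition assumes: log2 values;
conditions with 2–4 replicates sharing one true activity column (noise enters
only at the expression level, so replicate correlations are high);
round-robin project assignment with the first condition of each project as
reference; k sparse modules with condition-dependent activities; additive
Gaussian noise; a ground-truth TRN with one regulator per module
(targets = members) plus three planted mismatches (a superset regulon, a
partial regulon, a decoy) so all four overlap categories occur; and a module
overlap (modules 0/1 share 10 genes) so recovery is exercised on
non-disjoint membership.

Defaults and why:

- 2000 genes, 30 conditions × 3 replicates, 2 projects, 20 modules × 50
  genes — the stated desk-scale world for parameter-recovery testing.
- member weights sign · (0.5 + Exp(1)), unit-normalized: heavy-tailed
  (ICA-identifiable) with no near-zero members, so membership recovery is a
  well-posed target; the largest drawn magnitude is boosted ×1.5 into a clear
  flagship gene, making the sign-orientation convention stable under
  estimation error instead of being decided by a near-tie between
  opposite-signed top weights; columns are emitted in the canonical
  orientation so planted activity shifts keep their sign through recovery.
- activity sd 20 per condition; planted activations +20 for modules 2–4 in
  the last two conditions, which copy their project reference's baseline
  activities first — the activation is then the *only* systematic difference
  between target and reference states, exactly the contrast the
  differential stages are meant to detect. The activity scale also keeps the
  OLS cross-talk (∝ shift/activity-scale) below the activity noise floor.
- noise sd 0.1: replicate correlations ≈ 0.99, comfortably above the 0.95 QC
  cutoff for every condition. A noisier world (sd ≈ 0.3) drops low-signal
  conditions stochastically, which is realistic but makes downstream stages
  fail on unlucky seeds for structural rather than statistical reasons; the
  retained real compendium is likewise post-QC high quality.

What the generator does **not** emulate: probe-level microarray artifacts,
batch effects, hybridization chemistry, non-Gaussian measurement noise,
regulon overlap beyond the planted cases, or activity correlations between
modules. A green recovery test therefore establishes that the pipeline's
statistics behave as designed on data satisfying its model assumptions — not
that the biological compendium satisfies them.

## Determinism

Every stochastic operation takes an explicit seed; one master seed derives
per-run ICA seeds through a seeded generator. Identical configuration and
master seed reproduce all outputs bytewise (tested). DBSCAN, centroid
averaging, naming, and all emitted orderings are deterministic.

## Known limitations

- OLS activity cross-talk (above) bounds how small an activity change the
  KS screen can certify; sharper activity estimators (masked or robust
  regression) were deliberately not substituted for the standard procedure.
- The dimension-scan criterion assumes the scan reaches dimensions above the
  true source count; scanning entirely below it returns the gap-minimizing
  dimension with no warning beyond the diagnostics table.
- The enrichment universe is the expression matrix; regulons citing genes
  outside it are rejected rather than silently clipped.
- Welch's t with 2–4 replicates per group has limited power; the
  activity-threshold conjunct dominates in that regime by design.
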