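# Methods

This note documents the statistical model, the simulator, the numerical
choices, and the places where the design was genuinely open.

## 1. Mixture model and filtering threshold

Per-ASV abundance is the total read count over the samples of one sequencing
run; the model operates on x = log10(total reads), so every retained ASV
must have at least one read (zero-total rows are dropped at input).  The
density is a k-component univariate Gaussian mixture fitted by EM.
Components are reported in canonical order (means ascending).  The E step is
computed in log space; the M step uses weighted maximum-likelihood updates
(divide-by-n variances).  Fitting per run, rather than per sample, is
deliberate: single samples rarely contain enough ASVs to resolve the
abundance modes, and the command-line `all` subcommand accepts a
sample-to-run grouping so each run gets its own fit and threshold.

The threshold is the upper one-sided confidence limit (default level 0.95)
of the component with the second-largest mean: t = μ + z(level)·σ for that
component.  The uppermost component is interpreted as true variants, so this
limit bounds the error-abundance distribution from above; raising `level`
makes filtering more stringent.  Filtering removes ASVs strictly below t —
an ASV sitting exactly at the threshold is retained.  A k = 1 fit defines no
threshold; callers get an explicit error (library) or a warning and an
unfiltered pass-through (CLI).

Numerical choices:

* **Initialisation.** Deterministic quantile slicing (sorted data split into
  k contiguous blocks, per-block mean/SD, equal weights) plus `restarts`
  (default 5) random starts whose means are sampled observations; the best
  final log-likelihood wins.  The default path is therefore reproducible
  even without a seed.
* **Convergence.** Relative log-likelihood change below 1e-8 or 1000
  iterations.  The per-iteration log-likelihood is non-decreasing (the EM
  guarantee) and the reported value always equals a direct evaluation of the
  mixture density at the returned parameters.
* **SD floor.** Component SDs are bounded below by 0.1 log10 units
  (`sd_floor`).  Read counts are discrete: a large fraction of artefact ASVs
  have exactly one read, i.e. the identical value log10(1) = 0, and with a
  looser floor the likelihood is maximised by a spike component sitting on
  that atom, which makes the threshold meaningless (it degenerates to ~0).
  One third of the spacing between the 1-read and 2-read atoms (log10 2 ≈
  0.30) suppresses those spikes while leaving real abundance modes — whose
  spread is several times larger — unconstrained.  The floor is a parameter;
  analyses of continuous data can lower it.
* **Degenerate inputs.** Fewer than 5k observations, or all-equal data with
  k ≥ 2, raise explicit errors instead of returning a meaningless fit.

## 2. Choosing k

* **Two-fold cross-validation** (`cv_loglik`): per repeat, a seeded random
  split into halves; each half is fitted and scored on the other; all
  half-scores are averaged per k.  The chosen k is the smallest one within
  1.0 log-likelihood units of the maximum — a parsimony tie-break, since
  held-out curves are often flat past the true k.  Folds on which EM fails
  are dropped with a warning.
* **Sequential parametric bootstrap** (`bootstrap_seq_test`): for k = 1, 2,
  ... the statistic T = 2(ℓ_{k+1} − ℓ_k) is referred to B (default 100)
  datasets simulated from the fitted k model and refitted under both
  hypotheses; p = (1 + #{T_b ≥ T})/(B + 1), so p is never 0 and never below
  1/(B+1).  Testing stops at the first p > α.  Replicates whose refits fail
  to converge are redrawn (at most 10 times, then scored T_b = +∞, which
  can only inflate p — conservative).  The observed statistic and the
  bootstrap null are computed with an identical, deliberately light EM
  search budget (1 random restart beyond the deterministic quantile start,
  tol 1e-6): a deeper search applied to the observed data alone would bias
  T upward relative to T_b and inflate the type-I error, which we verified
  empirically before making the budgets symmetric.
* The CLI additionally accepts a forced k (`--k`), recorded as method
  "visual-override", because practitioners routinely confirm k against the
  abundance histogram.

On real denoised datasets both procedures tend to agree with visual
inspection (k = 2–4).  On the simulator's raw output the error distribution
is genuinely multimodal, so cross-validation often prefers k = 4–5; the
threshold is robust to this because it always uses the second-uppermost
component.

## 3. The eDNA metabarcoding simulator

The generator emulates one PCR-amplified, multinomially sequenced sample:

1. **Template pool.** `n_true` = 100 unique random variants of length 160 bp
   with an exact G+C count of round(0.56·160) = 90 (the GC constraint is
   per-sequence exact; positions random).  Initial proportions a_i0 are
   symmetric Dirichlet(γ = 1); absolute copies A_i0 = floor(10000·a_i0).
2. **Amplification.** Each cycle j, sequence i gains proportional abundance
   a'_ij = a_{i,j−1}·p_i·ε / Σa, with p_i ~ Beta(5, 5) (mean 0.5, SD 0.15)
   fixed per sequence and ε ~ Lognormal(0, 0.05²) drawn independently per
   sequence per cycle.  Absolute copies gain A'_ij = floor(A_{i,j−1}·p_i·ε).
3. **Artefacts.** A per-cycle substitution rate ξ ~ Beta(36, 3·10⁶) (mean
   1.2e-5 — a high-fidelity polymerase) converts E'_ij = floor(L·A'_ij·ξ)
   of the new copies of template i into single-substitution artefacts.  Each
   artefact copy gets a uniform random position and the transition at that
   position (A↔G, C↔T; transversions are not modelled); copies share the
   proportional abundance L·a'_ij·ξ equally and inherit p_i.  Artefacts join
   the pool and are amplified — and further mutated — in later cycles.
4. **Dereplication.** Sequences are keyed by (template, set of positions
   carrying an odd number of transitions); transitions are involutions, so
   identical mutations and reverse mutations merge exactly, without
   materialising strings until output.
5. **Sequencing.** After 35 cycles, R ~ Multinomial(a/Σa, N) with
   N = 1.5·10⁶; sequences with zero reads are unobserved.  ΣR = N exactly.

**The absolute-abundance recursion.**  Two bookkeepings coexist by design:
proportional abundances a (with the Σa normaliser, which damps growth as the
pool saturates — the competitive-PCR reading) shape the sequenced
composition, while absolute copy numbers A discretise artefact occurrence.
A is deliberately un-normalised (A' = floor(A·p·ε), exponential growth):
this is the reading under which the per-cycle artefact counts are integers
of the right order, and at the default settings it reproduces the intended
behaviour — across seeded replicates the simulation yields ≈ 2.8·10³ ± 1.5·10²
unique erroneous sequences, a mean of ≈ 2 reads per erroneous sequence, and
≈ 1.5·10⁴ reads per true sequence (the test suite and
`scripts/acceptance.py` recompute these).  Normalising A by Σa as well
(`growth="competitive"`), or applying the floor literally to the product of
absolute and proportional abundance (`growth="literal"`), freezes the
integer artefact counts at zero at this pool size; both readings are kept as
config switches for comparison but are not defaults.

What the simulator does *not* model: insertions, deletions and chimaeras;
more than one substitution per copy per cycle; sequencing error;
multi-sample or multi-species pools; primer/denoising pipelines.  Passing
tests on simulated data therefore show that the mixture threshold separates
abundance modes generated by this PCR-error mechanism — not that it corrects
every artefact class in real data (chimaeras in particular can be abundant).

## 4. Filters

* `abundance_filter`: retain iff log10(total) ≥ t; order preserving,
  idempotent, monotone in t.
* `detection_rate_filter`: the replicate-based comparison method — an ASV is
  "detected" in a replicate if it has ≥ 1 read there, and is retained iff
  its detection rate ≥ `min_rate` (default 1.0, i.e. present in all
  replicates).
* `confusion_counts` cross-tabulates either filter against truth labels
  (available from the simulator), counting retained/removed × true/false.

## 5. Problem sizes used in the shipped checks

The test suite runs the simulator at full study scale but with 20 seeded
replicates, and `scripts/acceptance.py` uses 30 (both well past the point
where the replicate means stabilise); bootstrap calibration checks use
n = 150–500 observations with B = 19–39 replicates, which keeps the add-one
p-value resolution (1/20–1/40) compatible with the α = 0.05 decisions being
checked.  These sizes are package defaults chosen to make the checks quick
to rerun; the statistical conclusions do not change at larger B or more
replicates.

## 6. Known limitations

* The Gaussian shape on the log10 scale is an approximation; the singleton
  atom and the discreteness of small counts are handled by the SD floor, not
  modelled.
* The threshold assumes the uppermost component is entirely true variants;
  rare true haplotypes whose abundance falls inside the error modes are
  removed (a false-negative risk inherent to abundance filtering).
* Mixture-order selection on strongly multimodal error distributions is
  unstable between k and k+1; the threshold rule (second-uppermost
  component) absorbs most of that instability, but reports always include
  the full CV curve or p-value ladder so the choice can be audited.
* Taxon-stratified filtering is out of scope: subset the table per taxon
  first if that is wanted.
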