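# Methods

## Model

For sample i ∈ (1..N) and region r ∈ (1..R), the observed region-level
methylation fraction is

    Y_ir = Σ_k π_ik [ (1 − Z_rk) δ0_r + Z_rk δ1_r ] + ε_ir

with constraints π_ik ≥ 0 and Σ_k π_ik = 1.  Z ∈ {0,1}^{R×K} encodes
whether region r is methylated in cell type k; it must have full
column rank K or the proportions are not identifiable (the package
refuses rank-deficient Z and names the dependent cell-type columns).
The state effects are region-indexed Gaussian random effects shared by
all samples measured on one platform,

    δ0 ~ N(α0·1, σ0² I_R),   δ1 ~ N(α1·1, σ1² I_R),

and ε_ir ~ N(0, τ²) is measurement error.  α0/α1 are the levels at
which the platform renders the unmethylated/methylated state (unitless
fractions in [0,1]), σ0²/σ1² the region-to-region spread of those
levels, τ² the residual noise variance.  Covariances follow from the
shared δ's: observations are coupled across samples *within* a region
and independent across regions; the case r ≠ r′, i = i′ has covariance
zero (independent region effects, independent noise).

Writing W0_ri = Σ_k π_ik (1 − Z_rk) and W1_ri = Σ_k π_ik Z_rk
(W0 + W1 = 1 on the simplex), region r's covariance block over its
observed samples is

    C_r = τ² I + σ0² w0 w0ᵀ + σ1² w1 w1ᵀ.

## Estimation

**Initialisation.**  Over regions unmethylated in all K cell types
(the R0 set), E(Y_ir) = α0 regardless of π, and by Jensen's inequality
Var(Y_ir) ≤ σ0² + τ².  The initial α0 is the mean over samples of the
per-sample R0-mean; the initial σ0² is the mean over samples of the
per-sample R0-variance (denominator R0 − 1), treating the variance
bound as an equality under the assumption that τ² is small — this
overstates σ0² by at most τ², which the subsequent EM iterations
correct.  R1 (all-methylated rows) gives α1, σ1² symmetrically.  If Z
lacks at least two all-zero or all-one rows (a Z built purely from
one-vs-rest DMRs cannot contain them), the rows whose state row-sums
are closest to 0 or K stand in, with a warning; the initialisation is
then biased toward the bulk mixture mean but the EM recovers.  π(0)
comes from the simplex-constrained projection on
X(0) = (1−Z)α0 + Zα1, and τ²(0) is the mean squared residual.

**E-step.**  δ0 and δ1 are conditioned on the full stacked data.
Because the covariance couples samples only within a region, the
conditional moments decompose per region:

    E[δ0_r | Y]   = α0 + σ0² w0ᵀ C_r⁻¹ e_r
    Var[δ0_r | Y] = σ0² − σ0⁴ w0ᵀ C_r⁻¹ w0

with e_r the observed residual vector against (Xπ)_r, and symmetric
expressions for δ1.  C_r⁻¹ is applied through the rank-2 Woodbury
identity written with V = [√σ0² w0, √σ1² w1] so that zero variances
need no special-casing; cost is O(N) per region, and the test suite
enforces exact agreement (≤1e-8, observed ~1e-14) with dense
joint-normal conditioning on instances up to RN + R = 60, with and
without missing entries.  Regions with no observed sample fall back to
the prior moments.

**M-step.**  With T1 = Σ_r E[δ0_r|Y], T3 = Σ_r E[δ0_r²|Y] (and T2, T4
for δ1), the complete-data MLEs are α0 = T1/R, σ0² = T3/R − α0², etc.
Variances are floored at 1e-12 to keep every C_r positive definite.
Each sample's π is then re-estimated by the simplex-constrained QP
against the posterior-mean design X = (1−Z)E[δ0|Y] + ZE[δ1|Y], and
τ² is the mean squared residual of that fit.  Because the π update
plugs in posterior means and ignores the posterior covariance terms of
the expected complete-data log-likelihood, the observed-data
log-likelihood is not guaranteed to increase monotonically; decreases
larger than 1e-6 are logged (in practice they are ~1e-2 at most and
shrink as the fit stabilises), never raised.

**Convergence.**  Iterations stop when the maximum relative change
over (α0, α1, σ0², σ1², τ²) and the maximum absolute change over π
both fall below `tol` (default 1e-4), or after `max_iter` (default
100) iterations, in which case the result is returned with
`converged=False` rather than raising.  On near-noiseless data the
variance parameters decay geometrically toward the floor and the
relative-change criterion can stay unmet for hundreds of iterations
while π is already stable to ~1e-8; callers who care only about
compositions can ignore the flag or loosen `tol`.  The fit contains no
randomness: rerunning is bit-identical.

**Quadratic programming.**  min ½πᵀQπ + aᵀπ with Q = XᵀX, a = −XᵀY_i,
subject to Σπ = 1 (optional) and π ≥ 0 (optional).  K is the number of
cell types (six for whole blood), so the QP is solved exactly by
active-set enumeration: every subset of the bound constraints is tried
in order of increasing size, the equality-constrained KKT system is
solved, and the first primal- and dual-feasible point (KKT residual
≤ 1e-8) is returned — for convex Q any KKT point is the global
minimum.  A symmetric ridge of 1e-10·trace(Q)/K is added if Q is
numerically singular.  The empty active set succeeds immediately for
interior solutions, which dominate in practice.  Cost is O(2^K K³);
the solver is intended for K ≤ ~15.

**Reference-based baseline.**  `houseman_estimate` intersects each
sample's measured CpGs with the reference profile's CpGs and solves
the same QP at CpG level with non-negativity only — proportions are
deliberately not rescaled to one so unaccounted cell types can absorb
mass (`sum_to_one=True` restores the simplex).  A sample whose
intersection falls below K CpGs is an error; this is precisely the
failure mode that motivates the region-level model on new platforms.

## Region discovery (Z construction)

The one-vs-rest DMR search replaces a smoothing/permutation-based
bump-hunting procedure with a deterministic, self-contained
equivalent: downstream estimation needs only a valid full-rank Z, not
calibrated family-wise error rates.  For each cell type the per-CpG
effect is the mean beta of that type minus the mean of all other
samples (identical to the two-group least-squares slope up to sign
convention), with a pooled-variance t-like score reported alongside.
Candidate regions are maximal runs of consecutive CpGs with |effect| ≥
`effect_cutoff` (default 0.3), equal sign, and inter-CpG gaps ≤
`max_gap` (default 500 bp).  Runs from all contrasts are ranked by
(CpG count, mean |effect|) and accepted greedily subject to pairwise
non-overlap — so accepted regions can be modelled as independent —
and a per-contrast cap (default 20).  Runs with fewer than `min_cpgs`
(default 2) CpGs are kept only when a contrast has nothing longer, or
when `include_single_cpgs` is set.  Z_rk is 1 where cell type k's mean
reference beta over the region exceeds `state_threshold` (default 0.5
— the natural dichotomisation for states that are required to be
clearly methylated or unmethylated).  All defaults are exposed; none
were derived from a specific dataset.

## Synthetic data

`simulate_mixtures` draws, per platform, δ0*, δ1* from the platform's
state distributions (clipped to [0,1]), assembles X* = (1−Z)δ0* +
Zδ1*, and generates Y = X*πᵀ + ε with π_i ~ Dirichlet(2,…,2) and
ε_ir ~ N(0, τ²).  The same π and the same ε are reused on every
platform, so platforms differ only through their state effects — the
bias mechanism under study (a flag redraws ε per platform).  Default
platform constants: array-like α* = (0.15, 0.85), sequencing-like
α* = (0.05, 0.95), both σ*² = 0.0025, τ = 0.03, N = 200 samples,
n_sims = 100 replicates; the study harness in the tests and the
acceptance script runs a scaled-down design (N = 50, 20 replicates)
that reproduces the same qualitative contrasts in seconds per fit.
Values are clipped to [0,1] and the clipped fraction is reported
(≈0.1% on the array platform, ≈2–3% on the sequencing platform, where
the unmethylated state sits one SD from the boundary; the induced bias
on α̂0 is ≈0.004, well inside the recovery tolerances).  The default
210-region Z contains ~6% all-unmethylated and ~6% all-methylated
consensus rows plus balanced one-vs-rest rows per cell type, mirroring
a whole-blood region set at the scale of a real sorted-cell screen.

What the generator does *not* emulate: read-depth-dependent
(binomial/beta-binomial) noise in sequencing data, spatially
correlated noise along the genome, batch effects within a platform,
and unaccounted cell types.  Passing tests therefore demonstrate
correctness of the estimation machinery under the stated model, not
robustness to those real-data phenomena.

`simulate_sorted_reference` generates the sorted-cell fixture used by
the DMR tests: 5-CpG blocks with between-group difference 0.8 against
within-group noise SD 0.05 (a 16:1 effect:SD ratio; recovery of exact
block boundaries is required in tests at ≥2:1), plus consensus blocks
and isolated background CpGs.  The packaged
`data/synthetic_wholeblood_regions.bed` fixture is the output of
`build_z_matrix` on this synthetic reference (fixed seed) and is
labelled synthetic accordingly.

## Assessment

RMSE_k = sqrt( (1/N) Σ_i (π̂_ik − π_ik)² ), averaged over cell types
to give the mean RMSE per replicate; the study harness reports
per-(platform, method) medians and IQRs over replicates.  Under the
default scaled-down design the latent-state model attains median mean
RMSE ≈ 0.01 on both platforms, while the reference-based baseline
moves from ≈ 0.007 on its own platform to ≈ 0.03 under cross-platform
mismatch.

## Numerical choices and edge cases

- Coordinates are 0-based half-open throughout; Bismark coverage input
  (1-based) is converted on read.  A CpG at position == region end is
  excluded, at position == start included.
- Region summaries: unweighted CpG mean for array input, pooled count
  ratio Σmeth/Σ(meth+unmeth) for sequencing input (identical when all
  CpGs have equal coverage).  Zero-coverage CpGs and uncovered regions
  are missing, never zero.
- Missing Y entries are excluded per sample from the QP rows and per
  region from the covariance blocks; samples with under 80%
  non-missing regions trigger a warning, samples with fewer than K
  usable regions an error.
- Beta values outside [0,1] by more than 1e-9 are a validation error
  unless clamping is requested; writers emit %.17g so beta tables
  round-trip bit-exactly.
- Ties in DMR ranking break deterministically by (chromosome, start,
  cell type, direction).

## Known limitations

- The Gaussian random-effect and noise assumptions are a practical
  approximation; count data would call for a binomial-type likelihood,
  which is out of scope here.
- The π update is a conditional-mean plug-in, so the EM is not a
  strict ascent algorithm (decreases are logged; see above).
- No standard errors or inference on π̂ are provided.
- The DMR search does not smooth and does not control family-wise
  error; it is a deterministic stand-in adequate for constructing Z,
  not a general-purpose DMR caller.
- σ0², σ1² estimates at initialisation absorb τ²; with large
  measurement error the first iterations start from inflated state
  variances.
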