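# Methods

This note documents the models implemented in `csfmotion`, the numerical
choices behind them, what the synthetic generator does and does not
emulate, and the design decisions taken where more than one defensible
option existed.

## Decay model and fitting

The trace DWI signal in a voxel is modeled as
`S(b) = S0·exp(−b·D) + N_floor`, with bounds D ∈ [0, 0.05] mm²/s,
S0 ∈ (0, 2·max S], N_floor ∈ [0, max S]. The floor term absorbs the Rician
magnitude-noise plateau; the "standard" model omits it and is kept for the
ablation comparison. The two models are nested, so on any curve the
floor model's residual sum of squares cannot exceed the standard model's at
the optimum; `fit_both_models` enforces that ordering by construction
(re-profiling the floor model at the standard model's D if the independent
searches ever disagree).

**Trace construction.** For b > 0 the voxelwise geometric mean over the six
diffusion directions (the trace-weighted convention); b = 0 volumes are
averaged arithmetically. An arithmetic-mean variant is available
(`trace_signal_arithmetic`, config `dwi.trace: arithmetic`) because either
convention is defensible; on the isotropic phantom they agree in
expectation.

**Optimizer.** Bounded trust-region least squares (`scipy` trf) with
analytic Jacobian. Initialization: N_floor₀ = min(S) clipped at 0,
S0₀ = max(S) − N_floor₀, D₀ from the log-linear slope of (S − N_floor₀)
over b ≤ 300 s/mm². Because the profiled objective in D develops a narrow
secondary basin at very small D (where exp(−bD) is nearly collinear with
the constant column), the optimizer start is chosen as the better of the
analytic init and a variable-projection scan over a D grid that is fine
(1e-4 spacing) below 0.004 mm²/s and coarser (~1e-3) above. After the
trust-region run, (S0, N_floor) are re-solved exactly by closed-form
nonnegative linear least squares at the fitted D and D is polished by a
bounded 1-D Brent refinement of the profiled objective (xatol 1e-13).
Noiseless curves are recovered to better than 1e-7 relative; the fitted
residual never exceeds a dense 200×200 (D, N_floor) grid search with
profiled S0 (tested on random noisy curves).

**Degenerate inputs.** Exactly constant curves have a flat objective in D;
the tie-break reports D = 0 with the constant folded into S0 + N_floor
(N_floor at its initialization, i.e. the constant) and the fit flagged
degenerate. Voxels with non-finite or all-zero curves are skipped and
counted, never errored. Non-convergence returns the best iterate with
`converged=False`.

**Diagnostics.** rss; R² = 1 − rss/TSS (defined as 1.0 for an exact fit to
a constant curve); rmse = sqrt(rss/n) so fit quality is comparable across
b-value subsets of different size; AIC in the least-squares form
n·ln(rss/n) + 2k (k = free parameters). The AIC variant matters only for
within-package comparisons, where the floor model's extra parameter is
penalized explicitly.

**Noise estimate.** In a region where true signal is fully suppressed (the
highest-b raw magnitude image inside cistern fluid) the magnitude is
Rayleigh distributed. The estimator is sigma = median(S)/sqrt(2·ln 2) — the
median-based constant, chosen over the mean-based sqrt(π/2) because the
median is robust to residual signal in the region and the matching constant
makes the estimator consistent (an estimator dividing the median by the
Rayleigh *mean* factor carries a systematic −6% bias). The implied floor
level sigma·sqrt(π/2) (the Rayleigh mean) is reported alongside and is used
only descriptively; N_floor always remains a free fitted parameter. The
estimate is taken on a raw high-b volume, not the direction-averaged trace,
whose noise law is altered by the averaging.

**Head motion.** The synthetic data are motion-free; a pass-through hook
occupies the place where a real-data pipeline would register volumes.
Registration, distortion and eddy-current correction are out of scope.

## ASL quantification

Perfusion is carried internally in mL g⁻¹ s⁻¹ (the printed unit
mL/100 g/min divided by 6000) so that f/λ in the apparent-T1 relation
shares units with 1/T1; conversion happens only at interfaces. The readout
time in the difference-signal model is taken as t = τ + PLD, so the
post-bolus exponential is exp(−(PLD_eff − Δt)/T1,app) — the standard
reading of the third-component model. Slice-delay correction assumes
ascending 2-D acquisition, PLD_eff = PLD + slice_index·slice_time; an
arbitrary acquisition order can be supplied as a permutation vector
(`ASLParams.slice_order`).

**Surround subtraction.** Each interior volume is differenced against the
mean of its two temporal neighbors (the other condition), oriented so
ΔM = control − label. A drift common to both conditions and linear in time
cancels exactly for interior volumes but not for one-sided edge
differences, so the default drops the two edge volumes from the average
(counted in the result); one-sided edge handling is available via
`include_edges=True`. A single control/label pair falls back to plain
subtraction, flagged.

**Inversion.** The forward curve ΔM(f) is checked numerically for strict
monotonicity on [0, 300] mL/100 g/min before bracketed (Brent) root
finding to |Δf| < 1e-4; a bracketed method was chosen over an analytic
approximation because monotonicity makes it exact and the per-voxel cost is
negligible. Negative ΔM voxels (inevitable under noise) clamp to f = 0 and
are counted; ΔM above the f = 300 forward value reports f at the bound with
an out-of-range flag. M0,blood is taken voxelwise from the M0 volume scaled
by a configurable blood-water factor (default 1), and voxels below
10 mL/100 g/min are excluded from the valid mask. Quantified values are
apparent perfusion: at short echo time the choroid plexus signal mixes
perfusion with blood–CSF water exchange, which this model does not separate.

## Synthetic generator

The generator's role is to produce data whose *statistics* match the
analysis assumptions, not anatomically realistic images. Tissue regions are
disjoint parametric solids (ellipsoids and a box) placed deterministically
with ≤ 1 voxel of seeded jitter on a 64×64×28 grid of 1.8×1.8×4.0 mm
voxels. Defaults: per-class decay-rate means and between-subject SDs equal
the normative control/PD group values; S0 follows a T2-weighted EPI
contrast (CSF ≈ 1000, parenchyma ≈ 450–500 signal units); Rician channel
noise sigma = 15 (cistern SNR ≈ 67); cohort sizes 32/27; choroid plexus
perfusion 32.7 ± 6.1 (control) and 32.8 ± 8.2 (PD) mL/100 g/min. The
choroid plexus decay rate has no normative value and defaults to
0.0030 mm²/s (between parenchyma and ventricular CSF, as befits a partly
fluid, highly vascular structure). The within-ROI voxelwise dispersion of D
likewise has no normative anchor and is exposed as a free parameter
(`d_sd_voxel`, default 0).

Noise model: two-channel Gaussian magnitude (Rician), drawn independently
per voxel, b-value and direction — the standard model for magnitude MRI.
Per-subject decay rates are normal with the group SDs, truncated at zero.
Directions are identical in expectation (isotropic phantom); they exist so
the trace operation is exercised.

**Perfusion–decay coupling.** The target is the *pooled* Spearman
correlation across both groups, because that is how the correlation is
measured downstream. A copula applied within each group's marginals would
attenuate the pooled coefficient (the between-group separation in D adds
rank variance uncorrelated with perfusion; predicted pooled |r| ≈ 0.285 for
a within-group 0.312). The generator therefore couples on pooled normal
scores: z = Φ⁻¹((rank(D)−0.5)/n) over the realized pooled D sample, perfusion
latent = ρ_lat·z + sqrt(1−ρ_lat²)·ε with ρ_lat = 2·sin(π·ρ_s/6), mapped
through the subject's group-specific perfusion marginal. Monte-Carlo
checks show the pooled sample Spearman recovers the target with
|mean bias| < 0.01 at n = 59.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: head motion, eddy currents and susceptibility
distortion; partial-volume mixing at region boundaries; cardiac-gated
pulsatile flow (decay is mono-exponential by construction, so the tests
validate estimation, not the adequacy of mono-exponential decay for real
cisternal CSF); anatomical geometry and registration error;
background-suppression dynamics and labeling-plane geometry in ASL; and
bolus-arrival-time variability (Δt is a constant).

## Statistics

Midranks are used everywhere; normal approximations carry the tie-corrected
variance. Exact enumeration thresholds — total n ≤ 12 for rank-sum
(≤ C(12,6) = 924 assignments) and n ≤ 8 for Spearman (≤ 40320
permutations) — keep enumeration cheap while covering every small-sample
case in the pipeline. Two-sided p-values are defined by
P(|T − E[T]| ≥ |observed|) under the permutation null. Sex (and group) enter
regressions as two-level indicators and the reported row is that contrast.
Regressions follow the separate-model design (one covariate at a time) with
a combined model as an option.

The voxelwise group map applies per-voxel rank-sum inside the region of
interest, Benjamini–Hochberg control at q = 0.10, and 26-connectivity
clustering with a configurable minimum extent; per-cluster sizes and
per-group mean decay rates are reported. This transparent procedure stands
in for atlas-based cluster inference tools and is labeled as such in the
output metadata. Under the global null it is conservative: the
any-surviving-voxel rate stays at or below q (rank-sum p-values are
discrete). Report rows for multiple ROIs are not cross-ROI
multiplicity-corrected; significance is flagged per row. The
perfusion–decay Spearman is pooled across groups by default, with a
stratified per-group option.

## Problem sizes and runtime choices

Default phantom 64×64×28 with compact regions (~90–330 voxels per class,
~1500 fitted voxels per subject) keeps a full 59-subject cohort run at
roughly 2–3 minutes on one CPU while leaving every stage statistically
meaningful. Reproducibility checks in the test suite use a reduced
32×32×14 phantom with 3+3 subjects — determinism does not depend on scale.
Monte-Carlo property tests use 200 cohorts (power), 500 cohorts (coupling
bias), 500 Rician replicates per condition (floor-bias direction) and 200
null phantoms (false-positive calibration). Manifest checksums cover all
written artifacts; volumes are written as uncompressed NIfTI-1 so the
checksums are byte-stable.

## Known limitations

Measured per-ROI decay-rate means carry a small upward bias relative to the
generating values (≈ 2–7% at the default SNR) — the usual noise-induced
bias of nonlinear exponential fitting — which affects absolute values, not
the group contrast. The ASL inversion assumes the fixed kinetic constants;
errors in Δt or T1 values translate directly into perfusion scale errors.
The voxelwise map tests each voxel marginally and ignores spatial
correlation beyond the clustering step. The generator's independence
assumptions (noise independent across volumes, subjects exchangeable within
group) are idealizations.
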