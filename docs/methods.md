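# Methods

## Generative model

Neuronal activity in n regions follows a linear stochastic differential
equation `dx/dt = A x + v`. `A` (Hz) is directed: `A[i, j]` couples source
region j to target region i, and the global convention row = target /
column = source is asserted by every reader and writer. Stability requires
all eigenvalues of `A` in the left half-plane; validity requires a strictly
negative diagonal (self-inhibition).

Endogenous fluctuations `v` have a power-law spectral density
`alpha_v * omega**-beta_v` (omega = 2*pi*f in rad/s). All spectra in the
package are two-sided densities over f in Hz, so integrating a density over
(−Nyquist, Nyquist) with measure df yields a variance; for white input
(beta = 0) and a unit observation kernel the spectral integral of the model
CSD equals the stationary covariance solving `A S + S A' + alpha I = 0`,
which is used as an oracle in the tests.

Observation is a linearized balloon model: vasodilatory signal and inflow,
venous volume and deoxyhemoglobin, expanded to first order around rest and
read out through the standard BOLD equation. Defaults (signal decay
0.64 s^-1, feedback 0.32 s^-1, transit 2.0 s, stiffness 0.32, resting
extraction 0.4) are canonical values; the implied kernel peaks at ~4.3 s
(verified in tests against a 3–7 s band). The same linearization supplies
both the simulator's convolution kernel and the forward model's transfer
function, so simulation and inference share one observation model exactly.

## Synthetic cohorts

The default region set has 15 regions in three networks (4 cDN, 5 SN,
6 DAN) with MNI coordinates packaged in `regions.py`. The group coupling
template sets the six between-network block means to SN→DAN 0.03,
SN→cDN −0.13, DAN→SN 0.02, DAN→cDN −0.10, cDN→SN 0.02, cDN→DAN 0.02 Hz —
the inhibitory/excitatory pattern whose consequences the analysis is meant
to recover. Within-network off-diagonals default to 0.0625 Hz and
self-connections to −0.5 Hz. The within-network value is a stability-driven
choice: a k-region block with uniform coupling w has Perron eigenvalue
`self + (k − 1) w`, so with the canonical −0.5 Hz self-inhibition any
w ≥ 0.1 destabilizes the 6-region DAN block; 0.0625 Hz (a typical prior
scale for couplings) keeps every block and the full template comfortably
stable while preserving clearly positive within-network correlations.

Subjects are drawn by adding independent N(0, sd²) noise (default sd =
0.05 Hz) to the off-diagonals only, rejection-sampling to stability;
self-connections stay at the template value, mirroring the inversion's
log-parameterization of the diagonal. Each subject's series is integrated
by Euler steps on a 0.1 s grid (≈20× oversampling of the 0.25 Hz band),
convolved with the hemodynamic kernel, downsampled to TR = 2 s for 170
volumes, and corrupted by white observation noise. A 64 s burn-in removes
transients, and the zero-frequency bin of the spectral synthesis is zeroed
(no DC drift — the data the analysis emulates are high-pass filtered by
nuisance regression). Power-law noise is synthesized in the frequency
domain; `generate_fluctuations` uses the per-sample periodogram convention
(variance ≈ amplitude for white noise), and the simulator rescales by
1/dt to realize physical densities so that simulated series, estimated
CSDs and model CSDs are mutually consistent (tested: relative Frobenius
error < 0.3 between a long simulation's MAR estimate and the model CSD).

Defaults the study conditions do not pin down were chosen once:
endogenous amplitude 0.01 with exponent 1 (a 1/f spectrum), observation
noise amplitude 0.5 (white), giving roughly 4:1 signal-to-noise in standard
deviation against the measured BOLD variance of the default template. The
per-subject master-seed policy is seed + subject index, making cohorts
bit-identical on regeneration.

What the generator does **not** emulate: voxel-level data and spatial
preprocessing, scanner drift and motion artifacts, non-Gaussian physiology,
nonlinear hemodynamics, or genetic covariance between subjects. Passing
tests therefore demonstrate internal consistency of the inference chain
under the model's own assumptions, not robustness to the full complexity of
real recordings.

## Cross-spectral estimation

The data feature is the complex CSD on 64 (forward default; 32 in the
pipeline, see below) linearly spaced frequencies from 1/(T·dt) to 0.25 Hz.
It is estimated with a least-squares multivariate AR model (default order
8 — a deliberate smoothness prior for 170-volume series; higher orders
resolve the low-frequency peak better on long series and the order is
exposed). Ill-conditioned normal equations (common at n = 15, T = 170)
trigger a small ridge penalty with a warning. The AR spectrum is Hermitian
positive semidefinite by construction.

## Inversion (variational Laplace)

Parameters: 210 off-diagonal couplings (Hz), 15 self-connection log-factors
(diagonal realized as −0.5·exp(θ)), log-amplitude and exponent deviations
for the endogenous and observation spectra, and per-region log transit-time
deviations; remaining hemodynamic constants are fixed at their defaults for
identifiability on short series. Priors: couplings N(0, 1/64), shrunk to
N(0, 1/512) where the empirical zero-lag correlation magnitude is below 0.1
(functional connectivity as an empirical prior); self-factors N(0, 1/256);
spectral/hemodynamic log-parameters N(0, 1/64). Zero prior variance fixes a
parameter exactly.

The observation model treats the stacked real and imaginary CSD entries
(upper triangle per bin) as independent Gaussians sharing one estimated
log-precision. Residuals are additionally scaled by a fixed per-frequency
weight, the reciprocal of the data CSD's mean diagonal power at that bin.
This is a known-precision profile, not an estimated quantity: power-law
spectra span orders of magnitude across the band, and without the flattening
the lowest bins dominate the quadratic fit and coupling recovery degrades
badly (correlation with truth 0.29 vs 0.98 on the 3-node benchmark).

Optimization is Gauss–Newton ascent on the free energy with
Levenberg–Marquardt damping: the damping factor persists across iterations
(warm-started at 1.0, ×4 on rejection, ÷4 on acceptance, up to 16 retries),
the log-precision is re-solved by Newton at every candidate, and a step is
accepted only if F increases — the accepted F trace is monotone by
construction. Convergence: ΔF < 0.01 for 4 consecutive accepted steps, cap
128 iterations; on failure the best iterate is returned flagged
non-converged. Derivatives of the model CSD are closed-form (a coupling
perturbation is a rank-one change of the resolvent, hence a rank-two
Hermitian update of G; spectral parameters scale input spectra); only the
hemodynamic transfer derivative uses central differences on the 4-state
balloon system. A full finite-difference path is kept and tested against
the analytic one (agreement ~1e-8 relative). After the last accepted step,
F, the posterior covariance and the log-precision are re-evaluated
self-consistently at the optimum, so `free_energy` reproduces the returned
F exactly. The inversion is deterministic given data and priors.

## Group analysis

PEB places a general linear model over the 225 coupling parameters of the
subject posteriors (means *and* covariances): θ_i = (x_i ⊗ I)β + ε_i with
ε_i ~ N(0, exp(−λ)·Q), Q = prior variance / 16 (a single component; the
scale means between-subject variability defaults to a sixteenth of the
prior variance). β is integrated out in closed form given λ; λ has a
N(0, 4) prior and is optimized by bounded scalar search on the Laplace
evidence. The first design column is the group mean; additional covariate
columns are mean-centered, and a null covariate changes group means by
well under a third of a prior standard deviation (tested).

Greedy BMR search: per sweep, every remaining off-diagonal coupling is
trial-pruned (prior pinned to variance 1e-8, mean 0 — closed-form evidence
via low-rank updates of the posterior precision); all removals that do not
decrease the evidence are applied jointly, with fallback to the best single
removal, until no removal qualifies. Accepting zero-change removals
implements the parsimony preference: when the data are uninformative the
search reduces maximally. Every model evaluated is returned, sorted by
evidence with ties broken toward sparser models; reduced posteriors are
materialized lazily since searches can score hundreds of models. BMA
soft-max-weights the best 256 models (interpreted as the 256 best among
*all* models scored during the search, a deterministic superset of any
final-sweep reading) and moment-matches the Gaussian mixture. Retention
probabilities are per-parameter with-vs-without BMR comparisons,
p = 1/(1 + exp(ΔF_without)), thresholded at 0.95.

## Network statistics

Between-network averages are equal-weight Bayesian contrasts over all
connections from source network to target network (within-network
off-diagonals on the diagonal), so every cell carries μ = c'M, σ² = c'Σc
and a posterior tail probability (two-sided by default, one-sided
available). Hierarchy strength sums the two unsigned efferent cells and
subtracts the two unsigned afferent cells; a `mode="mean"` option divides
by the number of other networks (the two differ only by that factor — the
sum form is the package default because it matches the worked arithmetic
the averages are seeded from). Clustering represents each region by its
concatenated afferent/efferent profile (self excluded), correlation
distance, average linkage — choices exposed as options; partitions are
compared by adjusted Rand index.

## Pipeline problem sizes and numerical choices

The packaged pipeline runs 20 subjects × 15 regions × 170 volumes with a
32-bin inversion grid and a 48-iteration cap — sizes chosen so a complete
run takes about two minutes on one CPU while leaving the group-level
quantities (block-mean signs, hierarchy ordering, two-mode clustering)
stable across seeds; the forward module's 64-bin default remains available
via `n_bins`. Degenerate inputs are rejected loudly: unstable matrices name
the offending eigenvalue, zero-variance regions are named in FC and
clustering errors, transposed matrix files are refused at parse time, and
rank-deficient design matrices list their collinear columns.

## Known limitations

Per-subject coupling recovery at 170 volumes is modest (correlation ~0.4
with truth); the group-level claims rest on PEB pooling across subjects,
which is exactly what they should rest on. The single shared log-precision
(even weighted) is a simplification — per-frequency precision components
are the natural extension. The AR estimator is biased at the steep
low-frequency end of 1/f spectra on short series; the inversion's weighting
limits, but does not remove, the effect. Hierarchy scores rank networks by
net unsigned influence only; they carry no claim about cortical hierarchy
in the anatomical sense.
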