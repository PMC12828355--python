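# Methods

This note documents the models, numerical choices and evaluation design
behind `microfit`, including what the synthetic data do and do not
emulate.

## Units and conventions

All computations use ms, µm, µm²/ms and mT/m, so b-values are in ms/µm²
(1 ms/µm² = 1000 s/mm²; file readers auto-detect s/mm² inputs by
magnitude and convert). The gyromagnetic ratio is
γ = 2.6752×10⁻⁴ rad·ms⁻¹·µm⁻¹·(mT/m)⁻¹. Shells are identified by the
tuple (TE, b, δ, Δ) rounded to three decimals, reflecting the finite
precision of acquisition side-car files; b < 0.05 ms/µm² counts as b=0
(so a nominal b=50 s/mm² shell is treated as a shell, not a baseline).
Gradient amplitudes are derived from b through the pulsed-gradient
spin-echo relation b = γ²G²δ²(Δ−δ/3) and validated against it.

## Forward models

Spherical-mean signals follow the standard powder-average closed forms
for Stick, Zeppelin and Iso compartments; the common factor
√(π/(4x))·erf(√x) is evaluated with a series branch below x = 10⁻⁸ so the
b→0 and D∥→D⊥ limits are smooth. Restricted diffusion in cylinders and
spheres uses the Gaussian-phase-distribution series over Bessel-root
boundary conditions: J₁′(β)=0 for the cylinder (β₁ ≈ 1.8412) and
(1/β)J₃⁄₂(β) = J₅⁄₂(β) for the sphere (β₁ ≈ 2.0816, bracketed
root-finding, roots cached). The printed form of the sphere root
condition is typographically ambiguous; the adopted reading is the one
that reproduces the standard first root 2.0816.

The series is truncated at 30 roots by default. This count was chosen as
the smallest with a safe margin on a 10⁻⁸ relative truncation error
against a 200-term reference across diameters 0.5–12 µm on the ex vivo
protocols (20 terms reach only 1.4×10⁻⁸ at the 12 µm edge). A convergence
monitor warns when the last term still moves the log-attenuation both
relatively (>10⁻⁸ of the sum) and absolutely (>10⁻⁶).

Compartmental T2 weighting e^(−TE/T2) enters only when the protocol
carries echo times and the compartment has T2 > 0 (t2 = 0 is the sentinel
for "no relaxation term"). Multi-TE model predictions are normalized by
the predicted signal at (minimum TE, b=0); per-TE normalization was the
open alternative, and the global convention is recorded in the model's
metadata so downstream code can tell which was used.

### Rotational invariants

Legendre-projected kernels K_l = ∫₀¹ e^(−bD∥ξ² − bD⊥(1−ξ²)) P_l(ξ) dξ are
computed by adaptive quadrature (absolute tolerance 10⁻¹⁰) in the
reference path and by fixed 96-point Gauss–Legendre rules in the batched
path used for training-set synthesis; the two agree to ~10⁻¹⁵ over the
relevant b-range and this equivalence is pinned by a test. No
(2l+1)/2-type normalization is applied to K_l.

The measured order-l rotational invariant is defined as
S_l = ‖c_l‖/√(4π(2l+1)) from a real, even-order, orthonormal spherical-
harmonic fit, with the order-0 invariant defined as the arithmetic shell
mean so that the identity "order 0 ≡ spherical mean" holds exactly for
any direction set (the SH fit supplies the l ≥ 2 magnitudes only).
Because the measured invariants are magnitudes, order-2 model predictions
return |p₂·Σᵢ fᵢK₂,ᵢ|. The signed kernel itself tends to K₂/K₀ → −1/2 for
a stick as b → ∞ (the integrand concentrates at ξ=0 where P₂ = −1/2);
the magnitude convention keeps forward predictions consistent with what a
spherical-harmonic fit of the data returns. Negative measurement values
inside the mask are clamped to zero before SH fitting (noise-floor
artifacts), with a logged count.

## Model composition

Models are fraction-weighted compartment mixtures with named parameters;
fractions form a simplex stored as the leading k−1 free fractions with
the last derived. Defaults follow the standard compositions: SMT shares
D∥ between compartments (the tortuosity link D⊥ec = (1−fia)·D∥ is an
option, off by default so fia, D∥ and the D⊥ fraction are all estimated);
ExCaliber links the cylinder's intrinsic diffusivity to the shared
parallel diffusivity and uses an immobile dot (ex vivo) or free-water
(in vivo) compartment; SANDI fixes the soma diffusivity at 3.0 µm²/ms;
SMIfw fixes free-water diffusivity and T2 at 3.0 µm²/ms and 2000 ms.
Default parameter bounds are soft, physiologically motivated ranges
(diffusivities ≤ 4 µm²/ms ≈ free water at body temperature; D∥ ∈ [1,3]
for in vivo white matter, [0.1,1.2] for fixed tissue) and are overridable
per model.

`pack_parameters` encodes the free fractions as stick-breaking
coordinates (each free in [0,1]) for optimizers that need an unconstrained
box; the MH sampler instead proposes the k−1 fractions directly and
rejects proposals whose sum exceeds one, because that preserves the
uniform-on-the-simplex prior exactly, which stick-breaking coordinates
with per-coordinate uniform proposals would not.

## MCMC estimator

Metropolis-within-Gibbs sweeps: each iteration proposes every sampled
parameter in turn from a symmetric Gaussian (default step 5% of the prior
width), rejecting out-of-bounds and simplex-violating proposals, which
implements the uniform prior without Jacobian bookkeeping. The Gaussian
noise level σ is sampled jointly by default (uniform prior on
[10⁻⁴, 0.2]) or can be fixed. Defaults are 20,000 iterations, 1,000
burn-in, thinning 100 for stored summaries; all evaluation runs in this
package use shorter, explicitly stated chains. A batched sampler runs
many independent chains in lockstep (one vectorized forward-model call
per proposal across chains) — statistically identical to per-voxel runs,
roughly an order of magnitude faster in Python, and used for the
multi-realization evaluations.

The two-stage scheme fixes the parameters dropped from stage 2 (by
default the diffusivities) at their stage-1 posterior means, then
re-samples the remaining parameters; on the ex vivo ground-truth voxel at
SNR 100 this reduces both the mean absolute error and the posterior
spread of the diameter index and intra-axonal fraction, which the
acceptance suite asserts as a direction over 25 noise realizations with
8,000-iteration chains.

Rician noise is deliberately not modeled: synthetic evaluation adds
Gaussian noise to spherical means, which is also what direction averaging
of many measurements approaches. Diagnostics (rank-normalized split-R̂ and
ESS) are delegated to arviz. Voxelwise map fitting seeds each voxel from
(seed, voxel index), making results independent of the thread count.

## Neural-network estimator

The estimator is a small fully connected network — default three hidden
layers of 48 ReLU units with dropout 0.1 after each hidden layer —
implemented directly on numpy (dense forward/backward, inverted dropout,
Adam, early stopping on a 20% validation split). Networks of this size
train in seconds on one CPU, so no deep-learning framework is required.
The dropout rate, width/depth, epochs (default 200), batch size (128) and
learning rate (10⁻³) are all configuration, since none of them is pinned
by the underlying method; the loss is (R)MSE over all parameters after
min–max scaling to [0,1] (RMSE and MSE have the same optimum; RMSE is
reported). A sizing heuristic recommends 50× the network's weight count
as the training-set size (factor 10–100 accepted with a warning outside
that band).

Training data are drawn from per-parameter priors (uniform or truncated
Gaussian within bounds; fractions from a Dirichlet with configurable
concentrations, flat by default) and pushed through the forward model
once; noise is added once at synthesis time (a fixed noisy set rather
than fresh noise per epoch). With a b=0-referenced SNR, the per-shell
noise std is 1/(SNR·√n_dirs), reflecting direction averaging; voxel-level
evaluation generators instead take SNR on the spherical-mean scale
(σ = 1/SNR) — both knobs exist because the two referents differ and both
are used in practice. At inference, dropout stays active and the default
100 stochastic passes give per-parameter posterior means and standard
deviations in physical units; fractions are predicted independently (no
softmax), so their sum is monitored, not enforced.

## Sensitivity analysis

The smallest robustly measurable attenuation is σ̄ = z_α/(SNR₀·√n): the
√n arises because averaging n directions reduces the noise std by √n.
The exact normal quantile is used (z₀.₀₅ = 1.6449; printed discussions
usually round to 1.64 — with the rounded value the ex vivo bounds move by
≤ 0.01 µm). Single-shell bounds are threshold crossings of the cylinder
signal against [σ̄, S_stick − σ̄] on a diameter grid (default 0.1–20 µm,
step 0.01 µm); grid-edge hits are flagged as unbounded rather than
reported as numbers. Multi-shell bounds minimize the summed squared error
against each bound across shells, restricting the noise-floor search to
shells with b ≥ 15 ms/µm² (configurable) because low-b shells remain
above the floor for arbitrarily large diameters and would dominate the
objective; ties break toward smaller diameters. All three shells of the
ex vivo triplet are taken at δ/Δ = 11/15.192 ms — the protocol that
contains exactly b = 18.1, 25 and 43 ms/µm² — an assumption confirmed by
the reproduced ranges.

## Synthetic data: what it does and does not emulate

Protocol presets reproduce published shell tables: the three ex vivo
multi-b protocols (δ/Δ = 9.6/12, 11/15.192, 11/21 ms, maximum b 25/43/64
ms/µm² at G ≈ 660 mT/m, 32 directions), a clinical three-shell protocol
(b = 1, 2, 3 ms/µm², 90 directions/shell, 18 b=0), a short-diffusion-time
ultra-high-gradient protocol (δ/Δ = 8/19 ms, b up to 6 ms/µm², 32/64
directions), and a multi-TE two-shell protocol (8 TEs 62–132 ms,
b = 0.7/2.0 ms/µm², δ/Δ = 15.2/25.2 ms, order-2 invariants).

Voxel generators add Gaussian noise directly to the normalized
spherical-mean signals; a per-direction mode synthesizes single-fiber
DWIs (including exactly band-limited l ≤ 2 signals used as the SH-fit
oracle). The phantoms have no spatial structure, no partial-volume
geometry, no Rician floor, no artifacts, and single-orientation fibers
without dispersion. Passing tests therefore demonstrate correctness of
the forward models, samplers and estimators under the stated noise model
— not robustness to the full complexity of in vivo data.

The default sweep ground truth is the ex vivo white-matter voxel
(da = 2 µm, fia = 0.7, fdot = 0.15, D∥ = 0.6 µm²/ms, D⊥/D∥ = 0.3).

## Evaluation problem sizes

The shipped end-to-end checks use reduced problem sizes chosen so the
directions of interest are stable across seeds: 25 noise realizations
with 8,000-iteration chains for the two-stage comparison; 4 ground-truth
diameters × 10 realizations for the single- vs multi-diffusion-time
comparison (Pearson correlation between estimates and ground truth,
ordering asserted); 30,000 training samples for estimator recovery and
degeneracy checks; 20,000 for the prior-effect comparison. The
sensitivity-range computation is deterministic and runs at full
resolution.

## Known limitations

Inter-compartment water exchange is not modeled; results on tissue where
exchange is fast relative to the diffusion time (e.g. gray matter at long
Δ) should be interpreted accordingly. Fiber orientation dispersion within
a voxel is summarized only through p₂. The MCMC sampler is random-walk
Metropolis — adequate for the ≤6-parameter models shipped, but chain
settings need care near bound-constrained, degenerate posteriors (the
diagnostics module exists for exactly that). Posterior summaries keep
only means and standard deviations; full chains are available per voxel
but are not written by the map-fitting CLI.
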