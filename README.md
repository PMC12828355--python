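# microfit

Probabilistic microstructure model fitting for diffusion MRI.

Diffusion-weighted MRI probes tissue at scales far below the voxel size:
the signal decay as a function of the diffusion weighting b carries the
signatures of axons, cell bodies and extra-cellular water. `microfit`
estimates these microstructural parameters — compartment signal
fractions, diffusivities, axon diameter index, soma radius, compartmental
T2 — from direction-averaged (spherical-mean) or rotational-invariant
multi-shell data, together with their posterior uncertainty. It is aimed
at researchers who design acquisition protocols and evaluate fitting
strategies before (or instead of) committing to scanner time: every
analysis in the package can be run end-to-end on synthetic data generated
from the same forward models used for fitting.

## The models

The normalized signal in a voxel is a mixture of compartments,
`S(b, t) = Σᵢ fᵢ Sᵢ(b, t)` with `Σ fᵢ = 1`. The per-compartment
spherical-mean forward models (units: ms, µm, µm²/ms, mT/m) are

- **Stick** (axons, zero perpendicular diffusivity):
  `S = e^(−t/T2) · √(π/(4bD∥)) · erf(√(bD∥))`
- **Zeppelin** (anisotropic extra-cellular space):
  `S = e^(−t/T2) · e^(−bD⊥) · √(π/(4b(D∥−D⊥))) · erf(√(b(D∥−D⊥)))`,
  with `D⊥` parameterized as a fraction of `D∥`
- **Cylinder** (axons with finite diameter `da`): the Zeppelin form with
  `bD⊥` given by the Gaussian-phase-distribution (GPD) series over the
  roots of `J₁′(β) = 0`
- **Sphere** (cell soma of radius `rs`): GPD series over the roots of
  `(1/β)J₃⁄₂(β) = J₅⁄₂(β)`
- **Iso** (free/extra-cellular/immobile water): `S = e^(−t/T2) · e^(−bD)`;
  `D = 0` is the "dot" of immobile water in fixed tissue.

For pulsed-gradient spin-echo encodings, `b = γ²G²δ²(Δ − δ/3)`. For
fiber-specific modeling, Stick/Zeppelin/Iso response kernels are
projected onto Legendre polynomials (`K_l`) and combined with the fiber
ODF invariants `p_l` to predict rotational invariants `S_l = p_l·K_l`
(order 0 is the spherical mean).

Named compositions: `SMT`, `MTE_SMT` (Stick+Zeppelin white-matter
models), `SANDI`, `SANDIdot`, `MTE_SANDI` (Sphere+Stick+Iso gray-matter
models), `ExCaliber` (Cylinder+Zeppelin+dot for axon-diameter mapping at
ultra-high gradients), `SMI` and `SMIfw` (rotational-invariant standard
model, optionally with free water).

Two estimators share every model:

- **MCMC** — Metropolis–Hastings with uniform priors on bounds, optional
  noise-level sampling, a two-stage scheme that fixes well-determined
  diffusivities at their stage-1 posterior means, split-R̂/ESS
  diagnostics, and threaded voxelwise map fitting.
- **MC-dropout MLP** — training data synthesized from configurable priors
  (uniform, truncated Gaussian, Dirichlet fraction simplex), a small
  dropout MLP trained on (R)MSE of min–max-scaled parameters, and
  posterior mean/std maps from stochastic forward passes at inference.

A sensitivity module computes the range of axon diameters a protocol can
actually resolve: the smallest measurable attenuation is
`σ̄ = z_α/(SNR·√n)`, and the diameter bounds are where the cylinder
signal can be distinguished from the zero-diameter (stick) signal and
from the noise floor, per shell or by a mean-squared-error search across
shells.

## Worked example

Which axon diameters can an ex vivo protocol with shells
b = 18.1/25/43 ms/µm² (δ/Δ = 11/15.192 ms, G ≤ 660 mT/m) resolve?

```bash
$ printf 'b\tdelta\tDelta\n18.1\t11\t15.192\n25.0\t11\t15.192\n43.0\t11\t15.192\n' > shells.tsv
$ microfit sensitivity --shells shells.tsv --d0 0.6 --ndirs 32 --snr 100 --snr 50 --snr 30
SNR=100: [1.43, 10.50] um
SNR=50: [1.70, 9.18] um
SNR=30: [1.94, 8.32] um
```

At b=0 SNR 100 with 32 directions the protocol distinguishes diameters
between about 1.4 and 10.5 µm; halving the SNR narrows that window from
both sides.

Fitting a simulated white-matter voxel (axon diameter index 2 µm,
intra-axonal fraction 0.7, dot fraction 0.15, D∥ 0.6 µm²/ms) with the
two-stage MCMC:

```python
import numpy as np
from microfit import make_model, Sampler, Noisemodel, two_stage_fit
from microfit.synthetic import protocol_preset, synth_voxel

model = make_model("ExCaliber")
protocol = protocol_preset("excaliber_exvivo_dt15")
gt = {"da": 2.0, "fia": 0.7, "fdot": 0.15, "dpara": 0.6, "dperp_frac": 0.3}
meas = synth_voxel(model, gt, protocol, snr=100.0, nrealizations=1, rng=42)[0]

stage1 = Sampler(nsamples=8000, burnin=2000, thinning=10)
stage2 = Sampler(params=["da", "fia", "fdot"], nsamples=8000, burnin=2000,
                 thinning=10)
_, _, summary = two_stage_fit(model, meas, protocol, stage1, stage2,
                              Noisemodel(), np.random.default_rng(0))
for name, (mean, std) in summary.items():
    print(f"{name:12s} {mean:7.3f} +/- {std:.3f}")
```

```
da             3.285 +/- 1.938
fia            0.638 +/- 0.069
fdot           0.162 +/- 0.073
sigma          0.014 +/- 0.007
dpara          0.528 +/- 0.000
dperp_frac     0.474 +/- 0.000
```

The fractions and noise level are recovered within their posterior
spread; the diameter posterior is honest about its breadth — single-voxel
diameter mapping at SNR 100 carries µm-scale uncertainty (this is
precisely what the sensitivity analysis and the sweep evaluations
quantify; averaging over noise realizations shows the two-stage scheme
reducing both error and spread).

Other entry points: `microfit simulate` (phantoms with text side-cars),
`microfit spherical-mean` (direction averaging / rotational invariants +
SNR maps), `microfit fit-mcmc` (voxelwise posterior maps),
`microfit train-nn` / `microfit fit-nn` (dropout-MLP estimators).

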