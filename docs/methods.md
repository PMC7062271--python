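# Methods

## Model

A diffusion MRI acquisition probes the q-space signal `E(q)`, the Fourier
dual of the ensemble average propagator (EAP) `P(R)`, the probability
density of water displacement over the effective diffusion time `τ`.
Three popular scalar summaries of the EAP are the return-to-origin,
return-to-plane and return-to-axis probabilities:

    RTOP = P(0)              = ∫_{R³} E(q) dq              [mm⁻³]
    RTPP = ∫ P(R⊥) dR⊥       = ∫_R  E(q∥) dq∥              [mm⁻¹]
    RTAP = ∫ P(R∥) dR∥       = ∫_{R²} E(q⊥) dq⊥            [mm⁻²]

where `q∥` is the maximum-diffusion direction and `q⊥` its normal plane.
Computed from a full EAP estimate these need dense multi-shell sampling.
This package computes their *apparent* single-shell counterparts: under a
mono-exponential radial model

    E(b, u) = exp(−b · D(u)),   b = 4π²τ‖q‖²,

with `D(u)` the apparent diffusion coefficient (ADC) as a function of the
unit direction `u` only, the three volumetric/line integrals collapse to
closed forms on the sphere.

## Derivation of the constants

Substituting the model into the defining integrals and integrating the
radial coordinate analytically (Gaussian moments
`∫₀^∞ e^{−aq²} q² dq = √π/(4a^{3/2})`,
`∫_{−∞}^∞ e^{−aq²} dq = √(π/a)`,
`∫₀^∞ e^{−aq²} q dq = 1/(2a)` with `a = 4π²τD`):

    RTOP = (√π/4) (4π²τ)^{−3/2} ∫_S D(u)^{−3/2} dS
    RTPP = (4πτ · D(r₀))^{−1/2}
    RTAP = (8π²τ)^{−1} ∫₀^{2π} D(θ′)^{−1} dθ′

with `r₀` the ADC maximum and `θ′` parameterizing the great circle normal
to `r₀`.  In the isotropic limit `D(u) ≡ D` these reduce to the exact
Gaussian values `(4πτD)^{−3/2}`, `(4πτD)^{−1/2}`, `(4πτD)^{−1}`, which
also coincide with the tensor-model closed forms

    RTOP = (4πτ)^{−3/2} (λ₁λ₂λ₃)^{−1/2} = RTPP · RTAP
    RTPP = (4πτ λ₁)^{−1/2}
    RTAP = (4πτ)^{−1} (λ₂λ₃)^{−1/2}

for eigenvalues `λ₁ ≥ λ₂ ≥ λ₃`.  All leading constants in the code are
pinned by this isotropic identity, which the test suite enforces to 1e-3
relative (machine precision in practice); this pinning is robust against
any transcription ambiguity in the printed formulas.

## Numerical implementation

The spherical quantities are estimated with real, antipodally symmetric
(even-order) spherical harmonics in the modified Descoteaux ordering:

* **RTOP** uses the DC coefficient: `∫_S H dS = √(4π)·C₀₀{H}`, so
  `RTOP = (4π)^{−2} τ^{−3/2} C₀₀{D^{−3/2}}`.
* **RTPP** evaluates the SH-smoothed ADC `D_SH` at `r₀` rather than
  taking a raw sample maximum, deliberately trading a small bias for
  robustness of the max operator.  `r₀` is the argmax of `D_SH` over a
  1281-point antipodally reduced subdivision-4 icosphere (~2° spacing;
  an order-6 expansion cannot localize maxima more finely, so no local
  refinement is performed; ties break to the lowest grid index).
* **RTAP** applies the Funk–Radon transform — diagonal in SH with
  eigenvalues `2π P_l(0)` = {2π, −π, 3π/4, −5π/8} for l = 0,2,4,6 — to
  the SH expansion of `1/D`, evaluated at `r₀`.

The SH fits are penalized least squares,
`c = (BᵀB + λΛ)⁻¹ Bᵀ s` with the Laplace–Beltrami diagonal
`Λ_jj = l²(l+1)²`.  The solve matrix is computed once per (scheme,
order, λ) and reused across voxels — the per-voxel cost is one small
matrix-vector product, which is why the whole pipeline runs in seconds
per volume.  Each of `D`, `1/D`, `D^{−3/2}` is fitted from its own
transformed samples (not from powers of a fitted `D`): the DC component
of the transformed samples is the unbiased estimator of the spherical
mean actually integrated.

Defaults: SH order 6, λ = 0.006, b-shell tolerance 50 s/mm², b0
threshold 50 s/mm².  `τ` is an acquisition parameter the gradient table
does not carry; the default 0.05 s only fixes the unit scale, since every
measure scales deterministically with τ (RTOP ∝ τ^{−3/2}, RTPP ∝
τ^{−1/2}, RTAP ∝ τ^{−1}).

### Guards for degenerate inputs

* Attenuations are clipped to `[1e-10, 1]`.  The upper clip enforces a
  non-negative ADC when noise pushes `S > S0`; the lower clip only keeps
  `log E` finite and is far below any physical decay (CSF at b = 5000
  still gives E ≈ 3e-7).
* ADC samples are floored at `D_min = 1e-7 mm²/s` before the inverse and
  `−3/2` power transforms, bounding them in near-zero-ADC voxels.
* A non-positive `D_SH(r₀)` (possible after heavy smoothing) is clamped
  to `D_min` and flagged; negative FRT values from SH ringing are clamped
  to 0 and flagged.
* Voxels with non-positive mean baseline are marked invalid and emit NaN.

## Accuracy characterization

On noise-free phantoms the measured errors of the SH implementation
against the independent quadrature oracle are:

| condition | RTOP | RTPP | RTAP |
|---|---|---|---|
| isotropic (any D, b, τ) | exact | exact | exact |
| prolate FA 0.36, λ=0 | <0.01% | <0.01% | −0.1% |
| prolate FA 0.62, λ=0 | <0.01% | <0.01% | −0.7% |
| prolate FA 0.80, λ=0 | 0.02% | <0.01% | −3.4% |
| prolate FA 0.80, λ=0.006 | 0.01% | +1.2% | −11.4% |
| 90°/60° crossings, λ=0 | <0.01% | ≤1.3% | ≤1.2% |
| 90°/60° crossings, λ=0.006 | ≤0.02% | +3.4…5.2% | ≤2.1% |

Two mechanisms drive the RTAP/RTPP errors:

1. **Order-6 truncation.**  `1/D` of a prolate tensor with λ₁/λ₃ = 5.7
   has slowly converging Legendre coefficients; the truncated FRT partial
   sum underestimates the equatorial integral by 3.3% at L = 6 (1.3% at
   L = 8, 0.2% at L = 12, measured by exact dense-grid projection).  This
   is a property of the order-6 design itself, independent of the fit.
2. **Laplace–Beltrami shrinkage.**  With an orthonormal basis and n
   directions, `BᵀB ≈ (n/4π)·I`, so λ = 0.006 multiplies order-l
   coefficients by roughly `1/(1 + 4πλ l²(l+1)²/n)` — at n = 64 that is
   0.96 (l=2), 0.68 (l=4), 0.32 (l=6).  This stabilizes noisy fits but
   biases sharp features; it also makes results depend mildly on the
   direction count (a −7% RTAP shift between 32- and 128-direction fits
   of the same prolate voxel at λ = 0.006, <0.7% at λ = 0).

Accordingly, the noise-free accuracy tests run the fits unregularized so
they probe discretization error alone, while the default operating point
(λ = 0.006, matching the published configuration) is used everywhere
else; both are characterized above.

Under Rician noise at SNR 30 (64 directions, b = 3000, gray-matter-like
isotropic voxel, medians over 10³ replicates) RTOP and RTAP recover to
~3%, while RTPP is biased −6%: the spherical maximum of a
noise-perturbed smooth field is an extreme-value statistic whose upward
bias in `D_SH(r₀)` survives the median across replicates.  The SH
smoothing reduces but cannot eliminate it.  At the same SNR, voxels
whose along-fiber attenuation falls below the Rician noise floor
(e.g. the prolate white-matter tensor at b = 3000, E ≈ 0.006 against a
floor of ≈0.04 at SNR 30) yield strongly biased RTPP/RTAP regardless of
estimator — a physical limit of magnitude MRI at high b, the reason
high-quality acquisitions average many baselines.

## Synthetic phantoms

`amura.phantom` generates multi-tensor voxels
`S = S0 Σᵢ fᵢ exp(−b gᵀDᵢg)` with Rician noise, over
electrostatic-repulsion direction schemes (L-BFGS descent of the
antipodal Coulomb energy with analytic gradients; n = 6 reproduces the
icosahedral optimum of 63.43° minimum angle to <0.01°).  Subsampling
greedily removes the direction contributing most repulsion energy.  The
default suite spans isotropic CSF-like (3.0e-3 mm²/s) and gray-like
(0.7e-3) voxels, a prolate white-matter tensor (1.7, 0.3, 0.3)e-3, and
90°/60° two-tensor crossings at 0.5/0.5 and 0.7/0.3 fractions; two
further prolates at FA 0.36 and 0.62 (fixed mean diffusivity 0.77e-3)
fill out the FA sweep.  Ground truths are the tensor closed forms for
single-compartment voxels and quadrature-oracle values for mixtures
(whose apparent ADC, hence truth, depends on b — by design).

What the phantoms do **not** emulate: spatial structure and partial
volume, eddy/motion artifacts, gradient nonlinearity, non-Gaussian
restricted-diffusion effects beyond tensor mixtures, and spatially
correlated noise.  Passing tests therefore validate the estimator
mathematics and its noise behavior per voxel, not robustness to
real-world acquisition artifacts.

## Oracle

`amura.oracle` evaluates the defining integrals directly from an
analytic ADC callable: product Gauss–Legendre × trapezoid surface
quadrature with grid-doubling to 1e-6 relative convergence (RTOP);
dense Fibonacci-grid maximization polished by a Nelder–Mead simplex on
spherical angles (RTPP — a 2-D derivative-free search); trapezoid rule
on the equator, spectrally accurate for the periodic integrand (RTAP).
It shares no code path with the SH implementation, so their agreement is
evidence rather than tautology.  Oracle self-consistency
(RTOP = RTPP·RTAP for any single tensor) holds to 1e-6.

## Problem sizes

Validation and acceptance computations use single-voxel noise-free
phantoms, 10³ replicate voxels for noise studies, 10⁴ voxels/tensors for
Monte-Carlo and identity checks, and 64–128-direction schemes — sizes at
which every quantity reported is converged and the full suite runs in
well under a minute on one core.

## Known limitations

* Apparent measures are b-dependent by construction; values are only
  comparable across datasets acquired at the same shell.
* Absolute magnitudes require the true `τ`, which bval/bvec files do not
  record; with the default `τ` the maps are correct up to a global
  per-measure scale.
* RTAP (and to a lesser degree RTPP) carries the order-6/regularization
  biases quantified above; trend and contrast are preserved (FA
  monotonicity holds throughout), absolute accuracy at high FA is not.
* The log-linear OLS tensor fit is a deterministic comparator, not a
  state-of-the-art estimator (no WLS/NLLS, no positivity constraint).
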