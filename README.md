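# amura

Apparent q-space scalar measures — return-to-origin (RTOP),
return-to-plane (RTPP) and return-to-axis (RTAP) probabilities — computed
from **one single b-shell** of diffusion MRI.

Full EAP-based versions of these microstructure indices need dense
multi-shell acquisitions and hours of non-linear fitting.  Under a
mono-exponential radial model `E(b, u) = exp(−b·D(u))`, the defining
q-space integrals collapse to closed forms on the sphere, evaluated with
spherical harmonics (SH):

* `RTOP = (4π)⁻² τ^(−3/2) · C₀₀{D^(−3/2)}` — the DC coefficient of the
  SH expansion of `D^(−3/2)` (units mm⁻³),
* `RTPP = (4πτ · D_SH(r₀))^(−1/2)` — the SH-smoothed ADC at the
  maximum-diffusion direction `r₀` (mm⁻¹),
* `RTAP = (8π²τ)⁻¹ · G{1/D}(r₀)` — the Funk–Radon transform (great-circle
  integral) of `1/D` at `r₀` (mm⁻²),

with `τ` the effective diffusion time and `b = 4π²τ‖q‖²`.  The only
per-voxel work is a cached linear solve, so whole volumes process in
seconds.  The package targets researchers who want EAP-style contrast
from standard single-shell HARDI protocols (b ≈ 2000–5000 s/mm²,
≥ 30 directions), plus everything needed to validate the estimator
without external data: a diffusion-tensor reference, a brute-force
quadrature oracle, and a multi-tensor phantom generator.
See `docs/methods.md` for derivations and accuracy characterization.

## Worked example

Generate a tiny synthetic phantom and run the pipeline end to end:

```python
import numpy as np
from amura import (Compartment, PhantomSpec, simulate_signal, make_scheme,
                   extract_shell, compute_all, phantom_truth)

scheme = make_scheme(64, seed=1)            # uniform 64-direction shell
spec = PhantomSpec([Compartment((0.7e-3,) * 3)],   # gray-matter-like voxel
                   shells=[(3000.0, 64)], tau=0.05)
shell = extract_shell(simulate_signal(spec, scheme=scheme), 3000.0, tau=0.05)
maps = compute_all(shell)
for name, m in maps.items():
    print(f"{name}: {m.values[0]:.6g} {m.units}")
print("exact :", phantom_truth(spec))
```

prints

```
RTOP: 108413 mm^-3
RTPP: 47.6827 mm^-1
RTAP: 2273.64 mm^-2
exact : {'RTOP': 108413.44311323874, 'RTPP': 47.68272270088961, 'RTAP': 2273.6420441699333}
```

For an isotropic voxel the three measures equal the exact Gaussian limits
`(4πτD)^(−3/2)`, `(4πτD)^(−1/2)`, `(4πτD)^(−1)` — the identity that pins
every constant in the code — and `RTOP = RTPP × RTAP`.  Anisotropic
voxels raise RTOP/RTAP (restriction across fibers) and lower RTPP.

On real data, from the shell:

```bash
amura compute --dwi dwi.nii.gz --bval dwi.bval --bvec dwi.bvec \
      --shell 3000 --tau 0.05 --tensor --fa-mask 0.2 --out-prefix out/sub01
```

writes `out/sub01_{rtop,rtpp,rtap}.nii.gz` (plus tensor closed-form
counterparts and FA/MD with `--tensor`) and a JSON sidecar recording b,
τ, SH order, λ and mask policy.  `amura validate` runs the synthetic
self-check suite and exits non-zero if any invariant fails.

## SH conventions

Real, antipodally symmetric even-order basis in the modified Descoteaux
ordering: coefficient j ↦ (l, m) with even l ascending and m = −l…l;
m < 0 ↦ √2·Re(Y_l^|m|), m = 0 ↦ Y_l⁰, m > 0 ↦ √2·Im(Y_l^m), so that
Y₀⁰ = 1/√(4π).  Fits use Laplace–Beltrami-penalized least squares
(penalty l²(l+1)², default λ = 0.006, order 6).

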