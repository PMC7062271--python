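"""Apparent RTOP, RTPP and RTAP from one b-shell.

Under a mono-exponential radial model the normalized shell signal is
``E(b, u) = exp(-b * D(u))`` with ``D(u)`` the apparent diffusion
coefficient on the sphere.  The return-to-origin, return-to-plane and
return-to-axis probabilities of the Gaussian-integrated propagator then
collapse to closed forms on a single shell:

* ``RTOP = (4*pi)^-2 * tau^-3/2 * C00{ D^-3/2 }``  (spherical average of
  ``D^-3/2`` via the DC coefficient of its SH expansion), units mm^-3;
* ``RTPP = (4*pi*tau*D_SH(r0))^-1/2`` with ``r0`` the maximum-diffusion
  direction of the SH-smoothed ADC, units mm^-1;
* ``RTAP = (8*pi^2*tau)^-1 * G{1/D}(r0)`` where ``G`` is the Funk-Radon
  transform (great-circle integral of ``1/D`` on the equator normal to
  ``r0``), units mm^-2.

The leading constants are pinned by the isotropic Gaussian limit, in
which the three measures must equal ``(4*pi*tau*D)^-3/2``,
``(4*pi*tau*D)^-1/2`` and ``(4*pi*tau*D)^-1`` exactly; the derivation is
in docs/methods.md and enforced by the test suite.

The three SH expansions (of ``D``, ``1/D`` and ``D^-3/2``) are fitted to
the *transformed samples*, not to powers of a single fitted ``D``: the
DC coefficient of ``D^-3/2`` is the unbiased estimate of the spherical
mean actually integrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gradients import ShellSignal
from .sh import (
    SHBasis,
    SHFitter,
    build_sh_basis,
    evaluate_sh,
    funk_radon_transform,
)
from .tessellation import hemisphere_tessellation

__all__ = [
    "ADCField",
    "MaxDirection",
    "ScalarMap",
    "DEFAULT_SH_ORDER",
    "DEFAULT_LB_LAMBDA",
    "D_MIN",
    "compute_adc",
    "max_diffusion_direction",
    "rtop_apparent",
    "rtpp_apparent",
    "rtap_apparent",
    "compute_all",
]

DEFAULT_SH_ORDER = 6
DEFAULT_LB_LAMBDA = 0.006
D_MIN = 1e-7  # mm^2/s floor: bounds 1/D and D^-3/2 in near-zero-ADC voxels


@dataclass
class ADCField:
    """Per-voxel ADC samples on the shell plus the three SH expansions."""

    samples: np.ndarray  # (n_voxels, n_directions), mm^2/s, >= D_MIN
    directions: np.ndarray
    b: float
    tau: float
    order: int
    lam: float
    sh_D: np.ndarray  # (n_voxels, n_coeffs)
    sh_invD: np.ndarray
    sh_D32: np.ndarray  # SH of D^-3/2
    valid: np.ndarray

    @property
    def n_voxels(self) -> int:
        return self.samples.shape[0]


@dataclass
class MaxDirection:
    """Maximum-diffusion direction per voxel, from the SH-smoothed ADC."""

    r0: np.ndarray  # (n_voxels, 3) unit vectors
    D_at_r0: np.ndarray  # mm^2/s, SH-reconstructed ADC at r0


@dataclass
class ScalarMap:
    """One scalar measure over the voxel set, with provenance metadata."""

    values: np.ndarray
    measure: str  # RTOP | RTPP | RTAP
    units: str
    b: float
    tau: float
    provenance: str = "amura"  # amura | tensor | oracle
    flags: np.ndarray | None = field(default=None, repr=False)


def compute_adc(
    shell: ShellSignal,
    order: int = DEFAULT_SH_ORDER,
    lam: float = DEFAULT_LB_LAMBDA,
    d_min: float = D_MIN,
) -> ADCField:
    """Per-direction ADC ``max(-ln(E)/b, d_min)`` and its three SH fits."""
    D = np.maximum(-np.log(shell.E) / shell.b, d_min)
    basis = build_sh_basis(shell.directions, order)
    fitter = SHFitter(basis, lam)
    return ADCField(
        samples=D,
        directions=shell.directions,
        b=shell.b,
        tau=shell.tau,
        order=order,
        lam=lam,
        sh_D=fitter.fit(D),
        sh_invD=fitter.fit(1.0 / D),
        sh_D32=fitter.fit(D ** -1.5),
        valid=shell.valid.copy(),
    )


def max_diffusion_direction(
    adc: ADCField,
    tessellation: np.ndarray | None = None,
) -> MaxDirection:
    """Argmax of the SH-reconstructed ADC over a dense hemisphere grid.

    Antipodal symmetry of even-order SH makes a hemisphere sufficient;
    ties break to the lowest grid index (np.argmax convention).  No local
    refinement: an order-6 expansion cannot localize its maximum beyond
    the ~2 degree grid spacing anyway.
    """
    if tessellation is None:
        tessellation = hemisphere_tessellation(4)  # 1281 points
    values = evaluate_sh(adc.sh_D, tessellation, adc.order)
    idx = np.argmax(values, axis=-1)
    rows = np.arange(values.shape[0])
    return MaxDirection(r0=tessellation[idx], D_at_r0=values[rows, idx])


def rtop_apparent(adc: ADCField, tau: float | None = None) -> ScalarMap:
    """Return-to-origin probability: (4 pi)^-2 tau^-3/2 C00{D^-3/2}, mm^-3."""
    tau = adc.tau if tau is None else tau
    c00 = adc.sh_D32[..., 0]
    values = c00 / ((4.0 * np.pi) ** 2 * tau ** 1.5)
    values = _mask_invalid(values, adc.valid)
    return ScalarMap(values, "RTOP", "mm^-3", adc.b, tau)


def rtpp_apparent(
    adc: ADCField,
    r0: MaxDirection,
    tau: float | None = None,
    d_min: float = D_MIN,
) -> ScalarMap:
    """Return-to-plane probability: (4 pi tau D_SH(r0))^-1/2, mm^-1.

    The SH-smoothed ADC at the maximum is used instead of the raw sample
    maximum to suppress the variability a max operator would pick up.
    """
    tau = adc.tau if tau is None else tau
    d = r0.D_at_r0
    flagged = d <= 0
    d = np.where(flagged, d_min, d)
    values = (4.0 * np.pi * tau * d) ** -0.5
    values = _mask_invalid(values, adc.valid)
    return ScalarMap(values, "RTPP", "mm^-1", adc.b, tau, flags=flagged)


def rtap_apparent(
    adc: ADCField,
    r0: MaxDirection,
    tau: float | None = None,
) -> ScalarMap:
    """Return-to-axis probability: (8 pi^2 tau)^-1 G{1/D}(r0), mm^-2.

    ``G`` is the Funk-Radon transform, so the value is the great-circle
    integral of ``1/D`` on the equator normal to the maximum-diffusion
    direction.  Negative values from SH ringing are clamped to 0 and
    flagged.
    """
    tau = adc.tau if tau is None else tau
    frt = funk_radon_transform(adc.sh_invD, adc.order)
    g = np.einsum(
        "...k,...k->...",
        frt,
        _basis_at_points(r0.r0, adc.order),
    )
    flagged = g < 0
    values = np.maximum(g, 0.0) / (8.0 * np.pi ** 2 * tau)
    values = _mask_invalid(values, adc.valid)
    return ScalarMap(values, "RTAP", "mm^-2", adc.b, tau, flags=flagged)


def _basis_at_points(points: np.ndarray, order: int) -> np.ndarray:
    """Row-wise SH basis values at one direction per voxel."""
    return build_sh_basis(points, order).values


def _mask_invalid(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if valid is not None and not np.all(valid):
        values = values.copy()
        values[~valid] = np.nan
    return values


def compute_all(
    shell: ShellSignal,
    order: int = DEFAULT_SH_ORDER,
    lam: float = DEFAULT_LB_LAMBDA,
    fa_mask: float | None = None,
    tessellation: np.ndarray | None = None,
) -> dict[str, ScalarMap]:
    """One pass: ADC field, maximum direction, and all three apparent maps.

    ``fa_mask`` (e.g. 0.2) additionally NaN-masks voxels whose tensor FA
    falls below the threshold, replicating the usual white-matter display
    masking.
    """
    adc = compute_adc(shell, order=order, lam=lam)
    r0 = max_diffusion_direction(adc, tessellation)
    maps = {
        "RTOP": rtop_apparent(adc, shell.tau),
        "RTPP": rtpp_apparent(adc, r0, shell.tau),
        "RTAP": rtap_apparent(adc, r0, shell.tau),
    }
    if fa_mask is not None:
        from .tensor import fit_dti, tensor_scalars

        fa = tensor_scalars(fit_dti(shell))["FA"]
        below = ~(fa >= fa_mask)  # NaN FA also masked
        for m in maps.values():
            m.values = m.values.copy()
            m.values[below] = np.nan
    return maps
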