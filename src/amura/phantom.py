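"""Synthetic multi-tensor diffusion phantoms with analytic ground truth.

Voxels are mixtures of Gaussian compartments: ``S(g, b) = S0 * sum_i f_i
exp(-b g^T D_i g)``, the standard multi-tensor HARDI simulation.  Every
phantom carries a truth record: for single-compartment voxels the
closed-form tensor measures, and for mixtures the quadrature-oracle
values of the apparent measures at the probed b (mixtures have no
b-independent truth — the apparent ADC of a mixture depends on b, which
is the behaviour the apparent measures are designed around).

Gradient schemes are generated by electrostatic-repulsion descent over
antipodal point pairs — the classic way uniform DW direction sets are
designed — and subsampled by greedy energy-minimizing removal.

Magnitude noise is Rician: ``sqrt((S + n1)^2 + n2^2)`` with independent
zero-mean Gaussians n1, n2 of scale sigma (SNR = S0/sigma).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .gradients import DWIDataset, GradientTable
from .oracle import multi_tensor_adc, quad_rtap, quad_rtop, quad_rtpp, tensor_adc
from .tensor import tensor_measures_from_eigenvalues

__all__ = [
    "Compartment",
    "PhantomSpec",
    "make_scheme",
    "subsample_scheme",
    "repulsion_energy",
    "reference_scheme_64",
    "tensor_from_axis",
    "simulate_signal",
    "add_rician_noise",
    "phantom_truth",
    "default_phantom_suite",
]

# Canonical eigenvalue sets (mm^2/s)
WM_EIGENVALUES = (1.7e-3, 0.3e-3, 0.3e-3)  # prolate white-matter-like tensor
GM_DIFFUSIVITY = 0.7e-3  # isotropic gray-matter-like
CSF_DIFFUSIVITY = 3.0e-3  # isotropic CSF-like


@dataclass(frozen=True)
class Compartment:
    """One Gaussian compartment: eigenvalues, principal axis, volume fraction."""

    eigenvalues: tuple[float, float, float]  # sorted descending, mm^2/s
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    fraction: float = 1.0

    def tensor(self) -> np.ndarray:
        return tensor_from_axis(self.eigenvalues, self.axis)


@dataclass
class PhantomSpec:
    """Recipe for one synthetic voxel population."""

    compartments: list[Compartment]
    S0: float = 1000.0
    shells: list[tuple[float, int]] = field(default_factory=lambda: [(3000.0, 64)])
    tau: float = 0.05  # s
    noise_sigma: float = 0.0
    seed: int = 0
    n_b0: int = 1
    name: str = "phantom"

    def __post_init__(self):
        total = sum(c.fraction for c in self.compartments)
        if not np.isclose(total, 1.0):
            raise ValueError(f"compartment fractions sum to {total}, not 1")
        if any(min(c.eigenvalues) < 0 for c in self.compartments):
            raise ValueError("negative tensor eigenvalues")
        if any(n < 6 for _, n in self.shells):
            raise ValueError("each shell needs at least 6 directions")


def tensor_from_axis(eigenvalues, axis) -> np.ndarray:
    """Build a 3x3 tensor with given eigenvalues, largest along ``axis``.

    The two transverse eigenvectors are an arbitrary orthonormal
    completion; for the axially symmetric tensors used here their
    orientation is immaterial.
    """
    l1, l2, l3 = eigenvalues
    e1 = np.asarray(axis, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    R = np.column_stack([e1, e2, e3])
    return R @ np.diag([l1, l2, l3]) @ R.T


# ---------------------------------------------------------------------------
# Electrostatic-repulsion gradient schemes


def _antipodal_energy_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
    """Coulomb energy of antipodal point pairs and its gradient.

    ``x`` holds n unconstrained 3-vectors; points are their radial
    projections onto the sphere.  Energy sums 1/distance over both the
    points and their antipodes, so the minimum spreads antipodal *axes*.
    """
    x = x.reshape(-1, 3)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    u = x / norms
    n = u.shape[0]
    diff = u[:, None, :] - u[None, :, :]
    summ = u[:, None, :] + u[None, :, :]
    dd = np.linalg.norm(diff, axis=-1)
    ds = np.linalg.norm(summ, axis=-1)
    iu = np.triu_indices(n, 1)
    energy = float(np.sum(1.0 / dd[iu]) + np.sum(1.0 / ds[iu]))

    np.fill_diagonal(dd, np.inf)
    np.fill_diagonal(ds, np.inf)
    # dE/du_i: each pair contributes -(u_i-u_j)/|.|^3 - (u_i+u_j)/|.|^3
    g_u = -(diff / dd[..., None] ** 3).sum(axis=1) - (summ / ds[..., None] ** 3).sum(axis=1)
    # chain rule through the normalization u = x/|x|
    g_x = (g_u - (np.sum(g_u * u, axis=1, keepdims=True)) * u) / norms
    return energy, g_x.ravel()


def repulsion_energy(directions: np.ndarray) -> float:
    """Antipodally symmetrized electrostatic energy of a direction set."""
    e, _ = _antipodal_energy_grad(np.asarray(directions, dtype=float).ravel())
    return e


def make_scheme(
    n: int,
    seed: int = 0,
    n_restarts: int = 4,
    maxiter: int = 1000,
) -> np.ndarray:
    """n approximately uniform unit directions by electrostatic repulsion.

    L-BFGS descent of the antipodal Coulomb energy from several random
    starts; the lowest-energy result is returned.  Deterministic for a
    given seed.  The returned set is canonically oriented into the upper
    hemisphere and sorted for reproducibility.
    """
    if n < 6:
        raise ValueError("at least 6 directions are required")
    rng = np.random.default_rng(seed)
    best = None
    best_e = np.inf
    for _ in range(n_restarts):
        x0 = rng.standard_normal(3 * n)
        res = minimize(
            _antipodal_energy_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10},
        )
        if res.fun < best_e:
            best_e = res.fun
            best = res.x
    u = best.reshape(-1, 3)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    flip = u[:, 2] < 0
    u[flip] *= -1.0
    order = np.lexsort((u[:, 0], u[:, 1], u[:, 2]))
    return u[order]


def min_pairwise_angle(directions: np.ndarray) -> float:
    """Smallest antipodally-folded angle (degrees) between any two directions."""
    u = np.asarray(directions, dtype=float)
    dots = np.abs(u @ u.T)
    np.fill_diagonal(dots, 0.0)
    return float(np.degrees(np.arccos(np.clip(dots.max(), -1.0, 1.0))))


def subsample_scheme(directions: np.ndarray, m: int) -> np.ndarray:
    """Greedy energy-minimizing subsample of a direction set.

    Repeatedly removes the direction whose deletion lowers the antipodal
    repulsion energy the most, until ``m`` remain.  Deterministic given
    the input ordering (ties break to the lowest index).
    """
    u = np.asarray(directions, dtype=float).copy()
    n = u.shape[0]
    if m > n:
        raise ValueError(f"cannot subsample {n} directions to {m}")
    if m < 6:
        raise ValueError("at least 6 directions must remain")
    keep = list(range(n))
    # pairwise energy contributions, symmetric
    diff = np.linalg.norm(u[:, None, :] - u[None, :, :], axis=-1)
    summ = np.linalg.norm(u[:, None, :] + u[None, :, :], axis=-1)
    with np.errstate(divide="ignore"):
        pair = 1.0 / diff + 1.0 / summ
    np.fill_diagonal(pair, 0.0)
    while len(keep) > m:
        sub = pair[np.ix_(keep, keep)]
        contrib = sub.sum(axis=1)  # energy removed by deleting each point
        drop = int(np.argmax(contrib))
        del keep[drop]
    return u[keep]


def reference_scheme_64() -> np.ndarray:
    """Synthetic 64-direction reference scheme (energy benchmark).

    A frozen, heavily converged electrostatic-repulsion design (many
    restarts, tight tolerances) shipped as a text fixture.  It is a
    synthetic stand-in for a published uniform 64-direction table and is
    used only as an energy yardstick in tests.
    """
    ref = importlib.resources.files("amura.data").joinpath("scheme64_synthetic.bvec")
    with importlib.resources.as_file(ref) as path:
        bvecs = np.loadtxt(path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return bvecs / np.linalg.norm(bvecs, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Signal synthesis


def simulate_signal(spec: PhantomSpec, scheme: np.ndarray | None = None,
                    n_voxels: int = 1) -> DWIDataset:
    """Noise-free multi-tensor signal for every shell in the spec.

    Returns a DWIDataset of shape (n_voxels, 1, 1, n_volumes): b0 volumes
    first, then each shell's directions.  If ``scheme`` is given it is
    used for every shell (its row count must match); otherwise each
    shell's scheme is generated from the spec seed.
    """
    bvals = [0.0] * spec.n_b0
    bvecs = [np.zeros(3)] * spec.n_b0
    signals = [np.full(spec.n_b0, spec.S0)]
    tensors = [c.tensor() for c in spec.compartments]
    fracs = [c.fraction for c in spec.compartments]
    for i, (b, n_dirs) in enumerate(spec.shells):
        dirs = scheme if scheme is not None else make_scheme(n_dirs, seed=spec.seed + i)
        if dirs.shape[0] != n_dirs:
            raise ValueError("scheme size does not match shell direction count")
        E = sum(
            f * np.exp(-b * np.einsum("ki,ij,kj->k", dirs, D, dirs))
            for f, D in zip(fracs, tensors)
        )
        bvals.extend([b] * n_dirs)
        bvecs.extend(dirs)
        signals.append(spec.S0 * E)
    table = GradientTable(np.array(bvals), np.array(bvecs))
    sig = np.concatenate(signals)
    vol = np.broadcast_to(sig, (n_voxels, 1, 1, sig.size)).copy()
    return DWIDataset(signal=vol, affine=np.eye(4), gradients=table)


def add_rician_noise(data: DWIDataset, sigma: float, seed: int = 0) -> DWIDataset:
    """Rician magnitude noise: sqrt((S+n1)^2 + n2^2), n1,n2 ~ N(0, sigma)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return DWIDataset(data.signal.copy(), data.affine, data.gradients,
                          None if data.mask is None else data.mask.copy())
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=data.signal.shape)
    n2 = rng.normal(0.0, sigma, size=data.signal.shape)
    noisy = np.sqrt((data.signal + n1) ** 2 + n2 ** 2)
    return DWIDataset(noisy, data.affine, data.gradients,
                      None if data.mask is None else data.mask.copy())


def phantom_truth(spec: PhantomSpec, b: float | None = None) -> dict[str, float]:
    """Ground-truth apparent measures for one phantom voxel.

    Single compartment: the closed-form tensor expressions (exact — the
    mono-exponential single-tensor signal satisfies both models).
    Mixtures: quadrature-oracle values of the apparent measures at the
    probed b-value.
    """
    tau = spec.tau
    if len(spec.compartments) == 1:
        l = sorted(spec.compartments[0].eigenvalues, reverse=True)
        rtop, rtpp, rtap = tensor_measures_from_eigenvalues(np.array(l), tau)
        return {"RTOP": float(rtop), "RTPP": float(rtpp), "RTAP": float(rtap)}
    if b is None:
        b = spec.shells[0][0]
    adc = multi_tensor_adc(
        [c.tensor() for c in spec.compartments],
        [c.fraction for c in spec.compartments],
        b,
    )
    return {
        "RTOP": quad_rtop(adc, tau),
        "RTPP": quad_rtpp(adc, tau),
        "RTAP": quad_rtap(adc, tau),
    }


def default_phantom_suite(
    b: float = 3000.0, n_dirs: int = 64, tau: float = 0.05, seed: int = 0
) -> list[PhantomSpec]:
    """The standard validation population.

    Isotropic CSF-like and gray-matter-like voxels, a prolate
    white-matter tensor, and 90/60-degree two-tensor crossings at 0.5/0.5
    and 0.7/0.3 volume fractions — spanning low-FA to high-FA regimes.
    """
    shells = [(b, n_dirs)]
    wm = WM_EIGENVALUES
    x, z = (1.0, 0.0, 0.0), (0.0, 0.0, 1.0)
    deg60 = (np.sin(np.pi / 3), 0.0, np.cos(np.pi / 3))
    iso = lambda d: (d, d, d)
    return [
        PhantomSpec([Compartment(iso(CSF_DIFFUSIVITY))], shells=shells, tau=tau,
                    seed=seed, name="csf_isotropic"),
        PhantomSpec([Compartment(iso(GM_DIFFUSIVITY))], shells=shells, tau=tau,
                    seed=seed, name="gray_isotropic"),
        PhantomSpec([Compartment(wm, z)], shells=shells, tau=tau, seed=seed,
                    name="wm_prolate"),
        PhantomSpec(
            [Compartment(wm, z, 0.5), Compartment(wm, x, 0.5)],
            shells=shells, tau=tau, seed=seed, name="crossing90_5050",
        ),
        PhantomSpec(
            [Compartment(wm, z, 0.7), Compartment(wm, x, 0.3)],
            shells=shells, tau=tau, seed=seed, name="crossing90_7030",
        ),
        PhantomSpec(
            [Compartment(wm, z, 0.5), Compartment(wm, deg60, 0.5)],
            shells=shells, tau=tau, seed=seed, name="crossing60_5050",
        ),
        PhantomSpec(
            [Compartment(wm, z, 0.7), Compartment(wm, deg60, 0.3)],
            shells=shells, tau=tau, seed=seed, name="crossing60_7030",
        ),
    ]
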