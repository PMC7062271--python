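"""Diffusion-tensor reference: log-linear fit, scalar invariants, closed forms.

The Gaussian (Stejskal-Tanner) model ``E = exp(-b g^T D g)`` admits exact
closed forms for the return probabilities in terms of the sorted
eigenvalues ``l1 >= l2 >= l3`` of the tensor::

    RTOP = (4 pi tau)^-3/2 (l1 l2 l3)^-1/2
    RTPP = (4 pi tau l1)^-1/2
    RTAP = (4 pi tau)^-1  (l2 l3)^-1/2

with ``RTOP = RTPP * RTAP`` holding identically (the Gaussian factorizes
along and across the principal axis).  These serve as the "end of scale"
comparator for the apparent single-shell measures, and the tensor scalars
(FA, MD, Westin's Cl/Cp/Cs) drive masking and outlier screening.

The fit is ordinary least squares on the log-signal — deterministic and
reproducible, which is what a comparator needs; no WLS/NLLS refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gradients import ShellSignal
from .measures import ScalarMap

__all__ = [
    "TensorFit",
    "fit_dti",
    "tensor_scalars",
    "tensor_measures",
    "tensor_measures_from_eigenvalues",
]


@dataclass
class TensorFit:
    """Eigen-decomposed tensor per voxel (eigenvalues sorted descending)."""

    eigenvalues: np.ndarray  # (n_voxels, 3), mm^2/s, l1 >= l2 >= l3
    eigenvectors: np.ndarray  # (n_voxels, 3, 3), columns matched to eigenvalues
    residual: np.ndarray  # per-voxel RMS of the log-signal fit
    clamped: np.ndarray  # voxels where a negative eigenvalue was clamped to 0

    @property
    def n_voxels(self) -> int:
        return self.eigenvalues.shape[0]


def _design_matrix(directions: np.ndarray, b: float) -> np.ndarray:
    """ln E = -b g^T D g -> linear in the 6 unique tensor components."""
    g = np.asarray(directions, dtype=float)
    return -b * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def fit_dti(shell: ShellSignal) -> TensorFit:
    """Ordinary least-squares tensor fit on the log attenuations.

    Requires at least 6 non-coplanar directions; the normal solve matrix
    is formed once for the scheme and applied to all voxels.
    """
    X = _design_matrix(shell.directions, shell.b)
    rank = np.linalg.matrix_rank(X)
    if rank < 6:
        raise ValueError(
            f"rank-deficient tensor design (rank {rank} from "
            f"{shell.n_directions} directions); need >= 6 non-coplanar"
        )
    y = np.log(shell.E)  # (n_voxels, n_directions)
    coef, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    coef = coef.T  # (n_voxels, 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    resid = y - coef @ X.T
    rms = np.sqrt(np.mean(resid ** 2, axis=-1))

    D = np.empty((coef.shape[0], 3, 3))
    D[:, 0, 0] = coef[:, 0]
    D[:, 1, 1] = coef[:, 1]
    D[:, 2, 2] = coef[:, 2]
    D[:, 0, 1] = D[:, 1, 0] = coef[:, 3]
    D[:, 0, 2] = D[:, 2, 0] = coef[:, 4]
    D[:, 1, 2] = D[:, 2, 1] = coef[:, 5]
    evals, evecs = np.linalg.eigh(D)  # ascending
    evals = evals[:, ::-1]
    evecs = evecs[:, :, ::-1]
    clamped = np.any(evals < 0, axis=-1)
    evals = np.maximum(evals, 0.0)
    return TensorFit(evals, evecs, rms, clamped)


def tensor_scalars(fit: TensorFit) -> dict[str, np.ndarray]:
    """FA, MD and the trace-normalized Westin shape scalars.

    ``Cl = (l1-l2)/tr``, ``Cp = 2(l2-l3)/tr``, ``Cs = 3*l3/tr`` so that
    ``Cl + Cp + Cs = 1``; all lie in [0, 1].  Zero-trace voxels get NaN.
    """
    l = fit.eigenvalues
    tr = l.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        md = tr / 3.0
        dev = l - md[..., None]
        denom = np.sqrt((l ** 2).sum(axis=-1))
        fa = np.sqrt(1.5 * (dev ** 2).sum(axis=-1)) / denom
        cl = (l[..., 0] - l[..., 1]) / tr
        cp = 2.0 * (l[..., 1] - l[..., 2]) / tr
        cs = 3.0 * l[..., 2] / tr
    bad = tr <= 0
    for arr in (fa, cl, cp, cs):
        arr[bad] = np.nan
    md = np.where(bad, np.nan, md)
    return {"FA": fa, "MD": md, "Cl": cl, "Cp": cp, "Cs": cs}


def tensor_measures_from_eigenvalues(
    eigenvalues: np.ndarray, tau: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form (RTOP, RTPP, RTAP) from sorted eigenvalues; NaN if any l <= 0."""
    l = np.asarray(eigenvalues, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rtpp = (4.0 * np.pi * tau * l[..., 0]) ** -0.5
        rtap = ((4.0 * np.pi * tau) * np.sqrt(l[..., 1] * l[..., 2])) ** -1.0
        rtop = (4.0 * np.pi * tau) ** -1.5 * np.prod(l, axis=-1) ** -0.5
    bad = np.any(l <= 0, axis=-1)
    rtop = np.where(bad, np.nan, rtop)
    rtpp = np.where(l[..., 0] <= 0, np.nan, rtpp)
    rtap = np.where((l[..., 1] <= 0) | (l[..., 2] <= 0), np.nan, rtap)
    return rtop, rtpp, rtap


def tensor_measures(fit: TensorFit, tau: float, b: float = np.nan) -> dict[str, ScalarMap]:
    """Tensor closed-form RTOP/RTPP/RTAP maps (provenance "tensor")."""
    rtop, rtpp, rtap = tensor_measures_from_eigenvalues(fit.eigenvalues, tau)
    return {
        "RTOP": ScalarMap(rtop, "RTOP", "mm^-3", b, tau, provenance="tensor"),
        "RTPP": ScalarMap(rtpp, "RTPP", "mm^-1", b, tau, provenance="tensor"),
        "RTAP": ScalarMap(rtap, "RTAP", "mm^-2", b, tau, provenance="tensor"),
    }
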