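"""Diffusion-weighted data I/O: NIfTI volumes, FSL gradient tables, shells.

A diffusion acquisition is a 4-D magnitude volume plus a gradient table
(b-values in s/mm^2 and unit encoding directions).  Everything downstream
works on one *shell*: the normalized attenuations ``E = S / S0`` at a
single b-value, together with the shell's direction set and the effective
diffusion time ``tau`` (seconds), which fixes the physical units of all
derived measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "GradientTable",
    "DWIDataset",
    "ShellSignal",
    "read_bvals_bvecs",
    "load_dwi",
    "extract_shell",
    "save_scalar_map",
    "load_scalar_map",
]

DEFAULT_B0_THRESHOLD = 50.0  # s/mm^2; scanner b-values jitter around nominal shells
DEFAULT_B_TOLERANCE = 50.0
DEFAULT_TAU = 0.05  # s; user-supplied in practice, fixes the unit scale only
E_CLIP_MIN = 1e-10  # lower clip on attenuation so log(E) is always defined;
# small enough not to truncate any physical decay (e.g. CSF at b=5000 gives
# E ~ 3e-7); division blow-ups are guarded by the separate ADC floor D_MIN


@dataclass(frozen=True)
class GradientTable:
    """Per-volume b-values and unit gradient directions.

    Directions are normalized on construction; volumes with
    ``bval <= b0_threshold`` count as baselines (their direction is kept
    as-is and never used).  Directions are treated as antipodally
    symmetric throughout, so bvec sign conventions are immaterial.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = DEFAULT_B0_THRESHOLD

    def __post_init__(self):
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2:
            raise ValueError("bvecs must be 2-D")
        if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
            bvecs = bvecs.T  # FSL files store 3 rows x n columns
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"gradient table mismatch: {bvals.size} b-values vs "
                f"{bvecs.shape[0]} directions"
            )
        if not (np.all(np.isfinite(bvals)) and np.all(np.isfinite(bvecs))):
            raise ValueError("non-finite values in gradient table")
        if np.any(bvals < 0):
            raise ValueError("negative b-values in gradient table")
        norms = np.linalg.norm(bvecs, axis=1)
        dwi = bvals > self.b0_threshold
        if np.any(norms[dwi] == 0):
            raise ValueError("zero-norm direction for a diffusion-weighted volume")
        bvecs = bvecs.copy()
        bvecs[dwi] /= norms[dwi, None]
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.b0_threshold

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    def __len__(self) -> int:
        return self.bvals.size


@dataclass
class DWIDataset:
    """4-D diffusion volume with its gradient table and optional mask."""

    signal: np.ndarray  # (x, y, z, n_volumes)
    affine: np.ndarray
    gradients: GradientTable
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be a 4-D array")
        if self.signal.shape[-1] != len(self.gradients):
            raise ValueError(
                f"signal has {self.signal.shape[-1]} volumes but gradient "
                f"table has {len(self.gradients)} entries"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("non-finite values in DWI signal")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.signal.shape[:3]:
                raise ValueError("mask shape does not match volume shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class ShellSignal:
    """Normalized attenuations of one b-shell, flattened over in-mask voxels.

    ``E`` is S/S0 clipped to ``[E_CLIP_MIN, 1]`` so the per-direction ADC
    ``-ln(E)/b`` is finite and non-negative.  Spatial bookkeeping (volume
    shape, mask, affine) is carried along so scalar maps can be written
    back as volumes; ``valid`` flags voxels whose mean baseline was
    positive.
    """

    E: np.ndarray  # (n_voxels, n_directions)
    directions: np.ndarray  # (n_directions, 3), unit
    b: float  # s/mm^2
    tau: float = DEFAULT_TAU  # s
    shape: tuple[int, int, int] | None = None
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None
    valid: np.ndarray | None = None  # (n_voxels,) bool

    def __post_init__(self):
        self.E = np.atleast_2d(np.asarray(self.E, dtype=float))
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if self.E.shape[-1] != self.directions.shape[0]:
            raise ValueError("E and directions disagree on direction count")
        if self.b <= 0 or self.tau <= 0:
            raise ValueError("b and tau must be positive")
        if np.any(self.E <= 0):
            raise ValueError("attenuations must be strictly positive (clip first)")
        if self.valid is None:
            self.valid = np.ones(self.E.shape[0], dtype=bool)

    @property
    def n_voxels(self) -> int:
        return self.E.shape[0]

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]

    def unflatten(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter per-voxel values back into the 3-D volume (NaN outside mask)."""
        if self.shape is None:
            return np.asarray(values)
        out = np.full(self.shape, fill, dtype=float)
        if self.mask is None:
            out = np.asarray(values, dtype=float).reshape(self.shape)
        else:
            out[self.mask] = values
        return out


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-style whitespace-separated bval/bvec text files.

    bvec files may be 3 rows x n columns (FSL) or n rows x 3 columns;
    the orientation is auto-detected from the shape.
    """
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.ndim == 1:
        bvecs = bvecs.reshape(-1, 3)
    return bvals, bvecs


def load_dwi(
    dwi_path,
    bval_path,
    bvec_path,
    mask_path=None,
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
) -> DWIDataset:
    """Load a 4-D NIfTI diffusion volume with its FSL gradient table."""
    img = nib.load(str(dwi_path))
    data = np.asarray(img.dataobj, dtype=float)
    bvals, bvecs = read_bvals_bvecs(bval_path, bvec_path)
    if data.ndim != 4:
        raise ValueError(f"{dwi_path}: expected a 4-D volume, got {data.ndim}-D")
    if data.shape[-1] != bvals.size:
        raise ValueError(
            f"{dwi_path} has {data.shape[-1]} volumes but {bval_path} lists "
            f"{bvals.size} b-values"
        )
    table = GradientTable(bvals, bvecs, b0_threshold=b0_threshold)
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    return DWIDataset(signal=data, affine=img.affine, gradients=table, mask=mask)


def extract_shell(
    data: DWIDataset,
    b_target: float,
    b_tolerance: float = DEFAULT_B_TOLERANCE,
    tau: float = DEFAULT_TAU,
) -> ShellSignal:
    """Select one b-shell and normalize it by the mean baseline.

    All volumes with ``|bval - b_target| <= b_tolerance`` (and above the
    b0 threshold) form the shell; the signal is divided voxel-wise by the
    arithmetic mean of all baseline volumes and clipped to
    ``[E_CLIP_MIN, 1]``.  Voxels with a non-positive mean baseline are
    flagged invalid.
    """
    gt = data.gradients
    if gt.n_b0 == 0:
        raise ValueError("no baseline (b0) volume available for normalization")
    sel = (~gt.b0_mask) & (np.abs(gt.bvals - b_target) <= b_tolerance)
    n_sel = int(sel.sum())
    if n_sel == 0:
        raise ValueError(
            f"no directions within {b_tolerance} s/mm^2 of b={b_target}"
        )
    if n_sel < 6:
        warnings.warn(
            f"only {n_sel} directions at b={b_target}: too few for any SH fit "
            "(order-2 minimum is 6)",
            stacklevel=2,
        )
    elif n_sel < 15:
        warnings.warn(
            f"{n_sel} directions at b={b_target}: fewer than the 15 needed "
            "for an order-4 SH fit",
            stacklevel=2,
        )

    s0 = data.signal[..., gt.b0_mask].mean(axis=-1)
    shell = data.signal[..., sel]
    mask = data.mask if data.mask is not None else np.ones(data.shape, bool)
    s0_flat = s0[mask]
    shell_flat = shell[mask]
    valid = s0_flat > 0
    E = np.full_like(shell_flat, 1.0)
    E[valid] = shell_flat[valid] / s0_flat[valid, None]
    E = np.clip(E, E_CLIP_MIN, 1.0)
    return ShellSignal(
        E=E,
        directions=gt.bvecs[sel],
        b=float(np.mean(gt.bvals[sel])),
        tau=tau,
        shape=data.shape,
        mask=mask,
        affine=data.affine,
        valid=valid,
    )


def save_scalar_map(path, values: np.ndarray, affine: np.ndarray) -> None:
    """Write a 3-D scalar map as NIfTI-1 (float64, value-preserving)."""
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine), str(path))


def load_scalar_map(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine
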