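"""Single-tensor estimation from DWI signals.

The estimator is ordinary log-linear least squares: with the design
matrix B built from the gradient scheme, each voxel solves

    -ln(S / S0) = B d,    d = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)

where S0 is the mean of the b=0 volumes (duplicate b=0 acquisitions
are averaged before fitting).  The log-linear inversion is exact for
noiseless single-compartment data; a weighted variant (WLS, weights
S^2) is available behind a flag for noisy data.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import DWIVolume
from .scheme import GradientScheme

__all__ = ["TensorField", "DiffusivityMaps", "fit_tensor_loglinear", "tensor_maps"]

SIGNAL_FLOOR_FRACTION = 1e-6  # clamp S <= 0 to this fraction of S0 before log


@dataclass
class TensorField:
    """Voxelwise symmetric tensor components (mm^2/s) in the order
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz), with a per-voxel quality flag.

    ``flags`` marks voxels whose signal was clamped before the log or
    whose fitted tensor has a negative eigenvalue.
    """

    components: np.ndarray  # (..., 6)
    flags: np.ndarray  # (...,) bool

    def as_matrices(self) -> np.ndarray:
        d = self.components
        out = np.empty(d.shape[:-1] + (3, 3))
        out[..., 0, 0] = d[..., 0]
        out[..., 1, 1] = d[..., 1]
        out[..., 2, 2] = d[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = d[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = d[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = d[..., 5]
        return out


@dataclass
class DiffusivityMaps:
    """Derived per-voxel maps: axis diffusivities, eigenvalues sorted
    descending, mean diffusivity and fractional anisotropy."""

    Dxx: np.ndarray
    Dyy: np.ndarray
    Dzz: np.ndarray
    eigenvalues: np.ndarray  # (..., 3), lam1 >= lam2 >= lam3
    MD: np.ndarray
    FA: np.ndarray
    flags: np.ndarray

    def write_niftis(self, outdir: str | Path, voxel_size: float = 2.0) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        affine = np.diag([voxel_size] * 3 + [1.0])
        for name in ("Dxx", "Dyy", "Dzz", "MD", "FA"):
            img = nib.Nifti1Image(getattr(self, name).astype(np.float32), affine)
            nib.save(img, str(outdir / f"{name}.nii.gz"))


def fit_tensor_loglinear(dwi: DWIVolume, weighted: bool = False) -> TensorField:
    """Fit one symmetric diffusion tensor per voxel by (weighted) linear
    least squares on the log signal.

    Non-positive signals are clamped to ``1e-6 * S0`` and the voxel is
    flagged; voxels with S0 <= 0 are flagged and returned as zero.
    """
    scheme = dwi.scheme
    b0 = scheme.b0_mask
    dwi_mask = ~b0
    design = scheme.design_matrix()[dwi_mask]
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError("design matrix is rank-deficient")

    signal = dwi.signal
    s0 = signal[..., b0].mean(axis=-1)
    s = signal[..., dwi_mask]

    dead = s0 <= 0
    s0_safe = np.where(dead, 1.0, s0)
    floor = SIGNAL_FLOOR_FRACTION * s0_safe[..., None]
    clamped = s < floor  # non-positive or underflowing signals
    s_safe = np.maximum(s, floor)

    y = -np.log(s_safe / s0_safe[..., None])  # (..., n_dwi)
    shape = y.shape[:-1]
    y2 = y.reshape(-1, y.shape[-1])

    if weighted:
        w = (s_safe.reshape(-1, y.shape[-1])) ** 2
        comps = np.empty((y2.shape[0], 6))
        for i in range(y2.shape[0]):
            wa = w[i][:, None] * design
            comps[i] = np.linalg.lstsq(wa, w[i] * y2[i], rcond=None)[0]
    else:
        pinv = np.linalg.pinv(design)
        comps = y2 @ pinv.T

    comps = comps.reshape(shape + (6,))
    flags = clamped.any(axis=-1) | dead
    comps[dead] = 0.0

    field = TensorField(components=comps, flags=flags)
    evals = np.linalg.eigvalsh(field.as_matrices())
    field.flags = field.flags | (evals[..., 0] < 0)
    return field


def tensor_maps(field: TensorField) -> DiffusivityMaps:
    """Eigen-decompose the tensor field and derive MD and FA.

    FA = sqrt(3/2) * ||lam - mean(lam)|| / ||lam||, computed on
    eigenvalues clamped at zero (negative eigenvalues are a noise
    artefact; clamping keeps FA in [0, 1]).  The axis diffusivities
    Dxx/Dyy/Dzz are reported unclamped, since they enter the ALPS
    ratios directly.
    """
    d = field.components
    if not np.all(np.isfinite(d)):
        raise ValueError("tensor field contains non-finite components")
    evals = np.linalg.eigvalsh(field.as_matrices())[..., ::-1]  # descending
    md = evals.mean(axis=-1)

    lam = np.clip(evals, 0.0, None)
    lam_bar = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt((np.square(lam - lam_bar)).sum(axis=-1))
    den = np.sqrt(np.square(lam).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)

    flags = field.flags | (evals[..., -1] < 0)
    return DiffusivityMaps(
        Dxx=d[..., 0], Dyy=d[..., 1], Dzz=d[..., 2],
        eigenvalues=evals, MD=md, FA=fa, flags=flags,
    )
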