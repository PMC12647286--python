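"""Diffusion gradient schemes and FSL-style bvec/bval I/O.

A single-shell scheme with at least six unique, non-collinear b>0
directions is required for single-tensor estimation: the log-linear
design matrix built from outer products of the directions must have
full column rank (6 unique tensor components).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GradientScheme", "default_scheme", "DEFAULT_BVALUE"]

DEFAULT_BVALUE = 1000.0  # s/mm^2, single shell

# Twelve-axis table obtained by minimising the antipodally symmetric
# electrostatic energy on the unit sphere (canonicalised to z >= 0).
# This is a stand-in scheme: clinical 12-axis tables are vendor specific
# and no canonical table is mandated anywhere in this package.
ELECTROSTATIC_12 = np.array(
    [
        (-0.803175268335156, -0.408459179215396, +0.433671058810057),
        (-0.692496009649294, +0.718866280552215, +0.060667514411170),
        (-0.641573052468476, +0.222504014533649, +0.734081726964166),
        (-0.252765385604663, -0.701789395125466, +0.666034011691265),
        (-0.226780816056799, +0.785719343758335, +0.575513313757887),
        (-0.093167109707508, -0.995158372431173, +0.031300214837720),
        (-0.025771189360033, -0.105646947918382, +0.994069699867419),
        (+0.323659413886593, +0.492445160316307, +0.807924716717859),
        (+0.440252501260441, -0.674542382207013, +0.592596245128514),
        (+0.709011860845945, +0.667086200498859, +0.228687958326988),
        (+0.743605167554630, -0.046236118818135, +0.667018422611165),
        (+0.995795237958701, -0.090564713967243, +0.013779573389843),
    ]
)


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume diffusion encoding: unit directions and b-values.

    Parameters
    ----------
    directions : (n, 3) array
        Gradient directions; rows with b > 0 must have unit norm.
        Directions attached to b = 0 volumes are ignored.
    bvalues : (n,) array
        b-value per volume in s/mm^2; at least one must be 0.
    """

    directions: np.ndarray
    bvalues: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        b = np.asarray(self.bvalues, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3:
            raise ValueError("directions must be an (n, 3) array")
        if b.shape != (d.shape[0],):
            raise ValueError("bvalues length must match directions")
        if not np.any(b == 0):
            raise ValueError("scheme must contain at least one b=0 volume")
        dwi = b > 0
        norms = np.linalg.norm(d[dwi], axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("b>0 directions must have unit norm (1e-9)")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "bvalues", b)
        dm = self.design_matrix()
        if np.linalg.matrix_rank(dm[dwi]) < 6:
            raise ValueError(
                "gradient directions are degenerate: design matrix is "
                "rank-deficient (need >= 6 unique non-collinear directions)"
            )

    def __len__(self) -> int:
        return self.bvalues.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.b0_mask))

    def design_matrix(self) -> np.ndarray:
        """Rows b * [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz].

        ``ln(S/S0) = -B d`` with d the 6 unique tensor components in
        the order (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz).
        """
        g = self.directions
        b = self.bvalues
        return b[:, None] * np.column_stack(
            [
                g[:, 0] ** 2,
                g[:, 1] ** 2,
                g[:, 2] ** 2,
                2 * g[:, 0] * g[:, 1],
                2 * g[:, 0] * g[:, 2],
                2 * g[:, 1] * g[:, 2],
            ]
        )

    # ------------------------------------------------------------------ I/O
    def to_files(self, bvec_path: str | Path, bval_path: str | Path) -> None:
        """Write FSL-style bvec (3 rows) and bval (1 row) text files."""
        np.savetxt(bvec_path, self.directions.T, fmt="%.15f")
        np.savetxt(bval_path, self.bvalues[None, :], fmt="%.1f")

    @classmethod
    def from_files(cls, bvec_path: str | Path, bval_path: str | Path) -> "GradientScheme":
        d = np.loadtxt(bvec_path)
        if d.shape[0] == 3:
            d = d.T
        b = np.atleast_1d(np.loadtxt(bval_path)).ravel()
        return cls(directions=d, bvalues=b)


def default_scheme(bvalue: float = DEFAULT_BVALUE, n_b0: int = 2) -> GradientScheme:
    """The packaged single-shell scheme: ``n_b0`` b=0 volumes followed by
    the 12-axis electrostatic table at ``bvalue`` s/mm^2.

    Duplicate b=0 volumes mirror two-average acquisitions; they are
    averaged before tensor fitting.
    """
    n_dwi = ELECTROSTATIC_12.shape[0]
    directions = np.vstack([np.zeros((n_b0, 3)), ELECTROSTATIC_12])
    bvalues = np.concatenate([np.zeros(n_b0), np.full(n_dwi, float(bvalue))])
    return GradientScheme(directions=directions, bvalues=bvalues)
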