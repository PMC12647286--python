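"""Voxel-backed imaging mode for the synthetic cohort.

For each scan row, a DWI phantom is simulated whose perivascular
fractions are chosen — via a noiseless calibration curve mapping
perivascular fraction to fitted index — so that the fitted ALPS and
variant indices track the scan's tabular (copula-drawn) targets.
Forcing an exact covariance through voxel simulation is impossible
(Rician noise and the nonlinear fraction-to-index map intervene), so
the voxel route reproduces the planted structure only approximately;
the tabular route is the statistical reference surface.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import all_indices, regional_means
from .phantom import PhantomSpec, build_phantom, simulate_dwi
from .scheme import default_scheme
from .tensorfit import fit_tensor_loglinear, tensor_maps

__all__ = ["calibration_curves", "simulate_scan_indices"]

_F_GRID = np.linspace(0.0, 0.6, 13)

_OVERWRITE_COLUMNS = [
    "ALPS", "ccgALPS", "ccbALPS", "ccsALPS",
    "projDxx", "projDyy", "projDzz",
    "assocDxx", "assocDyy", "assocDzz",
    "ccbDxx", "ccbDyy", "ccbDzz",
]


def _indices_for_fraction(f: float) -> dict[str, float]:
    regions = ("proj_L", "proj_R", "assoc_L", "assoc_R", "ccg", "ccb", "ccs")
    spec = PhantomSpec(
        pvs_fraction=float(f),
        pvs_fraction_by_region={r: float(f) for r in regions},
        snr=np.inf,
    )
    scheme = default_scheme()
    field = build_phantom(spec)
    dwi = simulate_dwi(field, scheme, snr=np.inf)
    maps = tensor_maps(fit_tensor_loglinear(dwi))
    reg = regional_means(maps, field.labels)
    return all_indices(reg).as_dict()


def calibration_curves() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Noiseless fraction -> index curves for ALPS and each variant.

    Each curve is monotone increasing in the perivascular fraction
    (the vessel-axis diffusivity can only grow with the fraction of
    the fast perivascular compartment), so it is invertible on the
    grid by linear interpolation.
    """
    values = {k: [] for k in ("ALPS", "ccgALPS", "ccbALPS", "ccsALPS")}
    for f in _F_GRID:
        idx = _indices_for_fraction(f)
        for k in values:
            values[k].append(idx[k])
    return {k: (_F_GRID.copy(), np.asarray(v)) for k, v in values.items()}


def _invert(curve: tuple[np.ndarray, np.ndarray], target: float) -> float:
    f_grid, index_vals = curve
    # clamp: targets below the f=0 index (ratio 1) map to f=0
    return float(np.interp(target, index_vals, f_grid))


def simulate_scan_indices(
    table: pd.DataFrame, seed: int = 0, snr: float = 20.0
) -> dict[str, list[float]]:
    """Simulate one phantom per scan row and return phantom-derived
    replacement columns (indices and regional diffusivities)."""
    curves = calibration_curves()
    scheme = default_scheme()
    child_seeds = np.random.SeedSequence(seed).spawn(len(table))
    out: dict[str, list[float]] = {c: [] for c in _OVERWRITE_COLUMNS}
    for (_, row), child in zip(table.iterrows(), child_seeds):
        fractions = {
            "proj_L": _invert(curves["ALPS"], row["ALPS"]),
            "proj_R": _invert(curves["ALPS"], row["ALPS"]),
            "assoc_L": _invert(curves["ALPS"], row["ALPS"]),
            "assoc_R": _invert(curves["ALPS"], row["ALPS"]),
            "ccg": _invert(curves["ccgALPS"], row["ccgALPS"]),
            "ccb": _invert(curves["ccbALPS"], row["ccbALPS"]),
            "ccs": _invert(curves["ccsALPS"], row["ccsALPS"]),
        }
        spec = PhantomSpec(pvs_fraction_by_region=fractions, snr=snr)
        field = build_phantom(spec)
        dwi = simulate_dwi(field, scheme, snr=snr, seed=child)
        maps = tensor_maps(fit_tensor_loglinear(dwi))
        reg = regional_means(maps, field.labels)
        idx = all_indices(reg).as_dict()
        for k in ("ALPS", "ccgALPS", "ccbALPS", "ccsALPS"):
            out[k].append(idx[k])
        for k in _OVERWRITE_COLUMNS[4:]:
            out[k].append(reg[k])
    return out
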