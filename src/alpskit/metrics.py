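"""Regional aggregation, ALPS indices, session deltas and head motion.

The ALPS index compares diffusivity along the perivascular (x) axis in
the periventricular projection- and association-fiber regions against
diffusivity across both the fibers and the vessels:

    ALPS = mean(projDxx, assocDxx) / mean(projDyy, assocDzz)

A value of 1 indicates no preferential diffusivity along the
perivascular axis.  The corpus-callosum variant indices apply the same
logic with each region's vessel axis in the numerator and the axis
perpendicular to both vessels and the left-right commissural fibers in
the denominator:

    ccgALPS = ccgDyy / ccgDzz   (genu: vessels along y)
    ccbALPS = ccbDzz / ccbDyy   (body: vessels along z)
    ccsALPS = ccsDyy / ccsDzz   (splenium: vessels along y)
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .phantom import REGION_LABELS, MotionTrace
from .tensorfit import DiffusivityMaps

__all__ = [
    "RegionalDiffusivity",
    "AlpsIndices",
    "FDSeries",
    "regional_means",
    "alps_index",
    "variant_alps",
    "all_indices",
    "delta_metrics",
    "framewise_displacement",
    "VARIANT_DEFS",
]

# region -> (numerator axis map key, denominator axis map key)
VARIANT_DEFS = {
    "ccg": ("Dyy", "Dzz"),
    "ccb": ("Dzz", "Dyy"),
    "ccs": ("Dyy", "Dzz"),
}

# hemisphere-pooled aggregation regions -> contributing labels
_POOLED = {
    "proj": ("proj_L", "proj_R"),
    "assoc": ("assoc_L", "assoc_R"),
    "ccg": ("ccg",),
    "ccb": ("ccb",),
    "ccs": ("ccs",),
}


@dataclass
class RegionalDiffusivity:
    """Per-region mean axis diffusivities (mm^2/s), FA means and voxel
    counts; keys like ``projDxx`` or ``ccbDzz``."""

    values: dict[str, float]
    voxel_counts: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]


@dataclass
class AlpsIndices:
    """ALPS index and the three corpus-callosum variants for one scan."""

    alps: float
    ccgALPS: float
    ccbALPS: float
    ccsALPS: float
    session: str | None = None  # "4PM" or "9AM"

    def as_dict(self) -> dict[str, float]:
        return {
            "ALPS": self.alps,
            "ccgALPS": self.ccgALPS,
            "ccbALPS": self.ccbALPS,
            "ccsALPS": self.ccsALPS,
        }


@dataclass
class FDSeries:
    """Per-volume framewise displacement (mm); first volume is 0 by
    convention."""

    fd: np.ndarray

    @property
    def mean_fd(self) -> float:
        if self.fd.shape[0] < 2:
            return 0.0
        return float(self.fd[1:].mean())

    @property
    def max_fd(self) -> float:
        return float(self.fd.max(initial=0.0))


def regional_means(maps: DiffusivityMaps, labels: np.ndarray) -> RegionalDiffusivity:
    """Arithmetic mean of Dxx/Dyy/Dzz/FA over each aggregation region.

    Left/right hemisphere ROIs of the projection and association areas
    are pooled into single regions before averaging.
    """
    if labels.shape != maps.Dxx.shape:
        raise ValueError("label map grid does not match the diffusivity maps")
    values: dict[str, float] = {}
    counts: dict[str, int] = {}
    for region, parts in _POOLED.items():
        mask = np.isin(labels, [REGION_LABELS[p] for p in parts])
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"empty region: {region}")
        counts[region] = n
        for axis in ("Dxx", "Dyy", "Dzz"):
            values[f"{region}{axis}"] = float(getattr(maps, axis)[mask].mean())
        values[f"{region}FA"] = float(maps.FA[mask].mean())
    return RegionalDiffusivity(values=values, voxel_counts=counts)


def alps_index(reg: RegionalDiffusivity) -> float:
    """mean(projDxx, assocDxx) / mean(projDyy, assocDzz)."""
    num = (reg["projDxx"] + reg["assocDxx"]) / 2.0
    den = (reg["projDyy"] + reg["assocDzz"]) / 2.0
    if den <= 0:
        raise ValueError("non-positive denominator in ALPS index")
    return num / den


def variant_alps(reg: RegionalDiffusivity, region: str) -> float:
    """Corpus-callosum variant index for ``region`` in {ccg, ccb, ccs}."""
    if region not in VARIANT_DEFS:
        raise ValueError(f"unknown corpus-callosum region {region!r}")
    num_axis, den_axis = VARIANT_DEFS[region]
    den = reg[f"{region}{den_axis}"]
    if den <= 0:
        raise ValueError(f"non-positive denominator in {region}ALPS")
    return reg[f"{region}{num_axis}"] / den


def all_indices(reg: RegionalDiffusivity, session: str | None = None) -> AlpsIndices:
    return AlpsIndices(
        alps=alps_index(reg),
        ccgALPS=variant_alps(reg, "ccg"),
        ccbALPS=variant_alps(reg, "ccb"),
        ccsALPS=variant_alps(reg, "ccs"),
        session=session,
    )


def delta_metrics(scan_4pm: dict[str, float], scan_9am: dict[str, float]) -> dict[str, float]:
    """Overnight change: 9 AM value minus 4 PM value, per shared key."""
    missing = set(scan_4pm) ^ set(scan_9am)
    if missing:
        raise ValueError(f"sessions do not share keys: {sorted(missing)}")
    return {k: scan_9am[k] - scan_4pm[k] for k in scan_4pm}


def framewise_displacement(trace: MotionTrace, sphere_radius: float = 50.0) -> FDSeries:
    """Power-style framewise displacement.

    FD_t = sum |delta translations| + r * sum |delta rotations| with
    r the head sphere radius in mm (rotations in radians); FD_1 = 0.
    """
    p = trace.params
    if p.shape[0] < 2:
        warnings.warn("single-volume trace: FD series is all zero", stacklevel=2)
        return FDSeries(fd=np.zeros(p.shape[0]))
    d = np.abs(np.diff(p, axis=0))
    fd = d[:, :3].sum(axis=1) + sphere_radius * d[:, 3:].sum(axis=1)
    return FDSeries(fd=np.concatenate([[0.0], fd]))
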