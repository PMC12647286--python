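"""Synthetic two-session cohort generator.

Generates a long-format scan table (one row per subject x session)
whose columns — ALPS and variant indices, regional diffusivities,
relative choroid-plexus and white-matter-hypointensity volumes, PSG
sleep metrics, head motion, demographics — follow configured marginal
means/SDs and a planted correlation structure.

The generator is a Gaussian copula with a subject/session factor
structure.  Per subject a latent vector U ~ N(0, R) is drawn over all
variables; each session's scan-level latent is

    Z_session = sqrt(rho) * U_scan + sqrt(1 - rho) * E_session

with E_session ~ N(0, R_scan) independent across sessions, so that
same-session cross-variable correlations equal the planted R, the
within-subject correlation of each scan variable across sessions is
rho, and subject-level variables (age, PSG) are shared by both scans.
Because subject-level variables correlate with a scan variable only
through U, their planted cross-correlations are divided by sqrt(rho)
on the latent scale so the observed pooled-scan correlation matches
the planted value.

Latent normals are mapped through per-variable marginals: plain
Gaussian for unbounded quantities, truncated Gaussian for bounded
ones (sleep efficiency in [0, 100], rates >= 0, ...).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

__all__ = [
    "VariableSpec",
    "CohortConfig",
    "CohortError",
    "generate_cohort",
    "attach_imaging",
    "subset_sensitivity",
    "write_cohort",
    "read_cohort",
    "DEFAULT_PLANTED_CORR",
    "SCAN_VARIABLES",
    "SUBJECT_VARIABLES",
]


class CohortError(ValueError):
    """Raised for infeasible cohort configurations."""


@dataclass(frozen=True)
class VariableSpec:
    """Marginal target for one generated variable.

    ``session_means``/``session_sds`` override the shared mean/SD per
    session label (used for the diurnal ALPS shift).  Bounds trigger a
    truncated-normal marginal.
    """

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf
    level: str = "scan"  # "scan" | "subject"
    session_means: dict | None = None
    session_sds: dict | None = None

    def marginal_params(self, session: str) -> tuple[float, float]:
        mu = self.mean if not self.session_means else self.session_means.get(session, self.mean)
        sd = self.sd if not self.session_sds else self.session_sds.get(session, self.sd)
        return mu, sd


# Scan-level imaging variables.  Index means/SDs follow the cohort
# descriptives the generator is calibrated to (ALPS 1.391 +/- 0.261 at
# 4 PM, 1.419 +/- 0.253 at 9 AM); variant indices sit slightly above 1
# with smaller spread; diffusivities use plausible deep-white-matter
# values in mm^2/s; mean FD is calibrated to 0.18 +/- 0.07 mm.
SCAN_VARIABLES: dict[str, VariableSpec] = {
    "ALPS": VariableSpec(1.405, 0.257,
                         session_means={"4PM": 1.391, "9AM": 1.419},
                         session_sds={"4PM": 0.261, "9AM": 0.253}),
    "ccgALPS": VariableSpec(1.06, 0.10, lower=0.0),
    "ccbALPS": VariableSpec(1.05, 0.09, lower=0.0),
    "ccsALPS": VariableSpec(1.05, 0.09, lower=0.0),
    "rCPV": VariableSpec(1.3e-3, 0.4e-3, lower=0.0),
    "rWMHV": VariableSpec(2.0e-3, 1.2e-3, lower=0.0),
    "mean_fd": VariableSpec(0.18, 0.07, lower=0.0),
    "projDxx": VariableSpec(0.60e-3, 0.06e-3, lower=0.0),
    "projDyy": VariableSpec(0.42e-3, 0.05e-3, lower=0.0),
    "projDzz": VariableSpec(1.10e-3, 0.10e-3, lower=0.0),
    "assocDxx": VariableSpec(0.62e-3, 0.06e-3, lower=0.0),
    "assocDyy": VariableSpec(1.00e-3, 0.10e-3, lower=0.0),
    "assocDzz": VariableSpec(0.46e-3, 0.05e-3, lower=0.0),
    "ccbDxx": VariableSpec(1.30e-3, 0.12e-3, lower=0.0),
    "ccbDyy": VariableSpec(0.45e-3, 0.05e-3, lower=0.0),
    "ccbDzz": VariableSpec(0.42e-3, 0.05e-3, lower=0.0),
}

# Subject-level covariates and overnight PSG metrics (shared between a
# subject's two scans).  PSG targets are plausible values for a sleep
# clinic OSA population; they are configuration, not estimates.
SUBJECT_VARIABLES: dict[str, VariableSpec] = {
    "age": VariableSpec(50.0, 14.0, lower=18.0, level="subject"),
    "tst": VariableSpec(360.0, 60.0, lower=0.0, level="subject"),
    "sleep_latency": VariableSpec(20.0, 15.0, lower=0.0, level="subject"),
    "rem_latency": VariableSpec(110.0, 50.0, lower=0.0, level="subject"),
    "waso": VariableSpec(60.0, 40.0, lower=0.0, level="subject"),
    "sleep_efficiency": VariableSpec(80.0, 10.0, lower=0.0, upper=100.0, level="subject"),
    "pct_n1": VariableSpec(15.0, 8.0, lower=0.0, upper=100.0, level="subject"),
    "pct_n2": VariableSpec(50.0, 10.0, lower=0.0, upper=100.0, level="subject"),
    "pct_n3": VariableSpec(10.0, 7.0, lower=0.0, upper=100.0, level="subject"),
    "pct_rem": VariableSpec(15.0, 6.0, lower=0.0, upper=100.0, level="subject"),
    "arousal_index": VariableSpec(25.0, 15.0, lower=0.0, level="subject"),
    "apnea_index": VariableSpec(12.0, 8.0, lower=0.0, level="subject"),
    "hypopnea_index": VariableSpec(15.0, 10.0, lower=0.0, level="subject"),
    "ahi": VariableSpec(25.0, 18.0, lower=0.0, level="subject"),
    "lowest_spo2": VariableSpec(82.0, 8.0, lower=0.0, upper=100.0, level="subject"),
    "odi3": VariableSpec(20.0, 15.0, lower=0.0, level="subject"),
    "t_spo2_lt90": VariableSpec(15.0, 10.0, lower=0.0, level="subject"),
    "plm_index": VariableSpec(12.0, 8.0, lower=0.0, level="subject"),
}

# Planted pooled-scan Pearson correlations.  The imaging-imaging block
# and the imaging-age / imaging-PSG entries are the calibration targets
# of the generator; every pair not listed is 0.
DEFAULT_PLANTED_CORR: dict[tuple[str, str], float] = {
    # imaging-imaging block
    ("rCPV", "rWMHV"): 0.547435,
    ("rCPV", "ALPS"): -0.44001,
    ("rCPV", "ccgALPS"): -0.38065,
    ("rCPV", "ccbALPS"): 0.126145,
    ("rCPV", "ccsALPS"): -0.17691,
    ("rWMHV", "ALPS"): -0.38406,
    ("rWMHV", "ccgALPS"): -0.28280,
    ("rWMHV", "ccbALPS"): 0.083471,
    ("rWMHV", "ccsALPS"): -0.07244,
    ("ALPS", "ccgALPS"): 0.24106,
    ("ALPS", "ccbALPS"): 0.03503,
    ("ALPS", "ccsALPS"): -0.09133,
    ("ccgALPS", "ccbALPS"): -0.02314,
    ("ccgALPS", "ccsALPS"): -0.08105,
    ("ccbALPS", "ccsALPS"): 0.00302,
    # imaging vs sleep / demographics
    ("ALPS", "rem_latency"): -0.47,
    ("ALPS", "tst"): 0.33,
    ("ALPS", "sleep_efficiency"): 0.29,
    ("ccbALPS", "sleep_latency"): -0.25,
    ("ccbDxx", "sleep_efficiency"): 0.36,
    ("ccbDyy", "sleep_efficiency"): 0.44,
    ("ccbDzz", "sleep_efficiency"): 0.41,
    ("rCPV", "age"): 0.61,
    ("rCPV", "waso"): 0.29,
    ("rCPV", "pct_n1"): 0.41,
    ("rCPV", "arousal_index"): 0.30,
    ("rWMHV", "age"): 0.65,
    ("rWMHV", "pct_rem"): 0.38,
}

DEFAULT_DIAGNOSIS_COUNTS = {
    "bipolar": 14, "depression": 14, "schizophrenia": 7,
    "adhd": 6, "ocd": 1, "none": 8,
}

DIAGNOSIS_DUMMIES = ["dx_bipolar", "dx_depression", "dx_schizophrenia", "dx_adhd", "dx_ocd"]

MAX_PLANTED_SHIFT = 0.05  # tolerated |r| change from the PSD repair


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-generator configuration; defaults are the packaged
    calibration (n=50 subjects, two sessions, 14/14/7/6/1/8 diagnosis
    split, 9 CPAP-pretreated subjects, 33 men)."""

    n_subjects: int = 50
    sessions: tuple[str, ...] = ("4PM", "9AM")
    seed: int = 0
    session_rho: float = 0.7
    variables: dict = field(default_factory=lambda: {**SCAN_VARIABLES, **SUBJECT_VARIABLES})
    planted_corr: dict = field(default_factory=lambda: dict(DEFAULT_PLANTED_CORR))
    diagnosis_counts: dict = field(default_factory=lambda: dict(DEFAULT_DIAGNOSIS_COUNTS))
    n_cpap: int = 9
    n_male: int = 33
    tiv_mean: float = 1.45e6  # mm^3
    tiv_sd: float = 1.2e5
    # enforce the planted correlation matrix on the pooled scan-level
    # latent scores in-sample (recoloring), not only in expectation;
    # requires more scans than scan variables and is skipped otherwise
    match_sample_corr: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise CohortError("n_subjects must be >= 1")
        if not (0.0 <= self.session_rho < 1.0):
            raise CohortError("session_rho must lie in [0, 1)")
        for (a, b), r in self.planted_corr.items():
            if a not in self.variables or b not in self.variables:
                raise CohortError(f"planted correlation names unknown variable: {(a, b)}")
            if not (-1.0 < r < 1.0):
                raise CohortError(f"planted correlation out of range for {(a, b)}")


# --------------------------------------------------------------------------
# latent correlation matrix


def _nearest_psd_corr(
    mat: np.ndarray,
    planted_mask: np.ndarray | None = None,
    eps: float = 1e-7,
    n_iter: int = 500,
) -> np.ndarray:
    """Positive-semi-definite correlation repair by alternating
    projections between the PSD cone and the affine set of matrices
    with unit diagonal and (optionally) fixed planted entries.

    Entries not planted (the default-zero pairs) are free and absorb
    most of the adjustment; if the planted entries are jointly
    infeasible the projections stop moving and the caller's shift
    check reports the offending pairs.
    """
    out = mat.copy()
    for _ in range(n_iter):
        w, v = np.linalg.eigh(out)
        if w.min() >= eps:
            break
        w = np.clip(w, eps, None)
        out = (v * w) @ v.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        if planted_mask is not None:
            out[planted_mask] = mat[planted_mask]
        np.fill_diagonal(out, 1.0)
        out = np.clip(out, -1.0, 1.0)
    # final strict-PSD pass without resets (moves entries by <= ~eps)
    w, v = np.linalg.eigh(out)
    if w.min() < 0:
        w = np.clip(w, eps, None)
        out = (v * w) @ v.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        np.fill_diagonal(out, 1.0)
    return out


def build_latent_corr(config: CohortConfig) -> tuple[np.ndarray, list[str], dict]:
    """Latent correlation matrix over all variables, PSD-repaired.

    Cross-level (scan x subject) planted entries are inflated by
    1/sqrt(session_rho) on the latent scale.  Raises ``CohortError``
    if the repair moves any planted correlation by more than 0.05 or
    inflation pushes an entry out of (-1, 1).
    """
    names = list(config.variables)
    idx = {n: i for i, n in enumerate(names)}
    levels = {n: spec.level for n, spec in config.variables.items()}
    p = len(names)
    target = np.eye(p)
    sq = np.sqrt(config.session_rho)
    bad_pairs = []
    for (a, b), r in config.planted_corr.items():
        latent = r
        if levels[a] != levels[b]:
            if config.session_rho == 0:
                raise CohortError(
                    "session_rho=0 cannot carry scan-subject correlations"
                )
            latent = r / sq
            if not (-1.0 < latent < 1.0):
                bad_pairs.append((a, b))
                continue
        target[idx[a], idx[b]] = target[idx[b], idx[a]] = latent
    if bad_pairs:
        raise CohortError(f"infeasible cross-level correlations: {bad_pairs}")

    planted_mask = np.zeros_like(target, dtype=bool)
    for (a, b) in config.planted_corr:
        planted_mask[idx[a], idx[b]] = planted_mask[idx[b], idx[a]] = True
    repaired = _nearest_psd_corr(target, planted_mask=planted_mask)
    shifts = {}
    offending = []
    for (a, b), r in config.planted_corr.items():
        scale = sq if levels[a] != levels[b] else 1.0
        realized = repaired[idx[a], idx[b]] * scale
        shifts[(a, b)] = abs(realized - r)
        if shifts[(a, b)] > MAX_PLANTED_SHIFT:
            offending.append((a, b, round(r, 4), round(realized, 4)))
    if offending:
        raise CohortError(
            "correlation matrix infeasible: PSD repair shifted planted "
            f"values by more than {MAX_PLANTED_SHIFT}: {offending}"
        )
    diagnostics = {
        "max_planted_shift": float(max(shifts.values(), default=0.0)),
        "min_eigenvalue": float(np.linalg.eigvalsh(repaired).min()),
    }
    return repaired, names, diagnostics


def _factor(mat: np.ndarray) -> np.ndarray:
    """A with A @ A.T = mat (eigh-based, tolerant of semidefiniteness)."""
    w, v = np.linalg.eigh(mat)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def _marginal(z: np.ndarray, spec: VariableSpec, session: str) -> np.ndarray:
    mu, sd = spec.marginal_params(session)
    if np.isinf(spec.lower) and np.isinf(spec.upper):
        return mu + sd * z
    a = (spec.lower - mu) / sd
    b = (spec.upper - mu) / sd
    u = sps.norm.cdf(z)
    return sps.truncnorm.ppf(np.clip(u, 1e-12, 1 - 1e-12), a, b, loc=mu, scale=sd)


def _allocate_counts(counts: dict[str, int], n: int) -> dict[str, int]:
    """Scale a count table to n subjects by largest remainder."""
    total = sum(counts.values())
    raw = {k: v * n / total for k, v in counts.items()}
    alloc = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(alloc.values())
    for k in sorted(raw, key=lambda k: raw[k] - alloc[k], reverse=True)[:short]:
        alloc[k] += 1
    return alloc


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Draw the synthetic scan table; deterministic under config.seed.

    Returns a DataFrame with one row per scan and provenance recorded
    in ``df.attrs``.
    """
    config = config or CohortConfig()
    corr, names, diagnostics = build_latent_corr(config)
    idx = {n: i for i, n in enumerate(names)}
    scan_names = [n for n in names if config.variables[n].level == "scan"]
    subj_names = [n for n in names if config.variables[n].level == "subject"]
    scan_ix = [idx[n] for n in scan_names]

    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss)

    n = config.n_subjects
    n_sess = len(config.sessions)
    A_full = _factor(corr)
    A_scan = _factor(corr[np.ix_(scan_ix, scan_ix)])

    U = rng.standard_normal((n, len(names))) @ A_full.T
    rho = config.session_rho
    Z = {}
    for s, session in enumerate(config.sessions):
        E = rng.standard_normal((n, len(scan_ix))) @ A_scan.T
        Z[session] = np.sqrt(rho) * U[:, scan_ix] + np.sqrt(1.0 - rho) * E

    # in-sample planting: recolor the pooled scan-level latent scores so
    # their empirical correlation equals the repaired planted matrix
    # exactly (the factor structure above guarantees it only in
    # expectation, and within-subject clustering inflates the sampling
    # noise of pooled correlations well beyond the nominal n)
    n_scans = n * n_sess
    if config.match_sample_corr and n_scans > len(scan_ix) + 1:
        pooled = np.vstack([Z[s] for s in config.sessions])
        pooled = pooled - pooled.mean(axis=0)
        emp = np.cov(pooled, rowvar=False)
        L_emp = np.linalg.cholesky(emp)
        L_tgt = np.linalg.cholesky(
            corr[np.ix_(scan_ix, scan_ix)]
            + np.eye(len(scan_ix)) * 1e-10
        )
        recolored = np.linalg.solve(L_emp, pooled.T)
        pooled = (L_tgt @ recolored).T
        for s, session in enumerate(config.sessions):
            Z[session] = pooled[s * n:(s + 1) * n]

    # non-copula subject attributes
    tiv = rng.normal(config.tiv_mean, config.tiv_sd, n)
    dx_alloc = _allocate_counts(config.diagnosis_counts, n)
    dx_labels = np.concatenate([[k] * v for k, v in dx_alloc.items()])
    dx_labels = dx_labels[rng.permutation(n)]
    cpap = np.zeros(n, dtype=int)
    cpap[rng.choice(n, size=min(config.n_cpap, n), replace=False)] = 1
    sex = np.array(["M"] * min(config.n_male, n) + ["F"] * max(0, n - config.n_male))
    sex = sex[rng.permutation(n)]

    rows = []
    for i in range(n):
        subj = {"subject": f"S{i + 1:03d}", "sex": sex[i],
                "cpap": int(cpap[i]), "diagnosis": dx_labels[i]}
        for dummy in DIAGNOSIS_DUMMIES:
            subj[dummy] = int(dx_labels[i] == dummy.removeprefix("dx_"))
        for v in subj_names:
            subj[v] = float(_marginal(U[i, idx[v]], config.variables[v], ""))
        subj["TIV"] = float(tiv[i])
        for session in config.sessions:
            row = dict(subj)
            row["session"] = session
            zrow = Z[session][i]
            for j, v in enumerate(scan_names):
                row[v] = float(_marginal(zrow[j], config.variables[v], session))
            row["CPV"] = row["rCPV"] * row["TIV"]
            row["WMHV"] = row["rWMHV"] * row["TIV"]
            rows.append(row)

    df = pd.DataFrame(rows)
    df.attrs["config_seed"] = config.seed
    df.attrs["repair_diagnostics"] = diagnostics
    df.attrs["imaging_mode"] = "tabular"
    return df


# --------------------------------------------------------------------------
# imaging attachment and sensitivity subsets


def attach_imaging(
    table: pd.DataFrame,
    mode: str = "tabular",
    seed: int = 0,
    snr: float = 20.0,
) -> pd.DataFrame:
    """Attach per-scan imaging indices.

    ``tabular``: the indices already drawn from the copula are the
    imaging surface; only provenance is recorded.  ``voxel``: each
    scan is backed by a DWI phantom whose perivascular fractions are
    modulated so the fitted indices track the scan's tabular targets
    (and therefore inherit the planted covariance up to simulation
    noise); the index and regional-diffusivity columns are replaced by
    the phantom-derived values.
    """
    if mode not in ("tabular", "voxel"):
        raise ValueError(f"unknown imaging mode {mode!r}")
    out = table.copy()
    out.attrs = dict(table.attrs)
    out.attrs["imaging_mode"] = mode
    if mode == "tabular":
        return out

    from .voxelback import simulate_scan_indices  # local import: heavy deps

    results = simulate_scan_indices(out, seed=seed, snr=snr)
    for col, values in results.items():
        out[col] = values
    return out


def subset_sensitivity(table: pd.DataFrame, which: str) -> pd.DataFrame:
    """Sensitivity subsets: ``no_psych`` keeps subjects with every
    diagnosis dummy 0; ``no_cpap`` drops CPAP-pretreated subjects.
    Both sessions of a kept subject are retained."""
    if which == "no_psych":
        keep = table[DIAGNOSIS_DUMMIES].sum(axis=1) == 0
    elif which == "no_cpap":
        keep = table["cpap"] == 0
    else:
        raise ValueError(f"unknown sensitivity subset {which!r}")
    out = table.loc[keep].copy()
    if out.empty:
        raise CohortError(f"sensitivity subset {which!r} is empty")
    out.attrs = dict(table.attrs)
    return out


# --------------------------------------------------------------------------
# I/O


def _config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["variables"] = {k: asdict(v) for k, v in config.variables.items()}
    d["planted_corr"] = {f"{a}|{b}": float(r) for (a, b), r in config.planted_corr.items()}
    d["sessions"] = list(config.sessions)
    return d


def write_cohort(table: pd.DataFrame, csv_path: str | Path,
                 config: CohortConfig | None = None) -> None:
    """Write the scan table as CSV plus a YAML sidecar recording the
    config, seed and copula repair diagnostics."""
    csv_path = Path(csv_path)
    table.to_csv(csv_path, index=False)
    sidecar = {
        "seed": table.attrs.get("config_seed"),
        "imaging_mode": table.attrs.get("imaging_mode"),
        "repair_diagnostics": table.attrs.get("repair_diagnostics"),
    }
    if config is not None:
        sidecar["config"] = _config_to_dict(config)
    with open(csv_path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False, default_flow_style=False)


def read_cohort(csv_path: str | Path) -> pd.DataFrame:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar = csv_path.with_suffix(".yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
        df.attrs.update({k: v for k, v in meta.items() if k != "config"})
    return df
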