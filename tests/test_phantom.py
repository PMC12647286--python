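"""Gradient scheme, phantom construction and DWI/motion simulation."""
import numpy as np
import pytest

from alpskit.phantom import (
    REGION_LABELS,
    PhantomSpec,
    build_phantom,
    cylindrical_tensor,
    simulate_dwi,
    simulate_motion,
    simulate_motion_cohort,
    MotionTrace,
)
from alpskit.scheme import GradientScheme, default_scheme
from alpskit.metrics import framewise_displacement


def _oracle_loglinear_fit(signal, scheme):
    """Independent single-voxel log-linear fit used as oracle."""
    g, b = scheme.directions, scheme.bvalues
    dwi = b > 0
    s0 = signal[~dwi].mean()
    B = b[dwi, None] * np.column_stack(
        [g[dwi, 0] ** 2, g[dwi, 1] ** 2, g[dwi, 2] ** 2,
         2 * g[dwi, 0] * g[dwi, 1], 2 * g[dwi, 0] * g[dwi, 2],
         2 * g[dwi, 1] * g[dwi, 2]]
    )
    y = -np.log(signal[dwi] / s0)
    return np.linalg.lstsq(B, y, rcond=None)[0]


class TestScheme:
    def test_default_scheme_is_single_shell_with_b0(self, scheme):
        assert scheme.n_b0 == 2
        assert np.all(scheme.bvalues[~scheme.b0_mask] == 1000.0)
        norms = np.linalg.norm(scheme.directions[~scheme.b0_mask], axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_design_matrix_full_rank(self, scheme):
        dm = scheme.design_matrix()[~scheme.b0_mask]
        assert np.linalg.matrix_rank(dm) == 6

    def test_missing_b0_rejected(self):
        d = np.eye(3)
        with pytest.raises(ValueError, match="b=0"):
            GradientScheme(directions=d, bvalues=np.full(3, 1000.0))

    def test_collinear_directions_rejected(self):
        d = np.vstack([np.zeros(3)] + [[1.0, 0, 0]] * 6)
        b = np.array([0.0] + [1000.0] * 6)
        with pytest.raises(ValueError, match="rank"):
            GradientScheme(directions=d, bvalues=b)

    def test_bvec_bval_roundtrip(self, scheme, tmp_path):
        scheme.to_files(tmp_path / "s.bvec", tmp_path / "s.bval")
        back = GradientScheme.from_files(tmp_path / "s.bvec", tmp_path / "s.bval")
        np.testing.assert_allclose(back.directions, scheme.directions, atol=1e-12)
        np.testing.assert_allclose(back.bvalues, scheme.bvalues)


class TestBuildPhantom:
    def test_zero_fraction_gives_pure_fiber_tensor(self):
        spec = PhantomSpec(pvs_fraction=0.0, pvs_fraction_by_region={})
        field = build_phantom(spec)
        mask = field.labels == REGION_LABELS["proj_L"]
        # projection fibers run along z
        expected = np.diag([0.3e-3, 0.3e-3, 1.7e-3])
        eff = np.einsum("vc,vcij->vij", field.fractions[mask], field.tensors[mask])
        np.testing.assert_allclose(eff, np.broadcast_to(expected, eff.shape))

    def test_unit_fraction_gives_pure_perivascular_tensor(self):
        spec = PhantomSpec(pvs_fraction_by_region={"ccb": 1.0})
        field = build_phantom(spec)
        mask = field.labels == REGION_LABELS["ccb"]
        # body-of-corpus-callosum vessels run along z
        expected = np.diag([0.3e-3, 0.3e-3, 3.0e-3])
        eff = np.einsum("vc,vcij->vij", field.fractions[mask], field.tensors[mask])
        np.testing.assert_allclose(eff, np.broadcast_to(expected, eff.shape))

    def test_genu_mixture_elevates_fitted_dyy_over_dzz(self, scheme):
        """Closed-form mixture signal for one genu voxel, fitted with an
        independent log-linear oracle: Dyy must exceed Dzz."""
        f = 0.1
        fiber = cylindrical_tensor("x", 1.7e-3, 0.3e-3)
        pvs = cylindrical_tensor("y", 3.0e-3, 0.3e-3)
        g, b = scheme.directions, scheme.bvalues
        s = (1 - f) * np.exp(-b * np.einsum("vj,jk,vk->v", g, fiber, g)) \
            + f * np.exp(-b * np.einsum("vj,jk,vk->v", g, pvs, g))
        d = _oracle_loglinear_fit(s, scheme)
        assert d[1] > d[2]  # Dyy > Dzz
        # package route agrees with the oracle
        spec = PhantomSpec(pvs_fraction_by_region={"ccg": f}, snr=np.inf)
        field = build_phantom(spec)
        dwi = simulate_dwi(field, scheme, snr=np.inf)
        vox = np.argwhere(field.labels == REGION_LABELS["ccg"])[0]
        d_pkg = _oracle_loglinear_fit(dwi.signal[tuple(vox)], scheme)
        np.testing.assert_allclose(d_pkg, d, atol=1e-12)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            PhantomSpec(pvs_fraction=1.2)
        with pytest.raises(ValueError, match="unknown region"):
            PhantomSpec(pvs_fraction_by_region={"thalamus": 0.1})


class TestSimulateDwi:
    def test_isotropic_closed_form_attenuation(self, scheme):
        spec = PhantomSpec(pvs_fraction=0.0, pvs_fraction_by_region={},
                           background_diffusivity=0.8e-3)
        field = build_phantom(spec)
        dwi = simulate_dwi(field, scheme, snr=np.inf)
        bg = field.labels == 0
        s = dwi.signal[bg][:, ~scheme.b0_mask] / spec.s0
        np.testing.assert_allclose(s, np.exp(-0.8), rtol=1e-12)

    def test_b0_equals_s0_noiseless(self, scheme):
        field = build_phantom(PhantomSpec())
        dwi = simulate_dwi(field, scheme, snr=np.inf)
        np.testing.assert_allclose(dwi.signal[..., scheme.b0_mask], 1000.0)

    def test_seed_determinism(self, scheme):
        field = build_phantom(PhantomSpec())
        a = simulate_dwi(field, scheme, snr=20, seed=42)
        b = simulate_dwi(field, scheme, snr=20, seed=42)
        assert np.array_equal(a.signal, b.signal)

    def test_invalid_snr_rejected(self, scheme):
        field = build_phantom(PhantomSpec())
        with pytest.raises(ValueError, match="snr"):
            simulate_dwi(field, scheme, snr=0.0)

    def test_rician_mean_converges_to_clean_signal(self, scheme):
        """At SNR 1000 the replicate-mean signal matches the noiseless
        signal within 3 standard errors (single background voxel)."""
        field = build_phantom(PhantomSpec())
        clean = simulate_dwi(field, scheme, snr=np.inf).signal[0, 0, 0]
        reps = np.stack([
            simulate_dwi(field, scheme, snr=1000, seed=i).signal[0, 0, 0]
            for i in range(1000)
        ])
        se = reps.std(axis=0, ddof=1) / np.sqrt(reps.shape[0])
        assert np.all(np.abs(reps.mean(axis=0) - clean) < 3 * se + 1e-9)

    def test_ccb_ratio_monotone_in_perivascular_fraction(self, scheme):
        """Noiseless fitted Dzz/Dyy in the callosal body is non-decreasing
        in the perivascular fraction over [0, 0.5]."""
        ratios = []
        for f in np.linspace(0.0, 0.5, 6):
            spec = PhantomSpec(pvs_fraction_by_region={"ccb": float(f)}, snr=np.inf)
            field = build_phantom(spec)
            dwi = simulate_dwi(field, scheme, snr=np.inf)
            vox = tuple(np.argwhere(field.labels == REGION_LABELS["ccb"])[0])
            d = _oracle_loglinear_fit(dwi.signal[vox], scheme)
            ratios.append(d[2] / d[1])
        assert np.all(np.diff(ratios) >= -1e-12)


class TestMotion:
    def test_zero_step_sd_gives_zero_trace(self):
        trace = simulate_motion(10, step_sd_trans=0.0, step_sd_rot=0.0, seed=1)
        assert np.all(trace.params == 0)

    def test_seed_determinism(self):
        a = simulate_motion(20, seed=7)
        b = simulate_motion(20, seed=7)
        assert np.array_equal(a.params, b.params)

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            simulate_motion(0)
        with pytest.raises(ValueError):
            simulate_motion(5, step_sd_trans=-1.0)

    def test_trace_file_roundtrip(self, tmp_path):
        trace = simulate_motion(8, seed=3)
        trace.to_file(tmp_path / "motion.par")
        back = MotionTrace.from_file(tmp_path / "motion.par")
        np.testing.assert_allclose(back.params, trace.params, atol=1e-9)

    def test_cohort_mean_fd_near_calibration(self):
        """Default motion calibration: cohort mean of per-subject mean FD
        close to 0.18 mm (large sample keeps the check tight)."""
        traces = simulate_motion_cohort(400, seed=5)
        fds = np.array([framewise_displacement(t).mean_fd for t in traces])
        assert abs(fds.mean() - 0.18) < 3 * fds.std(ddof=1) / np.sqrt(fds.size)
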