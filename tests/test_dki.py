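import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from axdki import dki, dti, model, phantom, schemes
from axdki.io import SignalVolume

from .conftest import signals_from_params
from .oracles import dense_regularized_solve


def _axis_field(axes, mask=None, frequency=None):
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    if mask is None:
        mask = np.ones((len(axes), 1, 1), dtype=bool)
    return dti.AxisField(axes=axes, mask=mask, frequency=frequency)


class TestPolarAngles:
    @pytest.mark.parametrize(
        "direction,expected",
        [((0, 0, 1), 0.0), ((1, 0, 0), np.pi / 2), ((0, 1, 1), np.pi / 4)],
    )
    def test_examples(self, direction, expected):
        sch = schemes.GradientScheme([direction], [1.0])
        theta = dki.polar_angles(_axis_field([0, 0, 1]), sch)
        assert theta[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_b0_gets_zero_angle(self):
        sch = schemes.GradientScheme([[0, 0, 0], [1, 0, 0]], [0.0, 1.0])
        theta = dki.polar_angles(_axis_field([0, 0, 1]), sch)
        assert theta[0, 0] == 0.0

    def test_antipodal_invariance(self):
        sch = schemes.GradientScheme([[0.3, -0.5, 0.8]], [1.0])
        t1 = dki.polar_angles(_axis_field([1, 2, 3]), sch)
        t2 = dki.polar_angles(_axis_field([-1, -2, -3]), sch)
        np.testing.assert_allclose(t1, t2, atol=1e-14)


class TestBuildDkiDesign:
    def test_axial_row_isolates_parallel_parameters(self):
        row = dki.build_dki_design(np.array([1.0]), np.array([0.0]))[0]
        np.testing.assert_allclose(row, [1, 0, -1, 0, 1 / 6, 0], atol=1e-14)

    def test_radial_row_isolates_perpendicular_parameters(self):
        row = dki.build_dki_design(np.array([1.0]), np.array([np.pi / 2]))[0]
        np.testing.assert_allclose(row, [1, -1, 0, 1 / 6, 0, 0], atol=1e-14)

    @given(
        theta=st.floats(0, np.pi / 2),
        b=st.floats(0, 3),
        d_perp=st.floats(0.05, 2),
        d_par=st.floats(0.05, 2),
        w_perp=st.floats(-0.5, 3),
        w_par=st.floats(-0.5, 3),
        w_mean=st.floats(-0.5, 3),
    )
    @settings(max_examples=100, deadline=None)
    def test_row_dot_parameters_equals_forward_model(
        self, theta, b, d_perp, d_par, w_perp, w_par, w_mean
    ):
        """The design row dotted with the parameter 6-vector reproduces the
        axisymmetric forward model to machine precision."""
        p = model.AxisymmetricParams(
            log_s0=0.3, d_perp=d_perp, d_par=d_par,
            w_perp=w_perp, w_par=w_par, w_mean=w_mean,
        )
        row = dki.build_dki_design(np.array([b]), np.array([theta]))[0]
        assert row @ p.linear_vector() == pytest.approx(
            model.predict_log_signal(p, b, theta), abs=1e-12
        )


class TestFitDkiRegularized:
    def test_noiseless_exact_recovery_with_true_axes(self, noiseless_phantom):
        data = noiseless_phantom
        axes = _axis_field(
            data.axes[data.volume.mask], mask=data.volume.mask, frequency=0.0
        )
        fit = dki.fit_dki_regularized(
            data.volume, data.scheme, axes, frequency=0.0, gamma_dk=0.0, tol=1e-12
        )
        truth = data.true_params(0.0)
        np.testing.assert_allclose(fit.params, truth.linear_vector(), atol=1e-8)

    def test_constant_phantom_unaffected_by_regularization(self, oblique_params):
        sch = phantom.default_scheme(frequencies=(0.0,))
        sig = signals_from_params(oblique_params, sch)
        vol = SignalVolume(data=np.broadcast_to(sig, (3, 3, 2, len(sig))).copy())
        axes = np.tile(oblique_params.axis, (18, 1))
        af = _axis_field(axes, mask=vol.mask)
        f0 = dki.fit_dki_regularized(vol, sch, af, gamma_dk=0.0, tol=1e-12)
        f1 = dki.fit_dki_regularized(vol, sch, af, gamma_dk=0.5, tol=1e-12)
        np.testing.assert_allclose(f1.params, f0.params, atol=1e-8)

    def test_noisy_fit_matches_dense_coupled_solve(self, noisy_phantom):
        data = noisy_phantom(seed=6, shape=(5, 5, 4))
        vol, sch = data.volume, data.scheme
        af = _axis_field(data.axes[vol.mask], mask=vol.mask)
        gamma = 0.075
        fit = dki.fit_dki_regularized(vol, sch, af, frequency=0.0, gamma_dk=gamma, tol=1e-12)
        theta = dki.polar_angles(af, sch)
        design = dki.build_dki_design(sch.bvalues, theta)
        ata = np.einsum("vni,vnj->vij", design, design)
        aty = np.einsum("vni,vn->vi", design, vol.log_signals())
        dense = dense_regularized_solve(ata, aty, vol.mask, gamma, dki.DK_PENALTY_WEIGHTS)
        np.testing.assert_allclose(fit.params, dense, atol=1e-8)

    def test_axis_sign_invariance(self, noisy_phantom):
        data = noisy_phantom(seed=9, shape=(3, 3, 2))
        vol, sch = data.volume, data.scheme
        ax = data.axes[vol.mask]
        f1 = dki.fit_dki_regularized(vol, sch, _axis_field(ax, mask=vol.mask), gamma_dk=0.1)
        f2 = dki.fit_dki_regularized(vol, sch, _axis_field(-ax, mask=vol.mask), gamma_dk=0.1)
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-10)

    def test_each_frequency_recovers_its_own_truth(self, noiseless_multifreq_phantom):
        """No cross-frequency coupling: each frequency's fit returns that
        frequency's programmed ground truth despite the shared axis field."""
        data = noiseless_multifreq_phantom
        af = _axis_field(data.axes[data.volume.mask], mask=data.volume.mask)
        for f in (0.0, 60.0, 120.0):
            fit = dki.fit_dki_regularized(
                data.volume, data.scheme, af, frequency=f, gamma_dk=0.0, tol=1e-12
            )
            np.testing.assert_allclose(
                fit.params, data.true_params(f).linear_vector(), atol=1e-8
            )

    def test_regularization_reduces_radial_kurtosis_error(self):
        """Base regularization lowers voxelwise K⊥ RMSE against ground truth
        on the standard noisy phantom (Monte-Carlo over noise draws)."""
        rmse = {0.0: [], 0.075: []}
        for seed in range(10):
            spec = phantom.PhantomSpec(shape=(8, 8, 4), snr=20.0, seed=seed)
            data = phantom.generate(
                spec, scheme=phantom.default_scheme(frequencies=(0.0,))
            )
            vol, sch = data.volume, data.scheme
            af = _axis_field(data.axes[vol.mask], mask=vol.mask)
            truth = model.derived_metrics(data.true_params(0.0))
            for g in rmse:
                fit = dki.fit_dki_regularized(vol, sch, af, frequency=0.0, gamma_dk=g)
                m = dki.extract_metrics(fit)
                err = m.k_perp - truth.k_perp
                rmse[g].append(np.sqrt(np.nanmean(err**2)))
        assert np.mean(rmse[0.075]) < np.mean(rmse[0.0])


class TestExtractMetrics:
    def test_algebraic_identity_k_par(self):
        params = np.array([[0.0, 0.5, 1.3, 0.0, 1.3**2, 0.0]])
        fit = dki.AxisymmetricField(params, np.ones((1, 1, 1), bool))
        assert dki.extract_metrics(fit).k_par[0] == pytest.approx(1.0)

    def test_w_mean_from_scaled_component(self):
        params = np.array([[0.0, 1.0, 1.0, 0.0, 0.0, 2 / 3]])
        fit = dki.AxisymmetricField(params, np.ones((1, 1, 1), bool))
        m = dki.extract_metrics(fit)
        assert m.d_mean[0] == pytest.approx(1.0)
        assert m.w_mean[0] == pytest.approx(2 / 3)

    def test_zero_diffusivity_marks_undefined(self):
        params = np.array([[0.0, 0.0, 1.0, 0.5, 0.5, 0.5]])
        fit = dki.AxisymmetricField(params, np.ones((1, 1, 1), bool))
        m = dki.extract_metrics(fit)
        assert np.isnan(m.k_perp[0]) and np.isfinite(m.k_par[0])

    def test_round_trip_params_to_metrics(self, oblique_params, two_shell_scheme):
        """params → signals → γ=0 fit → metrics reproduces the analytic
        metrics of the original parameters."""
        sig = signals_from_params(oblique_params, two_shell_scheme)
        vol = SignalVolume(data=sig.reshape(1, 1, 1, -1))
        af = _axis_field([oblique_params.axis])
        fit = dki.fit_dki_regularized(vol, two_shell_scheme, af, gamma_dk=0.0, tol=1e-13)
        m = dki.extract_metrics(fit)
        expected = model.derived_metrics(oblique_params)
        for name in ("d_mean", "fa", "k_par", "k_perp", "w_mean"):
            assert getattr(m, name)[0] == pytest.approx(
                float(getattr(expected, name)), abs=1e-8
            )


class TestRotationalInvariance:
    def test_scalar_maps_invariant_under_joint_rotation(self, oblique_params, two_shell_scheme):
        rng = np.random.default_rng(21)
        rot = Rotation.random(rng=rng).as_matrix()
        sig = signals_from_params(oblique_params, two_shell_scheme)
        vol = SignalVolume(data=sig.reshape(1, 1, 1, -1))
        sch_rot = schemes.GradientScheme(
            two_shell_scheme.directions @ rot.T,
            two_shell_scheme.bvalues,
            two_shell_scheme.frequencies,
        )
        f1 = dki.fit_dki_regularized(
            vol, two_shell_scheme, _axis_field([oblique_params.axis]), gamma_dk=0.0, tol=1e-13
        )
        f2 = dki.fit_dki_regularized(
            vol, sch_rot, _axis_field([rot @ oblique_params.axis]), gamma_dk=0.0, tol=1e-13
        )
        np.testing.assert_allclose(f2.params, f1.params, atol=1e-9)
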