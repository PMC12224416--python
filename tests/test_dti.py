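import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from axdki import dti, phantom, schemes
from axdki.io import SignalVolume
from axdki.model import AxisymmetricParams

from .conftest import signals_from_params
from .oracles import dense_regularized_solve


class TestBuildDtiDesign:
    def test_b0_row(self, two_shell_scheme):
        design = dti.build_dti_design(two_shell_scheme)
        np.testing.assert_allclose(design[0], [1, 0, 0, 0, 0, 0, 0])

    def test_single_axis_row(self):
        sch = schemes.GradientScheme([[1, 0, 0]], [1.0])
        np.testing.assert_allclose(
            dti.build_dti_design(sch)[0], [1, -1, 0, 0, 0, 0, 0], atol=1e-15
        )

    def test_two_channel_row_with_doubled_cross_term(self):
        sch = schemes.GradientScheme([[0, 1, 1]], [2.5])
        np.testing.assert_allclose(
            dti.build_dti_design(sch)[0], [1, 0, -1.25, -1.25, 0, 0, -2.5], atol=1e-12
        )

    def test_rank_deficient_subset_rejected(self):
        sch = schemes.GradientScheme(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0]], [0.0, 1.0, 1.0]
        )
        vol = SignalVolume(data=np.ones((1, 1, 1, 3)))
        with pytest.raises(ValueError, match="rank"):
            dti.fit_dti_regularized(vol, sch, gamma_dt=0.0)


def _dt_phantom(tensor, scheme, shape=(3, 3, 2), log_s0=0.2):
    """Noiseless pure-tensor signals (no kurtosis) on a constant grid."""
    design = dti.build_dti_design(scheme)
    x = np.r_[log_s0, tensor]
    logsig = design @ x
    data = np.broadcast_to(np.exp(logsig), shape + (len(scheme),)).copy()
    return SignalVolume(data=data)


TENSOR = np.array([1.2, 0.7, 0.5, 0.15, -0.1, 0.05])  # xx, yy, zz, xy, xz, yz


class TestFitDtiRegularized:
    def test_noiseless_exact_recovery_unregularized(self, two_shell_scheme):
        vol = _dt_phantom(TENSOR, two_shell_scheme)
        field = dti.fit_dti_regularized(vol, two_shell_scheme, gamma_dt=0.0, tol=1e-12)
        expected = np.tile(np.r_[0.2, TENSOR], (field.params.shape[0], 1))
        np.testing.assert_allclose(field.params, expected, atol=1e-9)

    def test_tv_penalty_inactive_on_constant_field(self, two_shell_scheme):
        """Derivatives vanish at the optimum, so γ>0 changes nothing."""
        vol = _dt_phantom(TENSOR, two_shell_scheme)
        f0 = dti.fit_dti_regularized(vol, two_shell_scheme, gamma_dt=0.0, tol=1e-12)
        f1 = dti.fit_dti_regularized(vol, two_shell_scheme, gamma_dt=0.5, tol=1e-12)
        np.testing.assert_allclose(f1.params, f0.params, atol=1e-8)

    def test_noisy_fit_matches_dense_normal_equations(self, noisy_phantom):
        data = noisy_phantom(seed=3, shape=(4, 4, 4))
        vol, sch = data.volume, data.scheme
        field = dti.fit_dti_regularized(vol, sch, gamma_dt=0.0, tol=1e-12)
        design = dti.build_dti_design(sch)
        dense = dense_regularized_solve(
            design.T @ design, vol.log_signals() @ design, vol.mask, 0.0,
            dti.DT_PENALTY_WEIGHTS,
        )
        np.testing.assert_allclose(field.params, dense, atol=1e-8)

    def test_tikhonov_tradeoff_monotone_in_gamma(self, noisy_phantom):
        """Residual grows and penalty shrinks as γ_DT increases."""
        data = noisy_phantom(seed=1, shape=(4, 4, 2))
        vol, sch = data.volume, data.scheme
        design = dti.build_dti_design(sch)
        y = vol.log_signals()
        from axdki import solver as slv

        residuals, penalties = [], []
        for g in (0.0, 0.2, 1.0, 5.0):
            f = dti.fit_dti_regularized(vol, sch, gamma_dt=g, tol=1e-12, maxiter=2000)
            residuals.append(np.linalg.norm(f.params @ design.T - y))
            grid = np.zeros((7,) + vol.mask.shape)
            grid[:, vol.mask] = f.params.T
            g3 = slv.masked_forward_diff(grid, vol.mask)
            penalties.append(
                np.linalg.norm(g3 * dti.DT_PENALTY_WEIGHTS[None, :, None, None, None])
            )
        assert np.all(np.diff(residuals) >= -1e-10)
        assert np.all(np.diff(penalties) <= 1e-10)

    def test_quadratic_mode_exact_on_kurtosis_data(self, oblique_params, two_shell_scheme):
        """Per-direction quadratic ADCs remove the O(b²W) tensor bias."""
        sig = signals_from_params(oblique_params, two_shell_scheme)
        vol = SignalVolume(data=np.broadcast_to(sig, (2, 2, 1, len(sig))).copy())
        field = dti.fit_dti_regularized(
            vol, two_shell_scheme, gamma_dt=0.0, adc_mode="quadratic", tol=1e-13
        )
        axis = dti.principal_axis(field).axes[0]
        assert schemes.central_angle(axis, oblique_params.axis) < 1e-6
        # eigenvalues are the true axial/radial diffusivities
        evals = np.linalg.eigvalsh(field.tensors()[0])
        np.testing.assert_allclose(
            np.sort(evals), [0.4, 0.4, 1.5], atol=1e-10
        )

    def test_quadratic_mode_needs_two_shells(self, oblique_params):
        sch = phantom.default_scheme(frequencies=(0.0,))
        low = sch.bvalues <= 1.5
        sig = signals_from_params(oblique_params, sch)
        vol = SignalVolume(data=sig[low].reshape(1, 1, 1, -1))
        with pytest.raises(ValueError, match="distinct non-zero"):
            dti.fit_dti_regularized(
                vol, sch.subset(np.where(low)[0]), gamma_dt=0.0, adc_mode="quadratic"
            )


class TestPrincipalAxis:
    @pytest.mark.parametrize(
        "diag,expected",
        [((2, 1, 1), (1, 0, 0)), ((1, 1, 3), (0, 0, 1))],
    )
    def test_axis_aligned(self, diag, expected):
        params = np.array([[0.0, diag[0], diag[1], diag[2], 0, 0, 0]])
        field = dti.DiffusionTensorField(params, np.ones((1, 1, 1), bool))
        np.testing.assert_allclose(dti.principal_axis(field).axes[0], expected)

    def test_rotated_tensor_recovers_rotation_column(self):
        rng = np.random.default_rng(5)
        rot = Rotation.random(rng=rng).as_matrix()
        t = rot @ np.diag([2.0, 1.0, 1.0]) @ rot.T
        params = np.array([[0.0, t[0, 0], t[1, 1], t[2, 2], t[0, 1], t[0, 2], t[1, 2]]])
        field = dti.DiffusionTensorField(params, np.ones((1, 1, 1), bool))
        axis = dti.principal_axis(field).axes[0]
        assert schemes.central_angle(axis, rot[:, 0]) < 1e-6

    def test_sign_convention_first_nonzero_positive(self):
        params = np.array([[0.0, 1, 1, 3, 0, 0, 0]])
        field = dti.DiffusionTensorField(params, np.ones((1, 1, 1), bool))
        ax = dti.principal_axis(field).axes[0]
        assert ax[2] > 0

    def test_rotational_invariance_of_eigenvalues(self, oblique_params, two_shell_scheme):
        """Rotating directions and phantom together rotates axes, not spectra."""
        rng = np.random.default_rng(12)
        rot = Rotation.random(rng=rng).as_matrix()
        sig = signals_from_params(oblique_params, two_shell_scheme)
        rotated_params = AxisymmetricParams(
            log_s0=oblique_params.log_s0, d_perp=oblique_params.d_perp,
            d_par=oblique_params.d_par, w_perp=oblique_params.w_perp,
            w_par=oblique_params.w_par, w_mean=oblique_params.w_mean,
            axis=rot @ oblique_params.axis,
        )
        sch_rot = schemes.GradientScheme(
            two_shell_scheme.directions @ rot.T, two_shell_scheme.bvalues,
            two_shell_scheme.frequencies,
        )
        sig_rot = signals_from_params(rotated_params, sch_rot)
        np.testing.assert_allclose(sig_rot, sig, atol=1e-12)
        vol = SignalVolume(data=sig.reshape(1, 1, 1, -1))
        vol_rot = SignalVolume(data=sig_rot.reshape(1, 1, 1, -1))
        f = dti.fit_dti_regularized(vol, two_shell_scheme, gamma_dt=0.0, tol=1e-12)
        f_rot = dti.fit_dti_regularized(vol_rot, sch_rot, gamma_dt=0.0, tol=1e-12)
        np.testing.assert_allclose(
            np.linalg.eigvalsh(f_rot.tensors()[0]),
            np.linalg.eigvalsh(f.tensors()[0]),
            atol=1e-9,
        )


class TestComputeAxes:
    def test_noiseless_strategies_agree(self):
        """Frequency-invariant orientation, no noise, Gaussian signal: the
        tensor fit is exact for every volume subset, so all three pooling
        strategies return identical axes."""
        regions = {
            "WM": phantom.RegionParams(d_par=1.5, d_perp=0.4, w_par=0, w_perp=0, w_mean=0),
            "GM": phantom.RegionParams(d_par=0.8, d_perp=0.6, w_par=0, w_perp=0, w_mean=0),
        }
        spec = phantom.PhantomSpec(shape=(8, 8, 4), noise_model="none", regions=regions)
        data = phantom.generate(spec)
        wm = data.labels[data.volume.mask] == 1
        bundles = {
            s: dti.compute_axes(data.volume, data.scheme, strategy=s, gamma_dt=0.0)
            for s in dti.STRATEGIES
        }
        for f in (0.0, 60.0, 120.0):
            a_ref = bundles["AFAB"].for_frequency(f).axes[wm]
            for s in ("SFAB", "SFLB"):
                a = bundles[s].for_frequency(f).axes[wm]
                angles = np.degrees(
                    np.arccos(np.clip(np.abs(np.sum(a * a_ref, axis=1)), 0, 1))
                )
                assert angles.max() < 0.2

    def test_afab_equals_sfab_on_single_frequency_data(self, noisy_phantom):
        data = noisy_phantom(seed=2, shape=(4, 4, 2), frequencies=(0.0,))
        afab = dti.compute_axes(data.volume, data.scheme, "AFAB", gamma_dt=0.0)
        sfab = dti.compute_axes(data.volume, data.scheme, "SFAB", gamma_dt=0.0)
        np.testing.assert_allclose(
            afab.for_frequency(0.0).axes, sfab.for_frequency(0.0).axes, atol=1e-12
        )

    def test_afab_most_consistent_across_frequencies_under_noise(self):
        """Pooling all frequencies gives the best cross-frequency axis agreement."""
        from axdki.evaluation import median_pair_angle

        med = {"AFAB": [], "SFAB": [], "SFLB": []}
        for seed in range(20):
            spec = phantom.PhantomSpec(shape=(6, 6, 3), snr=15.0, seed=seed)
            data = phantom.generate(spec)
            wm = data.labels[data.volume.mask] == 1
            for s in med:
                bundle = dti.compute_axes(data.volume, data.scheme, s, gamma_dt=0.0)
                axes = {f: a.axes for f, a in bundle.axes.items()}
                med[s].append(median_pair_angle(axes, select=wm))
        assert np.mean(med["AFAB"]) < np.mean(med["SFAB"])
        assert np.mean(med["AFAB"]) < np.mean(med["SFLB"])

    def test_unknown_strategy_rejected(self, noisy_phantom):
        data = noisy_phantom(seed=0, shape=(2, 2, 2))
        with pytest.raises(ValueError):
            dti.compute_axes(data.volume, data.scheme, "ALL")
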