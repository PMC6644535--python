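"""The calibration algorithm: similarity, Kronecker system, null solve, fitting."""

import warnings

import numpy as np
import pytest

from muellercal import (
    CalibrationSample,
    DegenerateCalibrationWarning,
    build_H,
    build_K,
    calibrate,
    fit_orientations,
    instrument_error,
    intermediate_matrix,
    orientation_objective,
    recover_A,
    sample_eigenvalues,
    simulate_measurement,
    solve_G,
)
from muellercal.ecm_core import _stack_K_terms
from muellercal.mueller_models import (
    DichroicRetarderSpec,
    dr_eigenvalues,
    dr_mueller3,
    sort_eigenvalues,
)

from conftest import measure_set


def scale_matched_rel_error(X_cal, X_true):
    s = np.sum(X_cal * X_true) / np.sum(X_cal * X_cal)
    return np.linalg.norm(s * X_cal - X_true) / np.linalg.norm(X_true)


class TestIntermediateMatrix:
    def test_three_state_similarity(self, nominal3, rng):
        M = dr_mueller3(DichroicRetarderSpec(25.0, 0.9, 0.2, 60.0))
        P_air = nominal3.air_measurement()
        P = simulate_measurement(nominal3, M)
        D = intermediate_matrix(P_air, P)
        np.testing.assert_allclose(
            np.sort(np.linalg.eigvals(D).real),
            np.sort(np.linalg.eigvals(M).real),
            atol=1e-10,
        )

    def test_four_state_has_extra_null_eigenvalue(self, nominal4):
        M = dr_mueller3(DichroicRetarderSpec(25.0, 0.9, 0.2, 60.0))
        D = intermediate_matrix(
            nominal4.air_measurement(), simulate_measurement(nominal4, M)
        )
        lams = np.sort(np.linalg.eigvals(D).real)
        expect = np.sort(np.append(np.linalg.eigvals(M).real, 0.0))
        np.testing.assert_allclose(lams, expect, atol=1e-10)

    def test_air_itself_gives_rank3_projector(self, nominal4):
        P_air = nominal4.air_measurement()
        D = intermediate_matrix(P_air, P_air)
        lams = np.sort(np.linalg.eigvalsh((D + D.T) / 2))
        np.testing.assert_allclose(lams, [0, 1, 1, 1], atol=1e-10)

    def test_rank_deficient_air_rejected(self):
        bad = np.outer([1, 1, 1, 1.0], [1, 2, 3, 4.0])
        with pytest.raises(ValueError, match="rank"):
            intermediate_matrix(bad, bad)


class TestSampleEigenvalues:
    def test_three_state_passthrough(self, nominal3):
        M = dr_mueller3(DichroicRetarderSpec(10.0, 0.8, 0.1, 30.0))
        D = intermediate_matrix(
            nominal3.air_measurement(), simulate_measurement(nominal3, M)
        )
        lams = sample_eigenvalues(D, "DR")
        np.testing.assert_allclose(
            lams,
            sort_eigenvalues(dr_eigenvalues(DichroicRetarderSpec(0, 0.8, 0.1, 30.0))),
            atol=1e-10,
        )

    def test_lp_discard_rule_four_state(self, nominal4):
        # finite-ER LP: the genuine small pair (2r, 2qr) must survive and the
        # rank-deficiency zero must go
        spec = DichroicRetarderSpec(30.0, 1.0, 0.01, 0.0)
        D = intermediate_matrix(
            nominal4.air_measurement(),
            simulate_measurement(nominal4, dr_mueller3(spec)),
        )
        lams = sample_eigenvalues(D, "LP")
        np.testing.assert_allclose(lams, [2.0, 0.02, 0.02], atol=1e-10)

    def test_qwp_discard_rule_four_state(self, nominal4):
        # imperfect wave plate: lam3 = 2 q r cos(delta) is small but genuine
        spec = DichroicRetarderSpec(70.0, 0.95, 0.95, 85.0)
        D = intermediate_matrix(
            nominal4.air_measurement(),
            simulate_measurement(nominal4, dr_mueller3(spec)),
        )
        lams = sample_eigenvalues(D, "QWP")
        np.testing.assert_allclose(
            lams, [1.9, 1.9, 2 * 0.95 * 0.95 * np.cos(np.deg2rad(85.0))], atol=1e-10
        )

    def test_complex_spectrum_rejected(self):
        # a rotation has eigenvalues exp(+-i phi): inconsistent with the model
        c, s = np.cos(1.0), np.sin(1.0)
        with pytest.raises(ValueError, match="complex"):
            sample_eigenvalues(np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]]))


class TestKroneckerSystem:
    def test_sylvester_identity_on_identity_psg(self, rng):
        M = rng.normal(size=(3, 3))
        H = build_H(M, M)  # D = M corresponds to G = I
        assert np.linalg.norm(H @ np.eye(3).reshape(-1, order="F")) < 1e-12

    def test_sylvester_identity_on_constructed_instances(self, rng):
        # the stated oracle: D = pinv(G0) M G0 makes vec(G0) a null vector
        for _ in range(20):
            G0 = rng.normal(size=(3, 4))
            M = rng.normal(size=(3, 3))
            D = np.linalg.pinv(G0) @ M @ G0
            H = build_H(D, M)
            v = G0.reshape(-1, order="F")
            assert np.linalg.norm(H @ v) <= 1e-10 * np.linalg.norm(v)

    def test_dimensions(self, rng):
        assert build_H(np.eye(3), np.eye(3)).shape == (9, 9)
        assert build_H(np.eye(4), np.eye(3)).shape == (12, 12)

    def test_K_is_psd_and_annihilates_null(self, rng):
        G0 = rng.normal(size=(3, 4))
        Hs = []
        for _ in range(3):
            M = rng.normal(size=(3, 3))
            Hs.append(build_H(np.linalg.pinv(G0) @ M @ G0, M))
        K = build_K(Hs)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() > -1e-12
        v = G0.reshape(-1, order="F")
        assert np.linalg.norm(K @ v) <= 1e-9 * np.linalg.norm(v)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_K([])


class TestSolveG:
    def test_sign_convention(self, rng):
        G0 = rng.normal(size=(3, 4))
        if G0[0].sum() < 0:
            G0 = -G0
        M = rng.normal(size=(3, 3))
        K = build_K([build_H(np.linalg.pinv(G0) @ M @ G0, M),
                     build_H(np.linalg.pinv(G0) @ M.T @ G0, M.T)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateCalibrationWarning)
            G, spectrum = solve_G(K)
        assert G[0].sum() > 0
        assert np.isclose(np.linalg.norm(G), 1.0)

    def test_double_null_triggers_degeneracy_warning(self, nominal4):
        # two ideal LPs only: K keeps more than one null direction
        specs = [
            DichroicRetarderSpec(0.0, 1.0, 0.0, 0.0),
            DichroicRetarderSpec(62.0, 1.0, 0.0, 0.0),
        ]
        air, P = measure_set(nominal4, specs)
        D = [intermediate_matrix(air, Pi) for Pi in P]
        eigs = [sample_eigenvalues(Di, "LP") for Di in D]
        K = np.sum(_stack_K_terms(D, eigs, {0: 0.0, 1: 62.0}), axis=0)
        with pytest.warns(DegenerateCalibrationWarning):
            solve_G(K)


class TestOrientationFit:
    @pytest.fixture
    def conf5_noiseless(self, nominal4):
        specs = [
            DichroicRetarderSpec(0.0, 0.98, 0.004, 0.0),
            DichroicRetarderSpec(19.0, 0.49, 0.47, 86.0),
            DichroicRetarderSpec(162.0, 0.50, 0.48, 92.0),
        ]
        air, P = measure_set(nominal4, specs)
        D = [intermediate_matrix(air, Pi) for Pi in P]
        types = ["LP", "QWP", "QWP"]
        eigs = [sample_eigenvalues(Di, t) for Di, t in zip(D, types)]
        return D, eigs

    def test_objective_zero_at_truth(self, conf5_noiseless):
        D, eigs = conf5_noiseless
        val = orientation_objective(np.array([19.0, 162.0]), D, eigs, [1, 2], {0: 0.0})
        assert val <= 1e-8

    def test_objective_larger_off_truth(self, conf5_noiseless):
        D, eigs = conf5_noiseless
        at_truth = orientation_objective(np.array([19.0, 162.0]), D, eigs, [1, 2], {0: 0.0})
        off = orientation_objective(np.array([39.0, 162.0]), D, eigs, [1, 2], {0: 0.0})
        assert off > max(at_truth, 1e-6)

    def test_objective_period_180(self, conf5_noiseless):
        D, eigs = conf5_noiseless
        a = orientation_objective(np.array([19.0, 162.0]), D, eigs, [1, 2], {0: 0.0})
        b = orientation_objective(np.array([199.0, 342.0]), D, eigs, [1, 2], {0: 0.0})
        assert np.isclose(a, b, atol=1e-10)

    def test_fit_recovers_free_qwp_orientation(self, conf5_noiseless):
        D, eigs = conf5_noiseless
        thetas = fit_orientations(D, eigs, [1, 2], {0: 0.0}, hints={1: 25.0, 2: 155.0})
        assert abs(thetas[1] - 19.0) < 0.1
        assert abs(thetas[2] - 162.0) < 0.1

    def test_refinement_never_increases_objective(self, conf5_noiseless):
        D, eigs = conf5_noiseless
        coarse = fit_orientations(
            D, eigs, [1, 2], {0: 0.0}, grid_step=5.0, refine=False,
            hints={1: 25.0, 2: 155.0},
        )
        fine = fit_orientations(
            D, eigs, [1, 2], {0: 0.0}, grid_step=5.0, refine=True,
            hints={1: 25.0, 2: 155.0},
        )
        obj = lambda th: orientation_objective(
            np.array([th[1], th[2]]), D, eigs, [1, 2], {0: 0.0}
        )
        assert obj(fine) <= obj(coarse) + 1e-15


class TestRecoverA:
    def test_least_squares_consistency(self, perturbed_truth, realistic_lp_set):
        air, P = measure_set(perturbed_truth, realistic_lp_set)
        A = recover_A(air, perturbed_truth.G)
        assert np.linalg.norm(A @ perturbed_truth.G - air) <= 1e-10 * np.linalg.norm(air)
        np.testing.assert_allclose(A, perturbed_truth.A, atol=1e-10)

    def test_scale_duality(self, perturbed_truth):
        air = perturbed_truth.air_measurement()
        A1 = recover_A(air, perturbed_truth.G)
        A2 = recover_A(air, 2.0 * perturbed_truth.G)
        np.testing.assert_allclose(A2, A1 / 2.0, atol=1e-12)
        np.testing.assert_allclose(A2 @ (2.0 * perturbed_truth.G), A1 @ perturbed_truth.G)

    def test_rank_deficient_G_rejected(self, nominal4):
        with pytest.raises(ValueError):
            recover_A(nominal4.air_measurement(), np.ones((3, 4)))


class TestCalibrate:
    def _samples(self, instrument, specs, types):
        air, P = measure_set(instrument, specs)
        samples = [
            CalibrationSample(
                t, Pi,
                theta_known=0.0 if i == 0 else None,
                theta_hint=None if i == 0 else s.theta,
            )
            for i, (t, Pi, s) in enumerate(zip(types, P, specs))
        ]
        return air, samples

    def test_four_lp_set_recovers_perturbed_instrument(
        self, perturbed_truth, realistic_lp_set
    ):
        air, samples = self._samples(perturbed_truth, realistic_lp_set, ["LP"] * 4)
        res = calibrate(air, samples)
        assert scale_matched_rel_error(res.G_cal, perturbed_truth.G) <= 1e-8
        assert scale_matched_rel_error(res.A_cal, perturbed_truth.A) <= 1e-8
        assert not res.degenerate

    def test_lp_plus_two_qwp_set_recovers_instrument(self, perturbed_truth):
        specs = [
            DichroicRetarderSpec(0.0, 0.98, 0.004, 0.0),
            DichroicRetarderSpec(19.0, 0.49, 0.47, 86.0),
            DichroicRetarderSpec(162.0, 0.50, 0.48, 92.0),
        ]
        air, samples = self._samples(perturbed_truth, specs, ["LP", "QWP", "QWP"])
        res = calibrate(air, samples)
        assert scale_matched_rel_error(res.G_cal, perturbed_truth.G) <= 1e-8
        # fitted orientations land on the simulated truth
        assert abs(res.fitted_thetas[1] - 19.0) < 1e-6
        assert abs(res.fitted_thetas[2] - 162.0) < 1e-6

    def test_two_lp_set_is_degenerate(self, nominal4):
        specs = [
            DichroicRetarderSpec(0.0, 1.0, 0.0, 0.0),
            DichroicRetarderSpec(62.0, 1.0, 0.0, 0.0),
        ]
        air, samples = self._samples(nominal4, specs, ["LP", "LP"])
        with pytest.warns(DegenerateCalibrationWarning):
            res = calibrate(air, samples)
        assert res.degenerate

    def test_needs_reference_sample(self, nominal4):
        air = nominal4.air_measurement()
        with pytest.raises(ValueError, match="known orientation"):
            calibrate(air, [CalibrationSample("LP", air), CalibrationSample("LP", air)])


class TestInstrumentError:
    def test_identical_matrices(self, rng):
        X = rng.normal(size=(3, 4))
        assert instrument_error(X, X) == 0.0

    def test_scale_matching_contract(self, rng):
        X = rng.normal(size=(3, 4))
        assert instrument_error(2.0 * X, X) < 1e-15
        assert instrument_error(-X, X) < 1e-15

    def test_against_brute_force_scalar_search(self, rng):
        # independent oracle: dense scan over the matching scalar
        X_cal = rng.normal(size=(3, 4))
        X_true = rng.normal(size=(3, 4))
        s_grid = np.linspace(-5, 5, 200001)
        errs = np.linalg.norm(
            s_grid[:, None, None] * X_cal[None] - X_true[None], axis=(1, 2)
        )
        expect = errs.min() / 12.0
        assert np.isclose(instrument_error(X_cal, X_true), expect, rtol=1e-6)

    def test_orthogonal_perturbation_arithmetic(self, rng):
        # when <X_cal, E> = 0 the matching scalar is exactly 1 and the error
        # is ||E||_F / N by hand
        X_cal = rng.normal(size=(3, 4))
        E = rng.normal(size=(3, 4))
        E -= X_cal * np.sum(E * X_cal) / np.sum(X_cal * X_cal)
        np.testing.assert_allclose(
            instrument_error(X_cal, X_cal + E), np.linalg.norm(E) / 12.0, rtol=1e-12
        )

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            instrument_error(np.eye(3), np.ones((3, 4)))
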