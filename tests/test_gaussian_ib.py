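"""Gaussian information-bottleneck solver: spectrum, encoders, curves."""

import numpy as np
import pytest

import predib as pb
from predib.gaussian_ib import analytic_info


class TestSpectrum:
    def test_independent_pair_has_unit_eigenvalues(self):
        joint = pb.JointGaussian(sigma_past=np.eye(2), sigma_future=np.eye(2),
                                 sigma_cross=np.zeros((2, 2)))
        spec = pb.ib_spectrum(joint)
        assert np.allclose(spec.eigenvalues, 1.0)
        assert np.all(np.isinf(spec.beta_c))

    def test_scalar_closed_form(self, scalar_joint):
        # lambda = 1 - rho^2, beta_c = 1/rho^2 for a correlated scalar pair
        spec = pb.ib_spectrum(scalar_joint)
        assert spec.eigenvalues[0] == pytest.approx(1 - 0.8 ** 2, abs=1e-12)
        assert spec.beta_c[0] == pytest.approx(1 / 0.8 ** 2, abs=1e-10)

    def test_left_eigenvector_relation(self, sddho_half):
        spec = pb.ib_spectrum(sddho_half)
        M = sddho_half.sigma_past_given_future @ np.linalg.inv(
            sddho_half.sigma_past)
        for i, lam in enumerate(spec.eigenvalues):
            w = spec.eigenvectors[:, i]
            assert np.linalg.norm(w @ M - lam * w) < 1e-10
            assert np.linalg.norm(w) == pytest.approx(1.0, abs=1e-12)

    def test_eigenvalues_sorted_and_bounded(self, sddho_half):
        spec = pb.ib_spectrum(sddho_half)
        assert np.all(np.diff(spec.eigenvalues) >= 0)
        assert np.all(spec.eigenvalues > 0)
        assert np.all(spec.eigenvalues <= 1)
        assert np.all(np.diff(spec.beta_c) >= 0)

    def test_invalid_covariance_rejected(self):
        with pytest.raises(pb.InvalidModelError, match="sigma_past"):
            pb.JointGaussian(sigma_past=[[1.0, 2.0], [2.0, 1.0]],
                             sigma_future=np.eye(2),
                             sigma_cross=np.zeros((2, 2)))


class TestOptimalEncoder:
    def test_below_first_critical_beta_encodes_nothing(self, sddho_half):
        spec = pb.ib_spectrum(sddho_half)
        enc = pb.optimal_encoder(sddho_half, 0.9 * spec.beta_c[0])
        assert enc.rank() == 0
        pt = pb.evaluate_encoder(enc, sddho_half)
        assert pt.i_past == 0.0 and pt.i_future == 0.0

    def test_rank_steps_up_at_critical_betas(self, sddho_half):
        spec = pb.ib_spectrum(sddho_half)
        for i, bc in enumerate(spec.beta_c):
            assert pb.optimal_encoder(sddho_half, bc * 0.999).rank() == i
            assert pb.optimal_encoder(sddho_half, bc * 1.001).rank() == i + 1

    def test_one_dimensional_between_criticals(self, sddho_half):
        spec = pb.ib_spectrum(sddho_half)
        beta = np.sqrt(spec.beta_c[0] * spec.beta_c[1])
        assert pb.optimal_encoder(sddho_half, beta).rank() == 1

    def test_saturates_to_total_information(self, sddho_half):
        pt = pb.evaluate_encoder(pb.optimal_encoder(sddho_half, 1e9),
                                 sddho_half)
        total = pb.total_predictive_info(pb.SDDHOParams(0.5, 1.0))
        assert pt.i_future == pytest.approx(total, abs=1e-5)

    def test_beats_random_encoders_at_matched_compression(self, sddho_half,
                                                          rng):
        """No random linear encoder exceeds the optimum's i_future."""
        beta = 50.0
        opt = pb.evaluate_encoder(pb.optimal_encoder(sddho_half, beta),
                                  sddho_half)
        for _ in range(200):
            A = rng.standard_normal((2, 2))
            enc = pb.GaussianEncoder(A=A, beta=beta)
            # rescale to the optimum's i_past by bisection on a scalar
            from scipy.optimize import brentq
            f = lambda s: pb.evaluate_encoder(
                pb.GaussianEncoder(A=np.exp(s) * A, beta=beta),
                sddho_half).i_past - opt.i_past
            s = brentq(f, -30, 30, xtol=1e-12)
            pt = pb.evaluate_encoder(
                pb.GaussianEncoder(A=np.exp(s) * A, beta=beta), sddho_half)
            assert pt.i_future <= opt.i_future + 1e-6

    def test_closed_form_matches_generic_evaluation(self, sddho_half):
        for beta in (3.0, 10.0, 300.0):
            enc = pb.optimal_encoder(sddho_half, beta)
            pt = pb.evaluate_encoder(enc, sddho_half)
            cf = analytic_info(sddho_half, beta)
            assert pt.i_past == pytest.approx(cf.i_past, abs=1e-9)
            assert pt.i_future == pytest.approx(cf.i_future, abs=1e-9)


class TestEvaluateEncoder:
    def test_zero_encoder_gives_origin(self, scalar_joint):
        pt = pb.evaluate_encoder(pb.GaussianEncoder(A=[[0.0]], beta=1.0),
                                 scalar_joint)
        assert pt.as_tuple() == (0.0, 0.0)

    def test_scalar_closed_form(self, scalar_joint):
        a, rho = 1.7, 0.8
        pt = pb.evaluate_encoder(pb.GaussianEncoder(A=[[a]], beta=1.0),
                                 scalar_joint)
        ip = 0.5 * np.log2(1 + a ** 2)
        assert pt.i_past == pytest.approx(ip, abs=1e-12)
        assert pt.i_future == pytest.approx(
            ip - 0.5 * np.log2(1 + a ** 2 * (1 - rho ** 2)), abs=1e-12)

    def test_data_processing_inequality(self, sddho_half, rng):
        bound = sddho_half.mutual_information()
        for _ in range(50):
            enc = pb.GaussianEncoder(A=rng.standard_normal((2, 2)), beta=1.0)
            pt = pb.evaluate_encoder(enc, sddho_half)
            assert 0 <= pt.i_future <= pt.i_past + 1e-12
            assert pt.i_future <= bound + 1e-9

    def test_dimension_mismatch_raises(self, scalar_joint):
        with pytest.raises(pb.DimensionMismatchError):
            pb.evaluate_encoder(pb.GaussianEncoder(A=np.eye(2), beta=1.0),
                                scalar_joint)


class TestInfoCurve:
    def test_independent_pair_curve_is_flat_zero(self):
        joint = pb.JointGaussian(sigma_past=np.eye(2), sigma_future=np.eye(2),
                                 sigma_cross=np.zeros((2, 2)))
        curve = pb.info_curve(joint, np.geomspace(1.01, 100, 20))
        assert np.allclose(curve.i_future, 0.0)

    def test_monotone_and_concave(self, sddho_half):
        curve = pb.info_curve(sddho_half)
        ip, ifu = curve.i_past, curve.i_future
        assert np.all(np.diff(ip) >= -1e-12)
        assert np.all(np.diff(ifu) >= -1e-12)
        # concavity of i_future(i_past) along the curve: slopes nonincreasing
        mask = np.diff(ip) > 1e-9
        slopes = np.diff(ifu)[mask] / np.diff(ip)[mask]
        assert np.all(np.diff(slopes) <= 1e-6)

    def test_initial_slope_matches_smallest_eigenvalue(self, sddho_half):
        # finite-difference slope at the smallest i_past == 1 - lambda_1
        spec = pb.ib_spectrum(sddho_half)
        b0 = spec.beta_c[0]
        pts = [analytic_info(sddho_half, b0 * (1 + eps))
               for eps in (1e-7, 2e-7)]
        slope = (pts[1].i_future - pts[0].i_future) / (
            pts[1].i_past - pts[0].i_past)
        assert slope == pytest.approx(1 - spec.eigenvalues[0], abs=1e-3)

    def test_curve_round_trips_through_csv(self, sddho_half, tmp_path):
        curve = pb.info_curve(sddho_half, np.geomspace(1.1, 50, 10))
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert list(df.columns) == ["beta", "i_past_bits", "i_future_bits"]
        assert np.allclose(df["i_future_bits"], curve.i_future)


class TestConditionalCovariances:
    def test_zero_encoder_returns_priors(self, sddho_half):
        enc = pb.GaussianEncoder(A=np.zeros((2, 2)), beta=1.0)
        cp, cf = pb.conditional_covariances(enc, sddho_half)
        assert np.allclose(cp, sddho_half.sigma_past)
        assert np.allclose(cf, sddho_half.sigma_future)

    def test_high_beta_limit_recovers_propagator_noise(self, sddho_half):
        enc = pb.optimal_encoder(sddho_half, 1e10)
        _, cf = pb.conditional_covariances(enc, sddho_half)
        cond_future_given_past = (
            sddho_half.sigma_future
            - sddho_half.sigma_cross.T @ np.linalg.solve(
                sddho_half.sigma_past, sddho_half.sigma_cross))
        assert np.allclose(cf, cond_future_given_past, atol=1e-6)

    def test_determinant_identity_with_i_past(self, sddho_half):
        enc = pb.optimal_encoder(sddho_half, 20.0)
        pt = pb.evaluate_encoder(enc, sddho_half)
        cp, _ = pb.conditional_covariances(enc, sddho_half)
        lhs = 0.5 * np.log2(np.linalg.det(sddho_half.sigma_past)
                            / np.linalg.det(cp))
        assert lhs == pytest.approx(pt.i_past, abs=1e-9)

    def test_conditionals_dominated_by_priors(self, sddho_half, rng):
        enc = pb.GaussianEncoder(A=rng.standard_normal((2, 2)), beta=1.0)
        cp, cf = pb.conditional_covariances(enc, sddho_half)
        assert np.linalg.eigvalsh(sddho_half.sigma_past - cp).min() > -1e-10
        assert np.linalg.eigvalsh(sddho_half.sigma_future - cf).min() > -1e-10


class TestRotateEncoder:
    def test_zero_rotation_is_identity_on_the_plane(self, sddho_half):
        enc = pb.optimal_encoder(sddho_half, 30.0)
        rot = pb.rotate_encoder(enc, 0.0, sddho_half)
        p0 = pb.evaluate_encoder(enc, sddho_half)
        p1 = pb.evaluate_encoder(rot, sddho_half)
        assert p1.i_past == pytest.approx(p0.i_past, abs=1e-9)
        assert p1.i_future == pytest.approx(p0.i_future, abs=1e-9)

    def test_quarter_turn_is_strictly_suboptimal(self, sddho_half):
        enc = pb.encoder_at_past_info(sddho_half, 3.0)
        rot = pb.rotate_encoder(enc, np.pi / 2, sddho_half)
        p0 = pb.evaluate_encoder(enc, sddho_half)
        p1 = pb.evaluate_encoder(rot, sddho_half)
        assert p1.i_past == pytest.approx(3.0, abs=1e-6)
        assert p1.i_future < p0.i_future - 0.05

    def test_i_past_preserved_for_any_angle(self, sddho_half):
        enc = pb.encoder_at_past_info(sddho_half, 2.0)
        for theta in (0.3, 1.0, 2.5):
            rot = pb.rotate_encoder(enc, theta, sddho_half)
            assert pb.evaluate_encoder(rot, sddho_half).i_past == \
                pytest.approx(2.0, abs=1e-6)

    def test_rotation_requires_two_dimensions(self, scalar_joint):
        enc = pb.GaussianEncoder(A=[[1.0]], beta=1.0)
        with pytest.raises(pb.DimensionMismatchError):
            pb.rotate_encoder(enc, 0.5, scalar_joint)


def test_encoder_json_round_trip(tmp_path, sddho_half):
    enc = pb.optimal_encoder(sddho_half, 12.0, source={"zeta": 0.5})
    path = tmp_path / "enc.json"
    enc.to_json(path, info=pb.evaluate_encoder(enc, sddho_half))
    back = pb.GaussianEncoder.from_json(path)
    assert np.allclose(back.A, enc.A)
    assert back.beta == enc.beta
    assert back.source == {"zeta": 0.5}
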