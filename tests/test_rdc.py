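import numpy as np
import pytest

from coilreg import rdc, synthetic
from coilreg.rdc import (AlignmentTensor, ConditioningError, RDCMeasurement,
                         UndefinedQError, UnderdeterminedError, back_calculate,
                         fit_tensor, fit_tensor_nonlinear, q_factor)
from coilreg.structure_io import amide_vectors
from conftest import random_rotation


def _unit(rng, n):
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1)[:, None]


class _Vec:
    def __init__(self, num, vec):
        self.residue_number = num
        self.vector = vec


def _measurements(vectors, tensor, sigma=1.0, noise=None):
    d = back_calculate(np.array([v.vector for v in vectors]), tensor)
    if noise is not None:
        d = d + noise
    return [RDCMeasurement(v.residue_number, float(x), sigma)
            for v, x in zip(vectors, d)]


class TestAlignmentTensor:
    def test_parameter_roundtrip(self):
        t = AlignmentTensor.from_parameters(8.0, 0.25, (12.0, 75.0, 140.0))
        assert t.da == pytest.approx(8.0, abs=1e-12)
        assert t.rhombicity == pytest.approx(0.25, abs=1e-12)
        assert abs(np.trace(t.saupe)) < 1e-9
        axx, ayy, azz = t.principal_components
        assert abs(azz) >= abs(ayy) >= abs(axx)
        # euler angles define the same principal frame (axis sign freedom)
        t2 = AlignmentTensor.from_parameters(8.0, 0.25, t.euler_deg)
        assert np.allclose(t2.saupe, t.saupe, atol=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            AlignmentTensor(np.eye(3))          # not traceless
        with pytest.raises(ValueError):
            AlignmentTensor.from_parameters(5.0, 0.9)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            RDCMeasurement(1, 5.0, 0.0)


class TestBackCalculate:
    def test_axial_vector_along_z(self):
        t = AlignmentTensor.from_parameters(7.0, 0.0)
        d = back_calculate(np.array([[0.0, 0.0, 1.0]]), t)
        assert d[0] == pytest.approx(2 * 7.0, abs=1e-12)

    def test_magic_angle_null(self):
        t = AlignmentTensor.from_parameters(7.0, 0.0)
        theta = np.radians(54.7356103)
        v = np.array([[np.sin(theta), 0.0, np.cos(theta)]])
        assert abs(back_calculate(v, t)[0]) < 1e-6 * 7.0

    def test_saupe_and_angle_formulations_agree(self, rng):
        t = AlignmentTensor.from_parameters(9.3, 0.41, (33.0, 61.0, 150.0))
        v = _unit(rng, 50)
        d1 = back_calculate(v, t, method="saupe")
        d2 = back_calculate(v, t, method="angles")
        assert np.max(np.abs(d1 - d2)) < 1e-9

    def test_axial_bound(self, rng):
        """|D| <= 2|Da| when the tensor is axially symmetric."""
        t = AlignmentTensor.from_parameters(6.0, 0.0, (10.0, 40.0, 5.0))
        d = back_calculate(_unit(rng, 500), t)
        assert np.all(np.abs(d) <= 2 * 6.0 + 1e-9)


class TestQFactor:
    def test_limits_and_scale_invariance(self, rng):
        d = rng.standard_normal(30)
        assert q_factor(d, d) == 0.0
        assert q_factor(d, np.zeros(30)) == pytest.approx(1.0, abs=1e-12)
        c = rng.standard_normal(30)
        assert q_factor(3.7 * d, 3.7 * c) == pytest.approx(q_factor(d, c),
                                                           abs=1e-12)

    def test_undefined_q(self):
        with pytest.raises(UndefinedQError):
            q_factor(np.zeros(5), np.ones(5))
        assert q_factor(np.zeros(5), np.zeros(5)) == 0.0


class TestFitTensor:
    def test_noiseless_recovery(self, ideal_dimer, planted_tensor):
        vecs = amide_vectors(ideal_dimer, ["A"])
        meas = _measurements(vecs, planted_tensor)
        fit = fit_tensor(vecs, meas)
        assert fit.tensor.da == pytest.approx(planted_tensor.da, rel=1e-3)
        assert fit.tensor.rhombicity == pytest.approx(
            planted_tensor.rhombicity, abs=0.005)
        assert fit.chi2 < 1e-6
        assert fit.q < 1e-4

    def test_five_measurements_interpolate(self, rng, planted_tensor):
        vecs = [_Vec(i, v) for i, v in enumerate(_unit(rng, 5))]
        fit = fit_tensor(vecs, _measurements(vecs, planted_tensor))
        assert np.max(np.abs(fit.residuals)) < 1e-9

    def test_null_data_gives_zero_tensor(self, rng):
        vecs = [_Vec(i, v) for i, v in enumerate(_unit(rng, 20))]
        meas = [RDCMeasurement(i, 0.0, 1.0) for i in range(20)]
        fit = fit_tensor(vecs, meas)
        assert fit.tensor.is_zero(1e-10)
        assert fit.q == 0.0

    def test_underdetermined(self, rng, planted_tensor):
        vecs = [_Vec(i, v) for i, v in enumerate(_unit(rng, 4))]
        with pytest.raises(UnderdeterminedError):
            fit_tensor(vecs, _measurements(vecs, planted_tensor))

    def test_collinear_vectors_conditioning_error(self, planted_tensor):
        v = np.array([0.6, 0.0, 0.8])
        vecs = [_Vec(i, v.copy()) for i in range(8)]
        with pytest.raises(ConditioningError):
            fit_tensor(vecs, _measurements(vecs, planted_tensor))

    def test_rotation_invariance_of_da_r(self, rng, planted_tensor):
        """Rotating the structure leaves Da and R unchanged; the principal
        frame co-rotates."""
        v = _unit(rng, 40)
        rot = random_rotation(rng)
        vecs = [_Vec(i, x) for i, x in enumerate(v)]
        vecs_rot = [_Vec(i, rot @ x) for i, x in enumerate(v)]
        meas = _measurements(vecs, planted_tensor)
        f1 = fit_tensor(vecs, meas)
        f2 = fit_tensor(vecs_rot, meas)
        assert f2.tensor.da == pytest.approx(f1.tensor.da, abs=1e-9)
        assert f2.tensor.rhombicity == pytest.approx(f1.tensor.rhombicity,
                                                     abs=1e-9)
        assert np.allclose(f2.tensor.saupe,
                           rot @ f1.tensor.saupe @ rot.T, atol=1e-9)

    def test_linear_and_nonlinear_solvers_agree(self, rng, planted_tensor):
        v = _unit(rng, 40)
        vecs = [_Vec(i, x) for i, x in enumerate(v)]
        noise = 0.5 * rng.standard_normal(40)
        meas = _measurements(vecs, planted_tensor, sigma=0.5, noise=noise)
        lin = fit_tensor(vecs, meas)
        nl = fit_tensor_nonlinear(vecs, meas)
        assert nl.chi2 == pytest.approx(lin.chi2, rel=1e-6)

    def test_unit_vs_sigma_weighting_differ(self, rng, planted_tensor):
        v = _unit(rng, 30)
        vecs = [_Vec(i, x) for i, x in enumerate(v)]
        noise = rng.standard_normal(30)
        meas = [RDCMeasurement(i, float(d), s) for i, (d, s) in enumerate(zip(
            back_calculate(v, planted_tensor) + noise,
            rng.uniform(0.2, 3.0, 30)))]
        fw = fit_tensor(vecs, meas, weighted=True)
        fu = fit_tensor(vecs, meas, weighted=False)
        assert not np.allclose(fw.tensor.saupe, fu.tensor.saupe, atol=1e-9)

    def test_mc_noise_propagation_linear(self, rng, planted_tensor):
        """sd of recovered Da over replicates scales linearly with the
        planted noise sd (R^2 > 0.95)."""
        v = _unit(rng, 40)
        vecs = [_Vec(i, x) for i, x in enumerate(v)]
        sigmas = np.array([0.25, 0.5, 1.0, 2.0])
        sds = []
        for s in sigmas:
            das = []
            for rep in range(200):
                noise = s * rng.standard_normal(40)
                fit = fit_tensor(vecs, _measurements(vecs, planted_tensor,
                                                     sigma=s, noise=noise))
                das.append(fit.tensor.da)
            sds.append(np.std(das))
        sds = np.array(sds)
        slope, intercept = np.polyfit(sigmas, sds, 1)
        pred = slope * sigmas + intercept
        ss_res = np.sum((sds - pred) ** 2)
        ss_tot = np.sum((sds - sds.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.95


def test_simulated_rdcs_match_mean(ideal_dimer, planted_tensor):
    """Mean of noisy replicates converges on the back-calculated coupling."""
    vecs = amide_vectors(ideal_dimer, ["A"])
    truth = back_calculate(vecs, planted_tensor)
    sums = np.zeros(len(vecs))
    n_rep = 400
    for s in range(n_rep):
        meas = synthetic.simulate_rdcs(ideal_dimer, planted_tensor,
                                       noise_sd=2.0, seed=s, chain_ids=["A"])
        sums += [m.d_obs for m in meas]
    mean = sums / n_rep
    se = 2.0 / np.sqrt(n_rep)
    assert np.all(np.abs(mean - truth) < 4 * se)
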