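"""Analytic sphere series: closed forms, gradients, physics invariants."""

import numpy as np
import pytest

from tesvox.errors import ConfigurationError, EvaluationError
from tesvox.oracle import SphereModel, sphere_field, sphere_voltage

RADII = (80.0, 83.0, 87.0, 92.0)
SIGMAS = (0.276, 1.65, 0.01, 0.465)


def _model(**kw):
    defaults = dict(radii_mm=RADII, sigmas_S_per_m=SIGMAS,
                    source=(0.0, 0.0, 1.0),
                    sink=(np.sin(np.deg2rad(170.0)), 0.0, np.cos(np.deg2rad(170.0))),
                    current_mA=1.0, n_terms=300)
    defaults.update(kw)
    return SphereModel(**defaults)


def _sample_points(rng, n=200, rmax=78.0):
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts * rng.uniform(5.0, rmax, size=(n, 1))


class TestValidation:
    def test_mismatched_lengths(self):
        with pytest.raises(ConfigurationError):
            SphereModel(radii_mm=(80.0, 92.0), sigmas_S_per_m=(0.3,))

    def test_nonascending_radii(self):
        with pytest.raises(ConfigurationError):
            SphereModel(radii_mm=(92.0, 80.0), sigmas_S_per_m=(0.3, 0.3))

    def test_non_unit_direction(self):
        with pytest.raises(ConfigurationError):
            SphereModel(radii_mm=(92.0,), sigmas_S_per_m=(0.3,), source=(0, 0, 2))

    def test_point_outside_sphere(self):
        m = _model()
        with pytest.raises(EvaluationError):
            m.voltage(np.array([[0.0, 0.0, 100.0]]))

    def test_point_at_electrode(self):
        m = _model()
        with pytest.raises(EvaluationError):
            m.voltage(np.array([[0.0, 0.0, 92.0]]))


class TestHomogeneousClosedForm:
    """With all conductivities equal the model must reduce to the exact
    homogeneous-sphere point-electrode potential (image-style closed form)."""

    @staticmethod
    def _homogeneous_reference(pts_mm, e_dir, R_mm, sigma, I_A):
        # V(x) = I/(4 pi sigma R) * (2/u - 2 + ln(2/(1 - t c + u))),
        # t = r/R, c = cos(angle to electrode), u = |x/R - e|
        pts = np.asarray(pts_mm, float) / 1000.0
        R = R_mm / 1000.0
        r = np.linalg.norm(pts, axis=1)
        t = r / R
        c = (pts @ e_dir) / np.maximum(r, 1e-300)
        u = np.sqrt(1 - 2 * t * c + t * t)
        K = I_A / (4 * np.pi * sigma * R)
        return K * (2 / u - 2 + np.log(2.0 / (1 - t * c + u)))

    def test_four_equal_shells_match_closed_form(self, rng):
        sigma = 0.4
        m = _model(sigmas_S_per_m=(sigma,) * 4, n_terms=400)
        pts = _sample_points(rng, n=150, rmax=88.0)
        got = m.voltage(pts, demean=False)
        src = np.array(m.source)
        snk = np.array(m.sink)
        ref = (self._homogeneous_reference(pts, src, 92.0, sigma, 1e-3)
               - self._homogeneous_reference(pts, snk, 92.0, sigma, 1e-3))
        assert np.allclose(got, ref, atol=1e-10 * np.abs(ref).max() + 1e-12)

    def test_single_shell_equals_four_equal_shells(self, rng):
        pts = _sample_points(rng, n=100, rmax=85.0)
        four = _model(sigmas_S_per_m=(0.4,) * 4, n_terms=300)
        one = SphereModel(radii_mm=(92.0,), sigmas_S_per_m=(0.4,),
                          source=four.source, sink=four.sink, n_terms=300)
        a = one.voltage(pts, demean=False)
        b = four.voltage(pts, demean=False)
        assert np.allclose(a, b, rtol=1e-9, atol=1e-12)


class TestFieldConsistency:
    def test_field_matches_finite_difference_gradient(self, rng):
        m = _model(n_terms=400)
        pts = _sample_points(rng, n=40, rmax=75.0)
        E = m.field(pts)
        eps = 1e-3  # mm
        for d in range(3):
            step = np.zeros(3)
            step[d] = eps
            vp = m.voltage(pts + step, demean=False)
            vm = m.voltage(pts - step, demean=False)
            # E = -dV/dx; voltage in V, distance converted mm -> m
            fd = -(vp - vm) / (2 * eps * 1e-3)
            assert np.allclose(E[:, d], fd, rtol=1e-5,
                               atol=1e-6 * np.abs(E).max())

    def test_on_axis_field_is_finite_and_axial(self):
        m = _model()
        pts = np.array([[0.0, 0.0, z] for z in (10.0, 40.0, 70.0)])
        E = m.field(pts)
        assert np.all(np.isfinite(E))
        # source on +z, sink nearly antipodal: dominant component is z
        assert np.all(np.abs(E[:, 2]) > np.abs(E[:, 1]))


class TestPhysicsInvariants:
    def test_antisymmetry_under_electrode_swap(self, rng):
        pts = _sample_points(rng, n=60)
        m = _model()
        swapped = _model(source=m.sink, sink=m.source)
        a = m.voltage(pts, demean=False)
        b = swapped.voltage(pts, demean=False)
        assert np.allclose(a, -b, rtol=1e-12, atol=1e-15)

    def test_current_scaling(self, rng):
        pts = _sample_points(rng, n=30)
        v1 = _model(current_mA=1.0).voltage(pts, demean=False)
        v2 = _model(current_mA=2.0).voltage(pts, demean=False)
        assert np.allclose(v2, 2 * v1, rtol=1e-12)

    def test_voltage_continuity_across_interfaces(self):
        m = _model(n_terms=600)
        for R in (80.0, 83.0, 87.0):
            direction = np.array([0.6, 0.48, 0.64])
            direction /= np.linalg.norm(direction)
            below = (R - 1e-6) * direction
            above = (R + 1e-6) * direction
            va, vb = m.voltage(np.array([below, above]), demean=False)
            assert va == pytest.approx(vb, rel=1e-5)

    def test_radial_current_continuity_across_interfaces(self):
        m = _model(n_terms=600)
        sig = dict(zip(RADII, SIGMAS))
        direction = np.array([0.6, 0.48, 0.64])
        direction /= np.linalg.norm(direction)
        for i, R in enumerate((80.0, 83.0, 87.0)):
            below = (R - 1e-5) * direction
            above = (R + 1e-5) * direction
            E = m.field(np.array([below, above]))
            jn_in = SIGMAS[i] * (E[0] @ direction)
            jn_out = SIGMAS[i + 1] * (E[1] @ direction)
            assert jn_in == pytest.approx(jn_out, rel=1e-4)

    def test_resistive_skull_reduces_brain_field(self, rng):
        # fixed-current injection: scalp shunting limits how much the skull
        # can attenuate the brain field, but the effect must have the right sign
        pts = _sample_points(rng, n=100, rmax=75.0)
        shielded = _model().field(pts)
        no_skull = _model(sigmas_S_per_m=(0.276, 1.65, 0.465, 0.465)).field(pts)
        assert (np.linalg.norm(shielded, axis=1).mean()
                < 0.95 * np.linalg.norm(no_skull, axis=1).mean())

    def test_skull_carries_the_dominant_voltage_drop(self):
        # the resistive skull concentrates the radial potential drop: across
        # the skull shell it must dwarf the drop across the CSF shell
        m = _model(n_terms=600)
        d = np.array([0.6, 0.48, 0.64])
        d /= np.linalg.norm(d)
        pts = np.array([[*(80.5 * d)], [*(82.5 * d)], [*(83.5 * d)], [*(86.5 * d)]])
        v = m.voltage(pts, demean=False)
        drop_csf = abs(v[1] - v[0])
        drop_skull = abs(v[3] - v[2])
        assert drop_skull > 10 * drop_csf


class TestSeriesNumerics:
    def test_tail_decreases_with_more_terms(self, rng):
        pts = _sample_points(rng, n=50, rmax=85.0)
        t100 = _model(n_terms=100).tail_estimate(pts)
        t400 = _model(n_terms=400).tail_estimate(pts)
        assert t400 < t100

    def test_convergence_of_the_voltage(self, rng):
        pts = _sample_points(rng, n=50, rmax=88.0)
        v300 = _model(n_terms=300).voltage(pts, demean=False)
        v600 = _model(n_terms=600).voltage(pts, demean=False)
        assert np.allclose(v300, v600, rtol=1e-6, atol=1e-9)

    def test_chunked_evaluation_matches_single_block(self, rng, monkeypatch):
        m = _model(n_terms=200)
        pts = _sample_points(rng, n=500)
        whole_V = m.voltage(pts, demean=False)
        whole_E = m.field(pts)
        monkeypatch.setattr(SphereModel, "_CHUNK", 64)
        chunk_V = m.voltage(pts, demean=False)
        chunk_E = m.field(pts)
        assert np.array_equal(whole_V, chunk_V)
        assert np.array_equal(whole_E, chunk_E)

    def test_module_level_wrappers(self, rng):
        m = _model()
        pts = _sample_points(rng, n=10)
        assert np.array_equal(sphere_voltage(m, pts), m.voltage(pts))
        assert np.array_equal(sphere_field(m, pts), m.field(pts))
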