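import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from ocusim.eye_model import (ConicSurface, GeometryError, GrinMedium,
                              LIOU_BRENNAN)
from ocusim.raytrace import (Ray, aim_rays, intersect_conic, refract, sag,
                             trace_grin_segment, trace_ray, trace_system)
from ocusim.synthetic_oracles import (make_homogeneous_grin_eye,
                                      make_homogeneous_twin,
                                      make_single_sphere_eye)


class TestSag:
    def test_vertex(self):
        s = ConicSurface(10.0, -0.5, 4.0)
        assert sag(s, 0.0) == 0.0

    def test_sphere_matches_circle_closed_form(self):
        r_c = 9.0
        s = ConicSurface(r_c, 0.0, 4.0)
        r = r_c / 2.0
        assert sag(s, r) == pytest.approx(r_c - np.sqrt(r_c**2 - r**2),
                                          abs=1e-12)

    def test_paraxial_limit(self):
        s = ConicSurface(20.0, -0.7, 4.0)
        r = 0.01 * 20.0
        assert sag(s, r) == pytest.approx(r * r / (2 * 20.0), rel=1e-4)

    def test_domain_error_names_surface(self):
        s = ConicSurface(5.0, 1.0, 3.0)
        with pytest.raises(GeometryError, match="R=5.0"):
            sag(s, 4.9)

    @settings(max_examples=30, derandomize=True)
    @given(radius=st.floats(6.0, 50.0), conic=st.floats(-2.0, 0.5),
           frac=st.floats(0.0, 0.5))
    def test_sag_nonnegative_convex(self, radius, conic, frac):
        s = ConicSurface(radius, conic, 3.0)
        assert sag(s, frac * 3.0) >= 0.0


class TestIntersect:
    def test_axial_ray_hits_vertex(self):
        s = ConicSurface(8.0, -0.3, 4.0, vertex_z_mm=2.0)
        q, n, ok, _ = intersect_conic(np.array([[0.0, 0.0, -1.0]]),
                                      np.array([[0.0, 0.0, 1.0]]), s)
        assert ok[0]
        assert q[0] == pytest.approx([0.0, 0.0, 2.0], abs=1e-12)
        assert n[0] == pytest.approx([0.0, 0.0, 1.0], abs=1e-12)

    def test_sphere_matches_quadratic_oracle(self):
        radius = 7.5
        s = ConicSurface(radius, 0.0, 5.0)
        p = np.array([[1.2, -0.7, -4.0]])
        u = np.array([[0.05, 0.02, 1.0]])
        u = u / np.linalg.norm(u)
        q, _, ok, t = intersect_conic(p, u, s)
        # closed form: |p + t u - c| = R with sphere centre (0,0,R)
        c = np.array([0.0, 0.0, radius])
        oc = p[0] - c
        b = np.dot(oc, u[0])
        disc = b * b - (np.dot(oc, oc) - radius * radius)
        t_ref = -b - np.sqrt(disc)
        assert ok[0]
        assert t[0] == pytest.approx(t_ref, abs=1e-10)

    def test_outside_aperture_vignettes_without_exception(self):
        s = ConicSurface(8.0, 0.0, 1.0)
        q, n, ok, _ = intersect_conic(np.array([[3.0, 0.0, -4.0]]),
                                      np.array([[0.0, 0.0, 1.0]]), s)
        assert not ok[0]


class TestRefract:
    def test_normal_incidence_unchanged(self):
        d = np.array([[0.0, 0.0, 1.0]])
        n = np.array([[0.0, 0.0, -1.0]])
        out, tir = refract(d, n, 1.0, 1.5)
        assert not tir[0]
        assert out[0] == pytest.approx(d[0], abs=1e-15)

    def test_equal_indices_unchanged(self):
        d = np.array([[0.3, 0.1, 0.9]])
        d = d / np.linalg.norm(d)
        n = np.array([[0.0, 0.0, -1.0]])
        out, _ = refract(d, n, 1.4, 1.4)
        assert out[0] == pytest.approx(d[0], abs=1e-14)

    def test_45_degree_scalar_snell(self):
        d = np.array([[np.sin(np.pi / 4), 0.0, np.cos(np.pi / 4)]])
        n = np.array([[0.0, 0.0, -1.0]])
        out, _ = refract(d, n, 1.0, 1.5)
        sin_t = np.sin(np.pi / 4) / 1.5
        assert out[0, 0] == pytest.approx(sin_t, abs=1e-14)
        assert np.linalg.norm(out[0]) == pytest.approx(1.0, abs=1e-14)

    def test_total_internal_reflection_flagged(self):
        d = np.array([[np.sin(np.deg2rad(80)), 0.0, np.cos(np.deg2rad(80))]])
        out, tir = refract(d, np.array([[0.0, 0.0, -1.0]]), 1.5, 1.0)
        assert tir[0]

    @settings(max_examples=50, derandomize=True)
    @given(angle=st.floats(0.0, 60.0), n1=st.floats(1.0, 1.7),
           n2=st.floats(1.0, 1.7))
    def test_snell_invariant_and_unit_norm(self, angle, n1, n2):
        """n sin(theta) is conserved and the output stays unit-norm."""
        a = np.deg2rad(angle)
        d = np.array([[np.sin(a), 0.0, np.cos(a)]])
        n = np.array([[0.0, 0.0, -1.0]])
        out, tir = refract(d, n, n1, n2)
        if not tir[0]:
            assert n2 * out[0, 0] == pytest.approx(n1 * np.sin(a), abs=1e-12)
        assert np.linalg.norm(out[0]) == pytest.approx(1.0, abs=1e-12)


class TestGrinIntegration:
    def _lb_lens(self):
        eye_constants = LIOU_BRENNAN
        ga = eye_constants["grin_anterior"]
        return GrinMedium(n00=ga["n00"], a1=ga["a1"], a2=ga["a2"],
                          b1=ga["b1"], valid_thickness_mm=1.59,
                          origin_z_mm=0.0)

    def test_homogeneous_limit_matches_straight_line(self):
        grin = GrinMedium(n00=1.42, valid_thickness_mm=3.0, origin_z_mm=0.0)
        exit_surface = ConicSurface(np.inf, 0.0, 5.0, vertex_z_mm=3.0)
        p = np.array([[0.5, -0.2, 0.0]])
        u = np.array([[0.08, 0.03, 1.0]])
        u = u / np.linalg.norm(u)
        opl = np.zeros(1)
        alive = np.ones(1, bool)
        pe, ue, ople, al = trace_grin_segment(p, u, opl, alive, grin,
                                              exit_surface, 0.01)
        t = 3.0 / u[0, 2]
        straight = p[0] + t * u[0]
        assert al[0]
        assert pe[0] == pytest.approx(straight, abs=1e-9)
        assert ue[0] == pytest.approx(u[0], abs=1e-12)
        assert ople[0] == pytest.approx(1.42 * t, abs=1e-9)

    def test_fourth_order_step_convergence(self):
        """Richardson check: halving the step moves the exit point < 1e-8 mm."""
        grin = self._lb_lens()
        exit_surface = ConicSurface(np.inf, 0.0, 5.0, vertex_z_mm=1.59)
        p = np.array([[1.0, 0.5, 0.0]])
        u = np.array([[0.15, -0.05, 1.0]])
        u = u / np.linalg.norm(u)
        outs = []
        for h in (0.02, 0.01):
            pe, _, _, _ = trace_grin_segment(p.copy(), u.copy(), np.zeros(1),
                                             np.ones(1, bool), grin,
                                             exit_surface, h)
            outs.append(pe[0])
        assert np.linalg.norm(outs[0] - outs[1]) < 1e-8

    def test_axial_optical_path_matches_quadrature(self):
        grin = self._lb_lens()
        exit_surface = ConicSurface(np.inf, 0.0, 5.0, vertex_z_mm=1.59)
        p = np.array([[0.0, 0.0, 0.0]])
        u = np.array([[0.0, 0.0, 1.0]])
        _, _, opl, _ = trace_grin_segment(p, u, np.zeros(1),
                                          np.ones(1, bool), grin,
                                          exit_surface, 0.01)
        ref = quad(lambda z: grin.axial_index(z), 0.0, 1.59, epsabs=1e-12)[0]
        assert abs(opl[0] - ref) * 1000.0 < 1e-6  # um

    def test_lateral_escape_vignettes(self):
        grin = GrinMedium(n00=1.42, valid_thickness_mm=5.0, origin_z_mm=0.0)
        exit_surface = ConicSurface(np.inf, 0.0, 0.5, vertex_z_mm=5.0)
        p = np.array([[0.4, 0.0, 0.0]])
        u = np.array([[0.3, 0.0, 1.0]])
        u = u / np.linalg.norm(u)
        _, _, _, alive = trace_grin_segment(p, u, np.zeros(1),
                                            np.ones(1, bool), grin,
                                            exit_surface, 0.01,
                                            semi_aperture_mm=0.5)
        assert not alive[0]

    def test_grin_system_matches_homogeneous_twin(self):
        """Zero-gradient GRIN eye traces identically to its homogeneous twin."""
        grin_eye = make_homogeneous_grin_eye()
        homog_eye = make_homogeneous_twin(grin_eye)
        p = np.array([[0.4, 0.3, -3.0], [-0.6, 0.0, -3.0]])
        u = np.tile([0.0, 0.0, 1.0], (2, 1))
        a = trace_system(grin_eye, p, u, to_image=False)
        b = trace_system(homog_eye, p, u, to_image=False)
        assert np.allclose(a.exit_positions, b.exit_positions, atol=1e-9)
        assert np.allclose(a.exit_opl_mm, b.exit_opl_mm, atol=1e-9)


class TestSystemTrace:
    def test_plane_symmetry_in_y(self, phakic_focused):
        """Mirroring the launch coordinates in y mirrors the whole trace."""
        p = np.array([[0.3, 0.8, -5.0], [0.3, -0.8, -5.0]])
        u = np.tile([np.sin(np.deg2rad(5)), 0.0, np.cos(np.deg2rad(5))], (2, 1))
        res = trace_system(phakic_focused, p, u)
        a, b = res.image_positions
        assert a[0] == b[0]
        assert a[1] == -b[1]
        assert a[2] == b[2]
        assert res.image_opl_mm[0] == res.image_opl_mm[1]

    def test_energy_bookkeeping(self, phakic_focused):
        n = 64
        xs = np.linspace(-4.0, 4.0, n)
        p = np.column_stack([xs, np.zeros(n), np.full(n, -5.0)])
        u = np.tile([0.0, 0.0, 1.0], (n, 1))
        res = trace_system(phakic_focused, p, u)
        assert res.n_launched == n
        assert res.n_vignetted + int(np.count_nonzero(res.alive)) == n
        assert res.n_vignetted > 0  # edge rays clipped by the 4 mm stop

    def test_tiny_pupil_focus_matches_paraxial_oracle(self):
        eye = make_single_sphere_eye(pupil_diameter_mm=0.02, at_focus=False)
        p = np.array([[0.01, 0.0, -2.0]])
        u = np.array([[0.0, 0.0, 1.0]])
        res = trace_system(eye, p, u, to_image=False)
        t_cross = -res.exit_positions[0, 0] / res.exit_directions[0, 0]
        z_cross = res.exit_positions[0, 2] + t_cross * res.exit_directions[0, 2]
        assert z_cross == pytest.approx(eye.metadata["analytic_focus_mm"],
                                        abs=0.05)

    def test_reversed_ray_retraces_to_entrance(self, phakic_focused):
        """Time-reversal through the (homogeneous) cornea returns the ray to
        its entrance point."""
        cornea = phakic_focused.elements[0]
        from ocusim.raytrace import trace_element
        from ocusim.eye_model import Medium
        p = np.array([[0.8, 0.5, -2.0]])
        u = np.array([[0.02, -0.01, 1.0]])
        u = u / np.linalg.norm(u)
        pf, uf, _, alive = trace_element(p.copy(), u.copy(), np.zeros(1),
                                         np.ones(1, bool), cornea, 1.0,
                                         Medium(index=1.336))
        assert alive[0]
        # reverse: swap surface order and indices
        from dataclasses import replace
        rev = replace(cornea,
                      surfaces=tuple(
                          ConicSurface(-s.radius_mm, s.conic,
                                       s.semi_aperture_mm, -s.vertex_z_mm)
                          for s in reversed(cornea.surfaces)))
        pr = pf * np.array([1.0, 1.0, -1.0])
        ur = uf * np.array([-1.0, -1.0, 1.0])
        pb, ub, _, alive2 = trace_element(pr, ur, np.zeros(1),
                                          np.ones(1, bool), rev, 1.336,
                                          Medium(index=1.0))
        assert alive2[0]
        back = pb[0] * np.array([1.0, 1.0, -1.0])
        t = (p[0, 2] - back[2]) / (ub[0] * np.array([-1, -1, 1]))[2]
        entry = back + t * ub[0] * np.array([-1.0, -1.0, 1.0])
        assert entry == pytest.approx(p[0], abs=1e-8)


class TestAiming:
    def test_chief_and_grid_converge(self, phakic_focused):
        r_p = phakic_focused.stop.semi_aperture_mm
        cx = phakic_focused.stop.decentration_x_mm
        targets = np.array([[cx, 0.0], [cx + 0.9 * r_p, 0.0],
                            [cx, 0.9 * r_p], [cx - 0.5 * r_p, -0.7 * r_p]])
        p0, u0, opl0, conv = aim_rays(phakic_focused, targets)
        assert conv.all()
        from ocusim.raytrace import _trace_to_stop
        hit, _ = _trace_to_stop(phakic_focused, p0[:, :2], p0[0, 2], u0)
        assert np.max(np.abs(hit - targets)) < 1e-9

    def test_single_ray_wrapper(self, phakic_focused):
        ray = Ray(position=np.array([0.0, 0.0, -5.0]),
                  direction=np.array([np.sin(np.deg2rad(5)), 0.0,
                                      np.cos(np.deg2rad(5))]))
        out = trace_ray(phakic_focused, ray)
        assert out.alive
        assert out.position[2] == pytest.approx(
            phakic_focused.image_plane_z_mm)
        assert out.optical_path_um > 0
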