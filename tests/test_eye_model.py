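import math
import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from ocusim import paraxial, wavefront
from ocusim.eye_model import (LIOU_BRENNAN, ConfigurationError, GeometryError,
                              IOLDesign, build_phakic_eye,
                              build_pseudophakic_eye,
                              equiconvex_radius_for_power, lens_equator_z_mm,
                              make_equiconvex_iol, mirror_lr,
                              set_misalignment)
from ocusim.raytrace import trace_system


class TestPhakicBuilder:
    def test_structure(self, phakic_focused):
        eye = phakic_focused
        assert eye.field_angle_deg == 5.0
        lens = eye.lens_element
        assert lens.is_lens and len(lens.surfaces) == 3
        assert lens.media[0].is_grin and lens.media[1].is_grin
        assert eye.stop.z_mm == pytest.approx(3.66)
        assert lens.misalignment.is_identity

    def test_grin_continuity_at_equator(self):
        """The two gradient-index halves join continuously on the axis."""
        eye = build_phakic_eye()
        lens = eye.lens_element
        z_eq = lens.surfaces[1].vertex_z_mm
        n_ant = lens.media[0].index_at(0.0, z_eq)
        n_post = lens.media[1].index_at(0.0, z_eq)
        assert n_ant == pytest.approx(n_post, abs=1e-6)
        assert 1.3 <= n_ant <= 1.5

    def test_axial_optical_path_matches_direct_summation(self, phakic_focused):
        """On-axis optical path equals the independent sum of thickness*index,
        with the GRIN contribution integrated by quadrature."""
        eye = phakic_focused
        z_img = eye.image_plane_z_mm
        res = trace_system(eye, [[0.0, 0.0, -5.0]], [[0.0, 0.0, 1.0]])
        traced = res.image_opl_mm[0] - 5.0  # subtract the air path from z=-5
        ga = LIOU_BRENNAN["grin_anterior"]
        gp = LIOU_BRENNAN["grin_posterior"]
        grin1 = quad(lambda z: ga["n00"] + ga["a1"] * z + ga["a2"] * z * z,
                     0.0, 1.59)[0]
        grin2 = quad(lambda z: gp["n00"] + gp["a1"] * z + gp["a2"] * z * z,
                     0.0, 2.43)[0]
        expected = (0.50 * 1.376 + 3.16 * 1.336 + grin1 + grin2
                    + (z_img - 7.68) * 1.336)
        assert traced == pytest.approx(expected, abs=1e-6)

    def test_zero_pupil_rejected(self):
        with pytest.raises(ConfigurationError, match="pupil"):
            build_phakic_eye(pupil_diameter_mm=0.0)

    def test_missing_constant_named(self):
        constants = dict(LIOU_BRENNAN)
        del constants["lens_front_radius_mm"]
        with pytest.raises(ConfigurationError, match="lens_front_radius_mm"):
            build_phakic_eye(constants)

    def test_center_stop_flag(self):
        eye = build_phakic_eye(center_stop=True)
        assert eye.stop.decentration_x_mm == 0.0
        assert eye.metadata["center_stop"] is True


class TestMisalignment:
    def test_identity_bitwise(self, phakic_focused):
        eye = set_misalignment(phakic_focused, 0.0, 0.0)
        p0 = np.array([[0.3, 0.2, -5.0], [-0.5, 0.1, -5.0]])
        u0 = np.tile([[0.05, 0.0, 1.0]] / np.linalg.norm([0.05, 0, 1]), (2, 1))
        a = trace_system(phakic_focused, p0, u0)
        b = trace_system(eye, p0, u0)
        assert np.array_equal(a.image_positions, b.image_positions)
        assert np.array_equal(a.image_opl_mm, b.image_opl_mm)

    def test_inverse_composition(self, phakic_focused):
        eye = set_misalignment(phakic_focused, 0.4, 6.0)
        back = set_misalignment(eye, -0.4, -6.0, relative=True)
        m = back.lens_element.misalignment
        assert abs(m.decentration_x_mm) < 1e-12
        assert abs(m.tilt_y_deg) < 1e-12

    def test_soft_bounds_warn(self, phakic_focused):
        with pytest.warns(UserWarning, match="soft bound"):
            set_misalignment(phakic_focused, 2.0, 0.0)
        with pytest.warns(UserWarning, match="soft bound"):
            set_misalignment(phakic_focused, 0.0, 20.0)

    def test_geometry_outside_lens_untouched(self, phakic_focused):
        eye = set_misalignment(phakic_focused, 1.0, 10.0)
        assert eye.elements[0] is phakic_focused.elements[0]
        assert eye.stop == phakic_focused.stop
        assert eye.field_angle_deg == phakic_focused.field_angle_deg


class TestEquiconvexSolver:
    def test_thin_lens_limit(self):
        """Vanishing thickness recovers the lensmaker radius 2(n-na)/P."""
        r = equiconvex_radius_for_power(20.0, 1.5, 1.0, 1e-9)
        assert r == pytest.approx(2.0 * 0.5 / 0.020, rel=1e-9)

    def test_thick_lens_retrace(self):
        """The solved radius reproduces the power through the independent
        paraxial matrix oracle."""
        n_mat, n_amb, t, p = 1.458, 1.336, 1.0, 21.0
        r = equiconvex_radius_for_power(p, n_mat, n_amb, t)
        phi1 = (n_mat - n_amb) / r
        refr1 = np.array([[1, 0], [-phi1, 1.0]])
        trans = np.array([[1, t / n_mat], [0, 1.0]])
        m = refr1 @ trans @ refr1
        assert -m[1, 0] * 1000.0 == pytest.approx(p, abs=1e-6)

    def test_near_zero_power_rejected(self):
        with pytest.raises(ConfigurationError, match="0.01 dpt"):
            equiconvex_radius_for_power(0.001, 1.5, 1.0, 1.0)


class TestIOLDesignRecord:
    def test_power_invariant(self):
        iol = make_equiconvex_iol(21.0)
        assert iol.paraxial_power_dpt(1.336) == pytest.approx(21.0, abs=1e-6)
        bad = IOLDesign(front_radius_mm=50.0, back_radius_mm=-50.0,
                        central_thickness_mm=1.0, material_index=1.458,
                        labelled_power_dpt=21.0)
        with pytest.raises(ConfigurationError, match="deviates"):
            bad.validate_power(1.336)

    def test_zero_thickness_rejected(self):
        with pytest.raises(ConfigurationError):
            IOLDesign(front_radius_mm=10.0, back_radius_mm=-10.0,
                      central_thickness_mm=0.0, material_index=1.458,
                      labelled_power_dpt=21.0)


class TestPseudophakicBuilder:
    def test_haptic_plane_at_equator(self, phakic_focused, aspheric_iol):
        pseudo = build_pseudophakic_eye(phakic_focused, aspheric_iol,
                                        solve_focus=False)
        z_eq = lens_equator_z_mm()
        iol_el = pseudo.lens_element
        assert iol_el.front_vertex_z_mm == pytest.approx(
            z_eq - aspheric_iol.haptic_offset_mm)

    def test_anterior_segment_untouched(self, phakic_focused,
                                        pseudophakic_focused):
        pseudo = pseudophakic_focused
        assert pseudo.elements[0] == phakic_focused.elements[0]
        assert pseudo.stop == phakic_focused.stop
        assert pseudo.field_angle_deg == phakic_focused.field_angle_deg
        assert pseudo.wavelength_um == phakic_focused.wavelength_um

    def test_both_image_planes_stored(self, phakic_focused,
                                      pseudophakic_focused):
        assert pseudophakic_focused.image_plane_z_mm is not None
        stored = pseudophakic_focused.metadata["phakic_image_plane_z_mm"]
        assert stored == pytest.approx(phakic_focused.image_plane_z_mm)
        assert (pseudophakic_focused.image_plane_z_mm
                != phakic_focused.image_plane_z_mm)

    def test_paraxial_focus_agrees_with_matrix_oracle(self, phakic_focused,
                                                      aspheric_iol):
        pseudo = build_pseudophakic_eye(phakic_focused, aspheric_iol,
                                        solve_focus=False)
        power, bfd = paraxial.paraxial_oracle(pseudo)
        # thin-IOL sanity: focus lands within 1% of the anatomical length
        z_focus = pseudo.elements[-1].back_vertex_z_mm + bfd
        assert z_focus == pytest.approx(23.95, rel=0.02)

    def test_too_thick_iol_rejected(self, phakic_focused):
        fat = IOLDesign(front_radius_mm=12.0, back_radius_mm=-12.0,
                        central_thickness_mm=5.0, material_index=1.458,
                        labelled_power_dpt=33.5)
        fat = IOLDesign(front_radius_mm=fat.front_radius_mm,
                        back_radius_mm=fat.back_radius_mm,
                        central_thickness_mm=5.0, material_index=1.458,
                        labelled_power_dpt=fat.paraxial_power_dpt(1.336))
        with pytest.raises(GeometryError, match="does not fit"):
            build_pseudophakic_eye(phakic_focused, fat, solve_focus=False)

    def test_flat_iol_warns_but_returns_finite(self, phakic_focused):
        flat = IOLDesign(front_radius_mm=math.inf, back_radius_mm=math.inf,
                         central_thickness_mm=1.0, material_index=1.458,
                         labelled_power_dpt=0.0)
        with pytest.warns(UserWarning):
            pseudo = build_pseudophakic_eye(phakic_focused, flat,
                                            focus_grid_n=24)
        assert np.isfinite(pseudo.image_plane_z_mm)
        m = wavefront.analyze_system(pseudo, grid_n=24).metrics
        assert np.isfinite(m.defocus_dpt)


class TestMirror:
    def test_mirror_negates_signed_horizontal_quantities(self, phakic_focused):
        left = mirror_lr(set_misalignment(phakic_focused, 0.6, 4.0))
        assert left.field_angle_deg == -phakic_focused.field_angle_deg
        assert left.stop.decentration_x_mm == \
            -phakic_focused.stop.decentration_x_mm
        m = left.lens_element.misalignment
        assert m.decentration_x_mm == -0.6
        assert m.tilt_y_deg == -4.0
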