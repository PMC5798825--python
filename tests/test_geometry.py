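"""Tests of the parametric vessel construction (the synthetic-input generator)."""

import json

import numpy as np
import pytest

import aawall as aw
from aawall.geometry import (
    AAAParameters, ReferentGeometryParameters, GeometryError, CS_SPACING, L_STAR,
    tortuosity_to_sagitta, circumferential_profile, build_referent, build_aaa,
    _arc_offset,
)


class TestTortuosity:
    def test_straight_centerline(self):
        assert tortuosity_to_sagitta(1.0, 128.0) == 0.0
        assert tortuosity_to_sagitta(-1.0, 128.0) == 0.0

    def test_sign_mirrors_offset(self):
        s = tortuosity_to_sagitta(1.05, 128.0)
        assert tortuosity_to_sagitta(-1.05, 128.0) == pytest.approx(-s)
        assert s > 0

    @pytest.mark.parametrize("tau", [1.02, 1.05, 1.175])
    def test_arc_length_consistency(self, tau):
        """Root-find cross-checked by quadrature of the arc length of the
        resulting centerline: arc/chord must reproduce the requested index."""
        chord = 128.0
        s = tortuosity_to_sagitta(tau, chord)
        z = np.linspace(0.0, chord, 200_001)
        off = _arc_offset(z, chord, s)
        arclen = np.sum(np.hypot(np.diff(z), np.diff(off)))
        assert arclen / chord == pytest.approx(tau, rel=1e-6)

    def test_subunit_index_rejected(self):
        with pytest.raises(GeometryError):
            tortuosity_to_sagitta(0.9, 128.0)


class TestCircumferentialProfile:
    def test_full_sweep_is_circle(self):
        r = circumferential_profile(360.0, 22.5, 10.0)
        th = np.linspace(-np.pi, np.pi, 720)
        assert np.allclose(r(th), 22.5)

    def test_no_bulge_recovers_referent_circle(self):
        r = circumferential_profile(90.0, 10.0, 10.0)
        th = np.linspace(-np.pi, np.pi, 720)
        assert np.allclose(r(th), 10.0)

    @pytest.mark.parametrize("extent", [90.0, 180.0, 270.0, 360.0])
    def test_enclosed_area_quadrature_vs_shoelace(self, extent):
        r = circumferential_profile(extent, 22.5, 10.0)
        th = np.linspace(-np.pi, np.pi, 200_000, endpoint=False)
        rr = r(th)
        area_quad = 0.5 * np.trapezoid(np.append(rr, rr[0]) ** 2,
                                       np.append(th, th[0] + 2 * np.pi))
        x, y = rr * np.cos(th), rr * np.sin(th)
        area_shoe = 0.5 * np.abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        assert area_quad == pytest.approx(area_shoe, rel=1e-6)

    def test_posterior_touches_referent_circle(self):
        r = circumferential_profile(270.0, 22.5, 10.0)
        assert r(np.array([np.pi]))[0] == pytest.approx(10.0)
        assert r(np.array([0.0]))[0] == pytest.approx(22.5)

    def test_invalid_extent_rejected(self):
        with pytest.raises(GeometryError):
            circumferential_profile(120.0, 22.5, 10.0)


class TestReferentSolid:
    def test_mid_abdominal_annulus_dimensions(self):
        solid = build_referent()
        th = np.linspace(-np.pi, np.pi, 64)
        z = np.full_like(th, 60.0)
        assert np.allclose(solid.r_outer(th, z), 10.0)
        assert np.allclose(solid.r_outer(th, z) - solid.r_inner(th, z), 2.0)

    def test_degenerate_wall_rejected(self):
        with pytest.raises(GeometryError):
            ReferentGeometryParameters(t=10.0)  # t = D/2: no lumen

    def test_zero_takeoff_angles_give_parallel_iliac_axes(self):
        solid = build_referent(ReferentGeometryParameters(alpha=0.0, beta=0.0))
        d = np.linspace(1.0, 8.0, 20)
        assert np.allclose(solid.lobe_center_x(d), 0.0, atol=1e-12)
        assert np.allclose(solid.lobe_center_y(d), 0.0, atol=1e-12)

    def test_junction_cross_section_continuous_at_bifurcation_plane(self):
        solid = build_referent()
        th = np.linspace(-np.pi, np.pi, 90)
        above = solid.r_outer(th, np.full_like(th, 1e-9))
        below = solid.r_outer(th, np.full_like(th, -1e-9))
        assert np.allclose(above, below, atol=1e-3)

    def test_cross_section_planes(self):
        solid = build_referent()
        cs = solid.cross_sections()
        assert len(cs) == 9
        assert np.allclose(np.diff([c.z for c in cs]), CS_SPACING)
        poly = cs[4].polygon_outer()
        assert np.hypot(*poly.T).max() == pytest.approx(10.0, rel=1e-9)

    def test_exports(self, tmp_path):
        solid = build_referent()
        solid.to_stl(tmp_path / "ref.stl", n_theta=24, n_z=30)
        solid.write_sidecar(tmp_path / "ref.json")
        assert (tmp_path / "ref.stl").read_text().startswith("solid")
        meta = json.loads((tmp_path / "ref.json").read_text())
        assert meta["referent"]["D"] == 20.0


class TestAAASolid:
    def test_baseline_max_transverse_diameter(self):
        solid = build_aaa()
        z = np.linspace(0.0, L_STAR, 3000)
        ro = solid.r_outer(np.zeros_like(z), z)
        assert 2 * ro.max() == pytest.approx(45.0, rel=1e-6)
        z_lo, z_hi = solid.sac_span
        assert (z_lo, z_hi) == (0.0, 64.0)

    def test_null_aneurysm_recovers_referent(self):
        null = build_aaa(aaa=AAAParameters(max_diameter=20.0, sac_thickness=2.0))
        ref = build_referent()
        th = np.linspace(-np.pi, np.pi, 48)
        for zv in (5.0, 32.0, 64.0, 100.0, -5.0):
            z = np.full_like(th, zv)
            assert np.allclose(null.r_outer(th, z), ref.r_outer(th, z), atol=1e-9)
            assert np.allclose(null.r_inner(th, z), ref.r_inner(th, z), atol=1e-9)

    @pytest.mark.parametrize("extent,loc", [(48.0, 48.0), (96.0, 56.0)])
    def test_measured_bulged_span_matches_extent(self, extent, loc):
        """Span where the outer radius exceeds the referent by >1% equals the
        requested axial extent (sacs placed clear of the CS0 clipping plane)."""
        solid = build_aaa(aaa=AAAParameters(axial_extent=extent, location_z=loc))
        z = np.linspace(0.0, L_STAR, 12_000)
        above = z[solid.r_outer(np.zeros_like(z), z) > 10.0 * 1.01]
        assert above.max() - above.min() == pytest.approx(extent, rel=0.01)

    def test_wall_thickness_profile(self):
        solid = build_aaa()
        th = np.linspace(-np.pi, np.pi, 32)
        # dilated plateau carries the sac thickness; far trunk the referent's
        mid = solid.r_outer(th, np.full_like(th, 32.0)) - solid.r_inner(th, np.full_like(th, 32.0))
        far = solid.r_outer(th, np.full_like(th, 100.0)) - solid.r_inner(th, np.full_like(th, 100.0))
        assert np.allclose(mid, 1.5, rtol=0.02)
        assert np.allclose(far, 2.0, rtol=0.02)

    def test_mirror_symmetry_about_symmetry_plane(self):
        solid = build_aaa()  # tort = 1, circ = 360
        th = np.linspace(-np.pi, np.pi, 61)
        for zv in (-5.0, 10.0, 32.0, 90.0):
            z = np.full_like(th, zv)
            r1 = solid.r_outer(th, z)
            r2 = solid.r_outer(np.pi - th, z)   # x -> -x
            assert np.allclose(r1, r2, atol=1e-9)

    def test_tortuous_centerline_offsets_sections(self):
        aaa = AAAParameters(tort_xz=1.05)
        solid = build_aaa(aaa=aaa)
        c = solid.center(np.array([0.0, 64.0, 128.0]))
        assert abs(c[1, 0]) > 1.0          # bowed at mid-field
        assert abs(c[0, 0]) < 1e-9 and abs(c[2, 0]) < 1e-9   # pinned ends
        mirrored = build_aaa(aaa=AAAParameters(tort_xz=-1.05))
        cm = mirrored.center(np.array([64.0]))
        assert cm[0, 0] == pytest.approx(-c[1, 0])

    @pytest.mark.parametrize("kw", [
        {"max_diameter": 18.0},          # below the referent diameter
        {"sac_thickness": 2.5},          # thicker than the referent wall
        {"tort_xz": 0.5},                # |tau| < 1
        {"circ_extent": 200.0},          # not one of the study levels
    ])
    def test_out_of_range_parameters_rejected(self, kw):
        with pytest.raises(GeometryError):
            build_aaa(aaa=AAAParameters(**kw))


class TestConfigLoading:
    def test_geometry_config_roundtrip(self, tmp_path):
        from aawall.geometry import load_geometry_config
        cfg = tmp_path / "geo.yaml"
        cfg.write_text(
            "referent: {D: 20.0, t: 2.0}\n"
            "aaa: {axial_extent: 80.0, circ_extent: 360, max_diameter: 50.0,\n"
            "      location_z: 48.0, sac_thickness: 1.25, tort_xz: 1.0, tort_yz: 1.0}\n")
        ref, aaa = load_geometry_config(cfg)
        assert ref.D == 20.0
        assert aaa.max_diameter == 50.0 and aaa.location_z == 48.0

    def test_defaults_when_sections_missing(self, tmp_path):
        from aawall.geometry import load_geometry_config
        cfg = tmp_path / "geo.yaml"
        cfg.write_text("{}")
        ref, aaa = load_geometry_config(cfg)
        assert ref == ReferentGeometryParameters()
        assert aaa is None
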