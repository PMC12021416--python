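"""Morphology data model: SWC I/O, metrics, surgery, electrotonic geometry."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cabletree as ct
from cabletree.morphology import Morphology, Section, soma_cylinder


def cylinder(length=100.0, diam=2.0, sec_type=ct.BASAL):
    return ct.cylinder_cell(length, diam, soma_diam=10.0, sec_type=sec_type)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

class TestSWC:
    def test_minimal_file_builds_one_soma_one_basal(self, swc_fixture):
        m = ct.load_swc(swc_fixture)
        assert len(m.sections) == 2
        basal = m.sections_of_type(ct.BASAL)
        assert len(basal) == 1
        assert basal[0].length == pytest.approx(100.0)
        assert m.soma.mean_diam == pytest.approx(10.0)

    def test_missing_parent_named_in_error(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 1 7\n")
        with pytest.raises(ct.SWCFormatError, match="2.*missing parent 7"):
            ct.load_swc(p)

    @pytest.mark.parametrize(
        "record,match",
        [
            ("2 3 10 0 0 0.0 1", "non-positive radius"),
            ("2 9 10 0 0 1.0 1", "unknown SWC type code"),
            ("2 3 10 0 0 1.0", "expected 7 columns"),
        ],
    )
    def test_malformed_records_rejected(self, tmp_path, record, match):
        p = tmp_path / "bad.swc"
        p.write_text(f"1 1 0 0 0 5 -1\n{record}\n")
        with pytest.raises(ct.SWCFormatError, match=match):
            ct.load_swc(p)

    def test_round_trip_identity(self, tmp_path, human_cell):
        m, _ = human_cell
        p1, p2 = tmp_path / "a.swc", tmp_path / "b.swc"
        ct.save_swc(m, p1)
        m1 = ct.load_swc(p1)
        ct.save_swc(m1, p2)
        m2 = ct.load_swc(p2)
        assert len(m1.sections) == len(m2.sections)
        r1, r2 = ct.morphometrics(m1), ct.morphometrics(m2)
        assert r1.total_length == pytest.approx(r2.total_length)
        assert r1.basal_area == pytest.approx(r2.basal_area)
        assert p1.read_text() == p2.read_text()
        # geometry preserved through the first load as well
        assert r1.total_length == pytest.approx(ct.morphometrics(m).total_length)

    def test_shrinkage_scales_lengths_and_diameters(self, swc_fixture):
        m = ct.load_swc(swc_fixture, shrinkage=(2.0, 1.0))
        basal = m.sections_of_type(ct.BASAL)[0]
        assert basal.length == pytest.approx(200.0)
        assert basal.diams[-1] == pytest.approx(4.0)


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------

class TestMorphometrics:
    def test_cylinder_closed_form(self):
        m = cylinder(length=100.0, diam=2.0)
        r = ct.morphometrics(m)
        assert r.total_length == pytest.approx(100.0)
        assert r.basal_area == pytest.approx(2 * np.pi * 100.0, rel=1e-9)

    def test_no_dendrites_flagged(self):
        m = Morphology([soma_cylinder(np.zeros(3), 10.0)])
        r = ct.morphometrics(m)
        assert r.no_dendrites and r.total_length == 0.0

    def test_lengths_additive(self, human_cell):
        r = ct.morphometrics(human_cell[0])
        assert r.total_length == pytest.approx(r.apical_length + r.basal_length)

    def test_basal_radius_profile_sums_radii(self):
        m = cylinder(length=100.0, diam=2.0)
        prof = ct.morphometrics(m).basal_radius_profile
        # one branch of radius 1 µm -> each 20 µm bin sums to ~1
        assert np.allclose(prof.radius_sum_um, 1.0)


# ---------------------------------------------------------------------------
# Hybrid-cell surgery
# ---------------------------------------------------------------------------

class TestSwapBasal:
    def test_self_swap_is_geometric_identity(self, human_cell):
        m, _ = human_cell
        hyb = ct.swap_basal_tree(m, m)
        a, b = ct.morphometrics(m), ct.morphometrics(hyb)
        assert a.total_length == pytest.approx(b.total_length)
        assert a.basal_area == pytest.approx(b.basal_area)
        pts_a = np.vstack([s.points for s in m.sections_of_type(ct.BASAL)])
        pts_b = np.vstack([s.points for s in hyb.sections_of_type(ct.BASAL)])
        assert pts_a.shape == pts_b.shape

    def test_donor_geometry_conserved(self, human_cell, rat_cell):
        hum, rat = human_cell[0], rat_cell[0]
        hyb = ct.swap_basal_tree(hum, rat)
        hyb.validate()
        rh, rr, rx = ct.morphometrics(hum), ct.morphometrics(rat), ct.morphometrics(hyb)
        assert rx.basal_area == pytest.approx(rr.basal_area, rel=1e-9)
        assert rx.basal_length == pytest.approx(rr.basal_length, rel=1e-9)
        assert rx.apical_length == pytest.approx(rh.apical_length, rel=1e-9)

    def test_donor_without_basal_rejected(self, human_cell):
        donor = ct.cylinder_cell(100.0, 2.0, sec_type=ct.APICAL)
        with pytest.raises(ct.MorphologyError, match="no basal"):
            ct.swap_basal_tree(human_cell[0], donor)


# ---------------------------------------------------------------------------
# Electrotonic geometry
# ---------------------------------------------------------------------------

class TestElectrotonicPath:
    def test_uniform_cylinder_unit_lambda(self, params):
        lam = ct.lambda_um(3.0, params.rm, params.ra)
        m = cylinder(length=lam, diam=3.0)
        dist, L = ct.electrotonic_path(m, (2, 1.0), params)
        assert dist == pytest.approx(lam, rel=1e-6)
        assert L == pytest.approx(1.0, rel=1e-6)

    def test_soma_location_is_origin(self, params, human_cell):
        assert ct.electrotonic_path(human_cell[0], (1, 0.3), params) == (0.0, 0.0)

    def test_tapered_cable_matches_fine_segmentation(self, params):
        m_coarse = ct.cylinder_cell(300.0, 3.0, soma_diam=10.0, taper_to=1.0, spacing=30.0)
        m_fine = ct.cylinder_cell(300.0, 3.0, soma_diam=10.0, taper_to=1.0, spacing=3.0)
        _, L1 = ct.electrotonic_path(m_coarse, (2, 1.0), params)
        _, L2 = ct.electrotonic_path(m_fine, (2, 1.0), params)
        assert L1 == pytest.approx(L2, rel=5e-3)

    @given(scale=st.floats(0.25, 4.0))
    def test_L_scales_inverse_sqrt_of_diameter(self, params, scale):
        m = cylinder(length=500.0, diam=2.0)
        _, L1 = ct.electrotonic_path(m, (2, 1.0), params)
        m2 = m.copy()
        for s in m2.sections.values():
            s.diams = s.diams * scale
        _, L2 = ct.electrotonic_path(m2, (2, 1.0), params)
        assert L2 == pytest.approx(L1 / np.sqrt(scale), rel=1e-9)


class TestEquivalentCable:
    def test_single_cylinder_flat(self, params):
        m = cylinder(length=400.0, diam=2.0)
        eq = ct.equivalent_cable(m, ct.BASAL, params)
        assert np.allclose(eq.d_eq, 2.0)

    def test_two_siblings_three_halves_power(self, params):
        soma = soma_cylinder(np.zeros(3), 10.0)
        kids = [
            Section(i + 2, ct.BASAL,
                    np.array([[0, 0, 0], [0, s * 200.0, 0]]),
                    np.array([1.0, 1.0]), 1)
            for i, s in enumerate((1.0, -1.0))
        ]
        m = Morphology([soma] + kids)
        eq = ct.equivalent_cable(m, ct.BASAL, params)
        assert np.allclose(eq.d_eq, 2.0 ** (2.0 / 3.0))

    def test_rall_matched_junction_is_flat(self, params):
        dp = 2.0
        dd = dp / 2.0 ** (2.0 / 3.0)  # daughters obey the 3/2-power rule
        soma = soma_cylinder(np.zeros(3), 0.01)
        par = Section(2, ct.BASAL, np.array([[0, 0, 0], [0, 200, 0]]),
                      np.array([dp, dp]), 1)
        d1 = Section(3, ct.BASAL, np.array([[0, 200, 0], [80, 400, 0]]),
                     np.array([dd, dd]), 2)
        d2 = Section(4, ct.BASAL, np.array([[0, 200, 0], [-80, 400, 0]]),
                     np.array([dd, dd]), 2)
        eq = ct.equivalent_cable(Morphology([soma, par, d1, d2]), ct.BASAL, params)
        off = np.abs(eq.d_eq - dp) > 0.01 * dp
        # flat everywhere except the single bin straddling the branch point,
        # where the overlap rule counts parent and daughters together
        assert off.sum() <= 1

    def test_adding_a_branch_never_decreases_d_eq(self, params):
        soma = soma_cylinder(np.zeros(3), 10.0)
        b1 = Section(2, ct.BASAL, np.array([[0, 0, 0], [0, 300, 0]]),
                     np.array([1.5, 1.5]), 1)
        m1 = Morphology([soma, b1])
        b2 = Section(3, ct.BASAL, np.array([[0, 0, 0], [300, 0, 0]]),
                     np.array([0.8, 0.8]), 1)
        m2 = Morphology([soma,
                         Section(2, ct.BASAL, b1.points.copy(), b1.diams.copy(), 1),
                         b2])
        e1 = ct.equivalent_cable(m1, ct.BASAL, params)
        e2 = ct.equivalent_cable(m2, ct.BASAL, params)
        n = min(len(e1.d_eq), len(e2.d_eq))
        assert np.all(e2.d_eq[:n] >= e1.d_eq[:n] - 1e-12)

    def test_empty_subtree_rejected(self, params):
        m = cylinder(sec_type=ct.BASAL)
        with pytest.raises(ct.MorphologyError, match="no apical"):
            ct.equivalent_cable(m, ct.APICAL, params)


class TestStructure:
    def test_diameter_fix_copies_parent_value(self, human_cell):
        m, _ = human_cell
        child = next(s for s in m.sections.values()
                     if s.parent is not None and s.parent != m.root)
        fixed = ct.apply_diameter_fixes(m, [child.id])
        expect = fixed.sections[child.parent].diams[-1]
        assert np.allclose(fixed.sections[child.id].diams, expect)

    def test_duplicate_root_rejected(self):
        s1 = soma_cylinder(np.zeros(3), 10.0, sec_id=1)
        s2 = soma_cylinder(np.ones(3), 10.0, sec_id=2)
        with pytest.raises(ct.MorphologyError):
            Morphology([s1, s2])

    def test_nonpositive_diameter_rejected(self):
        soma = soma_cylinder(np.zeros(3), 10.0)
        bad = Section(2, ct.BASAL, np.array([[0, 0, 0], [10, 0, 0]]),
                      np.array([1.0, 0.0]), 1)
        with pytest.raises(ct.MorphologyError, match="non-positive diameter"):
            Morphology([soma, bad])
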