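"""Piecewise-linear potential, electrostatics and profile assembly."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tscc.interaction import (
    DEFAULT_PLP,
    DegenerateGeometryError,
    HBOND,
    STERIC,
    PLPParams,
    atom_profile,
    build_profile_matrix,
    classify_pair,
    electrostatic_energy,
    plp_energy,
)
from tscc.structio import Atom, LigandPose, ReceptorSite, HB_DONOR


def _atom(serial, element, xyz, charge=0, hb="nonpolar", tag="A:SYN:1"):
    return Atom(serial=serial, element=element, name=f"{element}{serial}",
                coords=xyz, formal_charge=charge, hb_class=hb, residue_tag=tag)


@st.composite
def plp_params(draw):
    v1 = draw(st.floats(0.5, 3.0))
    gaps = [draw(st.floats(0.1, 1.5)) for _ in range(3)]
    v5 = draw(st.floats(0.0, 50.0))
    v6 = draw(st.floats(-5.0, 0.0))
    return PLPParams(v1, v1 + gaps[0], v1 + gaps[0] + gaps[1],
                     v1 + sum(gaps), v5, v6)


class TestPLP:
    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            PLPParams(3.0, 2.0, 4.0, 5.0, 20.0, -1.0)
        with pytest.raises(ValueError):
            PLPParams(1.0, 2.0, 3.0, 4.0, -1.0, -1.0)

    @pytest.mark.parametrize("cls", [HBOND, STERIC])
    def test_shape(self, cls):
        p = DEFAULT_PLP[cls]
        assert plp_energy(0.0, p) == pytest.approx(p.v5)
        assert plp_energy(p.v4 + 0.01, p) == 0.0
        assert plp_energy(100.0, p) == 0.0
        assert plp_energy((p.v2 + p.v3) / 2, p) == pytest.approx(p.v6)
        assert plp_energy((p.v1 + p.v2) / 2, p) == pytest.approx(p.v6 / 2)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(plp_params())
    def test_continuity_at_breakpoints(self, p):
        for bp in (p.v1, p.v2, p.v3, p.v4):
            left = plp_energy(np.nextafter(bp, 0.0), p)
            right = plp_energy(np.nextafter(bp, np.inf), p)
            assert abs(left - right) < 1e-9

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(plp_params())
    def test_minimum_is_well_depth(self, p):
        r = np.linspace(0.0, p.v4 + 1.0, 4001)
        vals = plp_energy(r, p)
        assert vals.min() == pytest.approx(p.v6)
        well = (r >= p.v2) & (r <= p.v3)
        assert np.allclose(vals[well], p.v6)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            plp_energy(-0.1, DEFAULT_PLP[STERIC])


class TestElectrostatics:
    def test_zero_when_uncharged(self):
        assert electrostatic_energy(0, -1, 3.0) == 0.0

    def test_coulomb_value(self):
        # 332 * (+1)(-1) / 3.32 = -100 kcal/mol
        assert electrostatic_energy(1, -1, 3.32) == pytest.approx(-100.0)

    def test_cutoff(self):
        assert electrostatic_energy(1, 1, 12.5, cutoff=12.0) == 0.0

    def test_degenerate_distance(self):
        with pytest.raises(DegenerateGeometryError):
            electrostatic_energy(1, 1, 0.0)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "ca,cb,expected",
        [
            ("donor", "acceptor", HBOND),
            ("acceptor", "donor", HBOND),
            ("both", "both", HBOND),
            ("donor", "both", HBOND),
            ("nonpolar", "acceptor", STERIC),
            ("donor", "donor", STERIC),
            ("acceptor", "acceptor", STERIC),
            ("nonpolar", "nonpolar", STERIC),
        ],
    )
    def test_rules_and_symmetry(self, ca, cb, expected):
        a = _atom(1, "N", (0, 0, 0), hb=ca)
        b = _atom(2, "O", (1, 0, 0), hb=cb)
        assert classify_pair(a, b) == expected
        assert classify_pair(b, a) == expected


def _toy_complex():
    site = ReceptorSite(
        atoms=[
            _atom(11, "N", (0.0, 0.0, 0.0), charge=1, hb="donor"),
            _atom(12, "C", (4.0, 0.0, 0.0), hb="nonpolar"),
        ],
        source_id="toy",
    )
    pose = LigandPose(
        pose_id="p1",
        atoms=[
            _atom(1, "O", (0.0, 2.9, 0.0), charge=-1, hb="acceptor"),
            _atom(2, "C", (4.0, 3.6, 0.0), hb="nonpolar"),
        ],
        bonds=[(0, 1, 1.0)],
        docked_energy=-5.0,
    )
    return site, pose


class TestAtomProfile:
    def test_matches_brute_force_double_loop(self):
        site, pose = _toy_complex()
        profile = atom_profile(site, pose)
        for j, sa in enumerate(site.atoms):
            expected = 0.0
            for la in pose.atoms:
                r = float(np.linalg.norm(sa.coords - la.coords))
                expected += plp_energy(r, DEFAULT_PLP[classify_pair(sa, la)])
                expected += electrostatic_energy(
                    sa.formal_charge, la.formal_charge, r
                )
            assert profile.energies[sa.serial] == pytest.approx(expected, abs=1e-9)

    def test_far_pose_gives_zero_profile(self):
        site, pose = _toy_complex()
        far = LigandPose(
            pose_id="far",
            atoms=[_atom(1, "C", (100.0, 100.0, 100.0))],
            bonds=[],
            docked_energy=0.0,
        )
        profile = atom_profile(site, far)
        assert all(v == 0.0 for v in profile.energies.values())

    def test_deterministic(self):
        site, pose = _toy_complex()
        p1 = atom_profile(site, pose)
        p2 = atom_profile(site, pose)
        assert p1.energies == p2.energies

    def test_overlapping_atoms_named_in_error(self):
        site, pose = _toy_complex()
        clash = LigandPose(
            pose_id="clash",
            atoms=[_atom(1, "C", (0.0, 0.0, 0.0))],
            bonds=[],
            docked_energy=0.0,
        )
        with pytest.raises(DegenerateGeometryError, match="11"):
            atom_profile(site, clash)

    def test_invariant_to_atom_reordering(self):
        site, pose = _toy_complex()
        site_r = ReceptorSite(atoms=list(reversed(site.atoms)), source_id="toy")
        pose_r = LigandPose(pose_id="p1", atoms=list(reversed(pose.atoms)),
                            bonds=[(0, 1, 1.0)], docked_energy=-5.0)
        a = atom_profile(site, pose)
        b = atom_profile(site_r, pose_r)
        for serial, val in a.energies.items():
            assert b.energies[serial] == pytest.approx(val, abs=1e-12)

    def test_rigid_translation_invariance(self):
        site, pose = _toy_complex()
        shift = np.array([13.7, -2.1, 8.4])
        site_t = ReceptorSite(
            atoms=[
                Atom(a.serial, a.element, a.name, a.coords + shift,
                     a.formal_charge, a.hb_class, a.residue_tag)
                for a in site.atoms
            ],
            source_id="toy",
        )
        pose_t = LigandPose(
            pose_id="p1",
            atoms=[
                Atom(a.serial, a.element, a.name, a.coords + shift,
                     a.formal_charge, a.hb_class, a.residue_tag)
                for a in pose.atoms
            ],
            bonds=[(0, 1, 1.0)],
            docked_energy=-5.0,
        )
        a = atom_profile(site, pose)
        b = atom_profile(site_t, pose_t)
        for serial in a.energies:
            assert b.energies[serial] == pytest.approx(a.energies[serial], abs=1e-9)

    def test_electrostatics_flag(self):
        site, pose = _toy_complex()
        with_es = atom_profile(site, pose, include_electrostatics=True)
        without = atom_profile(site, pose, include_electrostatics=False)
        assert with_es.energies[11] != without.energies[11]


class TestProfileMatrix:
    def _profiles(self, rows, serials=(11, 12, 13)):
        from tscc.interaction import InteractionProfile

        return [
            InteractionProfile(pose_id=f"p{i}", energies=dict(zip(serials, row)))
            for i, row in enumerate(rows)
        ]

    def test_zero_column_dropped(self):
        mat = build_profile_matrix(
            self._profiles([[1.0, 0.0, -2.0], [0.5, 0.0, 0.3], [2.0, 0.0, 1.0]])
        )
        assert mat.atom_serials == [11, 13]
        assert mat.values.shape == (3, 2)

    def test_no_zero_columns_identity(self):
        rows = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]
        mat = build_profile_matrix(self._profiles(rows))
        np.testing.assert_array_equal(mat.values, np.array(rows))
        assert mat.pose_ids == ["p0", "p1"]

    def test_survivors_match_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        rows = rng.normal(size=(6, 10))
        rows[:, [2, 5, 9]] = 0.0
        rows[:, 7] *= 1e-9  # below epsilon
        serials = tuple(range(101, 111))
        mat = build_profile_matrix(self._profiles(rows, serials), epsilon=1e-6)
        # independent scan: keep column iff some |value| >= epsilon
        expected = [
            s for k, s in enumerate(serials)
            if any(abs(rows[i, k]) >= 1e-6 for i in range(rows.shape[0]))
        ]
        assert mat.atom_serials == expected
        np.testing.assert_array_equal(
            mat.values, rows[:, [serials.index(s) for s in expected]]
        )

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            build_profile_matrix(self._profiles([[0.0, 0.0, 0.0]] * 2))

    def test_mismatched_sites_raise(self):
        p = self._profiles([[1.0, 2.0, 3.0]])
        q = self._profiles([[1.0, 2.0, 3.0]], serials=(1, 2, 3))
        with pytest.raises(ValueError):
            build_profile_matrix(p + q)
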