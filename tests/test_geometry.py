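"""Superposition RMSD, torsions and minimal circular chi1 ranges."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from apoholo.curation import Family, build_reference_numbering
from apoholo.geometry import (DegenerateGeometry, ca_rmsd, chi1_of_residue,
                              chi1_range, dihedral, family_max,
                              family_pair_scores, kabsch, site_chi1_tables)
from apoholo.synthetic import (FamilyFixtureSpec, make_family, make_ideal_chain,
                               perturb_backbone)

from conftest import load_fixture_structures

rng = np.random.default_rng(20240917)


def brute_force_arc(angles):
    """Minimal covering arc by trying every observed angle as arc start."""
    a = np.mod(np.asarray(angles, float), 360.0)
    if a.size <= 1:
        return 0.0
    return float(min(np.max(np.mod(a - start, 360.0)) for start in a))


def rmsd_by_numeric_optimization(X, Y):
    """Minimize RMSD over rotation vectors + translation numerically."""
    def cost(params):
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        t = params[3:]
        d = X - (Y @ R.T + t)
        return np.sqrt((d * d).sum() / len(X))

    best = np.inf
    for rv0 in [np.zeros(3), np.array([3.0, 0, 0]), np.array([0, 3.0, 0]),
                np.array([0, 0, 3.0]), np.array([1.8, 1.8, 1.8])]:
        x0 = np.concatenate([rv0, X.mean(0) - Y.mean(0)])
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14,
                                "maxiter": 20000, "maxfev": 20000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identity_gives_zero(self):
        X = rng.normal(size=(10, 3))
        _, _, r = kabsch(X, X)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        X = rng.normal(size=(12, 3)) * 5
        for _ in range(5):
            R = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
            t = rng.normal(size=3) * 10
            rot, trans, r = kabsch(X, X @ R.T + t)
            assert r <= 1e-9
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_always_proper(self):
        # mirror-image pair must not be matched by an improper rotation
        X = rng.normal(size=(8, 3))
        Y = X.copy()
        Y[:, 0] *= -1
        rot, _, r = kabsch(X, Y)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
        assert r > 0.1

    def test_small_point_sets_match_numeric_optimization_oracle(self):
        for _ in range(10):
            n = int(rng.integers(4, 8))
            X = rng.normal(size=(n, 3)) * 3
            Y = X + rng.normal(size=(n, 3)) * 0.3
            _, _, r = kabsch(X, Y)
            assert r == pytest.approx(rmsd_by_numeric_optimization(X, Y), abs=1e-5)

    def test_displaced_square_corner(self):
        X = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        Y = X.copy()
        Y[2, 0] += 0.2
        _, _, r = kabsch(X, Y)
        assert r == pytest.approx(rmsd_by_numeric_optimization(X, Y), abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometry):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateGeometry):
            kabsch(line, line)


class TestDihedral:
    def test_cis_is_zero_trans_is_minus_180(self):
        a, b, c = [0, 1, 0], [0, 0, 0], [1, 0, 0]
        assert dihedral(a, b, c, [1, 1, 0]) == pytest.approx(0.0, abs=1e-9)
        # +180 maps onto -180: the domain is half-open
        assert dihedral(a, b, c, [1, -1, 0]) == pytest.approx(-180.0, abs=1e-9)

    def test_sign_matches_independent_atan2_formula(self):
        def oracle(p1, p2, p3, p4):
            p1, p2, p3, p4 = map(np.asarray, (p1, p2, p3, p4))
            b0, b1, b2 = p1 - p2, p3 - p2, p4 - p3
            b1 = b1 / np.linalg.norm(b1)
            v = b0 - (b0 @ b1) * b1
            w = b2 - (b2 @ b1) * b1
            return float(np.degrees(np.arctan2(np.cross(b1, v) @ w, v @ w)))

        q = ([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0, 1])
        assert abs(dihedral(*q)) == pytest.approx(90.0, abs=1e-9)
        assert dihedral(*q) == pytest.approx(oracle(*q), abs=1e-9)
        for _ in range(50):
            p = rng.normal(size=(4, 3)) * 4
            assert dihedral(*p) == pytest.approx(oracle(*p), abs=1e-8)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateGeometry):
            dihedral([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])


class TestChi1OfResidue:
    @pytest.mark.parametrize("angle", [-150.0, -60.0, 0.0, 60.0, 175.0])
    @pytest.mark.parametrize("seq,which_res", [("ASA", "SER"), ("ACA", "CYS"),
                                               ("ATA", "THR"), ("AIA", "ILE"),
                                               ("ALA", "LEU"), ("AKA", "LYS")])
    def test_constructed_chi1_reads_back(self, seq, which_res, angle):
        s = make_ideal_chain(seq, chi1=angle)
        res = next(r for r in s.chains["A"] if r.name == which_res)
        out = dict(chi1_of_residue(res))
        assert out["primary"] == pytest.approx(angle, abs=1e-6)

    def test_valine_contributes_both_branches_120_apart(self):
        s = make_ideal_chain("AVA", chi1=-60.0)
        val = s.chains["A"][1]
        out = dict(chi1_of_residue(val))
        assert set(out) == {"primary", "valine_alt"}
        gap = (out["valine_alt"] - out["primary"]) % 360.0
        assert min(gap, 360.0 - gap) == pytest.approx(120.0, abs=1e-6)

    def test_gly_pro_ala_have_no_chi1(self):
        s = make_ideal_chain("GPA")
        for res in s.chains["A"]:
            assert chi1_of_residue(res) == []

    def test_missing_gamma_atom_flags_residue(self):
        s = make_ideal_chain("ASA")
        ser = s.chains["A"][1]
        ser.atoms = [a for a in ser.atoms if a.name != "OG"]
        with pytest.raises(KeyError, match="OG"):
            chi1_of_residue(ser)


class TestChi1Range:
    def test_printed_worked_example(self):
        assert chi1_range([30.0, 45.0, 100.0]) == pytest.approx(70.0)

    @pytest.mark.parametrize("angles,expected", [
        ([12.0], 0.0),
        ([-170.0, 170.0], 20.0),
        ([0.0, 120.0, 240.0], 240.0),
        ([-60.0, 180.0], 120.0),
    ])
    def test_wraparound_cases(self, angles, expected):
        assert chi1_range(angles) == pytest.approx(expected, abs=1e-9)
        assert chi1_range(angles) == pytest.approx(brute_force_arc(angles))

    def test_equals_brute_force_oracle_on_random_sets(self):
        for _ in range(300):
            n = int(rng.integers(1, 30))
            angles = rng.uniform(-180, 180, n)
            assert chi1_range(angles) == pytest.approx(
                brute_force_arc(angles), abs=1e-9)

    def test_invariant_under_global_circular_shift(self):
        angles = rng.uniform(-180, 180, 15)
        base = chi1_range(angles)
        for shift in (13.0, 111.0, 297.5):
            shifted = np.mod(angles + shift + 180.0, 360.0) - 180.0
            assert chi1_range(shifted) == pytest.approx(base, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            chi1_range([])


from hypothesis import given, settings, strategies as st  # noqa: E402


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.floats(min_value=-180.0, max_value=179.999), min_size=1,
                max_size=40))
def test_chi1_range_properties_hold_for_arbitrary_angle_sets(angles):
    r = chi1_range(angles)
    assert 0.0 <= r < 360.0
    assert r == pytest.approx(brute_force_arc(angles), abs=1e-9)
    shifted = np.mod(np.asarray(angles) + 97.3 + 180.0, 360.0) - 180.0
    assert chi1_range(shifted) == pytest.approx(r, abs=1e-9)


def _numbered_family(spec=None):
    fx = make_family(spec or FamilyFixtureSpec(seed=13))
    fam = Family("F1", load_fixture_structures(fx))
    build_reference_numbering(fam)
    return fx, fam


class TestCaRmsd:
    def test_self_comparison_is_zero(self):
        _, fam = _numbered_family()
        m = fam.members[0]
        r, n = ca_rmsd(m, m)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert n == len(m.chains["A"])

    def test_recovers_generator_ground_truth(self):
        fx, fam = _numbered_family()
        truth = fx.manifest["pair_rmsd"]
        by_id = {m.pdb_id: m for m in fam.members}
        for key, expected in truth.items():
            a, b = key.split("|")
            r, _ = ca_rmsd(by_id[a], by_id[b])
            assert r == pytest.approx(expected, abs=1e-6)

    def test_missing_residues_use_shared_intersection(self):
        _, fam = _numbered_family()
        a, b = fam.members[0], fam.members[1]
        import copy
        b_gap = copy.deepcopy(b)
        b_gap.chains["A"] = [r for r in b_gap.chains["A"]
                             if not 10 <= r.ref_index <= 15]
        a_trunc = copy.deepcopy(a)
        a_trunc.chains["A"] = [r for r in a_trunc.chains["A"]
                               if not 10 <= r.ref_index <= 15]
        r_gap, n_gap = ca_rmsd(a, b_gap)
        r_trunc, n_trunc = ca_rmsd(a_trunc, b_gap)
        assert n_gap == n_trunc == len(b_gap.chains["A"])
        assert r_gap == pytest.approx(r_trunc, abs=1e-12)

    def test_too_few_shared_atoms_is_flagged(self):
        _, fam = _numbered_family()
        import copy
        b = copy.deepcopy(fam.members[1])
        b.chains["A"] = b.chains["A"][:2]
        r, n = ca_rmsd(fam.members[0], b)
        assert r is None and n == 2


class TestFamilyPairs:
    def test_pair_combinatorics_two_plus_two(self):
        spec = FamilyFixtureSpec(seed=2, n_apo=2, n_holo=2)
        _, fam = _numbered_family(spec)
        scores = family_pair_scores(fam.members)
        classes = [s.pairing_class for s in scores]
        assert len(scores) == 6
        assert classes.count("AA") == 1
        assert classes.count("HH") == 1
        assert classes.count("AH") == 4

    def test_identical_members_give_zero_maxima(self):
        spec = FamilyFixtureSpec(seed=2, n_apo=2, n_holo=2, backbone_rmsd=0.0)
        _, fam = _numbered_family(spec)
        scores = family_pair_scores(fam.members)
        for pc in ("AA", "HH", "AH"):
            assert family_max(scores, pc) == pytest.approx(0.0, abs=1e-9)

    def test_displaced_apo_shows_in_aa_and_ah_only(self):
        spec = FamilyFixtureSpec(seed=6, n_apo=2, n_holo=2,
                                 backbone_rmsd=[1.5, 0.0, 0.0, 0.0])
        _, fam = _numbered_family(spec)
        scores = family_pair_scores(fam.members)
        assert family_max(scores, "AA") > 1.0
        assert family_max(scores, "AH") > 1.0
        assert family_max(scores, "HH") < 0.05

    def test_maxima_invariant_to_member_order(self):
        _, fam = _numbered_family()
        scores_fwd = family_pair_scores(fam.members)
        scores_rev = family_pair_scores(list(reversed(fam.members)))
        for pc in ("AA", "HH", "AH"):
            assert family_max(scores_fwd, pc) == family_max(scores_rev, pc)


class TestSiteChi1Tables:
    def test_identical_side_chains_have_zero_ranges(self):
        spec = FamilyFixtureSpec(seed=2, backbone_rmsd=0.0)
        _, fam = _numbered_family(spec)
        site = {("A", i) for i in (8, 9, 11)}
        _, summaries, dropped = site_chi1_tables("F1", fam.members, site)
        assert not dropped
        assert summaries
        for s in summaries:
            assert s.range == pytest.approx(0.0, abs=1e-6)

    def test_planted_apo_holo_displacement(self):
        spec = FamilyFixtureSpec(
            seed=2, backbone_rmsd=0.0,
            chi1_settings={9: {"apo": -60.0, "holo": 180.0}})
        _, fam = _numbered_family(spec)
        site = {("A", 9)}
        _, summaries, _ = site_chi1_tables("F1", fam.members, site)
        by_set = {s.set_label: s.range for s in summaries if s.which == "primary"}
        assert by_set["apo"] == pytest.approx(0.0, abs=1e-6)
        assert by_set["holo"] == pytest.approx(0.0, abs=1e-6)
        # nominal value; file-precision quantisation perturbs it by ~0.01 deg
        assert by_set["apo_holo"] == pytest.approx(120.0, abs=0.05)
        # exact against the manifest's measured truth
        fx = make_family(FamilyFixtureSpec(
            seed=2, backbone_rmsd=0.0,
            chi1_settings={9: {"apo": -60.0, "holo": 180.0}}))
        assert by_set["apo_holo"] == pytest.approx(
            fx.manifest["chi1_ranges"]["9"]["apo_holo"], abs=1e-6)

    def test_combined_range_dominates_single_sets(self):
        from apoholo.synthetic import make_cohort
        for fx in make_cohort(n_families=3, seed=31):
            fam = Family("F", load_fixture_structures(fx))
            build_reference_numbering(fam)
            site = {("A", int(k)) for k in fx.manifest["chi1_ranges"]}
            _, summaries, _ = site_chi1_tables("F", fam.members, site)
            per_res = {}
            for s in summaries:
                per_res.setdefault((s.ref_index, s.which), {})[s.set_label] = s.range
            for sets in per_res.values():
                assert sets["apo_holo"] >= max(sets["apo"], sets["holo"]) - 1e-9

    def test_missing_chi1_atom_drops_residue_family_wide(self):
        spec = FamilyFixtureSpec(seed=2, backbone_rmsd=0.0)
        _, fam = _numbered_family(spec)
        # knock the gamma atom out of residue 9 in ONE member only
        victim = fam.members[2]
        res = next(r for r in victim.chains["A"] if r.ref_index == 9)
        res.atoms = [a for a in res.atoms if not a.name.startswith("CG")]
        site = {("A", 9), ("A", 11)}
        records, summaries, dropped = site_chi1_tables("F1", fam.members, site)
        assert [(d[0], d[1]) for d in dropped] == [("A", 9)]
        assert all(r.ref_index != 9 for r in records)
        assert {s.ref_index for s in summaries} == {11}
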