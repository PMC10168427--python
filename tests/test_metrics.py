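"""Superposition, GDT_TS, TM-score, lDDT, INF, DI, DP, clashscore, MCQ."""
import itertools
import math

import numpy as np
import pytest

from rna_assess.annotation import InteractionNetwork, compute_torsions
from rna_assess.metrics import (DegenerateInputError, clashscore,
                                deformation_index, deformation_profile,
                                gdt_ts, inf, lddt_rna, mcq, rmsd_heavy,
                                superpose, tm_d0, tm_score)
from rna_assess.structure_io import (Atom, Residue, Structure,
                                     build_correspondence)
from rna_assess.synthetic import DecoySpec, build_duplex, make_decoy
from .conftest import random_rotation, structure_from_points, transform


class TestSuperpose:
    def test_rigid_copy_has_zero_rmsd(self):
        rng = np.random.default_rng(0)
        P = rng.uniform(-5, 5, (8, 3))
        Q = P @ random_rotation(rng).T + np.array([3.0, -1.0, 2.0])
        assert superpose(P, Q).rmsd <= 1e-9

    def test_pure_translation_removed(self):
        rng = np.random.default_rng(1)
        P = rng.uniform(-5, 5, (6, 3))
        assert superpose(P, P + np.array([1.0, 0, 0])).rmsd <= 1e-9

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        P = rng.uniform(-5, 5, (5, 3))
        Q = rng.uniform(-5, 5, (5, 3))
        res = superpose(P, Q)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_rotation_search(self):
        # oracle: best of many random rotations, polished by Nelder-Mead on
        # a rotation-vector parametrization — no Kabsch algebra involved
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        for _ in range(3):
            P = rng.uniform(-4, 4, (5, 3))
            Q = rng.uniform(-4, 4, (5, 3))

            def cost(rv):
                R = Rotation.from_rotvec(rv).as_matrix()
                A = (P - P.mean(0)) @ R.T
                B = Q - Q.mean(0)
                return np.sqrt(((A - B) ** 2).sum() / len(P))

            best = None
            for _ in range(300):
                rv = Rotation.random(random_state=rng).as_rotvec()
                c = cost(rv)
                if best is None or c < best[0]:
                    best = (c, rv)
            polished = minimize(cost, best[1], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 5000})
            assert superpose(P, Q).rmsd == pytest.approx(polished.fun,
                                                         abs=1e-3)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
                        dtype=float)
        with pytest.raises(DegenerateInputError):
            superpose(line, line)


class TestRmsdHeavy:
    def test_identity_is_zero(self):
        st, _ = build_duplex("GCAUGC")
        corr = build_correspondence(st, st)
        assert rmsd_heavy(st, st, corr) <= 1e-9

    def test_rigid_shift_removed(self):
        st, _ = build_duplex("GCAUGC")
        moved = transform(st, t=(1.0, 0, 0))
        corr = build_correspondence(moved, st)
        assert rmsd_heavy(moved, st, corr) <= 1e-9

    def test_single_displaced_residue_matches_two_stage_oracle(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 30, (10, 3))
        ref = structure_from_points(pts)
        moved_pts = pts.copy()
        moved_pts[4] += np.array([5.0, 0.0, 0.0])
        mod = structure_from_points(moved_pts)
        corr = build_correspondence(mod, ref)
        got = rmsd_heavy(mod, ref, corr)
        # independent two-stage computation: optimal R,t from Kabsch on the
        # full set, then the explicit RMSD formula
        sup = superpose(moved_pts, pts)
        diff = moved_pts @ sup.rotation.T + sup.translation - pts
        expected = math.sqrt((diff ** 2).sum() / 10)
        assert got == pytest.approx(expected, abs=1e-9)


def exhaustive_gdt(P, Q, cutoffs=(1.0, 2.0, 4.0, 8.0)):
    """All-subset superposition oracle (subsets of size >= 3)."""
    n = len(P)
    best = {c: 0 for c in cutoffs}
    for k in range(3, n + 1):
        for subset in itertools.combinations(range(n), k):
            idx = list(subset)
            try:
                sup = superpose(P[idx], Q[idx])
            except DegenerateInputError:
                continue
            d = np.linalg.norm(sup.apply(P) - Q, axis=1)
            for c in cutoffs:
                best[c] = max(best[c], int((d <= c).sum()))
    return 25.0 * sum(best[c] / n for c in cutoffs)


class TestGdtTs:
    def test_identity_is_100(self):
        st, _ = build_duplex("GCAUGCAU")
        corr = build_correspondence(st, st)
        assert gdt_ts(st, st, corr) == pytest.approx(100.0)

    def test_rigid_copy_is_100(self):
        st, _ = build_duplex("GCAUGCAU")
        rng = np.random.default_rng(6)
        moved = transform(st, random_rotation(rng), rng.uniform(-9, 9, 3))
        corr = build_correspondence(moved, st)
        assert gdt_ts(moved, st, corr) == pytest.approx(100.0)

    def test_engineered_residuals_match_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        Q = rng.uniform(0, 20, (6, 3))
        resid = [0.5, 0.5, 1.5, 3.0, 5.0, 9.0]
        dirs = rng.standard_normal((6, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        P = Q + dirs * np.array(resid)[:, None]
        model = structure_from_points(P)
        ref = structure_from_points(Q)
        corr = build_correspondence(model, ref)
        got = gdt_ts(model, ref, corr)
        oracle = exhaustive_gdt(P, Q)
        assert got >= oracle - 1.0
        assert got <= oracle + 1e-9

    def test_within_one_point_of_oracle_on_random_small_fixtures(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            n = int(rng.integers(5, 9))
            Q = rng.uniform(0, 15, (n, 3))
            P = Q + rng.normal(0, 2.0, (n, 3))
            model = structure_from_points(P)
            ref = structure_from_points(Q)
            corr = build_correspondence(model, ref)
            got = gdt_ts(model, ref, corr)
            oracle = exhaustive_gdt(P, Q)
            assert oracle - 1.0 <= got <= oracle + 1e-9


class TestTmScore:
    def test_d0_for_720_nt(self):
        assert round(tm_d0(720), 2) == 13.59

    def test_d0_floor_for_short_chains(self):
        assert tm_d0(10) == 0.3

    def test_identity_scores_one(self):
        st, _ = build_duplex("GCAUGCAUGC")
        corr = build_correspondence(st, st)
        score, d0 = tm_score(st, st, corr)
        assert score == pytest.approx(1.0, abs=1e-12)

    def test_search_at_least_global_superposition_oracle(self):
        # hand-evaluated sum under the single global superposition
        rng = np.random.default_rng(9)
        Q = rng.uniform(0, 40, (30, 3))
        P = Q + rng.normal(0, 2.0, (30, 3))
        model = structure_from_points(P, atom_name="C3'")
        ref = structure_from_points(Q, atom_name="C3'")
        corr = build_correspondence(model, ref)
        score, d0 = tm_score(model, ref, corr)
        sup = superpose(P, Q)
        d = np.linalg.norm(sup.apply(P) - Q, axis=1)
        oracle = float(np.sum(1 / (1 + (d / d0) ** 2)) / 30)
        assert score >= oracle - 1e-12
        assert score <= 1.0

    def test_normalized_by_reference_length(self):
        # model missing residues still divides by the full reference length
        rng = np.random.default_rng(10)
        Q = rng.uniform(0, 30, (20, 3))
        ref = structure_from_points(Q, atom_name="C3'")
        model = structure_from_points(Q[:10], atom_name="C3'")
        corr = build_correspondence(model, ref)
        score, _ = tm_score(model, ref, corr)
        assert score == pytest.approx(0.5, abs=1e-9)


class TestLddt:
    def test_identity_scores_one(self):
        st, _ = build_duplex("GCAUGC")
        corr = build_correspondence(st, st)
        assert lddt_rna(st, st, corr) == pytest.approx(1.0)

    def test_exact_3A_stretch_scores_quarter(self):
        # isolated two-residue dumbbells, each stretched by exactly 3 Å:
        # only the 4 Å threshold is satisfied
        ref_pts, mod_pts = [], []
        for k in range(3):
            base = np.array([100.0 * k, 0.0, 0.0])
            ref_pts += [base, base + np.array([4.0, 0, 0])]
            mod_pts += [base, base + np.array([7.0, 0, 0])]
        ref = structure_from_points(ref_pts)
        mod = structure_from_points(mod_pts)
        corr = build_correspondence(mod, ref)
        assert lddt_rna(mod, ref, corr) == pytest.approx(0.25)

    def test_matches_brute_force_double_loop(self):
        st, _ = build_duplex("GCAUG")
        decoy = make_decoy(st, DecoySpec("gaussian", sigma=1.0, seed=3))
        corr = build_correspondence(decoy, st)
        got = lddt_rna(decoy, st, corr)
        # independent enumeration over all atom pairs
        atoms = []
        for i, j in corr.pairs:
            rm, rr = decoy.residues[i], st.residues[j]
            for name in sorted(rm.atom_names() & rr.atom_names()):
                atoms.append((j, rm.atom(name).position,
                              rr.atom(name).position))
        fractions = []
        for thr in (0.5, 1.0, 2.0, 4.0):
            ok = tot = 0
            for a in range(len(atoms)):
                for b in range(a + 1, len(atoms)):
                    if atoms[a][0] == atoms[b][0]:
                        continue
                    dr = np.linalg.norm(atoms[a][2] - atoms[b][2])
                    if dr > 15.0:
                        continue
                    dm = np.linalg.norm(atoms[a][1] - atoms[b][1])
                    tot += 1
                    if abs(dm - dr) <= thr:
                        ok += 1
            fractions.append(ok / tot)
        assert got == pytest.approx(float(np.mean(fractions)), abs=1e-12)

    def test_superposition_free(self):
        st, _ = build_duplex("GCAUGC")
        rng = np.random.default_rng(11)
        moved = transform(st, random_rotation(rng), rng.uniform(-20, 20, 3))
        corr = build_correspondence(moved, st)
        assert lddt_rna(moved, st, corr) == pytest.approx(1.0)


def net_from_edges(edges):
    net = InteractionNetwork()
    net.wc = {frozenset(e) for e in edges}
    return net


class TestInf:
    def test_identical_networks_score_one(self):
        net = net_from_edges([("A:1", "B:8"), ("A:2", "B:7")])
        assert inf(net, net, "WC") == pytest.approx(1.0)

    def test_direct_formula(self):
        ref = net_from_edges([(f"A:{i}", f"B:{i}") for i in range(10)])
        mod = net_from_edges([(f"A:{i}", f"B:{i}") for i in range(8)]
                             + [(f"X:{i}", f"Y:{i}") for i in range(2)])
        # TP=8, FP=2, FN=2
        assert inf(ref, mod, "WC") == pytest.approx(0.8)

    def test_empty_reference_category_is_undefined(self):
        ref = InteractionNetwork()
        mod = net_from_edges([("A:1", "B:2")])
        assert inf(ref, mod, "WC") is None

    def test_random_networks_match_set_algebra_oracle(self):
        rng = np.random.default_rng(12)
        keys = [f"A:{i}" for i in range(10)]
        for _ in range(100):
            def rand_net():
                n = InteractionNetwork()
                for _ in range(12):
                    i, j = rng.choice(10, 2, replace=False)
                    n.wc.add(frozenset((keys[i], keys[j])))
                return n
            ref, mod = rand_net(), rand_net()
            got = inf(ref, mod, "WC")
            tp = sum(1 for e in mod.wc if e in ref.wc)
            fp = sum(1 for e in mod.wc if e not in ref.wc)
            fn = sum(1 for e in ref.wc if e not in mod.wc)
            if tp == 0:
                assert got == 0.0
            else:
                ppv, tpr = tp / (tp + fp), tp / (tp + fn)
                assert got == pytest.approx(math.sqrt(ppv * tpr), abs=1e-12)

    def test_category_composition(self):
        ref = InteractionNetwork(
            wc={frozenset(("A:1", "B:4"))}, nwc={frozenset(("A:2", "B:3"))},
            stack={frozenset(("A:1", "A:2"))})
        mod = InteractionNetwork(wc={frozenset(("A:1", "B:4"))})
        assert inf(ref, mod, "BPS") == pytest.approx(math.sqrt(1.0 * 0.5))
        assert inf(ref, mod, "ALL") == pytest.approx(math.sqrt(1.0 / 3.0))


class TestDeformationIndex:
    def test_simple_division(self):
        assert deformation_index(4.0, 0.8) == pytest.approx(5.0)

    def test_zero_rmsd(self):
        assert deformation_index(0.0, 0.5) == 0.0

    def test_zero_or_undefined_inf(self):
        assert deformation_index(3.0, 0.0) is None
        assert deformation_index(3.0, None) is None


class TestDeformationProfile:
    def test_identity_matrix_is_zero(self):
        st, _ = build_duplex("GCAUGC")
        corr = build_correspondence(st, st)
        dp = deformation_profile(st, st, corr)
        assert np.nanmax(dp.matrix) <= 1e-9
        assert dp.mean == pytest.approx(0.0, abs=1e-9)

    def test_hinge_localizes_deformation(self):
        st, _ = build_duplex("GCAUGCAUGC")
        n_a = 10
        decoy = make_decoy(st, DecoySpec("hinge", pivot=4, angle=30.0))
        corr = build_correspondence(decoy, st)
        dp = deformation_profile(decoy, st, corr)
        # anchor in the fixed arm (chain A residues 1-4): near-zero columns in
        # the fixed arm, large in the rotated arm (chain A residues 6-10)
        fixed_rows = range(0, 4)
        for i in fixed_rows:
            fixed_cols = dp.matrix[i, 0:4]
            moved_cols = dp.matrix[i, 5:n_a]
            assert np.nanmax(fixed_cols) <= 1e-6
            assert np.nanmin(moved_cols) > 1.0

    def test_mean_consistent_with_sum(self):
        st, _ = build_duplex("GCAUG")
        decoy = make_decoy(st, DecoySpec("gaussian", sigma=0.8, seed=5))
        corr = build_correspondence(decoy, st)
        dp = deformation_profile(decoy, st, corr)
        n_defined = int(np.sum(~np.isnan(dp.matrix)))
        assert n_defined == dp.matrix.size  # all anchors valid here
        assert dp.mean == pytest.approx(dp.sum / n_defined)


def free_atom_structure(positions, element="C"):
    residues = [Residue("A", i + 1, "LIG",
                        [Atom(element, element, np.asarray(p, dtype=float))],
                        kind="other")
                for i, p in enumerate(positions)]
    return Structure("atoms", residues)


class TestClashscore:
    def test_ideal_helix_is_clash_free(self):
        st, _ = build_duplex("GGACUAGCAU")
        assert clashscore(st) == 0.0

    def test_overlap_beyond_threshold_counts(self):
        st = free_atom_structure([(0, 0, 0), (2.9, 0, 0)])  # overlap 0.5
        assert clashscore(st) == pytest.approx(1000.0 * 1 / 2)

    def test_overlap_within_threshold_ignored(self):
        st = free_atom_structure([(0, 0, 0), (3.1, 0, 0)])  # overlap 0.3
        assert clashscore(st) == 0.0

    def test_per_residue_denominator(self):
        st = free_atom_structure([(0, 0, 0), (2.9, 0, 0)])
        assert clashscore(st, per_residue=True) == pytest.approx(500.0)

    def test_bonded_pairs_excluded(self):
        # two carbons at bond distance are not a clash despite the overlap
        st = Structure("b", [Residue("A", 1, "LIG",
                                     [Atom("C1", "C", np.zeros(3)),
                                      Atom("C2", "C", np.array([1.5, 0, 0]))],
                                     kind="other")])
        assert clashscore(st) == 0.0


class TestMcq:
    def _torsion_sets(self, shift=0.0, base_angles=None):
        from rna_assess.annotation import TorsionSet

        base_angles = base_angles or {"alpha": -60.0, "gamma": 50.0,
                                      "chi": -160.0}
        ref = TorsionSet({"A:1": dict(base_angles)})

        def wrap(v):
            v = (v + 180.0) % 360.0 - 180.0
            return 180.0 if v == -180.0 else v
        mod = TorsionSet({"A:1": {k: wrap(v + shift)
                                  for k, v in base_angles.items()}})
        return mod, ref

    def test_identical_torsions_give_zero(self):
        mod, ref = self._torsion_sets(0.0)
        assert mcq(mod, ref, None, key_pairs=[("A:1", "A:1")]) == 0.0

    def test_uniform_shift(self):
        mod, ref = self._torsion_sets(10.0)
        assert mcq(mod, ref, None,
                   key_pairs=[("A:1", "A:1")]) == pytest.approx(10.0)

    def test_circular_wrap(self):
        from rna_assess.annotation import TorsionSet

        mod = TorsionSet({"A:1": {"alpha": 175.0}})
        ref = TorsionSet({"A:1": {"alpha": -175.0}})
        assert mcq(mod, ref, None,
                   key_pairs=[("A:1", "A:1")]) == pytest.approx(10.0)

    def test_undefined_angles_skipped(self):
        from rna_assess.annotation import TorsionSet

        mod = TorsionSet({"A:1": {"alpha": 30.0, "beta": None}})
        ref = TorsionSet({"A:1": {"alpha": 40.0, "beta": 100.0}})
        assert mcq(mod, ref, None,
                   key_pairs=[("A:1", "A:1")]) == pytest.approx(10.0)

    def test_computed_on_duplex_identity(self):
        st, _ = build_duplex("GCAUGC")
        corr = build_correspondence(st, st)
        tors = compute_torsions(st)
        assert mcq(tors, tors, corr, st, st) == pytest.approx(0.0, abs=1e-9)
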