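import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ebase import (annotate_structure, cv_curve, drmsd, ermsd, ermsd_scalar,
                   gscalar, gvector, inf_score, make_trajectory,
                   naive_distance, perturb, rmsd)
from ebase.deviation import g_matrix
from ebase.errors import CorrespondenceError, InputError
from ebase.geometry import (PairAnnotation, ScalingParams, Zone, build_frame,
                            pair_vector)
from ebase.io import RnaStructure, Trajectory

GAMMA = math.pi / 2.4


def brute_force_g(r_tilde, cutoff=2.4):
    """Independent evaluation of the 4-D mapping from its closed form."""
    r_tilde = np.asarray(r_tilde, float)
    n = math.sqrt(sum(x * x for x in r_tilde))
    gamma = math.pi / cutoff
    if n >= cutoff:
        return np.zeros(4)
    if n == 0:
        return np.array([0, 0, 0, 2.0 / gamma])
    return np.array([
        math.sin(gamma * n) * r_tilde[0] / n,
        math.sin(gamma * n) * r_tilde[1] / n,
        math.sin(gamma * n) * r_tilde[2] / n,
        1.0 + math.cos(gamma * n),
    ]) / gamma


def brute_force_ermsd(a, b, params=ScalingParams()):
    """Explicit double loop over ordered pairs, independent of g_matrix."""
    n = len(a)
    total = 0.0
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            pa = pair_vector(build_frame(a[j]), build_frame(a[k]), params)
            pb = pair_vector(build_frame(b[j]), build_frame(b[k]), params)
            diff = brute_force_g(pa.r_tilde) - brute_force_g(pb.r_tilde)
            total += float(diff @ diff)
    return math.sqrt(total / n)


class TestGVector:
    def test_zero_beyond_cutoff(self):
        for direction in ([1, 0, 0], [0, 1, 0], [0.6, -0.48, 0.64]):
            v = 2.4 * np.asarray(direction) / np.linalg.norm(direction)
            assert np.linalg.norm(gvector(v).components) < 1e-12
            np.testing.assert_array_equal(gvector(3.0 * np.asarray(direction)
                                                  ).components, np.zeros(4))

    def test_origin_limit(self):
        comp = gvector([0.0, 0.0, 0.0]).components
        np.testing.assert_allclose(comp, [0, 0, 0, 2 * 2.4 / math.pi],
                                   atol=1e-12)

    def test_hand_evaluated_point(self):
        # gamma * 1.2 = pi/2 -> sin = 1, cos = 0
        comp = gvector([1.2, 0.0, 0.0]).components
        np.testing.assert_allclose(comp, [2.4 / math.pi, 0, 0, 2.4 / math.pi],
                                   atol=1e-12)

    def test_continuity_at_cutoff(self):
        eps = 1e-7
        below = gvector([2.4 - eps, 0.0, 0.0]).components
        at = gvector([2.4, 0.0, 0.0]).components
        assert np.linalg.norm(below - at) < 1e-6

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(-3, 3), min_size=3, max_size=3))
    def test_norm_bound_and_oracle(self, vec):
        g = gvector(np.array(vec)).components
        assert np.linalg.norm(g) <= 2.0 / GAMMA + 1e-12
        np.testing.assert_allclose(g, brute_force_g(vec), atol=1e-12)

    def test_small_r_isometry(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a = rng.normal(0, 0.2, 3)
            b = rng.normal(0, 0.2, 3)
            if max(np.linalg.norm(a), np.linalg.norm(b)) >= 0.5:
                continue
            dg = np.linalg.norm(gvector(a).components - gvector(b).components)
            dr = np.linalg.norm(a - b)
            if dr > 1e-6:
                assert abs(dg - dr) <= 0.1 * dr


@pytest.mark.parametrize("norm,expected", [
    (2.4, 0.0), (0.0, 2.4), (1.0, 1.4), (3.0, 0.0),
])
def test_gscalar(norm, expected):
    assert gscalar([norm, 0.0, 0.0]) == pytest.approx(expected)


class TestErmsd:
    def test_identity(self, duplex_gggg):
        assert ermsd(duplex_gggg, duplex_gggg) == 0.0

    def test_symmetry(self, duplex_gggg):
        for seed in (1, 2, 3):
            other = perturb(duplex_gggg, 1.0, seed)
            assert ermsd(duplex_gggg, other) == \
                pytest.approx(ermsd(other, duplex_gggg), abs=1e-12)

    def test_length_mismatch_raises(self, duplex_gggg, duplex_12nt):
        with pytest.raises(CorrespondenceError):
            ermsd(duplex_gggg, duplex_12nt)

    def test_brute_force_oracle_3nt(self, duplex_gggg):
        """Toy 3-nt structures match the explicit ordered-pair sum."""
        toy_a = duplex_gggg.subset([0, 1, 7])
        for seed in (11, 12, 13):
            toy_b = perturb(toy_a, 1.5, seed)
            assert ermsd(toy_a, toy_b) == \
                pytest.approx(brute_force_ermsd(toy_a, toy_b), abs=1e-12)

    def test_rigid_motion_invariance(self, duplex_gggg, random_rigid_motion):
        other = perturb(duplex_gggg, 1.0, 9)
        rot, trans = random_rigid_motion(21)
        assert ermsd(duplex_gggg, other.transformed(rot, trans)) == \
            pytest.approx(ermsd(duplex_gggg, other), abs=1e-9)

    def test_metric_axioms(self, duplex_gggg):
        rng_seeds = range(30)
        triples = [(perturb(duplex_gggg, 1.0, 3 * s),
                    perturb(duplex_gggg, 1.0, 3 * s + 1),
                    perturb(duplex_gggg, 2.0, 3 * s + 2)) for s in rng_seeds]
        for a, b, c in triples:
            dab, dbc, dac = ermsd(a, b), ermsd(b, c), ermsd(a, c)
            assert dab >= 0
            assert dac <= dab + dbc + 1e-12


class TestScalarVariant:
    def test_identity(self, duplex_gggg):
        assert ermsd_scalar(duplex_gggg, duplex_gggg) == 0.0

    def test_correlates_with_vector_form(self, duplex_12nt):
        """>4-nt structures: scalar and vector forms track each other."""
        es, esc = [], []
        for i in range(60):
            sigma = 0.3 + 2.0 * i / 59
            decoy = perturb(duplex_12nt, sigma, seed=100 + i)
            es.append(ermsd(duplex_12nt, decoy))
            esc.append(ermsd_scalar(duplex_12nt, decoy))
        r = np.corrcoef(es, esc)[0, 1]
        assert r > 0.9


class TestNaiveDistance:
    def test_identity(self, duplex_gggg):
        assert naive_distance(duplex_gggg, duplex_gggg) == 0.0

    def test_nonlocality_contrast(self, duplex_gggg):
        """Moving an already-distant base changes d but not the eRMSD."""
        nts = [nt.copy() for nt in duplex_gggg]
        nts[0].heavy_atoms = {k: v + np.array([50.0, 0, 0])
                              for k, v in nts[0].heavy_atoms.items()}
        far = RnaStructure(nts)
        nts2 = [nt.copy() for nt in far]
        nts2[0].heavy_atoms = {k: v + np.array([10.0, 0, 0])
                               for k, v in nts2[0].heavy_atoms.items()}
        farther = RnaStructure(nts2)
        assert ermsd(far, farther) == pytest.approx(0.0, abs=1e-12)
        assert naive_distance(far, farther) > 0.1

    def test_two_nt_brute_force(self, duplex_gggg, params):
        toy_a = duplex_gggg.subset([0, 7])
        toy_b = perturb(toy_a, 1.0, 42)
        total = 0.0
        for j, k in ((0, 1), (1, 0)):
            pa = pair_vector(build_frame(toy_a[j]), build_frame(toy_a[k]),
                             params)
            pb = pair_vector(build_frame(toy_b[j]), build_frame(toy_b[k]),
                             params)
            total += float(np.sum((pa.r_tilde - pb.r_tilde) ** 2))
        assert naive_distance(toy_a, toy_b) == \
            pytest.approx(math.sqrt(total / 2), abs=1e-12)


class TestRmsd:
    def test_translated_copy_is_zero(self, duplex_gggg):
        moved = duplex_gggg.transformed(None, np.array([5.0, -3.0, 2.0]))
        assert rmsd(duplex_gggg, moved) == pytest.approx(0.0, abs=1e-9)

    def test_register_shift_value(self, duplex_gggg, duplex_shift1):
        assert rmsd(duplex_gggg, duplex_shift1) == pytest.approx(1.9, abs=0.3)

    def test_mirror_image_not_zero(self, duplex_gggg):
        mirror = duplex_gggg.transformed(np.diag([-1.0, 1.0, 1.0]), None)
        assert rmsd(duplex_gggg, mirror) > 0.5

    def test_atom_mismatch_raises(self, duplex_gggg, duplex_12nt):
        with pytest.raises(CorrespondenceError):
            rmsd(duplex_gggg, duplex_12nt)


class TestDrmsd:
    def test_identity_and_rotation(self, duplex_gggg, random_rigid_motion):
        assert drmsd(duplex_gggg, duplex_gggg) == 0.0
        rot, trans = random_rigid_motion(3)
        assert drmsd(duplex_gggg, duplex_gggg.transformed(rot, trans)) == \
            pytest.approx(0.0, abs=1e-9)

    def test_three_nt_brute_force(self, duplex_gggg):
        toy_a = duplex_gggg.subset([0, 1, 7])
        toy_b = perturb(toy_a, 1.0, 8)
        ca, cb = toy_a.ring_centers(), toy_b.ring_centers()
        diffs = []
        for j in range(3):
            for k in range(j + 1, 3):
                diffs.append(np.linalg.norm(ca[j] - ca[k])
                             - np.linalg.norm(cb[j] - cb[k]))
        expected = math.sqrt(np.mean(np.square(diffs)))
        assert drmsd(toy_a, toy_b) == pytest.approx(expected, abs=1e-12)


def _ann(j, k, zone):
    return PairAnnotation(j=j, k=k, zone=zone)


class TestInf:
    def test_identical_sets(self, duplex_gggg):
        ann = annotate_structure(duplex_gggg)
        assert inf_score(ann, ann) == 1.0

    def test_disjoint_sets(self):
        ref = [_ann(0, 1, Zone.PAIRING)]
        cmp_ = [_ann(2, 3, Zone.PAIRING)]
        assert inf_score(ref, cmp_) == 0.0

    def test_half_overlap(self):
        # TP=2, FP=2, FN=2 -> sqrt(0.5 * 0.5) = 0.5
        ref = [_ann(0, 1, Zone.PAIRING), _ann(2, 3, Zone.PAIRING),
               _ann(4, 5, Zone.STACKING), _ann(6, 7, Zone.STACKING)]
        cmp_ = [_ann(0, 1, Zone.PAIRING), _ann(4, 5, Zone.STACKING),
                _ann(1, 2, Zone.PAIRING), _ann(5, 6, Zone.STACKING)]
        assert inf_score(ref, cmp_) == pytest.approx(0.5)

    def test_empty_reference_raises(self):
        with pytest.raises(InputError):
            inf_score([], [_ann(0, 1, Zone.PAIRING)])


class TestCvCurve:
    def test_constant_lag_distance_gives_zero_cv(self, duplex_gggg):
        a = duplex_gggg
        b = perturb(duplex_gggg, 1.0, 77)
        frames = [a if t % 2 == 0 else b for t in range(12)]
        curve = cv_curve(Trajectory(frames), "ermsd", lags=[1])
        assert curve.cv[0] == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self, duplex_gggg):
        traj = make_trajectory(duplex_gggg, 25, 0.3, seed=6)
        base = cv_curve(traj, ermsd, lags=[1, 3])
        doubled = cv_curve(traj, lambda x, y: 2.0 * ermsd(x, y), lags=[1, 3])
        np.testing.assert_allclose(base.cv, doubled.cv, atol=1e-12)

    def test_brute_force_agreement(self, duplex_gggg):
        """Named-metric fast path equals a direct two-pass computation."""
        traj = make_trajectory(duplex_gggg, 50, 0.3, seed=9)
        lags = [1, 2, 5]
        curve = cv_curve(traj, "ermsd", lags=lags)
        for i, tau in enumerate(lags):
            series = np.array([ermsd(traj[t], traj[t + tau])
                               for t in range(len(traj) - tau)])
            mean = series.sum() / len(series)
            sd = math.sqrt(((series - mean) ** 2).sum() / (len(series) - 1))
            assert curve.mean_d[i] == pytest.approx(mean, abs=1e-12)
            assert curve.cv[i] == pytest.approx(sd / mean, abs=1e-12)
            assert curve.cv_error[i] > 0

    def test_insufficient_frames_raise(self, duplex_gggg):
        traj = make_trajectory(duplex_gggg, 5, 0.1, seed=2)
        with pytest.raises(InputError):
            cv_curve(traj, "ermsd", lags=[10])

    def test_all_metric_names_run(self, duplex_gggg):
        traj = make_trajectory(duplex_gggg, 12, 0.3, seed=13)
        for name in ("ermsd", "ermsd-scalar", "naive", "drmsd", "rmsd"):
            curve = cv_curve(traj, name, lags=[1, 2])
            assert all(c >= 0 for c in curve.cv)


def test_g_matrix_matches_elementwise(duplex_gggg, params):
    g = g_matrix(duplex_gggg, params)
    for j in range(len(duplex_gggg)):
        for k in range(len(duplex_gggg)):
            if j == k:
                np.testing.assert_array_equal(g[j, k], np.zeros(4))
                continue
            pv = pair_vector(build_frame(duplex_gggg[j]),
                             build_frame(duplex_gggg[k]), params)
            np.testing.assert_allclose(g[j, k], brute_force_g(pv.r_tilde),
                                       atol=1e-12)
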