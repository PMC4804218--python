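import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from foldcep.synthetic import generate_toy_structures
from foldcep.tmscore import (
    AlignmentPairs,
    Structure,
    d0_scale,
    kabsch_superpose,
    pairwise_matrix,
    tm_score,
)


@pytest.mark.parametrize(
    "l_norm,expected",
    [
        (100, 1.24 * 85 ** (1 / 3) - 1.8),  # ~3.652
        (15, 0.5),  # floor engaged
        (21, 0.5),  # evaluates below the floor -> clamped
    ],
)
def test_d0_scale(l_norm, expected):
    assert d0_scale(l_norm) == pytest.approx(expected, abs=1e-4)


def test_d0_scale_invalid_length():
    with pytest.raises(ValueError):
        d0_scale(0)


class TestKabsch:
    def test_recovers_rigid_motion(self, rng):
        P = rng.normal(size=(20, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = (P - np.array([1.0, 2.0, 3.0])) @ R  # P = Q @ Rhat.T + that
        Rhat, that, rmsd = kabsch_superpose(P, Q)
        assert rmsd < 1e-8
        assert np.linalg.det(Rhat) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(Q @ Rhat.T + that, P, atol=1e-8)

    def test_identity(self, rng):
        P = rng.normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0.0, atol=1e-9)

    def test_mirror_image_not_recovered(self, rng):
        # reflections are excluded, so a chiral point set cannot reach rmsd 0
        P = rng.normal(size=(12, 3))
        Q = P * np.array([1.0, 1.0, -1.0])
        _, _, rmsd = kabsch_superpose(P, Q)
        assert rmsd > 0.1

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestTmScore:
    def test_self_score_is_one(self):
        structs, _ = generate_toy_structures(1, length=50, seed=0)
        s = structs[0]
        for mode in ("local", "global"):
            r = tm_score(s, s, AlignmentPairs.identity(50), mode)
            assert r.score == pytest.approx(1.0, abs=1e-9)
            assert np.linalg.det(r.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_nested_structure_closed_form(self):
        # 50-residue domain identical to the first half of a 100-residue one:
        # all d_i = 0, so score = L_ali / L_norm exactly
        structs, corr = generate_toy_structures(
            2, length=100, perturbation_sd=0.0, truncation=0.5, seed=0
        )
        full, half = structs
        pairs = corr[(full.domain_id, half.domain_id)]
        assert tm_score(full, half, pairs, "local").score == pytest.approx(1.0, abs=1e-9)
        assert tm_score(full, half, pairs, "global").score == pytest.approx(50 / 75, abs=1e-9)

    def test_swap_symmetry_and_rigid_invariance(self, rng):
        structs, corr = generate_toy_structures(2, length=40, perturbation_sd=1.0, seed=3)
        A, B = structs
        pairs = corr[(A.domain_id, B.domain_id)]
        s_ab = tm_score(A, B, pairs, "local").score
        s_ba = tm_score(B, A, pairs.reversed(), "local").score
        assert s_ab == pytest.approx(s_ba, abs=1e-9)
        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        B_moved = Structure("bm", B.ca_coords @ R.T + rng.normal(size=3) * 10)
        assert tm_score(A, B_moved, pairs, "local").score == pytest.approx(s_ab, abs=1e-9)

    def test_local_at_least_global_on_unequal_lengths(self):
        # nested-substructure pairs with moderate noise: the shorter-length
        # normalization can only help the local score
        rng = np.random.default_rng(7)
        for trial in range(100):
            length = int(rng.integers(60, 120))
            trunc = float(rng.uniform(0.5, 0.8))
            structs, corr = generate_toy_structures(
                2,
                length=length,
                perturbation_sd=0.2,
                truncation=trunc,
                seed=int(rng.integers(2**31)),
            )
            A, B = structs
            pairs = corr[(A.domain_id, B.domain_id)]
            s_loc = tm_score(A, B, pairs, "local").score
            s_glob = tm_score(A, B, pairs, "global").score
            assert s_loc >= s_glob - 1e-12

    def test_l_ali_too_small(self):
        structs, _ = generate_toy_structures(2, length=20, seed=0)
        with pytest.raises(ValueError):
            tm_score(structs[0], structs[1], AlignmentPairs.identity(3), "local")

    def test_invalid_mode(self):
        structs, _ = generate_toy_structures(2, length=20, seed=0)
        with pytest.raises(ValueError):
            tm_score(structs[0], structs[1], AlignmentPairs.identity(20), "sideways")


def _brute_force_tm(A, B, pairs, mode):
    """Independent maximization: optimize the 6-dof rigid transform of B
    directly with many starts (fragment superpositions + identity)."""
    arr = pairs.pairs
    pa, pb = A.ca_coords[arr[:, 0]], B.ca_coords[arr[:, 1]]
    l_norm = (
        min(A.length, B.length)
        if mode == "local"
        else int(np.floor((A.length + B.length) / 2 + 0.5))
    )
    d0 = d0_scale(l_norm)

    def neg_score(params):
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        t = params[3:]
        d2 = ((pb @ R.T + t - pa) ** 2).sum(axis=1)
        return -np.sum(1.0 / (1.0 + d2 / d0**2)) / l_norm

    starts = [np.zeros(6)]
    n = arr.shape[0]
    for frag in (4, max(n // 2, 4), n):
        for lo in range(0, n - frag + 1, 2):
            R, t, _ = kabsch_superpose(pa[lo : lo + frag], pb[lo : lo + frag])
            starts.append(np.concatenate([Rotation.from_matrix(R).as_rotvec(), t]))
    best = np.inf
    for s0 in starts:
        res = minimize(neg_score, s0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, res.fun)
    return -best


def test_seed_and_refine_matches_brute_force_oracle():
    structs, corr = generate_toy_structures(2, length=22, perturbation_sd=0.6, seed=9)
    A, B = structs
    pairs = corr[(A.domain_id, B.domain_id)]
    for mode in ("local", "global"):
        ours = tm_score(A, B, pairs, mode).score
        oracle = _brute_force_tm(A, B, pairs, mode)
        assert ours == pytest.approx(oracle, abs=1e-6)


class TestPairwiseMatrix:
    def test_identical_structures_all_ones(self):
        structs, corr = generate_toy_structures(3, length=30, perturbation_sd=0.0, seed=0)
        mat = pairwise_matrix(structs, corr, mode="local")
        assert np.allclose(mat.to_array(), 1.0, atol=1e-9)

    def test_delegates_to_tm_score(self):
        structs, corr = generate_toy_structures(2, length=30, perturbation_sd=1.0, seed=5)
        A, B = structs
        mat = pairwise_matrix(structs, corr, mode="global")
        direct = tm_score(A, B, corr[(A.domain_id, B.domain_id)], "global").score
        assert mat.get(A.domain_id, B.domain_id) == pytest.approx(direct, abs=1e-12)

    def test_missing_correspondence_error(self):
        structs, corr = generate_toy_structures(3, length=30, seed=0)
        corr = dict(corr)
        del corr[("toy000", "toy002")]
        with pytest.raises(KeyError, match="toy002"):
            pairwise_matrix(structs, corr)
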