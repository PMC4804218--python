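import numpy as np
import pytest
from scipy import stats

from foldcep.classify import QueryResult
from foldcep.evaluation import (
    heterogeneity_attraction_correlation,
    method_overlap,
    reclassification_rate,
    relative_length_difference,
)
from foldcep.profiles import FoldProfile


def _result(qid, original, assigned, method="cep"):
    return QueryResult(
        query_id=qid, original_fold=original, mode="local",
        assigned={method: assigned},
    )


class TestReclassificationRate:
    def test_all_agree(self):
        results = [_result(f"q{i}", "f1", "f1") for i in range(5)]
        s = reclassification_rate(results, "cep")
        assert s.disagreement_fraction == 0.0
        assert s.attraction == {}

    def test_one_of_ten(self):
        results = [_result(f"q{i}", "f1", "f1") for i in range(9)]
        results.append(_result("q9", "f1", "f2"))
        s = reclassification_rate(results, "cep")
        assert s.disagreement_fraction == pytest.approx(0.1)
        assert s.attraction == {"f2": 1}

    def test_all_differ_single_attractor(self):
        results = [_result(f"q{i}", "f1", "f9") for i in range(4)]
        s = reclassification_rate(results, "cep")
        assert s.disagreement_fraction == 1.0
        assert s.attraction == {"f9": 4}
        assert sum(s.attraction.values()) == s.n_disagreements

    def test_missing_original_fold(self):
        with pytest.raises(ValueError):
            reclassification_rate([_result("q", None, "f1")], "cep")


def _profiles(sds):
    out = {}
    for i, sd in enumerate(sds):
        x = np.clip(np.array([0.8 - sd, 0.8, 0.8 + sd]), 0.01, 1.0)
        out[f"f{i}"] = FoldProfile(f"f{i}", (f"f{i}a", f"f{i}b", f"f{i}c"), x, "local")
    return out


class TestAttractionCorrelation:
    def test_perfect_rank_order(self):
        profiles = _profiles([0.01, 0.02, 0.05, 0.10, 0.15])
        results = []
        q = 0
        for i, count in enumerate([0, 1, 2, 3, 4]):
            for _ in range(count):
                results.append(_result(f"q{q}", "f0" if i else "f1", f"f{i}"))
                q += 1
        summary = reclassification_rate(results, "cep")
        rho, p = heterogeneity_attraction_correlation(profiles, summary, "sd_x", seed=0)
        assert rho == pytest.approx(1.0)
        assert p < 0.05

    def test_constant_counts_error(self):
        profiles = _profiles([0.01, 0.02, 0.05])
        results = [_result("q0", "f0", "f0")]  # nobody reclassified
        summary = reclassification_rate(results, "cep")
        with pytest.raises(ValueError, match="undefined"):
            heterogeneity_attraction_correlation(profiles, summary, "sd_x")

    def test_rho_matches_independent_rank_oracle(self, rng):
        profiles = _profiles(rng.uniform(0.01, 0.2, size=8))
        counts = rng.integers(0, 5, size=8)
        results = []
        q = 0
        for i, c in enumerate(counts):
            for _ in range(c):
                results.append(_result(f"q{q}", "orig", f"f{i}"))
                q += 1
        results.append(_result("qx", "f0", "f0"))
        summary = reclassification_rate(results, "cep")
        rho, _ = heterogeneity_attraction_correlation(profiles, summary, "sd_x", seed=1)
        x = np.array([profiles[f].sd_x for f in sorted(profiles)])
        y = np.array([summary.attraction.get(f, 0) for f in sorted(profiles)])
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)


class TestMethodOverlap:
    def test_identical_sets_all_agree(self):
        a = [_result(f"q{i}", "f1", "f1", "cep") for i in range(4)]
        b = [_result(f"q{i}", "f1", "f1", "c3p") for i in range(4)]
        cells = method_overlap(a, b, "cep", "c3p")
        assert cells["all_agree"] == 4
        assert cells["n_queries"] == 4
        total = sum(cells[k] for k in (
            "all_agree", "ab_agree_not_original", "a_original_not_b",
            "b_original_not_a", "all_differ"))
        assert total == 4

    def test_b_differs_on_two(self):
        a = [_result(f"q{i}", "f1", "f1", "cep") for i in range(10)]
        b = [
            _result(f"q{i}", "f1", "f2" if i < 2 else "f1", "c3p")
            for i in range(10)
        ]
        cells = method_overlap(a, b, "cep", "c3p")
        assert cells["a_original_not_b"] == 2
        assert cells["all_agree"] == 8

    def test_same_way_fraction(self):
        # among A's reclassifications, how many does B send the same way
        a = [
            _result("q0", "f1", "f2", "cep"),
            _result("q1", "f1", "f2", "cep"),
            _result("q2", "f1", "f3", "cep"),
            _result("q3", "f1", "f1", "cep"),
        ]
        b = [
            _result("q0", "f1", "f2", "c3p"),
            _result("q1", "f1", "f9", "c3p"),
            _result("q2", "f1", "f3", "c3p"),
            _result("q3", "f1", "f1", "c3p"),
        ]
        cells = method_overlap(a, b, "cep", "c3p")
        assert cells["same_way_fraction"] == pytest.approx(2 / 3)

    def test_disjoint_reclassification_targets(self):
        a = [_result("q0", "f1", "f2", "cep")]
        b = [_result("q0", "f1", "f3", "c3p")]
        assert method_overlap(a, b, "cep", "c3p")["same_way_fraction"] == 0.0

    def test_query_mismatch_error(self):
        a = [_result("q0", "f1", "f1", "cep")]
        b = [_result("q1", "f1", "f1", "c3p")]
        with pytest.raises(ValueError):
            method_overlap(a, b, "cep", "c3p")


class TestRelativeLengthDifference:
    @pytest.mark.parametrize(
        "lq,lp,expected", [(100, 100, 0.0), (150, 100, 0.5), (100, 150, 0.5)]
    )
    def test_values_and_symmetry(self, lq, lp, expected):
        assert relative_length_difference(lq, lp) == pytest.approx(expected)

    def test_zero_iff_equal(self, rng):
        for _ in range(20):
            a, b = int(rng.integers(40, 400)), int(rng.integers(40, 400))
            d = relative_length_difference(a, b)
            assert (d == 0) == (a == b)
            assert d == relative_length_difference(b, a)

    def test_invalid_lengths(self):
        with pytest.raises(ValueError):
            relative_length_difference(0, 100)


def test_discrete_universe_zero_reclassification(discrete_universe):
    from foldcep.classify import FoldClassificationModel

    table, local, _, _ = discrete_universe
    res = FoldClassificationModel(table, local).fit(methods=("tm_max", "cep"))
    results = res.classify_members()
    for method in ("tm_max", "cep"):
        assert reclassification_rate(results, method).disagreement_fraction == 0.0
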