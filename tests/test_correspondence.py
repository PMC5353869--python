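"""Overlap-test kernel, map assembly, ordering and shuffle controls."""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import hypergeom

from exoncorr.correspondence import (
    AssociatedExonSet,
    NegativeControlConfig,
    between_test,
    build_map,
    calibration_pvalues,
    hypergeom_log_pmf,
    hypergeom_tail,
    order_samples,
    paired_status_rows,
    shuffle_control,
    within_test,
)
from exoncorr.errors import ConfigurationError, DomainError

import pandas as pd


def enumerate_tail(k: int, a: int, b: int, n: int) -> Fraction:
    """Exact P(|A n B| >= k) by enumerating all draws of B against a fixed A.

    By exchangeability the overlap distribution depends on |A| only, so fixing
    A = {0..a-1} and enumerating every size-b subset B is an exhaustive
    enumeration over equally likely draws.
    """
    items = range(n)
    a_set = set(range(a))
    total = hits = 0
    for b_set in itertools.combinations(items, b):
        total += 1
        hits += len(a_set & set(b_set)) >= k
    return Fraction(hits, total)


@pytest.mark.parametrize(
    "k,a,b,n,expected",
    [
        (0, 3, 5, 10, Fraction(1)),  # tail over the whole support
        (2, 2, 2, 4, Fraction(1, 6)),
        (4, 5, 4, 10, Fraction(1, 42)),
        (1, 2, 2, 6, Fraction(3, 5)),
        (1, 1, 1, 4, Fraction(1, 4)),
    ],
    ids=["k0", "n4", "n10", "n6", "n4-single"],
)
def test_tail_matches_printed_formula_examples(k, a, b, n, expected):
    got = 10.0 ** hypergeom_tail(k, a, b, n)
    assert got == pytest.approx(float(expected), rel=1e-12)
    assert enumerate_tail(k, a, b, n) == expected


def test_tail_k0_is_exactly_one():
    assert hypergeom_tail(0, 7, 5, 20) == 0.0


def test_tail_matches_enumeration_small_populations():
    for n in (5, 8):
        for a in range(n + 1):
            for b in range(n + 1):
                for k in range(min(a, b) + 1):
                    exact = float(enumerate_tail(k, a, b, n))
                    got = 10.0 ** hypergeom_tail(k, a, b, n)
                    assert got == pytest.approx(exact, rel=1e-12), (n, a, b, k)


def test_tail_agrees_with_scipy_survival_function():
    # independent library cross-check: P(X >= k) = sf(k - 1)
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(2, 400))
        a = int(rng.integers(0, n + 1))
        b = int(rng.integers(0, n + 1))
        k = int(rng.integers(0, min(a, b) + 1))
        ref = hypergeom(n, a, b).logsf(k - 1) / np.log(10)
        got = hypergeom_tail(k, a, b, n)
        assert got == pytest.approx(ref, rel=1e-9, abs=1e-12)


def test_tail_symmetry_and_monotonicity():
    n, a, b = 40, 12, 17
    vals = [hypergeom_tail(k, a, b, n) for k in range(min(a, b) + 1)]
    assert vals == sorted(vals, reverse=True)  # non-increasing in k
    for k in range(min(a, b) + 1):
        assert hypergeom_tail(k, a, b, n) == pytest.approx(
            hypergeom_tail(k, b, a, n), rel=1e-12, abs=1e-14
        )


def test_tail_domain_errors():
    with pytest.raises(DomainError):
        hypergeom_tail(3, 2, 5, 10)  # k > min(a, b)
    with pytest.raises(DomainError):
        hypergeom_tail(0, 11, 5, 10)  # size exceeds population


def test_pmf_sums_to_tail():
    n, a, b = 30, 10, 8
    for k in range(min(a, b) + 1):
        pmf_sum = sum(
            np.exp(hypergeom_log_pmf(i, a, b, n)) for i in range(k, min(a, b) + 1)
        )
        assert pmf_sum == pytest.approx(10.0 ** hypergeom_tail(k, a, b, n), rel=1e-10)


def _aset(sample, members):
    return AssociatedExonSet(sample_id=sample, members=frozenset(members))


class TestWithinTest:
    def test_identical_sets_maximal_overlap(self):
        a = _aset("s1", {("e1", "HIGH"), ("e2", "LOW")})
        res = within_test(a, a, n_cassette=5)
        assert res.statistic == len(a.members)
        assert res.population == 10

    def test_disjoint_sets_give_p_one(self):
        a = _aset("s1", {("e1", "HIGH")})
        b = _aset("s2", {("e2", "LOW")})
        res = within_test(a, b, n_cassette=4)
        assert res.log10_p == 0.0
        assert res.mapping_score == 0.0

    def test_toy_universe_quarter(self):
        # population of 4 status-exons; singleton overlap has p = 1/4
        a = _aset("s1", {("e1", "HIGH")})
        res = within_test(a, _aset("s2", {("e1", "HIGH")}), n_cassette=2)
        assert 10.0 ** res.log10_p == pytest.approx(0.25, rel=1e-12)

    def test_same_exon_opposite_status_does_not_overlap(self):
        a = _aset("s1", {("e1", "HIGH")})
        b = _aset("s2", {("e1", "LOW")})
        assert within_test(a, b, n_cassette=2).statistic == 0

    def test_conflicting_statuses_rejected(self):
        with pytest.raises(ConfigurationError):
            _aset("s1", {("e1", "HIGH"), ("e1", "LOW")})


class TestBetweenTest:
    def toy_rows(self):
        pairs = pd.DataFrame(
            {"fly_exon_id": ["f1", "f2", "f3"], "worm_exon_id": ["w1", "w2", "w3"]}
        )
        return paired_status_rows(pairs)

    def test_three_pair_toy(self):
        rows = self.toy_rows()
        res = between_test(
            _aset("F", {("f1", "HIGH"), ("f2", "LOW")}),
            _aset("W", {("w1", "HIGH"), ("w2", "HIGH")}),
            rows,
        )
        assert (res.statistic, res.size_a, res.size_b, res.population) == (1, 2, 2, 6)
        assert 10.0 ** res.log10_p == pytest.approx(3 / 5, rel=1e-12)

    def test_empty_fly_set(self):
        res = between_test(_aset("F", set()), _aset("W", {("w1", "HIGH")}), self.toy_rows())
        assert res.statistic == 0 and res.log10_p == 0.0

    def test_empty_pair_table_rejected(self):
        with pytest.raises(DomainError):
            paired_status_rows(pd.DataFrame({"fly_exon_id": [], "worm_exon_id": []}))

    def test_reduces_to_within_on_identity_pairing(self):
        rng = np.random.default_rng(0)
        exons = [f"e{i}" for i in range(12)]
        rows = paired_status_rows(
            pd.DataFrame({"fly_exon_id": exons, "worm_exon_id": exons})
        )
        for _ in range(20):
            def draw():
                members = set()
                for e in exons:
                    r = rng.random()
                    if r < 0.3:
                        members.add((e, "HIGH"))
                    elif r < 0.5:
                        members.add((e, "LOW"))
                return members
            a, b = _aset("A", draw()), _aset("B", draw())
            wt = within_test(a, b, n_cassette=len(exons))
            bt = between_test(a, b, rows)
            assert (wt.statistic, wt.size_a, wt.size_b, wt.population) == (
                bt.statistic, bt.size_a, bt.size_b, bt.population)
            assert wt.log10_p == bt.log10_p

    def test_one_to_many_exon_activates_every_row(self):
        # one worm exon paired with two fly exons occupies two h rows
        rows = paired_status_rows(
            pd.DataFrame({"fly_exon_id": ["f1", "f2"], "worm_exon_id": ["w1", "w1"]})
        )
        res = between_test(
            _aset("F", {("f1", "HIGH"), ("f2", "HIGH")}),
            _aset("W", {("w1", "HIGH")}),
            rows,
        )
        assert res.size_b == 2 and res.statistic == 2


class TestBuildMap:
    def test_within_same_set_map_is_symmetric(self):
        rng = np.random.default_rng(1)
        exons = [f"e{i}" for i in range(15)]
        sets = []
        for s in range(4):
            members = {
                (e, "HIGH" if rng.random() < 0.5 else "LOW")
                for e in exons
                if rng.random() < 0.4
            }
            sets.append(_aset(f"s{s}", members))
        cmap = build_map(sets, sets, "within", n_cassette=len(exons))
        assert np.allclose(cmap.scores, cmap.scores.T)
        assert np.all(cmap.scores >= 0)

    def test_single_sample_self_map(self):
        a = _aset("s", {("e1", "HIGH"), ("e2", "LOW")})
        cmap = build_map([a], [a], "within", n_cassette=3)
        expected = -within_test(a, a, 3).log10_p
        assert cmap.scores[0, 0] == expected

    def test_mode_requires_context(self):
        a = _aset("s", {("e1", "HIGH")})
        with pytest.raises(ConfigurationError):
            build_map([a], [a], "within")
        with pytest.raises(ConfigurationError):
            build_map([a], [a], "between")

    def test_relabeling_exons_leaves_scores_unchanged(self):
        rng = np.random.default_rng(5)
        exons = [f"e{i}" for i in range(10)]
        relabel = {e: f"x{i}" for i, e in enumerate(exons)}
        sets = []
        for s in range(3):
            members = {(e, "HIGH") for e in exons if rng.random() < 0.5}
            sets.append(_aset(f"s{s}", members))
        renamed = [
            _aset(a.sample_id, {(relabel[e], st) for e, st in a.members}) for a in sets
        ]
        m1 = build_map(sets, sets, "within", n_cassette=10)
        m2 = build_map(renamed, renamed, "within", n_cassette=10)
        assert np.array_equal(m1.scores, m2.scores)


class TestOrderSamples:
    def test_identical_rows_end_up_adjacent(self):
        scores = np.array([[5.0, 0.0], [0.0, 5.0], [5.0, 0.0]])
        cmap = _cmap(scores)
        order = list(order_samples(cmap, "rows"))
        assert abs(order.index(0) - order.index(2)) == 1

    def test_planted_clusters_are_contiguous(self):
        block = np.zeros((6, 6))
        block[:3, :3] = 8.0
        block[3:, 3:] = 8.0
        order = list(order_samples(_cmap(block), "rows"))
        first_cluster = {order.index(i) for i in (0, 1, 2)}
        assert max(first_cluster) - min(first_cluster) == 2

    def test_single_sample_identity(self):
        cmap = _cmap(np.array([[1.0, 2.0]]))
        assert list(order_samples(cmap, "rows")) == [0]


def _cmap(scores):
    from exoncorr.correspondence import CorrespondenceMap

    return CorrespondenceMap(
        row_labels=[f"r{i}" for i in range(scores.shape[0])],
        col_labels=[f"c{j}" for j in range(scores.shape[1])],
        scores=scores,
    )


class TestShuffleControl:
    def setup_method(self):
        rng = np.random.default_rng(9)
        exons_f = [f"f{i}" for i in range(40)]
        exons_w = [f"w{i}" for i in range(40)]
        self.rows = paired_status_rows(
            pd.DataFrame({"fly_exon_id": exons_f, "worm_exon_id": exons_w})
        )
        def sets(exons, tag):
            out = []
            for s in range(3):
                members = {
                    (e, "HIGH" if rng.random() < 0.5 else "LOW")
                    for e in exons
                    if rng.random() < 0.3
                }
                out.append(_aset(f"{tag}{s}", members))
            return out
        self.fly = sets(exons_f, "F")
        self.worm = sets(exons_w, "W")

    def test_identity_permutation_reproduces_unshuffled_map(self):
        cmap = build_map(self.fly, self.worm, "between", rows=self.rows)
        ctrl = shuffle_control(
            self.rows, self.fly, self.worm,
            NegativeControlConfig(n_shuffles=1, seed=0),
            permutations=[np.arange(self.rows.n_pairs)],
        )
        assert np.array_equal(ctrl.mean, cmap.scores)
        assert np.all(ctrl.sd == 0.0)

    def test_fixed_seed_is_reproducible(self):
        cfg = NegativeControlConfig(n_shuffles=5, seed=123)
        c1 = shuffle_control(self.rows, self.fly, self.worm, cfg)
        c2 = shuffle_control(self.rows, self.fly, self.worm, cfg)
        assert np.array_equal(c1.mean, c2.mean)
        assert np.array_equal(c1.sd, c2.sd)

    def test_calibration_pvalues_lie_in_unit_interval(self):
        ctrl = shuffle_control(
            self.rows, self.fly, self.worm, NegativeControlConfig(n_shuffles=4, seed=1)
        )
        pv = calibration_pvalues(ctrl, np.random.default_rng(0))
        assert pv.shape == ctrl.scores.shape
        assert np.all((pv >= 0) & (pv <= 1))

    def test_invalid_shuffle_count_rejected(self):
        with pytest.raises(ConfigurationError):
            NegativeControlConfig(n_shuffles=0)
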