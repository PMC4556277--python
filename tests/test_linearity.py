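"""Linearity (h, h'), DCI and dyad classification against independent oracles."""

import itertools

import numpy as np
import pytest

from domhier import (
    Sociomatrix,
    SociomatrixError,
    classify_relationships,
    dci,
    improved_h,
    landau_h,
    linearity_test,
    transpose_submission,
)

from conftest import build_matrix, linear_matrix


def random_count_matrix(rng, n, lam=1.2):
    counts = rng.poisson(lam, size=(n, n))
    np.fill_diagonal(counts, 0)
    return Sociomatrix(tuple(str(k) for k in range(n)), counts)


# ---------------------------------------------------------------------------
# dyad classification
# ---------------------------------------------------------------------------

class TestClassifyRelationships:
    def test_hand_enumeration(self, three_dyad_matrix):
        rel = classify_relationships(three_dyad_matrix)
        assert (rel.unknown, rel.one_way, rel.two_way, rel.tied) == (1, 1, 1, 0)

    def test_zero_matrix_all_unknown(self):
        rel = classify_relationships(build_matrix("ABC", {}))
        assert rel.unknown == 3 and rel.one_way == rel.two_way == 0
        assert rel.coverage == 0.0

    def test_counts_sum_to_dyads(self, rng):
        for n in (3, 5, 8):
            rel = classify_relationships(random_count_matrix(rng, n))
            assert rel.unknown + rel.one_way + rel.two_way == n * (n - 1) // 2
            assert rel.tied <= rel.two_way

    def test_percentages_one_decimal(self):
        rel = classify_relationships(build_matrix("ABC", {("A", "B"): 1}))
        assert rel.pct(rel.unknown) == 66.7


# ---------------------------------------------------------------------------
# DCI
# ---------------------------------------------------------------------------

class TestDCI:
    def test_one_way_matrix_is_one(self):
        assert dci(linear_matrix(5)).dci == 1.0

    def test_hand_formula(self, three_dyad_matrix):
        res = dci(three_dyad_matrix)
        assert (res.numerator, res.denominator) == (4, 6)
        assert res.dci == pytest.approx(4 / 6)

    def test_all_tied_is_zero(self):
        m = build_matrix("ABC", {(a, b): 2 for a in "ABC" for b in "ABC" if a != b})
        assert dci(m).dci == 0.0

    def test_all_zero_is_missing(self):
        with pytest.warns(UserWarning):
            assert dci(build_matrix("ABC", {})).dci is None

    def test_invariant_under_transposition(self, rng):
        m = random_count_matrix(rng, 6)
        assert dci(m).dci == pytest.approx(dci(transpose_submission(m)).dci)

    def test_invariant_under_permutation(self, rng):
        m = random_count_matrix(rng, 5)
        perm = list(m.labels)
        rng.shuffle(perm)
        assert dci(m).dci == pytest.approx(dci(m.permute(perm)).dci)


# ---------------------------------------------------------------------------
# Landau's h against a triad-counting oracle
# ---------------------------------------------------------------------------

def circular_triads(dom):
    """Brute-force count of cyclic triads in a complete tournament."""
    n = dom.shape[0]
    d = 0
    for i, j, k in itertools.combinations(range(n), 3):
        # a triad is cyclic iff it has no transitive order, i.e. every
        # member wins exactly once within the triad
        w = [dom[i, j] + dom[i, k], dom[j, i] + dom[j, k], dom[k, i] + dom[k, j]]
        d += sorted(w) == [1, 1, 1]
    return d


class TestLandauH:
    def test_transitive_three_is_one(self):
        assert landau_h(linear_matrix(3)) == pytest.approx(1.0)

    def test_all_unknown_is_zero(self):
        assert landau_h(build_matrix("ABC", {})) == pytest.approx(0.0)

    def test_four_cycle_tournament(self):
        # A>B>C>D>A plus A>C and B>D: two cyclic triads
        m = build_matrix(
            "ABCD",
            {("A", "B"): 1, ("B", "C"): 1, ("C", "D"): 1, ("D", "A"): 1,
             ("A", "C"): 1, ("B", "D"): 1},
        )
        dom = m.counts > m.counts.T
        d = circular_triads(dom)
        assert d == 2
        assert landau_h(m) == pytest.approx(1 - 24 * d / (4**3 - 4))

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_random_tournaments_match_triad_oracle(self, n, rng):
        for _ in range(10):
            upper = rng.integers(0, 2, size=(n, n))
            counts = np.triu(upper, 1) + np.tril(1 - upper.T, -1)
            m = Sociomatrix(tuple(str(k) for k in range(n)), counts)
            d = circular_triads(m.counts > m.counts.T)
            assert landau_h(m) == pytest.approx(1 - 24 * d / (n**3 - n))

    def test_too_small_group_rejected(self):
        with pytest.raises(SociomatrixError):
            landau_h(build_matrix("AB", {("A", "B"): 1}))


# ---------------------------------------------------------------------------
# improved h' against the unknown/tie-fill oracle
# ---------------------------------------------------------------------------

def fill_oracle(m, rng=None, n_fills=20000):
    """Expected plain h when each unknown-or-tied dyad is resolved at
    random (probability 1/2 each way).

    Enumerates all 2^u fills exactly when feasible (returning SE 0),
    otherwise Monte-Carlo averages and returns the standard error.
    """
    counts = m.counts
    n = m.n
    iu, ju = np.triu_indices(n, k=1)
    und = np.nonzero(counts[iu, ju] == counts[ju, iu])[0]
    base = np.full((n, n), 0.5)
    base[counts > counts.T] = 1.0
    base[counts < counts.T] = 0.0
    np.fill_diagonal(base, 0.0)

    def h_of(s):
        v = s.sum(axis=1)
        return 12.0 / (n**3 - n) * np.sum((v - (n - 1) / 2.0) ** 2)

    u = len(und)
    if u == 0:
        return h_of(base), 0.0
    if 2**u <= 4096:
        hs = []
        for bits in itertools.product((0.0, 1.0), repeat=u):
            s = base.copy()
            for b, k in zip(bits, und):
                s[iu[k], ju[k]] = b
                s[ju[k], iu[k]] = 1.0 - b
            hs.append(h_of(s))
        return float(np.mean(hs)), 0.0
    hs = np.empty(n_fills)
    for f in range(n_fills):
        s = base.copy()
        bits = rng.integers(0, 2, size=u)
        for b, k in zip(bits, und):
            s[iu[k], ju[k]] = float(b)
            s[ju[k], iu[k]] = 1.0 - b
        hs[f] = h_of(s)
    return float(hs.mean()), float(hs.std(ddof=1) / np.sqrt(n_fills))


class TestImprovedH:
    def test_no_unknowns_equals_h(self):
        m = linear_matrix(5)
        res = improved_h(m)
        assert res.u == 0 and res.h_prime == res.h

    def test_correction_is_nonnegative(self, rng):
        for n in (4, 6):
            m = Sociomatrix(tuple(str(k) for k in range(n)),
                            np.zeros((n, n), dtype=int))
            res = improved_h(m)
            assert res.h_prime >= res.h
            assert res.h_prime == pytest.approx(6 * res.u / (n**3 - n))

    def test_single_unknown_dyad_matches_fill_oracle(self):
        m = build_matrix(
            "ABCD",
            {("A", "B"): 3, ("A", "C"): 2, ("A", "D"): 1,
             ("B", "C"): 2, ("B", "D"): 1},  # C-D unknown
        )
        exact, se = fill_oracle(m)
        assert se == 0.0  # enumerated
        assert improved_h(m).h_prime == pytest.approx(exact, abs=1e-12)

    def test_ties_count_toward_the_correction(self):
        m = build_matrix("ABC", {("A", "B"): 2, ("B", "A"): 2, ("A", "C"): 1,
                                 ("B", "C"): 1})
        res = improved_h(m)
        assert res.u == 1
        exact, _ = fill_oracle(m)
        assert res.h_prime == pytest.approx(exact, abs=1e-12)


# ---------------------------------------------------------------------------
# randomization test
# ---------------------------------------------------------------------------

class TestLinearityTest:
    def test_seed_mandatory(self):
        with pytest.raises(ValueError):
            linearity_test(linear_matrix(4), seed=None)

    def test_all_unknown_degenerate_null_p_is_one(self):
        res = linearity_test(build_matrix("ABC", {}), n_rand=500, seed=7)
        assert res.p_right == 1.0

    def test_complete_linear_ten_is_significant(self):
        res = linearity_test(linear_matrix(10), n_rand=2000, seed=7)
        assert res.p_right <= 0.003

    def test_rerandomize_all_flag_changes_null(self):
        m = build_matrix("ABCDE", {("A", "B"): 1, ("B", "C"): 1, ("A", "C"): 1})
        kept = linearity_test(m, n_rand=500, seed=7)
        full = linearity_test(m, n_rand=500, seed=7, rerandomize_all_dyads=True)
        assert kept.h_prime == full.h_prime  # observed value unchanged
        assert kept.p_right != full.p_right

    def test_invariant_under_permutation(self, rng):
        m = random_count_matrix(rng, 6)
        perm = list(m.labels)
        rng.shuffle(perm)
        a = linearity_test(m, n_rand=800, seed=3)
        b = linearity_test(m.permute(perm), n_rand=800, seed=3)
        assert a.h_prime == pytest.approx(b.h_prime)
        assert a.p_right == pytest.approx(b.p_right, abs=0.05)

    def test_h_bounds(self, rng):
        for _ in range(20):
            m = random_count_matrix(rng, int(rng.integers(3, 9)))
            res = improved_h(m)
            assert 0.0 <= res.h <= res.h_prime <= 1.0 + 1e-12
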