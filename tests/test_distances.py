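import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import pdist_brute
from plectax import (
    Alignment,
    UNASSIGNED,
    distance_range,
    group_distance_summary,
    p_distance_matrix,
)
from plectax.distances import summary_table


def aln(*pairs):
    return Alignment(tuple(pairs))


class TestPDistance:
    @pytest.mark.parametrize("s1,s2,expected,comparable", [
        ("ACGT", "AGGT", 0.25, 4),
        ("AC-T", "ACGT", 0.0, 3),      # gap site dropped pairwise
        ("ACGT", "ACGT", 0.0, 4),
        ("ACGT", "ACRT", 0.0, 3),      # ambiguity excluded by default
    ])
    def test_pairwise_values(self, s1, s2, expected, comparable):
        dm = p_distance_matrix(aln(("x", s1), ("y", s2)))
        assert dm.pair("x", "y") == expected
        assert dm.comparable_sites[0, 1] == comparable

    def test_zero_comparable_sites_flagged(self):
        with pytest.warns(UserWarning, match="no comparable sites"):
            dm = p_distance_matrix(aln(("x", "A---"), ("y", "-CGT")))
        assert np.isnan(dm.pair("x", "y"))
        assert dm.undefined_pairs() == [("x", "y")]

    def test_brute_force_oracle_random_20mers(self, rng):
        seqs = [(f"s{i}", "".join(rng.choice(list("ACGT-N"), 20)))
                for i in range(12)]
        dm = p_distance_matrix(Alignment(tuple(seqs)))
        d_expect, comp_expect = pdist_brute(seqs)
        np.testing.assert_array_equal(dm.comparable_sites, comp_expect)
        np.testing.assert_allclose(np.nan_to_num(dm.d, nan=-1),
                                   np.nan_to_num(d_expect, nan=-1), rtol=0, atol=0)

    def test_gap_policies_agree_on_gap_free_pairs(self, rng):
        # where a pair compares at every site, the gap policies coincide
        seqs = [(f"s{i}", "".join(rng.choice(list("ACGT"), 30)))
                for i in range(4)]
        seqs += [(f"g{i}", "".join(rng.choice(list("ACGT-"), 30)))
                 for i in range(4)]
        a = Alignment(tuple(seqs))
        strict = p_distance_matrix(a, gap_policy="include-as-mismatch")
        lax = p_distance_matrix(a)
        gap_free = lax.comparable_sites == a.length
        assert gap_free.any()
        np.testing.assert_array_equal(strict.d[gap_free], lax.d[gap_free])
        # and a gap opposite a base counts as one extra mismatch
        pair = Alignment((("p", "AC-TACGT"), ("q", "ACCTACGA")))
        assert p_distance_matrix(pair).pair("p", "q") == pytest.approx(1 / 7)
        assert p_distance_matrix(pair, gap_policy="include-as-mismatch").pair(
            "p", "q") == pytest.approx(2 / 8)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGT-", min_size=15, max_size=15),
                    min_size=2, max_size=6))
    def test_matrix_invariants(self, seqs):
        a = Alignment(tuple((f"s{i}", s) for i, s in enumerate(seqs)))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dm = p_distance_matrix(a)
        d = dm.d
        assert np.allclose(np.diag(d), 0.0)
        m = ~np.isnan(d)
        assert (m == m.T).all()
        assert np.array_equal(d[m & m.T],
                              d.T[m & m.T])
        assert np.nanmin(d) >= 0.0 and np.nanmax(d) <= 1.0

    def test_permutation_invariance(self, rng):
        seqs = [(f"s{i}", "".join(rng.choice(list("ACGT"), 25)))
                for i in range(6)]
        dm = p_distance_matrix(Alignment(tuple(seqs)))
        perm = rng.permutation(6)
        dm2 = p_distance_matrix(Alignment(tuple(seqs[i] for i in perm)))
        np.testing.assert_array_equal(dm2.d, dm.d[np.ix_(perm, perm)])


class TestGroupSummary:
    def _dm(self):
        return p_distance_matrix(aln(
            ("a1", "AAAAAAAAAA"), ("a2", "AAAAAAAAAA"),
            ("b1", "AAAAAAAATT"), ("b2", "AAAAAAAGTT"),
            ("solo", "TTTTTTTTTT")))

    def test_within_and_between(self):
        dm = self._dm()
        s = group_distance_summary(dm, {"a1": "A", "a2": "A",
                                        "b1": "B", "b2": "B",
                                        "solo": UNASSIGNED})
        assert s.within["A"].mean == 0.0 and s.within["A"].max == 0.0
        assert s.within["B"].mean == pytest.approx(0.1)
        # cross pairs: a vs b distances {0.2, 0.2, 0.3, 0.3} -> mean 0.25
        assert s.between_mean("A", "B") == pytest.approx(0.25)
        assert set(s.within) == {"A", "B"}  # unassigned excluded

    def test_singleton_group_undefined_not_zero(self):
        dm = self._dm()
        s = group_distance_summary(dm, {"a1": "A", "a2": "A", "solo": "S"})
        assert not s.within["S"].defined
        assert np.isnan(s.within["S"].mean)
        tab = summary_table(s)
        assert tab.loc["S", "S"] == "n/c"

    def test_two_computations_agree(self, rng):
        seqs = [(f"s{i}", "".join(rng.choice(list("ACGT"), 40)))
                for i in range(9)]
        dm = p_distance_matrix(Alignment(tuple(seqs)))
        groups = {f"s{i}": f"G{i % 3}" for i in range(9)}
        s = group_distance_summary(dm, groups)
        for g in ("G0", "G1", "G2"):
            ix = [i for i in range(9) if i % 3 == int(g[1])]
            sub = dm.d[np.ix_(ix, ix)]
            alt = sub.sum() / (len(ix) * (len(ix) - 1))  # sum-of-submatrix / 2 pairs
            assert s.within[g].mean == pytest.approx(alt, abs=1e-12)

    def test_missing_member_raises(self):
        dm = self._dm()
        with pytest.raises(KeyError):
            group_distance_summary(dm, {"a1": "A", "ghost": "A"})


class TestDistanceRange:
    def test_single_pair(self):
        from plectax.distances import GroupDistanceSummary, WithinStats
        w = {g: WithinStats(0, 0, 1, True) for g in "AB"}
        s = GroupDistanceSummary(w, {("A", "B"): 0.1})
        assert distance_range(s) == (0.1, 0.1, ("A", "B"), ("A", "B"))

    def test_extrema_with_argmax(self):
        from plectax.distances import GroupDistanceSummary, WithinStats
        w = {g: WithinStats(0, 0, 1, True) for g in "ABC"}
        s = GroupDistanceSummary(w, {("A", "B"): 0.05, ("A", "C"): 0.18,
                                     ("B", "C"): 0.12})
        lo, hi, amin, amax = distance_range(s)
        assert (lo, amin) == (0.05, ("A", "B"))
        assert (hi, amax) == (0.18, ("A", "C"))

    def test_requires_two_groups(self):
        from plectax.distances import GroupDistanceSummary, WithinStats
        s = GroupDistanceSummary({"A": WithinStats(0, 0, 1, True)}, {})
        with pytest.raises(ValueError):
            distance_range(s)
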