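import numpy as np
import pytest

from helpers import validate_partition
from plectax import (
    Alignment,
    BootstrapConfig,
    DelimitationCriteria,
    GroupPartition,
    SimParams,
    UNASSIGNED,
    adjusted_rand,
    bootstrap_supports,
    compare_partitions,
    delimit,
    identity_labels,
    match_otus,
    overlap_identity,
    p_distance_matrix,
    simulate,
)


class TestDelimit:
    def test_two_clusters_fully_assigned(self, two_cluster_dataset):
        ds = two_cluster_dataset
        dm = p_distance_matrix(ds.coi)
        tree = bootstrap_supports(ds.coi, BootstrapConfig(replicates=100, seed=1))
        part = delimit(tree, dm)
        assert part.n_groups == 2
        assert part.unassigned() == frozenset()
        assert adjusted_rand(part, ds.truth) == 1.0
        assert validate_partition(part, tree, dm, DelimitationCriteria()) == []
        for ev in part.provenance.values():
            assert ev.support >= 99.0 and ev.within <= 0.06
            assert ev.nn_distance > ev.within

    def test_all_identical_sequences_one_group(self):
        aln = Alignment(tuple((f"s{i}", "ACGTACGTAC") for i in range(5)))
        dm = p_distance_matrix(aln)
        tree = bootstrap_supports(aln, BootstrapConfig(replicates=10, seed=0))
        part = delimit(tree, dm)
        assert part.groups() == {"HG1": frozenset(aln.ids)}

    def test_divergent_singleton_unassigned(self):
        ds = simulate(SimParams(k=2, n_per_group=(5, 1), seq_length=200,
                                d_within=0.005, d_between=0.2, seed=4))
        dm = p_distance_matrix(ds.coi)
        tree = bootstrap_supports(ds.coi, BootstrapConfig(replicates=100, seed=4))
        part = delimit(tree, dm)
        assert part.groups() == {"HG1": ds.truth.groups()["G1"]}
        assert part.unassigned() == ds.truth.groups()["G2"]

    def test_assigned_count_monotone_in_max_within(self):
        ds = simulate(SimParams(k=3, n_per_group=4, seq_length=250,
                                d_within=0.03, d_between=0.25, seed=9))
        dm = p_distance_matrix(ds.coi)
        tree = bootstrap_supports(ds.coi, BootstrapConfig(replicates=100, seed=9))
        counts = []
        for max_within in (0.005, 0.02, 0.06, 0.12, 0.3):
            part = delimit(tree, dm, DelimitationCriteria(max_within=max_within))
            counts.append(len(part.assignment) - len(part.unassigned()))
        assert counts == sorted(counts)

    def test_tree_leaf_missing_from_matrix(self, two_cluster_dataset):
        ds = two_cluster_dataset
        dm = p_distance_matrix(ds.coi).submatrix(ds.coi.ids[:-1])
        tree = bootstrap_supports(ds.coi, BootstrapConfig(replicates=5, seed=0))
        with pytest.raises(KeyError):
            delimit(tree, dm)


class TestComparePartitions:
    def test_total_collapse(self):
        fine = GroupPartition({"1": "A", "2": "A", "3": "B", "4": "B"})
        rep = compare_partitions(fine, {i: "x" for i in "1234"})
        assert rep.n_fine_groups == 2 and rep.n_coarse_labels == 1
        assert rep.n_collapsed_fine_groups == 2
        assert rep.collapse == {"x": ("A", "B")}

    def test_identity_partition_no_collapse(self):
        fine = GroupPartition({"1": "A", "2": "A", "3": "B"})
        rep = compare_partitions(fine, {"1": "u", "2": "u", "3": "v"})
        assert rep.n_collapsed_fine_groups == 0

    def test_five_of_six_collapse(self):
        ds = simulate(SimParams(seed=21))  # default collapse: 5 of 6 shared
        rep = compare_partitions(ds.truth, identity_labels(ds.ssu))
        assert rep.n_fine_groups == 6
        assert rep.n_coarse_labels == 2
        assert rep.n_collapsed_fine_groups == 5

    def test_relabeling_invariance(self):
        fine = GroupPartition({"1": "A", "2": "A", "3": "B", "4": "C"})
        coarse = {"1": "x", "2": "x", "3": "x", "4": "y"}
        rep1 = compare_partitions(fine, coarse)
        remap = {"A": "Z1", "B": "Z2", "C": "Z3"}
        fine2 = GroupPartition({k: remap[v] for k, v in fine.assignment.items()})
        coarse2 = {k: v.upper() for k, v in coarse.items()}
        rep2 = compare_partitions(fine2, coarse2)
        assert rep1.n_collapsed_fine_groups == rep2.n_collapsed_fine_groups
        assert sorted(len(v) for v in rep1.collapse.values()) == \
            sorted(len(v) for v in rep2.collapse.values())

    def test_disjoint_ids_raise(self):
        fine = GroupPartition({"1": "A"})
        with pytest.raises(ValueError):
            compare_partitions(fine, {"9": "x"})


class TestMatchOtus:
    def test_substring_identity_one(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 600))
        otu = ref[100:460]
        ident, matches, cols = overlap_identity(otu, ref)
        assert (ident, matches, cols) == (1.0, 360, 360)
        res = match_otus(Alignment((("otu1", otu),)),
                         Alignment((("ref1", ref),)))
        assert res["otu1"] == ("ref1", 1.0)

    def test_five_mismatches_below_threshold(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 360))
        q = list(ref)
        # interior mismatches: an end-free aligner may rightly trim terminal
        # mismatches, which would shorten the scored overlap
        for i in rng.choice(np.arange(20, 340), 5, replace=False):
            q[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[i]]
        ident, matches, cols = overlap_identity("".join(q), ref)
        # the 5 substitutions appear as 5 non-matching columns (a local
        # indel pair may trade one mismatch for a gap pair at equal count)
        assert cols - matches == 5
        assert ident == pytest.approx(0.986, abs=0.001)
        res = match_otus(Alignment((("o", "".join(q)),)),
                         Alignment((("r", ref),)), min_identity=0.99)
        assert res["o"][0] is None and res["o"][1] == pytest.approx(ident)

    def test_exact_reference_preferred(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 200))
        near = list(ref)
        near[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[near[50]]
        res = match_otus(Alignment((("o", ref),)),
                         Alignment((("exact", ref), ("near", "".join(near)))))
        assert res["o"][0] == "exact"

    def test_cross_check_against_edlib(self, rng):
        edlib = pytest.importorskip("edlib")
        ref = "".join(rng.choice(list("ACGT"), 500))
        q = list(ref[80:440])
        for i in rng.choice(len(q), 4, replace=False):
            q[i] = {"A": "G", "C": "T", "G": "A", "T": "C"}[q[i]]
        q = "".join(q)
        ident, matches, cols = overlap_identity(q, ref)
        res = edlib.align(q, ref, mode="HW", task="distance")
        assert cols - matches == res["editDistance"] == 4

    def test_empty_reference_set_raises(self):
        with pytest.raises(ValueError):
            match_otus(Alignment((("o", "ACGT"),)), Alignment(()))


class TestAdjustedRand:
    def test_identical_partitions(self):
        p = GroupPartition({"1": "A", "2": "A", "3": "B"})
        assert adjusted_rand(p, p) == 1.0

    def test_unassigned_breaks_perfection(self):
        truth = GroupPartition({"1": "A", "2": "A", "3": "B", "4": "B"})
        part = GroupPartition({"1": "A", "2": "A", "3": "B", "4": UNASSIGNED})
        assert adjusted_rand(part, truth) < 1.0
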