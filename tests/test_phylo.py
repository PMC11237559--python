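"""Stacked alignments, distances, NJ (with exhaustive topology oracles),
bootstrap, and clade assignment."""

import numpy as np
import pytest

from soxyprof.errors import IncomparablePairError, InvalidInputError
from soxyprof.phylo import (DistanceMatrix, StackedAlignment, assign_clades,
                            bipartitions, bootstrap_support, neighbor_joining,
                            pairwise_distance, read_newick, stack_alignments,
                            write_newick)
from soxyprof.profiles import align_to_profile

from .helpers import enumerate_topologies, least_squares_ssq, random_tree


def tree_splits(tree):
    """Bipartitions as frozensets of tip names (non-trivial only)."""
    return bipartitions(tree)


def dm_from_array(ids, arr, model="p"):
    return DistanceMatrix(ids=list(ids), data=np.asarray(arr, float),
                          model=model)


class TestStack:
    def test_width_and_no_allgap_rows(self, refs, profile):
        entries = []
        for name, seq in refs.signature_exemplars.items():
            _, trace = align_to_profile(profile, seq)
            entries.append((name, seq, trace))
        msa = stack_alignments(entries)
        assert msa.n_columns == profile.match_columns
        assert all(set(r) != {"-"} for r in msa.rows)

    def test_insertion_dropped(self, refs, profile):
        """A 3-residue insertion yields the same stacked row as its
        insertion-free twin."""
        base = refs.canonical_soxy
        with_ins = base[:70] + "WWW" + base[70:]
        _, t1 = align_to_profile(profile, base)
        _, t2 = align_to_profile(profile, with_ins)
        msa = stack_alignments([("plain", base, t1), ("ins", with_ins, t2)])
        assert msa.rows[0] == msa.rows[1]

    def test_row_rethreads_to_trace(self, refs, profile):
        seq = refs.signature_exemplars["S3"]
        _, trace = align_to_profile(profile, seq)
        msa = stack_alignments([("x", seq, trace)])
        for j, t in enumerate(trace):
            expected = seq[int(t)] if t >= 0 else "-"
            assert msa.rows[0][j] == expected

    def test_mixed_profiles_rejected(self):
        with pytest.raises(InvalidInputError):
            stack_alignments([("a", "AC", np.array([0, 1])),
                              ("b", "AC", np.array([0, 1, -1]))])


class TestDistances:
    def test_identical_rows_zero(self):
        msa = StackedAlignment(ids=["a", "b"], rows=["ACDEF", "ACDEF"])
        assert pairwise_distance(msa).data[0, 1] == 0

    def test_three_of_ten_shared(self):
        msa = StackedAlignment(ids=["a", "b"],
                               rows=["AAAAAAAAAA", "AAAAAAACDE"])
        assert pairwise_distance(msa).data[0, 1] == pytest.approx(0.3)

    def test_pairwise_deletion(self):
        msa = StackedAlignment(ids=["a", "b"], rows=["AA--AAAAAA",
                                                     "AAAA--ACDE"])
        # shared columns: 0,1,6,7,8,9 -> 3 mismatches of 6
        assert pairwise_distance(msa).data[0, 1] == pytest.approx(0.5)

    def test_poisson_correction(self):
        msa = StackedAlignment(ids=["a", "b"],
                               rows=["AAAAAAAAAA", "AAAAAAACDE"])
        d = pairwise_distance(msa, "poisson")
        assert d.data[0, 1] == pytest.approx(-np.log(0.7))
        assert d.data[0, 1] == pytest.approx(0.356675, abs=1e-5)

    def test_no_shared_columns(self):
        msa = StackedAlignment(ids=["a", "b"], rows=["AA--", "--AA"])
        with pytest.raises(IncomparablePairError):
            pairwise_distance(msa)

    def test_saturated_poisson(self):
        msa = StackedAlignment(ids=["a", "b"], rows=["AAAA", "CCCC"])
        with pytest.raises(IncomparablePairError):
            pairwise_distance(msa, "poisson")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = dm_from_array("abc", [[0, 2, 4], [2, 0, 6], [4, 6, 0]])
        tree = neighbor_joining(dm)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == {"a": 0.0, "b": 2.0, "c": 4.0}

    def test_fewer_than_three_rejected(self):
        with pytest.raises(InvalidInputError):
            neighbor_joining(dm_from_array("ab", [[0, 1], [1, 0]]))

    @pytest.mark.parametrize("case", range(100))
    def test_additive_six_taxon_recovery(self, case):
        """NJ is consistent: on additive matrices it recovers exactly the
        generating topology."""
        rng = np.random.default_rng(case)
        t, D = random_tree(6, rng)
        ids = [str(i) for i in range(6)]
        tree = neighbor_joining(dm_from_array(ids, D))
        got = {frozenset(int(x) for x in s) for s in tree_splits(tree)}
        assert got == t.splits()

    @pytest.mark.parametrize("case", range(20))
    def test_five_taxon_agreement_with_least_squares(self, case):
        """On additive 5-taxon matrices the NJ topology is the best of all
        15 topologies under OLS branch-length fitting."""
        rng = np.random.default_rng(500 + case)
        _, D = random_tree(5, rng)
        topologies = enumerate_topologies(5)
        assert len(topologies) == 15
        ssqs = [least_squares_ssq(t, D) for t in topologies]
        best = topologies[int(np.argmin(ssqs))]
        tree = neighbor_joining(dm_from_array([str(i) for i in range(5)], D))
        got = {frozenset(int(x) for x in s) for s in tree_splits(tree)}
        assert got == best.splits()
        assert min(ssqs) == pytest.approx(0.0, abs=1e-12)

    def test_all_equal_distances_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        ids = list("abcd")
        n1 = write_newick(neighbor_joining(dm_from_array(ids, D)))
        n2 = write_newick(neighbor_joining(dm_from_array(ids, D)))
        assert n1 == n2

    def test_negative_branches_clamped(self):
        rng = np.random.default_rng(3)
        # strongly non-additive matrix can produce negative NJ branches
        n = 6
        A = rng.uniform(0.01, 1.0, size=(n, n))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0)
        tree = neighbor_joining(dm_from_array([str(i) for i in range(n)], D))

        def walk(node):
            for c in node.children:
                assert c.length is None or c.length >= 0
                walk(c)

        walk(tree.root)

    def test_agrees_with_skbio_nj(self):
        """Independent cross-check against scikit-bio's NJ on a noisy
        matrix (no ties, so tie-break conventions cannot differ)."""
        import skbio

        rng = np.random.default_rng(11)
        t, D = random_tree(7, rng)
        D = D + rng.uniform(0, 0.01, size=D.shape)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        ids = [f"t{i}" for i in range(7)]
        mine = neighbor_joining(dm_from_array(ids, D))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(D, ids))
        sk_newick = str(sk_tree)
        theirs = read_newick(sk_newick)
        assert tree_splits(mine) == tree_splits(theirs)


class TestNewick:
    def test_round_trip_byte_identical(self):
        rng = np.random.default_rng(8)
        _, D = random_tree(6, rng)
        tree = neighbor_joining(
            dm_from_array([f"seq{i}" for i in range(6)], D))
        text = write_newick(tree)
        assert write_newick(read_newick(text)) == text
        assert text.endswith(";\n")


@pytest.fixture(scope="module")
def clade_msa(refs, profile):
    entries = []
    rng = np.random.default_rng(2)
    from soxyprof.synthetic import perturb_sequence
    for name, seq in refs.signature_exemplars.items():
        _, trace = align_to_profile(profile, seq)
        entries.append((f"REF_{name}", seq, trace))
        for k in range(3):
            mut = perturb_sequence(seq, 92, int(rng.integers(2 ** 31)),
                                   protected=refs.arm_span)
            _, tr = align_to_profile(profile, mut)
            entries.append((f"{name}_{k}", mut, tr))
    return stack_alignments(entries)


class TestBootstrap:

    def test_single_replicate_supports_binary(self, clade_msa):
        boots = bootstrap_support(clade_msa, replicates=1, seed=5)
        assert set(boots.supports.values()) <= {1.0}

    def test_seed_determinism(self, clade_msa):
        a = bootstrap_support(clade_msa, replicates=20, seed=9)
        b = bootstrap_support(clade_msa, replicates=20, seed=9)
        assert a.supports == b.supports

    def test_supports_are_frequencies(self, clade_msa):
        boots = bootstrap_support(clade_msa, replicates=20, seed=9)
        assert all(0 < v <= 1 for v in boots.supports.values())


class TestAssignClades:
    def test_exemplar_assigned_to_own_clade(self):
        D = np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0.0]])
        dm = dm_from_array(["e1", "x", "e2"], D)
        out = assign_clades(dm, {1: ["e1"], 2: ["e2"]})
        assert out.assignments == {"e1": 1, "x": 1, "e2": 2}

    def test_equidistant_tie_to_lowest_clade(self):
        D = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0.0]])
        dm = dm_from_array(["e1", "e2", "x"], D)
        out = assign_clades(dm, {1: ["e1"], 2: ["e2"]})
        assert out.assignments["x"] == 1

    def test_missing_exemplar_rejected(self):
        dm = dm_from_array(["a", "b"], [[0, 1], [1, 0]])
        with pytest.raises(InvalidInputError):
            assign_clades(dm, {1: ["a"], 2: ["zz"]})

    def test_monophyly_flags_on_clean_tree(self):
        # two clear clusters
        ids = ["a1", "a2", "b1", "b2"]
        D = np.array([[0, .1, 1, 1], [.1, 0, 1, 1],
                      [1, 1, 0, .1], [1, 1, .1, 0.0]])
        dm = dm_from_array(ids, D)
        tree = neighbor_joining(dm)
        out = assign_clades(dm, {1: ["a1"], 2: ["b1"]}, tree)
        assert out.monophyly == {1: True, 2: True}
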