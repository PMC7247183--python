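import math

import networkx as nx
import numpy as np
import pytest

from asrfam import jtt
from asrfam.phylo import (
    MSA,
    DistanceMatrix,
    bootstrap_supports,
    compute_distances,
    extract_groups,
    nj_tree,
    progressive_align,
)
from asrfam.seqio import SequenceRecord


def random_additive_matrix(rng, n):
    """Random unrooted tree -> its exact path metric (an additive matrix)."""
    g = nx.Graph()
    g.add_node("I0")
    for i in range(3):
        g.add_edge("I0", f"L{i}", weight=rng.uniform(0.1, 1.0))
    nxt = 1
    for i in range(3, n):
        u, v, dat = list(g.edges(data=True))[rng.integers(0, g.number_of_edges())]
        w = dat["weight"]
        g.remove_edge(u, v)
        mid = f"I{nxt}"
        nxt += 1
        a = rng.uniform(0.05, 0.95) * w
        g.add_edge(u, mid, weight=a)
        g.add_edge(mid, v, weight=w - a)
        g.add_edge(mid, f"L{i}", weight=rng.uniform(0.1, 1.0))
    leaves = [f"L{i}" for i in range(n)]
    sp = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    d = np.array([[sp[a][b] for b in leaves] for a in leaves])
    return DistanceMatrix(leaves, (d + d.T) / 2)


class TestNeighborJoining:
    def test_reproduces_additive_matrices_exactly(self, rng):
        """Four-point oracle: 100 random additive 4-10 taxon matrices."""
        for _ in range(100):
            dm = random_additive_matrix(rng, int(rng.integers(4, 11)))
            tree = nj_tree(dm)
            back = tree.leaf_distance_matrix()
            pos = {n: i for i, n in enumerate(back.ids)}
            perm = [pos[n] for n in dm.ids]
            assert np.abs(back.d[np.ix_(perm, perm)] - dm.d).max() < 1e-9

    def test_three_taxa_solves_three_point_equations(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_ultrametric_cherries_joined_first(self):
        # two clear cherries (a,b) and (c,d)
        d = np.array(
            [
                [0.0, 0.2, 1.0, 1.0],
                [0.2, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.2],
                [1.0, 1.0, 0.2, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(list("abcd"), d))
        sides = {frozenset(b) for b in tree.bipartitions()}
        assert frozenset({"a", "b"}) in sides or frozenset({"c", "d"}) in sides

    def test_topology_agrees_with_skbio(self, rng):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as skbio_nj

        dm = random_additive_matrix(rng, 8)
        mine = nj_tree(dm)
        ref = skbio_nj(SkDM(dm.d, dm.ids))
        allset = frozenset(dm.ids)

        def norm(bips):
            out = set()
            for b in bips:
                if 1 < len(b) < len(allset) - 1:
                    out.add(min(b, allset - b, key=lambda s: (len(s), sorted(s))))
            return out

        ref_bips = norm(
            {frozenset(t.name for t in node.tips()) for node in ref.non_tips()}
        )
        assert norm(set(mine.bipartitions())) == ref_bips

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))


class TestDistances:
    def test_identical_rows_zero(self):
        msa = MSA([SequenceRecord("a", "MKVL"), SequenceRecord("b", "MKVL")])
        assert compute_distances(msa, "p").d[0, 1] == 0.0

    def test_poisson_closed_form(self):
        row1 = "A" * 100
        row2 = "A" * 90 + "R" * 10
        msa = MSA([SequenceRecord("a", row1), SequenceRecord("b", row2)])
        assert compute_distances(msa, "p").d[0, 1] == pytest.approx(0.10)
        assert compute_distances(msa, "poisson").d[0, 1] == pytest.approx(
            -math.log(0.9), abs=1e-9
        )

    def test_pairwise_deletion_of_gap_columns(self):
        msa = MSA([SequenceRecord("a", "MK-L"), SequenceRecord("b", "MKV-")])
        # only columns 1,2 comparable; both match
        assert compute_distances(msa, "p").d[0, 1] == 0.0

    def test_no_comparable_columns_named_in_error(self):
        msa = MSA([SequenceRecord("a", "M-"), SequenceRecord("b", "-K")])
        with pytest.raises(ValueError, match="a.*b"):
            compute_distances(msa, "p")

    def test_jtt_ml_recovers_simulated_branch_length(self):
        """Sequences simulated under JTT at t=0.3: mean estimate within 10%."""
        rng = np.random.default_rng(42)
        P = jtt.transition_matrix(0.3)
        estimates = []
        for _ in range(50):
            anc = rng.choice(20, p=jtt.FREQUENCIES, size=500)
            der = np.array([rng.choice(20, p=P[a]) for a in anc])
            msa = MSA(
                [
                    SequenceRecord("x", "".join(jtt.AA_ORDER[i] for i in anc)),
                    SequenceRecord("y", "".join(jtt.AA_ORDER[i] for i in der)),
                ]
            )
            estimates.append(compute_distances(msa, "jtt_ml").d[0, 1])
        assert np.mean(estimates) == pytest.approx(0.3, rel=0.10)


class TestProgressiveAlign:
    def test_identical_sequences_gapless(self):
        msa = progressive_align(
            [SequenceRecord("a", "MKVLHEAGRT"), SequenceRecord("b", "MKVLHEAGRT")]
        )
        assert all("-" not in r.residues for r in msa.records)

    def test_planted_insertion_creates_single_gap_block(self):
        core = "MKVLHEAGRTWDNQPS"
        ins = core[:8] + "WWWWW" + core[8:]
        msa = progressive_align(
            [
                SequenceRecord("a", core),
                SequenceRecord("b", core),
                SequenceRecord("c", ins),
            ]
        )
        rows = {r.id: r.residues for r in msa.records}
        assert rows["a"].count("-") == 5
        assert "-----" in rows["a"] and "-----" in rows["b"]
        assert "-" not in rows["c"]

    def test_degapping_recovers_inputs(self, paper_shaped):
        msa = progressive_align(paper_shaped.proteome)
        originals = {r.id: r.residues for r in paper_shaped.proteome}
        for i, rec in enumerate(msa.records):
            assert msa.degapped(i) == originals[rec.id]

    def test_identical_group_aligns_gapless(self, paper_shaped):
        group6 = [p for p in paper_shaped.proteome if p.id.startswith("syn10")]
        assert len(group6) == 7
        msa = progressive_align(group6)
        assert all("-" not in r.residues for r in msa.records)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            progressive_align([SequenceRecord("a", "MKV")])


@pytest.fixture(scope="module")
def two_clade_msa():
    rows = [SequenceRecord(f"a{i}", "MKVLHEAG" * 5) for i in range(3)]
    rows += [SequenceRecord(f"b{i}", "WWTTRRSS" * 5) for i in range(3)]
    return MSA(rows)


class TestBootstrap:
    def test_clean_separation_gets_full_support(self, two_clade_msa):
        tree = bootstrap_supports(two_clade_msa, n_reps=50, seed=5)
        supports = [n.support for n in tree.internal_edges()]
        assert supports and all(s == 100.0 for s in supports)

    def test_fixed_seed_reproducible(self, two_clade_msa):
        t1 = bootstrap_supports(two_clade_msa, n_reps=30, seed=9)
        t2 = bootstrap_supports(two_clade_msa, n_reps=30, seed=9)
        s1 = sorted(n.support for n in t1.internal_edges())
        s2 = sorted(n.support for n in t2.internal_edges())
        assert s1 == s2

    def test_supports_within_sampling_envelope(self, rng):
        """200 vs 1000 replicates differ < 10 points on well-supported edges."""
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))

        def mutate(s, k):
            s = list(s)
            for pos in rng.choice(len(s), size=k, replace=False):
                s[pos] = str(rng.choice([c for c in "ACDEFGHIKLMNPQRSTVWY" if c != s[pos]]))
            return "".join(s)

        cladeA = mutate(base, 60)
        cladeB = mutate(base, 60)
        rows = [SequenceRecord(f"a{i}", mutate(cladeA, 5)) for i in range(4)]
        rows += [SequenceRecord(f"b{i}", mutate(cladeB, 5)) for i in range(4)]
        msa = MSA(rows)
        t_small = bootstrap_supports(msa, n_reps=200, seed=3)
        t_big = bootstrap_supports(msa, n_reps=1000, seed=4)
        sup_small = {side: n.support for side, n in t_small.bipartitions().items()}
        sup_big = {side: n.support for side, n in t_big.bipartitions().items()}
        shared = set(sup_small) & set(sup_big)
        assert shared
        for side in shared:
            if sup_big[side] > 90:
                assert abs(sup_big[side] - sup_small[side]) < 10

    def test_invalid_rep_count_rejected(self, two_clade_msa):
        with pytest.raises(ValueError):
            bootstrap_supports(two_clade_msa, n_reps=0)


class TestExtractGroups:
    def test_k1_single_group(self, rng):
        tree = nj_tree(random_additive_matrix(rng, 6))
        ga = extract_groups(tree, k=1)
        assert len(set(ga.groups.values())) == 1
        assert len(ga.groups) == 6

    def test_partition_property(self, rng):
        tree = nj_tree(random_additive_matrix(rng, 10))
        ga = extract_groups(tree, k=3)
        assert sorted(ga.groups) == sorted(tree.leaf_names())
        assert len(set(ga.groups.values())) == 3

    def test_planted_subfamilies_recovered(self, paper_shaped):
        """cut_k(6) on the paper-shaped family recovers the 6 planted groups."""
        msa = progressive_align(paper_shaped.proteome)
        tree = nj_tree(compute_distances(msa, "poisson"))
        ga = extract_groups(tree, k=6)
        truth = dict(
            zip(paper_shaped.truth["genes"].gene_id, paper_shaped.truth["genes"].group)
        )
        for members in ga.partition().values():
            assert len({truth[m] for m in members}) == 1
        assert len(ga.partition()) == 6

    def test_reference_mode_assigns_nearest_label(self, rng):
        dm = random_additive_matrix(rng, 6)
        tree = nj_tree(dm)
        ref = {"L0": "x", "L5": "y"}
        ga = extract_groups(tree, reference=ref)
        assert ga.groups["L0"] == "x"
        assert ga.groups["L5"] == "y"
        assert set(ga.groups.values()) <= {"x", "y"}

    def test_k_exceeding_leaves_rejected(self, rng):
        tree = nj_tree(random_additive_matrix(rng, 5))
        with pytest.raises(ValueError):
            extract_groups(tree, k=6)


def test_newick_contains_all_leaves_and_supports(rng):
    tree = nj_tree(random_additive_matrix(rng, 6))
    for node in tree.internal_edges():
        node.support = 87.0
    nwk = tree.newick()
    for name in tree.leaf_names():
        assert name in nwk
    assert "87" in nwk
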