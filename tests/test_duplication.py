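import numpy as np
import pytest

from asrfam.duplication import (
    HomologPair,
    assign_homoeologs,
    classify_duplications,
    find_homolog_pairs,
    summarize_chromosomes,
)
from asrfam.seqio import GeneLocus, SequenceRecord, family_table_loci


def make_pair(a, b, same=True, sep=None, ident=100.0):
    return HomologPair(a, b, ident, 1e-40, same, sep)


def loci_at(chrom, positions, span=1000, prefix="g"):
    return [
        GeneLocus(f"{prefix}{i + 1}", chrom, p + 1, p + span)
        for i, p in enumerate(positions)
    ]


class TestFindHomologPairs:
    def test_identical_proteins_on_different_chromosomes(self, make_protein):
        p = make_protein(100, "g1")
        q = SequenceRecord("g2", p.residues)
        loci = [GeneLocus("g1", "3A", 100, 1100), GeneLocus("g2", "3B", 100, 1100)]
        (pair,) = find_homolog_pairs([p, q], loci)
        assert not pair.same_chromosome
        assert pair.identity_pct == 100.0

    def test_70pct_identity_below_threshold(self, rng):
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        mutated = list(base)
        for pos in rng.choice(100, size=30, replace=False):
            mutated[pos] = str(
                rng.choice([c for c in "ACDEFGHIKLMNPQRSTVWY" if c != mutated[pos]])
            )
        loci = [GeneLocus("a", "1A", 1, 300), GeneLocus("b", "1A", 5000, 5300)]
        pairs = find_homolog_pairs(
            [SequenceRecord("a", base), SequenceRecord("b", "".join(mutated))], loci
        )
        assert pairs == []

    def test_unanchored_pair_flagged(self, make_protein):
        p = make_protein(100, "g1")
        q = SequenceRecord("g2", p.residues)
        loci = [GeneLocus("g1", "3A", 100, 1100), GeneLocus("g2", "Un", 100, 1100)]
        (pair,) = find_homolog_pairs([p, q], loci)
        assert pair.unanchored

    def test_order_invariance(self, small_genome):
        _, syn = small_genome
        fam = [p for p in syn.proteome if not p.id.startswith("decoy")]
        fwd = find_homolog_pairs(fam, syn.loci)
        rev = find_homolog_pairs(fam[::-1], syn.loci[::-1])
        assert {(p.gene_a, p.gene_b) for p in fwd} == {(p.gene_a, p.gene_b) for p in rev}


class TestClassify:
    def test_chain_of_three_within_window(self):
        # genes at 0, 100 kb, 190 kb: consecutive gaps ~99 kb and ~89 kb
        loci = loci_at("3A", [0, 100_000, 190_000])
        pairs = [
            make_pair("g1", "g2", sep=99_000),
            make_pair("g2", "g3", sep=89_000),
            make_pair("g1", "g3", sep=189_000),
        ]
        arrays, segmental = classify_duplications(pairs, loci)
        assert len(arrays) == 1
        assert arrays[0].members == ["g1", "g2", "g3"]
        assert arrays[0].n_pairs == 2
        assert segmental == []

    def test_gap_beyond_150kb_splits(self):
        loci = loci_at("3A", [0, 200_000])
        pairs = [make_pair("g1", "g2", sep=199_000)]
        arrays, _ = classify_duplications(pairs, loci)
        assert arrays == []

    def test_cross_chromosome_pair_is_segmental(self):
        loci = [GeneLocus("g1", "2A", 1, 1000), GeneLocus("g2", "2D", 1, 1000)]
        pairs = [make_pair("g1", "g2", same=False, sep=None)]
        arrays, segmental = classify_duplications(pairs, loci)
        assert arrays == []
        assert len(segmental) == 1
        assert {segmental[0].chromosome_a, segmental[0].chromosome_b} == {"2A", "2D"}

    def test_intervening_gene_breaks_chain_with_annotation(self):
        loci = loci_at("3A", [0, 100_000])
        pairs = [make_pair("g1", "g2", sep=99_000)]
        intruder = [GeneLocus("x", "3A", 50_000, 51_000)]
        arrays, _ = classify_duplications(pairs, loci, annotation=loci + intruder)
        assert arrays == []
        arrays2, _ = classify_duplications(pairs, loci, annotation=loci)
        assert len(arrays2) == 1

    def test_planted_arrays_recovered_across_seeded_genomes(self):
        """Precision = recall = 1 over 20 genomes; >150 kb gaps always split."""
        from asrfam.synthetic_data import SyntheticConfig, generate_family_genome

        for seed in range(20):
            cfg = SyntheticConfig(
                seed=1000 + seed, n_triads=2, tandem_array_sizes=(3, 2), n_decoys=0
            )
            syn = generate_family_genome(cfg)
            fam = [p for p in syn.proteome if not p.id.startswith("decoy")]
            pairs = find_homolog_pairs(fam, syn.loci)
            arrays, segmental = classify_duplications(pairs, syn.loci)
            found_pairs = {
                (a.members[i], a.members[i + 1])
                for a in arrays
                for i in range(len(a.members) - 1)
            }
            expected_pairs = set()
            for _, row in syn.truth["arrays"].iterrows():
                members = row["members"].split(",")
                spacings = [int(x) for x in row["spacings_bp"].split(",")]
                for i, sp in enumerate(spacings):
                    if sp <= 150_000:
                        expected_pairs.add((members[i], members[i + 1]))
            assert found_pairs == expected_pairs, f"seed {seed}"
            # triads appear as cross-chromosome segmental pairs
            seg_genes = {g for s in segmental for g in (s.gene_a, s.gene_b)}
            triad_genes = {
                g
                for _, row in syn.truth["triads"].iterrows()
                for g in (row["A"], row["B"], row["D"])
            }
            assert triad_genes <= seg_genes

    def test_arrays_partition_members(self, small_genome):
        _, syn = small_genome
        fam = [p for p in syn.proteome if not p.id.startswith("decoy")]
        pairs = find_homolog_pairs(fam, syn.loci)
        arrays, _ = classify_duplications(pairs, syn.loci)
        seen = []
        for a in arrays:
            seen.extend(a.members)
        assert len(seen) == len(set(seen))
        for a in arrays:
            assert all(s <= 150_000 for s in a.separations)


class TestSummarize:
    def test_family_table_counts(self, family_table):
        summ = summarize_chromosomes(family_table_loci(family_table))
        chrom = summ["chromosomes"].set_index("chromosome")
        assert chrom.loc["3A", "count"] == 12
        assert chrom.loc["3B", "count"] == 6
        assert chrom.loc["3D", "count"] == 8
        sub = summ["subgenomes"].set_index("subgenome")
        assert sub.loc["A", "count"] == 14
        assert sub.loc["B", "count"] == 8
        assert sub.loc["D", "count"] == 10
        grp = summ["chromosome_groups"].set_index("chromosome_group")
        assert grp.loc["3", "count"] == 26
        assert grp.loc["3", "pct"] == pytest.approx(78.8)

    def test_family_table_spans(self, family_table):
        summ = summarize_chromosomes(family_table_loci(family_table))
        chrom = summ["chromosomes"].set_index("chromosome")
        assert chrom.loc["3A", "span_kb"] == pytest.approx(579.8)
        assert chrom.loc["3D", "span_kb"] == pytest.approx(102.5)

    def test_percentages_sum_to_100(self, family_table):
        summ = summarize_chromosomes(family_table_loci(family_table))
        assert summ["chromosomes"]["pct"].sum() == pytest.approx(100, abs=0.25)

    def test_single_gene(self):
        summ = summarize_chromosomes([GeneLocus("g", "1A", 100, 2099)])
        row = summ["chromosomes"].iloc[0]
        assert row["count"] == 1
        assert row["span_kb"] == pytest.approx(2.0)


class TestHomoeologs:
    def test_identical_triplet_one_complete_group(self, make_protein):
        p = make_protein(100, "gA")
        loci = [
            GeneLocus("gA", "4A", 1, 1000),
            GeneLocus("gB", "4B", 1, 1000),
            GeneLocus("gD", "4D", 1, 1000),
        ]
        prots = [p, SequenceRecord("gB", p.residues), SequenceRecord("gD", p.residues)]
        pairs = find_homolog_pairs(prots, loci)
        (group,) = assign_homoeologs(pairs, loci)
        assert group.is_complete
        assert group.expansion_copies == []

    def test_bd_only_pair_missing_a_slot(self, make_protein):
        p = make_protein(100, "gB")
        loci = [GeneLocus("gB", "3B", 1, 1000), GeneLocus("gD", "3D", 1, 1000)]
        prots = [p, SequenceRecord("gD", p.residues)]
        (group,) = assign_homoeologs(find_homolog_pairs(prots, loci), loci)
        assert set(group.members) == {"B", "D"}
        assert not group.is_complete

    def test_planted_triads_and_expansion_copies(self, small_genome):
        _, syn = small_genome
        fam = [p for p in syn.proteome if not p.id.startswith("decoy")]
        pairs = find_homolog_pairs(fam, syn.loci)
        groups = assign_homoeologs(pairs, syn.loci)
        complete = [g for g in groups if g.is_complete]
        assert len(complete) >= len(syn.truth["triads"])
        for _, row in syn.truth["triads"].iterrows():
            matches = [
                g
                for g in groups
                if {row["A"], row["B"], row["D"]}
                <= set(g.members.values()) | set(g.expansion_copies)
            ]
            assert len(matches) == 1
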