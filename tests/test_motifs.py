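import numpy as np
import pytest

from asrfam.motifs import (
    PWM,
    Promoter,
    discover_motifs,
    extract_promoters,
    read_meme_minimal,
    scan_pwm,
    write_meme_minimal,
    _score_distribution,
    _score_table,
)
from asrfam.seqio import GeneLocus, SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture()
def sharp_pwm():
    counts = np.array(
        [[20, 0, 0, 0], [0, 20, 0, 0], [0, 0, 20, 0], [0, 0, 0, 20],
         [20, 0, 0, 0], [0, 20, 0, 0], [0, 0, 20, 0], [20, 0, 0, 0]]
    )
    return PWM.from_counts("TF1", "ACGT", counts, 0.1)


class TestPromoters:
    def test_plus_strand_arithmetic(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        genome = {"1A": SequenceRecord("1A", seq, "dna")}
        loci = [GeneLocus("g", "1A", 3000, 4000, "+")]
        prom = extract_promoters(genome, loci)["g"]
        assert prom.length == 2000
        assert not prom.truncated
        assert prom.sequence.residues == seq[999:2999]

    def test_truncation_at_contig_edge(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        genome = {"1A": SequenceRecord("1A", seq, "dna")}
        loci = [GeneLocus("g", "1A", 500, 1500, "+")]
        prom = extract_promoters(genome, loci)["g"]
        assert prom.length == 499
        assert prom.truncated

    def test_minus_strand_site_appears_forward(self, rng, sharp_pwm):
        site = sharp_pwm.consensus
        up = "".join(rng.choice(list("ACGT"), size=500))
        up = up[:100] + site + up[100 + len(site):]
        rc = str(SequenceRecord("x", up, "dna").reverse_complement().residues)
        body = "".join(rng.choice(list("ACGT"), size=1000))
        seq = body + rc  # minus-strand gene ends at len(body)
        genome = {"1A": SequenceRecord("1A", seq, "dna")}
        loci = [GeneLocus("g", "1A", 500, 1000, "-")]
        prom = extract_promoters(genome, loci, length=500)["g"]
        assert site in prom.sequence.residues
        assert prom.sequence.residues.find(site) == 100

    def test_missing_chromosome_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            extract_promoters({}, [GeneLocus("g", "9Z", 10, 20, "+")])


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(0)
    consensus = "HDWKQRAE"
    seqs, offsets = [], {}
    for i in range(30):
        s = list(rng.choice(list(AA), size=60))
        off = int(rng.integers(0, 52))
        word = list(consensus)
        if rng.random() < 0.5:  # up to one mutation
            p = int(rng.integers(0, 8))
            word[p] = str(rng.choice(list(AA)))
        s[off : off + 8] = word
        offsets[f"s{i}"] = off
        seqs.append(SequenceRecord(f"s{i}", "".join(s)))
    return consensus, seqs, offsets


class TestDiscovery:
    def test_planted_8mer_recovered_with_high_site_recall(self, planted):
        consensus, seqs, offsets = planted
        models = discover_motifs(seqs, max_motifs=3, width_range=(6, 12), seed=1)
        assert models
        top = models[0]
        assert top.pwm.consensus == consensus
        recall = sum(1 for sid, off in top.sites if off == offsets[sid]) / len(seqs)
        assert recall >= 0.9

    def test_repeated_motif_sequence_gives_near_onehot_pwm(self):
        seqs = [SequenceRecord(f"r{i}", "HDWKQRAE") for i in range(10)]
        models = discover_motifs(seqs, max_motifs=1, width_range=(8, 8))
        pwm = models[0].pwm
        assert pwm.consensus == "HDWKQRAE"
        # one-hot up to the +0.1 pseudocount: 10 sites -> 10.1/12 per cell
        assert pwm.matrix.max(axis=1).min() > 10.0 / 12.0

    def test_random_sequences_yield_no_motif(self):
        rng = np.random.default_rng(12)
        seqs = [
            SequenceRecord(f"r{i}", "".join(rng.choice(list(AA), size=60)))
            for i in range(30)
        ]
        assert discover_motifs(seqs, max_motifs=5, width_range=(6, 12), seed=1) == []

    def test_reported_motifs_do_not_overlap(self, planted):
        _, seqs, _ = planted
        models = discover_motifs(seqs, max_motifs=5, width_range=(6, 10), seed=1)
        claimed: dict[str, set] = {}
        for m in models:
            for sid, off in m.sites:
                span = set(range(off, off + m.width))
                assert not (claimed.get(sid, set()) & span)
                claimed.setdefault(sid, set()).update(span)

    def test_invalid_width_range_rejected(self, planted):
        _, seqs, _ = planted
        with pytest.raises(ValueError):
            discover_motifs(seqs, width_range=(1, 5))
        with pytest.raises(ValueError):
            discover_motifs(seqs, width_range=(100, 200))


class TestScan:
    def test_planted_consensus_site_found_once(self, rng, sharp_pwm):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        seq = seq[:100] + sharp_pwm.consensus + seq[108:]
        proms = {"g1": Promoter("g1", SequenceRecord("g1", seq, "dna"), 300, False, "+")}
        hits, counts = scan_pwm(proms, [sharp_pwm], p_max=1e-4)
        strong = [h for h in hits if h.position == 101 and h.strand == "+"]
        assert len(strong) == 1
        assert counts.loc["g1", "TF1"] == len(hits)

    def test_hits_match_brute_force_rescan(self, rng, sharp_pwm):
        """Every window rescored by an independent scorer: identical hits."""
        seq = "".join(rng.choice(list("ACGT"), size=500))
        seq = seq[:50] + sharp_pwm.consensus + seq[58:]
        proms = {"g": Promoter("g", SequenceRecord("g", seq, "dna"), 500, False, "+")}
        hits, _ = scan_pwm(proms, [sharp_pwm], p_max=1e-3)
        table = _score_table(sharp_pwm, 100)
        lo, tail = _score_distribution(table, sharp_pwm.background)
        idx = {c: i for i, c in enumerate("ACGT")}
        rc = sharp_pwm.reverse_complement()
        table_rc = _score_table(rc, 100)
        expected = set()
        w = sharp_pwm.width
        for strand, tab in (("+", table), ("-", table_rc)):
            for j in range(len(seq) - w + 1):
                window = seq[j : j + w]
                s = sum(int(tab[p, idx[c]]) for p, c in enumerate(window))
                pv = tail[s - lo] if 0 <= s - lo < len(tail) else (1.0 if s < lo else 0.0)
                if pv <= 1e-3:
                    expected.add((j + 1, strand, s))
        got = {(h.position, h.strand, int(round(h.score * 100))) for h in hits}
        assert got == expected

    def test_palindromic_pwm_hits_both_strands(self):
        counts = np.zeros((6, 4))
        for i, c in enumerate("ACGCGT"):  # reverse complement of itself
            counts[i, "ACGT".index(c)] = 20
        pwm = PWM.from_counts("pal", "ACGT", counts, 0.1)
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        seq = seq[:80] + "ACGCGT" + seq[86:]
        proms = {"g": Promoter("g", SequenceRecord("g", seq, "dna"), 200, False, "+")}
        hits, _ = scan_pwm(proms, [pwm], p_max=1e-3)
        pos = {(h.position, h.strand) for h in hits}
        assert (81, "+") in pos and (81, "-") in pos

    def test_pvalue_matches_monte_carlo(self, rng):
        """Exact DP tail probabilities vs 1e5 background draws, 5 PWMs."""
        for t in range(5):
            w = int(rng.integers(5, 9))
            counts = rng.integers(0, 12, size=(w, 4))
            pwm = PWM.from_counts(f"m{t}", "ACGT", counts, 0.5)
            table = _score_table(pwm, 100)
            lo, tail = _score_distribution(table, pwm.background)
            n = 100_000
            draws = np.array(
                [rng.choice(4, p=pwm.background, size=n) for _ in range(w)]
            ).T
            scores = table[np.arange(w)[None, :], draws].sum(axis=1)
            threshold = int(np.quantile(scores, 0.99))
            p_exact = tail[threshold - lo]
            p_mc = float((scores >= threshold).mean())
            se = np.sqrt(p_exact * (1 - p_exact) / n)
            assert abs(p_mc - p_exact) <= 3 * se + 1e-9

    def test_alphabet_mismatch_rejected(self, sharp_pwm):
        prot = PWM.from_counts("p", AA, np.ones((4, 20)), 0.1)
        proms = {"g": Promoter("g", SequenceRecord("g", "ACGTACGTACGT", "dna"), 12, False, "+")}
        with pytest.raises(ValueError, match="DNA"):
            scan_pwm(proms, [prot])


def test_meme_minimal_round_trip(tmp_path, sharp_pwm):
    write_meme_minimal([sharp_pwm], tmp_path / "m.meme")
    (back,) = read_meme_minimal(tmp_path / "m.meme")
    assert back.width == sharp_pwm.width
    assert back.consensus == sharp_pwm.consensus
    assert np.allclose(back.matrix, sharp_pwm.matrix, atol=1e-4)
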