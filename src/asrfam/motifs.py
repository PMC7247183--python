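"""De novo protein motif discovery (ZOOPS EM) and promoter PWM scanning.

Discovery fits a zero-or-one-occurrence-per-sequence (ZOOPS) mixture by
expectation-maximization, initialized from the most enriched exact word so
runs are deterministic; widths are chosen by a BIC-style penalized
likelihood and accepted motifs mask their sites before the next round.

Scanning scores every promoter window on both strands with log-odds
(log2 p/bg) and computes each score's p-value under the background exactly
by dynamic-programming convolution of the per-column score distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqio import SequenceRecord, GeneLocus

DNA = "ACGT"
PROTEIN = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "PWM",
    "MotifModel",
    "Promoter",
    "TFBSHit",
    "extract_promoters",
    "discover_motifs",
    "scan_pwm",
    "read_jaspar",
    "read_meme_minimal",
    "write_meme_minimal",
]


@dataclass
class PWM:
    name: str
    alphabet: str  # "ACGT" or the 20 amino acids
    matrix: np.ndarray  # width x |alphabet| probabilities, rows sum to 1
    background: np.ndarray
    pseudocount: float = 0.1

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.alphabet):
            raise ValueError("matrix shape does not match alphabet")
        if (self.matrix <= 0).any():
            raise ValueError("probabilities must be positive (apply a pseudocount)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join(self.alphabet[k] for k in np.argmax(self.matrix, axis=1))

    def reverse_complement(self) -> "PWM":
        if self.alphabet != DNA:
            raise ValueError("reverse complement is DNA-only")
        comp = [3, 2, 1, 0]  # A<->T, C<->G in "ACGT"
        return PWM(
            self.name + "_rc", DNA, self.matrix[::-1, comp],
            self.background[comp], self.pseudocount,
        )

    @classmethod
    def from_counts(cls, name, alphabet, counts, pseudocount=0.1, background=None):
        counts = np.asarray(counts, dtype=float) + pseudocount
        matrix = counts / counts.sum(axis=1, keepdims=True)
        if background is None:
            background = np.full(len(alphabet), 1.0 / len(alphabet))
        return cls(name, alphabet, matrix, np.asarray(background, float), pseudocount)


@dataclass
class MotifModel:
    pwm: PWM
    sites: list[tuple[str, int]]  # (sequence_id, 0-based offset)
    log_likelihood: float
    score: float  # penalized likelihood gain over the background model

    @property
    def width(self) -> int:
        return self.pwm.width


@dataclass
class Promoter:
    gene_id: str
    sequence: SequenceRecord
    length: int
    truncated: bool
    strand: str


def extract_promoters(
    genome: dict[str, SequenceRecord] | list[SequenceRecord],
    loci: list[GeneLocus],
    length: int = 2000,
) -> dict[str, Promoter]:
    """Strand-corrected upstream promoter sequences, truncated at contig edges.

    Plus strand: [start-length, start-1]; minus strand: reverse complement
    of [end+1, end+length]. Coordinates 1-based inclusive at this boundary.
    """
    if isinstance(genome, list):
        genome = {r.id: r for r in genome}
    chrom_of = {cid.removeprefix("chr"): rec for cid, rec in genome.items()}
    out: dict[str, Promoter] = {}
    for locus in loci:
        rec = chrom_of.get(locus.chromosome.removeprefix("chr"))
        if rec is None:
            raise ValueError(f"chromosome {locus.chromosome!r} absent from genome")
        seq = rec.residues
        if locus.strand == "-":
            lo = locus.end_bp  # 0-based slice start = end_bp
            hi = min(len(seq), locus.end_bp + length)
            sub = SequenceRecord(locus.gene_id, seq[lo:hi], "dna").reverse_complement() \
                if hi > lo else None
        else:
            lo = max(0, locus.start_bp - 1 - length)
            hi = locus.start_bp - 1
            sub = SequenceRecord(locus.gene_id, seq[lo:hi], "dna") if hi > lo else None
        if sub is None:
            raise ValueError(f"{locus.gene_id}: no upstream sequence on the contig")
        out[locus.gene_id] = Promoter(
            locus.gene_id, sub, len(sub), len(sub) < length, locus.strand
        )
    return out


# ---------------------------------------------------------------------------
# ZOOPS EM discovery


def _encode(seqs: list[SequenceRecord], alphabet: str) -> list[np.ndarray]:
    idx = {ch: k for k, ch in enumerate(alphabet)}
    return [
        np.array([idx.get(c, -1) for c in s.residues.upper()], dtype=int) for s in seqs
    ]


def _window_scores(enc: np.ndarray, valid: np.ndarray, table: np.ndarray, w: int):
    """Sum of table[pos, residue] over each length-w window; invalid -> -inf."""
    m = len(enc) - w + 1
    if m <= 0:
        return np.empty(0)
    scores = np.zeros(m)
    ok = np.ones(m, dtype=bool)
    for pos in range(w):
        col = enc[pos : pos + m]
        good = valid[pos : pos + m] & (col >= 0)
        ok &= good
        scores += np.where(good, table[pos, np.clip(col, 0, None)], 0.0)
    scores[~ok] = -np.inf
    return scores


def _zoops_em(encs, valids, background, w, alphabet_size, pseudocount, max_iter, tol):
    """Run ZOOPS EM at one width; returns (pwm_probs, gamma, rel_loglik, z)."""
    # init from the most enriched exact word (deterministic)
    word_counts: dict[tuple, int] = {}
    for enc, valid in zip(encs, valids):
        for j in range(len(enc) - w + 1):
            win = enc[j : j + w]
            if (win < 0).any() or not valid[j : j + w].all():
                continue
            key = tuple(win)
            word_counts[key] = word_counts.get(key, 0) + 1
    if not word_counts:
        return None
    seed_word = min(word_counts, key=lambda k: (-word_counts[k], k))
    probs = np.full((w, alphabet_size), (1.0 - 0.6) / (alphabet_size - 1))
    for pos, res in enumerate(seed_word):
        probs[pos, res] = 0.6
    gamma = 0.5
    prev_ll = -np.inf
    prev_obj = -np.inf
    traj = []
    z_all = None
    for _ in range(max_iter):
        log_ratio = np.log(probs) - np.log(background)[None, :]
        ll = 0.0
        z_all = []
        site_counts = np.full((w, alphabet_size), pseudocount)
        gamma_sum = 0.0
        for enc, valid in zip(encs, valids):
            scores = _window_scores(enc, valid, log_ratio, w)
            m = len(scores)
            if m == 0 or np.all(~np.isfinite(scores)):
                z_all.append((None, 0.0))
                continue
            ratios = np.exp(scores - np.max(scores[np.isfinite(scores)]))
            ratios[~np.isfinite(scores)] = 0.0
            shift = np.max(scores[np.isfinite(scores)])
            # mixture: (1-gamma) background + gamma/m * sum of site likelihoods
            site_term = (gamma / m) * ratios.sum() * math.exp(shift)
            total = (1.0 - gamma) + site_term
            ll += math.log(total)
            post_site = site_term / total
            zj = ratios / ratios.sum() * post_site if ratios.sum() > 0 else ratios
            z_all.append((zj, post_site))
            gamma_sum += post_site
            for pos in range(w):
                cols = enc[pos : pos + m]
                good = cols >= 0
                np.add.at(site_counts[pos], cols[good], zj[good])
        # with pseudocounts the M-step maximizes the MAP objective
        # (likelihood x Dirichlet prior); that objective is monotone
        obj = ll + pseudocount * float(np.log(probs).sum())
        traj.append(obj)
        if obj < prev_obj - 1e-8:
            raise AssertionError("EM penalized log-likelihood decreased")
        if obj - prev_obj < tol:
            prev_ll = ll
            break
        prev_obj = obj
        prev_ll = ll
        probs = site_counts / site_counts.sum(axis=1, keepdims=True)
        gamma = min(max(gamma_sum / len(encs), 1e-4), 1.0 - 1e-4)
    return probs, gamma, prev_ll, z_all, traj


def discover_motifs(
    proteins: list[SequenceRecord],
    max_motifs: int = 20,
    width_range: tuple[int, int] = (6, 50),
    seed: int | None = None,
    alphabet: str = PROTEIN,
    pseudocount: float = 0.1,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> list[MotifModel]:
    """Iterative ZOOPS EM motif discovery with site masking.

    Widths are searched on a coarse grid then refined around the best one;
    the best width wins by BIC-style penalized likelihood, and discovery
    stops when no candidate scores above the penalty or after
    ``max_motifs`` motifs. ``seed`` is accepted for API stability; the
    default enriched-word initialization is deterministic.
    """
    if len(proteins) < 2:
        raise ValueError("need at least 2 sequences")
    wmin, wmax = width_range
    max_len = max(len(p.residues) for p in proteins)
    if wmin < 2 or wmax < wmin or wmin > max_len:
        raise ValueError(f"width range {width_range} outside [2, sequence length]")
    wmax = min(wmax, max_len)
    encs = _encode(proteins, alphabet)
    valids = [np.ones(len(e), dtype=bool) for e in encs]
    flat = np.concatenate(encs)
    counts = np.bincount(flat[flat >= 0], minlength=len(alphabet)).astype(float)
    background = (counts + 1.0) / (counts + 1.0).sum()
    # only residues actually present are estimable PWM parameters
    k_eff = int((counts > 0).sum())
    n_seq = len(proteins)
    models: list[MotifModel] = []
    step = max(1, (wmax - wmin) // 6)
    for _ in range(max_motifs):
        best = None
        widths = sorted(set(range(wmin, wmax + 1, step)) | {wmax})
        for refine_round in range(2):
            for w in widths:
                fit = _zoops_em(
                    encs, valids, background, w, len(alphabet), pseudocount, max_iter, tol
                )
                if fit is None:
                    continue
                probs, gamma, ll, z_all, traj = fit
                n_params = w * (k_eff - 1) + 1
                score = ll - 0.5 * n_params * math.log(n_seq)
                if best is None or score > best[0]:
                    best = (score, w, probs, gamma, ll, z_all)
            if best is None or step == 1:
                break
            wb = best[1]
            widths = [w for w in range(max(wmin, wb - step + 1), min(wmax, wb + step - 1) + 1)
                      if w not in widths]
            if not widths:
                break
        if best is None or best[0] <= 0:
            break
        score, w, probs, gamma, ll, z_all = best
        pwm = PWM(f"motif_{len(models) + 1}", alphabet, probs, background, pseudocount)
        sites: list[tuple[str, int]] = []
        for (zj, post), rec, valid in zip(z_all, proteins, valids):
            if zj is None or post <= 0.5:
                continue
            offset = int(np.argmax(zj))
            sites.append((rec.id, offset))
            valid[offset : offset + w] = False  # mask the claimed site
        models.append(MotifModel(pwm, sites, ll, score))
        if not sites:
            break
    return models


# ---------------------------------------------------------------------------
# PWM scanning with exact p-values


@dataclass(frozen=True)
class TFBSHit:
    gene_id: str
    tf_name: str
    position: int  # 1-based on promoter forward coordinates
    strand: str
    score: float
    p_value: float


def _score_table(pwm: PWM, scale: int) -> np.ndarray:
    return np.round(scale * pwm.log_odds).astype(int)


def _score_distribution(table: np.ndarray, background: np.ndarray):
    """Exact distribution of the integer window score under the background."""
    w = table.shape[0]
    lo = int(table.min(axis=1).sum())
    hi = int(table.max(axis=1).sum())
    probs = np.zeros(hi - lo + 1)
    probs[-lo if lo < 0 else 0] = 0.0
    cur = {0: 1.0}
    for pos in range(w):
        nxt: dict[int, float] = {}
        for s, p in cur.items():
            for a, bg in enumerate(background):
                key = s + int(table[pos, a])
                nxt[key] = nxt.get(key, 0.0) + p * bg
        cur = nxt
    for s, p in cur.items():
        probs[s - lo] += p
    # P(score >= s) for every attainable integer score
    tail = np.cumsum(probs[::-1])[::-1]
    return lo, tail


def scan_pwm(
    promoters: dict[str, Promoter],
    pwms: list[PWM],
    p_max: float = 1e-4,
    scale: int = 100,
):
    """Scan promoters on both strands; exact background p-values.

    Returns (hits, counts) where counts is a genes x TF DataFrame.
    """
    import pandas as pd

    hits: list[TFBSHit] = []
    gene_ids = sorted(promoters)
    idx = {ch: k for k, ch in enumerate(DNA)}
    enc_cache = {
        g: np.array([idx.get(c, -1) for c in promoters[g].sequence.residues.upper()])
        for g in gene_ids
    }
    for pwm in pwms:
        if pwm.alphabet != DNA:
            raise ValueError(f"{pwm.name}: promoter scanning needs DNA PWMs")
        table_f = _score_table(pwm, scale)
        lo, tail = _score_distribution(table_f, pwm.background)
        table_r = _score_table(pwm.reverse_complement(), scale)
        w = pwm.width
        for g in gene_ids:
            enc = enc_cache[g]
            for strand, table in (("+", table_f), ("-", table_r)):
                valid = np.ones(len(enc), dtype=bool)
                scores = _window_scores(enc, valid, table.astype(float), w)
                for j in np.nonzero(np.isfinite(scores))[0]:
                    s = int(round(scores[j]))
                    k = min(max(s - lo, 0), len(tail) - 1)
                    pv = float(tail[k]) if s - lo < len(tail) else 0.0
                    if s - lo < 0:
                        pv = 1.0
                    if pv <= p_max:
                        hits.append(
                            TFBSHit(g, pwm.name, int(j) + 1, strand, s / scale, max(pv, 5e-324))
                        )
    counts = pd.DataFrame(
        0, index=gene_ids, columns=[p.name for p in pwms], dtype=int
    )
    for h in hits:
        counts.loc[h.gene_id, h.tf_name] += 1
    return hits, counts


# ---------------------------------------------------------------------------
# motif file formats (via Bio.motifs)


def _from_biomotif(m, pseudocount=0.1, background=None) -> PWM:
    counts = np.array([[m.counts[ch][i] for ch in DNA] for i in range(m.length)])
    return PWM.from_counts(
        m.name or m.base_id if hasattr(m, "base_id") else m.name,
        DNA, counts, pseudocount, background,
    )


def read_jaspar(path, pseudocount: float = 0.1) -> list[PWM]:
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    return [_from_biomotif(m, pseudocount) for m in records]


def read_meme_minimal(path, pseudocount: float = 0.1) -> list[PWM]:
    # parsed directly: the installed MEME-minimal readers quantize the
    # letter probabilities to integer counts, losing precision
    out: list[PWM] = []
    bg = np.full(4, 0.25)
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    for line in lines:
        if line.startswith("Background letter frequencies"):
            fields = next(lines).split()
            bg = np.array([float(fields[2 * i + 1]) for i in range(4)])
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            header = next(lines)
            while "letter-probability matrix" not in header:
                header = next(lines)
            w = int(header.split("w=")[1].split()[0])
            rows = [
                [float(x) for x in next(lines).split()[:4]] for _ in range(w)
            ]
            probs = np.clip(np.array(rows), 1e-6, None)
            probs /= probs.sum(axis=1, keepdims=True)
            out.append(PWM(name, DNA, probs, bg, pseudocount))
    return out


def write_meme_minimal(pwms: list[PWM], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{c} {b:.4f}" for c, b in zip(DNA, bg)) + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} nsites= 20 E= 0\n"
            )
            for row in p.matrix:
                fh.write(" " + " ".join(f"{x:8.6f}" for x in row) + "\n")
            fh.write("\n")
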