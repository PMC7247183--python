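"""Pairwise protein alignment, E-values, and profile-based family search.

The aligner is an exact affine-gap dynamic program (Gotoh): local mode is
Smith-Waterman, global mode Needleman-Wunsch. A gap of length L costs
gap_open + (L-1)*gap_extend. Traceback ties resolve diagonal > up > left
for reproducibility. E-values follow the Karlin-Altschul form
E = K*m*n*exp(-lambda*S) with published gapped parameters for the matrix.

The family-identification stage scores every proteome sequence against an
ungapped-column log-odds profile (built from a seed alignment) with
affine-gap local alignment — a transparent, fully testable stand-in for a
profile-HMM search, applied with the same thresholds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .seqio import SequenceRecord

NEG_INF = -1e30

__all__ = [
    "SubstitutionMatrix",
    "AlignmentResult",
    "FamilyProfile",
    "align_pair",
    "build_profile",
    "identify_family",
]


@dataclass
class SubstitutionMatrix:
    alphabet: str
    scores: np.ndarray  # symmetric, len(alphabet) x len(alphabet)
    gap_open: int = -11
    gap_extend: int = -1
    lambda_: float = 0.267  # gapped Karlin-Altschul parameters
    K: float = 0.041

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.allclose(self.scores, self.scores.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        self._index = {ch: i for i, ch in enumerate(self.alphabet)}

    @classmethod
    def blosum62(cls, gap_open: int = -11, gap_extend: int = -1) -> "SubstitutionMatrix":
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM62")
        alphabet = str(m.alphabet)
        return cls(alphabet, np.array(m), gap_open, gap_extend)

    def encode(self, seq: SequenceRecord) -> np.ndarray:
        try:
            return np.array([self._index[c] for c in seq.residues.upper()], dtype=int)
        except KeyError as exc:
            raise ValueError(
                f"{seq.id}: residue {exc.args[0]!r} not in matrix alphabet"
            ) from None


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    mode: str
    score: float
    aligned_cols: int
    identities: int
    evalue: float
    query_start: int = 0  # 0-based offsets of the aligned region
    subject_start: int = 0
    aligned_query: str = ""
    aligned_subject: str = ""

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identities / self.aligned_cols if self.aligned_cols else 0.0


def _affine_dp(sub: np.ndarray, gap_open: float, gap_extend: float, local: bool):
    """Fill Gotoh matrices for a precomputed (m x n) match-score matrix.

    Returns (M, Ix, Iy) of shape (m+1, n+1). Ix = gap in the subject
    (vertical/up move), Iy = gap in the query (horizontal/left move).
    """
    m, n = sub.shape
    M = np.full((m + 1, n + 1), NEG_INF)
    Ix = np.full((m + 1, n + 1), NEG_INF)
    Iy = np.full((m + 1, n + 1), NEG_INF)
    M[0, 0] = 0.0
    if not local:
        js = np.arange(1, n + 1)
        Iy[0, 1:] = gap_open + (js - 1) * gap_extend
        is_ = np.arange(1, m + 1)
        Ix[1:, 0] = gap_open + (is_ - 1) * gap_extend
    ext_j = gap_extend * np.arange(n + 1)
    for i in range(1, m + 1):
        prev_best = np.maximum.reduce([M[i - 1], Ix[i - 1], Iy[i - 1]])
        diag = prev_best[:-1]
        if local:
            diag = np.maximum(diag, 0.0)
        M[i, 1:] = sub[i - 1] + diag
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] + gap_open, Ix[i - 1, 1:] + gap_extend)
        # horizontal pass: Iy[j] = max_k<j (M[k] + open + (j-1-k)*ext)
        c = M[i] + gap_open - ext_j - gap_extend
        pref = np.maximum.accumulate(c)
        Iy[i, 1:] = ext_j[1:] + pref[:-1]
    return M, Ix, Iy


def _traceback(M, Ix, Iy, sub, gap_open, gap_extend, local):
    """Recover one optimal path; ties resolve diagonal > up > left."""
    m, n = sub.shape
    if local:
        flat = int(np.argmax(M))
        i, j = divmod(flat, n + 1)
        score = float(M[i, j])
        if score <= 0:
            return 0.0, []
        state = "M"
    else:
        i, j = m, n
        cands = [("M", M[i, j]), ("Ix", Ix[i, j]), ("Iy", Iy[i, j])]
        state, score = max(cands, key=lambda t: t[1])
        for s, v in cands:  # priority on exact ties
            if v == score:
                state = s
                break
        score = float(score)
    path = []  # (i, j, state) with 1-based i, j for M states
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                break
            path.append((i, j, "M"))
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            if local and target <= tol and M[i, j] < target - tol and Ix[i, j] < target - tol and Iy[i, j] < target - tol:
                break  # local alignment start
            for s, v in (("M", M[i, j]), ("Ix", Ix[i, j]), ("Iy", Iy[i, j])):
                if abs(v - target) <= tol:
                    state = s
                    break
            else:
                if local and target <= tol:
                    break
                raise AssertionError("traceback failure")
        elif state == "Ix":
            path.append((i, j, "Ix"))
            if abs(Ix[i, j] - (M[i - 1, j] + gap_open)) <= tol:
                state = "M"
            else:
                state = "Ix"
            i -= 1
            if local and state == "M" and i >= 0 and j >= 0:
                pass
        else:  # Iy
            path.append((i, j, "Iy"))
            if abs(Iy[i, j] - (M[i, j - 1] + gap_open)) <= tol:
                state = "M"
            else:
                state = "Iy"
            j -= 1
        if not local:
            if state == "M" and (i == 0 or j == 0):
                # remaining is boundary gaps
                while i > 0:
                    path.append((i, j, "Ix"))
                    i -= 1
                while j > 0:
                    path.append((i, j, "Iy"))
                    j -= 1
                break
        elif state == "M" and (i == 0 or j == 0):
            break
    path.reverse()
    return score, path


def align_pair(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix: SubstitutionMatrix | None = None,
    mode: str = "local",
) -> AlignmentResult:
    """Optimal pairwise alignment of two protein sequences.

    Identity is counted over aligned columns; internal gap columns are in
    the denominator (end gaps never appear in local mode).
    """
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    if mode not in ("local", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    ai, bi = matrix.encode(a), matrix.encode(b)
    sub = matrix.scores[np.ix_(ai, bi)]
    local = mode == "local"
    M, Ix, Iy = _affine_dp(sub, matrix.gap_open, matrix.gap_extend, local)
    score, path = _traceback(M, Ix, Iy, sub, matrix.gap_open, matrix.gap_extend, local)
    aq, as_ = [], []
    identities = 0
    for i, j, state in path:
        if state == "M":
            ca, cb = a.residues[i - 1], b.residues[j - 1]
            aq.append(ca)
            as_.append(cb)
            if ca.upper() == cb.upper():
                identities += 1
        elif state == "Ix":
            aq.append(a.residues[i - 1])
            as_.append("-")
        else:
            aq.append("-")
            as_.append(b.residues[j - 1])
    evalue = matrix.K * len(a) * len(b) * math.exp(-matrix.lambda_ * score)
    qstart = path[0][0] - 1 if path else 0
    sstart = path[0][1] - 1 if path else 0
    return AlignmentResult(
        a.id, b.id, mode, score, len(path), identities, evalue,
        qstart, sstart, "".join(aq), "".join(as_),
    )


@dataclass
class FamilyProfile:
    """Ungapped-column log-odds profile over the 20 standard residues.

    ``log_odds`` is (width x 20) in half-bit units (2*log2(p/bg)), so the
    Karlin-Altschul parameters of the default scoring system apply.
    """

    alphabet: str
    log_odds: np.ndarray
    probabilities: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.1
    name: str = "family_profile"

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(self.alphabet[k] for k in np.argmax(self.log_odds, axis=1))

    def to_json(self, path) -> None:
        doc = {
            "format_version": 1,
            "name": self.name,
            "alphabet": self.alphabet,
            "pseudocount": self.pseudocount,
            "background": self.background.tolist(),
            "probabilities": self.probabilities.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FamilyProfile":
        with open(path) as fh:
            doc = json.load(fh)
        probs = np.array(doc["probabilities"])
        bg = np.array(doc["background"])
        return cls(
            doc["alphabet"], 2.0 * np.log2(probs / bg[None, :]), probs, bg,
            doc["pseudocount"], doc["name"],
        )


PROFILE_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


def build_profile(
    seed_alignment: list[SequenceRecord],
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
) -> FamilyProfile:
    """Build a log-odds profile from an aligned seed family.

    Columns with more than ``max_gap_fraction`` gaps are dropped; residue
    frequencies get +pseudocount per residue; log-odds are taken against a
    uniform background unless one is supplied.
    """
    if len(seed_alignment) < 2:
        raise ValueError("profile requires at least 2 seed sequences")
    lengths = {len(r.residues) for r in seed_alignment}
    if len(lengths) != 1:
        raise ValueError("ragged seed alignment")
    idx = {ch: k for k, ch in enumerate(PROFILE_ALPHABET)}
    n_rows = len(seed_alignment)
    width_in = lengths.pop()
    cols = []
    for j in range(width_in):
        column = [r.residues[j].upper() for r in seed_alignment]
        gaps = sum(c == "-" for c in column)
        if gaps / n_rows > max_gap_fraction:
            continue
        counts = np.full(20, pseudocount)
        for c in column:
            if c in idx:
                counts[idx[c]] += 1.0
        cols.append(counts / counts.sum())
    if not cols:
        raise ValueError("no usable columns in seed alignment")
    probs = np.array(cols)
    bg = (
        np.asarray(background, dtype=float)
        if background is not None
        else np.full(20, 1.0 / 20)
    )
    log_odds = 2.0 * np.log2(probs / bg[None, :])
    return FamilyProfile(PROFILE_ALPHABET, log_odds, probs, bg, pseudocount)


def profile_align(
    profile: FamilyProfile,
    seq: SequenceRecord,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
):
    """Affine-gap local alignment of a profile (rows) to a sequence (cols).

    Returns (score, matched_profile_columns, path).
    """
    idx = {ch: k for k, ch in enumerate(profile.alphabet)}
    enc = [idx.get(c, -1) for c in seq.residues.upper()]
    sub = np.empty((profile.width, len(enc)))
    unknown = float(profile.log_odds.min())  # ambiguous residues score worst-case
    for j, k in enumerate(enc):
        sub[:, j] = profile.log_odds[:, k] if k >= 0 else unknown
    M, Ix, Iy = _affine_dp(sub, gap_open, gap_extend, local=True)
    score, path = _traceback(M, Ix, Iy, sub, gap_open, gap_extend, local=True)
    matched_cols = len({i for i, _, s in path if s in ("M", "Ix")})
    return score, matched_cols, path


def identify_family(
    proteome: list[SequenceRecord],
    profile: FamilyProfile,
    evalue_max: float = 1e-10,
    min_domain_coverage: float = 0.8,
    collapse_identity: float = 100.0,
    lambda_: float = 0.267,
    K: float = 0.041,
):
    """Profile search of a proteome with E-value and domain-span filters.

    A hit is kept iff E <= evalue_max and the match spans at least
    ``min_domain_coverage`` of the profile width (domain completeness).
    Exact-duplicate sequences are collapsed to one representative (the
    lexicographically smallest id); member ids are retained per row.
    Returns a pandas DataFrame hit table.
    """
    import pandas as pd

    if not proteome:
        raise ValueError("empty proteome")
    # collapse identical sequences
    by_seq: dict[str, list[str]] = {}
    for rec in proteome:
        by_seq.setdefault(rec.residues.upper(), []).append(rec.id)
    rep_of: dict[str, list[str]] = {}
    rec_by_id = {r.id: r for r in proteome}
    for seq_str, ids in by_seq.items():
        rep = min(ids)
        rep_of[rep] = sorted(ids)
    rows = []
    for rep in sorted(rep_of):
        rec = rec_by_id[rep]
        score, matched_cols, path = profile_align(profile, rec)
        evalue = K * profile.width * len(rec) * math.exp(-lambda_ * score)
        coverage = matched_cols / profile.width
        reasons = []
        if evalue > evalue_max:
            reasons.append("evalue above threshold")
        if coverage < min_domain_coverage:
            reasons.append("incomplete domain")
        rows.append(
            {
                "protein_id": rep,
                "members": ",".join(rep_of[rep]),
                "profile_score": score,
                "evalue": evalue,
                "match_span": matched_cols,
                "domain_coverage": coverage,
                "kept": not reasons,
                "reason": ";".join(reasons) if reasons else "pass",
            }
        )
    return pd.DataFrame(rows)


def write_hit_table(alignments, path) -> None:
    """BLAST outfmt-6-like TSV (qid sid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore-equivalent)."""
    with open(path, "w", newline="\n") as fh:
        for r in alignments:
            mism = r.aligned_cols - r.identities
            fh.write(
                "\t".join(
                    [
                        r.query_id, r.subject_id, f"{r.identity_pct:.2f}",
                        str(r.aligned_cols), str(mism), "0",
                        str(r.query_start + 1), str(r.query_start + len(r.aligned_query.replace('-', ''))),
                        str(r.subject_start + 1), str(r.subject_start + len(r.aligned_subject.replace('-', ''))),
                        f"{r.evalue:.3g}", f"{r.score:.1f}",
                    ]
                )
                + "\n"
            )
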