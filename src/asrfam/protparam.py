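"""Protein physicochemical characterization: Mw, isoelectric point, GRAVY.

Molecular weight uses average isotopic residue masses plus one water;
pI solves the Bjellqvist charge model by bisection; GRAVY is the mean
Kyte-Doolittle hydropathy. These are the conventions of the ExPASy
ProtParam tool, so values are comparable with ProtParam output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import SequenceRecord

# average isotopic residue masses (Da), i.e. amino acid minus water
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Bjellqvist pKa set (as used by ExPASy ProtParam); swappable via config
DEFAULT_PKA = {
    "positive": {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98},
    "negative": {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    # residue-specific terminal pKas
    "nterm_by_residue": {
        "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7,
    },
    "cterm_by_residue": {"D": 4.55, "E": 4.75},
}

STANDARD_RESIDUES = set(AVERAGE_RESIDUE_MASS)


@dataclass(frozen=True)
class ProtParamResult:
    gene_id: str
    aa_len: int
    mw_da: float
    pi: float
    gravy: float

    @property
    def mw_kda(self) -> float:
        return self.mw_da / 1000.0

    def display_row(self) -> dict:
        """Values rounded to the reporting precision (2 dp kDa/pI, 3 dp GRAVY)."""
        return {
            "gene_id": self.gene_id,
            "aa_len": self.aa_len,
            "mw_kda": round(self.mw_kda, 2),
            "pi": round(self.pi, 2),
            "gravy": round(self.gravy, 3),
        }


def _validate(seq: SequenceRecord) -> str:
    s = seq.residues.upper()
    bad = [str(i + 1) for i, ch in enumerate(s) if ch not in STANDARD_RESIDUES]
    if bad:
        raise ValueError(
            f"{seq.id}: non-standard residues at positions {', '.join(bad)}"
        )
    return s


def molecular_weight(seq: SequenceRecord) -> float:
    s = _validate(seq)
    return sum(AVERAGE_RESIDUE_MASS[ch] for ch in s) + WATER_MASS


def gravy(seq: SequenceRecord) -> float:
    s = _validate(seq)
    return sum(KYTE_DOOLITTLE[ch] for ch in s) / len(s)


def net_charge(seq_or_str, ph: float, pka: dict = DEFAULT_PKA) -> float:
    """Net charge at a given pH under the Bjellqvist model.

    Strictly decreasing in pH, which guarantees a unique root for pI.
    """
    s = seq_or_str.residues.upper() if isinstance(seq_or_str, SequenceRecord) else seq_or_str.upper()
    pos = pka["positive"]
    neg = pka["negative"]
    nterm_pk = pka["nterm_by_residue"].get(s[0], pos["Nterm"])
    cterm_pk = pka["cterm_by_residue"].get(s[-1], neg["Cterm"])
    charge = 1.0 / (1.0 + 10 ** (ph - nterm_pk))
    charge -= 1.0 / (1.0 + 10 ** (cterm_pk - ph))
    for res, pk in pos.items():
        if res == "Nterm":
            continue
        charge += s.count(res) / (1.0 + 10 ** (ph - pk))
    for res, pk in neg.items():
        if res == "Cterm":
            continue
        charge -= s.count(res) / (1.0 + 10 ** (pk - ph))
    return charge


def isoelectric_point(
    seq: SequenceRecord, pka: dict = DEFAULT_PKA, tol: float = 1e-4, max_iter: int = 200
) -> float:
    """pH at which net charge crosses zero, by bisection on [0, 14]."""
    s = _validate(seq)
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        q = net_charge(s, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def compute_protparam(seq: SequenceRecord, pka: dict = DEFAULT_PKA) -> ProtParamResult:
    s = _validate(seq)
    return ProtParamResult(
        gene_id=seq.id,
        aa_len=len(s),
        mw_da=molecular_weight(seq),
        pi=isoelectric_point(seq, pka),
        gravy=gravy(seq),
    )


@dataclass(frozen=True)
class FieldSummary:
    mean: float
    min: float
    argmin: str
    max: float
    argmax: str


@dataclass(frozen=True)
class FamilySummary:
    n_members: int
    aa_len: FieldSummary
    orf_bp: FieldSummary
    mw_kda: FieldSummary
    pi: FieldSummary
    gravy: FieldSummary


def _summarize_column(values, ids) -> FieldSummary:
    v = np.asarray(values, dtype=float)
    ids = list(ids)
    # extremes attributed by gene id; ties broken lexicographically
    imin = min(range(len(v)), key=lambda i: (v[i], ids[i]))
    imax = max(range(len(v)), key=lambda i: (v[i], _NegStr(ids[i])))
    return FieldSummary(float(v.mean()), float(v[imin]), ids[imin], float(v[imax]), ids[imax])


class _NegStr(str):
    """Reverses lexicographic order, so max() ties pick the smallest id."""

    def __lt__(self, other):
        return str.__gt__(self, other)


def summarize_family(results, orf_bp=None) -> FamilySummary:
    """Family-level ranges and means of the physicochemical columns.

    Accepts either a list of ProtParamResult (with ``orf_bp`` a parallel
    sequence of ORF lengths) or a DataFrame with columns gene_id, aa_len,
    orf_bp, mw_kda, pi, gravy (e.g. the packaged family table).
    """
    import pandas as pd

    if isinstance(results, pd.DataFrame):
        df = results
    else:
        results = list(results)
        if not results:
            raise ValueError("no results to summarize")
        if orf_bp is None:
            orf_bp = [3 * (r.aa_len + 1) for r in results]
        df = pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in results],
                "aa_len": [r.aa_len for r in results],
                "orf_bp": list(orf_bp),
                "mw_kda": [r.mw_kda for r in results],
                "pi": [r.pi for r in results],
                "gravy": [r.gravy for r in results],
            }
        )
    if df.empty:
        raise ValueError("no results to summarize")
    ids = df["gene_id"]
    return FamilySummary(
        n_members=len(df),
        aa_len=_summarize_column(df["aa_len"], ids),
        orf_bp=_summarize_column(df["orf_bp"], ids),
        mw_kda=_summarize_column(df["mw_kda"], ids),
        pi=_summarize_column(df["pi"], ids),
        gravy=_summarize_column(df["gravy"], ids),
    )
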