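"""Sequence, locus and gene-structure I/O.

Conventions
-----------
Internal arithmetic uses 0-based half-open coordinates; every I/O boundary
(FASTA, GFF3, locus strings, reports) is 1-based inclusive, converting
exactly at the boundary. Ambiguity codes are retained verbatim ('X'/'N'
allowed, never dropped).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")
DNA_ALPHABET = set("ACGTURYSWKMBDHVN-")

__all__ = [
    "SequenceRecord",
    "GeneLocus",
    "GeneStructure",
    "read_fasta",
    "write_fasta",
    "parse_locus",
    "format_locus",
    "read_gff3",
    "infer_gene_structure",
    "load_family_table",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein or DNA sequence."""

    id: str
    residues: str
    alphabet: str = "protein"  # {"protein", "dna"}

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        for pos, ch in enumerate(self.residues):
            if ch.upper() not in allowed:
                raise ValueError(
                    f"record {self.id!r}: non-IUPAC character {ch!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        if self.alphabet != "dna":
            raise ValueError("reverse complement requires a DNA record")
        return SequenceRecord(
            self.id, str(Seq(self.residues).reverse_complement()), "dna"
        )


def _trailing_letter_subgenome(chromosome: str) -> str:
    """Subgenome from the chromosome name's trailing letter; 'U' if unanchored."""
    if chromosome and chromosome[-1] in "ABD":
        return chromosome[-1]
    return "U"


@dataclass(frozen=True)
class GeneLocus:
    """A gene's genomic placement, 1-based inclusive coordinates."""

    gene_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    strand: str = "unknown"  # {"+", "-", "unknown"}
    subgenome: str = field(default="", compare=False)

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"{self.gene_id}: start {self.start_bp} > end {self.end_bp}"
            )
        if self.start_bp < 1:
            raise ValueError(f"{self.gene_id}: coordinates are 1-based")
        object.__setattr__(
            self, "subgenome", _trailing_letter_subgenome(self.chromosome)
        )

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def chromosome_group(self) -> str:
        """Numeric prefix of the chromosome name ('3' for 3A); 'Un' if none."""
        m = re.match(r"(\d+)", self.chromosome)
        return m.group(1) if m else "Un"


_LOCUS_RE = re.compile(r"^chr(\S+):\s*(\d+)-(\d+)$")


def parse_locus(text: str, gene_id: str = "") -> GeneLocus:
    """Parse a ``chr3D: 600607844-600608597`` style locus string."""
    m = _LOCUS_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed locus string: {text!r}")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    return GeneLocus(gene_id, chrom, start, end)


def format_locus(locus: GeneLocus) -> str:
    return f"chr{locus.chromosome}: {locus.start_bp}-{locus.end_bp}"


@dataclass
class GeneStructure:
    """Exon-intron layout of one transcript in gene-relative coordinates.

    Exons are (start, end) pairs, 1-based inclusive, 5'->3' in the gene's
    reading direction (minus-strand genes are flipped at parse time).
    """

    gene_id: str
    exons: list[tuple[int, int]]
    utr5_bp: int = 0
    utr3_bp: int = 0
    provenance: str = "annotation"  # {"annotation", "cds_comparison"}

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        self.exons = sorted(self.exons)
        prev_end = 0
        for s, e in self.exons:
            if s > e or s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span(self) -> int:
        return self.exons[-1][1] - self.exons[0][0] + 1


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into validated records, order preserved."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq), alphabet))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    recs = [_BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_gff3(path: str | Path) -> tuple[list[GeneStructure], list[GeneLocus]]:
    """Parse a GFF3 annotation into gene structures and loci.

    One GeneStructure per mRNA; exon intervals are converted to gene-relative
    coordinates and minus-strand genes are reported 5'->3'.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    structures: list[GeneStructure] = []
    loci: list[GeneLocus] = []
    for gene in db.features_of_type("gene", order_by="start"):
        locus = GeneLocus(
            gene.id,
            gene.seqid.removeprefix("chr"),
            gene.start,
            gene.end,
            gene.strand if gene.strand in "+-" else "unknown",
        )
        loci.append(locus)
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons = []
            for exon in db.children(mrna, featuretype="exon", order_by="start"):
                if exon.start < gene.start or exon.end > gene.end:
                    raise ValueError(
                        f"exon {exon.start}-{exon.end} outside gene {gene.id} bounds"
                    )
                if gene.strand == "-":
                    rel = (gene.end - exon.end + 1, gene.end - exon.start + 1)
                else:
                    rel = (exon.start - gene.start + 1, exon.end - gene.start + 1)
                exons.append(rel)
            if not exons:
                continue
            structures.append(GeneStructure(mrna.id, exons))
    # gffutils raises on structural problems; a missing Parent leaves orphans
    for mrna in db.features_of_type("mRNA"):
        if "Parent" not in mrna.attributes:
            raise ValueError(f"mRNA {mrna.id} has no Parent attribute")
    return structures, loci


def infer_gene_structure(cds: SequenceRecord, genomic: SequenceRecord) -> GeneStructure:
    """Infer exon-intron structure by exact spliced matching of CDS to genomic.

    Exons are maximal exact-match blocks found by greedy longest-prefix
    matching; among equally long candidate blocks the leftmost (intron-
    minimal) placement wins. The concatenated exon sequence equals the CDS
    exactly or the gene is reported unspliceable.
    """
    c, g = cds.residues.upper(), genomic.residues.upper()
    exons: list[tuple[int, int]] = []
    ci = 0  # consumed CDS prefix
    gi = 0  # genomic scan position (0-based)
    while ci < len(c):
        best_len, best_pos = 0, -1
        pos = g.find(c[ci], gi)
        while pos != -1:
            # maximal match length at this genomic position
            k = 0
            while ci + k < len(c) and pos + k < len(g) and c[ci + k] == g[pos + k]:
                k += 1
            if k > best_len:  # leftmost wins ties
                best_len, best_pos = k, pos
            if ci + best_len == len(c):
                break
            pos = g.find(c[ci], pos + 1)
        if best_len == 0:
            raise ValueError(f"unspliceable: CDS {cds.id} not found in {genomic.id}")
        exons.append((best_pos + 1, best_pos + best_len))
        ci += best_len
        gi = best_pos + best_len
    structure = GeneStructure(cds.id, exons, provenance="cds_comparison")
    spliced = "".join(g[s - 1 : e] for s, e in structure.exons)
    if spliced != c:
        raise ValueError(f"unspliceable: reconstruction mismatch for {cds.id}")
    return structure


def load_family_table(path: str | Path | None = None):
    """Load the packaged wheat ASR family table (or a compatible TSV).

    Returns a pandas DataFrame with parsed locus columns (chromosome,
    start_bp, end_bp, subgenome, chromosome_group, span_bp) added.
    """
    import pandas as pd

    if path is None:
        path = Path(__file__).parent / "data" / "wheat_asr_family.tsv"
    df = pd.read_csv(path, sep="\t")
    loci = [parse_locus(t, g) for g, t in zip(df["gene_id"], df["locus"])]
    df["chromosome"] = [l.chromosome for l in loci]
    df["start_bp"] = [l.start_bp for l in loci]
    df["end_bp"] = [l.end_bp for l in loci]
    df["subgenome"] = [l.subgenome for l in loci]
    df["chromosome_group"] = [l.chromosome_group for l in loci]
    df["span_bp"] = [l.span_bp for l in loci]
    if not df["orf_bp"].eq(3 * (df["aa_len"] + 1)).all():
        bad = df.loc[df["orf_bp"] != 3 * (df["aa_len"] + 1), "gene_id"].tolist()
        raise ValueError(f"ORF/protein length inconsistency for {bad}")
    return df


def family_table_loci(df) -> list[GeneLocus]:
    return [
        GeneLocus(g, c, s, e)
        for g, c, s, e in zip(df["gene_id"], df["chromosome"], df["start_bp"], df["end_bp"])
    ]
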