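"""Tandem/segmental duplication classification and homoeolog assignment.

Homolog pairs are BLASTP-style calls from exact local alignment with the
strict thresholds E < 1e-20 and identity > 75%. Tandem arrays are maximal
chains of same-chromosome homologs with consecutive separations <= 150 kb
(separation measured between nearer gene ends); segmental duplicates are
homolog pairs on different chromosomes. Unanchored genes are excluded from
both calls and reported separately.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .homology import SubstitutionMatrix, align_pair
from .seqio import GeneLocus, SequenceRecord

TANDEM_WINDOW_BP = 150_000

__all__ = [
    "HomologPair",
    "TandemArray",
    "SegmentalPair",
    "HomoeologGroup",
    "find_homolog_pairs",
    "classify_duplications",
    "summarize_chromosomes",
    "assign_homoeologs",
]


@dataclass(frozen=True)
class HomologPair:
    gene_a: str  # lexicographically smaller
    gene_b: str
    identity_pct: float
    evalue: float
    same_chromosome: bool
    separation_bp: int | None  # nearer-end separation; same chromosome only
    unanchored: bool = False

    def __post_init__(self):
        if self.gene_a > self.gene_b:
            raise ValueError("pair must be ordered gene_a < gene_b")


@dataclass
class TandemArray:
    chromosome: str
    members: list[str]  # ordered by start_bp
    separations: list[int]  # consecutive-pair nearer-end separations

    @property
    def n_pairs(self) -> int:
        """Consecutive-pair counting convention for tandem duplications."""
        return len(self.members) - 1


@dataclass(frozen=True)
class SegmentalPair:
    gene_a: str
    gene_b: str
    chromosome_a: str
    chromosome_b: str
    identity_pct: float


@dataclass
class HomoeologGroup:
    label: str
    members: dict[str, str]  # subgenome -> canonical gene_id
    expansion_copies: list[str] = field(default_factory=list)

    @property
    def is_complete(self) -> bool:
        return set(self.members) == {"A", "B", "D"}


def _separation(a: GeneLocus, b: GeneLocus) -> int:
    """Distance between nearer gene ends; overlapping genes separate by 0."""
    first, second = (a, b) if a.start_bp <= b.start_bp else (b, a)
    return max(0, second.start_bp - first.end_bp - 1)


def find_homolog_pairs(
    proteins: list[SequenceRecord],
    loci: list[GeneLocus],
    evalue_max: float = 1e-20,
    identity_min: float = 75.0,
    matrix: SubstitutionMatrix | None = None,
    strict: bool = False,
) -> list[HomologPair]:
    """All-vs-all local alignment; both thresholds applied strictly (<, >)."""
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    locus_by_id = {l.gene_id: l for l in loci}
    missing = [p.id for p in proteins if p.id not in locus_by_id]
    if missing and strict:
        raise ValueError(f"proteins without locus: {missing}")
    pairs: list[HomologPair] = []
    for a, b in itertools.combinations(sorted(proteins, key=lambda r: r.id), 2):
        res = align_pair(a, b, matrix, mode="local")
        if not (res.evalue < evalue_max and res.identity_pct > identity_min):
            continue
        la, lb = locus_by_id.get(a.id), locus_by_id.get(b.id)
        if la is None or lb is None:
            pairs.append(HomologPair(a.id, b.id, res.identity_pct, res.evalue, False, None, True))
            continue
        unanchored = la.subgenome == "U" or lb.subgenome == "U"
        same = (not unanchored) and la.chromosome == lb.chromosome
        sep = _separation(la, lb) if same else None
        pairs.append(
            HomologPair(a.id, b.id, res.identity_pct, res.evalue, same, sep, unanchored)
        )
    return pairs


def classify_duplications(
    pairs: list[HomologPair],
    loci: list[GeneLocus],
    annotation: list[GeneLocus] | None = None,
    window_bp: int = TANDEM_WINDOW_BP,
) -> tuple[list[TandemArray], list[SegmentalPair]]:
    """Chain same-chromosome homologs into maximal tandem arrays; emit
    cross-chromosome homolog pairs as segmental duplicates.

    With a full ``annotation`` the no-intervening-gene rule is enforced;
    without one the output is produced in family-only mode (documented
    relaxation), where only family genes can break a chain.
    """
    locus_by_id = {l.gene_id: l for l in loci}
    homolog = {frozenset((p.gene_a, p.gene_b)) for p in pairs if not p.unanchored}
    segmental = sorted(
        (SegmentalPair(
            p.gene_a,
            p.gene_b,
            locus_by_id[p.gene_a].chromosome,
            locus_by_id[p.gene_b].chromosome,
            p.identity_pct,
        )
        for p in pairs
        if not p.unanchored and not p.same_chromosome),
        key=lambda s: (s.gene_a, s.gene_b),
    )
    arrays: list[TandemArray] = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for l in loci:
        if l.subgenome != "U":
            by_chrom.setdefault(l.chromosome, []).append(l)
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda l: (l.start_bp, l.gene_id))
        chain: list[GeneLocus] = [genes[0]]
        seps: list[int] = []
        for prev, cur in zip(genes, genes[1:]):
            sep = _separation(prev, cur)
            linked = (
                frozenset((prev.gene_id, cur.gene_id)) in homolog
                and sep <= window_bp
                and not _intervening(prev, cur, annotation)
            )
            if linked:
                chain.append(cur)
                seps.append(sep)
            else:
                if len(chain) >= 2:
                    arrays.append(TandemArray(chrom, [g.gene_id for g in chain], seps))
                chain, seps = [cur], []
        if len(chain) >= 2:
            arrays.append(TandemArray(chrom, [g.gene_id for g in chain], seps))
    return arrays, segmental


def _intervening(a: GeneLocus, b: GeneLocus, annotation: list[GeneLocus] | None) -> bool:
    if annotation is None:
        return False
    lo, hi = a.end_bp, b.start_bp
    for g in annotation:
        if g.gene_id in (a.gene_id, b.gene_id) or g.chromosome != a.chromosome:
            continue
        if g.start_bp > lo and g.end_bp < hi:
            return True
    return False


def summarize_chromosomes(loci: list[GeneLocus]):
    """Per-chromosome / subgenome / homoeologous-group counts and spans.

    Returns a dict of pandas DataFrames: 'chromosomes' (count, span_kb,
    pct), 'subgenomes', 'chromosome_groups'. Percentages are of the full
    locus list (anchored + unanchored), rounded to 1 decimal.
    """
    import pandas as pd

    if not loci:
        raise ValueError("no loci to summarize")
    total = len(loci)
    rows = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for l in loci:
        by_chrom.setdefault(l.chromosome, []).append(l)
    for chrom in sorted(by_chrom):
        genes = by_chrom[chrom]
        span_kb = (max(g.end_bp for g in genes) - min(g.start_bp for g in genes)) / 1000.0
        rows.append(
            {
                "chromosome": chrom,
                "count": len(genes),
                "span_kb": round(span_kb, 1),
                "pct": round(100.0 * len(genes) / total, 1),
            }
        )
    chrom_df = pd.DataFrame(rows)
    sub = pd.Series([l.subgenome for l in loci]).value_counts().sort_index()
    sub_df = pd.DataFrame(
        {"subgenome": sub.index, "count": sub.values,
         "pct": (100.0 * sub.values / total).round(1)}
    )
    grp = pd.Series([l.chromosome_group for l in loci]).value_counts().sort_index()
    grp_df = pd.DataFrame(
        {"chromosome_group": grp.index, "count": grp.values,
         "pct": (100.0 * grp.values / total).round(1)}
    )
    return {"chromosomes": chrom_df, "subgenomes": sub_df, "chromosome_groups": grp_df}


def assign_homoeologs(
    pairs: list[HomologPair], loci: list[GeneLocus]
) -> list[HomoeologGroup]:
    """Homoeolog groups = connected components of the cross-subgenome
    homolog graph; one canonical member per subgenome (highest mean
    identity to the other subgenomes, ties by gene_id), surplus members
    flagged as expansion copies."""
    import networkx as nx

    locus_by_id = {l.gene_id: l for l in loci}
    g = nx.Graph()
    identity: dict[frozenset, float] = {}
    for p in pairs:
        if p.unanchored:
            continue
        la, lb = locus_by_id[p.gene_a], locus_by_id[p.gene_b]
        identity[frozenset((p.gene_a, p.gene_b))] = p.identity_pct
        if la.subgenome != lb.subgenome:
            g.add_edge(p.gene_a, p.gene_b)
    groups: list[HomoeologGroup] = []
    for comp in sorted(nx.connected_components(g), key=min):
        by_sub: dict[str, list[str]] = {}
        for gene in comp:
            by_sub.setdefault(locus_by_id[gene].subgenome, []).append(gene)
        members: dict[str, str] = {}
        extras: list[str] = []
        for sub, genes in sorted(by_sub.items()):
            def mean_cross_identity(gene: str) -> float:
                vals = [
                    identity.get(frozenset((gene, other)), 0.0)
                    for other in comp
                    if locus_by_id[other].subgenome != sub
                ]
                return sum(vals) / len(vals) if vals else 0.0

            canonical = min(genes, key=lambda x: (-mean_cross_identity(x), x))
            members[sub] = canonical
            extras.extend(sorted(set(genes) - {canonical}))
        groups.append(
            HomoeologGroup(f"HG{len(groups) + 1}", members, sorted(extras))
        )
    return groups
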