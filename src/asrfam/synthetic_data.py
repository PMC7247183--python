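"""Synthetic genomes, expression matrices and qPCR tables with known truth.

The generator emulates the statistical structure of an allopolyploid
gene-family survey: a family protein evolved into groups and homoeolog
triads across A/B/D subgenomes, tandem arrays with controlled spacings
straddling the 150-kb rule, shuffled decoy proteins, promoters with
planted PWM sites, group-structured log-normal FPKM values, and Ct tables
with planted ddCT effects. Every planted feature is recorded in truth
tables so downstream modules can be scored exactly. All outputs are pure
functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import jtt
from .motifs import PWM
from .seqio import GeneLocus, GeneStructure, SequenceRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticGenome",
    "generate_family_genome",
    "generate_paper_shaped_family",
    "generate_expression",
    "generate_qpcr",
    "write_genome_files",
]

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"], "E": ["GAA", "GAG"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "K": ["AAA", "AAG"],
    "M": ["ATG"], "F": ["TTT", "TTC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "W": ["TGG"], "Y": ["TAT", "TAC"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
}


@dataclass
class SyntheticConfig:
    seed: int
    subgenomes: tuple = ("A", "B", "D")
    chromosome_group: int = 3
    n_triads: int = 5
    tandem_array_sizes: tuple = (3,)
    spacing_range_bp: tuple = (5_000, 200_000)
    triad_identity: float = 0.96
    between_group_identity: float = 0.45
    protein_length: int = 150
    n_decoys: int = 50
    intron_length_range: tuple = (50, 500)
    promoter_length: int = 2000
    planted_pwms: list = field(default_factory=list)
    sites_per_promoter: int = 1
    expression_sd: float = 0.4
    qpcr_noise_sd: float = 0.2
    qpcr_replicates: int = 3

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 < self.triad_identity < 1 or not 0 < self.between_group_identity < 1:
            raise ValueError("identity targets must lie in (0, 1)")


@dataclass
class SyntheticGenome:
    genome: dict[str, SequenceRecord]  # chromosome -> sequence
    loci: list[GeneLocus]
    structures: list[GeneStructure]
    proteome: list[SequenceRecord]  # family members + decoys
    cds: dict[str, SequenceRecord]
    seed_alignment: list[SequenceRecord]  # group ancestors (ungapped, aligned)
    truth: dict[str, pd.DataFrame]


def _mutate(protein: str, fraction: float, rng: np.random.Generator) -> str:
    """Per-site substitution toward a target divergence, JTT-conditional."""
    L = len(protein)
    n_mut = int(round(fraction * L))
    if n_mut == 0:
        return protein
    idx = {ch: k for k, ch in enumerate(jtt.AA_ORDER)}
    P = jtt.transition_matrix(0.5)
    positions = rng.choice(L, size=n_mut, replace=False)
    out = list(protein)
    for pos in positions:
        row = P[idx[out[pos]]].copy()
        row[idx[out[pos]]] = 0.0
        row /= row.sum()
        out[pos] = jtt.AA_ORDER[rng.choice(20, p=row)]
    return "".join(out)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    codes = rng.choice(20, size=length, p=jtt.FREQUENCIES)
    return "".join(jtt.AA_ORDER[c] for c in codes)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein
    ) + "TAA"


_DNA_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    if n == 0:
        return ""
    return _DNA_BYTES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


@dataclass
class _GeneSpec:
    gene_id: str
    group: str
    chromosome: str
    protein: str
    spacing_to_prev: int | None  # None -> non-tandem gap
    strand: str
    in_array: bool


def _build_genome(specs: list[_GeneSpec], cfg: SyntheticConfig, rng: np.random.Generator):
    """Assemble chromosome sequences from gene specs; returns genome pieces."""
    genome: dict[str, str] = {}
    loci: list[GeneLocus] = []
    structures: list[GeneStructure] = []
    cds_records: dict[str, SequenceRecord] = {}
    site_rows = []
    by_chrom: dict[str, list[_GeneSpec]] = {}
    for s in specs:
        by_chrom.setdefault(s.chromosome, []).append(s)
    plen = cfg.promoter_length
    for chrom in sorted(by_chrom):
        parts: list[str] = [_random_dna(1000, rng)]
        pos = 1000  # 0-based length so far
        prev_end: int | None = None
        for spec in by_chrom[chrom]:
            cds = _back_translate(spec.protein, rng)
            split = int(rng.integers(3, len(cds) - 3))
            intron = _random_dna(int(rng.integers(*cfg.intron_length_range)), rng)
            # keep the splice boundary unambiguous for exact-match inference
            others = [b for b in "ACGT" if b != cds[split]]
            if intron[0] == cds[split]:
                intron = others[int(rng.integers(0, 3))] + intron[1:]
            if intron[-1] == cds[split - 1]:
                choices = [b for b in "ACGT" if b != cds[split - 1]]
                intron = intron[:-1] + choices[int(rng.integers(0, 3))]
            gene_seq = cds[:split] + intron + cds[split:]
            promoter = list(_random_dna(plen, rng))
            for pwm in cfg.planted_pwms:
                for _ in range(cfg.sites_per_promoter):
                    off = int(rng.integers(0, plen - pwm.width))
                    promoter[off : off + pwm.width] = list(pwm.consensus)
                    site_rows.append(
                        {"gene_id": spec.gene_id, "tf_name": pwm.name,
                         "offset_1based": off + 1, "site": pwm.consensus}
                    )
            promoter = "".join(promoter)
            if spec.spacing_to_prev is not None and prev_end is not None:
                # exact nearer-end separation: spacing bases between genes
                gap = spec.spacing_to_prev - (plen if spec.strand == "+" else 0)
                if gap < 0:
                    raise ValueError(
                        f"{spec.gene_id}: spacing {spec.spacing_to_prev} too small "
                        f"for a {plen}-bp promoter"
                    )
                filler = _random_dna(gap, rng)
            else:
                filler = _random_dna(int(rng.integers(250_000, 320_000)), rng)
            if spec.strand == "+":
                parts.extend([filler, promoter, gene_seq])
                start0 = pos + len(filler) + len(promoter)
            else:
                parts.extend([filler, gene_seq,
                              str(SequenceRecord("p", promoter, "dna").reverse_complement().residues)])
                start0 = pos + len(filler)
            end0 = start0 + len(gene_seq)  # half-open
            pos += len(filler) + len(promoter) + len(gene_seq)
            loci.append(GeneLocus(spec.gene_id, chrom, start0 + 1, end0, spec.strand))
            prev_end = end0
            if spec.strand == "+":
                exons = [(1, split), (split + len(intron) + 1, len(gene_seq))]
                cds_seq = cds
            else:
                # gene written on the minus strand: store reverse complement
                gene_rc = str(SequenceRecord("g", gene_seq, "dna").reverse_complement().residues)
                parts[-2] = gene_rc
                exons = [(1, split), (split + len(intron) + 1, len(gene_seq))]
                cds_seq = cds
            structures.append(GeneStructure(spec.gene_id, exons, provenance="annotation"))
            cds_records[spec.gene_id] = SequenceRecord(spec.gene_id, cds_seq, "dna")
        parts.append(_random_dna(1000, rng))
        genome[chrom] = "".join(parts)
    genome_records = {c: SequenceRecord(c, s, "dna") for c, s in genome.items()}
    return genome_records, loci, structures, cds_records, pd.DataFrame(site_rows)


def generate_family_genome(cfg: SyntheticConfig) -> SyntheticGenome:
    """Generate a genome with planted triads, tandem arrays and decoys."""
    rng = np.random.default_rng(cfg.seed)
    ancestor = _random_protein(cfg.protein_length, rng)
    f_between = (1.0 - cfg.between_group_identity) / 2.0
    f_within = (1.0 - cfg.triad_identity) / 2.0
    specs: list[_GeneSpec] = []
    triad_rows = []
    array_rows = []
    seed_alignment = []
    grp_num = cfg.chromosome_group
    for t in range(cfg.n_triads):
        group_anc = _mutate(ancestor, f_between, rng)
        seed_alignment.append(SequenceRecord(f"anc_T{t + 1}", group_anc))
        members = {}
        for sub in cfg.subgenomes:
            gid = f"T{t + 1}{sub}"
            members[sub] = gid
            specs.append(
                _GeneSpec(gid, f"triad_{t + 1}", f"{grp_num}{sub}",
                          _mutate(group_anc, f_within, rng), None, "+", False)
            )
        triad_rows.append({"group": f"triad_{t + 1}", **members})
    for a, size in enumerate(cfg.tandem_array_sizes):
        group_anc = _mutate(ancestor, f_between, rng)
        seed_alignment.append(SequenceRecord(f"anc_R{a + 1}", group_anc))
        spacings = [int(rng.integers(*cfg.spacing_range_bp)) for _ in range(size - 1)]
        members = []
        for j in range(size):
            gid = f"R{a + 1}A{j + 1}"
            members.append(gid)
            specs.append(
                _GeneSpec(gid, f"array_{a + 1}", f"{grp_num}A",
                          _mutate(group_anc, f_within, rng),
                          spacings[j - 1] if j > 0 else None, "+", True)
            )
        array_rows.append(
            {"chromosome": f"{grp_num}A", "members": ",".join(members),
             "spacings_bp": ",".join(map(str, spacings))}
        )
    if len(seed_alignment) < 2:
        seed_alignment = [SequenceRecord("anc_root", ancestor)] + seed_alignment
    genome, loci, structures, cds, motif_truth = _build_genome(specs, cfg, rng)
    proteome = [SequenceRecord(s.gene_id, s.protein) for s in specs]
    family_ids = {s.gene_id for s in specs}
    for i in range(cfg.n_decoys):
        base = specs[i % len(specs)].protein if specs else ancestor
        shuffled = "".join(np.array(list(base))[rng.permutation(len(base))])
        proteome.append(SequenceRecord(f"decoy{i + 1}", shuffled))
    gene_rows = [
        {"gene_id": s.gene_id, "group": s.group, "chromosome": s.chromosome,
         "subgenome": s.chromosome[-1] if s.chromosome[-1] in "ABD" else "U",
         "in_array": s.in_array, "protein": s.protein}
        for s in specs
    ]
    truth = {
        "genes": pd.DataFrame(gene_rows),
        "triads": pd.DataFrame(triad_rows),
        "arrays": pd.DataFrame(array_rows),
        "motif_sites": motif_truth,
        "family_ids": pd.DataFrame({"gene_id": sorted(family_ids)}),
    }
    return SyntheticGenome(genome, loci, structures, proteome, cds, seed_alignment, truth)


_PAPER_SHAPE = [
    # (gene_id, group, chromosome) -- 33 genes, 6 groups, a 7-member
    # identical group (6 tandem on 3A + 1 unanchored), triads on
    # chromosome groups 2/3/4, and a B/D-only pair in group 5.
    ("syn1D", "I", "3D"), ("syn1B", "I", "3B"), ("syn1A", "I", "3A"),
    ("syn2A", "I", "3A"), ("syn2D", "I", "3D"), ("syn2B", "I", "3B"),
    ("syn3A1", "I", "3A"), ("syn3D", "I", "3D"), ("syn3B", "I", "3B"),
    ("syn3A2", "I", "3A"),
    ("syn4D", "II", "4D"), ("syn4B", "II", "4B"), ("syn4A", "II", "4A"),
    ("syn5A", "III", "2A"), ("syn5B", "III", "2B"), ("syn5D", "III", "2D"),
    ("syn6D", "IV", "3D"), ("syn6A", "IV", "3A"), ("syn6B", "IV", "3B"),
    ("syn7D1", "IV", "3D"), ("syn7D2", "IV", "3D"),
    ("syn8B", "V", "3B"), ("syn8D", "V", "3D"), ("syn9A", "V", "3A"),
    ("syn9B", "V", "3B"), ("syn9D", "V", "3D"),
    ("syn10A1", "VI", "3A"), ("syn10A2", "VI", "3A"), ("syn10U", "VI", "Un"),
    ("syn10A3", "VI", "3A"), ("syn10A4", "VI", "3A"), ("syn10A5", "VI", "3A"),
    ("syn10A6", "VI", "3A"),
]


def generate_paper_shaped_family(seed: int, cfg: SyntheticConfig | None = None) -> SyntheticGenome:
    """A 33-gene family shaped like the wheat survey: 6 groups of sizes
    10/3/3/5/5/7, the 7-member group sequence-identical (6 tandem copies
    plus one unanchored), homoeolog triads on chromosome groups 2/3/4.
    All sequences are synthetic."""
    if cfg is None:
        cfg = SyntheticConfig(seed=seed)
    rng = np.random.default_rng(seed)
    ancestor = _random_protein(cfg.protein_length, rng)
    f_between = (1.0 - cfg.between_group_identity) / 2.0
    f_within = (1.0 - cfg.triad_identity) / 2.0
    groups = sorted({g for _, g, _ in _PAPER_SHAPE})
    group_anc = {}
    seed_alignment = []
    for g in groups:
        group_anc[g] = _mutate(ancestor, f_between, rng)
        seed_alignment.append(SequenceRecord(f"anc_{g}", group_anc[g]))
    proteins = {}
    for gid, g, _ in _PAPER_SHAPE:
        if g == "VI":
            proteins[gid] = group_anc[g]  # identical copies
        else:
            proteins[gid] = _mutate(group_anc[g], f_within, rng)
    specs = []
    tandem_chrom_count: dict[str, int] = {}
    for gid, g, chrom in _PAPER_SHAPE:
        if chrom == "Un":
            continue
        n_before = tandem_chrom_count.get(chrom, 0)
        tandem_chrom_count[chrom] = n_before + 1
        # same-group neighbors sit within the tandem window; groups are
        # separated by large gaps (handled by spacing=None)
        same_group_prev = any(
            s.chromosome == chrom and s.group == g for s in specs
        )
        spacing = int(rng.integers(20_000, 60_000)) if same_group_prev else None
        specs.append(_GeneSpec(gid, g, chrom, proteins[gid], spacing, "+", same_group_prev))
    genome, loci, structures, cds, motif_truth = _build_genome(specs, cfg, rng)
    # unanchored copy: own scaffold, no tandem context
    un_spec = [s for s in [_GeneSpec("syn10U", "VI", "Un", proteins["syn10U"], None, "+", False)]]
    g2, l2, s2, c2, _ = _build_genome(un_spec, cfg, rng)
    genome.update(g2)
    loci.extend(l2)
    structures.extend(s2)
    cds.update(c2)
    proteome = [SequenceRecord(gid, proteins[gid]) for gid, _, _ in _PAPER_SHAPE]
    gene_rows = [
        {"gene_id": gid, "group": g, "chromosome": chrom,
         "subgenome": chrom[-1] if chrom[-1] in "ABD" else "U",
         "in_array": False, "protein": proteins[gid]}
        for gid, g, chrom in _PAPER_SHAPE
    ]
    truth = {
        "genes": pd.DataFrame(gene_rows),
        "triads": pd.DataFrame(),
        "arrays": pd.DataFrame(),
        "motif_sites": motif_truth,
        "family_ids": pd.DataFrame({"gene_id": sorted(p[0] for p in _PAPER_SHAPE)}),
    }
    return SyntheticGenome(genome, loci, structures, proteome, cds, seed_alignment, truth)


_TISSUE_STAGES = [
    "grain_Z71", "grain_Z75", "grain_Z85", "leaf_Z10", "leaf_Z23", "leaf_Z71",
    "root_Z10", "root_Z13", "root_Z39", "spike_Z32", "spike_Z39", "spike_Z65",
    "stem_Z30", "stem_Z32", "stem_Z65",
]


def generate_expression(
    cfg: SyntheticConfig,
    groups: dict[str, str],
    group_means: dict[str, dict[str, float]] | None = None,
    specific_group: str | None = None,
    specific_condition: str = "stem_Z30",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-structured log-normal FPKM matrix (genes x tissue_stage).

    ``group_means`` maps group -> condition -> mean of log FPKM; unlisted
    conditions default to 1.0. ``specific_group`` expresses only in
    ``specific_condition`` (exact zeros elsewhere).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    conds = _TISSUE_STAGES
    if group_means is None:
        group_means = {}
        for i, g in enumerate(sorted(set(groups.values()))):
            group_means[g] = {c: (3.0 if (j + i) % 2 == 0 else 0.5)
                              for j, c in enumerate(conds)}
    rows = {}
    design = []
    for gene in sorted(groups):
        g = groups[gene]
        vals = []
        for c in conds:
            if specific_group is not None and g == specific_group and c != specific_condition:
                vals.append(0.0)
                continue
            mu = group_means.get(g, {}).get(c, 1.0)
            vals.append(float(np.exp(rng.normal(mu, cfg.expression_sd))))
        rows[gene] = vals
        design.append({"gene_id": gene, "group": g})
    df = pd.DataFrame.from_dict(rows, orient="index", columns=conds)
    df.index.name = "gene_id"
    return df, pd.DataFrame(design)


QPCR_DESIGN = [("NaCl", 6.0), ("NaCl", 24.0), ("PEG", 6.0), ("PEG", 48.0)]


def generate_qpcr(
    cfg: SyntheticConfig,
    genes: list[str],
    ddct_map: dict[tuple, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct table with planted ddCT effects, full factorial design.

    Cells: {NaCl(6, 24 h), PEG(6, 48 h)} x {leaf, root} plus one control
    cell per tissue, ``cfg.qpcr_replicates`` replicates each. ``ddct_map``
    keys are (gene, condition, timepoint_h, tissue); missing keys mean a
    null effect.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    ddct_map = ddct_map or {}
    rows = []
    truth = []
    for gene in genes:
        base_dct = float(rng.uniform(1.0, 6.0))
        for tissue in ("leaf", "root"):
            for rep in range(1, cfg.qpcr_replicates + 1):
                ref = float(rng.normal(18.0, 0.05))
                dct = base_dct + float(rng.normal(0.0, cfg.qpcr_noise_sd))
                rows.append(
                    {"gene_id": gene, "condition": "control", "timepoint_h": 0.0,
                     "tissue": tissue, "replicate": rep,
                     "ct_target": ref + dct, "ct_reference": ref}
                )
            for cond, tp in QPCR_DESIGN:
                ddct = float(ddct_map.get((gene, cond, tp, tissue), 0.0))
                truth.append(
                    {"gene_id": gene, "condition": cond, "timepoint_h": tp,
                     "tissue": tissue, "ddct": ddct,
                     "fold_change": 2.0 ** (-ddct)}
                )
                for rep in range(1, cfg.qpcr_replicates + 1):
                    ref = float(rng.normal(18.0, 0.05))
                    dct = base_dct + ddct + float(rng.normal(0.0, cfg.qpcr_noise_sd))
                    rows.append(
                        {"gene_id": gene, "condition": cond, "timepoint_h": tp,
                         "tissue": tissue, "replicate": rep,
                         "ct_target": ref + dct, "ct_reference": ref}
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth)


def write_genome_files(syn: SyntheticGenome, outdir) -> dict[str, str]:
    """Write genome FASTA, proteome FASTA, GFF3 and truth TSVs."""
    from pathlib import Path

    from .seqio import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_fasta(list(syn.genome.values()), outdir / "genome.fasta")
    paths["genome"] = str(outdir / "genome.fasta")
    write_fasta(syn.proteome, outdir / "proteome.fasta")
    paths["proteome"] = str(outdir / "proteome.fasta")
    write_fasta(syn.seed_alignment, outdir / "seed_alignment.fasta")
    paths["seed_alignment"] = str(outdir / "seed_alignment.fasta")
    if syn.cds:
        write_fasta(list(syn.cds.values()), outdir / "cds.fasta")
        paths["cds"] = str(outdir / "cds.fasta")
    gff = outdir / "annotation.gff3"
    struct_by_id = {s.gene_id: s for s in syn.structures}
    with open(gff, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for locus in sorted(syn.loci, key=lambda l: (l.chromosome, l.start_bp)):
            strand = locus.strand if locus.strand in "+-" else "."
            fh.write(
                f"{locus.chromosome}\tsynthetic\tgene\t{locus.start_bp}\t{locus.end_bp}"
                f"\t.\t{strand}\t.\tID={locus.gene_id}\n"
            )
            st = struct_by_id.get(locus.gene_id)
            if st is None:
                continue
            mrna = f"{locus.gene_id}.1"
            fh.write(
                f"{locus.chromosome}\tsynthetic\tmRNA\t{locus.start_bp}\t{locus.end_bp}"
                f"\t.\t{strand}\t.\tID={mrna};Parent={locus.gene_id}\n"
            )
            for s, e in st.exons:
                if locus.strand == "-":
                    gs = locus.end_bp - e + 1
                    ge = locus.end_bp - s + 1
                else:
                    gs = locus.start_bp + s - 1
                    ge = locus.start_bp + e - 1
                fh.write(
                    f"{locus.chromosome}\tsynthetic\texon\t{gs}\t{ge}\t.\t{strand}\t.\t"
                    f"Parent={mrna}\n"
                )
    paths["gff3"] = str(gff)
    for name, df in syn.truth.items():
        p = outdir / f"truth_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"truth_{name}"] = str(p)
    return paths
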