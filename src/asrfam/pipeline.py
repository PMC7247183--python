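"""End-to-end orchestration of the family characterization run.

Stages run in a fixed order (identify -> protparam -> phylo -> duplication
-> structure -> motifs -> tfbs -> expression -> qpcr); a stage whose input
is absent is marked skipped. Outputs are per-stage TSVs plus a JSON run
manifest recording the seed, every threshold actually used, and input
checksums. Stage outputs are pure functions of inputs + config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import duplication, expression, homology, motifs, phylo, protparam, seqio

log = logging.getLogger("asrfam")

STAGES = [
    "identify", "protparam", "phylo", "duplication", "structure",
    "motifs", "tfbs", "expression", "qpcr",
]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and run parameters; defaults are the survey's
    published thresholds."""

    proteome: str | None = None
    genome: str | None = None
    gff3: str | None = None
    seed_alignment: str | None = None
    pwms: str | None = None
    expression: str | None = None
    qpcr: str | None = None
    locus_table: str | None = None

    family_evalue_max: float = 1e-10
    homolog_evalue_max: float = 1e-20
    homolog_identity_min: float = 75.0
    tandem_window_bp: int = 150_000
    promoter_length_bp: int = 2000
    motif_width_min: int = 6
    motif_width_max: int = 50
    max_motifs: int = 20
    bootstrap_reps: int = 1000
    n_groups: int = 6
    tfbs_p_max: float = 1e-4
    distance_model: str = "poisson"

    seed: int = 0
    outdir: str = "asrfam_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages; returns the run manifest dict."""
    stages = stages or STAGES
    bad = set(stages) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages {sorted(bad)}")
    if cfg.proteome is None and cfg.locus_table is None:
        raise ValueError("a proteome or a locus table is mandatory")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "thresholds": {
            k: getattr(cfg, k)
            for k in (
                "family_evalue_max", "homolog_evalue_max", "homolog_identity_min",
                "tandem_window_bp", "promoter_length_bp", "motif_width_min",
                "motif_width_max", "max_motifs", "bootstrap_reps", "n_groups",
                "tfbs_p_max", "distance_model",
            )
        },
        "inputs": {},
        "stages": {},
        "outputs": {},
    }
    for key in ("proteome", "genome", "gff3", "seed_alignment", "pwms",
                "expression", "qpcr", "locus_table"):
        p = getattr(cfg, key)
        if p:
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

    proteome = seqio.read_fasta(cfg.proteome) if cfg.proteome else None
    loci: list[seqio.GeneLocus] = []
    structures: list[seqio.GeneStructure] = []
    if cfg.gff3:
        structures, loci = seqio.read_gff3(cfg.gff3)
    elif cfg.locus_table:
        df = seqio.load_family_table(cfg.locus_table)
        loci = seqio.family_table_loci(df)

    family = proteome

    def emit(name: str, df: pd.DataFrame):
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        manifest["outputs"][name] = str(p)

    def run_stage(name: str, needed: list, fn):
        if name not in stages:
            manifest["stages"][name] = "not requested"
            return
        if any(x is None or (isinstance(x, list) and not x) for x in needed):
            manifest["stages"][name] = "skipped (missing input)"
            log.info("stage %s skipped", name)
            return
        log.info("stage %s running", name)
        fn()
        manifest["stages"][name] = "ok"

    # --- identify -----------------------------------------------------
    def do_identify():
        nonlocal family
        seeds = seqio.read_fasta(cfg.seed_alignment)
        profile = homology.build_profile(seeds)
        hits = homology.identify_family(
            proteome, profile, evalue_max=cfg.family_evalue_max
        )
        emit("family_hits", hits)
        kept_ids: set[str] = set()
        for _, row in hits[hits["kept"]].iterrows():
            kept_ids.update(row["members"].split(","))
        family = [r for r in proteome if r.id in kept_ids]

    run_stage("identify", [proteome, cfg.seed_alignment], do_identify)

    # --- protparam ----------------------------------------------------
    def do_protparam():
        rows = [protparam.compute_protparam(r).display_row() for r in family]
        emit("protparam", pd.DataFrame(rows))

    run_stage("protparam", [family], do_protparam)

    # --- phylo --------------------------------------------------------
    groups_assignment = None

    def do_phylo():
        nonlocal groups_assignment
        msa = phylo.progressive_align(family)
        tree = phylo.bootstrap_supports(
            msa, n_reps=cfg.bootstrap_reps, seed=cfg.seed, model=cfg.distance_model
        )
        (outdir / "tree.nwk").write_text(tree.newick() + "\n")
        manifest["outputs"]["tree"] = str(outdir / "tree.nwk")
        k = min(cfg.n_groups, len(family))
        groups_assignment = phylo.extract_groups(tree, k=k)
        emit("groups", pd.DataFrame(
            sorted(groups_assignment.groups.items()), columns=["gene_id", "group"]
        ))

    run_stage("phylo", [family if family and len(family) >= 3 else None], do_phylo)

    # --- duplication --------------------------------------------------
    def do_duplication():
        pairs = duplication.find_homolog_pairs(
            family, loci,
            evalue_max=cfg.homolog_evalue_max,
            identity_min=cfg.homolog_identity_min,
        )
        emit("homolog_pairs", pd.DataFrame([vars(p) for p in pairs]))
        arrays, segmental = duplication.classify_duplications(
            pairs, loci, window_bp=cfg.tandem_window_bp
        )
        emit("tandem_arrays", pd.DataFrame(
            [{"chromosome": a.chromosome, "members": ",".join(a.members),
              "n_pairs": a.n_pairs,
              "separations_bp": ",".join(map(str, a.separations))}
             for a in arrays]
        ))
        emit("segmental_pairs", pd.DataFrame([vars(s) for s in segmental]))
        emit("homoeolog_groups", pd.DataFrame(
            [{"label": h.label, **h.members,
              "expansion_copies": ",".join(h.expansion_copies)}
             for h in duplication.assign_homoeologs(pairs, loci)]
        ))
        summ = duplication.summarize_chromosomes(loci)
        for key, df in summ.items():
            emit(f"summary_{key}", df)
        # CIRCOS-style two-interval link file for the segmental pairs
        locus_by_id = {l.gene_id: l for l in loci}
        with open(outdir / "links.txt", "w", newline="\n") as fh:
            for s in segmental:
                la, lb = locus_by_id[s.gene_a], locus_by_id[s.gene_b]
                fh.write(
                    f"{la.chromosome} {la.start_bp} {la.end_bp} "
                    f"{lb.chromosome} {lb.start_bp} {lb.end_bp}\n"
                )
        manifest["outputs"]["links"] = str(outdir / "links.txt")

    run_stage("duplication", [family, loci], do_duplication)

    # --- structure ----------------------------------------------------
    def do_structure():
        emit("gene_structure", pd.DataFrame(
            [{"gene_id": s.gene_id, "n_exons": len(s.exons),
              "exons": ";".join(f"{a}-{b}" for a, b in s.exons),
              "introns": ";".join(f"{a}-{b}" for a, b in s.introns),
              "provenance": s.provenance}
             for s in structures]
        ))

    run_stage("structure", [structures], do_structure)

    # --- motifs -------------------------------------------------------
    def do_motifs():
        models = motifs.discover_motifs(
            family, max_motifs=cfg.max_motifs,
            width_range=(cfg.motif_width_min, cfg.motif_width_max),
            seed=cfg.seed,
        )
        emit("motifs", pd.DataFrame(
            [{"motif": m.pwm.name, "width": m.width, "consensus": m.pwm.consensus,
              "n_sites": len(m.sites), "score": m.score}
             for m in models]
        ))
        emit("motif_sites", pd.DataFrame(
            [{"motif": m.pwm.name, "sequence_id": sid, "offset_1based": off + 1}
             for m in models for sid, off in m.sites]
        ))

    run_stage("motifs", [family if family and len(family) >= 2 else None], do_motifs)

    # --- tfbs ---------------------------------------------------------
    def do_tfbs():
        genome = {r.id: r for r in seqio.read_fasta(cfg.genome, alphabet="dna")}
        pwms = motifs.read_jaspar(cfg.pwms) if _looks_jaspar(cfg.pwms) \
            else motifs.read_meme_minimal(cfg.pwms)
        anchored = [l for l in loci if l.strand in "+-"]
        proms = motifs.extract_promoters(genome, anchored, cfg.promoter_length_bp)
        hits, counts = motifs.scan_pwm(proms, pwms, p_max=cfg.tfbs_p_max)
        emit("tfbs_hits", pd.DataFrame([vars(h) for h in hits]))
        counts.index.name = "gene_id"
        emit("tfbs_counts", counts.reset_index())

    run_stage("tfbs", [cfg.genome, cfg.pwms, loci], do_tfbs)

    # --- expression ---------------------------------------------------
    def do_expression():
        mat = pd.read_csv(cfg.expression, sep="\t", index_col=0)
        spec = expression.transform_fpkm(mat)
        out = spec.matrix.loc[spec.row_order]
        out.index.name = "gene_id"
        emit("expression_log2", out.reset_index())

    run_stage("expression", [cfg.expression], do_expression)

    # --- qpcr ---------------------------------------------------------
    def do_qpcr():
        records = pd.read_csv(cfg.qpcr)
        results = expression.ddct_fold_change(records)
        calls = expression.call_stress_response(results)
        emit("qpcr_results", calls)
        emit("qpcr_summary", calls.attrs["summary"])

    run_stage("qpcr", [cfg.qpcr], do_qpcr)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _looks_jaspar(path) -> bool:
    with open(path) as fh:
        head = fh.read(2048)
    return ">" in head and "MEME" not in head
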