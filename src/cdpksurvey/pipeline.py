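"""Survey orchestration: every stage from one configuration, with full
parameter provenance in the report bundle.

Stages run in dependency order (identification -> phylogeny/groups ->
motifs -> duplications -> network projection -> enrichment -> expression ->
qPCR), each writing plain-text outputs into the bundle directory.  A stage
failure halts the run with the stage name and the offending input.  Two
runs with the same seed produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import core_io, dups, expression, go, grn, identify, motifs, phylo, synth
from .msa import progressive_align, write_aligned_fasta

log = logging.getLogger("cdpksurvey")

STAGES = (
    "inputs", "family_identification", "phylogeny", "motif_discovery",
    "duplication_analysis", "grn_projection", "go_enrichment",
    "expression_qpcr",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All survey thresholds, defaulting to the published parameterisation:
    screen coverage 0.80 at e <= 1e-5, dual-domain confirmation, 1000
    bootstrap replicates, up to 10 motifs of width 6-50 with any number of
    repetitions, duplication rules >0.8/>0.8, enrichment alpha 0.05 and the
    FPKM > 1 expressed filter."""

    seed: int = 0
    synthetic: bool = True
    # input paths (used when synthetic is False)
    target_proteome: str | None = None
    reference_proteome: str | None = None
    reference_groups: str | None = None
    annotation_gff: str | None = None
    reference_network: str | None = None
    counts: str | None = None
    gene_lengths: str | None = None
    library_sizes: str | None = None
    ct_table: str | None = None
    go_annotations: str | None = None
    go_ontology: str | None = None
    family_table: str | None = None
    # thresholds (published defaults)
    min_coverage: float = 0.80
    evalue_cutoff: float = 1e-5
    domain_min_score_fraction: float = 0.60
    bootstrap_replicates: int = 1000
    max_motifs: int = 10
    motif_w_min: int = 6
    motif_w_max: int = 50
    dup_min_identity: float = 0.8
    dup_min_coverage: float = 0.8
    max_intervening: int = 1
    tandem_max_distance_bp: int = 100_000
    rbh_strict: bool = True
    subnetwork_hops: int = 1
    go_alpha: float = 0.05
    min_fpkm: float = 1.0
    lfc_threshold: float = 1.0
    control_timepoint: str = "0H"
    name_prefix: str = "TrCDPK"
    generator: dict = field(default_factory=dict)
    skip_stages: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _require(config: PipelineConfig, attr: str, stage: str) -> Path:
    value = getattr(config, attr)
    if value is None:
        raise StageError(stage, f"missing required input path {attr!r}")
    p = Path(value)
    if not p.exists():
        raise StageError(stage, f"input {attr} not found: {p}")
    return p


def run_survey(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full survey; returns the report dictionary (also written
    to ``<outdir>/report.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "parameters": dataclasses.asdict(config),
        "stages": {},
    }
    skip = set(config.skip_stages)

    # ---------------- inputs -------------------------------------------
    if config.synthetic:
        gen_cfg = synth.GeneratorConfig(seed=config.seed, **config.generator)
        bundle = synth.generate_all(gen_cfg, outdir / "inputs")
        paths = {
            "target_proteome": bundle.target_fasta,
            "reference_proteome": bundle.reference_fasta,
            "reference_groups": outdir / "inputs" / "reference_groups.tsv",
            "annotation_gff": bundle.gff_path,
            "reference_network": bundle.network_path,
            "counts": bundle.counts_path,
            "gene_lengths": bundle.lengths_path,
            "library_sizes": bundle.library_sizes_path,
            "ct_table": bundle.ct_path,
            "go_annotations": bundle.annotations_path,
            "go_ontology": bundle.ontology_path,
        }
        log.info("inputs: synthetic bundle generated (seed=%d)", config.seed)
    else:
        paths = {}
    report["stages"]["inputs"] = {"synthetic": config.synthetic}

    def input_path(attr: str, stage: str) -> Path:
        if config.synthetic:
            return paths[attr]
        return _require(config, attr, stage)

    # ---------------- family identification ----------------------------
    stage = "family_identification"
    targets = core_io.read_fasta(input_path("target_proteome", stage))
    references = core_io.read_fasta(input_path("reference_proteome", stage))
    import pandas as pd

    ref_groups = dict(
        pd.read_csv(input_path("reference_groups", stage), sep="\t").values
    )
    ref_family = [r for r in references if r.seq_id in ref_groups]
    if not ref_family:
        raise StageError(stage, "no reference proteins carry group labels")
    candidates = identify.screen_candidates(
        ref_family, targets, config.min_coverage, config.evalue_cutoff
    )
    models = tuple(
        dataclasses.replace(m, min_score_fraction=config.domain_min_score_fraction)
        for m in identify.DEFAULT_DOMAIN_MODELS
    )
    by_id = {t.seq_id: t for t in targets}
    domain_hits = {c: identify.scan_domains(by_id[c], models) for c in candidates}
    members = identify.confirm_members(candidates, domain_hits)
    with open(outdir / "domain_hits.tsv", "w") as fh:
        fh.write("protein_id\tdomain\tstart\tend\tscore\n")
        for c in sorted(domain_hits):
            for h in sorted(domain_hits[c], key=lambda h: (h.start, h.domain_label)):
                fh.write(
                    f"{h.protein_id}\t{h.domain_label}\t{h.start}\t{h.end}\t"
                    f"{h.hit_score:.1f}\n"
                )
    gene_records = {
        r.gene_id: r for r in core_io.read_gff3(input_path("annotation_gff", stage))
    }
    log.info(
        "%s: %d candidates -> %d confirmed members", stage, len(candidates),
        len(members),
    )
    report["stages"][stage] = {
        "n_targets": len(targets), "n_candidates": len(candidates),
        "n_members": len(members),
    }

    # ---------------- phylogeny and groups ------------------------------
    stage = "phylogeny"
    member_seqs = [by_id[m] for m in sorted(members)]
    ref_by_id = {r.seq_id: r for r in references}
    tree_seqs = member_seqs + [ref_by_id[r] for r in sorted(ref_groups)]
    aln = progressive_align(tree_seqs)
    write_aligned_fasta(aln, outdir / "family_alignment.fasta")
    tree = phylo.bootstrap_support(
        aln, n_replicates=config.bootstrap_replicates, seed=config.seed
    )
    tree.write_newick(outdir / "family_tree.nwk")
    groups = phylo.assign_groups(tree, ref_groups)
    log.info("%s: %d leaves, %d members grouped", stage, len(aln.ids),
             sum(g != core_io.UNGROUPED for g in groups.values()))
    report["stages"][stage] = {
        "n_leaves": len(aln.ids),
        "n_grouped": sum(g != core_io.UNGROUPED for g in groups.values()),
        "bootstrap_replicates": config.bootstrap_replicates,
    }

    table = identify.build_family_table(
        members, gene_records, by_id, groups, config.name_prefix
    )
    core_io.write_family_table(table, outdir / "family_table.tsv")
    summary = core_io.summarize_family_table(table)
    report["family_summary"] = {
        "n_members": summary.n_members,
        "max_length": list(summary.max_length),
        "min_length": list(summary.min_length),
        "max_introns": list(summary.max_introns),
        "min_introns": summary.min_introns,
        "per_chromosome": dict(sorted(summary.per_chromosome.items())),
        "per_group": dict(sorted(summary.per_group.items())),
    }

    # ---------------- motifs --------------------------------------------
    stage = "motif_discovery"
    if stage not in skip:
        found = motifs.discover_motifs(
            member_seqs, config.max_motifs, config.motif_w_min,
            config.motif_w_max, seed=config.seed,
        )
        motifs.write_meme_minimal(found, None, outdir / "motifs.meme.txt")
        occ = motifs.occurrence_matrix(found, member_seqs)
        occ.to_csv(outdir / "motif_occurrences.tsv", sep="\t")
        shared = motifs.shared_motifs(occ) if found else []
        report["stages"][stage] = {
            "n_motifs": len(found), "shared_by_all": shared,
        }
        log.info("%s: %d motifs, %d shared by all", stage, len(found),
                 len(shared))

    # ---------------- duplications --------------------------------------
    stage = "duplication_analysis"
    pairs = dups.find_duplicate_pairs(
        members, by_id, config.dup_min_identity, config.dup_min_coverage
    )
    events = dups.classify_events(
        pairs, gene_records, config.max_intervening,
        config.tandem_max_distance_bp,
    )
    dups.write_events_tsv(events, outdir / "duplication_events.tsv")
    dups.write_link_file(events, gene_records, outdir / "duplication_links.tsv")
    n_tandem = sum(e.kind == dups.TANDEM for e in events)
    report["stages"][stage] = {
        "n_pairs": len(pairs),
        "n_duplicated_genes": dups.duplicated_gene_count(pairs),
        "n_tandem_events": n_tandem,
        "n_segmental_events": len(events) - n_tandem,
    }
    log.info("%s: %d TD / %d SD events", stage, n_tandem, len(events) - n_tandem)

    # ---------------- network projection --------------------------------
    stage = "grn_projection"
    rbh = grn.reciprocal_best_hits(
        targets, references, config.evalue_cutoff, strict=config.rbh_strict
    )
    with open(outdir / "homolog_pairs.tsv", "w") as fh:
        fh.write("target_id\treference_id\tforward_score\treverse_score\n")
        for p in rbh:
            fh.write(
                f"{p.target_id}\t{p.reference_id}\t{p.forward_score:.1f}\t"
                f"{p.reverse_score:.1f}\n"
            )
    ref_edges = grn.read_edge_list(input_path("reference_network", stage))
    net = grn.project_network(ref_edges, rbh, set(members))
    grn.write_edge_list(net, outdir / "projected_network.tsv")
    seeds = [m for m in sorted(members) if m in net]
    sub, degrees = grn.extract_subnetwork(net, seeds, config.subnetwork_hops)
    grn.write_edge_list(sub, outdir / "family_subnetwork.tsv")
    grn.write_interchange_graph(sub, outdir / "family_subnetwork.gml")
    with open(outdir / "family_degrees.tsv", "w") as fh:
        fh.write("member\tdegree\n")
        for m in sorted(degrees):
            fh.write(f"{m}\t{degrees[m]}\n")
    report["stages"][stage] = {
        "n_homolog_pairs": len(rbh),
        "n_projected_nodes": net.number_of_nodes(),
        "n_projected_edges": net.number_of_edges(),
        "n_subnetwork_nodes": sub.number_of_nodes(),
        "n_subnetwork_edges": sub.number_of_edges(),
    }
    log.info("%s: %d pairs, projected %d nodes / %d edges", stage, len(rbh),
             net.number_of_nodes(), net.number_of_edges())

    # ---------------- enrichment ----------------------------------------
    stage = "go_enrichment"
    if stage not in skip:
        dag = go.load_ontology(input_path("go_ontology", stage))
        annotations = go.load_annotations(input_path("go_annotations", stage))
        population = set(annotations)
        study = (set(sub.nodes) - set(members)) & population
        results = go.elim_enrichment(
            study, population, annotations, dag, config.go_alpha
        )
        go.write_results_tsv(results, outdir / "go_enrichment.tsv")
        report["stages"][stage] = {
            "study_size": len(study),
            "population_size": len(population),
            "n_significant": sum(r.p_elim < config.go_alpha for r in results),
        }

    # ---------------- expression + qPCR ---------------------------------
    stage = "expression_qpcr"
    counts = expression.read_counts(input_path("counts", stage))
    lengths = expression.read_lengths(input_path("gene_lengths", stage))
    lib_sizes = None
    if config.synthetic or config.library_sizes:
        lib_sizes = expression.read_library_sizes(
            input_path("library_sizes", stage)
        )
    mat = expression.fpkm(counts, lengths, lib_sizes)
    mat.values.round(4).to_csv(outdir / "fpkm.tsv", sep="\t")
    expressed = expression.filter_expressed(mat, config.min_fpkm)
    kept = expression.ExpressionMatrix(
        mat.values.loc[expressed], "FPKM", mat.lengths
    )
    transformed = expression.log2_center_scale(kept)
    transformed.round(6).to_csv(outdir / "expression_scaled.tsv", sep="\t")
    leaf_order, _ = expression.cluster_genes(transformed)
    with open(outdir / "heatmap_leaf_order.txt", "w") as fh:
        fh.write("\n".join(leaf_order) + "\n")
    mean_fpkm = expression.average_replicates(kept)
    calls = expression.call_responses(
        mean_fpkm, config.control_timepoint, config.lfc_threshold
    )
    with open(outdir / "response_calls.tsv", "w") as fh:
        fh.write("gene\ttimepoint\tlog2_fold_change\tdirection\n")
        for c in calls:
            fh.write(
                f"{c.gene}\t{c.timepoint}\t{c.log2_fold_change:.4f}\t"
                f"{c.direction}\n"
            )
    expression.timepoint_quartiles(kept).round(4).to_csv(
        outdir / "fpkm_quartiles.tsv", sep="\t"
    )
    ct = expression.read_ct_table(input_path("ct_table", stage))
    folds = expression.delta_delta_ct(ct, config.control_timepoint)
    folds.round(4).to_csv(outdir / "qpcr_folds.tsv", sep="\t")
    up_30m = sorted(
        c.gene for c in calls if c.timepoint == "30M" and c.direction == "up"
    )
    report["stages"][stage] = {
        "n_expressed": len(expressed),
        "n_up_30M": len(up_30m),
        "n_qpcr_genes": int(folds.shape[0]),
    }
    log.info("%s: %d expressed, %d up at 30M", stage, len(expressed),
             len(up_30m))

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def validate_against_fixture(
    rows: list[core_io.FamilyTableRow], fixture: list[core_io.FamilyTableRow]
) -> list[str]:
    """Field-by-field diff of the two tables' summaries; empty means equal."""
    if not rows or not fixture:
        raise ValueError("both tables must be non-empty")
    a = core_io.summarize_family_table(rows)
    b = core_io.summarize_family_table(fixture)
    diffs = []
    for fname in (
        "n_members", "max_length", "min_length", "max_introns", "min_introns",
        "per_chromosome", "per_group",
    ):
        va, vb = getattr(a, fname), getattr(b, fname)
        if va != vb:
            diffs.append(f"{fname}: {va!r} != {vb!r}")
    return diffs
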