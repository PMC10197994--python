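"""Seeded synthetic-data generators emulating the survey's study system.

The generators emit every input the pipeline consumes, for an allotetraploid
16-chromosome genome (eight O/P homoeologous chromosome pairs, as in white
clover): a gene annotation with tandem clusters and cross-homoeolog
segmental copies, target and reference proteomes in which true family
members carry both a planted kinase-like and EF-hand-like consensus block
while decoys lack exactly one, a reference co-functional network over genes
with known orthology, an eight-point cold time course with a planted
early-up-regulated subset, and qPCR Ct tables with planted fold changes.
Every planted truth is recorded in a :class:`TruthManifest` so recovery
tests never have to re-infer it from the emitted files.

All randomness flows from ``GeneratorConfig.seed``; each generator stage
draws from an independent substream so outputs are byte-stable under a
fixed seed regardless of call order.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (
    GeneRecord,
    ProteinSequence,
    write_fasta,
    write_gff3,
)
from .identify import EFHAND_CONSENSUS, KINASE_CONSENSUS

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

TIMEPOINTS = ("0H", "30M", "1H", "3H", "6H", "12H", "24H", "72H")

# relative log2-fold weight of the planted cold response at each timepoint:
# full induction at 30 minutes, decaying back to baseline by 24 hours
RESPONSE_DECAY = {
    "0H": 0.0, "30M": 1.0, "1H": 0.75, "3H": 0.5,
    "6H": 0.25, "12H": 0.1, "24H": 0.0, "72H": 0.0,
}


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_chromosomes: int = 16
    chromosome_length: int = 60_000_000
    n_family_members: int = 50
    n_decoys: int = 20
    n_background_genes: int = 40
    n_reference_extra: int = 10
    groups: dict[str, int] = field(
        default_factory=lambda: {"I": 17, "II": 15, "III": 13, "IV": 5}
    )
    tandem_clusters: list[tuple[str, int]] = field(
        default_factory=lambda: [("Tr1O", 2), ("Tr1P", 2), ("Tr3P", 2), ("Tr5O", 2)]
    )
    segmental_pairs: int = 10
    domain_mutation_rate: float = 0.10
    # divergence among non-duplicate same-group members; must keep their
    # pairwise identity clearly below the >80% duplication rule so the
    # planted duplication pair set is exactly the detectable one
    member_mutation_rate: float = 0.22
    duplicate_mutation_rate: float = 0.02
    ortholog_divergence: float = 0.06
    orthology_fraction: float = 0.8
    network_edges: int = 150
    timepoints: tuple[str, ...] = TIMEPOINTS
    replicates: int = 3
    n_upregulated_30M: int = 32
    n_silent: int = 3
    fold_change: float = 4.0
    nb_dispersion: float = 0.1
    ct_noise_sd: float = 0.2
    n_qpcr_genes: int = 10
    qpcr_timepoints: tuple[str, ...] = ("0H", "30M", "1H", "3H")
    reference_gene_ct: float = 18.0

    def __post_init__(self) -> None:
        if sum(self.groups.values()) != self.n_family_members:
            raise ValueError("group counts must sum to n_family_members")
        for frac in (self.domain_mutation_rate, self.orthology_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_chromosomes % 2:
            raise ValueError("chromosomes come in O/P pairs")
        if self.timepoints[0] != "0H":
            raise ValueError("timepoints must start at the 0H control")

    @property
    def chromosome_names(self) -> list[str]:
        pairs = self.n_chromosomes // 2
        return [f"Tr{i}{s}" for i in range(1, pairs + 1) for s in "OP"]

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([stage, self.seed])


@dataclass
class TruthManifest:
    """Planted ground truth for every generated input."""

    member_groups: dict[str, str] = field(default_factory=dict)
    domain_intervals: dict[str, list[tuple[str, int, int]]] = field(
        default_factory=dict
    )
    intron_counts: dict[str, int] = field(default_factory=dict)
    tandem_clusters: list[list[str]] = field(default_factory=list)
    segmental_pairs: list[tuple[str, str]] = field(default_factory=list)
    duplication_pairs: list[tuple[str, str]] = field(default_factory=list)
    decoy_missing_domain: dict[str, str] = field(default_factory=dict)
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    reference_group_labels: dict[str, str] = field(default_factory=dict)
    network_edges: list[tuple[str, str]] = field(default_factory=list)
    expressed_genes: list[str] = field(default_factory=list)
    upregulated_genes: list[str] = field(default_factory=list)
    planted_ddct: dict[str, dict[str, float]] = field(default_factory=dict)
    protein_lengths: dict[str, int] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            raw = json.load(fh)
        m = cls(**raw)
        m.segmental_pairs = [tuple(p) for p in m.segmental_pairs]
        m.duplication_pairs = [tuple(p) for p in m.duplication_pairs]
        m.ortholog_pairs = [tuple(p) for p in m.ortholog_pairs]
        m.network_edges = [tuple(e) for e in m.network_edges]
        m.domain_intervals = {
            k: [tuple(iv) for iv in v] for k, v in m.domain_intervals.items()
        }
        return m


# ---------------------------------------------------------------------------
# genome


def generate_genome(
    config: GeneratorConfig, outdir: str | Path
) -> tuple[Path, list[GeneRecord], TruthManifest]:
    """Emit the GFF3 annotation and seed the truth manifest.

    Members are laid out so that tandem clusters are consecutive genes less
    than 100 kb apart and each segmental copy sits at the mirrored position
    on the O/P homoeologous partner chromosome; all other genes are spaced
    at least ~0.5 Mb apart.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng(1)
    manifest = TruthManifest()
    chroms = config.chromosome_names
    for chrom, _ in config.tandem_clusters:
        if chrom not in chroms:
            raise ValueError(f"unknown chromosome in tandem_clusters: {chrom}")

    n_tandem_copies = sum(size - 1 for _, size in config.tandem_clusters)
    n_copies = n_tandem_copies + config.segmental_pairs
    n_founders = config.n_family_members - n_copies
    if n_founders < len(config.tandem_clusters) + config.segmental_pairs:
        raise ValueError("too many duplication events for the member count")

    member_ids = [f"Tg{i:03d}" for i in range(1, config.n_family_members + 1)]
    decoy_ids = [f"Td{i:03d}" for i in range(1, config.n_decoys + 1)]
    background_ids = [f"Tb{i:03d}" for i in range(1, config.n_background_genes + 1)]

    founders = member_ids[:n_founders]
    copies = member_ids[n_founders:]
    copy_iter = iter(copies)

    # founders hosting duplication events are assigned round-robin
    founder_iter = iter(founders)
    tandem = []  # (founder, [copy ids], chromosome)
    for chrom, size in config.tandem_clusters:
        src = next(founder_iter)
        tandem.append((src, [next(copy_iter) for _ in range(size - 1)], chrom))
    segmental = []  # (founder, copy)
    for _ in range(config.segmental_pairs):
        segmental.append((next(founder_iter), next(copy_iter)))

    source_of = {}
    for src, cps, _ in tandem:
        for c in cps:
            source_of[c] = src
    for src, cp in segmental:
        source_of[cp] = src

    # group assignment: a duplication event's founder and copies must share
    # one group (they are near-identical sequences), so groups are assigned
    # to whole units — tandem clusters, segmental pairs, lone founders —
    # packed greedily so the configured tallies hold exactly
    units: list[list[str]] = [[src] + cps for src, cps, _ in tandem]
    units += [[src, cp] for src, cp in segmental]
    used = {m for u in units for m in u}
    units += [[m] for m in founders if m not in used]
    need = dict(config.groups)
    for unit in sorted(units, key=len, reverse=True):
        g = max(sorted(need), key=lambda k: need[k])
        if need[g] < len(unit):
            raise ValueError("group tallies cannot accommodate duplication units")
        need[g] -= len(unit)
        for m in unit:
            manifest.member_groups[m] = g

    # --- chromosome placement -------------------------------------------
    # queue of (gene_id, forced_chromosome or None); tandem clusters are
    # atomic blocks placed contiguously
    placements: dict[str, list[list[str]]] = {c: [] for c in chroms}
    placed = set()
    for src, cps, chrom in tandem:
        placements[chrom].append([src] + cps)
        placed.update([src] + cps)
    # segmental founders on a random O chromosome, copy mirrored on its P partner
    seg_positions = []
    for src, cp in segmental:
        o_chrom = chroms[2 * rng.integers(0, config.n_chromosomes // 2)]
        p_chrom = o_chrom[:-1] + ("P" if o_chrom.endswith("O") else "O")
        placements[o_chrom].append([src])
        placements[p_chrom].append([cp])
        seg_positions.append((src, o_chrom, cp, p_chrom))
        placed.update([src, cp])
    for gid in member_ids + decoy_ids + background_ids:
        if gid not in placed:
            placements[chroms[rng.integers(0, len(chroms))]].append([gid])

    # --- coordinates -----------------------------------------------------
    gene_records: list[GeneRecord] = []
    gff_entries = []
    mirror_pos: dict[str, int] = {}
    for chrom in chroms:
        blocks = placements[chrom]
        rng.shuffle(blocks)
        cursor = int(rng.integers(100_000, 500_000))
        for block in blocks:
            for k, gid in enumerate(block):
                if k > 0:  # tandem copy: small gap, well under 100 kb
                    cursor = prev_end + int(rng.integers(2_000, 40_000))
                is_member = gid.startswith("Tg")
                n_exons = int(rng.integers(5, 26)) if is_member else int(
                    rng.integers(1, 8)
                )
                exon_lens = rng.integers(120, 300, size=n_exons)
                intron_lens = rng.integers(200, 800, size=max(n_exons - 1, 0))
                start = cursor
                spans = []
                pos = start
                for i, el in enumerate(exon_lens):
                    spans.append((pos, pos + int(el) - 1))
                    pos += int(el)
                    if i < len(intron_lens):
                        pos += int(intron_lens[i])
                end = spans[-1][1]
                if end > config.chromosome_length:
                    raise ValueError(
                        f"chromosome {chrom} capacity exceeded at {gid}"
                    )
                strand = "+" if rng.random() < 0.5 else "-"
                rec = GeneRecord(gid, chrom, start, end, strand, n_exons)
                gene_records.append(rec)
                gff_entries.append((rec, spans))
                if is_member:
                    manifest.intron_counts[gid] = n_exons - 1
                mirror_pos[gid] = start
                prev_end = end
                cursor = end + int(rng.integers(500_000, 2_000_000))

    manifest.tandem_clusters = [[src] + cps for src, cps, _ in tandem]
    manifest.segmental_pairs = [(src, cp) for src, cp in segmental]
    pairs = [(src, cp) for src, cp in segmental]
    for src, cps, _ in tandem:
        members = [src] + cps
        pairs += [
            (members[i], members[j])
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]
    manifest.duplication_pairs = [tuple(sorted(p)) for p in pairs]

    gff_path = outdir / "target_annotation.gff3"
    gff_entries.sort(key=lambda e: (e[0].chromosome, e[0].start))
    write_gff3(gff_entries, gff_path)
    return gff_path, gene_records, manifest


# ---------------------------------------------------------------------------
# proteomes


def _random_protein(rng: np.random.Generator, length: int) -> np.ndarray:
    return AMINO_ACIDS[rng.integers(0, 20, size=length)]


def _mutate(
    rng: np.random.Generator, seq: np.ndarray, rate: float, protect=()
) -> np.ndarray:
    """Point-mutate ``seq`` at the given per-site rate (no indels)."""
    out = seq.copy()
    mask = rng.random(len(seq)) < rate
    for lo, hi in protect:
        mask[lo:hi] = False
    idx = np.flatnonzero(mask)
    if idx.size:
        out[idx] = AMINO_ACIDS[rng.integers(0, 20, size=idx.size)]
    return out


# EF-hand copy number per group: the calmodulin-like regulatory lobe of real
# family members carries one to four EF-hands
EF_COPIES = {"I": 2, "II": 2, "III": 1, "IV": 3}


def generate_proteomes(
    config: GeneratorConfig, manifest: TruthManifest, outdir: str | Path
) -> tuple[Path, Path, dict[str, str]]:
    """Emit target and reference proteomes plus reference group labels.

    Each group descends from its own random ancestral backbone carrying the
    planted kinase block and the group's EF-hand copy number; members are
    independent point-mutated derivatives (duplicate copies derive from
    their source member at a much lower rate), decoys carry exactly one of
    the two domains, and reference counterparts of founder members and of a
    configurable fraction of background genes are mutated copies of their
    target gene.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng(2)
    kin = np.array(list(KINASE_CONSENSUS))
    ef = np.array(list(EFHAND_CONSENSUS))

    member_ids = sorted(manifest.member_groups)
    copies = {c for cl in manifest.tandem_clusters for c in cl[1:]}
    copies |= {cp for _, cp in manifest.segmental_pairs}
    source_of = {}
    for cl in manifest.tandem_clusters:
        for c in cl[1:]:
            source_of[c] = cl[0]
    for src, cp in manifest.segmental_pairs:
        source_of[cp] = src
    founders = [m for m in member_ids if m not in copies]

    # ancestral backbone per group
    ancestors: dict[str, tuple[np.ndarray, list[tuple[str, int, int]]]] = {}
    for g in config.groups:
        n_ef = EF_COPIES.get(g, 2)
        length = int(rng.integers(290, 380))
        backbone = _random_protein(rng, length)
        intervals = []
        pos = int(rng.integers(15, 40))
        backbone[pos : pos + 60] = kin
        intervals.append(("kinase", pos, pos + 60))
        pos += 60 + int(rng.integers(15, 30))
        for _ in range(n_ef):
            if pos + 29 > length:
                backbone = np.concatenate([backbone, _random_protein(rng, 40)])
                length = len(backbone)
            backbone[pos : pos + 29] = ef
            intervals.append(("EF-hand", pos, pos + 29))
            pos += 29 + int(rng.integers(4, 12))
        ancestors[g] = (backbone, intervals)

    seqs: dict[str, np.ndarray] = {}
    domain_ivs: dict[str, list[tuple[str, int, int]]] = {}
    for m in founders:
        g = manifest.member_groups[m]
        backbone, intervals = ancestors[g]
        protect = [(lo, hi) for _, lo, hi in intervals]
        seq = _mutate(rng, backbone, config.member_mutation_rate, protect)
        for _, lo, hi in intervals:
            seq[lo:hi] = _mutate(
                rng, seq[lo:hi], config.domain_mutation_rate
            )
        seqs[m] = seq
        domain_ivs[m] = intervals
    for m in member_ids:
        if m in copies:
            src = source_of[m]
            # domain blocks are carried over verbatim so a copy's planted
            # block stays at the same distance from the consensus
            protect = [(lo, hi) for _, lo, hi in domain_ivs[src]]
            seqs[m] = _mutate(
                rng, seqs[src], config.duplicate_mutation_rate, protect
            )
            domain_ivs[m] = domain_ivs[src]
    for m in member_ids:
        manifest.domain_intervals[m] = [
            (lab, lo + 1, hi) for lab, lo, hi in domain_ivs[m]  # 1-based inclusive
        ]
        manifest.protein_lengths[m] = len(seqs[m])

    # decoys: a member-like backbone missing exactly one of the two domains
    decoy_ids = [f"Td{i:03d}" for i in range(1, config.n_decoys + 1)]
    group_cycle = list(config.groups)
    for i, d in enumerate(decoy_ids):
        g = group_cycle[i % len(group_cycle)]
        backbone, intervals = ancestors[g]
        seq = _mutate(rng, backbone, config.member_mutation_rate)
        missing = "EF-hand" if i % 2 == 0 else "kinase"
        for lab, lo, hi in intervals:
            if lab == missing:
                seq[lo:hi] = _random_protein(rng, hi - lo)
            else:
                seq[lo:hi] = _mutate(
                    rng, np.array(list(KINASE_CONSENSUS if lab == "kinase"
                                       else EFHAND_CONSENSUS)),
                    config.domain_mutation_rate,
                )
        seqs[d] = seq
        manifest.decoy_missing_domain[d] = missing
        manifest.protein_lengths[d] = len(seq)

    background_ids = [f"Tb{i:03d}" for i in range(1, config.n_background_genes + 1)]
    for b in background_ids:
        seqs[b] = _random_protein(rng, int(rng.integers(200, 500)))
        manifest.protein_lengths[b] = len(seqs[b])

    # reference proteome: counterparts of founders (always) and of a fraction
    # of background genes, plus unrelated reference-only proteins
    ref_seqs: dict[str, np.ndarray] = {}
    ref_groups: dict[str, str] = {}
    ref_counter = 0
    for m in founders:
        ref_counter += 1
        rid = f"Rg{ref_counter:03d}"
        ref_seqs[rid] = _mutate(rng, seqs[m], config.ortholog_divergence)
        ref_groups[rid] = manifest.member_groups[m]
        manifest.ortholog_pairs.append((m, rid))
    for b in background_ids:
        if rng.random() < config.orthology_fraction:
            ref_counter += 1
            rid = f"Rb{ref_counter:03d}"
            ref_seqs[rid] = _mutate(rng, seqs[b], config.ortholog_divergence)
            manifest.ortholog_pairs.append((b, rid))
    for i in range(config.n_reference_extra):
        rid = f"Rx{ref_counter + i + 1:03d}"
        ref_seqs[rid] = _random_protein(rng, int(rng.integers(200, 500)))
    manifest.reference_group_labels = ref_groups

    target_fa = outdir / "target_proteome.fasta"
    reference_fa = outdir / "reference_proteome.fasta"
    write_fasta(
        [ProteinSequence(k, "".join(seqs[k])) for k in sorted(seqs)], target_fa
    )
    write_fasta(
        [ProteinSequence(k, "".join(ref_seqs[k])) for k in sorted(ref_seqs)],
        reference_fa,
    )
    labels_path = outdir / "reference_groups.tsv"
    with open(labels_path, "w") as fh:
        fh.write("reference_id\tgroup\n")
        for rid, g in sorted(ref_groups.items()):
            fh.write(f"{rid}\t{g}\n")
    return target_fa, reference_fa, ref_groups


# ---------------------------------------------------------------------------
# reference network


def generate_reference_network(
    config: GeneratorConfig, manifest: TruthManifest, outdir: str | Path
) -> Path:
    """Emit an undirected simple-graph edge list over reference gene ids.

    Every family reference gets at least one partner; remaining edges are
    sampled uniformly from the non-family pairs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng(3)
    ref_ids = sorted({r for _, r in manifest.ortholog_pairs})
    n_extra_start = len(ref_ids)
    ref_ids += [f"Rx{n_extra_start + i + 1:03d}" for i in range(config.n_reference_extra)]
    n = len(ref_ids)
    max_edges = n * (n - 1) // 2
    if config.network_edges > max_edges:
        raise ValueError(
            f"requested {config.network_edges} edges but only {max_edges} possible"
        )
    family = sorted(manifest.reference_group_labels)
    others = [r for r in ref_ids if r not in manifest.reference_group_labels]
    edges: set[tuple[str, str]] = set()

    def canon(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)

    for fam in family:
        partner = others[rng.integers(0, len(others))]
        edges.add(canon(fam, partner))
        if len(edges) >= config.network_edges:
            break
    while len(edges) < config.network_edges:
        a, b = rng.choice(n, size=2, replace=False)
        edges.add(canon(ref_ids[a], ref_ids[b]))
    manifest.network_edges = sorted(edges)
    path = outdir / "reference_network.tsv"
    with open(path, "w") as fh:
        for a, b in sorted(edges):
            fh.write(f"{a}\t{b}\n")
    return path


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    config: GeneratorConfig, manifest: TruthManifest, outdir: str | Path
) -> tuple[Path, Path, Path]:
    """Emit a counts matrix and gene lengths for the cold time course.

    Counts are negative-binomial (gamma-Poisson) around a per-gene baseline;
    the planted up-regulated subset is multiplied by ``fold_change`` at 30M
    with a decaying tail, and ``n_silent`` genes are fully silent so the
    FPKM > 1 expression filter has a determinate answer.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng(4)
    genes = sorted(manifest.member_groups)
    n_genes = len(genes)
    if config.n_upregulated_30M + config.n_silent > n_genes:
        raise ValueError("planted up + silent sets exceed gene count")
    order = rng.permutation(n_genes)
    up = (
        sorted(genes[i] for i in order[: config.n_upregulated_30M])
        if config.fold_change != 1.0
        else []
    )
    silent = sorted(genes[i] for i in order[n_genes - config.n_silent :])
    manifest.upregulated_genes = up
    manifest.expressed_genes = [g for g in genes if g not in silent]

    lengths = {
        g: 3 * manifest.protein_lengths.get(g, 400) + 200 for g in genes
    }
    baseline = {g: float(rng.uniform(3, 60)) for g in genes}
    for g in silent:
        baseline[g] = 0.0

    samples = [
        f"{tp}_r{r}" for tp in config.timepoints for r in range(1, config.replicates + 1)
    ]
    lib_sizes = {s: float(rng.uniform(0.8e6, 1.6e6)) for s in samples}

    log2_fc = math.log2(config.fold_change) if config.fold_change > 0 else 0.0
    counts = np.zeros((n_genes, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        tp = s.rsplit("_", 1)[0]
        w = RESPONSE_DECAY.get(tp, 0.0)
        for i, g in enumerate(genes):
            fpkm_true = baseline[g]
            if g in up:
                fpkm_true *= 2 ** (log2_fc * w)
            mean = fpkm_true * lib_sizes[s] * lengths[g] / 1e9
            if mean <= 0:
                continue
            # gamma-Poisson mixture: NB with dispersion phi (var = m + phi m^2)
            shape = 1.0 / config.nb_dispersion
            lam = rng.gamma(shape, mean / shape)
            counts[i, j] = rng.poisson(lam)

    counts_path = outdir / "expression_counts.tsv"
    with open(counts_path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(samples) + "\n")
        for i, g in enumerate(genes):
            fh.write(g + "\t" + "\t".join(map(str, counts[i])) + "\n")
    lengths_path = outdir / "gene_lengths.tsv"
    with open(lengths_path, "w") as fh:
        fh.write("gene_id\tlength\n")
        for g in genes:
            fh.write(f"{g}\t{lengths[g]}\n")
    # the family panel is a slice of a whole transcriptome, so per-sample
    # mapped totals are an input of their own, not the panel column sums
    libs_path = outdir / "library_sizes.tsv"
    with open(libs_path, "w") as fh:
        fh.write("sample\tlibrary_size\n")
        for s in samples:
            fh.write(f"{s}\t{lib_sizes[s]:.1f}\n")
    return counts_path, lengths_path, libs_path


# ---------------------------------------------------------------------------
# qPCR


def generate_ct_table(
    config: GeneratorConfig, manifest: TruthManifest, outdir: str | Path
) -> Path:
    """Emit a qPCR Ct table with planted ddCt values per gene and timepoint.

    Target Ct at time t is ``baseline - planted_log2_fold(t) + noise``; the
    reference gene's Ct is constant in expectation, so the expected
    2^-ddCt fold change equals 2^(planted log2 fold).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng(5)
    up = manifest.upregulated_genes
    pool = up if len(up) >= config.n_qpcr_genes else sorted(manifest.member_groups)
    qpcr_genes = sorted(pool[: config.n_qpcr_genes])
    log2_fc = math.log2(config.fold_change) if config.fold_change > 0 else 0.0

    manifest.planted_ddct = {}
    for i, g in enumerate(qpcr_genes):
        # gene-specific peak induction; first gene gets a 32-fold (ddCt -5) peak
        peak = 5.0 if i == 0 else float(rng.uniform(1.0, max(log2_fc, 1.5)))
        manifest.planted_ddct[g] = {
            tp: -peak * RESPONSE_DECAY.get(tp, 0.0) for tp in config.qpcr_timepoints
        }

    path = outdir / "qpcr_ct.tsv"
    with open(path, "w") as fh:
        fh.write("gene\ttimepoint\treplicate\tct_target\tct_reference\n")
        for g in qpcr_genes:
            base = float(rng.uniform(22, 28))
            for tp in config.qpcr_timepoints:
                planted = manifest.planted_ddct[g][tp]  # = -log2 fold at tp
                for r in range(1, config.replicates + 1):
                    ct_t = base + planted + rng.normal(0, config.ct_noise_sd)
                    ct_r = config.reference_gene_ct + rng.normal(
                        0, config.ct_noise_sd
                    )
                    fh.write(f"{g}\t{tp}\t{r}\t{ct_t:.4f}\t{ct_r:.4f}\n")
    return path


# ---------------------------------------------------------------------------
# GO annotations (toy ontology for the enrichment stage)

_ONTOLOGY_ROWS = [
    # child, parent, namespace
    ("BP:regulation", "BP:root", "BP"),
    ("BP:signal_transduction", "BP:regulation", "BP"),
    ("BP:response_to_stimulus", "BP:regulation", "BP"),
    ("BP:metabolism", "BP:root", "BP"),
    ("MF:kinase_activity", "MF:root", "MF"),
    ("MF:binding", "MF:root", "MF"),
    ("CC:membrane", "CC:root", "CC"),
    ("CC:nucleus", "CC:root", "CC"),
]
_LEAF_TERMS = [
    "BP:signal_transduction", "BP:response_to_stimulus", "BP:metabolism",
    "MF:kinase_activity", "MF:binding", "CC:membrane", "CC:nucleus",
]


def generate_go_annotations(
    config: GeneratorConfig, manifest: TruthManifest, outdir: str | Path
) -> tuple[Path, Path]:
    """Emit a toy ontology and gene->term annotations for target genes.

    Target genes whose reference counterparts neighbor a family reference
    in the planted network are preferentially annotated to the signalling
    leaf term, planting the enrichment signal the survey looks for in
    family-centred subnetworks.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng(6)
    onto_path = outdir / "ontology.tsv"
    with open(onto_path, "w") as fh:
        fh.write("#child\tparent\tnamespace\n")
        for child, parent, ns in _ONTOLOGY_ROWS:
            fh.write(f"{child}\t{parent}\t{ns}\n")

    ref_to_target = {r: t for t, r in manifest.ortholog_pairs}
    family_refs = set(manifest.reference_group_labels)
    partner_targets = set()
    for a, b in manifest.network_edges:
        if a in family_refs and b in ref_to_target:
            partner_targets.add(ref_to_target[b])
        if b in family_refs and a in ref_to_target:
            partner_targets.add(ref_to_target[a])
    all_targets = sorted(
        set(manifest.member_groups) | set(ref_to_target.values())
    )
    ann_path = outdir / "go_annotations.tsv"
    with open(ann_path, "w") as fh:
        fh.write("#gene\tterm\n")
        for g in all_targets:
            terms = set()
            if g in partner_targets and rng.random() < 0.8:
                terms.add("BP:signal_transduction")
            n_extra = int(rng.integers(1, 3))
            for _ in range(n_extra):
                terms.add(_LEAF_TERMS[rng.integers(0, len(_LEAF_TERMS))])
            for t in sorted(terms):
                fh.write(f"{g}\t{t}\n")
    return ann_path, onto_path


# ---------------------------------------------------------------------------
# standalone motif test set


def generate_motif_sequences(
    n_seqs: int = 50,
    motif_widths: tuple[int, ...] = (10, 15, 20),
    mutation_rate: float = 0.10,
    seq_length: int = 300,
    seed: int = 0,
) -> tuple[list[ProteinSequence], dict[int, list[tuple[str, int]]]]:
    """Random sequences with one occurrence of each planted motif.

    Returns the sequences and the planted sites per motif index
    (1-based start positions), for motif-recovery tests.
    """
    rng = np.random.default_rng([7, seed])
    consensi = [_random_protein(rng, w) for w in motif_widths]
    seqs, truth = [], {i + 1: [] for i in range(len(motif_widths))}
    gap = 5
    for i in range(n_seqs):
        sid = f"S{i + 1:03d}"
        backbone = _random_protein(rng, seq_length)
        # place motifs left-to-right at jittered, non-overlapping offsets
        pos = int(rng.integers(0, 20))
        for mi, cons in enumerate(consensi):
            w = len(cons)
            start = pos + int(rng.integers(0, 15))
            planted = _mutate(rng, cons, mutation_rate)
            backbone[start : start + w] = planted
            truth[mi + 1].append((sid, start + 1))
            pos = start + w + gap
        seqs.append(ProteinSequence(sid, "".join(backbone)))
    return seqs, truth


# ---------------------------------------------------------------------------
# one-call bundle


@dataclass
class SyntheticBundle:
    config: GeneratorConfig
    manifest: TruthManifest
    gff_path: Path
    gene_records: list[GeneRecord]
    target_fasta: Path
    reference_fasta: Path
    reference_groups: dict[str, str]
    network_path: Path
    counts_path: Path
    lengths_path: Path
    library_sizes_path: Path
    ct_path: Path
    annotations_path: Path
    ontology_path: Path
    manifest_path: Path


def generate_all(config: GeneratorConfig, outdir: str | Path) -> SyntheticBundle:
    """Run every generator stage and save the manifest."""
    outdir = Path(outdir)
    gff_path, gene_records, manifest = generate_genome(config, outdir)
    target_fa, reference_fa, ref_groups = generate_proteomes(
        config, manifest, outdir
    )
    network_path = generate_reference_network(config, manifest, outdir)
    counts_path, lengths_path, libs_path = generate_expression(
        config, manifest, outdir
    )
    ct_path = generate_ct_table(config, manifest, outdir)
    ann_path, onto_path = generate_go_annotations(config, manifest, outdir)
    manifest_path = outdir / "manifest.json"
    manifest.save(manifest_path)
    return SyntheticBundle(
        config, manifest, gff_path, gene_records, target_fa, reference_fa,
        ref_groups, network_path, counts_path, lengths_path, libs_path,
        ct_path, ann_path, onto_path, manifest_path,
    )
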