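"""Domain types and readers/writers for the formats the survey touches.

Coordinate convention: all genomic coordinates are GFF3-style, 1-based and
inclusive at both ends.  Protein positions are 1-based amino-acid indices.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GROUPS = ("I", "II", "III", "IV")
UNGROUPED = "ungrouped"

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

FAMILY_TABLE_COLUMNS = [
    "name", "locus", "chromosome", "start", "end", "group", "intron", "length_aa",
]


class FormatError(ValueError):
    """A file does not conform to the expected format."""


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence over the 20 standard residues plus X."""

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise FormatError(f"empty sequence for {self.seq_id!r}")
        bad = set(self.residues) - AA_ALPHABET
        if bad:
            raise FormatError(
                f"{self.seq_id!r}: residues outside amino-acid alphabet: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneRecord:
    """One gene locus: chromosome, 1-based inclusive span, strand, exon count."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    exon_count: int = 1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.exon_count < 1:
            raise ValueError(f"{self.gene_id}: exon_count must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def intron_count(self) -> int:
        return self.exon_count - 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class FamilyTableRow:
    """One family-table record (name, locus, coordinates, group, introns, length)."""

    name: str
    locus: str
    chromosome: str
    start: int
    end: int
    group: str
    intron_count: int
    protein_length: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS + (UNGROUPED,):
            raise ValueError(f"{self.name}: unknown group {self.group!r}")
        if self.protein_length < 1:
            raise ValueError(f"{self.name}: protein_length must be >= 1")
        if self.intron_count < 0:
            raise ValueError(f"{self.name}: intron_count must be >= 0")


@dataclass
class FamilySummary:
    """Extrema and tallies over a family table."""

    n_members: int
    max_length: tuple[int, str]
    min_length: tuple[int, str]
    max_introns: tuple[int, str]
    min_introns: int
    per_chromosome: dict[str, int] = field(default_factory=dict)
    per_group: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a protein FASTA; residues are uppercased, record order preserved."""
    path = Path(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if not rec.id:
                raise FormatError(f"{path}: record with empty header")
            records.append(ProteinSequence(rec.id, str(rec.seq).upper()))
    except FormatError:
        raise
    except Exception as exc:  # Bio raises bare ValueError on malformed input
        raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s.residues), id=s.seq_id, description="") for s in seqs]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = 9


def read_gff3(path: str | Path) -> list[GeneRecord]:
    """Read gene models from a GFF3 file.

    Expects ``gene``, ``mRNA`` and ``exon`` features linked through
    ``ID``/``Parent`` attributes.  When a gene carries several mRNAs the one
    with the largest summed exon length is used (longest-transcript rule, the
    same semantics as a family table's "protein length" column).  Intron count
    is exon count minus one.  Duplicate exon lines (same mRNA and identical
    span) are dropped with a warning; an mRNA with no exon lines is an error.
    """
    path = Path(path)
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _GFF_COLS:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                genes[attr["ID"]] = {
                    "chromosome": chrom,
                    "start": int(start),
                    "end": int(end),
                    "strand": strand,
                }
            elif ftype == "mRNA":
                mrna_parent[attr["ID"]] = attr["Parent"]
            elif ftype == "exon":
                span = (int(start), int(end))
                lst = exons.setdefault(attr["Parent"], [])
                if span in lst:
                    warnings.warn(
                        f"{path}:{lineno}: duplicate exon line for {attr['Parent']}"
                    )
                    continue
                lst.append(span)
    records = []
    for gene_id, info in genes.items():
        mrnas = [m for m, parent in mrna_parent.items() if parent == gene_id]
        if not mrnas:
            raise FormatError(f"{path}: gene {gene_id} has no mRNA feature")
        best, best_len = None, -1
        for m in mrnas:
            if m not in exons:
                raise FormatError(f"{path}: mRNA {m} has no exon features")
            total = sum(e - s + 1 for s, e in exons[m])
            if total > best_len:
                best, best_len = m, total
        records.append(
            GeneRecord(
                gene_id=gene_id,
                chromosome=info["chromosome"],
                start=info["start"],
                end=info["end"],
                strand=info["strand"],
                exon_count=len(exons[best]),
            )
        )
    return records


def write_gff3(
    genes: Iterable[tuple[GeneRecord, list[tuple[int, int]]]], path: str | Path
) -> None:
    """Write (GeneRecord, exon span list) pairs as a minimal three-tier GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec, exon_spans in genes:
            base = (rec.chromosome, "cdpksurvey", "%s", str(rec.start), str(rec.end),
                    ".", rec.strand, ".")
            fh.write("\t".join(base) % "gene" + f"\tID={rec.gene_id}\n")
            mrna = f"{rec.gene_id}.1"
            fh.write("\t".join(base) % "mRNA" + f"\tID={mrna};Parent={rec.gene_id}\n")
            for s, e in exon_spans:
                fh.write(
                    "\t".join(
                        (rec.chromosome, "cdpksurvey", "exon", str(s), str(e),
                         ".", rec.strand, ".", f"Parent={mrna}")
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Family table

_LOCUS_SPAN = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)[–-](?P<end>\d+)$")


def parse_location(text: str) -> tuple[str, int, int]:
    """Parse a 'Chrom:start–end' location string (hyphen or en-dash)."""
    m = _LOCUS_SPAN.match(text)
    if not m:
        raise FormatError(f"cannot parse location {text!r}")
    return m["chrom"], int(m["start"]), int(m["end"])


def load_family_table(path: str | Path) -> list[FamilyTableRow]:
    """Load a family table TSV (columns: name, locus, chromosome, start, end,
    group, intron, length_aa)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"group": str})
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty family table")
        return []
    missing = set(FAMILY_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        FamilyTableRow(
            name=r["name"], locus=r["locus"], chromosome=r["chromosome"],
            start=int(r["start"]), end=int(r["end"]), group=r["group"],
            intron_count=int(r["intron"]), protein_length=int(r["length_aa"]),
        )
        for r in df.to_dict("records")
    ]


def write_family_table(rows: Iterable[FamilyTableRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.name, r.locus, r.chromosome, r.start, r.end, r.group,
             r.intron_count, r.protein_length)
            for r in rows
        ],
        columns=FAMILY_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def load_packaged_table1() -> list[FamilyTableRow]:
    """The packaged 50-member white clover CDPK family table."""
    with resources.as_file(
        resources.files("cdpksurvey.data") / "trcdpk_table1.tsv"
    ) as p:
        return load_family_table(p)


def summarize_family_table(rows: list[FamilyTableRow]) -> FamilySummary:
    """Extrema (with argmax/argmin member names) and per-chromosome/group tallies."""
    if not rows:
        raise ValueError("cannot summarize an empty family table")
    longest = max(rows, key=lambda r: r.protein_length)
    shortest = min(rows, key=lambda r: r.protein_length)
    most_introns = max(rows, key=lambda r: r.intron_count)
    per_chromosome: dict[str, int] = {}
    per_group: dict[str, int] = {}
    for r in rows:
        per_chromosome[r.chromosome] = per_chromosome.get(r.chromosome, 0) + 1
        per_group[r.group] = per_group.get(r.group, 0) + 1
    return FamilySummary(
        n_members=len(rows),
        max_length=(longest.protein_length, longest.name),
        min_length=(shortest.protein_length, shortest.name),
        max_introns=(most_introns.intron_count, most_introns.name),
        min_introns=min(r.intron_count for r in rows),
        per_chromosome=per_chromosome,
        per_group=per_group,
    )
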