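"""Sequence and annotation I/O plus gene-model structural facts.

This module owns the on-disk formats of the pipeline (FASTA, a constrained
GFF3 dialect, TSV result tables) and the in-memory :class:`GeneModel` /
:class:`GenomeSet` containers.  It also knows how to decode wheat-style gene
identifiers, in which the sub-genome (A/B/D), the chromosome number (1-7) and
the chromosome arm (S/L) are embedded in the identifier itself; genes whose
identifiers do not follow that convention are treated as scaffold-located and
carry no usable coordinates for duplication categorization.

Coordinates are 1-based inclusive throughout (GFF3 convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq


class FormatError(ValueError):
    """Raised for malformed input files or inconsistent gene models."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


class FastaDict(dict):
    """Order-preserving id->sequence map.

    ``stripped_stop_ids`` records which records had a trailing ``*``
    (translated stop) removed on read.
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.stripped_stop_ids: list[str] = []


def read_fasta(path: str | Path) -> FastaDict:
    """Read a FASTA file into an order-preserving id -> sequence map.

    Sequences are uppercased.  A single trailing ``*`` on a protein sequence
    is stripped and the record id noted in ``stripped_stop_ids``; an internal
    ``*`` is rejected.  Duplicate ids and empty sequences are errors.
    """
    path = Path(path)
    out = FastaDict()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if not rid:
            raise FormatError(f"{path}: record with empty header")
        if rid in out:
            raise FormatError(f"{path}: duplicate sequence id {rid!r}")
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
            out.stripped_stop_ids.append(rid)
        if "*" in seq:
            pos = seq.index("*") + 1
            raise FormatError(
                f"{path}: internal stop '*' in {rid!r} at position {pos}"
            )
        if not seq:
            raise FormatError(f"{path}: empty sequence for id {rid!r}")
        out[rid] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write an id -> sequence map as FASTA, wrapping at ``width`` columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq in seqs.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene identifiers
# ---------------------------------------------------------------------------


class ParsedId(NamedTuple):
    sub_genome: str  # 'A' | 'B' | 'D' | 'unknown'
    chromosome: int | str  # 1-7 or scaffold name
    arm: str  # 'S' | 'L' | 'none'
    placement: str  # 'chromosome' | 'scaffold'


@dataclass(frozen=True)
class GeneIdDialect:
    """Configurable pattern describing how ids encode genomic placement.

    ``chromosome_pattern`` must contain named groups ``chrom`` (a digit),
    ``sub`` (A/B/D) and optionally ``arm`` (S/L).  ``scaffold_pattern`` may
    capture a ``scaffold`` group naming the scaffold; ids matching neither
    pattern use the whole id as the scaffold name.
    """

    chromosome_pattern: str = (
        r"^(?P<prefix>[A-Za-z][A-Za-z0-9]*)_(?P<chrom>[1-7])(?P<sub>[ABD])"
        r"(?P<arm>[SL])?_(?P<serial>.+)$"
    )
    scaffold_pattern: str = r"^(?P<scaffold>scaffold[_\-][A-Za-z0-9]+)(?:_.*)?$"

    def parse(self, gene_id: str) -> ParsedId:
        m = re.match(self.chromosome_pattern, gene_id)
        if m:
            return ParsedId(
                sub_genome=m.group("sub"),
                chromosome=int(m.group("chrom")),
                arm=m.group("arm") or "none",
                placement="chromosome",
            )
        m = re.match(self.scaffold_pattern, gene_id)
        scaffold = m.group("scaffold") if m else gene_id
        return ParsedId("unknown", scaffold, "none", "scaffold")


DEFAULT_DIALECT = GeneIdDialect()


def parse_gene_id(gene_id: str, dialect: GeneIdDialect = DEFAULT_DIALECT) -> ParsedId:
    """Decode sub-genome / chromosome / arm / placement from a gene id.

    Total over strings: anything unparseable is a scaffold-located gene
    (sub-genome ``unknown``), never an error.
    """
    return dialect.parse(gene_id)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A gene with placement metadata, exon structure, CDS and protein.

    ``cds`` is stored strand-resolved (5'->3'); ``strand`` applies to the
    genomic coordinates only.  ``cds`` may or may not include the stop codon
    (``stop_included``), but must translate to ``protein`` under the standard
    genetic code.
    """

    gene_id: str
    sub_genome: str
    chromosome: int | str
    arm: str
    placement: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: str
    protein: str
    stop_included: bool = True

    @classmethod
    def from_parts(
        cls,
        gene_id: str,
        start: int,
        end: int,
        strand: str,
        exons: Iterable[tuple[int, int]],
        cds: str,
        protein: str,
        stop_included: bool = True,
        dialect: GeneIdDialect = DEFAULT_DIALECT,
    ) -> "GeneModel":
        p = dialect.parse(gene_id)
        g = cls(
            gene_id=gene_id,
            sub_genome=p.sub_genome,
            chromosome=p.chromosome,
            arm=p.arm,
            placement=p.placement,
            start=start,
            end=end,
            strand=strand,
            exons=tuple(tuple(e) for e in exons),
            cds=cds,
            protein=protein,
            stop_included=stop_included,
        )
        g.validate()
        return g

    @property
    def chrom_name(self) -> str:
        """Pseudo-molecule name, e.g. ``'2A'``; scaffold name otherwise."""
        if self.placement == "chromosome":
            return f"{self.chromosome}{self.sub_genome}"
        return str(self.chromosome)

    def validate(self) -> None:
        if self.end < self.start:
            raise FormatError(f"{self.gene_id}: end < start")
        prev_end = None
        for s, e in self.exons:
            if e < s:
                raise FormatError(f"{self.gene_id}: exon end < start")
            if s < self.start or e > self.end:
                raise FormatError(f"{self.gene_id}: exon outside gene span")
            if prev_end is not None and s <= prev_end:
                raise FormatError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e
        expected = 3 * len(self.protein) + (3 if self.stop_included else 0)
        if len(self.cds) != expected:
            raise FormatError(
                f"{self.gene_id}: CDS length {len(self.cds)} does not match "
                f"protein length {len(self.protein)} "
                f"(stop_included={self.stop_included})"
            )

    def translated(self) -> str:
        """Translate the stored CDS under the standard genetic code."""
        aa = str(Seq(self.cds).translate())
        if self.stop_included and aa.endswith("*"):
            aa = aa[:-1]
        return aa


@dataclass
class GenomeSet:
    """A named collection of gene models keyed by unique gene id."""

    species_label: str
    genes: dict[str, GeneModel] = field(default_factory=dict)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise FormatError(f"duplicate gene id {gene.gene_id!r}")
        self.genes[gene.gene_id] = gene

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def proteins(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self}

    def transcripts(self) -> dict[str, str]:
        return {g.gene_id: g.cds for g in self}


def count_exons_introns(gene: GeneModel) -> tuple[int, int]:
    """Return ``(n_exons, n_introns)``; introns are always ``n_exons - 1``."""
    if not gene.exons:
        raise FormatError(f"{gene.gene_id}: gene model has no exons")
    n = len(gene.exons)
    return n, n - 1


# ---------------------------------------------------------------------------
# GFF3 (constrained gene/mRNA/exon/CDS dialect)
# ---------------------------------------------------------------------------


def _attrs(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        k, _, v = chunk.partition("=")
        out[k] = v
    return out


def read_gff3(
    path: str | Path,
    cds: Mapping[str, str],
    proteins: Mapping[str, str],
    species_label: str = "genome",
    dialect: GeneIdDialect = DEFAULT_DIALECT,
) -> GenomeSet:
    """Assemble a :class:`GenomeSet` from a GFF3 file plus sequence maps.

    The file must use gene/mRNA/exon/CDS features with 1-based inclusive
    coordinates; exons outside their gene span are rejected with the
    offending line number.  ``cds`` and ``proteins`` are id -> sequence maps
    (e.g. from :func:`read_fasta`) keyed by gene id.
    """
    path = Path(path)
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attr = parts
            start, end = int(start), int(end)
            attrs = _attrs(attr)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene without ID")
                genes[gid] = {
                    "seqid": seqid,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "exons": [],
                    "line": lineno,
                }
            elif ftype == "mRNA":
                parent = attrs.get("Parent")
                if parent not in genes:
                    raise FormatError(
                        f"{path}:{lineno}: mRNA with unknown Parent {parent!r}"
                    )
                mrna_to_gene[attrs.get("ID", parent)] = parent
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                gid = mrna_to_gene.get(parent, parent)
                if gid not in genes:
                    raise FormatError(
                        f"{path}:{lineno}: {ftype} with unknown Parent {parent!r}"
                    )
                g = genes[gid]
                if start < g["start"] or end > g["end"]:
                    raise FormatError(
                        f"{path}:{lineno}: {ftype} outside gene span of {gid}"
                    )
                if ftype == "exon":
                    g["exons"].append((start, end))

    gs = GenomeSet(species_label=species_label)
    for gid, g in genes.items():
        if gid not in cds:
            raise FormatError(f"{path}: no CDS sequence for gene {gid!r}")
        if gid not in proteins:
            raise FormatError(f"{path}: no protein sequence for gene {gid!r}")
        c = cds[gid]
        if len(c) % 3 != 0:
            raise FormatError(
                f"{path}: CDS length for {gid!r} not divisible by 3"
            )
        prot = proteins[gid]
        stop_included = len(c) == 3 * len(prot) + 3
        gs.add(
            GeneModel.from_parts(
                gene_id=gid,
                start=g["start"],
                end=g["end"],
                strand=g["strand"],
                exons=sorted(g["exons"]),
                cds=c,
                protein=prot,
                stop_included=stop_included,
                dialect=dialect,
            )
        )
    return gs


def write_gff3(genome: GenomeSet, path: str | Path) -> None:
    """Write a GenomeSet in the constrained GFF3 dialect read by read_gff3."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome:
            seqid = g.chrom_name
            fh.write(
                f"{seqid}\tfamscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.m1"
            fh.write(
                f"{seqid}\tfamscan\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{seqid}\tfamscan\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )
                fh.write(
                    f"{seqid}\tfamscan\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# TSV result tables
# ---------------------------------------------------------------------------


def gene_table(genome: GenomeSet) -> pd.DataFrame:
    """Per-gene structural summary (placement, span, exon/intron counts)."""
    rows = []
    for g in genome:
        n_ex, n_in = count_exons_introns(g)
        rows.append(
            {
                "gene_id": g.gene_id,
                "sub_genome": g.sub_genome,
                "chromosome": g.chromosome,
                "arm": g.arm,
                "placement": g.placement,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "n_exons": n_ex,
                "n_introns": n_in,
                "cds_len": len(g.cds),
                "protein_len": len(g.protein),
            }
        )
    return pd.DataFrame(rows)


def write_tsv_tables(
    tables: Mapping[str, pd.DataFrame],
    outdir: str | Path,
    header_lines: Iterable[str] = (),
) -> list[Path]:
    """Write named DataFrames as ``<name>.tsv`` with deterministic columns.

    ``header_lines`` are emitted as ``#``-prefixed provenance comments at the
    top of every file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = outdir / f"{name}.tsv"
        with open(p, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        written.append(p)
    return written


def read_tsv_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
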