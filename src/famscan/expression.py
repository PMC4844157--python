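"""RPKM expression quantification and >=2-fold stress filtering.

Reads are assigned to genes by exact matching: a read counts toward a gene
iff it occurs verbatim (100% coverage, 100% identity) as a substring of the
gene's transcript or of its reverse complement.  A read matching k > 1
genes contributes 1/k to each by default (``multimap='fractional'``);
``'all'`` gives every matching gene a full count and ``'discard'`` drops
multi-mapping reads.

Expression is reported as RPKM = count * 1e9 / (transcript_length_bp *
library_total), where ``library_total`` is the whole-library mapped-read
count supplied as sample metadata (not the family-only mapped count; pass
``library_total=None`` per sample to fall back to the family-mapped total).

Stress responses follow the fold-change rule: replicate RPKMs are averaged,
FC = (mean_treated + c) / (mean_control + c) with a small pseudocount c,
and a gene is affected when FC >= 2 (up) or FC <= 0.5 (down).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FOLD_UP = 2.0
FOLD_DOWN = 0.5
DEFAULT_PSEUDOCOUNT = 0.1


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadSet:
    """One sequencing sample: condition labels plus fixed-length reads."""

    sample_id: str
    organ: str = ""
    stage: str = ""
    stress: str = ""
    timepoint: str = ""
    replicate: int = 1
    reads: list[str] = field(default_factory=list)
    library_total: int | None = None

    def meta_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "organ": self.organ,
            "stage": self.stage,
            "stress": self.stress,
            "timepoint": self.timepoint,
            "replicate": self.replicate,
            "library_total": self.library_total or 0,
        }


class TranscriptIndex:
    """Exact-substring index over transcripts for one read length.

    Maps every k-mer of every transcript (forward strand) to the sorted list
    of gene ids containing it; reverse-complement reads are handled at query
    time by also looking up the read's reverse complement.
    """

    def __init__(self, transcripts: Mapping[str, str], read_length: int):
        if not transcripts:
            raise ValueError("transcripts must be non-empty")
        if read_length < 1:
            raise ValueError("read_length must be positive")
        self.read_length = read_length
        self.gene_ids = list(transcripts)
        index: dict[str, set[str]] = {}
        for gid, seq in transcripts.items():
            seq = seq.upper()
            for i in range(len(seq) - read_length + 1):
                index.setdefault(seq[i : i + read_length], set()).add(gid)
        self._index = {k: tuple(sorted(v)) for k, v in index.items()}

    def genes_for(self, read: str) -> tuple[str, ...]:
        hits = set(self._index.get(read, ()))
        hits.update(self._index.get(reverse_complement(read), ()))
        return tuple(sorted(hits))


def map_reads_exact(
    reads: ReadSet | Iterable[str],
    transcripts: Mapping[str, str] | TranscriptIndex,
    multimap: str = "fractional",
) -> dict[str, float]:
    """Count reads per gene under the exact-match criterion.

    Returns a gene -> count map covering every gene of the index (zeros
    included).  Deterministic: counts depend only on the read multiset.
    """
    if multimap not in ("fractional", "all", "discard"):
        raise ValueError(f"unknown multimap mode {multimap!r}")
    read_list = reads.reads if isinstance(reads, ReadSet) else list(reads)
    if isinstance(transcripts, TranscriptIndex):
        index = transcripts
    else:
        if not read_list:
            raise ValueError("cannot infer read length from an empty read set")
        index = TranscriptIndex(transcripts, len(read_list[0]))
    counts = {g: 0.0 for g in index.gene_ids}
    for read in read_list:
        genes = index.genes_for(read.upper())
        k = len(genes)
        if k == 0:
            continue
        if k > 1 and multimap == "discard":
            continue
        w = 1.0 / k if multimap == "fractional" else 1.0
        for g in genes:
            counts[g] += w
    return counts


def rpkm(count: float, gene_length_bp: int, library_total: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_length_bp <= 0:
        raise ValueError("gene_length_bp must be positive")
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    return count * 1e9 / (gene_length_bp * library_total)


@dataclass
class ExpressionMatrix:
    """Genes x samples RPKM and raw-count matrices plus sample metadata."""

    rpkm: pd.DataFrame  # genes x samples, floats >= 0
    counts: pd.DataFrame  # same shape, fractional mapped-read counts
    samples: pd.DataFrame  # one row per sample (metadata)

    def sample_ids(self) -> list[str]:
        return list(self.rpkm.columns)


def quantify(
    read_sets: Sequence[ReadSet],
    transcripts: Mapping[str, str],
    multimap: str = "fractional",
) -> ExpressionMatrix:
    """Map every sample and assemble the RPKM / count matrices.

    Transcript lengths are the RPKM length denominator.  Samples without
    ``library_total`` metadata use their own family-mapped read total.
    """
    if not read_sets:
        raise ValueError("no read sets supplied")
    lengths = {g: len(s) for g, s in transcripts.items()}
    by_len: dict[int, TranscriptIndex] = {}
    count_cols = {}
    rpkm_cols = {}
    meta = []
    for rs in read_sets:
        if not rs.reads:
            counts = {g: 0.0 for g in transcripts}
        else:
            L = len(rs.reads[0])
            if L not in by_len:
                by_len[L] = TranscriptIndex(transcripts, L)
            counts = map_reads_exact(rs, by_len[L], multimap)
        total = rs.library_total
        if total is None:
            total = int(round(sum(counts.values()))) or 1
        count_cols[rs.sample_id] = counts
        rpkm_cols[rs.sample_id] = {
            g: rpkm(c, lengths[g], total) for g, c in counts.items()
        }
        meta.append(rs.meta_row())
    genes = list(transcripts)
    counts_df = pd.DataFrame(count_cols, index=genes)
    rpkm_df = pd.DataFrame(rpkm_cols, index=genes)
    return ExpressionMatrix(rpkm=rpkm_df, counts=counts_df, samples=pd.DataFrame(meta))


@dataclass(frozen=True)
class StressResponse:
    gene_id: str
    contrast: str
    fold_change: float
    direction: str  # 'up' | 'down' | 'unaffected'


def fold_changes(
    mat: ExpressionMatrix,
    contrast: tuple[Sequence[str], Sequence[str]],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    label: str = "",
) -> list[StressResponse]:
    """Per-gene fold changes for one treated-vs-control contrast.

    Replicate RPKMs on each side are averaged first; FC = (mean_treated +
    c) / (mean_control + c).  Genes with FC >= 2 are 'up', FC <= 0.5
    'down', the rest 'unaffected'.
    """
    treated, control = contrast
    if not len(treated) or not len(control):
        raise ValueError("both contrast sides need at least one sample")
    mt = mat.rpkm[list(treated)].mean(axis=1)
    mc = mat.rpkm[list(control)].mean(axis=1)
    fc = (mt + pseudocount) / (mc + pseudocount)
    out = []
    for gene, f in fc.items():
        direction = "up" if f >= FOLD_UP else ("down" if f <= FOLD_DOWN else "unaffected")
        out.append(StressResponse(gene, label, float(f), direction))
    return out


def responses_table(responses: Iterable[StressResponse]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "contrast": r.contrast,
                "fold_change": r.fold_change,
                "direction": r.direction,
            }
            for r in responses
        ]
    )


def specificity_summary(
    mat: ExpressionMatrix,
    top_n: int = 10,
    genome=None,
) -> dict:
    """Top expressed genes per sample plus per-gene organ attribution.

    Returns a dict with:

    * ``top_genes``: table of the ``top_n`` genes by RPKM in every sample
      (ties broken by gene id, deterministic);
    * ``organ_max``: per gene, the organ with the highest mean RPKM over
      that organ's samples (only samples with an organ label count);
    * ``top_gene_placement``: sub-genome/chromosome distribution of the top
      genes, when a :class:`~famscan.seqio.GenomeSet` is supplied.
    """
    rows = []
    for sample in mat.rpkm.columns:
        col = mat.rpkm[sample]
        ranked = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
        for rank, (gene, val) in enumerate(ranked, start=1):
            rows.append({"sample_id": sample, "rank": rank, "gene_id": gene, "rpkm": val})
    top_df = pd.DataFrame(rows)

    organ_of = dict(zip(mat.samples["sample_id"], mat.samples["organ"]))
    organs = sorted({o for o in organ_of.values() if o})
    organ_max = {}
    if organs:
        organ_means = pd.DataFrame(
            {
                o: mat.rpkm[[s for s in mat.rpkm.columns if organ_of.get(s) == o]].mean(axis=1)
                for o in organs
            }
        )
        for gene in organ_means.index:
            row = organ_means.loc[gene]
            organ_max[gene] = min(row.index[row == row.max()])
    out = {"top_genes": top_df, "organ_max": organ_max}

    if genome is not None:
        top_ids = sorted(set(top_df["gene_id"]))
        placement_rows = []
        for gid in top_ids:
            g = genome.genes.get(gid)
            if g is None:
                continue
            placement_rows.append(
                {"gene_id": gid, "sub_genome": g.sub_genome, "chromosome": g.chrom_name}
            )
        place = pd.DataFrame(placement_rows)
        out["top_gene_placement"] = (
            place.groupby(["sub_genome", "chromosome"]).size().reset_index(name="n_top_genes")
            if len(place)
            else pd.DataFrame(columns=["sub_genome", "chromosome", "n_top_genes"])
        )
    return out
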