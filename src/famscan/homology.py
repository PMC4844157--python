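"""Homolog clustering, nomenclature, duplication calling and orthology.

The homology layer consumes pairwise local-alignment hit tables (from
:mod:`famscan.align`) and gene placement metadata (from
:mod:`famscan.seqio`) and reproduces the classic gene-family bookkeeping of
polyploid genome surveys:

* homolog clusters: single-linkage components over pairs with identity
  strictly above 90% at e-value <= 1e-10, which in a hexaploid groups the
  A/B/D homoeologous copies of each gene;
* nomenclature: one representative ("gene") per cluster, remaining members
  numbered as its homologs (e.g. L-LRK13, L-LRK13.2);
* duplication events (paralogs): same-chromosome pairs at >= 80% identity,
  split into tandem (within a 5 Mb window) and segmental (beyond it), with
  scaffold-located members left uncategorized because their chromosomal
  position is unknown;
* orthologs across species by best bidirectional hit at e-value <= 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .seqio import GeneModel, GenomeSet

CLUSTER_IDENTITY_MIN = 90.0
DUPLICATION_IDENTITY_MIN = 80.0
EVALUE_MAX = 1e-10
TD_WINDOW_BP = 5_000_000


@dataclass
class HomologCluster:
    cluster_id: int
    family: str
    members: list[str]
    representative: str = ""
    names: dict[str, str] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class DuplicationEvent:
    gene_a: str
    gene_b: str
    identity_pct: float
    chromosome: str  # pseudo-molecule name, or '' when uncategorized
    distance_bp: int | None
    category: str  # 'TD' | 'SD' | 'uncategorized'


@dataclass(frozen=True)
class OrthologPair:
    gene_id_species1: str
    gene_id_species2: str
    score_fwd: float
    score_rev: float
    identity_fwd: float
    identity_rev: float


def _passing_edges(
    hits: pd.DataFrame,
    identity_min: float,
    evalue_max: float,
    strict: bool,
) -> pd.DataFrame:
    ident = hits["identity_pct"]
    mask = (ident > identity_min) if strict else (ident >= identity_min)
    mask &= hits["e_value"] <= evalue_max
    mask &= hits["query"] != hits["subject"]  # self-hits never count
    return hits.loc[mask]


def cluster_homologs(
    hits: pd.DataFrame,
    gene_ids: Sequence[str],
    identity_min: float = CLUSTER_IDENTITY_MIN,
    evalue_max: float = EVALUE_MAX,
    family: str = "",
    linkage: str = "single",
) -> list[HomologCluster]:
    """Partition ``gene_ids`` into homolog clusters (singletons included).

    ``hits`` is an all-vs-all table over the genes (each unordered pair once
    is enough).  The identity gate is strict ("more than" ``identity_min``).
    Single linkage is the default; ``linkage='complete'`` requires every
    within-cluster pair to pass the gate (greedy agglomeration, determinstic
    order).  Output clusters are sorted by descending size then smallest
    member id, and are independent of input order.
    """
    gene_ids = list(gene_ids)
    index = {g: i for i, g in enumerate(gene_ids)}
    edges = _passing_edges(hits, identity_min, evalue_max, strict=True)
    edges = edges[edges["query"].isin(index) & edges["subject"].isin(index)]

    if linkage == "single":
        rows = edges["query"].map(index).to_numpy()
        cols = edges["subject"].map(index).to_numpy()
        n = len(gene_ids)
        adj = coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
        _, labels = connected_components(adj, directed=False)
        groups: dict[int, list[str]] = {}
        for g, lab in zip(gene_ids, labels):
            groups.setdefault(int(lab), []).append(g)
        member_lists = [sorted(v) for v in groups.values()]
    elif linkage == "complete":
        pair_ok = {
            frozenset((q, s))
            for q, s in zip(edges["query"], edges["subject"])
        }
        member_lists = []
        for g in sorted(gene_ids):
            placed = False
            for grp in member_lists:
                if all(frozenset((g, m)) in pair_ok for m in grp):
                    grp.append(g)
                    placed = True
                    break
            if not placed:
                member_lists.append([g])
    else:
        raise ValueError(f"unknown linkage {linkage!r}")

    member_lists.sort(key=lambda ms: (-len(ms), ms[0]))
    return [
        HomologCluster(cluster_id=i + 1, family=family, members=ms)
        for i, ms in enumerate(member_lists)
    ]


def assign_nomenclature(
    clusters: Sequence[HomologCluster],
    family_prefix: str,
    proteins: Mapping[str, str],
) -> list[HomologCluster]:
    """Number clusters and name members in the gene/homolog style.

    Clusters are numbered 1..n by descending size then representative id.
    The representative (the "gene") is the longest protein (ties: smallest
    id) and receives ``<prefix><n>``; the remaining members (the homologs)
    get ``<prefix><n>.<k>`` with k assigned by descending protein length.
    Stable under permutation of the input.
    """

    def rep(ms: list[str]) -> str:
        longest = max(len(proteins[g]) for g in ms)
        return min(g for g in ms if len(proteins[g]) == longest)

    ordered = sorted(clusters, key=lambda c: (-c.size, rep(c.members)))
    out = []
    for n, c in enumerate(ordered, start=1):
        r = rep(c.members)
        names = {r: f"{family_prefix}{n}"}
        others = sorted(
            (m for m in c.members if m != r),
            key=lambda g: (-len(proteins[g]), g),
        )
        for k, m in enumerate(others, start=1):
            names[m] = f"{family_prefix}{n}.{k}"
        out.append(
            HomologCluster(
                cluster_id=n,
                family=c.family,
                members=sorted(c.members),
                representative=r,
                names=names,
            )
        )
    return out


def find_duplications(
    genes: GenomeSet | Mapping[str, GeneModel],
    hits: pd.DataFrame,
    identity_min: float = DUPLICATION_IDENTITY_MIN,
    evalue_max: float = EVALUE_MAX,
    window_bp: int = TD_WINDOW_BP,
) -> list[DuplicationEvent]:
    """Call duplication events (paralogs) and label them TD/SD.

    A pair at >= ``identity_min`` identity (e-value gated) is an event when
    both genes sit on the same named pseudo-molecule: tandem if their start
    coordinates are within ``window_bp``, segmental otherwise.  If either
    member is scaffold-located the event is kept but uncategorized, since
    the true chromosomal distance is unknown.  Pairs on different
    chromosomes are homoeologs/background, not duplication events.
    """
    gmap = genes.genes if isinstance(genes, GenomeSet) else dict(genes)
    edges = _passing_edges(hits, identity_min, evalue_max, strict=False)
    events = []
    for row in edges.itertuples(index=False):
        a = gmap.get(row.query)
        b = gmap.get(row.subject)
        if a is None or b is None:
            continue
        if a.placement == "scaffold" or b.placement == "scaffold":
            events.append(
                DuplicationEvent(
                    *sorted((a.gene_id, b.gene_id)),
                    identity_pct=float(row.identity_pct),
                    chromosome="",
                    distance_bp=None,
                    category="uncategorized",
                )
            )
            continue
        if a.chrom_name != b.chrom_name:
            continue
        dist = abs(a.start - b.start)
        events.append(
            DuplicationEvent(
                *sorted((a.gene_id, b.gene_id)),
                identity_pct=float(row.identity_pct),
                chromosome=a.chrom_name,
                distance_bp=dist,
                category="TD" if dist <= window_bp else "SD",
            )
        )
    events.sort(key=lambda e: (e.gene_a, e.gene_b))
    return events


def _best_hits(hits: pd.DataFrame, evalue_max: float) -> dict[str, tuple[str, float, float]]:
    """Per query: unique top subject by (score, identity, -id) ranking."""
    gated = hits[hits["e_value"] <= evalue_max]
    best: dict[str, tuple[str, float, float]] = {}
    for row in gated.itertuples(index=False):
        cur = best.get(row.query)
        key = (row.score, row.identity_pct)
        if cur is None:
            best[row.query] = (row.subject, row.score, row.identity_pct)
        else:
            ckey = (cur[1], cur[2])
            if key > ckey or (key == ckey and row.subject < cur[0]):
                best[row.query] = (row.subject, row.score, row.identity_pct)
    return best


def find_orthologs(
    species1_hits_vs_2: pd.DataFrame,
    species2_hits_vs_1: pd.DataFrame,
    evalue_max: float = EVALUE_MAX,
) -> list[OrthologPair]:
    """Best-bidirectional-hit orthology between two species.

    A pair (x, y) is reported iff y is x's top-scoring hit in species 2 and
    x is y's top-scoring hit in species 1 (ranking by alignment score, then
    identity, then smallest id; all hits e-value gated).  Symmetric in the
    order of the two input tables.
    """
    fwd = _best_hits(species1_hits_vs_2, evalue_max)
    rev = _best_hits(species2_hits_vs_1, evalue_max)
    pairs = []
    for x, (y, score_f, id_f) in fwd.items():
        back = rev.get(y)
        if back is not None and back[0] == x:
            pairs.append(
                OrthologPair(
                    gene_id_species1=x,
                    gene_id_species2=y,
                    score_fwd=float(score_f),
                    score_rev=float(back[1]),
                    identity_fwd=float(id_f),
                    identity_rev=float(back[2]),
                )
            )
    pairs.sort(key=lambda p: (p.gene_id_species1, p.gene_id_species2))
    return pairs


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def clusters_table(clusters: Sequence[HomologCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        for m in c.members:
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "family": c.family,
                    "member": m,
                    "name": c.names.get(m, ""),
                    "representative_flag": int(m == c.representative),
                }
            )
    return pd.DataFrame(rows)


def duplications_table(events: Sequence[DuplicationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": e.gene_a,
                "gene_b": e.gene_b,
                "identity_pct": e.identity_pct,
                "chromosome": e.chromosome,
                "distance_bp": -1 if e.distance_bp is None else e.distance_bp,
                "category": e.category,
            }
            for e in events
        ]
    )


def orthologs_table(pairs: Sequence[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_species1": p.gene_id_species1,
                "gene_species2": p.gene_id_species2,
                "score_fwd": p.score_fwd,
                "score_rev": p.score_rev,
                "identity_fwd": p.identity_fwd,
                "identity_rev": p.identity_rev,
            }
            for p in pairs
        ]
    )
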