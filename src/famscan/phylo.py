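"""Distance phylogenetics: center-star MSA, p-distances, NJ, bootstrap.

The tree-building path mirrors the classic family-survey workflow: align
full-length proteins, extract the confidently aligned columns, compute
p-distances (proportion of differing residues, pairwise deletion of gap
positions) and build a neighbor-joining tree whose internal edges are
annotated with non-parametric bootstrap supports.

The multiple alignment is a deterministic center-star construction: the
center sequence is the one maximizing the summed global-alignment score to
all others, every other sequence is merged against it under "once a gap,
always a gap", and columns that are gaps in more than half the rows are
dropped (the "aligned fragments" extraction step).  For the >=90%-identity
families this pipeline targets, center-star is an adequate, fully
reproducible stand-in for progressive aligners.

Neighbor joining is the Saitou-Nei agglomeration with the standard two-point
branch-length formulas; Q-matrix ties break to the lexicographically lowest
index pair and negative branch lengths are clamped to zero (flagged on the
tree).  NJ is consistent on additive distances, which is the headline
correctness property exercised by the test suite.

Trees are scikit-bio ``TreeNode`` objects; Newick round-trips through
``TreeNode.read`` / ``.write``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .align import DEFAULT_SCHEME, ScoringScheme, encode, needleman_wunsch

GAP = "-"


@dataclass
class MSA:
    """A gapped alignment: equal-length rows keyed by ordered taxa."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("MSA rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_fasta(self, path) -> None:
        from .seqio import write_fasta

        write_fasta(dict(zip(self.taxa, self.rows)), path)


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix in [0, 1] with zero diagonal."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=np.float64)
        if self.d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if (self.d < 0).any():
            raise ValueError("negative distances are not allowed")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")


# ---------------------------------------------------------------------------
# center-star MSA
# ---------------------------------------------------------------------------


def _merge_alignment(master: list[str], rows: list[list[str]], aligned_center: str, aligned_other: str, new_row: list[str]) -> None:
    """Merge one center/other pairwise alignment into the growing MSA.

    ``master`` is the center row with gaps accumulated so far; gaps inserted
    into the center by the new pairwise alignment are propagated into every
    existing row ("once a gap, always a gap").
    """
    mi = 0  # position in master
    out_master: list[str] = []
    out_rows: list[list[str]] = [[] for _ in rows]
    out_new: list[str] = []
    pi = 0  # position in aligned_center / aligned_other
    while pi < len(aligned_center) or mi < len(master):
        m_char = master[mi] if mi < len(master) else None
        p_char = aligned_center[pi] if pi < len(aligned_center) else None
        if m_char == GAP and (p_char != GAP or p_char is None):
            # existing column where center already has a gap
            out_master.append(GAP)
            for r, o in zip(rows, out_rows):
                o.append(r[mi])
            out_new.append(GAP)
            mi += 1
        elif p_char == GAP:
            # new gap in the center introduced by this pairwise alignment
            out_master.append(GAP)
            for o in out_rows:
                o.append(GAP)
            out_new.append(aligned_other[pi])
            pi += 1
        else:
            out_master.append(m_char)
            for r, o in zip(rows, out_rows):
                o.append(r[mi])
            out_new.append(aligned_other[pi])
            mi += 1
            pi += 1
    master[:] = out_master
    for r, o in zip(rows, out_rows):
        r[:] = o
    new_row[:] = out_new


def _pairwise_strings(a: str, b: str, scheme: ScoringScheme) -> tuple[str, str]:
    r = needleman_wunsch(a, b, scheme)
    sa, sb = [], []
    i = j = 0
    for t in r.trace:
        if t == "M":
            sa.append(a[i]); sb.append(b[j]); i += 1; j += 1
        elif t == "D":
            sa.append(a[i]); sb.append(GAP); i += 1
        else:
            sa.append(GAP); sb.append(b[j]); j += 1
    return "".join(sa), "".join(sb)


def center_star_msa(
    seqs: Mapping[str, str],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    max_gap_frac: float = 0.5,
) -> MSA:
    """Deterministic center-star multiple alignment with column extraction.

    Columns whose gap fraction exceeds ``max_gap_frac`` are removed after
    merging (set it >= 1 to keep everything).
    """
    taxa = list(seqs)
    if len(taxa) < 2:
        raise ValueError("center_star_msa requires at least 2 sequences")
    # choose the center: maximal summed global score to all others,
    # ties to the lowest input index
    scores = {t: 0.0 for t in taxa}
    pair_cache: dict[tuple[str, str], float] = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            s = needleman_wunsch(seqs[a], seqs[b], scheme).score
            pair_cache[(a, b)] = s
            scores[a] += s
            scores[b] += s
    center = max(taxa, key=lambda t: (scores[t], -taxa.index(t)))

    others = [t for t in taxa if t != center]
    master = list(seqs[center])
    rows: list[list[str]] = []
    for t in others:
        ac, ao = _pairwise_strings(seqs[center], seqs[t], scheme)
        new_row: list[str] = []
        _merge_alignment(master, rows, ac, ao, new_row)
        rows.append(new_row)

    ordered_taxa = [center] + others
    all_rows = ["".join(master)] + ["".join(r) for r in rows]
    # restore input order
    order = {t: i for i, t in enumerate(ordered_taxa)}
    all_rows = [all_rows[order[t]] for t in taxa]

    # column extraction: drop columns with gap fraction > max_gap_frac
    arr = np.array([list(r) for r in all_rows])
    gap_frac = (arr == GAP).mean(axis=0)
    keep = gap_frac <= max_gap_frac
    arr = arr[:, keep]
    return MSA(taxa=taxa, rows=["".join(r) for r in arr])


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------


def _msa_codes(msa: MSA) -> np.ndarray:
    """Integer-encode an MSA; gaps become -1."""
    arr = np.full((len(msa.taxa), msa.n_columns), -1, dtype=np.int16)
    for i, row in enumerate(msa.rows):
        for j, c in enumerate(row):
            if c != GAP:
                arr[i, j] = ord(c)
    return arr


def _pdist_from_codes(codes: np.ndarray) -> np.ndarray:
    n = codes.shape[0]
    valid = codes[:, None, :] >= 0
    both = valid & (codes[None, :, :] >= 0)
    diff = (codes[:, None, :] != codes[None, :, :]) & both
    compared = both.sum(axis=2)
    mism = diff.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(compared > 0, mism / np.maximum(compared, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def p_distance(msa: MSA) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gap positions.

    d(i, j) = mismatched columns / compared columns, where a column is
    compared only if neither row has a gap there.  Pairs sharing no gap-free
    column get distance 1.
    """
    return DistanceMatrix(list(msa.taxa), _pdist_from_codes(_msa_codes(msa)))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted (trifurcating) tree.

    Ties in the Q matrix break to the lowest (i, j) index pair; negative
    branch lengths are clamped to 0 and flagged via the tree attribute
    ``negative_branch_clamped``.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    D = dm.d.copy()
    nodes = [TreeNode(name=t) for t in dm.taxa]
    clamped = False

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        qvals = Q[iu]
        best = int(np.argmin(qvals))  # first minimum = lowest (i, j) pair
        i, j = int(iu[0][best]), int(iu[1][best])
        bi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        bj = D[i, j] - bi
        if bi < 0:
            bi, clamped = 0.0, True
        if bj < 0:
            bj, clamped = 0.0, True
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = float(bi)
        child_j.length = float(bj)
        parent = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D2[-1, : m - 2] = dnew[keep]
        D2[: m - 2, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]

    # final three nodes join at the unrooted center
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for node, b in zip(nodes, lengths):
        if b < 0:
            b, clamped = 0.0, True
        node.length = float(b)
    root = TreeNode(children=list(nodes))
    root.negative_branch_clamped = clamped
    return root


# ---------------------------------------------------------------------------
# bipartitions, Robinson-Foulds, bootstrap
# ---------------------------------------------------------------------------


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree.

    Each internal edge is represented by the side of its leaf split that
    does not contain the lexicographically smallest leaf, so representations
    are rooting-independent.
    """
    leaves = {t.name for t in tree.tips()}
    anchor = min(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(leaves) - len(side) < 2:
            continue
        if anchor in side:
            side = frozenset(leaves - side)
        out.add(side)
    return out


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Symmetric-difference (RF) distance between two unrooted topologies."""
    return len(bipartitions(t1) ^ bipartitions(t2))


def bootstrap(
    msa: MSA,
    n_reps: int = 1000,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree from the MSA with per-edge bootstrap supports (percent).

    Columns are resampled with replacement ``n_reps`` times, a tree is
    rebuilt from the p-distances of each replicate, and each internal edge
    of the original tree is annotated (as its node name) with the percentage
    of replicates containing the same bipartition.  With ``n_reps=0`` the
    topology is returned without supports.
    """
    codes = _msa_codes(msa)
    ncol = codes.shape[1]
    if ncol < 1:
        raise ValueError("MSA has no columns")
    tree = neighbor_joining(DistanceMatrix(list(msa.taxa), _pdist_from_codes(codes)))
    if n_reps == 0:
        return tree, {}

    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(tree)}
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_tree = neighbor_joining(
            DistanceMatrix(list(msa.taxa), _pdist_from_codes(codes[:, cols]))
        )
        rep_bps = bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}

    leaves = {t.name for t in tree.tips()}
    anchor = min(leaves)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(leaves) - len(side) < 2:
            continue
        key = side if anchor not in side else frozenset(leaves - side)
        node.name = str(int(round(supports[key])))
    return tree, supports


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def tree_to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
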