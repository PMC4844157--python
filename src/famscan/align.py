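"""Pairwise protein alignment and identity/e-value scoring.

Every similarity-search step of the pipeline (family clustering, paralogy,
cross-species orthology) runs through this module.  It provides optimal
local (Smith-Waterman) and global (Needleman-Wunsch) alignment under affine
gap penalties with a BLOSUM62 default, a Karlin-Altschul e-value gate, and a
shared-k-mer prefilter that keeps all-vs-all searches desk-scale.

Conventions
-----------
* Gap scoring: a gap of length ``g`` scores ``gap_open + (g-1)*gap_extend``
  (the opening position carries ``gap_open``); both penalties are negative.
* ``identity_pct`` is ``100 * identical_columns / aligned_columns`` where
  gap columns count in the denominator (BLAST ``pident`` convention).
* Traceback ties are broken diagonal > up (gap in subject) > left (gap in
  query), so results are deterministic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from numba import njit

#: Residue order used for integer encoding; X is scored by the matrix,
#: other ambiguity codes are rejected.
ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX"
_CODE = {c: i for i, c in enumerate(ALPHABET)}


def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Return the named substitution matrix over :data:`ALPHABET`."""
    m = substitution_matrices.load(name)
    out = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.float64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = m[a][b]
    return out


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap and e-value parameters.

    Defaults are the BLAST protein defaults (BLOSUM62, gap open -11 /
    extend -1) with the matching gapped Karlin-Altschul parameters
    lambda=0.267, K=0.041.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    lam: float = 0.267
    K: float = 0.041
    matrix: np.ndarray = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.matrix is None:
            object.__setattr__(self, "matrix", load_matrix(self.matrix_name))


DEFAULT_SCHEME = ScoringScheme()


def encode(seq: str) -> np.ndarray:
    """Encode a protein string over the 20 residues + X as int8 codes."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq):
        code = _CODE.get(c)
        if code is None:
            raise ValueError(f"illegal residue {c!r} at position {i + 1}")
        out[i] = code
    return out


@dataclass
class AlignmentResult:
    """One pairwise alignment with BLAST-like summary statistics."""

    query_id: str
    subject_id: str
    score: float
    identity_pct: float
    aligned_length: int
    n_identical: int
    query_coverage: float
    e_value: float
    trace: str  # column trace: M = aligned pair, D = gap in subject, I = gap in query
    q_start: int  # 1-based inclusive; 0 when the alignment is empty
    q_end: int
    s_start: int
    s_end: int


# trace codes used inside the kernels
_TM, _TD, _TI = 0, 1, 2


@njit(cache=True)
def _gotoh(a, b, sub, go, ge, local):  # pragma: no cover - exercised via wrappers
    """Affine-gap DP (three-state Gotoh) with deterministic traceback.

    Returns (score, q_start, q_end, s_start, s_end, trace, trace_len) with
    0-based half-open query/subject bounds and trace codes 0/1/2 for
    aligned-pair / gap-in-subject / gap-in-query columns.
    """
    n = a.shape[0]
    m = b.shape[0]
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in subject: consumes a ("up")
    Y = np.full((n + 1, m + 1), NEG)  # gap in query: consumes b ("left")
    # predecessor state per cell/state: 0=M 1=X 2=Y 3=start
    pM = np.full((n + 1, m + 1), 3, dtype=np.int8)
    pX = np.full((n + 1, m + 1), 3, dtype=np.int8)
    pY = np.full((n + 1, m + 1), 3, dtype=np.int8)

    M[0, 0] = 0.0
    if local:
        for i in range(n + 1):
            M[i, 0] = 0.0
        for j in range(m + 1):
            M[0, j] = 0.0
    else:
        for i in range(1, n + 1):
            X[i, 0] = go + (i - 1) * ge
            pX[i, 0] = 0 if i == 1 else 1
        for j in range(1, m + 1):
            Y[0, j] = go + (j - 1) * ge
            pY[0, j] = 0 if j == 1 else 2

    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M state: tie-break prefers diagonal M, then X, then Y
            s = sub[a[i - 1], b[j - 1]]
            vm = M[i - 1, j - 1]
            vx = X[i - 1, j - 1]
            vy = Y[i - 1, j - 1]
            v = vm
            p = 0
            if vx > v:
                v = vx
                p = 1
            if vy > v:
                v = vy
                p = 2
            if local and v <= 0.0:
                # restart: a non-positive prefix never helps a local alignment
                v = 0.0
                p = 3
            M[i, j] = v + s
            pM[i, j] = p

            # X state (gap in subject, consume a[i-1])
            vm = M[i - 1, j] + go
            vx = X[i - 1, j] + ge
            vy = Y[i - 1, j] + go
            v = vm
            p = 0
            if vx > v:
                v = vx
                p = 1
            if vy > v:
                v = vy
                p = 2
            X[i, j] = v
            pX[i, j] = p

            # Y state (gap in query, consume b[j-1])
            vm = M[i, j - 1] + go
            vx = X[i, j - 1] + go
            vy = Y[i, j - 1] + ge
            v = vm
            p = 0
            if vx > v:
                v = vx
                p = 1
            if vy > v:
                v = vy
                p = 2
            Y[i, j] = v
            pY[i, j] = p

            if local and M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j

    trace = np.empty(n + m, dtype=np.int8)
    tlen = 0

    if local:
        if best <= 0.0:
            return 0.0, 0, 0, 0, 0, trace, 0
        i, j, state = bi, bj, 0
        while True:
            if state == 0:
                p = pM[i, j]
                trace[tlen] = _TM
                tlen += 1
                i -= 1
                j -= 1
                if p == 3:
                    break
                state = p
            elif state == 1:
                p = pX[i, j]
                trace[tlen] = _TD
                tlen += 1
                i -= 1
                state = p
            else:
                p = pY[i, j]
                trace[tlen] = _TI
                tlen += 1
                j -= 1
                state = p
        # reverse in place
        for k in range(tlen // 2):
            trace[k], trace[tlen - 1 - k] = trace[tlen - 1 - k], trace[k]
        return best, i, bi, j, bj, trace, tlen

    # global: pick the best final state, preferring M > X > Y on ties
    score = M[n, m]
    state = 0
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            p = pM[i, j]
            trace[tlen] = _TM
            tlen += 1
            i -= 1
            j -= 1
            state = p
        elif state == 1:
            p = pX[i, j]
            trace[tlen] = _TD
            tlen += 1
            i -= 1
            state = p
        else:
            p = pY[i, j]
            trace[tlen] = _TI
            tlen += 1
            j -= 1
            state = p
    for k in range(tlen // 2):
        trace[k], trace[tlen - 1 - k] = trace[tlen - 1 - k], trace[k]
    return score, 0, n, 0, m, trace, tlen


_TRACE_CHARS = np.array(["M", "D", "I"])


def _result(
    query_id: str,
    subject_id: str,
    a: str,
    b: str,
    ea: np.ndarray,
    eb: np.ndarray,
    scheme: ScoringScheme,
    raw,
) -> AlignmentResult:
    score, qs, qe, ss, se, trace, tlen = raw
    tr = trace[:tlen]
    n_ident = 0
    i, j = qs, ss
    cols = []
    for t in tr:
        if t == _TM:
            if ea[i] == eb[j]:
                n_ident += 1
            i += 1
            j += 1
            cols.append("M")
        elif t == _TD:
            i += 1
            cols.append("D")
        else:
            j += 1
            cols.append("I")
    aligned_length = int(tlen)
    identity = 100.0 * n_ident / aligned_length if aligned_length else 0.0
    coverage = 100.0 * (qe - qs) / len(a) if len(a) else 0.0
    ev = evalue(score, len(a), len(b), scheme)
    empty = aligned_length == 0
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        score=float(score),
        identity_pct=identity,
        aligned_length=aligned_length,
        n_identical=n_ident,
        query_coverage=coverage,
        e_value=ev,
        trace="".join(cols),
        q_start=0 if empty else qs + 1,
        q_end=0 if empty else qe,
        s_start=0 if empty else ss + 1,
        s_end=0 if empty else se,
    )


def smith_waterman(
    a: str,
    b: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Optimal local alignment; the score never drops below zero.

    If no positive-scoring local alignment exists the result is empty with
    score 0 (coordinates 0 and an empty trace).
    """
    ea, eb = encode(a), encode(b)
    raw = _gotoh(ea, eb, scheme.matrix, scheme.gap_open, scheme.gap_extend, True)
    return _result(query_id, subject_id, a, b, ea, eb, scheme, raw)


def needleman_wunsch(
    a: str,
    b: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Optimal global alignment (no score floor, end gaps penalized)."""
    ea, eb = encode(a), encode(b)
    raw = _gotoh(ea, eb, scheme.matrix, scheme.gap_open, scheme.gap_extend, False)
    return _result(query_id, subject_id, a, b, ea, eb, scheme, raw)


def evalue(score: float, len_a: int, len_b: int, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Karlin-Altschul expectation ``E = K * m * n * exp(-lambda * S)``."""
    if len_a <= 0 or len_b <= 0:
        raise ValueError("sequence lengths must be positive")
    return scheme.K * len_a * len_b * math.exp(-scheme.lam * score)


# ---------------------------------------------------------------------------
# k-mer prefilter and batch searches
# ---------------------------------------------------------------------------


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_prefilter(
    queries: Mapping[str, str],
    subjects: Mapping[str, str] | None = None,
    k: int = 5,
    min_shared: int = 25,
) -> list[tuple[str, str]]:
    """Candidate pairs sharing at least ``min_shared`` distinct k-mers.

    With ``subjects is None`` (or identical to ``queries``) unordered pairs
    of distinct queries are returned.  The defaults are permissive enough
    that every pair at or above the duplication identity gate survives;
    identical sequences always share all their k-mers and are always kept.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    same = subjects is None or subjects is queries
    subj = queries if same else subjects
    index: dict[str, list[str]] = {}
    for sid, seq in subj.items():
        for kmer in _kmer_set(seq, k):
            index.setdefault(kmer, []).append(sid)
    qids = list(queries)
    order = {sid: i for i, sid in enumerate(subj)}
    out = []
    for qi, qid in enumerate(qids):
        counts: dict[str, int] = {}
        for kmer in _kmer_set(queries[qid], k):
            for sid in index.get(kmer, ()):
                counts[sid] = counts.get(sid, 0) + 1
        for sid, c in counts.items():
            if c < min_shared:
                continue
            if same:
                if order[sid] <= qi:
                    continue
            out.append((qid, sid))
    out.sort()
    return out


HIT_COLUMNS = [
    "query",
    "subject",
    "score",
    "identity_pct",
    "aligned_length",
    "query_coverage",
    "e_value",
]


def search(
    queries: Mapping[str, str],
    subjects: Mapping[str, str] | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    k: int = 5,
    min_shared: int = 25,
    prefilter: bool = True,
) -> pd.DataFrame:
    """Local-alignment search of ``queries`` against ``subjects``.

    Returns a BLAST-outfmt-6-like table (one row per surviving pair, sorted
    by query then subject).  With ``subjects is None`` the search is an
    all-vs-all over ``queries`` with each unordered pair reported once.
    """
    same = subjects is None or subjects is queries
    subj = queries if same else subjects
    if prefilter:
        pairs = kmer_prefilter(queries, None if same else subj, k, min_shared)
    else:
        if same:
            qids = list(queries)
            pairs = [
                (qids[i], qids[j])
                for i in range(len(qids))
                for j in range(i + 1, len(qids))
            ]
        else:
            pairs = list(itertools.product(queries, subj))
        pairs.sort()
    rows = []
    enc_q = {qid: encode(s) for qid, s in queries.items()}
    enc_s = enc_q if same else {sid: encode(s) for sid, s in subj.items()}
    for qid, sid in pairs:
        raw = _gotoh(
            enc_q[qid], enc_s[sid], scheme.matrix, scheme.gap_open,
            scheme.gap_extend, True,
        )
        r = _result(qid, sid, queries[qid], subj[sid], enc_q[qid], enc_s[sid], scheme, raw)
        rows.append(
            (r.query_id, r.subject_id, r.score, r.identity_pct,
             r.aligned_length, r.query_coverage, r.e_value)
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def all_vs_all(
    seqs: Mapping[str, str],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    k: int = 5,
    min_shared: int = 25,
    prefilter: bool = True,
) -> pd.DataFrame:
    """All-vs-all local alignment over one sequence set (pairs reported once)."""
    return search(seqs, None, scheme, k, min_shared, prefilter)
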