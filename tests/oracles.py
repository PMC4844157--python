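"""Independent oracles used by the test suite.

The alignment oracle scores pairs by exhaustive enumeration of monotone
column matchings, never by dynamic programming: every alignment is fully
described by its ordered set of aligned-residue columns (matches and
mismatches), and with affine penalties the unaligned residues between two
consecutive columns are optimally packed as one contiguous gap run per
sequence.  Enumerating all C(n+m, n) matchings and scoring each directly
is therefore exhaustive over alignments for |open| >= |extend|.
"""

from __future__ import annotations


def _gap(d: int, open_: float, extend: float) -> float:
    return 0.0 if d == 0 else open_ + (d - 1) * extend


def _matchings(n: int, m: int):
    """Yield every monotone matching of positions 0..n-1 with 0..m-1."""
    stack = [((), -1, -1)]
    while stack:
        matching, li, lj = stack.pop()
        yield matching
        for i in range(li + 1, n):
            for j in range(lj + 1, m):
                stack.append((matching + ((i, j),), i, j))


def brute_force_scores(a, b, scheme) -> tuple[float, float]:
    """(local, global) optimal scores by exhaustive matching enumeration."""
    from famscan.align import encode

    ea, eb = encode(a), encode(b)
    sub = scheme.matrix
    go, ge = scheme.gap_open, scheme.gap_extend
    n, m = len(ea), len(eb)

    best_local = 0.0  # the empty alignment
    best_global = _gap(n, go, ge) + _gap(m, go, ge)  # empty matching
    for matching in _matchings(n, m):
        if not matching:
            continue
        pairs_score = sum(sub[ea[i], eb[j]] for i, j in matching)
        interior = 0.0
        for (i1, j1), (i2, j2) in zip(matching, matching[1:]):
            interior += _gap(i2 - i1 - 1, go, ge) + _gap(j2 - j1 - 1, go, ge)
        local = pairs_score + interior
        if local > best_local:
            best_local = local
        (i0, j0), (iN, jN) = matching[0], matching[-1]
        ends = (
            _gap(i0, go, ge)
            + _gap(j0, go, ge)
            + _gap(n - 1 - iN, go, ge)
            + _gap(m - 1 - jN, go, ge)
        )
        glob = local + ends
        if glob > best_global:
            best_global = glob
    return best_local, best_global
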