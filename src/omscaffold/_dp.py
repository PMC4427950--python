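"""Numba kernels for overlap (semi-global) restriction-map alignment.

The DP state is a pair of fragment-boundary indices (i, j); a transition
consumes 1..delta fragments on each map and scores the resulting block.
A chain may start at any boundary pair — skipped fragments before the
start cost ``c_end_skip`` each beyond the ``free_end`` freely-truncated
terminal fragments, counted on the map with the smaller leftover (the
other map's leftover is overhang and free) — and ends symmetrically.
This keeps the alignment an overlap rather than a local alignment while
staying robust to ragged map ends.

The chain table C stores the best chain *ending with a block* at each
cell, kept separately from the restart potential so that an all-negative
best chain is still recoverable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e18
_TIE = 1e-9


@njit(cache=True)
def max_compatible_run(fa, fb, abs_tol, rel_tol):
    """Length of the longest diagonal run of size-compatible fragments
    between two fragment arrays (any offset).  A cheap necessary condition
    for a genuine overlap: molecules sharing a region keep runs of
    consecutive fragments whose sizes agree within noise, while unrelated
    maps rarely line up several in a row."""
    n = fa.shape[0]
    m = fb.shape[0]
    best = 0
    for d in range(-(m - 1), n):
        run = 0
        lo = d if d > 0 else 0
        hi = n if n < m + d else m + d
        for i in range(lo, hi):
            x = fa[i]
            y = fb[i - d]
            diff = x - y if x > y else y - x
            lim = abs_tol
            rl = rel_tol * (x if x > y else y)
            if rl > lim:
                lim = rl
            if diff <= lim:
                run += 1
                if run > best:
                    best = run
            else:
                run = 0
    return best


@njit(cache=True, inline="always")
def _better(v1, s1sum, nb1, si1, sj1, v2, s2sum, nb2, si2, sj2):
    """True when candidate 1 beats candidate 2: higher value, then longer
    chain (smaller start sum), then fewer blocks, then smaller start."""
    if v1 > v2 + _TIE:
        return True
    if v1 < v2 - _TIE:
        return False
    if s1sum != s2sum:
        return s1sum < s2sum
    if nb1 != nb2:
        return nb1 < nb2
    if si1 != si2:
        return si1 < si2
    return sj1 < sj2


@njit(cache=True)
def overlap_dp(pa, pb, c_match, v_size, c_cut, delta, free_end, c_end_skip):
    """Fill the chain table.

    Returns (C, NB, PI, PJ, SRC, SI, SJ): best chain score ending with a
    block at each boundary pair, its block count, the predecessor pair,
    whether the predecessor continued its own chain (1) or restarted
    there (0), and the chain start pair.
    """
    n = pa.shape[0] - 1
    m = pb.shape[0] - 1
    C = np.full((n + 1, m + 1), NEG)
    NB = np.zeros((n + 1, m + 1), np.int64)
    PI = np.full((n + 1, m + 1), -1, np.int64)
    PJ = np.full((n + 1, m + 1), -1, np.int64)
    SRC = np.zeros((n + 1, m + 1), np.int64)
    SI = np.full((n + 1, m + 1), -1, np.int64)
    SJ = np.full((n + 1, m + 1), -1, np.int64)
    for i in range(n + 1):
        for j in range(m + 1):
            bv = NEG
            bnb = 0
            bpi = -1
            bpj = -1
            bsrc = 0
            bsi = -1
            bsj = -1
            for ti in range(1, delta + 1):
                ii = i - ti
                if ii < 0:
                    break
                for tj in range(1, delta + 1):
                    jj = j - tj
                    if jj < 0:
                        break
                    x = pa[i] - pa[ii]
                    y = pb[j] - pb[jj]
                    sc = c_match - (x - y) * (x - y) / (v_size * (x + y)) - c_cut * (ti + tj - 2)
                    # source 1: restart at (ii, jj)
                    skip = min(ii, jj) - free_end
                    rbase = -c_end_skip * skip if skip > 0 else 0.0
                    sv = rbase
                    ssum = ii + jj
                    snb = 0
                    ssi = ii
                    ssj = jj
                    ssrc = 0
                    # source 2: continue the chain ending at (ii, jj)
                    if C[ii, jj] > NEG / 2 and _better(
                        C[ii, jj], SI[ii, jj] + SJ[ii, jj], NB[ii, jj], SI[ii, jj], SJ[ii, jj],
                        sv, ssum, snb, ssi, ssj,
                    ):
                        sv = C[ii, jj]
                        ssum = SI[ii, jj] + SJ[ii, jj]
                        snb = NB[ii, jj]
                        ssi = SI[ii, jj]
                        ssj = SJ[ii, jj]
                        ssrc = 1
                    cand = sv + sc
                    if _better(cand, ssum, snb + 1, ssi, ssj, bv, bsi + bsj, bnb, bsi, bsj):
                        bv = cand
                        bnb = snb + 1
                        bpi = ii
                        bpj = jj
                        bsrc = ssrc
                        bsi = ssi
                        bsj = ssj
            C[i, j] = bv
            NB[i, j] = bnb
            PI[i, j] = bpi
            PJ[i, j] = bpj
            SRC[i, j] = bsrc
            SI[i, j] = bsi
            SJ[i, j] = bsj
    return C, NB, PI, PJ, SRC, SI, SJ
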