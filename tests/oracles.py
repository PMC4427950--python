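"""Independent reference implementations used to validate the package.

Everything here is deliberately written from first principles — sorting and
scanning, substring comparison, exhaustive recursion — so the tests compare
two independent routes to the same quantity.
"""

from __future__ import annotations

from typing import Sequence


def brute_force_nx(lengths: Sequence[int], frac: float) -> int:
    """Nx by definition: sort descending, scan cumulatively."""
    total = sum(lengths)
    cum = 0
    for ln in sorted(lengths, reverse=True):
        cum += ln
        if cum >= frac * total:
            return ln
    return min(lengths)


def brute_force_count_to(lengths: Sequence[int], frac: float) -> int:
    total = sum(lengths)
    cum = 0
    for k, ln in enumerate(sorted(lengths, reverse=True), start=1):
        cum += ln
        if cum >= frac * total:
            return k
    return len(lengths)


def brute_force_sites(sequence: str, pattern: str) -> list[int]:
    """Every offset where the pattern matches exactly, by substring
    comparison at each position."""
    seq = sequence.upper()
    return [
        i for i in range(len(seq) - len(pattern) + 1) if seq[i : i + len(pattern)] == pattern
    ]


def brute_force_best_score(
    frags_a: Sequence[float],
    frags_b: Sequence[float],
    c_match: float,
    v_size: float,
    c_cut: float,
    delta: int,
    c_end_skip: float,
    free_end: int = 1,
) -> float | None:
    """Best overlap-chain score by exhaustive recursion over every legal
    block decomposition and start/end pair (one orientation).

    A chain is a strictly increasing sequence of boundary pairs with at
    most ``delta`` fragments consumed per map per block; ends anywhere,
    paying ``c_end_skip`` per skipped fragment beyond ``free_end`` on the
    side with the smaller leftover.
    """
    n = len(frags_a)
    m = len(frags_b)
    pa = [0.0]
    for f in frags_a:
        pa.append(pa[-1] + f)
    pb = [0.0]
    for f in frags_b:
        pb.append(pb[-1] + f)

    def start_pen(i: int, j: int) -> float:
        return c_end_skip * max(0, min(i, j) - free_end)

    def end_pen(i: int, j: int) -> float:
        return c_end_skip * max(0, min(n - i, m - j) - free_end)

    best: list[float | None] = [None]

    def consider(value: float) -> None:
        if best[0] is None or value > best[0]:
            best[0] = value

    def extend(i: int, j: int, acc: float) -> None:
        # chain may end here
        consider(acc - end_pen(i, j))
        for ti in range(1, delta + 1):
            if i + ti > n:
                break
            for tj in range(1, delta + 1):
                if j + tj > m:
                    break
                x = pa[i + ti] - pa[i]
                y = pb[j + tj] - pb[j]
                sc = c_match - (x - y) ** 2 / (v_size * (x + y)) - c_cut * (ti + tj - 2)
                extend(i + ti, j + tj, acc + sc)

    for i in range(n + 1):
        for j in range(m + 1):
            pen = start_pen(i, j)
            for ti in range(1, delta + 1):
                if i + ti > n:
                    break
                for tj in range(1, delta + 1):
                    if j + tj > m:
                        break
                    x = pa[i + ti] - pa[i]
                    y = pb[j + tj] - pb[j]
                    sc = c_match - (x - y) ** 2 / (v_size * (x + y)) - c_cut * (ti + tj - 2)
                    extend(i + ti, j + tj, sc - pen)

    return best[0]


def brute_force_best_score_both(
    frags_a: Sequence[float], frags_b: Sequence[float], **kw
) -> float | None:
    fwd = brute_force_best_score(frags_a, frags_b, **kw)
    rev = brute_force_best_score(frags_a, list(reversed(frags_b)), **kw)
    vals = [v for v in (fwd, rev) if v is not None]
    return max(vals) if vals else None


def greedy_feasible_subset_oracle(candidates):
    """All-subsets search for the greedy-order-maximal feasible join set.

    Feasible: every scaffold end used at most once and no cycles (simple
    paths only).  Among feasible subsets, the one whose membership vector
    over the greedy order is lexicographically maximal (prefer containing
    earlier candidates) is returned — by construction the set the greedy
    algorithm should produce.
    """
    from omscaffold.superscaffold import _greedy_order

    ordered = _greedy_order(candidates)
    k = len(ordered)

    def feasible(subset: list) -> bool:
        ends = set()
        parent = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                x = parent[x]
            return x

        for c in subset:
            ea, eb = (c.scaf_a, c.end_a), (c.scaf_b, c.end_b)
            if ea in ends or eb in ends:
                return False
            ra, rb = find(c.scaf_a), find(c.scaf_b)
            if ra == rb:
                return False
            parent[ra] = rb
            ends.update((ea, eb))
        return True

    best_mask = None
    for mask in range(1 << k):
        subset = [ordered[i] for i in range(k) if mask >> i & 1]
        if not feasible(subset):
            continue
        vec = tuple(1 if mask >> i & 1 else 0 for i in range(k))
        if best_mask is None or vec > best_mask[0]:
            best_mask = (vec, subset)
    return best_mask[1] if best_mask else []
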