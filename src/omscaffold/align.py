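"""Overlap alignment of two restriction maps by dynamic programming.

Two maps of the same genomic region differ by missed cuts (a true site not
observed), false cuts, and multiplicative sizing error on each fragment.
An alignment is therefore a chain of *blocks*: a block matches ``t``
consecutive fragments of map A (summed length ``x``) against ``s``
fragments of map B (summed length ``y``) and is scored

    c_match − (x − y)² / (v_size · (x + y)) − c_cut · ((t − 1) + (s − 1))

a fixed match reward minus a χ²-like sizing term (the variance of an
optical fragment length grows roughly linearly with its size) minus a
penalty for every cut present in one map but not the other inside the
block.  Alignment is *overlap* (semi-global): on each side one terminal
fragment truncates freely (molecules start and end mid-fragment), further
skipped fragments pay a small per-fragment end-gap cost on the map with
the smaller leftover, and the other map's leftover is unscored overhang.

Both orientations of map B are tried; reported coordinates for the reverse
orientation refer to the reversed map, with helpers to translate back.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._dp import NEG, overlap_dp
from .digest import RestrictionMap

__all__ = ["ScoringParams", "Block", "MapAlignment", "block_score", "overlap_align", "best_alignment"]

FREE_END_FRAGS = 1  # terminal fragments that may be truncated without penalty


@dataclass(frozen=True)
class ScoringParams:
    """Scoring constants for map-to-map overlap alignment.

    min_score / min_overlap_frags form the significance filter: an
    alignment is reportable only if its total score reaches min_score and
    it consumes at least min_overlap_frags fragments of the first
    (reference) map.  Setting both to 0 disables filtering.
    """

    c_match: float = 1.0
    v_size: float = 0.25
    c_cut: float = 1.0
    delta: int = 4
    min_score: float = 8.0
    min_overlap_frags: int = 5
    c_end_skip: float = 0.5

    def __post_init__(self) -> None:
        if self.c_match <= 0 or self.v_size <= 0 or self.c_cut <= 0:
            raise ValueError("scoring constants must be positive")
        if self.c_end_skip < 0:
            raise ValueError("c_end_skip must be non-negative")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")


@dataclass(frozen=True)
class Block:
    t: int
    s: int
    x: float
    y: float


def block_score(block: Block, params: ScoringParams) -> float:
    if block.t < 1 or block.s < 1 or block.x <= 0 or block.y <= 0:
        raise ValueError("invalid block")
    sizing = (block.x - block.y) ** 2 / (params.v_size * (block.x + block.y))
    return params.c_match - sizing - params.c_cut * (block.t - 1 + block.s - 1)


@dataclass
class MapAlignment:
    """Best-scoring overlap alignment of map B onto map A.

    ``a_range``/``b_range`` are half-open fragment-index intervals consumed
    by the chain; ``pairs`` the matched boundary-index pairs.  For
    ``orientation == 'reverse'`` all B indices refer to ``map_b.reversed()``;
    ``b_range_original`` translates back.  Overhangs count B fragments
    extending past each end of A (oriented frame).
    """

    a_id: str
    b_id: str
    orientation: str  # 'forward' | 'reverse'
    score: float
    blocks: list[Block]
    pairs: list[tuple[int, int]]
    a_n_fragments: int
    b_n_fragments: int
    end_skip_penalty: float = 0.0

    @property
    def a_range(self) -> tuple[int, int]:
        return (self.pairs[0][0], self.pairs[-1][0])

    @property
    def b_range(self) -> tuple[int, int]:
        return (self.pairs[0][1], self.pairs[-1][1])

    @property
    def b_range_original(self) -> tuple[int, int]:
        lo, hi = self.b_range
        if self.orientation == "forward":
            return (lo, hi)
        m = self.b_n_fragments
        return (m - hi, m - lo)

    @property
    def matched_a_fragments(self) -> int:
        return self.a_range[1] - self.a_range[0]

    @property
    def matched_b_fragments(self) -> int:
        return self.b_range[1] - self.b_range[0]

    @property
    def overhang_left(self) -> int:
        i0, j0 = self.pairs[0]
        return max(0, j0 - i0)

    @property
    def overhang_right(self) -> int:
        ik, jk = self.pairs[-1]
        return max(0, (self.b_n_fragments - jk) - (self.a_n_fragments - ik))


def _run_orientation(
    pa: np.ndarray, pb: np.ndarray, params: ScoringParams
) -> Optional[tuple[float, int, list[tuple[int, int]]]]:
    """Best overlap chain for one orientation of B.

    Returns (score, n_blocks, boundary pairs, end penalty) or None when no
    chain with at least one block exists.
    """
    C, NB, PI, PJ, SRC, SI, SJ = overlap_dp(
        pa,
        pb,
        params.c_match,
        params.v_size,
        params.c_cut,
        params.delta,
        FREE_END_FRAGS,
        params.c_end_skip,
    )
    n = len(pa) - 1
    m = len(pb) - 1
    best_key = None
    best_cell = None
    for i in range(n + 1):
        for j in range(m + 1):
            if C[i, j] <= NEG / 2:
                continue
            end_skip = max(0, min(n - i, m - j) - FREE_END_FRAGS)
            total = C[i, j] - params.c_end_skip * end_skip
            consumed = (i - SI[i, j]) + (j - SJ[i, j])
            key = (-total, -consumed, NB[i, j], SI[i, j], SJ[i, j], i, j)
            if best_key is None or key < best_key:
                best_key = key
                best_cell = (i, j)
    if best_cell is None:
        return None
    pairs: list[tuple[int, int]] = []
    i, j = best_cell
    while True:
        pairs.append((i, j))
        pi, pj, src = PI[i, j], PJ[i, j], SRC[i, j]
        if src == 0:
            pairs.append((pi, pj))
            break
        i, j = pi, pj
    pairs.reverse()
    i, j = best_cell
    end_skip = max(0, min(n - i, m - j) - FREE_END_FRAGS)
    start_skip = max(0, min(pairs[0][0], pairs[0][1]) - FREE_END_FRAGS)
    penalty = params.c_end_skip * (end_skip + start_skip)
    total = float(C[best_cell]) - params.c_end_skip * end_skip
    return total, int(NB[best_cell]), pairs, penalty


def _prefix(frags: Sequence[float]) -> np.ndarray:
    pa = np.zeros(len(frags) + 1)
    np.cumsum(np.asarray(frags, dtype=np.float64), out=pa[1:])
    return pa


def best_alignment(
    map_a: RestrictionMap, map_b: RestrictionMap, params: ScoringParams = ScoringParams()
) -> Optional[MapAlignment]:
    """Best overlap alignment over both orientations of B, ignoring the
    significance thresholds.  Returns None only when no end-reaching chain
    exists at all."""
    pa = _prefix(map_a.fragments)
    candidates = []
    for orientation, bmap in (("forward", map_b), ("reverse", map_b.reversed())):
        res = _run_orientation(pa, _prefix(bmap.fragments), params)
        if res is None:
            continue
        score, nb, pairs, penalty = res
        candidates.append(
            (score, 0 if orientation == "forward" else 1, nb, pairs, penalty, orientation, bmap)
        )
    if not candidates:
        return None
    # higher score wins; ties prefer forward, then fewer blocks
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    score, _, _, pairs, penalty, orientation, bmap = candidates[0]
    blocks = []
    for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
        blocks.append(
            Block(
                t=i1 - i0,
                s=j1 - j0,
                x=map_a.position(i1) - map_a.position(i0),
                y=bmap.position(j1) - bmap.position(j0),
            )
        )
    aln = MapAlignment(
        a_id=map_a.source_id,
        b_id=map_b.source_id,
        orientation=orientation,
        score=sum(block_score(b, params) for b in blocks) - penalty,
        blocks=blocks,
        pairs=pairs,
        a_n_fragments=map_a.n_fragments,
        b_n_fragments=map_b.n_fragments,
        end_skip_penalty=penalty,
    )
    return aln


def overlap_align(
    map_a: RestrictionMap, map_b: RestrictionMap, params: ScoringParams = ScoringParams()
) -> Optional[MapAlignment]:
    """Best overlap alignment of B onto A, or None when it fails the
    significance thresholds (score < min_score, or fewer than
    min_overlap_frags fragments of A consumed)."""
    aln = best_alignment(map_a, map_b, params)
    if aln is None:
        return None
    if aln.score < params.min_score or aln.matched_a_fragments < params.min_overlap_frags:
        return None
    return aln


def permutation_null_rank(
    map_a: RestrictionMap,
    map_b: RestrictionMap,
    params: ScoringParams,
    rng: np.random.Generator,
    n_permutations: int = 1000,
) -> float:
    """Empirical significance calibration: fraction of fragment-shuffled
    versions of B scoring at least as well as the observed alignment.
    Small values mean the observed score is unlikely under a random map of
    identical fragment composition."""
    obs = best_alignment(map_a, map_b, params)
    obs_score = obs.score if obs is not None else -np.inf
    frags = np.asarray(map_b.fragments, dtype=float)
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(frags)
        perm = RestrictionMap.from_fragments(map_b.source_id, list(frags))
        aln = best_alignment(map_a, perm, params)
        if aln is not None and aln.score >= obs_score:
            hits += 1
    return (hits + 1) / (n_permutations + 1)
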