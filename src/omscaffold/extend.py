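"""Iterative extension of in silico seed maps with recruited molecules.

Each scaffold's in silico map is a *seed*.  Molecules whose best overlap
alignment to the seed is significant and that overhang a seed end carry
restriction-site information beyond the scaffold boundary.  Overhanging
cuts are projected into seed coordinates (anchored at the outermost
matched cut pair, so sizing drift does not accumulate across the seed),
clustered with an uncertainty-aware single linkage, and averaged into
consensus cuts; scanning outward, the consensus keeps cuts supported by at
least ``min_cov`` molecules and stops where the spanning molecule depth
falls below ``min_cov`` — trimming the unreliable low-coverage fringe at
each end.  Feeding the extended map back in as the next seed lets molecules
that barely touched the original scaffold anchor on the new consensus
region, so the map grows over several iterations.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

import numpy as np

from ._dp import max_compatible_run
from .align import MapAlignment, ScoringParams, overlap_align
from .digest import RestrictionMap

__all__ = [
    "ExtensionConfig",
    "ConsensusCut",
    "ExtendedMap",
    "recruit_molecules",
    "consensus_extend",
    "iterate_extension",
]


@dataclass(frozen=True)
class ExtensionConfig:
    """iterations: recruit+consensus rounds; min_cov: molecules required to
    keep a consensus cut; cluster_tol_kb: single-linkage gap closing
    projected cuts into one cluster; max_extension_kb: cap per side per
    iteration, chosen so that projection scatter (which grows with the
    square root of the overhang distance) stays within the cluster
    tolerance — each iteration re-anchors at the new end, so growth
    compounds without degrading map quality; proj_cv: assumed fragment
    sizing CV used to scale projection uncertainties; min_support_frac:
    fraction of the spanning molecule depth a consensus cut must reach —
    real sites are observed by most spanning molecules, so clusters far
    below that are scatter satellites or co-located false cuts."""

    iterations: int = 4
    min_cov: int = 3
    cluster_tol_kb: float = 1.5
    max_extension_kb: float = 60.0
    proj_cv: float = 0.05
    min_support_frac: float = 0.35

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.min_cov < 1 or self.cluster_tol_kb <= 0:
            raise ValueError("invalid extension config")
        if self.proj_cv < 0:
            raise ValueError("proj_cv must be non-negative")
        if not 0 <= self.min_support_frac < 1:
            raise ValueError("min_support_frac must be in [0, 1)")


@dataclass(frozen=True)
class ConsensusCut:
    """One consensus cut in an extension: offset (kb, outward from the seed
    end) and the number of molecules supporting it."""

    offset_kb: float
    support: int


@dataclass
class ExtendedMap:
    """A seed map plus per-side consensus extensions.

    ``core`` is the original in silico map, never modified.  Extension
    offsets are kb outward from the respective core end, strictly
    increasing.  ``full_map`` concatenates everything: the outermost
    consensus cut on each side becomes the new map end (nothing is known
    beyond it), interior consensus cuts become ordinary cuts, and the core
    region is marked in ``meta`` (``core_start``/``core_end``, kb).
    """

    seed_id: str
    core: RestrictionMap
    left_ext: list[ConsensusCut] = field(default_factory=list)
    right_ext: list[ConsensusCut] = field(default_factory=list)
    iteration_log: list[dict] = field(default_factory=list)

    @property
    def left_span_kb(self) -> float:
        return self.left_ext[-1].offset_kb if self.left_ext else 0.0

    @property
    def right_span_kb(self) -> float:
        return self.right_ext[-1].offset_kb if self.right_ext else 0.0

    @property
    def full_map(self) -> RestrictionMap:
        ls = self.left_span_kb
        cuts: list[float] = []
        cuts.extend(ls - c.offset_kb for c in reversed(self.left_ext[:-1] if self.left_ext else []))
        cuts.extend(ls + c for c in self.core.cuts)
        core_end = ls + self.core.total_length
        cuts.extend(core_end + c.offset_kb for c in self.right_ext[:-1])
        total = core_end + self.right_span_kb
        return RestrictionMap(
            self.seed_id,
            total,
            tuple(cuts),
            {"core_start": ls, "core_end": core_end},
        )


_SCREEN_MIN_FRAGS = 8  # screen only maps long enough to demand a run
_SCREEN_MIN_RUN = 4


def _passes_screen(seed_frags: np.ndarray, mol: RestrictionMap) -> bool:
    fb = np.asarray(mol.fragments, dtype=np.float64)
    if min(seed_frags.shape[0], fb.shape[0]) < _SCREEN_MIN_FRAGS:
        return True
    if max_compatible_run(seed_frags, fb, 1.2, 0.15) >= _SCREEN_MIN_RUN:
        return True
    return max_compatible_run(seed_frags, fb[::-1].copy(), 1.2, 0.15) >= _SCREEN_MIN_RUN


def recruit_molecules(
    seed: RestrictionMap,
    molecules: Sequence[RestrictionMap],
    params: ScoringParams = ScoringParams(),
    prefilter: bool = True,
) -> list[tuple[RestrictionMap, MapAlignment]]:
    """Molecules significantly aligned to the seed with ≥ 1 fragment of
    overhang past a seed end, orientation-normalized so molecule
    coordinates read along the seed.

    ``prefilter`` screens each molecule with a cheap compatible-fragment
    run test before paying for the full dynamic program; maps too short
    for the screen always go through.
    """
    recruits: list[tuple[RestrictionMap, MapAlignment]] = []
    seed_frags = np.asarray(seed.fragments, dtype=np.float64)
    for mol in molecules:
        if prefilter and not _passes_screen(seed_frags, mol):
            continue
        aln = overlap_align(seed, mol, params)
        if aln is None:
            continue
        if aln.overhang_left < 1 and aln.overhang_right < 1:
            continue
        if aln.orientation == "reverse":
            mol = mol.reversed()
        recruits.append((mol, aln))
    return recruits


def _kde(arr: np.ndarray, hs: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    step = max(tol / 12.0, float(hs.min()) / 4.0)
    grid = np.arange(arr[0] - tol, arr[-1] + tol, step)
    dens = (
        np.exp(-0.5 * ((grid[:, None] - arr[None, :]) / hs[None, :]) ** 2) / hs[None, :]
    ).sum(axis=1)
    return grid, dens


def _partition(pts: list[tuple[float, float]], splits: list[float]) -> list[list[tuple[float, float]]]:
    out: list[list[tuple[float, float]]] = [[] for _ in range(len(splits) + 1)]
    for p in pts:
        out[int(np.searchsorted(splits, p[0]))].append(p)
    return [c for c in out if c]


def _split_multimodal(
    pts: list[tuple[float, float]], tol: float
) -> list[list[tuple[float, float]]]:
    """Split one linkage cluster at clear density valleys.

    Restriction sites a few kb apart project into clusters whose gap is
    below the linkage tolerance, so single linkage alone chains them into
    one blob.  An adaptive kernel density profile — each projected cut
    smoothed with its own positional uncertainty — separates the modes:
    the cluster is cut at every local minimum whose density falls below
    half of both neighbouring peaks.
    """
    if len(pts) < 4 or pts[-1][0] - pts[0][0] <= tol:
        return [pts]
    arr = np.array([p[0] for p in pts])
    hs = np.array([max(tol / 3.0, p[1]) for p in pts])
    grid, dens = _kde(arr, hs, tol)
    splits: list[float] = []
    k = 1
    last_peak = dens[0]
    while k < len(grid) - 1:
        if dens[k] <= dens[k - 1] and dens[k] < dens[k + 1]:  # local minimum
            right_peak = dens[k]
            for q in range(k + 1, len(grid) - 1):
                if dens[q] >= dens[q - 1] and dens[q] > dens[q + 1]:
                    right_peak = dens[q]
                    break
            else:
                right_peak = dens[-1]
            if dens[k] < 0.5 * min(last_peak, right_peak):
                splits.append(grid[k])
        if dens[k] >= dens[k - 1] and dens[k] > dens[k + 1]:
            last_peak = dens[k]
        k += 1
    if not splits:
        return [pts]
    return _partition(pts, splits)


def _force_split(pts: list[tuple[float, float]], tol: float) -> list[list[tuple[float, float]]]:
    """Bisect a cluster at its weakest interior density point.

    Used when a cluster holds more projected cuts than spanning molecules
    (several true cuts merged beyond the valley test's resolution); the
    split lands between the modes even when the valley is shallow.
    """
    if len(pts) < 4:
        return [pts]
    arr = np.array([p[0] for p in pts])
    hs = np.array([max(tol / 3.0, p[1]) for p in pts])
    grid, dens = _kde(arr, hs, tol)
    lo, hi = np.quantile(arr, [0.2, 0.8])
    inner = (grid > lo) & (grid < hi)
    if not inner.any():
        mid = len(pts) // 2
        return [pts[:mid], pts[mid:]]
    cut = float(grid[inner][np.argmin(dens[inner])])
    parts = _partition(pts, [cut])
    if len(parts) == 1:
        mid = len(pts) // 2
        return [pts[:mid], pts[mid:]]
    return parts


def _refine_cluster(
    pts: list[tuple[float, float]], tol: float, depth: int
) -> list[list[tuple[float, float]]]:
    parts = _split_multimodal(pts, tol)
    if len(parts) == 1 and depth >= 1 and len(pts) > 1.4 * depth:
        parts = _force_split(pts, tol)
    if len(parts) == 1:
        return parts
    out: list[list[tuple[float, float]]] = []
    for p in parts:
        out.extend(_refine_cluster(p, tol, depth))
    return out


def _consensus(cluster: list[tuple[float, float]]) -> ConsensusCut:
    w = np.array([1.0 / (sd * sd + 1e-6) for _o, sd in cluster])
    o = np.array([o for o, _sd in cluster])
    return ConsensusCut(float((w * o).sum() / w.sum()), len(cluster))


def _cluster(
    pts: list[tuple[float, float]], tol: float, depth_at=None
) -> list[ConsensusCut]:
    """Cluster projected cuts (offset, positional sd) into consensus cuts.

    Single linkage on sorted offsets with an uncertainty-aware link
    tolerance — two projections of one true cut differ by roughly the
    quadrature sum of their sds, which grows with the fragment lengths the
    projection traversed — followed by density-valley splitting of merged
    clusters.  ``depth_at`` (offset → spanning molecule count) enables the
    multiplicity check: a cluster with more members than spanning
    molecules must hold several true cuts and is split at its weakest
    interior point.  Order-independent by construction; consensus
    positions are inverse-variance weighted means.
    """
    if not pts:
        return []
    pts = sorted(pts)
    clusters: list[list[tuple[float, float]]] = [[pts[0]]]
    for o, sd in pts[1:]:
        po, psd = clusters[-1][-1]
        link = max(tol, math.hypot(sd, psd))
        if o - po <= link:
            clusters[-1].append((o, sd))
        else:
            clusters.append([(o, sd)])
    refined: list[list[tuple[float, float]]] = []
    for c in clusters:
        depth = depth_at(sum(p[0] for p in c) / len(c)) if depth_at is not None else 0
        refined.extend(_refine_cluster(c, tol, depth))
    return [_consensus(c) for c in refined]


def _side_offsets(
    seed: RestrictionMap,
    recruits: Sequence[tuple[RestrictionMap, MapAlignment]],
    side: str,
    proj_cv: float,
) -> tuple[list[tuple[float, float]], list[float]]:
    """Project overhanging molecule cuts to outward offsets from one end
    of the current map.

    Returns ((offset, positional sd) pairs, molecule reaches).  A reach is
    the projected offset of a molecule's far end — the depth profile of
    the extension.  Projections anchor on a median over the outermost
    matched pairs at real map cuts (the terminal boundaries are
    mid-fragment, and a forced end-match there would bias every
    projection; the median suppresses single mispaired anchors).  A cut's
    sd is the sizing uncertainty accumulated over the molecule fragments
    between anchor and cut (``proj_cv`` × the root-sum-square of those
    fragment lengths).
    """
    offsets: list[tuple[float, float]] = []
    reaches: list[float] = []
    n = seed.n_fragments
    n_anchor = 5  # outermost matched pairs voting on the projection offset
    for mol, aln in recruits:
        anchored = [(i, j) for i, j in aln.pairs if 0 < i < n]
        if not anchored:
            continue
        voters = anchored[-n_anchor:] if side == "right" else anchored[:n_anchor]
        shift = median(seed.position(i) - mol.position(j) for i, j in voters)
        anchor_j = voters[-1][1] if side == "right" else voters[0][1]
        frags = mol.fragments
        if side == "right":
            reach = shift + mol.total_length - seed.total_length
            rng_j = range(anchor_j + 1, mol.n_fragments)
        else:
            reach = -shift
            rng_j = range(anchor_j - 1, 0, -1)
        ssq = 0.0
        for j in rng_j:
            ssq += frags[j - 1 if side == "right" else j] ** 2
            proj = shift + mol.position(j)
            off = proj - seed.total_length if side == "right" else -proj
            if off > 0:
                offsets.append((off, max(0.15, proj_cv * math.sqrt(ssq))))
        if reach > 0:
            reaches.append(reach)
    return offsets, reaches


def consensus_extend(
    seed: RestrictionMap,
    recruits: Sequence[tuple[RestrictionMap, MapAlignment]],
    config: ExtensionConfig = ExtensionConfig(),
) -> ExtendedMap:
    """One consensus pass per side: cluster projected overhang cuts, then
    scan outward keeping clusters with enough molecule support.

    The scan stops where the spanning molecule depth drops below min_cov —
    the low-coverage fringe that gets discarded — or at max_extension_kb.
    A weak cluster *inside* well-covered territory is a false cut or a
    scatter satellite: it is dropped, but does not end the extension.
    """
    ext = ExtendedMap(seed_id=seed.source_id, core=seed)
    for side in ("left", "right"):
        offsets, reaches = _side_offsets(seed, recruits, side, config.proj_cv)
        reaches.sort()

        def depth_at(off: float) -> int:
            return len(reaches) - bisect.bisect_left(reaches, off)

        cand = _cluster(offsets, config.cluster_tol_kb, depth_at)
        kept: list[ConsensusCut] = []
        for cut in cand:  # ascending offset = outward scan
            depth = depth_at(cut.offset_kb)
            if depth < config.min_cov:
                break
            if cut.offset_kb > config.max_extension_kb:
                break
            # a real cut is observed by most molecules spanning it (digestion
            # efficiency); scatter satellites and co-located false cuts are not
            if cut.support >= max(config.min_cov, config.min_support_frac * depth):
                kept.append(cut)
        if side == "left":
            ext.left_ext = kept
        else:
            ext.right_ext = kept
    return ext


def _polish_extensions(
    acc: ExtendedMap,
    full: RestrictionMap,
    recruits: Sequence[tuple[RestrictionMap, MapAlignment]],
    min_meas: int = 2,
) -> None:
    """Re-estimate consensus cut positions in fragment space.

    Every 1:1-matched pair of adjacent map cuts in a molecule alignment is
    a direct measurement of that map fragment's length.  Fragment lengths
    in the extension regions are replaced by the mean of their
    measurements (where at least ``min_meas`` exist) and positions rebuilt
    cumulatively outward from the exact in silico core cuts, so projection
    drift does not compound across iterations.  The core itself is never
    touched.
    """
    n = full.n_fragments
    meas: dict[int, list[float]] = {}
    for mol, aln in recruits:
        for (i1, j1), (i2, j2) in zip(aln.pairs, aln.pairs[1:]):
            if i2 - i1 == 1 and 0 < i1 and i2 < n:
                meas.setdefault(i1, []).append(mol.position(j2) - mol.position(j1))
    frags = list(full.fragments)
    for i, vals in meas.items():
        if len(vals) >= min_meas:
            est = sum(vals) / len(vals)
            if est > 0.05:
                frags[i] = est
    ls = acc.left_span_kb
    core_end_pos = ls + acc.core.total_length
    L = len(acc.left_ext)
    R = len(acc.right_ext)
    # full-map boundary layout: 0 = outermost left cut, 1..L-1 = remaining
    # left ext cuts, L..n-R = core boundaries (cuts L..n-R-? exact),
    # n-R+1..n-1 = right ext cuts, n = outermost right cut
    if R:
        anchor_idx = n - R  # last boundary before the right extension
        pos = full.position(anchor_idx)
        new_offsets: list[float] = []
        for b in range(anchor_idx, n):
            pos += frags[b]
            new_offsets.append(pos - core_end_pos)
        if (
            len(new_offsets) == R
            and all(o > 0 for o in new_offsets)
            and all(b > a for a, b in zip(new_offsets, new_offsets[1:]))
        ):
            acc.right_ext = [
                ConsensusCut(o, c.support) for o, c in zip(new_offsets, acc.right_ext)
            ]
    if L:
        anchor_idx = L  # first boundary after the left extension
        pos = full.position(anchor_idx)
        new_offsets = []
        for b in range(anchor_idx - 1, -1, -1):
            pos -= frags[b]
            new_offsets.append(ls - pos)
        if (
            len(new_offsets) == L
            and all(o > 0 for o in new_offsets)
            and all(b > a for a, b in zip(new_offsets, new_offsets[1:]))
        ):
            acc.left_ext = [
                ConsensusCut(o, c.support) for o, c in zip(new_offsets, acc.left_ext)
            ]


def iterate_extension(
    seed: RestrictionMap,
    molecules: Sequence[RestrictionMap],
    params: ScoringParams = ScoringParams(),
    config: ExtensionConfig = ExtensionConfig(),
    min_keep_kb: float = 250.0,
) -> ExtendedMap:
    """Run recruit + consensus for ``config.iterations`` rounds, feeding
    each round's full map in as the next seed.  Molecules are re-recruited
    from scratch every round (the extended seed changes the alignment
    landscape) and only molecules ≥ ``min_keep_kb`` participate.  The
    returned map keeps the original seed as ``core`` with cumulative
    extensions and a per-iteration log."""
    pool = [m for m in molecules if m.total_length >= min_keep_kb]
    acc = ExtendedMap(seed_id=seed.source_id, core=seed)
    current = seed
    core_interior: set[int] = set()
    frag_arrays = [np.asarray(m.fragments, dtype=np.float64) for m in pool]
    frag_arrays_rev = [a[::-1].copy() for a in frag_arrays]
    for it in range(1, config.iterations + 1):
        recruits: list[tuple[RestrictionMap, MapAlignment]] = []
        refiners: list[tuple[RestrictionMap, MapAlignment]] = []
        seed_frags = np.asarray(current.fragments, dtype=np.float64)
        screenable = seed_frags.shape[0] >= _SCREEN_MIN_FRAGS
        cs = current.meta.get("core_start", 0.0)
        ce = current.meta.get("core_end", current.total_length)
        for k, mol in enumerate(pool):
            if k in core_interior:
                continue
            if (
                screenable
                and frag_arrays[k].shape[0] >= _SCREEN_MIN_FRAGS
                and max_compatible_run(seed_frags, frag_arrays[k], 1.2, 0.15) < _SCREEN_MIN_RUN
                and max_compatible_run(seed_frags, frag_arrays_rev[k], 1.2, 0.15) < _SCREEN_MIN_RUN
            ):
                continue
            aln = overlap_align(current, mol, params)
            if aln is None:
                continue
            if aln.orientation == "reverse":
                mol = mol.reversed()
            if aln.overhang_left < 1 and aln.overhang_right < 1:
                a_lo, a_hi = aln.a_range
                if current.position(a_lo) >= cs - 1e-9 and current.position(a_hi) <= ce + 1e-9:
                    # confined to the exact in silico region; contributes
                    # nothing to the extension now or in any later round
                    core_interior.add(k)
                else:
                    # interior but covering consensus territory: its matched
                    # fragments refine consensus cut positions
                    refiners.append((mol, aln))
                continue
            recruits.append((mol, aln))
        # polish existing consensus positions with this round's alignments
        if acc.left_ext or acc.right_ext:
            _polish_extensions(acc, current, recruits + refiners)
        step = consensus_extend(current, recruits, config)
        tol = config.cluster_tol_kb
        prev_left, prev_right = acc.left_span_kb, acc.right_span_kb
        acc.left_ext = acc.left_ext + [
            ConsensusCut(prev_left + c.offset_kb, c.support)
            for c in step.left_ext
            if c.offset_kb > tol or not acc.left_ext
        ]
        acc.right_ext = acc.right_ext + [
            ConsensusCut(prev_right + c.offset_kb, c.support)
            for c in step.right_ext
            if c.offset_kb > tol or not acc.right_ext
        ]
        acc.iteration_log.append(
            {
                "iteration": it,
                "recruited": len(recruits),
                "refiners": len(refiners),
                "left_added_kb": acc.left_span_kb - prev_left,
                "right_added_kb": acc.right_span_kb - prev_right,
                "left_added_cuts": len(step.left_ext),
                "right_added_cuts": len(step.right_ext),
            }
        )
        current = acc.full_map
    return acc
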