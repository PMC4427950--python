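"""Scaffold joining: detect overlaps between extended maps, resolve
conflicts on the scaffold graph, emit super-scaffolds as AGP + FASTA.

Two scaffolds adjacent on a chromosome acquire extensions that cross the
gap between them, so their extended maps overlap; a significant overlap
alignment that involves at least one extension region is a join candidate.
The candidate records which scaffold ends meet, the relative orientation,
and the gap implied by the distance between the two seed cores in the
shared alignment frame (negative when the cores themselves overlap).

Conflicts are resolved greedily by descending score under two hard rules:
every scaffold end is used at most once, and no cycles — the accepted set
is a collection of simple paths, each emitted as one super-scaffold.
Sequence output places either the constant 600 N gap (gap sizes estimated
from maps carry enough uncertainty that a recognizable constant spacer
simplifies downstream analysis) or the map-estimated gap floored at
100 N between members, and writes an AGP v2.1 description alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .align import MapAlignment, ScoringParams, overlap_align
from .assembly_io import ScaffoldRecord
from .digest import RestrictionMap
from .extend import ExtendedMap

__all__ = [
    "JoinCandidate",
    "SuperScaffold",
    "find_joins",
    "resolve_joins",
    "build_superscaffolds",
    "emit_sequences",
    "write_agp",
    "read_join_candidates",
    "write_join_candidates",
]


@dataclass(frozen=True)
class JoinCandidate:
    """A candidate connection between two scaffold ends.

    Canonical form has (scaf_a, end_a) lexicographically ≤ (scaf_b, end_b).
    ``relative_orientation`` is 'same' when the two scaffolds read in the
    same direction across the join (which is equivalent to the joined ends
    being opposite: right–left or left–right), 'flipped' otherwise.
    ``gap_kb`` is the signed distance between the two seed cores; negative
    means the cores overlap in the alignment frame.
    """

    scaf_a: str
    end_a: str
    scaf_b: str
    end_b: str
    relative_orientation: str
    score: float
    gap_kb: float

    def __post_init__(self) -> None:
        if self.scaf_a == self.scaf_b:
            raise ValueError(f"self-join on {self.scaf_a}")
        for e in (self.end_a, self.end_b):
            if e not in ("left", "right"):
                raise ValueError(f"bad end {e!r}")
        if self.relative_orientation not in ("same", "flipped"):
            raise ValueError(f"bad orientation {self.relative_orientation!r}")

    def canonical(self) -> "JoinCandidate":
        if (self.scaf_a, self.end_a) <= (self.scaf_b, self.end_b):
            return self
        return JoinCandidate(
            self.scaf_b,
            self.end_b,
            self.scaf_a,
            self.end_a,
            self.relative_orientation,
            self.score,
            self.gap_kb,
        )


@dataclass
class SuperScaffold:
    """Ordered, oriented members; ``gap_after_kb`` follows each member
    except the last (None there and for map-less joins)."""

    id: str
    members: list[tuple[str, str, float | None]]  # (scaffold_id, '+'/'-', gap_after_kb)


def _core_interval_oriented(ext: ExtendedMap, orientation: str) -> tuple[float, float]:
    full = ext.full_map
    cs, ce = full.meta["core_start"], full.meta["core_end"]
    if orientation == "forward":
        return cs, ce
    return full.total_length - ce, full.total_length - cs


def _candidate_from_alignment(
    ext_a: ExtendedMap, ext_b: ExtendedMap, aln: MapAlignment
) -> JoinCandidate:
    full_a = ext_a.full_map
    full_b = ext_b.full_map
    b_oriented = full_b if aln.orientation == "forward" else full_b.reversed()
    # offset of oriented-B coordinates into the A frame, averaged over
    # matched cut pairs
    offs = [full_a.position(i) - b_oriented.position(j) for i, j in aln.pairs]
    offset = sum(offs) / len(offs)
    a_cs, a_ce = full_a.meta["core_start"], full_a.meta["core_end"]
    b_cs_o, b_ce_o = _core_interval_oriented(ext_b, aln.orientation)
    b_cs, b_ce = offset + b_cs_o, offset + b_ce_o
    same = aln.orientation == "forward"
    if (b_cs + b_ce) / 2 >= (a_cs + a_ce) / 2:
        end_a = "right"
        end_b = "left" if same else "right"
        gap = b_cs - a_ce
    else:
        end_a = "left"
        end_b = "right" if same else "left"
        gap = a_cs - b_ce
    return JoinCandidate(
        ext_a.seed_id,
        end_a,
        ext_b.seed_id,
        end_b,
        "same" if same else "flipped",
        aln.score,
        gap,
    ).canonical()


def _extension_fragments(full: RestrictionMap) -> set[int]:
    cs, ce = full.meta["core_start"], full.meta["core_end"]
    out = set()
    for k in range(full.n_fragments):
        mid = (full.position(k) + full.position(k + 1)) / 2
        if mid < cs or mid > ce:
            out.add(k)
    return out


def find_joins(
    extended_maps: Sequence[ExtendedMap], params: ScoringParams = ScoringParams()
) -> list[JoinCandidate]:
    """Pairwise overlap alignment of all extended maps; significant
    alignments whose consumed range touches at least one extension
    fragment (on either map) become join candidates."""
    if len(extended_maps) < 2:
        raise ValueError("need at least 2 extended maps")
    candidates: list[JoinCandidate] = []
    fulls = [e.full_map for e in extended_maps]
    ext_frags = [_extension_fragments(f) for f in fulls]
    for ia in range(len(extended_maps)):
        for ib in range(ia + 1, len(extended_maps)):
            aln = overlap_align(fulls[ia], fulls[ib], params)
            if aln is None:
                continue
            a_lo, a_hi = aln.a_range
            b_lo, b_hi = aln.b_range_original
            touches = any(k in ext_frags[ia] for k in range(a_lo, a_hi)) or any(
                k in ext_frags[ib] for k in range(b_lo, b_hi)
            )
            if not touches:
                continue
            candidates.append(_candidate_from_alignment(extended_maps[ia], extended_maps[ib], aln))
    return candidates


def _greedy_order(candidates: Iterable[JoinCandidate]) -> list[JoinCandidate]:
    return sorted(
        (c.canonical() for c in candidates),
        key=lambda c: (-c.score, abs(c.gap_kb), c.scaf_a, c.end_a, c.scaf_b, c.end_b),
    )


def resolve_joins(candidates: Iterable[JoinCandidate]) -> list[JoinCandidate]:
    """Greedy by descending score (ties: smaller |gap|, then lexicographic):
    accept a candidate iff both scaffold ends are unused and no cycle is
    created.  The result is a set of simple paths over scaffolds."""
    accepted: list[JoinCandidate] = []
    used_ends: set[tuple[str, str]] = set()
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for c in _greedy_order(candidates):
        ea, eb = (c.scaf_a, c.end_a), (c.scaf_b, c.end_b)
        if ea in used_ends or eb in used_ends:
            continue
        ra, rb = find(c.scaf_a), find(c.scaf_b)
        if ra == rb:
            continue
        parent[ra] = rb
        used_ends.update((ea, eb))
        accepted.append(c)
    return accepted


def build_superscaffolds(
    scaffold_ids: Sequence[str], joins: Sequence[JoinCandidate]
) -> list[SuperScaffold]:
    """Chain accepted joins into super-scaffolds.

    Every input scaffold appears exactly once; unjoined scaffolds become
    singletons.  Each path is read from its lexicographically smaller
    terminus; a member is '+' when the path enters through its left end.
    """
    G = nx.Graph()
    G.add_nodes_from(scaffold_ids)
    for c in joins:
        if c.scaf_a not in G or c.scaf_b not in G:
            raise KeyError(f"join references unknown scaffold {c.scaf_a}/{c.scaf_b}")
        G.add_edge(c.scaf_a, c.scaf_b, join=c)
    paths: list[list[tuple[str, str, float | None]]] = []
    for comp in nx.connected_components(G):
        nodes = sorted(comp)
        if len(nodes) == 1:
            paths.append([(nodes[0], "+", None)])
            continue
        termini = sorted(n for n in nodes if G.degree[n] == 1)
        if len(termini) != 2:
            raise ValueError(f"joins do not form a simple path over {nodes}")
        start = termini[0]
        members: list[tuple[str, str, float | None]] = []
        prev = None
        cur = start
        entry_end: str | None = None
        while True:
            nbrs = [n for n in G.neighbors(cur) if n != prev]
            if entry_end is None:
                nxt = nbrs[0]
                join: JoinCandidate = G.edges[cur, nxt]["join"]
                exit_end = join.end_a if join.scaf_a == cur else join.end_b
                orient = "+" if exit_end == "right" else "-"
            else:
                orient = "+" if entry_end == "left" else "-"
            if not nbrs:
                members.append((cur, orient, None))
                break
            nxt = nbrs[0]
            join = G.edges[cur, nxt]["join"]
            exit_end = join.end_a if join.scaf_a == cur else join.end_b
            next_entry = join.end_b if join.scaf_a == cur else join.end_a
            expected_exit = "right" if orient == "+" else "left"
            if exit_end != expected_exit:
                raise ValueError(
                    f"contradictory orientations along path at {cur} "
                    f"(needs {expected_exit} end, join uses {exit_end})"
                )
            members.append((cur, orient, join.gap_kb))
            prev, cur, entry_end = cur, nxt, next_entry
        paths.append(members)
    paths.sort(key=lambda p: p[0][0])
    return [SuperScaffold(id=f"super{i + 1:03d}", members=m) for i, m in enumerate(paths)]


def _gap_bp(gap_kb: float | None, gap_mode: str, constant_gap_bp: int, min_gap_bp: int) -> int:
    if gap_mode == "constant" or gap_kb is None:
        return constant_gap_bp
    return max(min_gap_bp, round(gap_kb * 1000))


def emit_sequences(
    superscaffolds: Sequence[SuperScaffold],
    assembly: Sequence[ScaffoldRecord],
    gap_mode: str = "estimated",
    constant_gap_bp: int = 600,
    min_gap_bp: int = 100,
) -> tuple[list[ScaffoldRecord], list[str]]:
    """Render super-scaffolds to gapped sequences plus AGP v2.1 lines.

    Constant mode inserts exactly ``constant_gap_bp`` Ns between members;
    estimated mode inserts round(gap_kb × 1000) Ns floored at
    ``min_gap_bp`` (negative gaps floored too — sequence is never trimmed,
    since map evidence cannot adjudicate bases).  '-' members are
    reverse-complemented.
    """
    if gap_mode not in ("constant", "estimated"):
        raise ValueError("gap_mode must be 'constant' or 'estimated'")
    by_id = {}
    for rec in assembly:
        by_id[rec.id] = rec
    seen: set[str] = set()
    records: list[ScaffoldRecord] = []
    agp: list[str] = ["##agp-version\t2.1"]
    for ss in superscaffolds:
        parts: list[str] = []
        pos = 0
        part_no = 0
        for k, (sid, orient, gap_kb) in enumerate(ss.members):
            if sid not in by_id:
                raise KeyError(f"super-scaffold {ss.id} references unknown scaffold {sid!r}")
            if sid in seen:
                raise ValueError(f"scaffold {sid!r} appears in more than one super-scaffold")
            seen.add(sid)
            rec = by_id[sid]
            seq = rec.sequence if orient == "+" else rec.reverse_complement().sequence
            part_no += 1
            agp.append(
                "\t".join(
                    [
                        ss.id,
                        str(pos + 1),
                        str(pos + len(seq)),
                        str(part_no),
                        "W",
                        sid,
                        "1",
                        str(len(seq)),
                        orient,
                    ]
                )
            )
            parts.append(seq)
            pos += len(seq)
            if k < len(ss.members) - 1:
                nbp = _gap_bp(gap_kb, gap_mode, constant_gap_bp, min_gap_bp)
                part_no += 1
                agp.append(
                    "\t".join(
                        [
                            ss.id,
                            str(pos + 1),
                            str(pos + nbp),
                            str(part_no),
                            "N",
                            str(nbp),
                            "scaffold",
                            "yes",
                            "map",
                        ]
                    )
                )
                parts.append("N" * nbp)
                pos += nbp
        records.append(ScaffoldRecord(ss.id, "".join(parts)))
    return records, agp


def write_agp(agp_lines: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(agp_lines) + "\n")


_JOIN_COLS = ["scaf_a", "end_a", "scaf_b", "end_b", "relative_orientation", "score", "gap_kb"]


def write_join_candidates(candidates: Sequence[JoinCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_JOIN_COLS) + "\n")
        for c in candidates:
            fh.write(
                f"{c.scaf_a}\t{c.end_a}\t{c.scaf_b}\t{c.end_b}\t"
                f"{c.relative_orientation}\t{c.score:.4f}\t{c.gap_kb:.3f}\n"
            )


def read_join_candidates(path) -> list[JoinCandidate]:
    out: list[JoinCandidate] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _JOIN_COLS:
            raise ValueError(f"{path}: unexpected join-candidate header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(JoinCandidate(f[0], f[1], f[2], f[3], f[4], float(f[5]), float(f[6])))
    return out
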