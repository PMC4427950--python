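"""FISH-marker anchoring of super-scaffolds and the end-to-end pipeline.

A FISH marker ties a position inside a scaffold to a cytogenetic rank
along a chromosome (1 = p-terminus).  Markers lift from scaffold
coordinates to super-scaffold coordinates through the AGP layout; each
super-scaffold is then placed at the median rank of its markers (robust to
a single mislocalized probe) and oriented so marker ranks increase with
its internal coordinate.  Super-scaffolds with a single marker (or tied
ranks) cannot be oriented from markers alone: they default to '+' and are
flagged low-confidence rather than dropped.  Markers that violate the
final monotone order are reported as conflicts, never silently discarded.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

import numpy as np

from .align import ScoringParams
from .assembly_io import (
    AssemblyStats,
    ScaffoldRecord,
    compute_assembly_stats,
    format_stats_report,
)
from .digest import RestrictionEnzyme, RestrictionMap, digest_assembly, get_enzyme
from .extend import ExtendedMap, ExtensionConfig, iterate_extension
from .simulate import NoiseModel, SimConfig, simulate_molecules
from .superscaffold import (
    JoinCandidate,
    SuperScaffold,
    build_superscaffolds,
    emit_sequences,
    find_joins,
    resolve_joins,
)

__all__ = [
    "FishMarker",
    "ChromosomeBuild",
    "read_markers",
    "anchor_with_markers",
    "build_pseudochromosome",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]

log = logging.getLogger("omscaffold")


@dataclass(frozen=True)
class FishMarker:
    marker_id: str
    chromosome: str
    rank: int
    scaffold_id: str
    position_bp: int


def read_markers(path) -> list[FishMarker]:
    """5-column TSV (marker, chromosome, rank, scaffold, position_bp),
    header required; ranks must be unique per chromosome."""
    markers: list[FishMarker] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["marker", "chromosome", "rank", "scaffold", "position_bp"]:
            raise ValueError(f"{path}: unexpected marker header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            markers.append(FishMarker(f[0], f[1], int(f[2]), f[3], int(f[4])))
    seen: set[tuple[str, int]] = set()
    for m in markers:
        key = (m.chromosome, m.rank)
        if key in seen:
            raise ValueError(f"duplicate rank {m.rank} on chromosome {m.chromosome}")
        seen.add(key)
    return markers


@dataclass
class ChromosomeBuild:
    chromosome: str
    order: list[tuple[str, str]]  # (superscaffold_id, '+'/'-')
    conflicts: list[FishMarker]
    low_confidence: list[str]  # super-scaffolds oriented by default only
    unplaced: list[str]  # super-scaffolds without markers for this chromosome


def _member_layout(
    ss: SuperScaffold, lengths: dict[str, int], gap_bp: int
) -> dict[str, tuple[int, str]]:
    """Offset (bp) and orientation of each member within the super-scaffold,
    using the constant-gap layout."""
    layout: dict[str, tuple[int, str]] = {}
    pos = 0
    for k, (sid, orient, _gap) in enumerate(ss.members):
        layout[sid] = (pos, orient)
        pos += lengths[sid]
        if k < len(ss.members) - 1:
            pos += gap_bp
    return layout


def _lis_keep(ranks: list[int]) -> set[int]:
    """Indices of a longest strictly increasing subsequence (leftmost on
    ties); everything outside it is a conflict."""
    n = len(ranks)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if ranks[j] < ranks[i] and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: (best_len[i], -i))
    keep: set[int] = set()
    while end != -1:
        keep.add(end)
        end = prev[end]
    return keep


def anchor_with_markers(
    superscaffolds: Sequence[SuperScaffold],
    assembly: Sequence[ScaffoldRecord],
    markers: Sequence[FishMarker],
    chromosome: str,
    gap_bp: int = 600,
) -> ChromosomeBuild:
    """Order and orient super-scaffolds along one chromosome."""
    lengths = {r.id: r.length for r in assembly}
    scaffold_to_ss: dict[str, SuperScaffold] = {}
    for ss in superscaffolds:
        for sid, _o, _g in ss.members:
            scaffold_to_ss[sid] = ss
    chrom_markers = [m for m in markers if m.chromosome == chromosome]
    if not chrom_markers:
        raise ValueError(f"no markers for chromosome {chromosome!r}")
    for m in chrom_markers:
        if m.scaffold_id not in lengths:
            raise KeyError(f"marker {m.marker_id} references unknown scaffold {m.scaffold_id!r}")
        if not 0 <= m.position_bp < lengths[m.scaffold_id]:
            raise ValueError(f"marker {m.marker_id} position outside scaffold {m.scaffold_id}")

    # lift markers to super-scaffold coordinates
    per_ss: dict[str, list[tuple[FishMarker, int]]] = {}
    for m in chrom_markers:
        ss = scaffold_to_ss.get(m.scaffold_id)
        if ss is None:
            continue
        layout = _member_layout(ss, lengths, gap_bp)
        off, orient = layout[m.scaffold_id]
        ln = lengths[m.scaffold_id]
        pos = off + (m.position_bp if orient == "+" else ln - 1 - m.position_bp)
        per_ss.setdefault(ss.id, []).append((m, pos))
    if not per_ss:
        raise ValueError(f"no marker for chromosome {chromosome!r} maps into a super-scaffold")

    placed: list[tuple[float, str, str]] = []  # (median rank, ss_id, orientation)
    low_confidence: list[str] = []
    for ss_id, mlist in per_ss.items():
        ranks = [m.rank for m, _p in mlist]
        med = median(ranks)
        trend = 0
        for i in range(len(mlist)):
            for j in range(i + 1, len(mlist)):
                (mi, pi), (mj, pj) = mlist[i], mlist[j]
                trend += int(np.sign((mi.rank - mj.rank) * (pi - pj)))
        if trend > 0:
            orient = "+"
        elif trend < 0:
            orient = "-"
        else:
            orient = "+"
            low_confidence.append(ss_id)
        placed.append((med, ss_id, orient))
    placed.sort(key=lambda t: (t[0], t[1]))
    order = [(ss_id, orient) for _med, ss_id, orient in placed]

    # final marker sequence along the build; non-monotone ranks are conflicts
    ss_lengths = {
        ss.id: sum(lengths[s] for s, _o, _g in ss.members) + gap_bp * (len(ss.members) - 1)
        for ss in superscaffolds
    }
    final: list[tuple[int, FishMarker]] = []
    offset = 0
    for ss_id, orient in order:
        for m, pos in sorted(per_ss[ss_id], key=lambda t: t[1]):
            p = pos if orient == "+" else ss_lengths[ss_id] - 1 - pos
            final.append((offset + p, m))
        offset += ss_lengths[ss_id] + gap_bp
    final.sort(key=lambda t: t[0])
    ranks = [m.rank for _p, m in final]
    keep = _lis_keep(ranks)
    conflicts = [m for i, (_p, m) in enumerate(final) if i not in keep]
    unplaced = sorted(ss.id for ss in superscaffolds if ss.id not in per_ss)
    return ChromosomeBuild(
        chromosome=chromosome,
        order=order,
        conflicts=conflicts,
        low_confidence=sorted(low_confidence),
        unplaced=unplaced,
    )


def build_pseudochromosome(
    build: ChromosomeBuild,
    superscaffold_records: Sequence[ScaffoldRecord],
    gap_bp: int = 600,
    name: str | None = None,
) -> ScaffoldRecord:
    """Concatenate the ordered, oriented super-scaffold sequences with the
    configured constant gap.  Member sequences are never altered."""
    by_id = {r.id: r for r in superscaffold_records}
    parts: list[str] = []
    for k, (ss_id, orient) in enumerate(build.order):
        rec = by_id[ss_id]
        parts.append(rec.sequence if orient == "+" else rec.reverse_complement().sequence)
        if k < len(build.order) - 1:
            parts.append("N" * gap_bp)
    return ScaffoldRecord(name or f"chr{build.chromosome}", "".join(parts))


# --- pipeline driver -------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything the digest → simulate → extend → join → anchor pipeline
    needs; fully determines the run together with the input data."""

    seed: int
    enzyme: str = "KpnI"
    sim: SimConfig | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    extension: ExtensionConfig = field(default_factory=ExtensionConfig)
    min_keep_kb: float = 250.0
    gap_mode: str = "constant"
    constant_gap_bp: int = 600
    min_gap_bp: int = 100
    chromosome: str | None = None


@dataclass
class PipelineResult:
    stats_before: AssemblyStats
    stats_after: AssemblyStats
    candidates: list[JoinCandidate]
    accepted: list[JoinCandidate]
    superscaffolds: list[SuperScaffold]
    records: list[ScaffoldRecord]
    agp: list[str]
    extended: list[ExtendedMap]
    molecules_used: int
    chromosome_build: ChromosomeBuild | None
    pseudochromosome: ScaffoldRecord | None
    notes: list[str]

    def report(self) -> str:
        lines = [
            format_stats_report(
                {"Initial assembly": self.stats_before, "OM assembly": self.stats_after}
            ),
            "",
            f"Join candidates: {len(self.candidates)}  accepted: {len(self.accepted)}",
            f"Super-scaffolds: {len(self.superscaffolds)}  "
            f"from molecules: {self.molecules_used}",
        ]
        lines += [f"note: {n}" for n in self.notes]
        return "\n".join(lines)


def _stage(name: str, t0: float, **counts) -> None:
    extra = "  ".join(f"{k}={v}" for k, v in counts.items())
    log.info("stage %-12s %6.1fs  %s", name, time.perf_counter() - t0, extra)


def run_pipeline(
    assembly: Sequence[ScaffoldRecord],
    config: PipelineConfig,
    molecules: Sequence[RestrictionMap] | None = None,
    markers: Sequence[FishMarker] | None = None,
    reference_maps: Sequence[RestrictionMap] | None = None,
) -> PipelineResult:
    """Execute the whole workflow on an assembly.

    Molecules are either supplied (real data) or simulated; simulation
    samples from ``reference_maps`` when given (a truth genome) and
    otherwise from the assembly's own in silico maps.  Anchoring runs only
    when markers and a target chromosome are configured.  The run is
    deterministic given the seed.
    """
    notes: list[str] = []
    enzyme: RestrictionEnzyme = get_enzyme(config.enzyme)
    t0 = time.perf_counter()
    seeds = digest_assembly(assembly, enzyme)
    _stage("digest", t0, scaffolds=len(seeds), cuts=sum(len(m.cuts) for m in seeds))

    if molecules is None:
        sim = config.sim or SimConfig(seed=config.seed)
        if sim.seed != config.seed:
            sim = SimConfig(
                seed=config.seed,
                mean_len_kb=sim.mean_len_kb,
                len_sd_kb=sim.len_sd_kb,
                min_report_kb=sim.min_report_kb,
                min_keep_kb=sim.min_keep_kb,
                coverage=sim.coverage,
            )
        t0 = time.perf_counter()
        molecules = simulate_molecules(reference_maps or seeds, sim, config.noise)
        _stage("simulate", t0, molecules=len(molecules))
        notes.append(f"molecules simulated ({len(molecules)})")

    t0 = time.perf_counter()
    extended = [
        iterate_extension(s, molecules, config.scoring, config.extension, config.min_keep_kb)
        for s in seeds
    ]
    _stage(
        "extend",
        t0,
        added_kb=round(sum(e.left_span_kb + e.right_span_kb for e in extended), 1),
    )

    t0 = time.perf_counter()
    candidates = find_joins(extended, config.scoring) if len(extended) >= 2 else []
    accepted = resolve_joins(candidates)
    superscaffolds = build_superscaffolds([r.id for r in assembly], accepted)
    records, agp = emit_sequences(
        superscaffolds,
        assembly,
        gap_mode=config.gap_mode,
        constant_gap_bp=config.constant_gap_bp,
        min_gap_bp=config.min_gap_bp,
    )
    _stage("scaffold", t0, candidates=len(candidates), accepted=len(accepted))

    build = None
    pseudo = None
    if markers is not None and config.chromosome is not None:
        t0 = time.perf_counter()
        build = anchor_with_markers(
            superscaffolds, assembly, markers, config.chromosome, config.constant_gap_bp
        )
        pseudo = build_pseudochromosome(build, records, config.constant_gap_bp)
        _stage("anchor", t0, placed=len(build.order), conflicts=len(build.conflicts))
    else:
        notes.append("anchoring skipped (no markers provided)")

    return PipelineResult(
        stats_before=compute_assembly_stats(assembly),
        stats_after=compute_assembly_stats(records),
        candidates=candidates,
        accepted=accepted,
        superscaffolds=superscaffolds,
        records=records,
        agp=agp,
        extended=extended,
        molecules_used=len(molecules),
        chromosome_build=build,
        pseudochromosome=pseudo,
        notes=notes,
    )
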