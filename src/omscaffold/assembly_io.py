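"""Assembly FASTA I/O and contiguity statistics (N50/N90, N%, scaffold counts).

The Nx convention used throughout: sort scaffolds by length descending
(ties broken by input order) and scan cumulatively; Nx is the length of the
scaffold at which the cumulative sum first reaches ≥ x% of the total
assembly size.  ``count_to_90pct`` counts how many of those largest
scaffolds are needed to reach 90% (or any other coverage fraction) — the
headline "scaffolds covering 90% of the genome" statistic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ScaffoldRecord",
    "AssemblyStats",
    "load_assembly",
    "write_assembly",
    "compute_assembly_stats",
    "format_stats_report",
]

_ILLEGAL = re.compile(r"[^ACGTN]")


@dataclass
class ScaffoldRecord:
    """One named assembly sequence over the {A,C,G,T,N} alphabet,
    stored upper-case."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"scaffold {self.id!r}: empty sequence")
        m = _ILLEGAL.search(self.sequence)
        if m:
            raise ValueError(
                f"scaffold {self.id!r}: illegal character {m.group()!r} at position {m.start()}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "ScaffoldRecord":
        from .digest import reverse_complement

        return ScaffoldRecord(self.id, reverse_complement(self.sequence))


def load_assembly(path) -> list[ScaffoldRecord]:
    """Read a FASTA assembly; order preserved, ids must be unique.

    The record id is the first whitespace-delimited token of the header.
    Lower-case input is folded to upper-case; any character outside
    {A,C,G,T,N} raises with the offending record named.
    """
    records: list[ScaffoldRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate scaffold id {rec.id!r}")
        seen.add(rec.id)
        records.append(ScaffoldRecord(rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_assembly(records: Iterable[ScaffoldRecord], path) -> None:
    """Write FASTA at 60 columns."""
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


@dataclass(frozen=True)
class AssemblyStats:
    total_size: int
    scaffold_count: int
    n50: int
    n90: int
    n_percent: float
    count_to_90pct: int


def compute_assembly_stats(
    assembly: Sequence[ScaffoldRecord], coverage_fraction: float = 0.9
) -> AssemblyStats:
    if not assembly:
        raise ValueError("empty assembly")
    lengths = sorted((r.length for r in assembly), reverse=True)
    total = sum(lengths)
    n_count = sum(r.sequence.count("N") for r in assembly)

    def nx(frac: float) -> int:
        threshold = frac * total
        cum = 0
        for ln in lengths:
            cum += ln
            if cum >= threshold:
                return ln
        return lengths[-1]

    def count_to(frac: float) -> int:
        threshold = frac * total
        cum = 0
        for i, ln in enumerate(lengths, start=1):
            cum += ln
            if cum >= threshold:
                return i
        return len(lengths)

    return AssemblyStats(
        total_size=total,
        scaffold_count=len(lengths),
        n50=nx(0.5),
        n90=nx(0.9),
        n_percent=100.0 * n_count / total,
        count_to_90pct=count_to(coverage_fraction),
    )


def _fmt_bp(bp: int) -> str:
    if bp >= 10_000_000:
        return f"{bp / 1e6:.2f} Mb"
    if bp >= 10_000:
        return f"{bp / 1e3:.2f} kb"
    return f"{bp} bp"


def format_stats_report(stats_by_label: dict[str, AssemblyStats], tsv: bool = False) -> str:
    """Render a summary-of-assemblies table for one or more assemblies."""
    cols = ["Assembly", "Scaffold N50", "Scaffold N90", "N%", "Total size", "Scaffolds", "To 90%"]
    rows = [
        [
            label,
            _fmt_bp(s.n50),
            _fmt_bp(s.n90),
            f"{s.n_percent:.2f}",
            _fmt_bp(s.total_size),
            str(s.scaffold_count),
            str(s.count_to_90pct),
        ]
        for label, s in stats_by_label.items()
    ]
    if tsv:
        return "\n".join("\t".join(r) for r in [cols] + rows)
    widths = [max(len(r[i]) for r in [cols] + rows) for i in range(len(cols))]
    lines = ["  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip() for r in [cols] + rows]
    return "\n".join(lines)
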