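"""In silico restriction digestion and enzyme-compatibility evaluation.

A restriction map (*Rmap*) is the ordered list of fragment lengths produced
by cutting a sequence at every occurrence of an enzyme's recognition site.
At optical-mapping resolution the map — not the sequence — is the object
that gets aligned, so this module is the bridge from sequence space to map
space.  Coordinates are 0-based half-open in bases internally and exposed
in kilobases (kb) on :class:`RestrictionMap`.

N runs inside a scaffold contribute their nominal length to the enclosing
fragment: assembly gap sizes are length estimates, and a real molecule
spans the actual sequence, so a gap is not a cut point.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "RestrictionEnzyme",
    "RestrictionMap",
    "EnzymeEvaluation",
    "BUILTIN_ENZYMES",
    "get_enzyme",
    "find_sites",
    "digest_record",
    "digest_assembly",
    "evaluate_enzyme",
    "read_rmaps",
    "write_rmaps",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type II restriction endonuclease with a fixed recognition site.

    ``cut_offset`` is the distance in bases from the start of the
    recognition site to the cut on the top strand (e.g. KpnI GGTAC^C has
    offset 5).  Ambiguity codes are not supported: every base of
    ``recognition`` must be one of A, C, G, T.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        object.__setattr__(self, "recognition", rec)
        if len(rec) < 4:
            raise ValueError(f"{self.name}: recognition site shorter than 4 bp")
        if set(rec) - set("ACGT"):
            raise ValueError(
                f"{self.name}: recognition site {rec!r} contains non-ACGT characters"
            )
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError(f"{self.name}: cut offset outside recognition site")

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == reverse_complement(self.recognition)


#: The eight enzymes screened for compatibility with an avian genome before
#: optical mapping; all have palindromic 6-cutter sites.
BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {
    e.name: e
    for e in (
        RestrictionEnzyme("AflII", "CTTAAG", 1),
        RestrictionEnzyme("BamHI", "GGATCC", 1),
        RestrictionEnzyme("KpnI", "GGTACC", 5),
        RestrictionEnzyme("NcoI", "CCATGG", 1),
        RestrictionEnzyme("NheI", "GCTAGC", 1),
        RestrictionEnzyme("BglII", "AGATCT", 1),
        RestrictionEnzyme("SpeI", "ACTAGT", 1),
        RestrictionEnzyme("XbaI", "TCTAGA", 1),
    )
}


def get_enzyme(name: str) -> RestrictionEnzyme:
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; built-ins: {', '.join(sorted(BUILTIN_ENZYMES))}"
        ) from None


@dataclass
class RestrictionMap:
    """Ordered restriction map of a scaffold or a single molecule.

    Attributes
    ----------
    source_id
        Name of the scaffold or molecule the map derives from.
    total_length
        Map length in kb.
    cuts
        Strictly ascending interior cut coordinates in kb from the start.
        The two map ends are implicit boundaries, so a map with ``k`` cuts
        has ``k + 1`` fragments.
    meta
        Free-form annotations (simulation truth, core boundaries, ...).
    """

    source_id: str
    total_length: float
    cuts: tuple[float, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cuts = tuple(float(c) for c in self.cuts)
        if self.total_length <= 0:
            raise ValueError(f"{self.source_id}: non-positive map length")
        prev = 0.0
        for c in self.cuts:
            if not prev < c < self.total_length:
                raise ValueError(
                    f"{self.source_id}: cut {c} not strictly inside (0, {self.total_length})"
                )
            prev = c

    @classmethod
    def from_bp(
        cls, source_id: str, total_length_bp: int, cuts_bp: Sequence[int], meta: dict | None = None
    ) -> "RestrictionMap":
        return cls(
            source_id,
            total_length_bp / 1000.0,
            tuple(c / 1000.0 for c in cuts_bp),
            meta or {},
        )

    @classmethod
    def from_fragments(
        cls, source_id: str, fragments: Sequence[float], meta: dict | None = None
    ) -> "RestrictionMap":
        cuts = []
        pos = 0.0
        for f in fragments[:-1]:
            pos += f
            cuts.append(pos)
        total = pos + fragments[-1]
        return cls(source_id, total, tuple(cuts), meta or {})

    @property
    def fragments(self) -> tuple[float, ...]:
        bounds = (0.0, *self.cuts, self.total_length)
        return tuple(bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1))

    @property
    def n_fragments(self) -> int:
        return len(self.cuts) + 1

    def position(self, boundary: int) -> float:
        """Coordinate (kb) of fragment boundary ``boundary`` in 0..n_fragments."""
        if boundary == 0:
            return 0.0
        if boundary == self.n_fragments:
            return self.total_length
        return self.cuts[boundary - 1]

    def reversed(self) -> "RestrictionMap":
        cuts = tuple(self.total_length - c for c in reversed(self.cuts))
        meta = dict(self.meta)
        meta["reversed"] = not meta.get("reversed", False)
        return RestrictionMap(self.source_id, self.total_length, cuts, meta)

    def submap(self, start_kb: float, end_kb: float, source_id: str | None = None) -> "RestrictionMap":
        """Extract the map of the interval [start_kb, end_kb); terminal
        fragments are truncated at the interval ends."""
        if not 0.0 <= start_kb < end_kb <= self.total_length:
            raise ValueError("submap interval outside map")
        lo = bisect.bisect_right(self.cuts, start_kb)
        hi = bisect.bisect_left(self.cuts, end_kb)
        cuts = tuple(c - start_kb for c in self.cuts[lo:hi])
        return RestrictionMap(source_id or self.source_id, end_kb - start_kb, cuts)


def find_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Ascending 0-based start positions of every recognition-site match.

    Matching is exact — a site containing N never matches.  Overlapping
    occurrences are all reported.  Palindromic sites are scanned on one
    strand only; for a non-palindromic enzyme the reverse strand is also
    scanned, with the site reported at its forward-strand start and
    duplicates removed.
    """
    seq = sequence.upper()
    patterns = [enzyme.recognition]
    if not enzyme.is_palindromic:
        patterns.append(reverse_complement(enzyme.recognition))
    hits: set[int] = set()
    for pat in patterns:
        start = seq.find(pat)
        while start != -1:
            hits.add(start)
            start = seq.find(pat, start + 1)
    return sorted(hits)


def digest_record(record, enzyme: RestrictionEnzyme) -> RestrictionMap:
    """In silico digest of one scaffold.

    Cut coordinates are ``site_start + cut_offset``; cuts falling exactly on
    a sequence end are dropped so every fragment has positive length.
    Accepts any object with ``id`` and ``sequence`` attributes.
    """
    length = len(record.sequence)
    cuts = [
        p + enzyme.cut_offset
        for p in find_sites(record.sequence, enzyme)
        if 0 < p + enzyme.cut_offset < length
    ]
    return RestrictionMap.from_bp(record.id, length, cuts)


def digest_assembly(assembly: Iterable, enzyme: RestrictionEnzyme) -> list[RestrictionMap]:
    return [digest_record(rec, enzyme) for rec in assembly]


@dataclass(frozen=True)
class EnzymeEvaluation:
    """Compatibility metrics for one enzyme against an assembly, pooled over
    all scaffolds' fragments."""

    enzyme_name: str
    usable_pct_5_20: float
    usable_pct_6_12: float
    usable_pct_6_15: float
    frags_gt_100kb: int
    avg_frag_kb: float
    max_frag_kb: float


def evaluate_enzyme(assembly: Sequence, enzyme: RestrictionEnzyme, by: str = "count") -> EnzymeEvaluation:
    """Evaluate one enzyme's digest of an assembly.

    ``by='count'`` reports the usable-window percentages as fragment-count
    fractions; ``by='mass'`` weights each fragment by its length, a
    sensitivity variant for when small fragments dominate the count.
    """
    if not assembly:
        raise ValueError("empty assembly")
    if by not in ("count", "mass"):
        raise ValueError("by must be 'count' or 'mass'")
    frags: list[float] = []
    total_kb = 0.0
    for rec in assembly:
        m = digest_record(rec, enzyme)
        frags.extend(m.fragments)
        total_kb += m.total_length

    def window_pct(lo: float, hi: float) -> float:
        if by == "count":
            return 100.0 * sum(1 for f in frags if lo <= f <= hi) / len(frags)
        return 100.0 * sum(f for f in frags if lo <= f <= hi) / total_kb

    return EnzymeEvaluation(
        enzyme_name=enzyme.name,
        usable_pct_5_20=window_pct(5.0, 20.0),
        usable_pct_6_12=window_pct(6.0, 12.0),
        usable_pct_6_15=window_pct(6.0, 15.0),
        frags_gt_100kb=sum(1 for f in frags if f > 100.0),
        avg_frag_kb=total_kb / len(frags),
        max_frag_kb=max(frags),
    )


# --- Rmap tab-separated dialect -------------------------------------------
#
# One line per map:  source_id <TAB> total_length_kb <TAB> frag1 frag2 ...
# fragments in kb with 3 decimals (1 bp resolution).  With truth columns
# (simulated molecules) the line is
#   source_id  total_kb  origin  start_kb  strand  frag1 frag2 ...
# and the header comment marks the variant.

_HEADER_PLAIN = "#rmap\tv1"
_HEADER_TRUTH = "#rmap\tv1\ttruth"


def write_rmaps(maps: Iterable[RestrictionMap], path, truth: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write((_HEADER_TRUTH if truth else _HEADER_PLAIN) + "\n")
        for m in maps:
            frags = [round(f, 3) for f in m.fragments]
            fields = [m.source_id, f"{sum(frags):.3f}"]
            if truth:
                fields += [
                    str(m.meta.get("origin", ".")),
                    f"{m.meta.get('start_kb', 0.0):.3f}",
                    str(m.meta.get("strand", "+")),
                ]
            fields.append(" ".join(f"{f:.3f}" for f in frags))
            fh.write("\t".join(fields) + "\n")


def read_rmaps(path) -> list[RestrictionMap]:
    maps: list[RestrictionMap] = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first not in (_HEADER_PLAIN, _HEADER_TRUTH):
            raise ValueError(f"{path}: not an Rmap file (bad header {first!r})")
        truth = first == _HEADER_TRUTH
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            want = 6 if truth else 3
            if len(fields) != want:
                raise ValueError(f"{path}:{lineno}: expected {want} columns, got {len(fields)}")
            frags = [float(x) for x in fields[-1].split()]
            if not frags or any(f <= 0 for f in frags):
                raise ValueError(f"{path}:{lineno}: non-positive fragment")
            total = float(fields[1])
            if abs(total - sum(frags)) > 0.0015 * len(frags):
                raise ValueError(f"{path}:{lineno}: total does not match fragment sum")
            meta = {}
            if truth:
                meta = {
                    "origin": fields[2],
                    "start_kb": float(fields[3]),
                    "strand": fields[4],
                }
            maps.append(RestrictionMap.from_fragments(fields[0], frags, meta))
    return maps


def iter_fragment_pool(maps: Iterable[RestrictionMap]) -> Iterator[float]:
    for m in maps:
        yield from m.fragments
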