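"""Synthetic genomes with controlled restriction-site density.

A uniform random sequence has a fixed expected site spacing (4^6 ≈ 4.1 kb
for a 6-cutter), which is denser than a real avian genome digested with a
well-chosen enzyme (~10 kb average fragments).  The generator therefore
builds sequence with *no* recognition sites and implants sites at
exponentially distributed spacings with a configurable mean, giving full
control over the true map.  Scaffolds can carry N-gaps, and a chromosome
can be split into scaffolds separated by unassembled gaps with the true
order/orientation recorded — the substrate for truth-tracked end-to-end
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly_io import ScaffoldRecord
from .digest import RestrictionEnzyme, find_sites

__all__ = ["random_sequence_without_site", "make_chromosome", "split_chromosome", "TruthAssembly"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def random_sequence_without_site(rng: np.random.Generator, n: int, enzyme: RestrictionEnzyme) -> str:
    """Random ACGT sequence of length n free of the enzyme's recognition
    site (both strands)."""
    arr = _random_bases(rng, n)
    seq = arr.tobytes().decode()
    while True:
        sites = find_sites(seq, enzyme)
        if not sites:
            return seq
        for p in sites:
            mid = p + len(enzyme.recognition) // 2
            cur = seq[mid]
            repl = "A" if cur != "A" else "C"
            arr[mid] = ord(repl)
        seq = arr.tobytes().decode()


def make_chromosome(
    rng: np.random.Generator,
    length_bp: int,
    enzyme: RestrictionEnzyme,
    mean_frag_kb: float = 10.0,
    chrom_id: str = "chr1",
) -> ScaffoldRecord:
    """A chromosome whose restriction sites sit at exponentially spaced
    positions with mean ``mean_frag_kb``; no accidental sites elsewhere."""
    rec_len = len(enzyme.recognition)
    mean_bp = mean_frag_kb * 1000.0
    positions: list[int] = []
    pos = 0.0
    while True:
        pos += max(rec_len + 2, rng.exponential(mean_bp))
        if pos >= length_bp - rec_len - 1:
            break
        positions.append(int(pos))
    chunks: list[str] = []
    prev_end = 0
    for p in positions:
        chunks.append(random_sequence_without_site(rng, p - prev_end, enzyme))
        chunks.append(enzyme.recognition)
        prev_end = p + rec_len
    chunks.append(random_sequence_without_site(rng, length_bp - prev_end, enzyme))
    seq = "".join(chunks)
    # junctions between chunks can create accidental sites; mutate a base of
    # each extra site outside every implanted interval until clean
    implanted = set(positions)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    covered = np.zeros(length_bp, dtype=bool)
    for p in positions:
        covered[p : p + rec_len] = True
    while True:
        extra = [p for p in find_sites(seq, enzyme) if p not in implanted]
        if not extra:
            break
        for p in extra:
            for off in range(rec_len):
                if not covered[p + off]:
                    cur = chr(arr[p + off])
                    arr[p + off] = ord("A" if cur != "A" else "C")
                    break
        seq = arr.tobytes().decode()
    return ScaffoldRecord(chrom_id, seq)


@dataclass
class TruthAssembly:
    """A scaffolded-down chromosome with its ground truth.

    ``adjacencies`` lists, in chromosomal order, tuples
    (left_scaffold_id, right_scaffold_id, gap_bp); ``orientations`` maps
    scaffold id to the strand ('+'/'-') on which the emitted scaffold
    sequence sits relative to the chromosome.
    """

    chromosome: ScaffoldRecord
    scaffolds: list[ScaffoldRecord]
    order: list[str]
    orientations: dict[str, str]
    adjacencies: list[tuple[str, str, int]]


def split_chromosome(
    rng: np.random.Generator,
    chromosome: ScaffoldRecord,
    n_scaffolds: int,
    min_gap_bp: int = 5_000,
    max_gap_bp: int = 50_000,
    flip_prob: float = 0.5,
    n_gap_runs: int = 2,
    n_gap_len_bp: int = 100,
) -> TruthAssembly:
    """Cut a chromosome into scaffolds separated by unassembled gaps.

    Breakpoints are evenly spaced with jitter; each inter-scaffold gap
    drops ``min_gap_bp``..``max_gap_bp`` bases of real sequence (what the
    short-read assembly failed to reconstruct).  Each scaffold is
    independently reverse-complemented with probability ``flip_prob`` and
    may carry a few internal N runs (overwriting sequence, emulating
    sized assembly gaps).
    """
    L = chromosome.length
    if n_scaffolds < 2:
        raise ValueError("need at least 2 scaffolds")
    gaps = rng.integers(min_gap_bp, max_gap_bp + 1, n_scaffolds - 1)
    approx = L // n_scaffolds
    breaks = [0]
    for k in range(1, n_scaffolds):
        jitter = int(rng.integers(-approx // 4, approx // 4 + 1))
        breaks.append(min(L - 1, max(breaks[-1] + 1, k * approx + jitter)))
    breaks.append(L)
    scaffolds: list[ScaffoldRecord] = []
    order: list[str] = []
    orientations: dict[str, str] = {}
    adjacencies: list[tuple[str, str, int]] = []
    prev_id = None
    for k in range(n_scaffolds):
        g_prev = int(gaps[k - 1]) if k > 0 else 0
        g_next = int(gaps[k]) if k < n_scaffolds - 1 else 0
        lo = breaks[k] + (g_prev - g_prev // 2)
        hi = breaks[k + 1] - g_next // 2
        seq = chromosome.sequence[lo:hi]
        sid = f"scaf{k + 1:02d}"
        if n_gap_runs and len(seq) > 10 * n_gap_len_bp:
            chars = list(seq)
            for _ in range(n_gap_runs):
                p = int(rng.integers(n_gap_len_bp, len(seq) - 2 * n_gap_len_bp))
                chars[p : p + n_gap_len_bp] = "N" * n_gap_len_bp
            seq = "".join(chars)
        strand = "-" if rng.random() < flip_prob else "+"
        rec = ScaffoldRecord(sid, seq)
        if strand == "-":
            rec = rec.reverse_complement()
        scaffolds.append(rec)
        order.append(sid)
        orientations[sid] = strand
        if prev_id is not None:
            adjacencies.append((prev_id, sid, int(gaps[k - 1])))
        prev_id = sid
    return TruthAssembly(
        chromosome=chromosome,
        scaffolds=scaffolds,
        order=order,
        orientations=orientations,
        adjacencies=adjacencies,
    )
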