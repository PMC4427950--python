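"""Simulation of single-molecule restriction maps (SMRMs).

An optical-mapping run shears genomic DNA into long molecules, stretches
them, digests them in place and images the fragments.  Relative to the true
restriction map of the sampled locus, the observed molecule map suffers

* **missed cuts** — partial digestion leaves a true site uncut (Bernoulli,
  observation probability ``p_digest``);
* **false cuts** — random breakage and imaging artifacts add spurious cuts
  (Poisson along the molecule at ``false_cut_rate`` per kb);
* **sizing error** — each fragment length is measured with multiplicative
  Gaussian noise of coefficient ``sizing_cv``;
* **desorption** — fragments below ``detect_min_kb`` are not resolved and
  fuse with their neighbour.

Molecule lengths are drawn from a lognormal distribution (strictly
positive, right-skewed, matching the long upper tail of real mapping runs)
truncated below at the instrument's minimum reported size; molecules are
placed uniformly on the reference, either strand.  Generation stops once
the retained (≥ ``min_keep_kb``) molecules reach the configured coverage of
the genome.  Every simulated molecule carries its true origin, start and
strand in ``meta`` for downstream truth-tracked evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .digest import RestrictionMap

__all__ = [
    "NoiseModel",
    "SimConfig",
    "MoleculeSetStats",
    "MoleculeSummary",
    "apply_noise",
    "simulate_molecules",
    "summarize_molecules",
    "format_molecule_report",
]

SIZING_FLOOR_KB = 0.1  # no measured fragment shrinks below this


@dataclass(frozen=True)
class NoiseModel:
    """Observation model for one molecule map.

    Defaults are representative of high-density optical mapping cards:
    ~80% digestion efficiency, one false cut per 200 kb, 5% sizing CV and
    a 1.2 kb detection limit.
    """

    p_digest: float = 0.8
    false_cut_rate: float = 0.005
    sizing_cv: float = 0.05
    detect_min_kb: float = 1.2

    def __post_init__(self) -> None:
        if not 0 < self.p_digest <= 1:
            raise ValueError("p_digest must be in (0, 1]")
        if self.false_cut_rate < 0 or self.sizing_cv < 0 or self.detect_min_kb < 0:
            raise ValueError("noise rates must be non-negative")

    @classmethod
    def none(cls) -> "NoiseModel":
        """Identity observation: the molecule map equals the true sub-map."""
        return cls(p_digest=1.0, false_cut_rate=0.0, sizing_cv=0.0, detect_min_kb=0.0)


@dataclass(frozen=True)
class SimConfig:
    """Molecule-sampling configuration.

    ``mean_len_kb``/``len_sd_kb`` parameterize the lognormal length
    distribution before truncation at ``min_report_kb`` (the smallest
    molecule the instrument records).  ``min_keep_kb`` is the retention
    filter for assembly use; ``coverage`` is the target total retained
    molecule length as a multiple of the genome length.  The seed is
    mandatory — there is no silent nondeterminism.
    """

    seed: int
    mean_len_kb: float = 286.96
    len_sd_kb: float = 120.0
    min_report_kb: float = 150.0
    min_keep_kb: float = 250.0
    coverage: float = 500.0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not self.min_keep_kb >= self.min_report_kb >= 0:
            raise ValueError("need min_keep_kb >= min_report_kb >= 0")
        if self.mean_len_kb <= 0 or self.len_sd_kb < 0:
            raise ValueError("length parameters must be positive")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def apply_noise(true_map: RestrictionMap, noise: NoiseModel, rng: np.random.Generator) -> RestrictionMap:
    """Pass one true molecule map through the observation model.

    Order of effects: interior cuts dropped (Bernoulli), false cuts added
    (Poisson), fragment sizing error applied (multiplicative Gaussian with
    a 0.1 kb floor), sub-detection fragments merged into the following
    fragment (the last merges leftward).  Total length changes only through
    sizing error.
    """
    cuts = [c for c in true_map.cuts if rng.random() < noise.p_digest]
    n_false = rng.poisson(noise.false_cut_rate * true_map.total_length)
    if n_false:
        cuts.extend(rng.uniform(0.0, true_map.total_length, n_false).tolist())
        cuts = sorted(set(cuts))
    bounds = [0.0, *cuts, true_map.total_length]
    frags = [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]
    if noise.sizing_cv > 0:
        errs = rng.normal(0.0, noise.sizing_cv, len(frags))
        frags = [max(SIZING_FLOOR_KB, f * (1.0 + e)) for f, e in zip(frags, errs)]
    if noise.detect_min_kb > 0:
        merged: list[float] = []
        carry = 0.0
        for f in frags:
            if f + carry < noise.detect_min_kb:
                carry += f
            else:
                merged.append(f + carry)
                carry = 0.0
        if carry:
            if merged:
                merged[-1] += carry
            else:
                merged = [carry]
        frags = merged
    return RestrictionMap.from_fragments(true_map.source_id, frags, dict(true_map.meta))


def simulate_molecules(
    reference_maps: Sequence[RestrictionMap],
    config: SimConfig,
    noise: NoiseModel = NoiseModel(),
) -> list[RestrictionMap]:
    """Draw molecules from a reference until the retained subset reaches
    ``config.coverage`` times the genome length.

    The source map is chosen proportional to its length, the start
    uniformly, the strand uniformly; the true sub-map (terminal fragments
    truncated at the molecule ends) goes through :func:`apply_noise`.
    Molecules whose observed length falls below ``min_report_kb`` are
    discarded, mirroring the instrument's reporting threshold.
    """
    if not reference_maps:
        raise ValueError("no reference maps")
    lengths = np.array([m.total_length for m in reference_maps])
    if config.mean_len_kb > lengths.max():
        raise ValueError(
            f"mean molecule length {config.mean_len_kb} kb exceeds the longest "
            f"reference map ({lengths.max():.1f} kb); no molecule can be placed"
        )
    rng = np.random.default_rng(config.seed)
    weights = lengths / lengths.sum()
    mu, sigma = _lognormal_params(config.mean_len_kb, config.len_sd_kb)
    genome_kb = float(lengths.sum())
    target_kb = config.coverage * genome_kb
    retained_kb = 0.0
    molecules: list[RestrictionMap] = []
    serial = 0
    while retained_kb < target_kb:
        mol_len = float(rng.lognormal(mu, sigma))
        if mol_len < config.min_report_kb:
            continue
        idx = int(rng.choice(len(reference_maps), p=weights))
        ref = reference_maps[idx]
        if mol_len > ref.total_length:
            hosts = np.flatnonzero(lengths >= mol_len)
            if hosts.size == 0:
                mol_len = float(lengths.max())
                hosts = np.flatnonzero(lengths >= mol_len)
            w = lengths[hosts] / lengths[hosts].sum()
            idx = int(hosts[rng.choice(hosts.size, p=w)])
            ref = reference_maps[idx]
        start = float(rng.uniform(0.0, ref.total_length - mol_len))
        strand = "+" if rng.random() < 0.5 else "-"
        serial += 1
        true_sub = ref.submap(start, start + mol_len, source_id=f"mol{serial:06d}")
        if strand == "-":
            true_sub = true_sub.reversed()
        true_sub.meta = {"origin": ref.source_id, "start_kb": start, "strand": strand}
        obs = apply_noise(true_sub, noise, rng)
        if obs.total_length < config.min_report_kb:
            continue
        molecules.append(obs)
        if obs.total_length >= config.min_keep_kb:
            retained_kb += obs.total_length
    return molecules


@dataclass(frozen=True)
class MoleculeSetStats:
    total_size_mb: float
    n_molecules: int
    avg_molecule_kb: float
    min_molecule_kb: float
    avg_fragment_kb: float


def _set_stats(molecules: Sequence[RestrictionMap]) -> MoleculeSetStats:
    total_kb = sum(m.total_length for m in molecules)
    n_frags = sum(m.n_fragments for m in molecules)
    return MoleculeSetStats(
        total_size_mb=total_kb / 1000.0,
        n_molecules=len(molecules),
        avg_molecule_kb=total_kb / len(molecules),
        min_molecule_kb=min(m.total_length for m in molecules),
        avg_fragment_kb=total_kb / n_frags,
    )


@dataclass(frozen=True)
class MoleculeSummary:
    """Five summary statistics for all molecules and for the retained
    (≥ min_keep_kb) subset."""

    min_keep_kb: float
    all: MoleculeSetStats
    kept: MoleculeSetStats | None


def summarize_molecules(molecules: Sequence[RestrictionMap], min_keep_kb: float = 250.0) -> MoleculeSummary:
    if not molecules:
        raise ValueError("no molecules to summarize")
    kept = [m for m in molecules if m.total_length >= min_keep_kb]
    return MoleculeSummary(
        min_keep_kb=min_keep_kb,
        all=_set_stats(molecules),
        kept=_set_stats(kept) if kept else None,
    )


def format_molecule_report(summary: MoleculeSummary) -> str:
    rows = [
        ("Total size", "total_size_mb", "{:,.2f} Mb"),
        ("Number of molecules", "n_molecules", "{:,d}"),
        ("Average molecule size", "avg_molecule_kb", "{:.2f} kb"),
        ("Minimum molecule size", "min_molecule_kb", "{:.2f} kb"),
        ("Average fragment size", "avg_fragment_kb", "{:.3f} kb"),
    ]
    header = f"{'':28s}{'All':>18s}{f'Maps of >{summary.min_keep_kb:.0f} kb':>20s}"
    lines = [header]
    for label, attr, fmt in rows:
        left = fmt.format(getattr(summary.all, attr))
        right = fmt.format(getattr(summary.kept, attr)) if summary.kept else "-"
        lines.append(f"{label:28s}{left:>18s}{right:>20s}")
    return "\n".join(lines)
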