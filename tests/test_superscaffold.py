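"""Join detection, conflict resolution, super-scaffold assembly, AGP/FASTA
emission."""

import numpy as np
import pytest

from omscaffold.align import ScoringParams
from omscaffold.assembly_io import ScaffoldRecord
from omscaffold.digest import digest_record, reverse_complement
from omscaffold.extend import iterate_extension
from omscaffold.simulate import NoiseModel, SimConfig, simulate_molecules
from omscaffold.superscaffold import (
    JoinCandidate,
    SuperScaffold,
    build_superscaffolds,
    emit_sequences,
    find_joins,
    read_join_candidates,
    resolve_joins,
    write_join_candidates,
)
from omscaffold.synthetic import make_chromosome

from .oracles import greedy_feasible_subset_oracle


def jc(a, ea, b, eb, orient="same", score=10.0, gap=1.0):
    return JoinCandidate(a, ea, b, eb, orient, score, gap)


@pytest.fixture(scope="module")
def two_scaffold_world(kpni):
    """A chromosome cut into two scaffolds 40 kb apart, with zero-noise
    molecules: extensions must bridge the gap."""
    rng = np.random.default_rng(555)
    chrom = make_chromosome(rng, 1_200_000, kpni, mean_frag_kb=10.0)
    ref = digest_record(chrom, kpni)
    a = ScaffoldRecord("sA", chrom.sequence[:580_000])
    b = ScaffoldRecord("sB", chrom.sequence[620_000:])
    mols = simulate_molecules([ref], SimConfig(seed=8, coverage=25), NoiseModel.none())
    return chrom, ref, a, b, mols


class TestFindJoins:
    def test_gap_and_orientation_recovered(self, two_scaffold_world, kpni):
        _chrom, _ref, a, b, mols = two_scaffold_world
        exts = [iterate_extension(digest_record(r, kpni), mols, min_keep_kb=150.0) for r in (a, b)]
        cands = find_joins(exts)
        assert len(cands) == 1
        c = cands[0]
        assert (c.scaf_a, c.end_a, c.scaf_b, c.end_b) == ("sA", "right", "sB", "left")
        assert c.relative_orientation == "same"
        assert c.gap_kb == pytest.approx(40.0, abs=1.5)

    def test_flipped_scaffold_detected(self, two_scaffold_world, kpni):
        _chrom, _ref, a, b, mols = two_scaffold_world
        b_rc = b.reverse_complement()
        exts = [
            iterate_extension(digest_record(r, kpni), mols, min_keep_kb=150.0) for r in (a, b_rc)
        ]
        cands = find_joins(exts)
        assert len(cands) == 1
        c = cands[0]
        assert c.relative_orientation == "flipped"
        assert {c.end_a, c.end_b} == {"right"}
        assert c.gap_kb == pytest.approx(40.0, abs=1.5)

    def test_unrelated_scaffolds_give_no_candidate(self, kpni):
        rng = np.random.default_rng(77)
        chroms = [make_chromosome(rng, 700_000, kpni, chrom_id=f"c{i}") for i in range(2)]
        refs = [digest_record(c, kpni) for c in chroms]
        mols = simulate_molecules([refs[0]], SimConfig(seed=3, coverage=25))
        exts = [iterate_extension(r, mols) for r in refs]
        assert find_joins(exts) == []


class TestResolveJoins:
    def test_end_exclusivity(self):
        cands = [
            jc("A", "right", "B", "left", score=20),
            jc("A", "right", "C", "left", score=12),
        ]
        accepted = resolve_joins(cands)
        assert len(accepted) == 1
        assert accepted[0].scaf_b == "B"

    def test_cycle_rejected(self):
        cands = [
            jc("A", "right", "B", "left", score=20),
            jc("B", "right", "C", "left", score=19),
            jc("C", "right", "A", "left", score=18),
        ]
        accepted = resolve_joins(cands)
        assert len(accepted) == 2
        assert all(c.scaf_a != "C" or c.scaf_b != "A" for c in accepted)
        assert not any({c.scaf_a, c.scaf_b} == {"A", "C"} for c in accepted)

    def test_matches_subset_search_oracle(self):
        rng = np.random.default_rng(10)
        names = list("ABCDEFGH")
        for _ in range(25):
            cands = []
            n = rng.integers(3, 11)
            for _k in range(n):
                a, b = rng.choice(len(names), 2, replace=False)
                cands.append(
                    jc(
                        names[a],
                        rng.choice(["left", "right"]),
                        names[b],
                        rng.choice(["left", "right"]),
                        score=float(rng.integers(5, 30)),
                        gap=float(rng.uniform(-5, 40)),
                    )
                )
            assert resolve_joins(cands) == greedy_feasible_subset_oracle(cands)


class TestBuildSuperscaffolds:
    def test_chain_assembly(self):
        joins = [
            jc("A", "right", "B", "left"),
            jc("B", "right", "C", "left"),
        ]
        ss = build_superscaffolds(["A", "B", "C"], joins)
        assert len(ss) == 1
        assert [(m[0], m[1]) for m in ss[0].members] == [("A", "+"), ("B", "+"), ("C", "+")]

    def test_flipped_member(self):
        ss = build_superscaffolds(["A", "B"], [jc("A", "right", "B", "right", "flipped")])
        assert [(m[0], m[1]) for m in ss[0].members] == [("A", "+"), ("B", "-")]

    def test_singletons_preserved(self):
        ss = build_superscaffolds(["A", "B", "C"], [jc("A", "right", "C", "left")])
        ids = sorted(m[0] for s in ss for m in s.members)
        assert ids == ["A", "B", "C"]
        assert sum(len(s.members) == 1 for s in ss) == 1

    def test_contradictory_orientation_raises(self):
        joins = [
            jc("A", "right", "B", "left"),  # B '+'
            jc("B", "left", "C", "left"),  # needs B's left again -> contradiction
        ]
        with pytest.raises(ValueError):
            build_superscaffolds(["A", "B", "C"], joins)

    def test_path_read_from_lexicographically_smaller_terminus(self):
        ss = build_superscaffolds(["B", "A"], [jc("A", "right", "B", "left")])
        assert ss[0].members[0][0] == "A"


class TestEmit:
    def _two(self):
        rng = np.random.default_rng(4)
        a = ScaffoldRecord("A", "".join(rng.choice(list("ACGT"), 1000)))
        b = ScaffoldRecord("B", "".join(rng.choice(list("ACGT"), 2000)))
        return a, b

    def test_constant_gap_of_600(self):
        a, b = self._two()
        ss = [SuperScaffold("s1", [("A", "+", 5.0), ("B", "+", None)])]
        recs, agp = emit_sequences(ss, [a, b], gap_mode="constant")
        seq = recs[0].sequence
        assert len(seq) == 3600
        assert seq == a.sequence + "N" * 600 + b.sequence

    def test_singleton_identity(self):
        a, b = self._two()
        ss = [SuperScaffold("s1", [("A", "+", None)]), SuperScaffold("s2", [("B", "+", None)])]
        recs, _agp = emit_sequences(ss, [a, b])
        assert recs[0].sequence == a.sequence

    def test_estimated_negative_gap_floored_and_reverse_complement(self):
        a, b = self._two()
        ss = [SuperScaffold("s1", [("A", "+", -5.0), ("B", "-", None)])]
        recs, agp = emit_sequences(ss, [a, b], gap_mode="estimated")
        seq = recs[0].sequence
        assert seq == a.sequence + "N" * 100 + reverse_complement(b.sequence)
        w_lines = [l.split("\t") for l in agp if "\tW\t" in l]
        assert w_lines[1][8] == "-"

    def test_agp_reconstructs_fasta(self):
        a, b = self._two()
        ss = [SuperScaffold("s1", [("A", "-", 2.0), ("B", "+", None)])]
        recs, agp = emit_sequences(ss, [a, b], gap_mode="estimated")
        by_id = {r.id: r for r in (a, b)}
        rebuilt = {}
        for line in agp:
            if line.startswith("#"):
                continue
            f = line.split("\t")
            obj = rebuilt.setdefault(f[0], [])
            if f[4] == "W":
                comp = by_id[f[5]].sequence[int(f[6]) - 1 : int(f[7])]
                if f[8] == "-":
                    comp = reverse_complement(comp)
                obj.append(comp)
            else:
                obj.append("N" * int(f[5]))
            assert int(f[2]) - int(f[1]) + 1 == len(obj[-1])
        assert "".join(rebuilt["s1"]) == recs[0].sequence

    def test_base_conservation_all_gap_modes(self):
        a, b = self._two()
        for mode in ("constant", "estimated"):
            ss = [SuperScaffold("s1", [("A", "-", 3.0), ("B", "+", None)])]
            recs, _ = emit_sequences(ss, [a, b], gap_mode=mode)
            non_n = sum(len(r.sequence) - r.sequence.count("N") for r in recs)
            assert non_n == a.length + b.length

    def test_unknown_scaffold_and_duplicates_rejected(self):
        a, b = self._two()
        with pytest.raises(KeyError):
            emit_sequences([SuperScaffold("s1", [("Z", "+", None)])], [a, b])
        dup = [
            SuperScaffold("s1", [("A", "+", None)]),
            SuperScaffold("s2", [("A", "+", None)]),
        ]
        with pytest.raises(ValueError):
            emit_sequences(dup, [a, b])

    def test_join_candidate_tsv_round_trip(self, tmp_path):
        cands = [jc("A", "right", "B", "left", score=12.5, gap=-3.2)]
        p = tmp_path / "joins.tsv"
        write_join_candidates(cands, p)
        back = read_join_candidates(p)
        assert back == cands


class TestN50Improvement:
    def test_joining_improves_n50(self):
        """Whenever at least one join is accepted, super-scaffold N50 is at
        least the input N50 (the headline improvement direction)."""
        from omscaffold.assembly_io import compute_assembly_stats

        rng = np.random.default_rng(12)
        recs = [
            ScaffoldRecord(f"s{i}", "".join(rng.choice(list("ACGT"), int(n))))
            for i, n in enumerate(rng.integers(5_000, 50_000, 6))
        ]
        joins = [jc("s0", "right", "s3", "left", score=15.0, gap=1.0)]
        ss = build_superscaffolds([r.id for r in recs], joins)
        out, _ = emit_sequences(ss, recs, gap_mode="constant")
        assert (
            compute_assembly_stats(out).n50 >= compute_assembly_stats(recs).n50
        )
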