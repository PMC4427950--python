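"""Recognition-site scanning, in silico digestion, enzyme evaluation,
Rmap I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omscaffold.assembly_io import ScaffoldRecord
from omscaffold.digest import (
    BUILTIN_ENZYMES,
    RestrictionEnzyme,
    RestrictionMap,
    digest_record,
    evaluate_enzyme,
    find_sites,
    get_enzyme,
    read_rmaps,
    reverse_complement,
    write_rmaps,
)

from .oracles import brute_force_sites

KPNI = get_enzyme("KpnI")

random_dna = st.text(alphabet="ACGT", min_size=0, max_size=400)


class TestEnzymeTable:
    def test_eight_builtins_all_palindromic(self):
        assert len(BUILTIN_ENZYMES) == 8
        assert all(e.is_palindromic for e in BUILTIN_ENZYMES.values())

    @pytest.mark.parametrize(
        "name,recognition,offset",
        [("KpnI", "GGTACC", 5), ("AflII", "CTTAAG", 1), ("BglII", "AGATCT", 1)],
    )
    def test_recognition_and_cut_offset(self, name, recognition, offset):
        e = get_enzyme(name)
        assert (e.recognition, e.cut_offset) == (recognition, offset)

    def test_unknown_enzyme(self):
        with pytest.raises(KeyError, match="built-ins"):
            get_enzyme("EcoRI")

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            RestrictionEnzyme("BstXI", "CCANNNNNNTGG", 8)


class TestFindSites:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GGTACCAAGGTACC", [0, 8]),
            ("AAAA", []),
            ("GGTANC", []),  # N never matches
            ("ggtacc", [0]),  # case-insensitive
        ],
    )
    def test_examples(self, seq, expected):
        assert find_sites(seq, KPNI) == expected

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(random_dna)
    def test_matches_substring_scan(self, seq):
        assert find_sites(seq, KPNI) == brute_force_sites(seq, "GGTACC")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(random_dna)
    def test_palindromic_mirror_on_reverse_complement(self, seq):
        n, k = len(seq), len(KPNI.recognition)
        fwd = find_sites(seq, KPNI)
        rev = find_sites(reverse_complement(seq), KPNI)
        assert sorted(n - k - p for p in fwd) == rev

    def test_non_palindromic_scans_both_strands(self):
        enz = RestrictionEnzyme("toy", "ACGTAC", 1)  # revcomp GTACGT differs
        seq = "ACGTACTTGTACGT"
        #      ^ forward site   ^ reverse-strand site at forward start 8
        assert find_sites(seq, enz) == [0, 8]

    def test_overlapping_occurrences_reported(self):
        enz = RestrictionEnzyme("pal", "ATAT", 1)
        assert find_sites("ATATAT", enz) == [0, 2]


class TestDigest:
    def test_worked_example(self):
        m = digest_record(ScaffoldRecord("s", "GGTACCAAGGTACC"), KPNI)
        assert m.cuts == pytest.approx((0.005, 0.013))
        assert m.fragments == pytest.approx((0.005, 0.008, 0.001))
        assert m.total_length == pytest.approx(0.014)

    def test_no_sites_single_fragment(self):
        m = digest_record(ScaffoldRecord("s", "A" * 50_000), KPNI)
        assert m.cuts == ()
        assert m.fragments == (50.0,)

    def test_n_gap_keeps_nominal_length(self):
        seq = "GGTACC" + "N" * 1000 + "GGTACC"
        m = digest_record(ScaffoldRecord("s", seq), KPNI)
        assert len(m.cuts) == 2
        assert sum(m.fragments) * 1000 == pytest.approx(len(seq))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_of_length(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 5000))
        m = digest_record(ScaffoldRecord("s", seq), KPNI)
        assert sum(m.fragments) * 1000 == pytest.approx(len(seq), abs=1e-6)


class TestEvaluate:
    def test_three_fragment_example(self):
        # one 30 kb scaffold digesting to fragments [6, 12, 12] kb
        seq = ["A"] * 30_000
        site = KPNI.recognition
        for cut_kb in (6, 18):
            start = cut_kb * 1000 - KPNI.cut_offset
            seq[start : start + 6] = site
        ev = evaluate_enzyme([ScaffoldRecord("s", "".join(seq))], KPNI)
        assert ev.usable_pct_5_20 == pytest.approx(100.0)
        assert ev.frags_gt_100kb == 0
        assert ev.avg_frag_kb == pytest.approx(10.0)
        assert ev.max_frag_kb == pytest.approx(12.0)

    def test_invariant_to_scaffold_order(self):
        rng = np.random.default_rng(11)
        recs = [
            ScaffoldRecord(f"s{i}", "".join(rng.choice(list("ACGT"), 20_000)))
            for i in range(4)
        ]
        a = evaluate_enzyme(recs, KPNI)
        b = evaluate_enzyme(list(reversed(recs)), KPNI)
        assert a == b

    def test_matches_pooled_fragment_multiset(self):
        rng = np.random.default_rng(5)
        recs = [
            ScaffoldRecord(f"s{i}", "".join(rng.choice(list("ACGT"), 30_000)))
            for i in range(3)
        ]
        frags = [f for r in recs for f in digest_record(r, KPNI).fragments]
        ev = evaluate_enzyme(recs, KPNI)
        total = sum(r.length for r in recs) / 1000
        assert ev.avg_frag_kb == pytest.approx(total / len(frags))
        assert ev.max_frag_kb == pytest.approx(max(frags))
        in_win = sum(1 for f in frags if 5 <= f <= 20)
        assert ev.usable_pct_5_20 == pytest.approx(100 * in_win / len(frags))

    def test_by_mass_variant(self):
        m = RestrictionMap.from_fragments
        rng = np.random.default_rng(6)
        recs = [ScaffoldRecord("s", "".join(rng.choice(list("ACGT"), 50_000)))]
        count = evaluate_enzyme(recs, KPNI, by="count")
        mass = evaluate_enzyme(recs, KPNI, by="mass")
        assert 0 <= mass.usable_pct_5_20 <= 100
        # non-window metrics are identical between the variants
        assert mass.avg_frag_kb == count.avg_frag_kb
        with pytest.raises(ValueError):
            evaluate_enzyme(recs, KPNI, by="median")

    def test_empty_assembly_rejected(self):
        with pytest.raises(ValueError):
            evaluate_enzyme([], KPNI)


class TestRestrictionMap:
    def test_invariants(self):
        m = RestrictionMap("s", 10.0, (2.0, 5.0))
        assert m.n_fragments == 3
        assert sum(m.fragments) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            RestrictionMap("s", 10.0, (5.0, 2.0))
        with pytest.raises(ValueError):
            RestrictionMap("s", 10.0, (10.0,))

    def test_reversed_involution(self):
        m = RestrictionMap("s", 10.0, (1.0, 2.5, 7.0))
        r = m.reversed()
        assert r.cuts == pytest.approx((3.0, 7.5, 9.0))
        assert r.reversed().cuts == pytest.approx(m.cuts)

    def test_submap_truncates_terminals(self):
        m = RestrictionMap("s", 100.0, (10.0, 40.0, 90.0))
        sub = m.submap(5.0, 50.0)
        assert sub.total_length == pytest.approx(45.0)
        assert sub.cuts == pytest.approx((5.0, 35.0))


class TestRmapIO:
    def test_round_trip(self, tmp_path):
        maps = [
            RestrictionMap.from_fragments("m1", [10.0, 20.5, 3.25]),
            RestrictionMap.from_fragments("m2", [250.0]),
        ]
        p = tmp_path / "maps.rmap"
        write_rmaps(maps, p)
        back = read_rmaps(p)
        assert [m.source_id for m in back] == ["m1", "m2"]
        for a, b in zip(maps, back):
            assert np.allclose(a.fragments, b.fragments, atol=1e-3)

    def test_truth_columns(self, tmp_path):
        m = RestrictionMap.from_fragments(
            "m1", [10.0, 20.0], {"origin": "chr1", "start_kb": 123.456, "strand": "-"}
        )
        p = tmp_path / "t.rmap"
        write_rmaps([m], p, truth=True)
        back = read_rmaps(p)[0]
        assert back.meta["origin"] == "chr1"
        assert back.meta["strand"] == "-"
        assert back.meta["start_kb"] == pytest.approx(123.456)

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "x.rmap"
        p.write_text("m1\t30.000\t10.000 20.000\n")
        with pytest.raises(ValueError, match="header"):
            read_rmaps(p)
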