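"""Pseudo-pair splitting, exact-match placement, geometry classification."""

import re

import numpy as np
import pytest

from locuscope import (
    KnownJunction,
    LocusIndex,
    SplitConfig,
    classify_placement,
    discover,
    locate_mate,
    matches_known,
    place_pair,
    reverse_complement,
    split_read,
)
from locuscope.junction_discovery import PairPlacement


CFG50 = SplitConfig(k=20, O=30)   # 50-nt read geometry
CFG76 = SplitConfig(k=20, O=50)   # 76-nt read geometry


class TestSplitRead:
    def test_50nt_read_mouse_geometry(self):
        seq = "A" * 50
        pair = split_read("r", seq, CFG50)
        assert (pair.mate1, pair.mate2) == (seq[:20], seq[30:50])

    def test_short_second_mate_rejected(self):
        assert split_read("r", "A" * 45, CFG50) is None  # mate2 = 15 nt < 19

    def test_76nt_read_human_geometry(self):
        seq = "C" * 76
        pair = split_read("r", seq, CFG76)
        assert pair.mate2 == seq[50:70]
        assert len(pair.mate2) == 20  # min(O+k, L) = 70

    def test_reject_is_counted_not_raised(self, locus_sim):
        report = discover([("tiny", "ACGT" * 10)], locus_sim.index, CFG76)
        assert report.rejected == 1 and report.total_reads == 1


class TestLocateMate:
    def test_planted_occurrence_found_once(self, locus_sim):
        seq = locus_sim.index.sequence
        mate = seq[1234:1254]
        hits = locate_mate(mate, locus_sim.index, CFG76)
        plus = [h for h in hits if h[1] == "+"]
        assert (1234, "+") in hits and len(plus) == 1

    def test_reverse_complement_hits_minus_strand(self, locus_sim):
        seq = locus_sim.index.sequence
        mate = reverse_complement(seq[800:820])
        hits = locate_mate(mate, locus_sim.index, CFG76)
        assert (800, "-") in hits

    def test_absent_mate_gives_no_hits(self, locus_sim):
        assert locate_mate("A" * 25, locus_sim.index, CFG76) == [] \
            or "A" * 25 in locus_sim.index.sequence

    def test_n_containing_mate_unplaced_in_exact_mode(self, locus_sim):
        mate = locus_sim.index.sequence[100:120][:-1] + "N"
        assert locate_mate(mate, locus_sim.index, SplitConfig()) == []

    def test_one_mismatch_mode_recovers_substituted_mate(self, locus_sim):
        seq = locus_sim.index.sequence
        mate = list(seq[400:420])
        mate[7] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mate[7]]
        mate = "".join(mate)
        cfg = SplitConfig(mismatch="one_mismatch")
        assert (400, "+") in locate_mate(mate, locus_sim.index, cfg)


def oracle_place(pair, index, cfg):
    """Independent brute-force placement: regex-enumerate every hit of each
    mate on both strands, form all same-strand combinations, and pick the
    minimum |d - O| (ties: smallest p1) by exhaustive sort."""
    def hits(mate):
        out = []
        for strand, query in (("+", mate), ("-", reverse_complement(mate))):
            if "N" in query:
                continue
            for m in re.finditer(f"(?={re.escape(query)})", index.sequence):
                pos = m.start()
                t = pos if strand == "+" else len(index.sequence) - pos - len(mate)
                out.append((t, strand))
        return out

    combos = [(t1, t2, s1)
              for t1, s1 in hits(pair.mate1)
              for t2, s2 in hits(pair.mate2) if s1 == s2]
    if not combos or len(combos) > cfg.max_placements:
        return None
    best = sorted(combos, key=lambda c: (abs((c[1] - c[0]) - pair.O), c[0]))[0]
    return best


class TestPlacePair:
    def test_contiguous_read_places_with_d_equal_O(self, locus_sim):
        seq = locus_sim.index.sequence
        pair = split_read("r", seq[700:776], CFG76)
        pl = place_pair(pair, locus_sim.index, CFG76)
        assert (pl.p1, pl.d, pl.strand) == (700, 50, "+")

    def test_opposite_strand_mates_unplaced(self):
        # window built so mate1 exists only forward, mate2 only as revcomp;
        # both chosen non-palindromic so the strands stay distinct
        m1, m2 = "AAAAACCCCCAAAAACCCCC", "AAACCCAAACCCAAACCCAA"
        window = m1 + "TTTT" + reverse_complement(m2) + "ACAG" * 10
        index = LocusIndex(sequence=window)
        pair = split_read("r", m1 + "TGTGATGTGA" * 3 + m2 + "ACGTAC", SplitConfig())
        assert pair is not None
        assert place_pair(pair, index, SplitConfig()) is None

    def test_ambiguous_hits_resolve_to_contiguous_combination(self, rng):
        """With repeated mates, the combination closest to d == O wins."""
        core = "".join(rng.choice(list("ACGT"), 400))
        m1, m2 = core[100:120], core[150:170]
        window = core + core[90:180]  # duplicate the neighbourhood -> 2 hits each
        index = LocusIndex(sequence=window)
        pair = split_read("r", core[100:176], SplitConfig())
        pl = place_pair(pair, index, SplitConfig())
        oracle = oracle_place(pair, index, SplitConfig())
        assert pl is not None and oracle is not None
        assert (pl.p1, pl.p2, pl.strand) == oracle
        assert pl.d == 50

    def test_matches_exhaustive_oracle_on_random_reads(self, locus_sim):
        rng = np.random.default_rng(5)
        cfg = SplitConfig()
        seq = locus_sim.index.sequence
        for _ in range(300):
            start = int(rng.integers(0, len(seq) - 76))
            read = seq[start:start + 76]
            if rng.random() < 0.5:
                read = reverse_complement(read)
            pair = split_read("r", read, cfg)
            pl = place_pair(pair, locus_sim.index, cfg)
            oracle = oracle_place(pair, locus_sim.index, cfg)
            got = None if pl is None else (pl.p1, pl.p2, pl.strand)
            assert got == oracle


class TestClassifyPlacement:
    def test_contiguous(self, locus_sim):
        call = classify_placement(PairPlacement(1000, 1050, "+"), locus_sim.index, CFG76)
        assert (call.cls, call.relation) == ("contiguous", "internal")

    def test_forward_splice_span_from_construction(self, locus_sim):
        """Read built across a planted 650-nt intron (donor 3350 -> acceptor 4000)."""
        seq = locus_sim.index.sequence
        b = 30
        read = seq[3350 - b:3350] + seq[4000:4000 + 76 - b]
        pair = split_read("r", read, CFG76)
        pl = place_pair(pair, locus_sim.index, CFG76)
        call = classify_placement(pl, locus_sim.index, CFG76)
        assert call.cls == "forward_splice"
        assert call.intron_span == 650
        assert call.relation == "downstream_of_donor"

    def test_back_splice_spans_circle_junction(self, locus_sim):
        seq = locus_sim.index.sequence
        b = 40
        read = seq[3350 - b:3350] + seq[2000:2000 + 76 - b]
        pair = split_read("r", read, CFG76)
        pl = place_pair(pair, locus_sim.index, CFG76)
        call = classify_placement(pl, locus_sim.index, CFG76)
        assert call.cls == "back_splice"
        assert call.relation == "spans_circle_junction"
        assert call.d - CFG76.O == 2000 - 3350  # acceptor - donor

    def test_antisense_placement_flagged(self, locus_sim):
        call = classify_placement(PairPlacement(1000, 1050, "-"), locus_sim.index, CFG76)
        assert call.cls == "internal_other" and call.antisense

    def test_upstream_cryptic_donor_into_focal_acceptor(self, locus_sim):
        seq = locus_sim.index.sequence
        b = 25
        read = seq[1000 - b:1000] + seq[2000:2000 + 76 - b]
        pair = split_read("r", read, CFG76)
        call = classify_placement(place_pair(pair, locus_sim.index, CFG76),
                                  locus_sim.index, CFG76)
        assert (call.cls, call.relation) == ("forward_splice", "upstream_of_acceptor")


class TestMinusStrandLocus:
    """Geometry must be orientation-normalized for a - strand target."""

    def make_index(self):
        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list("ACGT"), 4000))
        # transcript runs right-to-left; focal exon window coords [1000, 2300)
        return LocusIndex(sequence=seq, target_strand="-",
                          exon_start=1000, exon_end=2300)

    def test_contiguous_round_trip_on_minus_strand(self):
        index = self.make_index()
        cfg = SplitConfig()
        transcript = reverse_complement(index.sequence)
        for start in (100, 1500, 3000):
            read = transcript[start:start + 76]
            pair = split_read("r", read, cfg)
            pl = place_pair(pair, index, cfg)
            assert pl is not None and pl.strand == "-"
            assert pl.d == cfg.O
            call = classify_placement(pl, index, cfg)
            assert call.cls == "contiguous" and not call.antisense

    def test_circle_junction_on_minus_strand(self):
        index = self.make_index()
        cfg = SplitConfig()
        transcript = reverse_complement(index.sequence)
        # in transcript coordinates the exon is [4000-2300, 4000-1000) = [1700, 3000)
        acc_t, don_t = index.acceptor_t, index.donor_t
        b = 35
        read = transcript[don_t - b:don_t] + transcript[acc_t:acc_t + 76 - b]
        pair = split_read("r", read, cfg)
        pl = place_pair(pair, index, cfg)
        call = classify_placement(pl, index, cfg)
        assert call.cls == "back_splice"
        assert call.relation == "spans_circle_junction"


class TestDiscover:
    def test_all_contiguous_reads_give_zero_splice_evidence(self, locus_sim):
        rng = np.random.default_rng(9)
        seq = locus_sim.index.sequence
        reads = []
        for i in range(200):
            start = int(rng.integers(0, len(seq) - 76))
            reads.append((f"c{i}", seq[start:start + 76]))
        report = discover(reads, locus_sim.index, CFG76)
        assert report.counts["forward_splice"] == 0
        assert report.counts["back_splice"] == 0
        assert report.counts["contiguous"] == 200

    def test_known_circle_junction_explains_all_its_reads(self, locus_sim):
        seq = locus_sim.index.sequence
        circle = KnownJunction("circle", donor_t=3350, acceptor_t=2000, kind="back")
        reads = []
        for i, b in enumerate(range(20, 51)):
            reads.append((f"bs{i}", seq[3350 - b:3350] + seq[2000:2000 + 76 - b]))
        report = discover(reads, locus_sim.index, CFG76, known_junctions=[circle])
        assert report.explained == len(reads)
        assert report.novel == 0

    def test_withholding_the_circle_junction_rediscovers_it_as_novel(self, locus_sim):
        """Positive-control logic: drop the known circle junction from the
        annotation and the same reads come back as novel back-splices."""
        seq = locus_sim.index.sequence
        reads = [(f"bs{b}", seq[3350 - b:3350] + seq[2000:2000 + 76 - b])
                 for b in range(20, 51)]
        report = discover(reads, locus_sim.index, CFG76, known_junctions=[])
        assert report.novel == len(reads)
        assert report.counts["back_splice"] == len(reads)
        assert (report.calls["relation"] == "spans_circle_junction").all()

    def test_empty_stream_is_an_empty_report(self, locus_sim):
        report = discover([], locus_sim.index, CFG76)
        assert report.total_reads == 0 and report.calls.empty

    def test_report_is_deterministic(self, locus_sim):
        a = discover(locus_sim.reads[:300], locus_sim.index, CFG76, locus_sim.known_junctions)
        b = discover(locus_sim.reads[:300], locus_sim.index, CFG76, locus_sim.known_junctions)
        assert a.to_json() == b.to_json()
        assert a.calls.equals(b.calls)

    def test_simulated_truth_recovered_for_observable_breakpoints(self, locus_sim):
        report = discover(locus_sim.reads, locus_sim.index, CFG76,
                          locus_sim.known_junctions)
        merged = report.calls.merge(locus_sim.truth, on="read_id")
        observable = merged[merged["observable"]]
        assert len(observable) > 100
        assert (observable["class_x"] == observable["class_y"]).all()
        # every observable planted junction read is explained by its junction
        splice = observable[observable["class_y"] != "contiguous"]
        assert (splice["known_junction"] == splice["junction"]).all()


def test_matches_known_respects_tolerance(locus_sim):
    cfg = CFG76
    seq = locus_sim.index.sequence
    read = seq[3350 - 30:3350] + seq[4000:4000 + 46]
    call = classify_placement(place_pair(split_read("r", read, cfg), locus_sim.index, cfg),
                              locus_sim.index, cfg)
    assert matches_known(call, KnownJunction("j", 3350, 4000), cfg)
    assert matches_known(call, KnownJunction("j2", 3352, 4000), cfg)  # within +/-2
    assert not matches_known(call, KnownJunction("far", 3350, 4200), cfg)
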