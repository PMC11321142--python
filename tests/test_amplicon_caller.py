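"""Amplicon caller tests: boundary inference, usable-pair filtering, CIGAR
pattern extraction (against an alignment-reconstruction oracle), percentage
reporting and the Sanger classifier."""

import math

import numpy as np
import pytest

from cerealcas import amplicon_caller as ac
from cerealcas import fixtures
from cerealcas.amplicon_caller import (
    AlignedReadPair,
    IndelPattern,
    LocusSpec,
    WT_PATTERN,
    call_locus,
    extract_pattern,
    filter_usable,
    modal_starts,
    sanger_classify,
)


def make_pair(start1=0, start2=150, cigar1="150M", cigar2="150M", pid="p1",
              locus_id="chr6Hg0653951"):
    return AlignedReadPair(pid, locus_id, start1, start2, cigar1, cigar2)


# ---------------------------------------------------------------------------
# oracle: rebuild the gapped alignment rows from the CIGAR and diff them

def alignment_oracle(start, cigar, window):
    """Expand the alignment into explicit columns, then read indels off the
    gap runs — an independent route to the same events."""
    cols = []  # (ref_pos or None, query_consumed)
    ref = start
    import re

    for length, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        length = int(length)
        if op in "M=X":
            for _ in range(length):
                cols.append((ref, True))
                ref += 1
        elif op in "DN":
            for _ in range(length):
                cols.append((ref, False))
                ref += 1
        elif op == "I":
            for _ in range(length):
                cols.append((None, True))
        # S/H/P consume no reference and produce no columns
    events = []
    i = 0
    w0, w1 = window
    while i < len(cols):
        rp, q = cols[i]
        if rp is not None and not q:          # deletion run
            j = i
            while j < len(cols) and cols[j][0] is not None and not cols[j][1]:
                j += 1
            d0, dlen = cols[i][0], j - i
            if d0 < w1 and d0 + dlen > w0:
                events.append(("D", d0, dlen))
            i = j
        elif rp is None:                      # insertion run
            j = i
            while j < len(cols) and cols[j][0] is None:
                j += 1
            point = next((cols[k][0] for k in range(j, len(cols))
                          if cols[k][0] is not None), None)
            if point is not None and w0 <= point < w1:
                events.append(("I", point, j - i))
            i = j
        else:
            i += 1
    return tuple(sorted(events, key=lambda e: (e[1], e[0])))


class TestModalStarts:
    def test_clear_majority(self):
        pairs = [make_pair(100, 250, pid=f"a{i}") for i in range(10)]
        pairs += [make_pair(101, 250, pid=f"b{i}") for i in range(2)]
        assert modal_starts(pairs) == (100, 250)

    def test_tie_breaks_toward_smaller_coordinate(self):
        pairs = [make_pair(100, 250, pid=f"a{i}") for i in range(5)]
        pairs += [make_pair(99, 250, pid=f"b{i}") for i in range(5)]
        assert modal_starts(pairs) == (99, 250)

    def test_single_pair(self):
        assert modal_starts([make_pair(7, 90)]) == (7, 90)

    def test_orientation_agnostic(self):
        pairs = [make_pair(250, 100, pid=f"s{i}") for i in range(3)]
        assert modal_starts(pairs) == (100, 250)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            modal_starts([])


class TestFilterUsable:
    def test_counts(self):
        good = [make_pair(0, 150, pid=f"g{i}") for i in range(10)]
        bad = [make_pair(3, 150, pid=f"b{i}") for i in range(2)]
        assert len(filter_usable(good + bad, (0, 150))) == 10

    def test_identity_when_all_at_boundaries(self):
        pairs = [make_pair(pid=f"p{i}") for i in range(5)]
        assert filter_usable(pairs, (0, 150)) == pairs

    def test_upstream_deletion_shifting_start_excludes_pair(self):
        """A deletion before a mate's start moves its leftmost position, so
        the boundary filter drops the pair — a documented consequence of
        filtering on exact start positions."""
        shifted = make_pair(start2=153, cigar2="147M")
        assert filter_usable([shifted], (0, 150)) == []


class TestExtractPattern:
    LOCUS = LocusSpec("chr6Hg0653951", "A" * 300, (85, 115))

    def test_pure_match_is_wildtype(self):
        pattern, disc = extract_pattern(make_pair(), self.LOCUS)
        assert pattern == WT_PATTERN and not disc

    def test_deletion_at_cut_site(self):
        # 90 aligned bases precede the deletion, so it starts at ref 90
        pattern, disc = extract_pattern(
            make_pair(cigar1="90M7D60M"), self.LOCUS)
        assert pattern.events == (("D", 90, 7),)
        assert not disc

    def test_insertion_point_arithmetic(self):
        pattern, _ = extract_pattern(make_pair(cigar1="100M3I47M"), self.LOCUS)
        assert pattern.events == (("I", 100, 3),)

    def test_indel_outside_window_ignored(self):
        pattern, _ = extract_pattern(make_pair(cigar1="10M2D140M"), self.LOCUS)
        assert pattern == WT_PATTERN

    def test_discordant_mates_flagged_with_union(self):
        pair = make_pair(start1=0, start2=20, cigar1="60M5D90M",
                         cigar2="70M2I80M")
        pattern, disc = extract_pattern(pair, LocusSpec("x", "A" * 300, (50, 120)))
        assert disc
        assert pattern.events == (("D", 60, 5), ("I", 90, 2))

    def test_deletions_only_mode_drops_insertions(self):
        pattern, _ = extract_pattern(make_pair(cigar1="100M3I47M"), self.LOCUS,
                                     deletions_only=True)
        assert pattern == WT_PATTERN

    def test_malformed_cigar_names_pair(self):
        with pytest.raises(ValueError, match="p1"):
            extract_pattern(make_pair(cigar1="7Q"), self.LOCUS)

    def test_agrees_with_alignment_reconstruction_oracle(self, rng):
        """1,000 random CIGARs against the column-expansion oracle."""
        locus = LocusSpec("x", "A" * 400, (120, 180))
        for _ in range(1000):
            start = int(rng.integers(0, 60))
            parts, ref_left = [], 400 - start - 5
            n_ops = int(rng.integers(1, 5))
            parts.append(f"{int(rng.integers(20, 80))}M")
            for _ in range(n_ops):
                kind = rng.choice(["D", "I", "M"])
                length = int(rng.integers(1, 12))
                parts.append(f"{length}{kind}")
                if kind != "M":
                    # an M spacer keeps same-type ops from fusing, so the
                    # oracle's run-collapsing matches op-by-op extraction
                    parts.append(f"{int(rng.integers(5, 15))}M")
            parts.append(f"{int(rng.integers(20, 80))}M")
            cigar = "".join(parts)
            pair = make_pair(start1=start, start2=start, cigar1=cigar,
                             cigar2=cigar)
            pattern, _ = extract_pattern(pair, locus)
            span = ac._ref_span(start, cigar)
            expected = (alignment_oracle(start, cigar, locus.cut_window)
                        if span[0] < 180 and span[1] > 120 else ())
            assert pattern.events == expected, cigar


class TestCallLocus:
    def _simulate(self, locus, fractions, n=200, seed=5, err=0.0, off=0.0):
        patterns = tuple(
            (IndelPattern.deletion(95 + 3 * i, 4 + i), f)
            for i, f in enumerate(fractions)
        )
        profile = fixtures.EditProfile(
            patterns=patterns, wt_frequency=1.0 - sum(fractions),
            n_pairs=n, seed=seed, substitution_error_rate=err,
            off_boundary_fraction=off,
        )
        sam, truth = fixtures.simulate_edited_reads(locus, profile)
        pairs, _ = ac.load_sam_text(sam, [locus])
        return call_locus("s1", pairs[locus.locus_id], locus), truth

    def test_seventy_percent_mutant(self, locus):
        report, _ = self._simulate(locus, [0.7])
        assert report.usable_pairs == 200
        assert report.pct_mutant == pytest.approx(70.0)

    def test_all_wildtype(self, locus):
        report, _ = self._simulate(locus, [])
        assert report.pct_wt == 100.0 and report.pattern_counts == {}

    def test_three_pattern_mixture_fully_mutant(self, locus):
        report, _ = self._simulate(locus, [0.2, 0.3, 0.5])
        assert report.pct_mutant == pytest.approx(100.0)
        assert sorted(report.pattern_counts.values()) == [40, 60, 100]

    def test_substitution_errors_never_count(self, locus):
        """0.5% substitution noise with no indels gives exactly 0% mutant."""
        report, _ = self._simulate(locus, [], err=0.005)
        assert report.pct_mutant == 0.0

    def test_off_boundary_pairs_reduce_usable(self, locus):
        report, _ = self._simulate(locus, [], off=0.1)
        assert report.total_pairs == 200
        assert report.usable_pairs == 180

    def test_accounting_identities(self, locus, rng):
        for f in (0.0, 0.1, 0.5, 0.9, 1.0):
            for n in (50, 500):
                report, _ = self._simulate(locus, [f] if f else [], n=n,
                                           seed=int(rng.integers(1 << 30)))
                assert report.usable_pairs <= report.total_pairs
                assert report.wt_pairs <= report.usable_pairs
                assert (sum(report.pattern_counts.values()) + report.wt_pairs
                        == report.usable_pairs)
                if report.usable_pairs:
                    assert report.pct_wt + report.pct_mutant == pytest.approx(100.0)
                    se = 100 * math.sqrt(f * (1 - f) / n)
                    assert abs(report.pct_mutant - 100 * f) <= 3 * se + 1e-9

    def test_zero_usable_flagged_not_raised(self, locus):
        pairs = [make_pair(start1=3, start2=152, pid="a"),
                 make_pair(start1=5, start2=151, pid="b")]
        report = call_locus("s", pairs, locus)
        assert report.no_usable and math.isnan(report.pct_wt)

    def test_expected_starts_override(self, locus):
        fixed = LocusSpec(locus.locus_id, locus.reference, locus.cut_window,
                          expected_starts=(0, 150))
        report, _ = self._simulate(fixed, [0.5])
        assert report.boundaries == (0, 150)


class TestLoadAlignments:
    def test_pass_through_and_per_locus_counts(self, locus, tmp_path):
        prof = fixtures.EditProfile(patterns=(), wt_frequency=1.0, n_pairs=10,
                                    seed=3)
        sam, _ = fixtures.simulate_edited_reads(locus, prof)
        pairs, counters = ac.load_sam_text(sam, [locus],
                                           tmp_path=tmp_path / "a.sam")
        assert len(pairs[locus.locus_id]) == 10
        assert not counters

    def test_orphan_and_unknown_reference_counters(self, locus, tmp_path):
        prof = fixtures.EditProfile(patterns=(), wt_frequency=1.0, n_pairs=2,
                                    seed=3)
        sam, _ = fixtures.simulate_edited_reads(locus, prof)
        lines = sam.rstrip("\n").split("\n")
        lines.append("\t".join(["orphan", "99", locus.locus_id, "1", "60",
                                "150M", "=", "151", "300", "*", "*"]))
        pairs, counters = ac.load_sam_text("\n".join(lines) + "\n", [locus],
                                           tmp_path=tmp_path / "b.sam")
        assert counters["orphan_pairs"] == 1
        assert len(pairs[locus.locus_id]) == 2

    def test_two_locus_stream_grouped_by_reference(self, tmp_path):
        refs = [str(fixtures.make_reference(300, 0.5, s).seq) for s in (1, 2)]
        loci = [LocusSpec(f"locus{i}", r, (90, 120)) for i, r in enumerate(refs)]
        sams = []
        for i, l in enumerate(loci):
            prof = fixtures.EditProfile(patterns=(), wt_frequency=1.0,
                                        n_pairs=5 + i, seed=i)
            sams.append(fixtures.simulate_edited_reads(l, prof)[0])
        header = ("@HD\tVN:1.6\tSO:unsorted\n"
                  + "".join(f"@SQ\tSN:{l.locus_id}\tLN:300\n" for l in loci))
        body = "".join(
            "\n".join(line for line in s.split("\n") if line and not
                      line.startswith("@")) + "\n"
            for s in sams
        )
        pairs, _ = ac.load_sam_text(header + body, loci,
                                    tmp_path=tmp_path / "c.sam")
        assert [len(pairs[l.locus_id]) for l in loci] == [5, 6]


class TestSangerClassify:
    def test_identity_not_mutated(self, locus):
        mutated, pattern = sanger_classify(locus.reference, locus)
        assert not mutated and pattern == WT_PATTERN

    def test_five_bp_deletion_at_cut_site(self, locus):
        query = locus.reference[:98] + locus.reference[103:]
        mutated, pattern = sanger_classify(query, locus)
        assert mutated
        assert pattern.events == (("D", 98, 5),)

    def test_insertion_at_cut_site(self, locus):
        query = locus.reference[:100] + "TTTTTT" + locus.reference[100:]
        mutated, pattern = sanger_classify(query, locus)
        assert mutated and pattern.events[0][0] == "I"

    def test_substitutions_alone_do_not_flag(self, locus):
        ref = locus.reference
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        query = ref[:100] + swap[ref[100]] + ref[101:]
        mutated, _ = sanger_classify(query, locus)
        assert not mutated

    def test_gap_outside_window_not_mutated(self, locus):
        query = locus.reference[:250] + locus.reference[255:]
        mutated, _ = sanger_classify(query, locus)
        assert not mutated

    def test_short_query_rejected(self, locus):
        with pytest.raises(ValueError, match="50"):
            sanger_classify("ACGT" * 10, locus)


class TestIndelPattern:
    def test_key_round_trip(self):
        p = IndelPattern((("D", 97, 7), ("I", 104, 2)))
        assert p.key == "D:98:7;I:105:2"
        assert IndelPattern.from_key(p.key) == p
        assert IndelPattern.from_key("") == WT_PATTERN

    def test_events_sorted_and_validated(self):
        p = IndelPattern((("I", 50, 1), ("D", 10, 3)))
        assert [e[1] for e in p.events] == [10, 50]
        with pytest.raises(ValueError):
            IndelPattern((("X", 1, 1),))
        with pytest.raises(ValueError):
            IndelPattern((("D", 1, 0),))

    def test_report_tables(self, locus):
        prof = fixtures.EditProfile(
            patterns=((IndelPattern.deletion(97, 7), 0.5),),
            wt_frequency=0.5, n_pairs=20, seed=1)
        sam, _ = fixtures.simulate_edited_reads(locus, prof)
        pairs, _ = ac.load_sam_text(sam, [locus])
        rep = call_locus("s1", pairs[locus.locus_id], locus)
        table = ac.reports_to_table([rep])
        assert table.loc[0, "usable"] == 20
        spec = ac.spectrum_to_table([rep])
        assert spec.loc[0, "count"] == 10


def test_loci_from_fasta_and_tsv(tmp_path, locus):
    (tmp_path / "ref.fa").write_text(f">{locus.locus_id}\n{locus.reference}\n")
    (tmp_path / "loci.tsv").write_text(
        "locus_id\twindow_start\twindow_end\n"
        f"{locus.locus_id}\t85\t115\n")
    loaded = ac.load_loci_fasta_tsv(tmp_path / "ref.fa", tmp_path / "loci.tsv")
    assert loaded == [LocusSpec(locus.locus_id, locus.reference, (85, 115))]
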