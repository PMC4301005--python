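"""N-stretch detection, flanking primer design, small-contig placement."""

import numpy as np
import pytest

from rdnafinish.ambiguity import (
    design_n_flanking_primers,
    find_n_stretches,
    place_small_contigs,
)
from rdnafinish.iupac import revcomp
from rdnafinish.primers import Undesignable, UniquenessScope, simulate_pcr
from rdnafinish.seqio import Contig


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFindNStretches:
    def test_single_maximal_run(self):
        (s,) = find_n_stretches(Contig("c", "ACGTNNNNACGT"))
        assert (s.start, s.end, s.length) == (4, 8, 4)

    def test_below_minimum_ignored(self):
        assert find_n_stretches(Contig("c", "ACNNA"), min_length=3) == []

    def test_terminal_runs_detected(self):
        out = find_n_stretches(Contig("c", "NNNACGTNNN"))
        assert [(s.start, s.end) for s in out] == [(0, 3), (7, 10)]

    def test_partitions_every_n_base(self):
        rng = np.random.default_rng(30)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGTN"), size=200, p=[0.2, 0.2, 0.2, 0.2, 0.2]))
            contig = Contig("c", seq)
            stretches = find_n_stretches(contig, min_length=3)
            in_stretch = set()
            for s in stretches:
                assert set(seq[s.start : s.end]) == {"N"}
                # maximality
                assert s.start == 0 or seq[s.start - 1] != "N"
                assert s.end == len(seq) or seq[s.end] != "N"
                in_stretch.update(range(s.start, s.end))
            # every N outside a stretch belongs to a sub-minimum run
            for i, ch in enumerate(seq):
                if ch == "N" and i not in in_stretch:
                    run = seq[max(0, i - 2) : i + 3]
                    assert "NNN" not in run

    def test_planted_runs_recovered_exactly(self, cr1):
        _truth, draft = cr1
        got = {
            (s.contig_id, s.start, s.end)
            for c in draft.contigs
            for s in find_n_stretches(c)
        }
        want = {(s.contig, s.start, s.end) for s in draft.stretches}
        assert got == want
        lengths = [e - s for _, s, e in got]
        assert len(lengths) == 198 and min(lengths) >= 9 and max(lengths) <= 769


class TestFlankingPrimers:
    def test_product_spans_the_stretch(self):
        rng = np.random.default_rng(31)
        seq = _random_dna(rng, 1000) + "N" * 100 + _random_dna(rng, 3900)
        contig = Contig("c", seq)
        (stretch,) = find_n_stretches(contig)
        pair = design_n_flanking_primers(contig, stretch)
        assert not isinstance(pair, Undesignable)
        (amp,) = simulate_pcr(contig, pair.forward, pair.reverse)
        assert amp.start < 1000 and amp.end > 1100

    def test_no_upstream_room_is_undesignable(self):
        rng = np.random.default_rng(32)
        seq = _random_dna(rng, 10) + "N" * 50 + _random_dna(rng, 1000)
        contig = Contig("c", seq)
        (stretch,) = find_n_stretches(contig)
        res = design_n_flanking_primers(contig, stretch)
        assert isinstance(res, Undesignable)

    def test_repeat_flanks_fail_uniqueness(self):
        rng = np.random.default_rng(33)
        repeat = _random_dna(rng, 400)
        # the stretch is flanked by a sequence present twelve times in scope
        host = Contig("host", repeat + "N" * 60 + repeat)
        decoys = [Contig(f"d{i}", _random_dna(rng, 100) + repeat + _random_dna(rng, 100))
                  for i in range(11)]
        scope = UniquenessScope([host] + decoys)
        (stretch,) = find_n_stretches(host)
        res = design_n_flanking_primers(host, stretch, scope=scope)
        assert isinstance(res, Undesignable)
        assert "unique" in res.reason


class TestPlacement:
    def _setup(self, rng, orientation="+"):
        host_seq = _random_dna(rng, 2000) + "N" * 400 + _random_dna(rng, 2000)
        host = Contig("host", host_seq)
        novel = _random_dna(rng, 400)
        small_seq = host_seq[1700:2000] + novel + host_seq[2400:2700]
        if orientation == "-":
            small_seq = revcomp(small_seq)
        small = Contig("small", small_seq)
        return host, small, novel

    def test_exact_placement_replaces_ns(self):
        rng = np.random.default_rng(34)
        host, small, novel = self._setup(rng)
        stretches = find_n_stretches(host)
        matches, unplaced, updated = place_small_contigs([small], [host], stretches)
        assert len(matches) == 1 and matches[0].orientation == "+"
        merged = next(c for c in updated if c.id == "host")
        assert merged.length == host.length
        assert "N" not in merged.seq
        assert merged.seq[2000:2400] == novel
        # non-N host bases untouched
        assert merged.seq[:2000] == host.seq[:2000]
        assert merged.seq[2400:] == host.seq[2400:]

    def test_reverse_complement_placement(self):
        rng = np.random.default_rng(35)
        host, small, novel = self._setup(rng, orientation="-")
        stretches = find_n_stretches(host)
        matches, _, updated = place_small_contigs([small], [host], stretches)
        assert len(matches) == 1 and matches[0].orientation == "-"
        merged = next(c for c in updated if c.id == "host")
        assert merged.seq == host.seq[:2000] + novel + host.seq[2400:]

    def test_equally_good_stretches_reported_ambiguous(self):
        rng = np.random.default_rng(36)
        flank_l = _random_dna(rng, 300)
        flank_r = _random_dna(rng, 300)
        novel = _random_dna(rng, 200)
        mid = _random_dna(rng, 1000)
        host_seq = (
            _random_dna(rng, 500) + flank_l + "N" * 200 + flank_r + mid
            + flank_l + "N" * 200 + flank_r + _random_dna(rng, 500)
        )
        host = Contig("host", host_seq)
        small = Contig("small", flank_l + novel + flank_r)
        stretches = find_n_stretches(host)
        matches, unplaced, updated = place_small_contigs([small], [host], stretches)
        assert matches == []
        assert unplaced and "ambiguous" in unplaced[0].reason
        assert len(unplaced[0].candidates) == 2
        # the unplaced contig stays in the working set
        assert any(c.id == "small" for c in updated)

    def test_length_mismatch_beyond_tolerance_rejected(self):
        rng = np.random.default_rng(37)
        host_seq = _random_dna(rng, 1000) + "N" * 100 + _random_dna(rng, 1000)
        host = Contig("host", host_seq)
        # insert is 400 bp for a 100 bp stretch: outside the +-50% band
        small = Contig("small", host_seq[700:1000] + _random_dna(rng, 400) + host_seq[1100:1400])
        matches, unplaced, _ = place_small_contigs([small], [host], find_n_stretches(host))
        assert matches == [] and unplaced

    def test_planted_fixture_placements_recovered(self, cr1):
        _truth, draft = cr1
        mains = {n for n, _o in draft.order}
        hosts = [c for c in draft.contigs if c.id in mains]
        smalls = [c for c in draft.contigs if c.id in draft.small_contigs]
        stretches = [s for c in hosts for s in find_n_stretches(c)]
        matches, unplaced, updated = place_small_contigs(smalls, hosts, stretches)
        assert len(matches) == 10 and not unplaced
        assert len(updated) == len(hosts)  # 28 -> 18 working set
        want = {s.small_contig: (s.contig, s.start) for s in draft.stretches if s.placeable}
        for m in matches:
            assert want[m.small_id] == (m.host_id, m.stretch.start)
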