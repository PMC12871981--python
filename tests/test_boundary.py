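"""VRR-region start detection: dual-threshold, single-threshold, run-based."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from telotide.boundary import (
    detect_vrr_start,
    detect_vrr_start_consecutive,
    detect_vrr_start_single_threshold,
    evaluate_mae,
)
from telotide.motif_model import scan_motifs
from telotide.probe_demux import locate_capture_probe
from telotide.simulate import DEFAULT_PROBE, SimSpec, generate_read, _build_vrr

from conftest import make_read
from oracles import brute_first_run

PROBE = DEFAULT_PROBE


def _construct(scrubbed_fn, motifs, subtel=2000, vrr=1000, tel=2000, seed=1, rng=None):
    """Noise-free read [subtelomere][VRR][telomere][probe]; returns read, truth."""
    rng = rng or np.random.default_rng(seed)
    sub = scrubbed_fn(subtel, seed=seed)
    vrr_seq = _build_vrr(vrr, 0.9, motifs, rng, variant_fraction=0.6)
    seq = sub + vrr_seq + "GGTTAG" * (tel // 6) + PROBE
    read = make_read(seq, oriented=True, strand="G")
    probe_hit = locate_capture_probe(read, PROBE, motifs)
    return read, len(sub), probe_hit


class TestDualThreshold:
    def test_clean_construct_exact(self, motifs, scrubbed_fn):
        read, truth, probe_hit = _construct(scrubbed_fn, motifs)
        call = detect_vrr_start(read, motifs, probe_hit=probe_hit)
        assert call.vrr_start == truth
        assert call.algorithm == "dual_threshold"

    def test_short_dip_tolerated(self, motifs, scrubbed_fn):
        # a ~150 bp non-repeat gap inside the telomere gives only ~4 full
        # sub-5% windows: far below the 15-window rescue run, so the
        # candidate start survives
        read, truth, _ = _construct(scrubbed_fn, motifs, tel=3000)
        gap = scrubbed_fn(150, seed=2)
        at = truth + 1800
        seq = read.seq[:at] + gap + read.seq[at:]
        read2 = make_read(seq, oriented=True)
        probe_hit = locate_capture_probe(read2, PROBE, motifs)
        call = detect_vrr_start(read2, motifs, probe_hit=probe_hit)
        assert call.vrr_start == truth

    def test_long_collapse_rejects_and_retriggers(self, motifs, scrubbed_fn):
        # >= 15 consecutive sub-5% windows (a 400 bp artifact block)
        # invalidate the first candidate; the scan re-triggers afterwards
        read, truth, _ = _construct(scrubbed_fn, motifs, vrr=600, tel=3000)
        gap = scrubbed_fn(400, seed=3)
        at = truth + 900
        seq = read.seq[:at] + gap + read.seq[at:]
        read2 = make_read(seq, oriented=True)
        probe_hit = locate_capture_probe(read2, PROBE, motifs)
        call = detect_vrr_start(read2, motifs, probe_hit=probe_hit)
        assert call.vrr_start is not None
        # called start lies at the far edge of the collapsed block (junction
        # variants may begin a few bases inside it), far past the candidate
        assert call.vrr_start >= at + 390

    def test_island_then_subtelomere_recovers_true_start(self, motifs, scrubbed_fn, rng):
        # telomere-like island deep in the subtelomere triggers a candidate
        # that the long sub-5% run invalidates; the true start is recovered
        island = _build_vrr(250, 0.9, motifs, rng, 0.6)
        sub1, sub2 = scrubbed_fn(1200, seed=4), scrubbed_fn(1500, seed=5)
        vrr = _build_vrr(800, 0.9, motifs, rng, 0.6)
        seq = sub1 + island + sub2 + vrr + "GGTTAG" * 300 + PROBE
        truth = len(sub1) + len(island) + len(sub2)
        read = make_read(seq, oriented=True)
        probe_hit = locate_capture_probe(read, PROBE, motifs)
        call = detect_vrr_start(read, motifs, probe_hit=probe_hit)
        assert call.vrr_start == truth

    def test_read_shorter_than_window(self, motifs):
        call = detect_vrr_start(make_read("GGTTAG" * 10, oriented=True), motifs)
        assert call.vrr_start is None
        assert call.reason == "too_short"

    def test_determinism(self, motifs, scrubbed_fn):
        read, _, probe_hit = _construct(scrubbed_fn, motifs)
        a = detect_vrr_start(read, motifs, probe_hit=probe_hit)
        b = detect_vrr_start(read, motifs, probe_hit=probe_hit)
        assert (a.vrr_start, a.trigger_window_start) == (b.vrr_start, b.trigger_window_start)


class TestSingleThreshold:
    def test_clean_equivalence_with_dual(self, motifs, scrubbed_fn):
        read, truth, probe_hit = _construct(scrubbed_fn, motifs)
        single = detect_vrr_start_single_threshold(read, motifs, probe_hit=probe_hit)
        dual = detect_vrr_start(read, motifs, probe_hit=probe_hit)
        assert single.vrr_start == dual.vrr_start == truth

    def test_island_not_called_prematurely(self, motifs, scrubbed_fn, rng):
        island = _build_vrr(250, 0.9, motifs, rng, 0.6)
        sub1, sub2 = scrubbed_fn(1200, seed=6), scrubbed_fn(1500, seed=7)
        vrr = _build_vrr(800, 0.9, motifs, rng, 0.6)
        seq = sub1 + island + sub2 + vrr + "GGTTAG" * 300 + PROBE
        read = make_read(seq, oriented=True)
        probe_hit = locate_capture_probe(read, PROBE, motifs)
        call = detect_vrr_start_single_threshold(read, motifs, probe_hit=probe_hit)
        assert call.vrr_start >= len(sub1) + len(island) + len(sub2)

    def test_mid_telomere_dip_rejects_where_dual_retains(self, motifs, scrubbed_fn):
        # one window between 5% and 60% late in the telomere: dual keeps the
        # original start, single moves past the dip
        read, truth, _ = _construct(scrubbed_fn, motifs, tel=3000)
        at = truth + 2000
        dip = scrubbed_fn(60, seed=8)  # ~40-60% coverage windows around it
        seq = read.seq[:at] + dip + read.seq[at:]
        read2 = make_read(seq, oriented=True)
        probe_hit = locate_capture_probe(read2, PROBE, motifs)
        dual = detect_vrr_start(read2, motifs, probe_hit=probe_hit)
        single = detect_vrr_start_single_threshold(read2, motifs, probe_hit=probe_hit)
        assert dual.vrr_start == truth
        assert single.vrr_start > truth


class TestConsecutiveRepeats:
    def test_eight_tandem_found(self, motifs, scrubbed_fn):
        seq = scrubbed_fn(500, seed=9) + "N" + "GGTTAG" * 8 + "N" + scrubbed_fn(100, seed=10)
        call = detect_vrr_start_consecutive(make_read(seq, oriented=True), motifs)
        assert call.vrr_start == 501

    def test_seven_tandem_not_enough(self, motifs, scrubbed_fn):
        seq = scrubbed_fn(500, seed=11) + "N" + "GGTTAG" * 7 + "N" + scrubbed_fn(100, seed=12)
        call = detect_vrr_start_consecutive(make_read(seq, oriented=True), motifs)
        assert call.vrr_start is None

    def test_interrupted_run_matches_brute_force(self, motifs, scrubbed_fn):
        # a single non-motif base inside the run breaks it
        seq = (
            scrubbed_fn(300, seed=13)
            + "N" + "GGTTAG" * 4 + "N" + "GGTTAG" * 4 + "N"
            + scrubbed_fn(100, seed=14)
        )
        read = make_read(seq, oriented=True)
        call = detect_vrr_start_consecutive(read, motifs)
        hits = [(h.start, h.length) for h in scan_motifs(seq, motifs)]
        assert call.vrr_start == brute_first_run(hits, 8) is None

    @given(st.lists(st.sampled_from(["GGTTAG", "GGTTA", "N", "CAC"]), min_size=0, max_size=30))
    def test_random_compositions_match_brute_force(self, motifs, parts):
        seq = "".join(parts)
        read = make_read(seq, oriented=True)
        call = detect_vrr_start_consecutive(read, motifs, run_length=4)
        hits = [(h.start, h.length) for h in scan_motifs(seq, motifs)]
        assert call.vrr_start == brute_first_run(hits, 4)


class TestEvaluateMae:
    def test_identical_calls(self):
        calls = {f"r{i}": 100 for i in range(10)}
        assert evaluate_mae(calls, dict(calls)) == 0.0

    def test_half_shifted(self):
        truths = {f"r{i}": 100 for i in range(10)}
        calls = {f"r{i}": 100 + (10 if i < 5 else 0) for i in range(10)}
        assert evaluate_mae(calls, truths) == pytest.approx(5.0)

    def test_uncalled_and_untruthed_reads_skipped(self):
        calls = {"a": 100, "b": None, "c": 120}
        truths = {"a": 90, "c": None}
        assert evaluate_mae(calls, truths) == pytest.approx(10.0)

    def test_empty_is_nan(self):
        assert np.isnan(evaluate_mae({}, {}))
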