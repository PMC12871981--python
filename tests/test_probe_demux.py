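"""Bounded-error probe matching and barcode demultiplexing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from telotide.probe_demux import (
    SampleSheet,
    demultiplex,
    fuzzy_find_all,
    locate_capture_probe,
)
from telotide.simulate import DEFAULT_PROBE, _random_seq

from conftest import make_read
from oracles import naive_exact_search, naive_hamming_search

PROBE = DEFAULT_PROBE  # 12 nt, motif-free


def _plant(background: str, pattern: str, pos: int) -> str:
    return background[:pos] + pattern + background[pos + len(pattern) :]


def _mutate(pattern: str, positions, rng) -> str:
    s = list(pattern)
    for p in positions:
        s[p] = "ACGT"[("ACGT".index(s[p]) + 1 + int(rng.integers(3))) % 4]
    return "".join(s)


class TestFuzzyFindAll:
    def test_planted_exact_single_hit(self, scrubbed_fn):
        seq = _plant(scrubbed_fn(800, seed=1), PROBE, 500)
        hits = fuzzy_find_all(seq, PROBE, 2)
        assert (500, 0) in hits
        assert all(e <= 2 for _, e in hits)

    def test_three_substitutions_need_three_errors(self, scrubbed_fn, rng):
        broken = _mutate(PROBE, [1, 5, 9], rng)
        seq = _plant(scrubbed_fn(600, seed=2), broken, 300)
        assert all(s != 300 for s, _ in fuzzy_find_all(seq, PROBE, 2))
        assert (300, 3) in fuzzy_find_all(seq, PROBE, 3)

    def test_zero_errors_equals_naive_exact_search(self, rng):
        for _ in range(20):
            seq = _random_seq(1000, rng)
            pat = _random_seq(int(rng.integers(6, 15)), rng)
            got = [s for s, e in fuzzy_find_all(seq, pat, 0)]
            assert got == naive_exact_search(seq, pat)

    @given(st.text(alphabet="ACGT", min_size=20, max_size=120), st.integers(0, 4))
    def test_matches_naive_hamming_oracle(self, seq, k):
        pat = "AGCATCGGAACT"[: 6 + k]
        assert fuzzy_find_all(seq, pat, k) == naive_hamming_search(seq, pat, k)

    def test_monotone_in_max_errors(self, scrubbed_fn):
        seq = _plant(scrubbed_fn(1000, seed=3), PROBE, 700)
        prev: set = set()
        for k in range(5):
            cur = {s for s, _ in fuzzy_find_all(seq, PROBE, k)}
            assert prev <= cur
            prev = cur

    def test_pattern_longer_than_sequence(self):
        assert fuzzy_find_all("ACGT", "ACGTACGT", 2) == []


def _telomeric_read(scrubbed_fn, probe=PROBE, tandem=1, decoy_at=None, tail=""):
    """Oriented read: scrubbed subtelomere + 30 repeats + probe(s) + tail."""
    sub = scrubbed_fn(900, seed=4)
    if decoy_at is not None:
        sub = _plant(sub, probe, decoy_at)
    seq = sub + "GGTTAG" * 30 + probe * tandem + tail
    return make_read(seq, oriented=True, strand="G"), len(sub) + 180


class TestLocateCaptureProbe:
    def test_planted_probe_found_near_read_end(self, motifs, scrubbed_fn):
        read, probe_pos = _telomeric_read(scrubbed_fn)
        hit = locate_capture_probe(read, PROBE, motifs)
        assert hit is not None
        assert hit.start == probe_pos
        assert hit.errors == 0
        assert hit.distance_to_read_end < 200

    def test_subtelomeric_decoy_rejected(self, motifs, scrubbed_fn):
        # an exact decoy before any repeats fails the 20-repeat gate
        read, probe_pos = _telomeric_read(scrubbed_fn, decoy_at=100)
        hit = locate_capture_probe(read, PROBE, motifs)
        assert hit is not None and hit.start == probe_pos

    def test_tandem_probes_folded(self, motifs, scrubbed_fn):
        read, probe_pos = _telomeric_read(scrubbed_fn, tandem=2)
        hit = locate_capture_probe(read, PROBE, motifs)
        assert hit.start == probe_pos
        assert hit.tandem_count == 1

    def test_too_few_repeats_returns_none(self, motifs, scrubbed_fn):
        seq = scrubbed_fn(600, seed=5) + "GGTTAG" * 10 + PROBE
        assert locate_capture_probe(make_read(seq, oriented=True), PROBE, motifs) is None

    def test_gate_invariant(self, motifs, scrubbed_fn, rng):
        # every accepted hit starts at or after the end of the 20th repeat
        from telotide.motif_model import scan_motifs

        for seed in range(5):
            read, _ = _telomeric_read(scrubbed_fn, tail=_random_seq(50, rng))
            hit = locate_capture_probe(read, PROBE, motifs)
            reps = scan_motifs(read.seq, motifs, include_variants=False)
            assert hit.start >= reps[19].end

    def test_probe_length_error_tradeoff(self, rng, scrubbed_fn):
        # at a fixed per-base error rate, longer probes are detected less
        # often at 2 errors, and detection is restored by allowing more
        probe24 = PROBE + "GTCCTAGTTGCA"
        n = 300
        rates = {}
        for pat, k in ((PROBE, 2), (probe24, 2), (probe24, 4)):
            found = 0
            for _ in range(n):
                nerr = rng.binomial(len(pat), 0.08)
                planted = _mutate(pat, rng.choice(len(pat), nerr, replace=False), rng)
                seq = _plant(scrubbed_fn(400, seed=6), planted, 200)
                if any(s == 200 for s, _ in fuzzy_find_all(seq, pat, k)):
                    found += 1
            rates[(len(pat), k)] = found / n
        assert rates[(24, 2)] < rates[(12, 2)]
        assert rates[(24, 4)] > rates[(24, 2)]


BARCODES = [("s1", "ACGTACGTACGT"), ("s2", "TGCATGCATGCA"), ("s3", "CATCCATCCGGA")]


class TestSampleSheet:
    def test_valid_sheet(self):
        sheet = SampleSheet(BARCODES, barcode_max_errors=2)
        assert [s for s, _ in sheet.entries] == ["s1", "s2", "s3"]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            SampleSheet([("s1", "ACGTACGTACGT"), ("s1", "TGCATGCATGCA")])

    def test_close_barcodes_rejected(self):
        with pytest.raises(ValueError, match="mismatches"):
            SampleSheet([("s1", "ACGTACGTACGT"), ("s2", "ACGTACGTACGA")])

    def test_from_tsv_with_header(self, tmp_path):
        p = tmp_path / "sheet.tsv"
        p.write_text("sample_id\tbarcode\n" + "\n".join(f"{s}\t{b}" for s, b in BARCODES))
        sheet = SampleSheet.from_tsv(p)
        assert sheet.entries == BARCODES


class TestDemultiplex:
    def _read_with_barcode(self, scrubbed_fn, motifs, barcode, offset=10, errors=0, rng=None):
        if errors:
            barcode = _mutate(barcode, rng.choice(len(barcode), errors, replace=False), rng)
        read, _ = _telomeric_read(
            scrubbed_fn, tail=scrubbed_fn(offset, seed=7) + barcode + scrubbed_fn(30, seed=8)
        )
        return read, locate_capture_probe(read, PROBE, motifs)

    def test_planted_barcode_assigned(self, motifs, scrubbed_fn, rng):
        sheet = SampleSheet(BARCODES, barcode_max_errors=2)
        read, hit = self._read_with_barcode(scrubbed_fn, motifs, "TGCATGCATGCA", errors=1, rng=rng)
        res = demultiplex(read, hit, sheet, probe_len=len(PROBE))
        assert res.sample_id == "s2"
        assert res.errors == 1

    def test_no_match_unassigned(self, motifs, scrubbed_fn, rng):
        sheet = SampleSheet(BARCODES, barcode_max_errors=1)
        read, hit = self._read_with_barcode(scrubbed_fn, motifs, "GGCCGGAATTGG", rng=rng)
        assert demultiplex(read, hit, sheet, probe_len=len(PROBE)).sample_id == "unassigned"

    def test_equal_error_tie_unassigned(self, motifs, scrubbed_fn, rng):
        # two barcodes matching different windows at the same error count
        sheet = SampleSheet(BARCODES[:2], barcode_max_errors=2)
        b1 = _mutate(BARCODES[0][1], [0, 5], rng)
        b2 = _mutate(BARCODES[1][1], [2, 7], rng)
        read, _ = _telomeric_read(scrubbed_fn, tail=b1 + "N" + b2)
        probe_hit = locate_capture_probe(read, PROBE, motifs)
        res = demultiplex(read, probe_hit, sheet, probe_len=len(PROBE))
        assert res.sample_id == "unassigned"

    def test_probe_free_barcode_defines_end(self, scrubbed_fn):
        sheet = SampleSheet(BARCODES, barcode_max_errors=2)
        seq = scrubbed_fn(500, seed=9) + "GGTTAG" * 40 + "ACGTACGTACGT"
        read = make_read(seq, oriented=True)
        res = demultiplex(read, None, sheet)
        assert res.sample_id == "s1"
        assert res.barcode_start == len(seq) - 12
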