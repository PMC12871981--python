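"""Capture-probe location and barcode demultiplexing.

The enrichment capture probe is ligated to the distal telomere end; finding
it certifies a fully sequenced telomere and fixes the telomere's distal
boundary.  Matching is bounded-error Hamming matching (substitutions only,
two errors by default for a 12-nt probe).  To avoid chance subtelomeric
matches, a probe hit is only accepted once twenty telomeric repeats have
been seen 5'->3'; tandemly ligated probes are folded into a single hit.

Barcodes placed 3' of the probe demultiplex pooled samples; without a
probe the barcode match itself defines the telomere end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motif_model import MotifSet, scan_motifs
from .read_io import ReadRecord

__all__ = [
    "ProbeHit",
    "SampleSheet",
    "DemuxResult",
    "fuzzy_find_all",
    "locate_capture_probe",
    "demultiplex",
]


@dataclass(frozen=True)
class ProbeHit:
    start: int
    errors: int
    tandem_count: int
    distance_to_read_end: int


def fuzzy_find_all(seq: str, pattern: str, max_errors: int) -> list[tuple[int, int]]:
    """Every window of len(pattern) within Hamming distance ``max_errors``.

    Returns (start, errors) pairs sorted by start; with ``max_errors=0``
    this is exact substring search.  A pattern longer than ``seq`` yields
    an empty list.
    """
    m = len(pattern)
    if m == 0 or m > len(seq):
        return []
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    p = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(a, m)
    errs = (windows != p).sum(axis=1)
    idx = np.nonzero(errs <= max_errors)[0]
    return [(int(i), int(errs[i])) for i in idx]


def locate_capture_probe(
    read: ReadRecord,
    probe: str,
    motifs: MotifSet,
    max_errors: int = 2,
    min_repeats_before: int = 20,
) -> ProbeHit | None:
    """First acceptable fuzzy probe match on an oriented read.

    Scanning 5'->3', canonical telomeric repeats (both strand motifs) are
    counted; the first probe match starting at or after the end of the
    ``min_repeats_before``-th repeat is accepted.  Matches starting within
    one probe length after the accepted hit's end are folded into
    ``tandem_count`` (the telomere end stays at the first probe's start).
    Returns None when no match is acceptable.
    """
    hits = scan_motifs(read.seq, motifs, include_variants=False)
    if len(hits) < min_repeats_before:
        return None
    gate = hits[min_repeats_before - 1].end
    matches = fuzzy_find_all(read.seq, probe, max_errors)
    m = len(probe)
    accepted = None
    for start, errors in matches:
        if start >= gate:
            accepted = (start, errors)
            break
    if accepted is None:
        return None
    start, errors = accepted
    tandem = 0
    cur_end = start + m
    for s, _ in matches:
        if s <= start:
            continue
        if s < cur_end:
            continue  # overlapping shifted self-match
        if s <= cur_end + m:
            tandem += 1
            cur_end = s + m
        else:
            break
    return ProbeHit(start, errors, tandem, len(read) - start)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class SampleSheet:
    """Ordered (sample_id, barcode) entries with a barcode error budget.

    Sample ids and barcodes must be unique, barcodes equal length, and
    pairwise Hamming distance must exceed ``2 * barcode_max_errors`` so a
    read can never match two barcodes at the accepted error level.
    """

    entries: list[tuple[str, str]]
    barcode_max_errors: int = 2

    def __post_init__(self):
        ids = [s for s, _ in self.entries]
        bcs = [b for _, b in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        if len(set(bcs)) != len(bcs):
            raise ValueError("barcodes must be unique")
        if len({len(b) for b in bcs}) > 1:
            raise ValueError("barcodes must be of equal length")
        for i in range(len(bcs)):
            for j in range(i + 1, len(bcs)):
                d = _hamming(bcs[i], bcs[j])
                if d <= 2 * self.barcode_max_errors:
                    raise ValueError(
                        f"barcodes {bcs[i]} and {bcs[j]} are only {d} mismatches "
                        f"apart; need > {2 * self.barcode_max_errors}"
                    )

    @classmethod
    def from_tsv(cls, path, barcode_max_errors: int = 2) -> "SampleSheet":
        """Load a two-column TSV (sample_id, barcode); a header row whose
        second field is not pure A/C/G/T is skipped."""
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        rows = df.values.tolist()
        if rows and any(ch not in "ACGT" for ch in str(rows[0][1]).upper()):
            rows = rows[1:]
        entries = [(str(r[0]), str(r[1]).upper()) for r in rows]
        return cls(entries, barcode_max_errors)


@dataclass(frozen=True)
class DemuxResult:
    sample_id: str  # "unassigned" when no unique best barcode
    barcode_start: int | None = None  # read coordinate of the barcode match
    errors: int | None = None


def demultiplex(
    read: ReadRecord,
    probe_hit: ProbeHit | None,
    sheet: SampleSheet,
    probe_len: int = 0,
    window: int = 100,
) -> DemuxResult:
    """Assign a sample from the barcode found 3' of the capture probe.

    With a probe hit, the ``window`` bases following the probe are searched
    for each barcode; the unique best (fewest-error) match assigns the
    sample.  Ties or no match leave the read unassigned.  Without a probe
    hit the whole read is searched and the barcode's position doubles as
    the telomere-end marker (probe-free multiplexed libraries).
    """
    if not sheet.entries:
        raise ValueError("sample sheet is empty")
    if probe_hit is not None:
        region_start = probe_hit.start + probe_len
        region = read.seq[region_start : region_start + window]
    else:
        region_start = 0
        region = read.seq
    best: list[tuple[int, str, int]] = []  # (errors, sample, start)
    for sample, barcode in sheet.entries:
        matches = fuzzy_find_all(region, barcode, sheet.barcode_max_errors)
        if matches:
            s, e = min(matches, key=lambda t: t[1])
            best.append((e, sample, region_start + s))
    if not best:
        return DemuxResult("unassigned")
    best.sort(key=lambda t: t[0])
    if len(best) > 1 and best[0][0] == best[1][0]:
        return DemuxResult("unassigned")
    e, sample, start = best[0]
    return DemuxResult(sample, start, e)
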