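"""Post-boundary quality filters and per-read telomere metrics.

Filters (applied to oriented reads, thresholds are strict inequalities):

* truncation — a read whose first 300 bp (the subtelomeric end) carry more
  than 20% telomere+1N content begins inside the repeat array and lacks the
  complete telomere;
* telomere content — the called telomere [vrr_start, probe_start) must hold
  at least 60% telomere+1N content, removing subtelomeric/interstitial
  mimics;
* upstream — the 2 kb immediately 5' of the called start must stay at or
  below 10% telomere+1N content, catching misplaced starts caused by
  basecalling-artifact blocks inside the telomere.

Telomere length is ``probe_start - vrr_start`` (0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motif_model import (
    MotifHit,
    MotifSet,
    coverage_mask,
    region_pct,
    revcomp,
    scan_motifs,
)
from .read_io import ReadRecord

__all__ = [
    "TelomereCall",
    "truncation_filter",
    "telomere_content_filter",
    "upstream_filter",
    "telomere_metrics",
    "restriction_site_counts",
    "mutant_stats",
    "trim_for_clustering",
]

#: fixed pipeline stage order
STAGES = ["isolation", "strand", "probe", "truncation", "boundary", "content", "upstream"]


@dataclass
class TelomereCall:
    """Per-read pipeline result.

    ``verdicts`` records pass/fail for every stage the read reached, in
    pipeline order; ``failure_stage`` is the first failing stage (None for
    a fully passing read).
    """

    read_id: str
    strand_tag: str = "unset"
    sample_id: str | None = None
    vrr_start: int | None = None
    probe_start: int | None = None
    telomere_length: int | None = None
    telomere_mean_quality: float | None = None
    wt_repeat_bases: int | None = None
    vrr_span_estimate: int | None = None
    mutant_repeat_count: int | None = None
    wt_repeat_count: int | None = None
    mutant_fraction: float | None = None
    probe_errors: int | None = None
    probe_tandem_count: int | None = None
    probe_free_end: bool = False
    verdicts: dict = field(default_factory=dict)
    failure_stage: str | None = None

    def record(self, stage: str, passed: bool) -> bool:
        self.verdicts[stage] = "pass" if passed else "fail"
        if not passed and self.failure_stage is None:
            self.failure_stage = stage
        return passed


def _mask(read: ReadRecord, motifs: MotifSet, include_mutant: bool, hits) -> np.ndarray:
    if hits is None:
        hits = scan_motifs(read.seq, motifs, include_variants=True, include_mutant=include_mutant)
    return coverage_mask(len(read), hits)


def truncation_filter(
    read: ReadRecord,
    motifs: MotifSet,
    span: int = 300,
    max_pct: float = 20.0,
    include_mutant: bool = False,
    hits: list[MotifHit] | None = None,
) -> bool:
    """Pass unless the first ``span`` bases exceed ``max_pct`` telomere+1N.

    Reads failing here begin inside the VRR region or repeat array and are
    proximally truncated.  Exactly ``max_pct`` passes (strict inequality).
    """
    mask = _mask(read, motifs, include_mutant, hits)
    return region_pct(mask, 0, span) <= max_pct


def telomere_content_filter(
    read: ReadRecord,
    motifs: MotifSet,
    vrr_start: int,
    probe_start: int,
    min_pct: float = 60.0,
    include_mutant: bool = False,
    hits: list[MotifHit] | None = None,
) -> bool:
    """Pass unless [vrr_start, probe_start) holds < ``min_pct`` telomere+1N."""
    mask = _mask(read, motifs, include_mutant, hits)
    return region_pct(mask, vrr_start, probe_start) >= min_pct


def upstream_filter(
    read: ReadRecord,
    motifs: MotifSet,
    vrr_start: int,
    span: int = 2000,
    max_pct: float = 10.0,
    include_mutant: bool = False,
    hits: list[MotifHit] | None = None,
) -> bool:
    """Pass unless the ``span`` bases 5' of the start exceed ``max_pct``.

    When ``vrr_start`` is closer than ``span`` to the read start, the
    available prefix is evaluated instead (the truncation filter already
    guards genuinely short subtelomeres).  An empty prefix passes.
    """
    mask = _mask(read, motifs, include_mutant, hits)
    return region_pct(mask, max(0, vrr_start - span), vrr_start) <= max_pct


def telomere_metrics(
    read: ReadRecord,
    motifs: MotifSet,
    vrr_start: int,
    probe_start: int,
    include_mutant: bool = False,
    hits: list[MotifHit] | None = None,
) -> tuple[int, float, int, int]:
    """(telomere_length, mean Phred quality, wild-type repeat bases,
    VRR span estimate) for the called telomere.

    ``wt_repeat_bases`` counts bases covered by canonical hits only
    (clipped to the telomere), enabling the wild-type-only length
    difference statistic.  The VRR span is estimated as the distance from
    the start to the end of the last variant-kind hit inside the telomere.
    """
    if hits is None:
        hits = scan_motifs(read.seq, motifs, include_variants=True, include_mutant=include_mutant)
    length = probe_start - vrr_start
    if length < 0:
        raise ValueError("probe_start must not precede vrr_start")
    mean_q = float(np.mean(read.quals[vrr_start:probe_start])) if length else 0.0
    wt = 0
    vrr_end = vrr_start
    for h in hits:
        lo, hi = max(h.start, vrr_start), min(h.end, probe_start)
        if hi <= lo:
            continue
        if h.kind == "canonical":
            wt += hi - lo
        elif h.kind == "variant":
            vrr_end = max(vrr_end, hi)
    return length, mean_q, wt, vrr_end - vrr_start


def restriction_site_counts(
    reads: list[ReadRecord], sites: list[str]
) -> dict[str, int]:
    """Per-site count of reads containing the recognition site.

    Either strand counts and each read counts once per site regardless of
    copy number.
    """
    counts = {}
    for site in sites:
        site = site.upper()
        rc = revcomp(site)
        counts[site] = sum(1 for r in reads if site in r.seq or rc in r.seq)
    return counts


def mutant_stats(
    read: ReadRecord,
    motifs: MotifSet,
    vrr_start: int,
    probe_start: int,
    hits: list[MotifHit] | None = None,
) -> tuple[int, int, float | None]:
    """(mutant hits, wild-type hits, mutant fraction) inside the telomere.

    Requires a motif set with mutant motifs (mutant mode); the fraction is
    None when no repeat of either kind falls in the telomere.
    """
    if not motifs.mutant:
        raise ValueError("motif set has no mutant motifs; enable mutant mode")
    if hits is None:
        hits = scan_motifs(read.seq, motifs, include_variants=True, include_mutant=True)
    mut = wt = 0
    for h in hits:
        if vrr_start <= h.start < probe_start:
            if h.kind == "mutant":
                mut += 1
            elif h.kind == "canonical":
                wt += 1
    total = mut + wt
    return mut, wt, (mut / total if total else None)


def trim_for_clustering(
    read: ReadRecord, vrr_start: int, before: int, after: int
) -> str:
    """Sequence window around the telomere start for external clustering.

    Returns ``seq[vrr_start - before : vrr_start + after)`` clipped to the
    read bounds (1 kb before / 3-4 kb after are typical choices).
    """
    lo = max(0, vrr_start - before)
    hi = min(len(read), vrr_start + after)
    return read.seq[lo:hi]
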