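"""Subtelomere-to-telomere boundary (VRR-region start) detection.

The default detector is a dual-threshold jumping window: a 100 bp window
advanced in 15 bp steps along the oriented read (5'->3', stopping at the
capture probe when one was found).  The first window whose telomere+1N
coverage reaches the primary threshold (60%) proposes the start of the
variant repeat-rich (VRR) region: the first telomere+1N hit beginning at or
after that window's start.  The candidate survives unless repeat content
later collapses below the secondary threshold (5%) for at least 15
consecutive windows — short dips are tolerated, long collapses (basecalling
artifacts, telomere-like islands followed by subtelomere) invalidate the
candidate and the scan re-triggers after the collapsed run.

Two simpler strategies are kept for benchmarking: a single-threshold window
(the 60% level must be maintained for the remainder of the read) and the
first run of eight back-to-back telomere+1N repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motif_model import (
    MotifHit,
    MotifSet,
    coverage_mask,
    profile_from_mask,
    scan_motifs,
)
from .probe_demux import ProbeHit
from .read_io import ReadRecord

__all__ = [
    "BoundaryCall",
    "detect_vrr_start",
    "detect_vrr_start_single_threshold",
    "detect_vrr_start_consecutive",
    "evaluate_mae",
]


@dataclass
class BoundaryCall:
    vrr_start: int | None
    trigger_window_start: int | None
    algorithm: str
    params: dict = field(default_factory=dict)
    reason: str | None = None  # set when vrr_start is None


def _first_hit_at_or_after(hits: list[MotifHit], pos: int, limit: int) -> MotifHit | None:
    for h in hits:
        if h.start >= pos and h.start < limit:
            return h
    return None


def _prepare(read, motifs, probe_hit, include_mutant, hits):
    if hits is None:
        hits = scan_motifs(read.seq, motifs, include_variants=True, include_mutant=include_mutant)
    limit = probe_hit.start if probe_hit is not None else len(read)
    mask = coverage_mask(len(read), hits)
    return hits, mask, limit


def detect_vrr_start(
    read: ReadRecord,
    motifs: MotifSet,
    window_size: int = 100,
    step: int = 15,
    primary_pct: float = 60.0,
    secondary_pct: float = 5.0,
    rescue_windows: int = 15,
    probe_hit: ProbeHit | None = None,
    include_mutant: bool = False,
    hits: list[MotifHit] | None = None,
) -> BoundaryCall:
    """Dual-threshold jumping-window VRR start caller (default strategy)."""
    params = dict(
        window_size=window_size,
        step=step,
        primary_pct=primary_pct,
        secondary_pct=secondary_pct,
        rescue_windows=rescue_windows,
    )
    hits, mask, limit = _prepare(read, motifs, probe_hit, include_mutant, hits)
    prof = profile_from_mask(mask, window_size, step, limit=limit)
    if prof.truncated or len(prof.coverage_pct) == 0:
        return BoundaryCall(None, None, "dual_threshold", params, reason="too_short")
    cov = prof.coverage_pct
    starts = prof.window_starts
    nwin = len(cov)
    i = 0
    while i < nwin:
        if cov[i] >= primary_pct:
            cand = _first_hit_at_or_after(hits, int(starts[i]), limit)
            if cand is None:
                i += 1
                continue
            # candidate is invalidated only by >= rescue_windows consecutive
            # sub-secondary windows later in the telomere
            run = 0
            invalid_end = None
            for j in range(i + 1, nwin):
                if cov[j] < secondary_pct:
                    run += 1
                    if run >= rescue_windows:
                        k = j
                        while k + 1 < nwin and cov[k + 1] < secondary_pct:
                            k += 1
                        invalid_end = k
                        break
                else:
                    run = 0
            if invalid_end is None:
                return BoundaryCall(cand.start, int(starts[i]), "dual_threshold", params)
            i = invalid_end + 1
        else:
            i += 1
    return BoundaryCall(None, None, "dual_threshold", params, reason="no_trigger")


def detect_vrr_start_single_threshold(
    read: ReadRecord,
    motifs: MotifSet,
    window_size: int = 100,
    step: int = 15,
    primary_pct: float = 60.0,
    probe_hit: ProbeHit | None = None,
    include_mutant: bool = False,
    hits: list[MotifHit] | None = None,
) -> BoundaryCall:
    """Single-threshold comparison strategy.

    The trigger window's coverage level must be maintained (every later
    window >= primary threshold) for the remainder of the read, so any
    later dip pushes the trigger past it.
    """
    params = dict(window_size=window_size, step=step, primary_pct=primary_pct)
    hits, mask, limit = _prepare(read, motifs, probe_hit, include_mutant, hits)
    prof = profile_from_mask(mask, window_size, step, limit=limit)
    if prof.truncated or len(prof.coverage_pct) == 0:
        return BoundaryCall(None, None, "single_threshold", params, reason="too_short")
    cov = prof.coverage_pct
    starts = prof.window_starts
    ok = cov >= primary_pct
    # suffix-and: first index from which every window stays above threshold
    suffix_ok = np.logical_and.accumulate(ok[::-1])[::-1]
    idx = np.nonzero(suffix_ok)[0]
    for i in idx:
        cand = _first_hit_at_or_after(hits, int(starts[i]), limit)
        if cand is not None:
            return BoundaryCall(cand.start, int(starts[i]), "single_threshold", params)
        break
    return BoundaryCall(None, None, "single_threshold", params, reason="no_trigger")


def detect_vrr_start_consecutive(
    read: ReadRecord,
    motifs: MotifSet,
    run_length: int = 8,
    probe_hit: ProbeHit | None = None,
    include_mutant: bool = False,
    hits: list[MotifHit] | None = None,
) -> BoundaryCall:
    """Baseline strategy: first run of ``run_length`` back-to-back repeats.

    Hits count as consecutive when each begins exactly where the previous
    ended.
    """
    params = dict(run_length=run_length)
    hits, _, limit = _prepare(read, motifs, probe_hit, include_mutant, hits)
    run_start = None
    run = 0
    prev_end = None
    for h in hits:
        if h.start >= limit:
            break
        if prev_end is not None and h.start == prev_end:
            run += 1
        else:
            run_start, run = h.start, 1
        prev_end = h.end
        if run >= run_length:
            return BoundaryCall(run_start, None, "consecutive_repeats", params)
    return BoundaryCall(None, None, "consecutive_repeats", params, reason="no_run")


def evaluate_mae(calls: dict, truths: dict) -> float:
    """Mean absolute error (nt) between called and true VRR starts.

    ``calls`` maps read_id -> called position (or None); ``truths`` maps
    read_id -> true position (or None).  Only reads with both are scored.
    Returns NaN when no read qualifies.
    """
    errs = [
        abs(calls[rid] - truths[rid])
        for rid in calls
        if calls[rid] is not None and truths.get(rid) is not None
    ]
    if not errs:
        return float("nan")
    return float(np.mean(errs))
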