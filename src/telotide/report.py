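"""Pipeline orchestration, stage ledger, summaries and report output.

Stages run in a fixed order — isolation, strand, probe, truncation,
boundary, content, upstream — and every input read appears exactly once in
the per-read table, either with its final metrics or with the first stage
that removed it.  The ledger records (entered, passed, failed) per stage
(and per sample when demultiplexed); percentages are always derived from
it, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import boundary as _boundary
from .isolation import classify_strand, first_pass_isolate, normalize_orientation
from .motif_model import MotifSet, build_motif_set, scan_motifs
from .probe_demux import ProbeHit, SampleSheet, demultiplex, locate_capture_probe
from .qc_filters import (
    STAGES,
    TelomereCall,
    mutant_stats,
    restriction_site_counts,
    telomere_content_filter,
    telomere_metrics,
    trim_for_clustering,
    truncation_filter,
    upstream_filter,
)
from .read_io import ReadRecord, read_input, write_annotated

__all__ = [
    "DIPLOID_HUMAN_ARMS",
    "PipelineConfig",
    "PipelineResult",
    "StageLedger",
    "run_pipeline",
    "uniform_arm_expectation",
    "summarize",
    "strand_comparison_report",
    "write_html_report",
]

#: chromosome arm count of a diploid human cell — the expected cluster count
#: when telomere alleles separate perfectly
DIPLOID_HUMAN_ARMS = 92


def uniform_arm_expectation(arm_count: int = DIPLOID_HUMAN_ARMS, exact: bool = False):
    """Expected per-arm percentage under a uniform read distribution.

    With 92 arms this is 100/92 = 1.08% (reported truncated to two
    decimals for plots and tables).  ``exact=True`` returns the value as a
    :class:`fractions.Fraction` so ``arm_count * x == 100`` holds exactly.
    """
    frac = Fraction(100, arm_count)
    if exact:
        return frac
    return int(frac * 100) / 100.0


class StageLedger:
    """Ordered (entered, passed, failed) counts per pipeline stage."""

    def __init__(self, stages: Iterable[str] = STAGES):
        self.stages = list(stages)
        self.counts = {s: [0, 0, 0] for s in self.stages}

    def record(self, stage: str, passed: bool) -> None:
        row = self.counts[stage]
        row[0] += 1
        row[1 if passed else 2] += 1

    def entered(self, stage: str) -> int:
        return self.counts[stage][0]

    def passed(self, stage: str) -> int:
        return self.counts[stage][1]

    def failed(self, stage: str) -> int:
        return self.counts[stage][2]

    def check_conservation(self) -> bool:
        """entered(k+1) == passed(k) for consecutive stages with traffic."""
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if self.entered(nxt) and self.entered(nxt) != self.passed(prev):
                return False
        return True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, *self.counts[s]) for s in self.stages],
            columns=["stage", "entered", "passed", "failed"],
        )

    def __add__(self, other: "StageLedger") -> "StageLedger":
        out = StageLedger(self.stages)
        for s in self.stages:
            for i in range(3):
                out.counts[s][i] = self.counts[s][i] + other.counts[s][i]
        return out


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters (defaults follow the validated run)."""

    canonical: str = "GGTTAG"
    mutant: tuple = ()
    min_repeats: int = 10
    c_strand_only: bool = False
    probe: str | None = None
    probe_errors: int = 2
    min_repeats_before_probe: int = 20
    sheet: SampleSheet | None = None
    barcode_window: int = 100
    window: int = 100
    step: int = 15
    primary_pct: float = 60.0
    secondary_pct: float = 5.0
    rescue_windows: int = 15
    strategy: str = "dual"  # dual | single | consecutive
    consecutive_run: int = 8
    truncation_span: int = 300
    truncation_max_pct: float = 20.0
    content_min_pct: float = 60.0
    upstream_span: int = 2000
    upstream_max_pct: float = 10.0
    restriction_sites: tuple = ()
    trim_before: int = 1000
    trim_after: int = 3000

    @property
    def mutant_mode(self) -> bool:
        return bool(self.mutant)

    def motifs(self) -> MotifSet:
        return build_motif_set(self.canonical, self.mutant or None)


@dataclass
class PipelineResult:
    calls: dict  # read_id -> TelomereCall
    oriented: dict  # read_id -> oriented ReadRecord (reads passing strand)
    ledger: StageLedger
    sample_ledgers: dict = field(default_factory=dict)
    restriction_counts: dict = field(default_factory=dict)

    @property
    def passing(self) -> list[TelomereCall]:
        return [c for c in self.calls.values() if c.failure_stage is None]

    def per_read_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls.values():
            rows.append(
                {
                    "read_id": c.read_id,
                    "sample_id": c.sample_id or "sample",
                    "strand": c.strand_tag,
                    "vrr_start": c.vrr_start,
                    "probe_start": c.probe_start,
                    "telomere_length": c.telomere_length,
                    "telomere_mean_quality": c.telomere_mean_quality,
                    "wt_repeat_bases": c.wt_repeat_bases,
                    "status": "pass" if c.failure_stage is None else "fail",
                    "failure_stage": c.failure_stage or "",
                }
            )
        return pd.DataFrame(rows)


def _detect(read, motifs, config: PipelineConfig, probe_hit, hits):
    if config.strategy == "dual":
        return _boundary.detect_vrr_start(
            read,
            motifs,
            window_size=config.window,
            step=config.step,
            primary_pct=config.primary_pct,
            secondary_pct=config.secondary_pct,
            rescue_windows=config.rescue_windows,
            probe_hit=probe_hit,
            include_mutant=config.mutant_mode,
            hits=hits,
        )
    if config.strategy == "single":
        return _boundary.detect_vrr_start_single_threshold(
            read,
            motifs,
            window_size=config.window,
            step=config.step,
            primary_pct=config.primary_pct,
            probe_hit=probe_hit,
            include_mutant=config.mutant_mode,
            hits=hits,
        )
    if config.strategy == "consecutive":
        return _boundary.detect_vrr_start_consecutive(
            read,
            motifs,
            run_length=config.consecutive_run,
            probe_hit=probe_hit,
            include_mutant=config.mutant_mode,
            hits=hits,
        )
    raise ValueError(f"unknown boundary strategy {config.strategy!r}")


def process_read(
    read: ReadRecord, motifs: MotifSet, config: PipelineConfig
) -> tuple[TelomereCall, ReadRecord | None]:
    """Run one read through every stage; returns (call, oriented read)."""
    call = TelomereCall(read.read_id)

    if not call.record("isolation", first_pass_isolate(read, motifs, config.min_repeats)):
        return call, None

    strand = classify_strand(read, motifs, config.c_strand_only)
    keep = strand.verdict == "C" if config.c_strand_only else strand.verdict in ("C", "G")
    if not call.record("strand", keep):
        call.strand_tag = strand.verdict
        return call, None
    oriented = normalize_orientation(read, strand)
    call.strand_tag = oriented.strand_tag

    # one variant-aware scan serves boundary detection and all filters
    hits = scan_motifs(
        oriented.seq, motifs, include_variants=True, include_mutant=config.mutant_mode
    )

    probe_hit: ProbeHit | None = None
    if config.probe:
        probe_hit = locate_capture_probe(
            oriented,
            config.probe,
            motifs,
            max_errors=config.probe_errors,
            min_repeats_before=config.min_repeats_before_probe,
        )
        if not call.record("probe", probe_hit is not None):
            return call, oriented
        call.probe_start = probe_hit.start
        call.probe_errors = probe_hit.errors
        call.probe_tandem_count = probe_hit.tandem_count
    if config.sheet is not None:
        demux = demultiplex(
            oriented,
            probe_hit,
            config.sheet,
            probe_len=len(config.probe or ""),
            window=config.barcode_window,
        )
        oriented.sample_id = demux.sample_id
        call.sample_id = demux.sample_id
        if probe_hit is None:
            # barcode position defines the telomere end in probe-free mode
            if not call.record("probe", demux.barcode_start is not None):
                return call, oriented
            call.probe_start = demux.barcode_start
    if call.probe_start is None:
        # probe-free, sheet-free: distal end defaults to the read's 3' end
        call.record("probe", True)
        call.probe_start = len(oriented)
        call.probe_free_end = True

    ok = truncation_filter(
        oriented,
        motifs,
        span=config.truncation_span,
        max_pct=config.truncation_max_pct,
        include_mutant=config.mutant_mode,
        hits=hits,
    )
    if not call.record("truncation", ok):
        return call, oriented

    bcall = _detect(oriented, motifs, config, probe_hit, hits)
    if not call.record("boundary", bcall.vrr_start is not None):
        return call, oriented
    call.vrr_start = bcall.vrr_start

    ok = telomere_content_filter(
        oriented,
        motifs,
        call.vrr_start,
        call.probe_start,
        min_pct=config.content_min_pct,
        include_mutant=config.mutant_mode,
        hits=hits,
    )
    if not call.record("content", ok):
        return call, oriented

    ok = upstream_filter(
        oriented,
        motifs,
        call.vrr_start,
        span=config.upstream_span,
        max_pct=config.upstream_max_pct,
        include_mutant=config.mutant_mode,
        hits=hits,
    )
    if not call.record("upstream", ok):
        return call, oriented

    length, mean_q, wt, vrr_span = telomere_metrics(
        oriented,
        motifs,
        call.vrr_start,
        call.probe_start,
        include_mutant=config.mutant_mode,
        hits=hits,
    )
    call.telomere_length = length
    call.telomere_mean_quality = mean_q
    call.wt_repeat_bases = wt
    call.vrr_span_estimate = vrr_span
    if config.mutant_mode:
        call.mutant_repeat_count, call.wt_repeat_count, call.mutant_fraction = mutant_stats(
            oriented, motifs, call.vrr_start, call.probe_start, hits=hits
        )
    return call, oriented


def run_pipeline(reads, config: PipelineConfig | None = None, outdir=None) -> PipelineResult:
    """Run the full pipeline over reads (a path or an iterable of records).

    Writes per-read TSV, ledger TSV, summary TSV, tagged BAM, trimmed
    FASTA and an HTML report when ``outdir`` is given.  Zero surviving
    reads is not an error: outputs are simply empty.
    """
    config = config or PipelineConfig()
    motifs = config.motifs()
    if isinstance(reads, (str, Path)):
        reads = read_input(reads)
    reads = list(reads)

    ledger = StageLedger()
    sample_ledgers: dict[str, StageLedger] = {}
    calls: dict[str, TelomereCall] = {}
    oriented: dict[str, ReadRecord] = {}
    for read in reads:
        call, orec = process_read(read, motifs, config)
        calls[read.read_id] = call
        if orec is not None:
            oriented[read.read_id] = orec
        sample = call.sample_id or "sample"
        sled = sample_ledgers.setdefault(sample, StageLedger())
        for stage, verdict in call.verdicts.items():
            ledger.record(stage, verdict == "pass")
            sled.record(stage, verdict == "pass")

    result = PipelineResult(calls, oriented, ledger, sample_ledgers)
    if config.restriction_sites:
        telomeric = [oriented[c.read_id] for c in calls.values() if c.read_id in oriented]
        result.restriction_counts = restriction_site_counts(
            telomeric, list(config.restriction_sites)
        )
    if outdir is not None:
        _write_outputs(result, reads, config, Path(outdir))
    return result


def summarize(result: PipelineResult) -> pd.DataFrame:
    """Per-sample telomere length / quality summary of passing reads."""
    rows = []
    by_sample: dict[str, list[TelomereCall]] = {}
    for c in result.passing:
        by_sample.setdefault(c.sample_id or "sample", []).append(c)
    for sample, group in sorted(by_sample.items()):
        lengths = np.array([c.telomere_length for c in group], dtype=float)
        quals = np.array([c.telomere_mean_quality for c in group], dtype=float)
        strands = [c.strand_tag for c in group]
        rows.append(
            {
                "sample_id": sample,
                "n": len(group),
                "mean_length": float(lengths.mean()),
                "median_length": float(np.median(lengths)),
                "sd_length": float(lengths.std(ddof=1)) if len(group) > 1 else 0.0,
                "q10_length": float(np.quantile(lengths, 0.10)),
                "q25_length": float(np.quantile(lengths, 0.25)),
                "q75_length": float(np.quantile(lengths, 0.75)),
                "q90_length": float(np.quantile(lengths, 0.90)),
                "mean_quality": float(quals.mean()),
                "n_c_strand": strands.count("C"),
                "n_g_strand": strands.count("G"),
            }
        )
    return pd.DataFrame(rows)


def strand_comparison_report(result: PipelineResult) -> dict:
    """Per-strand ledgers, length distributions and probe-detection rates.

    Strand is known once a read passes the strand stage, so the comparison
    covers the probe stage onward; the two per-strand ledgers partition
    the combined ledger over those stages.
    """
    out: dict[str, dict] = {}
    for strand in ("C", "G"):
        calls = [c for c in result.calls.values() if c.strand_tag == strand]
        led = StageLedger()
        for c in calls:
            for stage, verdict in c.verdicts.items():
                if stage in ("isolation", "strand"):
                    continue
                led.record(stage, verdict == "pass")
        probe_seen = [c for c in calls if "probe" in c.verdicts]
        out[strand] = {
            "ledger": led,
            "n": len(calls),
            "lengths": [c.telomere_length for c in calls if c.telomere_length is not None],
            "probe_detection_rate": (
                sum(1 for c in probe_seen if c.verdicts["probe"] == "pass") / len(probe_seen)
                if probe_seen
                else float("nan")
            ),
        }
    return out


def _write_outputs(result, reads, config, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    annotated_records = [result.oriented.get(r.read_id, r) for r in reads]
    per_read = write_annotated(
        outdir / "per_read.tsv", annotated_records, result.calls, bam_path=outdir / "reads.bam"
    )
    result.ledger.to_frame().to_csv(outdir / "ledger.tsv", sep="\t", index=False)
    summary = summarize(result)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    with open(outdir / "trimmed.fasta", "w") as fh:
        for call in result.passing:
            rec = result.oriented[call.read_id]
            trimmed = trim_for_clustering(
                rec, call.vrr_start, config.trim_before, config.trim_after
            )
            fh.write(f">{call.read_id}\n{trimmed}\n")
    _plot_lengths(result, outdir / "telomere_lengths.png")
    write_html_report(outdir / "report.html", result, summary, per_read)


def _plot_lengths(result: PipelineResult, path: Path) -> None:
    lengths = [c.telomere_length for c in result.passing]
    if not lengths:
        return
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:
        return
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(lengths, bins=40, color="#4878a8")
    ax.set_xlabel("telomere length (nt)")
    ax.set_ylabel("reads")
    ax.set_title("Telomere length distribution")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_html_report(path, result: PipelineResult, summary: pd.DataFrame, per_read=None) -> None:
    """Static HTML report: stage ledger and per-sample summary tables."""
    ledger_html = result.ledger.to_frame().to_html(index=False)
    summary_html = summary.to_html(index=False) if len(summary) else "<p>no passing reads</p>"
    n_in = result.ledger.entered("isolation")
    n_pass = len(result.passing)
    html = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>telotide report</title>
<style>body{{font-family:sans-serif;margin:2em}}table{{border-collapse:collapse}}
td,th{{border:1px solid #999;padding:0.3em 0.6em}}</style></head>
<body>
<h1>telotide report</h1>
<p>{n_in} input reads; {n_pass} high-confidence telomeric reads
({100.0 * n_pass / n_in if n_in else 0.0:.1f}%).</p>
<h2>Stage ledger</h2>
{ledger_html}
<h2>Per-sample summary</h2>
{summary_html}
<p>Uniform per-arm expectation for a diploid human:
{uniform_arm_expectation():.2f}% across {DIPLOID_HUMAN_ARMS} arms.</p>
</body></html>
"""
    Path(path).write_text(html)
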