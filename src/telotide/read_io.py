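"""Read/write sequencing reads and per-read annotations.

Supported inputs are FASTQ (plain or gzip, Phred+33) and unaligned BAM;
format is auto-detected from the file name.  All coordinates written by this
module are 0-based, half-open, so telomere length is simply
``probe_start - vrr_start``.

BAM tags used for annotated output: ``XS`` original strand, ``XV`` VRR
(telomere) start, ``XP`` capture-probe start, ``XL`` telomere length,
``XQ`` mean telomere Phred quality, ``XM`` sample id.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

from .motif_model import revcomp

__all__ = [
    "ReadRecord",
    "GroundTruth",
    "ReadParseError",
    "read_input",
    "write_fastq",
    "write_bam",
    "write_annotated",
    "read_truth",
    "write_truth",
]


class ReadParseError(ValueError):
    """Raised when an input file cannot be parsed; names the record index."""


@dataclass
class ReadRecord:
    """One nanopore read.

    ``strand_tag`` records the original strand (``C``/``G``/``unset``);
    ``oriented`` becomes True once the read has been normalized to G-strand
    orientation (telomere/probe toward the 3' end).
    """

    read_id: str
    seq: str
    quals: np.ndarray
    strand_tag: str = "unset"
    oriented: bool = False
    sample_id: str | None = None

    def __post_init__(self):
        self.quals = np.asarray(self.quals, dtype=np.uint8)
        if len(self.quals) != len(self.seq):
            raise ValueError(
                f"{self.read_id}: quality length {len(self.quals)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "ReadRecord":
        """New record with reverse-complemented sequence and reversed quals."""
        return replace(self, seq=revcomp(self.seq), quals=self.quals[::-1].copy())


@dataclass
class GroundTruth:
    """Simulator sidecar truth for one read (positions in G orientation)."""

    read_id: str
    true_strand: str
    true_vrr_start: int | None
    true_probe_start: int | None
    true_barcode: str | None = None
    read_class: str = "normal"

    def __post_init__(self):
        if (
            self.true_vrr_start is not None
            and self.true_probe_start is not None
            and not self.true_vrr_start < self.true_probe_start
        ):
            raise ValueError(
                f"{self.read_id}: true_vrr_start must precede true_probe_start"
            )


def _detect_format(path: str) -> str:
    name = str(path).lower()
    if name.endswith(".bam"):
        return "bam"
    if name.endswith(".gz"):
        return "fastq.gz"
    return "fastq"


def _iter_fastq(path: str) -> Iterator[ReadRecord]:
    idx = 0
    try:
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                if entry.quality is None:
                    raise ReadParseError(
                        f"{path}: record {idx} ({entry.name}) has no qualities"
                    )
                quals = np.array(entry.get_quality_array(), dtype=np.uint8)
                yield ReadRecord(entry.name, entry.sequence.upper(), quals)
                idx += 1
    except ReadParseError:
        raise
    except Exception as exc:  # truncated / garbled input
        raise ReadParseError(f"{path}: parse error at record {idx}: {exc}") from exc


def _iter_bam(path: str) -> Iterator[ReadRecord]:
    idx = 0
    try:
        with pysam.AlignmentFile(str(path), "rb", check_sq=False) as fh:
            for aln in fh.fetch(until_eof=True):
                quals = np.array(aln.query_qualities, dtype=np.uint8)
                rec = ReadRecord(aln.query_name, aln.query_sequence.upper(), quals)
                if aln.has_tag("XS"):
                    rec.strand_tag = aln.get_tag("XS")
                if aln.has_tag("XM"):
                    rec.sample_id = aln.get_tag("XM")
                yield rec
                idx += 1
    except Exception as exc:
        raise ReadParseError(f"{path}: parse error at record {idx}: {exc}") from exc


def read_input(path, fmt: str | None = None) -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord` from FASTQ, gzip FASTQ, or unaligned BAM."""
    path = str(path)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    fmt = fmt or _detect_format(path)
    if fmt == "bam":
        return _iter_bam(path)
    if fmt in ("fastq", "fastq.gz"):
        return _iter_fastq(path)
    raise ValueError(f"unsupported format {fmt!r}")


def write_fastq(path, records: Iterable[ReadRecord]) -> None:
    """Write records as Phred+33 FASTQ (gzip if the name ends in .gz).

    Gzip output uses a zeroed mtime so identical records give identical
    bytes.
    """
    path = str(path)
    opener = (
        (lambda p: gzip.GzipFile(filename="", mode="wb", fileobj=open(p, "wb"), mtime=0))
        if path.endswith(".gz")
        else (lambda p: open(p, "wb"))
    )
    with opener(path) as fh:
        for rec in records:
            q = (rec.quals + 33).tobytes().decode("ascii")
            fh.write(f"@{rec.read_id}\n{rec.seq}\n+\n{q}\n".encode("ascii"))


_BAM_HEADER = {"HD": {"VN": "1.6", "SO": "unknown"}}


def write_bam(path, records: Iterable[ReadRecord], calls=None) -> None:
    """Write unaligned BAM, with per-read annotation tags when calls given.

    ``calls`` maps read_id -> :class:`telotide.qc_filters.TelomereCall`.
    """
    calls = calls or {}
    with pysam.AlignmentFile(str(path), "wb", header=_BAM_HEADER) as fh:
        for rec in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rec.read_id
            a.query_sequence = rec.seq
            a.query_qualities = pysam.qualitystring_to_array(
                (rec.quals + 33).tobytes().decode("ascii")
            )
            a.flag = 4  # unmapped
            tags = []
            if rec.strand_tag != "unset":
                tags.append(("XS", rec.strand_tag))
            if rec.sample_id is not None:
                tags.append(("XM", rec.sample_id))
            call = calls.get(rec.read_id)
            if call is not None:
                if call.vrr_start is not None:
                    _check_coord(call.vrr_start, rec)
                    tags.append(("XV", int(call.vrr_start)))
                if call.probe_start is not None:
                    _check_coord(call.probe_start, rec)
                    tags.append(("XP", int(call.probe_start)))
                if call.telomere_length is not None:
                    tags.append(("XL", int(call.telomere_length)))
                if call.telomere_mean_quality is not None:
                    tags.append(("XQ", float(call.telomere_mean_quality)))
            a.tags = tags
            fh.write(a)


def _check_coord(pos: int, rec: ReadRecord) -> None:
    if not 0 <= pos <= len(rec):
        raise ValueError(f"coordinate {pos} outside read {rec.read_id} (len {len(rec)})")


#: required columns of the per-read TSV (0-based half-open coordinates)
TSV_COLUMNS = [
    "read_id",
    "sample_id",
    "strand",
    "vrr_start",
    "probe_start",
    "telomere_length",
    "telomere_mean_quality",
    "status",
    "failure_stage",
]


def write_annotated(path, records: Iterable[ReadRecord], calls, bam_path=None) -> pd.DataFrame:
    """Emit per-read calls as a TSV (and optionally a tagged BAM).

    ``calls`` maps read_id -> TelomereCall; every call must refer to an
    existing read and fit inside it.  Returns the DataFrame written.
    """
    records = list(records)
    by_id = {r.read_id: r for r in records}
    rows = []
    for read_id, call in calls.items():
        if read_id not in by_id:
            raise ValueError(f"call refers to unknown read {read_id}")
        rec = by_id[read_id]
        for pos in (call.vrr_start, call.probe_start):
            if pos is not None:
                _check_coord(pos, rec)
        rows.append(
            {
                "read_id": read_id,
                "sample_id": rec.sample_id if rec.sample_id is not None else "sample",
                "strand": call.strand_tag,
                "vrr_start": call.vrr_start,
                "probe_start": call.probe_start,
                "telomere_length": call.telomere_length,
                "telomere_mean_quality": call.telomere_mean_quality,
                "status": "pass" if call.failure_stage is None else "fail",
                "failure_stage": call.failure_stage or "",
            }
        )
    df = pd.DataFrame(rows, columns=TSV_COLUMNS)
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based, half-open\n")
        df.to_csv(fh, sep="\t", index=False)
    if bam_path is not None:
        write_bam(bam_path, records, calls)
    return df


_TRUTH_COLUMNS = [
    "read_id",
    "true_strand",
    "true_vrr_start",
    "true_probe_start",
    "true_barcode",
    "read_class",
]


def write_truth(path, truths: Iterable[GroundTruth]) -> None:
    rows = [
        {
            "read_id": t.read_id,
            "true_strand": t.true_strand,
            "true_vrr_start": "" if t.true_vrr_start is None else int(t.true_vrr_start),
            "true_probe_start": "" if t.true_probe_start is None else int(t.true_probe_start),
            "true_barcode": t.true_barcode or "",
            "read_class": t.read_class,
        }
        for t in truths
    ]
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list[GroundTruth]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            GroundTruth(
                read_id=str(row.read_id),
                true_strand=str(row.true_strand),
                true_vrr_start=None if row.true_vrr_start == "" else int(row.true_vrr_start),
                true_probe_start=None
                if row.true_probe_start == ""
                else int(row.true_probe_start),
                true_barcode=str(row.true_barcode) or None,
                read_class=str(row.read_class),
            )
        )
    return out
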