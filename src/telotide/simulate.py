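"""Synthetic telomere-enriched nanopore-like reads with ground truth.

Reads follow the enrichment library structure

    [scrubbed subtelomere][VRR region][invariant telomere][probe][barcode?]

in G-strand orientation, optionally reverse-complemented to the C strand.
The subtelomere is random sequence *scrubbed* of every telomere+1N match, so
before noise injection the recorded VRR start is exact by construction.  The
VRR region is a mixture of canonical and single-edit variant repeats: a
short onset "transition zone" where repeat units are interleaved with
scrubbed spacers (emulating the gradual subtelomere-to-telomere transition
seen in real reads) followed by a dense, near-contiguous repeat zone; the
drawn density target applies region-wide.  Substitution and indel errors
are injected uniformly (repeat copies are not protected) and truth
coordinates are remapped through every indel, so the sidecar truth refers
to the read as "sequenced", exactly like a manually annotated read.

Artifact read classes mirror the failure modes the pipeline filters:
proximally truncated reads, tandem probes, probe-absent reads, low-quality
mid-telomere artifact blocks, subtelomeric telomere-like islands, and
chimeric (mixed-strand) reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .motif_model import MotifSet, build_motif_set, revcomp, scan_motifs
from .probe_demux import SampleSheet
from .read_io import GroundTruth, ReadRecord, write_fastq, write_truth

__all__ = [
    "DEFAULT_PROBE",
    "ArtifactRates",
    "SimSpec",
    "scrub_subtelomere",
    "generate_read",
    "generate_cohort",
    "write_cohort",
]

#: synthetic stand-in for an enrichment capture probe (12 nt, motif-free);
#: real analyses supply their own probe sequence
DEFAULT_PROBE = "AGCATCGGAACT"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ArtifactRates:
    """Per-read probabilities of artifact classes (mutually exclusive draw)."""

    truncated_start: float = 0.0
    tandem_probe: float = 0.0
    probe_absent: float = 0.0
    mid_telomere_artifact: float = 0.0
    subtel_island: float = 0.0
    chimeric: float = 0.0

    def __post_init__(self):
        vals = asdict(self)
        if any(not 0.0 <= v <= 1.0 for v in vals.values()):
            raise ValueError("artifact rates must be probabilities")
        if sum(vals.values()) > 1.0:
            raise ValueError("artifact rates must sum to <= 1")


@dataclass
class SimSpec:
    """Study conditions for a simulated cohort.

    Defaults reproduce the boundary-accuracy truth-set experiment: 400
    reads, 2-5 kb scrubbed subtelomere, 0.3-3 kb VRR at 80-95% telomere+1N
    coverage, 1-8 kb invariant telomere, a 12-nt probe, 1% substitutions
    and 0.2% indels, both strands equally likely, no artifact classes.
    """

    n_reads: int = 400
    seed: int = 0
    canonical: str = "GGTTAG"
    subtel_len_range: tuple = (2000, 5000)
    vrr_len_range: tuple = (300, 3000)
    vrr_density_range: tuple = (0.80, 0.95)
    tel_len_distribution: tuple = ("uniform", (1000, 8000))
    probe: str | None = DEFAULT_PROBE
    barcode_sheet: SampleSheet | None = None
    strand_mix: float = 0.5  # fraction of reads emitted on the G strand
    error_rates: tuple = (0.01, 0.001, 0.001)  # substitution, insertion, deletion
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    mutant: tuple = ()
    mutant_tail_frac: float = 0.3  # distal telomere fraction built from mutant motifs
    variant_fraction: float = 0.6  # VRR units drawn as variants (vs canonical)

    def __post_init__(self):
        for lo, hi in (self.subtel_len_range, self.vrr_len_range):
            if not 0 < lo < hi:
                raise ValueError("length ranges must be non-degenerate")
        lo, hi = self.vrr_density_range
        if not 0.0 < lo < hi <= 1.0:
            raise ValueError("vrr_density_range must be a sub-interval of (0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.error_rates):
            raise ValueError("error rates must be probabilities")
        if not 0.0 <= self.strand_mix <= 1.0:
            raise ValueError("strand_mix must be in [0, 1]")
        family, _ = self.tel_len_distribution
        if family not in ("uniform", "lognormal"):
            raise ValueError(f"unknown telomere length distribution {family!r}")
        if self.probe is None and self.tel_len_distribution[1][0] <= 0:
            raise ValueError("zero-length telomere without a probe is degenerate")

    def motifs(self) -> MotifSet:
        return build_motif_set(self.canonical, self.mutant or None)


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def scrub_subtelomere(seq: str, motifs: MotifSet, max_iter: int = 100) -> str:
    """Destroy every telomere+1N match in ``seq``.

    Each matched window is overwritten with a position-phased CA filler
    (deterministic, so scrubbing is idempotent) and the scan repeats until
    a fixpoint with zero matches is reached.  One base change would not be
    enough: a canonical hit is still a variant after any single edit.
    """
    s = list(seq)
    for _ in range(max_iter):
        hits = scan_motifs("".join(s), motifs, include_variants=True, include_mutant=True)
        if not hits:
            return "".join(s)
        for h in hits:
            for p in range(h.start, h.end):
                s[p] = "CA"[p % 2]
    raise RuntimeError("scrub did not converge; filler collides with motif set")


def _draw_len(dist: tuple, rng: np.random.Generator) -> int:
    family, params = dist
    if family == "uniform":
        lo, hi = params
        return int(rng.integers(lo, hi + 1))
    mean, sigma = params  # lognormal parametrized by mean/sd in bases
    mu = np.log(mean**2 / np.sqrt(sigma**2 + mean**2))
    s = np.sqrt(np.log(1 + sigma**2 / mean**2))
    return max(1, int(rng.lognormal(mu, s)))


def _vrr_units(motifs: MotifSet, rng: np.random.Generator, variant_fraction: float):
    """One VRR repeat unit: variant (substitutions preferred) or canonical."""
    canon = motifs.canonical
    subs = sorted(v for v in motifs.variants_g if len(v) == len(canon) and v != canon)
    indels = sorted(v for v in motifs.variants_g if len(v) != len(canon))
    while True:
        if rng.random() < variant_fraction:
            pool = subs if rng.random() < 0.8 else indels
            yield pool[rng.integers(len(pool))]
        else:
            yield canon


def _build_vrr(
    length: int,
    density: float,
    motifs: MotifSet,
    rng: np.random.Generator,
    variant_fraction: float,
) -> str:
    """VRR block of ~``length`` bases, variant-rich with a graded onset.

    Transition zone (first ~20% of the region, 60-400 bases): repeat units
    interleaved with scrubbed spacers at the drawn onset density.  Dense
    zone: a near-contiguous repeat array (coverage ~0.98) with occasional
    degenerate interruptions, the way telomeric repeat arrays actually run
    once the transition is past.  The block always begins with a repeat
    unit, so the true VRR start is its first base.
    """
    trans_len = int(np.clip(0.2 * length, 60, 400))
    trans_len = min(trans_len, length)
    d_trans = density
    dense_len = length - trans_len
    d_dense = 0.98
    units = _vrr_units(motifs, rng, variant_fraction)

    def _zone(target_len: int, d: float, first_unit: bool) -> str:
        parts = []
        total = 0
        q = (1 - d) / d if d < 1 else 0.0
        mean_unit = len(motifs.canonical)
        first = first_unit
        while total < target_len:
            u = next(units)
            parts.append(u)
            total += len(u)
            # expected spacer bases per unit = q * unit length
            if not first and q > 0 and rng.random() < q * mean_unit / 8.0:
                sp = scrub_subtelomere(_random_seq(int(rng.integers(4, 13)), rng), motifs)
                parts.append(sp)
                total += len(sp)
            first = False
        return "".join(parts)

    return _zone(trans_len, d_trans, True) + (
        _zone(dense_len, d_dense, False) if dense_len > 0 else ""
    )


def _build_telomere(length: int, spec: SimSpec, rng: np.random.Generator) -> str:
    canon = spec.canonical
    n_units = max(1, length // len(canon))
    if spec.mutant:
        n_mut = int(n_units * spec.mutant_tail_frac)
        mut = [str(spec.mutant[rng.integers(len(spec.mutant))]) for _ in range(n_mut)]
        return canon * (n_units - n_mut) + "".join(mut)
    return canon * n_units


def _apply_errors(seq: str, rng: np.random.Generator, rates: tuple):
    """Inject substitutions/insertions/deletions; return (read, pos_map).

    ``pos_map[i]`` is the read coordinate of template position ``i``
    (``pos_map[len(seq)]`` is the read length), so truth annotations stay
    exact through indels.
    """
    p_sub, p_ins, p_del = rates
    n = len(seq)
    out = []
    pos_map = np.empty(n + 1, dtype=np.int64)
    draws = rng.random((n, 2))
    for i, b in enumerate(seq):
        pos_map[i] = len(out)
        r = draws[i, 0]
        if r < p_del:
            pass
        elif r < p_del + p_sub:
            alt = "ACGT"[rng.integers(4)]
            while alt == b:
                alt = "ACGT"[rng.integers(4)]
            out.append(alt)
        else:
            out.append(b)
        if draws[i, 1] < p_ins:
            out.append("ACGT"[rng.integers(4)])
    pos_map[n] = len(out)
    return "".join(out), pos_map


def _qualities(
    n: int, rng: np.random.Generator, low_ranges: list[tuple[int, int]]
) -> np.ndarray:
    base = int(rng.integers(12, 21))
    q = np.clip(np.rint(rng.normal(base, 3.0, size=n)), 2, 40).astype(np.uint8)
    for lo, hi in low_ranges:
        lo, hi = max(0, lo), min(n, hi)
        if hi > lo:
            q[lo:hi] = rng.integers(4, 10, size=hi - lo)
    return q


def _draw_class(rates: ArtifactRates, rng: np.random.Generator) -> str:
    classes = list(asdict(rates).items())
    r = rng.random()
    acc = 0.0
    for name, p in classes:
        acc += p
        if r < acc:
            return name
    return "normal"


def generate_read(
    spec: SimSpec, rng: np.random.Generator, read_id: str = "sim-read"
) -> tuple[ReadRecord, GroundTruth]:
    """One simulated read plus its ground truth (positions in G orientation)."""
    motifs = spec.motifs()
    canon = spec.canonical
    cls = _draw_class(spec.artifact_rates, rng)
    low_q: list[tuple[int, int]] = []  # template ranges with artifact-grade quality

    if cls == "chimeric":
        # two molecules of opposite strand fused: mixed G/C repeat content
        frac = rng.uniform(0.3, 0.7)
        total_units = int(rng.integers(60, 160))
        n_g = max(1, int(total_units * frac))
        n_c = max(1, total_units - n_g)
        flank = scrub_subtelomere(
            _random_seq(int(rng.integers(300, 1200)), rng), motifs
        )
        template = flank + canon * n_g + revcomp(canon * n_c)
        if spec.probe:
            template += spec.probe
        vrr_t = probe_t = None
    else:
        subtel_len = int(rng.integers(*spec.subtel_len_range))
        vrr_len = int(rng.integers(*spec.vrr_len_range))
        density = float(rng.uniform(*spec.vrr_density_range))
        tel_len = _draw_len(spec.tel_len_distribution, rng)
        if cls == "mid_telomere_artifact":
            tel_len = max(tel_len, 2500)  # room for an interior artifact block

        subtel = scrub_subtelomere(_random_seq(subtel_len, rng), motifs)
        if cls == "subtel_island":
            # telomere-like island well upstream of the true boundary
            island = _build_vrr(150, 0.70, motifs, rng, spec.variant_fraction)
            at = int(rng.integers(200, max(201, subtel_len - 700)))
            subtel = subtel[:at] + island + subtel[at:]
        vrr = _build_vrr(vrr_len, density, motifs, rng, spec.variant_fraction)
        tel = _build_telomere(tel_len, spec, rng)
        if cls == "mid_telomere_artifact" and len(tel) > 2000:
            # low-quality non-repeat block emulating a basecalling artifact
            block = scrub_subtelomere(
                _random_seq(int(rng.integers(500, 1000)), rng), motifs
            )
            at = int(rng.integers(500, len(tel) - 1000))
            low_q.append((len(subtel) + len(vrr) + at, len(subtel) + len(vrr) + at + len(block)))
            tel = tel[:at] + block + tel[at:]

        if cls == "truncated_start":
            # read begins inside the VRR / repeat array: no usable boundary
            cut = len(vrr) // 2
            template = vrr[cut:] + tel
            vrr_t = None
        else:
            template = subtel + vrr + tel
            # truth = first telomere+1N repeat at the junction; the base
            # preceding the first unit can extend it into an insertion
            # variant, so scan the junction rather than trusting block
            # arithmetic (this is what a manual annotator would mark)
            nominal = len(subtel)
            lo = max(0, nominal - 7)
            local = scan_motifs(template[lo : nominal + 14], motifs)
            vrr_t = lo + local[0].start if local else nominal

        if spec.probe and cls != "probe_absent":
            probe_t = len(template)
            template += spec.probe
            if cls == "tandem_probe":
                template += spec.probe
        else:
            probe_t = None

    barcode = None
    if spec.barcode_sheet is not None and spec.barcode_sheet.entries:
        idx = int(rng.integers(len(spec.barcode_sheet.entries)))
        _, barcode = spec.barcode_sheet.entries[idx]
        template += barcode
    # short scrubbed tail (adapter remnant)
    tail = scrub_subtelomere(_random_seq(int(rng.integers(0, 31)), rng), motifs)
    template += tail

    read_seq, pos_map = _apply_errors(template, rng, spec.error_rates)
    quals = _qualities(
        len(read_seq), rng, [(int(pos_map[a]), int(pos_map[b])) for a, b in low_q]
    )
    vrr_start = int(pos_map[vrr_t]) if vrr_t is not None else None
    probe_start = int(pos_map[probe_t]) if probe_t is not None else None

    strand = "G" if rng.random() < spec.strand_mix else "C"
    if strand == "C":
        read_seq = revcomp(read_seq)
        quals = quals[::-1].copy()

    rec = ReadRecord(read_id, read_seq, quals)
    truth = GroundTruth(
        read_id=read_id,
        true_strand=strand,
        true_vrr_start=vrr_start,
        true_probe_start=probe_start,
        true_barcode=barcode,
        read_class=cls,
    )
    return rec, truth


def generate_cohort(spec: SimSpec) -> tuple[list[ReadRecord], list[GroundTruth]]:
    """Deterministic cohort of ``spec.n_reads`` reads from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    records, truths = [], []
    for i in range(spec.n_reads):
        rec, truth = generate_read(spec, rng, read_id=f"sim-{i:06d}")
        records.append(rec)
        truths.append(truth)
    return records, truths


def write_cohort(spec: SimSpec, outdir) -> tuple[Path, Path]:
    """Write the cohort as FASTQ.gz plus a ground-truth TSV sidecar.

    A fixed seed gives byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truths = generate_cohort(spec)
    fq = outdir / "reads.fastq.gz"
    tsv = outdir / "truth.tsv"
    write_fastq(fq, records)
    write_truth(tsv, truths)
    return fq, tsv
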