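# Methods

## The telomere+1N alphabet

All stages measure repeat content over the *telomere+1N* motif set: the
canonical repeat (default `GGTTAG`), its reverse complement, and every
string within Levenshtein distance 1 (18 substitutions, 4 distinct
deletions, 22 distinct insertions for `GGTTAG`; duplicates from the GG/TT
doublets collapse). The full edit-distance-1 neighborhood is used for
insertions — all four bases at every gap position — rather than only
duplications; one-edit variants are how both true variant repeats and
single basecalling errors present, and the distinction is not recoverable
read-locally.

Scanning is greedy, left-to-right, non-overlapping. At each position the
canonical repeat is tried first, then mutant motifs, then variants
longest-first. Canonical-first (rather than longest-first) matters: any
base `X` directly before a canonical copy forms the insertion variant
`X+GGTTAG`, so a longest-first rule would re-read pure repeat arrays as
chains of 7-mer variants and erase the canonical/variant distinction that
the boundary caller and the wild-type-repeat statistics rely on. A
consequence worth knowing: the single base preceding a repeat block is
genuinely part of a one-edit insertion variant, so "first telomere+1N
repeat" can begin one base before the first full repeat unit. `N` never
matches.

Windowed "percent telomere+1N" is defined as the percent of window *bases*
covered by matched motifs, not a motif count — fractional counts are
ill-defined when variants are 5–7 bp long — and is therefore monotone in
[0, 100]. Final windows shorter than the window size are dropped, not
rescaled, to avoid inflated percentages at read ends.

## Stage thresholds

All thresholds follow the validated defaults and are strict inequalities:

| stage       | parameter                    | default     |
|-------------|------------------------------|-------------|
| isolation   | canonical repeats (either strand) | ≥ 10   |
| strand      | chimeric band of G-strand fraction | [0.20, 0.80] (closed) |
| probe       | Hamming errors / repeat gate | 2 errors, after 20 repeats |
| truncation  | telomere+1N in first 300 bp  | > 20% fails |
| boundary    | primary / secondary / rescue | 60% / 5% / 15 windows |
| content     | telomere+1N in telomere      | < 60% fails |
| upstream    | telomere+1N in 2 kb upstream | > 10% fails |

The chimeric band is closed: a read at exactly 20% or 80% G-strand content
is ambiguous and conservatively removed. Isolation counts canonical
repeats only (variants excluded) — the stricter reading — because variant
density in non-telomeric sequence would otherwise inflate counts under
noisy basecalling. Probe and barcode "errors" are substitutions only
(Hamming distance): reproducible, fast, and matching the mismatch budget
the probe length was validated with; indel-tolerant matching for long
probes is a possible extension.

## Boundary detection

The dual-threshold jumping window (100 bp window, 15 bp step — the 15 bp
step is slightly more precise than 10 bp and cheaper; 10 remains an
option) proposes the start of the variant repeat-rich (VRR) region at the
first telomere+1N hit whose start lies at or after the first window
reaching 60% coverage (hits straddling the window's left edge are
excluded). The candidate is invalidated only by ≥ 15 *consecutive*
windows (≈ 225 bp at defaults; counted in windows, not bases) below 5%
before the probe; shorter dips — real telomeres do dip — are tolerated.
After an invalidating run, scanning resumes past the run, so a read whose
telomere lies beyond a subtelomeric telomere-like island or an artifact
block can still be called; such displaced calls are then what the 2 kb
upstream filter removes. When a probe was found, windows are evaluated
only on `[0, probe_start)`.

The two benchmarking strategies: *single-threshold* requires every window
from the trigger to the probe to stay ≥ 60%, so any later dip pushes the
trigger past it; *consecutive-repeats* returns the first run of eight
back-to-back telomere+1N hits (each starting where the previous ended).

Telomere length is `probe_start − vrr_start` in 0-based half-open
coordinates; mean telomere quality is the arithmetic mean Phred over that
interval; `wt_repeat_bases` counts bases covered by canonical hits only,
enabling the wild-type-only length comparison.

## The simulator

`telotide.simulate` generates reads with the enrichment library structure
`[subtelomere][VRR][invariant telomere][probe][barcode?]` in G orientation,
optionally reverse-complemented, with a ground-truth sidecar. Study
conditions (the defaults): 400 reads, subtelomere 2–5 kb, VRR 0.3–3 kb,
invariant telomere uniform 1–8 kb, a 12-nt motif-free synthetic probe,
substitution/insertion/deletion rates 1% / 0.1% / 0.1%, both strands
equally likely, no artifact classes.

Design choices that matter:

* **Scrubbed subtelomere.** Random sequence is *scrubbed* of every
  telomere+1N match (matched windows overwritten with a position-phased CA
  filler, iterated to a fixpoint), so before noise injection nothing
  upstream of the VRR can trigger the caller and the recorded truth is
  exact by construction.
* **Graded VRR onset.** The VRR opens with a transition zone (20% of the
  region, 60–400 bp) where repeat units — 60% one-edit variants
  (substitutions preferred 4:1 over indels), 40% canonical — are
  interleaved with short scrubbed spacers at the drawn onset density
  (uniform 0.80–0.95), then continues as a near-contiguous array
  (coverage ≈ 0.98) with occasional degenerate interruptions. Real
  telomeric repeat arrays are contiguous once past the transition; the
  degenerate, lower-density sequence sits at the subtelomere junction.
  The drawn density parameter therefore governs the onset, and region-wide
  coverage is at least the drawn value.
* **Truth by annotation, not arithmetic.** The recorded VRR start is the
  first telomere+1N repeat at the junction of the error-free template
  (which may begin one base before the first unit, see above), then
  remapped through every injected indel — exactly what a manual annotator
  marking the read as sequenced would produce.
* **Errors are not motif-aware.** Substitutions and indels hit repeat
  copies too; only the subtelomere is scrubbed *before* noise, so residual
  upstream telomere+1N matches arise from noise alone.
* **Qualities.** Per-read baseline Phred drawn from 12–20 with ±3
  per-base jitter; artifact blocks are drawn at Phred 4–9, emulating the
  reduced quality of basecalling-artifact stretches.
* **Artifact classes** (mutually exclusive per-read draw): proximally
  truncated reads (begin mid-VRR; truth carries no start), tandem probes,
  probe-absent reads (duplex-enrichment G strands), low-quality
  mid-telomere artifact blocks (500–1000 bp scrubbed, low quality —
  removed downstream by the upstream filter), subtelomeric telomere-like
  islands, and chimeric mixed-strand fusions.

What the simulator does **not** emulate: sequence-dependent error
profiles, homopolymer-specific miscalls, real subtelomeric repeat families
(it uses motif-free random sequence), chromosome-arm identity, or raw
signal. Passing tests therefore demonstrate the pipeline's logic —
stage ordering, thresholds, boundary semantics, coordinate bookkeeping —
under calibrated noise, not performance on any particular biological
sample.

## Problem sizes and numerics

The boundary-accuracy experiment uses a 400-read cohort (the size of a
manually annotated truth set this experiment mirrors); property tests use
100–300 reads and the oracle-equivalence suite uses ≤ 200 bp instances
where brute force is exhaustive. On this cohort the dual-threshold
detector's mean absolute error is ~1 nt with > 95% of reads called, errors
skewed toward slight telomere-length overestimation (noise-induced variant
hits just upstream of the true start, within one trigger window).

Degenerate inputs: empty sequences scan to empty hit lists; reads shorter
than one window receive no boundary call with a recorded reason; an
upstream span truncated by the read start is evaluated on the available
prefix (the truncation filter already guards short subtelomeres); barcode
ties leave a read unassigned rather than arbitrarily assigned; zero reads
surviving isolation completes with empty outputs and a warning.

The per-arm uniform expectation for a diploid human (100/92 %) is reported
truncated to two decimals (1.08%), matching the convention used in
published per-arm distribution plots; the exact fraction is available for
arithmetic.

## Known limitations

* Organisms with heterogeneous telomeric repeats (e.g. *S. pombe*) are out
  of scope; the motif model assumes a single canonical repeat.
* Probe matching is substitution-only; a probe disrupted by an indel is
  lost (~2% of reads at 0.2% indel rate with a 12-nt probe), which is the
  dominant source of uncalled reads in clean simulations.
* The upstream filter removes genuinely repeat-rich subtelomeric structure
  (a known, accepted loss of a few percent of reads).
* Chromosome-arm assignment and clustering are external: the pipeline
  prepares boundary-trimmed FASTA but does not align or cluster.
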