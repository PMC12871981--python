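# telotide

Per-read telomere length estimation from Oxford Nanopore long reads.

Telomeres — `GGTTAG`-repeat arrays capping human chromosomes — can now be
sequenced end-to-end on nanopore platforms after enrichment protocols that
ligate a short capture probe to the distal telomere end. Turning those reads
into trustworthy per-molecule telomere lengths requires solving several
problems at once: picking the few telomeric reads out of a mostly genomic
library, handling reads from either strand, confirming each telomere was
sequenced to its very end, finding where the chromosome-specific subtelomere
gives way to telomeric repeats, and discarding reads corrupted by
basecalling artifacts. `telotide` implements that full analysis path for
researchers and clinicians working with telomere-enriched nanopore
libraries, together with a synthetic read simulator that makes every stage
testable offline with exact ground truth.

## Method

Reads flow through a fixed stage order; every read appears once in the
output with either its metrics or the first stage that removed it:

1. **Isolation** — keep reads with ≥ 10 non-consecutive copies of the
   canonical repeat (`GGTTAG`/`CTAACC`, both strands counted).
2. **Strand** — from the fraction *g* of canonical hits on the G strand:
   *g* < 0.20 → C-strand read, *g* > 0.80 → G-strand read,
   *g* ∈ [0.20, 0.80] → chimeric, removed. C reads are reverse-complemented
   into G orientation (original strand kept as a BAM tag). A
   `--c-strand-only` mode for splint-enriched libraries removes everything
   with *g* > 0.20.
3. **Capture probe** — Hamming matching of the probe (≤ 2 mismatches for a
   12-nt probe); a hit is accepted only after 20 telomeric repeats have been
   seen, which suppresses chance subtelomeric matches. Tandemly ligated
   probes fold into one hit. The probe start is the telomere's distal end.
   Barcodes in the 100 bp after the probe demultiplex pooled samples.
4. **Truncation filter** — reads whose first 300 bp (subtelomeric end)
   carry > 20% telomere+1N content begin inside the repeat array and are
   removed as proximally truncated.
5. **Boundary** — the telomere start is the start of the variant repeat-rich
   (VRR) region, detected with a dual-threshold jumping window over
   *telomere+1N* coverage (all motifs within one edit of the canonical
   repeat): scanning 100 bp windows in 15 bp steps, the first window ≥ 60%
   proposes the first telomere+1N repeat in that window as the start; the
   candidate is rejected only if coverage later stays < 5% for ≥ 15
   consecutive windows (short dips are tolerated; after a long collapse the
   scan re-triggers). Single-threshold and eight-consecutive-repeat
   strategies are included for benchmarking.
6. **Content filter** — the called telomere `[vrr_start, probe_start)` must
   hold ≥ 60% telomere+1N content.
7. **Upstream filter** — the 2 kb upstream of the called start must hold
   ≤ 10% telomere+1N content, catching starts displaced by low-quality
   artifact blocks.

Telomere length is `probe_start − vrr_start` (0-based, half-open). Optional
modes: mutant-repeat tracking (`--mutant`), restriction-site counting
(`--restriction-digest`), per-strand comparison, and trimming around the
boundary for external clustering tools.

## Worked example

Simulate a 100-read telomere-enriched cohort and analyze it:

```bash
telotide simulate --out demo/sim --n 100 --seed 7
telotide run demo/sim/reads.fastq.gz -o demo/out --probe AGCATCGGAACT
```

which prints:

```
isolation: entered 100, passed 100, failed 0
strand: entered 100, passed 100, failed 0
probe: entered 100, passed 99, failed 1
truncation: entered 99, passed 99, failed 0
boundary: entered 99, passed 99, failed 0
content: entered 99, passed 99, failed 0
upstream: entered 99, passed 99, failed 0
99 high-confidence telomeric reads -> demo/out
```

One read lost its probe to indel noise; the other 99 pass every filter.
`demo/out/summary.tsv` then reports the per-sample length distribution —
here mean 5958 nt, median 5951 nt (sd 2086) at mean telomere quality Q16.3,
from 52 C-strand and 47 G-strand reads — and `demo/out/` also holds the
per-read table (`per_read.tsv`), the stage ledger (`ledger.tsv`), a tagged
unaligned BAM (`XS` strand, `XV` VRR start, `XP` probe start, `XL` length,
`XQ` mean quality, `XM` sample), boundary-trimmed FASTA for clustering, a
length histogram, and an HTML report.

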