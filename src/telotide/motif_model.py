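"""Telomeric motif alphabet and windowed repeat-coverage profiles.

The telomere start caller works on the "telomere+1N" alphabet: the canonical
repeat (human G-strand default ``GGTTAG``), its reverse complement, and every
string within Levenshtein distance 1 of the canonical repeat (single-base
substitutions, insertions, and deletions).  Variant repeats of this kind are
abundant at the subtelomere-to-telomere transition (the variant repeat-rich,
or VRR, region) and their windowed density is the signal every downstream
stage consumes.

All scanning is greedy, left-to-right, and non-overlapping: at each position
the longest matching motif wins, with canonical preferred over mutant and
mutant over variant at equal length.  This makes hit sets deterministic and
windowed percentages well defined in [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "InvalidMotifError",
    "MotifSet",
    "MotifHit",
    "RepeatProfile",
    "revcomp",
    "build_motif_set",
    "scan_motifs",
    "coverage_mask",
    "coverage_profile",
    "profile_from_mask",
    "region_pct",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = "ACGT"


class InvalidMotifError(ValueError):
    """Raised when a motif contains characters outside A/C/G/T."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_motif(motif: str, what: str = "motif") -> None:
    if not motif or any(b not in _BASES for b in motif):
        raise InvalidMotifError(
            f"{what} must be a non-empty uppercase A/C/G/T string, got {motif!r}"
        )


def _edit1_neighborhood(motif: str) -> frozenset[str]:
    """All strings within edit distance 1 of ``motif`` (including itself)."""
    out = {motif}
    for i in range(len(motif)):
        for b in _BASES:
            out.add(motif[:i] + b + motif[i + 1 :])
        out.add(motif[:i] + motif[i + 1 :])
    for i in range(len(motif) + 1):
        for b in _BASES:
            out.add(motif[:i] + b + motif[i:])
    return frozenset(out)


@dataclass(frozen=True)
class MotifSet:
    """The telomeric repeat alphabet on both strands.

    Attributes
    ----------
    canonical : str
        G-strand repeat (default ``GGTTAG``).
    complement : str
        Reverse complement of ``canonical`` (the C-strand repeat).
    variants_g : frozenset[str]
        Full edit-distance-1 neighborhood of ``canonical`` (telomere+1N),
        canonical included.
    variants_c : frozenset[str]
        Reverse complements of ``variants_g``.
    mutant : frozenset[str]
        Optional mutant repeats (e.g. a telomerase RNA template mutation)
        treated as telomeric when mutant mode is on.
    """

    canonical: str
    complement: str
    variants_g: frozenset
    variants_c: frozenset
    mutant: frozenset


def build_motif_set(canonical: str = "GGTTAG", mutant=None) -> MotifSet:
    """Build the telomere+1N motif set for ``canonical``.

    Parameters
    ----------
    canonical : str
        The wild-type telomeric repeat in G-strand orientation.
    mutant : iterable of str, optional
        Mutant repeat motifs to track separately (mutant mode).
    """
    _check_motif(canonical, "canonical motif")
    mutant = frozenset(mutant or ())
    for m in mutant:
        _check_motif(m, "mutant motif")
    variants_g = _edit1_neighborhood(canonical)
    variants_c = frozenset(revcomp(v) for v in variants_g)
    return MotifSet(
        canonical=canonical,
        complement=revcomp(canonical),
        variants_g=variants_g,
        variants_c=variants_c,
        mutant=mutant,
    )


@dataclass(frozen=True)
class MotifHit:
    """One non-overlapping motif match.

    ``kind`` is ``canonical``, ``variant`` or ``mutant``; ``strand`` is ``G``
    or ``C`` depending on which strand's motif matched.
    """

    start: int
    length: int
    kind: str
    strand: str

    @property
    def end(self) -> int:
        return self.start + self.length


@lru_cache(maxsize=32)
def _lookup_tiers(motifs: MotifSet, include_variants: bool, include_mutant: bool):
    """Tiered lookup: canonical, then mutant, then variants.

    Each tier maps motif string -> (kind, strand) and carries its length
    set in descending order; earlier tiers take precedence regardless of
    match length, so a canonical repeat is never re-read as a longer
    insertion variant.
    """
    tiers = []
    canonical = {
        motifs.canonical: ("canonical", "G"),
        motifs.complement: ("canonical", "C"),
    }
    tiers.append(canonical)
    if include_mutant and motifs.mutant:
        mut: dict[str, tuple[str, str]] = {}
        for m in motifs.mutant:
            mut.setdefault(revcomp(m), ("mutant", "C"))
        for m in motifs.mutant:
            mut[m] = ("mutant", "G")
        tiers.append(mut)
    if include_variants:
        var: dict[str, tuple[str, str]] = {}
        for v in motifs.variants_c:
            var[v] = ("variant", "C")
        for v in motifs.variants_g:
            var[v] = ("variant", "G")
        tiers.append(var)
    return tuple(
        (t, tuple(sorted({len(k) for k in t}, reverse=True))) for t in tiers
    )


def scan_motifs(
    seq: str,
    motifs: MotifSet,
    include_variants: bool = True,
    include_mutant: bool = False,
) -> list[MotifHit]:
    """Greedy non-overlapping left-to-right motif scan.

    At each position the canonical repeat is tried first, then mutant
    motifs, then variant motifs longest-first; the first match wins and
    the scan jumps past it.  ``N`` never matches.
    """
    tiers = _lookup_tiers(motifs, include_variants, include_mutant)
    hits: list[MotifHit] = []
    n = len(seq)
    i = 0
    while i < n:
        matched = False
        for table, lengths in tiers:
            for L in lengths:
                if i + L <= n:
                    entry = table.get(seq[i : i + L])
                    if entry is not None:
                        hits.append(MotifHit(i, L, entry[0], entry[1]))
                        i += L
                        matched = True
                        break
            if matched:
                break
        if not matched:
            i += 1
    return hits


def coverage_mask(seq_len: int, hits: list[MotifHit]) -> np.ndarray:
    """Boolean per-base mask: True where a motif hit covers the base."""
    mask = np.zeros(seq_len, dtype=bool)
    for h in hits:
        mask[h.start : h.end] = True
    return mask


def region_pct(mask: np.ndarray, start: int, end: int) -> float:
    """Percent of bases in [start, end) covered by motif hits.

    Empty regions report 0.0.
    """
    start = max(0, start)
    end = min(len(mask), end)
    if end <= start:
        return 0.0
    return 100.0 * float(mask[start:end].sum()) / (end - start)


@dataclass
class RepeatProfile:
    """Windowed telomere+1N coverage percentages along a read.

    ``coverage_pct[i]`` is the percent of bases of the window starting at
    ``window_starts[i]`` covered by motif hits.  Windows never extend past
    the sequence end; a sequence shorter than one window yields a single
    truncated window with ``truncated=True`` (percentage over the available
    bases).
    """

    window_size: int
    step: int
    window_starts: np.ndarray
    coverage_pct: np.ndarray
    truncated: bool = False


def profile_from_mask(
    mask: np.ndarray, window_size: int = 100, step: int = 15, limit: int | None = None
) -> RepeatProfile:
    """Jumping-window coverage profile from a per-base mask.

    ``limit`` restricts the profiled region to ``[0, limit)`` (used to stop
    at the capture probe).  Final windows shorter than ``window_size`` are
    dropped, not rescaled.
    """
    n = len(mask) if limit is None else min(limit, len(mask))
    if n < window_size:
        if n == 0:
            return RepeatProfile(
                window_size, step, np.array([], dtype=int), np.array([]), truncated=True
            )
        pct = 100.0 * float(mask[:n].sum()) / n
        return RepeatProfile(
            window_size, step, np.array([0]), np.array([pct]), truncated=True
        )
    csum = np.concatenate(([0], np.cumsum(mask[:n], dtype=np.int64)))
    starts = np.arange(0, n - window_size + 1, step)
    counts = csum[starts + window_size] - csum[starts]
    pct = 100.0 * counts / window_size
    return RepeatProfile(window_size, step, starts, pct, truncated=False)


def coverage_profile(
    seq: str,
    motifs: MotifSet,
    window_size: int = 100,
    step: int = 15,
    include_mutant: bool = False,
) -> RepeatProfile:
    """Windowed percent of bases covered by telomere+1N hits.

    Precondition: ``window_size`` at least the canonical motif length and
    ``step >= 1``.
    """
    if window_size < len(motifs.canonical):
        raise ValueError("window_size must be >= canonical motif length")
    if step < 1:
        raise ValueError("step must be >= 1")
    hits = scan_motifs(seq, motifs, include_variants=True, include_mutant=include_mutant)
    return profile_from_mask(coverage_mask(len(seq), hits), window_size, step)
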