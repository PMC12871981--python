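"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive and structurally unrelated to the
package code: edit distance by textbook dynamic programming, motif
membership decided by recomputing edit distance (not by enumerating a
neighborhood), coverage by per-base loops, and searches by scanning every
window.
"""

from __future__ import annotations


def edit_distance(a: str, b: str) -> int:
    """Textbook DP Levenshtein distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def brute_scan(seq, canonical, include_variants=True, mutant=()):
    """Reference greedy scanner.

    At each position: canonical (exact equality, G then C), then mutant
    motifs, then variant membership decided by computing edit distance
    (== 1, no N) for window lengths L+1, L, L-1, longest first.  Returns
    (start, length, kind, strand) tuples.
    """
    comp = _revcomp(canonical)
    L = len(canonical)
    hits = []
    i = 0
    n = len(seq)
    while i < n:
        w = seq[i : i + L]
        if w == canonical:
            hits.append((i, L, "canonical", "G"))
            i += L
            continue
        if w == comp:
            hits.append((i, L, "canonical", "C"))
            i += L
            continue
        matched = False
        for m in mutant:
            for cand, strand in ((m, "G"), (_revcomp(m), "C")):
                if seq[i : i + len(cand)] == cand:
                    hits.append((i, len(cand), "mutant", strand))
                    i += len(cand)
                    matched = True
                    break
            if matched:
                break
        if matched:
            continue
        if include_variants:
            for Lv in (L + 1, L, L - 1):
                w = seq[i : i + Lv]
                if len(w) < Lv or "N" in w:
                    continue
                if edit_distance(w, canonical) == 1:
                    hits.append((i, Lv, "variant", "G"))
                    i += Lv
                    matched = True
                    break
                if edit_distance(w, comp) == 1:
                    hits.append((i, Lv, "variant", "C"))
                    i += Lv
                    matched = True
                    break
        if not matched:
            i += 1
    return hits


def brute_coverage_mask(seq_len: int, hits) -> list[bool]:
    mask = [False] * seq_len
    for start, length, *_ in hits:
        for p in range(start, start + length):
            mask[p] = True
    return mask


def brute_window_pct(mask, window_size, step):
    """(window_start, percent covered) for every full window."""
    out = []
    for s in range(0, len(mask) - window_size + 1, step):
        covered = sum(1 for p in range(s, s + window_size) if mask[p])
        out.append((s, 100.0 * covered / window_size))
    return out


def naive_exact_search(seq: str, pattern: str) -> list[int]:
    return [
        i for i in range(len(seq) - len(pattern) + 1) if seq[i : i + len(pattern)] == pattern
    ]


def naive_hamming_search(seq: str, pattern: str, max_errors: int):
    out = []
    m = len(pattern)
    for i in range(len(seq) - m + 1):
        errs = sum(1 for a, b in zip(seq[i : i + m], pattern) if a != b)
        if errs <= max_errors:
            out.append((i, errs))
    return out


def brute_first_run(hits, run_length: int):
    """Start of the first run of back-to-back hits, else None."""
    for i in range(len(hits)):
        end = hits[i][0] + hits[i][1]
        count = 1
        j = i + 1
        while j < len(hits) and hits[j][0] == end:
            end = hits[j][0] + hits[j][1]
            count += 1
            if count >= run_length:
                return hits[i][0]
            j += 1
        if count >= run_length:
            return hits[i][0]
    return None
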