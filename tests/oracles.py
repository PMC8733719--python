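"""Independent brute-force oracles for the search core.

Deliberately naive pure-python implementations, kept free of any code
from the package under test: plain string scanning over every window,
every strand and every single-gap placement.  The package's vectorized
scanners are asserted set-equal to these.
"""

from __future__ import annotations

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def naive_mismatch_search(records: dict[str, str], spacer: str, max_mm: int):
    """Set of (seq_id, strand, start, end, mm_positions) for NGG-adjacent
    windows within max_mm substitutions of the spacer (plus-strand coords)."""
    L = len(spacer)
    found = set()
    for seq_id, seq in records.items():
        n = len(seq)
        for strand, scan in (("+", seq), ("-", rc(seq))):
            for i in range(n - L - 2):
                pam = scan[i + L : i + L + 3]
                if pam[1:] != "GG":
                    continue
                mm = tuple(
                    j + 1 for j in range(L) if scan[i + j] != spacer[j]
                )
                if len(mm) <= max_mm:
                    if strand == "+":
                        start, end = i, i + L
                    else:
                        start, end = n - i - L, n - i
                    found.add((seq_id, strand, start, end, mm))
    return found


def naive_bulge_search(records: dict[str, str], spacer: str, max_mm: int):
    """Single-bulge oracle mirroring the documented preference rules.

    Tries every window and every internal single-gap placement (an extra
    genome base — dna — or a skipped genome base — rna), keeps sites
    with <= max_mm substitutions, drops sites that are mismatch-only
    reachable at <= max_mm, and keeps one interpretation per PAM
    position: fewest substitutions, then dna before rna, then leftmost
    gap.  Returns a set of (seq_id, strand, start, end, bulge_type,
    mm_count)."""
    L = len(spacer)
    mismatch_keys = {
        (seq_id, strand, end if strand == "+" else start - 3)
        for seq_id, strand, start, end, _ in naive_mismatch_search(
            records, spacer, max_mm
        )
    }
    candidates = {}
    for seq_id, seq in records.items():
        n = len(seq)
        for strand, scan in (("+", seq), ("-", rc(seq))):
            # dna bulge: site length L+1, skip genome base at k (internal)
            for i in range(n - L - 3):
                window = scan[i : i + L + 1]
                if scan[i + L + 2 : i + L + 4] != "GG":
                    continue
                for k in range(1, L):
                    aligned = window[:k] + window[k + 1 :]
                    mm = sum(1 for a, b in zip(aligned, spacer) if a != b)
                    if mm <= max_mm:
                        _keep(candidates, seq_id, strand, i, L + 1, n,
                              "dna", k, mm)
            # rna bulge: site length L-1, skip spacer base k (internal)
            for i in range(n - L - 1):
                window = scan[i : i + L - 1]
                if scan[i + L : i + L + 2] != "GG":
                    continue
                for k in range(1, L - 1):
                    aligned = spacer[:k] + spacer[k + 1 :]
                    mm = sum(1 for a, b in zip(window, aligned) if a != b)
                    if mm <= max_mm:
                        _keep(candidates, seq_id, strand, i, L - 1, n,
                              "rna", k, mm)
    out = set()
    for (seq_id, strand, pam_scan_start), (btype, k, mm, i, site_len, n) in (
        candidates.items()
    ):
        if strand == "+":
            start, end = i, i + site_len
            pam_start = end
        else:
            start, end = n - i - site_len, n - i
            pam_start = start - 3
        if (seq_id, strand, pam_start) in mismatch_keys:
            continue
        out.add((seq_id, strand, start, end, btype, mm))
    return out


_TYPE_RANK = {"dna": 0, "rna": 1}


def _keep(candidates, seq_id, strand, i, site_len, n, btype, k, mm):
    key = (seq_id, strand, i + site_len)  # PAM start in scan coordinates
    rank = (mm, _TYPE_RANK[btype], k)
    prev = candidates.get(key)
    if prev is None or rank < (prev[2], _TYPE_RANK[prev[0]], prev[1]):
        candidates[key] = (btype, k, mm, i, site_len, n)
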