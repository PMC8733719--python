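"""Genome-wide off-target enumeration for SpCas9 spacers.

Finds every NGG-adjacent near-match of a spacer on both strands of a
genome, either with substitutions only (up to 4 mismatches) or allowing a
single 1-nt bulge (an extra genome base — DNA bulge — or a skipped
genome base — RNA bulge) plus up to 3 substitutions.  Counts per mismatch
level feed the selection policy: no sites at <=2 mismatches, at most 3 at
3 mismatches and at most 30 at 4.

The scan is a vectorized sliding-window comparison over byte-encoded
sequence; correctness is defined against a brute-force oracle in the
test suite.  Windows containing ``N`` never match: an ``N`` counts as a
mismatch at every position it occupies, so gappy assemblies do not
produce phantom hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .genome_io import AnnotationSet, Genome, reverse_complement

PAM_LEN = 3
MAX_VALIDATED_MM = 4

BULGE_NONE = "none"
BULGE_DNA = "dna"  # extra base in the genomic site
BULGE_RNA = "rna"  # genomic site one base short of the spacer

_BULGE_RANK = {BULGE_NONE: 0, BULGE_DNA: 1, BULGE_RNA: 2}


@dataclass(frozen=True)
class OffTargetHit:
    """One near-match of a spacer, in plus-strand genome coordinates.

    ``site`` and ``pam`` are reported 5'->3' on the protospacer strand;
    ``mismatch_positions`` are 1-based spacer coordinates (5'->3').
    """

    seq_id: str
    strand: str
    start: int  # protospacer-equivalent site, 0-based half-open
    end: int
    site: str
    pam: str
    mismatch_count: int
    mismatch_positions: tuple[int, ...]
    bulge_type: str = BULGE_NONE
    bulge_size: int = 0
    bulge_pos: int = 0  # spacer coordinate 5' of the bulge (dna) / bulged spacer base (rna)
    location: Optional[str] = None
    is_on_target: bool = False

    @property
    def pam_key(self) -> tuple[str, str, int]:
        """Canonical site identity: one key per cut site."""
        pam_start = self.end if self.strand == "+" else self.start - PAM_LEN
        return (self.seq_id, self.strand, pam_start)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _check_spacer(spacer: str) -> None:
    if not spacer or set(spacer) - set("ACGT"):
        raise ValueError(f"spacer must be non-empty over ACGT, got {spacer!r}")


def _pam_ok_mask(arr: np.ndarray, relax_to_nag: bool) -> np.ndarray:
    """pam_ok[p] is true when a valid PAM starts at position p (p <= n-3)."""
    n = len(arr)
    if n < PAM_LEN:
        return np.zeros(0, dtype=bool)
    g = arr == ord("G")
    second = g[1 : n - 1]
    if relax_to_nag:
        second = second | (arr[1 : n - 1] == ord("A"))
    return second & g[2:n]


def _scan_strand_mismatch(
    arr: np.ndarray, spacer_arr: np.ndarray, max_mm: int, pam_ok: np.ndarray
) -> list[tuple[int, tuple[int, ...]]]:
    """Return (site_start, mismatch_positions) in scan-string coordinates."""
    n = len(arr)
    L = len(spacer_arr)
    if n < L + PAM_LEN:
        return []
    windows = sliding_window_view(arr, L)
    neq = windows != spacer_arr
    mm = neq.sum(axis=1)
    n_sites = n - L - PAM_LEN + 1
    hits = np.nonzero((mm[:n_sites] <= max_mm) & pam_ok[L : L + n_sites])[0]
    out = []
    for i in hits:
        positions = tuple(int(j) + 1 for j in np.nonzero(neq[i])[0])
        out.append((int(i), positions))
    return out


def _scan_strand_bulge(
    arr: np.ndarray, spacer_arr: np.ndarray, max_mm: int, pam_ok: np.ndarray
) -> list[tuple[int, str, int, tuple[int, ...]]]:
    """Return (site_start, bulge_type, bulge_pos, mismatch_positions)."""
    n = len(arr)
    L = len(spacer_arr)
    results: list[tuple[int, str, int, tuple[int, ...]]] = []

    # DNA bulge: site length L+1, one genome base (after spacer pos k) skipped
    if n >= L + 1 + PAM_LEN:
        W = sliding_window_view(arr, L + 1)
        n_sites = n - L - PAM_LEN
        for k in range(1, L):
            site_k = np.concatenate([W[:, :k], W[:, k + 1 :]], axis=1)
            neq = site_k != spacer_arr
            mm = neq.sum(axis=1)
            ok = np.nonzero((mm[:n_sites] <= max_mm) & pam_ok[L + 1 : L + 1 + n_sites])[0]
            for i in ok:
                positions = tuple(int(j) + 1 for j in np.nonzero(neq[i])[0])
                results.append((int(i), BULGE_DNA, k, positions))

    # RNA bulge: site length L-1, spacer base k+1 unpaired
    if L >= 3 and n >= L - 1 + PAM_LEN:
        W = sliding_window_view(arr, L - 1)
        n_sites = n - L - PAM_LEN + 2
        for k in range(1, L - 1):
            spacer_del = np.concatenate([spacer_arr[:k], spacer_arr[k + 1 :]])
            neq = W != spacer_del
            mm = neq.sum(axis=1)
            ok = np.nonzero((mm[:n_sites] <= max_mm) & pam_ok[L - 1 : L - 1 + n_sites])[0]
            for i in ok:
                positions = tuple(
                    int(j) + 1 if j < k else int(j) + 2 for j in np.nonzero(neq[i])[0]
                )
                results.append((int(i), BULGE_RNA, k + 1, positions))
    return results


def _hit_from_scan(
    seq_id: str,
    scan_strand: str,
    scan_seq: str,
    n: int,
    site_start: int,
    site_len: int,
    bulge_type: str,
    bulge_pos: int,
    positions: tuple[int, ...],
) -> OffTargetHit:
    site = scan_seq[site_start : site_start + site_len]
    pam = scan_seq[site_start + site_len : site_start + site_len + PAM_LEN]
    if scan_strand == "+":
        start, end = site_start, site_start + site_len
    else:
        start, end = n - site_start - site_len, n - site_start
    return OffTargetHit(
        seq_id=seq_id,
        strand=scan_strand,
        start=start,
        end=end,
        site=site,
        pam=pam,
        mismatch_count=len(positions),
        mismatch_positions=positions,
        bulge_type=bulge_type,
        bulge_size=0 if bulge_type == BULGE_NONE else 1,
        bulge_pos=bulge_pos,
    )


def _sort_hits(hits: list[OffTargetHit]) -> list[OffTargetHit]:
    hits.sort(
        key=lambda h: (h.seq_id, h.start, h.strand, _BULGE_RANK[h.bulge_type], h.bulge_pos)
    )
    return hits


def search_mismatch(
    genome: Genome,
    spacer: str,
    max_mm: int = 4,
    require_pam: bool = True,
    relax_to_nag: bool = False,
) -> list[OffTargetHit]:
    """All NGG-adjacent sites within ``max_mm`` substitutions of the spacer.

    Both strands of every contig are scanned; each qualifying window is
    reported exactly once with its mismatch positions numbered 5'->3'
    along the spacer.  ``max_mm`` above 4 is rejected (outside the
    validated regime).  ``require_pam=False`` drops the PAM constraint
    (useful for diagnostics only).
    """
    _check_spacer(spacer)
    if max_mm > MAX_VALIDATED_MM or max_mm < 0:
        raise ValueError(f"max_mm must be in [0, {MAX_VALIDATED_MM}], got {max_mm}")
    spacer_arr = _encode(spacer)
    hits: list[OffTargetHit] = []
    for seq_id, seq in genome.items():
        n = len(seq)
        for scan_strand, scan_seq in (("+", seq), ("-", reverse_complement(seq))):
            arr = _encode(scan_seq)
            if require_pam:
                pam_ok = _pam_ok_mask(arr, relax_to_nag)
            else:
                pam_ok = np.ones(max(0, n - 2), dtype=bool)
            for site_start, positions in _scan_strand_mismatch(
                arr, spacer_arr, max_mm, pam_ok
            ):
                hits.append(
                    _hit_from_scan(
                        seq_id, scan_strand, scan_seq, n,
                        site_start, len(spacer), BULGE_NONE, 0, positions,
                    )
                )
    return _sort_hits(hits)


def search_bulge(
    genome: Genome,
    spacer: str,
    max_mm: int = 3,
    bulge_size: int = 1,
    relax_to_nag: bool = False,
) -> list[OffTargetHit]:
    """Single-bulge off-target sites with up to ``max_mm`` substitutions.

    Reports sites alignable to the spacer with exactly one inserted
    genome base (DNA bulge) or one skipped genome base (RNA bulge).
    Sites already reachable as mismatch-only alignments at ``max_mm`` are
    suppressed (the fewer-edit interpretation wins); among bulged
    interpretations of one site, fewer substitutions win, then DNA before
    RNA, then the leftmost bulge placement.
    """
    _check_spacer(spacer)
    if bulge_size not in (0, 1):
        raise ValueError(f"bulge_size must be 0 or 1, got {bulge_size}")
    if max_mm > MAX_VALIDATED_MM or max_mm < 0:
        raise ValueError(f"max_mm must be in [0, {MAX_VALIDATED_MM}], got {max_mm}")
    if bulge_size == 0:
        return []
    spacer_arr = _encode(spacer)
    L = len(spacer)

    mismatch_keys = {h.pam_key for h in search_mismatch(genome, spacer, max_mm,
                                                        relax_to_nag=relax_to_nag)}
    best: dict[tuple[str, str, int], OffTargetHit] = {}
    for seq_id, seq in genome.items():
        n = len(seq)
        for scan_strand, scan_seq in (("+", seq), ("-", reverse_complement(seq))):
            arr = _encode(scan_seq)
            pam_ok = _pam_ok_mask(arr, relax_to_nag)
            for site_start, btype, bpos, positions in _scan_strand_bulge(
                arr, spacer_arr, max_mm, pam_ok
            ):
                site_len = L + 1 if btype == BULGE_DNA else L - 1
                hit = _hit_from_scan(
                    seq_id, scan_strand, scan_seq, n,
                    site_start, site_len, btype, bpos, positions,
                )
                key = hit.pam_key
                if key in mismatch_keys:
                    continue
                prev = best.get(key)
                if prev is None or _bulge_preference(hit) < _bulge_preference(prev):
                    best[key] = hit
    return _sort_hits(list(best.values()))


def _bulge_preference(hit: OffTargetHit) -> tuple[int, int, int]:
    return (hit.mismatch_count, _BULGE_RANK[hit.bulge_type], hit.bulge_pos)


@dataclass
class OffTargetProfile:
    """Aggregated off-target counts for one spacer.

    The on-target occurrence (a 0-mismatch hit at the design locus) is
    excluded from all counts but kept in ``hits`` flagged
    ``is_on_target``; its coordinates are recorded in ``on_target_site``.
    """

    spacer: str
    hits: list[OffTargetHit] = field(default_factory=list)
    on_target_site: Optional[tuple[str, str, int]] = None  # (seq_id, strand, start)

    @property
    def counts_by_mismatch(self) -> dict[int, int]:
        counts = {k: 0 for k in range(MAX_VALIDATED_MM + 1)}
        for h in self.hits:
            if not h.is_on_target:
                counts[h.mismatch_count] = counts.get(h.mismatch_count, 0) + 1
        return counts

    @property
    def counts_by_location(self) -> dict[int, dict[str, int]]:
        out: dict[int, dict[str, int]] = {}
        for h in self.hits:
            if h.is_on_target or h.location is None:
                continue
            out.setdefault(h.mismatch_count, {}).setdefault(h.location, 0)
            out[h.mismatch_count][h.location] += 1
        return out

    @property
    def total_offtargets(self) -> int:
        return sum(1 for h in self.hits if not h.is_on_target)


def build_profile(
    spacer: str,
    hits: Iterable[OffTargetHit],
    on_target_site: Optional[tuple[str, str, int]] = None,
    genome: Optional[Genome] = None,
    annotation: Optional[AnnotationSet] = None,
) -> OffTargetProfile:
    """Assemble a profile, flagging the on-target hit and filling locations.

    ``on_target_site`` is ``(seq_id, strand, site_start)`` of the design
    locus; the matching 0-mismatch hit is flagged and excluded from
    counts.  When genome and annotation are given, every hit is assigned
    its exonic/intronic/intergenic class.
    """
    annotated: list[OffTargetHit] = []
    for h in hits:
        if (
            on_target_site is not None
            and h.mismatch_count == 0
            and h.bulge_type == BULGE_NONE
            and (h.seq_id, h.strand, h.start) == on_target_site
        ):
            h = replace(h, is_on_target=True)
        if annotation is not None and genome is not None and h.location is None:
            h = replace(
                h, location=annotation.annotate_interval(genome, h.seq_id, h.start, h.end)
            )
        annotated.append(h)
    return OffTargetProfile(spacer=spacer, hits=annotated, on_target_site=on_target_site)


@dataclass
class OffTargetPolicy:
    """Per-mismatch-level caps used for guide selection.

    Defaults: no off-targets at 0-2 mismatches, at most 3 at 3 and 30 at
    4; bulge-aware verification considers up to 3 substitutions with a
    single 1-nt bulge.
    """

    max_hits_at_mismatch: dict[int, int] = field(
        default_factory=lambda: {0: 0, 1: 0, 2: 0, 3: 3, 4: 30}
    )
    bulge_check_enabled: bool = True
    bulge_max_mismatch: int = 3
    bulge_size: int = 1

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.max_hits_at_mismatch.values()):
            raise ValueError("off-target caps must be non-negative")


@dataclass
class PolicyResult:
    passed: bool
    first_violation: Optional[str] = None
    violations: list[str] = field(default_factory=list)


def evaluate_policy(
    profile: OffTargetProfile, policy: OffTargetPolicy = None
) -> PolicyResult:
    """Check per-level counts against the policy caps (inclusive bounds)."""
    if policy is None:
        policy = OffTargetPolicy()
    counts = profile.counts_by_mismatch
    violations = []
    for level in sorted(policy.max_hits_at_mismatch):
        cap = policy.max_hits_at_mismatch[level]
        n = counts.get(level, 0)
        if n > cap:
            violations.append(
                f"{n} off-target(s) at {level} mismatch(es) exceeds cap {cap} ({n} > {cap})"
            )
    return PolicyResult(
        passed=not violations,
        first_violation=violations[0] if violations else None,
        violations=violations,
    )


def hits_to_tsv(hits: Iterable[OffTargetHit], spacer_id: str = "") -> str:
    """TSV hit report (1-based inclusive coordinates)."""
    header = "\t".join(
        [
            "spacer_id", "seq_id", "start", "end", "strand", "site", "pam",
            "mismatch_count", "mismatch_positions", "bulge_type", "bulge_size",
            "location", "on_target",
        ]
    )
    lines = [header]
    for h in hits:
        lines.append(
            "\t".join(
                [
                    spacer_id,
                    h.seq_id,
                    str(h.start + 1),
                    str(h.end),
                    h.strand,
                    h.site,
                    h.pam,
                    str(h.mismatch_count),
                    ",".join(map(str, h.mismatch_positions)),
                    h.bulge_type,
                    str(h.bulge_size),
                    h.location or ".",
                    "yes" if h.is_on_target else "no",
                ]
            )
        )
    return "\n".join(lines) + "\n"
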