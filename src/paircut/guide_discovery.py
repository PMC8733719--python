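"""Enumeration of SpCas9 guide candidates (spacer + NGG PAM) in a region.

Scans both strands of a genomic region for every occurrence of an
``N{L}-NGG`` protospacer+PAM layout, recording for each candidate the
blunt-cut position (3 nt 5' of the PAM on the protospacer strand, as an
inter-base coordinate), the spacer GC content and the PAM variable base.
The default spacer length is 19 nt, matching a cloning scheme that
requires 19-mers; 17-25 nt are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .genome_io import Genome, fetch_subsequence, reverse_complement

MIN_SPACER = 17
MAX_SPACER = 25
PAM_LEN = 3
CUT_OFFSET = 3  # blunt cut 3 nt 5' of the PAM


@dataclass
class GuideCandidate:
    """One spacer+PAM occurrence on a genome strand.

    ``spacer_start``/``spacer_end`` and ``pam_start``/``pam_end`` are
    0-based half-open plus-strand genome coordinates regardless of strand;
    ``spacer`` and ``pam`` are given 5'->3' on the protospacer strand.
    ``cut_pos`` is an inter-base coordinate: the break falls between
    plus-strand positions ``cut_pos - 1`` and ``cut_pos``.
    """

    seq_id: str
    strand: str
    spacer: str
    pam: str
    spacer_start: int
    spacer_end: int
    pam_start: int
    pam_end: int
    cut_pos: int
    gc_percent: float
    pam_variable_base: str
    score: Optional[float] = None
    name: str = field(default="", compare=False)

    @property
    def spacer_length(self) -> int:
        return len(self.spacer)

    def validate(self, genome: Genome) -> None:
        """Re-fetch spacer and PAM from the genome and check consistency."""
        spacer = fetch_subsequence(
            genome, self.seq_id, self.spacer_start, self.spacer_end, self.strand
        )
        pam = fetch_subsequence(
            genome, self.seq_id, self.pam_start, self.pam_end, self.strand
        )
        if spacer != self.spacer:
            raise AssertionError(f"spacer mismatch at {self}: genome has {spacer}")
        if pam != self.pam:
            raise AssertionError(f"PAM mismatch at {self}: genome has {pam}")
        if pam[1:] != "GG":
            raise AssertionError(f"PAM {pam} is not NGG")


def gc_content(seq: str) -> float:
    """GC percentage of a sequence, 0-100."""
    if not seq:
        return 0.0
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def find_guides(
    genome: Genome,
    seq_id: str,
    start: int = 0,
    end: Optional[int] = None,
    spacer_length: int = 19,
    require_5prime_g: bool = False,
) -> list[GuideCandidate]:
    """Enumerate all spacer+NGG occurrences fully inside ``[start, end)``.

    Both strands are scanned.  Guides whose spacer or PAM overlaps an ``N``
    are discarded (an N cannot be confidently matched or cloned).  The
    result is sorted by spacer start, then strand (``+`` before ``-``).

    Parameters
    ----------
    require_5prime_g:
        If true, keep only spacers whose first base is G (for expression
        cassettes that do not supply the transcription-start G).
    """
    if seq_id not in genome:
        raise KeyError(f"unknown sequence id {seq_id!r}")
    if not (MIN_SPACER <= spacer_length <= MAX_SPACER):
        raise ValueError(
            f"spacer_length must be in [{MIN_SPACER}, {MAX_SPACER}], got {spacer_length}"
        )
    seq = genome[seq_id]
    if end is None:
        end = len(seq)
    if not (0 <= start <= end <= len(seq)):
        raise IndexError(f"region [{start}, {end}) out of bounds for {seq_id!r}")

    site_len = spacer_length + PAM_LEN
    region = seq[start:end]
    out: list[GuideCandidate] = []
    for i in range(0, len(region) - site_len + 1):
        window = region[i : i + site_len]
        if "N" in window:
            continue
        g_start = start + i
        # plus strand: spacer then NGG
        if window[spacer_length + 1 : spacer_length + 3] == "GG":
            spacer = window[:spacer_length]
            if not require_5prime_g or spacer[0] == "G":
                pam = window[spacer_length:]
                out.append(
                    _make_candidate(seq_id, "+", spacer, pam, g_start, spacer_length)
                )
        # minus strand: plus-strand layout is CCN then revcomp(spacer)
        if window[0:2] == "CC":
            spacer = reverse_complement(window[PAM_LEN:])
            if not require_5prime_g or spacer[0] == "G":
                pam = reverse_complement(window[:PAM_LEN])
                out.append(
                    _make_candidate(seq_id, "-", spacer, pam, g_start, spacer_length)
                )
    out.sort(key=lambda c: (c.seq_id, c.spacer_start, c.strand))
    return out


def _make_candidate(
    seq_id: str, strand: str, spacer: str, pam: str, site_start: int, L: int
) -> GuideCandidate:
    if strand == "+":
        spacer_start = site_start
        spacer_end = site_start + L
        pam_start = spacer_end
        pam_end = pam_start + PAM_LEN
        cut_pos = pam_start - CUT_OFFSET
    else:
        pam_start = site_start
        pam_end = site_start + PAM_LEN
        spacer_start = pam_end
        spacer_end = spacer_start + L
        cut_pos = pam_end + CUT_OFFSET
    return GuideCandidate(
        seq_id=seq_id,
        strand=strand,
        spacer=spacer,
        pam=pam,
        spacer_start=spacer_start,
        spacer_end=spacer_end,
        pam_start=pam_start,
        pam_end=pam_end,
        cut_pos=cut_pos,
        gc_percent=gc_content(spacer),
        pam_variable_base=pam[0],
    )


def gc_filter(
    candidates: list[GuideCandidate], min_gc: float = 40.0, max_gc: float = 70.0
) -> list[GuideCandidate]:
    """Keep candidates with ``min_gc <= GC% <= max_gc`` (inclusive bounds)."""
    if min_gc > max_gc:
        raise ValueError(f"min_gc ({min_gc}) exceeds max_gc ({max_gc})")
    return [c for c in candidates if min_gc <= c.gc_percent <= max_gc]


def guides_to_tsv(candidates: list[GuideCandidate]) -> str:
    """Render candidates as a TSV report (1-based inclusive coordinates)."""
    header = "\t".join(
        [
            "seq_id",
            "spacer_start",
            "spacer_end",
            "strand",
            "spacer",
            "pam",
            "cut_pos",
            "gc_percent",
            "score",
        ]
    )
    lines = [header]
    for c in candidates:
        lines.append(
            "\t".join(
                [
                    c.seq_id,
                    str(c.spacer_start + 1),
                    str(c.spacer_end),
                    c.strand,
                    c.spacer,
                    c.pam,
                    str(c.cut_pos),
                    f"{c.gc_percent:.1f}",
                    "" if c.score is None else f"{c.score:.3f}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
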