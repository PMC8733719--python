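"""Interpretation of Sanger-clone amplicons from edited plants.

The wet-lab workflow this mirrors: a nested PCR (outer then inner primer
pair, both outside the targeted region) amplifies across the paired-cut
locus, so a chromosome carrying the programmed deletion yields a product
shorter by the deletion size Δ; per-cut-site PCRs detect small indels at
each guide's cut position; and marker PCRs for the Cas9 and Rep/RepA
cassettes report whether T-DNA integrated.  Sequenced clones of those
amplicons are compared with the reference to call the edit on each
allele, and the clone calls plus the band pattern classify each plant as
chimeric (chi), heterozygous/monoallelic (Aa), homozygous-or-biallelic
(aa), or non-edited.

Breakpoints of deletions running through repeated bases are left-aligned
(leftmost equivalent placement) and the ambiguity span is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .genome_io import reverse_complement

WILD_TYPE = "wild-type"
LARGE_DELETION = "large-deletion"
INDEL_G1 = "indel-g1"
INDEL_G2 = "indel-g2"
COMPLEX = "complex"

CHI = "chi"
HET = "Aa"
HOM = "aa"
NON_EDITED = "non-edited"

#: events this long or longer that span both cut sites are large deletions
LARGE_DELETION_MIN = 50

MIN_PRIMER_LEN = 15
SEED_LEN = 12  # 3'-terminal bases requiring an exact match
MAX_5PRIME_MISMATCH = 1


class ForeignSequenceError(ValueError):
    """The amplicon shares no flank with the reference."""


@dataclass
class PrimerSet:
    """Outer and inner primer pairs for one nested-PCR target."""

    label: str
    outer_forward: str
    outer_reverse: str
    inner_forward: str
    inner_reverse: str

    def __post_init__(self) -> None:
        for name in ("outer_forward", "outer_reverse", "inner_forward", "inner_reverse"):
            p = getattr(self, name).upper()
            setattr(self, name, p)
            if len(p) < MIN_PRIMER_LEN:
                raise ValueError(f"{name} shorter than {MIN_PRIMER_LEN} nt")


def _primer_sites(template: str, primer: str) -> list[int]:
    """Start positions where the primer anneals on the plus strand.

    Matching is exact over the 3'-terminal ``SEED_LEN`` bases and allows
    up to one mismatch in the 5' remainder — a deterministic stand-in for
    PCR specificity.
    """
    L = len(primer)
    seed = primer[-SEED_LEN:]
    head = primer[:-SEED_LEN]
    sites = []
    start = 0
    while True:
        i = template.find(seed, start)
        if i < 0:
            break
        p_start = i - len(head)
        if p_start >= 0:
            mismatches = sum(
                1 for a, b in zip(head, template[p_start:i]) if a != b
            )
            if mismatches <= MAX_5PRIME_MISMATCH:
                sites.append(p_start)
        start = i + 1
    return sites


def in_silico_pcr(
    template: str, fwd: str, rev: str, max_product: int = 10000
) -> list[tuple[str, int]]:
    """Predict PCR products as (sequence, length), 5'-primer-end to 5'-end.

    The forward primer must anneal on the plus strand and the reverse
    complement of the reverse primer downstream of it, within
    ``max_product``.  No match yields an empty list.
    """
    template = template.upper()
    fwd = fwd.upper()
    rev_rc = reverse_complement(rev.upper())
    products = []
    fwd_sites = _primer_sites(template, fwd)
    # reverse primer anneals to the plus strand as its reverse complement;
    # the product's right edge is the primer's 5' end
    rev_sites = []
    # match rev_rc with the seed at its *left* end (primer 3' end)
    seed = rev_rc[:SEED_LEN]
    tail = rev_rc[SEED_LEN:]
    start = 0
    while True:
        i = template.find(seed, start)
        if i < 0:
            break
        frag = template[i + SEED_LEN : i + SEED_LEN + len(tail)]
        if len(frag) == len(tail):
            mismatches = sum(1 for a, b in zip(tail, frag) if a != b)
            if mismatches <= MAX_5PRIME_MISMATCH:
                rev_sites.append(i)
        start = i + 1
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(rev_rc)
            if end > f and end - f <= max_product and r >= f + len(fwd) - SEED_LEN:
                products.append((template[f:end], end - f))
    products.sort(key=lambda p: p[1])
    return products


def nested_pcr(
    template: str, primers: PrimerSet, max_product: int = 10000
) -> list[tuple[str, int]]:
    """Two-round amplification: inner products amplified from outer products."""
    inner_products: list[tuple[str, int]] = []
    for outer, _ in in_silico_pcr(template, primers.outer_forward, primers.outer_reverse, max_product):
        inner_products.extend(
            in_silico_pcr(outer, primers.inner_forward, primers.inner_reverse, max_product)
        )
    # deduplicate identical products from multiple outer templates
    seen = set()
    unique = []
    for seq, length in inner_products:
        if seq not in seen:
            seen.add(seq)
            unique.append((seq, length))
    return unique


@dataclass
class EditCall:
    """Per-amplicon interpretation of an editing outcome."""

    call_type: str
    deletion_size: int = 0
    breakpoint_left: Optional[int] = None
    breakpoint_right: Optional[int] = None
    junction_insertion: str = ""
    microhomology_span: int = 0
    insertion_size: int = 0
    supporting_clone_ids: tuple[str, ...] = ()

    @property
    def allele_signature(self) -> tuple:
        """Identity of the edited allele, for counting distinct alleles."""
        return (
            self.call_type,
            self.deletion_size,
            self.breakpoint_left,
            self.breakpoint_right,
            self.junction_insertion,
        )


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix_len(a: str, b: str, limit: int) -> int:
    n = min(len(a), len(b), limit)
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def call_edit(
    reference: str,
    amplicon: str,
    cut_sites: Sequence[int],
    clone_id: str = "",
    large_deletion_min: int = LARGE_DELETION_MIN,
) -> EditCall:
    """Call the edit carried by one clone sequence against the reference.

    The amplicon is auto-reverse-complemented if that orientation shares
    longer flanks with the reference.  The difference between reference
    and amplicon is decomposed into maximal shared prefix and suffix; the
    middle segments define a single replacement event which is then
    classified:

    - no event: wild-type;
    - a deletion >= ``large_deletion_min`` whose gap (allowing it to
      slide right across the microhomology span) covers both cut sites:
      large-deletion, with Δ, left-aligned breakpoints and any junction
      insertion;
    - a small event (< ``large_deletion_min``) overlapping exactly one
      cut site: indel-g1 / indel-g2;
    - anything else: complex.
    """
    reference = reference.upper()
    amplicon = amplicon.upper()
    if len(cut_sites) != 2 or cut_sites[0] > cut_sites[1]:
        raise ValueError("cut_sites must be two ascending coordinates")
    cut1, cut2 = cut_sites

    fwd_score = _orientation_score(reference, amplicon)
    rev_amp = reverse_complement(amplicon)
    rev_score = _orientation_score(reference, rev_amp)
    if max(fwd_score, rev_score) < 15:
        raise ForeignSequenceError(
            f"clone {clone_id or '<unnamed>'}: amplicon shares no flank with the reference"
        )
    if rev_score > fwd_score:
        amplicon = rev_amp

    clone_ids = (clone_id,) if clone_id else ()
    if amplicon == reference:
        return EditCall(call_type=WILD_TYPE, supporting_clone_ids=clone_ids)

    p = _common_prefix_len(reference, amplicon)
    limit = min(len(reference), len(amplicon)) - p
    s = _common_suffix_len(reference, amplicon, limit)
    ref_mid = reference[p : len(reference) - s]
    amp_mid = amplicon[p : len(amplicon) - s]
    del_len = len(ref_mid)
    ins_len = len(amp_mid)

    # left-align: the maximal-prefix decomposition lands on the rightmost
    # equivalent placement of a pure indel through repeated bases; slide
    # the event to its leftmost placement, the reporting convention
    if ins_len == 0 and del_len > 0:
        while p > 0 and reference[p - 1] == reference[p + del_len - 1]:
            p -= 1
        ref_mid = reference[p : p + del_len]
    elif del_len == 0 and ins_len > 0:
        while p > 0 and reference[p - 1] == amp_mid[-1]:
            amp_mid = amp_mid[-1] + amp_mid[:-1]
            p -= 1

    # microhomology: how far the left-aligned event can slide right and
    # stay equivalent (replacements do not slide)
    amb = 0
    if ins_len == 0 and del_len > 0:
        while (
            p + del_len + amb < len(reference)
            and reference[p + amb] == reference[p + del_len + amb]
        ):
            amb += 1
    elif del_len == 0 and ins_len > 0:
        while (
            p + amb < len(reference)
            and reference[p + amb] == amp_mid[(amb % ins_len) if ins_len else 0]
        ):
            amb += 1

    if del_len == 0 and ins_len == 0:
        return EditCall(call_type=WILD_TYPE, supporting_clone_ids=clone_ids)

    gap_start, gap_end = p, p + del_len
    spans_both = _can_cover(gap_start, del_len, amb, cut1, cut2)
    # a genuine junction insertion is short; a long "insertion" means the
    # middle segments diverged for another reason (e.g. two separate events)
    if del_len >= large_deletion_min and spans_both and ins_len < large_deletion_min:
        return EditCall(
            call_type=LARGE_DELETION,
            deletion_size=del_len,
            breakpoint_left=gap_start,
            breakpoint_right=gap_end,
            junction_insertion=amp_mid,
            microhomology_span=amb,
            insertion_size=ins_len,
            supporting_clone_ids=clone_ids,
        )

    event_size = max(del_len, ins_len)
    if event_size < large_deletion_min:
        hits1 = _overlaps_cut(gap_start, gap_end, amb, cut1)
        hits2 = _overlaps_cut(gap_start, gap_end, amb, cut2)
        if hits1 != hits2:
            return EditCall(
                call_type=INDEL_G1 if hits1 else INDEL_G2,
                deletion_size=del_len,
                breakpoint_left=gap_start,
                breakpoint_right=gap_end,
                junction_insertion=amp_mid,
                microhomology_span=amb,
                insertion_size=ins_len,
                supporting_clone_ids=clone_ids,
            )
    return EditCall(
        call_type=COMPLEX,
        deletion_size=del_len,
        breakpoint_left=gap_start,
        breakpoint_right=gap_end,
        junction_insertion=amp_mid,
        microhomology_span=amb,
        insertion_size=ins_len,
        supporting_clone_ids=clone_ids,
    )


def _orientation_score(reference: str, amplicon: str) -> int:
    p = _common_prefix_len(reference, amplicon)
    s = _common_suffix_len(reference, amplicon, min(len(reference), len(amplicon)))
    return max(p, s)


def _can_cover(gap_start: int, del_len: int, amb: int, cut1: int, cut2: int) -> bool:
    """Can some equivalent gap placement [gap_start+t, +del_len) cover both cuts?"""
    if del_len == 0:
        return False
    lo = max(0, cut2 - gap_start - del_len)
    hi = min(amb, cut1 - gap_start)
    return lo <= hi


def _overlaps_cut(gap_start: int, gap_end: int, amb: int, cut: int) -> bool:
    """Does any equivalent placement of the event touch the cut position?"""
    return gap_start <= cut <= gap_end + amb


@dataclass
class GenotypeCall:
    plant_id: str
    genotype: str
    transgene_markers: dict[str, bool] = field(default_factory=dict)
    n_clones: int = 0
    n_edited_clones: int = 0
    allele_signatures: tuple = ()
    evidence: str = ""


def classify_plant(
    calls: Sequence[EditCall],
    edited_band: bool,
    wt_band: bool,
    plant_id: str = "",
    het_fraction_window: tuple[float, float] = (0.2, 0.8),
) -> GenotypeCall:
    """Classify one plant from its clone calls and amplicon band pattern.

    - Only edited evidence (no wild-type band, no wild-type clones) with
      at most two distinct edited alleles: homozygous/biallelic (aa).
    - Both bands with exactly one edited allele and an edited-clone
      fraction inside ``het_fraction_window``: heterozygous (Aa).
    - More than two distinct allele sequences (wild type counts as one),
      an out-of-window edited fraction, or inconsistent band/clone
      evidence: chimeric (chi).
    - Only wild-type evidence: non-edited.

    The result is invariant to clone ordering.
    """
    if not calls:
        raise ValueError("classify_plant requires at least one clone call")
    edited = [c for c in calls if c.call_type != WILD_TYPE]
    n_wt = len(calls) - len(edited)
    signatures = sorted(set(c.allele_signature for c in edited))
    n_alleles = len(signatures) + (1 if (n_wt or wt_band) else 0)
    fraction_edited = len(edited) / len(calls)

    if not edited and not edited_band:
        genotype, why = NON_EDITED, "only wild-type evidence"
    elif not edited and edited_band:
        genotype, why = CHI, "edited band without edited clones (inconsistent)"
    elif n_alleles > 2:
        genotype, why = CHI, f"{n_alleles} distinct allele sequences"
    elif not wt_band and n_wt == 0:
        genotype, why = HOM, "no wild-type allele observed"
    elif edited and wt_band and not edited_band:
        genotype, why = CHI, "edited clones without an edited band (inconsistent)"
    else:
        lo, hi = het_fraction_window
        if len(signatures) == 1 and lo <= fraction_edited <= hi:
            genotype, why = HET, "one edited allele plus wild type"
        else:
            genotype, why = CHI, (
                f"edited-clone fraction {fraction_edited:.2f} outside "
                f"[{lo}, {hi}] for a heterozygote"
            )
    return GenotypeCall(
        plant_id=plant_id,
        genotype=genotype,
        n_clones=len(calls),
        n_edited_clones=len(edited),
        allele_signatures=tuple(signatures),
        evidence=why,
    )


def transgene_status(
    template: str,
    markers: dict[str, tuple[str, str, Optional[int]]],
    length_tolerance: int = 20,
    max_product: int = 10000,
) -> dict[str, bool]:
    """Detect transgene cassettes (e.g. Cas9, Rep/RepA) by marker PCR.

    ``markers`` maps a marker name to ``(fwd, rev, expected_length)``;
    the marker is present when in-silico PCR yields a product of the
    expected length within the tolerance (any product if the expected
    length is None).
    """
    status = {}
    for name, (fwd, rev, expected) in markers.items():
        products = in_silico_pcr(template, fwd, rev, max_product)
        if expected is None:
            status[name] = bool(products)
        else:
            status[name] = any(
                abs(length - expected) <= length_tolerance for _, length in products
            )
    return status


def genotypes_to_tsv(calls: Iterable[GenotypeCall]) -> str:
    header = "\t".join(
        ["plant_id", "genotype", "n_clones", "n_edited_clones", "markers", "evidence"]
    )
    lines = [header]
    for g in calls:
        markers = ";".join(f"{k}={'+' if v else '-'}" for k, v in g.transgene_markers.items())
        lines.append(
            "\t".join(
                [g.plant_id, g.genotype, str(g.n_clones), str(g.n_edited_clones),
                 markers or ".", g.evidence]
            )
        )
    return "\n".join(lines) + "\n"
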