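"""Seeded fixture generation: toy genomes with planted guides and
off-targets, gene models, and simulated edited amplicons with truth
manifests.

The generator builds uniform-composition random background sequence,
stamps protospacer+PAM sites and derived off-target sites at requested
mismatch/bulge distances, and then verifies by exhaustive search that no
accidental near-match exists within the requested mismatch radius —
resampling the background (bounded attempts) on collision.  Regeneration
from the same seed is byte-identical.

Amplicon simulation produces exact clone sequences (no sequencing-error
model): large deletions remove exactly the inter-cut segment, junction
insertions are seeded-random bases constrained so they cannot realign to
the flanks (keeping the truth manifest exact), and single-site indels
modify one cut position only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome_io import AnnotationSet, Feature, Genome, reverse_complement
from .guide_discovery import GuideCandidate, PAM_LEN, _make_candidate, gc_content
from .offtarget_search import (
    BULGE_DNA,
    BULGE_NONE,
    BULGE_RNA,
    search_bulge,
    search_mismatch,
)

BASES = "ACGT"

DEFAULT_MAX_ATTEMPTS = 100


class FixtureError(RuntimeError):
    """Raised when a fixture spec cannot be satisfied."""


@dataclass
class GeneSpec:
    """A gene model to stamp into the annotation (no sequence effect)."""

    seq_id: str
    start: int
    exon_lengths: Sequence[int]
    intron_lengths: Sequence[int]
    strand: str = "+"
    gene_id: str = "gene1"

    def features(self) -> list[Feature]:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need one fewer intron than exons")
        feats = []
        pos = self.start
        for i, exon_len in enumerate(self.exon_lengths):
            feats.append(
                Feature(self.seq_id, pos, pos + exon_len, "exon", self.strand, self.gene_id)
            )
            pos += exon_len
            if i < len(self.intron_lengths):
                pos += self.intron_lengths[i]
        feats.insert(
            0, Feature(self.seq_id, self.start, pos, "gene", self.strand, self.gene_id)
        )
        return feats

    @property
    def end(self) -> int:
        return self.start + sum(self.exon_lengths) + sum(self.intron_lengths)


@dataclass
class GuideSpec:
    """A protospacer+PAM site to plant.

    ``site_start`` is the plus-strand start of the full site (spacer+PAM
    on ``+``; PAM+spacer on ``-``).  The spacer is drawn at random
    (40-70% GC) when not given.
    """

    seq_id: str
    site_start: int
    strand: str = "+"
    spacer: Optional[str] = None
    spacer_length: int = 19
    pam_variable_base: str = "C"


@dataclass
class OffTargetSpec:
    """A near-match site to plant for one planted guide."""

    guide_index: int
    seq_id: str
    site_start: int
    strand: str = "+"
    mismatch_positions: Sequence[int] = ()  # 1-based spacer coordinates
    bulge_type: str = BULGE_NONE
    bulge_pos: int = 0  # spacer coordinate (see offtarget_search)


@dataclass
class FixtureManifest:
    seed: int
    attempt: int = 0
    guides: list[GuideCandidate] = field(default_factory=list)
    offtargets: list[dict] = field(default_factory=list)
    genes: list[GeneSpec] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [f"seed={self.seed}", f"attempt={self.attempt}"]
        for i, g in enumerate(self.guides):
            lines.append(
                f"guide.{i}={g.seq_id}:{g.spacer_start}-{g.spacer_end}({g.strand})"
                f" spacer={g.spacer} pam={g.pam} cut={g.cut_pos}"
            )
        for i, ot in enumerate(self.offtargets):
            lines.append(
                f"offtarget.{i}=guide{ot['guide_index']}"
                f" {ot['seq_id']}:{ot['start']}-{ot['end']}({ot['strand']})"
                f" mm={','.join(map(str, ot['mismatch_positions'])) or '-'}"
                f" bulge={ot['bulge_type']}"
            )
        for i, gene in enumerate(self.genes):
            lines.append(
                f"gene.{i}={gene.seq_id}:{gene.start}-{gene.end}({gene.strand})"
                f" exons={','.join(map(str, gene.exon_lengths))}"
            )
        return "\n".join(lines) + "\n"


@dataclass
class SimulatedGenome:
    genome: Genome
    annotation: AnnotationSet
    features: list[Feature]
    manifest: FixtureManifest


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    idx = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(BASES[i] for i in idx)


def _random_spacer(
    rng: np.random.Generator, length: int, min_gc: float = 40.0, max_gc: float = 70.0
) -> str:
    for _ in range(1000):
        spacer = _random_seq(rng, length)
        if min_gc <= gc_content(spacer) <= max_gc:
            return spacer
    raise FixtureError("could not draw a spacer in the GC window")


def _substitute(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in BASES if b != base]
    return choices[rng.integers(0, 3)]


def _offtarget_site(
    rng: np.random.Generator, spacer: str, spec: OffTargetSpec
) -> str:
    """Site sequence (protospacer-strand) realizing the requested edits."""
    site = list(spacer)
    for pos in spec.mismatch_positions:
        if not (1 <= pos <= len(spacer)):
            raise ValueError(f"mismatch position {pos} outside spacer")
        site[pos - 1] = _substitute(rng, spacer[pos - 1])
    if spec.bulge_type == BULGE_DNA:
        k = spec.bulge_pos
        if not (1 <= k <= len(spacer) - 1):
            raise ValueError("dna bulge_pos must be an internal spacer coordinate")
        site.insert(k, BASES[rng.integers(0, 4)])
    elif spec.bulge_type == BULGE_RNA:
        k = spec.bulge_pos
        if not (2 <= k <= len(spacer) - 1):
            raise ValueError("rna bulge_pos must be an internal spacer coordinate")
        del site[k - 1]
    elif spec.bulge_type != BULGE_NONE:
        raise ValueError(f"unknown bulge type {spec.bulge_type!r}")
    return "".join(site)


def _stamp(contigs: dict[str, list[str]], seq_id: str, start: int, text: str) -> None:
    seq = contigs[seq_id]
    if start < 0 or start + len(text) > len(seq):
        raise FixtureError(f"planted element outside {seq_id!r} bounds")
    seq[start : start + len(text)] = list(text)


def simulate_genome(
    n_contigs: int = 1,
    contig_length: int = 10000,
    genes: Sequence[GeneSpec] = (),
    guides: Sequence[GuideSpec] = (),
    offtargets: Sequence[OffTargetSpec] = (),
    seed: int = 0,
    gc: float = 0.5,
    mismatch_radius: int = 4,
    bulge_sweep_mm: int = 3,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
) -> SimulatedGenome:
    """Build a toy genome with planted guide and off-target sites.

    Contigs are named ``contig1..contigN``.  After stamping, an
    exhaustive sweep per guide (substitutions up to ``mismatch_radius``;
    single-bulge alignments up to ``bulge_sweep_mm`` substitutions)
    confirms that exactly the planted sites exist; on accidental extra
    near-matches the background is resampled, up to ``max_attempts``
    times before raising :class:`FixtureError`.
    """
    spacers: dict[int, str] = {}
    last_error = "unsatisfiable fixture spec"
    for attempt in range(max_attempts):
        rng = np.random.default_rng((seed, attempt))
        contigs = {
            f"contig{i + 1}": list(_random_seq(rng, contig_length, gc))
            for i in range(n_contigs)
        }
        occupied: dict[str, list[tuple[int, int]]] = {k: [] for k in contigs}

        def claim(seq_id: str, start: int, end: int) -> None:
            for a, b in occupied[seq_id]:
                if start < b and a < end:
                    raise FixtureError(
                        f"planted elements overlap on {seq_id!r}: "
                        f"[{start},{end}) vs [{a},{b})"
                    )
            occupied[seq_id].append((start, end))

        planted_guides: list[GuideCandidate] = []
        for gi, gspec in enumerate(guides):
            if gspec.spacer is not None:
                spacer = gspec.spacer.upper()
            else:
                spacer = spacers.setdefault(
                    gi, _random_spacer(rng, gspec.spacer_length)
                )
            pam = gspec.pam_variable_base + "GG"
            if gspec.strand == "+":
                text = spacer + pam
            else:
                text = reverse_complement(spacer + pam)
            claim(gspec.seq_id, gspec.site_start, gspec.site_start + len(text))
            _stamp(contigs, gspec.seq_id, gspec.site_start, text)
            planted_guides.append(
                _make_candidate(
                    gspec.seq_id, gspec.strand, spacer, pam,
                    gspec.site_start, len(spacer),
                )
            )

        planted_ots: list[dict] = []
        for ospec in offtargets:
            guide = planted_guides[ospec.guide_index]
            site = _offtarget_site(rng, guide.spacer, ospec)
            # variable base drawn from A/C/T: a GGG PAM could open a second
            # shifted NGG frame and confuse the planted-site bookkeeping
            pam = "ACT"[rng.integers(0, 3)] + "GG"
            if ospec.strand == "+":
                text = site + pam
                start = ospec.site_start
                end = start + len(site)
            else:
                text = reverse_complement(site + pam)
                start = ospec.site_start + PAM_LEN
                end = start + len(site)
            claim(ospec.seq_id, ospec.site_start, ospec.site_start + len(text))
            _stamp(contigs, ospec.seq_id, ospec.site_start, text)
            planted_ots.append(
                {
                    "guide_index": ospec.guide_index,
                    "seq_id": ospec.seq_id,
                    "start": start,
                    "end": end,
                    "strand": ospec.strand,
                    "site": site,
                    "mismatch_positions": tuple(sorted(ospec.mismatch_positions)),
                    "bulge_type": ospec.bulge_type,
                    "bulge_pos": ospec.bulge_pos,
                }
            )

        genome = Genome()
        for name, chars in contigs.items():
            genome.add(name, "".join(chars))

        ok, last_error = _sweep_clean(
            genome, planted_guides, planted_ots, mismatch_radius, bulge_sweep_mm
        )
        if not ok:
            continue

        features: list[Feature] = []
        for gene in genes:
            if gene.end > contig_length:
                raise FixtureError(f"gene {gene.gene_id!r} exceeds contig length")
            features.extend(gene.features())
        manifest = FixtureManifest(
            seed=seed,
            attempt=attempt,
            guides=planted_guides,
            offtargets=planted_ots,
            genes=list(genes),
        )
        return SimulatedGenome(
            genome=genome,
            annotation=AnnotationSet(features),
            features=features,
            manifest=manifest,
        )
    raise FixtureError(
        f"no clean background after {max_attempts} attempts: {last_error}"
    )


def _sweep_clean(
    genome: Genome,
    guides: list[GuideCandidate],
    offtargets: list[dict],
    mismatch_radius: int,
    bulge_sweep_mm: int,
) -> tuple[bool, str]:
    """Verify exactly the planted sites are discoverable for each guide."""
    for gi, guide in enumerate(guides):
        expected_mm = {(guide.seq_id, guide.strand, guide.spacer_start)}
        expected_bulge = set()
        for ot in offtargets:
            if ot["guide_index"] != gi:
                continue
            key = (ot["seq_id"], ot["strand"], ot["start"])
            if ot["bulge_type"] == BULGE_NONE:
                expected_mm.add(key)
            else:
                expected_bulge.add(key)
        found_mm = {
            (h.seq_id, h.strand, h.start)
            for h in search_mismatch(genome, guide.spacer, max_mm=mismatch_radius)
        }
        if found_mm != expected_mm:
            return False, (
                f"guide {gi}: mismatch sweep found {sorted(found_mm - expected_mm)} "
                f"unplanned / missing {sorted(expected_mm - found_mm)}"
            )
        found_bulge = {
            (h.seq_id, h.strand, h.start)
            for h in search_bulge(genome, guide.spacer, max_mm=bulge_sweep_mm)
        }
        if found_bulge != expected_bulge:
            return False, (
                f"guide {gi}: bulge sweep found {sorted(found_bulge - expected_bulge)} "
                f"unplanned / missing {sorted(expected_bulge - found_bulge)}"
            )
    return True, ""


# ---------------------------------------------------------------------------
# edited-amplicon simulation


@dataclass
class EditScenario:
    """One editing outcome to simulate.

    kind: wild-type | deletion | deletion+insertion | indel-g1 | indel-g2.
    ``insertion_len`` sizes the junction insertion for
    ``deletion+insertion``; ``indel_len`` is signed for indel scenarios
    (negative: deletion of that many bases ending at the cut; positive:
    insertion at the cut).
    """

    kind: str
    insertion_len: int = 0
    indel_len: int = 0

    KINDS = ("wild-type", "deletion", "deletion+insertion", "indel-g1", "indel-g2")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "deletion+insertion" and self.insertion_len <= 0:
            raise ValueError("deletion+insertion needs insertion_len > 0")
        if self.kind.startswith("indel") and self.indel_len == 0:
            raise ValueError("indel scenarios need a non-zero indel_len")


@dataclass
class AmpliconTruth:
    clone_id: str
    kind: str
    delta: int  # bases removed from the reference
    breakpoint_left: int
    breakpoint_right: int
    insertion: str = ""
    indel_len: int = 0

    def to_text(self) -> str:
        return (
            f"{self.clone_id}\t{self.kind}\t{self.delta}"
            f"\t{self.breakpoint_left}\t{self.breakpoint_right}"
            f"\t{self.insertion or '-'}\t{self.indel_len}"
        )


def _anchored_insertion(
    rng: np.random.Generator, length: int, left_neighbor: str, right_neighbor: str
) -> str:
    """Random insertion whose ends cannot realign to the flanking bases,
    so the truth breakpoints stay exact under left-alignment."""
    for _ in range(100):
        ins = _random_seq(rng, length)
        if ins[-1] != left_neighbor and ins[0] != right_neighbor:
            return ins
    raise FixtureError("could not draw an anchored insertion")


def simulate_edited_amplicons(
    reference: str,
    cut_sites: Sequence[int],
    scenarios: Sequence[EditScenario],
    clones_per_scenario: int = 1,
    seed: int = 0,
    plant_id: str = "plant",
) -> tuple[list[tuple[str, str]], list[AmpliconTruth]]:
    """Simulate sequenced clones for a list of editing scenarios.

    Returns ``(clones, truths)`` where clones are ``(clone_id,
    sequence)`` pairs.  Deletion scenarios remove exactly the inter-cut
    segment; insertion scenarios add anchored random bases at the
    junction; indel scenarios modify one cut site only.
    """
    reference = reference.upper()
    if len(cut_sites) != 2:
        raise ValueError("cut_sites must hold exactly two coordinates")
    cut1, cut2 = cut_sites
    if not (0 < cut1 < cut2 < len(reference)):
        raise ValueError("cut sites must be ascending and inside the reference")
    rng = np.random.default_rng((seed, cut1, cut2))
    clones: list[tuple[str, str]] = []
    truths: list[AmpliconTruth] = []
    for si, sc in enumerate(scenarios):
        for ci in range(clones_per_scenario):
            clone_id = f"{plant_id}_s{si}_{sc.kind}_{ci}"
            if sc.kind == "wild-type":
                seq = reference
                truth = AmpliconTruth(clone_id, sc.kind, 0, cut1, cut1)
            elif sc.kind == "deletion":
                seq = reference[:cut1] + reference[cut2:]
                truth = AmpliconTruth(clone_id, sc.kind, cut2 - cut1, cut1, cut2)
            elif sc.kind == "deletion+insertion":
                ins = _anchored_insertion(
                    rng, sc.insertion_len, reference[cut1 - 1], reference[cut2]
                )
                # the insertion must also not extend into the deleted segment
                while ins[0] == reference[cut1] or ins[-1] == reference[cut2 - 1]:
                    ins = _anchored_insertion(
                        rng, sc.insertion_len, reference[cut1 - 1], reference[cut2]
                    )
                seq = reference[:cut1] + ins + reference[cut2:]
                truth = AmpliconTruth(
                    clone_id, sc.kind, cut2 - cut1, cut1, cut2, insertion=ins
                )
            else:  # indel-g1 / indel-g2
                cut = cut1 if sc.kind == "indel-g1" else cut2
                n = sc.indel_len
                if n < 0:
                    start = cut + n
                    if start < 0:
                        raise ValueError("indel deletion runs off the reference")
                    seq = reference[:start] + reference[cut:]
                    truth = AmpliconTruth(
                        clone_id, sc.kind, -n, start, cut, indel_len=n
                    )
                else:
                    ins = _anchored_insertion(
                        rng, n, reference[cut - 1], reference[cut]
                    )
                    seq = reference[:cut] + ins + reference[cut:]
                    truth = AmpliconTruth(
                        clone_id, sc.kind, 0, cut, cut, insertion=ins, indel_len=n
                    )
            clones.append((clone_id, seq))
            truths.append(truth)
    return clones, truths


def clones_to_fasta(clones: Sequence[tuple[str, str]]) -> str:
    out = []
    for clone_id, seq in clones:
        out.append(f">{clone_id}")
        for i in range(0, len(seq), 70):
            out.append(seq[i : i + 70])
    return "\n".join(out) + "\n"
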