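"""Selection and ranking of deletion-inducing guide pairs.

A pair consists of an upstream and a downstream guide whose blunt cut
positions bracket a user-defined deletion window; perfect rejoining of
the two cut ends removes ``cut_down - cut_up`` base pairs (the predicted
deletion size, Δ).  Candidate guides pass a GC window (40-70% by
default), the score policy (individual >= 0.2, pair sum >= 0.4) and the
per-mismatch off-target caps before pairing; surviving pairs are ranked
by pair score, then total off-target burden, then a preference for C as
the PAM variable base, then larger Δ, then position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .genome_io import AnnotationSet, Genome
from .guide_discovery import (
    GuideCandidate,
    PAM_LEN,
    find_guides,
    gc_filter,
)
from .offtarget_search import (
    OffTargetPolicy,
    OffTargetProfile,
    build_profile,
    evaluate_policy,
    search_mismatch,
)
from .scoring import ScorePolicy, extract_context, score_guide, score_pair


@dataclass
class TargetRegion:
    """The genomic window to excise and how far around it guides may sit."""

    seq_id: str
    window_start: int  # 0-based half-open deletion window
    window_end: int
    flank_search_width: int = 1000

    def __post_init__(self) -> None:
        if self.window_end <= self.window_start:
            raise ValueError("deletion window must be non-empty")
        if self.flank_search_width < 17 + PAM_LEN:
            raise ValueError("flank_search_width must cover a spacer plus PAM")


@dataclass
class GuidePair:
    guide_up: GuideCandidate
    guide_down: GuideCandidate
    pair_score: float = 0.0
    profile_up: Optional[OffTargetProfile] = None
    profile_down: Optional[OffTargetProfile] = None

    def __post_init__(self) -> None:
        if self.guide_up.seq_id != self.guide_down.seq_id:
            raise ValueError("paired guides must sit on the same contig")
        if self.guide_up.cut_pos > self.guide_down.cut_pos:
            raise ValueError("guide_up must cut 5' of guide_down")

    @property
    def predicted_deletion_bp(self) -> int:
        return predict_deletion(self)

    @property
    def total_offtargets(self) -> int:
        n = 0
        for p in (self.profile_up, self.profile_down):
            if p is not None:
                n += p.total_offtargets
        return n

    @property
    def c_pam_count(self) -> int:
        return sum(
            1
            for g in (self.guide_up, self.guide_down)
            if g.pam_variable_base == "C"
        )


def predict_deletion(pair: GuidePair) -> int:
    """Base pairs removed by perfect rejoining of the two blunt cuts.

    Inter-base cut arithmetic: Δ = cut_down - cut_up, independent of the
    strands the guides sit on.
    """
    if pair.guide_up.seq_id != pair.guide_down.seq_id:
        raise ValueError("paired guides must sit on the same contig")
    return pair.guide_down.cut_pos - pair.guide_up.cut_pos


@dataclass
class DesignDiagnostics:
    """Per-stage elimination counts for one design run."""

    n_candidates_up: int = 0
    n_candidates_down: int = 0
    eliminated_gc: int = 0
    eliminated_score: int = 0
    eliminated_offtarget: int = 0
    n_passing_up: int = 0
    n_passing_down: int = 0
    n_pairs: int = 0

    def summary(self) -> str:
        return (
            f"candidates: {self.n_candidates_up} upstream, "
            f"{self.n_candidates_down} downstream; eliminated "
            f"{self.eliminated_gc} at GC, {self.eliminated_score} at score, "
            f"{self.eliminated_offtarget} at off-target policy; "
            f"{self.n_pairs} pair(s) emitted"
        )


@dataclass
class DesignResult:
    pairs: list[GuidePair] = field(default_factory=list)
    diagnostics: DesignDiagnostics = field(default_factory=DesignDiagnostics)


def design(
    genome: Genome,
    region: TargetRegion,
    annotation: Optional[AnnotationSet] = None,
    score_policy: Optional[ScorePolicy] = None,
    offtarget_policy: Optional[OffTargetPolicy] = None,
    gc_bounds: tuple[float, float] = (40.0, 70.0),
    spacer_length: int = 19,
    max_pairs: Optional[int] = None,
) -> DesignResult:
    """Design ranked guide pairs bracketing the deletion window.

    Upstream guides cut within ``flank_search_width`` of the window
    start, downstream guides within the same distance of the window end
    (cuts may fall inside the window near its edges).  Every emitted pair
    satisfies the GC window, the score policy and the off-target caps for
    both guides.  Ranking: pair score desc, total off-target count asc,
    C-PAM count desc, Δ desc, leftmost coordinate asc.
    """
    if score_policy is None:
        score_policy = ScorePolicy()
    if offtarget_policy is None:
        offtarget_policy = OffTargetPolicy()
    if region.seq_id not in genome:
        raise KeyError(f"unknown sequence id {region.seq_id!r}")
    contig_len = len(genome[region.seq_id])
    if not (0 <= region.window_start < region.window_end <= contig_len):
        raise IndexError("deletion window outside contig bounds")

    diag = DesignDiagnostics()
    flank = region.flank_search_width
    pad = spacer_length + PAM_LEN
    scan_start = max(0, region.window_start - flank - pad)
    scan_end = min(contig_len, region.window_end + flank + pad)
    candidates = find_guides(
        genome, region.seq_id, scan_start, scan_end, spacer_length=spacer_length
    )

    up_zone = (region.window_start - flank, region.window_start + flank)
    down_zone = (region.window_end - flank, region.window_end + flank)
    ups = [c for c in candidates if up_zone[0] <= c.cut_pos <= up_zone[1]]
    downs = [c for c in candidates if down_zone[0] <= c.cut_pos <= down_zone[1]]
    diag.n_candidates_up = len(ups)
    diag.n_candidates_down = len(downs)

    def filter_stage(cands: list[GuideCandidate]) -> list[GuideCandidate]:
        kept = gc_filter(cands, *gc_bounds)
        diag.eliminated_gc += len(cands) - len(kept)
        scored = []
        for c in kept:
            context, pam_index = extract_context(genome, c)
            score_guide(c, context, pam_index, scorer=score_policy.scorer_name)
            if c.score >= score_policy.min_individual:
                scored.append(c)
            else:
                diag.eliminated_score += 1
        passing = []
        for c in scored:
            profile = profile_guide(genome, c, annotation, offtarget_policy)
            if evaluate_policy(profile, offtarget_policy).passed:
                c_profile[id(c)] = profile
                passing.append(c)
            else:
                diag.eliminated_offtarget += 1
        return passing

    c_profile: dict[int, OffTargetProfile] = {}
    ups = filter_stage(ups)
    downs = filter_stage(downs)
    diag.n_passing_up = len(ups)
    diag.n_passing_down = len(downs)

    pairs: list[GuidePair] = []
    for gu in ups:
        for gd in downs:
            if gu.cut_pos >= gd.cut_pos:
                continue
            if not (gu.score is not None and gd.score is not None):
                continue
            if score_pair(gu.score, gd.score) < score_policy.min_pair:
                continue
            pairs.append(
                GuidePair(
                    guide_up=gu,
                    guide_down=gd,
                    pair_score=score_pair(gu.score, gd.score),
                    profile_up=c_profile[id(gu)],
                    profile_down=c_profile[id(gd)],
                )
            )
    pairs.sort(
        key=lambda p: (
            -p.pair_score,
            p.total_offtargets,
            -p.c_pam_count,
            -p.predicted_deletion_bp,
            p.guide_up.spacer_start,
            p.guide_down.spacer_start,
        )
    )
    if max_pairs is not None:
        pairs = pairs[:max_pairs]
    diag.n_pairs = len(pairs)
    return DesignResult(pairs=pairs, diagnostics=diag)


def profile_guide(
    genome: Genome,
    candidate: GuideCandidate,
    annotation: Optional[AnnotationSet] = None,
    policy: Optional[OffTargetPolicy] = None,
) -> OffTargetProfile:
    """Genome-wide mismatch profile for one guide, on-target excluded."""
    if policy is None:
        policy = OffTargetPolicy()
    max_mm = max(policy.max_hits_at_mismatch)
    hits = search_mismatch(genome, candidate.spacer, max_mm=max_mm)
    return build_profile(
        candidate.spacer,
        hits,
        on_target_site=(candidate.seq_id, candidate.strand, candidate.spacer_start),
        genome=genome,
        annotation=annotation,
    )


def pairs_to_tsv(pairs: list[GuidePair]) -> str:
    """One row per pair: both guides' fields, Δ, pair score, off-target totals."""
    header = "\t".join(
        [
            "seq_id",
            "up_spacer", "up_pam", "up_strand", "up_start", "up_cut", "up_gc", "up_score",
            "down_spacer", "down_pam", "down_strand", "down_start", "down_cut",
            "down_gc", "down_score",
            "pair_score", "deletion_bp", "offtargets_up", "offtargets_down",
        ]
    )
    lines = [header]
    for p in pairs:
        gu, gd = p.guide_up, p.guide_down
        lines.append(
            "\t".join(
                [
                    gu.seq_id,
                    gu.spacer, gu.pam, gu.strand, str(gu.spacer_start + 1),
                    str(gu.cut_pos), f"{gu.gc_percent:.1f}",
                    f"{gu.score:.3f}" if gu.score is not None else "",
                    gd.spacer, gd.pam, gd.strand, str(gd.spacer_start + 1),
                    str(gd.cut_pos), f"{gd.gc_percent:.1f}",
                    f"{gd.score:.3f}" if gd.score is not None else "",
                    f"{p.pair_score:.3f}",
                    str(p.predicted_deletion_bp),
                    str(p.profile_up.total_offtargets if p.profile_up else 0),
                    str(p.profile_down.total_offtargets if p.profile_down else 0),
                ]
            )
        )
    return "\n".join(lines) + "\n"
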