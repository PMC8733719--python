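"""On-target activity scoring for guide candidates and guide pairs.

The selection policy uses two thresholds: a minimum individual score of
0.2 per guide and a minimum paired score of 0.4, with the pair score
defined as the sum of the two individual scores (the only combination
rule under which the two thresholds coincide at the boundary).

Scorers are pluggable: any callable mapping a protospacer-strand sequence
context to a value in [0, 1] can be registered by name.  The default
``position_weight`` scorer is a logistic position-weight model — each
(position, base) pair relative to the PAM contributes an additive
log-odds weight read from a packaged table — and a constant ``null``
scorer (0.5 everywhere) exists for tests and for ranking-free selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Optional

from .genome_io import Genome, fetch_subsequence
from .guide_discovery import GuideCandidate, PAM_LEN

#: scorer signature: (context, pam_index, spacer_length) -> score in [0, 1]
Scorer = Callable[[str, int, int], float]

SCORERS: dict[str, Scorer] = {}

DEFAULT_FLANK_5 = 4
DEFAULT_FLANK_3 = 4


def register_scorer(name: str) -> Callable[[Scorer], Scorer]:
    def deco(fn: Scorer) -> Scorer:
        SCORERS[name] = fn
        return fn

    return deco


def _load_weight_table() -> dict[tuple[int, str], float]:
    weights: dict[tuple[int, str], float] = {}
    text = (
        resources.files("paircut").joinpath("data/position_weights.tsv").read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("offset"):
            continue
        offset, base, weight = line.split("\t")
        weights[(int(offset), base)] = float(weight)
    return weights


_WEIGHTS: Optional[dict[tuple[int, str], float]] = None


def position_weights() -> dict[tuple[int, str], float]:
    global _WEIGHTS
    if _WEIGHTS is None:
        _WEIGHTS = _load_weight_table()
    return _WEIGHTS


@register_scorer("position_weight")
def position_weight_scorer(context: str, pam_index: int, spacer_length: int) -> float:
    """Logistic position-weight activity model.

    The score is ``1 / (1 + exp(-s))`` where ``s`` sums the table weight
    of the base observed at every weighted offset relative to the PAM.
    Offsets outside the provided context raise an error (the context is
    too short for the scorer).
    """
    weights = position_weights()
    needed = {off for off, _ in weights}
    min_off = min(needed)
    max_off = max(needed)
    if pam_index + min_off < 0 or pam_index + max_off >= len(context):
        raise ValueError(
            f"context too short: scorer needs offsets [{min_off}, {max_off}] "
            f"around PAM index {pam_index} in a context of length {len(context)}"
        )
    s = 0.0
    for (offset, base), w in weights.items():
        if -offset > spacer_length:
            continue  # weight beyond the 5' end of a short spacer
        if context[pam_index + offset] == base:
            s += w
    return 1.0 / (1.0 + math.exp(-s))


@register_scorer("null")
def null_scorer(context: str, pam_index: int, spacer_length: int) -> float:
    """Constant 0.5 — useful for tests and score-free selection."""
    if pam_index < 0 or pam_index >= len(context):
        raise ValueError("context too short: PAM index outside context")
    return 0.5


def extract_context(
    genome: Genome,
    candidate: GuideCandidate,
    flank5: int = DEFAULT_FLANK_5,
    flank3: int = DEFAULT_FLANK_3,
) -> tuple[str, int]:
    """Fetch the protospacer-strand scoring context for a candidate.

    Returns ``(context, pam_index)`` where ``context`` covers
    ``flank5 + spacer + PAM + flank3`` on the protospacer strand and
    ``pam_index`` is the context index of the PAM variable base.
    Raises if the candidate sits too close to a contig edge.
    """
    L = candidate.spacer_length
    if candidate.strand == "+":
        start = candidate.spacer_start - flank5
        end = candidate.pam_end + flank3
    else:
        start = candidate.pam_start - flank3
        end = candidate.spacer_end + flank5
    length = len(genome[candidate.seq_id])
    if start < 0 or end > length:
        raise ValueError(
            f"context too short: guide at {candidate.seq_id}:"
            f"{candidate.spacer_start} is within {flank5}/{flank3} bp of a contig edge"
        )
    context = fetch_subsequence(
        genome, candidate.seq_id, start, end, candidate.strand
    )
    return context, flank5 + L


def score_guide(
    candidate: GuideCandidate,
    context: str,
    pam_index: Optional[int] = None,
    scorer: str = "position_weight",
) -> float:
    """Score a candidate in [0, 1] from its sequence context and store it.

    ``pam_index`` defaults to ``spacer_length + default 5' flank``, the
    layout produced by :func:`extract_context`.
    """
    if scorer not in SCORERS:
        raise KeyError(f"unknown scorer {scorer!r}; registered: {sorted(SCORERS)}")
    if pam_index is None:
        pam_index = DEFAULT_FLANK_5 + candidate.spacer_length
    if len(context) < candidate.spacer_length + PAM_LEN:
        raise ValueError("context too short: must cover protospacer and PAM")
    value = SCORERS[scorer](context, pam_index, candidate.spacer_length)
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"scorer {scorer!r} returned {value}, outside [0, 1]")
    candidate.score = value
    return value


@dataclass
class ScorePolicy:
    """Thresholds for individual and paired guide scores."""

    min_individual: float = 0.2
    min_pair: float = 0.4
    scorer_name: str = "position_weight"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_individual <= 1.0):
            raise ValueError("min_individual must lie in [0, 1]")
        if not (0.0 <= self.min_pair <= 2.0):
            raise ValueError("min_pair must lie in [0, 2]")


def score_pair(s1: float, s2: float) -> float:
    """Pair score: sum of the two individual scores (symmetric)."""
    return s1 + s2


def passes_scores(s1: float, s2: float, policy: ScorePolicy = ScorePolicy()) -> bool:
    """True iff both guides meet the individual threshold and the pair the
    paired threshold (inclusive comparisons)."""
    return (
        s1 >= policy.min_individual
        and s2 >= policy.min_individual
        and score_pair(s1, s2) >= policy.min_pair
    )
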