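"""Study-level summary arithmetic: editing rates, genotype-class
frequencies, and phenotype percent-reduction.

All percentages are rounded half-up to one decimal, the convention used
in the source tables this module's outputs mirror (e.g. 6/34 -> 17.6,
6/157 -> 3.8, 6/19 -> 31.6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

GENOTYPE_CLASSES = ("chi", "Aa", "aa")


def _round1(value: float) -> float:
    """Half-up rounding to one decimal (banker's rounding would disagree
    on e.g. x.x5 boundaries)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def editing_rate(n_edited: int, n_regenerated: int) -> float:
    """Edited lines / regenerated plantlets, as a percentage (1 decimal)."""
    if n_regenerated <= 0:
        raise ValueError("n_regenerated must be positive")
    if not (0 <= n_edited <= n_regenerated):
        raise ValueError("n_edited must lie in [0, n_regenerated]")
    return _round1(100.0 * n_edited / n_regenerated)


def class_frequency(n_class: int, n_total_edited: int) -> float:
    """Lines of one genotype class / total edited lines, as a percentage."""
    if n_total_edited <= 0:
        raise ValueError("n_total_edited must be positive")
    if n_class < 0:
        raise ValueError("n_class must be non-negative")
    return _round1(100.0 * n_class / n_total_edited)


def percent_reduction(wt_value: float, line_value: float) -> float:
    """Signed percent decrease of a line's metric relative to wild type.

    ``100 * (wt - line) / wt``; negative when the line exceeds wild type
    (a worse-than-WT phenotype).
    """
    if wt_value <= 0:
        raise ValueError("wt_value must be positive")
    if line_value < 0:
        raise ValueError("line_value must be non-negative")
    return _round1(100.0 * (wt_value - line_value) / wt_value)


@dataclass
class GeneEditingSummary:
    """Per-gene editing outcome: counts, rate, and class breakdown."""

    gene: str
    n_edited: int
    n_regenerated: int
    class_counts: dict[str, int] = field(default_factory=dict)
    #: denominator for class frequencies; the pooled total of edited lines
    #: across the experiment (defaults to this gene's edited count)
    total_edited_pool: Optional[int] = None

    @property
    def rate(self) -> float:
        return editing_rate(self.n_edited, self.n_regenerated)

    def frequencies(self) -> dict[str, float]:
        pool = self.total_edited_pool or self.n_edited
        return {
            cls: class_frequency(self.class_counts.get(cls, 0), pool)
            for cls in GENOTYPE_CLASSES
        }


def summarize_editing(
    summaries: Iterable[GeneEditingSummary],
) -> str:
    """TSV table mirroring the per-gene editing-outcome layout."""
    rows = ["gene\tedited/regenerated\tediting_rate_pct\tclass\tcount\tfrequency_pct"]
    for s in summaries:
        freqs = s.frequencies()
        first = True
        for cls in GENOTYPE_CLASSES:
            rows.append(
                "\t".join(
                    [
                        s.gene if first else "",
                        f"{s.n_edited}/{s.n_regenerated}" if first else "",
                        f"{s.rate:.1f}" if first else "",
                        cls,
                        str(s.class_counts.get(cls, 0)),
                        f"{freqs[cls]:.1f}",
                    ]
                )
            )
            first = False
    return "\n".join(rows) + "\n"


@dataclass
class PhenotypeRecord:
    """One line's disease metric against the wild-type mean."""

    line_id: str
    metric: str  # e.g. "infected-leaf-area %", "lesion-diameter mm"
    line_value: float
    wt_value: float
    significance: str = "ns"  # free text supplied by the user

    @property
    def reduction(self) -> float:
        return percent_reduction(self.wt_value, self.line_value)


def summarize_phenotype(records: Iterable[PhenotypeRecord]) -> str:
    """TSV table of per-line values and signed percent reductions."""
    rows = ["line_id\tmetric\tvalue\twt_value\treduction_pct\tsignificance"]
    for r in records:
        rows.append(
            "\t".join(
                [
                    r.line_id,
                    r.metric,
                    f"{r.line_value:g}",
                    f"{r.wt_value:g}",
                    f"{r.reduction:.1f}",
                    r.significance,
                ]
            )
        )
    return "\n".join(rows) + "\n"
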