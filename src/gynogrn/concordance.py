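"""Phenotype penetrance arithmetic and model/mutant concordance.

The knockout panel makes qualitative predictions: a perturbed circuit
whose steady state differs from wild type predicts disturbed gynoecium
development in the corresponding mutant.  This module carries the
reported experimental counts as a versioned JSON fixture, computes
penetrance percentages from them, and reconciles each in silico
knockout with the observed mutant phenotype.

Penetrance is the fraction of examined gynoecia of a genotype that show
the phenotype, printed as a percentage with one decimal, rounded
half-up (so 14/16 -> 87.5, 20/26 -> 76.9).  Percentages that were
reported without their underlying counts are stored as-is, flagged
``counts_printed=False``, and never recomputed.  Concordance itself is
qualitative — altered vs unaltered — because a Boolean steady state
carries no effect size.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

__all__ = [
    "ObservationRecord",
    "ConcordanceRow",
    "penetrance",
    "load_observations",
    "concordance_table",
    "format_concordance_tsv",
    "summarize_concordance",
]


def penetrance(affected: int, total: int) -> float:
    """``100 * affected / total``, rounded half-up to one decimal."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= affected <= total:
        raise ValueError(f"affected must lie in [0, total]; got "
                         f"{affected}/{total}")
    pct = Decimal(100) * Decimal(affected) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ObservationRecord:
    """One reported phenotype count (or qualitative report).

    ``perturbation`` names the clamped node of the knockout panel this
    record is matched to, or ``None`` for records kept only for
    penetrance arithmetic.  ``counts_printed`` distinguishes counts
    that can be recomputed from percentages reported bare.
    """

    label: str
    genotype: str
    phenotype: str
    altered: bool
    affected: int | None = None
    total: int | None = None
    reported_percent: float | None = None
    counts_printed: bool = True
    perturbation: str | None = None
    assay: str = ""
    note: str = ""

    def __post_init__(self):
        if self.affected is not None and self.total is not None:
            if not (self.total >= 1 and 0 <= self.affected <= self.total):
                raise ValueError(
                    f"{self.label}: invalid counts {self.affected}/"
                    f"{self.total}")

    @property
    def penetrance(self) -> float | None:
        """Recomputed penetrance, or the reported value when counts
        were not printed."""
        if self.counts_printed and self.affected is not None \
                and self.total is not None:
            return penetrance(self.affected, self.total)
        return self.reported_percent


def load_observations() -> list:
    """Load the packaged observation fixture."""
    text = (resources.files("gynogrn") / "data" / "observations.json"
            ).read_text(encoding="utf-8")
    payload = json.loads(text)
    return [ObservationRecord(
        label=rec["label"],
        genotype=rec["genotype"],
        phenotype=rec["phenotype"],
        altered=rec["altered"],
        affected=rec.get("affected"),
        total=rec.get("total"),
        reported_percent=rec.get("reported_percent"),
        counts_printed=rec.get("counts_printed", True),
        perturbation=rec.get("perturbation"),
        assay=rec.get("assay", ""),
        note=rec.get("note", ""),
    ) for rec in payload["observations"]]


@dataclass(frozen=True)
class ConcordanceRow:
    """One knockout reconciled with its observed phenotype."""

    node: str
    value: int
    model_altered: bool
    observation: ObservationRecord | None
    concordant: bool | None  # None when no observation is matched

    @property
    def observed_altered(self) -> bool | None:
        return self.observation.altered if self.observation else None


def concordance_table(panel, observations=None) -> list:
    """Match each perturbation to at most one observation by node name.

    ``concordant`` is true iff the model's altered/unaltered call equals
    the reported phenotype call.  Observations that match no panel entry
    trigger a warning (not a failure): the fixture also carries records
    kept purely for penetrance arithmetic.
    """
    if observations is None:
        observations = load_observations()
    by_node: dict = {}
    for obs in observations:
        if obs.perturbation is None:
            continue
        if obs.perturbation in by_node:
            raise ValueError(
                f"more than one observation mapped to {obs.perturbation!r}")
        by_node[obs.perturbation] = obs
    rows = []
    for result in panel:
        obs = by_node.pop(result.node, None)
        concordant = None if obs is None \
            else (result.altered == obs.altered)
        rows.append(ConcordanceRow(
            node=result.node, value=result.value,
            model_altered=result.altered, observation=obs,
            concordant=concordant))
    for node in by_node:
        warnings.warn(f"observation mapped to {node!r} matched no "
                      f"perturbation in the panel", stacklevel=2)
    return rows


def format_concordance_tsv(rows) -> str:
    """Tab-separated concordance table (UTF-8, Unix newlines)."""
    header = ["perturbation", "clamped_value", "model_altered", "genotype",
              "observed_phenotype", "penetrance_percent", "concordant"]
    lines = ["\t".join(header)]
    for row in rows:
        obs = row.observation
        pen = obs.penetrance if obs else None
        lines.append("\t".join([
            row.node,
            str(row.value),
            str(row.model_altered).lower(),
            obs.genotype if obs else "",
            obs.phenotype if obs else "",
            "" if pen is None else f"{pen:.1f}",
            "" if row.concordant is None else str(row.concordant).lower(),
        ]))
    return "\n".join(lines) + "\n"


def summarize_concordance(rows) -> str:
    """Human-readable one-paragraph summary of the concordance table."""
    matched = [r for r in rows if r.concordant is not None]
    agree = sum(1 for r in matched if r.concordant)
    parts = [
        f"{len(rows)} in silico knockouts; "
        f"{sum(1 for r in rows if r.model_altered)} alter the steady state."
    ]
    parts.append(f"{agree}/{len(matched)} matched observations are "
                 f"concordant with the model call.")
    for r in rows:
        if r.observation:
            pen = r.observation.penetrance
            pen_txt = f", penetrance {pen:.1f}%" if pen is not None else ""
            parts.append(f"  {r.node}<-{r.value}: model "
                         f"{'altered' if r.model_altered else 'unaltered'}; "
                         f"observed {r.observation.genotype} "
                         f"{'altered' if r.observation.altered else 'normal'}"
                         f"{pen_txt}.")
    return "\n".join(parts) + "\n"
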