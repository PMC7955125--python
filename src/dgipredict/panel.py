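"""Evidence weighting and greedy panel selection.

Genomic direction calls and transcriptome drug-response scores (DRS) are
combined into one of five weighted evidence categories per drug–sample
cell:

=====================  ==========================================
category               composition
=====================  ==========================================
CONFLICTING            resistance prediction + positive DRS
MUTATION_DEPENDENT     variant-dependent prediction, with or without DRS
RESISTANCE             resistance prediction, no positive DRS
SENSITIVITY            sensitivity or unspecific-sensitivity prediction
                       without DRS support, or positive DRS alone
SENSITIVITY_STRONG     sensitivity or unspecific-sensitivity prediction
                       corroborated by a positive DRS
NONE                   no prediction and no positive DRS
=====================  ==========================================

"no DRS" covers both an absent score and a non-positive one — a negative
score is non-informative, never a resistance signal.

A minimal gene panel is then chosen by greedy set cover: iteratively pick
the gene covering the most yet-uncovered samples (ties broken
lexicographically) until no gene adds coverage or a target coverage is
reached.  The covered fraction of the cohort measures the panel's reach.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

from .evidence import Direction, DirectedPrediction


class EvidenceCategory(str, enum.Enum):
    CONFLICTING = "CONFLICTING"
    MUTATION_DEPENDENT = "MUTATION_DEPENDENT"
    RESISTANCE = "RESISTANCE"
    SENSITIVITY = "SENSITIVITY"
    SENSITIVITY_STRONG = "SENSITIVITY_STRONG"
    NONE = "NONE"


def evidence_category(
    direction: Direction | None, drs_positive: bool | None
) -> EvidenceCategory:
    """Weighted evidence category of one (direction, DRS) combination.

    ``drs_positive`` is True for a positive score, False for a non-positive
    score, None when no score exists; the latter two are equivalent
    ("no DRS").
    """
    positive = bool(drs_positive)
    if direction is None:
        return EvidenceCategory.SENSITIVITY if positive else EvidenceCategory.NONE
    if direction is Direction.VARIANT_DEPENDENT:
        return EvidenceCategory.MUTATION_DEPENDENT
    if direction is Direction.RESISTANCE:
        return EvidenceCategory.CONFLICTING if positive else EvidenceCategory.RESISTANCE
    # SENSITIVITY or SENSITIVITY_UNSPECIFIC
    return EvidenceCategory.SENSITIVITY_STRONG if positive else EvidenceCategory.SENSITIVITY


@dataclass(frozen=True)
class EvidenceCell:
    sample_id: str
    drug: str
    category: EvidenceCategory
    genes: tuple[str, ...] = ()


_POLE = {
    Direction.SENSITIVITY: +1,
    Direction.SENSITIVITY_UNSPECIFIC: +1,
    Direction.RESISTANCE: -1,
    Direction.VARIANT_DEPENDENT: 0,
}


def _reduce_directions(directions: set[Direction]) -> Direction:
    """One representative direction for a multi-gene drug–sample cell.

    Mixed sensitivity/resistance poles are resolved upstream (CONFLICTING
    dominates); here the remaining set is pole-consistent.  A gene-internal
    mixture (VARIANT_DEPENDENT) outranks a plain direction, and a
    variant-attributed sensitivity outranks an unspecific one.
    """
    if Direction.VARIANT_DEPENDENT in directions:
        return Direction.VARIANT_DEPENDENT
    if Direction.RESISTANCE in directions:
        return Direction.RESISTANCE
    if Direction.SENSITIVITY in directions:
        return Direction.SENSITIVITY
    return Direction.SENSITIVITY_UNSPECIFIC


def build_evidence_matrix(
    predictions: Sequence[DirectedPrediction],
    drs_positive: Mapping[tuple[str, str], bool],
    cohort: Sequence[str],
    drugs: Sequence[str],
) -> list[EvidenceCell]:
    """One evidence cell per (drug, sample).

    Predictions from several genes are reduced to one cell state: opposing
    directions make the cell CONFLICTING outright; otherwise the shared
    direction combines with DRS positivity via the category table.
    """
    by_cell: dict[tuple[str, str], list[DirectedPrediction]] = {}
    for p in predictions:
        by_cell.setdefault((p.sample_id, p.drug), []).append(p)

    cells = []
    for drug in drugs:
        for sample_id in cohort:
            preds = by_cell.get((sample_id, drug), [])
            genes = tuple(sorted({p.gene for p in preds}))
            positive = drs_positive.get((sample_id, drug))
            if not preds:
                category = evidence_category(None, positive)
            else:
                poles = {_POLE[p.direction] for p in preds}
                if +1 in poles and -1 in poles:
                    category = EvidenceCategory.CONFLICTING
                else:
                    direction = _reduce_directions({p.direction for p in preds})
                    category = evidence_category(direction, positive)
            cells.append(EvidenceCell(sample_id, drug, category, genes))
    return cells


# -- greedy set cover -----------------------------------------------------

@dataclass(frozen=True)
class SelectionStep:
    gene: str
    marginal_gain: int
    cumulative_coverage: float


@dataclass(frozen=True)
class PanelResult:
    genes: tuple[str, ...]
    drugs: tuple[str, ...]
    covered_samples: frozenset[str]
    coverage_fraction: float
    selection_trace: tuple[SelectionStep, ...]


def greedy_set_cover(
    universe: Sequence[str],
    gene_to_samples: Mapping[str, frozenset[str] | set[str]],
    gene_to_drugs: Mapping[str, Sequence[str]] | None = None,
    target_coverage: float | None = None,
) -> PanelResult:
    """Greedy minimum set cover of the cohort by genes.

    Each round selects the gene covering the most yet-uncovered samples
    (lexicographically smallest symbol on ties) and stops when no gene adds
    coverage or ``target_coverage`` is reached.  The drug panel is the
    union of drugs attached to the selected genes.
    """
    universe_set = frozenset(universe)
    if not universe_set:
        raise ValueError("set cover requires a non-empty universe")
    sets = {g: frozenset(s) & universe_set for g, s in gene_to_samples.items()}

    covered: set[str] = set()
    selected: list[str] = []
    trace: list[SelectionStep] = []
    while True:
        if target_coverage is not None and len(covered) / len(universe_set) >= target_coverage:
            break
        best_gene, best_gain = None, 0
        for gene in sorted(sets):
            if gene in selected:
                continue
            gain = len(sets[gene] - covered)
            if gain > best_gain:
                best_gene, best_gain = gene, gain
        if best_gene is None:
            break
        covered |= sets[best_gene]
        selected.append(best_gene)
        trace.append(
            SelectionStep(best_gene, best_gain, len(covered) / len(universe_set))
        )

    drugs: set[str] = set()
    if gene_to_drugs:
        for g in selected:
            drugs.update(gene_to_drugs.get(g, ()))
    return PanelResult(
        genes=tuple(selected),
        drugs=tuple(sorted(drugs)),
        covered_samples=frozenset(covered),
        coverage_fraction=len(covered) / len(universe_set),
        selection_trace=tuple(trace),
    )


def coverage_fraction(
    predictions: Sequence[DirectedPrediction],
    cohort: Sequence[str],
    genes: Sequence[str] | None = None,
    drugs: Sequence[str] | None = None,
) -> float:
    """Fraction of cohort samples with at least one directed prediction.

    Optionally restricted to a panel's genes and/or drugs.
    """
    cohort_set = set(cohort)
    if not cohort_set:
        return 0.0
    gene_set = set(genes) if genes is not None else None
    drug_set = set(drugs) if drugs is not None else None
    covered = {
        p.sample_id
        for p in predictions
        if p.sample_id in cohort_set
        and (gene_set is None or p.gene in gene_set)
        and (drug_set is None or p.drug in drug_set)
    }
    return len(covered) / len(cohort_set)
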