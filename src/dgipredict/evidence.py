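"""Evidence integration: assigning a response direction to candidate DGIs.

Two evidence tiers can direct a candidate drug–gene interaction:

* **variant-level clinical evidence** (CIViC-style): items matching the
  candidate's variant (exactly, or via a gene-level wildcard) are first
  restricted to the target disease when any target-disease item exists,
  items without a stated direction are discarded, and a strict majority
  vote over sensitivity vs resistance decides; a tie resolves to UNKNOWN
  and the candidate is dropped;
* **manual curation**: variant-specific records matching the candidate's
  variant dominate; disagreeing variant-specific records within one gene
  yield a gene-level VARIANT_DEPENDENT call; an any-variant sensitivity
  record with no variant resolution yields SENSITIVITY_UNSPECIFIC; records
  that are all UNKNOWN drop the candidate.

Candidates supported by neither tier, or resolving to UNKNOWN in every
tier, are dropped with a machine-readable reason.  Retained predictions
never carry UNKNOWN.  Opposing directions for the same (sample, drug) —
within one tier or between tiers — are reported as divergences rather than
suppressed.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .dgi import CandidateDGI
from .knowledgebase import (
    CivicEvidence,
    CurationRecord,
    KnowledgeBase,
    Significance,
    VariantScope,
)


class Direction(str, enum.Enum):
    """Resolved response direction of a prediction (never UNKNOWN)."""

    SENSITIVITY = "SENSITIVITY"
    RESISTANCE = "RESISTANCE"
    #: sensitivity not attributable to a particular variant of the gene
    SENSITIVITY_UNSPECIFIC = "SENSITIVITY_UNSPECIFIC"
    #: different variants of the gene drive opposing directions
    VARIANT_DEPENDENT = "VARIANT_DEPENDENT"


class EvidenceSource(str, enum.Enum):
    CIVIC = "CIVIC"
    CURATION = "CURATION"


class DropReason(str, enum.Enum):
    NO_EVIDENCE = "NO_EVIDENCE"
    UNKNOWN_DIRECTION = "UNKNOWN_DIRECTION"
    TIE = "TIE"


class DivergenceKind(str, enum.Enum):
    WITHIN_CIVIC = "WITHIN_CIVIC"
    WITHIN_CURATION = "WITHIN_CURATION"
    BETWEEN_SOURCE = "BETWEEN_SOURCE"


@dataclass(frozen=True)
class DirectedPrediction:
    sample_id: str
    drug: str
    gene: str
    direction: Direction
    source: EvidenceSource
    supporting_items: tuple[str, ...] = ()


@dataclass(frozen=True)
class DroppedCandidate:
    candidate: CandidateDGI
    reason: DropReason


@dataclass(frozen=True)
class DivergenceReport:
    sample_id: str
    drug: str
    kind: DivergenceKind
    conflicting_predictions: tuple[DirectedPrediction, ...]

    def __post_init__(self) -> None:
        if len(self.conflicting_predictions) < 2:
            raise ValueError("a divergence needs at least two predictions")


# -- CIViC-style resolution ----------------------------------------------

def match_civic(candidate: CandidateDGI, kb: KnowledgeBase) -> list[CivicEvidence]:
    """Evidence items applicable to the candidate's variant.

    An item applies when its (gene, drug) matches and its variant
    descriptor equals the candidate's descriptor (protein change for SNVs,
    AMPLIFICATION/DELETION for copy-number events) or is the gene-level
    wildcard ``*``.
    """
    descriptor = candidate.variant_descriptor
    return [
        ev
        for ev in kb.civic_for(candidate.gene, candidate.drug)
        if ev.variant_descriptor == "*" or ev.variant_descriptor == descriptor
    ]


def civic_vote_counts(
    items: Sequence[CivicEvidence],
) -> tuple[int, int, list[CivicEvidence]]:
    """(sensitivity, resistance) vote counts after prioritization.

    Target-disease items, when present, exclude all others before the vote;
    directionless items never count.  Returns the counted items as well.
    """
    target = [ev for ev in items if ev.is_target_disease]
    pool = target if target else list(items)
    countable = [ev for ev in pool if ev.significance is not Significance.UNKNOWN]
    votes = Counter(ev.significance for ev in countable)
    return (
        votes[Significance.SENSITIVITY],
        votes[Significance.RESISTANCE],
        countable,
    )


def resolve_direction_civic(items: Sequence[CivicEvidence]) -> Significance:
    """Majority-vote direction of a set of evidence items.

    Empty input, no countable items, or a tied vote resolve to UNKNOWN.
    """
    if not items:
        return Significance.UNKNOWN
    n_sens, n_res, _ = civic_vote_counts(items)
    if n_sens > n_res:
        return Significance.SENSITIVITY
    if n_res > n_sens:
        return Significance.RESISTANCE
    return Significance.UNKNOWN


# -- manual-curation resolution ------------------------------------------

class CurationCall(str, enum.Enum):
    """Resolved direction classes from manual curation (UNKNOWN = drop)."""

    SENSITIVITY = "SENSITIVITY"
    RESISTANCE = "RESISTANCE"
    SENSITIVITY_UNSPECIFIC = "SENSITIVITY_UNSPECIFIC"
    VARIANT_DEPENDENT = "VARIANT_DEPENDENT"
    UNKNOWN = "UNKNOWN"


def resolve_direction_curation(
    candidate: CandidateDGI, records: Sequence[CurationRecord]
) -> tuple[CurationCall, list[CurationRecord]]:
    """Direction of a candidate under the curated records for its (gene, drug).

    Variant-specific records matching the candidate's variant dominate: a
    single directed consensus among them is returned as-is, and internal
    disagreement is a gene-level VARIANT_DEPENDENT call.  Without a
    matching specific record, disagreeing specific records elsewhere in the
    gene still force VARIANT_DEPENDENT; otherwise any-variant records
    decide, with sensitivity reported as SENSITIVITY_UNSPECIFIC because it
    cannot be pinned to the observed variant.  Conflicting any-variant
    records and all-UNKNOWN record sets resolve to UNKNOWN (drop).

    Returns the call and the records that produced it.
    """
    if not records:
        return CurationCall.UNKNOWN, []
    descriptor = candidate.variant_descriptor
    specific = [r for r in records if r.variant_scope is VariantScope.SPECIFIC_VARIANT]
    matching = [r for r in specific if r.variant_descriptor == descriptor]

    def _directed(recs: Sequence[CurationRecord]) -> list[CurationRecord]:
        return [r for r in recs if r.response is not Significance.UNKNOWN]

    matched_directed = _directed(matching)
    if matched_directed:
        directions = {r.response for r in matched_directed}
        if len(directions) > 1:
            return CurationCall.VARIANT_DEPENDENT, matched_directed
        return CurationCall(directions.pop().value), matched_directed

    specific_directed = _directed(specific)
    if len({r.response for r in specific_directed}) > 1:
        return CurationCall.VARIANT_DEPENDENT, specific_directed

    any_directed = _directed(
        [r for r in records if r.variant_scope is VariantScope.ANY_VARIANT]
    )
    if any_directed:
        directions = {r.response for r in any_directed}
        if len(directions) > 1:
            return CurationCall.UNKNOWN, any_directed
        direction = directions.pop()
        if direction is Significance.SENSITIVITY:
            return CurationCall.SENSITIVITY_UNSPECIFIC, any_directed
        return CurationCall.RESISTANCE, any_directed
    return CurationCall.UNKNOWN, list(records)


# -- integration ----------------------------------------------------------

def _civic_item_id(ev: CivicEvidence) -> str:
    return f"civic:{ev.gene}:{ev.variant_descriptor}:{ev.drug}:{ev.significance.value}:L{ev.evidence_level}"


def integrate(
    candidates: Sequence[CandidateDGI], kb: KnowledgeBase
) -> tuple[list[DirectedPrediction], list[DroppedCandidate]]:
    """Resolve every candidate to directed predictions or a dropped record.

    Each candidate yields up to two predictions (one per evidence tier);
    identical predictions from several variants of the same gene are
    deduplicated.  Every candidate is accounted for exactly once: either it
    contributed at least one prediction or it appears in the dropped list
    with a reason (NO_EVIDENCE, TIE on a split vote, UNKNOWN_DIRECTION).
    """
    predictions: dict[tuple, DirectedPrediction] = {}
    dropped: list[DroppedCandidate] = []
    for cand in candidates:
        civic_items = match_civic(cand, kb)
        curation_records = kb.curation_for(cand.gene, cand.drug)
        produced = False
        tie_seen = False

        if civic_items:
            n_sens, n_res, counted = civic_vote_counts(civic_items)
            direction = resolve_direction_civic(civic_items)
            if direction is not Significance.UNKNOWN:
                pred = DirectedPrediction(
                    sample_id=cand.sample_id,
                    drug=cand.drug,
                    gene=cand.gene,
                    direction=Direction(direction.value),
                    source=EvidenceSource.CIVIC,
                    supporting_items=tuple(sorted(_civic_item_id(e) for e in counted)),
                )
                key = (pred.sample_id, pred.drug, pred.gene, pred.direction, pred.source)
                predictions.setdefault(key, pred)
                produced = True
            elif n_sens == n_res and n_sens > 0:
                tie_seen = True

        if curation_records:
            call, used = resolve_direction_curation(cand, curation_records)
            if call is not CurationCall.UNKNOWN:
                pred = DirectedPrediction(
                    sample_id=cand.sample_id,
                    drug=cand.drug,
                    gene=cand.gene,
                    direction=Direction(call.value),
                    source=EvidenceSource.CURATION,
                    supporting_items=tuple(
                        sorted(f"curation:{r.reference_id}" for r in used)
                    ),
                )
                key = (pred.sample_id, pred.drug, pred.gene, pred.direction, pred.source)
                predictions.setdefault(key, pred)
                produced = True

        if not produced:
            if not civic_items and not curation_records:
                reason = DropReason.NO_EVIDENCE
            elif tie_seen:
                reason = DropReason.TIE
            else:
                reason = DropReason.UNKNOWN_DIRECTION
            dropped.append(DroppedCandidate(candidate=cand, reason=reason))
    return list(predictions.values()), dropped


# -- divergence detection -------------------------------------------------

_SIGN = {
    Direction.SENSITIVITY: +1,
    Direction.SENSITIVITY_UNSPECIFIC: +1,
    Direction.RESISTANCE: -1,
    Direction.VARIANT_DEPENDENT: 0,  # already mixed within one gene
}


def detect_divergences(
    predictions: Sequence[DirectedPrediction],
) -> list[DivergenceReport]:
    """Opposing sensitivity/resistance calls for one drug in one sample.

    Emits one report per applicable kind per (sample, drug): within the
    variant-level evidence tier, within manual curation, and between the
    two tiers.  VARIANT_DEPENDENT predictions are gene-internal mixtures
    and do not count as a cross-gene pole.
    """
    by_cell: dict[tuple[str, str], list[DirectedPrediction]] = {}
    for p in predictions:
        by_cell.setdefault((p.sample_id, p.drug), []).append(p)

    reports = []
    for (sample_id, drug), preds in sorted(by_cell.items()):
        directed = [p for p in preds if _SIGN[p.direction] != 0]

        def _opposing(pool: list[DirectedPrediction]) -> bool:
            signs = {_SIGN[p.direction] for p in pool}
            return +1 in signs and -1 in signs

        civic = [p for p in directed if p.source is EvidenceSource.CIVIC]
        curation = [p for p in directed if p.source is EvidenceSource.CURATION]
        if _opposing(civic):
            reports.append(
                DivergenceReport(sample_id, drug, DivergenceKind.WITHIN_CIVIC, tuple(civic))
            )
        if _opposing(curation):
            reports.append(
                DivergenceReport(sample_id, drug, DivergenceKind.WITHIN_CURATION, tuple(curation))
            )
        if civic and curation:
            cross = {(_SIGN[p.direction], p.source) for p in directed}
            if (
                ((+1, EvidenceSource.CIVIC) in cross and (-1, EvidenceSource.CURATION) in cross)
                or ((-1, EvidenceSource.CIVIC) in cross and (+1, EvidenceSource.CURATION) in cross)
            ):
                reports.append(
                    DivergenceReport(
                        sample_id, drug, DivergenceKind.BETWEEN_SOURCE, tuple(directed)
                    )
                )
    return reports
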