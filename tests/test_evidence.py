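"""Evidence integration: variant matching, majority vote, curation, divergences."""

from __future__ import annotations

import itertools

import pytest

from conftest import make_civic, make_curation, make_snv
from dgipredict.dgi import CandidateDGI, assemble_candidates
from dgipredict.evidence import (
    CurationCall,
    Direction,
    DivergenceKind,
    DropReason,
    EvidenceSource,
    DirectedPrediction,
    detect_divergences,
    integrate,
    match_civic,
    resolve_direction_civic,
    resolve_direction_curation,
)
from dgipredict.knowledgebase import (
    DGIRecord,
    KnowledgeBase,
    Significance,
    TrialCategory,
    VariantScope,
)

S, R, U = Significance.SENSITIVITY, Significance.RESISTANCE, Significance.UNKNOWN


def _candidate(gene="PIK3CA", drug="alpelisib", protein_change="E545K", sample="S1"):
    return CandidateDGI(
        sample_id=sample,
        gene=gene,
        drug=drug,
        variant_ref=make_snv(sample=sample, gene=gene, protein_change=protein_change),
        trial_category=TrialCategory.CT,
        needs_curation=False,
    )


# -- match_civic ----------------------------------------------------------

def test_exact_descriptor_match(small_kb):
    items = match_civic(_candidate(), small_kb)
    assert {i.variant_descriptor for i in items} == {"E545K"}


def test_mismatched_descriptor_not_matched(small_kb):
    assert match_civic(_candidate(protein_change="H1047R"), small_kb) == []


def test_wildcard_matches_any_variant(small_kb):
    items = match_civic(_candidate(drug="buparlisib", protein_change="H1047R"), small_kb)
    assert len(items) == 1 and items[0].variant_descriptor == "*"


# -- majority vote --------------------------------------------------------

def test_majority_wins():
    items = [make_civic(significance=S)] * 3 + [make_civic(significance=R)]
    assert resolve_direction_civic(items) is S


def test_tie_is_unknown():
    items = [make_civic(significance=S)] * 2 + [make_civic(significance=R)] * 2
    assert resolve_direction_civic(items) is U


def test_target_disease_restriction_precedes_vote():
    items = [make_civic(significance=R, target=True)] + [
        make_civic(significance=S, target=False) for _ in range(5)
    ]
    assert resolve_direction_civic(items) is R


def test_empty_or_directionless_items_are_unknown():
    assert resolve_direction_civic([]) is U
    assert resolve_direction_civic([make_civic(significance=U)] * 3) is U


def _oracle_vote(sigs_targets):
    """Independent re-statement of the vote: restrict, discard, count."""
    target = [(s, t) for s, t in sigs_targets if t]
    pool = target if target else sigs_targets
    n_s = sum(1 for s, _ in pool if s is S)
    n_r = sum(1 for s, _ in pool if s is R)
    return S if n_s > n_r else R if n_r > n_s else U


def test_vote_matches_exhaustive_oracle_up_to_four_items():
    types = list(itertools.product([S, R, U], [True, False]))
    for size in range(0, 5):
        for combo in itertools.combinations_with_replacement(types, size):
            items = [make_civic(significance=s, target=t) for s, t in combo]
            assert resolve_direction_civic(items) is _oracle_vote(list(combo)), combo


# -- curation -------------------------------------------------------------

def test_any_variant_sensitivity_is_unspecific():
    call, _ = resolve_direction_curation(
        _candidate(), [make_curation(response=S)]
    )
    assert call is CurationCall.SENSITIVITY_UNSPECIFIC


def test_opposing_specific_variants_give_variant_dependent():
    records = [
        make_curation(scope=VariantScope.SPECIFIC_VARIANT, descriptor="A100T", response=S),
        make_curation(scope=VariantScope.SPECIFIC_VARIANT, descriptor="R200Q", response=R),
    ]
    call, _ = resolve_direction_curation(_candidate(protein_change="G300S"), records)
    assert call is CurationCall.VARIANT_DEPENDENT


def test_matching_specific_record_dominates():
    records = [
        make_curation(scope=VariantScope.SPECIFIC_VARIANT, descriptor="E545K", response=R),
        make_curation(response=S),  # any-variant sensitivity would say unspecific
    ]
    call, used = resolve_direction_curation(_candidate(), records)
    assert call is CurationCall.RESISTANCE
    assert all(r.variant_descriptor == "E545K" for r in used)


def test_unknown_only_records_drop_candidate():
    call, _ = resolve_direction_curation(_candidate(), [make_curation(response=U)])
    assert call is CurationCall.UNKNOWN


def test_empty_records_are_unknown():
    assert resolve_direction_curation(_candidate(), [])[0] is CurationCall.UNKNOWN


# -- integrate ------------------------------------------------------------

def _kb(civic=(), curation=(), gene="PIK3CA", drug="alpelisib"):
    return KnowledgeBase(
        dgi=[DGIRecord(gene=gene, drug=drug, source_count=1)],
        civic=list(civic),
        curation=list(curation),
        trial_categories={drug: TrialCategory.CT},
    )


def test_civic_only_candidate_yields_one_prediction():
    kb = _kb(civic=[make_civic()])
    preds, dropped = integrate([_candidate()], kb)
    assert dropped == []
    (p,) = preds
    assert p.direction is Direction.SENSITIVITY and p.source is EvidenceSource.CIVIC


def test_no_evidence_drops_with_reason():
    preds, dropped = integrate([_candidate(gene="KRAS", drug="x")], _kb())
    assert preds == []
    assert dropped[0].reason is DropReason.NO_EVIDENCE


def test_tie_drop_reason():
    kb = _kb(civic=[make_civic(significance=S), make_civic(significance=R, level=3)])
    preds, dropped = integrate([_candidate()], kb)
    assert preds == []
    assert dropped[0].reason is DropReason.TIE


def test_unknown_direction_drop_reason():
    kb = _kb(civic=[make_civic(significance=U)])
    _, dropped = integrate([_candidate()], kb)
    assert dropped[0].reason is DropReason.UNKNOWN_DIRECTION


def test_both_sources_yield_two_predictions():
    kb = _kb(
        civic=[make_civic(significance=R)],
        curation=[make_curation(gene="PIK3CA", drug="alpelisib", response=S)],
    )
    preds, dropped = integrate([_candidate()], kb)
    assert dropped == []
    assert {(p.source, p.direction) for p in preds} == {
        (EvidenceSource.CIVIC, Direction.RESISTANCE),
        (EvidenceSource.CURATION, Direction.SENSITIVITY_UNSPECIFIC),
    }


def test_integration_accounts_for_every_candidate(small_kb):
    variants = [
        make_snv(sample=s, gene=g, pos=i + 1)
        for i, (s, g) in enumerate(
            itertools.product(["S1", "S2"], ["PIK3CA", "ERBB2", "FGFR3"])
        )
    ]
    candidates = assemble_candidates(variants, small_kb)
    preds, dropped = integrate(candidates, small_kb)
    predicted_keys = {(p.sample_id, p.drug, p.gene) for p in preds}
    for c in candidates:
        in_pred = (c.sample_id, c.drug, c.gene) in predicted_keys
        in_drop = any(d.candidate is c for d in dropped)
        assert in_pred != in_drop  # exactly one outcome per candidate


def test_predictions_never_carry_unknown(small_kb):
    variants = [make_snv(sample="S1"), make_snv(sample="S1", gene="ERBB2", pos=9)]
    preds, _ = integrate(assemble_candidates(variants, small_kb), small_kb)
    assert all(p.direction in Direction for p in preds)


# -- divergences ----------------------------------------------------------

def _pred(gene, direction, source, sample="S1", drug="drugx"):
    return DirectedPrediction(
        sample_id=sample, drug=drug, gene=gene, direction=direction, source=source
    )


def test_within_source_divergence():
    preds = [
        _pred("G1", Direction.SENSITIVITY, EvidenceSource.CIVIC),
        _pred("G2", Direction.RESISTANCE, EvidenceSource.CIVIC),
    ]
    (rep,) = detect_divergences(preds)
    assert rep.kind is DivergenceKind.WITHIN_CIVIC


def test_between_source_divergence():
    preds = [
        _pred("G1", Direction.SENSITIVITY, EvidenceSource.CIVIC),
        _pred("G1", Direction.RESISTANCE, EvidenceSource.CURATION),
    ]
    (rep,) = detect_divergences(preds)
    assert rep.kind is DivergenceKind.BETWEEN_SOURCE


def test_consistent_predictions_emit_nothing():
    preds = [
        _pred("G1", Direction.SENSITIVITY, EvidenceSource.CIVIC),
        _pred("G2", Direction.SENSITIVITY_UNSPECIFIC, EvidenceSource.CURATION),
    ]
    assert detect_divergences(preds) == []


def test_divergence_detection_is_order_symmetric():
    preds = [
        _pred("G1", Direction.SENSITIVITY, EvidenceSource.CIVIC),
        _pred("G2", Direction.RESISTANCE, EvidenceSource.CIVIC),
        _pred("G3", Direction.RESISTANCE, EvidenceSource.CURATION),
    ]
    kinds = lambda ps: sorted(r.kind.value for r in detect_divergences(ps))  # noqa: E731
    assert kinds(preds) == kinds(list(reversed(preds)))
    assert kinds(preds) == ["BETWEEN_SOURCE", "WITHIN_CIVIC"]
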