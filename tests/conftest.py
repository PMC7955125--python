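from __future__ import annotations

import pytest

from dgipredict.cohort_io import CNVCall, SNVCall
from dgipredict.knowledgebase import (
    CivicEvidence,
    CurationRecord,
    DGIRecord,
    DrugGeneCorrelation,
    KnowledgeBase,
    Significance,
    TrialCategory,
    VariantScope,
)


def make_snv(
    sample="S1",
    gene="PIK3CA",
    pos=100,
    callers=("caller1", "caller2"),
    impact_rank=25,
    damaging=True,
    protein_change="E545K",
    alt="T",
) -> SNVCall:
    return SNVCall(
        sample_id=sample,
        gene=gene,
        chrom="chr3",
        pos=pos,
        ref="A",
        alt=alt,
        callers=frozenset(callers),
        variant_class="missense",
        impact_rank=impact_rank,
        damaging=damaging,
        protein_change=protein_change,
    )


def make_cnv(sample="S1", gene="CDKN2A", copy_number=0) -> CNVCall:
    return CNVCall(sample_id=sample, gene=gene, copy_number=copy_number)


def make_civic(
    gene="PIK3CA",
    drug="alpelisib",
    descriptor="E545K",
    significance=Significance.SENSITIVITY,
    level=2,
    target=True,
) -> CivicEvidence:
    return CivicEvidence(
        gene=gene,
        variant_descriptor=descriptor,
        drug=drug,
        significance=significance,
        evidence_level=level,
        disease="bladder cancer" if target else "melanoma",
        is_target_disease=target,
    )


def make_curation(
    gene="ERBB2",
    drug="cetuximab",
    scope=VariantScope.ANY_VARIANT,
    descriptor=None,
    response=Significance.RESISTANCE,
    ref="PMID:1",
) -> CurationRecord:
    return CurationRecord(
        gene=gene,
        drug=drug,
        variant_scope=scope,
        variant_descriptor=descriptor,
        response=response,
        reference_id=ref,
    )


@pytest.fixture
def small_kb() -> KnowledgeBase:
    """A hand-built knowledge base covering all three evidence situations."""
    return KnowledgeBase(
        dgi=[
            DGIRecord(gene="PIK3CA", drug="alpelisib", source_count=3,
                      is_expert_curated=True),
            DGIRecord(gene="PIK3CA", drug="buparlisib", source_count=1),
            DGIRecord(gene="ERBB2", drug="cetuximab", source_count=2),
            DGIRecord(gene="FGFR3", drug="erdafitinib", source_count=4,
                      is_expert_curated=True),
            DGIRecord(gene="FGFR3", drug="aspirin", source_count=1),
        ],
        civic=[
            make_civic(),
            make_civic(significance=Significance.RESISTANCE, level=4, target=False),
            make_civic(drug="buparlisib", descriptor="*"),
        ],
        curation=[make_curation()],
        trial_categories={
            "alpelisib": TrialCategory.CT,
            "buparlisib": TrialCategory.CT,
            "cetuximab": TrialCategory.NCT,
            "erdafitinib": TrialCategory.CT,
            "aspirin": TrialCategory.OTHER,
        },
        correlations=[
            DrugGeneCorrelation(drug="alpelisib", gene="PIK3CA", r=0.5),
            DrugGeneCorrelation(drug="alpelisib", gene="AKT1", r=-0.5),
        ],
    )
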