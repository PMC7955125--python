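"""Drug–gene interaction assembly and cohort-level prioritization.

Filtered variants are joined to the interaction snapshot: every
(variant, interaction record) pair becomes a candidate drug–gene
interaction (DGI) for that sample.  Candidates are then prioritized by

* **trial category** — only drugs previously tested in cancer-related
  clinical trials (categories ``CT`` and ``NCT``) are kept;
* **cohort prevalence** — only genes altered in at least 15% of the cohort
  (by default) are kept, so the final selection is likely to offer at least
  one option per patient.

The per-sample **drug load** — the number of distinct drugs predicted for a
sample — summarizes each stage's effect; it can only shrink along the
cascade.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

from .cohort_io import CNVCall, SNVCall
from .knowledgebase import KnowledgeBase, TrialCategory

Variant = Union[SNVCall, CNVCall]


@dataclass(frozen=True)
class CandidateDGI:
    """One (sample, drug, gene) candidate backed by a retained variant."""

    sample_id: str
    gene: str
    drug: str
    variant_ref: Variant
    trial_category: TrialCategory
    needs_curation: bool

    @property
    def variant_descriptor(self) -> str:
        return self.variant_ref.descriptor


@dataclass(frozen=True)
class PrevalenceTable:
    """Gene → carriers mapping over the retained-variant cohort."""

    carriers: Mapping[str, frozenset[str]]
    cohort_size: int

    def __post_init__(self) -> None:
        if self.cohort_size < 0:
            raise ValueError("cohort_size must be >= 0")

    def prevalence(self, gene: str) -> float:
        if self.cohort_size == 0:
            raise ValueError("prevalence undefined for an empty cohort")
        return len(self.carriers.get(gene, frozenset())) / self.cohort_size

    def samples(self, gene: str) -> frozenset[str]:
        return self.carriers.get(gene, frozenset())


def build_prevalence(
    variants: Sequence[Variant], cohort: Sequence[str]
) -> PrevalenceTable:
    """Gene-level prevalence over retained variants, pooling SNVs and CNVs.

    Any retained variant in a gene counts the sample once for that gene.
    """
    cohort_set = set(cohort)
    carriers: dict[str, set[str]] = {}
    for v in variants:
        if v.sample_id not in cohort_set:
            raise ValueError(f"variant sample {v.sample_id!r} not in cohort")
        carriers.setdefault(v.gene, set()).add(v.sample_id)
    return PrevalenceTable(
        carriers={g: frozenset(s) for g, s in carriers.items()},
        cohort_size=len(cohort_set),
    )


def assemble_candidates(
    variants: Sequence[Variant], kb: KnowledgeBase
) -> list[CandidateDGI]:
    """Join retained variants to interaction records.

    Each (variant, record) pair yields one candidate; variants in genes
    without any recorded interaction yield nothing.  A candidate needs
    manual curation when its interaction record is not expert-curated and
    no variant-level evidence exists for the (gene, drug) pair.
    """
    candidates = []
    for v in variants:
        for rec in kb.lookup_dgis(v.gene):
            candidates.append(
                CandidateDGI(
                    sample_id=v.sample_id,
                    gene=rec.gene,
                    drug=rec.drug,
                    variant_ref=v,
                    trial_category=kb.trial_category(rec.drug),
                    needs_curation=not rec.is_expert_curated
                    and not kb.has_civic(rec.gene, rec.drug),
                )
            )
    return candidates


def filter_by_trial_category(
    candidates: Sequence[CandidateDGI],
    keep: frozenset[TrialCategory] = frozenset({TrialCategory.CT, TrialCategory.NCT}),
) -> list[CandidateDGI]:
    """Keep candidates whose drug was tested in a kept trial category."""
    return [c for c in candidates if c.trial_category in keep]


def prevalence_filter(
    candidates: Sequence[CandidateDGI],
    prevalence: PrevalenceTable,
    threshold: float = 0.15,
) -> list[CandidateDGI]:
    """Keep candidates whose gene reaches the cohort prevalence threshold."""
    if prevalence.cohort_size == 0:
        raise ValueError("prevalence filter requires a non-empty cohort")
    return [c for c in candidates if prevalence.prevalence(c.gene) >= threshold]


def drug_load(
    candidates: Sequence[CandidateDGI], cohort: Sequence[str]
) -> dict[str, int]:
    """Distinct drugs per sample; samples without candidates report 0."""
    loads: dict[str, set[str]] = {s: set() for s in cohort}
    for c in candidates:
        loads.setdefault(c.sample_id, set()).add(c.drug)
    return {s: len(d) for s, d in loads.items()}


def median_drug_load(loads: Mapping[str, int]) -> float:
    """Cohort median of the per-sample drug load (0 for an empty cohort)."""
    return float(statistics.median(loads.values())) if loads else 0.0
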