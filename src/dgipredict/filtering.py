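"""Variant-level selection cascade.

Three filters reduce raw somatic calls to candidates of likely clinical
relevance:

1. **caller consensus** — keep small variants reported by at least
   ``min_callers`` of the three callers (default 2), suppressing
   caller-specific false positives;
2. **clinical SNV filter** — keep variants with a high functional impact
   rank (strictly greater than 20 on the impact ordering by default, e.g.
   missense or stop-gain rather than synonymous) that are also predicted
   damaging;
3. **clinical CNV filter** — keep only deep deletions (0 copies) and high
   amplifications (more than 4 copies); single-copy losses and modest gains
   are discarded.

Each filter returns a subset of its input with order preserved, is
idempotent, and commutes with the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .cohort_io import CNVCall, CNVCategory, SNVCall, categorize_copy_number

__all__ = [
    "FilterConfig",
    "consensus_filter",
    "clinical_snv_filter",
    "categorize_cnv",
    "clinical_cnv_filter",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the variant selection cascade.

    ``impact_threshold`` is exclusive: a variant must rank strictly higher
    to pass.  ``cnv_keep_amp_above`` is likewise exclusive (copy number > 4
    by default), while ``cnv_keep_del_at`` is the exact deep-deletion copy
    number (0).
    """

    min_callers: int = 2
    impact_threshold: int = 20
    require_damaging: bool = True
    cnv_keep_del_at: int = 0
    cnv_keep_amp_above: int = 4

    def __post_init__(self) -> None:
        if self.min_callers < 1:
            raise ValueError("min_callers must be >= 1")
        if self.impact_threshold < 0 or self.cnv_keep_del_at < 0 or self.cnv_keep_amp_above < 0:
            raise ValueError("thresholds must be non-negative")


def consensus_filter(snvs: Sequence[SNVCall], cfg: FilterConfig = FilterConfig()) -> list[SNVCall]:
    """Keep calls reported by at least ``cfg.min_callers`` callers."""
    return [c for c in snvs if len(c.callers) >= cfg.min_callers]


def clinical_snv_filter(snvs: Sequence[SNVCall], cfg: FilterConfig = FilterConfig()) -> list[SNVCall]:
    """Keep high-impact (rank > threshold), damaging calls."""
    return [
        c for c in snvs
        if c.impact_rank > cfg.impact_threshold
        and (c.damaging or not cfg.require_damaging)
    ]


def categorize_cnv(copy_number: int) -> CNVCategory:
    """Copy-state category of an integer copy number (0 DEL … >4 AMP)."""
    return categorize_copy_number(copy_number)


def clinical_cnv_filter(cnvs: Sequence[CNVCall], cfg: FilterConfig = FilterConfig()) -> list[CNVCall]:
    """Keep deep deletions and high amplifications only."""
    return [
        c for c in cnvs
        if c.copy_number == cfg.cnv_keep_del_at or c.copy_number > cfg.cnv_keep_amp_above
    ]
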