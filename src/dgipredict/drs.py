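"""Transcriptome drug-response scores (DRS).

For each drug with known drug–gene expression/response correlations
(NCI-60 cell-line derived), a per-sample score is the correlation-weighted
sum of the sample's standardized expression over the correlated genes:

    DRS(sample, drug) = sum_g r(drug, g) * z(g, sample)

where z is the per-gene z-score of expression across the cohort.  A
positive score predicts drug sensitivity; a non-positive score is
non-informative — it never signals resistance.  Drugs with no correlated
gene present in the matrix produce no score at all rather than a zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .knowledgebase import DrugGeneCorrelation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DrugResponseScore:
    sample_id: str
    drug: str
    score: float
    n_genes: int

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("a score requires at least one contributing gene")

    @property
    def is_positive(self) -> bool:
        """Strict positivity: a score of exactly 0 is not a sensitivity signal."""
        return self.score > 0


def standardize_expression(expr: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-gene z-scores across samples (genes × samples in, same shape out).

    Uses the sample standard deviation (``ddof=1``) by convention.
    Zero-variance genes have no defined z-score and are dropped with a
    warning.
    """
    if expr.shape[1] < 2:
        raise ValueError("standardization requires at least 2 samples")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=ddof)
    keep = sd > 0
    if not keep.all():
        dropped = list(expr.index[~keep])
        logger.warning("dropping %d zero-variance genes: %s", len(dropped), dropped[:10])
    values = values[keep]
    mean = values.mean(axis=1, keepdims=True)
    z = (values - mean) / sd[keep][:, None]
    return pd.DataFrame(z, index=expr.index[keep], columns=expr.columns)


def compute_drs(
    z: pd.DataFrame, correlations: Sequence[DrugGeneCorrelation]
) -> list[DrugResponseScore]:
    """Correlation-weighted expression scores per (sample, drug).

    Correlation entries whose gene is absent from the matrix are skipped;
    drugs with no overlapping gene yield no score.
    """
    by_drug: dict[str, list[DrugGeneCorrelation]] = {}
    for c in correlations:
        by_drug.setdefault(c.drug, []).append(c)

    scores = []
    index = {g: i for i, g in enumerate(z.index)}
    values = z.to_numpy(dtype=float)
    for drug in sorted(by_drug):
        entries = [c for c in by_drug[drug] if c.gene in index]
        if not entries:
            continue
        rows = [index[c.gene] for c in entries]
        weights = np.array([c.r for c in entries])
        drug_scores = weights @ values[rows]  # one value per sample
        for sample_id, score in zip(z.columns, drug_scores):
            scores.append(
                DrugResponseScore(
                    sample_id=str(sample_id),
                    drug=drug,
                    score=float(score),
                    n_genes=len(entries),
                )
            )
    return scores


def positive_drs_map(scores: Sequence[DrugResponseScore]) -> dict[tuple[str, str], bool]:
    """(sample, drug) → strict positivity, for evidence-category lookup."""
    return {(s.sample_id, s.drug): s.is_positive for s in scores}
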