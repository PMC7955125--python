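"""Molecular-subtype association tests.

Two per-feature tests ask whether the molecular subtype of a tumor relates
to the pipeline's outputs:

* per **gene**: does mutation prevalence differ across subtypes?  A
  logistic regression of mutation status on the subtype factor is compared
  to the intercept-only model by analysis of deviance (likelihood-ratio
  test against chi-square with k−1 degrees of freedom for k subtypes);
* per **drug**: do drug-response scores differ across subtypes?
  Kruskal–Wallis rank-sum test with the standard tie correction.

Neuroendocrine-like and unassigned samples are excluded before testing.
Raw p-values are Benjamini–Hochberg adjusted within each feature family
(genes separately from drugs); significance is called at adjusted p < 0.01
by default.  Features with no information (a gene mutated in none or all
retained samples, fewer than two non-empty subtype groups, all-tied
scores) are flagged DEGENERATE with p = 1 rather than tested.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort_io import Subtype
from .drs import DrugResponseScore

EXCLUDED_SUBTYPES = frozenset({Subtype.NE_LIKE, Subtype.UNASSIGNED})


class AssociationTest(str, enum.Enum):
    LOGISTIC_ANOVA = "LOGISTIC_ANOVA"
    KRUSKAL_WALLIS = "KRUSKAL_WALLIS"


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    test: AssociationTest
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool
    n_used: int
    degenerate: bool = False


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def _retained(subtypes: Mapping[str, Subtype]) -> dict[str, Subtype]:
    return {s: st for s, st in subtypes.items() if st not in EXCLUDED_SUBTYPES}


def _logistic_deviance_lrt(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """LR statistic and p for a subtype-factor logistic model vs intercept.

    With a single categorical predictor the factor model's maximum
    likelihood is attained at the per-group mutation rates, so the deviance
    difference has the closed form of the G statistic on the 2 × k table;
    the chi-square reference uses k − 1 degrees of freedom.
    """
    labels, idx = np.unique(groups, return_inverse=True)
    k = labels.size
    n_g = np.bincount(idx, minlength=k).astype(float)
    y_g = np.bincount(idx, weights=y, minlength=k)
    p_hat = y.mean()

    def _ll(successes: np.ndarray, totals: np.ndarray, probs: np.ndarray) -> float:
        ll = 0.0
        for s, n, p in zip(successes, totals, probs):
            if 0 < p < 1:
                ll += s * np.log(p) + (n - s) * np.log1p(-p)
            # p of exactly 0 or 1 contributes 0 (observed = fitted boundary)
        return ll

    ll_null = _ll(y_g, n_g, np.full(k, p_hat))
    ll_full = _ll(y_g, n_g, y_g / n_g)
    lr = 2.0 * (ll_full - ll_null)
    lr = max(lr, 0.0)
    p_value = float(sps.chi2.sf(lr, df=k - 1))
    return float(lr), p_value


def gene_subtype_association(
    mutation_status: Mapping[str, Mapping[str, int]],
    subtypes: Mapping[str, Subtype],
    alpha: float = 0.01,
) -> list[AssociationResult]:
    """Per-gene test of mutation prevalence against molecular subtype.

    ``mutation_status`` maps gene → (sample → 0/1).  Samples excluded from
    the consensus definition do not enter the fit.  Genes mutated in none
    or all retained samples carry no information and are flagged
    DEGENERATE with p = 1.
    """
    retained = _retained(subtypes)
    results: list[tuple[str, float, float, int, bool]] = []
    for gene in sorted(mutation_status):
        status = mutation_status[gene]
        samples = [s for s in retained if s in status]
        y = np.array([status[s] for s in samples], dtype=float)
        groups = np.array([retained[s].value for s in samples])
        n = len(samples)
        if n == 0 or y.sum() in (0, n) or np.unique(groups).size < 2:
            results.append((gene, float("nan"), 1.0, n, True))
        else:
            stat, p = _logistic_deviance_lrt(y, groups)
            results.append((gene, stat, p, n, False))

    adjusted = bh_adjust([r[2] for r in results])
    return [
        AssociationResult(
            feature=gene,
            test=AssociationTest.LOGISTIC_ANOVA,
            statistic=stat,
            p_raw=p,
            p_adjusted=p_adj,
            significant=p_adj < alpha,
            n_used=n,
            degenerate=degen,
        )
        for (gene, stat, p, n, degen), p_adj in zip(results, adjusted)
    ]


def drs_subtype_association(
    drs_scores: Sequence[DrugResponseScore],
    subtypes: Mapping[str, Subtype],
    alpha: float = 0.01,
) -> list[AssociationResult]:
    """Per-drug Kruskal–Wallis test of score distributions across subtypes."""
    retained = _retained(subtypes)
    by_drug: dict[str, dict[str, list[float]]] = {}
    for s in drs_scores:
        if s.sample_id in retained:
            by_drug.setdefault(s.drug, {}).setdefault(
                retained[s.sample_id].value, []
            ).append(s.score)

    results: list[tuple[str, float, float, int, bool]] = []
    for drug in sorted(by_drug):
        groups = [np.asarray(v) for v in by_drug[drug].values() if len(v) > 0]
        n = int(sum(len(g) for g in groups))
        flat = np.concatenate(groups) if groups else np.array([])
        if len(groups) < 2 or np.unique(flat).size < 2:
            results.append((drug, float("nan"), 1.0, n, True))
        else:
            stat, p = sps.kruskal(*groups)
            results.append((drug, float(stat), float(p), n, False))

    adjusted = bh_adjust([r[2] for r in results])
    return [
        AssociationResult(
            feature=drug,
            test=AssociationTest.KRUSKAL_WALLIS,
            statistic=stat,
            p_raw=p,
            p_adjusted=p_adj,
            significant=p_adj < alpha,
            n_used=n,
            degenerate=degen,
        )
        for (drug, stat, p, n, degen), p_adj in zip(results, adjusted)
    ]


def results_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Tabular view of association results for TSV export."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "test": r.test.value,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
                "degenerate": r.degenerate,
                "n_used": r.n_used,
            }
            for r in results
        ]
    )
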