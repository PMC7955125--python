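"""Subtype association testing and multiple-testing correction."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from dgipredict.cohort_io import Subtype
from dgipredict.drs import DrugResponseScore
from dgipredict.stats import (
    AssociationTest,
    bh_adjust,
    drs_subtype_association,
    gene_subtype_association,
)


# -- Benjamini-Hochberg ---------------------------------------------------

def test_bh_single_p_is_identity():
    assert bh_adjust([0.004]) == [pytest.approx(0.004)]


def test_bh_three_element_worked_example():
    # min over the tail of p*m/rank: all three collapse to 0.03
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])


def test_bh_ties_p_times_m_over_rank():
    assert bh_adjust([0.5] * 10) == pytest.approx([0.5] * 10)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


def test_bh_monotone_geq_raw_leq_one():
    rng = np.random.default_rng(3)
    p = rng.uniform(size=25)
    adj = np.array(bh_adjust(p))
    assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-15).all()
    # fully collapsed (tied) adjusted sequences are fixed points
    tied = bh_adjust([0.01, 0.02, 0.03])
    assert bh_adjust(tied) == pytest.approx(tied)


# -- gene association -----------------------------------------------------

def _subtypes(n, rng, k=4):
    classes = [Subtype.LUM_P, Subtype.LUM_U, Subtype.BA_SQ, Subtype.STROMA_RICH][:k]
    return {f"S{i}": classes[rng.integers(0, k)] for i in range(n)}


def test_gene_lrt_matches_statsmodels_logistic_deviance():
    import statsmodels.api as sm
    import pandas as pd

    rng = np.random.default_rng(11)
    subtypes = _subtypes(120, rng)
    rates = {Subtype.LUM_P: 0.5, Subtype.LUM_U: 0.2,
             Subtype.BA_SQ: 0.35, Subtype.STROMA_RICH: 0.25}
    status = {f"S{i}": int(rng.random() < rates[subtypes[f"S{i}"]]) for i in range(120)}

    (res,) = gene_subtype_association({"GX": status}, subtypes)
    assert res.test is AssociationTest.LOGISTIC_ANOVA

    df = pd.DataFrame(
        {"y": [status[s] for s in sorted(status)],
         "g": [subtypes[s].value for s in sorted(status)]}
    )
    x = pd.get_dummies(df["g"], drop_first=True, dtype=float)
    x = sm.add_constant(x)
    full = sm.GLM(df["y"], x, family=sm.families.Binomial()).fit()
    null = sm.GLM(df["y"], np.ones((len(df), 1)), family=sm.families.Binomial()).fit()
    lr = null.deviance - full.deviance
    assert res.statistic == pytest.approx(lr, rel=1e-6)
    assert res.p_raw == pytest.approx(float(sps.chi2.sf(lr, df=3)), rel=1e-6)


def test_gene_lrt_matches_g_test_contingency_oracle():
    rng = np.random.default_rng(5)
    subtypes = _subtypes(150, rng)
    status = {s: int(rng.random() < 0.3) for s in subtypes}
    (res,) = gene_subtype_association({"GX": status}, subtypes)

    groups = sorted({st.value for st in subtypes.values()})
    table = np.array(
        [
            [sum(1 for s in subtypes if subtypes[s].value == g and status[s] == y)
             for g in groups]
            for y in (0, 1)
        ]
    )
    g_stat, p, _, _ = sps.chi2_contingency(table, lambda_="log-likelihood", correction=False)
    assert res.statistic == pytest.approx(float(g_stat), rel=1e-9)
    assert res.p_raw == pytest.approx(float(p), rel=1e-9)


def test_excluded_subtypes_do_not_enter_fit():
    rng = np.random.default_rng(6)
    subtypes = _subtypes(60, rng)
    subtypes["NE1"] = Subtype.NE_LIKE
    subtypes["UN1"] = Subtype.UNASSIGNED
    status = {s: int(rng.random() < 0.4) for s in subtypes}
    (res,) = gene_subtype_association({"GX": status}, subtypes)
    assert res.n_used == 60


def test_unmutated_gene_is_degenerate():
    rng = np.random.default_rng(7)
    subtypes = _subtypes(40, rng)
    status = {s: 0 for s in subtypes}
    (res,) = gene_subtype_association({"GX": status}, subtypes)
    assert res.degenerate and res.p_raw == 1.0 and not res.significant


# -- drug association -----------------------------------------------------

def _scores(values_by_sample):
    return [DrugResponseScore(s, "drugx", v, 1) for s, v in values_by_sample.items()]


def test_kruskal_wallis_matches_hand_instance():
    # two groups of three; H cross-checked against the rank-sum identity
    subtypes = {f"A{i}": Subtype.LUM_P for i in range(3)}
    subtypes.update({f"B{i}": Subtype.BA_SQ for i in range(3)})
    values = {"A0": 1.0, "A1": 2.0, "A2": 3.0, "B0": 4.0, "B1": 5.0, "B2": 6.0}
    (res,) = drs_subtype_association(_scores(values), subtypes)
    # ranks of group A = {1,2,3}: H = 12/(n(n+1)) * sum(R_g^2/n_g) - 3(n+1)
    h = 12 / (6 * 7) * (6**2 / 3 + 15**2 / 3) - 3 * 7
    assert res.statistic == pytest.approx(h)
    assert res.test is AssociationTest.KRUSKAL_WALLIS


def test_shifted_subtype_detected():
    rng = np.random.default_rng(8)
    subtypes = _subtypes(200, rng)
    values = {
        s: rng.normal(loc=2.0 if subtypes[s] is Subtype.BA_SQ else 0.0)
        for s in subtypes
    }
    (res,) = drs_subtype_association(_scores(values), subtypes)
    assert res.significant


def test_all_tied_scores_are_degenerate():
    rng = np.random.default_rng(9)
    subtypes = _subtypes(30, rng)
    values = {s: 1.0 for s in subtypes}
    (res,) = drs_subtype_association(_scores(values), subtypes)
    assert res.degenerate and res.p_raw == 1.0


def test_single_group_is_degenerate():
    subtypes = {f"S{i}": Subtype.LUM_P for i in range(10)}
    values = {f"S{i}": float(i) for i in range(10)}
    (res,) = drs_subtype_association(_scores(values), subtypes)
    assert res.degenerate


def test_null_lrt_pvalues_roughly_uniform():
    rng = np.random.default_rng(10)
    pvals = []
    for _ in range(200):
        subtypes = _subtypes(120, rng)
        status = {s: int(rng.random() < 0.3) for s in subtypes}
        (res,) = gene_subtype_association({"GX": status}, subtypes)
        if not res.degenerate:
            pvals.append(res.p_raw)
    stat = sps.kstest(pvals, "uniform").statistic
    assert stat < 0.12  # loose: chi-square approximation at n=120
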