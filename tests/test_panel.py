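"""Evidence categories, drug-sample matrix reduction, greedy set cover."""

from __future__ import annotations

import itertools
import random

import pytest

from dgipredict.evidence import Direction, DirectedPrediction, EvidenceSource
from dgipredict.panel import (
    EvidenceCategory,
    build_evidence_matrix,
    coverage_fraction,
    evidence_category,
    greedy_set_cover,
)

C = EvidenceCategory


@pytest.mark.parametrize(
    "direction,drs,expected",
    [
        (Direction.RESISTANCE, True, C.CONFLICTING),
        (Direction.RESISTANCE, False, C.RESISTANCE),
        (Direction.RESISTANCE, None, C.RESISTANCE),
        (Direction.VARIANT_DEPENDENT, True, C.MUTATION_DEPENDENT),
        (Direction.VARIANT_DEPENDENT, None, C.MUTATION_DEPENDENT),
        (Direction.SENSITIVITY, True, C.SENSITIVITY_STRONG),
        (Direction.SENSITIVITY, False, C.SENSITIVITY),
        (Direction.SENSITIVITY_UNSPECIFIC, True, C.SENSITIVITY_STRONG),
        (Direction.SENSITIVITY_UNSPECIFIC, None, C.SENSITIVITY),
        (None, True, C.SENSITIVITY),
        (None, False, C.NONE),
        (None, None, C.NONE),
    ],
)
def test_category_table(direction, drs, expected):
    assert evidence_category(direction, drs) is expected


def test_category_table_is_total_and_deterministic():
    inputs = list(itertools.product(list(Direction) + [None], [True, False, None]))
    for direction, drs in inputs:
        first = evidence_category(direction, drs)
        assert first in EvidenceCategory
        assert evidence_category(direction, drs) is first


def _pred(gene, direction, sample="S1", drug="drugx"):
    return DirectedPrediction(
        sample_id=sample, drug=drug, gene=gene,
        direction=direction, source=EvidenceSource.CIVIC,
    )


def test_matrix_single_prediction_no_drs():
    cells = build_evidence_matrix(
        [_pred("G1", Direction.SENSITIVITY)], {}, ["S1"], ["drugx"]
    )
    assert cells[0].category is C.SENSITIVITY
    assert cells[0].genes == ("G1",)


def test_matrix_opposing_genes_reduce_to_conflicting():
    preds = [_pred("G1", Direction.SENSITIVITY), _pred("G2", Direction.RESISTANCE)]
    (cell,) = build_evidence_matrix(preds, {}, ["S1"], ["drugx"])
    assert cell.category is C.CONFLICTING


def test_matrix_empty_cell_is_none():
    (cell,) = build_evidence_matrix([], {}, ["S1"], ["drugx"])
    assert cell.category is C.NONE


def test_matrix_drs_only_cell_is_sensitivity():
    (cell,) = build_evidence_matrix([], {("S1", "drugx"): True}, ["S1"], ["drugx"])
    assert cell.category is C.SENSITIVITY


# -- greedy set cover -----------------------------------------------------

def test_cover_two_gene_example():
    result = greedy_set_cover(
        ["A", "B", "C"],
        {"g1": {"A", "B"}, "g2": {"C"}},
        {"g1": ["drugx"], "g2": ["drugy"]},
    )
    assert result.genes == ("g1", "g2")
    assert result.coverage_fraction == 1.0
    assert result.drugs == ("drugx", "drugy")


def test_uncoverable_sample_leaves_partial_coverage():
    result = greedy_set_cover(["A", "B"], {"g1": {"A"}})
    assert result.coverage_fraction == 0.5
    assert result.covered_samples == frozenset({"A"})


def test_tie_broken_lexicographically_and_duplicate_skipped():
    result = greedy_set_cover(["A", "B"], {"g2": {"A", "B"}, "g1": {"A", "B"}})
    assert result.genes == ("g1",)  # g2 adds nothing afterwards


def test_empty_universe_is_error():
    with pytest.raises(ValueError):
        greedy_set_cover([], {"g1": {"A"}})


def test_target_coverage_stops_early():
    result = greedy_set_cover(
        ["A", "B", "C", "D"],
        {"g1": {"A", "B", "C"}, "g2": {"D"}},
        target_coverage=0.75,
    )
    assert result.genes == ("g1",)


def _brute_force_min_cover(universe, sets):
    names = sorted(sets)
    coverable = set().union(*(sets[n] for n in names)) & set(universe)
    best = None
    for k in range(len(names) + 1):
        for combo in itertools.combinations(names, k):
            if set().union(*(sets[n] for n in combo), set()) >= coverable:
                best = combo
                break
        if best is not None:
            break
    return len(best), coverable


def test_greedy_matches_brute_force_on_random_instances():
    rng = random.Random(42)
    import math

    for _ in range(50):
        n_samples = rng.randint(2, 10)
        n_genes = rng.randint(1, 6)
        universe = [f"S{i}" for i in range(n_samples)]
        sets = {
            f"g{j}": {s for s in universe if rng.random() < 0.4}
            for j in range(n_genes)
        }
        opt_size, coverable = _brute_force_min_cover(universe, sets)
        result = greedy_set_cover(universe, sets)
        assert result.covered_samples == frozenset(coverable)
        bound = opt_size * (1 + math.log(max(n_samples, 2)))
        assert len(result.genes) <= bound
        gains = [s.marginal_gain for s in result.selection_trace]
        assert gains == sorted(gains, reverse=True)


def test_coverage_fraction_examples():
    preds = [_pred("G1", Direction.SENSITIVITY, sample=f"S{i}") for i in range(19)]
    cohort = [f"S{i}" for i in range(20)]
    assert coverage_fraction(preds, cohort) == 0.95
    assert coverage_fraction([], cohort) == 0.0
    assert coverage_fraction(preds, cohort[:19]) == 1.0
    # restriction to a panel that excludes the predicted gene
    assert coverage_fraction(preds, cohort, genes=["OTHER"]) == 0.0


def test_coverage_monotone_in_gene_set():
    preds = [
        _pred("G1", Direction.SENSITIVITY, sample="S1"),
        _pred("G2", Direction.SENSITIVITY, sample="S2"),
    ]
    cohort = ["S1", "S2", "S3"]
    assert coverage_fraction(preds, cohort, genes=["G1"]) <= coverage_fraction(
        preds, cohort, genes=["G1", "G2"]
    )
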