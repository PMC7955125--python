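"""Seeded synthetic cohorts with planted ground truth.

The generator emulates the statistical structure of a tumor cohort as the
pipeline consumes it: per-caller somatic SNV calls with controlled caller
overlap, annotated impact ranks and damaging flags, gene-level integer
copy numbers, an expression matrix with planted drug–gene correlation
signal, molecular-subtype labels with planted prevalence differences, and
matched knowledge-base snapshots carrying drug–gene evidence of every
direction class.  Because every planted quantity is recorded, each
pipeline stage can be checked against a known answer offline.

The default configuration is the reference study condition used throughout
the test suite: 200 samples, 50 genes, 12 drugs, a per-gene prevalence
spectrum straddling the 15% cohort-prevalence threshold, 90% of true
variants reported by at least two of three callers, and planted
interactions covering every evidence tier (variant-level clinical
evidence, manual curation, unknown-only, and no evidence at all).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import Subtype, write_snv_calls, SNVCall
from .knowledgebase import (
    CivicEvidence,
    CurationAnnotation,
    CurationRecord,
    DGIRecord,
    DrugGeneCorrelation,
    KnowledgeBase,
    Significance,
    TrialCategory,
    VariantScope,
    write_snapshots,
)

CALLERS = ("caller1", "caller2", "caller3")


@dataclass(frozen=True)
class PlantedDGI:
    """One planted drug–gene interaction and the evidence written for it.

    ``tier`` is one of ``CIVIC``, ``CURATION``, ``UNKNOWN_ONLY``, ``NONE``;
    ``direction`` is the truth the evidence encodes (None for tiers that
    cannot direct a prediction).  ``variant_kind`` selects whether carriers
    receive an SNV or a high-amplification CNV.  ``civic_specific`` plants
    variant-descriptor-matched evidence instead of a gene-level wildcard.
    """

    gene: str
    drug: str
    direction: str | None
    tier: str
    prevalence: float
    variant_kind: str = "SNV"
    civic_specific: bool = False


def _default_planted() -> tuple[PlantedDGI, ...]:
    return (
        # one of each direction class, above the prevalence threshold
        PlantedDGI("GENE001", "drug01", "SENSITIVITY", "CIVIC", 0.40, civic_specific=True),
        PlantedDGI("GENE002", "drug02", "RESISTANCE", "CIVIC", 0.40),
        PlantedDGI("GENE003", "drug03", "SENSITIVITY", "CURATION", 0.40),
        PlantedDGI("GENE004", "drug04", "RESISTANCE", "CURATION", 0.40),
        PlantedDGI("GENE005", "drug05", "SENSITIVITY_UNSPECIFIC", "CURATION", 0.40),
        PlantedDGI("GENE006", "drug06", "VARIANT_DEPENDENT", "CURATION", 0.40),
        # below the 15% cohort-prevalence threshold: must not reach the panel
        PlantedDGI("GENE007", "drug07", "SENSITIVITY", "CIVIC", 0.06),
        # evidence exists but is directionless: dropped as UNKNOWN
        PlantedDGI("GENE008", "drug08", None, "UNKNOWN_ONLY", 0.40),
        # interaction with no supporting evidence at all: dropped
        PlantedDGI("GENE009", "drug09", None, "NONE", 0.40),
        # drug never tested in a cancer trial: removed by the trial filter
        PlantedDGI("GENE010", "drug10", "SENSITIVITY", "CIVIC", 0.40),
        # copy-number-driven interaction (amplification evidence)
        PlantedDGI("GENE011", "drug11", "SENSITIVITY", "CIVIC", 0.40, variant_kind="CNV"),
        # divergence partners: opposing direction on an already-used drug
        PlantedDGI("GENE012", "drug01", "RESISTANCE", "CIVIC", 0.40),
        PlantedDGI("GENE013", "drug03", "RESISTANCE", "CURATION", 0.40),
        PlantedDGI("GENE014", "drug05", "RESISTANCE", "CIVIC", 0.40),
    )


def _default_trial_map() -> dict[str, str]:
    cats = {f"drug{i:02d}": "CT" for i in range(1, 13)}
    cats["drug04"] = "NCT"   # off-label category still kept
    cats["drug10"] = "OTHER"  # excluded by the trial filter
    return cats


def _default_drs_signal() -> tuple[tuple, ...]:
    # (drug, genes, correlation coefficients, responder shift delta)
    return (
        ("drug01", ("GENE020", "GENE021", "GENE022"), (0.6, 0.5, 0.4), 1.0),
        ("drug12", ("GENE023", "GENE024", "GENE025"), (0.7, 0.6, -0.3), 1.0),
        ("drug03", ("GENE026", "GENE027"), (0.5, 0.4), 0.0),
    )


def _default_subtype_props() -> dict[str, float]:
    return {
        "LumP": 0.25, "LumU": 0.15, "LumNS": 0.10, "Stroma-rich": 0.14,
        "Ba/Sq": 0.31, "NE-like": 0.03, "UNASSIGNED": 0.02,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a synthetic cohort run."""

    n_samples: int = 200
    n_genes: int = 50
    seed: int = 0
    #: probability that a true variant is reported by exactly 1 / 2 / 3 callers
    caller_agreement_probs: tuple[float, float, float] = (0.1, 0.3, 0.6)
    #: background per-gene prevalence range (planted genes override)
    background_prevalence: tuple[float, float] = (0.02, 0.30)
    fraction_damaging: float = 0.85
    #: probability that a variant's impact rank exceeds the clinical threshold
    impact_high_prob: float = 0.85
    impact_threshold: int = 20
    impact_max: int = 35
    #: per-sample rate of incidental copy-number events on background genes
    cnv_background_rate: float = 0.05
    planted_dgis: tuple[PlantedDGI, ...] = field(default_factory=_default_planted)
    trial_category_map: Mapping[str, str] = field(default_factory=_default_trial_map)
    drs_signal: tuple[tuple, ...] = field(default_factory=_default_drs_signal)
    responder_fraction: float = 0.5
    subtype_proportions: Mapping[str, float] = field(default_factory=_default_subtype_props)
    #: gene → subtype → mutation prevalence override.  The default plants a
    #: strong enriched-in-one-subtype contrast whose population mixture still
    #: clears the 15% cohort-prevalence demand after caller/impact attrition.
    subtype_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "GENE002": {
                "Ba/Sq": 0.85, "LumP": 0.15, "LumU": 0.15, "LumNS": 0.15,
                "Stroma-rich": 0.15, "NE-like": 0.15, "UNASSIGNED": 0.15,
            }
        }
    )
    #: gene → subtype → additive expression shift (drives subtype DRS effects)
    subtype_expression_shifts: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"GENE023": {"Ba/Sq": 2.5}, "GENE024": {"Ba/Sq": 1.5}}
    )
    prevalence_threshold: float = 0.15

    def __post_init__(self) -> None:
        if abs(sum(self.caller_agreement_probs) - 1.0) > 1e-9:
            raise ValueError("caller_agreement_probs must sum to 1")
        for p in self.caller_agreement_probs:
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for dgi in self.planted_dgis:
            if not 0 <= dgi.prevalence <= 1:
                raise ValueError(f"prevalence out of [0, 1] for {dgi.gene}")
        lo, hi = self.background_prevalence
        if not (0 <= lo <= hi <= 1):
            raise ValueError("background_prevalence must be an ordered pair in [0, 1]")

    @property
    def gene_subtype_effects(self) -> dict[str, dict[str, float]]:
        return {g: dict(v) for g, v in self.subtype_effects.items()}


@dataclass
class GroundTruth:
    """Planted expectations, derivable deterministically from config + seed."""

    n_samples: int
    cohort: list[str]
    expected_retained_variants: int
    expected_candidate_dgis: int
    retained_prevalence: dict[str, float]
    #: "gene|drug" → planted direction, for interactions that must survive
    expected_directions: dict[str, str]
    expected_panel_genes: list[str]
    expected_panel_drugs: list[str]
    expected_coverage_fraction: float
    expected_significant_genes: list[str]
    expected_significant_drugs: list[str]
    responders: dict[str, list[str]]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _gene_descriptor(gene: str) -> str:
    """Canonical protein change carried by all simulated variants of a gene."""
    idx = int(gene[-3:])
    return f"E{500 + idx}K"


def simulate(cfg: SimulationConfig, out_dir: str | Path) -> GroundTruth:
    """Write a full synthetic input set and its ground truth to ``out_dir``.

    Emits per-caller SNV TSVs, a CNV table, an expression matrix, subtype
    labels, the five knowledge-base snapshots (under ``kb/``) and
    ``ground_truth.json``.  Identical (config, seed) reproduce identical
    bytes.
    """
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    genes = [f"GENE{i:03d}" for i in range(1, cfg.n_genes + 1)]
    planted_by_gene: dict[str, list[PlantedDGI]] = {}
    for dgi in cfg.planted_dgis:
        planted_by_gene.setdefault(dgi.gene, []).append(dgi)

    # -- subtypes --------------------------------------------------------
    subtype_names = list(cfg.subtype_proportions)
    props = np.array([cfg.subtype_proportions[s] for s in subtype_names], dtype=float)
    props = props / props.sum()
    subtype_of = {
        s: subtype_names[i]
        for s, i in zip(samples, rng.choice(len(subtype_names), size=len(samples), p=props))
    }
    pd.DataFrame(
        {"sample_id": samples, "subtype": [subtype_of[s] for s in samples]}
    ).to_csv(out / "subtypes.tsv", sep="\t", index=False)

    # -- per-gene prevalence targets -------------------------------------
    lo, hi = cfg.background_prevalence
    background = [g for g in genes if g not in planted_by_gene]
    spread = np.linspace(lo, hi, num=max(len(background), 1))
    prevalence_target = {g: float(p) for g, p in zip(background, spread)}
    for g, dgis in planted_by_gene.items():
        prevalence_target[g] = dgis[0].prevalence

    effects = cfg.gene_subtype_effects

    # -- variants --------------------------------------------------------
    impact = cfg.impact_threshold
    snv_calls: list[SNVCall] = []
    cnv_rows: list[dict] = []
    retained_carriers: dict[str, set[str]] = {g: set() for g in genes}
    retained_variant_counts: dict[str, int] = {g: 0 for g in genes}
    n_retained = 0

    cnv_gene_kinds = {
        g: dgis[0].variant_kind for g, dgis in planted_by_gene.items()
    }
    for gi, gene in enumerate(genes):
        base_p = prevalence_target.get(gene, 0.0)
        descriptor = _gene_descriptor(gene)
        kind = cnv_gene_kinds.get(gene, "SNV")
        for si, sample in enumerate(samples):
            p = effects.get(gene, {}).get(subtype_of[sample], base_p)
            if rng.random() >= p:
                continue
            if kind == "CNV":
                cn = int(rng.choice([5, 6]))
                cnv_rows.append({"sample_id": sample, "gene": gene, "copy_number": cn})
                retained_carriers[gene].add(sample)  # AMP always passes the CNV filter
                retained_variant_counts[gene] += 1
                n_retained += 1
                continue
            n_callers = int(rng.choice([1, 2, 3], p=cfg.caller_agreement_probs))
            callers = frozenset(
                CALLERS[i] for i in sorted(rng.choice(3, size=n_callers, replace=False))
            )
            damaging = bool(rng.random() < cfg.fraction_damaging)
            if rng.random() < cfg.impact_high_prob:
                rank = int(rng.integers(impact + 1, cfg.impact_max + 1))
                vclass = "missense"
            else:
                rank = int(rng.integers(0, impact + 1))
                vclass = "synonymous"
            snv_calls.append(
                SNVCall(
                    sample_id=sample,
                    gene=gene,
                    chrom="chrS",
                    pos=(gi + 1) * 100_000 + si + 1,
                    ref="A",
                    alt="T",
                    callers=callers,
                    variant_class=vclass,
                    impact_rank=rank,
                    damaging=damaging,
                    protein_change=descriptor,
                )
            )
            if n_callers >= 2 and damaging and rank > impact:
                retained_carriers[gene].add(sample)
                retained_variant_counts[gene] += 1
                n_retained += 1

    # incidental copy-number events on background genes: exercises every
    # copy-state category without touching planted bookkeeping
    for gene in background[:10]:
        for sample in samples:
            if rng.random() < cfg.cnv_background_rate:
                cn = int(rng.choice([0, 1, 2, 3, 4, 5], p=[0.1, 0.2, 0.25, 0.25, 0.1, 0.1]))
                cnv_rows.append({"sample_id": sample, "gene": gene, "copy_number": cn})
                if cn == 0 or cn > 4:
                    retained_carriers[gene].add(sample)
                    retained_variant_counts[gene] += 1
                    n_retained += 1

    for caller in CALLERS:
        write_snv_calls(snv_calls, out / f"snv_{caller}.tsv", caller)
    pd.DataFrame(cnv_rows, columns=["sample_id", "gene", "copy_number"]).to_csv(
        out / "cnv.tsv", sep="\t", index=False
    )

    # -- knowledge base ---------------------------------------------------
    trial_map = dict(cfg.trial_category_map)
    dgi_records = []
    civic_items: list[CivicEvidence] = []
    curation_records: list[CurationRecord] = []
    for dgi in cfg.planted_dgis:
        dgi_records.append(
            DGIRecord(
                gene=dgi.gene,
                drug=dgi.drug,
                source_count=int(rng.integers(1, 5)),
                reference_ids=(f"PMID:{10_000 + len(dgi_records)}",),
                is_expert_curated=dgi.tier == "CIVIC",
            )
        )
        descriptor = (
            "AMPLIFICATION" if dgi.variant_kind == "CNV"
            else (_gene_descriptor(dgi.gene) if dgi.civic_specific else "*")
        )
        if dgi.tier == "CIVIC":
            majority, minority = (
                (Significance.SENSITIVITY, Significance.RESISTANCE)
                if dgi.direction == "SENSITIVITY"
                else (Significance.RESISTANCE, Significance.SENSITIVITY)
            )
            for level in (1, 2, 3):
                civic_items.append(
                    CivicEvidence(
                        gene=dgi.gene, variant_descriptor=descriptor, drug=dgi.drug,
                        significance=majority, evidence_level=level,
                        disease="bladder cancer", is_target_disease=True,
                    )
                )
            # a contrarian item from another disease: excluded by the
            # target-disease restriction before the vote
            civic_items.append(
                CivicEvidence(
                    gene=dgi.gene, variant_descriptor=descriptor, drug=dgi.drug,
                    significance=minority, evidence_level=4,
                    disease="melanoma", is_target_disease=False,
                )
            )
        elif dgi.tier == "UNKNOWN_ONLY":
            for level in (3, 4):
                civic_items.append(
                    CivicEvidence(
                        gene=dgi.gene, variant_descriptor="*", drug=dgi.drug,
                        significance=Significance.UNKNOWN, evidence_level=level,
                        disease="bladder cancer", is_target_disease=True,
                    )
                )
        elif dgi.tier == "CURATION":
            ref = f"PMID:{20_000 + len(curation_records)}"
            if dgi.direction == "VARIANT_DEPENDENT":
                # opposing variant-specific records on descriptors the
                # cohort's variants do not carry → gene-level mixed call
                curation_records.extend(
                    [
                        CurationRecord(
                            gene=dgi.gene, drug=dgi.drug,
                            variant_scope=VariantScope.SPECIFIC_VARIANT,
                            variant_descriptor="A100T",
                            response=Significance.SENSITIVITY,
                            annotations=frozenset({CurationAnnotation.VARIANT_DEPENDENT}),
                            reference_id=ref + "a",
                        ),
                        CurationRecord(
                            gene=dgi.gene, drug=dgi.drug,
                            variant_scope=VariantScope.SPECIFIC_VARIANT,
                            variant_descriptor="R200Q",
                            response=Significance.RESISTANCE,
                            annotations=frozenset(
                                {CurationAnnotation.VARIANT_DEPENDENT,
                                 CurationAnnotation.CONFLICTING}
                            ),
                            reference_id=ref + "b",
                        ),
                    ]
                )
            elif dgi.direction == "SENSITIVITY_UNSPECIFIC":
                curation_records.append(
                    CurationRecord(
                        gene=dgi.gene, drug=dgi.drug,
                        variant_scope=VariantScope.ANY_VARIANT,
                        response=Significance.SENSITIVITY,
                        annotations=frozenset(
                            {CurationAnnotation.EXPRESSION_DEPENDENT,
                             CurationAnnotation.COMBINATION}
                        ),
                        combination_partner="drug12",
                        reference_id=ref,
                    )
                )
            elif dgi.direction == "SENSITIVITY":
                curation_records.append(
                    CurationRecord(
                        gene=dgi.gene, drug=dgi.drug,
                        variant_scope=VariantScope.SPECIFIC_VARIANT,
                        variant_descriptor=_gene_descriptor(dgi.gene),
                        response=Significance.SENSITIVITY,
                        annotations=frozenset({CurationAnnotation.QUALITY_RESTRICTED}),
                        reference_id=ref,
                    )
                )
            else:  # RESISTANCE
                curation_records.append(
                    CurationRecord(
                        gene=dgi.gene, drug=dgi.drug,
                        variant_scope=VariantScope.ANY_VARIANT,
                        response=Significance.RESISTANCE,
                        annotations=frozenset(
                            {CurationAnnotation.COVARIANT_DEPENDENT,
                             CurationAnnotation.DRUG_INFO}
                        ),
                        reference_id=ref,
                    )
                )

    # decoy interactions on background genes: no evidence → dropped
    for gene in background[:5]:
        dgi_records.append(
            DGIRecord(
                gene=gene, drug="drug09", source_count=1,
                reference_ids=(f"PMID:{30_000 + hash(gene) % 1000}",),
                is_expert_curated=False,
            )
        )

    correlations = []
    for drug, sig_genes, rs, _delta in cfg.drs_signal:
        for g, r in zip(sig_genes, rs):
            correlations.append(DrugGeneCorrelation(drug=drug, gene=g, r=float(r)))

    kb = KnowledgeBase(
        dgi=dgi_records,
        civic=civic_items,
        curation=curation_records,
        trial_categories={d: TrialCategory(c) for d, c in sorted(trial_map.items())},
        correlations=correlations,
    )
    write_snapshots(kb, out / "kb")

    # -- expression -------------------------------------------------------
    expr = rng.standard_normal((len(genes), len(samples)))
    responders: dict[str, list[str]] = {}
    gene_index = {g: i for i, g in enumerate(genes)}
    for drug, sig_genes, rs, delta in cfg.drs_signal:
        if delta == 0:
            continue
        flags = rng.random(len(samples)) < cfg.responder_fraction
        responders[drug] = [s for s, f in zip(samples, flags) if f]
        for g, r in zip(sig_genes, rs):
            if r > 0 and g in gene_index:
                expr[gene_index[g], flags] += delta
    for g, shifts in cfg.subtype_expression_shifts.items():
        if g in gene_index:
            for si, sample in enumerate(samples):
                expr[gene_index[g], si] += shifts.get(subtype_of[sample], 0.0)
    expr_df = pd.DataFrame(np.round(expr, 6), index=genes, columns=samples)
    expr_df.index.name = "gene"
    expr_df.to_csv(out / "expression.tsv", sep="\t")

    # -- ground truth -----------------------------------------------------
    n_candidates = 0
    dgi_count_by_gene: dict[str, int] = {}
    for rec in dgi_records:
        dgi_count_by_gene[rec.gene] = dgi_count_by_gene.get(rec.gene, 0) + 1
    # candidate count = Σ over retained variants of interactions on the gene
    for gene, n_vars in retained_variant_counts.items():
        n_candidates += n_vars * dgi_count_by_gene.get(gene, 0)

    retained_prevalence = {
        g: len(c) / cfg.n_samples for g, c in retained_carriers.items()
    }
    expected_directions = {}
    panel_genes: set[str] = set()
    panel_drugs: set[str] = set()
    covered: set[str] = set()
    for dgi in cfg.planted_dgis:
        if dgi.tier not in ("CIVIC", "CURATION"):
            continue
        if trial_map.get(dgi.drug, "OTHER") == "OTHER":
            continue
        if retained_prevalence[dgi.gene] < cfg.prevalence_threshold:
            continue
        expected_directions[f"{dgi.gene}|{dgi.drug}"] = dgi.direction
        panel_genes.add(dgi.gene)
        panel_drugs.add(dgi.drug)
        covered |= retained_carriers[dgi.gene]

    truth = GroundTruth(
        n_samples=cfg.n_samples,
        cohort=samples,
        expected_retained_variants=n_retained,
        expected_candidate_dgis=n_candidates,
        retained_prevalence=retained_prevalence,
        expected_directions=expected_directions,
        expected_panel_genes=sorted(panel_genes),
        expected_panel_drugs=sorted(panel_drugs),
        expected_coverage_fraction=len(covered) / cfg.n_samples,
        expected_significant_genes=sorted(
            g for g in effects if g in panel_genes
        ),
        expected_significant_drugs=sorted(
            {d for d, sig_genes, _rs, _delta in cfg.drs_signal
             for g in sig_genes if g in cfg.subtype_expression_shifts}
        ),
        responders={d: sorted(s) for d, s in sorted(responders.items())},
    )
    truth.to_json(out / "ground_truth.json")
    return truth


@dataclass
class VerificationReport:
    matches: list[str]
    mismatches: list[str]

    @property
    def ok(self) -> bool:
        return not self.mismatches


def verify(run_summary: Mapping[str, object], truth: GroundTruth) -> VerificationReport:
    """Field-by-field comparison of a pipeline run against planted truth.

    Deterministic expectations (counts, directions, panel membership,
    coverage) are compared exactly; planted statistical effects only
    require membership in the significant set (their detection is a power
    statement, checked in aggregate elsewhere).
    """
    matches: list[str] = []
    mismatches: list[str] = []

    def _check(name: str, got: object, want: object) -> None:
        if got == want:
            matches.append(f"{name}: {got!r}")
        else:
            mismatches.append(f"{name}: got {got!r}, expected {want!r}")

    _check("retained_variants", run_summary.get("retained_variants"),
           truth.expected_retained_variants)
    _check("candidate_dgis", run_summary.get("candidate_dgis"),
           truth.expected_candidate_dgis)
    _check("panel_genes", sorted(run_summary.get("panel_genes", [])),
           truth.expected_panel_genes)
    _check("panel_drugs", sorted(run_summary.get("panel_drugs", [])),
           truth.expected_panel_drugs)
    _check("directions", dict(run_summary.get("directions", {})),
           truth.expected_directions)
    _check("coverage_fraction", run_summary.get("coverage_fraction"),
           truth.expected_coverage_fraction)

    significant_genes = set(run_summary.get("significant_genes", []))
    for g in truth.expected_significant_genes:
        if g in significant_genes:
            matches.append(f"significant gene detected: {g}")
        else:
            mismatches.append(f"planted subtype effect not detected for gene {g}")
    significant_drugs = set(run_summary.get("significant_drugs", []))
    for d in truth.expected_significant_drugs:
        if d in significant_drugs:
            matches.append(f"significant drug detected: {d}")
        else:
            mismatches.append(f"planted subtype DRS effect not detected for drug {d}")
    return VerificationReport(matches=matches, mismatches=mismatches)
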