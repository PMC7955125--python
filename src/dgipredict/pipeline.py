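"""End-to-end pipeline orchestration.

Stages run in a fixed order — read inputs → caller consensus → clinical
variant filters → interaction assembly → trial-category and cohort-
prevalence filters → evidence integration → drug response scores →
evidence matrix → greedy set cover → subtype statistics — and every
stage's tabular output is written before the next begins.  Given identical
inputs and configuration the run directory is byte-identical, so reruns
(and reruns stopped after any stage) are reproducible.

The run manifest records configuration and input hashes plus per-stage
record counts and per-sample drug loads; the drug load can only shrink
along the cascade.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .cohort_io import (
    SNVCall,
    read_cnv_calls,
    read_expression,
    read_snv_calls,
    read_subtypes,
    subtype_map,
)
from .dgi import (
    CandidateDGI,
    PrevalenceTable,
    assemble_candidates,
    build_prevalence,
    drug_load,
    filter_by_trial_category,
    median_drug_load,
    prevalence_filter,
)
from .drs import compute_drs, positive_drs_map, standardize_expression
from .evidence import detect_divergences, integrate
from .filtering import (
    FilterConfig,
    clinical_cnv_filter,
    clinical_snv_filter,
    consensus_filter,
)
from .knowledgebase import TrialCategory, load_snapshots
from .panel import build_evidence_matrix, coverage_fraction, greedy_set_cover
from .stats import drs_subtype_association, gene_subtype_association, results_frame

logger = logging.getLogger(__name__)

#: execution order; ``stop_after`` accepts any of these names
STAGES = (
    "read", "consensus", "clinical", "assemble", "trial_prevalence",
    "evidence", "drs", "matrix", "cover", "stats",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass(frozen=True)
class PipelineConfig:
    """Single configuration object for a pipeline run (YAML-loadable)."""

    snv_files: Mapping[str, tuple[str, ...]]  # caller label -> files
    cnv_file: str
    expression_file: str
    subtype_file: str
    kb_dir: str
    filter: FilterConfig = field(default_factory=FilterConfig)
    trial_keep: tuple[str, ...] = ("CT", "NCT")
    prevalence_threshold: float = 0.15
    per_variant_prevalence: bool = False
    skip_drs: bool = False
    alpha: float = 0.01
    target_coverage: float | None = None
    cover_by: str = "genes"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        filt = FilterConfig(**raw.pop("filter", {}))
        snv_files = {k: tuple(v) for k, v in raw.pop("snv_files").items()}
        trial_keep = tuple(raw.pop("trial_keep", ("CT", "NCT")))
        return cls(snv_files=snv_files, filter=filt, trial_keep=trial_keep, **raw)

    @classmethod
    def for_run_dir(cls, run_dir: str | Path, **overrides) -> "PipelineConfig":
        """Configuration pointing at a directory laid out by ``simulate``."""
        d = Path(run_dir)
        return cls(
            snv_files={
                c: (str(d / f"snv_{c}.tsv"),)
                for c in ("caller1", "caller2", "caller3")
            },
            cnv_file=str(d / "cnv.tsv"),
            expression_file=str(d / "expression.tsv"),
            subtype_file=str(d / "subtypes.tsv"),
            kb_dir=str(d / "kb"),
            **overrides,
        )

    def kb_paths(self) -> dict[str, Path]:
        d = Path(self.kb_dir)
        return {
            k: d / f"{k}.tsv"
            for k in ("dgi", "civic", "curation", "trials", "correlations")
        }

    def digest(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class RunResult:
    """In-memory view of a completed run (files are the durable record)."""

    config: PipelineConfig
    predictions: list
    dropped: list
    divergences: list
    panel: object
    summary: dict


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _candidate_frame(candidates: Sequence[CandidateDGI]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id, "gene": c.gene, "drug": c.drug,
                "trial_category": c.trial_category.value,
                "variant_descriptor": c.variant_descriptor,
                "needs_curation": c.needs_curation,
            }
            for c in candidates
        ],
        columns=[
            "sample_id", "gene", "drug", "trial_category",
            "variant_descriptor", "needs_curation",
        ],
    )


def _variant_key(variant) -> str:
    if isinstance(variant, SNVCall):
        return f"{variant.gene}:{variant.chrom}:{variant.pos}:{variant.ref}:{variant.alt}"
    return f"{variant.gene}:{variant.descriptor}"


def run_pipeline(
    cfg: PipelineConfig, out_dir: str | Path, stop_after: str | None = None
) -> RunResult:
    """Execute the stages up to ``stop_after`` (default: all of them).

    Every intermediate table is written under ``out_dir`` before the next
    stage begins; a failure aborts with the stage name.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}; expected one of {STAGES}")
    last = STAGES.index(stop_after) if stop_after else len(STAGES) - 1

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    loads_per_stage: dict[str, dict[str, int]] = {}
    stage_order = ["raw", "clinical", "trial+prevalence", "curated"]

    predictions: list = []
    dropped: list = []
    divergences: list = []
    panel = None
    gene_results: list = []
    drug_results: list = []
    predicted_genes: list[str] = []
    predicted_drugs: list[str] = []
    cov_all = 0.0
    cohort: list[str] = []

    def _runs(name: str) -> bool:
        return STAGES.index(name) <= last

    stage = "read"
    try:
        logger.info("stage read")
        kb = load_snapshots(cfg.kb_paths())
        snvs = read_snv_calls(cfg.snv_files)
        cnvs = read_cnv_calls(cfg.cnv_file)
        expr = read_expression(cfg.expression_file)
        subtype_labels = read_subtypes(cfg.subtype_file)
        cohort = sorted(
            {c.sample_id for c in snvs}
            | {c.sample_id for c in cnvs}
            | set(map(str, expr.columns))
        )
        subtypes = subtype_map(subtype_labels, cohort)
        counts["snvs_raw"] = len(snvs)
        counts["cnvs_raw"] = len(cnvs)

        if _runs("consensus"):
            stage = "consensus"
            logger.info("stage consensus")
            snvs_consensus = consensus_filter(snvs, cfg.filter)
            counts["snvs_consensus"] = len(snvs_consensus)

        if _runs("clinical"):
            stage = "clinical"
            logger.info("stage clinical")
            snvs_clinical = clinical_snv_filter(snvs_consensus, cfg.filter)
            cnvs_clinical = clinical_cnv_filter(cnvs, cfg.filter)
            counts["snvs_clinical"] = len(snvs_clinical)
            counts["cnvs_clinical"] = len(cnvs_clinical)
            retained = list(snvs_clinical) + list(cnvs_clinical)
            counts["retained_variants"] = len(retained)
            _write_tsv(
                pd.DataFrame(
                    [
                        {"sample_id": v.sample_id, "gene": v.gene,
                         "kind": "SNV" if isinstance(v, SNVCall) else "CNV",
                         "descriptor": v.descriptor}
                        for v in retained
                    ],
                    columns=["sample_id", "gene", "kind", "descriptor"],
                ),
                out / "retained_variants.tsv",
            )

        if _runs("assemble"):
            stage = "assemble"
            logger.info("stage assemble")
            candidates_raw = assemble_candidates(list(snvs_consensus) + list(cnvs), kb)
            candidates = assemble_candidates(retained, kb)
            counts["candidates_raw"] = len(candidates_raw)
            counts["candidates_clinical"] = len(candidates)
            loads_per_stage["raw"] = drug_load(candidates_raw, cohort)
            loads_per_stage["clinical"] = drug_load(candidates, cohort)

        if _runs("trial_prevalence"):
            stage = "trial_prevalence"
            logger.info("stage trial_prevalence")
            keep = frozenset(TrialCategory(c) for c in cfg.trial_keep)
            candidates_trial = filter_by_trial_category(candidates, keep)
            gene_prev = build_prevalence(retained, cohort)
            if cfg.per_variant_prevalence:
                carriers: dict[str, set[str]] = {}
                for v in retained:
                    carriers.setdefault(_variant_key(v), set()).add(v.sample_id)
                var_prev = PrevalenceTable(
                    carriers={k: frozenset(s) for k, s in carriers.items()},
                    cohort_size=len(cohort),
                )
                candidates_final = [
                    c for c in candidates_trial
                    if var_prev.prevalence(_variant_key(c.variant_ref))
                    >= cfg.prevalence_threshold
                ]
            else:
                candidates_final = prevalence_filter(
                    candidates_trial, gene_prev, cfg.prevalence_threshold
                )
            counts["candidates_trial"] = len(candidates_trial)
            counts["candidates_final"] = len(candidates_final)
            loads_per_stage["trial+prevalence"] = drug_load(candidates_final, cohort)
            _write_tsv(_candidate_frame(candidates_final), out / "candidates.tsv")
            _write_tsv(
                pd.DataFrame(
                    [
                        {"gene": g, "n_samples": len(gene_prev.samples(g)),
                         "prevalence": gene_prev.prevalence(g)}
                        for g in sorted(gene_prev.carriers)
                    ],
                    columns=["gene", "n_samples", "prevalence"],
                ),
                out / "prevalence.tsv",
            )

        if _runs("evidence"):
            stage = "evidence"
            logger.info("stage evidence")
            predictions, dropped = integrate(candidates_final, kb)
            divergences = detect_divergences(predictions)
            counts["predictions"] = len(predictions)
            counts["dropped"] = len(dropped)
            counts["divergences"] = len(divergences)
            _write_tsv(
                pd.DataFrame(
                    [
                        {"sample_id": p.sample_id, "drug": p.drug, "gene": p.gene,
                         "direction": p.direction.value, "source": p.source.value,
                         "supporting_items": ";".join(p.supporting_items)}
                        for p in sorted(
                            predictions,
                            key=lambda p: (p.sample_id, p.drug, p.gene, p.source.value),
                        )
                    ],
                    columns=["sample_id", "drug", "gene", "direction", "source",
                             "supporting_items"],
                ),
                out / "predictions.tsv",
            )
            _write_tsv(
                pd.DataFrame(
                    [
                        {"sample_id": d.candidate.sample_id,
                         "gene": d.candidate.gene,
                         "drug": d.candidate.drug, "reason": d.reason.value}
                        for d in dropped
                    ],
                    columns=["sample_id", "gene", "drug", "reason"],
                ),
                out / "dropped.tsv",
            )
            _write_tsv(
                pd.DataFrame(
                    [
                        {"sample_id": r.sample_id, "drug": r.drug,
                         "kind": r.kind.value,
                         "genes": ";".join(
                             sorted({p.gene for p in r.conflicting_predictions}))}
                        for r in divergences
                    ],
                    columns=["sample_id", "drug", "kind", "genes"],
                ),
                out / "divergences.tsv",
            )
            predicted_drugs = sorted({p.drug for p in predictions})
            predicted_genes = sorted({p.gene for p in predictions})
            pred_keys = {(p.sample_id, p.drug, p.gene) for p in predictions}
            loads_per_stage["curated"] = drug_load(
                [c for c in candidates_final
                 if (c.sample_id, c.drug, c.gene) in pred_keys],
                cohort,
            )
            cov_all = coverage_fraction(predictions, cohort)

        drs_scores: list = []
        if _runs("drs"):
            stage = "drs"
            logger.info("stage drs")
            if not cfg.skip_drs and kb.correlations:
                z = standardize_expression(expr)
                drs_scores = compute_drs(z, kb.correlations)
            _write_tsv(
                pd.DataFrame(
                    [
                        {"sample_id": s.sample_id, "drug": s.drug,
                         "score": round(s.score, 9), "is_positive": s.is_positive,
                         "n_genes": s.n_genes}
                        for s in drs_scores
                    ],
                    columns=["sample_id", "drug", "score", "is_positive", "n_genes"],
                ),
                out / "drs.tsv",
            )

        if _runs("matrix"):
            stage = "matrix"
            logger.info("stage matrix")
            drs_pos = positive_drs_map(drs_scores)
            matrix_drugs = sorted(set(predicted_drugs) | {d for _s, d in drs_pos})
            cells = build_evidence_matrix(predictions, drs_pos, cohort, matrix_drugs)
            by_drug: dict[str, dict[str, str]] = {}
            for c in cells:
                by_drug.setdefault(c.drug, {})[c.sample_id] = c.category.value
            matrix = pd.DataFrame(
                [{"drug": drug, **by_drug[drug]} for drug in matrix_drugs],
                columns=["drug", *cohort],
            )
            _write_tsv(matrix, out / "evidence_matrix.tsv")

        if _runs("cover"):
            stage = "cover"
            logger.info("stage cover")
            gene_to_samples: dict[str, set[str]] = {}
            gene_to_drugs: dict[str, set[str]] = {}
            drug_to_samples: dict[str, set[str]] = {}
            for p in predictions:
                gene_to_samples.setdefault(p.gene, set()).add(p.sample_id)
                gene_to_drugs.setdefault(p.gene, set()).add(p.drug)
                drug_to_samples.setdefault(p.drug, set()).add(p.sample_id)
            if predictions:
                if cfg.cover_by == "drugs":
                    panel = greedy_set_cover(
                        cohort, drug_to_samples, None, cfg.target_coverage
                    )
                else:
                    panel = greedy_set_cover(
                        cohort, gene_to_samples,
                        {g: sorted(d) for g, d in gene_to_drugs.items()},
                        cfg.target_coverage,
                    )
            _write_tsv(
                pd.DataFrame(
                    [
                        {"gene": s.gene, "step": i + 1,
                         "marginal_gain": s.marginal_gain,
                         "cumulative_coverage": s.cumulative_coverage}
                        for i, s in enumerate(panel.selection_trace)
                    ] if panel else [],
                    columns=["gene", "step", "marginal_gain", "cumulative_coverage"],
                ),
                out / "panel.tsv",
            )
            directions_by_pair: dict[tuple[str, str], set[str]] = {}
            for p in predictions:
                directions_by_pair.setdefault((p.drug, p.gene), set()).add(
                    p.direction.value
                )
            _write_tsv(
                pd.DataFrame(
                    [
                        {"drug": drug, "gene": gene,
                         "directions": ";".join(sorted(dirs)),
                         "trial_category": kb.trial_category(drug).value}
                        for (drug, gene), dirs in sorted(directions_by_pair.items())
                    ],
                    columns=["drug", "gene", "directions", "trial_category"],
                ),
                out / "drug_panel.tsv",
            )

        if _runs("stats"):
            stage = "stats"
            logger.info("stage stats")
            mutation_status = {
                g: {s: int(s in gene_prev.samples(g)) for s in cohort}
                for g in predicted_genes
            }
            gene_results = gene_subtype_association(mutation_status, subtypes, cfg.alpha)
            drug_results = drs_subtype_association(drs_scores, subtypes, cfg.alpha)
            _write_tsv(results_frame(gene_results), out / "subtype_stats_genes.tsv")
            _write_tsv(results_frame(drug_results), out / "subtype_stats_drugs.tsv")
    except Exception as exc:  # noqa: BLE001 - stage attribution contract
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    load_rows = []
    for s in cohort:
        for st in stage_order:
            if st in loads_per_stage:
                load_rows.append({"sample_id": s, "stage": st,
                                  "drug_load": loads_per_stage[st].get(s, 0)})
    _write_tsv(
        pd.DataFrame(load_rows, columns=["sample_id", "stage", "drug_load"]),
        out / "drug_load_per_stage.tsv",
    )

    divergence_counts = {k: 0 for k in ("WITHIN_CIVIC", "WITHIN_CURATION", "BETWEEN_SOURCE")}
    for r in divergences:
        divergence_counts[r.kind.value] += 1

    directions: dict[str, set[str]] = {}
    for p in predictions:
        directions.setdefault(f"{p.gene}|{p.drug}", set()).add(p.direction.value)
    direction_summary = {
        k: sorted(v)[0] if len(v) == 1 else "/".join(sorted(v))
        for k, v in sorted(directions.items())
    }

    summary = {
        "cohort_size": len(cohort),
        "stages_run": list(STAGES[: last + 1]),
        "retained_variants": counts.get("retained_variants", 0),
        "candidate_dgis": counts.get("candidates_clinical", 0),
        "panel_genes": predicted_genes,
        "panel_drugs": predicted_drugs,
        "cover_selected_genes": list(panel.genes) if panel else [],
        "directions": direction_summary,
        "coverage_fraction": cov_all,
        "coverage_fraction_cover": panel.coverage_fraction if panel else 0.0,
        "median_drug_load": {
            st: median_drug_load(loads_per_stage[st])
            for st in stage_order if st in loads_per_stage
        },
        "divergence_counts": divergence_counts,
        "significant_genes": sorted(r.feature for r in gene_results if r.significant),
        "significant_drugs": sorted(r.feature for r in drug_results if r.significant),
        "counts": counts,
    }

    manifest = {
        "tool_version": __version__,
        "config_sha256": cfg.digest(),
        "input_sha256": {
            str(p): _hash_file(Path(p))
            for p in sorted(
                [f for files in cfg.snv_files.values() for f in files]
                + [cfg.cnv_file, cfg.expression_file, cfg.subtype_file]
                + [str(v) for v in cfg.kb_paths().values()]
            )
        },
        "stage_counts": counts,
        "median_drug_load": summary["median_drug_load"],
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return RunResult(
        config=cfg,
        predictions=predictions,
        dropped=dropped,
        divergences=divergences,
        panel=panel,
        summary=summary,
    )


def report(run_dir: str | Path) -> str:
    """Human-readable Markdown summary of a completed run."""
    run = Path(run_dir)
    summary_path = run / "summary.json"
    if not summary_path.exists():
        raise PipelineError("incomplete run: missing stage output summary.json")
    with open(summary_path, encoding="utf-8") as fh:
        s = json.load(fh)
    lines = [
        "# Drug-response prediction run report",
        "",
        f"Cohort size: {s['cohort_size']}",
        f"Retained variants: {s['retained_variants']}",
        f"Candidate drug-gene interactions: {s['candidate_dgis']}",
        f"Final panel: {len(s['panel_genes'])} genes, {len(s['panel_drugs'])} drugs",
        f"Cohort coverage (all panel genes): {s['coverage_fraction']:.1%}",
        f"Cohort coverage (greedy cover selection): {s['coverage_fraction_cover']:.1%}",
        "",
        "## Median drug load per stage",
        "",
        "| stage | median drug load |",
        "|---|---|",
    ]
    for st, v in s["median_drug_load"].items():
        lines.append(f"| {st} | {v} |")
    lines += ["", "## Divergences", "", "| kind | count |", "|---|---|"]
    for k, v in s["divergence_counts"].items():
        lines.append(f"| {k} | {v} |")
    lines += [
        "",
        "Significant subtype-associated genes: "
        + (", ".join(s["significant_genes"]) or "none"),
        "Significant subtype-associated drugs: "
        + (", ".join(s["significant_drugs"]) or "none"),
        "",
    ]
    text = "\n".join(lines)
    with open(run / "report.md", "w", encoding="utf-8") as fh:
        fh.write(text)
    return text
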