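# dgipredict

Semi-automated in silico drug-response prediction for tumor cohorts.

Comprehensive tumor sequencing surfaces far more potentially targetable
alterations than a tumor board can review: a naive join of somatic variants
against a drug–gene interaction (DGI) aggregator yields hundreds of drug
suggestions per patient, most of them undirected (no statement whether the
alteration confers sensitivity or resistance) and many clinically
irrelevant. `dgipredict` implements a filtering-and-evidence pipeline that
reduces this flood to a directed, evidence-weighted gene/drug panel:

1. **Consensus variant filtering.** Somatic SNVs are kept only when called
   by ≥ 2 of 3 callers; clinically relevant SNVs additionally require a
   functional impact rank > 20 and a damaging prediction. Gene-level copy
   numbers are kept only as deep deletions (0 copies) or high
   amplifications (> 4 copies).
2. **DGI assembly.** Retained variants are joined to a frozen DGI snapshot;
   drugs never tested in cancer-related clinical trials (category *other*,
   vs *ct*/*nct*) are removed, and genes altered in < 15% of the cohort are
   deprioritized.
3. **Evidence integration.** Variant-level clinical evidence (CIViC-style)
   is resolved per candidate by a target-disease-prioritized majority vote
   over sensitivity/resistance items; manually curated records resolve by
   variant-specific precedence, with gene-level classes
   *sensitivity-unspecific* and *variant-dependent*. Candidates with no
   supporting evidence, a tied vote, or only UNKNOWN statements are
   dropped with a machine-readable reason; opposing directions for one
   drug in one sample are reported as divergences.
4. **Drug response scores (DRS).** Per sample and drug,
   `DRS = Σ_g r(drug, g) · z(g, sample)` — the correlation-weighted sum of
   cohort-standardized expression over genes with known drug–expression
   correlations (NCI-60-style). A positive DRS predicts sensitivity; a
   non-positive DRS is non-informative, never a resistance signal.
5. **Evidence weighting and panel selection.** Genomic direction and DRS
   positivity combine into five evidence categories (conflicting /
   mutation-dependent / resistance / sensitivity / sensitivity-strong); a
   minimal gene panel is chosen by greedy minimum set cover and the covered
   cohort fraction reported.
6. **Subtype statistics.** Mutation prevalence of panel genes is tested
   against molecular subtype by a logistic-regression analysis of deviance
   (likelihood-ratio test, χ²(k−1)), DRS distributions by Kruskal–Wallis,
   both with Benjamini–Hochberg correction at α = 0.01; neuroendocrine-like
   and unassigned samples are excluded.

Because the knowledge bases the method consumes drift over time, all of
them are read as frozen TSV snapshots, and a seeded synthetic-cohort
generator (`dgipredict.simulate`) produces full input sets with planted
ground truth so every stage is testable offline.

## Worked example

```bash
dgipredict simulate --seed 1 --outdir demo/inputs
dgipredict run --indir demo/inputs --outdir demo/run
dgipredict report demo/run
```

The run prints

```
panel: 10 genes / 7 drugs; coverage 95.0%; divergences 37
```

meaning: of the 14 planted drug–gene interactions in the default synthetic
cohort (200 samples, 50 genes, 12 drugs), exactly the 10 with supporting
directed evidence, a cancer-trial drug and ≥ 15% cohort prevalence survive
to the final panel; 95.0% of samples carry at least one directed
prediction; and 37 drug–sample pairs received opposing
sensitivity/resistance calls from different genes or evidence sources
(split across within-evidence, within-curation and between-source kinds in
the report). The run directory contains every intermediate table
(`candidates.tsv`, `predictions.tsv`, `dropped.tsv`, `divergences.tsv`,
`drs.tsv`, `evidence_matrix.tsv`, `panel.tsv`, `subtype_stats_*.tsv`) plus
a `manifest.json` with config/input hashes and per-stage counts, and
`ground_truth.json` from the generator for field-by-field verification.

The same pipeline runs on real inputs via a YAML config
(`dgipredict run --config pipeline.yaml --outdir out`): per-caller VCF or
TSV SNV files, a gene-level copy-number table, a genes × samples expression
matrix, subtype labels, and the five knowledge-base snapshot TSVs.

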