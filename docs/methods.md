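# Methods

## Pipeline model and assumptions

`dgipredict` treats drug-response prediction as a deterministic cascade
over four inputs — per-caller somatic SNV calls, gene-level integer copy
numbers, a normalized expression matrix, and molecular-subtype labels —
joined against five frozen knowledge-base snapshots (drug–gene
interactions, variant-level clinical evidence, manual-curation records,
drug→trial-category annotations, and drug–gene expression correlations).
The package assumes all upstream heavy lifting is done elsewhere: variant
calling, functional annotation (impact rank, damaging prediction),
segment-to-gene copy-number mapping, expression normalization, and subtype
classification are inputs, not computations. Snapshots replace live
database queries deliberately: interaction aggregators and evidence bases
change continuously, and frozen TSVs are the only way to make a run
reproducible.

Symbol handling is intentionally minimal: gene symbols are uppercased,
drug names lowercased, protein-change descriptors uppercased with a
leading `p.` stripped; no alias or synonym resolution is attempted, so
joins across files are exact and deterministic.

## Filtering thresholds

| parameter | default | meaning |
|---|---|---|
| `min_callers` | 2 | callers that must report an SNV (of 3) |
| `impact_threshold` | 20 | impact rank must be **strictly** greater |
| `require_damaging` | true | damaging prediction required |
| `cnv_keep_del_at` / `cnv_keep_amp_above` | 0 / 4 | deep deletion = 0 copies; amplification = strictly more than 4 |
| `prevalence_threshold` | 0.15 | minimum cohort fraction with a retained variant in the gene |
| `trial_keep` | {CT, NCT} | drugs must have been in a cancer-related trial |
| `alpha` | 0.01 | post-BH significance level |

All boundaries are read literally ("higher than 20", "more than 4 copies"
are exclusive); each is a config field, so the inclusive alternative is one
setting away. Copy states categorize as 0 → DEL, 1 → LOSS, 2 → NEUTRAL,
3–4 → GAIN, > 4 → AMP. Cohort prevalence is computed at the gene level,
pooling SNVs and CNVs (any retained variant counts the sample once); a
`per_variant_prevalence` flag switches to exact-variant prevalence for
sensitivity analyses. Indels pass through the same consensus rule as SNVs;
no caller-specific handling is attempted.

## Evidence resolution

**Variant-level evidence (CIViC-style).** Items match a candidate when
their (gene, drug) agree and the variant descriptor equals the candidate's
descriptor exactly (protein change for SNVs; `AMPLIFICATION`/`DELETION`
keywords for copy-number events) or is the gene-level wildcard `*`.
Resolution then (1) restricts to target-disease items whenever at least
one exists — a hard restriction, not a weighting, since prioritization is
specified to precede the vote; (2) discards directionless items; (3) takes
the strict majority of sensitivity vs resistance. A tie resolves to
UNKNOWN and drops the candidate — the conservative reading when the
evidence cannot clearly predict response. Evidence levels are stored and
reported but do not weight the vote.

**Manual curation.** Variant-specific records matching the candidate's
variant dominate; if they disagree among themselves the gene is called
VARIANT_DEPENDENT. Without a matching specific record, disagreeing
specific records elsewhere in the gene still force VARIANT_DEPENDENT
(the gene's direction depends on which variant a sample carries);
otherwise any-variant records decide, with sensitivity downgraded to
SENSITIVITY_UNSPECIFIC because it cannot be pinned to the observed
variant. Conflicting any-variant records resolve to UNKNOWN (drop), the
same conservative choice as a tied vote. Combination-therapy records pass
through as labeled drug entries; no efficacy modelling is attempted.

A candidate with both evidence tiers yields up to two predictions; a
between-source conflict keeps both predictions and reports a divergence
rather than suppressing either — divergences are information, not errors.
Divergences are counted per (sample, drug) and per kind (within the
variant-level tier, within curation, between tiers); VARIANT_DEPENDENT
predictions are gene-internal mixtures and do not form a cross-gene pole.

## Drug response score

`DRS(sample, drug) = Σ_g r(drug, g) · z(g, sample)` over the genes with a
correlation entry for the drug that are present in the matrix. z-scores
are per-gene across the cohort with the sample standard deviation (n − 1;
configurable); zero-variance genes are dropped with a warning. The
weighted sum of standardized expression is the minimal construction
consistent with "correlation coefficients as weighting factors", and it is
isolated behind one function so an alternative kernel is a drop-in. The
sign contract is strict and asymmetric: score > 0 is a sensitivity signal;
score ≤ 0 contributes nothing downstream (it is never read as resistance).
Drugs with no overlapping gene produce no score at all rather than a zero,
so "no DRS" and "DRS = 0" are distinguishable states that the evidence
table nevertheless treats identically.

## Evidence categories and panel selection

The five-category table is total over (direction ∪ none) ×
(positive / non-positive / absent DRS): resistance + positive DRS →
conflicting; variant-dependent → mutation-dependent regardless of DRS;
resistance without DRS support → resistance; sensitivity (specific or
unspecific) without DRS → sensitivity, as is a positive DRS alone;
sensitivity corroborated by positive DRS → sensitivity-strong. When
several genes predict for one drug–sample cell, opposing directions make
the cell conflicting outright (surfacing the conflict is the
information-preserving reduction); otherwise variant-dependent outranks a
plain direction and a variant-attributed sensitivity outranks an
unspecific one.

Set cover runs over genes (drugs are inherited from the selected genes),
greedily picking the gene that covers the most yet-uncovered samples, ties
broken lexicographically, until no gene adds coverage (or an optional
target coverage is reached); a `cover_by="drugs"` mode covers by drug
instead. Because greedy runs to exhaustion by default, the cover's
coverage fraction equals the coverage of the full predicted gene set; both
are reported.

## Subtype statistics

The gene test is a logistic-regression analysis of deviance: the
subtype-factor model vs the intercept-only model, referred to χ² with
k − 1 degrees of freedom. With a single categorical predictor the factor
model's maximum likelihood is attained at the per-group rates, so the
deviance difference is computed in closed form (it equals the G statistic
on the 2 × k table); the unit tests cross-check it against a statsmodels
GLM fit and a log-likelihood-ratio contingency test. Plain maximum
likelihood is used; genes mutated in none or all retained samples are
flagged DEGENERATE with p = 1 rather than fitted. The drug test is
Kruskal–Wallis with the standard tie correction; all-tied score sets and
single-group inputs are DEGENERATE. BH correction is applied within each
feature family (genes separately from drugs). Note that BH adjustment is
not idempotent in general — only fully collapsed (tied) blocks are fixed
points.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline consumes,
with defaults chosen as a realistic reference condition: 200 samples, 50
genes, 12 drugs; a true variant is reported by 1/2/3 callers with
probability 0.1/0.3/0.6 (so 90% survive consensus); 85% of variants are
damaging and 85% exceed the impact threshold, giving a per-variant
retention rate of about 0.65; background gene prevalences spread 0.02–0.30
to straddle the 15% threshold, and planted interaction genes sit at 0.40
(0.06 for the deliberately sub-threshold plant). Fourteen planted
interactions cover every direction class, every evidence tier (including
unknown-only and no-evidence), a non-cancer-trial drug, a copy-number
driven interaction, and three divergence partners. Expression is standard
normal per gene with an additive +δ responder shift (δ = 1, half the
cohort) on positively correlated signal genes.

Planted statistical effects are deliberately decisive, mirroring the
order-of-magnitude contrasts such association tests are meant to detect:
the subtype-enriched gene carries mutation prevalence 0.85 in one subtype
vs 0.15 elsewhere (a 0.6-vs-0.05-style contrast cannot be planted directly
because its population mixture would fall below the 15% panel threshold
after retention attrition), and the subtype DRS effect shifts two
correlated genes by 2.5 and 1.5 sd in one subtype. Ground truth is
bookkept during generation (retained variants, candidate counts, expected
directions, panel membership, coverage) and compared exactly;
significance expectations are membership checks, with calibration and
power quantified separately over replicates.

What the generator does **not** emulate — mutational signatures,
correlated caller errors, read-level noise, batch effects, realistic
linkage between expression and mutation — bounds what passing tests show:
they demonstrate the pipeline's logic and numerics, not performance on
real tumor data.

## Numerical and design choices

* Determinism everywhere: a single seeded `numpy` generator in the
  simulator, canonical sort orders in every writer, fixed float rounding
  in emitted tables, and no wall-clock content in hashed outputs; the run
  manifest records config and input SHA-256 digests.
* The pipeline can stop after any stage (`stop_after`); stage outputs are
  written before the next stage begins, and identical inputs reproduce
  identical bytes, so partial and full runs agree on shared files.
* Problem sizes in the test suite (cohorts of 40–200 samples, 200–1000
  randomized oracle instances, 100–500 statistical replicates) were chosen
  to give tight oracle coverage and stable stochastic bounds at
  interactive runtimes.
* Error handling favors loud failure: malformed snapshot rows, duplicate
  records, out-of-range correlations, negative copy numbers and unknown
  caller labels abort with the file and row; stage failures name the
  stage.

## Known limitations

* No drug-name synonym or gene-alias resolution; snapshots must be
  pre-normalized to consistent symbols.
* The evidence-level ordinal is stored but unused in voting; a
  level-weighted vote would need a principled weighting the current
  design does not presume.
* Copy-number evidence matching relies on `AMPLIFICATION`/`DELETION`
  descriptor keywords in the snapshot.
* The greedy cover is an approximation (within the usual ln n factor of
  optimal); on the small panels this pipeline produces it is almost always
  exactly optimal, but that is not guaranteed.
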