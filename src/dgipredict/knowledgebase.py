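"""Local knowledge-base snapshots of drug–gene interaction resources.

Live databases (DGIdb-style interaction aggregators, CIViC-style variant
evidence, clinical-trial registries, NCI-60 drug–expression correlations)
drift over time, so the pipeline consumes frozen tab-separated snapshots
instead of querying services.  This module reads, validates, normalizes and
indexes the five snapshot files:

``dgi.tsv``
    one row per drug–gene interaction with the number of supporting source
    databases and whether any source is expert-curated;
``civic.tsv``
    variant-level clinical evidence items with a response direction
    (sensitivity / resistance / unknown) and an ordinal evidence level;
``curation.tsv``
    manually curated interaction records with a variant scope and
    restriction annotations;
``trials.tsv``
    drug → clinical-trial category (``CT`` = tested in the target cancer or
    solid-tumor baskets, ``NCT`` = tested in other cancers, ``OTHER`` = no
    cancer trial);
``correlations.tsv``
    drug–gene expression/response Pearson correlations used as drug
    response score weights.

Gene symbols are normalized to uppercase, drug names to lowercase; no alias
resolution is attempted, so joins across files are deterministic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

SNAPSHOT_HEADER = "#dgipredict-kb v1"

WILDCARD_DESCRIPTORS = {"", "*", "ANY"}


class Significance(str, enum.Enum):
    """Response direction of a single evidence item."""

    SENSITIVITY = "SENSITIVITY"
    RESISTANCE = "RESISTANCE"
    UNKNOWN = "UNKNOWN"


class VariantScope(str, enum.Enum):
    ANY_VARIANT = "ANY_VARIANT"
    SPECIFIC_VARIANT = "SPECIFIC_VARIANT"


class TrialCategory(str, enum.Enum):
    CT = "CT"
    NCT = "NCT"
    OTHER = "OTHER"


class CurationAnnotation(str, enum.Enum):
    QUALITY_RESTRICTED = "QUALITY_RESTRICTED"
    CONFLICTING = "CONFLICTING"
    VARIANT_DEPENDENT = "VARIANT_DEPENDENT"
    COVARIANT_DEPENDENT = "COVARIANT_DEPENDENT"
    EXPRESSION_DEPENDENT = "EXPRESSION_DEPENDENT"
    COMBINATION = "COMBINATION"
    DRUG_INFO = "DRUG_INFO"


class KnowledgeBaseError(ValueError):
    """Raised on malformed or invariant-violating snapshot content."""


def normalize_gene(symbol: str) -> str:
    return str(symbol).strip().upper()


def normalize_drug(name: str) -> str:
    return str(name).strip().lower()


def normalize_descriptor(descriptor: str | None) -> str:
    """Canonical form of a variant descriptor; wildcards collapse to ``*``."""
    if descriptor is None:
        return "*"
    d = str(descriptor).strip().upper()
    if d.startswith("P."):
        d = d[2:]
    return "*" if d in WILDCARD_DESCRIPTORS else d


@dataclass(frozen=True)
class DGIRecord:
    """One drug–gene interaction from the aggregated interaction snapshot."""

    gene: str
    drug: str
    source_count: int
    reference_ids: tuple[str, ...] = ()
    is_expert_curated: bool = False

    def __post_init__(self) -> None:
        if not self.gene or not self.drug:
            raise KnowledgeBaseError("DGIRecord gene and drug must be non-empty")
        if self.source_count < 1:
            raise KnowledgeBaseError(
                f"DGIRecord source_count must be >= 1, got {self.source_count}"
            )


@dataclass(frozen=True)
class CivicEvidence:
    """One variant-level evidence item (CIViC-style).

    ``variant_descriptor`` is a protein-level change (e.g. ``E545K``), a
    copy-number keyword (``AMPLIFICATION``/``DELETION``), or ``*`` for a
    gene-level statement that applies to any variant of the gene.
    ``evidence_level`` is ordinal with lower = stronger (A–E mapped 1–5).
    """

    gene: str
    variant_descriptor: str
    drug: str
    significance: Significance
    evidence_level: int
    disease: str = ""
    is_target_disease: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.evidence_level <= 5:
            raise KnowledgeBaseError(
                f"evidence_level must be in 1..5, got {self.evidence_level}"
            )


@dataclass(frozen=True)
class CurationRecord:
    """One manually curated interaction record."""

    gene: str
    drug: str
    variant_scope: VariantScope
    response: Significance
    variant_descriptor: str | None = None
    annotations: frozenset[CurationAnnotation] = frozenset()
    combination_partner: str | None = None
    reference_id: str = ""

    def __post_init__(self) -> None:
        has_combo = CurationAnnotation.COMBINATION in self.annotations
        if has_combo != (self.combination_partner is not None):
            raise KnowledgeBaseError(
                "COMBINATION annotation requires combination_partner and vice versa "
                f"({self.gene}/{self.drug})"
            )
        if self.variant_scope is VariantScope.SPECIFIC_VARIANT and not self.variant_descriptor:
            raise KnowledgeBaseError(
                f"SPECIFIC_VARIANT record without descriptor ({self.gene}/{self.drug})"
            )


@dataclass(frozen=True)
class DrugGeneCorrelation:
    drug: str
    gene: str
    r: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise KnowledgeBaseError(
                f"correlation out of [-1, 1]: {self.drug}/{self.gene} r={self.r}"
            )


@dataclass
class KnowledgeBase:
    """Indexed, normalized collections of the five snapshot record types."""

    dgi: list[DGIRecord] = field(default_factory=list)
    civic: list[CivicEvidence] = field(default_factory=list)
    curation: list[CurationRecord] = field(default_factory=list)
    trial_categories: dict[str, TrialCategory] = field(default_factory=dict)
    correlations: list[DrugGeneCorrelation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._dgi_by_gene: dict[str, list[DGIRecord]] = {}
        seen: set[tuple[str, str]] = set()
        for rec in self.dgi:
            key = (rec.gene, rec.drug)
            if key in seen:
                raise KnowledgeBaseError(f"duplicate DGI record for {key}")
            seen.add(key)
            self._dgi_by_gene.setdefault(rec.gene, []).append(rec)
        self._civic_by_pair: dict[tuple[str, str], list[CivicEvidence]] = {}
        for ev in self.civic:
            self._civic_by_pair.setdefault((ev.gene, ev.drug), []).append(ev)
        self._curation_by_pair: dict[tuple[str, str], list[CurationRecord]] = {}
        for rec in self.curation:
            self._curation_by_pair.setdefault((rec.gene, rec.drug), []).append(rec)
        corr_seen: set[tuple[str, str]] = set()
        for c in self.correlations:
            key = (c.drug, c.gene)
            if key in corr_seen:
                raise KnowledgeBaseError(f"duplicate correlation for {key}")
            corr_seen.add(key)

    # -- lookups ---------------------------------------------------------

    def lookup_dgis(self, gene: str) -> list[DGIRecord]:
        """All interaction records for a gene symbol (normalized); [] if none."""
        return list(self._dgi_by_gene.get(normalize_gene(gene), []))

    def civic_for(self, gene: str, drug: str) -> list[CivicEvidence]:
        return list(self._civic_by_pair.get((normalize_gene(gene), normalize_drug(drug)), []))

    def curation_for(self, gene: str, drug: str) -> list[CurationRecord]:
        return list(self._curation_by_pair.get((normalize_gene(gene), normalize_drug(drug)), []))

    def has_civic(self, gene: str, drug: str) -> bool:
        return bool(self._civic_by_pair.get((normalize_gene(gene), normalize_drug(drug))))

    def trial_category(self, drug: str) -> TrialCategory:
        """Trial category of a drug; drugs absent from the snapshot are OTHER."""
        return self.trial_categories.get(normalize_drug(drug), TrialCategory.OTHER)

    @property
    def genes(self) -> list[str]:
        return sorted(self._dgi_by_gene)


# -- snapshot I/O --------------------------------------------------------

_COLUMNS = {
    "dgi": ["gene", "drug", "source_count", "reference_ids", "is_expert_curated"],
    "civic": [
        "gene", "variant_descriptor", "drug", "significance",
        "evidence_level", "disease", "is_target_disease",
    ],
    "curation": [
        "gene", "drug", "variant_scope", "variant_descriptor", "response",
        "annotations", "combination_partner", "reference_id",
    ],
    "trials": ["drug", "category"],
    "correlations": ["drug", "gene", "r"],
}

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _parse_bool(value: str, *, where: str) -> bool:
    try:
        return _BOOL[str(value).strip().lower()]
    except KeyError:
        raise KnowledgeBaseError(f"{where}: not a boolean: {value!r}") from None


def _read_table(path: Path, kind: str) -> pd.DataFrame:
    if not path.exists():
        raise KnowledgeBaseError(f"missing snapshot file: {path}")
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        skip = 1 if first.startswith("#") else 0
    df = pd.read_csv(
        path, sep="\t", skiprows=skip, dtype=str, keep_default_na=False
    )
    expected = _COLUMNS[kind]
    if list(df.columns) != expected:
        raise KnowledgeBaseError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    return df


def _row_error(path: Path, i: int, exc: Exception) -> KnowledgeBaseError:
    # data rows start after header (and optional version line); report 1-based
    return KnowledgeBaseError(f"{path}: malformed row {i + 1}: {exc}")


def load_snapshots(paths: Mapping[str, str | Path]) -> KnowledgeBase:
    """Read the five snapshot TSVs into an indexed :class:`KnowledgeBase`.

    ``paths`` maps the keys ``dgi``, ``civic``, ``curation``, ``trials``,
    ``correlations`` to file paths.  All invariants of the record types are
    enforced; any violation aborts with the offending file and row.
    """
    paths = {k: Path(v) for k, v in paths.items()}
    missing = set(_COLUMNS) - set(paths)
    if missing:
        raise KnowledgeBaseError(f"missing snapshot paths for: {sorted(missing)}")

    dgi_df = _read_table(paths["dgi"], "dgi")
    dgi: list[DGIRecord] = []
    for i, row in enumerate(dgi_df.itertuples(index=False)):
        try:
            refs = tuple(r for r in str(row.reference_ids).split(";") if r)
            dgi.append(
                DGIRecord(
                    gene=normalize_gene(row.gene),
                    drug=normalize_drug(row.drug),
                    source_count=int(row.source_count),
                    reference_ids=refs,
                    is_expert_curated=_parse_bool(
                        row.is_expert_curated, where=f"{paths['dgi']}:{i}"
                    ),
                )
            )
        except (ValueError, KnowledgeBaseError) as exc:
            raise _row_error(paths["dgi"], i, exc)

    civic_df = _read_table(paths["civic"], "civic")
    civic: list[CivicEvidence] = []
    for i, row in enumerate(civic_df.itertuples(index=False)):
        try:
            civic.append(
                CivicEvidence(
                    gene=normalize_gene(row.gene),
                    variant_descriptor=normalize_descriptor(row.variant_descriptor),
                    drug=normalize_drug(row.drug),
                    significance=Significance(row.significance),
                    evidence_level=int(row.evidence_level),
                    disease=str(row.disease),
                    is_target_disease=_parse_bool(
                        row.is_target_disease, where=f"{paths['civic']}:{i}"
                    ),
                )
            )
        except (ValueError, KnowledgeBaseError) as exc:
            raise _row_error(paths["civic"], i, exc)

    cur_df = _read_table(paths["curation"], "curation")
    curation: list[CurationRecord] = []
    for i, row in enumerate(cur_df.itertuples(index=False)):
        try:
            annotations = frozenset(
                CurationAnnotation(a) for a in str(row.annotations).split(";") if a
            )
            partner = normalize_drug(row.combination_partner) or None
            descriptor = str(row.variant_descriptor).strip()
            curation.append(
                CurationRecord(
                    gene=normalize_gene(row.gene),
                    drug=normalize_drug(row.drug),
                    variant_scope=VariantScope(row.variant_scope),
                    variant_descriptor=(
                        normalize_descriptor(descriptor) if descriptor else None
                    ),
                    response=Significance(row.response),
                    annotations=annotations,
                    combination_partner=partner,
                    reference_id=str(row.reference_id),
                )
            )
        except (ValueError, KnowledgeBaseError) as exc:
            raise _row_error(paths["curation"], i, exc)

    trials_df = _read_table(paths["trials"], "trials")
    trials: dict[str, TrialCategory] = {}
    for i, row in enumerate(trials_df.itertuples(index=False)):
        try:
            drug = normalize_drug(row.drug)
            cat = TrialCategory(str(row.category).upper())
        except ValueError as exc:
            raise _row_error(paths["trials"], i, exc)
        if drug in trials and trials[drug] is not cat:
            raise _row_error(
                paths["trials"], i, ValueError(f"conflicting categories for {drug}")
            )
        trials[drug] = cat

    corr_df = _read_table(paths["correlations"], "correlations")
    correlations: list[DrugGeneCorrelation] = []
    for i, row in enumerate(corr_df.itertuples(index=False)):
        try:
            correlations.append(
                DrugGeneCorrelation(
                    drug=normalize_drug(row.drug),
                    gene=normalize_gene(row.gene),
                    r=float(row.r),
                )
            )
        except (ValueError, KnowledgeBaseError) as exc:
            raise _row_error(paths["correlations"], i, exc)

    return KnowledgeBase(
        dgi=dgi,
        civic=civic,
        curation=curation,
        trial_categories=trials,
        correlations=correlations,
    )


def write_snapshots(kb: KnowledgeBase, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a knowledge base back to the five snapshot TSVs.

    Rows are written in a canonical sort order so that a load → write → load
    round trip is byte-stable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, header: Iterable[str], rows: Iterable[Iterable[str]]) -> None:
        path = out / f"{name}.tsv"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(SNAPSHOT_HEADER + "\n")
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(str(v) for v in row) + "\n")
        paths[name] = path

    _write(
        "dgi",
        _COLUMNS["dgi"],
        (
            (r.gene, r.drug, r.source_count, ";".join(r.reference_ids),
             str(r.is_expert_curated).lower())
            for r in sorted(kb.dgi, key=lambda r: (r.gene, r.drug))
        ),
    )
    _write(
        "civic",
        _COLUMNS["civic"],
        (
            (e.gene, e.variant_descriptor, e.drug, e.significance.value,
             e.evidence_level, e.disease, str(e.is_target_disease).lower())
            for e in sorted(
                kb.civic,
                key=lambda e: (e.gene, e.drug, e.variant_descriptor,
                               e.evidence_level, e.significance.value, e.disease),
            )
        ),
    )
    _write(
        "curation",
        _COLUMNS["curation"],
        (
            (r.gene, r.drug, r.variant_scope.value, r.variant_descriptor or "",
             r.response.value, ";".join(sorted(a.value for a in r.annotations)),
             r.combination_partner or "", r.reference_id)
            for r in sorted(
                kb.curation,
                key=lambda r: (r.gene, r.drug, r.variant_scope.value,
                               r.variant_descriptor or "", r.response.value,
                               r.reference_id),
            )
        ),
    )
    _write(
        "trials",
        _COLUMNS["trials"],
        ((d, c.value) for d, c in sorted(kb.trial_categories.items())),
    )
    _write(
        "correlations",
        _COLUMNS["correlations"],
        (
            (c.drug, c.gene, repr(c.r))
            for c in sorted(kb.correlations, key=lambda c: (c.drug, c.gene))
        ),
    )
    return paths
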