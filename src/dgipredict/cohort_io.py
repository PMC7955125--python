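"""Cohort-level input readers.

Four inputs describe a tumor cohort:

* per-caller somatic SNV calls (matched tumor/normal), merged here into one
  call per unique (sample, chrom, pos, ref, alt) with the set of callers
  that reported it;
* gene-level integer copy-number calls;
* a genes × samples normalized expression matrix;
* per-sample molecular-subtype labels.

SNV files may be VCF 4.x (one single-sample VCF per caller and sample, with
annotations in INFO fields) or a tab-separated dialect with an explicit
``sample_id`` column.  Coordinates are 1-based inclusive (VCF convention);
impact rank and damaging status are precomputed annotation columns — the
pipeline does not run an annotator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .knowledgebase import normalize_descriptor, normalize_gene

KNOWN_CALLERS = ("caller1", "caller2", "caller3")


class CohortIOError(ValueError):
    """Raised on malformed cohort input files."""


class CNVCategory(str, enum.Enum):
    DEL = "DEL"          # deletion, 0 copies
    LOSS = "LOSS"        # copy-number loss, 1 copy
    NEUTRAL = "NEUTRAL"  # 2 copies
    GAIN = "GAIN"        # gain, 3-4 copies
    AMP = "AMP"          # amplification, > 4 copies


class Subtype(str, enum.Enum):
    """Consensus molecular subtype classes of muscle-invasive bladder cancer."""

    LUM_P = "LumP"
    LUM_U = "LumU"
    LUM_NS = "LumNS"
    STROMA_RICH = "Stroma-rich"
    BA_SQ = "Ba/Sq"
    NE_LIKE = "NE-like"
    UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class SNVCall:
    """One somatic small variant in one sample, annotated for filtering."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    callers: frozenset[str]
    variant_class: str
    impact_rank: int
    damaging: bool
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if not self.callers:
            raise CohortIOError("SNVCall.callers must be non-empty")
        if self.pos < 1:
            raise CohortIOError(f"SNVCall.pos must be >= 1, got {self.pos}")
        if self.impact_rank < 0:
            raise CohortIOError(f"SNVCall.impact_rank must be >= 0, got {self.impact_rank}")

    @property
    def locus_key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)

    @property
    def descriptor(self) -> str:
        """Evidence-matching descriptor: the protein change, or wildcard."""
        return normalize_descriptor(self.protein_change)


def categorize_copy_number(copy_number: int) -> CNVCategory:
    """Map an integer copy number to its categorical copy state.

    0 → DEL, 1 → LOSS, 2 → NEUTRAL, 3–4 → GAIN, > 4 → AMP.
    """
    cn = int(copy_number)
    if cn < 0:
        raise CohortIOError(f"copy number must be >= 0, got {cn}")
    if cn == 0:
        return CNVCategory.DEL
    if cn == 1:
        return CNVCategory.LOSS
    if cn == 2:
        return CNVCategory.NEUTRAL
    if cn <= 4:
        return CNVCategory.GAIN
    return CNVCategory.AMP


@dataclass(frozen=True)
class CNVCall:
    """Gene-level copy-number call; ``category`` is derived from the count."""

    sample_id: str
    gene: str
    copy_number: int
    category: CNVCategory = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", categorize_copy_number(self.copy_number))

    @property
    def descriptor(self) -> str:
        """Evidence-matching descriptor for copy-number events."""
        return "AMPLIFICATION" if self.category is CNVCategory.AMP else self.category.value.replace("DEL", "DELETION")


@dataclass(frozen=True)
class SubtypeLabel:
    sample_id: str
    subtype: Subtype


# -- SNV reading ---------------------------------------------------------

#: INFO keys / column names carrying the annotation fields, overridable per
#: input convention.
DEFAULT_ANNOTATION_CONFIG = {
    "gene": "GENE",
    "variant_class": "VARCLASS",
    "impact_rank": "IMPACT_RANK",
    "damaging": "DAMAGING",
    "protein_change": "PCHANGE",
}

_TSV_SNV_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene",
    "variant_class", "impact_rank", "damaging", "protein_change",
]

_TRUTHY = {"true": True, "1": True, "false": False, "0": False}


def _coerce_bool(value: object, where: str) -> bool:
    if isinstance(value, bool):
        return value
    try:
        return _TRUTHY[str(value).strip().lower()]
    except KeyError:
        raise CohortIOError(f"{where}: not a boolean: {value!r}") from None


def _read_snv_tsv(path: Path, caller: str) -> list[SNVCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_TSV_SNV_COLUMNS) - set(df.columns)
    if missing:
        raise CohortIOError(f"{path}: missing annotation columns {sorted(missing)}")
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            SNVCall(
                sample_id=str(row.sample_id),
                gene=normalize_gene(row.gene),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                callers=frozenset([caller]),
                variant_class=str(row.variant_class),
                impact_rank=int(row.impact_rank),
                damaging=_coerce_bool(row.damaging, f"{path}"),
                protein_change=str(row.protein_change) or None,
            )
        )
    return calls


def _read_snv_vcf(path: Path, caller: str, ann: Mapping[str, str]) -> list[SNVCall]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise CohortIOError(f"{path}: expected a single-sample VCF, found {vcf.samples}")
    sample_id = vcf.samples[0]
    calls = []
    for variant in vcf:
        info = dict(variant.INFO)
        try:
            gene = info[ann["gene"]]
            variant_class = info[ann["variant_class"]]
            impact_rank = int(info[ann["impact_rank"]])
            damaging = _coerce_bool(info[ann["damaging"]], f"{path}:{variant.POS}")
        except KeyError as exc:
            raise CohortIOError(f"{path}: missing annotation INFO field {exc}") from None
        protein_change = info.get(ann["protein_change"])
        for alt in variant.ALT:
            calls.append(
                SNVCall(
                    sample_id=sample_id,
                    gene=normalize_gene(gene),
                    chrom=str(variant.CHROM),
                    pos=int(variant.POS),
                    ref=str(variant.REF),
                    alt=str(alt),
                    callers=frozenset([caller]),
                    variant_class=str(variant_class),
                    impact_rank=impact_rank,
                    damaging=damaging,
                    protein_change=str(protein_change) if protein_change else None,
                )
            )
    return calls


def read_snv_calls(
    caller_files: Mapping[str, Sequence[str | Path]],
    annotation_config: Mapping[str, str] | None = None,
) -> list[SNVCall]:
    """Read per-caller SNV files and merge them into consensus-ready calls.

    ``caller_files`` maps a caller label (``caller1``/``caller2``/``caller3``)
    to its call files.  Calls identical in (sample, chrom, pos, ref, alt)
    across callers are merged into one :class:`SNVCall` whose ``callers`` is
    the set of reporting callers; annotations are taken from the first file
    that reported the call (annotation fields are locus properties, so
    callers agree on them).  The merge is order-independent.
    """
    ann = dict(DEFAULT_ANNOTATION_CONFIG)
    if annotation_config:
        ann.update(annotation_config)
    unknown = set(caller_files) - set(KNOWN_CALLERS)
    if unknown:
        raise CohortIOError(f"unknown caller labels: {sorted(unknown)}")

    merged: dict[tuple, SNVCall] = {}
    for caller in KNOWN_CALLERS:  # fixed iteration order for determinism
        for path in caller_files.get(caller, []):
            path = Path(path)
            reader = _read_snv_vcf if path.suffix.lower() == ".vcf" else _read_snv_tsv
            calls = (
                reader(path, caller, ann) if reader is _read_snv_vcf
                else reader(path, caller)
            )
            for call in calls:
                key = call.locus_key
                if key in merged:
                    merged[key] = replace(
                        merged[key], callers=merged[key].callers | call.callers
                    )
                else:
                    merged[key] = call
    return sorted(merged.values(), key=lambda c: c.locus_key)


def write_snv_calls(calls: Sequence[SNVCall], path: str | Path, caller: str) -> None:
    """Write the subset of calls reported by ``caller`` in the TSV dialect."""
    rows = [
        {
            "sample_id": c.sample_id, "chrom": c.chrom, "pos": c.pos,
            "ref": c.ref, "alt": c.alt, "gene": c.gene,
            "variant_class": c.variant_class, "impact_rank": c.impact_rank,
            "damaging": str(c.damaging).lower(),
            "protein_change": c.protein_change or "",
        }
        for c in calls
        if caller in c.callers
    ]
    pd.DataFrame(rows, columns=_TSV_SNV_COLUMNS).to_csv(path, sep="\t", index=False)


# -- CNV / expression / subtype reading ----------------------------------

def read_cnv_calls(path: str | Path) -> list[CNVCall]:
    """Read gene-level copy-number calls (sample_id, gene, copy_number)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "gene", "copy_number"}
    if not required <= set(df.columns):
        raise CohortIOError(f"{path}: expected columns {sorted(required)}")
    calls = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        cn = int(row.copy_number)
        if cn < 0:
            raise CohortIOError(f"{path}: negative copy number for {row.sample_id}/{row.gene}")
        key = (str(row.sample_id), normalize_gene(row.gene))
        if key in seen:
            raise CohortIOError(f"{path}: duplicate CNV row for {key}")
        seen.add(key)
        calls.append(CNVCall(sample_id=key[0], gene=key[1], copy_number=cn))
    return calls


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples expression matrix (TSV, gene symbols as index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [normalize_gene(g) for g in df.index]
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise CohortIOError(f"{path}: duplicated gene rows: {dupes}")
    if df.columns.duplicated().any():
        raise CohortIOError(f"{path}: duplicated sample columns")
    values = df.to_numpy()
    import numpy as np

    if not np.isfinite(values).all():
        raise CohortIOError(f"{path}: non-finite expression values")
    return df


def read_subtypes(path: str | Path) -> list[SubtypeLabel]:
    """Read per-sample subtype labels (sample_id, subtype)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"sample_id", "subtype"} <= set(df.columns):
        raise CohortIOError(f"{path}: expected columns sample_id, subtype")
    labels = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        sid = str(row.sample_id)
        if sid in seen:
            raise CohortIOError(f"{path}: duplicate subtype label for {sid}")
        seen.add(sid)
        try:
            subtype = Subtype(row.subtype)
        except ValueError:
            raise CohortIOError(f"{path}: unknown subtype {row.subtype!r}") from None
        labels.append(SubtypeLabel(sample_id=sid, subtype=subtype))
    return labels


def subtype_map(
    labels: Sequence[SubtypeLabel], samples: Sequence[str]
) -> dict[str, Subtype]:
    """Per-sample subtype; cohort samples without a label are UNASSIGNED."""
    known = {lab.sample_id: lab.subtype for lab in labels}
    return {s: known.get(s, Subtype.UNASSIGNED) for s in samples}
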