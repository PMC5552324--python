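"""Score-table joins, genomic region / splice-distance classification and
TF-peak overlap.

Score tables are TSV with a documented header. Recognized columns (all
optional except ``var_id``): ``chrom pos ref alt var_id gene hgvs
cadd_phred gwava_region genomiser spidex_dpsi maf_1000g maf_gnomad
clinical_class proband_freq tools``. Empty cells, ``NA`` and ``.`` load
as null; a literal ``0`` loads as numeric zero (the two spellings are
distinguished on purpose).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from deepintron.errors import AmbiguousScoreError, DataError
from deepintron.variant_model.core import GenomicVariant
from deepintron.variant_model.regions import GeneModel, TFPeaks


class ClinicalClass(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "VUS"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    CONFLICTING = "conflicting"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def is_pathogenic(self) -> bool:
        return self in (ClinicalClass.PATHOGENIC, ClinicalClass.LIKELY_PATHOGENIC)


class Region(str, enum.Enum):
    EXONIC = "exonic"
    CANONICAL_SPLICE_SITE = "canonical_splice_site"
    PROXIMAL_INTRONIC = "proximal_intronic"
    DEEP_INTRONIC = "deep_intronic"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ScoreRecord:
    """Precomputed pathogenicity scores, reference MAFs and clinical class
    for one variant. Nullable fields use ``None``, never sentinel zeros."""

    var_id: str
    variant_key: Optional[tuple[str, int, str, str]] = None
    gene: Optional[str] = None
    hgvs: Optional[str] = None
    cadd_phred: Optional[float] = None
    gwava_region: Optional[float] = None
    genomiser: Optional[float] = None
    spidex_dpsi: Optional[float] = None
    maf_1000g: Optional[float] = None
    maf_gnomad: Optional[float] = None
    clinical_class: ClinicalClass = ClinicalClass.UNCLASSIFIED
    proband_freq: Optional[float] = None

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("gwava_region", 0.0, 1.0),
            ("genomiser", 0.0, 1.0),
            ("maf_1000g", 0.0, 1.0),
            ("maf_gnomad", 0.0, 1.0),
            ("proband_freq", 0.0, 1.0),
        ):
            value = getattr(self, name)
            if value is not None and not (lo <= value <= hi):
                raise DataError(f"{self.var_id}: {name}={value} outside [{lo}, {hi}]")

    @property
    def all_null(self) -> bool:
        return all(
            getattr(self, f) is None
            for f in ("cadd_phred", "gwava_region", "genomiser", "spidex_dpsi")
        )


_NULL_STRINGS = {"", "NA", "na", "NaN", ".", "None"}
_SCORE_COLUMNS = (
    "cadd_phred", "gwava_region", "genomiser", "spidex_dpsi",
    "maf_1000g", "maf_gnomad", "proband_freq",
)


def _parse_float(value) -> Optional[float]:
    if value is None:
        return None
    text = str(value).strip()
    if text in _NULL_STRINGS:
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise DataError(f"cannot parse numeric value {value!r}") from exc


def _parse_class(value) -> ClinicalClass:
    if value is None:
        return ClinicalClass.UNCLASSIFIED
    text = str(value).strip()
    if text in _NULL_STRINGS:
        return ClinicalClass.UNCLASSIFIED
    aliases = {
        "pathogenic": ClinicalClass.PATHOGENIC,
        "likely pathogenic": ClinicalClass.LIKELY_PATHOGENIC,
        "likely_pathogenic": ClinicalClass.LIKELY_PATHOGENIC,
        "vus": ClinicalClass.VUS,
        "uncertain significance": ClinicalClass.VUS,
        "likely benign": ClinicalClass.LIKELY_BENIGN,
        "likely_benign": ClinicalClass.LIKELY_BENIGN,
        "benign": ClinicalClass.BENIGN,
        "conflicting": ClinicalClass.CONFLICTING,
        "unclassified": ClinicalClass.UNCLASSIFIED,
    }
    try:
        return aliases[text.lower()]
    except KeyError as exc:
        raise DataError(f"unrecognized clinical class {value!r}") from exc


def read_score_table(path: str | Path) -> list[ScoreRecord]:
    """Read a score-annotation TSV into :class:`ScoreRecord` rows."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "var_id" not in df.columns:
        raise DataError(f"{path}: score table requires a 'var_id' column")
    if "clinical_class" not in df.columns and "acmg_class" in df.columns:
        df = df.rename(columns={"acmg_class": "clinical_class"})
    records = []
    for _, row in df.iterrows():
        key = None
        if all(c in df.columns for c in ("chrom", "pos", "ref", "alt")) and str(row["chrom"]).strip() not in _NULL_STRINGS:
            key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        kwargs = {c: _parse_float(row[c]) for c in _SCORE_COLUMNS if c in df.columns}
        records.append(
            ScoreRecord(
                var_id=str(row["var_id"]),
                variant_key=key,
                gene=str(row["gene"]) if "gene" in df.columns and row["gene"] else None,
                hgvs=str(row["hgvs"]) if "hgvs" in df.columns and row["hgvs"] else None,
                clinical_class=_parse_class(row["clinical_class"]) if "clinical_class" in df.columns else ClinicalClass.UNCLASSIFIED,
                **kwargs,
            )
        )
    return records


def write_score_table(records: Iterable[ScoreRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "var_id": r.var_id,
            "gene": r.gene or "",
            "hgvs": r.hgvs or "",
            "clinical_class": r.clinical_class.value,
        }
        if r.variant_key is not None:
            row.update(zip(("chrom", "pos", "ref", "alt"), r.variant_key))
        for c in _SCORE_COLUMNS:
            value = getattr(r, c)
            row[c] = "NA" if value is None else repr(value)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _records_conflict(a: ScoreRecord, b: ScoreRecord) -> bool:
    fields = _SCORE_COLUMNS + ("clinical_class",)
    return any(getattr(a, f) != getattr(b, f) for f in fields)


def annotate_scores(
    variants: Sequence[GenomicVariant], score_table: Sequence[ScoreRecord]
) -> list[tuple[GenomicVariant, ScoreRecord]]:
    """Left-join score records onto variants (tuple key preferred, id fallback).

    Every input variant appears exactly once in the output; unmatched
    variants carry an all-null record. Two conflicting table rows for one
    join key raise :class:`AmbiguousScoreError` naming the key.
    """
    by_key: dict[tuple, ScoreRecord] = {}
    by_id: dict[str, ScoreRecord] = {}
    for rec in score_table:
        for index, key in ((by_key, rec.variant_key), (by_id, rec.var_id)):
            if key in (None, ""):
                continue
            existing = index.get(key)
            if existing is not None and _records_conflict(existing, rec):
                raise AmbiguousScoreError(f"conflicting score rows for key {key!r}")
            index.setdefault(key, rec)
    out = []
    for v in variants:
        rec = by_key.get(v.key)
        if rec is None and v.id:
            rec = by_id.get(v.id)
        if rec is None:
            rec = ScoreRecord(var_id=v.id or str(v), variant_key=v.key)
        out.append((v, rec))
    return out


@dataclass(frozen=True)
class RegionAnnotation:
    """Region class plus unsigned distance to the nearest exon boundary."""

    region: Region
    splice_distance: Optional[int]
    gene: Optional[str]

    def __post_init__(self) -> None:
        if self.region is Region.DEEP_INTRONIC and (self.splice_distance or 0) < 100:
            raise DataError("deep_intronic requires splice_distance >= 100")
        if self.region is Region.CANONICAL_SPLICE_SITE and (self.splice_distance or 99) > 2:
            raise DataError("canonical_splice_site requires splice_distance <= 2")


def _intron_distance(p0: int, exons: Sequence[tuple[int, int]]) -> int:
    """Distance in nt from an intronic 0-based position to the nearest
    exon boundary of the containing gene; the first intronic base is 1."""
    best = math.inf
    for s, e in exons:
        if p0 >= e:
            best = min(best, p0 - e + 1)
        if p0 < s:
            best = min(best, s - p0)
    return int(best)


def classify_region(v: GenomicVariant, models: Sequence[GeneModel]) -> RegionAnnotation:
    """Classify a variant position against gene models.

    Inside any exon -> exonic. Otherwise, within a gene span, the distance
    to the nearest exon boundary decides: <=2 canonical splice site, 3-99
    proximal intronic, >=100 deep intronic. Outside all spans -> intergenic.
    """
    p0 = v.pos - 1
    containing = [m for m in models if m.chrom == v.chrom and m.contains(v.pos)]
    best: Optional[tuple[int, str]] = None
    for m in containing:
        if any(s <= p0 < e for s, e in m.exons):
            d = min(min(p0 - s + 1, e - p0) for s, e in m.exons if s <= p0 < e)
            return RegionAnnotation(Region.EXONIC, d, m.gene)
        d = _intron_distance(p0, m.exons)
        if best is None or d < best[0]:
            best = (d, m.gene)
    if best is None:
        return RegionAnnotation(Region.INTERGENIC, None, None)
    distance, gene = best
    if distance <= 2:
        region = Region.CANONICAL_SPLICE_SITE
    elif distance < 100:
        region = Region.PROXIMAL_INTRONIC
    else:
        region = Region.DEEP_INTRONIC
    return RegionAnnotation(region, distance, gene)


def tfbs_overlap(v: GenomicVariant, peaks: TFPeaks) -> set[str]:
    """Names of all TFs whose peak intervals contain the variant position."""
    return peaks.overlapping(v)
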