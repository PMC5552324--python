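"""Interval containers: target regions, gene models, TF peak tracks.

All intervals are stored 0-based half-open (BED convention); VCF positions
are converted at the query boundary (``pos0 = pos - 1``).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from deepintron.errors import DataError
from deepintron.variant_model.core import GenomicVariant, normalize_chrom


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if s >= e:
            raise DataError(f"invalid interval [{s}, {e}): start must be < end")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class TargetRegions:
    """Sorted, merged target intervals per chromosome."""

    by_chrom: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int]], strip_prefixes: tuple[str, ...] = ("chr",)
    ) -> "TargetRegions":
        grouped: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            grouped.setdefault(normalize_chrom(chrom, strip_prefixes), []).append((s, e))
        return cls({c: merge_intervals(ivs) for c, ivs in grouped.items()})

    @classmethod
    def from_bed(cls, path: str | Path, strip_prefixes: tuple[str, ...] = ("chr",)) -> "TargetRegions":
        return cls.from_intervals(_read_bed3(path), strip_prefixes)

    def contains(self, chrom: str, pos: int, strip_prefixes: tuple[str, ...] = ("chr",)) -> bool:
        """True iff the 1-based ``pos`` falls inside a target interval."""
        ivs = self.by_chrom.get(normalize_chrom(chrom, strip_prefixes))
        if not ivs:
            return False
        p0 = pos - 1
        i = bisect.bisect_right([s for s, _ in ivs], p0) - 1
        return i >= 0 and ivs[i][0] <= p0 < ivs[i][1]

    def total_span(self) -> int:
        return sum(e - s for ivs in self.by_chrom.values() for s, e in ivs)

    def __iter__(self):
        for chrom in sorted(self.by_chrom):
            for s, e in self.by_chrom[chrom]:
                yield chrom, s, e

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in self:
                fh.write(f"{chrom}\t{s}\t{e}\n")


@dataclass(frozen=True)
class GeneModel:
    """Exon layout of one gene; exons are 0-based half-open, sorted."""

    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise DataError(f"gene {self.gene}: at least one exon required")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise DataError(f"gene {self.gene}: invalid exon [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise DataError(f"gene {self.gene}: exons overlap or are unsorted")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def contains(self, pos: int) -> bool:
        """Gene span containment for a 1-based position."""
        s, e = self.span
        return s <= pos - 1 < e


def _read_bed3(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


@dataclass
class TFPeaks:
    """TF ChIP peak intervals keyed by factor name (BED with name column)."""

    by_tf: dict[str, TargetRegions] = field(default_factory=dict)

    @classmethod
    def from_bed(cls, path: str | Path, strip_prefixes: tuple[str, ...] = ("chr",)) -> "TFPeaks":
        grouped: dict[str, list[tuple[str, int, int]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise DataError(f"{path}:{lineno}: TF peak BED needs a 4th name column")
                grouped.setdefault(parts[3], []).append((parts[0], int(parts[1]), int(parts[2])))
        return cls({tf: TargetRegions.from_intervals(ivs, strip_prefixes) for tf, ivs in grouped.items()})

    def overlapping(self, v: GenomicVariant) -> set[str]:
        """Names of all TFs whose peaks contain the variant position."""
        return {tf for tf, regions in self.by_tf.items() if regions.contains(v.chrom, v.pos)}


def read_bed12(path: str | Path, strip_prefixes: tuple[str, ...] = ("chr",)) -> list[GeneModel]:
    """Read gene models from a BED12 file (one gene per line)."""
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise DataError(f"{path}:{lineno}: BED12 line has {len(parts)} columns")
            chrom = normalize_chrom(parts[0], strip_prefixes)
            start = int(parts[1])
            name, strand = parts[3], parts[5]
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise DataError(f"{path}:{lineno}: block count mismatch")
            exons = tuple((start + o, start + o + sz) for o, sz in zip(starts, sizes))
            models.append(GeneModel(name, chrom, strand, exons))
    return models


def read_gff3(path: str | Path, strip_prefixes: tuple[str, ...] = ("chr",)) -> list[GeneModel]:
    """Read gene models (gene -> exon union) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    models = []
    for gene in db.features_of_type("gene"):
        exon_ivs = [(f.start - 1, f.end) for f in db.children(gene, featuretype="exon")]
        if not exon_ivs:
            continue
        name = gene.attributes.get("Name", [gene.id])[0]
        models.append(
            GeneModel(
                gene=name,
                chrom=normalize_chrom(gene.seqid, strip_prefixes),
                strand=gene.strand if gene.strand in ("+", "-") else "+",
                exons=tuple(merge_intervals(exon_ivs)),
            )
        )
    return models


def read_gene_models(path: str | Path, strip_prefixes: tuple[str, ...] = ("chr",)) -> list[GeneModel]:
    """Dispatch on file extension: .bed/.bed12 -> BED12, .gff/.gff3 -> GFF3."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return read_gff3(path, strip_prefixes)
    return read_bed12(path, strip_prefixes)


def write_gene_models_bed12(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            start, end = m.span
            sizes = ",".join(str(e - s) for s, e in m.exons)
            starts = ",".join(str(s - start) for s, e in m.exons)
            fh.write(
                f"{m.chrom}\t{start}\t{end}\t{m.gene}\t0\t{m.strand}\t{start}\t{end}\t0\t"
                f"{len(m.exons)}\t{sizes}\t{starts}\n"
            )
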