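"""Threshold-based tool-set partition and tiering of annotated variants.

Default comparisons (each configurable):

* CADD PHRED  -- pass if strictly greater than 15
* GWAVA region score -- pass if greater-or-equal 0.5
* Genomiser variant score -- pass if strictly greater than 0.6
* SPIDEX dPSI -- pass if absolute value strictly greater than 5

A null score never passes. Tier 1 = prioritized simultaneously by CADD,
GWAVA and Genomiser; tier 2 = any two tools; tier 3 = exactly one; 0 = none.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from deepintron.annotation import RegionAnnotation, ScoreRecord
from deepintron.errors import DataError
from deepintron.variant_model.core import GenomicVariant

TOOL_CADD = "CADD"
TOOL_GWAVA = "GWAVA"
TOOL_GENOMISER = "GENOMISER"
TOOL_SPIDEX = "SPIDEX"
TOOL_ORDER = (TOOL_CADD, TOOL_GWAVA, TOOL_GENOMISER, TOOL_SPIDEX)
TRIPLE = frozenset((TOOL_CADD, TOOL_GWAVA, TOOL_GENOMISER))


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-tool prioritization cutoffs with documented comparison direction."""

    cadd_min: float = 15.0       # strictly greater
    gwava_min: float = 0.5       # greater or equal
    genomiser_min: float = 0.6   # strictly greater
    spidex_abs_min: float = 5.0  # |dPSI| strictly greater

    def __post_init__(self) -> None:
        for name in ("cadd_min", "gwava_min", "genomiser_min", "spidex_abs_min"):
            value = getattr(self, name)
            if not (value == value and abs(value) != float("inf")):
                raise DataError(f"threshold {name} must be finite, got {value}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise DataError(f"{path}: unknown threshold keys {sorted(unknown)}")
        return cls(**data)

    def toolset(self, scores: ScoreRecord) -> frozenset[str]:
        """Tools whose score is present and passes its comparison."""
        tools = set()
        if scores.cadd_phred is not None and scores.cadd_phred > self.cadd_min:
            tools.add(TOOL_CADD)
        if scores.gwava_region is not None and scores.gwava_region >= self.gwava_min:
            tools.add(TOOL_GWAVA)
        if scores.genomiser is not None and scores.genomiser > self.genomiser_min:
            tools.add(TOOL_GENOMISER)
        if scores.spidex_dpsi is not None and abs(scores.spidex_dpsi) > self.spidex_abs_min:
            tools.add(TOOL_SPIDEX)
        return frozenset(tools)


def tier_for(toolset: frozenset[str]) -> int:
    if TRIPLE <= toolset:
        return 1
    if len(toolset) >= 2:
        return 2
    if len(toolset) == 1:
        return 3
    return 0


def toolset_label(toolset: frozenset[str]) -> str:
    """Canonical display label, e.g. ``"CADD, GWAVA, GENOMISER"``."""
    return ", ".join(t for t in TOOL_ORDER if t in toolset)


def parse_toolset_label(label: str) -> frozenset[str]:
    parts = [p.strip().upper() for p in label.split(",") if p.strip()]
    unknown = set(parts) - set(TOOL_ORDER)
    if unknown:
        raise DataError(f"unknown tool labels {sorted(unknown)} in {label!r}")
    return frozenset(parts)


@dataclass(frozen=True)
class PrioritizedVariant:
    """A variant with its scores, optional region annotation, tool set and tier."""

    scores: ScoreRecord
    toolset: frozenset[str]
    tier: int
    variant: Optional[GenomicVariant] = None
    region: Optional[RegionAnnotation] = None

    @property
    def var_id(self) -> str:
        return self.scores.var_id

    @property
    def label(self) -> str:
        return toolset_label(self.toolset)


def partition_by_tools(
    annotated: Sequence[ScoreRecord | tuple],
    cfg: ThresholdConfig = ThresholdConfig(),
) -> list[PrioritizedVariant]:
    """Compute each variant's tool set and tier.

    Accepts plain :class:`ScoreRecord` rows, ``(variant, scores)`` pairs,
    or ``(variant, scores, region)`` triples.
    """
    out = []
    for item in annotated:
        variant = region = None
        if isinstance(item, ScoreRecord):
            scores = item
        else:
            variant, scores = item[0], item[1]
            if len(item) > 2:
                region = item[2]
        ts = cfg.toolset(scores)
        out.append(
            PrioritizedVariant(scores=scores, toolset=ts, tier=tier_for(ts),
                               variant=variant, region=region)
        )
    return out


def venn_partition(
    prioritized: Iterable[PrioritizedVariant],
) -> dict[frozenset[str], list[PrioritizedVariant]]:
    """Group variants by exact tool set (empty tool sets are excluded)."""
    groups: dict[frozenset[str], list[PrioritizedVariant]] = {}
    for pv in prioritized:
        if pv.toolset:
            groups.setdefault(pv.toolset, []).append(pv)
    return groups


def write_prioritized_tsv(prioritized: Sequence[PrioritizedVariant], path: str | Path) -> None:
    """Write one row per variant, mirroring the published table layout."""
    with open(path, "w") as fh:
        fh.write(
            "tools\ttier\tgene\tvar_id\thgvs\tcadd_phred\tgwava_region\tgenomiser\t"
            "spidex_dpsi\tmaf_1000g\tmaf_gnomad\tproband_freq\tregion\tsplice_distance\n"
        )
        for pv in sorted(prioritized, key=lambda p: (p.tier if p.tier else 9, p.var_id)):
            s = pv.scores

            def fmt(x):
                return "NA" if x is None else (repr(x) if isinstance(x, float) else str(x))

            fh.write(
                "\t".join(
                    [
                        pv.label or "-",
                        str(pv.tier),
                        s.gene or "NA",
                        s.var_id,
                        s.hgvs or "NA",
                        fmt(s.cadd_phred),
                        fmt(s.gwava_region),
                        fmt(s.genomiser),
                        fmt(s.spidex_dpsi),
                        fmt(s.maf_1000g),
                        fmt(s.maf_gnomad),
                        fmt(s.proband_freq),
                        pv.region.region.value if pv.region else "NA",
                        str(pv.region.splice_distance) if pv.region and pv.region.splice_distance is not None else "NA",
                    ]
                )
                + "\n"
            )


def write_venn_tsv(groups: dict[frozenset[str], list[PrioritizedVariant]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("toolset\tcount\n")
        for ts in sorted(groups, key=lambda t: (-len(t), toolset_label(t))):
            fh.write(f"{toolset_label(ts)}\t{len(groups[ts])}\n")
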