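"""k-of-n ensemble consensus, depth/target filtering and truth benchmarking.

A variant is retained per sample when at least ``k`` of the ``n`` callers
report a non-reference genotype for it. Genotype consensus is a majority
vote over the supporting callers, with ties resolved toward het (the
weaker claim). The depth filter applies a configurable aggregate (min by
default) over the supporting callers' read depths.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from deepintron.errors import ParameterError
from deepintron.variant_model.core import (
    CallerObservation,
    Genotype,
    GenomicVariant,
)
from deepintron.variant_model.regions import TargetRegions
from deepintron.variant_model.vcfio import _build_header, _GT_CODES


@dataclass(frozen=True)
class ConsensusEntry:
    """One retained (sample, variant) with its supporting caller observations."""

    variant: GenomicVariant
    sample: str
    genotype: Genotype
    supporters: tuple[CallerObservation, ...]

    @property
    def support(self) -> frozenset[str]:
        return frozenset(o.caller for o in self.supporters)

    @property
    def n_support(self) -> int:
        return len(self.support)

    def depth_aggregate(self, how: str = "min") -> float:
        depths = [o.depth for o in self.supporters]
        if how == "min":
            return min(depths)
        if how == "max":
            return max(depths)
        if how == "mean":
            return sum(depths) / len(depths)
        raise ParameterError(f"unknown depth aggregate {how!r}")


@dataclass
class ConsensusCallset:
    """Result of a k-of-n merge over per-caller callsets."""

    entries: list[ConsensusEntry]
    k: int
    n: int
    callers: tuple[str, ...]

    @property
    def variants(self) -> set[GenomicVariant]:
        return {e.variant for e in self.entries}

    @property
    def variant_keys(self) -> set[tuple]:
        return {e.variant.key for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


def _majority_genotype(supporters: Sequence[CallerObservation]) -> Genotype:
    counts = Counter(o.genotype for o in supporters)
    top = counts.most_common()
    best_count = top[0][1]
    winners = [g for g, c in top if c == best_count]
    if len(winners) > 1:
        return Genotype.HET
    return winners[0]


def merge_callsets(
    callsets: Mapping[str, Sequence[CallerObservation]], k: int
) -> ConsensusCallset:
    """Merge per-caller observation lists into a k-of-n consensus callset.

    ``callsets`` maps caller label -> observations (normalized). A
    (sample, variant) is retained iff at least ``k`` distinct callers
    report a carrier genotype (het/hom_alt/hemi) for it.
    """
    callers = tuple(callsets)
    n = len(callers)
    if k < 1 or k > n:
        raise ParameterError(f"k must satisfy 1 <= k <= n={n}, got {k}")
    grouped: dict[tuple[str, tuple], dict[str, CallerObservation]] = {}
    for caller in callers:
        for obs in callsets[caller]:
            if obs.caller != caller:
                raise ParameterError(
                    f"observation labelled {obs.caller!r} found under caller {caller!r}"
                )
            if not obs.genotype.is_carrier:
                continue
            slot = grouped.setdefault((obs.sample, obs.variant.key), {})
            prev = slot.get(caller)
            if prev is None or obs.depth > prev.depth:
                slot[caller] = obs
    entries = []
    for (sample, _key), per_caller in grouped.items():
        if len(per_caller) < k:
            continue
        supporters = tuple(per_caller[c] for c in callers if c in per_caller)
        entries.append(
            ConsensusEntry(
                variant=supporters[0].variant,
                sample=sample,
                genotype=_majority_genotype(supporters),
                supporters=supporters,
            )
        )
    entries.sort(key=lambda e: (e.variant.chrom, e.variant.pos, e.variant.ref, e.variant.alt, e.sample))
    return ConsensusCallset(entries=entries, k=k, n=n, callers=callers)


def apply_depth_filter(
    cs: ConsensusCallset, min_depth: int = 20, aggregate: str = "min"
) -> ConsensusCallset:
    """Retain entries whose supporting-caller depth aggregate is >= ``min_depth``."""
    kept = [e for e in cs.entries if e.depth_aggregate(aggregate) >= min_depth]
    return replace(cs, entries=kept)


def restrict_to_targets(cs: ConsensusCallset, targets: TargetRegions) -> ConsensusCallset:
    """Keep entries whose variant position falls inside a target interval."""
    kept = [e for e in cs.entries if targets.contains(e.variant.chrom, e.variant.pos)]
    return replace(cs, entries=kept)


@dataclass(frozen=True)
class BenchmarkResult:
    """Allele-level confusion counts against a truth set.

    sensitivity = TP/(TP+FN); precision = TP/(TP+FP), ``None`` when the
    callset is empty (undefined rather than zero).
    """

    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> Optional[float]:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def precision(self) -> Optional[float]:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None


def benchmark(
    called: Iterable[GenomicVariant] | ConsensusCallset, truth: Iterable[GenomicVariant]
) -> BenchmarkResult:
    """Compare called variants to a truth set at the allele level."""
    if isinstance(called, ConsensusCallset):
        called_keys = called.variant_keys
    else:
        called_keys = {v.key for v in called}
    truth_keys = {v.key for v in truth}
    tp = len(called_keys & truth_keys)
    return BenchmarkResult(tp=tp, fp=len(called_keys - truth_keys), fn=len(truth_keys - called_keys))


def write_benchmark_tsv(results: Mapping[str, BenchmarkResult], path: str | Path) -> None:
    """Write per-caller / consensus benchmark rows as TSV."""
    with open(path, "w") as fh:
        fh.write("callset\tTP\tFP\tFN\tsensitivity\tprecision\n")
        for name, r in results.items():
            sens = "NA" if r.sensitivity is None else f"{r.sensitivity:.6f}"
            prec = "NA" if r.precision is None else f"{r.precision:.6f}"
            fh.write(f"{name}\t{r.tp}\t{r.fp}\t{r.fn}\t{sens}\t{prec}\n")


def write_consensus_vcf(
    cs: ConsensusCallset,
    path: str | Path,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write the consensus callset as one VCF with supporter INFO fields."""
    samples = sorted({e.sample for e in cs.entries if e.sample})
    by_variant: dict[tuple, list[ConsensusEntry]] = {}
    for e in cs.entries:
        by_variant.setdefault(e.variant.key, []).append(e)
    chroms = sorted({e.variant.chrom for e in cs.entries})
    contigs = [
        (
            c,
            (contig_lengths or {}).get(
                c,
                max(
                    (e.variant.pos + len(e.variant.ref) for e in cs.entries if e.variant.chrom == c),
                    default=1,
                )
                + 1000,
            ),
        )
        for c in chroms
    ]
    header = _build_header(
        contigs,
        samples,
        extra_info=[
            ("NSUP", 1, "Integer", "Maximum supporting-caller count over samples"),
            ("SUP", ".", "String", "Union of supporting caller labels over samples"),
        ],
    )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in sorted(by_variant):
            group = by_variant[key]
            v = group[0].variant
            sup = sorted({c for e in group for c in e.support})
            rec = out.new_record(contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt), id=v.id)
            rec.info["NSUP"] = max(e.n_support for e in group)
            rec.info["SUP"] = ",".join(sup)
            per_sample = {e.sample: e for e in group}
            for s in samples:
                if s in per_sample:
                    e = per_sample[s]
                    rec.samples[s]["GT"] = _GT_CODES[e.genotype]
                    rec.samples[s]["DP"] = int(e.depth_aggregate("min"))
                else:
                    rec.samples[s]["GT"] = (None, None)
            out.write(rec)
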