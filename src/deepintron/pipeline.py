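"""Pipeline orchestration: funnel stages, run manifest, end-to-end runs.

Stage order mirrors the analysis funnel: consensus merge -> depth filter
-> off-target removal -> annotation -> threshold prioritization ->
cohort enrichment -> segregation. Every intermediate is persisted as
text; reruns with identical inputs and seed are byte-identical for all
TSV/VCF outputs (the manifest carries timestamps and is exempt).
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from deepintron import __version__
from deepintron.annotation import annotate_scores, classify_region, read_score_table
from deepintron.cohort import (
    candidates_from,
    compute_enrichment,
    find_compound_het,
    read_cohort_tsv,
    segregation_summary,
    write_enrichment_tsv,
    write_segregation_tsv,
)
from deepintron.consensus import (
    apply_depth_filter,
    benchmark,
    merge_callsets,
    restrict_to_targets,
    write_benchmark_tsv,
    write_consensus_vcf,
)
from deepintron.errors import DataError
from deepintron.prioritization import (
    ThresholdConfig,
    partition_by_tools,
    venn_partition,
    write_prioritized_tsv,
    write_venn_tsv,
)
from deepintron.variant_model.pedigree import read_pedigree
from deepintron.variant_model.regions import TargetRegions, TFPeaks, read_gene_models
from deepintron.variant_model.vcfio import read_caller_vcf, read_truth_vcf


@dataclass
class RunManifest:
    """Auditable record of one pipeline run."""

    config: dict
    version: str = __version__
    input_digests: dict[str, str] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    started: str = ""
    finished: str = ""
    failed_stage: Optional[str] = None

    def record(self, name: str, n_in: int, n_out: int) -> None:
        self.stages.append({"stage": name, "n_in": n_in, "n_out": n_out})

    def check_funnel(self) -> None:
        for s in self.stages:
            if s["stage"].startswith("filter:") and s["n_out"] > s["n_in"]:
                raise DataError(f"funnel violated at stage {s['stage']}")

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
            fh.write("\n")


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_reference(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    with open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise DataError(f"{path}: pipeline config must be a mapping")
    return cfg


def run_pipeline(config: dict, outdir: str | Path) -> RunManifest:
    """Execute the configured stages and persist every intermediate.

    See README for the config schema. Raises :class:`DataError` before
    stage 1 when a referenced input file is missing.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config)
    manifest.started = datetime.datetime.now(datetime.timezone.utc).isoformat()

    input_paths: dict[str, str] = {}
    for key in ("reference", "truth_vcf", "targets_bed", "gene_models",
                "score_table", "exonic_table", "tf_peaks", "cohort"):
        if config.get(key):
            input_paths[key] = str(config[key])
    for label, path in (config.get("callers") or {}).items():
        input_paths[f"caller:{label}"] = str(path)
    for ped in config.get("pedigrees") or []:
        input_paths[f"pedigree:{ped['path']}"] = str(ped["path"])
    for name, path in input_paths.items():
        if not Path(path).exists():
            raise DataError(f"missing input file for {name!r}: {path}")
        manifest.input_digests[name] = _digest(path)

    thresholds = ThresholdConfig(**(config.get("thresholds") or {}))
    reference = _load_reference(config["reference"]) if config.get("reference") else None
    targets = TargetRegions.from_bed(config["targets_bed"]) if config.get("targets_bed") else None
    models = read_gene_models(config["gene_models"]) if config.get("gene_models") else None
    peaks = TFPeaks.from_bed(config["tf_peaks"]) if config.get("tf_peaks") else None

    try:
        consensus_variants = None
        if config.get("callers"):
            callsets = {
                label: read_caller_vcf(path, label, reference=reference)
                for label, path in config["callers"].items()
            }
            total_obs = sum(len(v) for v in callsets.values())
            k = int(config.get("k", 2))
            cs = merge_callsets(callsets, k=k)
            manifest.record("filter:consensus_merge", total_obs, len(cs))
            before = len(cs)
            cs = apply_depth_filter(cs, int(config.get("min_depth", 20)),
                                    config.get("depth_aggregate", "min"))
            manifest.record("filter:depth", before, len(cs))
            if targets is not None:
                before = len(cs)
                cs = restrict_to_targets(cs, targets)
                manifest.record("filter:on_target", before, len(cs))
            write_consensus_vcf(cs, outdir / "consensus.vcf")
            consensus_variants = sorted(cs.variants, key=lambda v: v.key)
            if config.get("truth_vcf"):
                truth = read_truth_vcf(config["truth_vcf"], reference=reference)
                results = {"consensus": benchmark(cs, truth)}
                for label, observations in callsets.items():
                    single = merge_callsets({label: observations}, k=1)
                    if targets is not None:
                        single = restrict_to_targets(single, targets)
                    results[label] = benchmark(single, truth)
                write_benchmark_tsv(results, outdir / "benchmark.tsv")

        score_records = read_score_table(config["score_table"]) if config.get("score_table") else []
        if consensus_variants is not None:
            annotated = annotate_scores(consensus_variants, score_records)
            rows: list[Any] = []
            for v, rec in annotated:
                region = classify_region(v, models) if models else None
                rows.append((v, rec, region))
            manifest.record("annotate", len(consensus_variants), len(rows))
        else:
            rows = list(score_records)
            manifest.record("annotate", len(score_records), len(rows))

        prioritized = partition_by_tools(rows, thresholds)
        n_prioritized = sum(1 for p in prioritized if p.toolset)
        manifest.record("filter:thresholds", len(prioritized), n_prioritized)
        write_prioritized_tsv(prioritized, outdir / "prioritized.tsv")
        write_venn_tsv(venn_partition(prioritized), outdir / "venn_counts.tsv")
        if peaks is not None:
            with open(outdir / "tfbs_overlap.tsv", "w") as fh:
                fh.write("var_id\ttfs\n")
                for pv in prioritized:
                    if pv.variant is not None:
                        tfs = sorted(peaks.overlapping(pv.variant))
                        fh.write(f"{pv.var_id}\t{','.join(tfs) or 'NA'}\n")

        if config.get("cohort"):
            cohort = read_cohort_tsv(config["cohort"], tuple(config.get("x_linked") or ()))
            enr_records = [pv.scores for pv in prioritized if pv.scores.var_id in cohort.variant_labels]
            enrichment = compute_enrichment(
                cohort, enr_records,
                fold_threshold=float(config.get("fold_threshold", 3.0)),
                reference=config.get("reference_population", "1000g"),
            )
            manifest.record("enrichment", len(enr_records), len(enrichment))
            write_enrichment_tsv(enrichment, outdir / "enrichment.tsv")
            exonic = read_score_table(config["exonic_table"]) if config.get("exonic_table") else []
            candidates = candidates_from(prioritized, exonic)
            pairs = find_compound_het(cohort, candidates)
            with open(outdir / "compound_het.tsv", "w") as fh:
                fh.write("sample\texonic\tintronic\tgenes\n")
                for sample in sorted(pairs):
                    for pair in pairs[sample]:
                        fh.write(
                            f"{sample}\t{pair.exonic.label}\t{pair.intronic.label}\t"
                            f"{pair.genes[0]},{pair.genes[1]}\n"
                        )

        for ped_cfg in config.get("pedigrees") or []:
            pedigree = read_pedigree(ped_cfg["path"])
            tracked = ped_cfg.get("variants") or pedigree.variant_labels
            summary = segregation_summary(pedigree, tracked)
            write_segregation_tsv(summary, outdir / f"segregation_{pedigree.family}.tsv")
    except Exception as exc:
        manifest.failed_stage = f"{type(exc).__name__}: {exc}"
        manifest.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
        manifest.write(outdir / "manifest.json")
        raise

    manifest.check_funnel()
    manifest.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
    manifest.write(outdir / "manifest.json")
    return manifest


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of one synthetic end-to-end replicate."""

    in_consensus: bool
    tier: int
    deep_intronic: bool
    enriched: bool

    @property
    def recovered(self) -> bool:
        return self.in_consensus and self.tier == 1 and self.enriched


def synthetic_end_to_end(cfg, k: int = 2, min_depth: int = 20, fold_threshold: float = 3.0) -> RecoveryResult:
    """Run the full in-memory pipeline on one synthetic replicate and
    report whether the planted enriched tier-1 variant is recovered."""
    import numpy as np

    from deepintron.annotation import Region
    from deepintron.cohort import cohort_allele_frequency, fold_enrichment
    from deepintron.synthetic import simulate_cohort, simulate_scores, simulate_truth_and_callers

    sim = simulate_truth_and_callers(cfg)
    cs = merge_callsets(sim.callsets, k=k)
    cs = apply_depth_filter(cs, min_depth)
    cs = restrict_to_targets(cs, sim.genome.targets)
    planted = sim.planted
    assert planted is not None
    in_consensus = planted.variant.key in cs.variant_keys

    consensus_variants = sorted(cs.variants, key=lambda v: v.key)
    flags = [v.key == planted.variant.key for v in consensus_variants]
    master = np.random.default_rng(cfg.seed)
    _, _, _, rng_cohort, _, rng_scores = master.spawn(6)
    records = simulate_scores(consensus_variants, flags, cfg, rng=rng_scores,
                              certain_ids=frozenset({"planted_1"}))
    annotated = []
    for v, rec in zip(consensus_variants, records):
        region = classify_region(v, sim.genome.genes)
        annotated.append((v, rec, region))
    prioritized = partition_by_tools(annotated)
    planted_pv = next((p for p in prioritized if p.variant is not None and p.variant.key == planted.variant.key), None)

    cohort = simulate_cohort(
        cfg, {"planted_1": cfg.planted_af}, rng_cohort,
        exact_labels=frozenset({"planted_1"}) if cfg.af_realization == "exact" else frozenset(),
    )
    af = cohort_allele_frequency(cohort, "planted_1")
    fold = fold_enrichment(af, cfg.planted_maf_1000g)
    return RecoveryResult(
        in_consensus=in_consensus,
        tier=planted_pv.tier if planted_pv is not None else 0,
        deep_intronic=bool(planted_pv and planted_pv.region and planted_pv.region.region is Region.DEEP_INTRONIC),
        enriched=fold.value >= fold_threshold,
    )
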