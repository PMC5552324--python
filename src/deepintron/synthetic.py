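"""Seeded generators for every input the pipeline consumes.

A toy genome with exon/intron gene structures is built first; true
variants are planted inside the target regions; per-caller callsets are
derived by applying independent per-caller sensitivity, uniform false
positives and (for indels) representation jitter; score tables, cohort
genotype matrices and pedigrees follow the same statistical structure the
analysis assumes (score distributions separated around the prioritization
thresholds, genotypes realized from planted allele frequencies, a family
generated under a digenic or monogenic penetrance rule).

All randomness flows from one master seed through per-generator spawned
streams, so identical configs regenerate byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from deepintron.cohort import CohortGenotypes, Ploidy, write_cohort_tsv
from deepintron.annotation import ScoreRecord, write_score_table
from deepintron.errors import ParameterError
from deepintron.prioritization import ThresholdConfig
from deepintron.variant_model.core import (
    CallerObservation,
    Genotype,
    GenomicVariant,
    ReferenceContext,
    Sex,
    normalize_variant,
)
from deepintron.variant_model.pedigree import (
    CarrierStatus,
    Pedigree,
    PedigreeMember,
    Phenotype,
    write_pedigree,
)
from deepintron.variant_model.regions import GeneModel, TargetRegions, write_gene_models_bed12
from deepintron.variant_model.vcfio import write_observations_vcf

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic pipeline inputs (see module docstring)."""

    seed: int = 0
    n_callers: int = 4
    caller_sensitivity: float | tuple[float, ...] = 0.9
    fp_rate_per_kb: float = 0.05
    indel_jitter_prob: float = 0.3
    n_truth_variants: int = 200
    n_samples: int = 16
    n_genes: int = 3
    exons_per_gene: int = 4
    exon_length: int = 150
    intron_length: int = 1500
    flank_length: int = 400
    indel_fraction: float = 0.2
    depth_mean: float = 60.0
    truth_af: float = 0.3
    # score model
    score_pass_prob: float = 0.9
    score_null_prob: float = 0.0
    # planted enriched candidate
    planted_af: float = 0.1875
    planted_maf_1000g: float = 0.06
    planted_maf_gnomad: float = 0.0671
    af_realization: str = "exact"  # "exact" | "binomial" (planted variant)
    pedigree_model: str = "digenic"  # "digenic" | "monogenic"
    caller_error_correlation: float = 0.0  # documented limitation; 0 = independent

    def sensitivities(self) -> tuple[float, ...]:
        s = self.caller_sensitivity
        if isinstance(s, (int, float)):
            return tuple(float(s) for _ in range(self.n_callers))
        if len(s) != self.n_callers:
            raise ParameterError("caller_sensitivity length must equal n_callers")
        return tuple(float(x) for x in s)

    def caller_labels(self) -> tuple[str, ...]:
        return tuple(f"caller_{i + 1}" for i in range(self.n_callers))

    def __post_init__(self) -> None:
        for name in ("fp_rate_per_kb", "indel_jitter_prob", "indel_fraction",
                     "truth_af", "score_pass_prob", "score_null_prob",
                     "planted_af", "caller_error_correlation"):
            value = getattr(self, name)
            if name != "fp_rate_per_kb" and not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name}={value} outside [0, 1]")
        for s in self.sensitivities():
            if not 0.0 <= s <= 1.0:
                raise ParameterError(f"caller sensitivity {s} outside [0, 1]")
        if self.af_realization not in ("exact", "binomial"):
            raise ParameterError("af_realization must be 'exact' or 'binomial'")
        if self.pedigree_model not in ("digenic", "monogenic"):
            raise ParameterError("pedigree_model must be 'digenic' or 'monogenic'")


@dataclass
class ToyGenome:
    sequences: dict[str, str]
    genes: list[GeneModel]
    targets: TargetRegions

    def context(self, chrom: str) -> ReferenceContext:
        return ReferenceContext(chrom, 1, self.sequences[chrom])


@dataclass(frozen=True)
class TruthVariant:
    variant: GenomicVariant
    genotypes: tuple[tuple[str, Genotype], ...]  # (sample, genotype), carriers only
    planted: bool = False

    @property
    def carriers(self) -> tuple[str, ...]:
        return tuple(s for s, g in self.genotypes if g.is_carrier)


@dataclass
class SimulatedCallsets:
    genome: ToyGenome
    truth: list[TruthVariant]
    callsets: dict[str, list[CallerObservation]]
    samples: list[str]

    @property
    def planted(self) -> Optional[TruthVariant]:
        for t in self.truth:
            if t.planted:
                return t
        return None

    @property
    def truth_variants(self) -> list[GenomicVariant]:
        return [t.variant for t in self.truth]


def make_toy_genome(cfg: SimulationConfig, rng: np.random.Generator) -> ToyGenome:
    """Random genome on one chromosome with evenly laid-out toy genes."""
    gene_span = cfg.exons_per_gene * cfg.exon_length + (cfg.exons_per_gene - 1) * cfg.intron_length
    total = cfg.flank_length + cfg.n_genes * (gene_span + cfg.flank_length)
    seq = "".join(rng.choice(_BASES, size=total))
    genes = []
    cursor = cfg.flank_length
    for i in range(cfg.n_genes):
        exons = []
        start = cursor
        for j in range(cfg.exons_per_gene):
            exons.append((start, start + cfg.exon_length))
            start += cfg.exon_length + cfg.intron_length
        genes.append(GeneModel(f"GENE{i + 1}", "1", "+" if i % 2 == 0 else "-", tuple(exons)))
        cursor += gene_span + cfg.flank_length
    targets = TargetRegions.from_intervals(
        [("1", max(0, g.span[0] - 100), g.span[1] + 100) for g in genes]
    )
    return ToyGenome(sequences={"1": seq}, genes=genes, targets=targets)


def _planted_position(genome: ToyGenome) -> int:
    """1-based deep-intronic position in intron 1 of the first gene."""
    first = genome.genes[0]
    donor_end = first.exons[0][1]  # 0-based exclusive end of exon 1
    return donor_end + 367  # 1-based position 367 nt into the intron


def _random_variant(
    genome: ToyGenome, pos: int, rng: np.random.Generator, indel: bool
) -> GenomicVariant:
    seq = genome.sequences["1"]
    ref_base = seq[pos - 1]
    if not indel:
        alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        return GenomicVariant("1", pos, ref_base, alt)
    length = int(rng.integers(1, 4))
    if rng.random() < 0.5:  # deletion
        ref = seq[pos - 1 : pos + length]
        return GenomicVariant("1", pos, ref, ref_base)
    insert = "".join(rng.choice(_BASES, size=length))
    return GenomicVariant("1", pos, ref_base, ref_base + insert)


def _hwe_genotype(af: float, rng: np.random.Generator) -> Genotype:
    alleles = int(rng.random() < af) + int(rng.random() < af)
    return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[alleles]


def simulate_truth(cfg: SimulationConfig, genome: ToyGenome, rng: np.random.Generator) -> list[TruthVariant]:
    samples = [f"S{i:02d}" for i in range(1, cfg.n_samples + 1)]
    target_positions = [
        pos
        for chrom, s, e in genome.targets
        for pos in range(s + 1, e + 1)
    ]
    planted_pos = _planted_position(genome)
    usable = [p for p in target_positions if abs(p - planted_pos) > 3]
    n_background = max(0, cfg.n_truth_variants - 1)
    chosen = rng.choice(len(usable), size=min(n_background, len(usable) // 4), replace=False)
    positions = sorted(usable[i] for i in chosen)
    # keep indel ref alleles from colliding with a neighbouring variant
    filtered, prev = [], -10
    for p in positions:
        if p - prev > 4:
            filtered.append(p)
            prev = p
    truth: list[TruthVariant] = []
    ctx = genome.context("1")
    for pos in filtered:
        indel = bool(rng.random() < cfg.indel_fraction)
        v = normalize_variant(_random_variant(genome, pos, rng, indel), ctx)
        genotypes = tuple(
            (s, g) for s in samples if (g := _hwe_genotype(cfg.truth_af, rng)).is_carrier
        )
        if not genotypes:
            genotypes = ((str(rng.choice(samples)), Genotype.HET),)
        truth.append(TruthVariant(v, genotypes))
    # planted deep-intronic SNV with an exactly-realized carrier count
    seq = genome.sequences["1"]
    ref_base = seq[planted_pos - 1]
    alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
    planted_variant = GenomicVariant("1", planted_pos, ref_base, alt, id="planted_1")
    if cfg.af_realization == "exact":
        n_carriers = int(round(cfg.planted_af * 2 * cfg.n_samples))
        carrier_idx = rng.choice(cfg.n_samples, size=min(n_carriers, cfg.n_samples), replace=False)
        genotypes = tuple((samples[i], Genotype.HET) for i in sorted(carrier_idx))
    else:
        genotypes = tuple(
            (s, g) for s in samples if (g := _hwe_genotype(cfg.planted_af, rng)).is_carrier
        )
    truth.append(TruthVariant(planted_variant, genotypes, planted=True))
    truth.sort(key=lambda t: t.variant.pos)
    return truth


def _jitter_spelling(
    v: GenomicVariant, genome: ToyGenome, rng: np.random.Generator
) -> GenomicVariant:
    """Emit an equivalent but unnormalized spelling of an indel."""
    seq = genome.sequences["1"]
    if rng.random() < 0.5 and v.pos + len(v.ref) <= len(seq):
        nxt = seq[v.pos - 1 + len(v.ref)]
        return GenomicVariant(v.chrom, v.pos, v.ref + nxt, v.alt + nxt, id=v.id)
    if v.pos >= 2:
        prev = seq[v.pos - 2]
        return GenomicVariant(v.chrom, v.pos - 1, prev + v.ref, prev + v.alt, id=v.id)
    return v


def simulate_truth_and_callers(
    cfg: SimulationConfig, outdir: Optional[str | Path] = None
) -> SimulatedCallsets:
    """Generate the toy genome, truth set and per-caller callsets.

    Each true (sample, variant) instance is reported by caller ``c`` with
    probability ``s_c``; false positives are placed uniformly in targets
    at ``fp_rate_per_kb`` per sample; with ``indel_jitter_prob`` a true
    indel is emitted in an alternative equivalent spelling.
    """
    master = np.random.default_rng(cfg.seed)
    rng_genome, rng_truth, rng_callers = master.spawn(3)
    genome = make_toy_genome(cfg, rng_genome)
    truth = simulate_truth(cfg, genome, rng_truth)
    samples = [f"S{i:02d}" for i in range(1, cfg.n_samples + 1)]
    sens = cfg.sensitivities()
    labels = cfg.caller_labels()
    truth_positions = {t.variant.pos for t in truth}
    span_kb = genome.targets.total_span() / 1000.0
    callsets: dict[str, list[CallerObservation]] = {}
    target_positions = [
        pos for chrom, s, e in genome.targets for pos in range(s + 1, e + 1)
        if pos not in truth_positions
    ]
    for caller, s_c in zip(labels, sens):
        rng = rng_callers.spawn(1)[0]
        observations: list[CallerObservation] = []
        for t in truth:
            emit = t.variant
            if not t.variant.is_snv and rng.random() < cfg.indel_jitter_prob:
                emit = _jitter_spelling(t.variant, genome, rng)
            for sample, genotype in t.genotypes:
                if rng.random() >= s_c:
                    continue
                depth = int(rng.poisson(cfg.depth_mean))
                observations.append(CallerObservation(caller, emit, sample, genotype, depth))
        for sample in samples:
            n_fp = int(rng.poisson(cfg.fp_rate_per_kb * span_kb))
            if n_fp:
                fp_idx = rng.choice(len(target_positions), size=n_fp, replace=False)
                for i in fp_idx:
                    v = _random_variant(genome, target_positions[i], rng, indel=False)
                    observations.append(
                        CallerObservation(caller, v, sample, Genotype.HET, int(rng.poisson(cfg.depth_mean)))
                    )
        callsets[caller] = observations
    result = SimulatedCallsets(genome=genome, truth=truth, callsets=callsets, samples=samples)
    if outdir is not None:
        _write_callsets(result, Path(outdir))
    return result


def _write_fasta(sequences: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_callsets(sim: SimulatedCallsets, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    contig_lengths = {c: len(s) for c, s in sim.genome.sequences.items()}
    _write_fasta(sim.genome.sequences, outdir / "reference.fa")
    sim.genome.targets.write_bed(outdir / "targets.bed")
    write_gene_models_bed12(sim.genome.genes, outdir / "genes.bed12")
    truth_obs = [
        CallerObservation("truth", t.variant, sample, genotype, depth=0)
        for t in sim.truth
        for sample, genotype in t.genotypes
    ]
    write_observations_vcf(truth_obs, outdir / "truth.vcf", contig_lengths)
    for caller, observations in sim.callsets.items():
        write_observations_vcf(observations, outdir / f"{caller}.vcf", contig_lengths)


def simulate_scores(
    variants: Sequence[GenomicVariant],
    pathogenic_flags: Sequence[bool],
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    thresholds: ThresholdConfig = ThresholdConfig(),
    certain_ids: frozenset[str] = frozenset(),
) -> list[ScoreRecord]:
    """Draw a score table separating pathogenic-like from benign-like rows.

    Pathogenic-like rows draw CADD/GWAVA/Genomiser above their thresholds
    with probability ``score_pass_prob`` each (independently) and are
    nulled with probability ``score_null_prob``; benign-like rows always
    draw below. Variants in ``certain_ids`` pass all three deterministically.
    """
    if len(variants) != len(pathogenic_flags):
        raise ParameterError("variants and pathogenic_flags must align")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    records = []
    for v, pathogenic in zip(variants, pathogenic_flags):
        var_id = v.id or str(v)
        certain = var_id in certain_ids
        pass_p = 1.0 if certain else cfg.score_pass_prob
        null_p = 0.0 if certain else cfg.score_null_prob

        def draw(passing_low, passing_high, failing_low, failing_high, want_pass):
            if want_pass and rng.random() < pass_p:
                return float(rng.uniform(passing_low, passing_high))
            return float(rng.uniform(failing_low, failing_high))

        cadd = draw(thresholds.cadd_min + 0.5, thresholds.cadd_min + 15.0,
                    0.0, thresholds.cadd_min - 0.5, pathogenic)
        gwava = draw(thresholds.gwava_min, min(1.0, thresholds.gwava_min + 0.4),
                     0.0, thresholds.gwava_min - 0.05, pathogenic)
        genomiser = draw(min(1.0, thresholds.genomiser_min + 0.01), 1.0,
                         0.0, thresholds.genomiser_min, pathogenic)
        spidex = float(rng.uniform(0.0, thresholds.spidex_abs_min - 1.0)) if rng.random() < 0.3 else None
        if rng.random() < null_p:
            cadd = None
        if rng.random() < null_p:
            gwava = None
        if rng.random() < null_p:
            genomiser = None
        records.append(
            ScoreRecord(
                var_id=var_id,
                variant_key=v.key,
                cadd_phred=cadd,
                gwava_region=gwava,
                genomiser=genomiser,
                spidex_dpsi=spidex,
                maf_1000g=cfg.planted_maf_1000g if certain else float(np.round(rng.uniform(0.01, 0.4), 4)),
                maf_gnomad=cfg.planted_maf_gnomad if certain else float(np.round(rng.uniform(0.01, 0.4), 4)),
            )
        )
    return records


def simulate_cohort(
    cfg: SimulationConfig,
    labels_af: dict[str, float],
    rng: Optional[np.random.Generator] = None,
    exact_labels: frozenset[str] = frozenset(),
) -> CohortGenotypes:
    """Realize planted allele frequencies as a 16-proband genotype matrix.

    Labels in ``exact_labels`` get exactly ``round(af * 2n)`` het carriers;
    the rest are sampled binomially under Hardy-Weinberg proportions.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    samples = [(f"S{i:02d}", Sex.MALE if i <= cfg.n_samples // 2 else Sex.FEMALE)
               for i in range(1, cfg.n_samples + 1)]
    genotypes: dict[tuple[str, str], Genotype] = {}
    for label, af in labels_af.items():
        if label in exact_labels:
            n_carriers = int(round(af * 2 * cfg.n_samples))
            idx = set(rng.choice(cfg.n_samples, size=min(n_carriers, cfg.n_samples), replace=False).tolist())
            for i, (sample, _) in enumerate(samples):
                genotypes[(sample, label)] = Genotype.HET if i in idx else Genotype.HOM_REF
        else:
            for sample, _ in samples:
                genotypes[(sample, label)] = _hwe_genotype(af, rng)
    return CohortGenotypes(
        samples=samples,
        variant_labels=list(labels_af),
        genotypes=genotypes,
        ploidy={label: Ploidy.AUTOSOMAL for label in labels_af},
    )


def simulate_pedigree(
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    labels: tuple[str, str] = ("varA_exonic", "varB_intronic"),
    n_children: int = 4,
) -> Pedigree:
    """Generate one two-generation family under the configured penetrance rule.

    Founder I-1 carries both tracked variants het; spouse I-2 carries
    neither; children inherit each variant independently with probability
    1/2. Phenotype: digenic -> affected iff both carried; monogenic ->
    affected iff the first variant is carried.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    first, second = labels
    members = [
        PedigreeMember("I-1", None, None, Sex.MALE, Phenotype.UNKNOWN),
        PedigreeMember("I-2", None, None, Sex.FEMALE, Phenotype.UNKNOWN),
    ]
    status: dict[str, dict[str, CarrierStatus]] = {
        "I-1": {first: CarrierStatus.CARRIER_HET, second: CarrierStatus.CARRIER_HET},
        "I-2": {first: CarrierStatus.NONCARRIER, second: CarrierStatus.NONCARRIER},
    }
    rows = [("I-1", status["I-1"]), ("I-2", status["I-2"])]
    for i in range(1, n_children + 1):
        member_id = f"II-{i}"
        carried = {
            label: (CarrierStatus.CARRIER_HET if rng.random() < 0.5 else CarrierStatus.NONCARRIER)
            for label in labels
        }
        status[member_id] = carried
        rows.append((member_id, carried))
        members.append(
            PedigreeMember(member_id, "I-1", "I-2",
                           Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
                           Phenotype.UNKNOWN)
        )
    # apply penetrance rule to all members with complete genotypes
    final_members = []
    for m in members:
        carrier_first = status[m.id][first].is_carrier
        carrier_second = status[m.id][second].is_carrier
        if cfg.pedigree_model == "digenic":
            affected = carrier_first and carrier_second
        else:
            affected = carrier_first
        final_members.append(
            PedigreeMember(m.id, m.father, m.mother, m.sex,
                           Phenotype.AFFECTED if affected else Phenotype.UNAFFECTED)
        )
    return Pedigree(family="SIM1", members=final_members,
                    variant_labels=list(labels), carrier_status=status)


def simulate_cohort_and_pedigree(
    cfg: SimulationConfig, outdir: Optional[str | Path] = None
) -> tuple[CohortGenotypes, Pedigree]:
    """Cohort matrix (planted variant at its configured AF plus background
    variants) and one family under the penetrance rule."""
    master = np.random.default_rng(cfg.seed)
    _, _, _, rng_cohort, rng_ped = master.spawn(5)
    labels_af = {"planted_1": cfg.planted_af,
                 "background_1": 0.25, "background_2": 0.05}
    exact = frozenset({"planted_1"}) if cfg.af_realization == "exact" else frozenset()
    cohort = simulate_cohort(cfg, labels_af, rng_cohort, exact_labels=exact)
    pedigree = simulate_pedigree(cfg, rng_ped)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort_tsv(cohort, outdir / "cohort.tsv")
        write_pedigree(pedigree, outdir / "pedigree.tsv")
    return cohort, pedigree


def run_simulation(cfg: SimulationConfig, outdir: str | Path) -> SimulatedCallsets:
    """Emit the full synthetic input bundle to ``outdir``."""
    outdir = Path(outdir)
    sim = simulate_truth_and_callers(cfg, outdir)
    master = np.random.default_rng(cfg.seed)
    _, _, _, _, _, rng_scores = master.spawn(6)
    records = simulate_scores(
        sim.truth_variants,
        [t.planted for t in sim.truth],
        cfg,
        rng=rng_scores,
        certain_ids=frozenset({"planted_1"}),
    )
    write_score_table(records, outdir / "scores.tsv")
    simulate_cohort_and_pedigree(cfg, outdir)
    return sim
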