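"""Cohort allele frequencies, enrichment vs reference populations,
compound-heterozygote detection and pedigree segregation summaries.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional, Sequence

from deepintron.annotation import ScoreRecord
from deepintron.errors import DataError, UndefinedFrequencyError
from deepintron.prioritization import PrioritizedVariant
from deepintron.variant_model.core import Genotype, Sex
from deepintron.variant_model.pedigree import CarrierStatus, Pedigree, Phenotype


class Ploidy(str, enum.Enum):
    AUTOSOMAL = "autosomal"
    X_LINKED = "x_linked"


@dataclass
class CohortGenotypes:
    """Sample-by-variant genotype matrix with per-variant ploidy rules.

    ``genotypes[(sample, label)]`` must be present for every sample/label
    pair (missingness is explicit). Hemizygous genotypes are only valid
    for males at X-linked variants.
    """

    samples: list[tuple[str, Sex]]
    variant_labels: list[str]
    genotypes: dict[tuple[str, str], Genotype]
    ploidy: dict[str, Ploidy] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sexes = dict(self.samples)
        for (sample, label), g in self.genotypes.items():
            if sample not in sexes:
                raise DataError(f"genotype for unknown sample {sample!r}")
            if label not in self.variant_labels:
                raise DataError(f"genotype for unknown variant label {label!r}")
            rule = self.ploidy.get(label, Ploidy.AUTOSOMAL)
            if g is Genotype.HEMI and (rule is Ploidy.AUTOSOMAL or sexes[sample] is not Sex.MALE):
                raise DataError(
                    f"hemizygous genotype for {sample}/{label} is only valid "
                    "for males at X-linked variants"
                )
        for sample, _sex in self.samples:
            for label in self.variant_labels:
                if (sample, label) not in self.genotypes:
                    raise DataError(f"matrix incomplete: missing genotype for {sample}/{label}")

    def genotype(self, sample: str, label: str) -> Genotype:
        return self.genotypes[(sample, label)]

    def carriers(self, label: str) -> list[str]:
        return [s for s, _ in self.samples if self.genotype(s, label).is_carrier]


_ALT_COUNT = {Genotype.HOM_REF: 0, Genotype.HET: 1, Genotype.HOM_ALT: 2, Genotype.HEMI: 1}


def cohort_allele_frequency(g: CohortGenotypes, label: str) -> float:
    """Alternate-allele frequency: alt alleles over total called alleles.

    Diploid samples contribute two alleles; hemizygous males at X-linked
    variants contribute one; missing genotypes are excluded from the
    denominator. Zero called alleles raise
    :class:`UndefinedFrequencyError`.
    """
    if label not in g.variant_labels:
        raise DataError(f"unknown variant label {label!r}")
    rule = g.ploidy.get(label, Ploidy.AUTOSOMAL)
    alt = total = 0
    for sample, sex in g.samples:
        geno = g.genotype(sample, label)
        if geno is Genotype.MISSING:
            continue
        n_alleles = 1 if (rule is Ploidy.X_LINKED and sex is Sex.MALE) else 2
        if rule is Ploidy.X_LINKED and sex is Sex.MALE and geno not in (
            Genotype.HEMI, Genotype.HOM_REF, Genotype.HOM_ALT,
        ):
            raise DataError(f"male X genotype for {sample}/{label} must be hemizygous, got {geno}")
        count = _ALT_COUNT[geno]
        alt += min(count, n_alleles)
        total += n_alleles
    if total == 0:
        raise UndefinedFrequencyError(f"no called alleles for {label!r}")
    return alt / total


@dataclass(frozen=True)
class Fold:
    """A fold-enrichment value with degeneracy flags."""

    value: float
    infinite: bool = False
    degenerate: bool = False


def fold_enrichment(proband_af: float, reference_maf: float) -> Fold:
    """Cohort allele frequency divided by a reference-population MAF.

    MAF 0 with a non-zero cohort frequency flags an infinite fold; both
    zero return fold 1 flagged degenerate.
    """
    if proband_af < 0 or reference_maf < 0:
        raise DataError("allele frequencies must be non-negative")
    if reference_maf == 0:
        if proband_af == 0:
            return Fold(1.0, degenerate=True)
        return Fold(math.inf, infinite=True)
    return Fold(proband_af / reference_maf)


@dataclass(frozen=True)
class EnrichmentResult:
    var_id: str
    proband_af: float
    maf_1000g: Optional[float]
    maf_gnomad: Optional[float]
    fold_1000g: Optional[Fold]
    fold_gnomad: Optional[Fold]
    enriched: Optional[bool]
    p_value: Optional[float] = None


def compute_enrichment(
    g: CohortGenotypes,
    records: Sequence[ScoreRecord],
    fold_threshold: float = 3.0,
    reference: str = "1000g",
    exact_test: bool = False,
) -> list[EnrichmentResult]:
    """Per-variant cohort AF and fold enrichment against reference MAFs.

    ``enriched`` compares the fold against the configured reference
    population (default 1000G EUR) to ``fold_threshold``; it is ``None``
    when that reference MAF is null. The optional two-sided exact binomial
    test on allele counts is off by default.
    """
    if reference not in ("1000g", "gnomad"):
        raise DataError(f"reference must be '1000g' or 'gnomad', got {reference!r}")
    results = []
    for rec in records:
        if rec.var_id not in g.variant_labels:
            continue
        af = cohort_allele_frequency(g, rec.var_id)
        fold_1000g = fold_enrichment(af, rec.maf_1000g) if rec.maf_1000g is not None else None
        fold_gnomad = fold_enrichment(af, rec.maf_gnomad) if rec.maf_gnomad is not None else None
        chosen = fold_1000g if reference == "1000g" else fold_gnomad
        enriched = None if chosen is None else (chosen.value >= fold_threshold)
        p_value = None
        ref_maf = rec.maf_1000g if reference == "1000g" else rec.maf_gnomad
        if exact_test and ref_maf is not None and 0 < ref_maf < 1:
            from scipy.stats import binomtest

            alt = total = 0
            rule = g.ploidy.get(rec.var_id, Ploidy.AUTOSOMAL)
            for sample, sex in g.samples:
                geno = g.genotype(sample, rec.var_id)
                if geno is Genotype.MISSING:
                    continue
                n = 1 if (rule is Ploidy.X_LINKED and sex is Sex.MALE) else 2
                alt += min(_ALT_COUNT[geno], n)
                total += n
            p_value = binomtest(alt, total, ref_maf, alternative="two-sided").pvalue
        results.append(
            EnrichmentResult(rec.var_id, af, rec.maf_1000g, rec.maf_gnomad,
                             fold_1000g, fold_gnomad, enriched, p_value)
        )
    return results


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    def fmt_fold(f: Optional[Fold]) -> str:
        if f is None:
            return "NA"
        if f.infinite:
            return "inf"
        return f"{f.value:.4f}" + ("(degenerate)" if f.degenerate else "")

    with open(path, "w") as fh:
        fh.write("var_id\tproband_af\tmaf_1000g\tmaf_gnomad\tfold_1000g\tfold_gnomad\tenriched\tp_value\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.var_id,
                        f"{r.proband_af:.6f}",
                        "NA" if r.maf_1000g is None else repr(r.maf_1000g),
                        "NA" if r.maf_gnomad is None else repr(r.maf_gnomad),
                        fmt_fold(r.fold_1000g),
                        fmt_fold(r.fold_gnomad),
                        "NA" if r.enriched is None else str(r.enriched).lower(),
                        "NA" if r.p_value is None else f"{r.p_value:.4g}",
                    ]
                )
                + "\n"
            )


@dataclass(frozen=True)
class Candidate:
    """A compound-het candidate: either a tier-1 intronic variant or an
    exonic pathogenic / likely-pathogenic variant."""

    label: str
    gene: str
    kind: str  # "intronic_tier1" | "exonic_plp"


def candidates_from(
    prioritized: Iterable[PrioritizedVariant],
    exonic: Iterable[ScoreRecord],
) -> list[Candidate]:
    """Build the candidate list for compound-het detection."""
    out = []
    for pv in prioritized:
        if pv.tier == 1:
            out.append(Candidate(pv.var_id, pv.scores.gene or "NA", "intronic_tier1"))
    for rec in exonic:
        if rec.clinical_class.is_pathogenic:
            out.append(Candidate(rec.var_id, rec.gene or "NA", "exonic_plp"))
    return out


@dataclass(frozen=True)
class CompoundHetPair:
    sample: str
    exonic: Candidate
    intronic: Candidate

    @property
    def genes(self) -> tuple[str, str]:
        return (self.exonic.gene, self.intronic.gene)


def find_compound_het(
    g: CohortGenotypes, candidates: Sequence[Candidate]
) -> dict[str, list[CompoundHetPair]]:
    """Per-sample unordered pairs of distinct carried candidate variants
    with one exonic pathogenic/likely-pathogenic and one tier-1 intronic
    member."""
    by_sample: dict[str, list[CompoundHetPair]] = {s: [] for s, _ in g.samples}
    usable = [c for c in candidates if c.label in g.variant_labels]
    for sample, _sex in g.samples:
        carried = [c for c in usable if g.genotype(sample, c.label).is_carrier]
        for a, b in combinations(carried, 2):
            if a.label == b.label:
                continue
            pair = None
            if a.kind == "exonic_plp" and b.kind == "intronic_tier1":
                pair = CompoundHetPair(sample, a, b)
            elif b.kind == "exonic_plp" and a.kind == "intronic_tier1":
                pair = CompoundHetPair(sample, b, a)
            if pair is not None:
                by_sample[sample].append(pair)
    return by_sample


CARRIER_CLASSES_TWO = ("both", "first_only", "second_only", "neither")
CARRIER_CLASSES_ONE = ("carrier", "noncarrier")


@dataclass
class SegregationSummary:
    """Carrier-class vs phenotype counts with model-consistency flags.

    ``monogenic_consistent`` tests the first tracked variant alone: all
    its carriers affected and all noncarriers unaffected.
    ``digenic_consistent`` (two tracked variants) requires all dual
    carriers affected and everyone else unaffected. Flags are ``None``
    (indeterminate) when no member has both complete genotype and known
    phenotype.
    """

    family: str
    variant_labels: list[str]
    counts: dict[str, dict[Phenotype, int]]
    monogenic_consistent: Optional[bool]
    digenic_consistent: Optional[bool]
    excluded_members: list[str]


def segregation_summary(p: Pedigree, variant_labels: Sequence[str]) -> SegregationSummary:
    if len(variant_labels) not in (1, 2):
        raise DataError("segregation_summary tracks 1 or 2 variants")
    for label in variant_labels:
        if label not in p.variant_labels:
            raise DataError(f"pedigree does not track variant {label!r}")
    two = len(variant_labels) == 2
    classes = CARRIER_CLASSES_TWO if two else CARRIER_CLASSES_ONE
    counts = {c: {ph: 0 for ph in Phenotype} for c in classes}
    excluded = []
    informative: list[tuple[str, Phenotype]] = []
    for m in p.members:
        statuses = [p.status(m.id, lbl) for lbl in variant_labels]
        if any(s is CarrierStatus.UNTYPED for s in statuses):
            excluded.append(m.id)
            continue
        carried = [s.is_carrier for s in statuses]
        if two:
            cls = {(True, True): "both", (True, False): "first_only",
                   (False, True): "second_only", (False, False): "neither"}[tuple(carried)]
        else:
            cls = "carrier" if carried[0] else "noncarrier"
        counts[cls][m.phenotype] += 1
        if m.phenotype is not Phenotype.UNKNOWN:
            informative.append((cls, m.phenotype))
    if not informative:
        mono = dig = None
    else:
        first_carrier_classes = ("both", "first_only") if two else ("carrier",)
        mono = all(
            (ph is Phenotype.AFFECTED) == (cls in first_carrier_classes)
            for cls, ph in informative
        )
        if two:
            dig = all((ph is Phenotype.AFFECTED) == (cls == "both") for cls, ph in informative)
        else:
            dig = None
    return SegregationSummary(
        family=p.family,
        variant_labels=list(variant_labels),
        counts=counts,
        monogenic_consistent=mono,
        digenic_consistent=dig,
        excluded_members=excluded,
    )


def write_segregation_tsv(summary: SegregationSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# family {summary.family}; variants: {', '.join(summary.variant_labels)}\n")
        fh.write("carrier_class\taffected\tunaffected\tunknown\n")
        for cls, by_ph in summary.counts.items():
            fh.write(
                f"{cls}\t{by_ph[Phenotype.AFFECTED]}\t{by_ph[Phenotype.UNAFFECTED]}\t"
                f"{by_ph[Phenotype.UNKNOWN]}\n"
            )
        fh.write(f"# monogenic_consistent\t{summary.monogenic_consistent}\n")
        fh.write(f"# digenic_consistent\t{summary.digenic_consistent}\n")
        if summary.excluded_members:
            fh.write(f"# excluded_untyped\t{','.join(summary.excluded_members)}\n")


def read_cohort_tsv(path: str | Path, x_linked: Sequence[str] = ()) -> CohortGenotypes:
    """Read a sample-by-variant genotype matrix TSV.

    Layout: header ``sample<TAB>sex<TAB><label>...``; genotype cells are
    ``hom_ref/het/hom_alt/hemi/missing`` (or ``0/0``-style codes).
    """
    gt_aliases = {
        "hom_ref": Genotype.HOM_REF, "0/0": Genotype.HOM_REF,
        "het": Genotype.HET, "0/1": Genotype.HET, "1/0": Genotype.HET,
        "hom_alt": Genotype.HOM_ALT, "1/1": Genotype.HOM_ALT,
        "hemi": Genotype.HEMI, "1": Genotype.HEMI,
        "missing": Genotype.MISSING, "./.": Genotype.MISSING, ".": Genotype.MISSING,
    }
    sex_aliases = {"m": Sex.MALE, "male": Sex.MALE, "1": Sex.MALE,
                   "f": Sex.FEMALE, "female": Sex.FEMALE, "2": Sex.FEMALE,
                   "unknown": Sex.UNKNOWN, "0": Sex.UNKNOWN}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise DataError(f"{path}: empty cohort file")
    header = lines[0].split("\t")
    if [h.lower() for h in header[:2]] != ["sample", "sex"]:
        raise DataError(f"{path}: cohort header must start with 'sample<TAB>sex'")
    labels = header[2:]
    samples: list[tuple[str, Sex]] = []
    genotypes: dict[tuple[str, str], Genotype] = {}
    for lineno, line in enumerate(lines[1:], 2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise DataError(f"{path}:{lineno}: expected {len(header)} columns")
        sample = parts[0]
        try:
            sex = sex_aliases[parts[1].lower()]
        except KeyError as exc:
            raise DataError(f"{path}:{lineno}: unknown sex code {parts[1]!r}") from exc
        samples.append((sample, sex))
        for label, cell in zip(labels, parts[2:]):
            try:
                genotypes[(sample, label)] = gt_aliases[cell.lower()]
            except KeyError as exc:
                raise DataError(f"{path}:{lineno}: unknown genotype {cell!r}") from exc
    ploidy = {lbl: (Ploidy.X_LINKED if lbl in x_linked else Ploidy.AUTOSOMAL) for lbl in labels}
    return CohortGenotypes(samples=samples, variant_labels=labels, genotypes=genotypes, ploidy=ploidy)


def write_cohort_tsv(g: CohortGenotypes, path: str | Path) -> None:
    sex_out = {Sex.MALE: "M", Sex.FEMALE: "F", Sex.UNKNOWN: "0"}
    with open(path, "w") as fh:
        fh.write("sample\tsex\t" + "\t".join(g.variant_labels) + "\n")
        for sample, sex in g.samples:
            row = [sample, sex_out[sex]]
            row += [g.genotype(sample, lbl).value for lbl in g.variant_labels]
            fh.write("\t".join(row) + "\n")
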