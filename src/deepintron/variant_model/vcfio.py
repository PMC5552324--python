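"""VCF reading/writing built on pysam.

Readers split multiallelic records, extract per-sample genotype and DP,
and normalize every variant on load (left-alignment requires a reference;
without one, only allele trimming is applied — adequate for SNV-only data).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from deepintron.errors import VcfParseError
from deepintron.variant_model.core import (
    CallerObservation,
    Genotype,
    GenomicVariant,
    ReferenceContext,
    normalize_chrom,
    normalize_variant,
)

_ALLELE_OK = frozenset("ACGT")


def _context_for(
    reference: Optional[Mapping[str, str]], chrom: str, strip_prefixes: tuple[str, ...]
) -> Optional[ReferenceContext]:
    if reference is None:
        return None
    for key in (chrom, "chr" + chrom):
        if key in reference:
            return ReferenceContext(chrom, 1, str(reference[key]))
    norm = normalize_chrom(chrom, strip_prefixes)
    if norm in reference:
        return ReferenceContext(chrom, 1, str(reference[norm]))
    return None


def _trim_only(v: GenomicVariant) -> GenomicVariant:
    """Trailing/leading trim without left-alignment (no reference needed)."""
    pos, ref, alt = v.pos, v.ref, v.alt
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return GenomicVariant(v.chrom, pos, ref, alt, id=v.id, hgvs=v.hgvs)


def _normalize_loaded(
    v: GenomicVariant, reference: Optional[Mapping[str, str]], strip_prefixes: tuple[str, ...]
) -> GenomicVariant:
    ctx = _context_for(reference, v.chrom, strip_prefixes)
    if ctx is None:
        return v if v.is_snv else _trim_only(v)
    return normalize_variant(v, ctx)


def _genotype_for_alt(gt: Optional[tuple], alt_index: int) -> Genotype:
    if gt is None:
        return Genotype.MISSING
    called = [a for a in gt if a is not None]
    if not called:
        return Genotype.MISSING
    n_alt = sum(1 for a in called if a == alt_index)
    if len(called) == 1:
        return Genotype.HEMI if n_alt == 1 else Genotype.HOM_REF
    if n_alt >= 2:
        return Genotype.HOM_ALT
    if n_alt == 1:
        return Genotype.HET
    return Genotype.HOM_REF


def read_caller_vcf(
    path: str | Path,
    caller: str,
    reference: Optional[Mapping[str, str]] = None,
    strip_prefixes: tuple[str, ...] = ("chr",),
    keep_hom_ref: bool = False,
) -> list[CallerObservation]:
    """Read one caller's VCF into per-sample observations.

    Multiallelic records are split into one observation per alternate
    allele. Samples with a missing genotype yield no observation; explicit
    hom-ref genotypes are kept only when ``keep_hom_ref`` is set. A missing
    FORMAT/DP is recorded as depth 0 (it then fails any depth filter).
    """
    observations: list[CallerObservation] = []
    try:
        vf = pysam.VariantFile(str(path))
    except Exception as exc:  # pragma: no cover - depends on pysam internals
        raise VcfParseError(f"{path}: cannot open VCF: {exc}") from exc
    header_lines = str(vf.header).count("\n")
    with vf:
        samples = list(vf.header.samples)
        record_iter = iter(vf)
        i = 0
        while True:
            try:
                rec = next(record_iter)
            except StopIteration:
                break
            except Exception as exc:
                raise VcfParseError(f"{path}: line {header_lines + i + 1}: {exc}") from exc
            i += 1
            lineno = header_lines + i
            if rec.alts is None:
                continue
            for alt_index, alt in enumerate(rec.alts, start=1):
                if alt in (None, "*", "<NON_REF>"):
                    continue
                if not set(rec.ref or "") <= _ALLELE_OK or not set(alt) <= _ALLELE_OK:
                    raise VcfParseError(
                        f"{path}: line {lineno}: non-ACGT alleles {rec.ref!r}>{alt!r}"
                    )
                variant = GenomicVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    id=rec.id,
                )
                variant = _normalize_loaded(variant, reference, strip_prefixes)
                if not samples:
                    # Sites-only VCF: record a single anonymous observation.
                    observations.append(
                        CallerObservation(caller, variant, sample="", genotype=Genotype.HET, depth=0)
                    )
                    continue
                for sample in samples:
                    fmt = rec.samples[sample]
                    genotype = _genotype_for_alt(fmt.get("GT"), alt_index)
                    if genotype is Genotype.MISSING:
                        continue
                    if genotype is Genotype.HOM_REF and not keep_hom_ref:
                        continue
                    depth = fmt.get("DP")
                    observations.append(
                        CallerObservation(
                            caller=caller,
                            variant=variant,
                            sample=sample,
                            genotype=genotype,
                            depth=int(depth) if depth is not None else 0,
                        )
                    )
    return observations


def read_truth_vcf(
    path: str | Path,
    reference: Optional[Mapping[str, str]] = None,
    strip_prefixes: tuple[str, ...] = ("chr",),
) -> list[GenomicVariant]:
    """Read a truth-set VCF as a list of normalized variants (allele-level)."""
    seen: dict[tuple, GenomicVariant] = {}
    try:
        vf = pysam.VariantFile(str(path))
    except Exception as exc:  # pragma: no cover
        raise VcfParseError(f"{path}: cannot open VCF: {exc}") from exc
    with vf:
        for rec in vf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if alt in (None, "*", "<NON_REF>"):
                    continue
                v = GenomicVariant(rec.chrom, rec.pos, rec.ref, alt, id=rec.id)
                v = _normalize_loaded(v, reference, strip_prefixes)
                seen.setdefault(v.key, v)
    return list(seen.values())


def _build_header(
    contigs: Sequence[tuple[str, int]], samples: Sequence[str], extra_info: Sequence[tuple] = ()
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs:
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for info_id, number, vtype, desc in extra_info:
        header.info.add(info_id, number, vtype, desc)
    for s in samples:
        header.add_sample(s)
    return header


_GT_CODES = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
    Genotype.HEMI: (1,),
    Genotype.MISSING: (None, None),
}


def write_observations_vcf(
    observations: Iterable[CallerObservation],
    path: str | Path,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write one caller's observations as a multi-sample VCF 4.2 file."""
    obs = list(observations)
    samples = sorted({o.sample for o in obs if o.sample})
    by_variant: dict[tuple, list[CallerObservation]] = {}
    for o in obs:
        by_variant.setdefault(o.variant.key, []).append(o)
    chroms = sorted({o.variant.chrom for o in obs})
    contigs = [
        (
            c,
            (contig_lengths or {}).get(
                c, max((o.variant.pos + len(o.variant.ref) for o in obs if o.variant.chrom == c), default=1) + 1000
            ),
        )
        for c in chroms
    ]
    header = _build_header(contigs, samples)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in sorted(by_variant, key=lambda k: (k[0], k[1], k[2], k[3])):
            group = by_variant[key]
            v = group[0].variant
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt), id=v.id
            )
            per_sample = {o.sample: o for o in group}
            for s in samples:
                if s in per_sample:
                    o = per_sample[s]
                    rec.samples[s]["GT"] = _GT_CODES[o.genotype]
                    rec.samples[s]["DP"] = o.depth
                else:
                    rec.samples[s]["GT"] = (None, None)
            out.write(rec)
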