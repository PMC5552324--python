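"""Core variant representation, normalization and matching.

Coordinates follow the VCF convention: positions are 1-based and point at
the first reference base of the allele. Interval types (BED, gene models)
use 0-based half-open coordinates; conversion happens at the boundary.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Optional

from deepintron.errors import (
    ContractViolationError,
    InsufficientContextError,
    ReferenceMismatchError,
)

_ALLELE_RE = re.compile(r"^[ACGT]+$")


class Genotype(str, enum.Enum):
    """Per-sample genotype call relative to one alternate allele."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI = "hemi"
    MISSING = "missing"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def is_carrier(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI)


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GenomicVariant:
    """A single-allele variant keyed by (chrom, pos, ref, alt).

    Parameters
    ----------
    chrom : str
        Chromosome name as given by the source file.
    pos : int
        1-based position of the first reference base.
    ref, alt : str
        Reference and alternate allele (A/C/G/T only, non-empty).
    id : str, optional
        dbSNP identifier when known.
    hgvs : str, optional
        HGVS-c display string, e.g. ``"c.499+367T>C"``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: Optional[str] = field(default=None, compare=False)
    hgvs: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not _ALLELE_RE.match(allele):
                raise ValueError(f"{name} allele {allele!r} must be non-empty A/C/G/T")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r})")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class ReferenceContext:
    """A window of reference sequence anchored at a 1-based start position."""

    chrom: str
    start: int  # 1-based position of seq[0]
    seq: str

    def base(self, pos: int) -> str:
        """Return the reference base at 1-based position ``pos``."""
        i = pos - self.start
        if i < 0 or i >= len(self.seq):
            raise InsufficientContextError(
                f"position {self.chrom}:{pos} outside context "
                f"[{self.start}, {self.start + len(self.seq)})"
            )
        return self.seq[i]

    def slice(self, pos: int, length: int) -> str:
        i = pos - self.start
        if i < 0 or i + length > len(self.seq):
            raise InsufficientContextError(
                f"interval {self.chrom}:{pos}+{length} outside context window"
            )
        return self.seq[i : i + length]


@dataclass(frozen=True)
class CallerObservation:
    """One caller's record of one variant in one sample."""

    caller: str
    variant: GenomicVariant
    sample: str
    genotype: Genotype
    depth: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"depth must be non-negative, got {self.depth}")


def is_normalized(v: GenomicVariant) -> bool:
    """Syntactic normalization check (trimming only).

    A fully normalized variant also requires left-alignment against the
    reference, which cannot be verified without sequence context; this
    check covers what is verifiable from the alleles alone: no shared
    trailing base, and a shared leading base only when one allele would
    otherwise be empty.
    """
    if v.is_snv:
        return True
    if v.ref[-1] == v.alt[-1]:
        return False
    if v.ref[0] == v.alt[0] and len(v.ref) > 1 and len(v.alt) > 1:
        return False
    return True


def normalize_variant(v: GenomicVariant, context: ReferenceContext) -> GenomicVariant:
    """Return the canonical left-aligned, trimmed spelling of ``v``.

    SNVs are returned unchanged. For indels the standard left-align/trim
    loop is applied: shared trailing bases are removed; when an allele
    would become empty, both alleles are extended with the preceding
    reference base and the position decremented; finally shared leading
    bases are trimmed. The operation is idempotent.

    Raises
    ------
    ReferenceMismatchError
        If ``v.ref`` does not match the context sequence at ``v.pos``.
    InsufficientContextError
        If left-alignment runs off the start of the context window.
    """
    if context.chrom != v.chrom:
        raise ReferenceMismatchError(
            f"context chrom {context.chrom!r} != variant chrom {v.chrom!r}"
        )
    observed = context.slice(v.pos, len(v.ref))
    if observed != v.ref:
        raise ReferenceMismatchError(
            f"ref allele {v.ref!r} at {v.chrom}:{v.pos} does not match "
            f"reference sequence {observed!r}"
        )
    if v.is_snv:
        return v

    pos, ref, alt = v.pos, v.ref, v.alt
    while True:
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            prev = context.base(pos - 1)
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(v, pos=pos, ref=ref, alt=alt)


def same_variant(a: GenomicVariant, b: GenomicVariant) -> bool:
    """True iff two *normalized* variants denote the same allele.

    Raises :class:`ContractViolationError` when either input fails the
    syntactic normalization check.
    """
    for v in (a, b):
        if not is_normalized(v):
            raise ContractViolationError(f"variant {v} is not normalized")
    return a.key == b.key


def normalize_chrom(name: str, strip_prefixes: tuple[str, ...] = ("chr",)) -> str:
    """Reconcile chromosome-name dialects ("chr10" vs "10") at load time."""
    for p in strip_prefixes:
        if name.lower().startswith(p.lower()) and len(name) > len(p):
            return name[len(p) :]
    return name
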