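"""Pedigree representation and PED-style TSV reader.

File layout (tab-separated, one header line)::

    family  individual  father  mother  sex  phenotype  <variant label> ...

``father``/``mother`` use ``0`` for unknown. ``sex``: 1/M = male,
2/F = female, 0 = unknown. ``phenotype``: 2/affected, 1/unaffected,
0/-9/unknown. Each additional column tracks carrier status for one
variant: ``het``, ``hom``, ``ref`` or ``untyped``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from deepintron.errors import StructuralError
from deepintron.variant_model.core import Sex


class Phenotype(str, enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class CarrierStatus(str, enum.Enum):
    CARRIER_HET = "carrier_het"
    CARRIER_HOM = "carrier_hom"
    NONCARRIER = "noncarrier"
    UNTYPED = "untyped"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def is_carrier(self) -> bool:
        return self in (CarrierStatus.CARRIER_HET, CarrierStatus.CARRIER_HOM)


_SEX_CODES = {"1": Sex.MALE, "m": Sex.MALE, "male": Sex.MALE,
              "2": Sex.FEMALE, "f": Sex.FEMALE, "female": Sex.FEMALE,
              "0": Sex.UNKNOWN, "unknown": Sex.UNKNOWN}
_PHENO_CODES = {"2": Phenotype.AFFECTED, "affected": Phenotype.AFFECTED,
                "1": Phenotype.UNAFFECTED, "unaffected": Phenotype.UNAFFECTED,
                "0": Phenotype.UNKNOWN, "-9": Phenotype.UNKNOWN, "unknown": Phenotype.UNKNOWN}
_CARRIER_CODES = {"het": CarrierStatus.CARRIER_HET, "carrier_het": CarrierStatus.CARRIER_HET,
                  "hom": CarrierStatus.CARRIER_HOM, "carrier_hom": CarrierStatus.CARRIER_HOM,
                  "ref": CarrierStatus.NONCARRIER, "noncarrier": CarrierStatus.NONCARRIER,
                  "untyped": CarrierStatus.UNTYPED, ".": CarrierStatus.UNTYPED}


@dataclass(frozen=True)
class PedigreeMember:
    id: str
    father: Optional[str]
    mother: Optional[str]
    sex: Sex
    phenotype: Phenotype


@dataclass
class Pedigree:
    """One family: members plus per-member carrier status per tracked variant."""

    family: str
    members: list[PedigreeMember]
    variant_labels: list[str] = field(default_factory=list)
    carrier_status: dict[str, dict[str, CarrierStatus]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {m.id for m in self.members}
        if len(ids) != len(self.members):
            raise StructuralError(f"family {self.family}: duplicate member ids")
        for m in self.members:
            for parent in (m.father, m.mother):
                if parent is not None and parent not in ids:
                    raise StructuralError(
                        f"family {self.family}: member {m.id} references "
                        f"unknown parent {parent!r}"
                    )

    def member(self, member_id: str) -> PedigreeMember:
        for m in self.members:
            if m.id == member_id:
                return m
        raise KeyError(member_id)

    def status(self, member_id: str, variant_label: str) -> CarrierStatus:
        return self.carrier_status.get(member_id, {}).get(variant_label, CarrierStatus.UNTYPED)

    @property
    def affected(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.phenotype is Phenotype.AFFECTED]


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a single-family PED-style TSV (see module docstring for layout)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise StructuralError(f"{path}: empty pedigree file")
    header = lines[0].split("\t")
    required = ["family", "individual", "father", "mother", "sex", "phenotype"]
    if [h.lower() for h in header[: len(required)]] != required:
        raise StructuralError(
            f"{path}: header must start with {required}, got {header[:6]}"
        )
    variant_labels = header[len(required):]
    members: list[PedigreeMember] = []
    carriers: dict[str, dict[str, CarrierStatus]] = {}
    family: Optional[str] = None
    for lineno, line in enumerate(lines[1:], 2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise StructuralError(f"{path}:{lineno}: expected {len(header)} columns, got {len(parts)}")
        fam, ind, father, mother, sex, pheno = parts[:6]
        if family is None:
            family = fam
        elif fam != family:
            raise StructuralError(f"{path}:{lineno}: multiple families in one file ({family!r}, {fam!r})")
        try:
            member = PedigreeMember(
                id=ind,
                father=None if father in ("0", "", ".") else father,
                mother=None if mother in ("0", "", ".") else mother,
                sex=_SEX_CODES[sex.lower()],
                phenotype=_PHENO_CODES[pheno.lower()],
            )
        except KeyError as exc:
            raise StructuralError(f"{path}:{lineno}: unrecognized code {exc}") from exc
        members.append(member)
        row_status = {}
        for label, value in zip(variant_labels, parts[6:]):
            try:
                row_status[label] = _CARRIER_CODES[value.lower()]
            except KeyError as exc:
                raise StructuralError(
                    f"{path}:{lineno}: unrecognized carrier status {value!r}"
                ) from exc
        carriers[ind] = row_status
    if not members:
        raise StructuralError(f"{path}: pedigree file has a header but no members")
    return Pedigree(family=family or "", members=members,
                    variant_labels=variant_labels, carrier_status=carriers)


_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_PHENO_OUT = {Phenotype.AFFECTED: "2", Phenotype.UNAFFECTED: "1", Phenotype.UNKNOWN: "0"}
_CARRIER_OUT = {CarrierStatus.CARRIER_HET: "het", CarrierStatus.CARRIER_HOM: "hom",
                CarrierStatus.NONCARRIER: "ref", CarrierStatus.UNTYPED: "untyped"}


def write_pedigree(p: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        header = ["family", "individual", "father", "mother", "sex", "phenotype"] + p.variant_labels
        fh.write("\t".join(header) + "\n")
        for m in p.members:
            row = [p.family, m.id, m.father or "0", m.mother or "0",
                   _SEX_OUT[m.sex], _PHENO_OUT[m.phenotype]]
            row += [_CARRIER_OUT[p.status(m.id, lbl)] for lbl in p.variant_labels]
            fh.write("\t".join(row) + "\n")
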