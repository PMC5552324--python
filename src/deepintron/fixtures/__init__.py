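"""Packaged fixtures: published score/variant tables, two family
pedigrees, a frequency-consistent 16-proband genotype matrix, and a toy
gene model + TF peak track for region/TFBS demos.

The gene model and TF peaks use synthetic coordinates chosen so that the
demo variant sits 367 nt from the nearest exon boundary inside all three
packaged TF peaks; they are illustrative, not genome-build coordinates.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from deepintron.annotation import ScoreRecord, read_score_table
from deepintron.cohort import CohortGenotypes, read_cohort_tsv
from deepintron.prioritization import parse_toolset_label
from deepintron.variant_model.core import GenomicVariant
from deepintron.variant_model.pedigree import Pedigree, read_pedigree
from deepintron.variant_model.regions import GeneModel, TFPeaks, read_bed12

# Labels of the MYBPC3 variants used by the family fixtures.
MYBPC3_SPLICE = "rs397515893"   # c.1227-13G>A, family 6
MYBPC3_MISSENSE = "rs200411226"  # c.1484G>A p.Arg495Gln, family 15
VCL_DEEP_INTRONIC = "rs113195070"  # c.499+367T>C

#: Demo variant placed 367 nt into intron 1 of the toy gene model.
DEMO_VARIANT = GenomicVariant(chrom="10", pos=1567, ref="T", alt="C",
                              id=VCL_DEEP_INTRONIC, hgvs="c.499+367T>C")


def fixture_path(name: str) -> Path:
    return Path(resources.files("deepintron.fixtures") / name)


def load_intronic_scores() -> list[ScoreRecord]:
    """The 26-row prioritized intronic score table."""
    return read_score_table(fixture_path("table3_scores.tsv"))


def load_intronic_labels() -> dict[str, frozenset[str]]:
    """Printed tool-set label per var_id (ground truth for the partition)."""
    df = pd.read_csv(fixture_path("table3_scores.tsv"), sep="\t", dtype=str)
    return {row["var_id"]: parse_toolset_label(row["tools"]) for _, row in df.iterrows()}


def load_exonic_variants() -> pd.DataFrame:
    """Exonic / splice-site classified variants (patient, gene, class...)."""
    return pd.read_csv(fixture_path("table2_variants.tsv"), sep="\t", dtype=str)


def load_exonic_scores() -> list[ScoreRecord]:
    """Exonic variants as ScoreRecords carrying gene + clinical class."""
    from deepintron.annotation import _parse_class  # shared alias table

    df = load_exonic_variants()
    records = {}
    for _, row in df.iterrows():
        records.setdefault(
            row["var_id"],
            ScoreRecord(
                var_id=row["var_id"],
                gene=row["gene"],
                hgvs=row["hgvs"],
                clinical_class=_parse_class(row["acmg_class"]),
            ),
        )
    return list(records.values())


def load_family(family: int) -> Pedigree:
    if family not in (6, 15):
        raise ValueError("packaged pedigrees: family 6 or 15")
    return read_pedigree(fixture_path(f"family{family}.tsv"))


def load_cohort() -> CohortGenotypes:
    """16-proband genotype matrix consistent with the printed frequencies."""
    return read_cohort_tsv(fixture_path("cohort_genotypes.tsv"))


def load_toy_gene_models() -> list[GeneModel]:
    return read_bed12(fixture_path("vcl_toy_gene.bed12"))


def load_tf_peaks() -> TFPeaks:
    return TFPeaks.from_bed(fixture_path("tf_peaks.bed"))
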