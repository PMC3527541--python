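"""Packaged reference tables: published enhancer/CNV coordinates.

The shipped TSVs transcribe published coordinate tables of VISTA enhancer
loci overlapping validated copy-number polymorphisms (CNP), genotyped
polymorphic CNV regions ("polymorphic-DC"), DGV-deposited small Indels, and
sequencing-confirmed patient deletions. Position strings are 1-based
inclusive; loaders convert them to the internal half-open convention.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .intervals import FeatureSet, GenomeAssembly, read_chrom_sizes, read_feature_table

__all__ = [
    "hg19_assembly",
    "load_cnp_overlaps",
    "load_polymorphic_dc_overlaps",
    "load_dgv_indel_overlaps",
    "load_patient_deletions",
    "data_path",
]


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(resources.files("enhancercnv").joinpath("data", name)))


def hg19_assembly() -> GenomeAssembly:
    """The hg19 chromosome-size table (chr1-chr22, chrX, chrY)."""
    return read_chrom_sizes(data_path("hg19.chrom.sizes"), name="hg19")


def _load_pair_table(
    name: str,
    target_col: str,
    cover_col: str,
    cover_id_col: str,
    cover_kind: str,
    assembly: GenomeAssembly | None,
) -> tuple[FeatureSet, FeatureSet]:
    """Load a two-locus overlap table into (target set, cover set).

    Targets repeated across rows (one row per overlapping variant) are
    deduplicated by id; cover intervals keep one entry per variant.
    """
    path = data_path(name)
    targets_all = read_feature_table(
        path,
        schema={"locus": target_col, "id": "enhancer_id"},
        assembly=assembly,
        kind="enhancer",
        label="enhancers",
    )
    seen: set[str] = set()
    uniq = []
    for f in targets_all:
        if f.id not in seen:
            seen.add(f.id or "")
            uniq.append(f)
    targets = FeatureSet(uniq, assembly=assembly, kind="enhancer", label="enhancers")
    cover = read_feature_table(
        path,
        schema={"locus": cover_col, "id": cover_id_col},
        assembly=assembly,
        kind=cover_kind,
        label=Path(name).stem,
    )
    return targets, cover


def load_cnp_overlaps(assembly: GenomeAssembly | None = None) -> tuple[FeatureSet, FeatureSet]:
    """Enhancer loci and the CNP intervals that overlap them."""
    return _load_pair_table(
        "cnp_overlaps.tsv", "enhancer_position", "cnv_position", "cnv_id", "cnv", assembly
    )


def load_polymorphic_dc_overlaps(
    assembly: GenomeAssembly | None = None,
) -> tuple[FeatureSet, FeatureSet]:
    """Enhancer loci and the polymorphic-DC CNV intervals that overlap them."""
    return _load_pair_table(
        "polymorphic_dc_overlaps.tsv", "enhancer_position", "cnv_position", "cnv_id", "cnv",
        assembly,
    )


def load_dgv_indel_overlaps(
    assembly: GenomeAssembly | None = None,
) -> tuple[FeatureSet, FeatureSet]:
    """Enhancer loci and the DGV small Indels that overlap them."""
    return _load_pair_table(
        "dgv_indel_overlaps.tsv", "enhancer_position", "indel_position", "indel_id", "indel",
        assembly,
    )


def load_patient_deletions(
    assembly: GenomeAssembly | None = None,
) -> tuple[FeatureSet, FeatureSet]:
    """Enhancer loci deleted in patients and the confirmed deletion intervals."""
    return _load_pair_table(
        "patient_enhancer_deletions.tsv", "enhancer_position", "deletion_position", "sample",
        "cnv", assembly,
    )
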