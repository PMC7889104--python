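"""Readers and writers for the pipeline's external file formats.

All tabular files are plain text: CSV (comma-separated, UTF-8, header
required) for sample sheets and probe annotation, TSV for site x sample
matrices and per-site result tables, GMT for gene sets, and one-symbol-per-
line text for locus lists.  Cells holding sets (feature classes, gene
symbols) use ';' as the intra-cell delimiter so the two levels of
delimiting never collide.

Genomic positions in the annotation CSV are 1-based (UCSC browser
convention).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, PairingError

logger = logging.getLogger("methcord")

TISSUES = ("bone", "blood")
FEATURE_CLASSES = ("TSS200", "TSS1500", "5UTR", "1stExon", "Body", "3UTR", "intergenic")
ISLAND_CLASSES = ("island", "n_shore", "s_shore", "n_shelf", "s_shelf", "open_sea")

SAMPLE_SHEET_COLUMNS = ("sample_id", "subject_id", "tissue", "batch", "age")
ANNOTATION_COLUMNS = (
    "probe_id", "chrom", "pos", "feature_class", "island_class", "genes", "snp_overlap",
)


@dataclass(frozen=True)
class SampleSheet:
    """Sample -> (subject, tissue, batch, age) mapping for a matched design.

    Every subject contributes exactly one bone and one blood sample; the
    pairing is what licenses within-subject correlation and paired tests.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"sample sheet missing column(s): {missing}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample_id: {dup!r}")
        bad_tissue = set(t["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise FormatError(f"unknown tissue value(s): {sorted(bad_tissue)}")
        if not pd.api.types.is_numeric_dtype(t["age"]):
            raise FormatError("age column must be numeric")
        counts = t.groupby(["subject_id", "tissue"]).size()
        bad = counts[counts != 1]
        if not bad.empty:
            raise PairingError(
                f"subject/tissue combinations without exactly one sample: "
                f"{bad.index.tolist()}"
            )
        per_subject = t.groupby("subject_id")["tissue"].nunique()
        unpaired = per_subject[per_subject != 2]
        if not unpaired.empty:
            raise PairingError(f"unpaired subject(s): {unpaired.index.tolist()}")
        if self.n_subjects < 3:
            raise PairingError(
                f"need >=3 subjects for correlation testing (df = n-2), "
                f"got {self.n_subjects}"
            )

    @property
    def subjects(self) -> list[str]:
        return sorted(self.table["subject_id"].unique())

    @property
    def n_subjects(self) -> int:
        return self.table["subject_id"].nunique()

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def samples_for(self, tissue: str) -> list[str]:
        """Sample ids of one tissue, ordered by subject id (pairing order)."""
        t = self.table[self.table["tissue"] == tissue]
        return t.set_index("subject_id").loc[self.subjects, "sample_id"].tolist()

    def paired_samples(self) -> tuple[list[str], list[str]]:
        """(bone_ids, blood_ids), aligned so position i is the same subject."""
        return self.samples_for("bone"), self.samples_for("blood")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read and validate a sample sheet CSV (columns: sample_id, subject_id,
    tissue, batch, age)."""
    try:
        table = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str,
                                         "batch": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse sample sheet {path}: {exc}") from exc
    if "age" in table.columns and not pd.api.types.is_numeric_dtype(table["age"]):
        raise FormatError("age column must be numeric")
    return SampleSheet(table.reset_index(drop=True))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index=False)


def _split_cell(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return frozenset()
    return frozenset(s for s in str(cell).split(";") if s)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a probe annotation CSV into a probe_id-indexed frame.

    ``feature_class`` and ``genes`` cells are ';'-delimited sets; unmapped
    probes default to feature_class={'intergenic'}, island_class='open_sea'.
    """
    raw = pd.read_csv(path, dtype={"probe_id": str, "chrom": str, "genes": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"annotation missing column(s): {missing}")
    if raw["probe_id"].duplicated().any():
        dup = raw.loc[raw["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"duplicate probe_id in annotation: {dup!r}")
    ann = raw.copy()
    ann["feature_class"] = [
        fc if fc else frozenset({"intergenic"})
        for fc in (_split_cell(c) for c in raw["feature_class"])
    ]
    unknown_feat = set().union(*ann["feature_class"]) - set(FEATURE_CLASSES)
    if unknown_feat:
        raise FormatError(f"unknown feature_class token(s): {sorted(unknown_feat)}")
    island = raw["island_class"].fillna("open_sea").replace("", "open_sea")
    bad_island = set(island) - set(ISLAND_CLASSES)
    if bad_island:
        raise FormatError(f"unknown island_class token(s): {sorted(bad_island)}")
    ann["island_class"] = island
    ann["genes"] = [_split_cell(c) for c in raw["genes"]]
    ann["snp_overlap"] = raw["snp_overlap"].astype(bool)
    return ann.set_index("probe_id")


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    out = annotation.reset_index().copy()
    out["feature_class"] = [";".join(sorted(s)) for s in out["feature_class"]]
    out["genes"] = [";".join(sorted(s)) for s in out["genes"]]
    out["snp_overlap"] = out["snp_overlap"].astype(int)
    out.to_csv(path, index=False, columns=list(ANNOTATION_COLUMNS))


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT file (name, description, genes...) into {name: gene set}."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return sets


def write_gmt(sets: dict[str, frozenset[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list; '#' starts a comment line.

    Duplicate symbols (case-insensitive) are collapsed to the first
    occurrence, preserving order.
    """
    seen: set[str] = set()
    genes: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if not sym:
                continue
            key = sym.upper()
            if key not in seen:
                seen.add(key)
                genes.append(sym)
    return genes


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a site x sample TSV (first column probe_id) into a float frame."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    try:
        return mat.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric value in matrix {path}: {exc}") from exc


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")


def write_site_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-site result table (DMP or SMP calls) as TSV.

    The written table round-trips through :func:`read_site_table` with
    float values preserved to full precision.
    """
    out = table.reset_index() if table.index.name == "probe_id" else table
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_site_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if "probe_id" not in table.columns:
        raise FormatError(f"site table {path} lacks a probe_id column")
    return table.set_index("probe_id")


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
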