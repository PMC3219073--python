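"""Readers and writers for the pipeline's external formats.

All tabular formats are plain text: tab-separated for matrices (first
column holds the row identifier, remaining columns one sample each),
comma-separated for clinical data, one identifier per line for gene
lists.  Readers validate structural invariants and fail loudly instead of
silently intersecting or dropping records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tinstab")

__all__ = [
    "ValidationError",
    "ChipDefinition",
    "read_chipdef",
    "write_chipdef",
    "read_intensity_matrix",
    "read_matrix",
    "write_matrix",
    "read_clinical",
    "write_clinical",
    "read_gene_list",
    "write_gene_list",
    "write_tin_profiles",
    "read_tin_profiles",
    "write_correlations",
]

CLINICAL_COLUMNS = ["time_years", "event", "stage", "msi", "age", "sex", "location"]
STAGE_LEVELS = ("II", "III")
SEX_LEVELS = ("M", "F")
LOCATION_LEVELS = ("right", "left", "rectum")

TIN_PROFILE_COLUMNS = [
    "n_skip", "n_incl", "n_total",
    "rel_skip", "rel_incl", "rel_total", "skew",
    "is_sTIN", "is_oTIN",
]


class ValidationError(ValueError):
    """Raised when an input file violates a structural invariant."""


@dataclass(frozen=True)
class ChipDefinition:
    """Probe -> probe set (exon) -> transcript cluster (gene) hierarchy.

    The probe set is the unit scored for deviating exon usage; the
    transcript cluster is the unit the gene-level probe model is fitted
    to.  Row order is the file order and is preserved so that grouped
    slicing is deterministic.
    """

    records: pd.DataFrame  # columns: probe_id, probe_set_id, gene_id

    def __post_init__(self) -> None:
        df = self.records
        required = ["probe_id", "probe_set_id", "gene_id"]
        if list(df.columns) != required:
            raise ValidationError(
                f"chip definition needs columns {required}, got {list(df.columns)}"
            )
        if len(df) == 0:
            raise ValidationError("chip definition is empty")
        dup = df["probe_id"].duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate probe_id(s): {sorted(df.loc[dup, 'probe_id'].unique())[:5]}"
            )
        n_genes_per_set = df.groupby("probe_set_id", sort=False)["gene_id"].nunique()
        bad = n_genes_per_set[n_genes_per_set > 1]
        if len(bad):
            raise ValidationError(
                f"probe set(s) mapped to more than one gene: {sorted(bad.index)[:5]}"
            )

    # -- derived views -------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.records["probe_id"])

    @property
    def probe_set_ids(self) -> pd.Index:
        return pd.Index(self.records["probe_set_id"].unique())

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.records["gene_id"].unique())

    @property
    def n_probes(self) -> int:
        return len(self.records)

    @property
    def n_probe_sets(self) -> int:
        return self.records["probe_set_id"].nunique()

    @property
    def n_genes(self) -> int:
        return self.records["gene_id"].nunique()

    def probe_sets_per_gene(self) -> pd.Series:
        return self.records.groupby("gene_id", sort=False)["probe_set_id"].nunique()

    def gene_of_probe_set(self) -> pd.Series:
        """Map probe_set_id -> gene_id (unique by invariant)."""
        return (
            self.records.drop_duplicates("probe_set_id")
            .set_index("probe_set_id")["gene_id"]
        )

    def iter_genes(self) -> Iterable[tuple[str, pd.DataFrame]]:
        """Yield (gene_id, sub-table) in file order of first appearance."""
        yield from self.records.groupby("gene_id", sort=False)


def read_chipdef(path: str | Path) -> ChipDefinition:
    """Read a 3-column tab-separated chip definition file."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if len(df) == 0:
        raise ValidationError(f"{path}: chip definition file has no records")
    cdf = ChipDefinition(df)
    logger.info(
        "read chipdef %s: %d probes, %d probe sets, %d genes",
        path, cdf.n_probes, cdf.n_probe_sets, cdf.n_genes,
    )
    return cdf


def write_chipdef(path: str | Path, chipdef: ChipDefinition) -> None:
    chipdef.records.to_csv(path, sep="\t", index=False)


def _check_rectangular(path: str | Path, sep: str = "\t") -> None:
    with open(path) as fh:
        header = fh.readline()
        n_fields = header.count(sep)
        for i, line in enumerate(fh, start=2):
            if line.strip() and line.count(sep) != n_fields:
                raise ValidationError(f"{path}: ragged row at line {i}")


def read_matrix(path: str | Path, *, kind: str = "matrix") -> pd.DataFrame:
    """Read a TSV matrix (rows = features, columns = samples).

    The first column holds the row identifier.  Duplicate row or column
    identifiers are rejected; values are parsed with the round-trip float
    parser so write -> read is lossless.
    """
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())[:5]
        raise ValidationError(f"{path}: duplicate row identifier(s): {dups}")
    if pd.Index(df.columns).duplicated().any():
        raise ValidationError(f"{path}: duplicate sample identifier(s)")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValidationError(f"{path}: non-numeric values in column(s) {non_numeric[:5]}")
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing values in {kind}")
    logger.info("read %s %s: %d rows x %d samples", kind, path, *df.shape)
    return df


def read_intensity_matrix(path: str | Path) -> pd.DataFrame:
    """Read raw linear-scale probe intensities; entries must be > 0."""
    df = read_matrix(path, kind="intensity matrix")
    vals = df.to_numpy()
    if (vals <= 0).any():
        r, c = np.argwhere(vals <= 0)[0]
        raise ValidationError(
            f"{path}: non-positive intensity at probe {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    return df


def write_matrix(path: str | Path, matrix: pd.DataFrame, *, index_name: str = "id") -> None:
    out = matrix.copy()
    out.index.name = out.index.name or index_name
    out.to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical CSV (sample_id,time_years,event,stage,msi,age,sex,location)."""
    df = pd.read_csv(path, dtype={"stage": str, "sex": str, "location": str},
                     float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing sample_id column")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing clinical column(s) {missing}")
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id")
    if (df["time_years"] <= 0).any():
        bad = df.index[df["time_years"] <= 0][0]
        raise ValidationError(f"{path}: non-positive follow-up time for sample {bad!r}")
    if not df["event"].isin([0, 1]).all():
        raise ValidationError(f"{path}: event must be 0 or 1")
    for col, levels in (("stage", STAGE_LEVELS), ("sex", SEX_LEVELS),
                        ("location", LOCATION_LEVELS)):
        unknown = set(df[col].unique()) - set(levels)
        if unknown:
            raise ValidationError(
                f"{path}: unknown {col} level(s) {sorted(unknown)}; allowed {levels}"
            )
    if not df["msi"].isin([0, 1]).all():
        raise ValidationError(f"{path}: msi must be 0 or 1")
    logger.info("read clinical %s: %d patients, %d events",
                path, len(df), int(df["event"].sum()))
    return df[CLINICAL_COLUMNS]


def write_clinical(path: str | Path, clinical: pd.DataFrame) -> None:
    out = clinical[CLINICAL_COLUMNS].copy()
    out.index.name = "sample_id"
    out.to_csv(path)


def read_gene_list(path: str | Path, *, chipdef: ChipDefinition | None = None,
                   known_genes: Sequence[str] | None = None,
                   allow_subset: bool = False) -> list[str]:
    """Read one gene identifier per line (blank lines ignored).

    When a chip definition (or explicit gene universe) is supplied, members
    absent from it are reported; with ``allow_subset`` they are dropped with
    a logged count, otherwise reading fails.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    genes = [ln for ln in lines if ln]
    if not genes:
        raise ValidationError(f"{path}: gene list is empty")
    if len(set(genes)) != len(genes):
        raise ValidationError(f"{path}: gene list contains duplicates")
    universe = None
    if chipdef is not None:
        universe = set(chipdef.gene_ids)
    elif known_genes is not None:
        universe = set(known_genes)
    if universe is not None:
        missing = [g for g in genes if g not in universe]
        if missing:
            if not allow_subset:
                raise ValidationError(
                    f"{path}: {len(missing)} gene(s) absent from the chip definition, "
                    f"e.g. {missing[:5]} (pass allow_subset to intersect)"
                )
            logger.warning("gene list %s: dropping %d gene(s) absent from chipdef",
                           path, len(missing))
            genes = [g for g in genes if g in universe]
            if not genes:
                raise ValidationError(f"{path}: no gene-list members on the chip")
    logger.info("read gene list %s: %d genes", path, len(genes))
    return genes


def write_gene_list(path: str | Path, genes: Iterable[str]) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def write_tin_profiles(path: str | Path, profiles: pd.DataFrame) -> None:
    """Write per-sample TIN profiles in a fixed column order (TSV)."""
    out = profiles[TIN_PROFILE_COLUMNS].copy()
    out.index.name = "sample_id"
    out["is_sTIN"] = out["is_sTIN"].astype(int)
    out["is_oTIN"] = out["is_oTIN"].astype(int)
    out.to_csv(path, sep="\t")


def read_tin_profiles(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in TIN_PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing profile column(s) {missing}")
    df["is_sTIN"] = df["is_sTIN"].astype(bool)
    df["is_oTIN"] = df["is_oTIN"].astype(bool)
    return df


def write_correlations(path: str | Path, table: pd.DataFrame) -> None:
    """Write a per-gene correlation table (gene_id, r, p, significant)."""
    out = table[["r", "p", "significant"]].copy()
    out.index.name = "gene_id"
    out["significant"] = out["significant"].astype(int)
    out.to_csv(path, sep="\t")


def check_sample_alignment(*id_sets: Sequence[str], allow_subset: bool = False,
                           context: str = "inputs") -> list[str]:
    """Verify that sample identifier collections agree across files.

    Returns the common samples (first collection's order).  Mismatches are
    an error unless ``allow_subset``, in which case the intersection is used
    and the dropped count logged.
    """
    sets = [list(s) for s in id_sets]
    common = [s for s in sets[0] if all(s in set(o) for o in sets[1:])]
    total = {x for s in sets for x in s}
    dropped = len(total) - len(common)
    if dropped:
        if not allow_subset:
            raise ValidationError(
                f"{context}: sample identifiers disagree across files "
                f"({dropped} non-shared of {len(total)}); pass allow_subset to intersect"
            )
        logger.warning("%s: intersecting samples, dropping %d of %d",
                       context, dropped, len(total))
    if not common:
        raise ValidationError(f"{context}: no samples in common")
    return common
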