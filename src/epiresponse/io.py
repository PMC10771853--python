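"""Readers and writers for the tabular formats used throughout the pipeline.

All on-disk formats are plain text: beta/M matrices and probe manifests are
TSV, sample sheets and derived tables are CSV.  Matrices are stored probes x
samples with the probe id in the first column.  Every writer round-trips
losslessly through the corresponding reader (float64 values are written with
full precision).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

MANIFEST_COLUMNS = ["chrom", "pos", "gene", "feature"]

_ALLOSOME_LABELS = {"X", "Y", "chrX", "chrY"}


def _sep_for(path: str | os.PathLike) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate {what}: {dups[:10]}")


def validate_beta_matrix(beta: pd.DataFrame, name: str = "beta matrix") -> None:
    """Check id uniqueness and the [0, 1] value range of a beta matrix.

    Raises :class:`ValidationError` naming the offending probe and sample for
    the first out-of-range or missing cell found.
    """
    _check_unique(beta.index, "probe ids")
    _check_unique(beta.columns, "sample ids")
    values = beta.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"{name} contains non-numeric entries")
    bad = ~np.isfinite(values) | (values < 0.0) | (values > 1.0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{name} value out of [0, 1] (or missing) at probe "
            f"{beta.index[i]!r}, sample {beta.columns[j]!r}: {values[i, j]!r}"
        )


def read_beta_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a probes x samples beta matrix (TSV, or CSV by extension)."""
    beta = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    beta.index = beta.index.astype(str)
    validate_beta_matrix(beta)
    return beta


def write_beta_matrix(beta: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_beta_matrix(beta)
    beta.to_csv(path, sep=_sep_for(path), index_label="probe_id", float_format="%.17g")


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a probes x samples numeric matrix without the beta range check."""
    m = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    m.index = m.index.astype(str)
    _check_unique(m.index, "probe ids")
    _check_unique(m.columns, "sample ids")
    return m


def write_matrix(m: pd.DataFrame, path: str | os.PathLike) -> None:
    m.to_csv(path, sep=_sep_for(path), index_label="probe_id", float_format="%.17g")


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-sample clinical sheet (CSV, sample id in the first column)."""
    sheet = pd.read_csv(path, index_col=0)
    sheet.index = sheet.index.astype(str)
    _check_unique(sheet.index, "sample ids")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | os.PathLike) -> None:
    sheet.to_csv(path, index_label="sample_id")


def validate_manifest(manifest: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise SchemaError(f"manifest missing columns: {missing}")
    _check_unique(manifest.index, "probe ids")
    pos = manifest["pos"]
    if not np.issubdtype(pos.dtype, np.number) or (pos <= 0).any():
        raise ValidationError("manifest positions must be positive integers (1-based)")


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a probe manifest: probe id, chrom, 1-based position, gene, feature.

    Accepts either the package's column names or Illumina-style headers
    (``CGID``/``chr``/``pos``).  Absent gene annotation is kept as NaN
    ("NA" in the file).
    """
    manifest = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype={"chrom": str, "chr": str})
    manifest.index = manifest.index.astype(str)
    manifest = manifest.rename(columns={"chr": "chrom"})
    validate_manifest(manifest)
    return manifest


def write_manifest(manifest: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_manifest(manifest)
    manifest.to_csv(path, sep=_sep_for(path), index_label="probe_id", na_rep="NA")


def is_allosomal(chrom: pd.Series | np.ndarray) -> np.ndarray:
    """Boolean mask: True where the chromosome label is X or Y."""
    return pd.Series(chrom).astype(str).isin(_ALLOSOME_LABELS).to_numpy()


def read_reference_profiles(path: str | os.PathLike) -> pd.DataFrame:
    refs = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    refs.index = refs.index.astype(str)
    _check_unique(refs.index, "probe ids")
    return refs


def write_reference_profiles(refs: pd.DataFrame, path: str | os.PathLike) -> None:
    refs.to_csv(path, sep=_sep_for(path), index_label="probe_id", float_format="%.17g")


def read_gene_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read gene intervals: gene, chrom, start, end (1-based inclusive)."""
    genes = pd.read_csv(path, sep=_sep_for(path), dtype={"chrom": str})
    required = {"gene", "chrom", "start", "end"}
    missing = required - set(genes.columns)
    if missing:
        raise SchemaError(f"gene table missing columns: {sorted(missing)}")
    return genes


def write_gene_table(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    genes.to_csv(path, sep=_sep_for(path), index=False)
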