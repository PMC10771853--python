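"""Methylation preprocessing: beta/M transforms, allosome exclusion, gap hunting.

The beta value is the methylation fraction in [0, 1]; the M-value is
``log2(beta / (1 - beta))``, the variance-stabilized scale used for the
statistical analysis.  Gap hunting flags probes whose per-sample beta
distribution splits into well separated clusters — the bi-/tri-modal
signature of an underlying genetic variant rather than a methylation signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .io import is_allosomal

DEFAULT_GAP_THRESHOLD = 0.3
DEFAULT_MIN_GROUP_FRACTION = 0.01


def beta_to_m(beta, offset: float = 0.0):
    """Convert beta values to M-values: ``log2((b + offset) / (1 - b + offset))``.

    ``offset`` guards against infinite M at beta of exactly 0 or 1; the
    default of 0 is exact but rejects such values with an error advising an
    offset (1e-6 is a sensible choice for real matrices).
    Accepts scalars, arrays, or DataFrames; the container type is preserved.
    """
    arr = np.asarray(beta, dtype=float)
    if offset < 0:
        raise ValidationError("offset must be >= 0")
    if np.any((arr < 0) | (arr > 1)):
        raise ValidationError("beta values must lie in [0, 1]")
    if offset == 0 and np.any((arr == 0) | (arr == 1)):
        raise ValidationError(
            "beta of exactly 0 or 1 gives an infinite M-value; pass a small "
            "positive offset (e.g. 1e-6)"
        )
    m = np.log2((arr + offset) / (1.0 - arr + offset))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index, name=beta.name)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` at offset 0: ``beta = 2^M / (2^M + 1)``."""
    arr = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("M-values must be finite")
    # expit on the natural-log scale of 2^M, written to avoid overflow
    b = np.where(arr >= 0, 1.0 / (1.0 + 2.0 ** (-arr)), 2.0**arr / (2.0**arr + 1.0))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(b, index=m.index, name=m.name)
    if np.isscalar(m):
        return float(b)
    return b


def filter_allosomes(matrix: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Restrict a probes x samples matrix to autosomal probes, preserving order.

    Every matrix probe must be present in the manifest; missing probes raise
    a :class:`SchemaError` listing the ids.  Idempotent.
    """
    missing = matrix.index.difference(manifest.index)
    if len(missing):
        raise SchemaError(f"probes absent from manifest: {missing.tolist()[:10]}")
    chrom = manifest.loc[matrix.index, "chrom"]
    keep = ~is_allosomal(chrom)
    if not keep.any():
        warnings.warn("all probes are allosomal; returning an empty matrix", stacklevel=2)
    return matrix.loc[matrix.index[keep]]


@dataclass
class GapReport:
    """Result of gap hunting one probe.

    ``n_groups`` counts clusters whose size reaches ``min_group_fraction`` of
    the samples; smaller clusters are treated as outliers and recorded in
    ``n_outlier_groups`` but do not by themselves cause flagging.
    """

    probe_id: str
    n_groups: int
    n_outlier_groups: int
    boundaries: list = field(default_factory=list)
    largest_gap: float = 0.0
    flagged: bool = False


def gap_hunt(
    values,
    threshold: float = DEFAULT_GAP_THRESHOLD,
    min_group_fraction: float = DEFAULT_MIN_GROUP_FRACTION,
    probe_id: str = "",
) -> GapReport:
    """Flag a probe whose sorted betas split into >= 2 clusters at gaps > threshold.

    Values are sorted ascending and cut wherever consecutive values differ by
    more than ``threshold``; clusters holding fewer than
    ``min_group_fraction`` of the samples are outliers.  A probe is flagged
    iff at least two non-outlier clusters remain — the characteristic pattern
    of a genotype-driven (SNP-affected) probe.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise ValidationError("gap hunting requires at least 2 samples")
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie in (0, 1)")
    diffs = np.diff(x)
    cuts = np.flatnonzero(diffs > threshold)
    sizes = np.diff(np.concatenate([[0], cuts + 1, [n]]))
    boundaries = [float(0.5 * (x[c] + x[c + 1])) for c in cuts]
    min_size = min_group_fraction * n
    n_real = int(np.sum(sizes >= min_size))
    n_outlier = int(len(sizes) - n_real)
    return GapReport(
        probe_id=probe_id,
        n_groups=n_real,
        n_outlier_groups=n_outlier,
        boundaries=boundaries,
        largest_gap=float(diffs.max()) if n > 1 else 0.0,
        flagged=n_real >= 2,
    )


def gap_hunt_matrix(
    beta: pd.DataFrame,
    threshold: float = DEFAULT_GAP_THRESHOLD,
    min_group_fraction: float = DEFAULT_MIN_GROUP_FRACTION,
) -> pd.DataFrame:
    """Run :func:`gap_hunt` on every row; returns a per-probe report table."""
    rows = []
    for probe, row in zip(beta.index, beta.to_numpy()):
        rep = gap_hunt(row, threshold, min_group_fraction, probe_id=str(probe))
        rows.append(
            {
                "probe_id": rep.probe_id,
                "n_groups": rep.n_groups,
                "n_outlier_groups": rep.n_outlier_groups,
                "largest_gap": rep.largest_gap,
                "flagged": rep.flagged,
            }
        )
    return pd.DataFrame(rows).set_index("probe_id")
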