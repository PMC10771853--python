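"""Gene-level aggregation of per-CpG results.

Three pieces:

* probe-to-gene annotation within a 20-kb window of the gene interval;
* Brown's method — Fisher's combination of p-values generalized to
  correlated tests by matching the first two moments of the combined
  statistic to a scaled chi-square with reduced effective degrees of
  freedom; pairwise covariances of the -2 ln p scores use the
  Kost-McDermott polynomial approximation
  ``cov = 3.263 r + 0.710 r^2 + 0.027 r^3`` (clipped to [0, 4]);
* per-gene regional delta-methylation profiles smoothed with a degree-1
  loess (tricube weights) and pointwise standard errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

ANNOTATION_WINDOW = 20_000
KOST_MCDERMOTT = (3.263, 0.710, 0.027)


def annotate_probes(
    manifest: pd.DataFrame, gene_table: pd.DataFrame, max_distance: int = ANNOTATION_WINDOW
) -> pd.DataFrame:
    """Assign each probe to the nearest gene within ``max_distance`` bp.

    Distance is 0 inside the gene body (1-based inclusive interval) and the
    distance to the closer boundary otherwise.  Ties are broken by the gene
    whose interval midpoint is closer, then by lexicographic symbol.  Probes
    with no gene in range get an absent annotation (NA).  Returns a copy of
    the manifest with ``gene`` and ``gene_distance`` columns replaced.
    """
    bad = gene_table[gene_table["start"] > gene_table["end"]]
    if len(bad):
        raise ValidationError(f"malformed gene intervals (start > end): {bad['gene'].tolist()[:5]}")
    out = manifest.copy()
    genes_assigned = np.full(len(out), None, dtype=object)
    dist_assigned = np.full(len(out), np.nan)
    by_chrom = dict(tuple(gene_table.groupby("chrom")))
    for chrom, sub in out.groupby("chrom"):
        gt = by_chrom.get(str(chrom))
        if gt is None:
            continue
        pos = sub["pos"].to_numpy(dtype=float)[:, None]
        start = gt["start"].to_numpy(dtype=float)[None, :]
        end = gt["end"].to_numpy(dtype=float)[None, :]
        inside = (pos >= start) & (pos <= end)
        dist = np.where(inside, 0.0, np.minimum(np.abs(pos - start), np.abs(pos - end)))
        mid_dist = np.abs(pos - 0.5 * (start + end))
        symbols = gt["gene"].to_numpy()
        # resolve per probe: smallest (dist, mid_dist, symbol) among in-range genes
        idx_probe = np.where(out.index.isin(sub.index))[0]
        for i in range(len(pos)):
            in_range = np.flatnonzero(dist[i] <= max_distance)
            if in_range.size == 0:
                continue
            keys = sorted(
                in_range, key=lambda g: (dist[i, g], mid_dist[i, g], str(symbols[g]))
            )
            g = keys[0]
            genes_assigned[idx_probe[i]] = symbols[g]
            dist_assigned[idx_probe[i]] = dist[i, g]
    out["gene"] = genes_assigned
    out["gene_distance"] = dist_assigned
    return out


@dataclass
class GeneAggregate:
    """Brown-combined evidence for one gene."""

    gene: str
    k: int
    psi: float  # Fisher statistic -2 sum(ln p)
    expected: float  # E[psi] under the null = 2k
    variance: float  # Var[psi] including pairwise covariances
    scale: float  # c = Var / (2 E)
    df: float  # effective degrees of freedom f = 2 E^2 / Var
    p_value: float


def brown_combine(pvalues, correlations=None, gene: str = "") -> GeneAggregate:
    """Combine correlated p-values into one by Brown's method.

    ``correlations`` is the k x k Pearson correlation matrix of the
    underlying scores (identity / None means independence, in which case
    the result is exactly Fisher's method).  p-values must lie in (0, 1];
    an exact zero is rejected with advice to floor it upstream.
    """
    p = np.asarray(pvalues, dtype=float)
    k = p.size
    if k < 1:
        raise ValidationError("need at least one p-value")
    if np.any(p <= 0):
        raise ValidationError(
            "p-value of 0 cannot be log-combined; floor it at a small positive value"
        )
    if np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    if correlations is None:
        rho = np.eye(k)
    else:
        rho = np.asarray(correlations, dtype=float)
        if rho.shape != (k, k):
            raise ValidationError(f"correlation matrix must be {k}x{k}")
        if not np.allclose(rho, rho.T, atol=1e-8) or not np.allclose(np.diag(rho), 1.0, atol=1e-8):
            raise ValidationError("correlation matrix must be symmetric with unit diagonal")
        if k > 1 and np.linalg.eigvalsh(rho).min() < -1e-8:
            warnings.warn(
                "correlation matrix is not positive semi-definite; "
                "pairwise covariances are still applied",
                stacklevel=2,
            )

    psi = float(-2.0 * np.log(p).sum())
    expected = 2.0 * k
    a, b, c3 = KOST_MCDERMOTT
    iu = np.triu_indices(k, 1)
    r = rho[iu]
    cov = np.clip(a * r + b * r**2 + c3 * r**3, 0.0, 4.0)
    variance = 4.0 * k + 2.0 * cov.sum()
    scale = variance / (2.0 * expected)
    df = 2.0 * expected**2 / variance
    p_comb = float(stats.chi2.sf(psi / scale, df))
    return GeneAggregate(gene, k, psi, expected, variance, scale, df, p_comb)


def gene_level_scan(
    dm: pd.DataFrame,
    manifest: pd.DataFrame,
    m_matrix: pd.DataFrame,
    genes,
    method: str = "pearson",
) -> pd.DataFrame:
    """Brown-combine per-CpG p-values for each requested gene.

    Probe membership comes from the manifest's gene column; correlations are
    estimated from the probes' M-values across all samples (Pearson by
    default, Spearman available).  Genes with no annotated probe are
    reported as absent rather than raising.
    """
    rows = []
    for gene in genes:
        probes = manifest.index[manifest["gene"] == gene]
        probes = probes.intersection(dm.index)
        if len(probes) == 0:
            rows.append(
                {"gene": gene, "k": 0, "psi": np.nan, "df": np.nan, "p_value": np.nan, "absent": True}
            )
            continue
        sub = m_matrix.loc[probes]
        if method == "pearson":
            rho = np.corrcoef(sub.to_numpy())
        elif method == "spearman":
            rho = stats.spearmanr(sub.to_numpy(), axis=1).statistic
            rho = np.atleast_2d(rho)
        else:
            raise ValidationError(f"unknown correlation method {method!r}")
        rho = np.nan_to_num(np.atleast_2d(rho), nan=0.0)
        np.fill_diagonal(rho, 1.0)
        agg = brown_combine(dm.loc[probes, "p_value"].to_numpy(), rho, gene=gene)
        rows.append(
            {
                "gene": gene,
                "k": agg.k,
                "psi": agg.psi,
                "df": agg.df,
                "p_value": agg.p_value,
                "absent": False,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


@dataclass
class RegionalProfile:
    """Per-gene positional delta-methylation profile with a loess trend."""

    gene: str
    points: pd.DataFrame  # probe, pos, delta (sorted by position)
    grid: np.ndarray | None  # evaluation positions
    fit: np.ndarray | None  # loess-smoothed delta
    se: np.ndarray | None  # pointwise standard error
    first_exon: tuple[int, int] | None = None
    note: str = ""

    @property
    def smoothed(self) -> bool:
        return self.fit is not None


def _loess_fit(x, y, span, xgrid):
    """Degree-1 tricube-weighted local regression with pointwise SE.

    For each grid point the bandwidth is the distance to the
    ceil(span * n)-th nearest data point; the fitted value is a linear
    smoother l(x0)' y so its variance is sigma^2 ||l||^2 with sigma^2
    estimated from the smoother's residuals at the data points.
    """
    n = x.size
    q = max(2, math.ceil(span * n))

    def smoother_row(x0):
        d = np.abs(x - x0)
        h = np.sort(d)[min(q, n) - 1]
        if h <= 0:
            h = max(d.max(), 1.0) * 1e-9
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        if (w > 0).sum() < 2:
            w = np.where(d <= np.partition(d, 1)[1], 1.0, w)
        X = np.column_stack([np.ones(n), x - x0])
        XtW = X.T * w
        A = np.linalg.pinv(XtW @ X)
        return (A @ XtW)[0]  # prediction row at x0 (intercept term)

    L_data = np.vstack([smoother_row(xi) for xi in x])
    resid = y - L_data @ y
    dof = max(n - 2, 1)
    sigma2 = float(resid @ resid) / dof
    rows = np.vstack([smoother_row(g) for g in xgrid])
    fit = rows @ y
    se = np.sqrt(sigma2 * np.einsum("ij,ij->i", rows, rows))
    return fit, se


def regional_profile(
    gene: str,
    dm: pd.DataFrame,
    manifest: pd.DataFrame,
    span: float = 0.75,
    grid_points: int = 200,
    first_exon: tuple[int, int] | None = None,
) -> RegionalProfile:
    """Delta-methylation versus position for one gene, loess-smoothed.

    Uses the ``delta_beta`` column of the differential-methylation table.
    With fewer than 3 probes the raw points are returned and smoothing is
    skipped with a notice.  The smoothed curve is only defined within the
    probe position range.
    """
    if not 0.0 < span <= 1.0:
        raise ValidationError("span must lie in (0, 1]")
    probes = manifest.index[manifest["gene"] == gene].intersection(dm.index)
    if len(probes) == 0:
        raise ValidationError(f"gene {gene!r} has no annotated probes")
    pts = pd.DataFrame(
        {
            "probe": probes,
            "pos": manifest.loc[probes, "pos"].to_numpy(),
            "delta": dm.loc[probes, "delta_beta"].to_numpy(),
        }
    ).sort_values("pos", ignore_index=True)
    if len(pts) < 3:
        return RegionalProfile(
            gene, pts, None, None, None, first_exon, note="fewer than 3 probes; smoothing skipped"
        )
    x = pts["pos"].to_numpy(dtype=float)
    y = pts["delta"].to_numpy(dtype=float)
    grid = np.linspace(x.min(), x.max(), grid_points)
    fit, se = _loess_fit(x, y, span, grid)
    return RegionalProfile(gene, pts, grid, fit, se, first_exon)
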