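"""Reference-based leukocyte deconvolution from methylation, plus group ANOVA.

Whole blood is a mixture of cell types, each with its own methylation
profile, so the beta value at a cell-type discriminating probe is (to first
order) the reference profiles mixed by the sample's cell fractions:
``b = R w``.  Per sample we solve the constrained least-squares problem

    min_w || R w - b ||^2   subject to  w >= 0

by non-negative least squares.  Following reference-based projection
practice, the sum-to-one constraint is not imposed during optimization; the
raw coefficients are reported alongside row-normalized proportions (on
noiseless mixtures the raw solution already sums to one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import SchemaError, ValidationError


@dataclass
class CellProportions:
    """Per-sample cell-composition estimates.

    ``raw`` holds the unconstrained-scale non-negative coefficients,
    ``normalized`` the same rows scaled to sum to one.
    """

    raw: pd.DataFrame  # samples x cell types
    normalized: pd.DataFrame
    residual_norm: pd.Series  # ||R w - b|| per sample


def estimate_proportions(betas: pd.DataFrame, references: pd.DataFrame) -> CellProportions:
    """Estimate cell proportions for every sample of a beta matrix.

    ``betas`` (probes x samples) and ``references`` (probes x cell types)
    must cover identical probe sets; rows are aligned by probe id, so probe
    order is irrelevant.
    """
    if set(betas.index) != set(references.index):
        raise SchemaError(
            "probe sets of beta matrix and reference profiles differ "
            f"({len(betas.index.symmetric_difference(references.index))} mismatching probes)"
        )
    R = references.loc[betas.index].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        raise ValidationError("reference matrix is rank-deficient; cell types are not separable")
    W = np.empty((betas.shape[1], R.shape[1]))
    resid = np.empty(betas.shape[1])
    B = betas.to_numpy(dtype=float)
    for j in range(betas.shape[1]):
        W[j], resid[j] = optimize.nnls(R, B[:, j])
    raw = pd.DataFrame(W, index=betas.columns, columns=references.columns)
    sums = raw.sum(axis=1)
    if (sums <= 0).any():
        raise ValidationError("a sample produced an all-zero composition estimate")
    normalized = raw.div(sums, axis=0)
    return CellProportions(raw=raw, normalized=normalized, residual_norm=pd.Series(resid, index=betas.columns))


@dataclass
class AnovaResult:
    """Two-way ANOVA of proportion ~ response group x cell type."""

    table: pd.DataFrame  # factors x (sum_sq, df, F, PR(>F))
    contrasts: pd.DataFrame  # per-cell-type two-sample group comparison


def compare_proportions(
    proportions: pd.DataFrame | CellProportions, labels: pd.Series
) -> AnovaResult:
    """Compare estimated cell composition between response groups.

    Fits a fixed-effects two-way ANOVA (type-II sums of squares, appropriate
    for the unbalanced 49/43-style design) of proportion on response group,
    cell type and their interaction, and reports per-cell-type two-sample
    t-contrasts as a secondary output.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if isinstance(proportions, CellProportions):
        proportions = proportions.normalized
    labels = labels.loc[proportions.index]
    counts = labels.value_counts()
    if len(counts) != 2 or (counts < 2).any():
        raise ValidationError("need two response groups with at least 2 samples each")

    long = proportions.reset_index(names="sample_id").melt(
        id_vars="sample_id", var_name="celltype", value_name="proportion"
    )
    long["group"] = labels.loc[long["sample_id"]].to_numpy()
    model = smf.ols("proportion ~ C(group) * C(celltype)", data=long).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(group)": "group",
            "C(celltype)": "celltype",
            "C(group):C(celltype)": "group:celltype",
            "Residual": "residual",
        }
    )

    rows = []
    level_a, level_b = sorted(counts.index)
    for ct in proportions.columns:
        a = proportions.loc[labels == level_a, ct]
        b = proportions.loc[labels == level_b, ct]
        t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            {
                "celltype": ct,
                f"mean_{level_a}": a.mean(),
                f"mean_{level_b}": b.mean(),
                "t": float(t),
                "p_value": float(p),
            }
        )
    return AnovaResult(table=table, contrasts=pd.DataFrame(rows).set_index("celltype"))
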