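"""Per-CpG covariate-adjusted differential methylation on the M-value scale.

Each probe's M-values are regressed by ordinary least squares on a design of
intercept + response indicator + optional clinical covariates (age, sex,
smoking, concomitant methotrexate).  The response coefficient is tested with
a t-test on the residual degrees of freedom; the effect is additionally
reported as the difference of group mean betas (the percentage-methylation
scale used for interpretation).  With no covariates the per-probe test is
algebraically identical to the pooled-variance two-sample t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError, ValidationError
from .labels import RESPONDER

DEFAULT_COVARIATES = ("age", "sex", "smoking", "mtx")


def _encode_binary(col: pd.Series, name: str) -> np.ndarray:
    vals = col.dropna().unique()
    if col.isna().any():
        missing = col.index[col.isna()].tolist()
        raise ValidationError(f"covariate {name!r} missing for samples: {missing[:10]}")
    if np.issubdtype(col.dtype, np.number):
        return col.to_numpy(dtype=float)
    if len(vals) > 2:
        raise ValidationError(f"categorical covariate {name!r} has >2 levels: {sorted(vals)}")
    order = {v: i for i, v in enumerate(sorted(vals))}
    return col.map(order).to_numpy(dtype=float)


def build_design(sheet: pd.DataFrame, covariates=()) -> pd.DataFrame:
    """Build the samples x columns design: intercept, response, covariates.

    The response indicator is 1 for responders.  Categorical covariates are
    coded 0/1; a constant column (e.g. every sample a smoker) makes the
    design rank-deficient and raises.
    """
    if "response" not in sheet.columns:
        raise ValidationError("sample sheet has no 'response' column")
    resp = sheet["response"]
    if np.issubdtype(resp.dtype, np.number):
        response = resp.to_numpy(dtype=float)
    else:
        response = (resp == RESPONDER).astype(float).to_numpy()
    if set(np.unique(response)) != {0.0, 1.0}:
        raise ValidationError("response column must contain both groups")
    cols = {"intercept": np.ones(len(sheet)), "response": response}
    for cov in covariates:
        if cov not in sheet.columns:
            raise ValidationError(f"covariate {cov!r} not in sample sheet")
        cols[cov] = _encode_binary(sheet[cov], cov)
    design = pd.DataFrame(cols, index=sheet.index)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValidationError(
            "design matrix is rank-deficient (a covariate is constant or collinear)"
        )
    return design


def fit_dm(
    m_matrix: pd.DataFrame, design: pd.DataFrame, beta_matrix: pd.DataFrame | None = None
) -> pd.DataFrame:
    """OLS of every probe's M-values on the design; t-test on the response term.

    Returns a per-probe table with the response coefficient (M scale), its
    standard error, t statistic, two-sided p-value, residual df and — when a
    beta matrix is supplied — the difference of group mean betas
    (responders minus non-responders).  Probes with zero variance across
    samples are reported with coefficient 0 and p = 1.
    """
    if list(design.index) != list(m_matrix.columns):
        if set(design.index) != set(m_matrix.columns):
            raise SchemaError("samples of design and M matrix differ")
        design = design.loc[m_matrix.columns]
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    dof = n - p
    if dof < 1:
        raise ValidationError(f"residual degrees of freedom < 1 (n={n}, p={p})")
    j = design.columns.get_loc("response")

    Y = m_matrix.to_numpy(dtype=float)  # probes x samples
    XtX_inv = np.linalg.inv(X.T @ X)
    coefs = Y @ X @ XtX_inv  # probes x p
    resid = Y - coefs @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[j, j], 0.0))

    coef = coefs[:, j]
    zero_var = Y.var(axis=1) <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    pval = 2.0 * stats.t.sf(np.abs(t), dof)
    coef = np.where(zero_var, 0.0, coef)
    t = np.where(zero_var, 0.0, t)
    pval = np.where(zero_var, 1.0, pval)

    out = pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "t": t,
            "p_value": pval,
            "df_resid": dof,
            "zero_variance": zero_var,
        },
        index=m_matrix.index,
    )
    if beta_matrix is not None:
        if set(beta_matrix.columns) != set(m_matrix.columns):
            raise SchemaError("samples of beta and M matrices differ")
        B = beta_matrix.loc[m_matrix.index, m_matrix.columns].to_numpy(dtype=float)
        resp_mask = X[:, j] == 1.0
        out["delta_beta"] = B[:, resp_mask].mean(axis=1) - B[:, ~resp_mask].mean(axis=1)
        out["direction"] = np.where(out["delta_beta"] > 0, "hypermethylation", "hypomethylation")
    return out


def covariate_robustness(
    panel,
    m_matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    beta_matrix: pd.DataFrame | None = None,
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Per-probe p-values with and without covariate adjustment for a panel.

    Fits the response-only and the fully adjusted design on the panel probes
    and reports both p-values; the attrs carry the count of probes below
    0.05 under each design (association robust to confounders).
    An empty panel yields an empty table.
    """
    panel = [p for p in panel]
    if not panel:
        out = pd.DataFrame(columns=["p_unadjusted", "p_adjusted"])
        out.attrs["n_sig_unadjusted"] = 0
        out.attrs["n_sig_adjusted"] = 0
        return out
    missing = [p for p in panel if p not in m_matrix.index]
    if missing:
        raise SchemaError(f"panel probes absent from matrix: {missing[:10]}")
    sub_m = m_matrix.loc[panel]
    sub_b = beta_matrix.loc[panel] if beta_matrix is not None else None
    plain = fit_dm(sub_m, build_design(sheet), sub_b)
    full = fit_dm(sub_m, build_design(sheet, covariates), sub_b)
    out = pd.DataFrame(
        {"p_unadjusted": plain["p_value"], "p_adjusted": full["p_value"]}, index=sub_m.index
    )
    out.attrs["n_sig_unadjusted"] = int((out["p_unadjusted"] < 0.05).sum())
    out.attrs["n_sig_adjusted"] = int((out["p_adjusted"] < 0.05).sum())
    return out


def export_results(
    dm: pd.DataFrame, manifest: pd.DataFrame, path, adjusted: pd.Series | None = None
) -> pd.DataFrame:
    """Write a Table-style TSV: CGID, chr, pos, delta methylation, p, gene, feature, direction."""
    table = pd.DataFrame(
        {
            "CGID": dm.index,
            "chr": manifest.loc[dm.index, "chrom"].to_numpy(),
            "pos": manifest.loc[dm.index, "pos"].to_numpy(),
            "delta_methylation": dm.get("delta_beta", pd.Series(np.nan, index=dm.index)).to_numpy(),
            "p_value": dm["p_value"].to_numpy(),
            "annotated_gene": manifest.loc[dm.index, "gene"].to_numpy(),
            "gene_feature": manifest.loc[dm.index, "feature"].to_numpy(),
            "direction": dm.get("direction", pd.Series("", index=dm.index)).to_numpy(),
        }
    )
    if adjusted is not None:
        table["p_value_adjusted"] = adjusted.loc[dm.index].to_numpy()
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
    return table
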