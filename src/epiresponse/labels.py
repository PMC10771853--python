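"""DAS28-based therapy-response classification and cohort characteristics.

The clinical decision rule binarizes response after 3-6 months of treatment
from the Disease Activity Score in 28 joints (DAS28, a 1-10 scale):

* responder  — follow-up DAS28 < 3.2, or a decrease of at least 1.2 points;
* non-responder — follow-up DAS28 > 5.1, or a decrease of less than 0.6.

The two clauses can both fire (e.g. a large decrease that still ends above
5.1) or neither (moderate improvement ending in the middle range); those
cases are surfaced as ``conflict`` and ``indeterminate`` rather than being
silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

RESPONDER = "responder"
NON_RESPONDER = "non_responder"
INDETERMINATE = "indeterminate"
CONFLICT = "conflict"

#: Boundary semantics, exactly as printed in the clinical criteria:
#: "decrease of at least 1.2" is >= 1.2, "decrease of < 0.6" is strict,
#: "DAS28 < 3.2" and "> 5.1" are strict.
RESPONDER_FOLLOWUP = 3.2
RESPONDER_DECREASE = 1.2
NONRESPONDER_FOLLOWUP = 5.1
NONRESPONDER_DECREASE = 0.6


@dataclass
class ResponseCall:
    baseline: float
    followup: float
    decrease: float
    label: str
    sample_id: str | None = None


def label_response(baseline: float, followup: float, sample_id: str | None = None) -> ResponseCall:
    """Classify one patient from baseline and follow-up DAS28.

    Pure and total on [0, 10]^2.  The decrease is rounded at the 9th decimal
    so that scores recorded at clinical precision (one or two decimals) hit
    the rule boundaries exactly despite binary floating point.
    """
    if not (0.0 <= baseline <= 10.0) or not (0.0 <= followup <= 10.0):
        raise ValidationError(f"DAS28 scores must lie in [0, 10]: ({baseline}, {followup})")
    decrease = round(baseline - followup, 9)
    resp = followup < RESPONDER_FOLLOWUP or decrease >= RESPONDER_DECREASE
    nonresp = followup > NONRESPONDER_FOLLOWUP or decrease < NONRESPONDER_DECREASE
    if resp and nonresp:
        label = CONFLICT
    elif resp:
        label = RESPONDER
    elif nonresp:
        label = NON_RESPONDER
    else:
        label = INDETERMINATE
    return ResponseCall(baseline, followup, decrease, label, sample_id)


def label_samples(sheet: pd.DataFrame) -> pd.Series:
    """Apply :func:`label_response` to every row of a sample sheet.

    Requires ``das28_baseline`` and ``das28_followup`` columns.
    """
    for col in ("das28_baseline", "das28_followup"):
        if col not in sheet.columns:
            raise ValidationError(f"sample sheet missing column {col!r}")
    out = [
        label_response(b, f, sample_id=s).label
        for s, b, f in zip(sheet.index, sheet["das28_baseline"], sheet["das28_followup"])
    ]
    return pd.Series(out, index=sheet.index, name="response")


CATEGORICAL = "categorical"
CONTINUOUS_NORMAL = "continuous_normal"
CONTINUOUS_SKEWED = "continuous_skewed"

#: Exact Mann-Whitney distribution is used up to this smaller-group size;
#: beyond it the normal approximation with tie correction applies.
_EXACT_MW_MAX_N = 8


def _chi2_test(x: pd.Series, groups: pd.Series, correction: bool) -> float:
    table = pd.crosstab(x, groups)
    stat = stats.chi2_contingency(table.to_numpy(), correction=correction)
    return float(stat.pvalue)


def cohort_table(
    sheet: pd.DataFrame,
    variable_spec: Mapping[str, str],
    group_col: str = "response",
    chi2_continuity_correction: bool = False,
) -> pd.DataFrame:
    """Baseline-characteristics table with per-variable two-sided tests.

    ``variable_spec`` declares each variable as ``categorical`` (summarized
    as n (%), chi-square test), ``continuous_normal`` (mean (SD), two-sample
    t-test) or ``continuous_skewed`` (median (IQR), Mann-Whitney U).
    Missing values are dropped per variable and the effective n reported.
    Significance is flagged at p <= 0.05.
    """
    if group_col not in sheet.columns:
        raise ValidationError(f"group column {group_col!r} missing from sheet")
    groups = sheet[group_col]
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValidationError(f"expected exactly 2 groups, found {levels}")
    if (groups.value_counts() < 2).any():
        raise ValidationError("each group needs at least 2 samples")

    rows = []
    for var, kind in variable_spec.items():
        if var not in sheet.columns:
            raise ValidationError(f"unknown variable {var!r}")
        data = sheet[[var, group_col]].dropna()
        a = data.loc[data[group_col] == levels[0], var]
        b = data.loc[data[group_col] == levels[1], var]
        note = ""
        if kind == CATEGORICAL:
            summ_a = _cat_summary(a)
            summ_b = _cat_summary(b)
            test = "chi-square"
            p = _chi2_test(data[var], data[group_col], chi2_continuity_correction)
        elif kind == CONTINUOUS_NORMAL:
            summ_a = f"{a.mean():.2f} ({a.std(ddof=1):.2f})"
            summ_b = f"{b.mean():.2f} ({b.std(ddof=1):.2f})"
            test = "t-test"
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                p, note = np.nan, "zero variance in both groups; test skipped"
            else:
                p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        elif kind == CONTINUOUS_SKEWED:
            summ_a = f"{a.median():.2f} ({a.quantile(0.25):.2f}-{a.quantile(0.75):.2f})"
            summ_b = f"{b.median():.2f} ({b.quantile(0.25):.2f}-{b.quantile(0.75):.2f})"
            test = "mann-whitney"
            if a.nunique() == 1 and b.nunique() == 1 and a.iloc[0] == b.iloc[0]:
                p, note = np.nan, "zero variance in both groups; test skipped"
            else:
                method = "exact" if min(len(a), len(b)) <= _EXACT_MW_MAX_N else "asymptotic"
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
        else:
            raise ValidationError(f"unknown variable type {kind!r} for {var!r}")
        rows.append(
            {
                "variable": var,
                "type": kind,
                f"{levels[0]} (n={int((groups == levels[0]).sum())})": summ_a,
                f"{levels[1]} (n={int((groups == levels[1]).sum())})": summ_b,
                "n_effective": len(data),
                "test": test,
                "p_value": p,
                "significant": bool(p <= 0.05) if np.isfinite(p) else False,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def _cat_summary(x: pd.Series) -> str:
    n = len(x)
    pos = int((x == x.max()).sum()) if x.nunique() <= 2 else n
    if x.nunique() <= 2:
        return f"{pos} ({100.0 * pos / n:.1f}%)"
    return ", ".join(f"{k}: {v}" for k, v in x.value_counts().items())
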