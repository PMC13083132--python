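"""Group-contrast statistics: Welch tests, effect sizes, FDR, ANOVA, Fisher.

The familial contrast framework compares feature distributions between
diagnostic groups with Welch's unequal-variance t-test (Welch-Satterthwaite
degrees of freedom), quantifies effects with Cohen's d (pooled SD), and
controls the false discovery rate per declared test family with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import GroupSummary, ValidationError

#: The four familial contrasts, in reporting order.
DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("SCZ", "CON"),
    ("SCZ", "SCZ-SIB"),
    ("SCZ-SIB", "CON-SIB"),
    ("CON", "CON-SIB"),
)


@dataclass(frozen=True)
class WelchResult:
    t: float
    nu: float
    p: float


def welch_t(a: np.ndarray, b: np.ndarray) -> WelchResult:
    """Welch's two-sample t-test with Welch-Satterthwaite df (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("welch_t needs at least 2 observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValidationError("welch_t undefined when both variances are zero")
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), nu=float(res.df), p=float(res.pvalue))


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with (n1-1, n2-1)-weighted pooled SD, no small-sample correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValidationError("cohens_d needs at least 2 observations per group")
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValidationError("cohens_d undefined with zero pooled SD")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _contrast_frame(
    df: pd.DataFrame,
    feature_columns: list[str],
    contrasts: list[tuple[str, str]],
    conditions: list[str],
) -> pd.DataFrame:
    rows = []
    for cond in conditions:
        sub = df[df["condition"] == cond]
        for g1, g2 in contrasts:
            a = sub.loc[sub["group"] == g1, feature_columns].to_numpy(dtype=float)
            b = sub.loc[sub["group"] == g2, feature_columns].to_numpy(dtype=float)
            for g, name in ((a, g1), (b, g2)):
                if g.shape[0] < 2:
                    raise ValidationError(
                        f"group {name!r} missing or has n < 2 in condition {cond!r}"
                    )
            res = sps.ttest_ind(a, b, axis=0, equal_var=False)
            n1, n2 = a.shape[0], b.shape[0]
            m1, m2 = a.mean(axis=0), b.mean(axis=0)
            v1, v2 = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
            pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
            with np.errstate(divide="ignore", invalid="ignore"):
                d = (m1 - m2) / pooled
            for j, feat in enumerate(feature_columns):
                rows.append(
                    {
                        "condition": cond,
                        "contrast": f"{g1}:{g2}",
                        "feature": feat,
                        "n1": n1,
                        "n2": n2,
                        "mean1": m1[j],
                        "mean2": m2[j],
                        "sd1": np.sqrt(v1[j]),
                        "sd2": np.sqrt(v2[j]),
                        "t": float(res.statistic[j]),
                        "nu": float(res.df[j]),
                        "p": float(res.pvalue[j]),
                        "d": float(d[j]),
                    }
                )
    return pd.DataFrame(rows)


def run_contrasts(
    features: pd.DataFrame,
    feature_columns: list[str],
    contrasts: list[tuple[str, str]] | None = None,
    conditions: list[str] | None = None,
    family: str = "class",
) -> pd.DataFrame:
    """Welch t / Cohen's d / BH-FDR for every condition x contrast x feature.

    ``features`` is a long table with ``group`` and ``condition`` metadata
    columns plus the feature columns.  ``family`` declares the BH grouping:
    ``"class"`` adjusts within condition x contrast x feature class (the
    default: e.g. the 21 inter-network tests form one family), ``"all"``
    adjusts within condition x contrast.
    """
    from .metrics import feature_class  # local import to avoid cycle

    contrasts = list(contrasts) if contrasts is not None else list(DEFAULT_CONTRASTS)
    if conditions is None:
        conditions = list(dict.fromkeys(features["condition"]))
    out = _contrast_frame(features, list(feature_columns), contrasts, list(conditions))
    if family == "class":
        out["family"] = [
            f"{c}|{k}|{feature_class(f)}"
            for c, k, f in zip(out["condition"], out["contrast"], out["feature"])
        ]
    elif family == "all":
        out["family"] = [f"{c}|{k}" for c, k in zip(out["condition"], out["contrast"])]
    else:
        raise ValidationError(f"unknown family rule {family!r}")
    out["q"] = np.nan
    for _, idx in out.groupby("family").groups.items():
        out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    return out.drop(columns="family")


def nodal_contrasts(
    nodal: pd.DataFrame,
    roi_columns: list[str],
    contrasts: list[tuple[str, str]] | None = None,
    conditions: list[str] | None = None,
) -> pd.DataFrame:
    """Per-ROI contrasts; the BH family is all ROIs within condition x contrast."""
    return run_contrasts(nodal, roi_columns, contrasts, conditions, family="all")


def anova_eta(groups: list[GroupSummary]) -> tuple[float, int, int, float]:
    """One-way ANOVA F and partial eta squared from group summary statistics.

    Returns (F, df_between, df_within, eta_p_squared) where
    eta_p^2 = SSB / (SSB + SSW).
    """
    if len(groups) < 2:
        raise ValidationError("anova_eta needs at least 2 groups")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    sd = np.array([g.sd for g in groups], dtype=float)
    grand = float((n * m).sum() / n.sum())
    ssb = float((n * (m - grand) ** 2).sum())
    ssw = float(((n - 1) * sd**2).sum())
    if ssb == 0 and ssw == 0:
        raise ValidationError("ANOVA undefined: no between- or within-group variability")
    df1 = len(groups) - 1
    df2 = int(n.sum()) - len(groups)
    f = (ssb / df1) / (ssw / df2) if ssw > 0 else np.inf
    eta = ssb / (ssb + ssw)
    return float(f), df1, df2, float(eta)


def fisher_exact_2x2(table: np.ndarray | list[list[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Sums hypergeometric probabilities no larger than that of the observed
    table.  Zero margins are rejected (the test is undefined).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValidationError("fisher_exact_2x2 needs a 2x2 table of non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("fisher_exact_2x2 undefined with a zero margin")
    return float(sps.fisher_exact(t.astype(int), alternative="two-sided")[1])
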