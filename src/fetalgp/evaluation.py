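"""ROC analysis and descriptive group comparisons.

The ROC is the empirical curve over all unique score thresholds; the area
under it (trapezoidal rule) equals the Mann–Whitney U statistic between the
two classes divided by n_pos·n_neg, ties counted half.  The 95% confidence
interval for the AUC uses the DeLong structural-components variance.
Detection rates at fixed false-positive rates (5% and 10%) use the
conservative step-function convention — the sensitivity at the largest
empirical threshold whose FPR does not exceed the target — with a linearly
interpolated variant available behind a flag for sensitivity analysis.

Descriptive comparisons follow the clinical-table convention: continuous
variables by the (tie-corrected, normal-approximation) Mann–Whitney test with
mean (SD) and median (IQR) summaries; binary/categorical variables by the
Pearson chi-square test without continuity correction (Fisher's exact test
available behind a flag for small cells), summarised as N (%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact, mannwhitneyu
from sklearn.metrics import roc_curve

__all__ = [
    "RocSummary",
    "GroupComparison",
    "roc",
    "auc_ci",
    "dr_at_fpr",
    "compare_groups",
    "comparisons_to_frame",
]


@dataclass
class RocSummary:
    """Empirical ROC with AUC, DeLong CI, and fixed-FPR detection rates."""

    auc: float
    auc_ci95: tuple[float, float]
    dr_at_fpr5: float
    dr_at_fpr10: float
    n_pos: int
    n_neg: int
    curve_points: np.ndarray  # (k, 3) columns: threshold, fpr, tpr
    ci_degenerate: bool = False

    @property
    def fpr(self) -> np.ndarray:
        return self.curve_points[:, 1]

    @property
    def tpr(self) -> np.ndarray:
        return self.curve_points[:, 2]


def _delong_auc_var(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from the two score samples."""
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float)
    psi[diff == 0] = 0.5
    v10 = psi.mean(axis=1)  # per-positive structural components
    v01 = psi.mean(axis=0)
    auc = float(psi.mean())
    s10 = float(np.var(v10, ddof=1))
    s01 = float(np.var(v01, ddof=1))
    return auc, s10 / len(pos) + s01 / len(neg)


def roc(scores, labels, direction: str = "higher_risk", with_ci: bool = True) -> RocSummary:
    """Empirical ROC of ``scores`` against boolean ``labels``.

    ``direction="lower_risk"`` negates the scores first (for inverse-risk
    markers such as MCA PI MoM, CPR MoM, EFW centiles, %ExFW3t and maternal
    height, whose low values indicate risk).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    if direction not in ("higher_risk", "lower_risk"):
        raise ValueError(f"unknown direction {direction!r}")
    if direction == "lower_risk":
        s = -s
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")

    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    points = np.column_stack([thr, fpr, tpr])

    ci: tuple[float, float] = (float("nan"), float("nan"))
    degenerate = False
    if with_ci and n_pos >= 2 and n_neg >= 2:
        auc_d, var = _delong_auc_var(s[y], s[~y])
        if auc_d in (0.0, 1.0) or var == 0.0:
            ci = (auc_d, auc_d)
            degenerate = True
        else:
            half = 1.959964 * math.sqrt(var)
            ci = (max(0.0, auc_d - half), min(1.0, auc_d + half))

    summary = RocSummary(
        auc=auc,
        auc_ci95=ci,
        dr_at_fpr5=float("nan"),
        dr_at_fpr10=float("nan"),
        n_pos=n_pos,
        n_neg=n_neg,
        curve_points=points,
        ci_degenerate=degenerate,
    )
    summary.dr_at_fpr5 = dr_at_fpr(summary, 0.05)
    summary.dr_at_fpr10 = dr_at_fpr(summary, 0.10)
    return summary


def auc_ci(scores, labels, direction: str = "higher_risk") -> tuple[float, float]:
    """DeLong 95% interval for the AUC, clipped to [0, 1].

    Requires at least two subjects in each class; a degenerate AUC (0 or 1)
    collapses the interval to a point (flagged on :class:`RocSummary` when
    computed through :func:`roc`).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if direction == "lower_risk":
        s = -s
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("DeLong interval needs n_pos >= 2 and n_neg >= 2")
    auc, var = _delong_auc_var(s[y], s[~y])
    if var == 0.0:
        return (auc, auc)
    half = 1.959964 * math.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def dr_at_fpr(summary: RocSummary, fpr_target: float, interpolate: bool = False) -> float:
    """Detection rate (%) at a fixed false-positive rate.

    Step-function convention: the TPR at the largest empirical threshold whose
    FPR ≤ target.  ``interpolate=True`` instead interpolates the curve
    linearly at exactly the target FPR.
    """
    if not 0.0 <= fpr_target <= 1.0:
        raise ValueError(f"fpr target must be in [0, 1], got {fpr_target}")
    fpr, tpr = summary.fpr, summary.tpr
    if interpolate:
        return float(np.interp(fpr_target, fpr, tpr)) * 100.0
    mask = fpr <= fpr_target + 1e-12
    return float(tpr[mask].max()) * 100.0 if mask.any() else 0.0


@dataclass
class GroupComparison:
    """One row of the descriptive between-group table."""

    variable: str
    kind: str  # "continuous" | "categorical"
    summary_all: str
    summary_no_ifc: str
    summary_ifc: str
    test: str
    statistic: float
    p_value: float


def _cont_summary(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{np.mean(x):.2f} ({np.std(x, ddof=1):.2f}); {med:.2f} ({q1:.2f}, {q3:.2f})"


def _cat_summary(x: np.ndarray) -> str:
    n = int(np.sum(x))
    return f"{n} ({100.0 * n / len(x):.1f}%)"


def compare_groups(
    df: pd.DataFrame,
    continuous: list[str] | tuple[str, ...] = (),
    categorical: list[str] | tuple[str, ...] = (),
    outcome: str = "ifc",
    fisher: bool = False,
) -> list[GroupComparison]:
    """Between-group descriptive table: Mann–Whitney / chi-square per variable.

    All-missing variables are skipped (recorded as a comparison with
    ``test="skipped"`` and p = NaN rather than silently dropped).
    """
    y = df[outcome].to_numpy(dtype=int).astype(bool)
    out: list[GroupComparison] = []
    for var in continuous:
        col = df[var].to_numpy(dtype=float)
        ok = np.isfinite(col)
        if not ok.any() or len(np.unique(col[ok])) < 2:
            out.append(
                GroupComparison(var, "continuous", "-", "-", "-", "skipped", float("nan"), float("nan"))
            )
            continue
        x0, x1 = col[ok & ~y], col[ok & y]
        stat, p = mannwhitneyu(x0, x1, alternative="two-sided", method="asymptotic")
        out.append(
            GroupComparison(
                variable=var,
                kind="continuous",
                summary_all=_cont_summary(col[ok]),
                summary_no_ifc=_cont_summary(x0),
                summary_ifc=_cont_summary(x1),
                test="mann_whitney",
                statistic=float(stat),
                p_value=float(p),
            )
        )
    for var in categorical:
        col = df[var].to_numpy(dtype=float)
        ok = np.isfinite(col)
        if not ok.any():
            out.append(
                GroupComparison(var, "categorical", "-", "-", "-", "skipped", float("nan"), float("nan"))
            )
            continue
        x = col[ok].astype(int)
        yy = y[ok]
        table = pd.crosstab(x, yy)
        if table.shape[0] < 2 or table.shape[1] < 2:
            # no variation in variable or outcome: identical proportions
            out.append(
                GroupComparison(
                    var, "categorical", _cat_summary(x), _cat_summary(x[~yy]), _cat_summary(x[yy]),
                    "chi_square", 0.0, 1.0,
                )
            )
            continue
        if fisher and table.shape == (2, 2):
            stat, p = fisher_exact(table.to_numpy())
            test = "fisher_exact"
        else:
            stat, p, _, _ = chi2_contingency(table.to_numpy(), correction=False)
            test = "chi_square"
        out.append(
            GroupComparison(
                variable=var,
                kind="categorical",
                summary_all=_cat_summary(x),
                summary_no_ifc=_cat_summary(x[~yy]),
                summary_ifc=_cat_summary(x[yy]),
                test=test,
                statistic=float(stat),
                p_value=float(p),
            )
        )
    return out


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [c.variable for c in comparisons],
            "kind": [c.kind for c in comparisons],
            "all": [c.summary_all for c in comparisons],
            "no_ifc": [c.summary_no_ifc for c in comparisons],
            "ifc": [c.summary_ifc for c in comparisons],
            "test": [c.test for c in comparisons],
            "statistic": [c.statistic for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
        }
    )
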