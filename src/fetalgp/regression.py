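"""Univariable screen and predefined multivariable logistic models.

Every candidate predictor is first fitted alone against the binary
intrapartum-fetal-compromise outcome; the significant set is then combined
into eight predefined multivariable models, each anchored on a cerebral
Doppler term (MCA PI MoM or CPR MoM), optionally adding a fetal-weight term
(local EFW centile or the growth-potential percentage) and maternal height.
Models are compared by the Akaike information criterion (AIC = 2k − 2·logL,
lower is better, a difference of ≥ 2 units treated as meaningful) and by the
area under the ROC curve.

Maximum-likelihood estimation is delegated to ``statsmodels``' Newton/IRLS
logistic fitter; Wald standard errors come from the observed information
matrix, and 95% confidence intervals for odds ratios are
exp(beta ± 1.959964·SE).  Predictors enter untransformed (per-unit odds
ratios); missing data are handled complete-case per model with the dropped
count recorded; no multiple-testing correction is applied in the screen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .cohort import Cohort
from .evaluation import RocSummary, roc

__all__ = [
    "Z975",
    "SEPARATION_BETA",
    "ModelSpec",
    "LogisticFit",
    "fit_logistic",
    "odds_ratio",
    "univariable_screen",
    "predefined_models",
    "rank_models_by_aic",
]

Z975 = 1.959964
#: |beta| beyond which a monotone-likelihood fit is flagged as separated.
SEPARATION_BETA = 15.0


@dataclass(frozen=True)
class ModelSpec:
    """A named logistic model: ordered predictor column names."""

    name: str
    predictors: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("model needs at least one predictor")
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError(f"duplicate predictors in {self.name!r}")


@dataclass
class LogisticFit:
    """One fitted logistic model with Wald inference and AIC."""

    model: ModelSpec
    intercept: float
    beta: dict[str, float]
    se: dict[str, float]
    or_: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    p_wald: dict[str, float]
    loglik: float
    loglik_null: float
    aic: float
    n: int
    n_events: int
    n_dropped: int
    converged: bool
    p_model: float
    roc: RocSummary | None = None

    @property
    def n_params(self) -> int:
        """Estimated parameters, intercept included."""
        return len(self.beta) + 1

    @property
    def auc(self) -> float:
        return self.roc.auc if self.roc is not None else float("nan")


def _safe_exp(x: float) -> float:
    """exp that saturates to inf instead of raising on diverged (separated) fits."""
    try:
        return math.exp(x)
    except OverflowError:
        return float("inf")


def odds_ratio(beta: float) -> float:
    """Per-unit odds ratio, exp(beta)."""
    if not math.isfinite(beta):
        raise ValueError(f"beta must be finite, got {beta!r}")
    return math.exp(beta)


def _as_frame(cohort) -> pd.DataFrame:
    return cohort.data if isinstance(cohort, Cohort) else cohort


def fit_logistic(
    cohort,
    spec: ModelSpec,
    outcome: str = "ifc",
    attach_roc: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of ``spec`` on the cohort.

    Complete-case per model; at least one event and one non-event required;
    a constant predictor raises.  Perfect separation (monotone likelihood,
    diverging coefficients) yields a fit flagged ``converged=False`` rather
    than a silent failure.
    """
    df = _as_frame(cohort)
    missing_cols = [c for c in (*spec.predictors, outcome) if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort lacks columns {missing_cols} for model {spec.name!r}")
    sub = df[[outcome, *spec.predictors]].dropna()
    n_dropped = len(df) - len(sub)
    y = sub[outcome].to_numpy(dtype=float)
    if not ((y == 0) | (y == 1)).all():
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    n_events = int(y.sum())
    if n_events == 0 or n_events == len(y):
        raise ValueError(f"model {spec.name!r}: need at least one event and one non-event")
    X = sub[list(spec.predictors)].to_numpy(dtype=float)
    const_cols = [p for p, col in zip(spec.predictors, X.T) if np.ptp(col) == 0]
    if const_cols:
        raise ValueError(f"model {spec.name!r}: constant predictor(s) {const_cols}")

    exog = sm.add_constant(X, has_constant="add")
    logit = sm.Logit(y, exog)
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = logit.fit(disp=0, maxiter=100, warn_convergence=False)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        res = None
        separated = True

    names = list(spec.predictors)
    if res is None:
        nan = float("nan")
        return LogisticFit(
            model=spec,
            intercept=nan,
            beta={p: nan for p in names},
            se={p: nan for p in names},
            or_={p: nan for p in names},
            ci95={p: (nan, nan) for p in names},
            p_wald={p: nan for p in names},
            loglik=nan,
            loglik_null=nan,
            aic=nan,
            n=len(y),
            n_events=n_events,
            n_dropped=n_dropped,
            converged=False,
            p_model=nan,
        )

    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    converged = bool(res.mle_retvals.get("converged", False)) and not separated
    if np.max(np.abs(params)) > SEPARATION_BETA and spec.predictors != ():
        # monotone likelihood / quasi-separation: estimates diverge
        scale = np.nanmax(np.abs(params[1:])) if len(params) > 1 else abs(params[0])
        if scale > SEPARATION_BETA:
            converged = False

    beta = dict(zip(names, params[1:]))
    se = dict(zip(names, bse[1:]))
    k = len(params)
    loglik = float(res.llf)
    aic = 2.0 * k - 2.0 * loglik
    lr = 2.0 * (loglik - float(res.llnull))
    fit = LogisticFit(
        model=spec,
        intercept=float(params[0]),
        beta=beta,
        se=se,
        or_={p: _safe_exp(b) for p, b in beta.items()},
        ci95={
            p: (_safe_exp(beta[p] - Z975 * se[p]), _safe_exp(beta[p] + Z975 * se[p]))
            for p in names
        },
        p_wald=dict(zip(names, np.asarray(res.pvalues, dtype=float)[1:])),
        loglik=loglik,
        loglik_null=float(res.llnull),
        aic=aic,
        n=len(y),
        n_events=n_events,
        n_dropped=n_dropped,
        converged=converged,
        p_model=float(chi2.sf(max(lr, 0.0), df=len(names))),
    )
    if attach_roc:
        fit.roc = roc(np.asarray(res.predict(), dtype=float), y.astype(bool))
    return fit


def univariable_screen(
    cohort,
    candidate_columns,
    outcome: str = "ifc",
) -> tuple[list[LogisticFit], dict[str, str]]:
    """One single-predictor fit per candidate, in the given order.

    Per-candidate failures (constant column, missing column, ...) are
    recorded in the returned error map and the screen continues.
    """
    fits: list[LogisticFit] = []
    errors: dict[str, str] = {}
    for cand in candidate_columns:
        spec = cand if isinstance(cand, ModelSpec) else ModelSpec(name=str(cand), predictors=(str(cand),))
        try:
            fits.append(fit_logistic(cohort, spec, outcome=outcome))
        except ValueError as exc:
            errors[spec.name] = str(exc)
    return fits, errors


#: Human-readable labels for the univariable screen, in report order.
UNIVARIABLE_SET: tuple[tuple[str, str], ...] = (
    ("Maternal age", "maternal_age"),
    ("Nulliparity", "nulliparity"),
    ("Maternal height", "maternal_height_cm"),
    ("Maternal weight", "maternal_weight_kg"),
    ("Smoking", "smoking"),
    ("Fetal sex", "male_sex"),
    ("MCA PI MoM", "mca_pi_mom"),
    ("UA PI MoM", "ua_pi_mom"),
    ("CPR MoM", "cpr_mom"),
    ("EFW centiles (local population)", "efwc_local"),
    ("EFW centiles (Intergrowth 21st)", "efwc_ig"),
    ("%ExFW3t", "pct_exfw3t"),
)


def predefined_models() -> tuple[list[ModelSpec], list[ModelSpec]]:
    """The eight predefined multivariable models and the univariable set.

    Each multivariable model pairs a cerebral Doppler anchor (MCA PI MoM for
    models 1–4, CPR MoM for 5–8) with a fetal-weight term (local EFW centile
    or %ExFW3t), with and without maternal height.
    """
    mca, cpr = "mca_pi_mom", "cpr_mom"
    efwc, pct, height = "efwc_local", "pct_exfw3t", "maternal_height_cm"
    multivariable = [
        ModelSpec("Model 1: MCA PI MoM + EFWc (local)", (mca, efwc)),
        ModelSpec("Model 2: MCA PI MoM + %ExFW3t", (mca, pct)),
        ModelSpec("Model 3: MCA PI MoM + EFWc (local) + maternal height", (mca, efwc, height)),
        ModelSpec("Model 4: MCA PI MoM + %ExFW3t + maternal height", (mca, pct, height)),
        ModelSpec("Model 5: CPR MoM + EFWc (local)", (cpr, efwc)),
        ModelSpec("Model 6: CPR MoM + %ExFW3t", (cpr, pct)),
        ModelSpec("Model 7: CPR MoM + EFWc (local) + maternal height", (cpr, efwc, height)),
        ModelSpec("Model 8: CPR MoM + %ExFW3t + maternal height", (cpr, pct, height)),
    ]
    univariable = [ModelSpec(label, (col,)) for label, col in UNIVARIABLE_SET]
    return multivariable, univariable


def rank_models_by_aic(fits: list[LogisticFit]) -> pd.DataFrame:
    """Rank fits ascending by AIC; flag adjacent pairs separated by >= 2 units.

    Ties are broken by higher AUC, then by fewer parameters.  All fits must
    come from the same cohort/outcome, hence share n (AIC is not comparable
    across differing sample sizes).
    """
    if not fits:
        raise ValueError("no fits to rank")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError(f"fits on differing n {sorted(ns)}: AIC values are not comparable")
    ordered = sorted(fits, key=lambda f: (f.aic, -(-1e9 if math.isnan(f.auc) else f.auc), f.n_params))
    rows = []
    prev_aic = None
    for rank, f in enumerate(ordered, start=1):
        delta = float("nan") if prev_aic is None else f.aic - prev_aic
        rows.append(
            {
                "rank": rank,
                "model": f.model.name,
                "n_params": f.n_params,
                "auc": f.auc,
                "aic": f.aic,
                "dr_fpr5": f.roc.dr_at_fpr5 if f.roc is not None else float("nan"),
                "dr_fpr10": f.roc.dr_at_fpr10 if f.roc is not None else float("nan"),
                "p_model": f.p_model,
                "delta_aic_prev": delta,
                "distinguishable_from_prev": bool(delta >= 2.0) if prev_aic is not None else False,
            }
        )
        prev_aic = f.aic
    return pd.DataFrame(rows)
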