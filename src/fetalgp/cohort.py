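"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

Two generators are provided.

``generate_group_conditional`` draws the outcome labels first (a fixed number
of intrapartum-fetal-compromise events, 52 of 777 by default, so the emulated
prevalence is exact in sample size) and then draws each covariate from a
group-conditional law: log-normal for MoM-type quantities and the
growth-potential percentage (positive, mildly right-skewed), normal for
maternal height.  The MCA and UA pulsatility-index MoMs are drawn jointly
through a Gaussian copula at a configurable rank correlation (default −0.2,
a mild "brain-sparing" redistribution assumption, not an observed value); the
cerebroplacental ratio is *derived* as MCA PI / UA PI at the raw-PI level.
The 20-week EFW MoM is drawn from the same law in both groups, encoding the
study design's null: both groups start from the same growth potential.
Raw scans are back-solved from the drawn MoMs through the reference curves so
that the entire downstream pipeline — not just the summary statistics — can
run on the generated data.

``generate_from_logistic`` draws covariates from a pooled law and the outcome
from a Bernoulli with logistic link at user-supplied coefficients; it exists
for parameter-recovery simulations against published model coefficients.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .curves import CurveSet

__all__ = [
    "Law",
    "CohortSpec",
    "Cohort",
    "GenerativeModel",
    "REFERENCE_RISK_MODEL",
    "default_cohort_spec",
    "generate_group_conditional",
    "generate_from_logistic",
    "pooled_covariate_law",
    "permute_labels",
]


@dataclass(frozen=True)
class Law:
    """A (family, mean, sd) sampling law on the natural scale.

    ``lognormal`` laws are parameterised by their natural-scale mean and SD
    (converted internally to log-scale mu/sigma), so spec values copied from a
    "mean (SD)" table row are matched exactly in expectation.  ``sd == 0``
    degenerates to the constant ``mean``.
    """

    family: str  # "normal" | "lognormal"
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown law family {self.family!r}")
        if self.sd < 0:
            raise ValueError(f"scale must be non-negative, got {self.sd}")
        if self.family == "lognormal" and self.mean <= 0:
            raise ValueError("lognormal law needs a positive mean")

    def _log_params(self) -> tuple[float, float]:
        sigma2 = math.log1p((self.sd / self.mean) ** 2)
        mu = math.log(self.mean) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)

    def from_z(self, z: np.ndarray) -> np.ndarray:
        """Transform standard-normal draws (copula margin)."""
        z = np.asarray(z, dtype=float)
        if self.sd == 0:
            return np.full_like(z, self.mean)
        if self.family == "normal":
            return self.mean + self.sd * z
        mu, sigma = self._log_params()
        return np.exp(mu + sigma * z)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.from_z(rng.standard_normal(n))


GROUPS = ("no_ifc", "ifc")

# Group-conditional laws emulating the study cohort's descriptive margins.
_DEFAULT_LAWS: dict[str, dict[str, Law]] = {
    "no_ifc": {
        "mca_pi_mom": Law("lognormal", 0.97, 0.22),
        "ua_pi_mom": Law("lognormal", 1.09, 0.24),
        "maternal_height_cm": Law("normal", 162.9, 6.0),
        "pct_exfw3t": Law("lognormal", 97.52, 13.5),
        "maternal_age": Law("normal", 32.5, 5.2),
        "maternal_weight_kg": Law("lognormal", 62.3, 11.7),
        "ga3t_weeks": Law("normal", 39.0, 1.2),
        "interval_days": Law("normal", 6.5, 3.9),
    },
    "ifc": {
        "mca_pi_mom": Law("lognormal", 0.81, 0.21),
        "ua_pi_mom": Law("lognormal", 1.19, 0.33),
        "maternal_height_cm": Law("normal", 160.2, 7.8),
        "pct_exfw3t": Law("lognormal", 89.9, 13.0),
        "maternal_age": Law("normal", 33.6, 4.3),
        "maternal_weight_kg": Law("lognormal", 63.0, 12.6),
        "ga3t_weeks": Law("normal", 38.5, 2.1),
        "interval_days": Law("normal", 5.2, 4.5),
    },
}

# Bernoulli margins for the categorical nuisance columns, per group.
_DEFAULT_PROBS: dict[str, dict[str, float]] = {
    "no_ifc": {
        "nulliparity": 0.521,
        "smoking": 0.145,
        "male_sex": 0.495,
        "induction": 0.480,
        "neonatal_ward": 0.037,
    },
    "ifc": {
        "nulliparity": 0.635,
        "smoking": 0.096,
        "male_sex": 0.577,
        "induction": 0.865,
        "neonatal_ward": 0.21,
    },
}


@dataclass(frozen=True)
class CohortSpec:
    """Generator configuration; defaults emulate the reference cohort (777/52)."""

    n_total: int = 777
    n_ifc: int = 52
    laws: dict[str, dict[str, Law]] = field(default_factory=lambda: _DEFAULT_LAWS)
    probs: dict[str, dict[str, float]] = field(default_factory=lambda: _DEFAULT_PROBS)
    efw20_mom_law: Law = Law("lognormal", 0.97, 0.11)  # shared across groups
    rank_corr_mca_ua: float = -0.2

    def __post_init__(self) -> None:
        if not 0 < self.n_ifc < self.n_total:
            raise ValueError(f"need 0 < n_ifc < n_total, got {self.n_ifc}/{self.n_total}")
        if not -1.0 < self.rank_corr_mca_ua < 1.0:
            raise ValueError(
                f"rank correlation must lie strictly inside (-1, 1), got {self.rank_corr_mca_ua}"
            )
        for g in GROUPS:
            if g not in self.laws:
                raise ValueError(f"missing laws for group {g!r}")

    def to_jsonable(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_ifc": self.n_ifc,
            "laws": {g: {k: asdict(v) for k, v in d.items()} for g, d in self.laws.items()},
            "probs": self.probs,
            "efw20_mom_law": asdict(self.efw20_mom_law),
            "rank_corr_mca_ua": self.rank_corr_mca_ua,
        }

    @classmethod
    def from_jsonable(cls, obj: dict) -> "CohortSpec":
        kwargs: dict = {}
        if "n_total" in obj:
            kwargs["n_total"] = int(obj["n_total"])
        if "n_ifc" in obj:
            kwargs["n_ifc"] = int(obj["n_ifc"])
        if "laws" in obj:
            kwargs["laws"] = {
                g: {k: Law(**v) for k, v in d.items()} for g, d in obj["laws"].items()
            }
        if "probs" in obj:
            kwargs["probs"] = obj["probs"]
        if "efw20_mom_law" in obj:
            kwargs["efw20_mom_law"] = Law(**obj["efw20_mom_law"])
        if "rank_corr_mca_ua" in obj:
            kwargs["rank_corr_mca_ua"] = float(obj["rank_corr_mca_ua"])
        return cls(**kwargs)


def default_cohort_spec() -> CohortSpec:
    return CohortSpec()


@dataclass
class Cohort:
    """A cohort table plus its provenance.

    ``latents`` holds the generator's drawn MoM-level values (not part of the
    CSV contract); it is used to verify that re-assessing the back-solved raw
    scans recovers the drawn quantities.
    """

    data: pd.DataFrame
    provenance: dict
    latents: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data["ifc"].sum())


@dataclass(frozen=True)
class GenerativeModel:
    """Logistic data-generating truth: P(event) = expit(intercept + beta . x)."""

    intercept: float
    beta: dict[str, float]

    def __post_init__(self) -> None:
        values = [self.intercept, *self.beta.values()]
        if not all(math.isfinite(v) for v in values):
            raise ValueError("model coefficients must be finite")

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(df), self.intercept, dtype=float)
        for name, b in self.beta.items():
            eta += b * df[name].to_numpy(dtype=float)
        return eta


#: Published three-term clinical risk model for intrapartum fetal compromise
#: (cerebral Doppler MoM + growth-potential percentage + maternal height),
#: used as a data-generating truth in parameter-recovery simulations.
REFERENCE_RISK_MODEL = GenerativeModel(
    intercept=13.32,
    beta={
        "mca_pi_mom": -3.533,
        "pct_exfw3t": -0.02645,
        "maternal_height_cm": -0.06240,
    },
)


def _rank_to_pearson(rho_s: float) -> float:
    # Gaussian-copula identity: Spearman rho -> Pearson rho of the latent normals
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def generate_group_conditional(
    spec: CohortSpec | None = None,
    curves: CurveSet | None = None,
    seed: int = 0,
) -> Cohort:
    """Draw a full synthetic cohort; deterministic given (spec, seed)."""
    spec = spec if spec is not None else default_cohort_spec()
    curves = curves if curves is not None else CurveSet.default()
    rng = np.random.default_rng(seed)
    n = spec.n_total

    ifc = np.zeros(n, dtype=int)
    ifc[: spec.n_ifc] = 1
    ifc = ifc[rng.permutation(n)]

    rho = _rank_to_pearson(spec.rank_corr_mca_ua)
    cols: dict[str, np.ndarray] = {c: np.empty(n, dtype=float) for c in ()}

    def alloc(name, dtype=float):
        cols[name] = np.empty(n, dtype=dtype)

    for c in (
        "maternal_age",
        "maternal_height_cm",
        "maternal_weight_kg",
        "ga3t_weeks",
        "interval_days",
        "mca_mom_true",
        "ua_mom_true",
        "pct_true",
        "cord_ph",
    ):
        alloc(c)
    for c in ("nulliparity", "smoking", "male_sex", "induction", "neonatal_ward", "parity", "apgar5"):
        alloc(c, dtype=int)

    for group, flag in (("no_ifc", 0), ("ifc", 1)):
        mask = ifc == flag
        m = int(mask.sum())
        laws = spec.laws[group]
        probs = spec.probs[group]

        # joint MCA/UA draw through the Gaussian copula
        z1 = rng.standard_normal(m)
        z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal(m)
        cols["mca_mom_true"][mask] = laws["mca_pi_mom"].from_z(z1)
        cols["ua_mom_true"][mask] = laws["ua_pi_mom"].from_z(z2)
        cols["pct_true"][mask] = laws["pct_exfw3t"].sample(rng, m)
        cols["maternal_height_cm"][mask] = laws["maternal_height_cm"].sample(rng, m)
        cols["maternal_age"][mask] = np.clip(laws["maternal_age"].sample(rng, m), 16.0, 52.0)
        cols["maternal_weight_kg"][mask] = np.clip(
            laws["maternal_weight_kg"].sample(rng, m), 38.0, 150.0
        )
        cols["ga3t_weeks"][mask] = np.clip(
            laws["ga3t_weeks"].sample(rng, m), 30.0, 40.0 + 6.0 / 7.0
        )
        cols["interval_days"][mask] = np.clip(
            np.rint(laws["interval_days"].sample(rng, m)), 0, 14
        )
        for name in ("nulliparity", "smoking", "male_sex", "induction", "neonatal_ward"):
            cols[name][mask] = (rng.random(m) < probs[name]).astype(int)
        # cord pH: lower in compromised labours
        ph_mean, ph_sd = (7.24, 0.07) if flag == 0 else (7.16, 0.10)
        cols["cord_ph"][mask] = np.round(np.clip(rng.normal(ph_mean, ph_sd, m), 6.80, 7.45), 2)
        apgar_low_p = 0.004 if flag == 0 else 0.02
        low = rng.random(m) < apgar_low_p
        cols["apgar5"][mask] = np.where(low, rng.integers(3, 7, m), rng.integers(8, 11, m))

    cols["parity"] = np.where(
        cols["nulliparity"] == 1, 0, 1 + rng.poisson(0.4, n)
    ).astype(int)

    # back-solve raw scans from the drawn MoM-level quantities
    efw20_mom = spec.efw20_mom_law.sample(rng, n)  # same law for both groups
    ga20 = np.clip(rng.normal(20.0, 0.35, n), 19.05, 20.95)
    efw20_g = efw20_mom * np.asarray(curves.efw.median(ga20), dtype=float)
    ga3t = cols["ga3t_weeks"]
    exfw3t = efw20_mom * np.asarray(curves.efw.median(ga3t), dtype=float)
    efw3t_g = cols["pct_true"] / 100.0 * exfw3t
    ua_pi = cols["ua_mom_true"] * np.asarray(curves.ua.median(ga3t), dtype=float)
    mca_pi = cols["mca_mom_true"] * np.asarray(curves.mca.median(ga3t), dtype=float)
    ga_delivery = np.minimum(ga3t + cols["interval_days"] / 7.0, 43.0)
    birthweight_g = np.rint(efw3t_g * np.exp(rng.normal(0.02, 0.05, n))).astype(int)

    height_m = cols["maternal_height_cm"] / 100.0
    data = pd.DataFrame(
        {
            "subject_id": np.arange(1, n + 1),
            "ifc": ifc,
            "maternal_age": np.round(cols["maternal_age"], 1),
            "maternal_height_cm": np.round(cols["maternal_height_cm"], 1),
            "maternal_weight_kg": np.round(cols["maternal_weight_kg"], 1),
            "bmi": np.round(
                np.round(cols["maternal_weight_kg"], 1) / (np.round(cols["maternal_height_cm"], 1) / 100.0) ** 2,
                1,
            ),
            "parity": cols["parity"],
            "nulliparity": cols["nulliparity"],
            "smoking": cols["smoking"],
            "male_sex": cols["male_sex"],
            "ga20_weeks": ga20,
            "efw20_g": efw20_g,
            "ga3t_weeks": ga3t,
            "efw3t_g": efw3t_g,
            "ua_pi": ua_pi,
            "mca_pi": mca_pi,
            "induction": cols["induction"],
            "interval_days": cols["interval_days"].astype(int),
            "ga_delivery_weeks": ga_delivery,
            "birthweight_g": birthweight_g,
            "apgar5": cols["apgar5"],
            "cord_ph": cols["cord_ph"],
            "neonatal_ward": cols["neonatal_ward"],
        }
    )
    latents = pd.DataFrame(
        {
            "efw20_mom": efw20_mom,
            "pct_exfw3t": cols["pct_true"],
            "ua_pi_mom": cols["ua_mom_true"],
            "mca_pi_mom": cols["mca_mom_true"],
            "exfw3t_g": exfw3t,
        }
    )
    provenance = {
        "generator": "group_conditional",
        "seed": int(seed),
        "spec": spec.to_jsonable(),
        "curves": curves.provenance,
    }
    return Cohort(data=data, provenance=provenance, latents=latents)


def pooled_covariate_law(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Pooled (whole-cohort) covariate law for the reference risk model's terms."""
    return pd.DataFrame(
        {
            "mca_pi_mom": Law("lognormal", 0.97, 0.22).sample(rng, n),
            "pct_exfw3t": Law("lognormal", 97.0, 13.6).sample(rng, n),
            "maternal_height_cm": Law("normal", 162.7, 6.2).sample(rng, n),
        }
    )


def generate_from_logistic(
    model: GenerativeModel,
    covariate_law: Callable[[np.random.Generator, int], pd.DataFrame] | None = None,
    n: int = 777,
    seed: int = 0,
) -> Cohort:
    """Covariates from ``covariate_law``, outcome Bernoulli(expit(eta))."""
    covariate_law = covariate_law if covariate_law is not None else pooled_covariate_law
    rng = np.random.default_rng(seed)
    X = covariate_law(rng, n)
    missing = [c for c in model.beta if c not in X.columns]
    if missing:
        raise ValueError(f"covariate law does not produce model predictors: {missing}")
    eta = model.linear_predictor(X)
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < p).astype(int)
    data = X.copy()
    data.insert(0, "subject_id", np.arange(1, n + 1))
    data["ifc"] = y
    provenance = {
        "generator": "from_logistic",
        "seed": int(seed),
        "model": {"intercept": model.intercept, "beta": dict(model.beta)},
        "expected_prevalence": float(p.mean()),
    }
    return Cohort(data=data, provenance=provenance)


def permute_labels(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    """Shuffle the outcome labels (breaks every covariate-outcome association)."""
    data = cohort.data.copy()
    data["ifc"] = data["ifc"].to_numpy()[rng.permutation(len(data))]
    return Cohort(data=data, provenance={**cohort.provenance, "permuted": True})
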