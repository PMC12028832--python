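"""Gestational-age reference curves: medians, spreads, MoM and centile maps.

A raw measurement (estimated fetal weight, umbilical- or middle-cerebral-artery
pulsatility index, cerebroplacental ratio) is normalised to *multiples of the
median* (MoM) by dividing it by the reference median at the same gestational
age.  Centile conversion uses a log-normal model around that median:

    z = ln(value / median(GA)) / log_sd,      centile = 100 * Phi(z)

so a value sitting exactly on the median maps to the 50th centile for every
gestational age and every reference.

The module ships replaceable default curves:

* ``default_efw_curve`` — gram-scale EFW median, a log-quadratic anchored at
  (20 w, 373.5 g), (30 w, 1550 g), (40 w, 3450 g); strictly increasing over
  its valid range (a constructor-enforced property of the default).
* ``default_mca_curve`` — middle cerebral artery PI median, the quadratic
  ``printed_median_polynomial`` (single interior maximum near 29 weeks, the
  canonical cerebral-PI shape).
* ``default_ua_curve`` — umbilical artery PI median, gently decreasing with
  gestation.
* ``default_cpr_curve`` — cerebroplacental-ratio median defined as the ratio
  of the MCA and UA medians, which makes CPR MoM equal MCA MoM / UA MoM.

All curves are loadable from a JSON config (polynomial coefficients or a
monotonically interpolated knot table) so that a site-specific reference can
replace any default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Union

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.stats import norm

__all__ = [
    "GA_MIN",
    "GA_MAX",
    "CurveDomainError",
    "GestationalAge",
    "ReferenceCurve",
    "CentileReference",
    "CurveSet",
    "printed_median_polynomial",
    "median_at",
    "centile_from_value",
    "value_from_centile",
    "default_efw_curve",
    "default_ua_curve",
    "default_mca_curve",
    "default_cpr_curve",
    "default_local_reference",
    "default_intergrowth_like_reference",
    "curve_from_json",
]

GA_MIN = 12.0
GA_MAX = 43.0

#: Coefficients of the quadratic median equation shipped "as printed"
#: (constant, linear, quadratic term).  See ``printed_median_polynomial``.
PRINTED_MEDIAN_COEFFS = (-3.266164164, 0.368135209, -0.006318278)


class CurveDomainError(ValueError):
    """Raised when a curve is evaluated outside its valid gestational range."""


@dataclass(frozen=True)
class GestationalAge:
    """Gestational age in decimal weeks (e.g. 33 w + 1 d -> 33.142857...).

    Kept at full precision internally; round only for display (the clinical
    convention prints two decimals, 33.14).
    """

    weeks: float

    def __post_init__(self) -> None:
        w = float(self.weeks)
        if not math.isfinite(w) or not (GA_MIN <= w <= GA_MAX):
            raise ValueError(
                f"gestational age must be within [{GA_MIN}, {GA_MAX}] weeks, got {self.weeks!r}"
            )

    @classmethod
    def from_weeks_days(cls, weeks: int, days: int) -> "GestationalAge":
        if not 0 <= int(days) <= 6:
            raise ValueError(f"days must be in 0..6, got {days}")
        return cls(int(weeks) + int(days) / 7.0)

    def __float__(self) -> float:
        return float(self.weeks)

    @property
    def display(self) -> float:
        """Two-decimal clinical display form (33 w + 1 d -> 33.14)."""
        return round(float(self.weeks), 2)


GALike = Union[GestationalAge, float, np.ndarray]


def _as_weeks(ga: GALike) -> Union[float, np.ndarray]:
    if isinstance(ga, GestationalAge):
        return float(ga)
    arr = np.asarray(ga, dtype=float)
    return arr if arr.ndim else float(arr)


def printed_median_polynomial(ga: GALike) -> Union[float, np.ndarray]:
    """Evaluate the quadratic median equation exactly as printed.

    ``-3.266164164 + 0.368135209*GA - 0.006318278*GA**2`` over GA in [20, 41]
    decimal weeks, with no rescaling.

    Note: the equation's magnitude (~1.3-2.1 over its range, peaking near
    29 weeks) is that of a Doppler pulsatility-index median, not of a
    gram-scale fetal weight; it is therefore shipped verbatim here and the
    pipeline's EFW median is a separate, configurable gram-scale curve
    (see ``default_efw_curve``).
    """
    g = _as_weeks(ga)
    arr = np.asarray(g, dtype=float)
    if np.any(arr < 20.0) or np.any(arr > 41.0):
        raise CurveDomainError(
            f"printed median polynomial is defined for GA in [20, 41] weeks, got {g!r}"
        )
    c0, c1, c2 = PRINTED_MEDIAN_COEFFS
    out = c0 + c1 * arr + c2 * arr * arr
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ReferenceCurve:
    """Gestational-age reference model: median and (log-scale) spread.

    ``median_fn`` maps decimal weeks to a strictly positive median (grams for
    EFW, dimensionless for PI indices); ``log_sd`` is the multiplicative SD on
    the log scale used for centile conversion (a constant or a callable of GA).
    Evaluation outside ``valid_range`` raises :class:`CurveDomainError`.
    """

    index_name: str
    median_fn: Callable[[np.ndarray], np.ndarray]
    log_sd: Union[float, Callable[[np.ndarray], np.ndarray]]
    valid_range: tuple[float, float]
    provenance: str = ""
    monotone: str | None = None  # optional constructor check: "increasing"/"decreasing"

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        if not (GA_MIN <= lo < hi <= GA_MAX):
            raise ValueError(f"invalid curve range {self.valid_range}")
        grid = np.linspace(lo, hi, 211)
        med = np.asarray(self.median_fn(grid), dtype=float)
        if not np.all(np.isfinite(med)) or np.any(med <= 0):
            raise ValueError(f"median of {self.index_name!r} must be finite and positive over range")
        sd = np.asarray(self._spread_arr(grid), dtype=float)
        if not np.all(np.isfinite(sd)) or np.any(sd <= 0):
            raise ValueError(f"log-sd of {self.index_name!r} must be finite and positive")
        if self.monotone == "increasing" and np.any(np.diff(med) <= 0):
            raise ValueError(f"median of {self.index_name!r} is not strictly increasing")
        if self.monotone == "decreasing" and np.any(np.diff(med) >= 0):
            raise ValueError(f"median of {self.index_name!r} is not strictly decreasing")

    def _spread_arr(self, ga: np.ndarray) -> np.ndarray:
        if callable(self.log_sd):
            return np.asarray(self.log_sd(ga), dtype=float)
        return np.full_like(np.asarray(ga, dtype=float), float(self.log_sd))

    def _check_range(self, weeks: Union[float, np.ndarray]) -> None:
        lo, hi = self.valid_range
        arr = np.asarray(weeks, dtype=float)
        if np.any(arr < lo - 1e-12) or np.any(arr > hi + 1e-12):
            raise CurveDomainError(
                f"{self.index_name} curve evaluated at GA {weeks!r}, outside [{lo}, {hi}]"
            )

    def median(self, ga: GALike) -> Union[float, np.ndarray]:
        w = _as_weeks(ga)
        self._check_range(w)
        out = np.asarray(self.median_fn(np.asarray(w, dtype=float)), dtype=float)
        return out if out.ndim else float(out)

    def spread(self, ga: GALike) -> Union[float, np.ndarray]:
        w = _as_weeks(ga)
        self._check_range(w)
        out = self._spread_arr(np.asarray(w, dtype=float))
        return out if out.ndim else float(out)


def median_at(curve: ReferenceCurve, ga: GALike) -> Union[float, np.ndarray]:
    """Reference median of ``curve`` at gestational age ``ga`` (decimal weeks)."""
    return curve.median(ga)


@dataclass(frozen=True)
class CentileReference:
    """A named EFW centile standard: 'local' or 'intergrowth_like'.

    Both are log-normal (median, log-SD) references around the same default
    gram-scale median curve; they differ only in parameterisation.  Neither
    reproduces the exact proprietary local standard or the Intergrowth-21st
    skew-normal equations — both of those are pluggable via the JSON config.
    """

    name: str
    curve: ReferenceCurve


def centile_from_value(value, ga: GALike, ref: CentileReference):
    """Centile (0, 100) of ``value`` against ``ref`` at ``ga``; median -> 50 exactly."""
    v = np.asarray(value, dtype=float)
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError(f"value must be positive and finite, got {value!r}")
    med = np.asarray(ref.curve.median(ga), dtype=float)
    sd = np.asarray(ref.curve.spread(ga), dtype=float)
    z = np.log(v / med) / sd
    out = 100.0 * norm.cdf(z)
    return out if out.ndim else float(out)


def value_from_centile(centile, ga: GALike, ref: CentileReference):
    """Inverse of :func:`centile_from_value` (used by the synthetic module)."""
    c = np.asarray(centile, dtype=float)
    if np.any(c <= 0) or np.any(c >= 100):
        raise ValueError(f"centile must lie strictly inside (0, 100), got {centile!r}")
    med = np.asarray(ref.curve.median(ga), dtype=float)
    sd = np.asarray(ref.curve.spread(ga), dtype=float)
    out = med * np.exp(norm.ppf(c / 100.0) * sd)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# shipped defaults


def _quadratic_through(points: tuple[tuple[float, float], ...], log_scale: bool) -> np.ndarray:
    """Exact quadratic (ascending coefficients) through three (ga, value) anchors."""
    ga = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if log_scale:
        y = np.log(y)
    vand = np.vander(ga, 3, increasing=True)
    return np.linalg.solve(vand, y)


_EFW_ANCHORS = ((20.0, 373.5), (30.0, 1550.0), (40.0, 3450.0))
_UA_ANCHORS = ((20.0, 1.21), (30.0, 1.00), (40.0, 0.87))


def default_efw_curve(log_sd: float = 0.11) -> ReferenceCurve:
    """Gram-scale EFW median: log-quadratic through the shipped anchors.

    Anchors: 373.5 g at 20 w (mid-trimester median consistent with the
    emulated cohort), 1550 g at 30 w, 3450 g at 40 w (realistic term median).
    Strictly increasing over [16, 42] weeks (enforced at construction).
    """
    coeffs = _quadratic_through(_EFW_ANCHORS, log_scale=True)

    def median_fn(g: np.ndarray) -> np.ndarray:
        return np.exp(coeffs[0] + coeffs[1] * g + coeffs[2] * g * g)

    return ReferenceCurve(
        index_name="EFW",
        median_fn=median_fn,
        log_sd=log_sd,
        valid_range=(16.0, 42.0),
        provenance="default log-quadratic EFW median anchored at 20/30/40 weeks "
        "(373.5/1550/3450 g)",
        monotone="increasing",
    )


def default_ua_curve(log_sd: float = 0.21) -> ReferenceCurve:
    """Umbilical-artery PI median: quadratic, strictly decreasing with gestation."""
    coeffs = _quadratic_through(_UA_ANCHORS, log_scale=False)

    def median_fn(g: np.ndarray) -> np.ndarray:
        return coeffs[0] + coeffs[1] * g + coeffs[2] * g * g

    return ReferenceCurve(
        index_name="UA_PI",
        median_fn=median_fn,
        log_sd=log_sd,
        valid_range=(20.0, 41.0),
        provenance="default UA PI median, decreasing quadratic through "
        "(20, 1.21), (30, 1.00), (40, 0.87)",
        monotone="decreasing",
    )


def default_mca_curve(log_sd: float = 0.22) -> ReferenceCurve:
    """MCA PI median: the printed quadratic (interior maximum near 29 weeks)."""
    return ReferenceCurve(
        index_name="MCA_PI",
        median_fn=lambda g: printed_median_polynomial(g),
        log_sd=log_sd,
        valid_range=(20.0, 41.0),
        provenance="default MCA PI median, quadratic peaking at 29.1 weeks "
        "(printed-coefficient curve, PI-scale)",
    )


def default_cpr_curve(
    mca: ReferenceCurve | None = None,
    ua: ReferenceCurve | None = None,
    log_sd: float = 0.28,
) -> ReferenceCurve:
    """CPR median as the ratio of the MCA and UA medians.

    With this default, CPR MoM equals MCA PI MoM / UA PI MoM identically.
    An independent CPR curve can be loaded from config instead.
    """
    mca = mca if mca is not None else default_mca_curve()
    ua = ua if ua is not None else default_ua_curve()
    lo = max(mca.valid_range[0], ua.valid_range[0])
    hi = min(mca.valid_range[1], ua.valid_range[1])

    def median_fn(g: np.ndarray) -> np.ndarray:
        return np.asarray(mca.median_fn(g), dtype=float) / np.asarray(ua.median_fn(g), dtype=float)

    return ReferenceCurve(
        index_name="CPR",
        median_fn=median_fn,
        log_sd=log_sd,
        valid_range=(lo, hi),
        provenance="default CPR median = MCA median / UA median",
    )


def default_local_reference(log_sd: float = 0.11) -> CentileReference:
    return CentileReference(name="local", curve=default_efw_curve(log_sd=log_sd))


def default_intergrowth_like_reference(log_sd: float = 0.125) -> CentileReference:
    return CentileReference(name="intergrowth_like", curve=default_efw_curve(log_sd=log_sd))


# ---------------------------------------------------------------------------
# JSON config loading


def curve_from_json(obj: dict) -> ReferenceCurve:
    """Build a curve from a JSON-style dict.

    Schema::

        {"index": "EFW", "type": "polynomial", "coefficients": [c0, c1, ...],
         "log_sd": 0.11, "range": [16, 42]}
        {"index": "UA_PI", "type": "table", "knots": [[20, 1.21], [30, 1.0], ...],
         "log_sd": 0.21, "range": [20, 41]}

    Polynomial coefficients are ascending and evaluated on the natural scale;
    table curves are interpolated monotonically in GA (PCHIP).
    """
    kind = obj.get("type")
    index = obj.get("index", "CUSTOM")
    log_sd = float(obj["log_sd"])
    lo, hi = (float(x) for x in obj["range"])
    if kind == "polynomial":
        coeffs = np.asarray(obj["coefficients"], dtype=float)

        def median_fn(g: np.ndarray) -> np.ndarray:
            return np.polynomial.polynomial.polyval(np.asarray(g, dtype=float), coeffs)

        prov = f"polynomial config curve ({len(coeffs)} coefficients)"
    elif kind == "table":
        knots = np.asarray(obj["knots"], dtype=float)
        if knots.ndim != 2 or knots.shape[1] != 2 or knots.shape[0] < 2:
            raise ValueError("table curve needs >= 2 [ga, median] knots")
        order = np.argsort(knots[:, 0])
        interp = PchipInterpolator(knots[order, 0], knots[order, 1], extrapolate=False)

        def median_fn(g: np.ndarray) -> np.ndarray:
            return interp(np.asarray(g, dtype=float))

        prov = f"table config curve ({knots.shape[0]} knots, monotone interpolation)"
    else:
        raise ValueError(f"unknown curve type {kind!r} (expected 'polynomial' or 'table')")
    return ReferenceCurve(
        index_name=index,
        median_fn=median_fn,
        log_sd=log_sd,
        valid_range=(lo, hi),
        provenance=obj.get("provenance", prov),
    )


@dataclass(frozen=True)
class CurveSet:
    """The full set of curves and centile references one analysis run uses."""

    efw: ReferenceCurve
    ua: ReferenceCurve
    mca: ReferenceCurve
    cpr: ReferenceCurve
    local_ref: CentileReference
    intergrowth_ref: CentileReference

    @classmethod
    def default(cls) -> "CurveSet":
        mca = default_mca_curve()
        ua = default_ua_curve()
        return cls(
            efw=default_efw_curve(),
            ua=ua,
            mca=mca,
            cpr=default_cpr_curve(mca=mca, ua=ua),
            local_ref=default_local_reference(),
            intergrowth_ref=default_intergrowth_like_reference(),
        )

    @classmethod
    def from_json(cls, source: Union[str, Path, dict]) -> "CurveSet":
        """Default set with any of efw/ua/mca/cpr/local/intergrowth overridden."""
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                cfg = json.load(fh)
        else:
            cfg = dict(source)
        base = cls.default()
        updates: dict = {}
        for key in ("efw", "ua", "mca", "cpr"):
            if key in cfg:
                updates[key] = curve_from_json(cfg[key])
        if "mca" in updates or "ua" in updates:
            # keep the ratio default consistent unless an explicit CPR curve is given
            if "cpr" not in cfg:
                updates["cpr"] = default_cpr_curve(
                    mca=updates.get("mca", base.mca), ua=updates.get("ua", base.ua)
                )
        if "local" in cfg:
            updates["local_ref"] = CentileReference("local", curve_from_json(cfg["local"]))
        if "intergrowth" in cfg:
            updates["intergrowth_ref"] = CentileReference(
                "intergrowth_like", curve_from_json(cfg["intergrowth"])
            )
        return replace(base, **updates)

    @property
    def provenance(self) -> dict[str, str]:
        return {
            "efw": self.efw.provenance,
            "ua": self.ua.provenance,
            "mca": self.mca.provenance,
            "cpr": self.cpr.provenance,
            "local": self.local_ref.curve.provenance,
            "intergrowth": self.intergrowth_ref.curve.provenance,
        }
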