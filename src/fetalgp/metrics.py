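"""Per-subject derived quantities: EFW, MoM, growth-potential extrapolation.

The central statistic is the *percentage of expected fetal weight achieved in
the third trimester*.  The 20-week estimated fetal weight (EFW), expressed as
a multiple of the median (MoM), is carried forward to the third-trimester
median, giving the weight the fetus would attain if it kept its mid-pregnancy
growth trajectory:

    EFW MoM(20w)  = EFW(20w) / median(20w)
    ExFW3t        = EFW MoM(20w) * median(GA_3t)
    %ExFW3t       = 100 + 100 * (EFW3t - ExFW3t) / ExFW3t  ==  100 * EFW3t / ExFW3t

The printed form and its algebraic simplification are identical; the code
computes ``100 * EFW3t / ExFW3t``.  Because both EFW3t and ExFW3t are in the
same units and ExFW3t is proportional to the reference median, %ExFW3t is
invariant to the units of the median curve.

Doppler indices (UA PI, MCA PI) are normalised to MoM against their own
curves; the cerebroplacental ratio (CPR) is the simple ratio MCA PI / UA PI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, NamedTuple, Union

import numpy as np

from .curves import (
    CentileReference,
    CurveSet,
    GestationalAge,
    ReferenceCurve,
    _as_weeks,
    centile_from_value,
)

if TYPE_CHECKING:  # pragma: no cover
    from .io import PregnancyRecord

__all__ = [
    "GA20_WINDOW",
    "GA3T_WINDOW",
    "BiometryScan",
    "DopplerScan",
    "DopplerMoms",
    "GrowthAssessment",
    "hadlock4_efw",
    "scan_efw",
    "efw_mom",
    "expected_fw_3t",
    "pct_expected_fw",
    "doppler_moms",
    "assess",
    "assess_cohort",
]

# Eligibility windows: mid-pregnancy scan at week 20 +/- 1, third-trimester
# scan between 30+0 and 40+6 weeks.
GA20_WINDOW = (19.0, 21.0)
GA3T_WINDOW = (30.0, 40.0 + 6.0 / 7.0)

# Four-parameter Hadlock EFW formula (cm in, grams out):
# log10 EFW = 1.3596 + 0.0064 HC + 0.0424 AC + 0.174 FL + 0.00061 BPD*AC - 0.00386 AC*FL
HADLOCK4_COEFFS = {
    "intercept": 1.3596,
    "hc": 0.0064,
    "ac": 0.0424,
    "fl": 0.174,
    "bpd_ac": 0.00061,
    "ac_fl": -0.00386,
}


@dataclass(frozen=True)
class BiometryScan:
    """One ultrasound biometry examination.

    Either all four biometry measurements (cm) or a directly supplied
    ``efw_grams`` must be present.
    """

    ga: GestationalAge
    bpd: float | None = None
    hc: float | None = None
    ac: float | None = None
    fl: float | None = None
    efw_grams: float | None = None

    def __post_init__(self) -> None:
        fields = {"bpd": self.bpd, "hc": self.hc, "ac": self.ac, "fl": self.fl}
        have_biometry = all(v is not None for v in fields.values())
        if not have_biometry and self.efw_grams is None:
            missing = [k for k, v in fields.items() if v is None]
            raise ValueError(
                f"scan needs either all of BPD/HC/AC/FL or efw_grams; missing {missing}"
            )
        for name, v in fields.items():
            if v is not None and not (0.0 <= float(v) < 60.0):
                raise ValueError(f"biometry field {name}={v!r} out of plausible range [0, 60) cm")
        if self.efw_grams is not None and float(self.efw_grams) <= 0:
            raise ValueError(f"efw_grams must be positive, got {self.efw_grams!r}")


@dataclass(frozen=True)
class DopplerScan:
    """UA and MCA pulsatility indices at one examination."""

    ga: GestationalAge
    ua_pi: float
    mca_pi: float

    def __post_init__(self) -> None:
        for name, v in (("ua_pi", self.ua_pi), ("mca_pi", self.mca_pi)):
            if not (0.0 < float(v) < 5.0):
                raise ValueError(f"{name}={v!r} outside plausible range (0, 5)")


class DopplerMoms(NamedTuple):
    ua_pi_mom: float
    mca_pi_mom: float
    cpr: float
    cpr_mom: float


@dataclass(frozen=True)
class GrowthAssessment:
    """All derived quantities for one pregnancy."""

    efw20_grams: float
    efw20_mom: float
    efw3t_grams: float
    exfw3t_grams: float
    pct_exfw3t: float
    efwc_local: float
    efwc_intergrowth: float
    ua_pi_mom: float
    mca_pi_mom: float
    cpr: float
    cpr_mom: float


def hadlock4_efw(bpd, hc, ac, fl):
    """Four-parameter Hadlock estimated fetal weight (inputs cm, output grams)."""
    for name, v in (("bpd", bpd), ("hc", hc), ("ac", ac), ("fl", fl)):
        if v is None:
            raise ValueError(f"missing biometry field {name!r} for Hadlock EFW")
    bpd = np.asarray(bpd, dtype=float)
    hc = np.asarray(hc, dtype=float)
    ac = np.asarray(ac, dtype=float)
    fl = np.asarray(fl, dtype=float)
    c = HADLOCK4_COEFFS
    exponent = (
        c["intercept"]
        + c["hc"] * hc
        + c["ac"] * ac
        + c["fl"] * fl
        + c["bpd_ac"] * bpd * ac
        + c["ac_fl"] * ac * fl
    )
    out = np.power(10.0, exponent)
    return out if out.ndim else float(out)


def scan_efw(scan: BiometryScan) -> float:
    """EFW in grams: as supplied, or computed from biometry via Hadlock-4."""
    if scan.efw_grams is not None:
        return float(scan.efw_grams)
    return hadlock4_efw(scan.bpd, scan.hc, scan.ac, scan.fl)


def efw_mom(efw, ga, efw_curve: ReferenceCurve):
    """EFW as multiples of the reference median at the same gestational age."""
    e = np.asarray(efw, dtype=float)
    if np.any(e <= 0):
        raise ValueError(f"EFW must be positive, got {efw!r}")
    out = e / np.asarray(efw_curve.median(ga), dtype=float)
    return out if out.ndim else float(out)


def _check_window(name: str, weeks, window: tuple[float, float]) -> None:
    arr = np.asarray(np.asarray(weeks, dtype=float))
    lo, hi = window
    if np.any(arr < lo - 1e-9) or np.any(arr > hi + 1e-9):
        raise ValueError(
            f"{name} gestational age {weeks!r} outside the eligibility window "
            f"[{lo:.3f}, {hi:.3f}] weeks (pass enforce_windows=False to override)"
        )


def expected_fw_3t(efw20, ga20, ga3t, efw_curve: ReferenceCurve, enforce_windows: bool = True):
    """Expected third-trimester weight: the 20-week MoM carried to the 3t median.

    Strictly linear in ``efw20``; invariant to the units of the median curve as
    long as ``efw20`` matches them (the MoM cancels the scale).
    """
    if enforce_windows:
        _check_window("mid-pregnancy scan", _as_weeks(ga20), GA20_WINDOW)
        _check_window("third-trimester scan", _as_weeks(ga3t), GA3T_WINDOW)
    mom20 = efw_mom(efw20, ga20, efw_curve)
    out = np.asarray(mom20, dtype=float) * np.asarray(efw_curve.median(ga3t), dtype=float)
    return out if out.ndim else float(out)


def pct_expected_fw(efw3t, exfw3t):
    """Percentage of the expected weight achieved: 100 * EFW3t / ExFW3t.

    Algebraically identical to the printed form
    ``100 + 100 * (EFW3t - ExFW3t) / ExFW3t``.
    """
    b = np.asarray(exfw3t, dtype=float)
    if np.any(b <= 0) or not np.all(np.isfinite(b)):
        raise ValueError(f"expected weight must be positive and finite, got {exfw3t!r}")
    out = 100.0 * np.asarray(efw3t, dtype=float) / b
    return out if out.ndim else float(out)


def doppler_moms(
    scan: DopplerScan,
    ua_curve: ReferenceCurve,
    mca_curve: ReferenceCurve,
    cpr_curve: ReferenceCurve,
) -> DopplerMoms:
    """UA/MCA MoM, the raw CPR ratio, and CPR MoM at the scan's GA."""
    ga = scan.ga
    cpr = float(scan.mca_pi) / float(scan.ua_pi)
    return DopplerMoms(
        ua_pi_mom=float(scan.ua_pi) / float(ua_curve.median(ga)),
        mca_pi_mom=float(scan.mca_pi) / float(mca_curve.median(ga)),
        cpr=cpr,
        cpr_mom=cpr / float(cpr_curve.median(ga)),
    )


def assess(
    record: "PregnancyRecord",
    curves: CurveSet | None = None,
    enforce_windows: bool = True,
) -> GrowthAssessment:
    """Full growth/Doppler assessment for one pregnancy record."""
    curves = curves if curves is not None else CurveSet.default()
    missing = [
        name
        for name, value in (
            ("scan20", getattr(record, "scan20", None)),
            ("scan3t", getattr(record, "scan3t", None)),
            ("doppler3t", getattr(record, "doppler3t", None)),
        )
        if value is None
    ]
    if missing:
        raise ValueError(f"record {getattr(record, 'subject_id', '?')} missing inputs: {missing}")

    efw20 = scan_efw(record.scan20)
    efw3t = scan_efw(record.scan3t)
    mom20 = efw_mom(efw20, record.scan20.ga, curves.efw)
    exfw3t = expected_fw_3t(
        efw20, record.scan20.ga, record.scan3t.ga, curves.efw, enforce_windows=enforce_windows
    )
    dm = doppler_moms(record.doppler3t, curves.ua, curves.mca, curves.cpr)
    return GrowthAssessment(
        efw20_grams=efw20,
        efw20_mom=mom20,
        efw3t_grams=efw3t,
        exfw3t_grams=exfw3t,
        pct_exfw3t=pct_expected_fw(efw3t, exfw3t),
        efwc_local=centile_from_value(efw3t, record.scan3t.ga, curves.local_ref),
        efwc_intergrowth=centile_from_value(efw3t, record.scan3t.ga, curves.intergrowth_ref),
        ua_pi_mom=dm.ua_pi_mom,
        mca_pi_mom=dm.mca_pi_mom,
        cpr=dm.cpr,
        cpr_mom=dm.cpr_mom,
    )


#: Column names of the per-subject assessment table (fixed export contract).
ASSESSMENT_COLUMNS = (
    "efw20_mom",
    "exfw3t_g",
    "pct_exfw3t",
    "ua_pi_mom",
    "mca_pi_mom",
    "cpr",
    "cpr_mom",
    "efwc_local",
    "efwc_ig",
)


def assess_cohort(df, curves: CurveSet | None = None, enforce_windows: bool = False):
    """Vectorised assessment of a cohort table.

    Requires columns ``ga20_weeks, efw20_g, ga3t_weeks, efw3t_g, ua_pi,
    mca_pi`` (EFW columns may be replaced by 20-week / 3t biometry columns
    ``bpd20_cm, hc20_cm, ac20_cm, fl20_cm`` etc., converted via Hadlock-4).
    Returns a DataFrame of :data:`ASSESSMENT_COLUMNS` indexed like ``df``.
    """
    import pandas as pd

    curves = curves if curves is not None else CurveSet.default()
    ga20 = df["ga20_weeks"].to_numpy(dtype=float)
    ga3t = df["ga3t_weeks"].to_numpy(dtype=float)
    if "efw20_g" in df.columns:
        efw20 = df["efw20_g"].to_numpy(dtype=float)
    else:
        efw20 = hadlock4_efw(df["bpd20_cm"], df["hc20_cm"], df["ac20_cm"], df["fl20_cm"])
    if "efw3t_g" in df.columns:
        efw3t = df["efw3t_g"].to_numpy(dtype=float)
    else:
        efw3t = hadlock4_efw(df["bpd3t_cm"], df["hc3t_cm"], df["ac3t_cm"], df["fl3t_cm"])
    if enforce_windows:
        _check_window("mid-pregnancy scan", ga20, GA20_WINDOW)
        _check_window("third-trimester scan", ga3t, GA3T_WINDOW)

    mom20 = efw_mom(efw20, ga20, curves.efw)
    exfw3t = mom20 * np.asarray(curves.efw.median(ga3t), dtype=float)
    ua = df["ua_pi"].to_numpy(dtype=float)
    mca = df["mca_pi"].to_numpy(dtype=float)
    cpr = mca / ua
    out = pd.DataFrame(
        {
            "efw20_mom": mom20,
            "exfw3t_g": exfw3t,
            "pct_exfw3t": pct_expected_fw(efw3t, exfw3t),
            "ua_pi_mom": ua / np.asarray(curves.ua.median(ga3t), dtype=float),
            "mca_pi_mom": mca / np.asarray(curves.mca.median(ga3t), dtype=float),
            "cpr": cpr,
            "cpr_mom": cpr / np.asarray(curves.cpr.median(ga3t), dtype=float),
            "efwc_local": centile_from_value(efw3t, ga3t, curves.local_ref),
            "efwc_ig": centile_from_value(efw3t, ga3t, curves.intergrowth_ref),
        },
        index=df.index,
    )
    return out
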