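"""Gold-standard metabolic measures and surrogate markers.

Four physiologic axes of glucose dysregulation are quantified per
participant:

* muscle insulin resistance — steady-state plasma glucose (SSPG, mg/dl)
  from the insulin-suppression test, carried as an input;
* beta-cell function — disposition index (DI): early insulin secretion
  (C-peptide deconvolution, 0-30 min) normalized by SSPG;
* incretin effect (IE%) — relative excess of C-peptide during oral versus
  glucose-matched intravenous loading;
* hepatic insulin resistance — regression surrogate from insulin AUC,
  body-fat %, HDL and BMI.

Alongside these, the usual fasting/OGTT surrogates (HOMA-IR, HOMA-B,
Matsuda) and an additive polygenic risk score are provided, plus the
threshold tables that convert continuous measures to binary/ternary class
labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import AnalyteSeries
from .kinetics import SecretionSeries

__all__ = [
    "disposition_index",
    "incretin_effect",
    "body_fat_percent",
    "hepatic_ir_index",
    "surrogate_markers",
    "polygenic_score",
    "Thresholds",
    "classify_measures",
]


def disposition_index(isr: SecretionSeries, sspg: float) -> float:
    """Disposition index: trapezoid integral of ISR over [0, 30] min / SSPG.

    Units (pmol dl)/(kg ml) with ISR in pmol/kg/min and SSPG in mg/dl.
    """
    if sspg <= 0:
        raise ValueError("SSPG must be positive")
    if isr.times[0] > 0 or isr.times[-1] < 30:
        raise ValueError("secretion series must cover [0, 30] min")
    return isr.auc(0.0, 30.0) / sspg


def incretin_effect(cpep_ogtt: AnalyteSeries, cpep_iigi: AnalyteSeries) -> float:
    """Incretin effect, %: 100 * (AUC_OGTT - AUC_IIGI) / AUC_OGTT over [0,180].

    May be negative; never exceeds 100 (IIGI concentrations are >= 0).
    """
    if cpep_ogtt.times.shape != cpep_iigi.times.shape or not np.allclose(
        cpep_ogtt.times, cpep_iigi.times
    ):
        raise ValueError("OGTT and IIGI series must share the same grid")
    auc_ogtt = cpep_ogtt.auc(0.0, 180.0)
    if auc_ogtt == 0:
        raise ZeroDivisionError("OGTT C-peptide AUC is zero; IE undefined")
    auc_iigi = cpep_iigi.auc(0.0, 180.0)
    return 100.0 * (auc_ogtt - auc_iigi) / auc_ogtt


def body_fat_percent(bmi: float, age: float, sex: int) -> float:
    """Deurenberg body-fat estimate: -5.4 + 1.2*BMI + 0.23*age - 10.8*sex.

    sex: 1 = male, 0 = female.
    """
    if sex not in (0, 1):
        raise ValueError("sex must be 0 (female) or 1 (male)")
    if bmi <= 0 or age <= 0:
        raise ValueError("bmi and age must be positive")
    return -5.4 + 1.2 * bmi + 0.23 * age - 10.8 * sex


def hepatic_ir_index(
    insulin_auc_0_180: float, bf_pct: float, hdl: float, bmi: float
) -> float:
    """Hepatic insulin-resistance surrogate index (natural logs).

    -0.091 + 0.4 ln(insulin AUC 0-180) + 0.346 ln(BF%) - 0.408 ln(HDL)
    + 0.435 ln(BMI), with insulin in uIU/ml, HDL in mg/dl, BMI kg/m^2.
    """
    args = dict(insulin_auc=insulin_auc_0_180, bf_pct=bf_pct, hdl=hdl, bmi=bmi)
    for name, v in args.items():
        if v <= 0:
            raise ValueError(f"{name} must be positive (log undefined)")
    return (
        -0.091
        + 0.4 * np.log(insulin_auc_0_180)
        + 0.346 * np.log(bf_pct)
        - 0.408 * np.log(hdl)
        + 0.435 * np.log(bmi)
    )


def surrogate_markers(
    fpg: float,
    fasting_insulin: float,
    ogtt_glucose: AnalyteSeries | None = None,
    ogtt_insulin: AnalyteSeries | None = None,
) -> tuple[float, float, float]:
    """Fasting/OGTT surrogates: (HOMA-IR, HOMA-B, Matsuda index).

    HOMA-IR = FPG*FPI/405, HOMA-B = 360*FPI/(FPG-63) (undefined at
    FPG <= 63, returned as NaN with a warning), Matsuda =
    10000/sqrt(FPG*FPI*Gbar*Ibar) with Gbar/Ibar the trapezoid-weighted mean
    glucose/insulin over 0-120 min of the OGTT.  Glucose mg/dl, insulin
    uIU/ml.  When the OGTT series are omitted, Matsuda falls back to the
    fasting-only form 10000/(FPG*FPI).
    """
    if fpg <= 0 or fasting_insulin <= 0:
        raise ValueError("fasting concentrations must be positive")
    homa_ir = fpg * fasting_insulin / 405.0
    if fpg > 63:
        homa_b = 360.0 * fasting_insulin / (fpg - 63.0)
    else:
        warnings.warn("HOMA-B undefined for FPG <= 63 mg/dl", RuntimeWarning)
        homa_b = float("nan")
    if ogtt_glucose is None or ogtt_insulin is None:
        g_mean, i_mean = fpg, fasting_insulin
    else:
        g_mean = _window_mean(ogtt_glucose)
        i_mean = _window_mean(ogtt_insulin)
    matsuda = 10000.0 / np.sqrt(fpg * fasting_insulin * g_mean * i_mean)
    return homa_ir, homa_b, matsuda


def _window_mean(series: AnalyteSeries, t_min: float = 0.0, t_max: float = 120.0) -> float:
    """Trapezoid time-weighted mean over [t_min, t_max]."""
    mask = (series.times >= t_min) & (series.times <= t_max)
    t, v = series.times[mask], series.values[mask]
    if t.size < 2:
        raise ValueError("need >= 2 points in the averaging window")
    return float(np.trapezoid(v, t) / (t[-1] - t[0]))


def polygenic_score(
    dosages: pd.Series | dict,
    weights: pd.Series | dict,
    allele_freqs: pd.Series | dict | None = None,
    standardize_with: pd.Series | None = None,
) -> float:
    """Additive polygenic score over risk-allele dosages.

    score = sum_present dosage*weight + sum_missing 2*weight*freq, the
    missing-variant term substituting the population-expected dosage.
    ``standardize_with`` (a cohort score distribution) optionally converts
    the raw score to a cohort Z-score.
    """
    weights = pd.Series(weights, dtype=float)
    dosages = pd.Series(dosages, dtype=float)
    freqs = pd.Series(allele_freqs, dtype=float) if allele_freqs is not None else pd.Series(dtype=float)
    if weights.empty:
        warnings.warn("empty weight set; polygenic score is 0", RuntimeWarning)
        return 0.0
    score = 0.0
    for variant, w in weights.items():
        if variant in dosages.index and not np.isnan(dosages[variant]):
            d = dosages[variant]
            if not 0.0 <= d <= 2.0:
                raise ValueError(f"dosage for {variant} outside [0, 2]")
            score += d * w
        elif variant in freqs.index:
            score += 2.0 * w * freqs[variant]
        else:
            raise LookupError(
                f"variant {variant} missing from both dosages and allele_freqs"
            )
    if standardize_with is not None:
        mu, sd = float(np.mean(standardize_with)), float(np.std(standardize_with, ddof=1))
        score = (score - mu) / sd
    return float(score)


@dataclass(frozen=True)
class Thresholds:
    """Cut-points converting the four measures to class labels.

    Binary cut-points are cohort 50th percentiles from the reference study;
    ternary bands follow its reported categories.  Boundary values are
    assigned to the non-dysfunction side except SSPG, where >= 120 counts as
    insulin resistant (the stricter of the two wordings in the source).
    """

    sspg_ir: float = 120.0
    di_binary: float = 1.58
    di_ternary: tuple[float, float] = (1.2, 2.2)
    ie_binary: float = 53.38
    ie_ternary: tuple[float, float] = (39.0, 64.0)
    hepatic_binary: float = 4.35
    hepatic_ternary: tuple[float, float] = (3.95, 4.8)


def classify_measures(
    profile: pd.Series | dict, thresholds: Thresholds = Thresholds()
) -> dict:
    """Binary and ternary class labels for one participant's measures.

    ``profile`` needs keys among {sspg, di, ie_pct, hepatic_ir}; labels for
    missing measures are omitted (and noted via warning).
    """
    p = dict(profile)
    th = thresholds
    labels: dict[str, object] = {}

    def have(key):
        return key in p and p[key] is not None and not (
            isinstance(p[key], float) and np.isnan(p[key])
        )

    if have("sspg"):
        labels["muscle_ir"] = bool(p["sspg"] >= th.sspg_ir)
        labels["muscle_class"] = "IR" if labels["muscle_ir"] else "IS"
    if have("di"):
        di = p["di"]
        labels["beta_dysfunction"] = bool(di < th.di_binary)
        lo, hi = th.di_ternary
        labels["beta_class"] = (
            "dysfunction" if di < lo else "normal" if di > hi else "intermediate"
        )
    if have("ie_pct"):
        ie = p["ie_pct"]
        labels["incretin_dysfunction"] = bool(ie < th.ie_binary)
        lo, hi = th.ie_ternary
        labels["incretin_class"] = (
            "dysfunction" if ie < lo else "normal" if ie > hi else "intermediate"
        )
    if have("hepatic_ir"):
        h = p["hepatic_ir"]
        labels["hepatic_ir_flag"] = bool(h >= th.hepatic_binary)
        lo, hi = th.hepatic_ternary
        labels["hepatic_class"] = (
            "IS" if h < lo else "IR" if h > hi else "intermediate"
        )
    missing = {"sspg", "di", "ie_pct", "hepatic_ir"} - {
        k for k in ("sspg", "di", "ie_pct", "hepatic_ir") if have(k)
    }
    if missing:
        warnings.warn(
            f"measures missing, labels absent: {sorted(missing)}", RuntimeWarning
        )
    return labels
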