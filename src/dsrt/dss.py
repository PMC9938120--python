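"""Drug sensitivity scores: partial AUC over an activity window (DSS1/DSS3),
selective scores against healthy-control profiles, and effectiveness calls.

The score integrates the fitted logistic curve above an activity threshold
``t`` (default 10%) from the dose where the curve first reaches ``t`` (or the
lowest tested dose) up to the highest tested dose:

    I  = integral over [x1, x2] of (min(y(x), ceiling) - t) dx
    DSS1 = 100 * I / ((ceiling - t) * (x_max - x_min))
    DSS3 = DSS1 * ((x2 - x1) / (x_max - x_min)) / log10(a)

DSS3 additionally penalises curves with a low maximal response by dividing by
the base-10 logarithm of the (clipped) top asymptote.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DSSConfig
from .curves import LN10, FourPLFit, dose_at_inhibition

DRUG_CLASSES = ("chemotherapy", "targeted")


@dataclass(frozen=True)
class DSSResult:
    dss: float
    dss1: float
    dss3: float
    x1: float
    x2: float
    partial_auc: float
    flag: str = ""


def _antiderivative(x: float, b: float, a: float, m: float, s: float,
                    t: float) -> float:
    # F'(x) = (b - t) + (a - b) / (1 + 10^(s (m - x))) = y(x) - t
    return (b - t) * x + (a - b) / (s * LN10) * np.logaddexp(0.0, s * LN10 * (x - m))


def partial_auc(fit: FourPLFit, x1: float, x2: float, threshold: float,
                ceiling: float) -> float:
    """Closed-form integral of (min(y, ceiling) - threshold) over [x1, x2]."""
    if x2 <= x1:
        return 0.0
    b, a, m, s = fit.b, fit.a, fit.m, fit.s
    if a <= ceiling:
        return _antiderivative(x2, b, a, m, s, threshold) - _antiderivative(
            x1, b, a, m, s, threshold)
    # Curve exceeds the ceiling: integrate the curve up to the crossing, the
    # constant ceiling afterwards.
    xc = dose_at_inhibition(fit, ceiling)
    if xc is None or xc <= x1:
        return (ceiling - threshold) * (x2 - x1)
    xc = min(xc, x2)
    head = _antiderivative(xc, b, a, m, s, threshold) - _antiderivative(
        x1, b, a, m, s, threshold)
    return head + (ceiling - threshold) * (x2 - xc)


def compute_dss(fit: FourPLFit, config: DSSConfig) -> DSSResult:
    """Score one fitted curve.

    Non-converged fits and curves whose top asymptote never clears the
    activity threshold score 0 with an explanatory flag.
    """
    config.validate()
    t, ceiling = config.activity_threshold, config.response_ceiling
    x_min, x_max = config.x_min, config.x_max
    empty = DSSResult(dss=0.0, dss1=0.0, dss3=0.0, x1=x_max, x2=x_max,
                      partial_auc=0.0)

    if not fit.converged:
        return dataclasses.replace(empty, flag="not_converged")
    if fit.a <= max(t, 1.0):
        return dataclasses.replace(empty, flag="inactive")

    x_start = dose_at_inhibition(fit, t)
    x1 = x_min if x_start is None else max(x_min, x_start)
    x2 = x_max
    if x1 >= x2:
        return dataclasses.replace(empty, flag="window_empty")

    area = partial_auc(fit, x1, x2, t, ceiling)
    span = x_max - x_min
    dss1 = 100.0 * area / ((ceiling - t) * span)
    a_clip = min(max(fit.a, t * (1 + 1e-12)), ceiling)
    dss3 = dss1 * ((x2 - x1) / span) / math.log10(a_clip)
    dss = dss3 if config.metric == "DSS3" else dss1
    return DSSResult(dss=dss, dss1=dss1, dss3=dss3, x1=x1, x2=x2,
                     partial_auc=area)


def score_screen(fits_df: pd.DataFrame, config: DSSConfig) -> pd.DataFrame:
    """Score a whole fits table; returns the long-format dss table."""
    rows = []
    for rec in fits_df.itertuples(index=False):
        fit = FourPLFit(b=rec.b, a=rec.a, m=rec.m, s=rec.s, rss=rec.rss,
                        converged=bool(rec.converged))
        r = compute_dss(fit, config)
        rows.append({"sample_id": rec.sample_id, "drug_id": rec.drug_id,
                     "dss": r.dss, "dss1": r.dss1, "dss3": r.dss3,
                     "x1": r.x1, "x2": r.x2, "variant": config.metric})
    return pd.DataFrame(rows)


def compute_selective_dss(dss_df: pd.DataFrame,
                          controls_df: pd.DataFrame) -> pd.DataFrame:
    """Sample DSS minus the mean DSS of healthy control donors, per drug.

    Drugs absent from every control donor get ``sdss = NaN`` and a
    ``missing_control`` flag rather than a silent zero.
    """
    control_mean = controls_df.groupby("drug_id")["dss"].mean()
    out = dss_df[["sample_id", "drug_id", "dss"]].copy()
    out["control_mean"] = out["drug_id"].map(control_mean)
    out["sdss"] = out["dss"] - out["control_mean"]
    out["flag"] = np.where(out["control_mean"].isna(), "missing_control", "")
    return out


@dataclass
class ScreenMatrix:
    """Samples x drugs DSS matrix with sample and drug annotations."""

    dss: pd.DataFrame  # index sample_id, columns drug_id
    samples: pd.DataFrame  # index sample_id: patient_id, subtype, serial_index
    drugs: pd.DataFrame  # index drug_id: class, mechanism_tags
    annotations: dict = field(default_factory=dict)

    @classmethod
    def from_long(cls, dss_df: pd.DataFrame, samples_df: pd.DataFrame,
                  library_df: pd.DataFrame) -> "ScreenMatrix":
        wide = dss_df.pivot(index="sample_id", columns="drug_id", values="dss")
        if wide.isna().any().any():
            n = int(wide.isna().sum().sum())
            raise ValueError(f"screen matrix has {n} missing cells")
        samples = samples_df.set_index("sample_id").loc[wide.index]
        drugs = library_df.set_index("drug_id").loc[wide.columns]
        return cls(dss=wide, samples=samples, drugs=drugs)

    @property
    def subtypes(self) -> pd.Series:
        return self.samples["subtype"]


@dataclass(frozen=True)
class EffectivenessResult:
    calls: pd.DataFrame  # boolean samples x drugs
    fractions: pd.DataFrame  # samples x {all, chemotherapy, targeted}
    pooled_quantile85: float
    threshold: float


def effectiveness_calls(matrix: ScreenMatrix,
                        threshold: float = 10.0) -> EffectivenessResult:
    """Flag drugs with DSS >= threshold and compute per-sample effective
    fractions overall and per drug class.

    Also reports the empirical 85% quantile (linear interpolation between
    order statistics) of the pooled DSS distribution, for comparison with the
    fixed threshold; the fixed threshold is what the calls use.
    """
    classes = matrix.drugs["class"]
    unknown = set(classes) - set(DRUG_CLASSES)
    if unknown:
        raise ValueError(f"unknown drug classes: {sorted(unknown)}")
    calls = matrix.dss >= threshold
    frac = {"all": calls.mean(axis=1)}
    for cls_name in DRUG_CLASSES:
        cols = classes.index[classes == cls_name]
        frac[cls_name] = (calls[cols].mean(axis=1) if len(cols)
                          else pd.Series(np.nan, index=calls.index))
    fractions = pd.DataFrame(frac)
    q85 = float(np.quantile(matrix.dss.to_numpy().ravel(), 0.85))
    return EffectivenessResult(calls=calls, fractions=fractions,
                               pooled_quantile85=q85, threshold=threshold)
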