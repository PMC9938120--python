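"""Plate-control normalization of raw viability signals to %inhibition.

Controls are pooled per plate: DMSO-analogue negative controls anchor 0%
inhibition, cytotoxic positive controls anchor 100%.  Values outside [0, 100]
are preserved so the curve-fitting layer sees raw behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DoseResponseSeries:
    """One (sample, drug) %inhibition series over increasing concentrations."""

    sample_id: str
    drug_id: str
    concentrations: np.ndarray  # nM, strictly increasing
    inhibition: np.ndarray  # percent

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        inh = np.asarray(self.inhibition, dtype=float)
        if conc.shape != inh.shape or conc.ndim != 1:
            raise ValueError("concentrations and inhibition must match in shape")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive (nM)")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "inhibition", inh)

    @property
    def x(self) -> np.ndarray:
        """log10(concentration in nM)."""
        return np.log10(self.concentrations)

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class PlateQC:
    plate_id: str
    mu_neg: float
    sigma_neg: float
    mu_pos: float
    sigma_pos: float
    z_prime: float

    @property
    def passing(self) -> bool:
        return self.mu_neg > self.mu_pos


class ControlError(ValueError):
    """Raised when plate controls are missing or inverted."""


def _plate_qc(plate_id: str, plate: pd.DataFrame) -> PlateQC:
    neg = plate.loc[plate["role"] == "neg_ctrl", "signal"].to_numpy(float)
    pos = plate.loc[plate["role"] == "pos_ctrl", "signal"].to_numpy(float)
    if len(neg) < 2 or len(pos) < 2:
        raise ControlError(
            f"plate {plate_id}: needs >=2 wells of each control class "
            f"(got {len(neg)} negative, {len(pos)} positive)")
    mu_neg, mu_pos = float(neg.mean()), float(pos.mean())
    if mu_neg <= mu_pos:
        raise ControlError(
            f"plate {plate_id}: control inversion (mu_neg={mu_neg:.4g} <= "
            f"mu_pos={mu_pos:.4g})")
    sd_neg, sd_pos = float(neg.std(ddof=1)), float(pos.std(ddof=1))
    z_prime = 1.0 - 3.0 * (sd_neg + sd_pos) / (mu_neg - mu_pos)
    return PlateQC(plate_id, mu_neg, sd_neg, mu_pos, sd_pos, z_prime)


def normalize_plates(wells: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert raw signals to %inhibition per plate.

    inhibition = 100 * (mu_neg - signal) / (mu_neg - mu_pos)

    Returns (normalized sample wells, QC table).  Raises :class:`ControlError`
    on missing controls or control inversion.
    """
    out_frames, qc_rows = [], []
    for plate_id, plate in wells.groupby("plate_id", sort=True):
        qc = _plate_qc(str(plate_id), plate)
        qc_rows.append(qc)
        sample_wells = plate[plate["role"] == "sample"].copy()
        sample_wells["inhibition_pct"] = (
            100.0 * (qc.mu_neg - sample_wells["signal"])
            / (qc.mu_neg - qc.mu_pos))
        out_frames.append(sample_wells)
    normalized = pd.concat(out_frames, ignore_index=True)
    qc_df = pd.DataFrame([
        {"plate_id": q.plate_id, "mu_neg": q.mu_neg, "sigma_neg": q.sigma_neg,
         "mu_pos": q.mu_pos, "sigma_pos": q.sigma_pos, "z_prime": q.z_prime}
        for q in qc_rows])
    return normalized, qc_df


def assemble_series(normalized: pd.DataFrame, min_doses: int = 4,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse normalized wells into one sorted series per (sample, drug).

    Replicate wells at an identical concentration are averaged.  Series with
    fewer than ``min_doses`` distinct concentrations are excluded; the second
    return value lists them with a reason.
    """
    agg = (normalized.groupby(["sample_id", "drug_id", "conc_nM"], sort=True)
           ["inhibition_pct"].mean().reset_index())
    counts = agg.groupby(["sample_id", "drug_id"])["conc_nM"].size()
    short = counts[counts < min_doses]
    excluded = pd.DataFrame({
        "sample_id": [i[0] for i in short.index],
        "drug_id": [i[1] for i in short.index],
        "n_doses": short.to_numpy(),
        "reason": f"fewer than {min_doses} distinct concentrations",
    })
    if len(short):
        keep = counts[counts >= min_doses].index
        agg = agg.set_index(["sample_id", "drug_id"]).loc[keep].reset_index()
    agg = agg.sort_values(["sample_id", "drug_id", "conc_nM"]).reset_index(drop=True)
    return agg, excluded


def series_objects(series_df: pd.DataFrame):
    """Yield :class:`DoseResponseSeries` from a long-format series table."""
    for (sample_id, drug_id), grp in series_df.groupby(
            ["sample_id", "drug_id"], sort=True):
        grp = grp.sort_values("conc_nM")
        yield DoseResponseSeries(
            sample_id=str(sample_id), drug_id=str(drug_id),
            concentrations=grp["conc_nM"].to_numpy(),
            inhibition=grp["inhibition_pct"].to_numpy())
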