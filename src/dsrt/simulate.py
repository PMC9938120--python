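"""Synthetic plate-format screens with known ground truth.

Generates raw 384-well-style plate tables (sample wells plus negative/positive
control wells), a drug library with mechanism tags, a drug-target bioactivity
table, healthy-control DSS profiles and 7x7 combination matrices.  Every
series has a ground-truth 4PL record so parameter-recovery and cohort-recovery
tests can assert against what was planted rather than against fitted output.

Noise is applied on the raw-signal scale (CV of the true signal), so the
control-based normalization downstream is genuinely exercised; zero noise
round-trips to the true %inhibition exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .curves import FourPLFit, logistic4
from .synergy import CombinationMatrix

# Mechanism tags with planted subtype effects get fixed library slots; the
# remainder of the targeted arm cycles through filler tags.
KEY_TAGS = {
    "MDM2": 14, "ERBB": 16, "MEK": 18, "ERK": 14,
    "CHK1": 14, "WEE1": 12, "SMAC": 12, "SHP2": 8,
}
FILLER_TAGS = (
    "PI3K", "AKT", "MTOR", "CDK", "BCL2", "HDAC", "PARP", "JAK", "BRAF",
    "SRC", "KIT", "FLT3", "AURK", "VEGFR", "ALK", "BTK", "PLK1", "EZH2",
    "BET", "PROTEASOME", "IGF1R", "FGFR", "MET", "RET", "XPO1",
)
CHEMO_TAGS = ("DNA_damaging", "antimetabolite", "tubulin", "topoisomerase")
ENDPOINTS = ("Kd", "Ki", "IC50")

#: Tags whose drugs are treated as kinase inhibitors for kinase-only TAS runs.
KINASE_TAGS = frozenset({
    "MEK", "ERK", "CHK1", "WEE1", "ERBB", "PI3K", "AKT", "MTOR", "CDK",
    "JAK", "BRAF", "SRC", "KIT", "FLT3", "AURK", "VEGFR", "ALK", "BTK",
    "PLK1", "IGF1R", "FGFR", "MET", "RET",
})


@dataclass(frozen=True)
class SimulatedScreen:
    wells: pd.DataFrame
    library: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame  # one row per (sample, drug): true b, a, m, s


def _dose_series(config: SimulationConfig) -> np.ndarray:
    return np.geomspace(config.top_conc_nM / config.dose_range_fold,
                        config.top_conc_nM, config.n_doses)


def build_library(config: SimulationConfig, rng: np.random.Generator,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drug library plus hidden per-drug base 4PL parameters.

    The top asymptote follows a mixture — inactive mass near 0, active mass in
    [40, 95] — which reproduces a long-tailed DSS distribution; log10-EC50 is
    uniform inside the tested range and the slope is lognormal around 1.
    """
    n = config.n_drugs
    n_chemo = max(1, round(config.chemo_fraction * n)) if n > 1 else 0
    n_targeted = n - n_chemo

    key_expanded = [tag for tag, slots in KEY_TAGS.items() for _ in range(slots)]
    tags = key_expanded[:n_targeted]
    i = 0
    while len(tags) < n_targeted:
        tags.append(FILLER_TAGS[i % len(FILLER_TAGS)])
        i += 1
    chemo_tags = [CHEMO_TAGS[i % len(CHEMO_TAGS)] for i in range(n_chemo)]

    classes = ["targeted"] * n_targeted + ["chemotherapy"] * n_chemo
    all_tags = tags + chemo_tags
    drug_ids = [f"D{i:04d}" for i in range(n)]
    library = pd.DataFrame({
        "drug_id": drug_ids,
        "name": [f"compound-{i:04d}" for i in range(n)],
        "class": classes,
        "mechanism_tags": all_tags,
    })

    active = rng.random(n) > config.inactive_fraction
    # Chemotherapy is broadly cytotoxic: higher active mass than targeted.
    chemo_mask = np.array([c == "chemotherapy" for c in classes])
    active |= chemo_mask & (rng.random(n) < 0.35)
    a_base = np.where(active, rng.uniform(40.0, 95.0, n),
                      rng.uniform(0.0, 12.0, n))
    m_base = rng.uniform(config.x_min + 0.5, config.x_max - 0.5, n)
    s_base = rng.lognormal(mean=0.0, sigma=0.3, size=n)
    base = pd.DataFrame({"drug_id": drug_ids, "a": a_base, "m": m_base,
                         "s": np.clip(s_base, 0.2, 5.0)})
    return library, base


def build_samples(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: patients per subtype plus serial re-samples."""
    serial = {(sub, idx): count for sub, idx, count in config.serial_samples}
    rows = []
    for subtype in sorted(config.n_samples_per_subtype):
        for pi in range(config.n_samples_per_subtype[subtype]):
            patient = f"P{subtype[:2]}{pi + 1:02d}"
            n_serial = serial.get((subtype, pi), 1)
            for k in range(1, n_serial + 1):
                rows.append({"sample_id": f"{patient}_{k}",
                             "patient_id": patient, "subtype": subtype,
                             "serial_index": k})
    return pd.DataFrame(rows)


def _true_params(config: SimulationConfig, library: pd.DataFrame,
                 base: pd.DataFrame, samples: pd.DataFrame,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Per-(sample, drug) true 4PL parameters.

    Subtype shifts come from ``config.subtype_effect_map``; patient-level
    jitter is drawn once per patient so serial samples share true parameters
    exactly and differ only in plate noise.
    """
    tag_by_drug = dict(zip(library["drug_id"], library["mechanism_tags"]))
    rows = []
    patients = samples.drop_duplicates("patient_id")
    jitter_a = {p: rng.normal(0.0, config.patient_jitter_a, len(base))
                for p in patients["patient_id"]}
    jitter_m = {p: rng.normal(0.0, config.patient_jitter_m, len(base))
                for p in patients["patient_id"]}
    for sample in samples.itertuples(index=False):
        ja = jitter_a[sample.patient_id]
        jm = jitter_m[sample.patient_id]
        for j, drug in enumerate(base.itertuples(index=False)):
            tag = tag_by_drug[drug.drug_id]
            da, dm = 0.0, 0.0
            effects = config.subtype_effect_map.get(tag)
            if effects and sample.subtype in effects:
                da, dm = effects[sample.subtype]
            rows.append({
                "sample_id": sample.sample_id, "drug_id": drug.drug_id,
                "b": 0.0,
                "a": float(np.clip(drug.a + da + ja[j], 0.0, 100.0)),
                "m": float(drug.m + dm + jm[j]),
                "s": drug.s,
            })
    return pd.DataFrame(rows)


def _signal_from_inhibition(inh: np.ndarray, config: SimulationConfig,
                            rng: np.random.Generator) -> np.ndarray:
    span = config.signal_neg - config.signal_pos
    true_signal = config.signal_neg - inh / 100.0 * span
    if config.noise_cv > 0:
        true_signal = true_signal + rng.normal(
            0.0, config.noise_cv * np.abs(true_signal))
    return true_signal


def simulate_screen(config: SimulationConfig) -> SimulatedScreen:
    """Generate raw plate tables, library, sample sheet and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    library, base = build_library(config, rng)
    samples = build_samples(config)
    truth = _true_params(config, library, base, samples, rng)
    doses = _dose_series(config)
    x = np.log10(doses)

    well_frames = []
    per_plate = config.sample_wells_per_plate
    n_ctrl = config.control_wells_per_plate
    for sample_id, truth_s in truth.groupby("sample_id", sort=True):
        a = truth_s["a"].to_numpy()[:, None]
        m = truth_s["m"].to_numpy()[:, None]
        s = truth_s["s"].to_numpy()[:, None]
        inh = logistic4(x[None, :], 0.0, a, m, s)
        drug_ids = np.repeat(truth_s["drug_id"].to_numpy(), len(doses))
        conc = np.tile(doses, len(truth_s))
        flat_inh = inh.ravel()
        n_wells = len(flat_inh)
        n_plates = math.ceil(n_wells / per_plate)
        for p in range(n_plates):
            lo, hi = p * per_plate, min((p + 1) * per_plate, n_wells)
            plate_id = f"{sample_id}-PL{p + 1:02d}"
            sig = _signal_from_inhibition(flat_inh[lo:hi], config, rng)
            n_sample = hi - lo
            neg = _signal_from_inhibition(np.zeros(n_ctrl), config, rng)
            pos = _signal_from_inhibition(np.full(n_ctrl, 100.0), config, rng)
            frame = pd.DataFrame({
                "plate_id": plate_id,
                "well": [f"W{i + 1:03d}" for i in range(n_sample + 2 * n_ctrl)],
                "sample_id": sample_id,
                "drug_id": np.concatenate([
                    drug_ids[lo:hi], ["neg_ctrl"] * n_ctrl, ["pos_ctrl"] * n_ctrl]),
                "conc_nM": np.concatenate([conc[lo:hi], np.zeros(2 * n_ctrl)]),
                "signal": np.concatenate([sig, neg, pos]),
                "role": (["sample"] * n_sample + ["neg_ctrl"] * n_ctrl
                         + ["pos_ctrl"] * n_ctrl),
            })
            well_frames.append(frame)
    wells = pd.concat(well_frames, ignore_index=True)
    return SimulatedScreen(wells=wells, library=library, samples=samples,
                           truth=truth)


def simulate_target_map(library: pd.DataFrame, config: SimulationConfig,
                        seed: int | None = None) -> pd.DataFrame:
    """Quantitative drug-target bioactivity table.

    Each drug hits the target named by its mechanism tag with nanomolar
    potency plus a handful of weaker off-targets, mimicking a bioactivity-
    database extract with mixed Kd/Ki/IC50 endpoints.
    """
    rng = np.random.default_rng(config.seed + 7 if seed is None else seed)
    all_tags = sorted(set(library["mechanism_tags"]))
    rows = []
    for drug in library.itertuples(index=False):
        primary = drug.mechanism_tags
        rows.append({
            "drug_id": drug.drug_id, "target_id": primary,
            "endpoint": ENDPOINTS[rng.integers(len(ENDPOINTS))],
            "potency_nM": float(rng.lognormal(math.log(20.0), 1.0)),
        })
        for _ in range(rng.binomial(3, 0.35)):
            off = all_tags[rng.integers(len(all_tags))]
            if off == primary:
                continue
            rows.append({
                "drug_id": drug.drug_id, "target_id": off,
                "endpoint": ENDPOINTS[rng.integers(len(ENDPOINTS))],
                "potency_nM": float(rng.lognormal(math.log(400.0), 1.2)),
            })
    return pd.DataFrame(rows)


def simulate_healthy_controls(library: pd.DataFrame, config: SimulationConfig,
                              n_donors: int = 2,
                              seed: int | None = None) -> pd.DataFrame:
    """DSS profiles for healthy-donor control cells.

    Targeted drugs score low (mean < 5); cytotoxic chemotherapy scores
    moderately, so selective-DSS filtering has signal to work with.
    """
    if n_donors < 2:
        raise ValueError("need >=2 control donors")
    rng = np.random.default_rng(config.seed + 13 if seed is None else seed)
    rows = []
    for d in range(1, n_donors + 1):
        donor = f"HC{d:02d}"
        for drug_id, drug_class in zip(library["drug_id"], library["class"]):
            if drug_class == "chemotherapy":
                dss = max(0.0, rng.normal(13.0, 4.0))
            else:
                dss = float(rng.gamma(1.5, 1.2))
            rows.append({"donor_id": donor, "drug_id": drug_id, "dss": dss})
    return pd.DataFrame(rows)


def simulate_combination_matrix(
    drugA: FourPLFit,
    drugB: FourPLFit,
    synergy_excess: float,
    config: SimulationConfig,
    *,
    drugA_id: str = "drugA",
    drugB_id: str = "drugB",
    combo_range_fold: float = 1000.0,
    seed: int | None = None,
) -> CombinationMatrix:
    """7x7 combination matrix with a planted HSA excess.

    Row 0 / column 0 carry the single-agent responses; interior cells are
    ``min(100, max(monoA_i, monoB_j) + synergy_excess)``.  The surface is
    converted to raw signal, noised at the configured CV, and re-normalized
    with noisy simulated controls — exactly the treatment single-agent plates
    receive.
    """
    if synergy_excess < 0:
        raise ValueError("synergy_excess must be >= 0")
    config.validate()
    rng = np.random.default_rng(config.seed + 29 if seed is None else seed)
    concs = np.concatenate([[0.0], np.geomspace(
        config.top_conc_nM / combo_range_fold, config.top_conc_nM, 6)])
    monoA = np.concatenate([[0.0], logistic4(np.log10(concs[1:]), drugA.b,
                                             drugA.a, drugA.m, drugA.s)])
    monoB = np.concatenate([[0.0], logistic4(np.log10(concs[1:]), drugB.b,
                                             drugB.a, drugB.m, drugB.s)])
    truth = np.maximum(monoA[:, None], monoB[None, :])
    truth[1:, 1:] = np.minimum(100.0, truth[1:, 1:] + synergy_excess)
    truth[0, 0] = 0.0

    span = config.signal_neg - config.signal_pos
    signal = config.signal_neg - truth / 100.0 * span
    n_ctrl = config.control_wells_per_plate
    neg = np.full(n_ctrl, config.signal_neg)
    pos = np.full(n_ctrl, config.signal_pos)
    if config.noise_cv > 0:
        signal = signal + rng.normal(0.0, config.noise_cv * np.abs(signal))
        neg = neg + rng.normal(0.0, config.noise_cv * neg)
        pos = pos + rng.normal(0.0, config.noise_cv * pos)
    mu_neg, mu_pos = neg.mean(), pos.mean()
    inhibition = 100.0 * (mu_neg - signal) / (mu_neg - mu_pos)
    return CombinationMatrix(drugA_id=drugA_id, drugB_id=drugB_id,
                             concsA=concs, concsB=concs.copy(),
                             inhibition=inhibition)
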