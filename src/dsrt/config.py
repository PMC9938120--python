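"""Configuration objects shared across pipeline stages."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

#: Subtype labels used by the default cohort simulation.
SUBTYPES = ("HGSOC", "LGSOC", "MUCOC")

#: Default per-mechanism-tag sensitivity shifts, expressed as
#: (delta top-asymptote in %inhibition, delta log10-EC50 in log10-nM) per subtype.
#: Negative delta-m means the drug is more potent in that subtype.
DEFAULT_SUBTYPE_EFFECTS: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "MDM2": {"LGSOC": (35.0, -0.7)},
    "ERBB": {"LGSOC": (35.0, -0.7)},
    "MEK": {"LGSOC": (25.0, -0.5), "MUCOC": (30.0, -0.6)},
    "ERK": {"LGSOC": (25.0, -0.5), "MUCOC": (30.0, -0.6)},
    "CHK1": {"HGSOC": (30.0, -0.6)},
    "WEE1": {"HGSOC": (30.0, -0.6)},
    "SMAC": {"HGSOC": (30.0, -0.6)},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic screen generator.

    The defaults emulate a 13-patient / 16-sample cohort (5 HGSOC, 5 LGSOC and
    3 MUCOC patients, with two LGSOC patients contributing serial samples)
    screened against 526 drugs in five concentrations over a 10,000-fold range.
    """

    n_samples_per_subtype: Mapping[str, int] = field(
        default_factory=lambda: {"HGSOC": 5, "LGSOC": 5, "MUCOC": 3}
    )
    #: (subtype, patient index within subtype, number of serial samples)
    serial_samples: Sequence[tuple[str, int, int]] = (("LGSOC", 0, 3), ("LGSOC", 1, 2))
    n_drugs: int = 526
    n_doses: int = 5
    dose_range_fold: float = 1e4
    top_conc_nM: float = 1e4
    control_wells_per_plate: int = 16
    sample_wells_per_plate: int = 352
    noise_cv: float = 0.05
    signal_neg: float = 100_000.0
    signal_pos: float = 2_000.0
    chemo_fraction: float = 0.15
    inactive_fraction: float = 0.8
    patient_jitter_a: float = 4.0
    patient_jitter_m: float = 0.1
    subtype_effect_map: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_SUBTYPE_EFFECTS
    )
    seed: int = 0

    def validate(self) -> None:
        if not self.n_samples_per_subtype:
            raise ValueError("need at least one subtype")
        for subtype, count in self.n_samples_per_subtype.items():
            if count < 1:
                raise ValueError(f"subtype {subtype!r} needs >=1 sample, got {count}")
        if self.n_drugs < 1 or self.n_doses < 2:
            raise ValueError("n_drugs >= 1 and n_doses >= 2 required")
        if self.dose_range_fold <= 1:
            raise ValueError("dose_range_fold must exceed 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.signal_neg <= self.signal_pos:
            raise ValueError(
                "control separation non-positive: signal_neg must exceed signal_pos"
            )
        if self.control_wells_per_plate < 2:
            raise ValueError("need >=2 control wells per class per plate")
        if self.sample_wells_per_plate < 1:
            raise ValueError("sample_wells_per_plate must be >=1")

    @property
    def x_min(self) -> float:
        return math.log10(self.top_conc_nM / self.dose_range_fold)

    @property
    def x_max(self) -> float:
        return math.log10(self.top_conc_nM)


@dataclass(frozen=True)
class DSSConfig:
    """Parameters of the drug sensitivity score.

    ``activity_threshold`` is the minimum %inhibition counted as activity;
    the integration window runs from the dose reaching that threshold (or the
    lowest tested dose) to the highest tested dose, on the log10-concentration
    scale bounded by ``x_min``/``x_max``.
    """

    activity_threshold: float = 10.0
    response_ceiling: float = 100.0
    metric: str = "DSS3"
    x_min: float = 0.0
    x_max: float = 4.0

    def validate(self) -> None:
        if not 0 < self.activity_threshold < self.response_ceiling:
            raise ValueError("require 0 < activity_threshold < response_ceiling")
        if self.x_min >= self.x_max:
            raise ValueError("x_min must be < x_max")
        if self.metric not in ("DSS1", "DSS3"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass(frozen=True)
class TASConfig:
    potency_cutoff_nM: float = 1000.0
    min_drugs_per_target: int = 2
    n_permutations: int = 2000
    kinase_only: bool = False

    def validate(self) -> None:
        if self.potency_cutoff_nM <= 0:
            raise ValueError("potency_cutoff_nM must be positive")
        if self.min_drugs_per_target < 1:
            raise ValueError("min_drugs_per_target must be >=1")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >=100")


def config_digest(obj) -> str:
    """Stable sha256 digest of a (nested) config for run manifests."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}
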