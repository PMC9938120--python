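"""CSV schemas and deterministic readers/writers for inter-stage artifacts."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

WELLS_COLUMNS = ["plate_id", "well", "sample_id", "drug_id", "conc_nM", "signal", "role"]
LIBRARY_COLUMNS = ["drug_id", "name", "class", "mechanism_tags"]
TARGETS_COLUMNS = ["drug_id", "target_id", "endpoint", "potency_nM"]
SAMPLES_COLUMNS = ["sample_id", "patient_id", "subtype", "serial_index"]
SERIES_COLUMNS = ["sample_id", "drug_id", "conc_nM", "inhibition_pct"]
FITS_COLUMNS = ["sample_id", "drug_id", "b", "a", "m", "s", "rss", "converged"]
DSS_COLUMNS = ["sample_id", "drug_id", "dss", "dss1", "dss3", "x1", "x2", "variant"]
CONTROLS_COLUMNS = ["donor_id", "drug_id", "dss"]

ROLES = ("sample", "neg_ctrl", "pos_ctrl")

#: Fixed float formatting keeps repeated runs byte-identical.
FLOAT_FORMAT = "%.10g"


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def _read(path, columns, dtypes=None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=dtypes)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_wells(path) -> pd.DataFrame:
    df = _read(path, WELLS_COLUMNS, dtypes={"plate_id": str, "well": str,
                                            "sample_id": str, "drug_id": str})
    bad = set(df["role"]) - set(ROLES)
    if bad:
        raise ValueError(f"{path}: unknown well roles {sorted(bad)}")
    return df


def read_library(path) -> pd.DataFrame:
    return _read(path, LIBRARY_COLUMNS, dtypes={"drug_id": str})


def read_targets(path) -> pd.DataFrame:
    df = _read(path, TARGETS_COLUMNS, dtypes={"drug_id": str, "target_id": str})
    if (df["potency_nM"] <= 0).any():
        raise ValueError(f"{path}: potency_nM must be positive")
    return df


def read_samples(path) -> pd.DataFrame:
    return _read(path, SAMPLES_COLUMNS, dtypes={"sample_id": str, "patient_id": str})


def read_series(path) -> pd.DataFrame:
    return _read(path, SERIES_COLUMNS, dtypes={"sample_id": str, "drug_id": str})


def read_fits(path) -> pd.DataFrame:
    return _read(path, FITS_COLUMNS, dtypes={"sample_id": str, "drug_id": str})


def read_dss(path) -> pd.DataFrame:
    return _read(path, DSS_COLUMNS, dtypes={"sample_id": str, "drug_id": str})


def read_controls(path) -> pd.DataFrame:
    return _read(path, CONTROLS_COLUMNS, dtypes={"donor_id": str, "drug_id": str})
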