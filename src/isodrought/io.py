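"""CSV/JSON/YAML I/O for met series, drought indices and results.

Column dictionary for met CSV files (ISO-8601 timestamps, missing values
empty or ``NA``)::

    timestamp, TA_C, SW_IN_Wm2, RN_Wm2, G_Wm2, U2_ms, EA_kPa,
    LE_Wm2, PPFD_umol, SWC_m3m3

``SWC_m3m3`` is optional.  Unknown columns are accepted with a warning;
missing required columns and malformed timestamps fail loudly.  Writers
round floats to 6 significant digits, so write-then-read round-trips are
identity up to that precision.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from isodrought.emission import EmissionConfig
from isodrought.gamma import LegacySMParams, PDSParams
from isodrought.met import DroughtIndex

#: CSV header -> internal met column
MET_CSV_COLUMNS = {
    "TA_C": "t_air",
    "SW_IN_Wm2": "sw_in",
    "RN_Wm2": "r_n",
    "G_Wm2": "g_soil",
    "U2_ms": "u2",
    "EA_kPa": "e_a",
    "LE_Wm2": "le",
    "PPFD_umol": "ppfd",
    "SWC_m3m3": "theta",
}
_OPTIONAL = {"SWC_m3m3"}
FLOAT_FORMAT = "%.6g"


def _parse_timestamps(raw: pd.Series, path) -> pd.DatetimeIndex:
    parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # 1-based, plus header line
        raise ValueError(f"{path}: malformed timestamp at row {row}: {raw[bad].iloc[0]!r}")
    return pd.DatetimeIndex(parsed)


def read_met_csv(path) -> pd.DataFrame:
    """Read a met CSV into the canonical internal frame (DatetimeIndex)."""
    df = pd.read_csv(path, na_values=["NA"])
    if "timestamp" not in df.columns:
        raise ValueError(f"{path}: missing required column 'timestamp'")
    missing = [c for c in MET_CSV_COLUMNS if c not in df.columns and c not in _OPTIONAL]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    unknown = [
        c for c in df.columns if c not in MET_CSV_COLUMNS and c != "timestamp"
    ]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)

    out = pd.DataFrame(index=_parse_timestamps(df["timestamp"], path))
    for csv_name, internal in MET_CSV_COLUMNS.items():
        if csv_name in df.columns:
            out[internal] = pd.to_numeric(df[csv_name], errors="coerce").to_numpy()
        else:
            out[internal] = np.nan
    return out


def write_met_csv(met: pd.DataFrame, path) -> None:
    """Write a canonical met frame using the documented CSV dialect."""
    out = pd.DataFrame({"timestamp": met.index.strftime("%Y-%m-%dT%H:%M:%S")})
    for csv_name, internal in MET_CSV_COLUMNS.items():
        if internal in met.columns:
            out[csv_name] = met[internal].to_numpy()
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_index_csv(index: DroughtIndex, path, normalized: pd.Series | None = None) -> None:
    """Write a daily index CSV: date, raw, smoothed, normalized, source."""
    raw = index.raw if index.raw is not None else index.values
    out = pd.DataFrame(
        {
            "date": index.values.index.strftime("%Y-%m-%d"),
            "raw_fpet": raw.to_numpy(),
            "smoothed_fpet": index.values.to_numpy(),
            "normalized_index": (
                normalized.to_numpy() if normalized is not None
                else index.values.to_numpy() if index.normalized
                else np.nan
            ),
            "source": index.source,
        }
    )
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_index_csv(path) -> DroughtIndex:
    """Read a daily index CSV (uses ``normalized_index`` when present)."""
    df = pd.read_csv(path, na_values=["NA"])
    if "date" not in df.columns:
        raise ValueError(f"{path}: missing required column 'date'")
    col = "normalized_index" if "normalized_index" in df.columns else "value"
    if col not in df.columns:
        raise ValueError(f"{path}: missing required column 'normalized_index' or 'value'")
    dates = _parse_timestamps(df["date"], path)
    values = pd.Series(pd.to_numeric(df[col], errors="coerce").to_numpy(), index=dates)
    source = str(df["source"].iloc[0]) if "source" in df.columns else "custom"
    normalized = bool(values.dropna().between(0.0, 1.0).all())
    return DroughtIndex(values=values, source=source, normalized=normalized)


def write_flux_csv(flux: pd.DataFrame, path) -> None:
    """Write a flux run result: timestamp, gamma_p, gamma_t, gamma_sm, flux."""
    out = flux.copy()
    out.insert(0, "timestamp", flux.index.strftime("%Y-%m-%dT%H:%M:%S"))
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_pairs_csv(path) -> pd.DataFrame:
    """Read a paired-flux CSV: timestamp, f_obs, f_mod, index."""
    df = pd.read_csv(path, na_values=["NA"])
    for col in ("timestamp", "f_obs", "f_mod", "index"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    out = df[["f_obs", "f_mod", "index"]].apply(pd.to_numeric, errors="coerce")
    out.index = _parse_timestamps(df["timestamp"], path)
    return out


def write_pairs_csv(pairs: pd.DataFrame, path) -> None:
    out = pairs.copy()
    out.insert(0, "timestamp", pairs.index.strftime("%Y-%m-%dT%H:%M:%S"))
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_result_json(result, path) -> None:
    """Serialize a calibration result (schema version 1) to JSON."""
    doc = {"schema_version": 1}
    for field in dataclasses.fields(result):
        value = getattr(result, field.name)
        if dataclasses.is_dataclass(value):
            value = dataclasses.asdict(value)
        elif isinstance(value, np.ndarray):
            value = value.tolist()
        doc[field.name] = value
    Path(path).write_text(json.dumps(doc, indent=2))


def load_config(path) -> dict:
    """Load a YAML run configuration; returns {} for an empty file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def emission_config_from_dict(cfg: dict) -> EmissionConfig:
    return EmissionConfig(**cfg.get("emission", {}))


def pds_params_from_dict(cfg: dict) -> PDSParams:
    return PDSParams(**cfg.get("pds", {}))


def legacy_params_from_dict(cfg: dict) -> LegacySMParams:
    return LegacySMParams(**cfg.get("legacy_sm", {}))
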