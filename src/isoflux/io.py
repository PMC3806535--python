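"""CSV and configuration I/O.

Gas-exchange tables are plain UTF-8 CSV with LF line endings and ``#``
comment lines documenting units; run configuration is a flat YAML file
whose blocks map one-to-one onto the parameter dataclasses (unknown keys
are rejected).  Every output file embeds the hash of the resolved
configuration so runs can be traced.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .photo import LeafEnvironment, PhotoParams
from .models import EnergeticIsoParams, G93Params, NiinemetsParams

__all__ = [
    "SchemaError",
    "ConfigError",
    "REQUIRED_COLUMNS",
    "read_gas_exchange",
    "write_gas_exchange",
    "records_from_table",
    "RunConfig",
]

logger = logging.getLogger(__name__)

#: Mandatory columns of a gas-exchange table and their units.
REQUIRED_COLUMNS = {
    "par": "umol photons m-2 s-1 (absorbed)",
    "t_leaf_c": "degC",
    "ci": "umol mol-1",
    "a_net": "umol CO2 m-2 s-1",
    "iso": "nmol isoprene m-2 s-1",
}
OPTIONAL_COLUMNS = {"rd": "umol CO2 m-2 s-1", "o2": "mmol mol-1",
                    "a_net_true": "umol CO2 m-2 s-1",
                    "iso_true": "nmol isoprene m-2 s-1"}


class SchemaError(ValueError):
    """The table does not match the gas-exchange schema."""


class ConfigError(ValueError):
    """The configuration file is malformed."""


def read_gas_exchange(path) -> pd.DataFrame:
    """Read and validate a gas-exchange CSV.

    ``#`` lines are comments.  Raises :class:`SchemaError` naming any
    missing required column; unparseable cells raise a row-level error
    with the data row number.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    numeric_cols = [c for c in df.columns
                    if c in REQUIRED_COLUMNS or c in OPTIONAL_COLUMNS]
    for col in numeric_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"unparseable value {df[col].iloc[row]!r} in column {col!r} "
                f"at data row {row + 1}"
            )
        df[col] = parsed
    logger.info("read %d record(s) from %s", len(df), path)
    return df


def write_gas_exchange(df: pd.DataFrame, path, comments: Optional[dict] = None) -> None:
    """Write a gas-exchange table as commented CSV (UTF-8, LF)."""
    path = Path(path)
    buf = _io.StringIO()
    for col, unit in {**REQUIRED_COLUMNS, **OPTIONAL_COLUMNS}.items():
        if col in df.columns:
            buf.write(f"# {col}: {unit}\n")
    for key, value in (comments or {}).items():
        buf.write(f"# {key}: {value}\n")
    df.to_csv(buf, index=False, lineterminator="\n")
    path.write_text(buf.getvalue(), encoding="utf-8", newline="")


def records_from_table(df: pd.DataFrame):
    """Convert a validated table into :class:`GasExchangeRecord` objects."""
    from .fitting import GasExchangeRecord

    records = []
    for row in df.itertuples(index=False):
        env = LeafEnvironment(
            par_absorbed=float(row.par),
            t_leaf=float(row.t_leaf_c),
            ci=float(row.ci),
            o2=float(getattr(row, "o2", 210.0)) if hasattr(row, "o2") else 210.0,
        )
        rd = getattr(row, "rd", None)
        records.append(
            GasExchangeRecord(
                env=env,
                a_net_obs=float(row.a_net),
                iso_obs=float(row.iso),
                rd_obs=float(rd) if rd is not None and np.isfinite(rd) else None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_KNOWN_TOP_KEYS = {"seed", "log_level", "photo", "models", "sweep", "synth",
                   "normalization", "output"}
_KNOWN_SWEEP_KEYS = {"driver", "start", "stop", "step", "fixed", "normalize",
                     "co2_mode", "ca"}
_KNOWN_SYNTH_KEYS = {"kind", "start", "stop", "step", "fixed", "cv_a", "cv_iso",
                     "replicates", "t_start", "t_stop", "t_step"}
_KNOWN_FIXED_KEYS = {"par", "t_leaf", "ci", "o2"}
_MODEL_CLASSES = {"energetic": EnergeticIsoParams, "g93": G93Params,
                  "niinemets": NiinemetsParams}


@dataclass
class RunConfig:
    """Resolved run configuration."""

    seed: int = 0
    log_level: str = "INFO"
    photo: PhotoParams = field(default_factory=PhotoParams)
    models: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def fixed_env(self, block: dict) -> LeafEnvironment:
        fixed = dict(block.get("fixed", {}))
        unknown = set(fixed) - _KNOWN_FIXED_KEYS
        if unknown:
            raise ConfigError(f"unknown fixed-environment key(s): {sorted(unknown)}")
        return LeafEnvironment(
            par_absorbed=float(fixed.get("par", 1000.0)),
            t_leaf=float(fixed.get("t_leaf", 30.0)),
            ci=float(fixed.get("ci", 273.0)),
            o2=float(fixed.get("o2", 210.0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration must be a mapping")
        unknown = set(raw) - _KNOWN_TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")

        try:
            photo = PhotoParams(**raw.get("photo", {}))
        except TypeError as exc:
            raise ConfigError(f"photo block: {exc}") from None

        models = {}
        for model_id, block in (raw.get("models") or {}).items():
            if model_id not in _MODEL_CLASSES:
                raise ConfigError(f"unknown model {model_id!r}")
            try:
                models[model_id] = _MODEL_CLASSES[model_id](**(block or {}))
            except TypeError as exc:
                raise ConfigError(f"models.{model_id} block: {exc}") from None

        for name, known in (("sweep", _KNOWN_SWEEP_KEYS), ("synth", _KNOWN_SYNTH_KEYS)):
            extra = set(raw.get(name, {}) or {}) - known
            if extra:
                raise ConfigError(f"unknown {name} key(s): {sorted(extra)}")

        cfg = cls(
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
            photo=photo,
            models=models,
            sweep=dict(raw.get("sweep", {}) or {}),
            synth=dict(raw.get("synth", {}) or {}),
            raw=raw,
        )
        logger.info("resolved config (hash %s): %s", cfg.config_hash,
                    json.dumps(raw, sort_keys=True, default=str))
        return cfg
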