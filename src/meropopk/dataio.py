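"""Dataset and configuration I/O.

The single tabular interchange format is a long CSV with one row per dose
or observation event (see ``DATASET_COLUMNS`` in :mod:`meropopk.synthetic`
and the README for the column dialect).  Configuration is YAML; a packaged
default carries the final population model estimates and the simulation
settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pkmodel import PopulationModel
from .synthetic import DATASET_COLUMNS

__all__ = [
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "RunConfig",
    "load_config",
    "save_config",
    "default_config",
    "default_model",
    "example_mic_path",
]

_REQUIRED = set(DATASET_COLUMNS)


class DatasetError(ValueError):
    """A dataset failed structural validation."""


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Check the dataset invariants; return the (typed) frame.

    Dose rows must have a positive amount and no concentration; observation
    rows the reverse; times must be non-decreasing within each subject.
    Errors name the offending row.
    """
    missing = _REQUIRED - set(df.columns)
    if missing:
        raise DatasetError(f"missing mandatory column(s): {sorted(missing)}")
    unknown = set(df.columns) - _REQUIRED
    if unknown:
        raise DatasetError(f"unknown column(s): {sorted(unknown)}")
    bad_event = ~df["event_type"].isin(["dose", "observation"])
    if bad_event.any():
        row = df.index[bad_event][0]
        raise DatasetError(f"row {row}: invalid event_type {df.loc[row, 'event_type']!r}")
    doses = df[df["event_type"] == "dose"]
    obs = df[df["event_type"] == "observation"]
    bad = doses[~(doses["amount"] > 0)]
    if len(bad):
        raise DatasetError(f"row {bad.index[0]}: dose row needs amount > 0")
    bad = doses[doses["concentration"].notna()]
    if len(bad):
        raise DatasetError(f"row {bad.index[0]}: dose row carries a concentration")
    bad = obs[obs["concentration"].isna()]
    if len(bad):
        raise DatasetError(f"row {bad.index[0]}: observation row lacks a concentration")
    bad = obs[obs["amount"].notna()]
    if len(bad):
        raise DatasetError(f"row {bad.index[0]}: observation row carries a dose amount")
    for sid, grp in df.groupby("subject_id"):
        t = grp["time"].to_numpy(dtype=float)
        if np.any(np.diff(t) < -1e-9):
            raise DatasetError(f"subject {sid}: times are not non-decreasing")
    out = df.copy()
    out["below_lloq"] = out["below_lloq"].astype(bool)
    out["crrt"] = out["crrt"].astype(bool)
    for col in ("time", "amount", "infusion_duration", "concentration", "ce"):
        out[col] = pd.to_numeric(out[col], errors="raise")
    return out


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate a dataset CSV."""
    df = pd.read_csv(path)
    return validate_dataset(df)


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    """Validate and write a dataset CSV."""
    validate_dataset(df).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Everything a seeded end-to-end run needs."""

    model: PopulationModel = field(default_factory=PopulationModel)
    seed: int = 1861
    n_empirical: int = 10_000
    n_per_band: int = 1000
    egfr_median: float = 90.0
    egfr_sdlog: float = 0.5
    egfr_upper: float = 130.0
    grid_step: float = 0.02
    mic_table: str | None = None  # path; None -> packaged illustrative table
    output_dir: str = "meropopk_output"

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        model = d.pop("model", {})
        if isinstance(model, dict):
            model = PopulationModel(**model)
        return cls(model=model, **d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.from_dict(raw or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def default_config() -> RunConfig:
    """The packaged default configuration (final model estimates)."""
    with resources.files("meropopk.data").joinpath("default_config.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.from_dict(raw)


def default_model() -> PopulationModel:
    return default_config().model


def example_mic_path() -> Path:
    """Path to the packaged illustrative MIC frequency table.

    The table is synthetic (doubling dilutions 0.06-16 mg/L with a
    plausible unimodal shape); it is NOT the EUCAST distribution.  Supply a
    real frequency table as CSV for inference about actual pathogens.
    """
    return Path(str(resources.files("meropopk.data").joinpath("example_mic_distribution_synthetic.csv")))
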