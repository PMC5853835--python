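"""Plain-text formats: events TSV, wide channel-series TSV with JSON
sidecars, behavioral tables, amplitude maps, and the run configuration.

Everything round-trips losslessly (to float formatting tolerance for the
series).  Events follow the BIDS-events dialect -- ``onset`` and
``duration`` in seconds, 0-based from run start, plus ``trial_type`` --
with per-sentence phrase onsets carried in extra columns.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import EventDesign
from .recordings import EEGRecording, HbRecording

EVENT_COLUMNS = ("onset", "duration", "trial_type")


# -------------------------------------------------------------------- events

def write_events(design: EventDesign, path: str | Path) -> None:
    design.trials.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path: str | Path) -> EventDesign:
    # keep_default_na off so the 'null' trial label survives parsing
    df = pd.read_csv(path, sep="\t", na_values=["n/a"],
                     keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("onset", "duration"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: malformed {col} {df[col].iloc[row]!r} at data row "
                f"{row + 1} (line {row + 2})")
        df[col] = pd.to_numeric(df[col])
    onsets = df["onset"].to_numpy()
    if np.any(np.diff(onsets) < 0):
        row = int(np.flatnonzero(np.diff(onsets) < 0)[0]) + 1
        raise ValueError(f"{path}: onsets unsorted at data row {row + 1} "
                         f"(line {row + 2})")
    return EventDesign(df)


# -------------------------------------------------------------- wide series

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_series(rec: HbRecording | EEGRecording, path: str | Path) -> None:
    """Wide TSV (time + one column per channel/species) with a JSON sidecar
    holding rate, units, kind and provenance flags."""
    path = Path(path)
    if isinstance(rec, HbRecording):
        n = rec.n_samples
        cols = {"time": np.arange(n) / rec.rate_hz}
        for sp in ("oxy", "deoxy"):
            arr = rec.species(sp)
            for i, ch in enumerate(rec.channels):
                cols[f"{ch}_{sp}"] = arr[i]
        meta = {"kind": "fnirs", "rate_hz": rec.rate_hz, "units": rec.units,
                "channels": list(rec.channels), "detrended": rec.detrended,
                "precolored": rec.precolored}
    elif isinstance(rec, EEGRecording):
        n = rec.n_samples
        cols = {"time": np.arange(n) / rec.rate_hz}
        for i, ch in enumerate(rec.channels):
            cols[ch] = rec.data[i]
        meta = {"kind": "eeg", "rate_hz": rec.rate_hz, "units": "uV",
                "channels": list(rec.channels),
                "filters": list(rec.filters)}
    else:
        raise TypeError(f"cannot serialise {type(rec).__name__}")
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False,
                              float_format="%.10g")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_series(path: str | Path) -> HbRecording | EEGRecording:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path, sep="\t")
    n = len(df)
    rate = float(meta["rate_hz"])
    if n > 1:
        dt = float(df["time"].iloc[1] - df["time"].iloc[0])
        if abs(dt * rate - 1.0) > 1e-6:
            raise ValueError(f"{path}: sample spacing {dt} does not match "
                             f"sidecar rate {rate} Hz")
    channels = tuple(meta["channels"])
    if meta["kind"] == "fnirs":
        oxy = np.stack([df[f"{ch}_oxy"].to_numpy() for ch in channels])
        deoxy = np.stack([df[f"{ch}_deoxy"].to_numpy() for ch in channels])
        return HbRecording(oxy=oxy, deoxy=deoxy, channels=channels,
                           rate_hz=rate, detrended=meta.get("detrended", False),
                           precolored=meta.get("precolored", False))
    if meta["kind"] == "eeg":
        data = np.stack([df[ch].to_numpy() for ch in channels])
        return EEGRecording(data=data, channels=channels, rate_hz=rate,
                            filters=tuple(meta.get("filters", ())))
    raise ValueError(f"unknown series kind {meta['kind']!r}")


# ---------------------------------------------------------------- run config

@dataclasses.dataclass
class RunConfig:
    """Serialisable options for an end-to-end run."""

    seed: int = 0
    n_boys: int = 31
    n_girls: int = 22
    detrend_method: str = "dct"
    dct_cutoff_hz: float = 1.0 / 128.0
    tau_min: int = 3
    tau_max: int = 20
    reference_channel: int = 16
    top_fraction: float = 0.10
    family_alpha: float = 0.05
    secondary_alpha: float = 0.05
    true_tau_p: float = 5.0
    artifact_fraction: float = 0.05

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @property
    def tau_grid(self) -> tuple[int, ...]:
        return tuple(range(self.tau_min, self.tau_max + 1))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
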