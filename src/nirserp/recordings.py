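"""In-memory containers for the two recording modalities.

Arrays are channel-major float64; channel identity travels with the data so
hemisphere/index addressing (``L-16``) survives every pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

FNIRS_RATE_HZ = 10.0
EEG_RATE_HZ = 500.0

#: scalp electrodes of the five-site montage, then references and EOG
EEG_SCALP = ("Fz", "Cz", "Pz", "F5", "F6")
EEG_REFERENCE = ("A1", "A2")
EEG_EOG = "EOG"
EEG_CHANNELS = EEG_SCALP + EEG_REFERENCE + (EEG_EOG,)


def _check_matrix(name: str, arr: np.ndarray, n_channels: int) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != n_channels:
        raise ValueError(f"{name} must be (n_channels, n_samples)")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class OpticalRecording:
    """Two-wavelength optical-density changes, channel x time, 10 Hz."""

    od: np.ndarray                  # (n_channels, n_wavelengths, n_samples)
    channels: tuple[str, ...]       # e.g. ("L-1", ..., "R-22")
    wavelengths_nm: tuple[float, float] = (695.0, 830.0)
    rate_hz: float = FNIRS_RATE_HZ

    def __post_init__(self) -> None:
        od = np.asarray(self.od, dtype=float)
        if od.ndim != 3 or od.shape[:2] != (len(self.channels),
                                            len(self.wavelengths_nm)):
            raise ValueError("od must be (n_channels, n_wavelengths, n_samples)")
        if not np.all(np.isfinite(od)):
            raise ValueError("od contains non-finite values")
        object.__setattr__(self, "od", od)

    @property
    def n_samples(self) -> int:
        return self.od.shape[2]


@dataclass(frozen=True)
class HbRecording:
    """Oxy-/deoxy-haemoglobin concentration-change series in mM*mm, 10 Hz."""

    oxy: np.ndarray                 # (n_channels, n_samples)
    deoxy: np.ndarray
    channels: tuple[str, ...]
    rate_hz: float = FNIRS_RATE_HZ
    units: str = "mM*mm"
    detrended: bool = False
    precolored: bool = False

    def __post_init__(self) -> None:
        oxy = _check_matrix("oxy", self.oxy, len(self.channels))
        deoxy = _check_matrix("deoxy", self.deoxy, len(self.channels))
        if oxy.shape != deoxy.shape:
            raise ValueError("oxy and deoxy must have identical shape")
        object.__setattr__(self, "oxy", oxy)
        object.__setattr__(self, "deoxy", deoxy)

    @property
    def n_samples(self) -> int:
        return self.oxy.shape[1]

    def species(self, name: str) -> np.ndarray:
        if name == "oxy":
            return self.oxy
        if name == "deoxy":
            return self.deoxy
        raise KeyError(f"unknown species {name!r}")

    def with_data(self, oxy: np.ndarray, deoxy: np.ndarray,
                  **flags) -> "HbRecording":
        return replace(self, oxy=oxy, deoxy=deoxy, **flags)


@dataclass(frozen=True)
class EEGRecording:
    """Continuous EEG in microvolts at 500 Hz with fixed channel roles."""

    data: np.ndarray                # (n_channels, n_samples)
    channels: tuple[str, ...] = EEG_CHANNELS
    rate_hz: float = EEG_RATE_HZ
    filters: tuple[str, ...] = ()   # provenance of applied filters

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        data = _check_matrix("data", self.data, len(self.channels))
        object.__setattr__(self, "data", data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None

    def get(self, name: str) -> np.ndarray:
        return self.data[self.index(name)]

    def scalp_indices(self) -> list[int]:
        return [self.index(c) for c in EEG_SCALP if c in self.channels]

    def with_data(self, data: np.ndarray, note: str | None = None) -> "EEGRecording":
        filters = self.filters + ((note,) if note else ())
        return replace(self, data=data, filters=filters)
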