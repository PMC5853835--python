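"""Optical-density to haemoglobin conversion and temporal conditioning.

Three stages, in the order the downstream GLM expects them:

1. ``mbll`` -- the modified Beer-Lambert law for a highly scattering
   medium: per channel and time point, solve the 2x2 linear system
   ``dOD(lambda) = eps_oxy(lambda)*dHbO + eps_deoxy(lambda)*dHbR`` for the
   oxy-/deoxy-haemoglobin changes.  Differential pathlength is folded into
   the output units (mM*mm), matching the convention of continuous-wave
   instruments that report concentration x pathlength.
2. ``detrend`` -- removal of slow global trends (drift, vasomotor and other
   low-frequency physiology).  Two interchangeable estimators: a cosine
   (DCT) high-pass with an explicit cutoff, and a discrete-wavelet trend
   with the decomposition depth selected by a minimum-description-length
   cost over levels.
3. ``precolor`` -- temporal smoothing by convolution with the unit-sum
   canonical HRF, imposing a known autocorrelation before ordinary least
   squares.  The matching kernel must also be applied to the design matrix
   (see ``nirserp.glm``) to keep the amplitude estimates unbiased.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .hrf import HRFParams, CANONICAL, sample_hrf_unit_sum
from .recordings import HbRecording, OpticalRecording


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients, 1/(mM*mm), for the two wavelengths."""

    wavelengths_nm: tuple[float, float]
    #: rows = wavelengths, columns = (oxy, deoxy)
    eps: np.ndarray

    def __post_init__(self) -> None:
        eps = np.asarray(self.eps, dtype=float)
        if eps.shape != (2, 2):
            raise ValueError("extinction matrix must be 2x2")
        cond = np.linalg.cond(eps)
        if not np.isfinite(cond) or cond > 1e8:
            raise ValueError(
                f"extinction matrix is singular or near-singular (cond={cond:.3g})")
        object.__setattr__(self, "eps", eps)


def default_extinction() -> ExtinctionTable:
    """Standard tabulated coefficients at 695/830 nm shipped with the package."""
    ref = importlib.resources.files("nirserp.data") / "extinction_695_830.csv"
    with importlib.resources.as_file(ref) as path:
        tab = pd.read_csv(path)
    wls = tuple(sorted(tab["wavelength_nm"].unique()))
    eps = np.array([
        [float(tab[(tab["wavelength_nm"] == wl)
                   & (tab["species"] == sp)]["epsilon_per_mM_mm"].iloc[0])
         for sp in ("oxy", "deoxy")]
        for wl in wls
    ])
    return ExtinctionTable((float(wls[0]), float(wls[1])), eps)


def mbll(od: OpticalRecording,
         ext: ExtinctionTable | None = None) -> HbRecording:
    """Invert the modified Beer-Lambert law channel- and sample-wise."""
    ext = ext or default_extinction()
    if tuple(od.wavelengths_nm) != tuple(ext.wavelengths_nm):
        raise ValueError(
            f"wavelength mismatch: recording {od.wavelengths_nm} vs "
            f"extinction table {ext.wavelengths_nm}")
    inv = np.linalg.inv(ext.eps)
    # od: (ch, wl, t) -> hb: (ch, species, t)
    hb = np.einsum("sw,cwt->cst", inv, od.od)
    return HbRecording(oxy=hb[:, 0], deoxy=hb[:, 1],
                       channels=od.channels, rate_hz=od.rate_hz)


def forward_mbll(hb: HbRecording,
                 ext: ExtinctionTable | None = None) -> OpticalRecording:
    """Forward model: haemoglobin changes to two-wavelength optical density."""
    ext = ext or default_extinction()
    stacked = np.stack([hb.oxy, hb.deoxy], axis=1)      # (ch, species, t)
    od = np.einsum("ws,cst->cwt", ext.eps, stacked)
    return OpticalRecording(od=od, channels=hb.channels,
                            wavelengths_nm=ext.wavelengths_nm,
                            rate_hz=hb.rate_hz)


# ---------------------------------------------------------------- detrending

def dct_basis(n: int, rate_hz: float, cutoff_hz: float) -> np.ndarray:
    """Orthonormal trend basis: DCT-II cosines with frequency k*rate/(2N)
    below ``cutoff_hz`` (including the constant, k=0) plus a linear ramp so
    that constant and linear drift are removed exactly."""
    k_max = int(np.ceil(cutoff_hz * 2.0 * n / rate_hz))
    k = np.arange(max(k_max, 1))
    t = np.arange(n)
    cosines = np.cos(np.pi * (t[:, None] + 0.5) * k[None, :] / n)
    ramp = (t - t.mean()).astype(float)
    basis = np.column_stack([cosines, ramp])
    q, _ = np.linalg.qr(basis)
    return q


def dct_trend(y: np.ndarray, rate_hz: float, cutoff_hz: float) -> np.ndarray:
    """Low-frequency trend: orthogonal projection of each row onto the
    retained cosine-plus-ramp basis."""
    q = dct_basis(y.shape[-1], rate_hz, cutoff_hz)
    return (y @ q) @ q.T


def wavelet_mdl_trend(y: np.ndarray, wavelet: str = "db5") -> np.ndarray:
    """Trend as the approximation branch of a DWT, depth chosen by an MDL
    cost: (n/2)*log(RSS/n) + (k/2)*log(n) over candidate levels, where k is
    the number of approximation coefficients retained.  Deeper levels give
    smoother trends with fewer coefficients but larger residuals; the MDL
    minimum balances the two."""
    y = np.atleast_2d(y)
    n = y.shape[-1]
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    if max_level < 1:
        raise ValueError("series too short for wavelet detrending")
    def approx_trend(arr, level):
        coeffs = pywt.wavedec(arr, wavelet, level=level, axis=-1)
        rec = pywt.waverec(
            [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]],
            wavelet, axis=-1)[..., :n]
        return rec, coeffs[0].shape[-1]

    best_cost, best_level = np.inf, 1
    for level in range(1, max_level + 1):
        trend, k = approx_trend(y, level)
        rss = max(float(np.sum((y - trend) ** 2)), 1e-300)
        cost = (n / 2.0) * np.log(rss / n) + (k / 2.0) * np.log(n)
        if cost < best_cost:
            best_cost, best_level = cost, level
    # the approximation branch is only approximately a projection (boundary
    # leakage); iterate removal at the chosen depth to near-idempotency
    trend = np.zeros_like(y)
    resid = y
    for _ in range(4):
        step, _ = approx_trend(resid, best_level)
        trend = trend + step
        resid = y - trend
    return trend


def detrend(hb: HbRecording, method: str = "dct",
            cutoff_hz: float = 1.0 / 128.0,
            wavelet: str = "db5") -> HbRecording:
    """Subtract the slow global trend from every channel of both species.

    ``method='dct'`` removes the retained low-frequency cosine basis below
    ``cutoff_hz`` (deterministic, exactly idempotent); ``method='wavelet_mdl'``
    subtracts the MDL-selected wavelet approximation.  Output is mean-zero
    per channel.
    """
    if hb.n_samples < 16:
        raise ValueError("series too short to estimate a trend")
    if method == "dct":
        trend_fn = lambda y: dct_trend(y, hb.rate_hz, cutoff_hz)
    elif method == "wavelet_mdl":
        trend_fn = lambda y: wavelet_mdl_trend(y, wavelet)
    else:
        raise ValueError(f"unknown detrending method {method!r}")
    out = {}
    for sp in ("oxy", "deoxy"):
        y = hb.species(sp)
        resid = y - trend_fn(y)
        resid = resid - resid.mean(axis=-1, keepdims=True)
        out[sp] = resid
    return hb.with_data(out["oxy"], out["deoxy"], detrended=True)


# ---------------------------------------------------------------- precoloring

def smooth_with_hrf(arr: np.ndarray, rate_hz: float,
                    params: HRFParams = CANONICAL) -> np.ndarray:
    """Causal convolution with the unit-sum canonical HRF, truncated to the
    input length.  Applied identically to data rows and design columns."""
    kernel = sample_hrf_unit_sum(params, rate_hz)
    arr = np.atleast_2d(arr)
    n = arr.shape[-1]
    out = np.empty_like(arr, dtype=float)
    for i in range(arr.shape[0]):
        out[i] = np.convolve(arr[i], kernel)[:n]
    return out


def precolor(hb: HbRecording, params: HRFParams = CANONICAL) -> HbRecording:
    """Temporal smoothing of both species with the canonical HRF kernel."""
    return hb.with_data(smooth_with_hrf(hb.oxy, hb.rate_hz, params),
                        smooth_with_hrf(hb.deoxy, hb.rate_hz, params),
                        precolored=True)
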