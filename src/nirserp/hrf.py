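"""Double-gamma hemodynamic response function with a tunable first-peak latency.

The kernel used throughout the package is

    h(tau_p, t) = t**tau_p * exp(-t) / Gamma(tau_p + 1)
                - t**(tau_p + tau_d) * exp(-t) / (A * Gamma(tau_p + tau_d + 1))

where ``tau_p`` is the latency (s) of the first, positive peak, ``tau_p +
tau_d`` the latency of the small post-stimulus undershoot, and ``A`` the
amplitude ratio between the two peaks.  The factorials of the integer-latency
formulation are generalised through the gamma function so non-integer
latencies are legal.  The widely used default is ``(tau_p, tau_d, A) =
(6, 10, 6)``; peak-latency sweeps scan ``tau_p`` over an integer grid,
conventionally 3-20 s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln

#: default sweep grid for the first-peak latency (seconds)
DEFAULT_TAU_GRID = tuple(range(3, 21))

#: kernel support truncation (seconds); |h| < 1e-6 beyond this for the
#: latencies on the default sweep grid
KERNEL_SUPPORT_S = 60.0


@dataclass(frozen=True)
class HRFParams:
    """Temporal parameters of the double-gamma HRF.

    Parameters
    ----------
    tau_p : first-peak latency in seconds (> 0).
    tau_d : delay of the undershoot peak after the first peak, seconds (> 0).
    A : first/second peak amplitude ratio (> 0).
    """

    tau_p: float = 6.0
    tau_d: float = 10.0
    A: float = 6.0

    def __post_init__(self) -> None:
        if not (self.tau_p > 0 and self.tau_d > 0 and self.A > 0):
            raise ValueError(
                f"HRF parameters must be positive, got "
                f"(tau_p, tau_d, A) = ({self.tau_p}, {self.tau_d}, {self.A})"
            )

    def with_tau_p(self, tau_p: float) -> "HRFParams":
        return replace(self, tau_p=tau_p)


CANONICAL = HRFParams()


def hrf_curve(params: HRFParams, t: np.ndarray) -> np.ndarray:
    """Evaluate the double-gamma HRF on a grid of non-negative times.

    Both gamma-shaped terms are evaluated in log space for numerical
    stability; ``h(0) = 0`` exactly.

    Parameters
    ----------
    params : HRF temporal parameters.
    t : time grid in seconds, all values >= 0.

    Returns
    -------
    ndarray of ``h(t)`` with the same shape as ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("HRF is causal: time grid must be non-negative")
    p, d, A = params.tau_p, params.tau_d, params.A
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    logt = np.log(tp)
    first = np.exp(p * logt - tp - gammaln(p + 1.0))
    under = np.exp((p + d) * logt - tp - gammaln(p + d + 1.0)) / A
    out[pos] = first - under
    return out


def sample_hrf(params: HRFParams, rate_hz: float,
               support_s: float = KERNEL_SUPPORT_S) -> np.ndarray:
    """Sample the HRF at a recording rate over its truncated support."""
    n = int(round(support_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    return hrf_curve(params, t)


def sample_hrf_unit_sum(params: HRFParams, rate_hz: float,
                        support_s: float = KERNEL_SUPPORT_S) -> np.ndarray:
    """Sampled HRF normalised to unit sum, for use as a smoothing kernel."""
    h = sample_hrf(params, rate_hz, support_s)
    s = h.sum()
    if abs(s) < 1e-12:
        raise ValueError("HRF kernel sums to ~0; cannot normalise")
    return h / s
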