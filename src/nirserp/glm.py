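"""GLM amplitude estimation with an adaptive-latency HRF.

The haemodynamic regression model is built by convolving a boxcar for each
stimulus condition with the double-gamma HRF of ``nirserp.hrf`` sampled at
the recording rate.  Because the canonical 6 s peak latency need not fit a
given population or cortical region, the first-peak latency ``tau_p`` is
swept over an integer grid (default 3-20 s), the whole GLM refit at each
latency, and the best latency chosen from the grand-average amplitude of a
reference channel in each hemisphere (the channel must itself sit within
the top fraction of per-hemisphere peak amplitudes for the rule to be
trusted; the report records the check).

Sentence conditions (correct/incorrect/filler) are modeled as regressors of
interest; the pure-tone vigilance probes enter as a nuisance regressor and
silent null events span the unmodelled baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import EventDesign
from .hrf import HRFParams, DEFAULT_TAU_GRID, sample_hrf
from .montage import ProbeLayout
from .preprocess import smooth_with_hrf
from .recordings import HbRecording

MODELED_CONDITIONS = ("correct", "incorrect", "filler", "tone")
SENTENCE_REGRESSORS = ("correct", "incorrect", "filler")
CONSTANT = "constant"


@dataclass(frozen=True)
class DesignMatrix:
    """Time x regressor matrix with labels and the HRF that built it."""

    X: np.ndarray
    labels: tuple[str, ...]
    rate_hz: float
    hrf: HRFParams

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.labels):
            raise ValueError("label count must match column count")

    def column(self, label: str) -> np.ndarray:
        return self.X[:, self.labels.index(label)]


def boxcar(onsets: np.ndarray, durations: np.ndarray, rate_hz: float,
           n_samples: int) -> np.ndarray:
    """Indicator series: 1 while any event is on, half-open [on, on+dur)."""
    out = np.zeros(n_samples)
    for on, dur in zip(onsets, durations):
        i0 = int(np.ceil(on * rate_hz - 1e-9))
        i1 = int(np.ceil((on + dur) * rate_hz - 1e-9))
        out[max(i0, 0):min(i1, n_samples)] = 1.0
    return out


def build_design_matrix(design: EventDesign, params: HRFParams,
                        rate_hz: float, n_samples: int,
                        precolor_with: HRFParams | None = None) -> DesignMatrix:
    """Boxcar-convolved regressors for every modeled condition plus constant.

    Null events contribute no regressor.  If ``precolor_with`` is given the
    task columns are smoothed with that canonical kernel, matching the
    precoloring applied to the data.
    """
    if design.total_duration_s * rate_hz > n_samples + 1e-6:
        raise ValueError("design extends beyond the recording")
    h = sample_hrf(params, rate_hz)
    cols, labels = [], []
    trials = design.trials
    for cond in MODELED_CONDITIONS:
        sel = trials[trials["trial_type"] == cond]
        if sel.empty:
            continue
        box = boxcar(sel["onset"].to_numpy(), sel["duration"].to_numpy(),
                     rate_hz, n_samples)
        col = np.convolve(box, h)[:n_samples]
        if not np.any(col):
            raise ValueError(f"regressor {cond!r} is identically zero")
        cols.append(col)
        labels.append(cond)
    if precolor_with is not None and cols:
        smoothed = smooth_with_hrf(np.array(cols), rate_hz, precolor_with)
        cols = list(smoothed)
    cols.append(np.ones(n_samples))
    labels.append(CONSTANT)
    return DesignMatrix(np.column_stack(cols), tuple(labels), rate_hz, params)


@dataclass(frozen=True)
class GLMFit:
    """Per-channel amplitude estimates for one recording and design."""

    betas: pd.DataFrame     # columns: channel, species, condition, beta, t
    sigma2: pd.DataFrame    # columns: channel, species, sigma2, df


def _check_rank(dm: DesignMatrix) -> None:
    rank = np.linalg.matrix_rank(dm.X)
    if rank < dm.X.shape[1]:
        # name the offending columns by correlation structure (constant
        # columns yield NaN rows; harmless for the diagnostic)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.corrcoef(dm.X.T)
        bad = [
            f"{dm.labels[i]}~{dm.labels[j]}"
            for i in range(len(dm.labels)) for j in range(i + 1, len(dm.labels))
            if abs(c[i, j]) > 1 - 1e-10
        ]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {dm.X.shape[1]}); "
            f"collinear columns: {bad or 'not pairwise'}")


def fit_glm(hb: HbRecording, dm: DesignMatrix,
            species: tuple[str, ...] = ("oxy", "deoxy")) -> GLMFit:
    """Ordinary least squares per channel and species with t statistics.

    ``beta = argmin ||y - X beta||^2``; ``t_j = beta_j / sqrt(s2 * inv(X'X)_jj)``
    with ``s2`` the residual variance on ``n - p`` degrees of freedom.
    """
    if hb.n_samples != dm.X.shape[0]:
        raise ValueError("recording length does not match design matrix rows")
    _check_rank(dm)
    X = dm.X
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    n, p = X.shape
    dof = n - p
    rows, srows = [], []
    for sp in species:
        Y = hb.species(sp)                       # (ch, t)
        B = Y @ pinv.T                           # (ch, p)
        resid = Y - B @ X.T
        s2 = (resid ** 2).sum(axis=1) / dof      # (ch,)
        se = np.sqrt(np.outer(s2, np.diag(xtx_inv)))
        with np.errstate(divide="ignore", invalid="ignore"):
            T = np.where(se > 0, B / se, np.inf * np.sign(B))
        for ci, ch in enumerate(hb.channels):
            srows.append((ch, sp, s2[ci], dof))
            for j, lab in enumerate(dm.labels):
                rows.append((ch, sp, lab, B[ci, j], T[ci, j]))
    betas = pd.DataFrame(rows, columns=["channel", "species", "condition",
                                        "beta", "t"])
    sigma2 = pd.DataFrame(srows, columns=["channel", "species", "sigma2", "df"])
    return GLMFit(betas, sigma2)


def fit_subjects(subjects: list[tuple[HbRecording, EventDesign]],
                 params: HRFParams,
                 precolor_with: HRFParams | None = None,
                 species: tuple[str, ...] = ("oxy", "deoxy")) -> pd.DataFrame:
    """BetaMap slice at one latency: long table over subjects.

    Subjects sharing the same ``EventDesign`` object share one design
    matrix.  Returns columns subject, channel, species, condition, tau_p,
    beta, t.
    """
    cache: dict[int, DesignMatrix] = {}
    frames = []
    for sid, (hb, design) in enumerate(subjects):
        key = id(design)
        if key not in cache or cache[key].X.shape[0] != hb.n_samples:
            cache[key] = build_design_matrix(design, params, hb.rate_hz,
                                             hb.n_samples, precolor_with)
        fit = fit_glm(hb, cache[key], species)
        b = fit.betas.copy()
        b.insert(0, "subject", sid)
        frames.append(b)
    out = pd.concat(frames, ignore_index=True)
    out["tau_p"] = params.tau_p
    return out


def sweep_tau(subjects: list[tuple[HbRecording, EventDesign]],
              tau_grid: tuple[int, ...] = DEFAULT_TAU_GRID,
              base_params: HRFParams | None = None,
              precolor_with: HRFParams | None = None,
              conditions: tuple[str, ...] = SENTENCE_REGRESSORS,
              species: tuple[str, ...] = ("oxy", "deoxy")) -> pd.DataFrame:
    """Full GLM refit at every latency on the sweep grid.

    Returns the grand-average amplitude surface: one row per (tau_p,
    channel, species), with ``beta`` averaged over subjects and the
    sentence conditions (vigilance tones and null events excluded).
    """
    base = base_params or HRFParams()
    surfaces = []
    for tau in tau_grid:
        bm = fit_subjects(subjects, base.with_tau_p(float(tau)),
                          precolor_with, species)
        bm = bm[bm["condition"].isin(conditions)]
        surf = (bm.groupby(["channel", "species"], as_index=False)["beta"]
                .mean())
        surf["tau_p"] = float(tau)
        surfaces.append(surf)
    return pd.concat(surfaces, ignore_index=True)[
        ["tau_p", "channel", "species", "beta"]]


@dataclass(frozen=True)
class TauSelection:
    """Outcome of the optimal-latency rule with its audit trail."""

    tau_star: float
    per_hemisphere_argmax: dict[str, float]
    reference_in_top_fraction: dict[str, bool]
    rounded: bool
    species: str
    reference_channel: int
    top_fraction: float

    def to_dict(self) -> dict:
        return {
            "tau_star": self.tau_star,
            "per_hemisphere_argmax": self.per_hemisphere_argmax,
            "reference_in_top_fraction": self.reference_in_top_fraction,
            "rounded": self.rounded,
            "species": self.species,
            "reference_channel": self.reference_channel,
            "top_fraction": self.top_fraction,
        }


def select_optimal_tau(surface: pd.DataFrame, layout: ProbeLayout,
                       reference_channel: int = 16,
                       top_fraction: float = 0.10,
                       species: str = "oxy") -> TauSelection:
    """Latency selection from a reference channel's amplitude peak.

    Per hemisphere, the latency maximising the reference channel's
    grand-average amplitude is found (ties broken toward the smallest
    latency); the selected latency is the mean of the two, rounded half-up
    to the sweep grid when fractional.  The rule is only meaningful when
    the reference channel is among the strongest responders, so the report
    records whether its peak amplitude lies within the top ``top_fraction``
    of per-hemisphere channel peaks.
    """
    if not 1 <= reference_channel <= layout.n_channels:
        raise ValueError(
            f"reference channel {reference_channel} not in layout 1.."
            f"{layout.n_channels}")
    surf = surface[surface["species"] == species]
    if surf.empty:
        raise ValueError(f"surface has no rows for species {species!r}")
    argmax, in_top = {}, {}
    grid = np.sort(surf["tau_p"].unique())
    for hemi in ("L", "R"):
        ref = f"{hemi}-{reference_channel}"
        sub = surf[surf["channel"] == ref].sort_values("tau_p")
        if sub.empty:
            raise ValueError(f"reference channel {ref} absent from surface")
        betas = sub["beta"].to_numpy()
        argmax[hemi] = float(sub["tau_p"].to_numpy()[int(np.argmax(betas))])
        hemi_peaks = (surf[surf["channel"].str.startswith(hemi + "-")]
                      .groupby("channel")["beta"].max())
        n_top = max(1, int(round(top_fraction * len(hemi_peaks))))
        top = set(hemi_peaks.sort_values(ascending=False).head(n_top).index)
        in_top[hemi] = ref in top
    mean_tau = (argmax["L"] + argmax["R"]) / 2.0
    on_grid = np.isclose(grid, mean_tau).any()
    if on_grid:
        tau_star, rounded = float(mean_tau), False
    else:
        # half-up to the nearest grid value
        tau_star = float(grid[np.searchsorted(grid, mean_tau)])
        below = grid[grid <= mean_tau]
        if below.size and mean_tau - below[-1] < tau_star - mean_tau:
            tau_star = float(below[-1])
        rounded = True
    return TauSelection(tau_star, argmax, in_top, rounded, species,
                        reference_channel, top_fraction)
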