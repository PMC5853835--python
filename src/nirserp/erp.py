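"""ERP conditioning, violation-locked epoching, and phase-window statistics.

The processing chain mirrors standard practice for a five-electrode
sentence-violation paradigm: linked-earlobe re-reference, regression-based
ocular correction, zero-phase 30 Hz low-pass (second-order Butterworth
applied forward-backward, i.e. a 12 dB/octave design), epoching from 200 ms
before to 1000 ms after the second-phrase (violation) onset with baseline
subtraction, +-100 uV artifact rejection, and mean amplitudes in four
analysis windows: phase 1 (100-300 ms, early anterior negativity), phase
2-a (300-450 ms), phase 2-b (450-600 ms, N400-like negativity), and phase 3
(600-800 ms).

Group inference is a split-plot ANOVA -- sex between subjects,
grammaticality (2) and electrode (5) within -- with Greenhouse-Geisser
correction of the degrees of freedom for effects involving the electrode
factor, partial eta squared per effect, and paired/Welch post hoc tests
with Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .recordings import EEG_SCALP, EEGRecording

#: analysis windows, ms post violation onset, half-open [start, end)
PHASES = {
    "phase1": (100.0, 300.0),
    "phase2a": (300.0, 450.0),
    "phase2b": (450.0, 600.0),
    "phase3": (600.0, 800.0),
}


# ------------------------------------------------------------- conditioning

def rereference(eeg: EEGRecording) -> EEGRecording:
    """Subtract the mean of the two earlobe electrodes from every scalp
    channel (off-line linked-earlobe reference)."""
    for ref in ("A1", "A2"):
        if ref not in eeg.channels:
            raise ValueError(f"earlobe channel {ref} missing")
    ref = 0.5 * (eeg.get("A1") + eeg.get("A2"))
    data = eeg.data.copy()
    for i in eeg.scalp_indices():
        data[i] = data[i] - ref
    return eeg.with_data(data, note="linked_earlobes")


def eog_correct(eeg: EEGRecording) -> EEGRecording:
    """Remove blink leakage by run-wise least-squares EOG regression.

    Per scalp channel, subtract ``b * EOG`` with ``b = cov(ch, EOG) /
    var(EOG)``.  A flat EOG channel leaves the data untouched (with a
    warning) rather than dividing by zero.
    """
    import warnings
    eog = eeg.get("EOG")
    var = float(np.var(eog))
    if var < 1e-12:
        warnings.warn("EOG channel is flat; skipping ocular correction")
        return eeg
    eog_c = eog - eog.mean()
    data = eeg.data.copy()
    for i in eeg.scalp_indices():
        b = float(np.dot(data[i] - data[i].mean(), eog_c)) / (var * len(eog))
        data[i] = data[i] - b * eog
    return eeg.with_data(data, note="eog_regression")


def lowpass_zero_phase(eeg: EEGRecording, cutoff_hz: float = 30.0) -> EEGRecording:
    """Forward-backward second-order Butterworth low-pass (12 dB/octave
    one-way; the two passes double the effective attenuation and cancel the
    phase shift)."""
    if cutoff_hz >= eeg.rate_hz / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = signal.butter(2, cutoff_hz, btype="low", fs=eeg.rate_hz,
                        output="sos")
    data = eeg.data.copy()
    for i in eeg.scalp_indices():
        data[i] = signal.sosfiltfilt(sos, data[i])
    return eeg.with_data(data, note=f"lowpass_{cutoff_hz:g}Hz_zero_phase")


# ------------------------------------------------------------------ epoching

@dataclass
class EpochSet:
    """Violation-locked epochs with a rejection mask.

    ``data`` is (n_trials, n_scalp_channels, n_times) in uV, baseline
    corrected; ``times`` in seconds relative to the violation onset;
    ``dropped`` counts trials whose window fell outside the recording.
    """

    data: np.ndarray
    times: np.ndarray
    conditions: np.ndarray
    channels: tuple[str, ...]
    rate_hz: float
    rejected: np.ndarray = field(default=None)
    reject_reason: list = field(default_factory=list)
    dropped: int = 0

    def __post_init__(self) -> None:
        if self.rejected is None:
            self.rejected = np.zeros(len(self.conditions), dtype=bool)
            self.reject_reason = [""] * len(self.conditions)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def surviving(self, condition: str | None = None) -> np.ndarray:
        keep = ~self.rejected
        if condition is not None:
            keep &= self.conditions == condition
        return np.flatnonzero(keep)


def epoch_and_baseline(eeg: EEGRecording, onsets: pd.DataFrame,
                       window_s: tuple[float, float] = (-0.2, 1.0)) -> EpochSet:
    """Extract violation-locked epochs and subtract the pre-onset baseline.

    ``onsets`` needs columns ``onset`` (s, absolute) and ``trial_type``.
    Windows are half-open ``[start, end)``; the onset sample is included.
    The per-epoch, per-channel mean over the pre-onset part of the window
    is subtracted.  Trials whose window exceeds the recording bounds are
    dropped and counted, not extracted.
    """
    rate = eeg.rate_hz
    n_times = int(round((window_s[1] - window_s[0]) * rate))
    start_samp = int(round(window_s[0] * rate))
    times = np.arange(start_samp, start_samp + n_times) / rate
    scalp_idx = eeg.scalp_indices()
    channels = tuple(eeg.channels[i] for i in scalp_idx)
    epochs, conds, dropped = [], [], 0
    for _, row in onsets.iterrows():
        i0 = int(round((row["onset"] + window_s[0]) * rate))
        i1 = i0 + n_times
        if i0 < 0 or i1 > eeg.n_samples:
            dropped += 1
            continue
        seg = eeg.data[scalp_idx, i0:i1].astype(float)
        base = seg[:, times < 0].mean(axis=1, keepdims=True)
        epochs.append(seg - base)
        conds.append(row["trial_type"])
    data = (np.stack(epochs) if epochs
            else np.empty((0, len(channels), n_times)))
    return EpochSet(data=data, times=times,
                    conditions=np.asarray(conds, dtype=object),
                    channels=channels, rate_hz=rate, dropped=dropped)


def reject_artifacts(epochs: EpochSet,
                     threshold_uv: float = 100.0) -> EpochSet:
    """Mask every trial with any scalp sample exceeding the amplitude
    threshold; earlier masks are preserved."""
    peak = np.abs(epochs.data).max(axis=(1, 2)) if epochs.n_trials else \
        np.empty(0)
    bad = peak > threshold_uv
    rejected = epochs.rejected | bad
    reasons = [
        (r if r else (f"amplitude>{threshold_uv:g}uV" if b else ""))
        for r, b in zip(epochs.reject_reason, bad)
    ]
    return EpochSet(data=epochs.data, times=epochs.times,
                    conditions=epochs.conditions, channels=epochs.channels,
                    rate_hz=epochs.rate_hz, rejected=rejected,
                    reject_reason=reasons, dropped=epochs.dropped)


def rejection_counts(epochs: EpochSet) -> pd.DataFrame:
    rows = []
    for cond in pd.unique(epochs.conditions):
        m = epochs.conditions == cond
        rows.append((cond, int(m.sum()), int((m & epochs.rejected).sum())))
    return pd.DataFrame(rows, columns=["condition", "n_trials", "n_rejected"])


def window_amplitudes(epochs: EpochSet,
                      phases: dict[str, tuple[float, float]] = PHASES
                      ) -> pd.DataFrame:
    """Mean amplitude per electrode x condition x phase window.

    Per-trial window means (half-open [start, end) in ms) are averaged over
    surviving trials.  A condition with no surviving trials is reported
    with NaN and flagged via the ``missing`` column.
    """
    # round away float jitter so window boundaries land on exact samples
    t_ms = np.round(epochs.times * 1000.0, 6)
    rows = []
    for cond in pd.unique(epochs.conditions):
        idx = epochs.surviving(cond)
        for phase, (lo, hi) in phases.items():
            m = (t_ms >= lo) & (t_ms < hi)
            for ci, ch in enumerate(epochs.channels):
                if idx.size == 0:
                    rows.append((ch, cond, phase, np.nan, True))
                else:
                    val = epochs.data[np.ix_(idx, [ci])][:, 0, m].mean()
                    rows.append((ch, cond, phase, float(val), False))
    return pd.DataFrame(rows, columns=["electrode", "condition", "phase",
                                       "amplitude", "missing"])


# ---------------------------------------------------------------- statistics

def gg_epsilon(within_covariance: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k within-factor covariance.

    Double-centers the covariance and returns ``tr(C)^2 / ((k-1) * sum
    C_ij^2)``, clipped to ``[1/(k-1), 1]``.
    """
    S = np.asarray(within_covariance, dtype=float)
    k = S.shape[0]
    if S.ndim != 2 or S.shape != (k, k) or k < 2:
        raise ValueError("need a square covariance with k >= 2 levels")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    row = S.mean(axis=0, keepdims=True)
    col = S.mean(axis=1, keepdims=True)
    C = S - row - col + S.mean()
    denom = (k - 1) * float(np.sum(C * C))
    if denom <= 0:
        return 1.0
    eps = float(np.trace(C)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal basis of the mean-zero subspace (Helmert)."""
    H = np.zeros((k, k - 1))
    for j in range(1, k):
        H[:j, j - 1] = 1.0
        H[j, j - 1] = -j
        H[:, j - 1] /= np.linalg.norm(H[:, j - 1])
    return H


def _type3_ss(Z: np.ndarray, groups: np.ndarray):
    """Per-column Type III sums of squares for intercept and group effect
    (effect-coded) plus residual SS, summed over columns of Z."""
    levels = pd.unique(groups)
    a = len(levels)
    n = len(groups)
    # effect coding: a-1 columns, last level = -1 on all
    G = np.zeros((n, a - 1))
    for j, lev in enumerate(levels[:-1]):
        G[groups == lev, j] = 1.0
    G[groups == levels[-1], :] = -1.0
    ones = np.ones((n, 1))

    def rss(X):
        if X.shape[1] == 0:
            return float(np.sum(Z * Z))
        beta, *_ = np.linalg.lstsq(X, Z, rcond=None)
        return float(np.sum((Z - X @ beta) ** 2))

    full = np.hstack([ones, G])
    rss_full = rss(full)
    ss_intercept = rss(G) - rss_full
    ss_group = rss(ones) - rss_full
    return ss_intercept, ss_group, rss_full, a


def mixed_anova(table: pd.DataFrame,
                dv: str = "amplitude",
                between: str = "sex",
                within: tuple[str, str] = ("condition", "electrode"),
                subject: str = "subject") -> pd.DataFrame:
    """Split-plot ANOVA: one between factor, two fully crossed within
    factors, via orthonormal-contrast projection of each subject's within-
    cell vector and Type III sums of squares on the contrast scores (exact
    for the balanced-within, possibly unequal-group design used here).

    Greenhouse-Geisser epsilon (from the pooled within-group covariance of
    each effect's contrast scores) corrects the p-value of every effect
    whose contrast space has more than one dimension.  Partial eta squared
    is ``SS_effect / (SS_effect + SS_error)``.
    """
    w1, w2 = within
    lev1 = sorted(table[w1].unique())
    lev2 = sorted(table[w2].unique())
    b, c = len(lev1), len(lev2)
    wide = table.pivot_table(index=[subject, between], columns=[w1, w2],
                             values=dv)
    wide = wide.reindex(columns=pd.MultiIndex.from_product([lev1, lev2]))
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.get_level_values(0)
        raise ValueError(f"missing within-cells for subjects: "
                         f"{sorted(set(missing))}")
    Y = wide.to_numpy()
    groups = wide.index.get_level_values(between).to_numpy()
    n = Y.shape[0]
    if min(pd.Series(groups).value_counts()) < 2:
        raise ValueError("need at least 2 subjects per between-group level")

    Cb, Cc = _orthonormal_contrasts(b), _orthonormal_contrasts(c)
    jb, jc = np.ones((b, 1)) / np.sqrt(b), np.ones((c, 1)) / np.sqrt(c)
    effects = {
        w1: np.kron(Cb, jc),
        w2: np.kron(jb, Cc),
        f"{w1}*{w2}": np.kron(Cb, Cc),
    }

    tol = 1e-12 * max(1.0, float(np.sum(Y * Y)))

    def f_ratio(ss, df1, sse, df2):
        if ss <= tol:
            return 0.0
        if sse <= tol:
            return np.inf
        return (ss / df1) / (sse / df2)

    def eta_p(ss, sse):
        return ss / (ss + sse) if ss + sse > 0 else 0.0

    rows = []
    # between-subjects stratum on the scaled subject means
    m = Y @ np.kron(jb, jc)
    ss_int, ss_A, ss_err, a = _type3_ss(m, groups)
    df_A, df_err = a - 1, n - a
    F = f_ratio(ss_A, df_A, ss_err, df_err)
    rows.append((between, ss_A, df_A, ss_err, df_err, F, 1.0,
                 stats.f.sf(F, df_A, df_err),
                 eta_p(ss_A, ss_err)))

    for name, M in effects.items():
        Z = Y @ M
        q = Z.shape[1]
        ss_w, ss_aw, ss_e, a = _type3_ss(Z, groups)
        df_e = (n - a) * q
        # pooled within-group covariance of the contrast scores
        resid = np.vstack([Z[groups == g] - Z[groups == g].mean(axis=0)
                           for g in pd.unique(groups)])
        S = resid.T @ resid / (n - a)
        trace_sq = float(np.trace(S)) ** 2
        denom = q * float(np.sum(S * S))
        eps = 1.0 if (q == 1 or denom <= 0) else float(np.clip(
            trace_sq / denom, 1.0 / q, 1.0))
        for label, ss, df1 in ((name, ss_w, q),
                               (f"{between}*{name}", ss_aw, (a - 1) * q)):
            F = f_ratio(ss, df1, ss_e, df_e)
            p = stats.f.sf(F, df1 * eps, df_e * eps)
            rows.append((label, ss, df1, ss_e, df_e, F, eps, p,
                         eta_p(ss, ss_e)))
    return pd.DataFrame(rows, columns=["effect", "ss", "df1", "ss_error",
                                       "df2", "F", "epsilon", "p_gg",
                                       "partial_eta_sq"])


def posthoc_grammaticality(table: pd.DataFrame,
                           dv: str = "amplitude",
                           between: str = "sex",
                           condition: str = "condition",
                           subject: str = "subject",
                           levels: tuple[str, str] = ("incorrect", "correct")
                           ) -> pd.DataFrame:
    """Per-sex paired t-test of the grammaticality contrast (averaged over
    electrodes) with a pooled-SD Cohen's d of the paired difference."""
    agg = (table.groupby([subject, between, condition], as_index=False)[dv]
           .mean())
    rows = []
    for sex, sub in agg.groupby(between):
        wide = sub.pivot(index=subject, columns=condition, values=dv)
        x, y = wide[levels[0]].to_numpy(), wide[levels[1]].to_numpy()
        t, p = stats.ttest_rel(x, y)
        from .groupstats import cohen_d
        rows.append((sex, float(np.mean(x - y)), float(t), float(p),
                     cohen_d(x, y), len(x)))
    return pd.DataFrame(rows, columns=[between, "mean_diff", "t", "p",
                                       "cohen_d", "n"])
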