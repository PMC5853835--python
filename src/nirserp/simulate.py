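"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a passive L2 sentence-listening study in young
adolescents: a 296-event run (48 sentences per condition x 3 conditions,
147 silent nulls, 5 vigilance tones; 4 s trials), simultaneous 10 Hz
two-hemisphere fNIRS and 500 Hz five-electrode EEG, and a behavioral
battery (two proficiency tests, two grammar tests, and a reading-span
working-memory test).

Three properties of the emulated population are first-class and
configurable rather than incidental:

* behavioral scores reproduce the battery's descriptive statistics and the
  sex-specific coupling between working-memory span and grammar-listening
  score (strongly positive in girls, near zero in boys);
* true haemodynamic amplitudes vary with the grammar-listening score
  according to a sign map over (region group x hemisphere x condition x
  sex) -- boys gain anterior activation with proficiency for correct
  sentences and lose activation broadly for incorrect ones, girls gain
  posterior activation for both;
* the EEG carries a grammaticality (incorrect - correct) negativity that
  spans 100-800 ms post-violation in boys but is confined to 450-600 ms in
  girls, on top of pink/white background noise, eye blinks, and an
  adjustable fraction of high-amplitude artifact trials.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import EventDesign
from .glm import boxcar
from .hrf import HRFParams, sample_hrf
from .montage import ProbeLayout, region_group
from .recordings import (EEG_CHANNELS, EEG_SCALP, EEGRecording, HbRecording,
                         OpticalRecording)

SEXES = ("boy", "girl")

#: per-test maximum raw scores (reading-span test max = 4 span levels x 5
#: sets: 2*5 + 3*5 + 4*5 + 5*5 = 70)
TEST_MAXIMA = {"KET_L": 25, "KET_RW": 60, "Grammar_L": 48,
               "Grammar_R": 15, "RST": 70}


# ------------------------------------------------------------------ behavior

@dataclass(frozen=True)
class ScoreParams:
    """Population parameters of one behavioral test, in percent units.

    ``sex_gap_d`` is the girls-minus-boys standardised difference;
    ``loading`` the correlation with the grammar-listening factor (the
    reading-span loading is sex-specific and lives in ``CohortConfig``).
    """

    mean: float
    sd: float
    sex_gap_d: float = 0.0
    loading: float = 0.0


def default_test_params() -> dict[str, ScoreParams]:
    return {
        "Grammar_L": ScoreParams(54.44, 13.31, sex_gap_d=0.98, loading=1.0),
        "Grammar_R": ScoreParams(75.60, 21.04, sex_gap_d=0.0, loading=0.451),
        "KET_L": ScoreParams(43.25, 22.16, sex_gap_d=0.76, loading=0.605),
        "KET_RW": ScoreParams(42.89, 19.02, sex_gap_d=0.0, loading=0.551),
        "RST": ScoreParams(100 * 51.89 / 70, 100 * 7.85 / 70, sex_gap_d=0.82),
    }


# --------------------------------------------------------------------- fNIRS

@dataclass(frozen=True)
class NoiseConfig:
    """Structured fNIRS noise, amplitudes in mM*mm.

    Sinusoidal cardiac/respiratory/Mayer-wave terms with per-channel random
    phase, a random linear drift plus random walk, and white sensor noise.
    """

    cardiac_hz: float = 1.1
    cardiac_amp: float = 0.010
    resp_hz: float = 0.25
    resp_amp: float = 0.015
    mayer_hz: float = 0.10
    mayer_amp: float = 0.010
    drift_span: float = 0.05        # max |linear drift| over the run
    random_walk_step: float = 5e-4
    white_sd: float = 0.010

    def scaled(self, factor: float) -> "NoiseConfig":
        return NoiseConfig(self.cardiac_hz, self.cardiac_amp * factor,
                           self.resp_hz, self.resp_amp * factor,
                           self.mayer_hz, self.mayer_amp * factor,
                           self.drift_span * factor,
                           self.random_walk_step * factor,
                           self.white_sd * factor)


SILENT = NoiseConfig(cardiac_amp=0.0, resp_amp=0.0, mayer_amp=0.0,
                     drift_span=0.0, random_walk_step=0.0, white_sd=0.0)


@dataclass(frozen=True)
class AmplitudeMap:
    """True oxy-Hb response amplitudes and their proficiency coupling.

    The true per-channel amplitude for a subject is

        beta = base[condition] + slope(sex, condition, region) *
               hemisphere_gain * z(Grammar_L) + subject noise

    with ``z`` the within-sex standardised grammar-listening score.  The
    default slopes encode the observed sign structure: boys anterior-
    positive for correct and globally negative for incorrect sentences,
    girls posterior-positive for both.
    """

    effect: float = 0.015           # slope magnitude per score SD, mM*mm
    base: dict = field(default_factory=lambda: {
        "correct": 0.020, "incorrect": 0.020, "filler": 0.015,
        "tone": 0.010})
    hemisphere_gain: dict = field(default_factory=lambda: {"L": 1.0, "R": 0.7})
    subject_sd: float = 0.008
    deoxy_ratio: float = -0.3
    # auditory stimulation drives the channels over auditory cortex hardest;
    # baseline amplitude is boosted around that lattice position
    auditory_center_channel: int = 16
    auditory_boost: float = 2.5
    auditory_sigma_cm: float = 3.0

    def auditory_gain(self, layout: ProbeLayout) -> pd.Series:
        """Per-channel baseline gain peaking at the auditory channel."""
        center = next(ch.position for ch in layout.channels
                      if ch.index == self.auditory_center_channel)
        out = {}
        for hemi in ("L", "R"):
            for ch in layout.channels:
                d2 = ((ch.position[0] - center[0]) ** 2
                      + (ch.position[1] - center[1]) ** 2)
                g = 1.0 + (self.auditory_boost - 1.0) * np.exp(
                    -d2 / (2.0 * self.auditory_sigma_cm ** 2))
                out[f"{hemi}-{ch.index}"] = g
        return pd.Series(out)

    def slope(self, sex: str, condition: str, region: str) -> float:
        s = self.effect
        if condition not in ("correct", "incorrect"):
            return 0.0
        if sex == "boy":
            if condition == "correct":
                return s if region == "anterior" else 0.0
            return -s
        if sex == "girl":
            return s if region == "posterior" else 0.0
        raise ValueError(f"unknown sex {sex!r}")

    def channel_slopes(self, layout: ProbeLayout, sex: str,
                       condition: str) -> pd.Series:
        """Planted slope per channel label over both hemispheres."""
        out = {}
        for hemi in ("L", "R"):
            gain = self.hemisphere_gain[hemi]
            for ch in layout.channels:
                region = region_group(ch, layout.cols, layout.spacing_cm)
                out[f"{hemi}-{ch.index}"] = gain * self.slope(
                    sex, condition, region)
        return pd.Series(out)


# ----------------------------------------------------------------------- EEG

@dataclass(frozen=True)
class ERPEffectConfig:
    """Condition- and sex-dependent ERP structure, microvolts."""

    boy_window_ms: tuple[float, float] = (100.0, 800.0)
    boy_amp: float = -2.5
    girl_window_ms: tuple[float, float] = (450.0, 600.0)
    girl_amp: float = -2.0
    auditory_amp: float = 3.0       # shared evoked response, both conditions
    pink_sd: float = 8.0
    white_sd: float = 2.0
    blink_rate_hz: float = 0.15
    blink_amp: float = 180.0
    blink_width_s: float = 0.15
    artifact_fraction: float = 0.05
    artifact_amp: float = 150.0
    anterior_weights: dict = field(default_factory=lambda: {
        "Fz": 1.0, "F5": 0.9, "F6": 0.9, "Cz": 0.7, "Pz": 0.4})
    centroparietal_weights: dict = field(default_factory=lambda: {
        "Fz": 0.7, "F5": 0.6, "F6": 0.6, "Cz": 1.0, "Pz": 0.9})

    def grammaticality_component(self, sex: str):
        """(window_ms, amplitude, channel weights) added to incorrect trials."""
        if sex == "boy":
            return self.boy_window_ms, self.boy_amp, self.anterior_weights
        return self.girl_window_ms, self.girl_amp, self.centroparietal_weights


# -------------------------------------------------------------------- cohort

@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a full synthetic cohort."""

    n_boys: int = 31
    n_girls: int = 22
    tests: dict = field(default_factory=default_test_params)
    rst_grammar_corr: dict = field(default_factory=lambda: {
        "boy": 0.042, "girl": 0.672})
    amplitudes: AmplitudeMap = field(default_factory=AmplitudeMap)
    true_hrf: HRFParams = field(default_factory=lambda: HRFParams(5.0, 10.0, 6.0))
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    erp: ERPEffectConfig = field(default_factory=ERPEffectConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for sex, r in self.rst_grammar_corr.items():
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"correlation for {sex} outside [-1, 1]: {r}")
        for name, tp in self.tests.items():
            if tp.sd < 0:
                raise ValueError(f"negative SD for {name}")
            if not -1.0 <= tp.loading <= 1.0:
                raise ValueError(f"loading for {name} outside [-1, 1]")


def _sex_means(tp: ScoreParams, n_boys: int, n_girls: int) -> dict[str, float]:
    """Split the pooled mean by the standardised sex gap so that the
    group-size-weighted average recovers the pooled mean."""
    n = n_boys + n_girls
    delta = tp.sex_gap_d * tp.sd
    return {"boy": tp.mean - delta * n_girls / n,
            "girl": tp.mean + delta * n_boys / n}


def simulate_behavior(config: CohortConfig,
                      seed: int | None = None) -> pd.DataFrame:
    """Draw the behavioral score table for one cohort.

    Scores follow a one-factor model within each sex: the standardised
    grammar-listening score is the factor, and every other test loads on it
    with its configured correlation (the reading-span loading is the
    sex-specific target).  Rows with any percent score outside [0, 100] are
    redrawn rather than clipped, preserving the correlation structure; the
    generating means are first calibrated on a large internal draw so that
    the post-truncation means still match the configured values (rejection
    preferentially discards extreme rows, which would otherwise shift every
    correlated test).

    Returns a table with one row per subject: ``subject``, ``sex``, and for
    each test ``<name>_raw`` and ``<name>_pct``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    names = list(config.tests)
    frames = []
    for sex, n in (("boy", config.n_boys), ("girl", config.n_girls)):
        if n == 0:
            continue
        loadings = {}
        for name, tp in config.tests.items():
            lam = (config.rst_grammar_corr[sex] if name == "RST"
                   else tp.loading)
            if abs(lam) > 1:
                raise ValueError(f"infeasible loading {lam} for {name}")
            loadings[name] = lam
        target = {name: _sex_means(tp, config.n_boys, config.n_girls)[sex]
                  for name, tp in config.tests.items()}

        def draw(batch, means, rng):
            z_f = rng.standard_normal(batch)
            vals = np.empty((batch, len(names)))
            for j, name in enumerate(names):
                tp = config.tests[name]
                lam = loadings[name]
                z = lam * z_f + np.sqrt(max(0.0, 1 - lam * lam)) * \
                    rng.standard_normal(batch)
                vals[:, j] = means[name] + tp.sd * z
            ok = np.all((vals >= 0.0) & (vals <= 100.0), axis=1)
            return vals[ok]

        # calibrate generating means against truncation bias on a separate
        # stream so cohort draws stay reproducible per (config, seed)
        means = dict(target)
        cal_rng = np.random.default_rng(rng.integers(2 ** 31))
        if any(tp.sd > 0 for tp in config.tests.values()):
            for _ in range(3):
                sample = draw(8000, means, cal_rng)
                for j, name in enumerate(names):
                    means[name] += target[name] - sample[:, j].mean()

        rows = np.empty((0, len(names)))
        while rows.shape[0] < n:
            got = draw(max(4 * n, 32), means, rng)
            rows = np.vstack([rows, got])
        rows = rows[:n]
        df = pd.DataFrame(rows, columns=[f"{n_}_pct" for n_ in names])
        df.insert(0, "sex", sex)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "subject", [f"S{i + 1:03d}" for i in range(len(out))])
    for name in names:
        out[f"{name}_raw"] = out[f"{name}_pct"] * TEST_MAXIMA[name] / 100.0
    return out


def grammar_z(behavior: pd.DataFrame) -> pd.Series:
    """Within-sex standardised grammar-listening percent score."""
    g = behavior.groupby("sex")["Grammar_L_pct"]
    mu = g.transform("mean")
    sd = g.transform("std").replace(0.0, 1.0)
    return (behavior["Grammar_L_pct"] - mu) / sd


def true_betas(layout: ProbeLayout, sex: str, z_score: float,
               amplitudes: AmplitudeMap,
               rng: np.random.Generator) -> pd.DataFrame:
    """Planted oxy-Hb amplitudes per channel x condition for one subject."""
    channels = layout.channel_names()
    gain = amplitudes.auditory_gain(layout)
    rows = []
    for cond, base in amplitudes.base.items():
        slopes = (amplitudes.channel_slopes(layout, sex, cond)
                  if cond in ("correct", "incorrect")
                  else pd.Series(0.0, index=channels))
        noise = rng.normal(0.0, amplitudes.subject_sd, size=len(channels))
        for i, ch in enumerate(channels):
            rows.append((ch, cond,
                         base * gain[ch] + slopes[ch] * z_score + noise[i]))
    return pd.DataFrame(rows, columns=["channel", "condition", "beta"])


def simulate_fnirs(design: EventDesign, layout: ProbeLayout, sex: str,
                   z_score: float, true_hrf: HRFParams, noise: NoiseConfig,
                   seed: int, amplitudes: AmplitudeMap | None = None,
                   as_optical: bool = False, return_truth: bool = False):
    """Forward-simulate one subject's two-hemisphere haemoglobin recording.

    Per channel: sum over conditions of true amplitude times the
    boxcar-convolved HRF, plus the structured noise terms.  The deoxy
    series is the oxy series scaled by the (negative) deoxy ratio with its
    own noise.  With ``as_optical`` the result is pushed through the
    forward Beer-Lambert model to two-wavelength optical density.
    """
    amplitudes = amplitudes or AmplitudeMap()
    rng = np.random.default_rng(seed)
    rate = 10.0
    n = int(round(design.total_duration_s * rate))
    t = np.arange(n) / rate
    channels = tuple(layout.channel_names())
    truth = true_betas(layout, sex, z_score, amplitudes, rng)

    h = sample_hrf(true_hrf, rate)
    regressors = {}
    for cond in amplitudes.base:
        onsets = design.onsets(cond)
        if onsets.size == 0:
            continue
        durs = design.trials.loc[design.trials["trial_type"] == cond,
                                 "duration"].to_numpy()
        regressors[cond] = np.convolve(boxcar(onsets, durs, rate, n), h)[:n]

    beta_wide = truth.pivot(index="channel", columns="condition",
                            values="beta").loc[list(channels)]
    oxy = np.zeros((len(channels), n))
    for cond, reg in regressors.items():
        oxy += np.outer(beta_wide[cond].to_numpy(), reg)
    deoxy = amplitudes.deoxy_ratio * oxy

    for arr, scale in ((oxy, 1.0), (deoxy, 0.5)):
        for freq, amp in ((noise.cardiac_hz, noise.cardiac_amp),
                          (noise.resp_hz, noise.resp_amp),
                          (noise.mayer_hz, noise.mayer_amp)):
            if amp > 0:
                phases = rng.uniform(0, 2 * np.pi, size=len(channels))
                gains = rng.uniform(0.5, 1.5, size=len(channels))
                arr += (scale * amp * gains[:, None]
                        * np.sin(2 * np.pi * freq * t[None, :]
                                 + phases[:, None]))
        if noise.drift_span > 0:
            slopes = rng.uniform(-noise.drift_span, noise.drift_span,
                                 size=len(channels))
            arr += scale * slopes[:, None] * (t[None, :] / max(t[-1], 1.0))
        if noise.random_walk_step > 0:
            steps = rng.normal(0, noise.random_walk_step,
                               size=(len(channels), n))
            arr += scale * np.cumsum(steps, axis=1)
        if noise.white_sd > 0:
            arr += scale * rng.normal(0, noise.white_sd,
                                      size=(len(channels), n))

    hb = HbRecording(oxy=oxy, deoxy=deoxy, channels=channels, rate_hz=rate)
    rec = hb if not as_optical else _to_optical(hb)
    return (rec, truth) if return_truth else rec


def _to_optical(hb: HbRecording) -> OpticalRecording:
    from .preprocess import forward_mbll
    return forward_mbll(hb)


def _component(window_ms: tuple[float, float], rate: float) -> np.ndarray:
    """Smooth (Hann) unit-amplitude bump spanning a post-onset window."""
    n = int(round((window_ms[1] - window_ms[0]) / 1000.0 * rate))
    return np.hanning(max(n, 3))


def simulate_eeg(design: EventDesign, sex: str, seed: int,
                 effects: ERPEffectConfig | None = None) -> EEGRecording:
    """Forward-simulate one subject's continuous EEG at 500 Hz.

    Both sentence conditions receive an identical auditory evoked response
    at trial onset; incorrect trials additionally receive the sex-specific
    grammaticality negativity locked to the second-phrase (violation)
    onset.  Background is pink + white noise per scalp channel; eye blinks
    live on the EOG channel and leak into the scalp with fixed frontal
    coefficients; a configurable fraction of sentence trials carries a
    high-amplitude artifact burst for the rejection stage to catch.
    """
    effects = effects or ERPEffectConfig()
    rng = np.random.default_rng(seed)
    rate = 500.0
    n = int(round(design.total_duration_s * rate))
    t_idx = np.arange(n)
    data = np.zeros((len(EEG_CHANNELS), n))
    name_to_row = {c: i for i, c in enumerate(EEG_CHANNELS)}

    # background noise: pink (1/f amplitude shaping) + white, per scalp channel
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    for ch in EEG_SCALP:
        spec = (rng.standard_normal(freqs.size)
                + 1j * rng.standard_normal(freqs.size)) * shaping
        pink = np.fft.irfft(spec, n=n)
        pink *= effects.pink_sd / max(pink.std(), 1e-12)
        data[name_to_row[ch]] += pink + rng.normal(0, effects.white_sd, n)

    # earlobe references: low-level sensor noise only
    for ch in ("A1", "A2"):
        data[name_to_row[ch]] += rng.normal(0, 1.0, n)

    def add_bump(row: int, start_s: float, bump: np.ndarray, amp: float):
        i0 = int(round(start_s * rate))
        i1 = min(i0 + bump.size, n)
        if i0 < n and i1 > i0 >= 0:
            data[row, i0:i1] += amp * bump[:i1 - i0]

    # shared auditory evoked response at every sentence onset
    aud = _component((0.0, 400.0), rate) * np.sin(
        2 * np.pi * 3.0 * np.arange(int(0.4 * rate)) / rate)
    for cond in ("correct", "incorrect", "filler"):
        for onset in design.onsets(cond):
            for ch in EEG_SCALP:
                add_bump(name_to_row[ch], onset, aud, effects.auditory_amp)

    # sex-specific grammaticality negativity on incorrect trials
    window_ms, amp, weights = effects.grammaticality_component(sex)
    bump = _component(window_ms, rate)
    viol = design.violation_onsets(conditions=("incorrect",))
    for onset in viol["onset"]:
        start = onset + window_ms[0] / 1000.0
        for ch, w in weights.items():
            add_bump(name_to_row[ch], start, bump, amp * w)

    # eye blinks on EOG, leaking to frontal channels
    leak = {"Fz": 0.30, "F5": 0.25, "F6": 0.25, "Cz": 0.15, "Pz": 0.08}
    n_blinks = rng.poisson(effects.blink_rate_hz * design.total_duration_s)
    blink_times = rng.uniform(0, design.total_duration_s, size=n_blinks)
    bw = int(effects.blink_width_s * rate)
    blink_shape = np.exp(-0.5 * ((np.arange(2 * bw) - bw) / (bw / 2.5)) ** 2)
    for bt in blink_times:
        add_bump(name_to_row["EOG"], bt, blink_shape, effects.blink_amp)
        for ch, c in leak.items():
            add_bump(name_to_row[ch], bt, blink_shape,
                     c * effects.blink_amp)
    data[name_to_row["EOG"]] += rng.normal(0, 5.0, n)

    # planted high-amplitude artifact trials
    sent = design.trials[design.trials["trial_type"].isin(
        ("correct", "incorrect"))]
    art = _component((0.0, 120.0), rate)
    for _, row in sent.iterrows():
        if rng.random() < effects.artifact_fraction:
            viol_on = row["onset"] + row["phrase_onset_2"] / 1000.0
            ch = EEG_SCALP[rng.integers(len(EEG_SCALP))]
            lag = rng.uniform(0.0, 0.6)
            sign = rng.choice((-1.0, 1.0))
            add_bump(name_to_row[ch], viol_on + lag, art,
                     sign * effects.artifact_amp * 1.5)
    return EEGRecording(data=data)
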