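"""Event-related stimulus design for the passive sentence-listening run.

The run interleaves three sentence conditions (syntactically correct,
incorrect with verb-object order swapped, and verb-less filler), silent null
events that provide temporal jitter, and a handful of pure-tone vigilance
probes.  The reference configuration is 48 sentences per condition plus 147
null and 5 tone events -- 296 events of 4 s each, a 1184 s run.

Every sentence carries four phrases; the syntactic violation point is the
onset of the second phrase, so per-trial phrase onsets are attached to each
sentence trial.  Mean phrase durations are 607, 497, 625 and 1149 ms, with
configurable multiplicative per-trial jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SENTENCE_CONDITIONS = ("correct", "incorrect", "filler")
ALL_CONDITIONS = SENTENCE_CONDITIONS + ("null", "tone")

#: mean phrase durations (ms), phrases 1-4
DEFAULT_PHRASE_MS = (607.0, 497.0, 625.0, 1149.0)


@dataclass(frozen=True)
class EventDesign:
    """Ordered, non-overlapping trials with per-sentence phrase onsets.

    ``trials`` has columns onset (s), duration (s), trial_type; sentence
    rows additionally carry phrase_onset_1..4 (ms, relative to trial onset;
    NaN for null/tone rows).  Sampling-rate agnostic.
    """

    trials: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.trials
        required = {"onset", "duration", "trial_type"}
        if not required.issubset(t.columns):
            raise ValueError(f"trials must have columns {sorted(required)}")
        onsets = t["onset"].to_numpy()
        if np.any(np.diff(onsets) < 0):
            raise ValueError("trials must be sorted by onset")
        ends = onsets + t["duration"].to_numpy()
        if np.any(onsets[1:] < ends[:-1] - 1e-9):
            raise ValueError("trials overlap")
        unknown = set(t["trial_type"]) - set(ALL_CONDITIONS)
        if unknown:
            raise ValueError(f"unknown trial types: {sorted(unknown)}")

    @property
    def n_events(self) -> int:
        return len(self.trials)

    @property
    def total_duration_s(self) -> float:
        if self.trials.empty:
            return 0.0
        last = self.trials.iloc[-1]
        return float(last["onset"] + last["duration"])

    def counts(self) -> dict[str, int]:
        c = self.trials["trial_type"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ALL_CONDITIONS}

    def onsets(self, condition: str) -> np.ndarray:
        """Trial onsets (s) of one condition."""
        m = self.trials["trial_type"] == condition
        return self.trials.loc[m, "onset"].to_numpy(dtype=float)

    def violation_onsets(self, conditions=("correct", "incorrect")) -> pd.DataFrame:
        """Second-phrase onsets (s, absolute) of sentence trials.

        The second phrase is where the word-order violation (if any)
        begins; ERP epochs are locked to it.
        """
        m = self.trials["trial_type"].isin(conditions)
        sel = self.trials.loc[m]
        onset = sel["onset"] + sel["phrase_onset_2"] / 1000.0
        return pd.DataFrame({
            "onset": onset.to_numpy(dtype=float),
            "trial_type": sel["trial_type"].to_numpy(),
        })


def build_design(n_per_sentence_condition: int = 48,
                 n_null: int = 147,
                 n_tone: int = 5,
                 trial_ms: float = 4000.0,
                 seed: int = 0,
                 phrase_ms: tuple[float, float, float, float] = DEFAULT_PHRASE_MS,
                 phrase_jitter: float = 0.10) -> EventDesign:
    """Build a seeded, shuffled event design with fixed-length trial slots.

    Trial order is a uniform seeded permutation of all events; the null
    events scattered through the run provide the inter-stimulus jitter
    (an approximation of design-optimisation tools that schedule events on
    the same fixed slot grid).  Totals and the run duration are exact
    functions of the counts: ``3*n_sent + n_null + n_tone`` events of
    ``trial_ms`` each.

    ``phrase_jitter`` scales phrase durations per trial by independent
    uniform factors in ``[1-j, 1+j]`` around the configured means.
    """
    if n_per_sentence_condition < 0 or n_null < 0 or n_tone < 0:
        raise ValueError("event counts must be non-negative")
    if n_per_sentence_condition == 0 and n_null == 0 and n_tone == 0:
        raise ValueError("design must contain at least one event")
    if trial_ms <= 0:
        raise ValueError("trial length must be positive")

    rng = np.random.default_rng(seed)
    labels = (list(SENTENCE_CONDITIONS) * n_per_sentence_condition
              + ["null"] * n_null + ["tone"] * n_tone)
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    trial_s = trial_ms / 1000.0
    onsets = np.arange(len(labels)) * trial_s
    df = pd.DataFrame({
        "onset": onsets,
        "duration": trial_s,
        "trial_type": labels,
    })

    phrase_ms_arr = np.asarray(phrase_ms, dtype=float)
    is_sentence = df["trial_type"].isin(SENTENCE_CONDITIONS).to_numpy()
    n_sent_trials = int(is_sentence.sum())
    jitter = rng.uniform(1.0 - phrase_jitter, 1.0 + phrase_jitter,
                         size=(n_sent_trials, 4))
    durs = phrase_ms_arr[None, :] * jitter
    # phrase k onset = cumulative duration of phrases 1..k-1
    rel_onsets = np.concatenate(
        [np.zeros((n_sent_trials, 1)), np.cumsum(durs, axis=1)[:, :3]], axis=1)
    for k in range(4):
        col = np.full(len(df), np.nan)
        col[is_sentence] = rel_onsets[:, k]
        df[f"phrase_onset_{k + 1}"] = col
    return EventDesign(df)
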