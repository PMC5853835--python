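"""Channel-wise group inference on GLM amplitudes.

Covers the second-level statistics of the fNIRS arm: one-sample t maps of
activation, Pearson and partial correlation maps of amplitude against the
grammar-listening score (reading-span score as covariate), multiplicity
control for spatially correlated channels via the Dubey/Armitage-Parmar
(D/AP) boundary

    alpha_adj = 1 - (1 - alpha) ** (1 / m ** (1 - r_bar)),

which interpolates between the Sidak correction (independent tests,
``r_bar = 0``) and no correction (perfectly correlated tests, ``r_bar =
1``), and region-of-interest formation: core channels below the adjusted
threshold grown to grid-adjacent channels below a secondary threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .montage import ProbeLayout
from .simulate import TEST_MAXIMA


@dataclass(frozen=True)
class MultiplicityContext:
    """Inputs of the D/AP correction: m tests at family-wise level alpha
    with mean pairwise correlation r_bar between the test variables."""

    m: int
    r_bar: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("need at least one test")
        if not 0.0 <= self.r_bar <= 1.0:
            raise ValueError(f"r_bar must be in [0, 1], got {self.r_bar}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def dap_alpha(ctx: MultiplicityContext) -> float:
    """Adjusted per-test significance level of the D/AP boundary."""
    return 1.0 - (1.0 - ctx.alpha) ** (1.0 / ctx.m ** (1.0 - ctx.r_bar))


def mean_interchannel_corr(betas: pd.DataFrame,
                           value: str = "beta",
                           channel: str = "channel",
                           subject: str = "subject",
                           floor_at_zero: bool = True) -> tuple[float, dict]:
    """Mean pairwise Pearson correlation between channels' amplitude
    vectors across subjects, pooled over whatever conditions/groups are in
    the table.

    Negative pairwise correlations enter the mean as signed values; a
    negative mean is floored at 0 for use in the D/AP formula (the report
    flags whether flooring occurred).  Constant channels are excluded with
    a warning entry in the report.
    """
    import warnings
    wide = betas.pivot_table(index=subject, columns=channel, values=value)
    if wide.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    sds = wide.std()
    constant = list(sds.index[sds < 1e-12])
    if constant:
        warnings.warn(f"excluding constant channels: {constant}")
        wide = wide.drop(columns=constant)
    C = np.corrcoef(wide.to_numpy().T)
    iu = np.triu_indices_from(C, k=1)
    raw = float(np.nanmean(C[iu]))
    floored = floor_at_zero and raw < 0
    r_bar = max(raw, 0.0) if floor_at_zero else raw
    return r_bar, {"raw_mean": raw, "floored": floored,
                   "excluded_channels": constant,
                   "n_channels": wide.shape[1]}


def one_sample_t(betas: pd.DataFrame, value: str = "beta",
                 channel: str = "channel", popmean: float = 0.0
                 ) -> pd.DataFrame:
    """Per-channel one-sample t-test of the amplitudes against zero.

    Zero-variance channels get a degenerate p (0 if the mean differs from
    the null value, 1 otherwise) and a flag.
    """
    rows = []
    for ch, grp in betas.groupby(channel):
        x = grp[value].to_numpy(dtype=float)
        n = x.size
        if n < 2:
            raise ValueError(f"channel {ch}: need n >= 2")
        sd = x.std(ddof=1)
        if sd < 1e-15:
            diff = x.mean() - popmean
            p = 0.0 if abs(diff) > 0 else 1.0
            rows.append((ch, np.inf * np.sign(diff) if diff else 0.0,
                         p, n, True))
            continue
        t = (x.mean() - popmean) / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), n - 1)
        rows.append((ch, float(t), float(p), n, False))
    out = pd.DataFrame(rows, columns=[channel, "stat", "p", "n",
                                      "zero_variance"])
    out["kind"] = "t"
    return out


def _pearson_map(B: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Pearson r of each column of B with score, plus two-sided p."""
    n = len(score)
    xs = (score - score.mean()) / score.std()
    Bc = B - B.mean(axis=0)
    sd = B.std(axis=0)
    r = (Bc.T @ xs) / (n * np.where(sd > 0, sd, np.inf))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return r, p


def corr_map(betas: pd.DataFrame, scores: pd.Series,
             value: str = "beta", channel: str = "channel",
             subject: str = "subject") -> pd.DataFrame:
    """Per-channel Pearson correlation between amplitude and a behavioral
    score over subjects.  ``scores`` is indexed by subject id."""
    wide = betas.pivot_table(index=subject, columns=channel, values=value)
    s = scores.loc[wide.index].to_numpy(dtype=float)
    if len(s) < 3:
        raise ValueError("need at least 3 subjects")
    if s.std() < 1e-15:
        raise ValueError("behavioral score is constant")
    r, p = _pearson_map(wide.to_numpy(), s)
    out = pd.DataFrame({channel: wide.columns, "stat": r, "p": p,
                        "n": len(s)})
    out["kind"] = "r"
    return out


def partial_corr(x: np.ndarray, y: np.ndarray, z: np.ndarray
                 ) -> tuple[float, float]:
    """First-order partial correlation r_xy.z with its two-sided p on
    n - 3 degrees of freedom."""
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    rxy = float(np.corrcoef(x, y)[0, 1])
    rxz = float(np.corrcoef(x, z)[0, 1])
    ryz = float(np.corrcoef(y, z)[0, 1])
    denom = (1 - rxz ** 2) * (1 - ryz ** 2)
    if denom <= 1e-15:
        raise ValueError("covariate is collinear with a variable; partial "
                         "correlation undefined")
    r = (rxy - rxz * ryz) / np.sqrt(denom)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    t = r * np.sqrt(df / max(1 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def partial_corr_map(betas: pd.DataFrame, scores: pd.Series,
                     covariate: pd.Series, value: str = "beta",
                     channel: str = "channel", subject: str = "subject"
                     ) -> pd.DataFrame:
    """Per-channel partial correlation of amplitude with the score,
    controlling for the covariate (e.g. reading-span)."""
    wide = betas.pivot_table(index=subject, columns=channel, values=value)
    s = scores.loc[wide.index].to_numpy(dtype=float)
    z = covariate.loc[wide.index].to_numpy(dtype=float)
    rows = []
    for ch in wide.columns:
        r, p = partial_corr(wide[ch].to_numpy(), s, z)
        rows.append((ch, r, p, len(s)))
    out = pd.DataFrame(rows, columns=[channel, "stat", "p", "n"])
    out["kind"] = "partial_r"
    return out


# ----------------------------------------------------------------- ROI rule

@dataclass(frozen=True)
class ROI:
    roi_id: int
    core: tuple[str, ...]
    members: tuple[str, ...]
    r: float | None = None
    p: float | None = None


def form_rois(stat_map: pd.DataFrame, layout: ProbeLayout,
              alpha_adj: float, secondary_alpha: float = 0.05,
              channel: str = "channel",
              betas: pd.DataFrame | None = None,
              scores: pd.Series | None = None,
              subject: str = "subject") -> list[ROI]:
    """Grow regions of interest from corrected-threshold seeds.

    Seeds are channels with ``p < alpha_adj``; members are added
    iteratively from grid-adjacent channels with ``p < secondary_alpha``;
    overlapping regions merge (maximal connected components).  Hemispheres
    never merge because adjacency is defined within a hemisphere's channel
    lattice.  When subject-level amplitudes and a score are supplied, each
    ROI also carries the correlation of its member-averaged amplitude with
    the score.
    """
    pvals = dict(zip(stat_map[channel], stat_map["p"]))
    adj = layout.adjacency()
    G = nx.Graph()
    for hemi in ("L", "R"):
        for a, b in adj:
            G.add_edge(f"{hemi}-{a}", f"{hemi}-{b}")
    seeds = {ch for ch, p in pvals.items() if p < alpha_adj}
    grown = set(seeds)
    frontier = set(seeds)
    while frontier:
        nxt = set()
        for ch in frontier:
            for nb in G.neighbors(ch):
                if nb not in grown and pvals.get(nb, 1.0) < secondary_alpha:
                    nxt.add(nb)
        grown |= nxt
        frontier = nxt
    sub = G.subgraph(grown)
    components = [comp for comp in nx.connected_components(sub)
                  if comp & seeds]
    # isolated seeds with no qualifying neighbours form singleton ROIs
    isolated = seeds - set().union(*components) if components else set(seeds)
    comps = components + [{ch} for ch in sorted(isolated)]

    def sort_key(ch: str):
        hemi, idx = ch.split("-")
        return (hemi, int(idx))

    rois = []
    wide = None
    if betas is not None and scores is not None:
        wide = betas.pivot_table(index=subject, columns=channel,
                                 values="beta")
    for i, comp in enumerate(sorted(comps, key=lambda c: sort_key(min(c, key=sort_key)))):
        members = tuple(sorted(comp, key=sort_key))
        core = tuple(ch for ch in members if ch in seeds)
        r = p = None
        if wide is not None:
            avg = wide[list(members)].mean(axis=1)
            s = scores.loc[avg.index].to_numpy(dtype=float)
            rr = np.corrcoef(avg.to_numpy(), s)[0, 1]
            n = len(s)
            t = rr * np.sqrt((n - 2) / max(1 - rr * rr, 1e-300))
            r, p = float(rr), float(2 * stats.t.sf(abs(t), n - 2))
        rois.append(ROI(i + 1, core, members, r, p))
    return rois


def rois_to_frame(rois: list[ROI]) -> pd.DataFrame:
    rows = [(roi.roi_id, ",".join(roi.core), ",".join(roi.members),
             roi.r, roi.p) for roi in rois]
    return pd.DataFrame(rows, columns=["roi_id", "core", "members", "r", "p"])


# ------------------------------------------------------------ small helpers

def adjusted_r2(r: float, n: int, predictors: int = 1) -> float:
    """Adjusted coefficient of determination for a simple regression:
    ``1 - (1 - r^2) * (n - 1) / (n - 1 - predictors)``."""
    if n < predictors + 2:
        raise ValueError(f"need n >= {predictors + 2}")
    return 1.0 - (1.0 - r * r) * (n - 1) / (n - 1 - predictors)


def cohen_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Standardised mean difference with the pooled-SD denominator on
    ``n_a + n_b - 2`` degrees of freedom."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled < 1e-15:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


def percent_score(raw: float, maximum: float) -> float:
    """Convert a raw test score to percent of the test maximum."""
    if maximum <= 0:
        raise ValueError("maximum must be positive")
    if not 0 <= raw <= maximum:
        raise ValueError(f"raw score {raw} outside [0, {maximum}]")
    return 100.0 * raw / maximum


SCORE_MAXIMA = dict(TEST_MAXIMA)
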