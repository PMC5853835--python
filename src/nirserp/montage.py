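"""Optode grid montage and the channel lattice it induces.

A lateral probe pad holds sources and detectors alternating on a rectangular
grid (rows x cols, fixed inter-optode spacing).  Every grid-adjacent
source-detector pair forms a measurement channel located at the optode
midpoint.  A 3 x 5 pad with 3 cm spacing (8 sources, 7 detectors) yields 22
channels per hemisphere: 12 horizontal plus 10 vertical adjacencies.
Channels are numbered row-major, 1-based, per hemisphere, so "channel 16"
addresses the same lattice position on both sides of the head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HEMISPHERES = ("L", "R")


@dataclass(frozen=True)
class Channel:
    index: int            # 1-based, per hemisphere
    source: tuple[int, int]
    detector: tuple[int, int]
    position: tuple[float, float]  # optode midpoint, cm


@dataclass(frozen=True)
class ProbeLayout:
    """Per-hemisphere channel list derived from an alternating optode grid."""

    rows: int
    cols: int
    spacing_cm: float
    channels: tuple[Channel, ...]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_names(self, hemisphere: str | None = None) -> list[str]:
        """Channel labels ``{L|R}-{index}``; both hemispheres if None."""
        hemis = HEMISPHERES if hemisphere is None else (hemisphere,)
        return [f"{h}-{ch.index}" for h in hemis for ch in self.channels]

    def adjacency(self) -> list[tuple[int, int]]:
        """Pairs of 1-based channel indices that are nearest neighbours on
        the channel lattice: two channels are adjacent iff their optode
        pairs share an optode (one hemisphere)."""
        pairs = []
        chans = sorted(self.channels, key=lambda ch: ch.index)
        for i, a in enumerate(chans):
            a_opt = {a.source, a.detector}
            for b in chans[i + 1:]:
                if a_opt & {b.source, b.detector}:
                    pairs.append((a.index, b.index))
        return pairs


def build_probe_layout(rows: int = 3, cols: int = 5,
                       spacing_cm: float = 3.0) -> ProbeLayout:
    """Enumerate channels of an alternating source/detector grid.

    Optodes alternate in row-major order starting with a source at the
    top-left corner; every pair of optodes at grid distance ``spacing_cm``
    is then automatically a source-detector pair and becomes a channel.

    Raises
    ------
    ValueError : if the grid is degenerate (no adjacent pair exists).
    """
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise ValueError("grid must contain at least two optodes")
    if spacing_cm <= 0:
        raise ValueError("optode spacing must be positive")

    def role(r: int, c: int) -> str:
        return "S" if (r * cols + c) % 2 == 0 else "D"

    # conventional numbering: per grid row, first the horizontal pairs of
    # that row, then the vertical pairs connecting it to the next row
    pairs: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for r in range(rows):
        pairs.extend(((r, c), (r, c + 1)) for c in range(cols - 1))
        if r + 1 < rows:
            pairs.extend(((r, c), (r + 1, c)) for c in range(cols))

    channels: list[Channel] = []
    for index, (a, b) in enumerate(pairs, start=1):
        if role(*a) == role(*b):  # cannot happen when cols is odd
            raise ValueError(
                f"optodes {a} and {b} share role {role(*a)}; "
                "alternation is not well-defined for this grid"
            )
        src, det = (a, b) if role(*a) == "S" else (b, a)
        mid = ((a[1] + b[1]) / 2.0 * spacing_cm,
               (a[0] + b[0]) / 2.0 * spacing_cm)
        channels.append(Channel(index, src, det, mid))
    return ProbeLayout(rows, cols, spacing_cm, tuple(channels))


def region_group(channel: Channel, cols: int, spacing_cm: float) -> str:
    """Coarse anterior/posterior split of a lateral pad by midpoint column.

    The pad is worn with low column indices toward the front of the head;
    midpoints left of the grid's vertical midline are 'anterior', the rest
    'posterior'.  This is a labelling convention for the simulator and ROI
    summaries, not an anatomical registration.
    """
    midline = (cols - 1) / 2.0 * spacing_cm
    return "anterior" if channel.position[0] < midline else "posterior"
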