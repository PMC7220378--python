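"""Core in-memory containers shared by the imaging pipelines.

A *session block* is one awake forced-locomotion experiment: an ordered list
of 40 s recordings acquired before (``pre``) and after (``post``) drug
delivery, each carrying per-ROI somatic and surrounding-neuropil fluorescence
traces plus the treadmill rotary-encoder trace.  Because ROIs are re-detected
after drug application, the pre- and post-drug recordings are keyed by
independent ROI label sets; the two sets are joined later by mask matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

PRE = "pre_drug"
POST = "post_drug"


def window_to_frames(window: tuple[float, float], frame_rate: float, n_frames: int) -> slice:
    """Convert a half-open time window [start, end) in seconds to a frame slice.

    Frames are 0-based; the boundary convention is floor(start*rate) to
    floor(end*rate) so that adjacent windows never double-count a frame.
    """
    start, end = window
    if end <= start:
        raise ValueError(f"empty window {window!r}")
    lo = int(np.floor(start * frame_rate))
    hi = int(np.floor(end * frame_rate))
    lo = max(lo, 0)
    hi = min(hi, n_frames)
    if hi <= lo:
        raise ValueError(f"window {window!r} maps to no frames at {frame_rate} Hz")
    return slice(lo, hi)


@dataclass
class Recording:
    """One 40 s acquisition: traces are (frames x ROIs) DataFrames whose
    columns are integer ROI labels matching the session's label image."""

    index: int                      # 1-based position in acquisition order
    condition: str                  # PRE or POST
    soma: pd.DataFrame
    neuropil: pd.DataFrame
    encoder: pd.DataFrame           # columns: time_s, position_cm
    frame_rate: float = 30.0
    wavelength: int = 910

    def __post_init__(self) -> None:
        if self.condition not in (PRE, POST):
            raise ValueError(f"condition must be {PRE!r} or {POST!r}, got {self.condition!r}")
        if self.soma.shape != self.neuropil.shape:
            raise ValueError("soma and neuropil traces must have identical shape")
        if not self.soma.columns.equals(self.neuropil.columns):
            raise ValueError("soma and neuropil traces must share ROI labels")

    @property
    def n_frames(self) -> int:
        return len(self.soma)

    @property
    def roi_labels(self) -> np.ndarray:
        return self.soma.columns.to_numpy()


@dataclass
class SessionBlock:
    """Ordered recordings of one experiment plus the two ROI label images."""

    recordings: list[Recording]
    masks: dict[str, np.ndarray] = field(default_factory=dict)  # condition -> label image
    pixel_size_um: float = 0.78
    frame_rate: float = 30.0

    def __iter__(self) -> Iterator[Recording]:
        return iter(self.recordings)

    def by_condition(self, condition: str) -> list[Recording]:
        return [r for r in self.recordings if r.condition == condition]

    @property
    def pre(self) -> list[Recording]:
        return self.by_condition(PRE)

    @property
    def post(self) -> list[Recording]:
        return self.by_condition(POST)


@dataclass
class DffMatrix:
    """Rest-normalized traces for the recordings of one condition block.

    ``traces`` maps the recording's global 1-based index to a
    (frames x ROIs) DataFrame of dF/F_rest values; ``f_rest`` is the per-ROI
    resting fluorescence (a.u.) taken from the least-active recording ``k``.
    """

    traces: dict[int, pd.DataFrame]
    f_rest: pd.Series
    least_active: int
    condition: str
    frame_rate: float = 30.0


@dataclass
class GroundTruth:
    """Planted parameters emitted alongside synthetic session blocks."""

    baseline: pd.Series             # designed pre-drug locomotion fluorescence b_i
    change: pd.Series               # designed drug-induced change d_i
    designed_L: pd.DataFrame        # recordings x ROIs designed percentile values
    decay: tuple[float, float, float]
    shift_px: tuple[int, int]
    label_map: pd.Series            # pre-drug label -> post-drug label
    f_rest: pd.Series
    population_r: float             # analytic corr(b, b+d) under the generator
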