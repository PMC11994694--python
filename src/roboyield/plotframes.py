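"""Frame-to-plot assignment and splitter-based frame sampling.

Frames extracted from a collection video carry timestamps; a plot-interval
table (one row per plot: start and stop time, produced upstream by the
robot's LiDAR-based boundary detection) maps each frame to the plot it shows,
or to an alleyway between plots. Within a plot, frames are organised by row
(1 or 2) and row side (A or B), giving four time-ordered sequences.

Because several hundred frames may cover one plot, a fixed subsample is taken
for counting and yield work: each row-side sequence's time span is divided
into eight equal sections by seven splitters, the middle five splitters are
kept (the first and last sit too close to the plot edges), and the frame
nearest each kept splitter is selected. Concatenating a side's two rows gives
10 images per side, 20 per plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PlotFramesError(ValueError):
    pass


class DegeneratePlotWarning(UserWarning):
    """A plot sequence is too short to sample; the plot is excluded."""


ALLEYWAY = None  # assignment label for frames outside every plot interval

#: Of the seven splitters (positions i/8 of the span, i=1..7), those kept.
KEPT_SPLITTERS: tuple[int, ...] = (2, 3, 4, 5, 6)
N_SECTIONS = 8


@dataclass
class Frame:
    """One extracted video frame."""

    timestamp: float
    image: np.ndarray | None = None
    frame_id: str | None = None


@dataclass
class PlotFrameSet:
    """A plot's frames grouped into the four (row, side) sequences."""

    plot_id: tuple[int, int]
    sequences: dict[tuple[int, str], list[Frame]]

    def __post_init__(self) -> None:
        for key, frames in self.sequences.items():
            ts = [f.timestamp for f in frames]
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise PlotFramesError(
                    f"sequence {key} of plot {self.plot_id} not strictly time-ordered"
                )


@dataclass
class SampledPlotImages:
    """The 20-image subsample of a plot: 10 per side (5 per row-side)."""

    plot_id: tuple[int, int]
    sides: dict[str, list[Frame]]  # side -> row-1 frames then row-2 frames

    @property
    def n_images(self) -> int:
        return sum(len(v) for v in self.sides.values())

    def images(self, side: str) -> list[np.ndarray]:
        return [f.image for f in self.sides[side]]


def validate_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Check a plot-interval table (columns range, pass, start_s, stop_s) is
    sorted and non-overlapping; returns it sorted by start time."""
    required = {"range", "pass", "start_s", "stop_s"}
    if not required.issubset(intervals.columns):
        raise PlotFramesError(f"interval table needs columns {sorted(required)}")
    iv = intervals.sort_values("start_s").reset_index(drop=True)
    if (iv["stop_s"] <= iv["start_s"]).any():
        bad = iv[iv["stop_s"] <= iv["start_s"]]
        raise PlotFramesError(f"empty or inverted intervals: {bad.to_dict('records')}")
    overlap = iv["start_s"].to_numpy()[1:] < iv["stop_s"].to_numpy()[:-1]
    if overlap.any():
        idx = np.flatnonzero(overlap)
        offenders = iv.iloc[np.unique(np.concatenate([idx, idx + 1]))]
        raise PlotFramesError(f"overlapping intervals: {offenders.to_dict('records')}")
    return iv


def assign_frames_to_plots(
    frame_times: np.ndarray, intervals: pd.DataFrame
) -> list[tuple[int, int] | None]:
    """Assign each frame time to the plot whose [start, stop) interval
    contains it, or ``None`` (alleyway) if no interval does.

    The half-open convention means a frame at a plot's exact stop time never
    belongs to the closing plot.
    """
    iv = validate_intervals(intervals)
    starts = iv["start_s"].to_numpy(float)
    stops = iv["stop_s"].to_numpy(float)
    plot_ids = list(zip(iv["range"].astype(int), iv["pass"].astype(int)))
    times = np.asarray(frame_times, dtype=float)
    pos = np.searchsorted(starts, times, side="right") - 1
    out: list[tuple[int, int] | None] = []
    for t, i in zip(times, pos):
        if i >= 0 and starts[i] <= t < stops[i]:
            out.append(plot_ids[i])
        else:
            out.append(ALLEYWAY)
    return out


def sample_splitter_frames(plot: PlotFrameSet) -> SampledPlotImages | None:
    """Select the splitter subsample of a plot: per (row, side) sequence the
    frames nearest splitters 2..6 of the eight-section division of its time
    span, rows of a side concatenated (row 1 then row 2).

    Splitters live on the time axis (a proxy for distance at constant robot
    speed). A nearest-frame tie is broken toward the earlier frame. Any
    sequence shorter than 8 frames makes the plot degenerate: a warning is
    issued and ``None`` returned so the caller can exclude it.
    """
    expected = {(row, side) for row in (1, 2) for side in ("A", "B")}
    if set(plot.sequences) != expected:
        raise PlotFramesError(
            f"plot {plot.plot_id} must have the four (row, side) sequences, "
            f"got {sorted(plot.sequences)}"
        )
    for key, frames in plot.sequences.items():
        if len(frames) < N_SECTIONS:
            warnings.warn(
                f"plot {plot.plot_id} sequence {key} has {len(frames)} < "
                f"{N_SECTIONS} frames; plot excluded",
                DegeneratePlotWarning,
                stacklevel=2,
            )
            return None
    sides: dict[str, list[Frame]] = {"A": [], "B": []}
    for side in ("A", "B"):
        for row in (1, 2):
            frames = plot.sequences[(row, side)]
            ts = np.array([f.timestamp for f in frames])
            t0, t1 = ts[0], ts[-1]
            for i in KEPT_SPLITTERS:
                target = t0 + i * (t1 - t0) / N_SECTIONS
                # ties toward the earlier frame: strict improvement required
                j = int(np.argmin(np.abs(ts - target)))
                sides[side].append(frames[j])
    return SampledPlotImages(plot_id=plot.plot_id, sides=sides)


def group_frames(
    frame_records,
) -> dict[tuple[int, int], PlotFrameSet]:
    """Group simulator/extraction frame records (objects with .timestamp,
    .plot_id, .row, .side, .image) into PlotFrameSets, dropping alleyway
    frames (plot_id None)."""
    buckets: dict[tuple[int, int], dict[tuple[int, str], list[Frame]]] = {}
    for rec in frame_records:
        if rec.plot_id is None:
            continue
        seqs = buckets.setdefault(rec.plot_id, {})
        seqs.setdefault((rec.row, rec.side), []).append(
            Frame(timestamp=rec.timestamp, image=rec.image)
        )
    out = {}
    for plot_id, seqs in buckets.items():
        for frames in seqs.values():
            frames.sort(key=lambda f: f.timestamp)
        out[plot_id] = PlotFrameSet(plot_id=plot_id, sequences=seqs)
    return out
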