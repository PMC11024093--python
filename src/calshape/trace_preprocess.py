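"""Preprocessing of single-cell fluorescence time series.

Raw acquisitions sample one frame every 30 s.  The first frame is
discarded (it predates image alignment), the next eight frames
(indices 0..7 of the retained series) form the pre-stimulus baseline,
and the transient starts at retained index 8.  Two baseline references
are supported: relative change dF/F0 and plain baseline subtraction.
Per-trace summaries (AUC in an early and a late window, peak and final
dF/F0) use the trapezoidal rule on the uniform 30 s grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .transient_model import BASELINE_FRAMES, TRANSIENT_START

__all__ = [
    "TraceMatrix",
    "BaselineSplit",
    "TraceSummary",
    "drop_first_frame",
    "normalize_dff",
    "baseline_split",
    "summary_stats",
    "read_traces",
    "write_traces",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = ["cell_id", "shape_group", "concentration_uM", "well", "replicate"]

#: Default early/late AUC window boundary (seconds).
DEFAULT_BOUNDARY_S = 750.0


@dataclass
class TraceMatrix:
    """Cells x frames fluorescence on a shared uniform time grid.

    ``values`` is an (n_cells, n_frames) array in arbitrary fluorescence
    units; ``dt`` the frame spacing in seconds; ``metadata`` one row per
    cell (cell_id, shape_group, concentration_uM, well, replicate).
    """

    values: np.ndarray
    dt: float
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x frames)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if len(self.metadata) != self.values.shape[0]:
            raise ValueError("metadata rows must match the number of cells")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Per-frame times in seconds, re-anchored so frame 0 is t = 0."""
        return np.arange(self.n_frames) * self.dt


@dataclass(frozen=True)
class BaselineSplit:
    """Baseline mean and baseline-subtracted transient of one trace."""

    baseline_mean: float
    transient: np.ndarray
    start_index: int = TRANSIENT_START


@dataclass(frozen=True)
class TraceSummary:
    auc_early: float  # area over [0, boundary] in dF/F0 * s
    auc_late: float   # area over [boundary, end]
    max_dff: float
    last_dff: float


def drop_first_frame(traces: TraceMatrix) -> TraceMatrix:
    """Remove frame 0 and re-anchor time so the next frame becomes t = 0."""
    if traces.n_frames < 2:
        raise ValueError("need at least 2 frames to drop the first")
    return replace(traces, values=traces.values[:, 1:].copy())


def normalize_dff(traces: TraceMatrix, baseline_frames: int = BASELINE_FRAMES) -> TraceMatrix:
    """Relative fluorescence change (F - F0)/F0, F0 = mean of the baseline frames."""
    f0 = traces.values[:, :baseline_frames].mean(axis=1)
    if np.any(f0 <= 0):
        bad = np.flatnonzero(f0 <= 0)
        raise ValueError(f"non-positive baseline mean for cell rows {bad.tolist()}")
    dff = (traces.values - f0[:, None]) / f0[:, None]
    return replace(traces, values=dff)


def baseline_split(trace: np.ndarray) -> BaselineSplit:
    """Split one trace into baseline mean and baseline-subtracted transient.

    The transient is y[8:] - mean(y[0:8]); for model fitting its first
    sample is taken as t = 0.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < TRANSIENT_START + 1:
        raise ValueError(f"need at least {TRANSIENT_START + 1} frames, got {trace.size}")
    mean = float(trace[:BASELINE_FRAMES].mean())
    return BaselineSplit(baseline_mean=mean, transient=trace[TRANSIENT_START:] - mean)


def summary_stats(series: np.ndarray, times: np.ndarray, boundary: float = DEFAULT_BOUNDARY_S) -> TraceSummary:
    """Windowed AUCs plus peak and final values of one normalized trace.

    Areas use the trapezoidal rule; the series is split at ``boundary``
    (interpolating a sample there if the grid has none), so the two
    windows share the boundary point and their areas add up to the
    full-window AUC exactly.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.shape != times.shape:
        raise ValueError("series and times must align")
    if not (times[0] <= boundary <= times[-1]):
        raise ValueError(f"boundary {boundary} outside time range [{times[0]}, {times[-1]}]")
    left = times <= boundary
    right = times >= boundary
    t_left, y_left = times[left], series[left]
    t_right, y_right = times[right], series[right]
    if t_left[-1] != boundary:
        yb = float(np.interp(boundary, times, series))
        t_left = np.append(t_left, boundary)
        y_left = np.append(y_left, yb)
        t_right = np.insert(t_right, 0, boundary)
        y_right = np.insert(y_right, 0, yb)
    return TraceSummary(
        auc_early=float(np.trapezoid(y_left, t_left)),
        auc_late=float(np.trapezoid(y_right, t_right)),
        max_dff=float(series.max()),
        last_dff=float(series[-1]),
    )


def write_traces(traces: TraceMatrix, path) -> None:
    """Serialize to TSV: metadata columns then one column per frame (f0, f1, ...)."""
    frames = pd.DataFrame(
        traces.values, columns=[f"f{i}" for i in range(traces.n_frames)]
    )
    out = pd.concat([traces.metadata.reset_index(drop=True), frames], axis=1)
    out.insert(0, "dt_s", traces.dt)
    out.to_csv(path, sep="\t", index=False)


def read_traces(path) -> TraceMatrix:
    df = pd.read_csv(path, sep="\t")
    frame_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    frame_cols.sort(key=lambda c: int(c[1:]))
    meta_cols = [c for c in df.columns if c not in frame_cols and c != "dt_s"]
    return TraceMatrix(
        values=df[frame_cols].to_numpy(float),
        dt=float(df["dt_s"].iloc[0]),
        metadata=df[meta_cols].copy(),
    )
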