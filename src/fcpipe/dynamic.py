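"""Sliding-window dynamic connectivity and cortical stability.

A subject's series is cut into overlapping rectangular windows (default
62 TR long, 2 TR steps; 300 volumes then yield 120 windows), a Pearson
correlation matrix is computed per window, and each parcel's *cortical
stability* is the one-way random-effects intraclass correlation, ICC(1,1),
of its connectivity profile: the (N-1) edges to all other parcels are the
rated targets and the windows are the repeated measurements.  High ICC
means the parcel's connectivity fingerprint barely changes across
windows (low flexibility); negative estimates are reported as computed.

Windowed matrices keep raw correlations — no negative suppression and no
sparsity thresholding is applied in the dynamic analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import ParcelTimeSeries

__all__ = [
    "WindowedConnectome",
    "StabilityMap",
    "sliding_window_starts",
    "windowed_connectomes",
    "icc_oneway",
    "icc_twoway",
    "cortical_stability",
]


@dataclass(frozen=True)
class WindowedConnectome:
    """N x N x W stack of per-window correlation matrices."""

    stack: np.ndarray
    window_length: int
    step: int
    window_starts: tuple

    @property
    def n_parcels(self) -> int:
        return self.stack.shape[0]

    @property
    def n_windows(self) -> int:
        return self.stack.shape[2]


@dataclass(frozen=True)
class StabilityMap:
    """Per-parcel ICC of windowed connectivity profiles."""

    icc: np.ndarray


def sliding_window_starts(T: int, L: int, step: int) -> list[int]:
    """Start indices 0, step, 2*step, ... with last start <= T - L."""
    if L < 2:
        raise ValueError("window length must be >= 2")
    if L > T:
        raise ValueError(f"window length {L} exceeds series length {T}")
    if step < 1:
        raise ValueError("step must be >= 1")
    return list(range(0, T - L + 1, step))


def windowed_connectomes(ts: ParcelTimeSeries, L: int = 62, step: int = 2) -> WindowedConnectome:
    """Per-window Pearson correlation matrices (raw, negatives retained)."""
    starts = sliding_window_starts(ts.n_timepoints, L, step)
    n = ts.n_parcels
    # contiguous (W, N, N) buffer; the public (N, N, W) stack is a view
    buf = np.empty((len(starts), n, n))
    for w, s in enumerate(starts):
        window = ts.data[s : s + L]
        centered = window - window.mean(axis=0)
        norms = np.sqrt((centered**2).sum(axis=0))
        if np.any(norms == 0):
            bad = int(np.flatnonzero(norms == 0)[0])
            raise ValueError(
                f"subject {ts.subject_id}: parcel {bad} has zero variance in "
                f"window {w} (start {s})"
            )
        c = (centered.T @ centered) / np.outer(norms, norms)
        np.fill_diagonal(c, 0.0)
        buf[w] = c
    return WindowedConnectome(
        stack=buf.transpose(1, 2, 0),
        window_length=L,
        step=step,
        window_starts=tuple(starts),
    )


def icc_oneway(measurements: np.ndarray) -> float:
    """One-way random-effects ICC(1,1) of an E x W matrix.

    Rows are targets (edges), columns repeated measurements (windows):
    ICC = (BMS - WMS) / (BMS + (W - 1) * WMS) from the one-way ANOVA
    between-/within-target mean squares.  May be negative; a globally
    constant matrix is degenerate and returns 0 with a warning.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need an E x W matrix with E >= 2 targets, W >= 2 measurements")
    e, w = m.shape
    row_means = m.mean(axis=1)
    grand = m.mean()
    ssb = w * float(((row_means - grand) ** 2).sum())
    ssw = float(((m - row_means[:, None]) ** 2).sum())
    bms = ssb / (e - 1)
    wms = ssw / (e * (w - 1))
    denom = bms + (w - 1) * wms
    if denom <= 1e-300:
        warnings.warn("degenerate ICC input: all measurements identical; returning 0")
        return 0.0
    return float((bms - wms) / denom)


def icc_twoway(measurements: np.ndarray) -> float:
    """Two-way random-effects ICC(2,1) (absolute agreement, single rater)."""
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need an E x W matrix with E >= 2 targets, W >= 2 measurements")
    e, w = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = w * float(((row_means - grand) ** 2).sum())
    ss_cols = e * float(((col_means - grand) ** 2).sum())
    ss_total = float(((m - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (e - 1)
    jms = ss_cols / (w - 1)
    ems = ss_err / ((e - 1) * (w - 1))
    denom = bms + (w - 1) * ems + w * (jms - ems) / e
    if denom <= 1e-300:
        warnings.warn("degenerate ICC input: all measurements identical; returning 0")
        return 0.0
    return float((bms - ems) / denom)


def cortical_stability(wc: WindowedConnectome, form: str = "icc1") -> StabilityMap:
    """Per-parcel ICC of its (N-1) x W connectivity profile across windows."""
    if wc.n_windows < 2:
        raise ValueError("need at least 2 windows for stability")
    if form not in ("icc1", "icc2"):
        raise ValueError("form must be 'icc1' or 'icc2'")
    n = wc.n_parcels
    if form == "icc2":
        out = np.empty(n)
        mask = ~np.eye(n, dtype=bool)
        for i in range(n):
            out[i] = icc_twoway(wc.stack[i][mask[i]])
        return StabilityMap(icc=out)

    # ICC(1,1) vectorized across parcels: for parcel i the target rows are
    # its N-1 edges, so per-row means/SS can be pooled from full-matrix sums
    # after excluding the (zero) diagonal entries.
    arr = np.ascontiguousarray(wc.stack.transpose(2, 0, 1))  # (W, N, N)
    w = wc.n_windows
    e = n - 1
    row_means = arr.mean(axis=0)  # (N, N): mean over windows per edge
    ss_within = np.einsum("wij,wij->ij", arr, arr) - w * row_means**2
    ss_within = np.clip(ss_within, 0.0, None)
    mask = ~np.eye(n, dtype=bool)
    grand = np.where(mask, row_means, 0.0).sum(axis=1) / e
    ssb = w * (
        np.where(mask, (row_means - grand[:, None]) ** 2, 0.0).sum(axis=1)
    )
    ssw = np.where(mask, ss_within, 0.0).sum(axis=1)
    bms = ssb / (e - 1)
    wms = ssw / (e * (w - 1))
    denom = bms + (w - 1) * wms
    degenerate = denom <= 1e-300
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} parcel(s) have a degenerate (constant) "
            "connectivity profile; their ICC is reported as 0"
        )
    out = np.where(degenerate, 0.0, (bms - wms) / np.where(degenerate, 1.0, denom))
    return StabilityMap(icc=out)


def cohort_stability(series, L: int = 62, step: int = 2, form: str = "icc1"):
    """Stability maps for a list of subjects; returns subject x parcel array."""
    import pandas as pd

    rows = {}
    for ts in series:
        wc = windowed_connectomes(ts, L, step)
        rows[ts.subject_id] = cortical_stability(wc, form=form).icc
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"p{j}" for j in range(df.shape[1])]
    df.index.name = "subject_id"
    return df
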