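"""Peak detection and integration of mass-flow electropherograms.

Peak areas are computed by the trapezoidal rule on the mass-flow trace
(ng/min) against time; the s -> min conversion happens exactly once,
here, so areas come out in ng of sulfur.  Baseline handling is global —
the blank mass flow was already subtracted upstream — so no local
baseline is re-estimated inside a window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .isotope_core import MassFlowTrace

__all__ = [
    "PeakWindow",
    "PeakResult",
    "integrate_peak",
    "detect_peaks",
    "integrate_all",
    "read_windows",
    "write_windows",
]


@dataclass(frozen=True)
class PeakWindow:
    """A labelled migration-time window, seconds."""

    label: str
    t_start: float
    t_end: float

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise ValidationError(
                f"window {self.label!r}: t_start must be < t_end")


@dataclass(frozen=True)
class PeakResult:
    """Integration result for one window: area in ng of sulfur."""

    label: str
    area: float       # ng
    apex_time: float  # s
    height: float     # ng/min
    n_points: int

    def __post_init__(self):
        if self.n_points < 3:
            raise ValidationError("a peak result needs >= 3 points")


def integrate_peak(mft: MassFlowTrace, w: PeakWindow) -> PeakResult:
    """Trapezoidal integral of the mass flow over a window -> ng of S.

    Negative point values (blank-subtracted noise) are kept as-is so the
    integral is unbiased; the reported area is floored at zero.
    """
    sel = (mft.time >= w.t_start) & (mft.time <= w.t_end)
    t = mft.time[sel]
    mf = mft.mf[sel]
    ok = np.isfinite(mf)
    t, mf = t[ok], mf[ok]
    if len(t) < 3:
        raise InsufficientDataError(
            f"window {w.label!r} contains {len(t)} usable points (< 3)")
    area = float(np.trapezoid(mf, t / 60.0))  # ng/min * min = ng
    apex = int(np.argmax(mf))
    return PeakResult(label=w.label, area=max(area, 0.0),
                      apex_time=float(t[apex]), height=float(mf[apex]),
                      n_points=int(len(t)))


def detect_peaks(mft: MassFlowTrace, min_height: float,
                 min_width: float) -> list[PeakWindow]:
    """Threshold-based peak finding with local-minimum boundary extension.

    Maximal contiguous runs with mf > min_height lasting at least
    min_width seconds form peak cores; each core is extended outward to
    the nearest flanking local minima of the trace, mimicking manual
    region placement.  Returned windows are disjoint and time-ordered.
    """
    if not (min_height > 0 and min_width > 0):
        raise ValidationError("detection thresholds must be > 0")
    mf = np.nan_to_num(mft.mf, nan=0.0)
    t = mft.time
    above = mf > min_height
    windows: list[PeakWindow] = []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [0] if above[0] else []
    starts += [e + 1 for e in edges if above[e + 1]]
    ends = [e for e in edges if above[e]]
    if above[-1]:
        ends.append(len(mf) - 1)

    prev_end_idx = -1
    for s, e in zip(starts, ends):
        if t[e] - t[s] < min_width:
            continue
        # extend to flanking local minima
        lo = s
        while lo > prev_end_idx + 1 and mf[lo - 1] <= mf[lo]:
            lo -= 1
        hi = e
        while hi < len(mf) - 1 and mf[hi + 1] <= mf[hi]:
            hi += 1
        prev_end_idx = hi
        windows.append(PeakWindow(label=f"peak{len(windows) + 1}",
                                  t_start=float(t[lo]), t_end=float(t[hi])))
    return windows


def integrate_all(mft: MassFlowTrace,
                  windows: Sequence[PeakWindow] | None = None,
                  min_height: float = 1.0,
                  min_width: float = 2.0) -> list[PeakResult]:
    """Integrate configured windows, or auto-detected ones if none given.

    Configured windows take precedence over detection and must not
    overlap.
    """
    if windows is not None and len(windows) > 0:
        ordered = sorted(windows, key=lambda w: w.t_start)
        for a, b in zip(ordered, ordered[1:]):
            if b.t_start < a.t_end:
                raise ValidationError(
                    f"windows {a.label!r} and {b.label!r} overlap")
        use = list(ordered)
    else:
        use = detect_peaks(mft, min_height=min_height, min_width=min_width)
    return [integrate_peak(mft, w) for w in use]


def read_windows(path) -> list[PeakWindow]:
    """Read peak windows from a 3-column TSV (label, t_start_s, t_end_s)."""
    df = pd.read_csv(Path(path), sep="\t")
    for col in ("label", "t_start_s", "t_end_s"):
        if col not in df.columns:
            raise ValidationError(f"windows file missing column {col!r}")
    return [PeakWindow(label=str(r.label), t_start=float(r.t_start_s),
                       t_end=float(r.t_end_s)) for r in df.itertuples()]


def write_windows(windows: Sequence[PeakWindow], path) -> None:
    pd.DataFrame([{"label": w.label, "t_start_s": w.t_start,
                   "t_end_s": w.t_end} for w in windows]).to_csv(
        path, sep="\t", index=False)
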