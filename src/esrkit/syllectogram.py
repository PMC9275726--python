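"""Syllectogram processing: aggregation indices from light-transmission traces.

After abrupt cessation of flow, transmitted light intensity through a thin
blood layer passes through a minimum (I_MIN, the moment of complete
dispersion) and then rises as rouleaux and three-dimensional aggregates
form and the optical path clears.  The aggregation index over a window of
length T is the area ratio

    AI_T = A / (A + B),   A = int_0^T (I(t) - I_MIN) dt,
                          B = int_0^T (I_MAX - I(t)) dt,

a dimensionless number in (0, 1) that grows with aggregation speed.  The
hematocrit-corrected index HAI = AI - k (Ht - 0.40) removes the
near-linear dependence of AI on hematocrit so that aggregability can be
compared across samples.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SyllectogramTrace",
    "AggregationIndices",
    "HtCorrectedIndex",
    "DegenerateSyllectogramError",
    "detect_start",
    "compute_ai",
    "average_detectors",
    "compute_indices",
    "compute_hai",
]

DEFAULT_WINDOWS = (5.0, 10.0, 30.0, 60.0, 120.0)
#: length of the window-end averaging segment used for I_MAX [s]
I_MAX_AVG_S = 0.1
#: default detector-disagreement tolerance on AI
DETECTOR_TOL = 0.10


class DegenerateSyllectogramError(ValueError):
    """Raised when a trace has no usable dynamic range (I_MAX <= I_MIN)."""


@dataclass
class SyllectogramTrace:
    """Transmitted-intensity time series from one or two detectors.

    channels: list of equal-length intensity arrays (ADC units, >= 0);
    dt: sampling interval [s] (10 ms on the reference instrument);
    t0_index: per-channel index of the detected intensity minimum (flow
    stop), or None until ``detect_start`` has run.  Synthetic traces that
    begin exactly at flow stop may set t0_index explicitly.
    """

    sample_id: str
    channels: list
    dt: float = 0.010
    t0_index: list | None = None

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        self.channels = [np.asarray(ch, dtype=float) for ch in self.channels]
        if not 1 <= len(self.channels) <= 2:
            raise ValueError("trace must have 1 or 2 channels")
        n = self.channels[0].size
        if n == 0:
            raise ValueError("empty trace")
        for ch in self.channels:
            if ch.size != n:
                raise ValueError("all channels must have the same length")
            if not np.all(np.isfinite(ch)) or np.any(ch < 0):
                raise ValueError("intensities must be finite and non-negative")
        if self.t0_index is not None:
            for i in self.t0_index:
                if not 0 <= i < n:
                    raise ValueError("t0_index out of bounds")

    @property
    def n_samples(self) -> int:
        return self.channels[0].size

    @property
    def duration(self) -> float:
        """Trace duration [s]."""
        return (self.n_samples - 1) * self.dt


@dataclass
class AggregationIndices:
    """Per-window aggregation indices with a detector-disagreement flag."""

    sample_id: str
    ai: dict = field(default_factory=dict)  # window_s -> AI
    qc_flag: bool = False


@dataclass(frozen=True)
class HtCorrectedIndex:
    """Hematocrit-corrected aggregation index HAI = AI - k (Ht - 0.40)."""

    hai: float
    window_s: float
    ht: float
    k_used: float


def detect_start(trace: SyllectogramTrace, search_window_s: float = 2.0) -> list:
    """Locate the intensity minimum (flow stop) per channel.

    Returns the index of the global minimum within the first
    ``search_window_s`` seconds of each channel (earliest index on ties)
    and records it on ``trace.t0_index``.  A constant search segment
    triggers a degenerate-trace warning.
    """
    if search_window_s <= 0 or search_window_s > trace.duration + trace.dt:
        raise ValueError("search window outside trace")
    n_search = min(int(round(search_window_s / trace.dt)) + 1, trace.n_samples)
    indices = []
    for ch in trace.channels:
        seg = ch[:n_search]
        if np.ptp(seg) == 0:
            warnings.warn("degenerate trace: constant intensity in search window",
                          RuntimeWarning, stacklevel=2)
        indices.append(int(np.argmin(seg)))
    trace.t0_index = indices
    return indices


def _ai_from_segment(seg: np.ndarray, dt: float, i_max_seg: np.ndarray) -> float:
    """AI of one windowed segment; I_MIN is the first sample, I_MAX the
    mean of ``i_max_seg`` (the trailing averaging segment)."""
    i_min = seg[0]
    i_max = float(np.mean(i_max_seg))
    if i_max <= i_min:
        raise DegenerateSyllectogramError(
            "degenerate syllectogram: no dynamic range (I_MAX <= I_MIN)")
    T = (seg.size - 1) * dt
    area_a = float(np.trapezoid(seg - i_min, dx=dt))
    area_b = float(np.trapezoid(i_max - seg, dx=dt))
    total = (i_max - i_min) * T
    # trapezoid is linear, so A + B telescopes to the bounding rectangle
    assert abs((area_a + area_b) - total) <= 1e-9 * max(total, 1.0)
    return area_a / total


def compute_ai(trace: SyllectogramTrace, window_s: float, channel: int = 0,
               i_max_mode: str = "window_end") -> float:
    """Aggregation index AI_T over a window of ``window_s`` seconds.

    I_MIN is the intensity at the detected start (``trace.t0_index``);
    I_MAX is the mean intensity over the final 100 ms of the window
    (``i_max_mode="window_end"``, the default, which makes AI_T computable
    from a T-second record) or of the whole trace
    (``i_max_mode="trace_end"``, the full-record convention).
    Integration is trapezoidal on the recorded grid.
    """
    if trace.t0_index is None:
        raise ValueError("start not detected; call detect_start first "
                         "or set t0_index")
    t0 = trace.t0_index[channel]
    ch = trace.channels[channel]
    n_win = int(round(window_s / trace.dt))
    if n_win < 1:
        raise ValueError("window too short for the sampling interval")
    if t0 + n_win >= ch.size:
        raise ValueError("window exceeds trace duration after start")
    seg = ch[t0:t0 + n_win + 1]
    n_avg = max(int(round(I_MAX_AVG_S / trace.dt)), 1)
    if i_max_mode == "window_end":
        i_max_seg = seg[-n_avg:]
    elif i_max_mode == "trace_end":
        i_max_seg = ch[-n_avg:]
    else:
        raise ValueError("i_max_mode must be 'window_end' or 'trace_end'")
    return _ai_from_segment(seg, trace.dt, i_max_seg)


def average_detectors(ai_ch1: float, ai_ch2: float,
                      tol: float = DETECTOR_TOL) -> tuple:
    """Mean AI of the two detectors with a disagreement QC flag.

    Checking the inter-detector difference flags bubble artefacts trapped
    in one optical path.  Returns ``(mean_ai, qc_flag)``.
    """
    for ai in (ai_ch1, ai_ch2):
        if not 0.0 <= ai <= 1.0:
            raise ValueError("AI must lie in [0, 1]")
    return 0.5 * (ai_ch1 + ai_ch2), abs(ai_ch1 - ai_ch2) > tol


def compute_indices(trace: SyllectogramTrace, windows=DEFAULT_WINDOWS,
                    tol: float = DETECTOR_TOL,
                    i_max_mode: str = "window_end") -> AggregationIndices:
    """All windowed AIs for a trace, averaged over detectors when present."""
    if trace.t0_index is None:
        detect_start(trace)
    out = AggregationIndices(sample_id=trace.sample_id)
    for w in windows:
        ai_per_ch = [compute_ai(trace, w, channel=i, i_max_mode=i_max_mode)
                     for i in range(len(trace.channels))]
        if len(ai_per_ch) == 2:
            ai, flag = average_detectors(ai_per_ch[0], ai_per_ch[1], tol=tol)
            out.qc_flag = out.qc_flag or flag
        else:
            ai = ai_per_ch[0]
        out.ai[float(w)] = ai
    return out


def compute_hai(ai: float, ht: float, k: float = 0.284,
                window_s: float = 5.0) -> HtCorrectedIndex:
    """Hematocrit-corrected aggregation index HAI = AI - k (Ht - 0.40).

    The correction references Ht 0.40, so HAI equals AI there for any k.
    The result is deliberately not clamped to [0, 1]; downstream
    regressions handle out-of-range values.
    """
    if not 0.0 <= ai <= 1.0:
        raise ValueError("AI must lie in [0, 1]")
    if not 0.0 < ht < 1.0:
        raise ValueError("ht must lie in (0, 1)")
    return HtCorrectedIndex(hai=ai - k * (ht - 0.40), window_s=window_s,
                            ht=ht, k_used=k)
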