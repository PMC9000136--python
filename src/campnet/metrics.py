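"""Pulse-response signal metrics and the shift/peak-normalization
variability decomposition.

For a stimulus pulse with signal values S_start (at onset), S_max (maximum
during the pulse) and S_end (at the end of the pulse):

* ``time_to_max`` — minutes from pulse onset to the first sample attaining
  S_max (a proxy for when overshoot peaks, or when a monotone response
  reaches steady state);
* ``time_to_ss`` — minutes from onset to the first sample at or after the
  maximum whose value is within 30 percent of S_end relative to S_max,
  i.e. |S(t) - S_end| <= 0.3 * (S_max - S_end); always >= time_to_max;
* ``overshoot_ratio`` — (S_max - S_start) / (S_end - S_start); ~1 for a
  first-order rise, > 1 when the signal peaks then relaxes.  A trace is
  classified as overshooting when the ratio exceeds 1.1.
* ``undershoot_depth`` — max(0, S_start - min over the post-pulse off
  period): how far the signal dips below its pre-pulse baseline after the
  light turns off.

Metrics are computed on the sampled grid without interpolation, mirroring
what a 3-minute imaging cadence can measure; ties in the maximum break to
the earliest sample.  All metrics are invariant to affine rescaling of the
signal (a*S + b, a > 0).

The variability decomposition shifts every single-cell trace to zero at a
chosen pulse onset and optionally normalizes it by its own (peak - onset)
amplitude in that pulse; if cell-to-cell variability is dominated by peak
amplitude, peak normalization collapses the in-pulse population standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PulseMetrics",
    "OVERSHOOT_THRESHOLD",
    "compute_pulse_metrics",
    "pulse_metrics_for_protocol",
    "classify_pool_response",
    "post_pulse_decay_time",
    "shift_traces",
    "peak_normalize",
    "population_mean_sd",
]

#: Overshoot-ratio threshold separating "overshooting" from first-order-like
#: responses.
OVERSHOOT_THRESHOLD = 1.1

#: Fraction of (S_max - S_end) defining the steady-state convergence band.
SS_FRACTION = 0.3


@dataclass
class PulseMetrics:
    pulse_index: int
    s_start: float
    s_max: float
    s_end: float
    time_to_max: float
    time_to_ss: float
    overshoot_ratio: float
    undershoot_depth: float
    valid: bool

    @property
    def overshooting(self) -> bool:
        return self.valid and self.overshoot_ratio > OVERSHOOT_THRESHOLD


def _window_indices(time: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.flatnonzero((time >= lo - 1e-9) & (time <= hi + 1e-9))


def compute_pulse_metrics(
    time: np.ndarray,
    signal: np.ndarray,
    window: tuple[float, float],
    off_end: float | None = None,
    ss_fraction: float = SS_FRACTION,
    eps: float | None = None,
    pulse_index: int = 1,
    two_sided_ss: bool = True,
) -> PulseMetrics:
    """Pulse metrics of one trace over one stimulus window.

    ``window`` is the (t_on, t_off) pulse interval; ``off_end`` closes the
    post-pulse off period used for the undershoot depth (defaults to the end
    of the trace).  ``eps`` is the degenerate-denominator guard; by default
    1 percent of the trace's global dynamic range.  When
    |S_end - S_start| < eps the trace is flagged invalid and the ratio is
    NaN rather than +/-inf.
    """
    time = np.asarray(time, dtype=float)
    signal = np.asarray(signal, dtype=float)
    t_on, t_off = window
    if t_on < time[0] - 1e-9 or t_off > time[-1] + 1e-9:
        raise ValueError("pulse window must lie within the trace span")
    idx = _window_indices(time, t_on, t_off)
    if idx.size < 3:
        raise ValueError("need at least 3 samples inside the pulse window")
    if eps is None:
        eps = 0.01 * float(signal.max() - signal.min())

    seg = signal[idx]
    s_start = float(seg[0])
    s_end = float(seg[-1])
    k_max = int(np.argmax(seg))  # earliest index attaining the max
    s_max = float(seg[k_max])
    time_to_max = float(time[idx[k_max]] - t_on)

    band = ss_fraction * (s_max - s_end)
    tail = seg[k_max:]
    if two_sided_ss:
        in_band = np.abs(tail - s_end) <= band + 1e-15
    else:
        in_band = tail - s_end <= band + 1e-15
    k_ss = k_max + int(np.argmax(in_band)) if in_band.any() else idx.size - 1
    time_to_ss = float(time[idx[k_ss]] - t_on)

    if off_end is None:
        off_end = float(time[-1])
    off_idx = _window_indices(time, t_off, off_end)
    if off_idx.size:
        undershoot = max(0.0, s_start - float(signal[off_idx].min()))
    else:
        undershoot = 0.0

    denom = s_end - s_start
    valid = denom != 0.0 and abs(denom) >= eps
    ratio = (s_max - s_start) / denom if valid else float("nan")
    return PulseMetrics(
        pulse_index=pulse_index,
        s_start=s_start,
        s_max=s_max,
        s_end=s_end,
        time_to_max=time_to_max,
        time_to_ss=time_to_ss,
        overshoot_ratio=ratio,
        undershoot_depth=undershoot,
        valid=valid,
    )


def pulse_metrics_for_protocol(
    time: np.ndarray,
    signal: np.ndarray,
    pulses: list[tuple[float, float, float]] | tuple,
    **kwargs,
) -> list[PulseMetrics]:
    """Metrics for every pulse of a protocol; the off period of each pulse
    runs to the next pulse onset (or the end of the trace)."""
    out = []
    for k, (t_on, t_off, _) in enumerate(pulses):
        off_end = pulses[k + 1][0] if k + 1 < len(pulses) else float(time[-1])
        out.append(
            compute_pulse_metrics(
                time, signal, (t_on, t_off), off_end=off_end,
                pulse_index=k + 1, **kwargs,
            )
        )
    return out


def post_pulse_decay_time(
    time: np.ndarray,
    signal: np.ndarray,
    t_on: float,
    t_off: float,
    fraction: float = 0.5,
    off_end: float | None = None,
) -> float:
    """Minutes after pulse shutoff for the signal to decay to ``fraction``
    of its end-of-pulse elevation above the pre-pulse baseline.

    The crossing time is linearly interpolated between samples (the decay
    can be faster than the output cadence).  Returns ``inf`` when the
    signal never reaches the target level within the off period.
    """
    time = np.asarray(time, dtype=float)
    signal = np.asarray(signal, dtype=float)
    k_on = int(np.argmin(np.abs(time - t_on)))
    k_off = int(np.argmin(np.abs(time - t_off)))
    base = signal[k_on]
    target = base + fraction * (signal[k_off] - base)
    stop = time[-1] if off_end is None else off_end
    for k in range(k_off, time.size - 1):
        if time[k + 1] > stop + 1e-9:
            break
        s0, s1 = signal[k], signal[k + 1]
        if (s0 - target) * (s1 - target) <= 0 and s0 != s1:
            return float(time[k] + (s0 - target) / (s0 - s1)
                         * (time[k + 1] - time[k]) - t_off)
    return float("inf")


def classify_pool_response(
    m: PulseMetrics, tau_far: float = 15.0
) -> str:
    """Classify an emitter pulse response by its inactive-pool composition.

    A monolayer emitter whose permeability regulation is carried by the
    slow ("far", trafficking) connexin population peaks late — near the
    mean activation delay ``tau_far``; a fast membrane-proximal ("near")
    population drains the emitter almost immediately, so the response
    peaks early with no late overshoot; a mixture rises fast and then
    relaxes through the delayed component (biphasic).  The classifier uses
    only (time_to_max, overshoot_ratio):

    * ``"first_order"`` — no overshoot (ratio <= 1.1);
    * ``"slow_overshoot"`` — overshoot peaking at or after 0.55 * tau_far;
    * ``"fast_no_late_overshoot"`` — peak before tau_far / 2.5;
    * ``"biphasic"`` — overshoot peaking in between.
    """
    if not m.valid or not np.isfinite(m.overshoot_ratio):
        return "invalid"
    if m.overshoot_ratio <= OVERSHOOT_THRESHOLD:
        return "first_order"
    if m.time_to_max >= 0.55 * tau_far:
        return "slow_overshoot"
    if m.time_to_max < tau_far / 2.5:
        return "fast_no_late_overshoot"
    return "biphasic"


def _onset_index(time: np.ndarray, onset: float) -> int:
    k = int(np.argmin(np.abs(time - onset)))
    if abs(time[k] - onset) > (time[1] - time[0]) + 1e-9:
        raise ValueError("pulse onset lies outside the time grid")
    return k


def shift_traces(
    traces: np.ndarray, time: np.ndarray, onset: float
) -> np.ndarray:
    """Shift each trace so its value at the pulse onset is exactly zero.

    ``traces`` is (n_cells, n_t) on a shared grid.  By construction the
    population standard deviation at the onset sample is zero.
    """
    traces = np.asarray(traces, dtype=float)
    k = _onset_index(np.asarray(time, dtype=float), onset)
    return traces - traces[:, k][:, None]


def peak_normalize(
    traces: np.ndarray,
    time: np.ndarray,
    window: tuple[float, float],
    eps: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Shift traces to zero at the window onset and divide each by its own
    (peak - onset) amplitude within the window.

    Returns ``(normalized, kept)`` where ``kept`` flags traces whose
    amplitude exceeded ``eps`` (flat traces are excluded, with a warning
    counted in ``kept``); each kept trace has normalized peak exactly 1 in
    the window.
    """
    import warnings

    time = np.asarray(time, dtype=float)
    shifted = shift_traces(traces, time, window[0])
    idx = _window_indices(time, *window)
    amp = shifted[:, idx].max(axis=1)
    kept = amp > eps
    if not kept.all():
        warnings.warn(
            f"excluded {int((~kept).sum())} flat trace(s) from peak "
            "normalization",
            stacklevel=2,
        )
    normalized = shifted[kept] / amp[kept][:, None]
    return normalized, kept


def population_mean_sd(
    traces: np.ndarray,
    time: np.ndarray,
    onsets: tuple[float, ...] | list[float] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise population mean and sample standard deviation.

    When pulse ``onsets`` are given, each inter-onset segment is first
    shifted per-trace to zero at its own onset (enforcing zero sd at each
    pulse start) and the statistics are computed segment-wise, matching the
    per-pulse variability protocol.
    """
    traces = np.asarray(traces, dtype=float)
    time = np.asarray(time, dtype=float)
    if traces.shape[0] < 2:
        raise ValueError("population statistics need at least 2 traces")
    if not onsets:
        return traces.mean(axis=0), traces.std(axis=0, ddof=1)
    mean = np.empty(time.size)
    sd = np.empty(time.size)
    bounds = list(onsets) + [time[-1] + 1.0]
    start = 0.0
    done = np.zeros(time.size, dtype=bool)
    for onset, nxt in zip(onsets, bounds[1:]):
        seg = (time >= onset - 1e-9) & (time < nxt - 1e-9) & ~done
        if not seg.any():
            continue
        shifted = shift_traces(traces, time, onset)
        mean[seg] = shifted[:, seg].mean(axis=0)
        sd[seg] = shifted[:, seg].std(axis=0, ddof=1)
        done |= seg
    pre = ~done
    mean[pre] = traces[:, pre].mean(axis=0)
    sd[pre] = traces[:, pre].std(axis=0, ddof=1)
    return mean, sd
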