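"""Raw-trace conditioning: low-pass filter, piecewise detrend, baseline
subtraction, and Lykken-Venables range correction.

The full chain (:func:`preprocess_session`) applies the four stages in
that order and records each one in the output's provenance.  The chain is
invariant under positive affine rescaling of the raw trace: amplifier
gain cancels in the range correction and offset in the baseline
subtraction, which is what makes the resulting dimensionless signal
comparable across subjects.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import (
    ConfigurationError,
    DegenerateRangeError,
    DegenerateSegmentError,
    LayoutError,
)
from .trace import ProcessedTrace, RawTrace, SessionLayout

__all__ = [
    "lowpass",
    "piecewise_detrend",
    "subtract_baseline",
    "range_correct",
    "preprocess_session",
]

DEFAULT_CUTOFF_HZ = 0.6
DEFAULT_FILTER_ORDER = 4


def _zero_phase_design_cutoff(cutoff: float, order: int) -> float:
    """Design cutoff giving -3 dB of the *forward-backward* response.

    One Butterworth pass is -3 dB at its design cutoff, so two passes are
    -6 dB there; pre-warping by (2**0.5 - 1)**(-1/(2*order)) puts the half-
    power point of the overall zero-phase filter at the requested frequency.
    """
    return cutoff / (2**0.5 - 1.0) ** (1.0 / (2 * order))


def lowpass(
    trace: RawTrace,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> RawTrace:
    """Zero-phase Butterworth low-pass; DC gain 1, -3 dB at ``cutoff``.

    Applied forward and backward (``sosfiltfilt``) so SCR latencies are
    not shifted; motion artifacts above the EDA band are removed.
    """
    nyquist = trace.sampling_rate / 2.0
    if not 0 < cutoff:
        raise ConfigurationError("cutoff: must be > 0")
    design_cutoff = _zero_phase_design_cutoff(cutoff, order)
    if design_cutoff >= nyquist:
        raise ConfigurationError(
            f"cutoff: {cutoff} Hz needs a design cutoff {design_cutoff:.3g} Hz "
            f">= Nyquist ({nyquist:.3g} Hz)"
        )
    sos = sps.butter(order, design_cutoff, btype="low", fs=trace.sampling_rate, output="sos")
    # Pad by ~10 cutoff periods: the default padlen leaves a visible edge
    # transient at sub-hertz cutoffs (a pure ramp would not pass through).
    padlen = min(trace.n_samples - 1, int(10 * trace.sampling_rate / cutoff))
    filtered = sps.sosfiltfilt(sos, trace.samples, padlen=padlen)
    return trace.replace_samples(filtered)


def piecewise_detrend(
    trace: RawTrace, breakpoints: Sequence[float] = ()
) -> RawTrace:
    """Remove per-segment linear drift, preserving each segment's mean.

    ``breakpoints`` split the trace into contiguous segments (half-open at
    each breakpoint); an OLS line is fit within each and only its slope
    component ``b*(t - t_mean)`` subtracted, so the electrode drift that
    accumulates within a run is removed while the level information that
    baseline subtraction needs is retained.
    """
    times = trace.times()
    edges = [trace.start_time, *sorted(breakpoints), trace.start_time + trace.duration]
    for bp in breakpoints:
        if not (trace.start_time <= bp <= trace.start_time + trace.duration):
            raise ConfigurationError(f"breakpoints: {bp} outside the trace span")
    out = trace.samples.copy()
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (times >= lo) & (times < hi)
        if hi == edges[-1]:
            mask = (times >= lo) & (times <= hi)
        n = int(mask.sum())
        if n == 0:
            continue
        if n < 2:
            raise DegenerateSegmentError(
                f"segment [{lo}, {hi}) has {n} sample(s); need >= 2 for a line fit"
            )
        t_seg = times[mask]
        y_seg = out[mask]
        t_c = t_seg - t_seg.mean()
        slope = float(np.dot(t_c, y_seg) / np.dot(t_c, t_c))
        out[mask] = y_seg - slope * t_c
    return trace.replace_samples(out)


def subtract_baseline(trace: RawTrace, layout: SessionLayout) -> RawTrace:
    """Subtract each run's silent-baseline mean from that run's samples.

    Accounts for between-subject differences in resting conductance; every
    sample in run r (baseline included) is centred by the mean over run
    r's baseline interval.
    """
    times = trace.times()
    out = trace.samples.copy()
    for run in layout.runs:
        base = layout.baseline_for_run(run)
        i0, i1 = trace.index_range(base.start, base.end)
        if i1 <= i0:
            raise LayoutError(f"baseline for run {run} contains no samples")
        mean = float(np.mean(trace.samples[i0:i1]))
        r0, r1 = layout.run_span(run)
        mask = (times >= r0) & (times < r1)
        if run == layout.runs[-1]:
            mask = times >= r0
        out[mask] -= mean
    return trace.replace_samples(out)


def range_correct(
    trace: RawTrace, provenance: tuple[dict, ...] = ()
) -> ProcessedTrace:
    """Map the trace through (SCL - SCLmin) / (SCLmax - SCLmin).

    Session-wide min and max define the subject's individual range; output
    lies in [0, 1] with both endpoints attained.  A constant trace has no
    range and raises :class:`DegenerateRangeError`.
    """
    lo = float(np.min(trace.samples))
    hi = float(np.max(trace.samples))
    # Relative degeneracy guard: a numerically constant trace (e.g. pure
    # drift after detrending) has no usable range either.
    if hi - lo <= 1e-9 * max(1.0, abs(hi), abs(lo)):
        raise DegenerateRangeError(
            "range correction undefined: trace max equals min"
        )
    corrected = (trace.samples - lo) / (hi - lo)
    step = {"step": "range_correct", "scl_min": lo, "scl_max": hi}
    return ProcessedTrace(
        corrected,
        trace.sampling_rate,
        trace.start_time,
        provenance=(*provenance, step),
    )


def preprocess_session(
    trace: RawTrace,
    layout: SessionLayout,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
    breakpoints: Sequence[float] | None = None,
) -> ProcessedTrace:
    """Full conditioning chain: filter, detrend, baseline-subtract,
    range-correct, in that order.

    Detrend breakpoints default to the run boundaries (electrodes come off
    at the break, so drift restarts per run).
    """
    if breakpoints is None:
        breakpoints = [
            layout.baseline_for_run(run).start
            for run in layout.runs
            if layout.baseline_for_run(run).start > trace.start_time
        ]
    provenance = [
        {"step": "lowpass", "cutoff_hz": cutoff, "order": order, "zero_phase": True},
        {"step": "piecewise_detrend", "breakpoints": [float(b) for b in breakpoints],
         "mode": "slope_only"},
        {"step": "subtract_baseline", "per_run": True},
    ]
    filtered = lowpass(trace, cutoff=cutoff, order=order)
    detrended = piecewise_detrend(filtered, breakpoints)
    centred = subtract_baseline(detrended, layout)
    return range_correct(centred, provenance=tuple(provenance))
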