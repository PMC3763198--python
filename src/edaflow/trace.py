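"""Core in-memory containers: conductance traces and session layouts.

Time is seconds from session start, intervals are half-open ``[start, end)``.
A :class:`RawTrace` holds microsiemens samples on a uniform grid; a
:class:`ProcessedTrace` holds the dimensionless range-corrected signal
together with an append-only provenance of the steps that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ConfigurationError, LayoutError

__all__ = ["RawTrace", "ProcessedTrace", "Interval", "SessionLayout"]


@dataclass(frozen=True)
class RawTrace:
    """Uniformly sampled skin-conductance series in microsiemens (μS)."""

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ConfigurationError("samples: need a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ConfigurationError("samples: all values must be finite")
        if not self.sampling_rate > 0:
            raise ConfigurationError("sampling_rate: must be > 0")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Span covered by the samples, in seconds."""
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def replace_samples(self, samples: np.ndarray) -> "RawTrace":
        return RawTrace(samples, self.sampling_rate, self.start_time)

    def index_range(self, start: float, end: float) -> tuple[int, int]:
        """Sample indices covering the half-open interval ``[start, end)``.

        The slice holds ``floor(duration * rate)`` samples, which pins down
        the otherwise ambiguous +-1 sample at 30-s epochs.
        """
        fs = self.sampling_rate
        i0 = int(round((start - self.start_time) * fs))
        n = int(np.floor((end - start) * fs))
        if i0 < 0 or i0 + n > self.n_samples:
            raise LayoutError(
                f"interval [{start}, {end}) falls outside the trace span "
                f"[{self.start_time}, {self.start_time + self.duration})"
            )
        return i0, i0 + n


@dataclass(frozen=True)
class ProcessedTrace:
    """Range-corrected (dimensionless) conductance plus its provenance."""

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    provenance: tuple[dict[str, Any], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "provenance", tuple(self.provenance))

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def index_range(self, start: float, end: float) -> tuple[int, int]:
        return RawTrace.index_range(self, start, end)  # type: ignore[arg-type]


@dataclass(frozen=True)
class Interval:
    """One labelled stretch of the session: a baseline or a trial."""

    label: str  # "baseline" | "trial"
    start: float
    end: float
    run: int
    trial_index: int | None = None
    excerpt_id: int | None = None
    exposure: int | None = None

    def __post_init__(self) -> None:
        if self.label not in ("baseline", "trial"):
            raise ConfigurationError(f"label: unknown interval label {self.label!r}")
        if not self.end > self.start:
            raise ConfigurationError("interval: end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def to_dict(self) -> dict[str, Any]:
        return {
            "label": self.label,
            "start": self.start,
            "end": self.end,
            "run": self.run,
            "trial_index": self.trial_index,
            "excerpt_id": self.excerpt_id,
            "exposure": self.exposure,
        }

    @staticmethod
    def from_dict(d: dict[str, Any]) -> "Interval":
        return Interval(
            label=d["label"],
            start=float(d["start"]),
            end=float(d["end"]),
            run=int(d["run"]),
            trial_index=None if d.get("trial_index") is None else int(d["trial_index"]),
            excerpt_id=None if d.get("excerpt_id") is None else int(d["excerpt_id"]),
            exposure=None if d.get("exposure") is None else int(d["exposure"]),
        )


@dataclass(frozen=True)
class SessionLayout:
    """Ordered, non-overlapping baseline/trial intervals of one session."""

    intervals: tuple[Interval, ...]

    def __post_init__(self) -> None:
        intervals = tuple(self.intervals)
        object.__setattr__(self, "intervals", intervals)
        if not intervals:
            raise LayoutError("layout: needs at least one interval")
        prev_end = -np.inf
        for iv in intervals:
            if iv.start < prev_end:
                raise LayoutError(
                    f"layout: interval starting at {iv.start} overlaps or is out of order"
                )
            prev_end = iv.end
        per_run: dict[int, int] = {}
        for iv in intervals:
            if iv.label == "baseline":
                per_run[iv.run] = per_run.get(iv.run, 0) + 1
        for run in self.runs:
            if per_run.get(run, 0) != 1:
                raise LayoutError(f"layout: run {run} must have exactly one baseline")

    @property
    def runs(self) -> list[int]:
        return sorted({iv.run for iv in self.intervals})

    def trials(self) -> list[Interval]:
        return [iv for iv in self.intervals if iv.label == "trial"]

    def baselines(self) -> list[Interval]:
        return [iv for iv in self.intervals if iv.label == "baseline"]

    def baseline_for_run(self, run: int) -> Interval:
        for iv in self.intervals:
            if iv.label == "baseline" and iv.run == run:
                return iv
        raise LayoutError(f"layout: no baseline interval for run {run}")

    def run_span(self, run: int) -> tuple[float, float]:
        """Time span a run occupies: from its baseline start to the start of
        the next run's baseline (last run: to the session end)."""
        runs = self.runs
        start = self.baseline_for_run(run).start
        later = [r for r in runs if r > run]
        end = self.baseline_for_run(later[0]).start if later else self.span[1]
        return start, end

    @property
    def span(self) -> tuple[float, float]:
        return self.intervals[0].start, self.intervals[-1].end
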