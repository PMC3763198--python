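"""Per-excerpt dependent measures: mean SCL and SCR count (nSCR).

The processed (range-corrected) signal is cut into one epoch per trial
interval; each epoch yields the arithmetic mean level and a trough-to-peak
SCR count.  Detection uses the classical amplitude-criterion convention
(minimum rise of 0.01 on the unit range, at least 1 s between peaks),
both fully configurable via :class:`ScrParams`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import AlignmentError, ConfigurationError, LayoutError
from .trace import Interval, ProcessedTrace, SessionLayout

__all__ = [
    "ScrParams",
    "segment_epochs",
    "mean_scl",
    "detect_scrs",
    "extract_features",
]


@dataclass(frozen=True)
class ScrParams:
    """SCR detection criteria on the range-corrected (unit) scale.

    ``search_post`` extends the detection window past the epoch end: an
    SCR peaks ~1-2 s after its onset, so a response elicited near the end
    of an excerpt crests just after it.  Such peaks are counted for the
    epoch containing their onset (trough).
    """

    min_amplitude: float = 0.01   # trough-to-peak rise, fraction of unit range
    min_inter_peak: float = 1.0   # s between accepted peaks
    search_post: float = 2.0      # s of post-epoch window for late peaks
    detection_cutoff: float | None = 2.0  # Hz; None = detect on the SCL signal

    def validate(self) -> None:
        if not self.min_amplitude > 0:
            raise ConfigurationError("min_amplitude: must be > 0")
        if self.min_inter_peak < 0:
            raise ConfigurationError("min_inter_peak: must be >= 0")
        if self.search_post < 0:
            raise ConfigurationError("search_post: must be >= 0")
        if self.detection_cutoff is not None and not self.detection_cutoff > 0:
            raise ConfigurationError("detection_cutoff: must be > 0 or None")


def segment_epochs(
    trace: ProcessedTrace, layout: SessionLayout
) -> list[tuple[Interval, np.ndarray]]:
    """One epoch of samples per trial interval, baselines excluded.

    Epoch length is ``floor(duration * rate)`` samples on the half-open
    interval, removing the +-1-sample rounding ambiguity.
    """
    epochs = []
    for iv in layout.trials():
        try:
            i0, i1 = trace.index_range(iv.start, iv.end)
        except LayoutError:
            raise LayoutError(
                f"trial {iv.trial_index} [{iv.start}, {iv.end}) outside trace span"
            ) from None
        epochs.append((iv, trace.samples[i0:i1]))
    return epochs


def mean_scl(epoch: np.ndarray) -> float:
    """Arithmetic mean conductance level of one epoch."""
    epoch = np.asarray(epoch, dtype=float)
    if epoch.size == 0:
        raise LayoutError("mean_scl: empty epoch")
    return float(np.mean(epoch))


def detect_scrs(
    epoch: np.ndarray,
    sampling_rate: float,
    params: ScrParams | None = None,
    onset_limit: int | None = None,
) -> tuple[int, np.ndarray]:
    """Count SCRs in an epoch by trough-to-peak criterion.

    All local maxima are located; each is measured against the minimum
    since the previous maximum (or the epoch start) and kept when the rise
    reaches ``min_amplitude``.  Accepted peaks closer than
    ``min_inter_peak`` to the previous accepted peak are discarded
    (greedy, in time order).  ``onset_limit`` restricts counting to peaks
    whose onset trough lies before that sample index (used when the search
    window extends past the epoch proper).  Returns the count and the
    accepted peak sample indices.
    """
    if params is None:
        params = ScrParams()
    params.validate()
    epoch = np.asarray(epoch, dtype=float)
    if epoch.size < 3:
        return 0, np.empty(0, dtype=int)
    peaks, _ = sps.find_peaks(epoch)
    if peaks.size == 0:
        return 0, np.empty(0, dtype=int)
    min_gap = params.min_inter_peak * sampling_rate
    accepted: list[int] = []
    prev_peak = 0
    for p in peaks:
        segment = epoch[prev_peak : p + 1]
        trough_idx = prev_peak + int(np.argmin(segment))
        rise = float(epoch[p]) - float(epoch[trough_idx])
        prev_peak = p
        if rise < params.min_amplitude:
            continue
        if onset_limit is not None and trough_idx >= onset_limit:
            continue
        if accepted and (p - accepted[-1]) < min_gap:
            continue
        accepted.append(int(p))
    return len(accepted), np.asarray(accepted, dtype=int)


def extract_features(
    trace: ProcessedTrace,
    layout: SessionLayout,
    ratings: pd.DataFrame,
    params: ScrParams | None = None,
    detection_trace: ProcessedTrace | None = None,
) -> pd.DataFrame:
    """Join epoch measures with the ratings table: one row per trial.

    Mean SCL comes from ``trace`` (the tonic-band signal); SCR counting
    runs on ``detection_trace`` when given - a parallel range-corrected
    signal filtered in the wider phasic band, where closely spaced
    responses are still separable.  Ratings must cover exactly the
    layout's trial set (matched on the trial index); a mismatch raises
    :class:`AlignmentError`.
    """
    detection = detection_trace if detection_trace is not None else trace
    if detection.n_samples != trace.n_samples:
        raise AlignmentError("detection trace and SCL trace differ in length")
    epochs = segment_epochs(trace, layout)
    layout_trials = [iv.trial_index for iv, _ in epochs]
    rating_trials = list(ratings["trial"].astype(int))
    if sorted(rating_trials) != sorted(layout_trials):
        raise AlignmentError(
            f"ratings cover {len(rating_trials)} trials, layout has "
            f"{len(layout_trials)}; trial indices must match"
        )
    if params is None:
        params = ScrParams()
    by_trial = ratings.set_index(ratings["trial"].astype(int))
    post = int(params.search_post * trace.sampling_rate)
    rows = []
    for iv, samples in epochs:
        r = by_trial.loc[iv.trial_index]
        i0, i1 = trace.index_range(iv.start, iv.end)
        extended = detection.samples[i0 : min(i1 + post, detection.n_samples)]
        n_scr, _ = detect_scrs(
            extended, trace.sampling_rate, params, onset_limit=i1 - i0
        )
        row = {
            "run": iv.run,
            "trial": iv.trial_index,
            "excerpt": iv.excerpt_id,
            "exposure": iv.exposure,
            "pleasure": int(r["pleasure"]),
            "arousal": int(r["arousal"]),
            "familiarity": int(r["familiarity"]),
            "mean_scl": mean_scl(samples),
            "n_scr": int(n_scr),
        }
        if "subject" in ratings.columns:
            row = {"subject": int(r["subject"]), **row}
        rows.append(row)
    return pd.DataFrame(rows)
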