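"""Generative model of a music-listening skin-conductance session.

The simulator renders what the analysis pipeline assumes a recording
contains: a tonic conductance level around 10 μS, a slow per-run linear
electrode drift, phasic skin-conductance responses (SCRs) arriving as a
Poisson process and shaped by a bi-exponential kernel, white sensor noise,
and per-trial ratings (pleasure −5..+5, arousal 0..10, familiarity 0..10)
whose means can be coupled to familiarity and repeated exposure.  Every
stochastic ingredient is recorded in a :class:`GroundTruth` so recovery
tests can compare what the pipeline measures against what was injected.

The session design mirrors the two-run listening task: a 2-minute silent
baseline before each run, then 35 trials of 30 s separated by rating
periods.  In the repetition design (``exp2``) the second run replays the
first run's 35 excerpts in a shuffled order and its trials carry
``exposure == 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ResourceError
from .trace import Interval, RawTrace, SessionLayout

__all__ = [
    "SimConfig",
    "DesignSpec",
    "GroundTruth",
    "SubjectDataset",
    "build_layout",
    "scr_kernel",
    "scr_kernel_peak_time",
    "simulate_trace",
    "simulate_ratings",
    "simulate_subject",
    "simulate_experiment",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the generative model (units in field comments).

    Defaults are the study conditions the analysis expects: tonic level
    ~10 μS, downward drift of a fraction of a μS over a 25-minute run,
    ~4 SCRs per 30-s excerpt, and rating scales centred so that all six
    non-negative pleasure levels are populated.
    """

    sampling_rate: float = 256.0          # Hz
    tonic_level: float = 10.0             # μS
    drift_slope_per_run: tuple[float, ...] = (-0.04, -0.05)  # μS/min, per run
    noise_sd: float = 0.02                # μS, white sensor noise
    scr_rate_base: float = 8.0            # events/min during trials
    scr_amplitude_mean: float = 0.30      # μS
    scr_amplitude_sd: float = 0.10        # μS, truncated at 0
    kernel_rise: float = 0.75             # s
    kernel_decay: float = 2.0             # s
    exposure_scl_delta: float = 0.1       # μS added to tonic on exposure-2 trials
    exposure_rate_delta: float = 0.5      # events/min added on exposure-2 trials
    pleasure_scl_slope: float = 0.0       # μS per pleasure rating unit (null finding)
    familiarity_pleasure_slope: float = 1.0   # rating units per familiarity bin
    familiarity_arousal_slope: float = 0.75   # rating units per familiarity bin
    base_pleasure: float = 1.5            # rating units before coupling/noise
    base_arousal: float = 4.0
    rating_noise_sd: float = 2.0          # rating units
    familiarity_probs: tuple[float, float, float] = (0.70, 0.20, 0.10)
    recognition_prob: float = 0.3         # P(familiarity > 0 on an exposure-2 trial)
    max_duration_s: float = 4 * 3600.0    # resource guard for rendered spans
    seed: int = 0

    def resampled(self, sampling_rate: float) -> "SimConfig":
        """Config at another sampling rate with equivalent in-band noise.

        White sensor noise has flat power spectral density noise_sd^2 / fs,
        so keeping noise_sd fixed while lowering fs would concentrate more
        noise power inside the sub-0.6 Hz analysis band.  Scaling noise_sd
        by sqrt(fs_new / fs_old) preserves the PSD, making runs at reduced
        rates statistically comparable to full-rate sessions.
        """
        if not sampling_rate > 0:
            raise ConfigurationError("sampling_rate: must be > 0")
        factor = math.sqrt(sampling_rate / self.sampling_rate)
        return replace(
            self, sampling_rate=sampling_rate, noise_sd=self.noise_sd * factor
        )

    def validate(self) -> None:
        if not self.sampling_rate > 0:
            raise ConfigurationError("sampling_rate: must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd: must be >= 0")
        if not (self.kernel_decay > self.kernel_rise > 0):
            raise ConfigurationError(
                "kernel_rise/kernel_decay: need kernel_decay > kernel_rise > 0"
            )
        if not self.scr_amplitude_mean > 0:
            raise ConfigurationError("scr_amplitude_mean: must be > 0")
        if self.scr_amplitude_sd < 0:
            raise ConfigurationError("scr_amplitude_sd: must be >= 0")
        if self.scr_rate_base < 0:
            raise ConfigurationError("scr_rate_base: must be >= 0")
        if self.rating_noise_sd < 0:
            raise ConfigurationError("rating_noise_sd: must be >= 0")
        if not math.isclose(sum(self.familiarity_probs), 1.0, abs_tol=1e-9):
            raise ConfigurationError("familiarity_probs: must sum to 1")
        if not 0 <= self.recognition_prob <= 1:
            raise ConfigurationError("recognition_prob: must lie in [0, 1]")
        if not self.max_duration_s > 0:
            raise ConfigurationError("max_duration_s: must be > 0")


@dataclass(frozen=True)
class DesignSpec:
    """Structure of one session: runs, trials, baselines, gaps."""

    experiment: str = "exp1"              # "exp1" | "exp2"
    n_runs: int = 2
    trials_per_run: int = 35
    trial_duration: float = 30.0          # s
    baseline_duration: float = 120.0      # s
    inter_trial_gap: float = 10.0         # s, rating period between trials
    n_excerpts: int | None = None         # default: 70 (exp1) or 35 (exp2)

    def validate(self) -> None:
        if self.experiment not in ("exp1", "exp2"):
            raise ConfigurationError(f"experiment: unknown tag {self.experiment!r}")
        if self.n_runs < 1:
            raise ConfigurationError("n_runs: must be >= 1")
        if self.trials_per_run < 1:
            raise ConfigurationError("trials_per_run: must be >= 1")
        if not self.trial_duration > 0:
            raise ConfigurationError("trial_duration: must be > 0")
        if not self.baseline_duration > 0:
            raise ConfigurationError("baseline_duration: must be > 0")
        if self.inter_trial_gap < 0:
            raise ConfigurationError("inter_trial_gap: must be >= 0")
        n_exc = self.resolved_n_excerpts
        if self.experiment == "exp1" and n_exc != self.n_runs * self.trials_per_run:
            raise ConfigurationError(
                "n_excerpts: exp1 needs one distinct excerpt per trial"
            )
        if self.experiment == "exp2":
            if self.n_runs != 2:
                raise ConfigurationError("n_runs: exp2 requires exactly 2 runs")
            if n_exc != self.trials_per_run:
                raise ConfigurationError(
                    "n_excerpts: exp2 repeats the run-1 set, so n_excerpts "
                    "must equal trials_per_run"
                )

    @property
    def resolved_n_excerpts(self) -> int:
        if self.n_excerpts is not None:
            return self.n_excerpts
        if self.experiment == "exp2":
            return self.trials_per_run
        return self.n_runs * self.trials_per_run


@dataclass(frozen=True)
class GroundTruth:
    """Everything the simulator injected, for recovery tests.

    ``trials`` has one row per trial interval with the deterministic tonic
    mean over the trial (level + drift + exposure/pleasure shifts, no SCRs,
    no noise) and the number of SCR events placed in it.
    """

    event_times: np.ndarray
    event_amplitudes: np.ndarray
    trials: pd.DataFrame  # run, trial, excerpt, exposure, tonic_mean, n_events


@dataclass(frozen=True)
class SubjectDataset:
    subject: int
    layout: SessionLayout
    trace: RawTrace
    ratings: pd.DataFrame
    ground_truth: GroundTruth


def build_layout(
    design: DesignSpec,
    rng: np.random.Generator | None = None,
    excerpt_order: Sequence[int] | None = None,
) -> SessionLayout:
    """Lay out baselines and trials on the session time axis.

    Each run opens with a silent baseline, followed by ``trials_per_run``
    trials separated by the rating gap.  ``excerpt_order`` overrides the
    run-1 excerpt sequence (used for counterbalancing across subjects); in
    ``exp2`` the run-2 order is a non-identity permutation of run 1's,
    drawn from ``rng`` when given and a cyclic shift otherwise.
    """
    design.validate()
    n_exc = design.resolved_n_excerpts
    if excerpt_order is None:
        base_order = list(range(n_exc))
    else:
        base_order = list(int(e) for e in excerpt_order)
        if sorted(base_order) != list(range(n_exc)):
            raise ConfigurationError(
                "excerpt_order: must be a permutation of range(n_excerpts)"
            )

    per_run_orders: list[list[int]] = []
    if design.experiment == "exp1":
        for r in range(design.n_runs):
            lo = r * design.trials_per_run
            per_run_orders.append(base_order[lo : lo + design.trials_per_run])
    else:  # exp2: run 2 repeats run 1 in a different order
        run1 = base_order
        run2 = _nonidentity_permutation(run1, rng)
        per_run_orders = [run1, run2]

    intervals: list[Interval] = []
    t = 0.0
    trial_counter = 0
    for r in range(1, design.n_runs + 1):
        intervals.append(
            Interval("baseline", t, t + design.baseline_duration, run=r)
        )
        t += design.baseline_duration
        for i, excerpt in enumerate(per_run_orders[r - 1]):
            exposure = (r if design.experiment == "exp2" else 1)
            intervals.append(
                Interval(
                    "trial",
                    t,
                    t + design.trial_duration,
                    run=r,
                    trial_index=trial_counter,
                    excerpt_id=excerpt,
                    exposure=exposure,
                )
            )
            trial_counter += 1
            t += design.trial_duration
            if i < design.trials_per_run - 1:
                t += design.inter_trial_gap
    return SessionLayout(tuple(intervals))


def _nonidentity_permutation(
    items: Sequence[int], rng: np.random.Generator | None
) -> list[int]:
    items = list(items)
    if len(items) < 2:
        return items
    if rng is None:
        return items[1:] + items[:1]
    while True:
        perm = [int(v) for v in rng.permutation(items)]
        if perm != items:
            return perm


def scr_kernel_peak_time(rise: float, decay: float) -> float:
    """Time of the bi-exponential kernel's single interior maximum."""
    return decay * rise / (decay - rise) * math.log(decay / rise)


def scr_kernel(t: np.ndarray | float, rise: float, decay: float) -> np.ndarray:
    """Unit-peak bi-exponential SCR shape exp(-t/decay) - exp(-t/rise).

    Zero at onset, peaks at 1, decays to zero; zero for t < 0.
    """
    if not (decay > rise > 0):
        raise ConfigurationError("kernel: need decay > rise > 0")
    t = np.asarray(t, dtype=float)
    t_peak = scr_kernel_peak_time(rise, decay)
    peak = math.exp(-t_peak / decay) - math.exp(-t_peak / rise)
    out = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay) - np.exp(-np.maximum(t, 0) / rise), 0.0)
    return out / peak


def _tonic_component(
    config: SimConfig,
    layout: SessionLayout,
    times: np.ndarray,
    ratings: pd.DataFrame | None,
) -> np.ndarray:
    tonic = np.full(times.shape, config.tonic_level)
    slopes = config.drift_slope_per_run
    for k, run in enumerate(layout.runs):
        slope = slopes[min(k, len(slopes) - 1)]
        r0, r1 = layout.run_span(run)
        mask = (times >= r0) & (times < r1)
        tonic[mask] += slope * (times[mask] - r0) / 60.0
    pleasure_by_trial: dict[int, float] = {}
    if ratings is not None and config.pleasure_scl_slope != 0.0:
        pleasure_by_trial = dict(
            zip(ratings["trial"].astype(int), ratings["pleasure"].astype(float))
        )
    for iv in layout.trials():
        shift = 0.0
        if iv.exposure == 2:
            shift += config.exposure_scl_delta
        if pleasure_by_trial and iv.trial_index in pleasure_by_trial:
            shift += config.pleasure_scl_slope * pleasure_by_trial[iv.trial_index]
        if shift:
            i0 = np.searchsorted(times, iv.start, side="left")
            i1 = np.searchsorted(times, iv.end, side="left")
            tonic[i0:i1] += shift
    return tonic


def simulate_trace(
    config: SimConfig,
    layout: SessionLayout,
    rng: np.random.Generator | None = None,
    ratings: pd.DataFrame | None = None,
) -> tuple[RawTrace, GroundTruth]:
    """Render the conductance trace for a laid-out session.

    trace = tonic level + per-run drift (+ exposure / pleasure-coupled tonic
    shifts during trials) + sum of SCR kernels + white noise.  SCR events
    arrive as a homogeneous Poisson process at ``scr_rate_base`` within
    trials (plus ``exposure_rate_delta`` on exposure-2 trials) and at half
    the base rate during baselines, with truncated-normal amplitudes.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t0, t1 = layout.span
    span = t1 - t0
    if span > config.max_duration_s:
        raise ResourceError(
            f"session span {span:.0f}s exceeds max_duration_s={config.max_duration_s:.0f}s"
        )
    fs = config.sampling_rate
    n = int(round(span * fs))
    times = t0 + np.arange(n) / fs

    tonic = _tonic_component(config, layout, times, ratings)

    event_times: list[float] = []
    event_amps: list[float] = []
    trial_rows: list[dict] = []
    for iv in layout.intervals:
        if iv.label == "trial":
            rate = config.scr_rate_base
            if iv.exposure == 2:
                rate += config.exposure_rate_delta
        else:
            rate = config.scr_rate_base / 2.0
        rate = max(rate, 0.0)
        n_ev = rng.poisson(rate * iv.duration / 60.0)
        ts = np.sort(rng.uniform(iv.start, iv.end, size=n_ev))
        amps = _truncated_normal(
            rng, config.scr_amplitude_mean, config.scr_amplitude_sd, n_ev
        )
        event_times.extend(ts.tolist())
        event_amps.extend(amps.tolist())
        if iv.label == "trial":
            i0 = np.searchsorted(times, iv.start, side="left")
            i1 = np.searchsorted(times, iv.end, side="left")
            trial_rows.append(
                {
                    "run": iv.run,
                    "trial": iv.trial_index,
                    "excerpt": iv.excerpt_id,
                    "exposure": iv.exposure,
                    "tonic_mean": float(np.mean(tonic[i0:i1])) if i1 > i0 else np.nan,
                    "n_events": int(n_ev),
                }
            )

    signal = tonic + _render_events(
        times, np.asarray(event_times), np.asarray(event_amps), config
    )
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=n)

    gt = GroundTruth(
        event_times=np.asarray(event_times),
        event_amplitudes=np.asarray(event_amps),
        trials=pd.DataFrame(
            trial_rows,
            columns=["run", "trial", "excerpt", "exposure", "tonic_mean", "n_events"],
        ),
    )
    return RawTrace(signal, fs, start_time=t0), gt


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Positive-truncated normal draws by rejection (fast for mean >> sd)."""
    if size == 0:
        return np.empty(0)
    out = rng.normal(mean, sd, size=size)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def _render_events(
    times: np.ndarray,
    event_times: np.ndarray,
    event_amps: np.ndarray,
    config: SimConfig,
) -> np.ndarray:
    phasic = np.zeros(times.shape)
    if event_times.size == 0:
        return phasic
    fs = config.sampling_rate
    # Kernel support: ~10 decay constants bounds the truncation error at <5e-5.
    support = 10.0 * config.kernel_decay
    n_k = int(round(support * fs))
    for t_ev, amp in zip(event_times, event_amps):
        i0 = int(np.searchsorted(times, t_ev, side="left"))
        i1 = min(i0 + n_k, times.size)
        if i0 >= times.size:
            continue
        tt = times[i0:i1] - t_ev
        phasic[i0:i1] += amp * scr_kernel(tt, config.kernel_rise, config.kernel_decay)
    return phasic


def simulate_ratings(
    config: SimConfig,
    layout: SessionLayout,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-trial integer ratings.

    Familiarity: exposure-1 trials of the repetition design are novel music
    (familiarity 0); exposure-2 trials are recognized with probability
    ``recognition_prob`` and then rated 1-5; single-exposure sessions draw
    the familiarity bin from ``familiarity_probs`` (0 / 1-5 / 6-10).
    Pleasure and arousal are Gaussian around a linear predictor in the
    familiarity bin, rounded then clipped to their scales (clipping last).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for iv in layout.trials():
        if iv.exposure == 2:
            if rng.random() < config.recognition_prob:
                fam = int(rng.integers(1, 6))
            else:
                fam = 0
        elif iv.exposure == 1 and any(t.exposure == 2 for t in layout.trials()):
            fam = 0  # first hearing of novel music in the repetition design
        else:
            b = int(rng.choice(3, p=config.familiarity_probs))
            if b == 0:
                fam = 0
            elif b == 1:
                fam = int(rng.integers(1, 6))
            else:
                fam = int(rng.integers(6, 11))
        fam_bin = 0 if fam == 0 else (1 if fam <= 5 else 2)
        pleasure = (
            config.base_pleasure
            + config.familiarity_pleasure_slope * fam_bin
            + rng.normal(0.0, config.rating_noise_sd)
        )
        arousal = (
            config.base_arousal
            + config.familiarity_arousal_slope * fam_bin
            + rng.normal(0.0, config.rating_noise_sd)
        )
        rows.append(
            {
                "run": iv.run,
                "trial": iv.trial_index,
                "excerpt": iv.excerpt_id,
                "exposure": iv.exposure,
                "pleasure": int(np.clip(round(pleasure), -5, 5)),
                "arousal": int(np.clip(round(arousal), 0, 10)),
                "familiarity": fam,
            }
        )
    return pd.DataFrame(
        rows, columns=["run", "trial", "excerpt", "exposure", "pleasure", "arousal", "familiarity"]
    )


def simulate_subject(
    config: SimConfig,
    design: DesignSpec,
    subject: int = 0,
    seed: int | None = None,
    excerpt_order: Sequence[int] | None = None,
) -> SubjectDataset:
    """Simulate one subject's full session (layout, ratings, trace)."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed % _MAX_SEED)
    layout = build_layout(design, rng=rng, excerpt_order=excerpt_order)
    ratings = simulate_ratings(config, layout, rng=rng)
    trace, gt = simulate_trace(config, layout, rng=rng, ratings=ratings)
    ratings = ratings.copy()
    ratings.insert(0, "subject", subject)
    return SubjectDataset(subject, layout, trace, ratings, gt)


def simulate_experiment(
    config: SimConfig, design: DesignSpec, n_subjects: int
) -> list[SubjectDataset]:
    """Simulate independent subjects with counterbalanced excerpt order.

    Subject ``s`` gets seed ``config.seed + s`` and the excerpt sequence
    cyclically rotated by ``s`` positions (a Latin-square style
    counterbalancing of presentation order).
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects: must be >= 1")
    design.validate()
    n_exc = design.resolved_n_excerpts
    datasets = []
    for s in range(n_subjects):
        rot = s % n_exc
        order = list(range(rot, n_exc)) + list(range(rot))
        datasets.append(
            simulate_subject(
                config,
                design,
                subject=s,
                seed=(config.seed + s) % _MAX_SEED,
                excerpt_order=order,
            )
        )
    return datasets
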