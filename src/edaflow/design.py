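"""Trial-exclusion rules, factor definitions, and per-subject cell means.

Each sub-analysis keeps a different trial subset:

* 1A - non-negative pleasure AND familiarity exactly 0 (novel music only);
* 1B - non-negative pleasure (familiar excerpts retained);
* 2  - non-negative pleasure AND familiarity at most 5.

Factors are within-subject: Pleasure (levels 0-5 after exclusion),
Arousal (0-10), Run (1-2), Exposure (1-2) and the three-level Familiarity
binning (0 / 1-5 / 6-10).  :func:`build_cells` aggregates trial features
into a subject x level matrix of means; empty cells are tracked (NaN with
a zero count), never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RangeViolationError

__all__ = [
    "FactorSpec",
    "CellMeans",
    "FAMILIARITY_LEVELS",
    "subject_inclusion",
    "exclude_trials",
    "bin_familiarity",
    "pleasure_factor",
    "arousal_factor",
    "run_factor",
    "exposure_factor",
    "familiarity_factor",
    "build_cells",
    "group_by_run_familiarity",
]

FAMILIARITY_LEVELS = ("Unfamiliar", "Somewhat Familiar", "Very Familiar")


@dataclass(frozen=True)
class FactorSpec:
    """A within-subject factor: ordered levels plus a trial-to-level map."""

    name: str
    levels: tuple
    assign: Callable[[pd.Series], object]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ConfigurationError("levels: factor needs at least one level")


def pleasure_factor() -> FactorSpec:
    # Six levels "neutral".."loved it": negative trials are excluded upstream.
    return FactorSpec("Pleasure", tuple(range(6)), lambda row: int(row["pleasure"]))


def arousal_factor() -> FactorSpec:
    return FactorSpec("Arousal", tuple(range(11)), lambda row: int(row["arousal"]))


def run_factor() -> FactorSpec:
    return FactorSpec("Run", (1, 2), lambda row: int(row["run"]))


def exposure_factor() -> FactorSpec:
    return FactorSpec("Exposure", (1, 2), lambda row: int(row["exposure"]))


def familiarity_factor() -> FactorSpec:
    return FactorSpec(
        "Familiarity",
        FAMILIARITY_LEVELS,
        lambda row: bin_familiarity(int(row["familiarity"])),
    )


def bin_familiarity(rating: int) -> str:
    """Map a 0-10 familiarity rating to its three-level label."""
    if not 0 <= rating <= 10:
        raise RangeViolationError(f"familiarity={rating} out of range [0, 10]")
    if rating == 0:
        return FAMILIARITY_LEVELS[0]
    if rating <= 5:
        return FAMILIARITY_LEVELS[1]
    return FAMILIARITY_LEVELS[2]


def subject_inclusion(ratings: pd.DataFrame) -> bool:
    """True iff every pleasure level 0..5 has at least 5 trials.

    The variance criterion for admitting a subject to the Experiment-1
    analyses; an empty table fails it.
    """
    if len(ratings) == 0:
        return False
    counts = ratings["pleasure"].value_counts()
    return all(counts.get(level, 0) >= 5 for level in range(6))


_RULES = {
    "1a": lambda df: (df["pleasure"] >= 0) & (df["familiarity"] == 0),
    "1b": lambda df: df["pleasure"] >= 0,
    "2": lambda df: (df["pleasure"] >= 0) & (df["familiarity"] <= 5),
}


def exclude_trials(trials: pd.DataFrame, experiment: str) -> pd.DataFrame:
    """Apply the per-analysis trial-exclusion rule; returns the kept rows.

    The rules are idempotent pure row filters, so applying one twice or
    composing it with itself changes nothing.
    """
    key = str(experiment).lower()
    if key not in _RULES:
        raise ConfigurationError(
            f"experiment: unknown tag {experiment!r}; expected one of "
            f"{sorted(_RULES)}"
        )
    return trials.loc[_RULES[key](trials)].copy()


@dataclass(frozen=True)
class CellMeans:
    """Subject x factor-level means of one dependent, with trial counts."""

    dependent: str
    factor: str
    means: pd.DataFrame   # index: subject, columns: levels, NaN = missing cell
    counts: pd.DataFrame  # same shape, per-cell trial counts

    @property
    def levels(self) -> list:
        return list(self.means.columns)

    def complete(self) -> pd.DataFrame:
        """Rows (subjects) with every cell occupied - the listwise set."""
        return self.means.dropna(axis=0, how="any")

    def missing_cells(self) -> list[tuple]:
        out = []
        for subject, row in self.means.iterrows():
            for level in self.means.columns:
                if pd.isna(row[level]):
                    out.append((subject, level))
        return out


def build_cells(
    features: pd.DataFrame, factor: FactorSpec, dependent: str
) -> CellMeans:
    """Mean of ``dependent`` per subject and factor level.

    Cells with no trials are NaN with count 0 and left to the caller's
    listwise handling; nothing is imputed.
    """
    if dependent not in features.columns:
        raise ConfigurationError(f"dependent: column {dependent!r} not in features")
    if "subject" not in features.columns:
        features = features.assign(subject=0)
    levels = list(factor.levels)
    subjects = sorted(features["subject"].unique())
    means = pd.DataFrame(np.nan, index=subjects, columns=levels, dtype=float)
    counts = pd.DataFrame(0, index=subjects, columns=levels, dtype=int)
    assigned = features.apply(factor.assign, axis=1)
    for (subject, level), group in features.groupby([features["subject"], assigned]):
        if level not in means.columns:
            raise ConfigurationError(
                f"factor {factor.name}: trial assigned to unknown level {level!r}"
            )
        means.loc[subject, level] = float(group[dependent].mean())
        counts.loc[subject, level] = int(len(group))
    means.index.name = "subject"
    counts.index.name = "subject"
    return CellMeans(dependent, factor.name, means, counts)


def group_by_run_familiarity(
    features: pd.DataFrame, dependent: str
) -> dict[str, CellMeans]:
    """Exposure-1 vs exposure-2 cells split by second-hearing familiarity.

    For the repetition design: each excerpt is labelled by the familiarity
    bin of its own exposure-2 rating (Unfamiliar = still rated 0, Somewhat
    Familiar = rated 1-5); both exposures of the excerpt inherit that
    label.  Returns one Exposure-factor :class:`CellMeans` per label, the
    contrast of recognized vs unrecognized repeats.
    """
    if "exposure" not in features.columns:
        raise ConfigurationError("features: need an 'exposure' column (exp2 data)")
    if "subject" not in features.columns:
        features = features.assign(subject=0)
    second = features.loc[features["exposure"] == 2]
    label_map = {
        (row["subject"], row["excerpt"]): bin_familiarity(int(row["familiarity"]))
        for _, row in second.iterrows()
    }
    labels = features.apply(
        lambda row: label_map.get((row["subject"], row["excerpt"])), axis=1
    )
    out: dict[str, CellMeans] = {}
    for group_label in FAMILIARITY_LEVELS[:2]:
        sub = features.loc[labels == group_label]
        if len(sub) == 0:
            continue
        out[group_label] = build_cells(sub, exposure_factor(), dependent)
    return out
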