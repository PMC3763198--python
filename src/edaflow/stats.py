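"""Within-subject inference: one-way repeated-measures ANOVA with the
Greenhouse-Geisser sphericity correction, Friedman's rank ANOVA, Wilcoxon
signed-rank post-hocs with Bonferroni adjustment and effect size
r = z / sqrt(n), and the Pearson correlation.

All tests are two-sided by default.  Ties are handled with mid-ranks and
the usual variance tie corrections; the rank tests offer exact small-n
p values by enumeration alongside the normal / chi-square approximations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .design import CellMeans
from .errors import ConfigurationError, UndefinedTestError

__all__ = [
    "AnovaResult",
    "FriedmanResult",
    "WilcoxonResult",
    "CorrelationResult",
    "rm_anova",
    "gg_epsilon",
    "friedman",
    "wilcoxon_signed_rank",
    "pearson",
    "bonferroni",
]


@dataclass(frozen=True)
class AnovaResult:
    """One-way repeated-measures ANOVA with both raw and GG-corrected p.

    ``epsilon_gg`` multiplies both degrees of freedom; the corrected p is
    conventionally the primary one when epsilon falls below 0.75, but both
    are always reported.
    """

    F: float
    df_num: int
    df_den: int
    epsilon_gg: float
    p_uncorrected: float
    p_gg: float
    n_subjects: int
    k_levels: int

    @property
    def df_num_gg(self) -> float:
        return self.epsilon_gg * self.df_num

    @property
    def df_den_gg(self) -> float:
        return self.epsilon_gg * self.df_den

    def to_dict(self) -> dict:
        return {
            "test": "rm_anova",
            "F": self.F,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "epsilon_gg": self.epsilon_gg,
            "df_num_gg": self.df_num_gg,
            "df_den_gg": self.df_den_gg,
            "p_uncorrected": self.p_uncorrected,
            "p_gg": self.p_gg,
            "n_subjects": self.n_subjects,
            "k_levels": self.k_levels,
        }


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    df: int
    p: float
    n_subjects: int
    method: str

    def to_dict(self) -> dict:
        return {
            "test": "friedman",
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "n_subjects": self.n_subjects,
            "method": self.method,
        }


@dataclass(frozen=True)
class WilcoxonResult:
    T: float
    z: float
    p: float
    p_bonferroni: float
    r: float
    n_nonzero: int
    method: str

    def to_dict(self) -> dict:
        return {
            "test": "wilcoxon_signed_rank",
            "T": self.T,
            "z": self.z,
            "p": self.p,
            "p_bonferroni": self.p_bonferroni,
            "r": self.r,
            "n_nonzero": self.n_nonzero,
            "method": self.method,
        }


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int

    def to_dict(self) -> dict:
        return {"test": "pearson", "r": self.r, "p": self.p, "n": self.n}


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, CellMeans):
        mat = data.means.to_numpy(dtype=float)
        if np.isnan(mat).any():
            raise UndefinedTestError(
                "cells are incomplete; drop subjects with missing cells "
                "(listwise) before testing"
            )
        return mat
    if isinstance(data, pd.DataFrame):
        data = data.to_numpy(dtype=float)
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ConfigurationError("data: need a subjects x levels matrix")
    if np.isnan(data).any():
        raise UndefinedTestError("data contain missing entries")
    return data


def gg_epsilon(level_covariance: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon-hat from the level covariance matrix.

    With P the centring projector and S the sample covariance of the k
    within-subject level scores,

        eps = tr(PSP)^2 / ((k - 1) * tr((PSP)^2)),

    equal to 1 under compound symmetry and to its floor 1/(k-1) when all
    variance lies in a single contrast.
    """
    S = np.asarray(level_covariance, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1] or S.shape[0] < 2:
        raise ConfigurationError("level_covariance: need a k x k matrix with k >= 2")
    k = S.shape[0]
    P = np.eye(k) - np.ones((k, k)) / k
    D = P @ S @ P
    denom = (k - 1) * float(np.trace(D @ D))
    if denom <= 0 or not np.isfinite(denom):
        # No within-subject variance left: sphericity is vacuous.
        return 1.0
    eps = float(np.trace(D)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova(cells: "CellMeans | pd.DataFrame | np.ndarray") -> AnovaResult:
    """Classical one-way within-subject decomposition with GG correction.

    Rows are subjects, columns the factor levels.  F compares the level
    mean square against the subject-by-level interaction mean square; the
    GG-corrected p re-evaluates F on epsilon-shrunk degrees of freedom.
    """
    y = _as_matrix(cells)
    n, k = y.shape
    if k < 2:
        raise ConfigurationError("rm_anova: need at least 2 levels")
    if n < 2:
        raise ConfigurationError("rm_anova: need at least 2 subjects")
    grand = y.mean()
    col = y.mean(axis=0)
    row = y.mean(axis=1)
    ss_treat = n * float(np.sum((col - grand) ** 2))
    resid = y - row[:, None] - col[None, :] + grand
    ss_err = float(np.sum(resid**2))
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    if ss_treat <= 1e-12 * max(1.0, abs(grand)) ** 2:
        F = 0.0
    elif ss_err == 0.0:
        F = math.inf
    else:
        F = (ss_treat / df1) / (ss_err / df2)
    eps = gg_epsilon(np.cov(y, rowvar=False))
    p_unc = float(sst.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    p_gg = float(sst.f.sf(F, eps * df1, eps * df2)) if np.isfinite(F) else 0.0
    if F == 0.0:
        p_unc = 1.0
        p_gg = 1.0
    return AnovaResult(
        F=float(F),
        df_num=df1,
        df_den=df2,
        epsilon_gg=eps,
        p_uncorrected=p_unc,
        p_gg=p_gg,
        n_subjects=n,
        k_levels=k,
    )


_EXACT_FRIEDMAN_LIMIT = 300_000  # max (k!)^n assignments to enumerate


def friedman(data, method: str = "auto") -> FriedmanResult:
    """Friedman's rank ANOVA with mid-rank ties and tie correction.

    chi2 = (k-1) * sum_j (R_j - n(k+1)/2)^2 / (sum_ij r_ij^2 - n k (k+1)^2 / 4)

    which reduces to the textbook 12/(nk(k+1)) form without ties.  ``method``:
    ``"approx"`` uses the chi-square reference with k-1 df; ``"exact"``
    enumerates the permutation null (all within-row rearrangements);
    ``"auto"`` picks exact when the enumeration is small enough.
    """
    y = _as_matrix(data)
    n, k = y.shape
    if k < 2:
        raise ConfigurationError("friedman: need at least 2 levels")
    ranks = np.apply_along_axis(sst.rankdata, 1, y)
    denom = float(np.sum(ranks**2)) - n * k * (k + 1) ** 2 / 4.0
    if denom <= 0:
        # Every row fully tied: no rank information at all.
        return FriedmanResult(0.0, k - 1, 1.0, n, "degenerate")
    col_sums = ranks.sum(axis=0)
    dev2 = float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2))
    chi2 = (k - 1) * dev2 / denom
    n_assign = math.factorial(k) ** n
    if method == "auto":
        method = "exact" if n_assign <= _EXACT_FRIEDMAN_LIMIT else "approx"
    if method == "approx":
        p = float(sst.chi2.sf(chi2, k - 1))
    elif method == "exact":
        if n_assign > _EXACT_FRIEDMAN_LIMIT:
            raise ConfigurationError(
                f"friedman: exact enumeration of {n_assign} assignments too large"
            )
        # chi2 is monotone in dev2 for fixed data, so enumerate dev2.
        row_perms = [
            sorted(set(itertools.permutations(r))) for r in ranks
        ]
        count = 0
        total = 0
        target = dev2 - 1e-9
        centre = n * (k + 1) / 2.0
        for combo in itertools.product(*row_perms):
            sums = np.sum(combo, axis=0)
            d2 = float(np.sum((sums - centre) ** 2))
            total += 1
            if d2 >= target:
                count += 1
        p = count / total
    else:
        raise ConfigurationError(f"method: unknown {method!r}")
    return FriedmanResult(float(chi2), k - 1, p, n, method)


_EXACT_WILCOXON_LIMIT = 24  # max n for 2^n sign enumeration


def wilcoxon_signed_rank(
    x,
    y,
    m_comparisons: int = 1,
    method: str = "auto",
    alternative: str = "two-sided",
) -> WilcoxonResult:
    """Paired signed-rank test with z, exact-or-approximate p, and r.

    Zero differences are dropped; T is the smaller of the positive- and
    negative-rank sums.  The normal approximation carries the mid-rank tie
    correction and a 0.5 continuity correction; ``r = z / sqrt(n)`` with
    the sign of the median difference.  ``p_bonferroni`` multiplies p by
    ``m_comparisons`` (capped at 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x, y: need equal-length 1-D paired sequences")
    if alternative not in ("two-sided", "greater", "less"):
        raise ConfigurationError(f"alternative: unknown {alternative!r}")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise UndefinedTestError("all paired differences are zero")
    ranks = sst.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    T = min(w_plus, w_minus)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    if sigma2 <= 0:
        raise UndefinedTestError("no rank variance (all |differences| tied at one value)")
    sigma = math.sqrt(sigma2)
    z = (T - mu + 0.5) / sigma if T < mu else (T - mu) / sigma

    if method == "auto":
        method = "exact" if n <= 15 else "approx"
    if method == "exact":
        if n > _EXACT_WILCOXON_LIMIT:
            raise ConfigurationError(f"wilcoxon: exact enumeration for n={n} too large")
        p = _wilcoxon_exact_p(ranks, w_plus, alternative)
    elif method == "approx":
        p_low = float(sst.norm.cdf(z))
        if alternative == "two-sided":
            p = min(1.0, 2.0 * p_low)
        else:
            # One-sided: tail of the matching rank sum.
            w = w_minus if alternative == "greater" else w_plus
            zz = (w - mu + 0.5) / sigma
            p = float(sst.norm.cdf(zz))
    else:
        raise ConfigurationError(f"method: unknown {method!r}")

    direction = float(np.sign(np.median(d)))
    if direction == 0:
        direction = float(np.sign(w_plus - w_minus)) or 1.0
    r = direction * abs(z) / math.sqrt(n)
    if m_comparisons < 1:
        raise ConfigurationError("m_comparisons: must be >= 1")
    return WilcoxonResult(
        T=T,
        z=float(z),
        p=float(p),
        p_bonferroni=min(1.0, m_comparisons * float(p)),
        r=float(r),
        n_nonzero=n,
        method=method,
    )


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float, alternative: str) -> float:
    """Exact null distribution of W+ by enumerating all sign assignments."""
    n = ranks.size
    w_values = np.zeros(2**n)
    for i, signs in enumerate(itertools.product((0.0, 1.0), repeat=n)):
        w_values[i] = float(np.dot(signs, ranks))
    eps = 1e-9
    p_ge = float(np.mean(w_values >= w_plus - eps))
    p_le = float(np.mean(w_values <= w_plus + eps))
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with the two-sided t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x, y: need equal-length 1-D sequences")
    if x.size < 3:
        raise ConfigurationError("pearson: need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedTestError("pearson: constant input")
    res = sst.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))


def bonferroni(p_list) -> list[float]:
    """Family-wise adjustment: each p becomes min(1, m * p), m = family size."""
    p_list = list(p_list)
    m = len(p_list)
    for p in p_list:
        if not 0 <= p <= 1:
            raise ConfigurationError(f"p value {p} outside [0, 1]")
    return [min(1.0, m * float(p)) for p in p_list]
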