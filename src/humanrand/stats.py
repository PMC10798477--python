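"""Rank-sum comparison and inverse-variance weighted regression.

The rank-sum test (Mann-Whitney U convention, as R's ``wilcox.test``
reports it) checks order effects between counterbalanced task groups.  The
weighted least-squares fit relates a participant-level complexity score to
an ability measure, weighting each participant by the reciprocal of the
variance of their rolling-complexity profile: noisy generators count less.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .complexity import ComplexityProfile
from .errors import DomainError, ValidationError

#: below this profile variance a participant's weight is considered infinite
ZERO_VARIANCE = 1e-12

#: exact enumeration is used up to this combined sample size
EXACT_LIMIT = 16


@dataclass(frozen=True)
class RankSumResult:
    W: float
    p_value: float
    method: Literal["exact", "normal_approx_tie_corrected"]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_CI95: tuple[float, float]
    weighted_R2: float
    F: float
    p_value: float
    n: int
    weights_spec: str = "1/var(rolling complexity) per participant"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of the first sample, with midranks for ties."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2)


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["auto", "exact", "normal"] = "auto",
) -> RankSumResult:
    """Two-sided rank-sum test in the Mann-Whitney U convention.

    ``auto`` enumerates the exact permutation distribution of U (midranks,
    so ties are handled) when the combined sample has at most 16
    observations, and otherwise uses the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    if np.ptp(np.concatenate([x, y])) == 0:
        raise DomainError("all values identical: rank variance is zero")
    u = _u_statistic(x, y)
    if mode == "auto":
        mode = "exact" if n1 + n2 <= EXACT_LIMIT else "normal"
    if mode == "exact":
        ranks = sps.rankdata(np.concatenate([x, y]))
        base = n1 * (n1 + 1) / 2
        center = n1 * n2 / 2
        dev = abs(u - center) - 1e-12  # guard the >= comparison against fp noise
        hits = 0
        total = 0
        for combo in combinations(range(n1 + n2), n1):
            u_perm = ranks[list(combo)].sum() - base
            total += 1
            if abs(u_perm - center) >= dev:
                hits += 1
        return RankSumResult(W=u, p_value=hits / total, method="exact")
    n = n1 + n2
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12 * (n + 1 - tie_term)
    if sigma2 <= 0:
        raise DomainError("degenerate rank variance")
    center = n1 * n2 / 2
    z = (u - center - 0.5 * np.sign(u - center)) / math.sqrt(sigma2)
    p = 2 * sps.norm.sf(abs(z))
    return RankSumResult(
        W=u, p_value=min(1.0, float(p)), method="normal_approx_tie_corrected"
    )


def participant_weight(
    profile: ComplexityProfile, cap: float | None = None
) -> float:
    """Inverse variance of one participant's rolling-complexity profile."""
    if profile.values.size < 2:
        raise DomainError(
            f"profile of {profile.participant_id!r} has fewer than 2 values"
        )
    var = float(np.var(profile.values, ddof=1))
    if var < ZERO_VARIANCE:
        if cap is None:
            raise DomainError(
                f"profile of {profile.participant_id!r} has zero variance and "
                "no weight cap was given"
            )
        return cap
    w = 1.0 / var
    return min(w, cap) if cap is not None else w


def participant_weights(profiles: Sequence[ComplexityProfile]) -> np.ndarray:
    """Cohort inverse-variance weights, with zero-variance profiles capped.

    The cap is 10 times the 99th percentile of the finite weights, so a
    constant-output participant dominates nothing.
    """
    finite = [
        1.0 / v
        for p in profiles
        if (v := float(np.var(p.values, ddof=1))) >= ZERO_VARIANCE
    ]
    if not finite:
        raise DomainError("every profile has zero variance")
    cap = 10.0 * float(np.percentile(finite, 99))
    return np.array([participant_weight(p, cap=cap) for p in profiles])


def wls_fit(
    y: Sequence[float],
    x: Sequence[float],
    weights: Sequence[float],
    weights_spec: str = "1/var(rolling complexity) per participant",
) -> RegressionResult:
    """Weighted least-squares line of ``y`` on ``x`` (closed form).

    The slope CI comes from the t distribution with ``n - 2`` degrees of
    freedom; the weighted R-squared compares weighted residual and total
    sums of squares around the weighted mean; F tests the slope.  Results
    are invariant to rescaling all weights by a constant.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (len(y) == len(x) == len(w)):
        raise ValidationError("y, x and weights must have equal length")
    if len(y) < 3:
        raise DomainError("need at least 3 points")
    if (w <= 0).any():
        raise ValidationError("weights must be positive")
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    if sxx <= 0:
        raise DomainError("predictor has zero weighted variance")
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    n = len(y)
    sse = (w * resid**2).sum()
    sst = (w * (y - ybar) ** 2).sum()
    r2 = 0.0 if sst <= 0 else max(0.0, 1.0 - sse / sst)
    df = n - 2
    s2 = sse / df
    se_slope = math.sqrt(s2 / sxx)
    if se_slope > 0:
        t_stat = slope / se_slope
        p = 2 * sps.t.sf(abs(t_stat), df)
        f_stat = t_stat**2
    else:
        t_stat, p, f_stat = math.inf, 0.0, math.inf
    tcrit = sps.t.ppf(0.975, df)
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        slope_CI95=(float(slope - tcrit * se_slope), float(slope + tcrit * se_slope)),
        weighted_R2=float(r2),
        F=float(f_stat),
        p_value=float(p),
        n=n,
        weights_spec=weights_spec,
    )
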