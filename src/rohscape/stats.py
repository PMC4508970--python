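"""Enrichment statistics: interaction regressions, worked count predictions,
correlation and group-comparison tests.

The central model stacks two response groups (e.g. the deleterious and
non-deleterious proportions f of alternate homozygotes falling inside ROH)
against genome ROH coverage G with a group indicator D:

    f = beta0 + beta1 * G + beta2 * D + beta3 * G * D + error

A two-tailed t-test on beta2 tests for an intercept difference between the
two per-group regressions and on beta3 for a slope difference. The same
model compares ROH size classes pairwise, with D = 1 for the larger class
of the pairing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class RegressionFit:
    """OLS fit of the stacked interaction model."""

    beta: np.ndarray  # (4,) beta0..beta3
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray  # two-tailed
    n: int
    n_dropped: int
    pearson_r0: float  # r of (G, f) within the D=0 group
    pearson_r1: float  # within the D=1 group

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """(4, 2) t-based confidence bounds."""
        q = sps.t.ppf(1 - alpha / 2, self.n - 4)
        return np.column_stack([self.beta - q * self.se, self.beta + q * self.se])

    def to_frame(self, model: str = "interaction") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": model,
                "coefficient": ["beta0", "beta1", "beta2", "beta3"],
                "estimate": self.beta,
                "se": self.se,
                "t": self.t,
                "p": self.p,
                "n": self.n,
            }
        )


def fit_interaction_model(f0, g0, f1, g1) -> RegressionFit:
    """Fit the stacked model; group 0 is the reference (D = 0).

    Pairs with a missing response or covariate are dropped (count reported
    in ``n_dropped``). Raises on a rank-deficient design (e.g. constant G).
    """
    f0 = np.asarray(f0, dtype=float)
    g0 = np.asarray(g0, dtype=float)
    f1 = np.asarray(f1, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    if f0.shape != g0.shape or f1.shape != g1.shape:
        raise ValueError("response/covariate length mismatch")
    k0 = np.isfinite(f0) & np.isfinite(g0)
    k1 = np.isfinite(f1) & np.isfinite(g1)
    n_dropped = int((~k0).sum() + (~k1).sum())
    f0, g0, f1, g1 = f0[k0], g0[k0], f1[k1], g1[k1]
    if len(f0) < 5 or len(f1) < 5:
        raise ValueError("need >= 5 observations per group")
    y = np.concatenate([f0, f1])
    g = np.concatenate([g0, g1])
    d = np.concatenate([np.zeros(len(f0)), np.ones(len(f1))])
    X = np.column_stack([np.ones_like(g), g, d, g * d])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("rank-deficient design (constant coverage within a group?)")
    res = sm.OLS(y, X).fit()
    r0, _ = pearson_with_test(g0, f0)
    r1, _ = pearson_with_test(g1, f1)
    return RegressionFit(
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        t=np.asarray(res.tvalues),
        p=np.asarray(res.pvalues),
        n=int(res.nobs),
        n_dropped=n_dropped,
        pearson_r0=r0,
        pearson_r1=r1,
    )


#: size ordering used to pick the indicator group in pairwise fits
_SIZE_RANK = {"S": 0, "M": 1, "L": 2}


def pairwise_sizeclass_model(f_by_class: dict[str, np.ndarray], g_by_class: dict[str, np.ndarray]) -> dict[tuple[str, str], RegressionFit]:
    """Fit the interaction model for every pairing of ROH size classes.

    Keys are (larger, smaller); D = 1 marks the larger class.
    """
    classes = sorted(f_by_class, key=lambda c: _SIZE_RANK[c])
    out: dict[tuple[str, str], RegressionFit] = {}
    for small, large in combinations(classes, 2):
        out[(large, small)] = fit_interaction_model(
            f_by_class[small], g_by_class[small], f_by_class[large], g_by_class[large]
        )
    return out


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class CountPrediction:
    change_in: int
    change_out: int
    net: int
    baseline: int


def predict_counts(
    slope_in: float,
    intercept_in: float,
    slope_out: float,
    intercept_out: float,
    delta_g: float,
    net_from_rounded: bool = False,
) -> CountPrediction:
    """Worked predictions from the two fitted lines of homozygote counts
    inside and outside ROH versus genome ROH coverage G.

    For a coverage increase ``delta_g``: expected change of the inside-ROH
    count, of the outside-ROH count, their net, and the outside-ROH baseline
    at G = 0 (the expected count for a non-inbred individual). Components are
    rounded half-away-from-zero; the net is computed from the unrounded
    components by default.
    """
    change_in = slope_in * delta_g
    change_out = slope_out * delta_g
    if net_from_rounded:
        net = _round_half_away(change_in) + _round_half_away(change_out)
    else:
        net = _round_half_away(change_in + change_out)
    return CountPrediction(
        change_in=_round_half_away(change_in),
        change_out=_round_half_away(change_out),
        net=net,
        baseline=_round_half_away(intercept_out),
    )


def pearson_with_test(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the t-based two-tailed test.

    NaN pairs are dropped; returns (nan, nan) when either side has zero
    variance or fewer than 3 pairs remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    r, p = sps.pearsonr(x, y)
    return (float(r), float(p))


def split_low_high(profiles: pd.DataFrame, cutoff: float = 0.20) -> pd.DataFrame:
    """Classify individuals by genome ROH coverage: G_R < cutoff -> 'low',
    otherwise 'high' (ties at the cutoff go to 'high')."""
    if not len(profiles):
        raise ValueError("no coverage profiles given")
    out = profiles[["sample", "G_R"]].copy()
    out["group"] = np.where(out["G_R"].to_numpy() < cutoff, "low", "high")
    return out


def breed_ttest(values_a, values_b) -> tuple[float, float]:
    """Welch two-sample two-tailed t-test between groups of individuals."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: no within-group variance
        return (0.0, 1.0) if a.mean() == b.mean() else (float("inf"), 0.0)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return (float(t), float(p))
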