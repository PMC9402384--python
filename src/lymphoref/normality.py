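"""Normality screening and Box-Cox normalization.

The screening criterion is the skewness/kurtosis z-test: a sample is judged
normal iff both |skewness| / SE_skew and |excess kurtosis| / SE_kurt fall
below 1.96 (two-sided 5% per moment). Non-normal analytes are power-
transformed with the Box-Cox family; the fitted transform supplies the
"analysis scale" on which outlier fences, ANOVA and the two-sample z-test
are computed. Reference-interval percentiles themselves are always taken on
the original measurement scale (the transform is strictly monotone, so the
two uses never conflict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

Z_CRIT = 1.96


class InsufficientSampleError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


def skewness_se(n: int) -> float:
    """Large-sample standard error of sample skewness,
    sqrt(6n(n-1) / ((n-2)(n+1)(n+3)))."""
    return float(np.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3))))


def kurtosis_se(n: int) -> float:
    """Standard error of sample excess kurtosis,
    2 * SE_skew * sqrt((n^2-1) / ((n-3)(n+5)))."""
    return float(2.0 * skewness_se(n) * np.sqrt((n * n - 1.0) / ((n - 3) * (n + 5))))


@dataclass(frozen=True)
class NormalityAssessment:
    n: int
    skewness: float
    excess_kurtosis: float
    se_skewness: float
    se_kurtosis: float
    skew_z: float
    kurt_z: float
    is_normal: bool


def assess_normality(values: np.ndarray, z_crit: float = Z_CRIT) -> NormalityAssessment:
    """Skewness/kurtosis normality screen.

    Uses bias-adjusted sample skewness (G1) and excess kurtosis (G2) with
    their exact small-sample standard errors; the sample is normal iff both
    z-ratios are below ``z_crit`` in magnitude.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 8:
        raise InsufficientSampleError(f"need at least 8 values for the skew/kurtosis test, got {n}")
    if np.ptp(v) == 0 or np.var(v) == 0:
        raise DegenerateDataError("zero-variance sample: normality is undefined")
    g1 = float(stats.skew(v, bias=False))
    g2 = float(stats.kurtosis(v, fisher=True, bias=False))
    se_s = skewness_se(n)
    se_k = kurtosis_se(n)
    zs = g1 / se_s
    zk = g2 / se_k
    return NormalityAssessment(
        n=n,
        skewness=g1,
        excess_kurtosis=g2,
        se_skewness=se_s,
        se_kurtosis=se_k,
        skew_z=zs,
        kurt_z=zk,
        is_normal=bool(abs(zs) < z_crit and abs(zk) < z_crit),
    )


@dataclass(frozen=True)
class BoxCoxResult:
    lam: float
    shift: float
    transformed: np.ndarray
    profile_loglik: float

    def apply(self, x: np.ndarray) -> np.ndarray:
        return boxcox_apply(x, self.lam, self.shift)


def boxcox_apply(x: np.ndarray, lam: float, shift: float = 0.0) -> np.ndarray:
    """y = ((x+shift)^λ - 1)/λ, the natural log at λ = 0.

    Implemented as expm1(λ·ln(x+shift))/λ, which is continuous through λ -> 0
    to machine precision.
    """
    x = np.asarray(x, dtype=float)
    z = x + shift
    if np.any(z <= 0):
        raise ValueError("Box-Cox domain error: all values must be positive after shift")
    logz = np.log(z)
    if lam == 0.0:
        return logz
    return np.expm1(lam * logz) / lam


def _profile_loglik(logz: np.ndarray, lam: float) -> float:
    # profile log-likelihood of λ for a normal model on the transformed scale
    n = logz.size
    if lam == 0.0:
        y = logz
    else:
        y = np.expm1(lam * logz) / lam
    var = np.var(y)
    if var <= 0:
        return -np.inf
    return -0.5 * n * np.log(var) + (lam - 1.0) * np.sum(logz)


def _golden_refine(f, lo: float, hi: float, tol: float = 1e-6) -> float:
    """Golden-section maximization of f on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def default_shift(x: np.ndarray) -> float:
    """0 unless min(x) <= 0, then |min| + half the smallest positive value.

    Counts of rare subsets can be exactly 0 in small children; the shift keeps
    the power transform defined without distorting the bulk.
    """
    x = np.asarray(x, dtype=float)
    mn = x.min()
    if mn > 0:
        return 0.0
    pos = x[x > 0]
    if pos.size == 0:
        raise DegenerateDataError("all values non-positive; Box-Cox shift undefined")
    return float(abs(mn) + 0.5 * pos.min())


def boxcox_transform(
    values: np.ndarray,
    lam: float | None = None,
    shift: float | None = None,
    grid: tuple[float, float, float] = (-3.0, 3.0, 0.05),
) -> BoxCoxResult:
    """Box-Cox transform with λ estimated by profile maximum likelihood.

    The search evaluates the profile log-likelihood on a λ grid (default
    [-3, 3] in steps of 0.05, ties broken toward 0) and refines the best grid
    point by golden section. Pass ``lam`` to fix λ instead.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("values must be a non-empty finite array")
    if np.ptp(x) == 0:
        raise DegenerateDataError("flat data cannot be normalized")
    s = default_shift(x) if shift is None else float(shift)
    z = x + s
    if np.any(z <= 0):
        raise ValueError("Box-Cox domain error: all values must be positive after shift")
    logz = np.log(z)

    if lam is None:
        lo, hi, step = grid
        lams = np.arange(lo, hi + step / 2, step)
        lls = np.array([_profile_loglik(logz, l) for l in lams])
        best_ll = lls.max()
        tied = np.flatnonzero(lls >= best_ll - 1e-9)
        best = lams[tied[np.argmin(np.abs(lams[tied]))]]  # tie toward 0
        lam_hat = _golden_refine(
            lambda l: _profile_loglik(logz, l),
            max(lo, best - step),
            min(hi, best + step),
        )
    else:
        lam_hat = float(lam)

    y = boxcox_apply(x, lam_hat, s)
    return BoxCoxResult(lam=lam_hat, shift=s, transformed=y, profile_loglik=_profile_loglik(logz, lam_hat))
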