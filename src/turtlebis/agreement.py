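"""Method-comparison statistics: Bland-Altman, maximum allowed difference,
Passing-Bablok, Lin's concordance, Pearson r, and absolute percentage error.

These are the agreement battery applied to paired adipose-tissue estimates
from the reference method (CT) and the test method (BIS prediction), on the
kg scale and on the percent-of-body-mass scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ArgumentError, ConvergenceError

__all__ = [
    "BlandAltman",
    "PBRegression",
    "AgreementReport",
    "bland_altman",
    "loa_from_summary",
    "max_allowed_difference",
    "agreement_power",
    "passing_bablok",
    "lin_ccc",
    "pearson_r",
    "mape",
    "compare_methods",
]


@dataclass(frozen=True)
class BlandAltman:
    """Bias and limits of agreement for paired differences (test - reference).

    ``loa_lower/upper = bias -/+ multiplier * sd_diff``; confidence intervals
    use the exact t-based variances of Bland & Altman (1999):
    Var(bias) = sd^2/n and Var(limit) = sd^2 * (1/n + multiplier^2/(2(n-1))).
    ``prop_bias_slope`` is the least-squares slope of the differences on the
    pairwise means (None in summary mode).
    """

    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    bias_ci: tuple[float, float]
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    multiplier: float = 1.96
    alpha: float = 0.05
    prop_bias_slope: float | None = None
    prop_bias_slope_ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class PBRegression:
    """Passing-Bablok structural regression estimates with rank-based CIs."""

    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    n_pairs: int


@dataclass
class AgreementReport:
    """The full agreement battery for one method pair."""

    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    max_allowed_diff: float
    prop_bias_slope: float | None
    prop_bias_slope_ci: tuple[float, float] | None
    ccc: float
    pearson_r: float
    mape_median: float
    loa_multiplier: float = 1.96
    power: float = 0.80
    alpha: float = 0.05

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        for key in ("loa_lower_ci", "loa_upper_ci", "prop_bias_slope_ci"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------


def _ba_from_moments(n, bias, sd, multiplier, alpha, slope=None, slope_ci=None):
    tq = stats.t.ppf(1 - alpha / 2, n - 1)
    se_bias = sd / math.sqrt(n)
    se_loa = sd * math.sqrt(1.0 / n + multiplier ** 2 / (2.0 * (n - 1)))
    lo = bias - multiplier * sd
    hi = bias + multiplier * sd
    return BlandAltman(
        n=n, bias=bias, sd_diff=sd, loa_lower=lo, loa_upper=hi,
        bias_ci=(bias - tq * se_bias, bias + tq * se_bias),
        loa_lower_ci=(lo - tq * se_loa, lo + tq * se_loa),
        loa_upper_ci=(hi - tq * se_loa, hi + tq * se_loa),
        multiplier=multiplier, alpha=alpha,
        prop_bias_slope=slope, prop_bias_slope_ci=slope_ci,
    )


def bland_altman(reference, test, multiplier: float = 1.96,
                 alpha: float = 0.05) -> BlandAltman:
    """Bland-Altman analysis of ``test - reference`` differences.

    Proportional bias is the least-squares regression of the differences on
    the pairwise means; a slope CI excluding zero indicates the disagreement
    grows with the measured magnitude.
    """
    reference = np.asarray(reference, float)
    test = np.asarray(test, float)
    if reference.shape != test.shape or reference.ndim != 1:
        raise ArgumentError("reference and test must be equal-length 1-D vectors")
    n = reference.size
    if n < 3:
        raise ArgumentError("need at least 3 pairs")
    diffs = test - reference
    means = (test + reference) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    slope = slope_ci = None
    if np.ptp(means) > 0:
        X = np.column_stack([np.ones(n), means])
        beta, ssr_arr, *_ = np.linalg.lstsq(X, diffs, rcond=None)
        slope = float(beta[1])
        resid = diffs - X @ beta
        dof = n - 2
        if dof > 0:
            sxx = float(((means - means.mean()) ** 2).sum())
            se = math.sqrt(float(resid @ resid) / dof / sxx) if sxx > 0 else 0.0
            tq = stats.t.ppf(1 - alpha / 2, dof)
            slope_ci = (slope - tq * se, slope + tq * se)
    return _ba_from_moments(n, bias, sd, multiplier, alpha, slope, slope_ci)


def loa_from_summary(n: int, bias: float, sd_diff: float,
                     multiplier: float = 1.96, alpha: float = 0.05) -> BlandAltman:
    """Bland-Altman limits from published summary statistics (n, bias, SD)."""
    if n < 3:
        raise ArgumentError("need n >= 3")
    if sd_diff < 0:
        raise ArgumentError("sd_diff must be >= 0")
    return _ba_from_moments(n, bias, sd_diff, multiplier, alpha)


# ---------------------------------------------------------------------------
# Maximum allowed difference (Lu et al. 2016)
# ---------------------------------------------------------------------------


def _nct_sf(x: float, df: int, ncp: float) -> float:
    # scipy's nct loses accuracy / returns NaN at large noncentrality;
    # by then the tail probability is 1 to double precision
    if ncp - x > 12.0:
        return 1.0
    p = stats.nct.sf(x, df, ncp)
    if math.isnan(p):
        return float(stats.norm.sf(x - ncp))
    return float(p)


def agreement_power(delta: float, n: int, bias: float, sd_diff: float,
                    alpha: float = 0.05, multiplier: float = 1.96) -> float:
    """Power of the Bland-Altman agreement test at margin ``delta``.

    The test concludes agreement when both limits of agreement lie inside
    (-delta, delta) with confidence 1 - alpha; its power is approximated by
    two noncentral-t tail probabilities with noncentralities
    (delta -/+ |bias| - multiplier*sd) / (sd * sqrt(1/n + multiplier^2/(2(n-1)))).
    """
    if n < 3:
        raise ArgumentError("need n >= 3")
    if sd_diff <= 0:
        raise ArgumentError("sd_diff must be positive for a power computation")
    df = n - 1
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    se = sd_diff * math.sqrt(1.0 / n + multiplier ** 2 / (2.0 * (n - 1)))
    tau1 = (delta - abs(bias) - multiplier * sd_diff) / se
    tau2 = (delta + abs(bias) - multiplier * sd_diff) / se
    return _nct_sf(tcrit, df, tau1) + _nct_sf(tcrit, df, tau2) - 1.0


def max_allowed_difference(n: int, bias: float, sd_diff: float,
                           power: float = 0.80, alpha: float = 0.05,
                           multiplier: float = 1.96,
                           cap_factor: float = 100.0) -> float:
    """Smallest margin Delta at which the agreement test reaches ``power``.

    Solved by bisection to 1e-6 on the monotone power curve. Differences
    below Delta are considered irrelevant at the given sample size, power and
    alpha. Degenerate ``sd_diff = 0`` returns |bias| (the limits collapse
    onto the bias). Raises :class:`ConvergenceError` when no margin below
    ``cap_factor * sd_diff`` achieves the requested power.
    """
    if n < 3:
        raise ArgumentError("need n >= 3")
    if sd_diff < 0:
        raise ArgumentError("sd_diff must be >= 0")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ArgumentError("power and alpha must lie in (0, 1)")
    if sd_diff == 0:
        return abs(bias)
    lo = abs(bias)
    hi = abs(bias) + cap_factor * sd_diff
    if agreement_power(hi, n, bias, sd_diff, alpha, multiplier) < power:
        raise ConvergenceError(
            f"no margin below {hi:.3g} reaches power {power} at n={n}")
    while hi - lo > 1e-6:
        mid = (lo + hi) / 2.0
        if agreement_power(mid, n, bias, sd_diff, alpha, multiplier) >= power:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2.0


# ---------------------------------------------------------------------------
# Passing-Bablok
# ---------------------------------------------------------------------------


def _pairwise_slopes(x: np.ndarray, y: np.ndarray):
    """All C(n,2) pairwise slopes with the 1983 conventions.

    Slopes equal to -1 are excluded; pairs with dx = 0 contribute +/-inf
    (sign of dy) and dx = dy = 0 pairs are dropped entirely.
    """
    i, j = np.triu_indices(x.size, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    keep = ~((dx == 0) & (dy == 0))
    dx, dy = dx[keep], dy[keep]
    with np.errstate(divide="ignore"):
        s = np.where(dx == 0, np.inf * np.sign(dy), dy / np.where(dx == 0, 1, dx))
    return s[s != -1.0]


def passing_bablok(x, y, alpha: float = 0.05) -> PBRegression:
    """Passing-Bablok regression (1983 procedure, analytic rank CIs).

    The slope is the shifted median of the pairwise slopes: with K the number
    of slopes below -1, the median is offset by K so the estimator is
    invariant to swapping the axes (slope -> 1/slope). The intercept is
    ``median(y - slope*x)``; its CI comes from re-evaluating at the slope CI
    bounds. No jackknife.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ArgumentError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ArgumentError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ArgumentError("all x identical; slope undefined")
    s = np.sort(_pairwise_slopes(x, y))
    N = s.size
    if N == 0:
        raise ArgumentError("all pairwise slopes undefined")
    K = int((s < -1.0).sum())
    if N % 2:
        b = s[(N + 1) // 2 + K - 1]
    else:
        b = 0.5 * (s[N // 2 + K - 1] + s[N // 2 + K])

    w = stats.norm.ppf(1 - alpha / 2) * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((N - w) / 2.0))
    m2 = N - m1 + 1
    lo_idx = max(m1 + K - 1, 0)
    hi_idx = min(m2 + K - 1, N - 1)
    b_lo, b_hi = float(s[lo_idx]), float(s[hi_idx])

    a = float(np.median(y - b * x))
    a_lo = float(np.median(y - b_hi * x))
    a_hi = float(np.median(y - b_lo * x))
    return PBRegression(slope=float(b), slope_ci=(b_lo, b_hi),
                        intercept=a, intercept_ci=(a_lo, a_hi), n_pairs=n)


# ---------------------------------------------------------------------------
# Concordance, correlation, percentage error
# ---------------------------------------------------------------------------


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (sample, n-1 moments).

    ccc = 2*cov(x,y) / (var(x) + var(y) + (mean(x) - mean(y))^2); penalizes
    both dispersion and location departures from the identity line, so
    |ccc| <= |pearson r|.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ArgumentError("x and y must be equal-length 1-D vectors, n >= 2")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    dm = x.mean() - y.mean()
    denom = vx + vy + dm * dm
    if denom == 0:
        raise ArgumentError("ccc undefined: zero variance and equal means")
    cov = ((x - x.mean()) * (y - y.mean())).sum() / (x.size - 1)
    return float(2.0 * cov / denom)


def pearson_r(x, y) -> float:
    """Pearson correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ArgumentError("pearson r undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def mape(reference, predicted, center: str = "median") -> float:
    """Absolute percentage error, summarized by median (default) or mean.

    APE_i = 100 * |pred_i - ref_i| / |ref_i|. The tabulated convention for
    this battery is the median of the APEs; the mean is also exposed.
    """
    reference = np.asarray(reference, float)
    predicted = np.asarray(predicted, float)
    if reference.shape != predicted.shape:
        raise ArgumentError("reference and predicted must have equal shape")
    zeros = np.flatnonzero(reference == 0)
    if zeros.size:
        raise ArgumentError(f"zero reference value at index {int(zeros[0])}")
    ape = 100.0 * np.abs(predicted - reference) / np.abs(reference)
    if center == "median":
        return float(np.median(ape))
    if center == "mean":
        return float(np.mean(ape))
    raise ArgumentError("center must be 'median' or 'mean'")


def compare_methods(reference, test, multiplier: float = 1.96,
                    power: float = 0.80, alpha: float = 0.05) -> AgreementReport:
    """Run the full battery on one pair of paired vectors."""
    ba = bland_altman(reference, test, multiplier=multiplier, alpha=alpha)
    mad = max_allowed_difference(ba.n, ba.bias, ba.sd_diff, power=power,
                                 alpha=alpha, multiplier=multiplier)
    return AgreementReport(
        n=ba.n, bias=ba.bias, sd_diff=ba.sd_diff,
        loa_lower=ba.loa_lower, loa_upper=ba.loa_upper,
        loa_lower_ci=ba.loa_lower_ci, loa_upper_ci=ba.loa_upper_ci,
        max_allowed_diff=mad,
        prop_bias_slope=ba.prop_bias_slope,
        prop_bias_slope_ci=ba.prop_bias_slope_ci,
        ccc=lin_ccc(reference, test),
        pearson_r=pearson_r(reference, test),
        mape_median=mape(reference, test, center="median"),
        loa_multiplier=multiplier, power=power, alpha=alpha,
    )
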