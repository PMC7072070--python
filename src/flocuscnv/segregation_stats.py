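"""Segregation and rate statistics for the gynoecy-loss analyses.

Covers the χ² goodness-of-fit tests on F2 sex-expression ratios (with closed
forms for the one- and two-degree-of-freedom cases), exact binomial mutation
rates with Clopper–Pearson intervals, Welch's t for expression/ethylene
contrasts, and the calibration of the per-meiosis unequal-crossover rate μ to
an observed screen-level mutant frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .locus_model import Genotype
from .transmission import ScreenDesign, UCOParams, expected_screen


# ---------------------------------------------------------------------------
# chi-square goodness of fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GofResult:
    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]
    expected: tuple[float, ...]
    chi2: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        assert self.chi2 >= 0 and 0.0 <= self.p_value <= 1.0
        assert self.df == len(self.observed) - 1


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail chi-square probability.

    Closed forms for the common segregation cases: df=1 is erfc(√(x/2)) and
    df=2 is exp(−x/2); other df fall back to the regularised incomplete gamma.
    """
    if x < 0:
        raise ValueError("chi-square statistic must be >= 0")
    if df == 1:
        return float(special.erfc(math.sqrt(x / 2.0)))
    if df == 2:
        return math.exp(-x / 2.0)
    return float(special.gammaincc(df / 2.0, x / 2.0))


def chisq_gof(observed, expected_ratio) -> GofResult:
    """χ² goodness of fit of observed counts to a segregation ratio.

    The ratio is scale-invariant (1:2:1 and 2:4:2 agree exactly); no
    continuity correction is applied.
    """
    obs = tuple(int(o) for o in observed)
    ratio = tuple(float(r) for r in expected_ratio)
    if len(obs) != len(ratio):
        raise ValueError("observed and ratio lengths differ")
    if any(r <= 0 for r in ratio):
        raise ValueError("expected ratio weights must be positive")
    total = sum(obs)
    if total <= 0:
        raise ValueError("need a positive total count")
    expected = tuple(total * r / sum(ratio) for r in ratio)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(obs, expected))
    df = len(obs) - 1
    return GofResult(obs, ratio, expected, chi2, df, chi2_sf(chi2, df))


# ---------------------------------------------------------------------------
# mutation rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateEstimate:
    successes: int
    trials: int
    rate: float
    percent: float          # exact, in percent
    percent_display: float  # truncated to 2 decimals, the convention used
                            # for the printed gynoecy-loss rates
    ci_low: float           # exact (Clopper–Pearson) 95% CI on the proportion
    ci_high: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.rate <= 1.0
        assert self.ci_low - 1e-12 <= self.rate <= self.ci_high + 1e-12


def mutation_rate(successes: int, trials: int,
                  confidence: float = 0.95) -> RateEstimate:
    """Binomial rate with an exact Clopper–Pearson interval.

    The display percentage truncates at the second decimal (3/2236 → 0.13%,
    3/2573 → 0.11%, 6/4809 → 0.12%), matching how such screen rates are
    conventionally quoted.
    """
    if not 0 <= successes <= trials or trials < 1:
        raise ValueError("need 0 <= successes <= trials, trials >= 1")
    rate = successes / trials
    alpha = 1.0 - confidence
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    hi = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    pct = 100.0 * rate
    disp = math.floor(pct * 100.0 + 1e-9) / 100.0
    return RateEstimate(successes, trials, rate, pct, disp, lo, hi)


# ---------------------------------------------------------------------------
# two-sample comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float
    significant_005: bool
    significant_001: bool


def welch_t(group_a, group_b) -> TTestResult:
    """Two-sided Welch's unequal-variance t-test.

    Degenerate input with zero variance in both groups and equal means is
    reported as p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, float(len(a) + len(b) - 2), 1.0, False, False)
        return TTestResult(math.inf, float(len(a) + len(b) - 2), 0.0, True, True)
    res = stats.ttest_ind(a, b, equal_var=False)
    df = float(getattr(res, "df", _welch_df(a, b)))
    p = float(res.pvalue)
    return TTestResult(float(res.statistic), df, p, p < 0.05, p < 0.01)


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))


# ---------------------------------------------------------------------------
# UCO-rate calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    mu: float
    mu_ci_low: float
    mu_ci_high: float
    expected_rate: float  # expected confirmed-mutant frequency at mu
    design: ScreenDesign


def calibrate_uco_rate(observed: RateEstimate, design: ScreenDesign,
                       founder: Genotype | None = None,
                       base: UCOParams | None = None,
                       mu_max: float = 0.5) -> CalibrationResult:
    """Solve for the per-meiosis UCO rate μ matching an observed screen rate.

    Inverts the exact screen expectation (selfing-generation composition of
    the gamete enumeration, then progeny-test confirmation) by monotone
    bisection; the CI is the image of the observed rate's Clopper–Pearson
    interval under the same inverse map.
    """
    from .locus_model import build_line_structure

    founder = founder or build_line_structure("gynoecious_Gy14_like")

    def forward(mu: float) -> float:
        return expected_screen(founder, mu, design, base)["p_confirmed"]

    def invert(target: float) -> float:
        if target <= 0.0:
            return 0.0
        hi = forward(mu_max)
        if target > hi:
            raise ValueError(
                f"observed rate {target:.4g} exceeds the achievable expectation "
                f"{hi:.4g} at mu <= {mu_max}")
        return float(optimize.brentq(lambda m: forward(m) - target,
                                     0.0, mu_max, xtol=1e-12))

    mu = invert(observed.rate)
    return CalibrationResult(mu, invert(observed.ci_low),
                             invert(observed.ci_high), forward(mu), design)


# ---------------------------------------------------------------------------
# printed segregation data (observed counts used as inputs downstream)
# ---------------------------------------------------------------------------

def table1_segregation() -> list[dict]:
    """The key segregating-population rows: counts and their expected ratios."""
    return [
        {"population": "(Gy14 x 9930) F2", "observed": (47, 98, 55),
         "classes": ("G", "SubG", "M"), "ratio": (1, 2, 1)},
        {"population": "(AM297 x 9930) F2", "observed": (735, 265),
         "classes": ("G", "M"), "ratio": (3, 1)},
    ]
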