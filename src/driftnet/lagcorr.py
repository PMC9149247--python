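"""Lag-scanned Pearson cross-correlation between two city series.

The strength of a potential interaction between pollutant series X1 and X2
is the maximum of the profile

    P(tau) = Corr(X1(t), X2(t - tau)),       tau in [tau_min, tau_max],

scanned hourly over (by default) +/- 168 h — one synoptic week either side.
P_max = max_tau P(tau) measures the strength and T_delay = argmax_tau P(tau)
the temporal order: a *negative* T_delay means X2 lags X1 (best alignment is
obtained by shifting X1 later), i.e. candidate direction X1 -> X2.

Two significance gates follow:

* a two-sided t-test that P_max differs from zero,
  t = r * sqrt(n - 2) / sqrt(1 - r^2)  on  n - 2  degrees of freedom;
* a one-sided Fisher r-to-z comparison that P_max exceeds the zero-lag
  correlation P(0),
  z = (atanh(r_max) - atanh(r_0)) / sqrt(1/(n_max - 3) + 1/(n_0 - 3)).

Correlations use pairwise-complete overlap; the n fed to each test is the
overlap count at the relevant lag.  Note the Fisher test treats the two
coefficients as independent samples even though they share data — this
mirrors common practice and is a documented approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientOverlapError
from .ingest import SiteSeries

#: |r| at or beyond this is saturated before atanh to avoid infinities.
FISHER_R_CAP = 1.0 - 1e-15

#: Reported p-value floor when |r| = 1 makes the t statistic infinite.
P_UNDERFLOW_FLOOR = float(np.finfo(float).tiny)

DEFAULT_MIN_OVERLAP = 30


@dataclass(frozen=True)
class LagGrid:
    """Hourly lag scan range; must straddle zero so P(0) is defined."""

    tau_min: int = -168
    tau_max: int = 168
    step: int = 1

    def __post_init__(self):
        if not (self.tau_min <= 0 <= self.tau_max):
            raise ValueError("lag grid must satisfy tau_min <= 0 <= tau_max")
        if self.step < 1:
            raise ValueError("lag grid step must be >= 1")
        if self.tau_min % self.step or self.tau_max % self.step:
            raise ValueError("grid bounds must be multiples of step so tau=0 is on-grid")

    def taus(self) -> np.ndarray:
        return np.arange(self.tau_min, self.tau_max + 1, self.step, dtype=int)


@dataclass
class SignificanceReport:
    test: str
    statistic: float
    df: float  # degrees of freedom (t) or effective pooled n proxy (z: inf)
    p_value: float
    alpha: float
    significant: bool


@dataclass
class LagCorrelationResult:
    """Full P(tau) profile for one ordered city pair plus both gate tests."""

    city_1: str
    city_2: str
    tau_grid: np.ndarray
    profile: np.ndarray          # P(tau), NaN where undefined
    n_overlap: np.ndarray        # pairwise-complete count per lag
    p_max: float
    t_delay: int
    p_zero: float                # P(0); NaN if undefined at tau=0
    r_test: SignificanceReport = None
    fisher_test: SignificanceReport | None = None
    significant: bool = False
    boundary: bool = False
    alpha: float = 0.05
    config: dict = field(default_factory=dict)

    @property
    def p_r(self) -> float:
        return self.r_test.p_value

    @property
    def p_fisher(self) -> float:
        return float("nan") if self.fisher_test is None else self.fisher_test.p_value

    @property
    def n_max(self) -> int:
        return int(self.n_overlap[np.flatnonzero(self.tau_grid == self.t_delay)[0]])

    @property
    def n_zero(self) -> int:
        return int(self.n_overlap[np.flatnonzero(self.tau_grid == 0)[0]])

    @property
    def candidate_direction(self) -> tuple[str, str] | None:
        """(source, target) implied by the sign of T_delay; None at lag zero."""
        if self.t_delay < 0:
            return (self.city_1, self.city_2)
        if self.t_delay > 0:
            return (self.city_2, self.city_1)
        return None


# ---------------------------------------------------------------------------
# Significance tests
# ---------------------------------------------------------------------------

def test_r_nonzero(r: float, n: int, alpha: float = 0.05) -> SignificanceReport:
    """Two-sided t-test that a Pearson correlation differs from zero."""
    if n < 4:
        raise ValueError("test_r_nonzero requires n >= 4")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    df = n - 2
    if abs(r) == 1.0:
        return SignificanceReport("pearson-t", math.inf, df, P_UNDERFLOW_FLOOR, alpha, True)
    t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df)
    return SignificanceReport("pearson-t", t, df, float(p), alpha, p < alpha)


def fisher_compare(
    r_max: float,
    r_zero: float,
    n_max: int,
    n_zero: int,
    alpha: float = 0.05,
) -> SignificanceReport:
    """One-sided Fisher r-to-z test of r_max > r_zero.

    Correlations with |r| = 1 are saturated at ``FISHER_R_CAP`` (with a
    warning) so the transform stays finite.
    """
    if n_max < 4 or n_zero < 4:
        raise ValueError("fisher_compare requires n >= 4 on both sides")

    def _z(r: float) -> float:
        if abs(r) >= FISHER_R_CAP:
            warnings.warn(
                "correlation saturated at the Fisher transform cap", RuntimeWarning,
                stacklevel=3,
            )
            r = math.copysign(FISHER_R_CAP, r)
        return math.atanh(r)

    se = math.sqrt(1.0 / (n_max - 3) + 1.0 / (n_zero - 3))
    z = (_z(r_max) - _z(r_zero)) / se
    p = float(stats.norm.sf(z))
    return SignificanceReport("fisher-z", z, math.inf, p, alpha, p < alpha)


def significant_pair(result: LagCorrelationResult, alpha: float = 0.05) -> bool:
    """Gate a pair: P_max nonzero AND (lag zero OR P_max > P(0)).

    At T_delay = 0 the Fisher comparison would compare P_max with itself and
    is vacuous; such a pair can be "significant at lag zero" but carries no
    direction and yields no directed edge downstream.
    """
    if not result.r_test.significant or result.r_test.alpha != alpha:
        rt = test_r_nonzero(result.p_max, result.n_max, alpha)
    else:
        rt = result.r_test
    if not rt.significant:
        return False
    if result.t_delay == 0:
        return True
    if result.fisher_test is None or not np.isfinite(result.p_zero):
        return False
    return bool(result.fisher_test.p_value < alpha)


# ---------------------------------------------------------------------------
# The lag scan
# ---------------------------------------------------------------------------

def _align(x1: SiteSeries, x2: SiteSeries) -> tuple[np.ndarray, np.ndarray]:
    """Place both series on one absolute-time hourly grid (union of spans)."""
    e1, e2 = x1.epoch_hours, x2.epoch_hours
    lo = min(e1[0], e2[0])
    hi = max(e1[-1], e2[-1])
    n = int(hi - lo) + 1
    a = np.full(n, np.nan)
    b = np.full(n, np.nan)
    a[e1 - lo] = x1.values
    b[e2 - lo] = x2.values
    return a, b


def _pearson_masked(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson r of two equal-length complete vectors; NaN if degenerate."""
    n = len(u)
    um = u - u.mean()
    vm = v - v.mean()
    su = float(um @ um)
    sv = float(vm @ vm)
    if su <= 0.0 or sv <= 0.0:
        return float("nan")
    r = float(um @ vm) / math.sqrt(su * sv)
    return min(1.0, max(-1.0, r))


def lag_correlation(
    x1: SiteSeries,
    x2: SiteSeries,
    grid: LagGrid = LagGrid(),
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    alpha: float = 0.05,
    use_effective_n: bool = False,
) -> LagCorrelationResult:
    """Scan P(tau) = Corr(X1(t), X2(t - tau)) over the lag grid.

    Each lag uses the pairwise-complete overlap of the two series; lags with
    fewer than ``min_overlap`` complete pairs (or zero variance) are
    undefined.  P_max and T_delay are taken over defined lags only; argmax
    ties resolve to the smallest |tau| and then to the negative lag, the
    weakest (shortest-delay) claim.  A T_delay on the grid edge is flagged
    ``boundary`` — an argmax at the scan limit is not a located peak.

    With ``use_effective_n`` the n fed to both significance tests is the
    Bartlett-type :func:`effective_sample_size` of the two series instead of
    the raw overlap count (stricter under strong autocorrelation; off by
    default to match the plain formulation).
    """
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    a, b = _align(x1, x2)
    n_grid = len(a)
    taus = grid.taus()
    profile = np.full(len(taus), np.nan)
    n_overlap = np.zeros(len(taus), dtype=int)

    for k, tau in enumerate(taus):
        if tau >= 0:
            u, v = a[tau:], b[: n_grid - tau]
        else:
            u, v = a[: n_grid + tau], b[-tau:]
        mask = np.isfinite(u) & np.isfinite(v)
        n = int(mask.sum())
        n_overlap[k] = n
        if n < min_overlap:
            continue
        profile[k] = _pearson_masked(u[mask], v[mask])

    defined = np.isfinite(profile)
    if not defined.any():
        raise InsufficientOverlapError(
            f"no lag in [{grid.tau_min}, {grid.tau_max}] has >= {min_overlap} "
            f"overlapping hours for pair ({x1.city_id}, {x2.city_id})"
        )

    p_max = float(np.nanmax(profile))
    ties = np.flatnonzero(defined & (profile == p_max))
    t_delay = int(min((abs(int(taus[i])), int(taus[i])) for i in ties)[1])
    k_delay = int(np.flatnonzero(taus == t_delay)[0])
    k_zero = int(np.flatnonzero(taus == 0)[0])
    p_zero = float(profile[k_zero]) if defined[k_zero] else float("nan")

    n_delay = int(n_overlap[k_delay])
    n_zero = int(n_overlap[k_zero])
    if use_effective_n:
        n_raw = min(int(np.isfinite(a).sum()), int(np.isfinite(b).sum()))
        shrink = effective_sample_size(a, b) / max(n_raw, 1)
        n_delay = int(round(n_delay * shrink))
        n_zero = int(round(n_zero * shrink))
    r_test = test_r_nonzero(p_max, max(n_delay, 4), alpha)
    fisher = None
    if t_delay != 0 and np.isfinite(p_zero):
        fisher = fisher_compare(
            p_max, p_zero, max(n_delay, 4), max(n_zero, 4), alpha,
        )

    result = LagCorrelationResult(
        city_1=x1.city_id,
        city_2=x2.city_id,
        tau_grid=taus,
        profile=profile,
        n_overlap=n_overlap,
        p_max=p_max,
        t_delay=t_delay,
        p_zero=p_zero,
        r_test=r_test,
        fisher_test=fisher,
        boundary=t_delay in (grid.tau_min, grid.tau_max),
        alpha=alpha,
        config={"tau_min": grid.tau_min, "tau_max": grid.tau_max,
                "step": grid.step, "min_overlap": min_overlap},
    )
    result.significant = significant_pair(result, alpha)
    return result


def effective_sample_size(x: np.ndarray, y: np.ndarray) -> float:
    """Bartlett-type effective n for two autocorrelated complete series.

    n_eff = n * (1 - rho1*rho2) / (1 + rho1*rho2) with lag-1 autocorrelations
    rho1, rho2.  Optional honesty correction for the significance tests; the
    default pipeline uses the raw overlap count.
    """
    def lag1(v: np.ndarray) -> float:
        v = v[np.isfinite(v)]
        if len(v) < 3 or v.std() == 0:
            return 0.0
        return float(np.corrcoef(v[:-1], v[1:])[0, 1])

    n = min(int(np.isfinite(x).sum()), int(np.isfinite(y).sum()))
    r1, r2 = lag1(x), lag1(y)
    prod = r1 * r2
    if prod >= 1.0:
        prod = 1.0 - 1e-12
    return n * (1.0 - prod) / (1.0 + prod)
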