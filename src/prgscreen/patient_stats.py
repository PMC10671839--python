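"""Patient-side statistics: median split, Kaplan-Meier, log-rank,
Pearson correlation and univariate least squares.

These are implemented directly from their defining formulas (the screen's
survival claims rest on them, so the arithmetic is kept transparent and is
cross-checked against independent library implementations in the test
suite).  Conventions: patients exactly at the median expression go to the
low group; at tied times deaths are processed before censorings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SurvivalCurve:
    """Product-limit estimate: S(t) steps down at each distinct death time
    by the factor (1 - d/n)."""

    event_times: np.ndarray  # distinct death times, increasing
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # n at risk just before each event time
    deaths: np.ndarray  # d at each event time

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi_sq: float
    p: float
    observed: tuple[float, float]
    expected: tuple[float, float]
    degenerate: bool = False


def load_survival(path) -> pd.DataFrame:
    """Read a survival TSV with columns patient_id, time_days, event."""
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "time_days", "event"}
    if not required <= set(df.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    return _validate_records(df)


def _validate_records(df: pd.DataFrame) -> pd.DataFrame:
    if (df["time_days"] <= 0).any() or ~np.isfinite(df["time_days"]).all():
        raise ValueError("survival times must be finite and positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (death)")
    return df


def median_split(expression: pd.Series) -> pd.Series:
    """Label patients 'high' when expression strictly exceeds the median,
    otherwise 'low' (median-valued patients go low)."""
    x = expression.astype(float)
    if len(x) < 4:
        raise ValueError("median split needs >= 4 patients")
    med = float(np.median(x))
    if float(x.max()) == float(x.min()):
        raise ValueError("all expression values identical; cannot split")
    labels = np.where(x > med, "high", "low")
    return pd.Series(labels, index=expression.index, name="group")


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    ``times`` are positive follow-up times; ``events`` are 1 for death and 0
    for censoring.  Censored subjects at a death time are still at risk for
    that death (deaths before censorings at ties).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("need >= 1 record")
    _validate_records(pd.DataFrame({"time_days": t, "event": e, "patient_id": 0}))
    death_times = np.unique(t[e == 1])
    n = t.size
    at_risk = np.empty(death_times.size, dtype=int)
    deaths = np.empty(death_times.size, dtype=int)
    surv = np.empty(death_times.size)
    s = 1.0
    for i, dt in enumerate(death_times):
        at_risk[i] = int(np.sum(t >= dt))
        deaths[i] = int(np.sum((t == dt) & (e == 1)))
        s *= 1.0 - deaths[i] / at_risk[i]
        surv[i] = s
    return SurvivalCurve(death_times, surv, at_risk, deaths)


def log_rank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct death time the observed deaths in group A are compared
    with the expectation under the hypergeometric null; the squared summed
    difference over the summed variance is chi-square with 1 df.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    death_times = np.unique(all_t[all_e == 1])
    o_a = e_a = var = 0.0
    obs_a = obs_b = exp_a = exp_b = 0.0
    for dt in death_times:
        n_a = float(np.sum(ta >= dt))
        n_b = float(np.sum(tb >= dt))
        n = n_a + n_b
        d_a = float(np.sum((ta == dt) & (ea == 1)))
        d_b = float(np.sum((tb == dt) & (eb == 1)))
        d = d_a + d_b
        if n < 1 or d == 0:
            continue
        exp_at = d * n_a / n
        obs_a += d_a
        obs_b += d_b
        exp_a += exp_at
        exp_b += d - exp_at
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
        o_a += d_a - exp_at
    if var <= 0:
        return LogRankResult(0.0, 1.0, (obs_a, obs_b), (exp_a, exp_b), True)
    chi_sq = o_a**2 / var
    p = float(stats.chi2.sf(chi_sq, df=1))
    return LogRankResult(float(chi_sq), p, (obs_a, obs_b), (exp_a, exp_b))


def pearson_correlation(x, y):
    """Product-moment correlation with a two-sided p-value from
    t = r sqrt((n-2)/(1-r^2)) on n-2 df.  Returns (r, p, n)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need two equal-length vectors with n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance input")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p, n


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r_sq: float
    p: float
    n: int


def ols_univariate(x, y) -> RegressionResult:
    """Simple least-squares regression y ~ x.

    For one predictor, R^2 is exactly the squared Pearson r and the slope's
    p-value equals the correlation p-value; both identities hold here by
    construction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r, p, n = pearson_correlation(x, y)
    xc = x - x.mean()
    slope = float((xc * (y - y.mean())).sum() / (xc**2).sum())
    intercept = float(y.mean() - slope * x.mean())
    return RegressionResult(slope, intercept, r, r * r, p, n)


def write_curve(curve: SurvivalCurve, path) -> None:
    pd.DataFrame(
        {
            "time": curve.event_times,
            "at_risk": curve.at_risk,
            "deaths": curve.deaths,
            "survival": curve.survival,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")
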