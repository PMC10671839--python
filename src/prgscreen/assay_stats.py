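"""Quantitative analytics for wet-lab readouts.

Covers the plate-based viability workflow (CCK-8 style OD450 readings):
background-corrected percent viability, four-parameter logistic (4PL)
dose-response fits yielding IC50, the resistance index (ratio of resistant
to parental IC50), relative qPCR quantification by 2^-ddCt, and one-way
ANOVA for multi-group comparisons.

The 4PL model for decreasing viability is

    y(x) = bottom + (top - bottom) / (1 + (x / ic50)^hill),   hill > 0,

so y(ic50) is the midpoint of the asymptotes (relative IC50).  Zero-dose
wells anchor the top asymptote: x = 0 is replaced by eps * (smallest
nonzero dose) with eps = 1e-3, far left on the log axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

ZERO_DOSE_EPS = 1e-3


class FitError(RuntimeError):
    """4PL fit failure carrying per-start diagnostics."""


def viability_percent(treated_od, control_od, blank_od: float) -> np.ndarray:
    """Percent viability 100 * (treated - blank) / (mean(control) - blank)."""
    treated = np.asarray(treated_od, dtype=float)
    control = np.asarray(control_od, dtype=float)
    denom = control.mean() - blank_od
    if denom <= 0:
        raise ValueError("mean control OD must exceed the blank OD")
    return 100.0 * (treated - blank_od) / denom


@dataclass
class DoseResponseData:
    """Replicate responses per concentration (nM), ascending doses."""

    concentrations: np.ndarray
    responses: list[np.ndarray]  # one replicate array per concentration

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if (self.concentrations < 0).any():
            raise ValueError("concentrations must be >= 0")
        if len(self.responses) != self.concentrations.size:
            raise ValueError("one replicate block per concentration required")
        order = np.argsort(self.concentrations)
        self.concentrations = self.concentrations[order]
        self.responses = [np.asarray(self.responses[i], float) for i in order]
        if np.unique(self.concentrations).size < 5:
            raise ValueError("need >= 5 distinct concentrations")

    @classmethod
    def read_csv(cls, path) -> "DoseResponseData":
        """CSV with header ``concentration_nM,rep1,rep2,...``."""
        df = pd.read_csv(path)
        if df.columns[0] != "concentration_nM":
            raise ValueError("first column must be concentration_nM")
        conc = df["concentration_nM"].to_numpy(float)
        reps = [row.dropna().to_numpy(float) for _, row in df.iloc[:, 1:].iterrows()]
        return cls(conc, reps)

    def flattened(self) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = [], []
        for c, reps in zip(self.concentrations, self.responses):
            xs.extend([c] * len(reps))
            ys.extend(reps)
        return np.asarray(xs), np.asarray(ys)


@dataclass(frozen=True)
class FourPLFit:
    bottom: float
    top: float
    hill: float
    ic50: float
    rss: float

    def predict(self, x) -> np.ndarray:
        return four_pl(np.asarray(x, float), self.bottom, self.top, self.hill, self.ic50)


def four_pl(x, bottom, top, hill, ic50):
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def fit_4pl(data: DoseResponseData) -> FourPLFit:
    """Least-squares 4PL fit with multi-start over log-spaced IC50 seeds.

    Bounds stabilize the fit: bottom >= 0, top <= 120% of the observed
    maximum, hill in (0.1, 10].  Monotone-increasing responses (no decline)
    are rejected.
    """
    x_raw, y = data.flattened()
    nonzero = x_raw[x_raw > 0]
    if nonzero.size == 0:
        raise FitError("all doses are zero")
    x = np.where(x_raw == 0, ZERO_DOSE_EPS * nonzero.min(), x_raw)

    means = np.array([r.mean() for r in data.responses])
    if means[-1] >= means[0]:
        raise FitError("responses do not decline with dose; 4PL needs a decline")

    y_max = float(y.max())
    lo = np.array([0.0, 0.5 * y_max, 0.1, 1e-6 * nonzero.min()])
    hi = np.array([0.6 * y_max, 1.2 * y_max, 10.0, 1e3 * nonzero.max()])

    def residuals(theta):
        return four_pl(x, *theta) - y

    starts = np.geomspace(nonzero.min(), nonzero.max(), 7)
    best = None
    diagnostics = []
    for ic50_0 in starts:
        theta0 = np.array(
            [max(means.min(), 0.0), min(means.max(), 1.2 * y_max), 1.0, ic50_0]
        )
        theta0 = np.clip(theta0, lo + 1e-9, hi - 1e-9)
        try:
            sol = optimize.least_squares(
                residuals, theta0, bounds=(lo, hi), method="trf"
            )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            diagnostics.append(f"start ic50={ic50_0:.3g}: {exc}")
            continue
        rss = float(np.sum(sol.fun**2))
        if sol.success and (best is None or rss < best[0]):
            best = (rss, sol.x)
        if not sol.success:
            diagnostics.append(f"start ic50={ic50_0:.3g}: {sol.message}")
    if best is None:
        raise FitError("4PL fit failed from all starts: " + "; ".join(diagnostics))
    rss, (bottom, top, hill, ic50) = best
    if top <= bottom:
        raise FitError("degenerate fit: top <= bottom")
    return FourPLFit(float(bottom), float(top), float(hill), float(ic50), rss)


@dataclass(frozen=True)
class ResistanceIndex:
    ri: float
    ic50_resistant: float
    ic50_sensitive: float


def resistance_index(fit_resistant, fit_sensitive) -> ResistanceIndex:
    """RI = IC50(resistant) / IC50(sensitive); accepts fits or raw IC50s."""
    ic_r = fit_resistant.ic50 if hasattr(fit_resistant, "ic50") else float(fit_resistant)
    ic_s = fit_sensitive.ic50 if hasattr(fit_sensitive, "ic50") else float(fit_sensitive)
    if ic_r <= 0 or ic_s <= 0:
        raise ValueError("IC50 values must be positive")
    return ResistanceIndex(ic_r / ic_s, ic_r, ic_s)


def ddct_fold_change(
    ct_gene_treat: float,
    ct_ref_treat: float,
    ct_gene_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by 2^-ddCt: the target gene's Ct is normalized to
    the reference gene within each condition, then treated vs control."""
    cts = (ct_gene_treat, ct_ref_treat, ct_gene_ctrl, ct_ref_ctrl)
    for ct in cts:
        if not (0.0 < ct < 45.0):
            raise ValueError(f"Ct value {ct} outside the plausible (0, 45) range")
    ddct = (ct_gene_treat - ct_ref_treat) - (ct_gene_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def one_way_anova(groups):
    """One-way ANOVA across >= 3 groups; returns (F, df1, df2, p).

    All-identical constant groups are degenerate (no within- or between-
    variance): F = 0, p = 1 with a warning.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ValueError("one-way ANOVA here requires >= 3 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs >= 2 values")
    df1 = len(arrays) - 1
    df2 = sum(a.size for a in arrays) - len(arrays)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:
        warnings.warn("all values identical: ANOVA is degenerate (F=0, p=1)")
        return 0.0, df1, df2, 1.0
    f, p = stats.f_oneway(*arrays)
    return float(f), df1, df2, float(p)
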