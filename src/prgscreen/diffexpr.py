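"""Two-group differential expression with empirical-Bayes variance shrinkage.

Each sensitive/resistant cohort is analysed separately with a moderated
t-statistic: the gene-wise pooled variance s_g^2 is shrunk toward a prior
(d0, s0^2) estimated across genes by moment-matching on log s^2, and the
resulting t is referred to a t distribution with d0 + d_g degrees of
freedom.  The cross-cohort confirmation step (one value per cohort, paired
by cohort) uses an ordinary paired t-test.

Model: s_g^2 | sigma_g^2 ~ sigma_g^2 * chi2_{d_g} / d_g with a scaled
inverse-chi-square prior sigma_g^2 ~ s0^2 d0 / chi2_{d0}.  Then

    E[log s^2]   = log s0^2 + psi(d_g/2) - log(d_g/2) - psi(d0/2) + log(d0/2)
    Var[log s^2] = psi'(d_g/2) + psi'(d0/2)

which the prior fit inverts (psi = digamma, psi' = trigamma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .expression_core import CohortPair, ExpressionMatrix

DE_COLUMNS = ["gene", "cohort", "log2fc", "t", "df", "p"]


@dataclass(frozen=True)
class VariancePrior:
    """Prior degrees of freedom and location for the gene-variance prior.

    ``d0`` may be ``inf`` (all genes share the variance ``s0_sq``) or 0
    (no shrinkage: the moderated t degrades to the ordinary pooled t).
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be non-negative (possibly inf)")
        if not np.isfinite(self.s0_sq) or self.s0_sq < 0:
            raise ValueError("s0_sq must be finite and non-negative")


@dataclass
class PooledStats:
    """Per-gene two-group summaries for one cohort.

    ``s_sq`` is NaN when both arms are singletons (d_g = 0); such genes fall
    back to the full-shrinkage variance in :func:`moderated_t_table`.
    """

    genes: list[str]
    log2fc: np.ndarray
    s_sq: np.ndarray
    d_g: float
    v_g: float
    n_resistant: int
    n_sensitive: int


def gene_pooled_stats(matrix: ExpressionMatrix, pair: CohortPair) -> PooledStats:
    """log2 fold change (resistant - sensitive), pooled within-group variance,
    residual df d_g = n1+n2-2 and scale v_g = 1/n1 + 1/n2, per gene."""
    res = matrix.data[list(pair.resistant_samples)].to_numpy(dtype=float)
    sen = matrix.data[list(pair.sensitive_samples)].to_numpy(dtype=float)
    n1, n2 = res.shape[1], sen.shape[1]
    log2fc = res.mean(axis=1) - sen.mean(axis=1)
    d_g = float(n1 + n2 - 2)
    if d_g >= 1:
        ss_res = ((res - res.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        ss_sen = ((sen - sen.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        s_sq = (ss_res + ss_sen) / d_g
    else:
        s_sq = np.full(res.shape[0], np.nan)
    return PooledStats(
        genes=matrix.gene_ids,
        log2fc=log2fc,
        s_sq=s_sq,
        d_g=d_g,
        v_g=1.0 / n1 + 1.0 / n2,
        n_resistant=n1,
        n_sensitive=n2,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on 1/trigamma, which is
    nearly linear; the standard approach for this inversion)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s_sq_values, d_g: float) -> VariancePrior:
    """Moment-match (d0, s0^2) from gene-wise pooled variances.

    d0 solves trigamma(d0/2) = max(0, var(log s^2) - trigamma(d_g/2)); a
    non-positive right-hand side means the observed spread of log s^2 is no
    wider than pure chi-square sampling noise, so d0 = inf and all genes
    share s0^2 = mean(s^2).  Otherwise s0^2 comes from the mean equation.
    """
    s_sq = np.asarray(s_sq_values, dtype=float)
    s_sq = s_sq[np.isfinite(s_sq)]
    if s_sq.size < 2:
        raise ValueError("need >=2 finite gene variances to fit the prior")
    if not d_g >= 1:
        raise ValueError("d_g must be >= 1")
    positive = s_sq[s_sq > 0]
    if positive.size < s_sq.size:
        # zero variances carry no log-scale information; genuinely constant
        # genes are vanishingly rare in real data
        if positive.size == 0:
            return VariancePrior(d0=np.inf, s0_sq=float(s_sq.mean()))
    e = np.log(positive)
    evar = float(np.var(e, ddof=1)) if positive.size > 1 else 0.0
    rhs = evar - float(special.polygamma(1, d_g / 2.0))
    if rhs <= 0:
        return VariancePrior(d0=np.inf, s0_sq=float(s_sq.mean()))
    d0 = 2.0 * _trigamma_inverse(rhs)
    log_s0_sq = (
        float(np.mean(e))
        - float(special.digamma(d_g / 2.0))
        + np.log(d_g / 2.0)
        + float(special.digamma(d0 / 2.0))
        - np.log(d0 / 2.0)
    )
    return VariancePrior(d0=float(d0), s0_sq=float(np.exp(log_s0_sq)))


def moderated_t_table(
    matrix: ExpressionMatrix, pair: CohortPair, prior: VariancePrior
) -> pd.DataFrame:
    """Moderated t per gene for one cohort.

    s_tilde^2 = (d0 s0^2 + d_g s^2) / (d0 + d_g); t = log2fc / (s_tilde
    sqrt(v_g)); two-sided p from t with d0 + d_g df (normal when d0 = inf).
    Genes without a defined s^2 (singleton arms) use s0^2 with df d0.
    """
    ps = gene_pooled_stats(matrix, pair)
    d0, s0_sq = prior.d0, prior.s0_sq
    s_sq = ps.s_sq.copy()
    undefined = ~np.isfinite(s_sq)
    if np.isinf(d0):
        s_tilde_sq = np.full_like(ps.log2fc, s0_sq)
        df_total = np.inf
    else:
        s_sq[undefined] = 0.0
        d_eff = np.where(undefined, 0.0, ps.d_g)
        s_tilde_sq = (d0 * s0_sq + d_eff * s_sq) / (d0 + d_eff)
        df_total = d0 + ps.d_g
    with np.errstate(divide="ignore", invalid="ignore"):
        t = ps.log2fc / np.sqrt(s_tilde_sq * ps.v_g)
    t = np.where(np.isnan(t), 0.0, t)  # 0/0: no change, no evidence
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    elif undefined.any() and not np.isinf(d0):
        df_vec = np.where(undefined, d0, df_total)
        p = 2.0 * stats.t.sf(np.abs(t), df_vec)
        df_total = df_vec
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "gene": ps.genes,
            "cohort": pair.cohort_id,
            "log2fc": ps.log2fc,
            "t": t,
            "df": df_total,
            "p": p,
        },
        columns=DE_COLUMNS,
    )


def de_table_for_cohorts(
    matrix: ExpressionMatrix, pairs, *, min_genes_for_prior: int = 10
) -> pd.DataFrame:
    """Fit the variance prior and compute the moderated-t table per cohort,
    concatenated into one long DETable (columns gene/cohort/log2fc/t/df/p)."""
    tables = []
    for pair in pairs:
        cols = list(pair.sensitive_samples) + list(pair.resistant_samples)
        sub = matrix.subset_samples(cols)
        ps = gene_pooled_stats(sub, pair)
        finite = ps.s_sq[np.isfinite(ps.s_sq)]
        if ps.d_g >= 1 and finite.size >= min_genes_for_prior:
            prior = fit_variance_prior(ps.s_sq, ps.d_g)
        else:
            # singleton arms: full-shrinkage fallback across genes
            lfc_var = float(np.var(ps.log2fc, ddof=1)) / ps.v_g
            prior = VariancePrior(d0=np.inf, s0_sq=max(lfc_var, 1e-12))
        tables.append(moderated_t_table(sub, pair, prior))
    return pd.concat(tables, ignore_index=True)


def paired_t_test(values_a, values_b):
    """Paired two-sided t-test on index-matched values.

    Returns ``(t, df, p)``.  Degenerate cases: all differences zero ->
    (0, n-1, 1); zero-variance differences with nonzero mean -> p = 0
    (the limit), t = signed inf.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test needs two equal-length 1-D vectors")
    n = a.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    df = n - 1
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0
        return float(np.sign(mean) * np.inf), df, 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.8g")
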