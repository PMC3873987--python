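"""Unreplicated two-library negative-binomial differential expression.

With a single infected and a single uninfected library there are no biological
replicates, so dispersion is estimated *blind*: the two libraries are treated
as replicates of each other, the resulting gene-wise moment estimates are
smoothed by a mean-dispersion trend, and each gene's dispersion is a maximum a
posteriori (MAP) compromise between its own (2-point) likelihood and a
log-normal prior centred on the trend.  Testing then uses a conditional exact
NB test (condition on the per-gene total, enumerate splits), independent
filtering on the mean of normalized counts — with the filter cutoff capped at
the median of that mean — and Benjamini–Hochberg adjustment.

This is intentionally conservative: a truly regulated gene inflates its own
blind dispersion estimate, so only changes large relative to the prior-shrunk
dispersion reach significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import CountRecord

__all__ = [
    "SizeFactors",
    "DispersionFit",
    "DEConfig",
    "estimate_size_factors",
    "estimate_blind_dispersion",
    "nb_test",
    "independent_filter_and_adjust",
    "run_de",
    "STATUS_UP",
    "STATUS_DOWN",
    "STATUS_NS",
    "STATUS_FILTERED",
    "STATUS_NO_EXPRESSION",
]

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "not_significant"
STATUS_FILTERED = "low_expression_filtered"
STATUS_NO_EXPRESSION = "no_expression"

_MIN_ALPHA = 1e-8
_MAX_ALPHA = 20.0


@dataclass(frozen=True)
class SizeFactors:
    s_infected: float
    s_uninfected: float

    def __post_init__(self) -> None:
        if self.s_infected <= 0 or self.s_uninfected <= 0:
            raise ValueError("size factors must be positive")


@dataclass
class DispersionFit:
    """Per-gene dispersion estimates aligned with the input gene order."""

    gene_ids: list[str]
    alpha_mom: np.ndarray  # moment estimates, >= 0 (nan where mean is 0)
    trend_a0: float
    trend_a1: float
    alpha_map: np.ndarray  # MAP estimates, > 0 (nan where mean is 0)
    sigma_prior: float

    def trend(self, mean: np.ndarray | float) -> np.ndarray | float:
        return self.trend_a0 + self.trend_a1 / np.maximum(np.asarray(mean, float), 1e-12)

    def alpha_of(self) -> dict[str, float]:
        return dict(zip(self.gene_ids, self.alpha_map.tolist()))


@dataclass(frozen=True)
class DEConfig:
    fdr_level: float = 0.10
    pseudo_count: float = 0.5  # display-only, used in log2fc; never in p-values
    sigma_prior: float = 0.5  # log-normal prior spread on dispersion
    min_informative_genes: int = 100


# ---------------------------------------------------------------------------
# Size factors (median-of-ratios)
# ---------------------------------------------------------------------------


def _count_matrix(counts: Sequence[CountRecord]) -> tuple[list[str], np.ndarray]:
    genes = [c.gene_id for c in counts]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene_id in counts")
    k = np.array([[c.count_infected, c.count_uninfected] for c in counts], dtype=float)
    return genes, k


def estimate_size_factors(counts: Sequence[CountRecord]) -> SizeFactors:
    """Median-of-ratios normalization over genes with positive counts in both libraries."""
    _, k = _count_matrix(counts)
    pos = (k > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no gene has positive counts in both libraries")
    kp = k[pos]
    geo_mean = np.exp(np.log(kp).mean(axis=1, keepdims=True))
    s = np.median(kp / geo_mean, axis=0)
    return SizeFactors(float(s[0]), float(s[1]))


# ---------------------------------------------------------------------------
# Blind dispersion estimation
# ---------------------------------------------------------------------------


def _nb_logpmf(k: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB log pmf with mean mu and variance mu + alpha*mu^2 (broadcasting)."""
    r = 1.0 / alpha
    p = r / (r + mu)
    return stats.nbinom.logpmf(k, r, p)


def _fit_trend(m: np.ndarray, a_mom: np.ndarray) -> tuple[float, float]:
    """Fit alpha_trend(mu) = a0 + a1/mu by IRLS with Tukey-bisquare down-weighting.

    Coefficients are clipped at zero; genes whose moment estimate is an extreme
    outlier relative to the current fit contribute nothing to the next round.
    """
    X = np.column_stack([np.ones_like(m), 1.0 / m])
    y = a_mom
    w = np.ones_like(y)
    a = np.array([np.median(y), 0.0])
    for _ in range(12):
        WX = X * w[:, None]
        coef, *_ = np.linalg.lstsq(WX, y * w, rcond=None)
        coef = np.clip(coef, 0.0, None)
        resid = y - X @ coef
        scale = np.median(np.abs(resid)) * 1.4826 + 1e-12
        u = resid / (4.685 * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if np.allclose(coef, a, rtol=1e-8, atol=1e-12):
            a = coef
            break
        a = coef
    return float(a[0]), float(a[1])


def estimate_blind_dispersion(
    counts: Sequence[CountRecord],
    size_factors: SizeFactors,
    config: DEConfig | None = None,
) -> DispersionFit:
    """Blind (condition-agnostic) dispersion estimation.

    Per gene the moment estimate is ``max(0, (v - m) / m^2)`` with ``m`` the
    mean and ``v`` the two-point sample variance of the normalized counts.  A
    trend ``a0 + a1/mu`` is fitted over genes with a positive moment estimate,
    and the MAP estimate maximizes the two-point NB log-likelihood plus a
    log-normal prior centred at the trend with spread ``sigma_prior``.
    """
    config = config or DEConfig()
    genes, k = _count_matrix(counts)
    s = np.array([size_factors.s_infected, size_factors.s_uninfected])
    y = k / s  # normalized counts
    m = y.mean(axis=1)
    v = 0.5 * (y[:, 0] - y[:, 1]) ** 2  # two-point sample variance
    with np.errstate(divide="ignore", invalid="ignore"):
        a_mom = np.where(m > 0, np.maximum(0.0, (v - m) / m**2), np.nan)

    informative = (m > 0) & (a_mom > 0)
    if int(informative.sum()) < config.min_informative_genes:
        raise ValueError(
            f"only {int(informative.sum())} genes have a positive moment dispersion "
            f"estimate (need >= {config.min_informative_genes}); supply a larger "
            "count table"
        )
    a0, a1 = _fit_trend(m[informative], a_mom[informative])

    expressed = m > 0
    alpha_map = np.full(len(genes), np.nan)
    mu = m[expressed, None] * s[None, :]  # fitted means per sample
    kk = k[expressed]
    a_tr = np.maximum(a0 + a1 / m[expressed], _MIN_ALPHA)

    # profile the posterior on a log-spaced dispersion grid, then refine by
    # parabolic interpolation in log-alpha (the posterior is smooth there)
    grid = np.exp(np.linspace(math.log(_MIN_ALPHA), math.log(_MAX_ALPHA), 121))
    ll = np.zeros((kk.shape[0], grid.size))
    for j, alpha in enumerate(grid):
        ll[:, j] = _nb_logpmf(kk, mu, np.full((1, 1), alpha)).sum(axis=1)
    log_grid = np.log(grid)
    prior = -((log_grid[None, :] - np.log(a_tr)[:, None]) ** 2) / (
        2.0 * config.sigma_prior**2
    )
    post = ll + prior
    best = np.argmax(post, axis=1)

    refined = np.empty(kk.shape[0])
    for i, b in enumerate(best):
        if b == 0 or b == grid.size - 1:
            refined[i] = log_grid[b]
            continue
        x0, x1, x2 = log_grid[b - 1 : b + 2]
        y0, y1, y2 = post[i, b - 1 : b + 2]
        denom = (y0 - 2 * y1 + y2)
        refined[i] = x1 if denom >= 0 else x1 + 0.5 * (y0 - y2) / denom * (x1 - x0)
    alpha_map[expressed] = np.clip(np.exp(refined), _MIN_ALPHA, _MAX_ALPHA)

    return DispersionFit(
        gene_ids=genes,
        alpha_mom=a_mom,
        trend_a0=a0,
        trend_a1=a1,
        alpha_map=alpha_map,
        sigma_prior=config.sigma_prior,
    )


# ---------------------------------------------------------------------------
# Conditional exact NB test
# ---------------------------------------------------------------------------


def _exact_nb_pvalue(k_inf: int, k_unf: int, mu_inf: float, mu_unf: float, alpha: float) -> float:
    """Two-sided conditional exact test.

    Under the null of a common underlying rate, condition on the observed
    total and sum the NB-model probabilities of all splits that are no more
    likely than the observed one.
    """
    total = k_inf + k_unf
    a = np.arange(total + 1)
    logp = _nb_logpmf(a, np.full(total + 1, mu_inf), np.full(1, alpha)) + _nb_logpmf(
        total - a, np.full(total + 1, mu_unf), np.full(1, alpha)
    )
    # normalize within the conditional slice for numerical stability
    logp -= logp.max()
    p = np.exp(logp)
    p_obs = p[k_inf]
    keep = p <= p_obs * (1.0 + 1e-8)
    return float(min(1.0, p[keep].sum() / p.sum()))


def nb_test(
    counts: Sequence[CountRecord],
    size_factors: SizeFactors,
    dispersions: DispersionFit,
    config: DEConfig | None = None,
) -> pd.DataFrame:
    """Per-gene base mean, log2 fold change and exact-test p-value.

    Returns a DataFrame indexed by gene_id with columns ``base_mean``,
    ``log2fc``, ``pvalue`` and ``status`` (only ``no_expression`` assigned at
    this stage; significance labels come from
    :func:`independent_filter_and_adjust`).  The pseudo-count enters only the
    displayed fold change, never the p-value.
    """
    config = config or DEConfig()
    genes, k = _count_matrix(counts)
    alpha_of = dispersions.alpha_of()
    s = np.array([size_factors.s_infected, size_factors.s_uninfected])
    y = k / s
    base_mean = y.mean(axis=1)
    c = config.pseudo_count
    log2fc = np.log2((y[:, 0] + c) / (y[:, 1] + c))

    pvals = np.full(len(genes), np.nan)
    status = np.array([""] * len(genes), dtype=object)
    for i, gene in enumerate(genes):
        ki, ku = int(k[i, 0]), int(k[i, 1])
        if ki == 0 and ku == 0:
            status[i] = STATUS_NO_EXPRESSION
            continue
        alpha = alpha_of.get(gene, np.nan)
        if not np.isfinite(alpha):
            raise ValueError(f"no dispersion estimate for expressed gene {gene}")
        q = base_mean[i]
        pvals[i] = _exact_nb_pvalue(ki, ku, s[0] * q, s[1] * q, alpha)

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "pvalue": pvals,
            "status": status,
        },
        index=pd.Index(genes, name="gene_id"),
    )


# ---------------------------------------------------------------------------
# Independent filtering + BH
# ---------------------------------------------------------------------------


def independent_filter_and_adjust(
    results: pd.DataFrame,
    fdr_level: float = 0.10,
) -> pd.DataFrame:
    """Choose the low-count filter that maximizes BH rejections, then adjust.

    Candidate cutoffs are the 0, 1, ..., 95 percent quantiles of the mean
    normalized count over testable genes, truncated at the median of that mean
    (genes with higher means are never filtered merely to gain rejections);
    a no-filtering candidate is always included.  Genes whose mean falls below
    the chosen cutoff get status ``low_expression_filtered`` and no adjusted
    p-value; the rest are BH-adjusted and labelled up/down at ``fdr_level``.
    """
    out = results.copy()
    testable = out["status"] != STATUS_NO_EXPRESSION
    if testable.any() and out.loc[testable, "pvalue"].isna().any():
        missing = out.index[testable & out["pvalue"].isna()].tolist()
        raise ValueError(f"missing p-values for testable genes: {missing[:5]} ...")
    out["padj"] = np.nan
    if not testable.any():
        return out

    bm = out.loc[testable, "base_mean"].to_numpy()
    pv = out.loc[testable, "pvalue"].to_numpy()
    cap = float(np.median(bm))
    quantiles = np.quantile(bm, np.arange(0, 96) / 100.0)
    candidates = [-np.inf] + sorted({float(q) for q in quantiles if q <= cap})

    def n_reject(threshold: float) -> int:
        sel = bm > threshold
        if not sel.any():
            return 0
        rej, *_ = multipletests(pv[sel], alpha=fdr_level, method="fdr_bh")
        return int(rej.sum())

    rejections = [n_reject(t) for t in candidates]
    best_idx = int(np.argmax(rejections))  # ties: the least aggressive filter
    threshold = candidates[best_idx]

    keep = bm > threshold
    kept_index = out.index[testable][keep]
    dropped_index = out.index[testable][~keep]
    _, padj, *_ = multipletests(pv[keep], alpha=fdr_level, method="fdr_bh")
    out.loc[kept_index, "padj"] = padj
    out.loc[dropped_index, "status"] = STATUS_FILTERED

    sig = out.index.isin(kept_index) & (out["padj"] <= fdr_level)
    out.loc[kept_index, "status"] = STATUS_NS
    out.loc[sig & (out["log2fc"] > 0), "status"] = STATUS_UP
    out.loc[sig & (out["log2fc"] < 0), "status"] = STATUS_DOWN
    out.attrs["filter_threshold"] = None if np.isinf(threshold) else threshold
    out.attrs["filter_cap"] = cap
    out.attrs["fdr_level"] = fdr_level
    return out


def run_de(counts: Sequence[CountRecord], config: DEConfig | None = None) -> pd.DataFrame:
    """Full DE stage: size factors → blind dispersion → exact test → filter + BH."""
    config = config or DEConfig()
    sf = estimate_size_factors(counts)
    disp = estimate_blind_dispersion(counts, sf, config)
    res = nb_test(counts, sf, disp, config)
    res = independent_filter_and_adjust(res, fdr_level=config.fdr_level)
    res.attrs["size_factors"] = (sf.s_infected, sf.s_uninfected)
    res.attrs["dispersion_trend"] = (disp.trend_a0, disp.trend_a1)
    return res
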