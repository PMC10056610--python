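"""Two-group negative-binomial differential expression.

Counts for feature g in sample s are modelled as NB with mean
``mu_gs = exp(beta_g) * N_s`` (N_s the effective, factor-adjusted
library size) and variance ``mu + phi * mu**2``.  Per-feature
dispersions are method-of-moments estimates shrunk toward a
mean-expression trend; the group effect is tested by a likelihood-ratio
test between a two-group-mean and a single-mean model with the
dispersion held fixed, the statistic referred to chi-squared with one
degree of freedom.  Multiplicity is controlled by Benjamini-Hochberg
FDR, and features are called up/down with the fold-change convention
type2/type1 (fast-fiber-predominant over slow-fiber-predominant).

Also provides the per-group descriptive statistics (mean, SD, range,
Welch two-sided p) used for fiber-type percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .expression_matrix import CountMatrix, GroupDesign, InputError, compute_cpm


# ---------------------------------------------------------------------------
# NB machinery
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; phi = 0 rows use the Poisson limit."""
    mu = np.maximum(mu, 1e-12)
    out = np.zeros(y.shape[0])
    pois = phi == 0
    if pois.any():
        yp, mp = y[pois], mu[pois]
        out[pois] = np.sum(yp * np.log(mp) - mp - gammaln(yp + 1), axis=1)
    nb = ~pois
    if nb.any():
        yn, mn = y[nb], mu[nb]
        r = 1.0 / phi[nb][:, None]  # NB size parameter
        out[nb] = np.sum(
            gammaln(yn + r)
            - gammaln(r)
            - gammaln(yn + 1)
            + yn * np.log(mn / (mn + r))
            + r * np.log(r / (mn + r)),
            axis=1,
        )
    return out


def _fit_log_rate(
    y: np.ndarray, offsets: np.ndarray, phi: np.ndarray, n_iter: int = 60
) -> np.ndarray:
    """ML log-rate per feature for mu = exp(beta) * offsets, phi fixed.

    Fisher scoring, vectorized over features; exact in one step when
    phi = 0 (Poisson mean = total/total-offset).
    """
    tot = y.sum(axis=1)
    beta = np.log(np.maximum(tot, 0.25) / offsets.sum())
    for _ in range(n_iter):
        mu = np.exp(beta)[:, None] * offsets[None, :]
        denom = 1.0 + phi[:, None] * mu
        score = np.sum((y - mu) / denom, axis=1)
        info = np.sum(mu / denom, axis=1)
        step = np.clip(score / np.maximum(info, 1e-12), -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def estimate_dispersions(
    cm: CountMatrix,
    design: GroupDesign,
    shrinkage: float = 0.5,
    trend_frac: float = 0.5,
) -> pd.Series:
    """Per-feature NB dispersion, shrunk toward a mean-expression trend.

    Raw estimates are method-of-moments on library-size-adjusted counts
    with group means removed: ``phi = (var - mean) / mean**2`` floored at
    zero.  A lowess trend of the raw values against log2 mean expression
    supplies the shrinkage target; the returned value is
    ``shrinkage * trend + (1 - shrinkage) * raw``.
    """
    labels = design.labels_for(cm.sample_ids)
    names = np.unique(labels)
    if len(names) < 2:
        raise InputError("two groups required")
    for g in names:
        if (labels == g).sum() < 2:
            raise InputError(f"group {g!r} has fewer than two samples")

    eff = cm.effective_library_sizes.to_numpy(dtype=float)
    scale = np.exp(np.mean(np.log(eff))) / eff  # bring samples to a common size
    z = cm.counts.to_numpy(dtype=float) * scale[None, :]

    n = z.shape[1]
    resid_ss = np.zeros(z.shape[0])
    for g in names:
        zg = z[:, labels == g]
        resid_ss += ((zg - zg.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    var = resid_ss / (n - len(names))
    mean = z.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mean) / mean**2
    raw = np.where(np.isfinite(raw), raw, 0.0)
    raw = np.maximum(raw, 0.0)

    expressed = mean > 0
    trend = np.zeros_like(raw)
    if expressed.sum() >= 10:
        x = np.log2(mean[expressed] + 0.5)
        sm = lowess(raw[expressed], x, frac=trend_frac, return_sorted=True)
        trend[expressed] = np.interp(np.log2(mean[expressed] + 0.5), sm[:, 0], sm[:, 1])
        trend = np.maximum(trend, 0.0)
    else:
        trend[:] = np.median(raw[expressed]) if expressed.any() else 0.0

    phi = np.maximum(shrinkage * trend + (1.0 - shrinkage) * raw, 0.0)
    return pd.Series(phi, index=cm.feature_ids, name="dispersion")


def nb_test(
    cm: CountMatrix, design: GroupDesign, dispersions: pd.Series
) -> pd.DataFrame:
    """NB likelihood-ratio test of a group effect, per feature.

    Compares a model with one mean per group against a single shared
    mean (both on effective-library-size offsets, dispersion fixed at
    the supplied estimate); the statistic is referred to chi2(1).
    All-zero features get statistic 0 and p = 1.
    """
    labels = design.labels_for(cm.sample_ids)
    names = np.unique(labels)
    if len(names) != 2:
        raise InputError("exactly two groups required")
    y = cm.counts.to_numpy(dtype=float)
    eff = cm.effective_library_sizes.to_numpy(dtype=float)
    phi = dispersions.reindex(cm.feature_ids).to_numpy(dtype=float)

    beta0 = _fit_log_rate(y, eff, phi)
    mu0 = np.exp(beta0)[:, None] * eff[None, :]
    ll0 = _nb_loglik(y, mu0, phi)

    ll1 = np.zeros_like(ll0)
    mu1 = np.empty_like(mu0)
    for g in names:
        sel = labels == g
        beta_g = _fit_log_rate(y[:, sel], eff[sel], phi)
        mu1[:, sel] = np.exp(beta_g)[:, None] * eff[sel][None, :]
    ll1 = _nb_loglik(y, mu1, phi)

    stat = np.maximum(2.0 * (ll1 - ll0), 0.0)
    p = stats.chi2.sf(stat, df=1)
    allzero = y.sum(axis=1) == 0
    stat[allzero] = 0.0
    p[allzero] = 1.0
    return pd.DataFrame(
        {"statistic": stat, "p_value": p}, index=cm.feature_ids
    )


# ---------------------------------------------------------------------------
# Multiple testing and calling
# ---------------------------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    results: pd.DataFrame, fdr_max: float = 0.05, lfc_min: float = 1.0
) -> pd.DataFrame:
    """Attach up/down/ns calls at the given FDR and |log2FC| thresholds."""
    out = results.copy()
    up = (out["fdr"] < fdr_max) & (out["log2FC"] > lfc_min)
    down = (out["fdr"] < fdr_max) & (out["log2FC"] < -lfc_min)
    out["call"] = np.where(up, "up", np.where(down, "down", "ns"))
    return out


def de_table(
    cm: CountMatrix,
    design: GroupDesign,
    dispersions: pd.Series | None = None,
    fdr_max: float = 0.05,
    lfc_min: float = 1.0,
    pseudo_cpm: float = 0.5,
) -> pd.DataFrame:
    """Full two-group DE analysis on a (TMM-normalized) count matrix.

    log2FC is log2 of the ratio of group-mean CPM (type2/type1) with
    ``pseudo_cpm`` added to numerator and denominator; mean_log2CPM is
    log2 of the overall mean CPM plus the same pseudo count.
    """
    if dispersions is None:
        dispersions = estimate_dispersions(cm, design)
    test = nb_test(cm, design, dispersions)
    labels = design.labels_for(cm.sample_ids)
    cpm = compute_cpm(cm)
    m1 = cpm.loc[:, labels == "type1"].mean(axis=1)
    m2 = cpm.loc[:, labels == "type2"].mean(axis=1)
    lfc = np.log2((m2 + pseudo_cpm) / (m1 + pseudo_cpm))
    out = pd.DataFrame(
        {
            "log2FC": lfc,
            "mean_log2CPM": np.log2(cpm.mean(axis=1) + pseudo_cpm),
            "dispersion": dispersions.reindex(cm.feature_ids),
            "p_value": test["p_value"],
        },
        index=cm.feature_ids,
    )
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    allzero = cm.counts.sum(axis=1) == 0
    out.loc[allzero, "log2FC"] = 0.0
    return call_de(out, fdr_max=fdr_max, lfc_min=lfc_min)


# ---------------------------------------------------------------------------
# Group descriptive statistics
# ---------------------------------------------------------------------------


@dataclass
class GroupStats:
    group: str
    n: int
    mean: float
    sd: float
    range: tuple[float, float]


def group_stats(values_by_group: dict[str, np.ndarray]):
    """Per-group mean/SD/range plus a Welch two-sided p for two groups.

    SD uses the n-1 denominator.  Returns ``(stats_list, welch_p)``;
    ``welch_p`` is None unless exactly two groups are supplied.
    """
    out = []
    arrays = {}
    for g, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise InputError(f"group {g!r} needs at least two values")
        arrays[g] = v
        out.append(
            GroupStats(
                group=g,
                n=int(v.size),
                mean=float(v.mean()),
                sd=float(v.std(ddof=1)),
                range=(float(v.min()), float(v.max())),
            )
        )
    welch_p = None
    if len(arrays) == 2:
        a, b = arrays.values()
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            # degenerate Welch denominator: decide by the means alone
            welch_p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            welch_p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return out, welch_p
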