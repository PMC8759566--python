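"""Negative-binomial Wald differential expression between two tissue groups.

The model is the standard RNA-seq count GLM: counts y_ij ~ NB(mu_ij, alpha_i)
with variance mu + alpha*mu^2, log link, mu_ij = s_j * exp(b0_i + b1_i * x_j)
where x_j indicates the case group and s_j is a median-of-ratios size factor.
Per-gene dispersions are method-of-moments estimates shrunk toward a fitted
mean-dispersion trend alpha_tr(mu) = a0 + a1/mu; the Wald statistic tests
b1 = 0, p-values are BH-adjusted, and noisy fold changes are shrunk by an
empirical-Bayes zero-centred normal prior.  The same trend parameterizes the
closed-form variance-stabilizing transformation.

Deliberate simplifications relative to full DESeq2-style machinery (no
Cox-Reid adjustment, no apeglm prior, no independent filtering, no outlier
replacement) are documented in the methods note.

Log2 scale throughout: LFC and SE are reported in log2 units, and the
physiological-relevance filter requires FDR < 0.05, |LFC| > 0.58 and a mean
expression above 100 RPM in at least one of the compared tissues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import CountMatrix

__all__ = [
    "DEConfig",
    "DispersionModel",
    "size_factors",
    "estimate_dispersions",
    "wald_test",
    "shrink_lfc",
    "bh_adjust",
    "vst",
    "relevance_filter",
    "de_analysis",
]

LN2 = np.log(2.0)


@dataclass(frozen=True)
class DEConfig:
    fdr_threshold: float = 0.05
    lfc_threshold: float = 0.58
    rpm_threshold: float = 100.0
    use_shrunk_lfc: bool = True      # relevance filter on shrunk LFC
    dispersion_floor: float = 1e-8
    trend_weight: float = 0.5        # blend of trend vs genewise (log scale)
    irls_tol: float = 1e-8
    irls_max_iter: int = 100
    min_prior_var: float = 0.0625    # LFC shrinkage prior variance floor


@dataclass
class DispersionModel:
    genewise: pd.Series          # method-of-moments alpha_i
    a0: float                    # asymptotic dispersion
    a1: float                    # extra-Poisson term: alpha_tr = a0 + a1/mu
    final: pd.Series             # trend-shrunk alpha*_i
    base_mean: pd.Series         # mean normalized count per gene

    def trend(self, mu: np.ndarray) -> np.ndarray:
        return self.a0 + self.a1 / np.maximum(mu, 1e-12)


# ---------------------------------------------------------------------------
# normalization


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    s_j = median over genes (with all-positive counts) of y_ij / geomean_i.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    y = counts.to_numpy(dtype=float)
    if y.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    allpos = (y > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene with all-positive counts; consider a pseudo-reference "
            "(add a pseudocount or use only high-count genes)")
    logs = np.log(y[allpos])
    log_geomean = logs.mean(axis=1)
    log_ratios = logs - log_geomean[:, None]
    s = np.exp(np.median(log_ratios, axis=0))
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion


def estimate_dispersions(
    counts: pd.DataFrame | CountMatrix,
    s: pd.Series,
    groups: pd.Series | None = None,
    config: DEConfig = DEConfig(),
) -> DispersionModel:
    """Method-of-moments dispersions with a mean-dispersion trend.

    Within each group, on normalized counts q = y/s:
    E[var(q)] ~= mu * mean(1/s) + alpha * mu^2, so
    alpha_i = (pooled_var - mu_i * mean(1/s)) / mu_i^2, floored at 1e-8.
    The trend alpha_tr(mu) = a0 + a1/mu is fitted by trimmed non-negative
    least squares, and the final dispersion is the log-scale blend
    exp(w*log(alpha_tr) + (1-w)*log(alpha_i)) with w = 0.5.
    """
    if isinstance(counts, CountMatrix):
        if groups is None:
            groups = counts.meta["tissue"]
        counts = counts.counts
    y = counts.to_numpy(dtype=float)
    sv = s.loc[counts.columns].to_numpy()
    q = y / sv
    if groups is None:
        groups = pd.Series("all", index=counts.columns)
    groups = groups.loc[counts.columns]
    inv_s_mean = np.mean(1.0 / sv)
    num = np.zeros(y.shape[0])
    den = 0.0
    mu = q.mean(axis=1)
    for g in groups.unique():
        idx = (groups == g).to_numpy()
        n_g = int(idx.sum())
        if n_g < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        v_g = q[:, idx].var(axis=1, ddof=1)
        m_g = q[:, idx].mean(axis=1)
        # excess variance above the Poisson/size-factor component
        num += (n_g - 1) * (v_g - m_g * inv_s_mean)
        den += n_g - 1
    excess = num / den
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu > 0, excess / np.maximum(mu, 1e-12) ** 2, np.nan)
    alpha = np.maximum(alpha, config.dispersion_floor)
    genewise = pd.Series(alpha, index=counts.index, name="alpha")

    ok = (mu > 0) & np.isfinite(alpha)
    a0, a1 = _fit_trend(alpha[ok], mu[ok], floor=config.dispersion_floor)
    trend = a0 + a1 / np.maximum(mu, 1e-12)
    trend = np.maximum(trend, config.dispersion_floor)
    w = config.trend_weight
    final = np.exp(w * np.log(trend) + (1 - w) * np.log(alpha))
    return DispersionModel(
        genewise=genewise,
        a0=float(a0),
        a1=float(a1),
        final=pd.Series(final, index=counts.index, name="alpha_final"),
        base_mean=pd.Series(mu, index=counts.index, name="base_mean"),
    )


def _fit_trend(alpha: np.ndarray, mu: np.ndarray, floor: float,
               trim: float = 0.1, passes: int = 2) -> tuple[float, float]:
    """Trimmed NNLS fit of alpha ~ a0 + a1/mu (both coefficients >= 0)."""
    keep = np.ones(len(alpha), dtype=bool)
    a0 = a1 = 0.0
    for _ in range(passes):
        A = np.column_stack([np.ones(keep.sum()), 1.0 / mu[keep]])
        coef, _ = optimize.nnls(A, alpha[keep])
        a0, a1 = coef
        resid = np.abs(alpha - (a0 + a1 / mu))
        cutoff = np.quantile(resid, 1 - trim)
        keep = resid <= cutoff
        if keep.sum() < 2:
            break
    return max(a0, floor), max(a1, 0.0)


# ---------------------------------------------------------------------------
# Wald test


def wald_test(
    counts: pd.DataFrame,
    s: pd.Series,
    disp: DispersionModel | pd.Series,
    group_a: list[str],
    group_b: list[str],
    config: DEConfig = DEConfig(),
) -> pd.DataFrame:
    """Per-gene NB GLM Wald test of group B (case) vs group A (control).

    Design: intercept + case indicator, offset log s_j, dispersion fixed at
    alpha*_i; positive LFC means higher in group B.  Fitted by IRLS,
    vectorized across genes; SE from the Fisher information.  Non-converged
    genes are flagged and get NaN p-values (excluded from the BH denominator
    downstream).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    samples = list(group_a) + list(group_b)
    y = counts[samples].to_numpy(dtype=float)
    sv = s.loc[samples].to_numpy()
    x = np.array([0.0] * len(group_a) + [1.0] * len(group_b))
    alpha = (disp.final if isinstance(disp, DispersionModel) else disp
             ).loc[counts.index].to_numpy()

    G, n = y.shape
    log_s = np.log(sv)
    # initial values from group means of normalized counts
    qa = (y[:, x == 0] / sv[x == 0]).mean(axis=1)
    qb = (y[:, x == 1] / sv[x == 1]).mean(axis=1)
    eps = 0.5 * np.minimum(1.0, 1.0 / np.maximum(sv.mean(), 1e-12))
    b0 = np.log(np.maximum(qa, eps))
    b1 = np.log(np.maximum(qb, eps)) - b0

    tested = (y.sum(axis=1) > 0)
    converged = np.zeros(G, dtype=bool)
    active = tested.copy()
    for _ in range(config.irls_max_iter):
        if not active.any():
            break
        eta = b0[:, None] + b1[:, None] * x[None, :] + log_s[None, :]
        eta = np.clip(eta, -500, 500)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - log_s[None, :]) + (y - mu) / mu
        a11 = W.sum(axis=1)
        a12 = (W * x).sum(axis=1)
        a22 = (W * x * x).sum(axis=1)
        r1 = (W * z).sum(axis=1)
        r2 = (W * x * z).sum(axis=1)
        det = a11 * a22 - a12 * a12
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        nb0 = (a22 * r1 - a12 * r2) / det
        nb1 = (a11 * r2 - a12 * r1) / det
        step0 = np.clip(nb0 - b0, -5, 5)
        step1 = np.clip(nb1 - b1, -5, 5)
        move = np.maximum(np.abs(step0), np.abs(step1))
        upd = active & np.isfinite(move)
        b0[upd] += step0[upd]
        b1[upd] += step1[upd]
        newly = upd & (move < config.irls_tol)
        converged |= newly
        active &= ~newly
        b0 = np.clip(b0, -50, 50)
        b1 = np.clip(b1, -30, 30)

    # final weights for the SE
    eta = b0[:, None] + b1[:, None] * x[None, :] + log_s[None, :]
    eta = np.clip(eta, -500, 500)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[:, None] * mu)
    a11 = W.sum(axis=1)
    a12 = (W * x).sum(axis=1)
    a22 = (W * x * x).sum(axis=1)
    det = a11 * a22 - a12 * a12
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = a11 / det
    se_nat = np.sqrt(np.maximum(var_b1, 0.0))

    lfc = b1 / LN2
    se = se_nat / LN2
    ok = tested & converged & np.isfinite(se) & (se > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(ok, lfc / se, np.nan)
    p = np.where(ok, 2.0 * stats.norm.sf(np.abs(zstat)), np.nan)
    return pd.DataFrame(
        {
            "LFC_mle": np.where(tested, lfc, np.nan),
            "SE": np.where(tested, se, np.nan),
            "wald_z": zstat,
            "p_value": p,
            "converged": ok,
            "tested": tested,
        },
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# shrinkage / BH / VST / relevance


def shrink_lfc(results: pd.DataFrame, prior_var: float | None = None,
               config: DEConfig = DEConfig()) -> pd.Series:
    """Posterior-mean LFC under a zero-centred normal prior.

    LFC_shrunk = LFC * sigma2 / (sigma2 + SE^2); the prior variance is
    estimated from the data as max(mean(LFC^2) - mean(SE^2), 0.0625) unless
    supplied.  High-variance estimates are pulled strongly toward zero,
    precise ones barely move.
    """
    lfc = results["LFC_mle"]
    se = results["SE"]
    ok = lfc.notna() & se.notna()
    if prior_var is None:
        if ok.any():
            prior_var = max(float((lfc[ok] ** 2).mean() - (se[ok] ** 2).mean()),
                            config.min_prior_var)
        else:
            prior_var = config.min_prior_var
    shrunk = lfc * prior_var / (prior_var + se ** 2)
    return shrunk.rename("LFC_shrunk")


def bh_adjust(pvalues: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up FDR; NaNs pass through and do not count
    toward the number of tests."""
    is_series = isinstance(pvalues, pd.Series)
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    pv = p[ok]
    m = pv.size
    if m:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.minimum(q, 1.0)
        res = np.empty(m)
        res[order] = q
        out[ok] = res
    if is_series:
        return pd.Series(out, index=pvalues.index, name="fdr")
    return out


def vst(counts: pd.DataFrame, s: pd.Series,
        disp: DispersionModel) -> pd.DataFrame:
    """Closed-form variance-stabilizing transformation of normalized counts.

    With the dispersion trend alpha(mu) = a0 + a1/mu the integral of
    1/sqrt(variance) has the closed form below; it is monotone in n and
    approaches log2(n) + const for large n.
    """
    q = counts / s.loc[counts.columns]
    a0, a1 = disp.a0, disp.a1
    if a0 <= 0:
        warnings.warn("non-positive asymptotic dispersion; falling back to "
                      "log2(n + 1)")
        return np.log2(q + 1.0)
    n = np.maximum(q.to_numpy(dtype=float), 0.0)
    out = np.log2((1.0 + a1 + 2.0 * a0 * n +
                   2.0 * np.sqrt(a0 * n * (1.0 + a1 + a0 * n))) / (4.0 * a0))
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def relevance_filter(results: pd.DataFrame,
                     config: DEConfig = DEConfig()) -> pd.Series:
    """Physiological-relevance gate on DE results.

    relevant <=> FDR < 0.05 AND |LFC| > 0.58 AND max of the two group mean
    RPMs > 100 (all comparisons strict).  Uses the shrunken LFC unless
    configured otherwise.
    """
    lfc = results["LFC_shrunk" if config.use_shrunk_lfc else "LFC_mle"]
    max_rpm = results[["mean_rpm_case", "mean_rpm_control"]].max(axis=1)
    rel = (
        (results["fdr"] < config.fdr_threshold)
        & (lfc.abs() > config.lfc_threshold)
        & (max_rpm > config.rpm_threshold)
    )
    return rel.fillna(False).rename("relevant")


# ---------------------------------------------------------------------------
# end-to-end contrast


def de_analysis(
    cm: CountMatrix,
    case: str,
    control: str,
    config: DEConfig = DEConfig(),
    s: pd.Series | None = None,
    disp: DispersionModel | None = None,
) -> pd.DataFrame:
    """Run the full DE contrast case-vs-control on a count matrix.

    Positive LFC = higher in ``case``.  Genes with all-zero counts across the
    two groups are excluded before testing and from the BH denominator.
    Returns one row per tested gene with mean RPMs, MLE and shrunken LFC, SE,
    Wald statistics, BH FDR and the relevance flag.
    """
    case_samples = cm.tissue_samples(case)
    ctrl_samples = cm.tissue_samples(control)
    if len(case_samples) < 2 or len(ctrl_samples) < 2:
        raise ValueError(f"need >= 2 samples per group for {case} vs {control}")
    sub = cm.counts[ctrl_samples + case_samples]
    nonzero = sub.sum(axis=1) > 0
    sub = sub.loc[nonzero]
    if s is None:
        s = size_factors(sub)
    if disp is None:
        labels = pd.Series(
            [control] * len(ctrl_samples) + [case] * len(case_samples),
            index=ctrl_samples + case_samples)
        disp = estimate_dispersions(sub, s, labels, config)
    res = wald_test(sub, s, disp, ctrl_samples, case_samples, config)
    res["LFC_shrunk"] = shrink_lfc(res, config=config)
    res["fdr"] = bh_adjust(res["p_value"])
    rpm_all = cm.rpm()
    res["mean_rpm_case"] = rpm_all.loc[nonzero, case_samples].mean(axis=1)
    res["mean_rpm_control"] = rpm_all.loc[nonzero, ctrl_samples].mean(axis=1)
    res["relevant"] = relevance_filter(res, config)
    res.attrs["case"] = case
    res.attrs["control"] = control
    return res
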