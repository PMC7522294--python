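"""EMT scoring, Bayesian-regularized differential expression, variable genes.

All computations are performed on log2(x + 1) transformed abundances (the
standard convention for FPKM-like values); fold changes are reported on the
linear scale.

* EMT score: the first principal component of a 76-gene epithelial /
  mesenchymal signature's expression, oriented so that higher score means
  more mesenchymal (anchor gene VIM, else the mean mesenchymal loading).
* DEG calling follows the Cyber-T scheme: a t-test whose per-gene variance is
  shrunk toward a local background variance estimated from the ``window``
  genes nearest in average log expression,

      s~^2 = (nu0 * s0^2 + (n - 1) * s^2) / (nu0 + n - 2),

  and a gene is called when |fold change| >= 2 (or <= 0.5) and p < 0.05.
* Variable-gene selection ranks genes by median absolute deviation of their
  log expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EmtScoreResult",
    "emt_score",
    "cybert_deg",
    "top_variable_genes",
    "log_transform",
]

EPITHELIAL = "epithelial"
MESENCHYMAL = "mesenchymal"


def log_transform(values: pd.DataFrame, already_log: bool = False) -> pd.DataFrame:
    """log2(x + 1) on nonnegative abundances (identity if already log scale)."""
    if already_log:
        return values
    if (values < 0).any().any():
        raise ValueError("abundances must be nonnegative")
    return np.log2(values + 1.0)


@dataclass
class EmtScoreResult:
    per_sample_score: pd.Series
    explained_variance_pc1: float
    orientation_anchor: str
    loadings: pd.Series


def emt_score(
    expr: pd.DataFrame,
    signature: pd.Series,
    anchor: str = "VIM",
    already_log: bool = False,
) -> EmtScoreResult:
    """EMT score = PC1 projection of the signature genes' expression.

    Parameters
    ----------
    expr : DataFrame
        genes x samples abundance matrix.
    signature : Series
        per-gene label ('epithelial' / 'mesenchymal') indexed by gene symbol.
    anchor : str
        Mesenchymal gene whose loading fixes the sign (higher score = more
        mesenchymal); falls back to the mean mesenchymal loading if absent.
    """
    sig_genes = signature.index
    present = sig_genes.intersection(expr.index)
    if len(present) < 0.5 * len(sig_genes):
        raise ValueError(
            f"only {len(present)}/{len(sig_genes)} signature genes present (< 50%)"
        )
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for a meaningful PC1")
    x = log_transform(expr.loc[present], already_log)
    centered = x.sub(x.mean(axis=1), axis=0)  # center per gene
    if np.allclose(centered.to_numpy(), 0.0):
        raise ValueError("constant expression matrix: PC1 undefined")
    # samples as observations, genes as features
    mat = centered.to_numpy(dtype=float).T
    _, s, vt = np.linalg.svd(mat, full_matrices=False)
    loadings = pd.Series(vt[0], index=present)
    scores = pd.Series(mat @ vt[0], index=expr.columns)
    explained = float(s[0] ** 2 / np.sum(s**2))
    mes_genes = signature[signature == MESENCHYMAL].index.intersection(present)
    if anchor in loadings.index and signature.get(anchor) == MESENCHYMAL:
        used_anchor, sign_val = anchor, loadings[anchor]
    else:
        used_anchor = f"mean({MESENCHYMAL})"
        sign_val = loadings[mes_genes].mean() if len(mes_genes) else loadings.iloc[0]
    if sign_val < 0:
        loadings, scores = -loadings, -scores
    scores = scores - scores.mean()  # centered scores, mean 0
    return EmtScoreResult(
        per_sample_score=scores,
        explained_variance_pc1=explained,
        orientation_anchor=used_anchor,
        loadings=loadings,
    )


def _local_background_variance(
    mean_log: np.ndarray, var: np.ndarray, window: int
) -> np.ndarray:
    """Mean variance of the `window` genes nearest in average log expression
    (a symmetric rank window around each gene after sorting by mean)."""
    n = len(var)
    if window > n:
        warnings.warn(f"window {window} > gene count {n}; clamped", stacklevel=3)
        window = n
    order = np.argsort(mean_log, kind="stable")
    var_sorted = var[order]
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(var_sorted)])
    bg_sorted = np.empty(n)
    for i in range(n):
        lo = max(0, min(i - half, n - window))
        hi = lo + window
        bg_sorted[i] = (csum[hi] - csum[lo]) / window
    bg = np.empty(n)
    bg[order] = bg_sorted
    return bg


def cybert_deg(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    prior_df: int = 10,
    window: int = 101,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    already_log: bool = False,
) -> pd.DataFrame:
    """Cyber-T style differential expression between two sample groups.

    Returns a per-gene table with ``fold_change`` (ratio of linear-scale group
    means, a / b), ``t``, ``p`` and the ``called`` flag
    (|FC| >= threshold in either direction and p below threshold).
    """
    common = group_a.index.intersection(group_b.index)
    a_lin, b_lin = group_a.loc[common], group_b.loc[common]
    na, nb = a_lin.shape[1], b_lin.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 samples per group")
    a = log_transform(a_lin, already_log).to_numpy(dtype=float)
    b = log_transform(b_lin, already_log).to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    overall_mean = np.concatenate([a, b], axis=1).mean(axis=1)
    bg_a = _local_background_variance(overall_mean, var_a, window)
    bg_b = _local_background_variance(overall_mean, var_b, window)
    nu0 = prior_df
    s2_a = (nu0 * bg_a + (na - 1) * var_a) / (nu0 + na - 2)
    s2_b = (nu0 * bg_b + (nb - 1) * var_b) / (nu0 + nb - 2)
    se = np.sqrt(s2_a / na + s2_b / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / se
    df = na + nb - 2 + 2 * nu0  # variance augmented by nu0 pseudo-observations per group
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(t), p, np.where(mean_a == mean_b, 1.0, 0.0))
    fc = np.divide(
        a_lin.mean(axis=1).to_numpy(),
        b_lin.mean(axis=1).to_numpy(),
        out=np.full(len(common), np.inf),
        where=b_lin.mean(axis=1).to_numpy() != 0,
    )
    called = ((fc >= fc_threshold) | (fc <= 1.0 / fc_threshold)) & (p < p_threshold)
    return pd.DataFrame(
        {"fold_change": fc, "t": t, "p": p, "called": called}, index=common
    )


def top_variable_genes(expr: pd.DataFrame, n: int = 2000, already_log: bool = False) -> list[str]:
    """Top-n genes by median absolute deviation of log2(x+1) expression;
    ties break lexicographically by gene id."""
    if n > expr.shape[0]:
        raise ValueError(f"n={n} exceeds gene count {expr.shape[0]}")
    x = log_transform(expr, already_log)
    mad = pd.Series(
        stats.median_abs_deviation(x.to_numpy(dtype=float), axis=1), index=x.index
    )
    ranked = mad.sort_index().sort_values(ascending=False, kind="stable")
    return list(ranked.index[:n])
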