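"""Methylation probe filtering, DMP calling, clustering and subtype prediction.

Probe-level QC applies six filters (in reported order): detection p-value
> 0.01 in any sample; beadcount < 3 in >= 5% of samples; non-CpG probe; SNP
overlap; multi-mapping; X/Y chromosome.  Differentially methylated probes
(DMPs) are assessed with a moderated t-test (empirical-Bayes variance
shrinkage across probes) and defined by BH-adjusted p <= 0.05 together with
an absolute difference of group median beta values >= 0.3.

Molecular classification uses cancer-specific hypermethylation probes
(normal median beta < 0.2 and tumor median beta > 0.3) and agglomerative
hierarchical clustering with Euclidean distance and Ward linkage.
Transcriptional subtypes are assigned by the nearest-centroid rule: the
predictor centroid with the maximum Pearson correlation to the sample's
median-centered log expression.  Methylation-subtype similarity is the
Euclidean distance to per-subtype mean beta profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .expression import log_transform

__all__ = [
    "FILTER_RULES",
    "filter_probes",
    "moderated_t_test",
    "call_dmps",
    "select_cancer_specific_hyper_probes",
    "ClusterAssignment",
    "hierarchical_cluster",
    "select_comethylation_probes",
    "nearest_centroid_subtype",
    "methylation_subtype_similarity",
]

FILTER_RULES = ("detection_p", "beadcount", "non_cg", "snp", "multimap", "sex_chrom")


def _is_sex_chrom(chrom: pd.Series) -> pd.Series:
    c = chrom.astype(str).str.replace("^chr", "", regex=True).str.upper()
    return c.isin(["X", "Y"])


def filter_probes(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    beadcount: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the six probe filters; returns (filtered beta, per-probe reason).

    ``annotation`` must carry ``chrom``, ``is_cg``, ``has_snp``, ``multimap``
    per probe; ``detection_p`` and ``beadcount`` are probes x samples tables.
    The report gives the first violated rule in the canonical order, or
    ``kept``.
    """
    for col, rule in [("chrom", "sex_chrom"), ("is_cg", "non_cg"),
                      ("has_snp", "snp"), ("multimap", "multimap")]:
        if col not in annotation.columns:
            raise ValueError(f"annotation missing column {col!r} needed for rule {rule!r}")
    if detection_p is None:
        raise ValueError("detection_p table required for rule 'detection_p'")
    if beadcount is None:
        raise ValueError("beadcount table required for rule 'beadcount'")
    ann = annotation.reindex(beta.index)
    dp = detection_p.reindex(index=beta.index, columns=beta.columns)
    bc = beadcount.reindex(index=beta.index, columns=beta.columns)
    violations = pd.DataFrame(index=beta.index, columns=FILTER_RULES, dtype=bool)
    violations["detection_p"] = (dp > 0.01).any(axis=1)
    violations["beadcount"] = (bc < 3).mean(axis=1) >= 0.05
    violations["non_cg"] = ~ann["is_cg"].astype(bool)
    violations["snp"] = ann["has_snp"].astype(bool)
    violations["multimap"] = ann["multimap"].astype(bool)
    violations["sex_chrom"] = _is_sex_chrom(ann["chrom"])
    reason = pd.Series("kept", index=beta.index, name="reason")
    for rule in reversed(FILTER_RULES):  # earlier rules overwrite later ones
        reason[violations[rule]] = rule
    kept = reason == "kept"
    return beta.loc[kept], reason


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (limma's approach)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-8:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-method fit of the scaled inverse-chi-square variance prior
    (prior df d0 and prior variance s0^2) from observed gene variances."""
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        return 4.0, float(np.mean(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    if not np.isfinite(d0) or d0 <= 0 or not np.isfinite(s02):
        return 4.0, float(np.mean(s2))
    return d0, s02


def moderated_t_test(
    group_a: pd.DataFrame, group_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-row moderated t-test with empirical-Bayes variance shrinkage.

    Pools the two groups' within-group variances row-wise, shrinks them
    toward a prior fitted across all rows, and returns ``diff_mean``, ``t``,
    ``p`` and ``adj_p`` (Benjamini-Hochberg).
    """
    common = group_a.index.intersection(group_b.index)
    a = group_a.loc[common].to_numpy(dtype=float)
    b = group_b.loc[common].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 samples per group")
    df_resid = na + nb - 2
    var_pooled = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / df_resid
    diff = a.mean(axis=1) - b.mean(axis=1)
    if np.all(var_pooled == 0):
        warnings.warn("zero variance at all rows; falling back to ordinary t", stacklevel=2)
        p = np.where(diff == 0, 1.0, 0.0)
        t = np.where(diff == 0, 0.0, np.sign(diff) * np.inf)
    else:
        d0, s02 = _fit_variance_prior(var_pooled, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(var_pooled, s02)
            df_total = 1e6
        else:
            s2_post = (d0 * s02 + df_resid * var_pooled) / (d0 + df_resid)
            df_total = d0 + df_resid
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        p = np.where(np.isfinite(t), p, np.where(diff == 0, 1.0, 0.0))
    adj_p = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"diff_mean": diff, "t": t, "p": p, "adj_p": adj_p}, index=common
    )


def call_dmps(
    beta: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    adj_p_threshold: float = 0.05,
    delta_beta_threshold: float = 0.3,
) -> pd.DataFrame:
    """Differentially methylated probes between two sample groups.

    The test statistic is the moderated t on beta values; the effect size is
    the difference of group median beta values (both reported).  A probe is a
    DMP iff BH-adjusted p <= 0.05 and |delta median beta| >= 0.3.
    """
    a, b = beta[group_a], beta[group_b]
    res = moderated_t_test(a, b)
    delta_median = a.median(axis=1) - b.median(axis=1)
    res["delta_beta"] = delta_median
    res["is_dmp"] = (res["adj_p"] <= adj_p_threshold) & (
        res["delta_beta"].abs() >= delta_beta_threshold
    )
    return res


def select_cancer_specific_hyper_probes(
    tumor: pd.DataFrame, normal: pd.DataFrame
) -> list[str]:
    """Probes unmethylated in normals (median beta < 0.2) and methylated in
    tumors (median beta > 0.3)."""
    common = tumor.index.intersection(normal.index)
    nmed = normal.loc[common].median(axis=1)
    tmed = tumor.loc[common].median(axis=1)
    sel = (nmed < 0.2) & (tmed > 0.3)
    return list(common[sel])


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample -> C1/C2/...
    linkage: np.ndarray
    k: int


def hierarchical_cluster(matrix: pd.DataFrame, k: int) -> ClusterAssignment:
    """Ward / Euclidean agglomerative clustering of samples (rows), cut at k.

    Cluster labels C1..Ck are assigned by decreasing cluster size (ties by
    first sample occurrence); features with missing values are dropped.
    """
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds sample count {matrix.shape[0]}")
    x = matrix.dropna(axis=1)
    if x.shape[1] < matrix.shape[1]:
        warnings.warn(
            f"dropped {matrix.shape[1] - x.shape[1]} features with missing values",
            stacklevel=2,
        )
    Z = hierarchy.linkage(x.to_numpy(dtype=float), method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    first_seen = {c: int(np.argmax(raw == c)) for c in sizes.index}
    ordered = sorted(sizes.index, key=lambda c: (-sizes[c], first_seen[c]))
    rename = {c: f"C{i + 1}" for i, c in enumerate(ordered)}
    labels = pd.Series([rename[c] for c in raw], index=matrix.index, name="cluster")
    return ClusterAssignment(labels=labels, linkage=Z, k=int(len(sizes)))


def select_comethylation_probes(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    delta: float = 0.2,
    n_top: int = 3000,
    adj_p_threshold: float = 0.05,
) -> list[str]:
    """Probes significantly differential between tumor and normal (moderated
    t, BH adj p <= 0.05) with |mean beta difference| >= ``delta``, then the
    ``n_top`` most variable among tumors by MAD."""
    common = tumor.index.intersection(normal.index)
    res = moderated_t_test(tumor.loc[common], normal.loc[common])
    qualifying = res.index[
        (res["adj_p"] <= adj_p_threshold) & (res["diff_mean"].abs() >= delta)
    ]
    if len(qualifying) < n_top:
        warnings.warn(
            f"only {len(qualifying)} qualifying probes (< {n_top}); returning all",
            stacklevel=2,
        )
    mad = pd.Series(
        stats.median_abs_deviation(tumor.loc[qualifying].to_numpy(dtype=float), axis=1),
        index=qualifying,
    )
    ranked = mad.sort_index().sort_values(ascending=False, kind="stable")
    return list(ranked.index[:n_top])


def nearest_centroid_subtype(
    expr: pd.DataFrame, centroids: pd.DataFrame, already_log: bool = False
) -> pd.DataFrame:
    """Nearest-centroid transcriptional subtype prediction.

    Each sample's log2(x+1), gene-median-centered profile is correlated
    (Pearson) with every centroid over the genes common to the expression
    matrix and the predictor; the label is the centroid with maximum
    correlation (ties go to the earliest centroid column and are flagged).
    """
    common = expr.index.intersection(centroids.index)
    if len(common) < 10:
        raise ValueError(f"only {len(common)} genes common to predictor (< 10)")
    x = log_transform(expr.loc[common], already_log)
    x = x.sub(x.median(axis=1), axis=0)  # gene-median centering across the cohort
    cent = centroids.loc[common]
    rows = []
    for s in x.columns:
        v = x[s].to_numpy(dtype=float)
        row: dict = {"sample": s}
        if np.ptp(v) == 0:
            row.update({"label": None, "flag": "zero_variance"})
            for st in cent.columns:
                row[f"cor_{st}"] = np.nan
        else:
            cors = {st: stats.pearsonr(v, cent[st].to_numpy(dtype=float))[0] for st in cent.columns}
            best = max(cors.values())
            winners = [st for st in cent.columns if cors[st] == best]
            row["label"] = winners[0]
            row["flag"] = "tie" if len(winners) > 1 else ""
            for st in cent.columns:
                row[f"cor_{st}"] = cors[st]
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


def methylation_subtype_similarity(
    samples: pd.DataFrame, subtype_profiles: pd.DataFrame
) -> pd.DataFrame:
    """Euclidean distance of each sample's beta vector to each subtype's mean
    beta profile over the common probes (smaller = more similar)."""
    common = samples.index.intersection(subtype_profiles.index)
    if len(common) == 0:
        raise ValueError("empty probe intersection between samples and subtype profiles")
    s = samples.loc[common].to_numpy(dtype=float)
    p = subtype_profiles.loc[common].to_numpy(dtype=float)
    d = np.sqrt(((s[:, :, None] - p[:, None, :]) ** 2).sum(axis=0))
    out = pd.DataFrame(d, index=samples.columns, columns=subtype_profiles.columns)
    out["nearest"] = out.idxmin(axis=1)
    return out
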