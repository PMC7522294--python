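"""Leukocyte-fraction deconvolution from methylation and ssGSEA scoring.

The leukocyte fraction (LF) of a tumor sample is estimated from a
two-population mixture at informative CpG loci.  At locus *i* the observed
beta value is modeled as

    beta_i = beta_iL * pi + beta_iT * (1 - pi),

where ``beta_iL`` is the leukocyte reference (mean over leukocyte reference
samples), ``beta_iT`` a pure-tumor surrogate, and ``pi`` the leukocyte
fraction.  Solving per locus gives pi_i = (beta_i - beta_iT) /
(beta_iL - beta_iT), clipped to [0, 1]; the sample's LF is the mode of a
Gaussian kernel density estimate of the per-locus solutions.

Informative loci are the CpGs most differentially methylated between normal
lung and leukocytes (default 2000, 1000 in each direction).  The pure-tumor
surrogate per locus is the tumor with the least evidence of leukocyte
methylation: the extreme beta value in the anti-leukocyte direction.

ssGSEA (single-sample gene set enrichment) scores a gene set against one
sample's expression ranking using the difference between an exponent-weighted
in-set ECDF and the out-of-set ECDF, summed over the ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LFModel",
    "LFEstimate",
    "select_lf_loci",
    "estimate_pure_tumor_reference",
    "estimate_leukocyte_fraction",
    "ssgsea_score",
    "LeukocyteFractionModel",
    "LeukocyteFractionResults",
]

LEUKOCYTE_HIGH = "leukocyte_high"
LEUKOCYTE_LOW = "leukocyte_low"


@dataclass
class LFModel:
    """Locus panel for the mixture model: leukocyte reference, pure-tumor
    surrogate and the direction of each locus."""

    loci: pd.Index
    beta_L: pd.Series
    beta_T: pd.Series | None
    direction: pd.Series  # LEUKOCYTE_HIGH / LEUKOCYTE_LOW per locus


@dataclass
class LFEstimate:
    per_locus_pi: np.ndarray
    lf: float
    n_loci_used: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.lf <= 1.0:
            raise ValueError("lf must lie in [0, 1]")


def select_lf_loci(
    normal_lung: pd.DataFrame,
    leukocyte: pd.DataFrame,
    n_per_direction: int = 1000,
) -> LFModel:
    """Pick the probes most differentially methylated between leukocytes and
    normal lung, ``n_per_direction`` in each direction, ranked by the
    difference of group means (leukocyte - lung)."""
    common = normal_lung.index.intersection(leukocyte.index)
    if len(common) == 0:
        raise ValueError("no shared probes between normal lung and leukocyte matrices")
    diff = leukocyte.loc[common].mean(axis=1) - normal_lung.loc[common].mean(axis=1)
    pos = diff[diff > 0].sort_values(ascending=False)
    neg = diff[diff < 0].sort_values(ascending=True)
    if len(pos) == 0 and len(neg) == 0:
        raise ValueError("no discriminating probes between leukocyte and normal lung")
    if len(pos) < n_per_direction or len(neg) < n_per_direction:
        warnings.warn(
            f"fewer discriminating probes than requested "
            f"({len(pos)} high, {len(neg)} low vs {n_per_direction} per direction); "
            "proceeding with all available",
            stacklevel=2,
        )
    high = pos.index[:n_per_direction]
    low = neg.index[:n_per_direction]
    loci = high.append(low)
    direction = pd.Series(
        [LEUKOCYTE_HIGH] * len(high) + [LEUKOCYTE_LOW] * len(low), index=loci
    )
    beta_L = leukocyte.loc[loci].mean(axis=1)
    return LFModel(loci=loci, beta_L=beta_L, beta_T=None, direction=direction)


def estimate_pure_tumor_reference(tumors: pd.DataFrame, model: LFModel) -> pd.Series:
    """Per-locus pure-tumor surrogate: the tumor beta value most distant from
    the leukocyte reference in the anti-leukocyte direction (min over tumors
    at leukocyte-high loci, max at leukocyte-low loci).  All-missing loci are
    dropped from the model."""
    if tumors.shape[1] < 1:
        raise ValueError("need at least one tumor sample")
    sub = tumors.reindex(model.loci)
    keep = ~sub.isna().all(axis=1)
    if not keep.all():
        model.loci = model.loci[keep]
        model.beta_L = model.beta_L[keep]
        model.direction = model.direction[keep]
        sub = sub.loc[model.loci]
    beta_T = pd.Series(index=model.loci, dtype=float)
    hi = model.direction == LEUKOCYTE_HIGH
    beta_T[hi] = sub.loc[model.loci[hi]].min(axis=1)
    beta_T[~hi] = sub.loc[model.loci[~hi]].max(axis=1)
    model.beta_T = beta_T
    return beta_T


def _kde_mode(values: np.ndarray, grid_step: float = 0.001) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) on a [0, 1] grid; ties and
    degenerate (near-constant) inputs resolve to the smallest candidate pi."""
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    if np.ptp(values) < 1e-12:
        return float(np.clip(values[0], 0.0, 1.0))
    kde = stats.gaussian_kde(values, bw_method="silverman")
    dens = kde(grid)
    return float(grid[int(np.argmax(dens))])  # argmax takes the first (smallest) tie


def estimate_leukocyte_fraction(
    sample: pd.Series,
    model: LFModel,
    spread_threshold: float = 0.05,
    min_loci: int = 50,
) -> LFEstimate:
    """Solve the mixture per locus and take the KDE mode as the sample's LF."""
    if model.beta_T is None:
        raise ValueError("model has no pure-tumor reference; run estimate_pure_tumor_reference")
    beta = sample.reindex(model.loci)
    spread = model.beta_L - model.beta_T
    usable = (~beta.isna()) & (spread.abs() >= spread_threshold)
    if usable.sum() < min_loci:
        raise ValueError(
            f"only {int(usable.sum())} usable loci (< {min_loci}); LF estimate unreliable"
        )
    pi = (beta[usable] - model.beta_T[usable]) / spread[usable]
    pi = np.clip(pi.to_numpy(dtype=float), 0.0, 1.0)
    lf = _kde_mode(pi)
    return LFEstimate(per_locus_pi=pi, lf=lf, n_loci_used=int(usable.sum()))


class LeukocyteFractionModel:
    """Methylation mixture-model LF deconvolution for a tumor cohort,
    statsmodels-style.

    Parameters
    ----------
    tumors : DataFrame
        probes x samples beta matrix of the tumors to deconvolve.
    normal_lung, leukocyte : DataFrame
        Reference beta matrices used to select informative loci; the
        leukocyte reference profile is the per-locus mean over its samples.
    n_per_direction : int
        Loci per direction (default 1000, i.e. a 2000-locus panel).
    """

    def __init__(
        self,
        tumors: pd.DataFrame,
        normal_lung: pd.DataFrame,
        leukocyte: pd.DataFrame,
        n_per_direction: int = 1000,
        spread_threshold: float = 0.05,
    ):
        self.tumors = tumors
        self.normal_lung = normal_lung
        self.leukocyte = leukocyte
        self.n_per_direction = n_per_direction
        self.spread_threshold = spread_threshold

    def fit(self) -> "LeukocyteFractionResults":
        model = select_lf_loci(self.normal_lung, self.leukocyte, self.n_per_direction)
        estimate_pure_tumor_reference(self.tumors, model)
        rows = []
        estimates = {}
        for s in self.tumors.columns:
            est = estimate_leukocyte_fraction(
                self.tumors[s], model, self.spread_threshold
            )
            estimates[s] = est
            rows.append({"sample": s, "lf": est.lf, "n_loci_used": est.n_loci_used})
        table = pd.DataFrame(rows).set_index("sample")
        return LeukocyteFractionResults(self, model, table, estimates)


class LeukocyteFractionResults:
    """Fitted LF deconvolution: per-sample leukocyte fractions."""

    def __init__(self, parent, model: LFModel, table: pd.DataFrame, estimates: dict):
        self.model_spec = parent
        self.locus_model = model
        self.table = table
        self.estimates = estimates

    @property
    def lf(self) -> pd.Series:
        return self.table["lf"]

    def summary(self) -> str:
        lines = [
            "Leukocyte fraction (methylation mixture model)",
            "==============================================",
            f"loci in panel:  {len(self.locus_model.loci)}",
            f"samples:        {len(self.table)}",
            "",
            self.table.to_string(float_format=lambda x: f"{x:.3f}"),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Per-locus pi densities with the LF mode marked, one line per sample."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        grid = np.linspace(0, 1, 501)
        for s, est in self.estimates.items():
            if np.ptp(est.per_locus_pi) >= 1e-12:
                kde = stats.gaussian_kde(est.per_locus_pi, bw_method="silverman")
                ax.plot(grid, kde(grid), label=s, alpha=0.7)
            ax.axvline(est.lf, ls=":", color="gray", alpha=0.5)
        ax.set_xlabel("per-locus leukocyte fraction")
        ax.set_ylabel("density")
        if len(self.estimates) <= 8:
            ax.legend(fontsize=8)
        return ax


def ssgsea_score(expr: pd.Series, gene_set: list[str] | set[str], alpha: float = 0.75) -> float:
    """Single-sample GSEA enrichment of ``gene_set`` in one expression vector.

    Genes are ranked by expression (descending; ties get average ranks).  The
    score is the running sum over the ranking of the difference between the
    in-set ECDF weighted by rank^alpha and the unweighted out-of-set ECDF.
    Positive scores mean the set is concentrated at the top of the ranking.
    """
    expr = expr.dropna()
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression vector contains non-finite values")
    in_set = expr.index.isin(set(gene_set))
    if not in_set.any():
        raise ValueError("gene set has empty intersection with the expression vector")
    n = len(expr)
    # rank 1 = lowest expression; order genes from highest to lowest
    ranks = stats.rankdata(expr.to_numpy(dtype=float), method="average")
    order = np.argsort(-ranks, kind="stable")
    ranks_sorted = ranks[order]
    in_sorted = in_set[order]
    w = np.abs(ranks_sorted) ** alpha
    w_in = np.where(in_sorted, w, 0.0)
    denom_in = w_in.sum()
    p_in = np.cumsum(w_in) / denom_in
    n_out = n - int(in_sorted.sum())
    if n_out == 0:
        p_out = np.zeros(n)
    else:
        p_out = np.cumsum(~in_sorted) / n_out
    return float(np.sum(p_in - p_out))
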