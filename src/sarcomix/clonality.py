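"""Clonality-index testing of common origin between paired tumor components.

Two microdissected components of one tumor are called clonally related when
the somatic mutations they share are collectively too improbable to co-occur
in two unrelated tumors.  For each shared mutation the chance of observing it
in both members of a random pair is the binomial term

    P(X) = C(n, k) p^k (1 - p)^(n - k),   n = 2, k = 2  =>  P(X) = p^2,

where ``p`` is the background probability that a random tumor from a
reference cohort carries that mutation.  The clonality index aggregates the
evidence over the M shared mutations:

    CI = -log10( prod_m P(X)_m ),

computed in log space so that M up to 1e4 with p down to 1e-6 cannot
underflow.  CI = 0 when nothing is shared; larger CI means stronger evidence
of a common clonal origin.

The decision cutoff is calibrated by resampling: positive-control pairs are
built by drawing 40/60/80% of each cohort sample's mutations twice
(two independent subsets of one tumor = a known-related pair), matched
negative-control pairs are random pairs of unrelated cohort samples, and the
threshold maximizing Youden's J over the pooled CI values is recorded.  The
whole procedure is repeated (default 100x) and the median cutoff with its
2.5/97.5 percentile interval is used to classify observed pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .catalogs import Mutation, MutationCatalog, ReferenceCohort

__all__ = [
    "BackgroundProb",
    "ClonalityResult",
    "CutoffCalibration",
    "BackgroundModel",
    "estimate_background_probability",
    "compute_clonality_index",
    "make_positive_control_pair",
    "make_negative_control_pairs",
    "calibrate_cutoff",
    "classify_relatedness",
    "pair_clonality",
    "ClonalityModel",
    "ClonalityResults",
]


@dataclass(frozen=True)
class BackgroundProb:
    """Background probability for one mutation.

    ``level`` records whether the estimate came from exact-variant (hotspot)
    recurrence or from gene-level recurrence.
    """

    key: str
    p: float
    level: str  # "hotspot" | "gene"

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"background probability must be in (0, 1], got {self.p}")


@dataclass
class ClonalityResult:
    M: int
    per_mutation_P: list[float]
    CI: float

    def __post_init__(self) -> None:
        if self.M != len(self.per_mutation_P):
            raise ValueError("M must equal the number of per-mutation P(X) values")
        if self.CI < 0 and not np.isclose(self.CI, 0.0):
            raise ValueError("CI must be nonnegative")


@dataclass
class CutoffCalibration:
    per_repeat_cutoffs: list[float]
    cutoff_median: float
    ci95: tuple[float, float]
    fractions: tuple[float, ...]
    repeats: int

    def __post_init__(self) -> None:
        if len(self.per_repeat_cutoffs) != self.repeats:
            raise ValueError("length of per_repeat_cutoffs must equal repeats")
        lo, hi = self.ci95
        if not (lo <= self.cutoff_median <= hi):
            raise ValueError("ci95 must bracket the median cutoff")


class BackgroundModel:
    """Precomputed gene- and variant-level recurrence counts for a cohort.

    p uses add-one smoothing, p = (c + 1) / (N + 1), where c is the number of
    cohort samples carrying the mutation: counted at exact-variant level when
    the identical (chrom, pos, ref, alt) recurs in the cohort (>= 2 samples),
    gene-level otherwise.
    """

    def __init__(self, cohort: ReferenceCohort, hotspot_min_recurrence: int = 2):
        self.N = cohort.N
        self.gene_counts = cohort.gene_sample_counts()
        self.key_counts = cohort.key_sample_counts()
        self.hotspot_min_recurrence = hotspot_min_recurrence

    def prob(self, mutation: Mutation) -> BackgroundProb:
        c_key = self.key_counts.get(mutation.key, 0)
        if c_key >= self.hotspot_min_recurrence:
            return BackgroundProb(
                key=":".join(map(str, mutation.key)), p=(c_key + 1) / (self.N + 1), level="hotspot"
            )
        if not mutation.gene:
            raise ValueError(
                f"mutation {mutation.key} has no gene annotation; "
                "gene-level background probability is undefined"
            )
        c_gene = self.gene_counts.get(mutation.gene, 0)
        return BackgroundProb(key=mutation.gene, p=(c_gene + 1) / (self.N + 1), level="gene")


def estimate_background_probability(mutation: Mutation, cohort: ReferenceCohort) -> BackgroundProb:
    """Background probability of one mutation under the cohort (see BackgroundModel)."""
    return BackgroundModel(cohort).prob(mutation)


def compute_clonality_index(shared: list[tuple[Mutation, BackgroundProb]]) -> ClonalityResult:
    """CI = -log10 prod_m p_m^2 over the shared mutations, in log space."""
    log10_P = []
    for _, bp in shared:
        if not 0.0 < bp.p <= 1.0:
            raise ValueError(f"p must be in (0, 1], got {bp.p}")
        log10_P.append(2.0 * np.log10(bp.p))  # log10 P(X) with P(X) = p^2
    ci = -float(np.sum(log10_P)) if log10_P else 0.0
    return ClonalityResult(
        M=len(shared),
        per_mutation_P=[float(10.0**lp) for lp in log10_P],
        CI=max(ci, 0.0),
    )


def _shared_mutations(a: MutationCatalog, b: MutationCatalog) -> list[Mutation]:
    keys_b = b.keys
    return [m for m in a if m.key in keys_b]


def pair_clonality(
    a: MutationCatalog, b: MutationCatalog, background: BackgroundModel
) -> ClonalityResult:
    """Clonality index of a pair of catalogs under a background model."""
    shared = _shared_mutations(a, b)
    return compute_clonality_index([(m, background.prob(m)) for m in shared])


def make_positive_control_pair(
    catalog: MutationCatalog,
    fraction: float,
    rng: np.random.Generator,
) -> tuple[MutationCatalog, MutationCatalog]:
    """Two independent uniform subsets of one catalog, each of size
    round(fraction * |catalog|); a known clonally-related pseudo-pair."""
    if len(catalog) == 0:
        raise ValueError("cannot draw positive controls from an empty catalog")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    size = int(round(fraction * len(catalog)))
    muts = list(catalog.mutations)
    subsets = []
    for rep in ("a", "b"):
        idx = rng.choice(len(muts), size=size, replace=False)
        subsets.append(
            MutationCatalog(
                sample_id=f"{catalog.sample_id}|pos{int(fraction*100)}{rep}",
                mutations=[muts[i] for i in sorted(idx)],
            )
        )
    return subsets[0], subsets[1]


def make_negative_control_pairs(
    cohort: ReferenceCohort, n_pairs: int, rng: np.random.Generator
) -> list[tuple[MutationCatalog, MutationCatalog]]:
    """n_pairs distinct unordered pairs of different cohort samples."""
    all_pairs = list(itertools.combinations(range(cohort.N), 2))
    if n_pairs > len(all_pairs):
        raise ValueError(f"n_pairs={n_pairs} exceeds C({cohort.N},2)={len(all_pairs)}")
    idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    return [(cohort.catalogs[all_pairs[i][0]], cohort.catalogs[all_pairs[i][1]]) for i in sorted(idx)]


def youden_optimal_cutoff(positives: np.ndarray, negatives: np.ndarray) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    A pair is called positive when its CI is strictly above the threshold.
    Candidate thresholds are the midpoints between consecutive distinct
    pooled CI values; ties in J break toward the larger threshold (favoring
    specificity).
    """
    pooled = np.unique(np.concatenate([positives, negatives]))
    if len(pooled) < 2:
        raise ValueError("all CI values identical: cutoff undefined")
    candidates = (pooled[:-1] + pooled[1:]) / 2.0
    best_t, best_j = None, -np.inf
    for t in candidates:
        sens = float(np.mean(positives > t))
        spec = float(np.mean(negatives <= t))
        j = sens + spec - 1.0
        if j >= best_j:  # >= : ties break toward the larger threshold
            best_j, best_t = j, float(t)
    return best_t


def _one_repeat_cis(
    cohort: ReferenceCohort,
    background: BackgroundModel,
    fractions: tuple[float, ...],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    pos_cis = []
    for cat in cohort:
        if len(cat) == 0:
            continue
        for frac in fractions:
            a, b = make_positive_control_pair(cat, frac, rng)
            pos_cis.append(pair_clonality(a, b, background).CI)
    n_pairs = min(len(pos_cis), len(list(itertools.combinations(range(cohort.N), 2))))
    neg_pairs = make_negative_control_pairs(cohort, n_pairs, rng)
    neg_cis = [pair_clonality(a, b, background).CI for a, b in neg_pairs]
    return np.asarray(pos_cis), np.asarray(neg_cis)


def calibrate_cutoff(
    cohort: ReferenceCohort,
    fractions: tuple[float, ...] = (0.4, 0.6, 0.8),
    repeats: int = 100,
    seed: int | np.random.Generator = 0,
    background: BackgroundModel | None = None,
) -> CutoffCalibration:
    """Resampling calibration of the CI cutoff (one pooled cutoff per repeat)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if background is None:
        background = BackgroundModel(cohort)
    cutoffs = []
    for _ in range(repeats):
        pos, neg = _one_repeat_cis(cohort, background, tuple(fractions), rng)
        cutoffs.append(youden_optimal_cutoff(pos, neg))
    arr = np.asarray(cutoffs)
    return CutoffCalibration(
        per_repeat_cutoffs=[float(c) for c in cutoffs],
        cutoff_median=float(np.median(arr)),
        ci95=(float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5))),
        fractions=tuple(fractions),
        repeats=repeats,
    )


def classify_relatedness(ci: ClonalityResult, calibration: CutoffCalibration) -> dict:
    """Clonal iff CI strictly exceeds the median calibrated cutoff."""
    lo, hi = calibration.ci95
    return {
        "call": "clonal" if ci.CI > calibration.cutoff_median else "not_clonal",
        "CI": ci.CI,
        "M": ci.M,
        "cutoff_median": calibration.cutoff_median,
        "above_ci95_upper": bool(ci.CI > hi),
        "below_ci95_lower": bool(ci.CI < lo),
    }


class ClonalityModel:
    """Clonality analysis of one tumor pair against a reference cohort,
    statsmodels-style: construct from data, ``fit()`` returns results.

    Parameters
    ----------
    pair : (MutationCatalog, MutationCatalog)
        The two microdissected components.
    cohort : ReferenceCohort
        Unrelated tumors supplying background mutation probabilities and the
        material for cutoff calibration.
    fractions, repeats
        Calibration settings (see :func:`calibrate_cutoff`).
    """

    def __init__(
        self,
        pair: tuple[MutationCatalog, MutationCatalog],
        cohort: ReferenceCohort,
        fractions: tuple[float, ...] = (0.4, 0.6, 0.8),
        repeats: int = 100,
    ):
        self.pair = pair
        self.cohort = cohort
        self.fractions = tuple(fractions)
        self.repeats = repeats
        self.background = BackgroundModel(cohort)

    def fit(self, seed: int = 0) -> "ClonalityResults":
        calibration = calibrate_cutoff(
            self.cohort, self.fractions, self.repeats, seed, self.background
        )
        ci = pair_clonality(self.pair[0], self.pair[1], self.background)
        return ClonalityResults(self, ci, calibration)


class ClonalityResults:
    """Fitted clonality analysis: CI, calibrated cutoff and the call."""

    def __init__(self, model: ClonalityModel, ci: ClonalityResult, calibration: CutoffCalibration):
        self.model = model
        self.ci = ci
        self.calibration = calibration
        self.classification = classify_relatedness(ci, calibration)

    @property
    def call(self) -> str:
        return self.classification["call"]

    def summary(self) -> str:
        a, b = self.model.pair
        lo, hi = self.calibration.ci95
        lines = [
            "Clonality analysis",
            "==================",
            f"pair:            {a.sample_id} vs {b.sample_id}",
            f"shared (M):      {self.ci.M}",
            f"CI:              {self.ci.CI:.4f}",
            f"cutoff (median): {self.calibration.cutoff_median:.4f}",
            f"cutoff 95% CI:   [{lo:.4f}, {hi:.4f}]",
            f"repeats:         {self.calibration.repeats}"
            f"  fractions: {', '.join(f'{f:g}' for f in self.calibration.fractions)}",
            f"call:            {self.call}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar of the pair's CI against the calibrated cutoff band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.bar([0], [self.ci.CI], color="#4C72B0", width=0.5)
        ax.axhline(self.calibration.cutoff_median, color="k", ls="--", label="cutoff (median)")
        lo, hi = self.calibration.ci95
        ax.axhspan(lo, hi, color="gray", alpha=0.3, label="cutoff 95% CI")
        ax.set_xticks([0])
        a, b = self.model.pair
        ax.set_xticklabels([f"{a.sample_id}\nvs {b.sample_id}"])
        ax.set_ylabel("clonality index")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            **self.classification,
            "ci95": list(self.calibration.ci95),
            "fractions": list(self.calibration.fractions),
            "repeats": self.calibration.repeats,
        }
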