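"""Seeded synthetic data with known ground truth for every analysis stage.

These generators emulate the structure the analyses assume — a reference
cohort of unrelated mutation catalogs with long-tailed gene recurrence,
paired tumor components with a controllable shared-mutation fraction,
methylation beta matrices formed as leukocyte / pure-tumor mixtures with a
known mixing fraction, expression matrices with planted subtype centroids,
an EMT axis and an infiltration-signature gradient, and paired CNV segment
sets with a controllable same-state overlap.

Every generator takes an explicit seed (or Generator) and is bit-reproducible
for a fixed seed.  Planted parameters are returned as a separate ground-truth
mapping (written to a sidecar file by the pipeline) so that analysis stages
can never read them from the data themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalogs import (
    GAIN,
    LOSS,
    NONSYNONYMOUS,
    SYNONYMOUS,
    Mutation,
    MutationCatalog,
    ReferenceCohort,
    SegmentSet,
)

__all__ = [
    "GeneratorConfig",
    "default_gene_frequencies",
    "generate_reference_cohort",
    "generate_paired_components",
    "generate_methylation_mixture",
    "generate_lf_dataset",
    "make_default_centroids",
    "make_emt_signature",
    "make_li_signature",
    "generate_expression_with_structure",
    "generate_cnv_pair",
    "generate_methylation_cluster_cohort",
]

_BASES = np.array(list("ACGT"))


@dataclass
class GeneratorConfig:
    """Bundle of generator settings plus the planted ground truth.

    Identical configs (same seed included) produce bit-identical synthetic
    data; ``ground_truth`` fully determines the planted signal and is meant
    for sidecar serialization only.
    """

    seed: int = 0
    n_genes: int = 200
    n_samples: int = 30
    noise_sd: float = 0.03
    effect_size: float = 2.0
    ground_truth: dict = field(default_factory=dict)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def default_gene_frequencies(n_genes: int = 200) -> pd.Series:
    """Long-tailed per-gene recurrence spec: a handful of frequently mutated
    genes and a long tail of rare ones (configuration, not a biological
    claim)."""
    idx = np.arange(n_genes)
    freq = np.minimum(0.6, 0.9 / (idx + 1.5) ** 0.8)
    freq = np.maximum(freq, 0.02)
    return pd.Series(freq, index=[f"G{i:04d}" for i in idx])


def _gene_coords(gene: str, gene_index: int) -> tuple[str, int, int]:
    """Deterministic synthetic locus for a gene: chromosome and a 10 kb window."""
    chrom = f"chr{(gene_index % 22) + 1}"
    start = 1 + 100_000 * (gene_index + 1)
    return chrom, start, start + 10_000


def _random_snv(rng: np.random.Generator) -> tuple[str, str]:
    ref = rng.choice(_BASES)
    alt = rng.choice(_BASES[_BASES != ref])
    return str(ref), str(alt)


def generate_reference_cohort(
    n_samples: int,
    gene_freq_spec: pd.Series | dict | None = None,
    muts_per_sample: float = 180.0,
    seed: int | np.random.Generator = 0,
    nonsyn_fraction: float = 0.7,
) -> ReferenceCohort:
    """Cohort of unrelated mutation catalogs.

    Each gene in ``gene_freq_spec`` is mutated independently per sample with
    its stated probability (one variant at a random position inside the
    gene's synthetic window).  An additional Poisson(``muts_per_sample``)
    count of passenger mutations per sample carries private gene symbols, so
    unrelated catalogs share no mutation keys except by rare coincidence.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if gene_freq_spec is None:
        gene_freq_spec = default_gene_frequencies()
    freqs = pd.Series(gene_freq_spec, dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        bad = freqs[(freqs < 0) | (freqs > 1)]
        raise ValueError(f"gene frequencies must lie in [0, 1]; offending: {dict(bad.head())}")
    rng = _rng(seed)
    gene_list = list(freqs.index)
    catalogs = []
    for s in range(n_samples):
        muts: dict = {}
        present = rng.random(len(freqs)) < freqs.to_numpy()
        for gi, gene in enumerate(gene_list):
            if not present[gi]:
                continue
            chrom, lo, hi = _gene_coords(gene, gi)
            pos = int(rng.integers(lo, hi))
            ref, alt = _random_snv(rng)
            effect = NONSYNONYMOUS if rng.random() < nonsyn_fraction else SYNONYMOUS
            m = Mutation(chrom, pos, ref, alt, gene, effect)
            muts[m.key] = m
        for _ in range(int(rng.poisson(muts_per_sample))):
            gi = int(rng.integers(0, 10_000))
            gene = f"P{gi:05d}"
            chrom = f"chr{int(rng.integers(1, 23))}"
            pos = int(rng.integers(50_000_000, 250_000_000))
            ref, alt = _random_snv(rng)
            effect = NONSYNONYMOUS if rng.random() < nonsyn_fraction else SYNONYMOUS
            m = Mutation(chrom, pos, ref, alt, gene, effect)
            muts[m.key] = m
        catalogs.append(MutationCatalog(sample_id=f"S{s:03d}", mutations=list(muts.values())))
    return ReferenceCohort(catalogs=catalogs)


def generate_paired_components(
    n_total: int,
    shared_fraction: float,
    cohort: ReferenceCohort | None = None,
    seed: int | np.random.Generator = 0,
    nonsyn_fraction: float = 0.7,
) -> tuple[MutationCatalog, MutationCatalog, dict]:
    """Paired epithelial/sarcomatoid catalogs with a planted shared fraction.

    The union holds ``n_total`` mutations of which round(shared_fraction *
    n_total) are identical by (chrom, pos, ref, alt) in both components; the
    rest are split between the two components as private mutations.  Gene
    symbols are drawn from the cohort's gene universe when one is supplied,
    so background probabilities exist for every shared mutation.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    rng = _rng(seed)
    if cohort is not None:
        gene_pool = sorted({g for c in cohort for g in c.genes()})
    else:
        gene_pool = [f"G{i:04d}" for i in range(500)]
    n_shared = int(round(shared_fraction * n_total))
    muts: dict = {}
    while len(muts) < n_total:
        gene = gene_pool[int(rng.integers(0, len(gene_pool)))]
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos = int(rng.integers(1_000_000, 250_000_000))
        ref, alt = _random_snv(rng)
        effect = NONSYNONYMOUS if rng.random() < nonsyn_fraction else SYNONYMOUS
        m = Mutation(chrom, pos, ref, alt, gene, effect)
        muts[m.key] = m
    pool = list(muts.values())
    order = rng.permutation(n_total)
    shared = [pool[i] for i in order[:n_shared]]
    rest = [pool[i] for i in order[n_shared:]]
    spec_a, spec_b = rest[::2], rest[1::2]
    a = MutationCatalog("epithelial", shared + spec_a)
    b = MutationCatalog("sarcomatoid", shared + spec_b)
    truth = {
        "shared_fraction": shared_fraction,
        "n_total": n_total,
        "n_shared": n_shared,
        "n_specific_a": len(spec_a),
        "n_specific_b": len(spec_b),
    }
    return a, b, truth


def generate_methylation_mixture(
    n_loci: int,
    pi_true: float,
    leukocyte_profile: np.ndarray,
    tumor_profile: np.ndarray,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One beta column: clip(beta_L * pi + beta_T * (1 - pi) + eps, 0, 1)."""
    bl = np.asarray(leukocyte_profile, dtype=float)
    bt = np.asarray(tumor_profile, dtype=float)
    if bl.shape != bt.shape or len(bl) != n_loci:
        raise ValueError("profile length mismatch")
    rng = _rng(seed)
    eps = rng.normal(0.0, noise_sd, size=n_loci) if noise_sd > 0 else np.zeros(n_loci)
    return np.clip(bl * pi_true + bt * (1.0 - pi_true) + eps, 0.0, 1.0)


def generate_lf_dataset(
    pis: list[float],
    n_loci: int = 2000,
    noise_sd: float = 0.03,
    n_leukocyte: int = 6,
    n_lung: int = 6,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Complete LF-deconvolution input set with known mixing fractions.

    Builds a leukocyte reference panel (``n_leukocyte`` donors), a normal-lung
    panel, and one tumor column per entry of ``pis`` mixed from a common pure
    tumor profile.  Half the loci are leukocyte-high, half leukocyte-low.
    Returns dict with 'tumors', 'leukocyte', 'normal_lung' DataFrames and the
    ground truth mapping.
    """
    rng = _rng(seed)
    half = n_loci // 2
    loci = [f"cg{i:07d}" for i in range(n_loci)]
    beta_L = np.concatenate([rng.uniform(0.7, 0.95, half), rng.uniform(0.05, 0.3, n_loci - half)])
    beta_T = np.concatenate([rng.uniform(0.05, 0.3, half), rng.uniform(0.7, 0.95, n_loci - half)])

    def panel(profile: np.ndarray, n: int, prefix: str) -> pd.DataFrame:
        cols = {
            f"{prefix}{j}": np.clip(profile + rng.normal(0, noise_sd, n_loci), 0, 1)
            for j in range(n)
        }
        return pd.DataFrame(cols, index=loci)

    leukocyte = panel(beta_L, n_leukocyte, "PBMC")
    # normal lung approximates the tumor-side methylation state at these loci
    normal_lung = panel(beta_T, n_lung, "LUNG")
    tumors = {}
    for j, pi in enumerate(pis):
        tumors[f"T{j:02d}"] = generate_methylation_mixture(
            n_loci, pi, beta_L, beta_T, noise_sd, rng
        )
    return {
        "tumors": pd.DataFrame(tumors, index=loci),
        "leukocyte": leukocyte,
        "normal_lung": normal_lung,
        "ground_truth": {"pi_true": {f"T{j:02d}": float(pi) for j, pi in enumerate(pis)}},
    }


def make_default_centroids(
    n_genes: int = 500,
    subtypes: tuple[str, ...] = ("primitive", "classical", "secretory", "basal"),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Random subtype predictor centroids on the log2 scale."""
    rng = _rng(seed)
    genes = [f"EG{i:04d}" for i in range(n_genes)]
    return pd.DataFrame(
        rng.uniform(2.0, 10.0, size=(n_genes, len(subtypes))), index=genes, columns=list(subtypes)
    )


def make_emt_signature(n_epithelial: int = 38, n_mesenchymal: int = 38) -> pd.Series:
    """Synthetic stand-in for a 76-gene E/M signature; VIM is mesenchymal."""
    genes = [f"EPI{i:02d}" for i in range(n_epithelial)]
    genes += ["VIM"] + [f"MES{i:02d}" for i in range(n_mesenchymal - 1)]
    labels = ["epithelial"] * n_epithelial + ["mesenchymal"] * n_mesenchymal
    return pd.Series(labels, index=genes, name="label")


def make_li_signature(n_genes: int = 18) -> list[str]:
    """Synthetic stand-in for the 18-gene lymphocyte-infiltration signature."""
    return [f"LI{i:02d}" for i in range(n_genes)]


def generate_expression_with_structure(
    centroids: pd.DataFrame,
    labels: list[str],
    emt_signature: pd.Series | None = None,
    emt_shift: float = 0.0,
    emt_samples: list[int] | None = None,
    li_signature: list[str] | None = None,
    infiltration_level: list[float] | None = None,
    noise_sd: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict]:
    """Expression matrix (linear scale) with planted subtype, EMT and
    infiltration structure.

    Per sample: log2 profile = its subtype centroid, plus ``emt_shift`` on
    the mesenchymal signature genes for samples listed in ``emt_samples``,
    plus ``infiltration_level[s]`` on the infiltration signature genes, plus
    Gaussian noise.  Signature genes absent from the centroid index are
    appended with a baseline of 4 log-units.
    """
    unknown = set(labels) - set(centroids.columns)
    if unknown:
        raise ValueError(f"unknown subtype labels: {sorted(unknown)}")
    rng = _rng(seed)
    genes = list(centroids.index)
    extra = []
    if emt_signature is not None:
        extra += [g for g in emt_signature.index if g not in centroids.index]
    if li_signature is not None:
        extra += [g for g in li_signature if g not in centroids.index and g not in extra]
    all_genes = genes + extra
    base_extra = pd.Series(4.0, index=extra, dtype=float)
    emt_samples = set(emt_samples or [])
    cols = {}
    for s, lab in enumerate(labels):
        v = pd.concat([centroids[lab].astype(float), base_extra])
        if emt_signature is not None and emt_shift != 0.0 and s in emt_samples:
            mes = emt_signature[emt_signature == "mesenchymal"].index
            v.loc[v.index.intersection(mes)] += emt_shift
        if li_signature is not None and infiltration_level is not None:
            v.loc[v.index.intersection(pd.Index(li_signature))] += infiltration_level[s]
        v = v + rng.normal(0.0, noise_sd, len(v)) if noise_sd > 0 else v
        cols[f"X{s:03d}"] = np.maximum(np.exp2(v) - 1.0, 0.0)
    expr = pd.DataFrame(cols, index=all_genes)
    truth = {
        "labels": {f"X{s:03d}": lab for s, lab in enumerate(labels)},
        "emt_samples": sorted(f"X{s:03d}" for s in emt_samples),
        "infiltration_level": (
            {f"X{s:03d}": float(x) for s, x in enumerate(infiltration_level)}
            if infiltration_level is not None
            else None
        ),
    }
    return expr, truth


def generate_cnv_pair(
    genome_length: int,
    target_shared_pct: float,
    seed: int | np.random.Generator = 0,
    n_pieces: int = 8,
    covered_fraction: float = 0.3,
) -> tuple[SegmentSet, SegmentSet, dict]:
    """Paired CNV segment sets whose same-state shared percentage equals the
    target (exactly, by construction, up to integer rounding of lengths).

    A union footprint of ``covered_fraction * genome_length`` bases is split
    into a shared block (same state in both samples) and two private blocks,
    each scattered into disjoint pieces along the genome.
    """
    if not 0.0 <= target_shared_pct <= 100.0:
        raise ValueError("target_shared_pct must lie in [0, 100]")
    rng = _rng(seed)
    union_len = max(int(covered_fraction * genome_length), 100)
    shared_len = int(round(target_shared_pct / 100.0 * union_len))
    spec_len = union_len - shared_len
    spec_a_len, spec_b_len = spec_len // 2, spec_len - spec_len // 2

    def split(total: int) -> list[int]:
        if total <= 0:
            return []
        k = min(n_pieces, total)
        cuts = np.sort(rng.choice(np.arange(1, total), size=k - 1, replace=False)) if k > 1 else []
        bounds = np.concatenate([[0], cuts, [total]])
        return list(np.diff(bounds).astype(int))

    pieces = (
        [("shared", ln) for ln in split(shared_len)]
        + [("a", ln) for ln in split(spec_a_len)]
        + [("b", ln) for ln in split(spec_b_len)]
    )
    rng.shuffle(pieces)
    gap_total = genome_length - union_len
    gaps = rng.multinomial(gap_total, np.ones(len(pieces) + 1) / (len(pieces) + 1))
    rows_a, rows_b = [], []
    cursor = 0
    for (kind, ln), gap in zip(pieces, gaps):
        cursor += int(gap) + 1  # at least 1-base gap so distinct pieces never merge
        start, end = cursor, cursor + ln
        state = GAIN if rng.random() < 0.5 else LOSS
        if kind == "shared":
            rows_a.append(("chr1", start, end, state))
            rows_b.append(("chr1", start, end, state))
        elif kind == "a":
            rows_a.append(("chr1", start, end, state))
        else:
            rows_b.append(("chr1", start, end, state))
        cursor = end
    cols = ["chrom", "start", "end", "state"]
    a = SegmentSet("epithelial", pd.DataFrame(rows_a, columns=cols))
    b = SegmentSet("sarcomatoid", pd.DataFrame(rows_b, columns=cols))
    truth = {
        "target_shared_pct": target_shared_pct,
        "union_length": union_len,
        "shared_length": shared_len,
    }
    return a, b, truth


def generate_methylation_cluster_cohort(
    n_probes: int = 1000,
    n_per_cluster: int = 10,
    n_clusters: int = 3,
    separation: float = 0.35,
    noise_sd: float = 0.03,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict]:
    """Tumor beta matrix with planted methylation clusters.

    Each cluster has its own baseline beta profile; within-cluster samples
    are that profile plus truncated Gaussian noise.  ``separation`` sets the
    typical per-probe distance between cluster baselines.
    """
    rng = _rng(seed)
    probes = [f"cg{i:07d}" for i in range(n_probes)]
    centers = []
    for _ in range(n_clusters):
        base = rng.uniform(0.1, 0.9 - separation, n_probes)
        shift = rng.random(n_probes) < 0.5
        centers.append(np.where(shift, base + separation, base))
    cols, truth = {}, {}
    s = 0
    for c in range(n_clusters):
        for _ in range(n_per_cluster):
            name = f"M{s:03d}"
            cols[name] = np.clip(centers[c] + rng.normal(0, noise_sd, n_probes), 0, 1)
            truth[name] = f"cluster{c + 1}"
            s += 1
    return pd.DataFrame(cols, index=probes), {"cluster": truth}
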