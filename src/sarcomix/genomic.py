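"""Genomic summary statistics for paired tumor components.

Covers tumor mutation burden, shared/specific mutation partitioning, CNV
overlap between components, the two-leaf trunk/branch phylogeny and a
Monte-Carlo mutual-exclusivity test for gene mutation patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogs import (
    GAIN,
    LOSS,
    NONSYNONYMOUS,
    MutationCatalog,
    SegmentSet,
    _merge_intervals,
    _overlap_length,
)

__all__ = [
    "compute_tmb",
    "PartitionResult",
    "partition_mutations",
    "cnv_shared_percentage",
    "build_phylogenetic_tree",
    "mutual_exclusivity_test",
]


def compute_tmb(catalog: MutationCatalog, region_size_mb: float) -> float:
    """Tumor mutation burden: somatic SNVs + indels per megabase of the
    interrogated coding region (the denominator is an explicit parameter —
    e.g. the total target length of the capture design)."""
    if region_size_mb <= 0:
        raise ValueError("region_size_mb must be positive")
    return len(catalog) / region_size_mb


@dataclass
class PartitionResult:
    """Shared/specific partition of two catalogs' mutations.

    Identity is (chrom, pos, ref, alt); ``shared_pct`` = 100 * |shared| /
    |union| (0 with ``empty_union`` flagged when both catalogs are empty).
    """

    shared: list
    specific_a: list
    specific_b: list
    shared_pct: float
    empty_union: bool = False

    @property
    def n_union(self) -> int:
        return len(self.shared) + len(self.specific_a) + len(self.specific_b)


def partition_mutations(a: MutationCatalog, b: MutationCatalog) -> PartitionResult:
    keys_a, keys_b = a.keys, b.keys
    shared_keys = keys_a & keys_b
    shared = [m for m in a if m.key in shared_keys]
    specific_a = [m for m in a if m.key not in shared_keys]
    specific_b = [m for m in b if m.key not in shared_keys]
    n_union = len(shared) + len(specific_a) + len(specific_b)
    if n_union == 0:
        return PartitionResult([], [], [], 0.0, empty_union=True)
    return PartitionResult(
        shared, specific_a, specific_b, 100.0 * len(shared) / n_union
    )


def cnv_shared_percentage(a: SegmentSet, b: SegmentSet) -> float:
    """Percentage of same-state CNV length shared by two components relative
    to the aggregated CNV length of their union.

    shared = gain-with-gain overlap + loss-with-loss overlap; union = bases
    covered by any CNV in either sample.  Both empty => 0.
    """
    shared = 0
    for state in (GAIN, LOSS):
        cov_a, cov_b = a.covered(state), b.covered(state)
        for chrom in set(cov_a) & set(cov_b):
            shared += _overlap_length(cov_a[chrom], cov_b[chrom])
    union = 0
    both = pd.concat([a.segments, b.segments], ignore_index=True)
    if len(both) == 0:
        return 0.0
    for _, grp in both.groupby("chrom"):
        merged = _merge_intervals(grp[["start", "end"]].to_numpy(dtype=np.int64))
        union += int((merged[:, 1] - merged[:, 0]).sum())
    return 100.0 * shared / union


def build_phylogenetic_tree(
    partition: PartitionResult,
    leaf_a: str = "E",
    leaf_b: str = "S",
    restrict_to: str | None = NONSYNONYMOUS,
) -> str:
    """Two-leaf Newick tree with trunk = shared count and branches = specific
    counts (default restricted to nonsynonymous mutations, matching the
    convention of trunk/branch mutation trees)."""

    def _count(muts) -> int:
        if restrict_to is None:
            return len(muts)
        return sum(1 for m in muts if m.effect == restrict_to)

    trunk = _count(partition.shared)
    ba = _count(partition.specific_a)
    bb = _count(partition.specific_b)
    return f"({leaf_a}:{ba},{leaf_b}:{bb}):{trunk};"


def mutual_exclusivity_test(
    matrix: pd.DataFrame,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Monte-Carlo mutual-exclusivity test on a genes x samples 0/1 matrix.

    The observed statistic is the number of samples mutated in >= 2 of the
    genes.  The null permutes each gene's sample assignments independently
    (preserving per-gene mutation counts and the sample count); exclusivity
    is supported by small overlap, so p = (1 + #{permutations with overlap
    <= observed}) / (n_perm + 1).
    """
    if matrix.shape[0] < 2:
        raise ValueError("mutual exclusivity needs at least 2 genes")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = (matrix.to_numpy() != 0).astype(np.int8)
    n_genes, n_samples = x.shape
    observed = int((x.sum(axis=0) >= 2).sum())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = x.sum(axis=1)
    hits = 0
    perm = np.zeros((n_genes, n_samples), dtype=np.int8)
    for _ in range(n_perm):
        perm[:] = 0
        for g in range(n_genes):
            idx = rng.choice(n_samples, size=counts[g], replace=False)
            perm[g, idx] = 1
        if int((perm.sum(axis=0) >= 2).sum()) <= observed:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return {"observed_overlap": observed, "p": float(p), "n_perm": int(n_perm)}
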