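"""Core domain containers: mutation catalogs, reference cohorts, CNV segments.

Mutation identity is the tuple ``(chrom, pos, ref, alt)``; the gene symbol and
effect class are annotations, never part of identity.  Point mutations use
1-based coordinates (MAF/VCF convention); CNV segments use 0-based half-open
intervals (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

NONSYNONYMOUS = "nonsynonymous"
SYNONYMOUS = "synonymous"

MutationKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class Mutation:
    """A somatic point mutation or small indel.

    Attributes
    ----------
    chrom, pos, ref, alt
        Genomic identity of the variant (1-based position).
    gene
        Annotated gene symbol ("" if intergenic / unannotated).
    effect
        Effect class: ``nonsynonymous``, ``synonymous`` or ``other``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    effect: str = NONSYNONYMOUS

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref!r}")

    @property
    def key(self) -> MutationKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class MutationCatalog:
    """Set of somatic mutations for one sample (duplicate keys rejected)."""

    sample_id: str
    mutations: list[Mutation] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [m.key for m in self.mutations]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate mutation keys in catalog {self.sample_id!r}")

    def __len__(self) -> int:
        return len(self.mutations)

    def __iter__(self) -> Iterator[Mutation]:
        return iter(self.mutations)

    @property
    def keys(self) -> set[MutationKey]:
        return {m.key for m in self.mutations}

    def genes(self) -> set[str]:
        return {m.gene for m in self.mutations if m.gene}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample": self.sample_id,
                    "chrom": m.chrom,
                    "pos": m.pos,
                    "ref": m.ref,
                    "alt": m.alt,
                    "gene": m.gene,
                    "effect": m.effect,
                }
                for m in self.mutations
            ],
            columns=["sample", "chrom", "pos", "ref", "alt", "gene", "effect"],
        )


@dataclass
class ReferenceCohort:
    """Collection of unrelated mutation catalogs used for background rates."""

    catalogs: list[MutationCatalog]

    def __post_init__(self) -> None:
        if len(self.catalogs) < 2:
            raise ValueError("a reference cohort needs at least 2 catalogs")
        ids = [c.sample_id for c in self.catalogs]
        if len(ids) != len(set(ids)):
            raise ValueError("cohort sample_ids must be unique")

    @property
    def N(self) -> int:
        return len(self.catalogs)

    def __iter__(self) -> Iterator[MutationCatalog]:
        return iter(self.catalogs)

    def gene_sample_counts(self) -> dict[str, int]:
        """Number of cohort samples carrying >=1 mutation in each gene."""
        counts: dict[str, int] = {}
        for cat in self.catalogs:
            for g in cat.genes():
                counts[g] = counts.get(g, 0) + 1
        return counts

    def key_sample_counts(self) -> dict[MutationKey, int]:
        """Number of cohort samples carrying each exact variant."""
        counts: dict[MutationKey, int] = {}
        for cat in self.catalogs:
            for k in cat.keys:
                counts[k] = counts.get(k, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        frames = [c.to_frame() for c in self.catalogs]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


GAIN = "gain"
LOSS = "loss"


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent [start, end) intervals (n x 2 int array)."""
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0])]
    merged = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def _overlap_length(iv_a: np.ndarray, iv_b: np.ndarray) -> int:
    """Total overlap of two merged, sorted interval lists (each n x 2)."""
    total, i, j = 0, 0, 0
    while i < len(iv_a) and j < len(iv_b):
        lo = max(iv_a[i, 0], iv_b[j, 0])
        hi = min(iv_a[i, 1], iv_b[j, 1])
        if lo < hi:
            total += int(hi - lo)
        if iv_a[i, 1] < iv_b[j, 1]:
            i += 1
        else:
            j += 1
    return total


@dataclass
class SegmentSet:
    """Per-sample copy-number segments; same-state segments per chromosome are
    merged on construction so invariants (disjoint, start < end) always hold."""

    sample_id: str
    segments: pd.DataFrame  # columns: chrom, start, end, state

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.segments, columns=["chrom", "start", "end", "state"])
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("malformed interval: start must be < end")
        if len(df) and ~df["state"].isin([GAIN, LOSS]).all():
            raise ValueError("segment state must be 'gain' or 'loss'")
        rows = []
        for (chrom, state), grp in df.groupby(["chrom", "state"], sort=True):
            iv = _merge_intervals(grp[["start", "end"]].to_numpy(dtype=np.int64))
            for s, e in iv:
                rows.append((chrom, int(s), int(e), state))
        self.segments = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
        # one locus cannot be both gained and lost in the same sample
        for chrom, grp in self.segments.groupby("chrom"):
            gain = grp[grp["state"] == GAIN][["start", "end"]].to_numpy(dtype=np.int64)
            loss = grp[grp["state"] == LOSS][["start", "end"]].to_numpy(dtype=np.int64)
            if len(gain) and len(loss) and _overlap_length(gain, loss) > 0:
                raise ValueError(
                    f"conflicting gain/loss states overlap on {chrom} "
                    f"in sample {self.sample_id!r}"
                )

    def covered(self, state: str) -> dict[str, np.ndarray]:
        """Merged intervals of the given state keyed by chromosome."""
        out: dict[str, np.ndarray] = {}
        sel = self.segments[self.segments["state"] == state]
        for chrom, grp in sel.groupby("chrom"):
            out[chrom] = grp[["start", "end"]].to_numpy(dtype=np.int64)
        return out

    def total_length(self) -> int:
        return int((self.segments["end"] - self.segments["start"]).sum())


def catalog_from_frame(df: pd.DataFrame, sample_id: str | None = None) -> MutationCatalog:
    """Build a MutationCatalog from a MAF-like DataFrame (one sample)."""
    if sample_id is None:
        ids = df["sample"].unique()
        if len(ids) != 1:
            raise ValueError("frame holds multiple samples; pass sample_id")
        sample_id = str(ids[0])
    else:
        if "sample" in df.columns:
            df = df[df["sample"] == sample_id]
    muts = [
        Mutation(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            gene="" if pd.isna(r.gene) else str(r.gene),
            effect=str(r.effect),
        )
        for r in df.itertuples()
    ]
    return MutationCatalog(sample_id=sample_id, mutations=muts)


def cohort_from_frame(df: pd.DataFrame) -> ReferenceCohort:
    cats = [catalog_from_frame(grp, str(sid)) for sid, grp in df.groupby("sample", sort=True)]
    return ReferenceCohort(catalogs=cats)
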