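"""Readers and writers for the package's plain-text formats.

All tables are UTF-8 tab-separated files with '.' decimal and ``NA`` for
missing values.  Conventions:

* mutation TSV — MAF-like columns ``sample, chrom, pos, ref, alt, gene,
  effect`` (1-based positions);
* segment TSV — BED-like columns ``chrom, start, end, state`` (0-based
  half-open) plus ``sample``;
* beta / expression TSV — feature ids in the first column (index), sample
  columns;
* gene-set files — one symbol per line, or GMT (name, description, genes...),
  or two-column TSV ``gene<TAB>label`` for labeled signatures.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .catalogs import MutationCatalog, ReferenceCohort, SegmentSet, catalog_from_frame, cohort_from_frame

_TSV = dict(sep="\t", na_rep="NA")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index=index)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample matrix TSV (first column = feature ids)."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def read_mutations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str, "ref": str, "alt": str})
    required = {"sample", "chrom", "pos", "ref", "alt", "gene", "effect"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mutation TSV missing columns: {sorted(missing)}")
    return df


def read_catalog(path: str | Path, sample_id: str | None = None) -> MutationCatalog:
    return catalog_from_frame(read_mutations(path), sample_id)


def read_cohort(path: str | Path) -> ReferenceCohort:
    """Cohort from a multi-sample mutation TSV or a directory of per-sample TSVs."""
    p = Path(path)
    if p.is_dir():
        frames = [read_mutations(f) for f in sorted(p.glob("*.tsv"))]
        if not frames:
            raise ValueError(f"no *.tsv files in {p}")
        return cohort_from_frame(pd.concat(frames, ignore_index=True))
    return cohort_from_frame(read_mutations(p))


def write_catalog(catalog: MutationCatalog, path: str | Path) -> None:
    write_tsv(catalog.to_frame(), path, index=False)


def write_cohort(cohort: ReferenceCohort, path: str | Path) -> None:
    write_tsv(cohort.to_frame(), path, index=False)


def read_segments(path: str | Path) -> list[SegmentSet]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "state": str})
    required = {"sample", "chrom", "start", "end", "state"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"segment TSV missing columns: {sorted(missing)}")
    return [
        SegmentSet(str(sid), grp[["chrom", "start", "end", "state"]])
        for sid, grp in df.groupby("sample", sort=True)
    ]


def write_segments(segsets: list[SegmentSet], path: str | Path) -> None:
    frames = []
    for ss in segsets:
        df = ss.segments.copy()
        df.insert(0, "sample", ss.sample_id)
        frames.append(df)
    write_tsv(pd.concat(frames, ignore_index=True), path, index=False)


def read_gene_set(path: str | Path) -> list[str]:
    """One-symbol-per-line or single-line GMT gene set."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) == 1 and "\t" in lines[0]:
        fields = lines[0].split("\t")
        return fields[2:]  # GMT: name, description, genes...
    return [ln.split("\t")[0] for ln in lines]


def read_labeled_signature(path: str | Path) -> pd.Series:
    """Two-column TSV gene<TAB>label -> Series label indexed by gene."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "label"], comment="#")
    if df["label"].isna().any():
        raise ValueError("labeled signature requires a label for every gene")
    return df.set_index("gene")["label"]


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_ground_truth(truth: dict, path: str | Path) -> None:
    """Ground-truth sidecar (YAML). Analysis stages must never read this."""
    Path(path).write_text(yaml.safe_dump(truth, sort_keys=True))


def read_ground_truth(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
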