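"""End-to-end workflows wiring stage outputs to stage inputs.

Each workflow takes a :class:`RunConfig`, derives one recorded sub-seed per
stochastic stage from the global seed (SHA-256 of ``"<seed>:<stage>"``,
reduced mod 2^31), writes every artifact as TSV/JSON text and finishes with
a ``manifest.json`` listing each output file with its SHA-256 checksum.
Outputs carry no timestamps, so a repeated run with the same seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import clonality as clonal
from . import expression as expr_mod
from . import genomic, immune, io, subtyping, synthetic

logger = logging.getLogger("sarcomix")

__all__ = ["RunConfig", "derive_seed", "run_clonality_workflow", "run_classification_workflow"]


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    simulate: bool = True
    # clonality workflow inputs (ignored when simulate=True)
    pair_paths: tuple[str, str] | None = None
    cohort_path: str | None = None
    fractions: tuple[float, ...] = (0.4, 0.6, 0.8)
    repeats: int = 100
    # simulation settings
    n_cohort: int = 30
    pair_n_total: int = 100
    pair_shared_fraction: float = 0.6
    # classification workflow settings
    n_probes: int = 1000
    n_per_cluster: int = 8
    k: int = 3
    lf_pis: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6)
    params: dict = field(default_factory=dict)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed: SHA-256 of '<seed>:<stage>' mod 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, seeds: dict[str, int]) -> Path:
    files = sorted(
        p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "stage_seeds": seeds,
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


class StageError(RuntimeError):
    """Raised when a workflow stage fails; names the stage and the input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


def run_clonality_workflow(config: RunConfig) -> dict:
    """Calibrate the CI cutoff, score the pair, emit partition stats and tree.

    Returns the per-pair report dict; writes calibration TSV, pair report
    JSON, Newick tree and manifest under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: derive_seed(config.seed, s) for s in ("cohort", "pair", "calibration")}

    if config.simulate:
        cohort = synthetic.generate_reference_cohort(
            config.n_cohort, seed=seeds["cohort"]
        )
        a, b, truth = synthetic.generate_paired_components(
            config.pair_n_total, config.pair_shared_fraction, cohort, seed=seeds["pair"]
        )
        io.write_cohort(cohort, out / "cohort.tsv")
        io.write_catalog(a, out / "component_a.tsv")
        io.write_catalog(b, out / "component_b.tsv")
        io.write_ground_truth(truth, out / "ground_truth.yaml")
    else:
        if config.cohort_path is None:
            raise StageError("calibration", "missing cohort path")
        if config.pair_paths is None:
            raise StageError("pair_scoring", "missing pair paths")
        try:
            cohort = io.read_cohort(config.cohort_path)
        except Exception as e:  # noqa: BLE001
            raise StageError("calibration", f"cannot read cohort {config.cohort_path}: {e}") from e
        a = io.read_catalog(config.pair_paths[0])
        b = io.read_catalog(config.pair_paths[1])

    logger.info("calibrating CI cutoff: %d repeats", config.repeats)
    model = clonal.ClonalityModel(
        (a, b), cohort, fractions=config.fractions, repeats=config.repeats
    )
    try:
        res = model.fit(seed=seeds["calibration"])
    except ValueError as e:
        raise StageError("calibration", str(e)) from e

    part = genomic.partition_mutations(a, b)
    tree = genomic.build_phylogenetic_tree(part)
    calib_df = pd.DataFrame(
        {"repeat": range(1, res.calibration.repeats + 1),
         "cutoff": res.calibration.per_repeat_cutoffs}
    )
    io.write_tsv(calib_df, out / "calibration.tsv", index=False)
    report = {
        **res.to_dict(),
        "shared_pct": part.shared_pct,
        "n_shared": len(part.shared),
        "n_specific_a": len(part.specific_a),
        "n_specific_b": len(part.specific_b),
        "newick": tree,
    }
    io.write_json(report, out / "pair_report.json")
    (out / "tree.nwk").write_text(tree + "\n")
    _write_manifest(out, seeds)
    return report


def run_classification_workflow(config: RunConfig) -> dict:
    """Methylation clustering, LF deconvolution, EMT / LI scores and
    nearest-centroid subtype predictions on one simulated (or supplied)
    cohort; writes each table plus a checksum manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_names = ("meth_cohort", "lf", "expression")
    seeds = {s: derive_seed(config.seed, s) for s in stage_names}
    if not config.simulate:
        raise StageError("inputs", "user-data classification runs use the module CLIs; "
                         "the workflow currently drives the synthetic cohort")
    if config.n_per_cluster * config.k == 0:
        raise StageError("inputs", "empty sample set")

    # -- methylation clustering ------------------------------------------
    betas, truth_m = synthetic.generate_methylation_cluster_cohort(
        n_probes=config.n_probes,
        n_per_cluster=config.n_per_cluster,
        n_clusters=config.k,
        seed=seeds["meth_cohort"],
    )
    assign = subtyping.hierarchical_cluster(betas.T, k=config.k)
    io.write_tsv(assign.labels.to_frame(), out / "clusters.tsv")

    # -- leukocyte fraction ----------------------------------------------
    lf_data = synthetic.generate_lf_dataset(list(config.lf_pis), seed=seeds["lf"])
    lf_res = immune.LeukocyteFractionModel(
        lf_data["tumors"], lf_data["normal_lung"], lf_data["leukocyte"]
    ).fit()
    io.write_tsv(lf_res.table, out / "leukocyte_fraction.tsv")

    # -- expression: EMT, LI, subtype ------------------------------------
    centroids = synthetic.make_default_centroids(seed=derive_seed(config.seed, "centroids"))
    emt_sig = synthetic.make_emt_signature()
    li_sig = synthetic.make_li_signature()
    subtypes = list(centroids.columns)
    n_expr = 24
    labels = [subtypes[i % len(subtypes)] for i in range(n_expr)]
    rng_levels = [0.25 * (i % 5) for i in range(n_expr)]
    expr, truth_e = synthetic.generate_expression_with_structure(
        centroids,
        labels,
        emt_signature=emt_sig,
        emt_shift=2.0,
        emt_samples=list(range(n_expr // 2)),
        li_signature=li_sig,
        infiltration_level=rng_levels,
        noise_sd=0.1,
        seed=seeds["expression"],
    )
    emt = expr_mod.emt_score(expr, emt_sig)
    io.write_tsv(emt.per_sample_score.rename("emt_score").to_frame(), out / "emt_scores.tsv")
    li = pd.Series(
        {s: immune.ssgsea_score(expr[s], li_sig) for s in expr.columns}, name="LIexpression"
    )
    io.write_tsv(li.to_frame(), out / "li_expression.tsv")
    pred = subtyping.nearest_centroid_subtype(expr, centroids)
    io.write_tsv(pred, out / "subtype_predictions.tsv")

    io.write_ground_truth(
        {"methylation": truth_m, "expression": truth_e,
         "lf": lf_data["ground_truth"]},
        out / "ground_truth.yaml",
    )
    _write_manifest(out, seeds)
    label_acc = float((pred["label"] == pd.Series(truth_e["labels"])).mean())
    return {
        "n_clusters": assign.k,
        "lf": lf_res.table["lf"].to_dict(),
        "subtype_accuracy": label_acc,
    }
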