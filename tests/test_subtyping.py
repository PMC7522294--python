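"""Probe filtering, DMP calling, clustering, centroid prediction."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from sarcomix import synthetic as syn
from sarcomix.subtyping import (
    call_dmps,
    filter_probes,
    hierarchical_cluster,
    methylation_subtype_similarity,
    moderated_t_test,
    nearest_centroid_subtype,
    select_cancer_specific_hyper_probes,
    select_comethylation_probes,
)


def _probe_fixture():
    """Six probes, one per filter rule, plus one clean probe."""
    probes = ["p_det", "p_bead", "p_noncg", "p_snp", "p_multi", "p_sexy", "p_ok"]
    samples = [f"s{i}" for i in range(20)]
    beta = pd.DataFrame(0.5, index=probes, columns=samples)
    ann = pd.DataFrame(
        {
            "chrom": ["chr1"] * 5 + ["chrX", "chr2"],
            "is_cg": [True, True, False, True, True, True, True],
            "has_snp": [False, False, False, True, False, False, False],
            "multimap": [False, False, False, False, True, False, False],
        },
        index=probes,
    )
    det = pd.DataFrame(0.001, index=probes, columns=samples)
    det.loc["p_det", "s3"] = 0.02
    bead = pd.DataFrame(10, index=probes, columns=samples)
    bead.loc["p_bead", ["s0"]] = 2  # 1/20 = 5% of samples
    return beta, ann, det, bead


class TestFilterProbes:
    @pytest.mark.parametrize(
        "probe,reason",
        [
            ("p_det", "detection_p"),
            ("p_bead", "beadcount"),
            ("p_noncg", "non_cg"),
            ("p_snp", "snp"),
            ("p_multi", "multimap"),
            ("p_sexy", "sex_chrom"),
            ("p_ok", "kept"),
        ],
    )
    def test_each_rule_fires_with_its_reason(self, probe, reason):
        beta, ann, det, bead = _probe_fixture()
        filtered, report = filter_probes(beta, ann, det, bead)
        assert report[probe] == reason
        assert (probe in filtered.index) == (reason == "kept")

    def test_first_violated_rule_wins(self):
        beta, ann, det, bead = _probe_fixture()
        ann.loc["p_sexy", "has_snp"] = True  # violates snp AND sex_chrom
        _, report = filter_probes(beta, ann, det, bead)
        assert report["p_sexy"] == "snp"

    def test_chr_prefix_tolerated_for_sex_chromosomes(self):
        beta, ann, det, bead = _probe_fixture()
        ann.loc["p_sexy", "chrom"] = "Y"
        _, report = filter_probes(beta, ann, det, bead)
        assert report["p_sexy"] == "sex_chrom"

    def test_idempotent(self):
        beta, ann, det, bead = _probe_fixture()
        filtered, _ = filter_probes(beta, ann, det, bead)
        again, report2 = filter_probes(filtered, ann, det, bead)
        pd.testing.assert_frame_equal(filtered, again)
        assert (report2 == "kept").all()

    def test_missing_annotation_column_names_blocked_rule(self):
        beta, ann, det, bead = _probe_fixture()
        with pytest.raises(ValueError, match="sex_chrom"):
            filter_probes(beta, ann.drop(columns="chrom"), det, bead)


class TestModeratedT:
    def test_shrinkage_pulls_variances_toward_prior(self):
        rng = np.random.default_rng(51)
        idx = [f"p{i}" for i in range(500)]
        a = pd.DataFrame(rng.normal(0.4, 0.05, (500, 5)), index=idx)
        b = pd.DataFrame(rng.normal(0.4, 0.05, (500, 5)), index=idx)
        res = moderated_t_test(a, b)
        assert res["p"].between(0, 1).all()
        # BH monotonicity: adj_p is non-decreasing along increasing p
        adj_by_p = res.sort_values("p")["adj_p"].to_numpy()
        assert (np.diff(adj_by_p) >= -1e-12).all()
        assert (res["adj_p"] >= res["p"] - 1e-12).all()

    def test_agrees_with_limma_reference_implementation(self, tmp_path):
        rng = np.random.default_rng(52)
        n = 60
        a = rng.normal(0.5, 0.08, (n, 6))
        b = rng.normal(0.5, 0.08, (n, 6))
        b[:5] += 0.3
        mat = np.hstack([a, b])
        csv = tmp_path / "m.csv"
        pd.DataFrame(mat).to_csv(csv, index=False)
        script = tmp_path / "limma.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.csv("{csv}"))
            design <- cbind(Intercept = 1, Diff = c(rep(0, 6), rep(1, 6)))
            fit <- eBayes(lmFit(x, design))
            write.csv(data.frame(t = fit$t[, "Diff"], p = fit$p.value[, "Diff"]),
                      "{tmp_path}/out.csv", row.names = FALSE)
        """))
        try:
            subprocess.run(["Rscript", str(script)], check=True, capture_output=True, timeout=120)
        except (FileNotFoundError, subprocess.CalledProcessError) as e:
            pytest.skip(f"Rscript/limma unavailable: {e}")
        ref = pd.read_csv(tmp_path / "out.csv")
        idx = [f"p{i}" for i in range(n)]
        mine = moderated_t_test(
            pd.DataFrame(b, index=idx), pd.DataFrame(a, index=idx)
        )
        # same moment-method shrinkage => t statistics agree closely
        assert np.allclose(mine["t"].to_numpy(), ref["t"].to_numpy(), rtol=1e-3, atol=1e-3)
        assert np.allclose(mine["p"].to_numpy(), ref["p"].to_numpy(), rtol=5e-3, atol=1e-6)


class TestCallDmps:
    def _planted(self, seed=53, n_probes=5000, n_planted=100, delta=0.4, sd=0.05, n=10):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.2, 0.5, n_probes)
        a = np.clip(base[:, None] + rng.normal(0, sd, (n_probes, n)), 0, 1)
        shifted = base.copy()
        shifted[:n_planted] += delta
        b = np.clip(shifted[:, None] + rng.normal(0, sd, (n_probes, n)), 0, 1)
        idx = [f"cg{i:05d}" for i in range(n_probes)]
        cols_a = [f"A{i}" for i in range(n)]
        cols_b = [f"B{i}" for i in range(n)]
        beta = pd.DataFrame(
            np.hstack([a, b]), index=idx, columns=cols_a + cols_b
        )
        return beta, cols_a, cols_b, n_planted

    def test_planted_probes_recovered_with_error_control(self):
        beta, cols_a, cols_b, n_planted = self._planted()
        res = call_dmps(beta, cols_b, cols_a)
        called = res.index[res["is_dmp"]]
        tp = sum(int(p[2:]) < n_planted for p in called)
        assert tp / n_planted >= 0.9
        assert (len(called) - tp) / max(len(called), 1) <= 0.1

    def test_effect_size_below_threshold_never_called(self):
        rng = np.random.default_rng(54)
        idx = [f"cg{i}" for i in range(300)]
        a = pd.DataFrame(np.clip(rng.normal(0.3, 0.01, (300, 6)), 0, 1), index=idx,
                         columns=[f"A{i}" for i in range(6)])
        b = a + 0.29  # highly significant but |delta| < 0.3
        b.columns = [f"B{i}" for i in range(6)]
        beta = pd.concat([a, b], axis=1)
        res = call_dmps(beta, list(b.columns), list(a.columns))
        assert (res["adj_p"] < 1e-4).all()
        assert not res["is_dmp"].any()

    def test_thresholds_exactly_enforced_on_output(self):
        beta, cols_a, cols_b, _ = self._planted(seed=55, n_probes=1000, n_planted=30)
        res = call_dmps(beta, cols_b, cols_a)
        dmps = res[res["is_dmp"]]
        assert (dmps["adj_p"] <= 0.05).all()
        assert (dmps["delta_beta"].abs() >= 0.3).all()

    def test_zero_variance_everywhere_falls_back_with_warning(self):
        idx = [f"cg{i}" for i in range(10)]
        a = pd.DataFrame(0.2, index=idx, columns=["a1", "a2"])
        b = pd.DataFrame(0.8, index=idx, columns=["b1", "b2"])
        beta = pd.concat([a, b], axis=1)
        with pytest.warns(UserWarning, match="zero variance"):
            res = call_dmps(beta, ["b1", "b2"], ["a1", "a2"])
        assert res["is_dmp"].all()


class TestHyperProbes:
    @pytest.mark.parametrize(
        "normal_med,tumor_med,selected",
        [(0.15, 0.40, True), (0.25, 0.90, False), (0.10, 0.30, False)],
    )
    def test_threshold_rules(self, normal_med, tumor_med, selected):
        idx = ["cg1"]
        tumor = pd.DataFrame(tumor_med, index=idx, columns=["t1", "t2", "t3"])
        normal = pd.DataFrame(normal_med, index=idx, columns=["n1", "n2", "n3"])
        got = select_cancer_specific_hyper_probes(tumor, normal)
        assert (idx[0] in got) == selected


class TestHierarchicalCluster:
    def test_planted_blobs_recovered_exactly(self):
        betas, truth = syn.generate_methylation_cluster_cohort(
            n_probes=400, n_per_cluster=8, n_clusters=3, seed=56
        )
        assign = hierarchical_cluster(betas.T, k=3)
        cross = pd.crosstab(assign.labels, pd.Series(truth["cluster"]))
        assert (cross.gt(0).sum(axis=1) == 1).all()  # one planted cluster per label

    def test_identical_samples_single_cluster_zero_heights(self):
        m = pd.DataFrame(np.ones((5, 10)), index=[f"s{i}" for i in range(5)])
        assign = hierarchical_cluster(m, k=1)
        assert assign.labels.nunique() == 1
        assert np.allclose(assign.linkage[:, 2], 0.0)

    def test_merge_sequence_matches_brute_force_ward(self):
        rng = np.random.default_rng(57)
        pts = rng.uniform(0, 10, (6, 2))
        m = pd.DataFrame(pts, index=[f"s{i}" for i in range(6)])
        assign = hierarchical_cluster(m, k=1)
        # oracle: greedy agglomeration minimizing the within-cluster SSE increase
        clusters = [{i} for i in range(6)]
        merges = []
        while len(clusters) > 1:
            best = None
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    u, v = clusters[i], clusters[j]
                    pu, pv = pts[list(u)], pts[list(v)]
                    sse = lambda p: ((p - p.mean(0)) ** 2).sum()
                    inc = sse(np.vstack([pu, pv])) - sse(pu) - sse(pv)
                    if best is None or inc < best[0]:
                        best = (inc, i, j)
            _, i, j = best
            merges.append(frozenset(clusters[i] | clusters[j]))
            clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [
                clusters[i] | clusters[j]
            ]
        # reconstruct scipy's merge sequence as sets of leaves
        Z = assign.linkage
        members = {i: frozenset([i]) for i in range(6)}
        scipy_merges = []
        for step, (l, r, *_rest) in enumerate(Z):
            merged = members[int(l)] | members[int(r)]
            members[6 + step] = merged
            scipy_merges.append(merged)
        assert scipy_merges == merges

    def test_sample_order_invariance(self):
        betas, _ = syn.generate_methylation_cluster_cohort(
            n_probes=200, n_per_cluster=5, n_clusters=3, seed=58
        )
        a1 = hierarchical_cluster(betas.T, k=3).labels
        shuffled = betas.T.sample(frac=1.0, random_state=4)
        a2 = hierarchical_cluster(shuffled, k=3).labels
        cross = pd.crosstab(a1, a2[a1.index])
        assert (cross.gt(0).sum(axis=1) == 1).all()

    def test_k_above_sample_count_rejected(self):
        m = pd.DataFrame(np.eye(3), index=list("abc"))
        with pytest.raises(ValueError, match="exceeds sample count"):
            hierarchical_cluster(m, k=5)


class TestComethylationProbes:
    def test_effect_and_ranking_rules(self):
        rng = np.random.default_rng(59)
        n = 400
        idx = [f"cg{i:04d}" for i in range(n)]
        base = rng.uniform(0.3, 0.5, n)
        normal = pd.DataFrame(
            np.clip(base[:, None] + rng.normal(0, 0.02, (n, 8)), 0, 1), index=idx
        )
        shift = np.zeros(n)
        shift[:50] = 0.3   # qualifying probes
        shift[50:80] = 0.19  # below the delta threshold
        tumor = pd.DataFrame(
            np.clip((base + shift)[:, None] + rng.normal(0, 0.02, (n, 8)), 0, 1), index=idx
        )
        tumor.columns = [f"t{i}" for i in range(8)]
        with pytest.warns(UserWarning, match="qualifying probes"):
            got = select_comethylation_probes(tumor, normal, n_top=3000)
        planted = {f"cg{i:04d}" for i in range(50)}
        assert planted <= set(got)
        # extras are allowed only where the realized mean difference crossed
        # the threshold by sampling noise (clipping keeps |diff| near planted)
        realized = (tumor.mean(axis=1) - normal.mean(axis=1)).abs()
        for extra in set(got) - planted:
            assert realized[extra] >= 0.2

    def test_exact_count_returns_all(self):
        rng = np.random.default_rng(60)
        idx = [f"cg{i}" for i in range(100)]
        normal = pd.DataFrame(np.clip(rng.normal(0.2, 0.02, (100, 6)), 0, 1), index=idx)
        tumor = pd.DataFrame(np.clip(rng.normal(0.6, 0.05, (100, 6)), 0, 1), index=idx,
                             columns=[f"t{i}" for i in range(6)])
        got = select_comethylation_probes(tumor, normal, n_top=100)
        assert set(got) == set(idx)


class TestNearestCentroid:
    def test_sample_equal_to_centroid_gets_its_label_with_unit_correlation(self):
        cen = syn.make_default_centroids(n_genes=60, seed=61)
        # cohort of the centroid-0 profile and its mirror around a constant:
        # the per-gene median is then constant, so median centering preserves
        # the correlation with the centroid exactly
        c0 = cen.iloc[:, 0]
        expr = pd.DataFrame(
            {"s0": np.exp2(c0) - 1, "s1": np.exp2(24.0 - c0) - 1}, index=cen.index
        )
        pred = nearest_centroid_subtype(expr, cen)
        assert pred.loc["s0", "label"] == cen.columns[0]
        assert pred.loc["s0", f"cor_{cen.columns[0]}"] == pytest.approx(1.0)

    def test_anticorrelated_sample_gets_other_label_in_two_subtype_predictor(self):
        rng = np.random.default_rng(62)
        genes = [f"g{i}" for i in range(40)]
        c1 = rng.normal(0, 1, 40)
        cen = pd.DataFrame({"alpha": c1, "beta": -c1}, index=genes)
        expr = pd.DataFrame(
            {"s0": np.maximum(np.exp2(5 - c1) - 1, 0), "s1": np.maximum(np.exp2(5 + c1) - 1, 0)},
            index=genes,
        )
        pred = nearest_centroid_subtype(expr, cen)
        assert pred.loc["s0", "label"] == "beta"
        assert pred.loc["s1", "label"] == "alpha"

    def test_planted_labels_fully_recovered(self):
        cen = syn.make_default_centroids(n_genes=400, seed=63)
        subtypes = list(cen.columns)
        labels = [subtypes[i % 4] for i in range(100)]
        spread = cen.to_numpy().std()
        rng = np.random.default_rng(64)
        cols = {
            f"s{i:03d}": np.maximum(
                np.exp2(cen[labels[i]] + rng.normal(0, 0.25 * spread, len(cen))) - 1, 0
            )
            for i in range(100)
        }
        expr = pd.DataFrame(cols, index=cen.index)
        pred = nearest_centroid_subtype(expr, cen)
        assert (pred["label"].to_numpy() == np.array(labels)).all()

    def test_correlations_bounded_and_too_few_genes_rejected(self):
        cen = syn.make_default_centroids(n_genes=30, seed=65)
        expr = pd.DataFrame(
            np.random.default_rng(66).uniform(0, 100, (30, 5)), index=cen.index
        )
        pred = nearest_centroid_subtype(expr, cen)
        cors = pred[[c for c in pred.columns if c.startswith("cor_")]].to_numpy(dtype=float)
        assert np.nanmin(cors) >= -1 - 1e-12 and np.nanmax(cors) <= 1 + 1e-12
        with pytest.raises(ValueError, match="common to predictor"):
            nearest_centroid_subtype(expr.iloc[:5], cen.iloc[:5])


class TestMethylationSimilarity:
    def test_zero_distance_to_matching_profile(self):
        rng = np.random.default_rng(67)
        idx = [f"cg{i}" for i in range(50)]
        profiles = pd.DataFrame(rng.uniform(0, 1, (50, 3)), index=idx,
                                columns=["low", "mid", "high"])
        samples = pd.DataFrame({"s0": profiles["mid"]})
        d = methylation_subtype_similarity(samples, profiles)
        assert d.loc["s0", "mid"] == pytest.approx(0.0)
        assert d.loc["s0", "nearest"] == "mid"

    def test_planted_sources_mostly_recovered(self):
        rng = np.random.default_rng(68)
        idx = [f"cg{i}" for i in range(300)]
        profiles = pd.DataFrame(rng.uniform(0.1, 0.9, (300, 3)), index=idx,
                                columns=["cimp_low", "cimp_int", "cimp_high"])
        truth, cols = [], {}
        for i in range(60):
            src = profiles.columns[i % 3]
            truth.append(src)
            cols[f"s{i:02d}"] = np.clip(profiles[src] + rng.normal(0, 0.05, 300), 0, 1)
        d = methylation_subtype_similarity(pd.DataFrame(cols, index=idx), profiles)
        assert (d["nearest"].to_numpy() == np.array(truth)).mean() >= 0.95

    def test_empty_probe_intersection_rejected(self):
        a = pd.DataFrame([[0.5]], index=["cgA"], columns=["s"])
        b = pd.DataFrame([[0.5]], index=["cgB"], columns=["p"])
        with pytest.raises(ValueError, match="empty probe intersection"):
            methylation_subtype_similarity(a, b)
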