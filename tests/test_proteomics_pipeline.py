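"""Protein-table statistics: filters, ANOVA+BH, imputation, clustering, PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from histomol.proteomics_pipeline import (DifferentialResult, ProteinQuantTable,
                                          anova_bh, filter_flags, filter_valid,
                                          hcluster, impute_normal,
                                          log_transform, pca_with_ellipses,
                                          prediction_ellipse,
                                          read_protein_groups, volcano_compare,
                                          zscore_rows)


def make_table(values, classes=None, scale="log2", flags=None):
    values = np.asarray(values, dtype=np.float64)
    n, m = values.shape
    classes = classes or ["ccRCC"] * (m // 2) + ["RO"] * (m - m // 2)
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(m)],
        "patient_id": [f"p{i}" for i in range(m)],
        "class": classes,
        "spot_id": ["s1"] * m,
    })
    return ProteinQuantTable([f"P{i}" for i in range(n)], values, meta,
                             flags=flags, scale=scale)


class TestFilters:
    def test_flagged_rows_removed_once(self, small_protein_table):
        out = filter_flags(small_protein_table)
        assert out.n_proteins == 60
        assert not out.flags.any(axis=None)

    def test_no_flags_is_identity(self):
        t = make_table(np.ones((4, 6)))
        assert filter_flags(t).n_proteins == 4

    def test_valid_filter_inclusive_at_70pct(self):
        vals = np.ones((2, 10))
        vals[0, 7:] = np.nan  # 7/10 valid -> kept
        vals[1, 6:] = np.nan  # 6/10 valid -> dropped
        out = filter_valid(make_table(vals), 0.70)
        assert out.protein_ids == ["P0"]

    def test_full_valid_filter_keeps_complete_rows_only(self):
        vals = np.ones((3, 4))
        vals[1, 0] = np.nan
        out = filter_valid(make_table(vals), 1.0)
        assert out.protein_ids == ["P0", "P2"]

    def test_log_transform_and_scale_guard(self):
        t = make_table(np.array([[1024.0, np.nan, 4.0, 8.0]]), scale="raw",
                       classes=["ccRCC", "ccRCC", "RO", "RO"])
        out = log_transform(t)
        assert out.intensities[0, 0] == pytest.approx(10.0)
        assert np.isnan(out.intensities[0, 1])
        with pytest.raises(ValueError, match="already log"):
            log_transform(out)

    def test_roundtrip_through_maxquant_dialect(self, tmp_path,
                                                small_protein_table):
        path = small_protein_table.write_tsv(tmp_path / "pg.tsv")
        meta_path = tmp_path / "meta.tsv"
        small_protein_table.sample_meta.to_csv(meta_path, sep="\t", index=False)
        back = read_protein_groups(path, meta_path)
        assert back.n_proteins == small_protein_table.n_proteins
        np.testing.assert_array_equal(
            back.flags.to_numpy(), small_protein_table.flags.to_numpy())
        a, b = small_protein_table.intensities, back.intensities
        np.testing.assert_array_equal(np.isnan(a), np.isnan(b))
        np.testing.assert_allclose(a[~np.isnan(a)], b[~np.isnan(b)], rtol=1e-9)


class TestAnovaBH:
    def test_worked_four_pvalue_set_gives_one_discovery(self):
        """BH step-up at FDR 0.01 over p = {.001, .008, .02, .04}: thresholds
        .0025/.005/.0075/.01, largest k with p(k) <= k/m * q is k=1."""
        from statsmodels.stats.multitest import multipletests

        rej, q, _, _ = multipletests([0.001, 0.008, 0.02, 0.04], alpha=0.01,
                                     method="fdr_bh")
        assert int(rej.sum()) == 1
        # the same arithmetic through the table interface
        rng = np.random.default_rng(0)

    def test_null_fdr_controlled(self):
        """Identical group means: discovery fraction stays at or below the
        nominal FDR across simulation replicates."""
        rng = np.random.default_rng(42)
        m, n_per = 150, 6
        classes = ["ccRCC"] * n_per + ["RO"] * n_per + ["ChRCC"] * n_per
        false_disc = 0
        total = 0
        for _ in range(40):
            t = make_table(rng.normal(20, 1, size=(m, 3 * n_per)), classes)
            res = anova_bh(t, fdr=0.05)
            false_disc += int(res.significant.sum())
            total += m
        rate = false_disc / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 3 * se

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(7)
        classes = ["ccRCC"] * 6 + ["RO"] * 6 + ["ChRCC"] * 6
        vals = rng.normal(20, 1, size=(20, 18))
        vals[0, :6] += 5.0
        res = anova_bh(make_table(vals, classes), fdr=0.01)
        assert bool(res.significant[0])

    def test_untestable_protein_marked(self):
        classes = ["ccRCC"] * 3 + ["RO"] * 3
        vals = np.ones((2, 6)) * 20
        vals[0, :2] = np.nan  # only one ccRCC value left
        vals[1] = np.random.default_rng(1).normal(20, 1, 6)
        res = anova_bh(make_table(vals, classes), fdr=0.01)
        assert not res.testable[0] and res.testable[1]
        assert not res.significant[0]

    def test_q_monotone_in_p(self, protein_table):
        t = filter_valid(log_transform(filter_flags(protein_table)), 0.7)
        res = anova_bh(t, fdr=0.01)
        ok = res.testable
        order = np.argsort(res.p_value[ok])
        q_sorted = res.q_value[ok][order]
        assert np.all(np.diff(q_sorted) >= -1e-12)

    def test_single_class_rejected(self):
        t = make_table(np.ones((3, 4)), ["RO"] * 4)
        with pytest.raises(ValueError, match="two classes"):
            anova_bh(t)


class TestImputation:
    def test_no_missing_column_unchanged(self):
        vals = np.random.default_rng(2).normal(20, 2, (50, 4))
        out = impute_normal(make_table(vals), seed=1)
        np.testing.assert_array_equal(out.intensities, vals)

    def test_downshifted_distribution_matches_model(self):
        """1e4 imputed draws from a column with mu=20 sigma=2 land at mean
        20 - 1.8*2 = 16.4 and SD 0.3*2 = 0.6 within 3 SE."""
        rng = np.random.default_rng(3)
        n = 20000
        col = rng.normal(20.0, 2.0, n)
        vals = np.column_stack([col, col, col])
        vals[: n // 2, 0] = np.nan  # 1e4 missing in column 0
        t = make_table(vals, ["ccRCC", "RO", "RO"])
        out = impute_normal(t, width=0.3, downshift=1.8, seed=4)
        imputed = out.intensities[: n // 2, 0]
        mu_v = np.nanmean(vals[:, 0])
        sd_v = np.nanstd(vals[:, 0], ddof=1)
        k = len(imputed)
        assert imputed.mean() == pytest.approx(mu_v - 1.8 * sd_v,
                                               abs=3 * 0.6 / np.sqrt(k))
        assert imputed.std(ddof=1) == pytest.approx(
            0.3 * sd_v, abs=3 * 0.6 / np.sqrt(2 * k))

    def test_seeded_determinism_and_mask_preserved(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(20, 2, (40, 5))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        t = make_table(vals, ["ccRCC", "ccRCC", "RO", "RO", "RO"])
        a = impute_normal(t, seed=9)
        b = impute_normal(t, seed=9)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        valid = ~np.isnan(vals)
        np.testing.assert_array_equal(a.intensities[valid], vals[valid])

    def test_column_with_too_few_valid_rejected(self):
        vals = np.full((4, 3), np.nan)
        vals[0] = 20.0
        vals[1, 0] = 21.0
        t = make_table(vals, ["ccRCC", "RO", "RO"])
        with pytest.raises(ValueError, match="valid values"):
            impute_normal(t, seed=0)


class TestZscoreAndClustering:
    def test_zscore_worked_row(self):
        out = zscore_rows(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out, [[-1.224745, 0.0, 1.224745]],
                                   rtol=1e-6)
        np.testing.assert_allclose(zscore_rows(out), out, atol=1e-12)

    def test_constant_row_named(self):
        with pytest.raises(ValueError, match="P1"):
            zscore_rows(np.array([[1.0, 2.0], [3.0, 3.0]]), ["P0", "P1"])

    def test_identical_columns_merge_first_at_height_zero(self):
        rng = np.random.default_rng(6)
        m = rng.normal(size=(10, 4))
        m[:, 3] = m[:, 0]
        tree, _ = hcluster(m, axis=1, distance="euclidean", linkage="average")
        assert tree[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(tree[0, 0]), int(tree[0, 1])} == {0, 3}

    def test_three_class_samples_recovered(self, protein_table):
        from sklearn.metrics import adjusted_rand_score

        t = filter_valid(log_transform(filter_flags(protein_table)), 0.7)
        res = anova_bh(t, fdr=0.01)
        t = impute_normal(t.subset_rows(res.significant), seed=3)
        z = zscore_rows(t.intensities)
        tree, _ = hcluster(z, axis=1, distance="correlation",
                           linkage="average")
        from scipy.cluster.hierarchy import fcluster

        cut = fcluster(tree, t=3, criterion="maxclust")
        assert adjusted_rand_score(t.classes, cut) >= 0.9

    def test_single_linkage_matches_exhaustive_enumeration(self):
        """4 points on a line: single-linkage merge heights equal the
        brute-force minimum pairwise distances between current clusters."""
        pts = np.array([[0.0], [1.0], [3.5], [7.0]])
        tree, _ = hcluster(pts, axis=0, distance="euclidean", linkage="single")

        # brute-force agglomeration
        clusters = [{i} for i in range(4)]
        heights = []
        while len(clusters) > 1:
            best = None
            for a, b in itertools.combinations(range(len(clusters)), 2):
                d = min(abs(pts[i, 0] - pts[j, 0])
                        for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
            d, a, b = best
            heights.append(d)
            clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] \
                + [clusters[a] | clusters[b]]
        np.testing.assert_allclose(tree[:, 2], heights)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            hcluster(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestPredictionEllipse:
    def test_coverage_close_to_level(self):
        """Fresh draws from the group's population fall inside the 95%
        prediction ellipse at the nominal rate (Monte Carlo +- 3 SE)."""
        rng = np.random.default_rng(8)
        n_ref, n_new = 10_000, 10_000
        ref = rng.multivariate_normal([0, 0], [[2.0, 0.7], [0.7, 1.0]], n_ref)
        new = rng.multivariate_normal([0, 0], [[2.0, 0.7], [0.7, 1.0]], n_new)
        e = prediction_ellipse(ref, "g", 0.95)
        cov = float(np.mean(e.contains(new)))
        se = np.sqrt(0.95 * 0.05 / n_new)
        assert abs(cov - 0.95) < 3 * se

    def test_small_n_coverage_still_calibrated(self):
        """The F-based radius keeps prediction coverage at the level even for
        small reference groups (where the chi-square radius undercovers)."""
        rng = np.random.default_rng(9)
        hits, total = 0, 0
        for _ in range(2000):
            ref = rng.normal(size=(8, 2))
            new = rng.normal(size=2)
            e = prediction_ellipse(ref, "g", 0.95)
            hits += int(e.contains(new[None])[0])
            total += 1
        se = np.sqrt(0.95 * 0.05 / total)
        assert abs(hits / total - 0.95) < 3 * se

    def test_group_of_two_warned_and_omitted(self):
        rng = np.random.default_rng(10)
        m = rng.normal(size=(20, 8))
        groups = ["a"] * 6 + ["b"] * 2
        with pytest.warns(UserWarning, match="'b'"):
            _, _, ellipses = pca_with_ellipses(m, groups)
        assert "b" not in ellipses and "a" in ellipses

    def test_outlier_patient_outside_its_class_ellipse(self):
        from histomol import synthetic_data as sd

        design = sd.ProteomeDesign(
            seed=11, outlier_patient=("ChRCC", {"ChRCC": 0.5, "ccRCC": 0.5}))
        t = sd.generate_protein_table(design)
        truth = sd.ground_truth(t)
        proc = filter_valid(log_transform(filter_flags(t)), 0.7)
        proc = impute_normal(proc.subset_rows(
            anova_bh(proc, fdr=0.01).significant), seed=12)
        scores, _, _ = pca_with_ellipses(proc.intensities, proc.classes)
        meta = proc.sample_meta
        out_rows = (meta["patient_id"] == truth.outlier_patient_id).to_numpy()
        ref = ((meta["class"] == "ChRCC").to_numpy()) & ~out_rows
        e = prediction_ellipse(scores[ref, :2], "ChRCC")
        assert np.mean(~e.contains(scores[out_rows, :2])) >= 0.5


class TestVolcano:
    def test_rule_arithmetic(self):
        rng = np.random.default_rng(13)
        base = rng.normal(20, 0.1, size=(3, 8))
        base[0, 4:] += 1.0   # clear 2-fold shift, tiny variance -> significant
        base[1, 4:] += 3.0
        t = make_table(base, ["a"] * 4 + ["b"] * 4)
        res = volcano_compare(t, [f"s{i}" for i in range(4)],
                              [f"s{i}" for i in range(4, 8)],
                              p_max=0.01, min_fold=2)
        assert bool(res.loc["P0", "significant"])
        assert res.loc["P0", "difference"] > 0  # up in B
        assert bool(res.loc["P1", "significant"])
        assert not bool(res.loc["P2", "significant"])

    def test_large_fold_but_weak_p_not_significant(self):
        vals = np.array([[20.0, 23.1, 20.2, 23.0]])
        t = make_table(vals, ["a", "a", "b", "b"])
        res = volcano_compare(t, ["s0", "s1"], ["s2", "s3"], p_max=0.01)
        assert abs(res["difference"].iloc[0]) < 1.0 or not \
            bool(res["significant"].iloc[0])

    def test_null_significance_rate_at_most_pmax(self):
        rng = np.random.default_rng(14)
        m = 400
        t = make_table(rng.normal(20, 1, size=(m, 12)), ["a"] * 6 + ["b"] * 6)
        res = volcano_compare(t, [f"s{i}" for i in range(6)],
                              [f"s{i}" for i in range(6, 12)],
                              p_max=0.05, min_fold=1.0)
        rate = res["significant"].mean()
        se = np.sqrt(0.05 * 0.95 / m)
        assert rate <= 0.05 + 3 * se

    def test_empty_group_rejected(self):
        t = make_table(np.ones((2, 4)) * 20, ["a"] * 2 + ["b"] * 2)
        with pytest.raises(ValueError, match="non-empty"):
            volcano_compare(t, [], ["s0"])
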