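import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from refcompass.cohort_io import CohortError, ExpressionMatrix, derive_stage_class
from refcompass.diffstab import log2_transform, zscore_genes
from refcompass.subtyping import (
    Embedding, build_contingency, chi_square_enrichment, flag_outliers,
    fold_change_flags, pca_embed, select_high_cv_panel,
)


def _embedding(coords: np.ndarray, ids=None) -> Embedding:
    ids = ids or [f"S{i}" for i in range(len(coords))]
    k = coords.shape[1]
    return Embedding(
        coords=pd.DataFrame(coords, index=ids, columns=[f"PC{i+1}" for i in range(k)]),
        explained_variance_ratio=np.full(k, 1.0 / k),
        components=np.eye(k),
    )


class TestPcaEmbed:
    def test_rank_one_matrix_loads_everything_on_pc1(self):
        # two perfectly anticorrelated genes: a single direction of variation
        z = pd.DataFrame([[1.0, -1.0, 0.5, -0.5], [-1.0, 1.0, -0.5, 0.5]],
                         columns=list("ABCD"))
        emb = pca_embed(z, k=2)
        assert emb.explained_variance_ratio[0] == pytest.approx(1.0)
        assert emb.explained_variance_ratio[1] == pytest.approx(0.0, abs=1e-12)

    def test_full_rank_reconstruction(self, rng):
        z = zscore_genes(pd.DataFrame(rng.normal(size=(6, 10))))
        k = min(z.shape)
        emb = pca_embed(z, k=k)
        x = z.to_numpy().T
        xc = x - x.mean(axis=0)
        recon = emb.coords.to_numpy() @ emb.components
        assert np.abs(recon - xc).max() < 1e-8

    def test_components_orthonormal_and_evr_sums_below_one(self, rng):
        z = zscore_genes(pd.DataFrame(rng.normal(size=(20, 12))))
        emb = pca_embed(z, k=3)
        np.testing.assert_allclose(emb.components @ emb.components.T, np.eye(3),
                                   atol=1e-10)
        assert emb.explained_variance_ratio.sum() <= 1 + 1e-12

    def test_deterministic_sign_convention(self, rng):
        z = zscore_genes(pd.DataFrame(rng.normal(size=(8, 15))))
        e1, e2 = pca_embed(z, k=2), pca_embed(z, k=2)
        np.testing.assert_array_equal(e1.coords.to_numpy(), e2.coords.to_numpy())
        for row in e1.components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_planted_tumor_normal_structure_separates(self, small_cohort):
        from sklearn.metrics import silhouette_score
        matrix, samples, truth, _ = small_cohort
        genes = truth.genes_of("hallmark_up") + truth.genes_of("hallmark_down")
        z = zscore_genes(log2_transform(matrix.subset(genes=genes)))
        emb = pca_embed(z, k=2)
        tissue = [("tumor" if s.startswith("T") else "normal")
                  for s in emb.sample_ids]
        assert silhouette_score(emb.coords.to_numpy(), tissue) > 0

    def test_invalid_k_rejected(self):
        z = pd.DataFrame([[1.0, -1.0]], columns=["A", "B"])
        with pytest.raises(CohortError, match="out of range"):
            pca_embed(z, k=5)


class TestFlagOutliers:
    def test_coincident_samples_yield_no_outliers(self):
        emb = _embedding(np.zeros((10, 2)))
        res = flag_outliers(emb, radius=1.0)
        assert not res.outside.any()

    def test_single_displaced_sample_is_flagged(self, rng):
        coords = rng.normal(0, 0.1, size=(20, 2))
        coords[7] = [30.0, -25.0]
        res = flag_outliers(_embedding(coords), radius_quantile=90.0)
        assert res.outside.iloc[7]
        assert res.outside.sum() <= 2

    def test_rotation_invariance(self, rng):
        coords = rng.normal(size=(30, 2))
        theta = 0.77
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        a = flag_outliers(_embedding(coords))
        b = flag_outliers(_embedding(coords @ rot.T))
        pd.testing.assert_series_equal(a.outside, b.outside)

    def test_manual_center_and_radius_override(self):
        coords = np.array([[0.0, 0.0], [10.0, 0.0]])
        res = flag_outliers(_embedding(coords), center=(10.0, 0.0), radius=5.0)
        assert list(res.outside) == [True, False]

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(CohortError, match="radius"):
            flag_outliers(_embedding(np.zeros((3, 2))), radius=0.0)

    def test_planted_outlier_recovery_across_seeds(self):
        """The 4-fold transport collapse in planted patients puts both their
        tumor and adjacent normal outside the 90th-percentile circle."""
        from refcompass import SyntheticConfig, generate_cohort
        recalls = []
        for seed in range(20):
            m, samples, truth = generate_cohort(SyntheticConfig(seed=seed))
            panel = truth.genes_of("transport_panel")
            z = zscore_genes(log2_transform(m.subset(genes=panel)))
            res = flag_outliers(pca_embed(z, k=2))
            planted = set(truth.outlier_samples)
            flagged = {s for s, f in res.flags.items() if f}
            recalls.append(len(flagged & planted) / len(planted))
        assert np.mean(recalls) >= 0.7


class TestContingencyAndEnrichment:
    def test_printed_cohort_counts(self):
        flags = {}
        classes = {}
        for i in range(106):
            flags[f"H{i}"] = i < 10
            classes[f"H{i}"] = "HST" if i % 2 else "HSN"
        for i in range(52):
            flags[f"L{i}"] = False
            classes[f"L{i}"] = "LST" if i % 2 else "LSN"
        table = build_contingency(flags, classes)
        assert table.tolist() == [[10, 96], [0, 52]]

    def test_no_outliers_and_all_outliers(self):
        classes = {"A": "HST", "B": "LSN"}
        none = build_contingency({"A": False, "B": False}, classes)
        assert none[:, 0].sum() == 0
        both = build_contingency({"A": True, "B": True}, classes)
        assert both[:, 1].sum() == 0

    def test_unknown_class_excluded_not_fatal(self):
        table = build_contingency({"A": True, "B": False},
                                  {"A": "HST"})
        assert table.sum() == 1

    def test_independence_gives_zero_statistic(self):
        res = chi_square_enrichment(np.array([[10, 90], [5, 45]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_statistic_matches_hand_computed_oracle(self):
        res = chi_square_enrichment(np.array([[10, 96], [0, 52]]))
        assert res.statistic == pytest.approx(5.236, abs=0.005)
        assert res.p_value == pytest.approx(0.0221, abs=0.0005)
        res2 = chi_square_enrichment(np.array([[23, 83], [1, 51]]))
        assert res2.p_value < 0.0038

    def test_agrees_with_first_principles_on_small_tables(self):
        """Exhaustive oracle: Pearson statistic computed from the margin
        formula chi2 = N(ad-bc)^2 / (r1 r2 c1 c2) on all small tables."""
        for a in range(9):
            for b in range(9):
                for c in range(9):
                    for d in range(9):
                        t = np.array([[a, b], [c, d]])
                        r1, r2 = a + b, c + d
                        c1, c2 = a + c, b + d
                        if r1 == 0 or r2 == 0:
                            continue
                        res = chi_square_enrichment(t)
                        if c1 == 0 or c2 == 0:
                            assert res.statistic == 0.0 and res.p_value == 1.0
                            continue
                        n = t.sum()
                        expected_stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
                        assert res.statistic == pytest.approx(expected_stat, abs=1e-9)
                        assert res.p_value == pytest.approx(
                            sps.chi2.sf(expected_stat, 1), abs=1e-12)

    @pytest.mark.parametrize("table", [
        [[30, 70], [20, 80]],
        [[25, 75], [10, 90]],
        [[40, 60], [35, 65]],
    ])
    def test_p_value_agrees_with_permutation_null(self, table, rng):
        """Condition on the margins (hypergeometric draws of the top-left
        cell) and compare the Monte-Carlo tail of the Pearson statistic with
        the asymptotic p."""
        t = np.array(table)
        res = chi_square_enrichment(t)
        r1, r2 = t.sum(axis=1)
        c1, _ = t.sum(axis=0)
        n = t.sum()
        draws = rng.hypergeometric(r1, r2, c1, size=100_000)
        b = r1 - draws
        c = c1 - draws
        d = r2 - c
        stats = n * (draws * d - b * c) ** 2 / (r1 * r2 * c1 * (n - c1))
        p_upper = (stats >= res.statistic - 1e-9).mean()   # inclusive tail
        p_lower = (stats > res.statistic + 1e-9).mean()    # strict tail
        se = np.sqrt(p_upper * (1 - p_upper) / 100_000)
        # the null is discrete: the continuous approximation must land
        # inside the discreteness bracket, up to Monte-Carlo error
        assert p_lower - 3 * se <= res.p_value <= p_upper + 3 * se

    def test_zero_row_margin_rejected(self):
        with pytest.raises(CohortError, match="row margin"):
            chi_square_enrichment(np.array([[0, 0], [1, 5]]))

    def test_low_expected_cell_warns_in_result(self):
        res = chi_square_enrichment(np.array([[1, 1], [1, 50]]))
        assert res.low_expected_warning


class TestHighCvPanel:
    def _matrix(self, values):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(pd.DataFrame(
            values, index=[f"G{i}" for i in range(values.shape[0])],
            columns=[f"S{j}" for j in range(values.shape[1])]))

    def test_top_k_by_subgroup_cv(self, rng):
        base = np.abs(100 + rng.normal(0, 1, size=(10, 12)))
        spread = np.linspace(1, 30, 10)
        vals = 100 + (base - 100) * spread[:, None]
        m = self._matrix(np.abs(vals))
        got = select_high_cv_panel(m.gene_ids, m, m.sample_ids[:6], k=3)
        assert set(got) == {"G7", "G8", "G9"}

    def test_tie_broken_by_gene_id(self):
        vals = [[90.0, 110.0], [90.0, 110.0], [100.0, 100.0]]
        m = self._matrix(vals)
        got = select_high_cv_panel(["G1", "G0", "G2"], m, m.sample_ids, k=1)
        assert got == ["G0"]

    def test_k_larger_than_candidates_rejected(self, tiny_matrix):
        with pytest.raises(CohortError, match="exceeds"):
            select_high_cv_panel(["G1"], tiny_matrix, tiny_matrix.sample_ids, k=2)

    def test_transport_panel_recovered_from_candidates(self):
        from refcompass import (SyntheticConfig, generate_cohort, gene_stats,
                                filter_reference_candidates, pair_cohort)
        recalls = []
        for seed in range(20):
            m, samples, truth = generate_cohort(SyntheticConfig(seed=seed))
            pairing = pair_cohort(samples)
            classes = {s.sample_id: derive_stage_class(s) for s in samples}
            cand = filter_reference_candidates(gene_stats(m, pairing))
            hst = [s for s, c in classes.items() if c == "HST"]
            panel = select_high_cv_panel(cand, m, hst, k=8)
            recalls.append(len(set(panel) & set(truth.genes_of("transport_panel"))) / 8)
        assert np.mean(recalls) >= 0.75


class TestFoldChangeFlags:
    def test_strict_fourfold_boundary(self):
        m = ExpressionMatrix(pd.DataFrame(
            [[100.0, 100.0, 20.0, 25.0]], index=["G1"],
            columns=["B1", "B2", "S1", "S2"]))
        flags = fold_change_flags(m, ["G1"], ["B1", "B2"], fold=4.0)
        assert bool(flags.loc["G1", "S1"]) is True      # 20 < 25
        assert bool(flags.loc["G1", "S2"]) is False     # 25 < 25 is false: strict

    def test_zero_baseline_gene_skipped(self):
        m = ExpressionMatrix(pd.DataFrame(
            [[0.0, 0.0, 5.0], [100.0, 100.0, 10.0]], index=["G0", "G1"],
            columns=["B1", "B2", "S1"]))
        flags = fold_change_flags(m, ["G0", "G1"], ["B1", "B2"], fold=4.0)
        assert list(flags.index) == ["G1"]

    def test_empty_baseline_rejected(self, tiny_matrix):
        with pytest.raises(CohortError, match="baseline"):
            fold_change_flags(tiny_matrix, ["G1"], [], fold=4.0)

    def test_planted_outliers_have_majority_of_panel_flagged(self):
        from refcompass import SyntheticConfig, generate_cohort
        fracs = []
        for seed in range(20):
            m, samples, truth = generate_cohort(SyntheticConfig(seed=seed))
            classes = {s.sample_id: derive_stage_class(s) for s in samples}
            lsn = [s for s, c in classes.items() if c == "LSN"]
            panel = truth.genes_of("transport_panel")
            flags = fold_change_flags(m, panel, lsn, fold=4.0)
            planted = truth.outlier_samples
            fracs.append(float(flags[planted].mean(axis=0).median()))
        assert np.median(fracs) > 0.5
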