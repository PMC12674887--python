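import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import linkage

from dscore.association import (
    CorrelationMap,
    compare_groups,
    emt_score,
    hallmark_correlation,
    signature_correlation,
)
from dscore.enrichment import EnrichmentConfig
from dscore.expression import ExpressionMatrix
from dscore.genesets import GeneSet, load_core_panel
from dscore.scoring import ScoreTable, compute_dscore
from dscore.simulate import SimulationConfig, simulate_cohort

from oracles import average_linkage_oracle, wilcoxon_exact_oracle


def score_table(samples, dscore):
    d = np.asarray(dscore, dtype=float)
    return ScoreTable(tuple(samples), d, np.zeros_like(d), d)


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(SimulationConfig(seed=5, n_background_genes=300))


@pytest.fixture(scope="module")
def cohort_scores(cohort):
    return compute_dscore(cohort.expr, load_core_panel())


class TestHallmarkCorrelation:
    def test_promoter_set_self_correlates_positively(self, cohort, cohort_scores):
        panel = load_core_panel()
        sets = [GeneSet("promoter_program", panel.promoters.genes)]
        cmap = hallmark_correlation(cohort.expr, cohort_scores, sets)
        assert (cmap.rho.loc["promoter_program"] > 0).all()

    def test_planted_program_recovered(self, cohort, cohort_scores):
        # genes planted to co-vary with the score act as a division-like program
        planted = tuple(cohort.truth.loc[cohort.truth.role == "candidate_promoter", "gene"][:10])
        cmap = hallmark_correlation(cohort.expr, cohort_scores, [GeneSet("division_like", planted)])
        row = cmap.rho.loc["division_like"].dropna()
        assert (row > 0).mean() >= 0.8

    def test_shuffled_score_null(self, cohort, cohort_scores):
        rng = np.random.default_rng(0)
        shuffled = score_table(cohort_scores.samples, rng.permutation(cohort_scores.dscore))
        panel = load_core_panel()
        sets = [GeneSet("promoter_program", panel.promoters.genes),
                GeneSet("suppressor_program", panel.suppressors.genes)]
        cmap = hallmark_correlation(cohort.expr, shuffled, sets)
        cells_sig = (cmap.p_adjusted < 0.05).to_numpy()
        valid = np.isfinite(cmap.rho.to_numpy())
        assert cells_sig[valid].mean() <= 0.05

    def test_failed_pathway_is_missing_row(self, cohort, cohort_scores):
        cmap = hallmark_correlation(
            cohort.expr, cohort_scores, [GeneSet("absent", ("NOPE1", "NOPE2"))]
        )
        assert cmap.rho.loc["absent"].isna().all()


class TestSignatureCorrelation:
    def test_identity_and_negation_rows(self, cohort, cohort_scores):
        s = cohort_scores.as_series()
        sig = pd.DataFrame({"same": s, "anti": -s, "noise": np.random.default_rng(1).normal(size=len(s))},
                           index=s.index)
        cmap, order = signature_correlation(sig, cohort_scores, cohort.expr.annotation("cancer_type"))
        assert np.allclose(cmap.rho.loc["same"].dropna(), 1.0)
        assert np.allclose(cmap.rho.loc["anti"].dropna(), -1.0)
        # identical-up-to-sign rows are not co-clustered with noise first
        assert set(order) == {"same", "anti", "noise"}

    def test_planted_signature_directions(self, cohort, cohort_scores):
        cmap, _ = signature_correlation(
            cohort.signatures, cohort_scores, cohort.expr.annotation("cancer_type")
        )
        assert cmap.rho.loc["RPS"].mean() < 0  # repair-proficiency-like
        assert cmap.rho.loc["HRD"].mean() > 0  # instability-like

    def test_all_missing_signature_dropped(self, cohort, cohort_scores):
        sig = cohort.signatures.copy()
        sig["EMPTY"] = np.nan
        with pytest.warns(UserWarning, match="EMPTY"):
            cmap, _ = signature_correlation(sig, cohort_scores, cohort.expr.annotation("cancer_type"))
        assert "EMPTY" not in cmap.rho.index

    def test_linkage_merge_order_matches_naive_oracle(self, rng):
        # 5 signature rows with a fixed distance structure
        rows = rng.normal(size=(5, 12))
        dist = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                if i != j:
                    dist[i, j] = 1 - np.corrcoef(rows[i], rows[j])[0, 1]
        condensed = dist[np.triu_indices(5, k=1)]
        Z = linkage(condensed, method="average")
        merges = average_linkage_oracle(dist.tolist())
        for k, (i, j, h, size) in enumerate(merges):
            assert {int(Z[k, 0]), int(Z[k, 1])} == {i, j}
            assert Z[k, 2] == pytest.approx(h, abs=1e-10)
            assert int(Z[k, 3]) == size


class TestEmtScore:
    def _expr(self, values, genes, samples=None):
        samples = samples or tuple(f"S{i}" for i in range(values.shape[1]))
        return ExpressionMatrix(tuple(genes), samples, values)

    def test_rank_one_matrix_explains_everything(self):
        u = np.array([1.0, 2.0, 3.0])[:, None]
        v = np.array([1.0, -1.0, 2.0, 0.5])[None, :]
        expr = self._expr(u @ v + 5.0, ("VIM", "CDH2", "ZEB1"))
        res = emt_score(expr, GeneSet("emt", ("VIM", "CDH2", "ZEB1")), "VIM")
        assert res.explained_variance_fraction == pytest.approx(1.0)

    def test_two_gene_fixture_matches_analytic_eigvec(self):
        values = np.array([[1.0, 2.0, 4.0, 5.0], [0.5, 2.5, 3.5, 6.0], [0.0, 0.0, 0.0, 0.1]])
        genes = ("VIM", "CDH2", "PAD")
        expr = self._expr(values, genes)
        res = emt_score(expr, GeneSet("emt", ("VIM", "CDH2", "PAD")), "VIM")
        # oracle: eigendecomposition of the 3x3 covariance of centered columns
        X = values.T - values.T.mean(axis=0)
        cov = X.T @ X / (X.shape[0])
        w, V = np.linalg.eigh(cov)
        pc1 = V[:, -1]
        if pc1[0] < 0:
            pc1 = -pc1
        expected = X @ pc1
        assert np.allclose(res.emt_score, expected, atol=1e-10)
        assert res.explained_variance_fraction == pytest.approx(w[-1] / w.sum(), abs=1e-10)

    def test_negation_keeps_marker_positive(self, rng):
        values = rng.normal(size=(4, 6))
        genes = ("VIM", "A", "B", "C")
        gs = GeneSet("emt", genes)
        res = emt_score(self._expr(values, genes), gs, "VIM")
        res_neg = emt_score(self._expr(-values, genes), gs, "VIM")
        assert np.allclose(np.abs(res_neg.emt_score), np.abs(res.emt_score), atol=1e-10)

    def test_gene_constant_shift_invariance(self, rng):
        values = rng.normal(size=(4, 6))
        genes = ("VIM", "A", "B", "C")
        gs = GeneSet("emt", genes)
        res = emt_score(self._expr(values, genes), gs, "VIM")
        shifted = values + np.array([5.0, -3.0, 2.0, 100.0])[:, None]
        res2 = emt_score(self._expr(shifted, genes), gs, "VIM")
        assert np.allclose(res.emt_score, res2.emt_score, atol=1e-9)

    def test_centered_scores(self, rng):
        values = rng.normal(size=(5, 8))
        genes = ("VIM", "A", "B", "C", "D")
        res = emt_score(self._expr(values, genes), GeneSet("emt", genes), "VIM")
        assert abs(res.emt_score.mean()) < 1e-10

    def test_errors(self, rng):
        values = rng.normal(size=(4, 6))
        genes = ("VIM", "A", "B", "C")
        with pytest.raises(ValueError, match=">= 3 EMT genes"):
            emt_score(self._expr(values, genes), GeneSet("emt", ("VIM", "A")), "VIM")
        with pytest.raises(ValueError, match="orientation marker"):
            emt_score(self._expr(values, genes), GeneSet("emt", ("VIM", "A", "B")), "ZZZ")
        with pytest.raises(ValueError, match="zero-variance"):
            emt_score(self._expr(np.ones((4, 6)), genes), GeneSet("emt", genes), "VIM")


class TestCompareGroups:
    def test_identical_groups(self):
        v = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        lab = ["a", "a", "a", "b", "b", "b"]
        res = compare_groups(v, lab)
        assert res.p_value > 0.9
        assert res.direction == 0

    def test_fully_separated_exact_p(self):
        v = [1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0]
        lab = ["a"] * 4 + ["b"] * 4
        res = compare_groups(v, lab)
        assert res.p_value == pytest.approx(2 / 70, abs=1e-12)
        assert res.direction == -1

    def test_exact_matches_enumeration_oracle(self, rng):
        a = rng.normal(size=5).tolist()
        b = (rng.normal(size=6) + 0.8).tolist()
        res = compare_groups(a + b, ["a"] * 5 + ["b"] * 6)
        assert res.p_value == pytest.approx(wilcoxon_exact_oracle(a, b), abs=1e-9)

    def test_exact_and_asymptotic_close_at_n9(self, rng):
        for _ in range(10):
            a = rng.normal(size=9)
            b = rng.normal(size=9) + 0.5
            exact = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            approx = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            assert abs(exact - approx) < 0.01

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], ["a", "a"])

    def test_metastasis_direction(self, cohort):
        plus_scores = compute_dscore(cohort.expr, load_core_panel())
        mstage = cohort.expr.annotation("mstage")
        s = plus_scores.as_series()
        assert s[mstage == "M1"].mean() < s[mstage == "M0"].mean()
        res = compare_groups(s, mstage)
        # direction is median(M0) - median(M1); metastatic scores are lower
        assert res.p_value < 0.05 and res.direction == 1


class TestCorrelationMap:
    def test_congruence_enforced(self):
        rho = pd.DataFrame([[0.5, np.nan]], index=["r"], columns=["a", "b"])
        p_bad = pd.DataFrame([[0.01, 0.02]], index=["r"], columns=["a", "b"])
        with pytest.raises(ValueError, match="missingness"):
            CorrelationMap(rho, p_bad)

    def test_monotone_transform_invariance(self, cohort, cohort_scores):
        transformed_values = np.exp(cohort.expr.values / 3.0)
        expr2 = ExpressionMatrix(
            cohort.expr.genes, cohort.expr.samples, transformed_values, cohort.expr.annotations
        )
        panel = load_core_panel()
        sets = [GeneSet("promoter_program", panel.promoters.genes)]
        cfg = EnrichmentConfig()
        a = hallmark_correlation(cohort.expr, cohort_scores, sets, cfg)
        b = hallmark_correlation(expr2, cohort_scores, sets, cfg)
        assert np.allclose(
            a.rho.loc["promoter_program"].to_numpy(dtype=float),
            b.rho.loc["promoter_program"].to_numpy(dtype=float),
            atol=1e-10,
        )
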