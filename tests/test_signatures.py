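"""Background cutoff, signature rules, clustering and group statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from epimark import signatures
from epimark.occupancy import matrix_columns
from epimark.signatures import (
    NONROD_RETINAL,
    NO_MARK,
    OTHER,
    ROD_SPECIFIC,
    UBIQUITOUS,
    SignatureThresholds,
)

COLS = matrix_columns()


def _matrix(rows: dict[str, list[float]]) -> pd.DataFrame:
    """rows: gene -> 8 values in canonical (mark-major) column order."""
    return pd.DataFrame.from_dict(rows, orient="index", columns=COLS)


class TestBackgroundAndCutoff:
    @pytest.mark.parametrize("vals,expected", [([9.12] * 8, 9.12), ([0, 0], 0.0), ([8, 10], 9.0)])
    def test_gfp_background_mean(self, vals, expected):
        assert signatures.gfp_background(vals) == pytest.approx(expected)

    def test_gfp_background_empty_raises(self):
        with pytest.raises(ValueError):
            signatures.gfp_background([])

    def test_study_background_gives_study_cutoff(self):
        assert round(signatures.no_mark_cutoff(9.12, 8), 2) == 25.80

    @pytest.mark.parametrize("b,dims,expected", [(0.0, 8, 0.0), (1.0, 4, 2.0)])
    def test_cutoff_formula(self, b, dims, expected):
        assert signatures.no_mark_cutoff(b, dims) == pytest.approx(expected)


class TestNoMark:
    def test_all_zero_row_is_no_mark(self):
        flags = signatures.classify_no_mark(_matrix({"g": [0.0] * 8}), 25.80)
        assert flags["g"]

    def test_row_exactly_on_cutoff_is_kept_as_marked(self):
        """The comparison is strict: norm == cutoff is NOT no-mark."""
        row = [9.12] * 8
        cutoff = float(np.linalg.norm(row))  # == sqrt(8)*9.12 up to rounding
        flags = signatures.classify_no_mark(_matrix({"g": row}), cutoff)
        assert not flags["g"]
        assert cutoff == pytest.approx(signatures.no_mark_cutoff(9.12, 8))


class TestRodScreen:
    B = 10.0

    def _screen(self, rows, **kw):
        return signatures.rod_signature_screen(_matrix(rows), self.B, **kw)

    def test_planted_rod_profile_flagged(self):
        # K4 folds 1,1,4,8 x b; K27 absent
        rows = {"rod": [10, 10, 40, 80, 0, 0, 0, 0]}
        assert self._screen(rows)["rod"]

    def test_constant_high_k4_fails_de_novo_condition(self):
        rows = {"ubiq": [80, 80, 80, 80, 0, 0, 0, 0]}
        assert not self._screen(rows)["ubiq"]

    def test_high_k27_fails_repression_condition(self):
        rows = {"nonrod": [10, 10, 40, 80, 60, 60, 60, 60]}
        assert not self._screen(rows)["nonrod"]

    def test_late_gain_must_clear_fold_over_early(self):
        # PN15 >= c_act*b (30) but below f_min x max(E17.5, b) = 36
        rows = {"slow": [12, 10, 30, 31, 0, 0, 0, 0]}
        assert not self._screen(rows)["slow"]

    def test_body_rule_optionally_required(self):
        tss = {"rod": [10, 10, 40, 80, 0, 0, 0, 0]}
        body_flat = _matrix({"rod": [40, 40, 40, 40, 0, 0, 0, 0]})
        flags = signatures.rod_signature_screen(
            _matrix(tss), self.B, body_matrix=body_flat, use_body=True
        )
        assert not flags["rod"]  # body shows no de novo gain


class TestClassify:
    B = 10.0

    def test_precedence_and_labels(self):
        rows = {
            "silent": [0, 0, 0, 0, 0, 0, 0, 0],
            "rod": [10, 10, 40, 80, 0, 0, 0, 0],
            "nonrod": [12, 12, 12, 12, 70, 70, 70, 70],
            "ubiq": [80, 80, 80, 80, 5, 5, 5, 5],
            "down": [80, 60, 20, 5, 5, 10, 20, 40],
        }
        labels = signatures.classify_signatures(_matrix(rows), self.B)
        assert labels.loc["silent", "label"] == NO_MARK
        assert labels.loc["rod", "label"] == ROD_SPECIFIC
        assert labels.loc["nonrod", "label"] == NONROD_RETINAL
        assert labels.loc["ubiq", "label"] == UBIQUITOUS
        assert labels.loc["down", "label"] == OTHER

    def test_exactly_one_label_per_gene(self):
        rng = np.random.default_rng(3)
        rows = {f"g{i}": list(rng.uniform(0, 100, 8)) for i in range(50)}
        labels = signatures.classify_signatures(_matrix(rows), self.B)
        assert labels["label"].isin(signatures.SIGNATURE_LABELS).all()

    def test_depth_invariance_of_classification(self):
        """Occupancies remove depth, so a common scale changes nothing."""
        rows = {
            "rod": [10, 10, 40, 80, 0, 0, 0, 0],
            "ubiq": [80, 80, 80, 80, 5, 5, 5, 5],
        }
        m = _matrix(rows)
        l1 = signatures.classify_signatures(m, self.B)
        l2 = signatures.classify_signatures(m * 3.0, self.B * 3.0)
        assert (l1["label"] == l2["label"]).all()


def rand_index(a, b) -> float:
    agree = total = 0
    for i, j in itertools.combinations(range(len(a)), 2):
        total += 1
        agree += (a[i] == a[j]) == (b[i] == b[j])
    return agree / total


class TestClustering:
    def test_identical_rows_merge_first_at_height_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=list("abc"))
        result = signatures.hierarchical_cluster(m)
        assert sorted(result.linkage[0, :2]) == [0, 1]
        assert result.linkage[0, 2] == 0.0

    def test_average_linkage_hand_computation(self):
        # 1-D points 0, 1, 10.5: d12=1, d13=10.5, d23=9.5 -> final height 10
        m = pd.DataFrame([[0.0], [1.0], [10.5]])
        z = signatures.hierarchical_cluster(m).linkage
        assert sorted(z[0, :2]) == [0, 1]
        assert z[0, 2] == pytest.approx(1.0)
        assert z[1, 2] == pytest.approx(10.0)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.normal(size=(30, 8)))
        z = signatures.hierarchical_cluster(m).linkage
        assert (np.diff(z[:, 2]) >= -1e-12).all()

    def test_archetype_recovery_at_k4(self):
        """Four planted stagexmark archetypes are recovered by a k=4 cut."""
        archetypes = np.array(
            [
                [10, 10, 40, 80, 0, 0, 0, 0],
                [12, 12, 12, 12, 70, 70, 70, 70],
                [80, 80, 80, 80, 5, 5, 5, 5],
                [80, 60, 20, 5, 5, 10, 20, 40],
            ],
            dtype=float,
        )
        rng = np.random.default_rng(8)
        rows = np.vstack([a + rng.normal(0, 4, size=(10, 8)) for a in archetypes])
        truth = np.repeat(np.arange(4), 10)
        m = pd.DataFrame(rows, columns=COLS)
        result = signatures.hierarchical_cluster(m, k=4)
        assert rand_index(truth, result.labels.to_numpy()) >= 0.9

    def test_uncentered_correlation_zero_row_distance_one(self):
        m = pd.DataFrame([[0.0] * 4, [1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]])
        z = signatures.hierarchical_cluster(m, metric="uncentered_correlation").linkage
        # proportional rows are identical under the metric; zero row is at 1
        assert sorted(z[0, :2]) == [1, 2]
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert z[1, 2] == pytest.approx(1.0)

    def test_single_row_raises(self):
        with pytest.raises(ValueError):
            signatures.hierarchical_cluster(pd.DataFrame([[1.0, 2.0]]))


class TestPooledT:
    def test_identical_groups(self):
        res = signatures.pooled_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)
        assert res.stars == "ns"

    def test_textbook_example(self):
        res = signatures.pooled_t_test([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.2247, abs=5e-5)
        assert res.df == 4
        assert res.p == pytest.approx(0.288, abs=1e-3)

    def test_matches_scipy_closed_form(self):
        rng = np.random.default_rng(21)
        for n, m in [(5, 5), (8, 13), (3, 40)]:
            x, y = rng.normal(size=n), rng.normal(1, 2, size=m)
            res = signatures.pooled_t_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=True)
            assert res.t == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    @pytest.mark.parametrize(
        "p,stars", [(0.5, "ns"), (0.049, "*"), (0.011, "*"), (0.005, "**"), (0.0005, "***")]
    )
    def test_star_annotation_bands(self, p, stars):
        assert signatures.significance_stars(p) == stars

    def test_zero_pooled_variance_raises(self):
        with pytest.raises(ValueError):
            signatures.pooled_t_test([1.0, 1.0], [1.0, 1.0])

    def test_too_small_groups_raise(self):
        with pytest.raises(ValueError):
            signatures.pooled_t_test([1.0], [1.0, 2.0])


class TestPromoterBody:
    def _matrices(self, body_factor, n=50, seed=4):
        rng = np.random.default_rng(seed)
        prom = pd.DataFrame(
            rng.normal(60, 8, size=(n, 8)).clip(0), columns=COLS,
            index=[f"g{i}" for i in range(n)],
        )
        body = prom * body_factor
        return prom, body

    def test_reduced_body_is_significant(self):
        prom, body = self._matrices(0.3)
        out = signatures.compare_promoter_body(prom, body)
        assert (out["p"] < 0.001).all()
        assert (out["stars"] == "***").all()

    def test_equal_profiles_not_significant(self):
        prom, body = self._matrices(1.0)
        out = signatures.compare_promoter_body(prom, body)
        assert (out["t"] == 0.0).all()
        assert (out["stars"] == "ns").all()

    def test_empty_gene_set_raises(self):
        prom, body = self._matrices(0.5)
        with pytest.raises(ValueError):
            signatures.compare_promoter_body(prom, body, gene_set=[])

    def test_single_gene_set_raises(self):
        prom, body = self._matrices(0.5)
        with pytest.raises(ValueError):
            signatures.compare_promoter_body(prom, body, gene_set=["g0"])


class TestGenotypeComparison:
    def test_identical_matrices_fold_one_p_one(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.uniform(1, 50, size=(30, 8)), columns=COLS,
                         index=[f"g{i}" for i in range(30)])
        res = signatures.compare_genotypes(m, m.copy(), list(m.index), "H3K4me2_PN15")
        assert res.fold == pytest.approx(1.0)
        assert res.test.p == pytest.approx(1.0)
        assert not res.infinite_fold

    def test_zero_mutant_mean_flagged_infinite(self):
        rng = np.random.default_rng(12)
        m = pd.DataFrame(rng.uniform(5, 15, size=(5, 8)), columns=COLS, index=list("abcde"))
        z = m.copy()
        z["H3K4me2_PN15"] = [0.0, 0.0, 0.0, 10.0, 10.0]
        res = signatures.compare_genotypes(m, z, list("abc"), "H3K4me2_PN15", normalize=False)
        assert res.infinite_fold
        assert math.isinf(res.fold)

    def test_composition_factor_recovers_uniform_scale(self):
        rng = np.random.default_rng(9)
        ref = pd.Series(rng.uniform(5, 80, 200))
        assert signatures.composition_scale_factor(ref, ref / 2) == pytest.approx(2.0)

    def test_composition_factor_ignores_one_sided_minority(self):
        """A 20% block of truly changed genes must not drag the factor."""
        rng = np.random.default_rng(10)
        target = pd.Series(rng.uniform(5, 80, 200))
        ref = target * np.exp(rng.normal(0, 0.1, 200))
        ref.iloc[:40] *= 6.0  # one-sided changed minority
        s = signatures.composition_scale_factor(ref, target)
        assert 0.9 < s < 1.15
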