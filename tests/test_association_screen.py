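"""Signature scores, Pearson correlation, two-stage FDR, screens."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import bky_brute, exact_corr_vector
from paslab import (
    ExpressionMatrix,
    correlation_screen,
    fdr_twostage,
    pas_association,
    pearson,
    signature_score,
)
from paslab.association_screen import read_gmt
from paslab.errors import UndefinedCorrelation


class TestSignatureScore:
    def test_mean_of_squares(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [1.0, 2.0]}, index=["A", "B"]))
        assert signature_score(m, ["A", "B"])["s"] == pytest.approx(2.5)

    def test_all_zero_is_zero(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [0.0, 0.0]}, index=["A", "B"]))
        assert signature_score(m, ["A", "B"])["s"] == 0.0

    def test_single_gene_is_square(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [3.0]}, index=["A"]))
        assert signature_score(m, ["A"])["s"] == pytest.approx(9.0)

    def test_missing_genes_dropped(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [2.0]}, index=["A"]))
        assert signature_score(m, ["A", "ZZZ"])["s"] == pytest.approx(4.0)

    def test_no_measured_gene_rejected_by_name(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [2.0]}, index=["A"]))
        with pytest.raises(ValueError, match="mysig"):
            signature_score(m, ["X", "Y"], name="mysig")

    def test_rms_mode_is_sqrt_of_mean_square(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [1.0, 2.0]}, index=["A", "B"]))
        assert signature_score(m, ["A", "B"], mode="rms")["s"] == pytest.approx(
            np.sqrt(2.5))

    def test_monotone_in_member_magnitude(self):
        lo = ExpressionMatrix(pd.DataFrame({"s": [1.0, 5.0]}, index=["A", "B"]))
        hi = ExpressionMatrix(pd.DataFrame({"s": [2.0, 5.0]}, index=["A", "B"]))
        assert signature_score(hi, ["A", "B"])["s"] > signature_score(lo, ["A", "B"])["s"]


class TestPearson:
    def test_affine_dependence_gives_one(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_hand_example(self):
        r, _ = pearson([1.0, 2.0, 3.0], [1.0, 3.0, 2.0])
        assert r == pytest.approx(0.5)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedCorrelation):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_pairwise_complete_deletion(self):
        x = np.array([1.0, 2.0, 3.0, np.nan, 4.0])
        y = np.array([2.0, 4.0, 6.0, 100.0, 8.0])
        r, _ = pearson(x, y)
        assert r == pytest.approx(1.0)

    def test_too_few_pairs_undefined(self):
        with pytest.raises(UndefinedCorrelation):
            pearson([1.0, np.nan, 2.0], [1.0, 2.0, np.nan])

    def test_p_matches_t_transform(self, rng):
        from scipy import stats

        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        r, p = pearson(x, y)
        t = r * np.sqrt(18 / (1 - r * r))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=18), rel=1e-10)


class TestFdrTwostage:
    def test_all_ones_no_rejection(self):
        _, reject = fdr_twostage(np.ones(10))
        assert not reject.any()

    def test_all_zeros_all_rejected(self):
        _, reject = fdr_twostage(np.zeros(10))
        assert reject.all()

    def test_empty_input(self):
        q, reject = fdr_twostage([])
        assert len(q) == 0 and len(reject) == 0

    def test_q_monotone_in_p(self, rng):
        p = np.sort(rng.uniform(0, 1, 50))
        q, _ = fdr_twostage(p)
        assert np.all(np.diff(q) >= -1e-15)

    def test_matches_brute_force_on_exhaustive_grid(self):
        # every monotone 4-vector over a small p-grid
        grid = [0.001, 0.02, 0.04, 0.2, 0.8, 1.0]
        for combo in itertools.combinations_with_replacement(grid, 4):
            p = np.array(combo)
            _, reject = fdr_twostage(p, alpha=0.05)
            np.testing.assert_array_equal(reject, bky_brute(p, 0.05),
                                          err_msg=str(p))

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.uniform(0, 1, m) ** rng.uniform(0.3, 3)
            for alpha in (0.01, 0.05, 0.1):
                _, reject = fdr_twostage(p, alpha=alpha)
                np.testing.assert_array_equal(reject, bky_brute(p, alpha))

    def test_worked_example_vector(self):
        p = np.array([0.001, 0.02, 0.04, 0.8])
        _, reject = fdr_twostage(p, alpha=0.05)
        np.testing.assert_array_equal(reject, bky_brute(p, 0.05))
        assert reject.tolist() == [True, True, True, False]


class TestCorrelationScreen:
    def _scores(self, rows, samples):
        return pd.DataFrame(rows, columns=samples)

    def test_planted_feature_called_significant(self, rng):
        n = 100
        driver = pd.Series(rng.standard_normal(n),
                           index=[f"s{i}" for i in range(n)])
        rows = {f"null{i}": rng.standard_normal(n) for i in range(20)}
        rows["planted"] = exact_corr_vector(driver.to_numpy(), 0.9, rng)
        scores = pd.DataFrame(rows, index=driver.index).T
        records, counts = correlation_screen(driver, scores, alpha=0.05, r_min=0.2)
        by_name = {r.feature: r for r in records}
        assert by_name["planted"].significant
        assert by_name["planted"].r > 0
        assert counts.loc["all", "n_pos_sig"] >= 1

    def test_large_r_small_n_threshold_semantics(self, rng):
        # r = 0.15 with huge n: p tiny but |r| <= 0.2 fails the effect floor
        n = 5000
        driver = pd.Series(rng.standard_normal(n),
                           index=[f"s{i}" for i in range(n)])
        planted = exact_corr_vector(driver.to_numpy(), 0.15, rng)
        scores = pd.DataFrame({"weak": planted}, index=driver.index).T
        records, _ = correlation_screen(driver, scores, alpha=0.05, r_min=0.2)
        rec = records[0]
        assert rec.p < 1e-6 and not rec.significant

    def test_affine_driver_invariance(self, rng):
        n = 50
        idx = [f"s{i}" for i in range(n)]
        driver = pd.Series(rng.standard_normal(n), index=idx)
        scores = pd.DataFrame(rng.standard_normal((5, n)),
                              index=[f"f{i}" for i in range(5)], columns=idx)
        a, _ = correlation_screen(driver, scores)
        b, _ = correlation_screen(driver * 3.0 + 11.0, scores)
        for ra, rb in zip(a, b):
            assert ra.r == pytest.approx(rb.r, abs=1e-12)
            assert ra.p == pytest.approx(rb.p, rel=1e-9)

    def test_sample_order_invariance(self, rng):
        n = 30
        idx = [f"s{i}" for i in range(n)]
        driver = pd.Series(rng.standard_normal(n), index=idx)
        scores = pd.DataFrame(rng.standard_normal((4, n)),
                              index=[f"f{i}" for i in range(4)], columns=idx)
        a, _ = correlation_screen(driver, scores)
        perm = list(rng.permutation(idx))
        b, _ = correlation_screen(driver.loc[perm], scores[perm])
        for ra, rb in zip(a, b):
            assert ra.r == pytest.approx(rb.r, abs=1e-12)

    def test_constant_feature_logged_not_fatal(self, rng):
        n = 20
        idx = [f"s{i}" for i in range(n)]
        driver = pd.Series(rng.standard_normal(n), index=idx)
        scores = pd.DataFrame(
            {"flat": np.ones(n), "ok": rng.standard_normal(n)}, index=idx).T
        records, counts = correlation_screen(driver, scores)
        assert {r.feature for r in records} == {"ok"}
        assert counts.loc["all", "n_undefined"] == 1

    def test_per_cohort_correction_family(self, rng):
        n = 60
        idx = [f"s{i}" for i in range(n)]
        cohorts = pd.Series(["A"] * 30 + ["B"] * 30, index=idx)
        driver = pd.Series(rng.standard_normal(n), index=idx)
        scores = pd.DataFrame(rng.standard_normal((3, n)),
                              index=["f0", "f1", "f2"], columns=idx)
        records, counts = correlation_screen(driver, scores, cohorts=cohorts)
        assert sorted({r.cohort for r in records}) == ["A", "B"]
        assert len(records) == 6
        assert set(counts.index) == {"A", "B"}


class TestPasAssociation:
    def test_constant_driver_rejected(self, rng):
        pas = pd.DataFrame(rng.standard_normal((10, 3)),
                           index=[f"s{i}" for i in range(10)],
                           columns=["p1", "p2", "p3"])
        driver = pd.Series(1.0, index=pas.index)
        with pytest.raises(UndefinedCorrelation):
            pas_association(pas, driver)

    def test_planted_pathway_significant_no_rmin(self, rng):
        n = 80
        idx = [f"s{i}" for i in range(n)]
        driver = pd.Series(rng.standard_normal(n), index=idx)
        pas = pd.DataFrame(
            {f"null{i}": rng.standard_normal(n) for i in range(10)}, index=idx)
        pas["planted"] = exact_corr_vector(driver.to_numpy(), 0.8, rng)
        records, n_sig = pas_association(pas, driver, alpha=0.05)
        by_name = {r.feature: r for r in records}
        assert by_name["planted"].significant and by_name["planted"].r > 0
        assert n_sig >= 1

    def test_null_rate_near_alpha(self, rng):
        # independent PAS table: expected significant fraction <= alpha-ish
        n, m, reps = 50, 40, 30
        total_sig = 0
        for _ in range(reps):
            idx = [f"s{i}" for i in range(n)]
            driver = pd.Series(rng.standard_normal(n), index=idx)
            pas = pd.DataFrame(rng.standard_normal((n, m)), index=idx,
                               columns=[f"p{j}" for j in range(m)])
            _, n_sig = pas_association(pas, driver, alpha=0.05)
            total_sig += n_sig
        assert total_sig / (m * reps) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / (m * reps))


def test_read_gmt(tmp_path):
    p = tmp_path / "s.gmt"
    p.write_text("sigA\tdesc\tKIT\tMYC\nsigB\tdesc\tTP53\n")
    sigs = read_gmt(p)
    assert sigs == {"sigA": ["KIT", "MYC"], "sigB": ["TP53"]}
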