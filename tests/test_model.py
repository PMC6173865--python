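"""Accessibility scoring, correlations, variance decomposition and motif
scanning."""

import numpy as np
import pandas as pd
import pytest

from cpgscape.errors import DegenerateInputError, ValidationError
from cpgscape.genome import GenomeIndex, GenomicInterval
from cpgscape.model import (
    accessibility_score,
    motif_scan_fraction,
    pearson_r2,
    reverse_complement_motif,
    select_top_accessible,
    variance_decomposition,
)


class TestAccessibilityScore:
    def test_identical_inputs_give_plain_zscore(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3, 2, 100)
        score = accessibility_score(x, x)
        z = (x - x.mean()) / x.std(ddof=1)
        assert np.allclose(score, z)

    def test_zero_mean_unit_or_less_sd(self):
        rng = np.random.default_rng(1)
        score = accessibility_score(rng.normal(size=500), rng.normal(size=500))
        assert abs(score.mean()) < 1e-12
        assert score.std(ddof=1) <= 1.0 + 1e-12

    def test_independent_inputs_sd_near_sqrt_half(self):
        rng = np.random.default_rng(2)
        score = accessibility_score(rng.normal(size=20_000), rng.normal(size=20_000))
        assert score.std(ddof=1) == pytest.approx(np.sqrt(0.5), abs=0.02)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        d, a = rng.normal(size=50), rng.normal(size=50)
        assert np.allclose(
            accessibility_score(d, a), accessibility_score(3 * d + 7, 0.1 * a - 2)
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            accessibility_score(np.ones(10), np.arange(10))


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(100, dtype=float)
        r, r2 = pearson_r2(x, 2 * x + 3)
        assert (r, r2) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_perfect_anticorrelation(self):
        x = np.arange(100, dtype=float)
        r, r2 = pearson_r2(x, -x)
        assert r == pytest.approx(-1.0) and r2 == pytest.approx(1.0)

    def test_null_simulation(self):
        rng = np.random.default_rng(4)
        r, _ = pearson_r2(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(r) < 0.05

    def test_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_r2(np.ones(10), np.arange(10.0))


class TestTopAccessible:
    def test_distinct_scores_select_exactly_ten_percent(self):
        mask = select_top_accessible(np.arange(100.0))
        assert mask.sum() == 10
        assert mask[-10:].all()

    def test_all_ties_selected(self):
        assert select_top_accessible(np.full(50, 3.3)).all()


class TestVarianceDecomposition:
    def frame(self, n=200, seed=5):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "f1": rng.normal(size=n),
                "f2": rng.normal(size=n),
                "f3": rng.normal(size=n),
            }
        )
        return df, rng

    def test_exact_single_feature_response(self):
        df, _ = self.frame()
        df["y"] = 2.0 * df["f3"]
        res = variance_decomposition(df, ["f1", "f2", "f3"], "y")
        assert res.joint_r2 == pytest.approx(1.0)
        assert res.marginal_r2["f3"] == pytest.approx(1.0)
        assert res.coefficients["f3"] == pytest.approx(2.0)

    def test_null_response(self):
        df, rng = self.frame(n=10_000, seed=6)
        df["y"] = rng.normal(size=10_000)
        res = variance_decomposition(df, ["f1", "f2", "f3"], "y")
        assert res.joint_r2 < 0.01

    def test_known_coefficients_recovered(self):
        df, rng = self.frame(n=2000, seed=7)
        a, b, c, sd = 1.5, -0.7, 0.3, 0.5
        df["y"] = a * df.f1 + b * df.f2 + c * df.f3 + rng.normal(0, sd, 2000)
        res = variance_decomposition(df, ["f1", "f2", "f3"], "y")
        for feat, truth in zip(("f1", "f2", "f3"), (a, b, c)):
            assert abs(res.coefficients[feat] - truth) <= 3 * res.std_errors[feat]
        analytic_r2 = (a**2 + b**2 + c**2) / (a**2 + b**2 + c**2 + sd**2)
        assert res.joint_r2 == pytest.approx(analytic_r2, abs=0.03)

    def test_matches_normal_equations_solver(self):
        """Backend independence: OLS result equals a hand-rolled
        normal-equations solution."""
        df, rng = self.frame(n=500, seed=8)
        df["y"] = df.f1 - 2 * df.f2 + rng.normal(0, 1, 500)
        res = variance_decomposition(df, ["f1", "f2", "f3"], "y")
        X = np.column_stack([np.ones(len(df)), df.f1, df.f2, df.f3])
        beta = np.linalg.solve(X.T @ X, X.T @ df.y.to_numpy())
        assert res.intercept == pytest.approx(beta[0], abs=1e-8)
        for i, feat in enumerate(("f1", "f2", "f3")):
            assert res.coefficients[feat] == pytest.approx(beta[i + 1], abs=1e-8)

    def test_joint_r2_non_decreasing_in_features(self):
        df, rng = self.frame(n=300, seed=9)
        df["y"] = df.f1 + rng.normal(0, 1, 300)
        r2_1 = variance_decomposition(df, ["f1"], "y").joint_r2
        r2_2 = variance_decomposition(df, ["f1", "f2"], "y").joint_r2
        r2_3 = variance_decomposition(df, ["f1", "f2", "f3"], "y").joint_r2
        assert r2_1 <= r2_2 + 1e-12 <= r2_3 + 1e-12
        # and joint >= best marginal
        res = variance_decomposition(df, ["f1", "f2", "f3"], "y")
        assert res.joint_r2 >= max(res.marginal_r2.values()) - 1e-12

    def test_sequential_anova_sums_to_total(self):
        df, rng = self.frame(n=400, seed=10)
        df["y"] = df.f1 + 0.5 * df.f2 + rng.normal(0, 1, 400)
        res = variance_decomposition(df, ["f1", "f2", "f3"], "y")
        assert res.anova.seq_r2.sum() == pytest.approx(1.0)
        assert res.anova.drop(index="residual").seq_r2.sum() == pytest.approx(
            res.joint_r2
        )

    def test_rank_deficiency_rejected(self):
        df, rng = self.frame(n=100, seed=11)
        df["f2"] = 2 * df["f1"]
        df["y"] = rng.normal(size=100)
        with pytest.raises(DegenerateInputError):
            variance_decomposition(df, ["f1", "f2"], "y")

    def test_too_few_loci_rejected(self):
        df, _ = self.frame(n=5)
        df["y"] = df.f1
        with pytest.raises(ValidationError):
            variance_decomposition(df, ["f1"], "y")


class TestMotifScan:
    def test_reverse_complement_iupac(self):
        assert reverse_complement_motif("ACGR") == "YCGT"

    def test_all_instances_planted_in_cgis(self):
        seq = "A" * 1000 + "TTCGCGAA" + "A" * 1000 + "TTCGCGAA" + "A" * 1000
        cgis = [GenomicInterval("chr1", 900, 1100), GenomicInterval("chr1", 1900, 2100)]
        res = motif_scan_fraction("TTCGCGAA", {"chr1": seq}, ["chr1"], cgis)
        assert res.fraction_in_cgi == 1.0

    def test_absent_motif_rejected(self):
        with pytest.raises(DegenerateInputError):
            motif_scan_fraction("CGCGCGCG", {"chr1": "A" * 500}, ["chr1"], [])

    def test_matches_position_by_position_oracle(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), 20_000))
        cgis = [GenomicInterval("chr1", 2000, 4000), GenomicInterval("chr1", 11_000, 12_500)]
        motif = "ACGT"  # palindromic: one count per position, not per strand
        res = motif_scan_fraction(motif, {"chr1": seq}, ["chr1"], cgis)
        expected = [i for i in range(len(seq) - 3) if seq[i : i + 4] == "ACGT"]
        assert res.n_matches == len(expected)
        in_cgi = sum(2000 <= i < 4000 or 11_000 <= i < 12_500 for i in expected)
        assert res.n_in_cgi == in_cgi
        # companion CpG statistic against the same oracle
        cpg_pos = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
        cpg_in = sum(2000 <= i < 4000 or 11_000 <= i < 12_500 for i in cpg_pos)
        assert res.cpg_fraction_in_cgi == pytest.approx(cpg_in / len(cpg_pos))

    def test_non_palindromic_counts_both_strands(self):
        seq = "GGGACCCGGG"  # ACCC forward at 3; GGGT matches on reverse strand
        res = motif_scan_fraction("ACCC", {"chr1": seq + "ACCCAAAA"}, ["chr1"], [])
        fwd = seq.count("ACCC") + 1
        rc = (seq + "ACCCAAAA").count("GGGT")
        assert res.n_matches == fwd + rc
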