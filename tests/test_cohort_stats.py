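"""Spearman battery, group t-test, phylum summaries, PCR decomposition."""

import math

import numpy as np
import pandas as pd
import pytest

from strandbias.cohort_stats import (
    group_t_test,
    pcr_decomposition,
    phylum_summaries,
    run_correlation_battery,
    spearman,
)
from strandbias.errors import UndefinedStatisticError

from conftest import spearman_bruteforce


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)

    def test_perfect_antitone(self):
        assert spearman([1, 2, 3, 4], [40, 30, 20, 10]).rho == pytest.approx(-1.0)

    def test_pairwise_deletion(self):
        r = spearman([1, 2, 3, 4, math.nan], [1, 4, 9, 16, 25])
        assert r.n_pairs == 4
        assert r.rho == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            spearman([1, 2], [1, 2])

    def test_constant_vector_gives_na(self):
        r = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(r.rho)

    def test_tied_vectors_match_rank_then_pearson_bruteforce(self, rng):
        """Average-rank handling equals an O(n^2) midrank + Pearson oracle."""
        for _ in range(50):
            n = int(rng.integers(4, 13))
            x = rng.integers(0, 5, size=n).astype(float)
            y = rng.integers(0, 5, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y).rho == pytest.approx(
                spearman_bruteforce(x, y), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert spearman(x, y**3).rho == pytest.approx(base, abs=1e-12)


class TestGroupTTest:
    def test_identical_groups(self):
        r = group_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_separated_groups_significant(self, rng):
        g2 = rng.normal(0, 1, size=30)
        r = group_t_test(g2 + 100, g2)
        assert r.p_value < 1e-6
        assert r.mean_group1 > r.mean_group2

    def test_small_group_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            group_t_test([1.0], [1.0, 2.0])

    def test_welch_vs_pooled_differ_under_unequal_variance(self, rng):
        g1 = rng.normal(0, 5, size=10)
        g2 = rng.normal(0, 0.5, size=50)
        welch = group_t_test(g1, g2, equal_var=False)
        pooled = group_t_test(g1, g2, equal_var=True)
        assert welch.p_value != pytest.approx(pooled.p_value)


class TestPhylumSummaries:
    def test_mean_sd_variance(self):
        rows = pd.DataFrame(
            {"phylum": ["P", "P"], "score": [0.1, 0.3], "genome_size": [1e6, 2e6]}
        )
        out = phylum_summaries(rows)
        assert out.loc[0, "score_mean"] == pytest.approx(0.2)
        assert out.loc[0, "score_sd"] == pytest.approx(0.1414, abs=1e-4)
        assert out.loc[0, "score_variance"] == pytest.approx(0.02)
        assert out.loc[0, "score_variance"] == pytest.approx(
            out.loc[0, "score_sd"] ** 2
        )

    def test_singleton_phylum_reports_na(self):
        rows = pd.DataFrame({"phylum": ["Solo"], "score": [0.5]})
        out = phylum_summaries(rows)
        assert math.isnan(out.loc[0, "score_sd"])
        assert math.isnan(out.loc[0, "score_variance"])

    def test_alphabetical_order_and_groupby_oracle(self, rng):
        phyla = rng.choice(list("ZQAM"), size=40)
        scores = rng.uniform(0, 0.1, size=40)
        rows = pd.DataFrame({"phylum": phyla, "score": scores})
        out = phylum_summaries(rows)
        assert list(out["phylum"]) == sorted(set(phyla))
        for _, rec in out.iterrows():
            sel = scores[phyla == rec["phylum"]]
            assert rec["score_mean"] == pytest.approx(sel.mean())
            assert rec["n"] == len(sel)


class TestPCRDecomposition:
    def test_identity_case(self, rng):
        """y equal to one feature, features orthogonalized in sample."""
        n = 40
        raw = rng.normal(size=(n, 3))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        X = pd.DataFrame(q, columns=["f1", "f2", "f3"])
        res = pcr_decomposition(X, q[:, 0])
        assert res.total_r2 == pytest.approx(1.0)
        assert res.as_dict()["f1"] == pytest.approx(1.0, abs=1e-9)
        assert res.as_dict()["f2"] == pytest.approx(0.0, abs=1e-9)

    def test_null_case(self, rng):
        X = pd.DataFrame(rng.normal(size=(400, 4)), columns=list("abcd"))
        res = pcr_decomposition(X, rng.normal(size=400))
        assert res.total_r2 < 0.08

    def test_matches_ols_oracle_and_sums(self, rng):
        """total R^2 equals least-squares R^2 on the components; the
        per-feature contributions sum to it."""
        for _ in range(50):
            X = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
            y = rng.normal(size=50) + X["a"].to_numpy() * rng.uniform(0, 2)
            res = pcr_decomposition(X, y)
            Z = (X - X.mean()) / X.std(ddof=1)
            corr = Z.to_numpy().T @ Z.to_numpy() / 49
            _, vecs = np.linalg.eigh(corr)
            comps = Z.to_numpy() @ vecs
            design = np.column_stack([np.ones(50), comps])
            resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
            yc = y - y.mean()
            r2_ols = 1 - (resid @ resid) / (yc @ yc)
            assert res.total_r2 == pytest.approx(r2_ols, abs=1e-9)
            assert sum(res.contributions) == pytest.approx(res.total_r2, abs=1e-9)
            assert all(c >= -1e-12 for c in res.contributions)

    def test_contributions_invariant_to_feature_rescaling(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        y = X["b"].to_numpy() + rng.normal(size=60)
        base = pcr_decomposition(X, y).as_dict()
        X2 = X.copy()
        X2["a"] = 100 * X2["a"] - 7  # affine rescale
        rescaled = pcr_decomposition(X2, y).as_dict()
        for f in "abcd":
            assert rescaled[f] == pytest.approx(base[f], abs=1e-9)

    def test_constant_feature_rejected(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=30), "b": np.ones(30)})
        with pytest.raises(UndefinedStatisticError):
            pcr_decomposition(X, rng.normal(size=30))

    def test_single_feature_rejected(self, rng):
        with pytest.raises(ValueError):
            pcr_decomposition(pd.DataFrame({"a": rng.normal(size=30)}),
                              rng.normal(size=30))


class TestCorrelationBattery:
    def _rows(self, rng, n=200):
        score = rng.uniform(0, 0.1, size=n)
        return pd.DataFrame(
            {
                "genome_id": [f"g{i}" for i in range(n)],
                "score": score,
                "density": score + rng.normal(0, 0.02, size=n),
                "gc": -score + rng.normal(0, 0.02, size=n),
                "noise": rng.normal(size=n),
                "constant": np.ones(n),
                "phylum": ["P"] * n,
                "obligate_intracellular": [False] * n,
            }
        )

    def test_planted_signs_recovered(self, rng):
        out = run_correlation_battery(self._rows(rng)).set_index("feature")
        assert out.loc["density", "rho"] > 0
        assert out.loc["density", "p_value"] < 0.01
        assert out.loc["gc", "rho"] < 0
        assert out.loc["gc", "p_value"] < 0.01

    def test_constant_column_yields_na_row(self, rng):
        out = run_correlation_battery(self._rows(rng)).set_index("feature")
        assert math.isnan(out.loc["constant", "rho"])
        assert not out.loc["constant", "significant"]

    def test_significance_flags(self, rng):
        out = run_correlation_battery(self._rows(rng)).set_index("feature")
        assert bool(out.loc["density", "significant"])
        assert bool(out.loc["density", "significant_strict"])
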