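"""Partial Spearman estimator, BH-FDR, and the permutation null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from connmed import (
    fdr_bh,
    partial_spearman,
    permutation_null,
    roi_association_screen,
)
from oracles import bh_stepup, first_order_partial_spearman


class TestPartialSpearman:
    def test_no_covariates_equals_ordinary_spearman(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        res = partial_spearman(x, y)
        ref = spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=0.05)

    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.standard_normal(30)
        res = partial_spearman(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)

    def test_matches_first_order_closed_form(self, rng):
        # one covariate: recursive partial-correlation formula on ranks
        for _ in range(10):
            z = rng.standard_normal(30)
            x = 0.5 * z + rng.standard_normal(30)
            y = -0.4 * z + 0.3 * x + rng.standard_normal(30)
            res = partial_spearman(x, y, z)
            assert res.rho == pytest.approx(
                first_order_partial_spearman(x, y, z), abs=1e-10
            )

    def test_invariant_to_monotone_x_and_affine_covariates(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        c = rng.standard_normal((50, 2))
        base = partial_spearman(x, y, c)
        warped = partial_spearman(np.exp(x), y, 3.0 * c - 7.0)
        assert warped.rho == pytest.approx(base.rho, abs=1e-12)
        assert warped.p == pytest.approx(base.p, abs=1e-12)

    def test_degenerate_variable_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate"):
            partial_spearman(np.ones(20), rng.standard_normal(20))

    def test_too_small_n_rejected(self, rng):
        with pytest.raises(ValueError):
            partial_spearman(
                rng.standard_normal(5), rng.standard_normal(5),
                rng.standard_normal((5, 2)),
            )


class TestFdrBH:
    def test_four_test_worked_example(self):
        q = fdr_bh(np.array([0.004, 0.021, 0.002, 0.478]))
        assert np.round(q, 3) == pytest.approx([0.008, 0.028, 0.008, 0.478])

    def test_second_worked_example_at_printed_rounding(self):
        q = fdr_bh(np.array([0.003, 0.383, 0.006, 0.87]))
        assert np.round(q, 4) == pytest.approx([0.012, 0.5107, 0.012, 0.87])
        assert np.round(q, 2) == pytest.approx([0.01, 0.51, 0.01, 0.87])

    def test_single_p_unchanged(self):
        assert fdr_bh(np.array([0.037]))[0] == pytest.approx(0.037)

    @given(
        st.lists(st.floats(1e-6, 1.0, allow_nan=False), min_size=1, max_size=12)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_stepup_oracle_and_dominates_p(self, ps):
        p = np.asarray(ps)
        q = fdr_bh(p)
        assert np.abs(q - bh_stepup(p)).max() < 1e-12
        assert (q >= p - 1e-15).all() and (q <= 1.0 + 1e-15).all()

    def test_permutation_invariance(self, rng):
        p = rng.uniform(1e-4, 1, size=8)
        perm = rng.permutation(8)
        assert fdr_bh(p)[perm] == pytest.approx(fdr_bh(p[perm]), abs=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.0, 0.5]))


class TestPermutationNull:
    def test_extreme_observation_hits_p_floor(self, rng):
        x = np.arange(101.0)
        y = x + 0.01 * rng.standard_normal(101)
        res = permutation_null(x, y, B=500, seed=1)
        assert res.empirical_p == pytest.approx(1.0 / 501.0)

    def test_same_seed_reproduces_null_distribution(self, rng):
        x = rng.standard_normal(60)
        y = rng.standard_normal(60)
        c = rng.standard_normal((60, 2))
        a = permutation_null(x, y, c, B=200, seed=9)
        b = permutation_null(x, y, c, B=200, seed=9)
        assert np.array_equal(a.null_rhos, b.null_rhos)
        assert a.empirical_p == b.empirical_p

    def test_small_b_warns(self, rng):
        with pytest.warns(UserWarning, match="resolution"):
            permutation_null(
                rng.standard_normal(30), rng.standard_normal(30), B=50, seed=0
            )

    def test_observed_rho_matches_partial_spearman(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        c = rng.standard_normal((50, 3))
        res = permutation_null(x, y, c, B=100, seed=2)
        assert res.observed_rho == pytest.approx(
            partial_spearman(x, y, c).rho, abs=1e-12
        )

    def test_empirical_and_t_approximation_agree(self):
        # independent normals at n=101: the two p-values agree closely
        diffs = []
        for seed in range(200):
            gen = np.random.default_rng(seed)
            x = gen.standard_normal(101)
            y = gen.standard_normal(101)
            c = gen.standard_normal((101, 3))
            p_t = partial_spearman(x, y, c).p
            p_e = permutation_null(x, y, c, B=1000, seed=seed).empirical_p
            diffs.append(abs(p_t - p_e))
        assert np.mean(diffs) < 0.02


class TestRoiAssociationScreen:
    def _tables(self, rng, effect=0.0):
        n = 60
        ids = [f"s{i}" for i in range(n)]
        cov = rng.standard_normal((n, 3))
        y = rng.standard_normal(n)
        values = pd.DataFrame(
            {r: rng.standard_normal(n) for r in ("A", "B", "C", "D")}, index=ids
        )
        values["A"] += effect * y
        pheno = pd.DataFrame(
            {
                "subject_id": ids,
                "speed": y,
                "age": cov[:, 0],
                "sex": (cov[:, 1] > 0).astype(int),
                "education": cov[:, 2],
            }
        )
        return values, pheno

    def test_null_screen_q_dominates_p(self, rng):
        values, pheno = self._tables(rng)
        out = roi_association_screen(
            values, pheno, ["A", "B", "C", "D"], "speed"
        )
        assert (out["q"] >= out["p"] - 1e-15).all()
        assert list(out["region"]) == ["A", "B", "C", "D"]

    def test_planted_region_has_largest_association(self):
        hits = 0
        for seed in range(50):
            gen = np.random.default_rng(seed)
            values, pheno = self._tables(gen, effect=0.8)
            out = roi_association_screen(
                values, pheno, ["A", "B", "C", "D"], "speed"
            ).set_index("region")
            hits += out["rho"].abs().idxmax() == "A"
        assert hits >= 45

    def test_single_region_q_equals_p(self, rng):
        values, pheno = self._tables(rng)
        out = roi_association_screen(values, pheno, ["B"], "speed")
        assert out.loc[0, "q"] == pytest.approx(out.loc[0, "p"])

    def test_permutation_columns_present_when_requested(self, rng):
        values, pheno = self._tables(rng)
        out = roi_association_screen(
            values, pheno, ["A", "B"], "speed", permutation_B=200, seed=4
        )
        assert {"empirical_p", "B"} <= set(out.columns)
        assert out["empirical_p"].between(1 / 201, 1).all()

    def test_insufficient_overlap_rejected(self, rng):
        values, pheno = self._tables(rng)
        with pytest.raises(ValueError, match="subjects"):
            roi_association_screen(
                values.iloc[:4], pheno, ["A"], "speed", min_n=10
            )
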