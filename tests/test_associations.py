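import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from metaboclock import (
    PathwayAnnotation,
    bh_adjust,
    concordance_quadrants,
    pathway_ora,
    set_overlap_test,
    univariate_assoc,
)
from metaboclock.associations import (
    AGE_ONLY,
    CONCORDANT,
    DISCORDANT,
    NEITHER,
    OBSTRUCTION_ONLY,
)


class TestUnivariateAssoc:
    def test_exact_linear_relation(self):
        X = pd.DataFrame({"m1": [1.0, 2.0, 3.0, 4.0]})
        rec = univariate_assoc(X, 2.0 * X["m1"].to_numpy())
        assert rec.loc["m1", "slope"] == pytest.approx(2.0)
        assert rec.loc["m1", "p"] < 1e-10
        assert np.isfinite(rec.loc["m1", "signed_logp"])

    def test_closed_form_small_case(self):
        X = pd.DataFrame({"m1": [1.0, 2.0, 3.0]})
        rec = univariate_assoc(X, np.array([1.0, 2.0, 4.0]))
        assert rec.loc["m1", "slope"] == pytest.approx(1.5)
        assert rec.loc["m1", "p"] == pytest.approx(0.121, abs=1e-3)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(0, 1, (50, 4)),
                         columns=[f"m{j}" for j in range(4)])
        y = rng.normal(60, 5, 50)
        perm = rng.permutation(50)
        a = univariate_assoc(X, y)
        b = univariate_assoc(X.iloc[perm].reset_index(drop=True), y[perm])
        pd.testing.assert_frame_equal(a, b)

    def test_constant_metabolite_flagged(self):
        X = pd.DataFrame({"m1": [1.0, 1.0, 1.0, 1.0],
                          "m2": [1.0, 2.0, 3.0, 4.0]})
        rec = univariate_assoc(X, np.array([1.0, 2.0, 1.5, 2.5]))
        assert bool(rec.loc["m1", "constant"])
        assert np.isnan(rec.loc["m1", "p"])
        assert not rec.loc["m2", "constant"]

    def test_signed_logp_invariants(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(0, 1, (60, 10)),
                         columns=[f"m{j}" for j in range(10)])
        y = X["m0"] * 3 - X["m1"] * 2 + rng.normal(0, 1, 60)
        rec = univariate_assoc(X, y.to_numpy())
        ok = ~rec["constant"]
        assert (np.sign(rec.loc[ok, "signed_logp"])
                == np.sign(rec.loc[ok, "slope"])).all()
        np.testing.assert_allclose(np.abs(rec.loc[ok, "signed_logp"]),
                                   -np.log10(rec.loc[ok, "p"]))

    def test_regression_direction_symmetry(self):
        """Simple OLS slope sign and p are unchanged by swapping the roles
        of regressor and response."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.normal(0, 1, 30)
            y = 0.5 * x + rng.normal(0, 1, 30)
            fwd = univariate_assoc(pd.DataFrame({"m": x}), y)
            rev = univariate_assoc(pd.DataFrame({"m": y}), x)
            assert np.sign(fwd.loc["m", "slope"]) == np.sign(rev.loc["m", "slope"])
            assert fwd.loc["m", "p"] == pytest.approx(rev.loc["m", "p"], rel=1e-9)


class TestConcordanceQuadrants:
    def _rec(self, slope, p):
        return pd.DataFrame({"slope": [slope], "p": [p]},
                            index=pd.Index(["m1"], name="metabolite_id"))

    @pytest.mark.parametrize("s_age,p_age,s_ratio,p_ratio,expected", [
        (1.0, 0.01, -1.0, 0.01, CONCORDANT),   # up with age, worse obstruction
        (1.0, 0.01, 1.0, 0.01, DISCORDANT),
        (1.0, 0.01, 1.0, 0.5, AGE_ONLY),
        (1.0, 0.5, -1.0, 0.01, OBSTRUCTION_ONLY),
        (1.0, 0.5, 1.0, 0.5, NEITHER),
    ])
    def test_default_orientation(self, s_age, p_age, s_ratio, p_ratio, expected):
        cls = concordance_quadrants(self._rec(s_age, p_age),
                                    self._rec(s_ratio, p_ratio))
        assert cls.loc["m1"] == expected

    def test_orientation_flag_flips_concordance(self):
        cls = concordance_quadrants(self._rec(1.0, 0.01), self._rec(-1.0, 0.01),
                                    obstruction_sign_flip=False)
        assert cls.loc["m1"] == DISCORDANT

    def test_mismatched_sets_rejected(self):
        a = self._rec(1.0, 0.01)
        b = a.copy()
        b.index = pd.Index(["other"], name="metabolite_id")
        with pytest.raises(ValueError, match="differ"):
            concordance_quadrants(a, b)


class TestSetOverlap:
    def test_score_model_sized_example(self):
        universe = {f"m{i}" for i in range(831)}
        a = {f"m{i}" for i in range(378)}
        b = {f"m{i}" for i in range(148, 148 + 461)}  # overlap 230
        res = set_overlap_test(a, b, universe)
        assert res.observed_overlap == 230
        assert res.expected_overlap == pytest.approx(378 * 461 / 831, abs=1e-9)
        assert res.chi2_statistic == pytest.approx(8.1, abs=0.1)
        assert res.chi2_p == pytest.approx(0.004, abs=5e-4)
        assert res.hypergeom_p < res.chi2_p  # one-sided tail is tighter here

    def test_identical_sets_statistic_zero_is_degenerate(self):
        u = {f"m{i}" for i in range(10)}
        res = set_overlap_test(u, u, u)
        assert res.observed_overlap == 10
        assert res.expected_overlap == 10.0
        assert res.chi2_statistic == 0.0

    def test_disjoint_partition_negative_association(self):
        u = {f"m{i}" for i in range(20)}
        a = {f"m{i}" for i in range(8)}
        b = u - a
        res = set_overlap_test(a, b, u)
        assert res.observed_overlap == 0
        assert res.expected_overlap > 0
        assert res.hypergeom_p == pytest.approx(1.0)

    def test_empty_set_warns_p_one(self):
        u = {"m1", "m2"}
        with pytest.warns(UserWarning, match="empty"):
            res = set_overlap_test(set(), {"m1"}, u)
        assert res.chi2_p == 1.0

    def test_chi2_and_hypergeom_same_order_of_magnitude(self):
        """For comfortably large expected overlap the two tests agree in
        order of magnitude."""
        rng = np.random.default_rng(3)
        u = {f"m{i}" for i in range(500)}
        a = set(rng.choice(sorted(u), 200, replace=False))
        b = set(rng.choice(sorted(u), 250, replace=False))
        res = set_overlap_test(a, b, u)
        if res.chi2_p > 1e-12 and res.hypergeom_p > 1e-12:
            assert abs(np.log10(res.chi2_p) - np.log10(res.hypergeom_p)) < 1.5


class TestPathwayORA:
    def _annotation(self, assignment: dict):
        return PathwayAnnotation(
            sub_pathway=dict(assignment),
            super_pathway={m: None for m in assignment},
        )

    def test_hypergeometric_example(self):
        # universe 20, pathway of 5, 8 selected, overlap 4
        ann = self._annotation(
            {f"m{i}": ("pw" if i < 5 else "bg") for i in range(20)})
        selected = [f"m{i}" for i in [0, 1, 2, 3, 7, 8, 9, 10]]
        res = pathway_ora(selected, ann, level="sub")
        row = res[res["pathway"] == "pw"].iloc[0]
        assert row["overlap"] == 4
        assert row["p"] == pytest.approx(0.0578, abs=2e-4)

    def test_exact_enumeration_oracle(self):
        """ORA p equals the brute-force tail mass over all hypergeometric
        outcomes on small universes."""
        rng = np.random.default_rng(4)
        for trial in range(6):
            n_univ = int(rng.integers(10, 25))
            n_path = int(rng.integers(2, n_univ - 1))
            n_sel = int(rng.integers(1, n_univ))
            mets = [f"m{i}" for i in range(n_univ)]
            ann = self._annotation(
                {m: ("pw" if i < n_path else "bg") for i, m in enumerate(mets)})
            selected = list(rng.choice(mets, n_sel, replace=False))
            res = pathway_ora(selected, ann, level="sub")
            row = res[res["pathway"] == "pw"].iloc[0]
            k_obs = row["overlap"]
            from math import comb
            total = comb(n_univ, n_sel)
            brute = sum(comb(n_path, k) * comb(n_univ - n_path, n_sel - k)
                        for k in range(k_obs, min(n_path, n_sel) + 1)) / total
            assert row["p"] == pytest.approx(brute, rel=1e-9)

    def test_selected_equals_pathway_extreme(self):
        ann = self._annotation(
            {f"m{i}": ("pw" if i < 4 else "bg") for i in range(16)})
        res = pathway_ora([f"m{i}" for i in range(4)], ann, level="sub")
        row = res[res["pathway"] == "pw"].iloc[0]
        from math import comb
        assert row["p"] == pytest.approx(1 / comb(16, 4), rel=1e-9)

    def test_unannotated_excluded_from_universe(self):
        ann = PathwayAnnotation(
            sub_pathway={"m1": "pw", "m2": "pw", "m3": "bg", "m4": None},
            super_pathway={"m1": None, "m2": None, "m3": None, "m4": None})
        res = pathway_ora(["m1", "m4"], ann, level="sub")
        assert (res["n_universe"] == 3).all()  # m4 cannot count anywhere
        assert (res["n_selected"] == 1).all()

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(5)
        assignment = {f"m{i}": f"pw{i % 5}" for i in range(40)}
        ann = self._annotation(assignment)
        sel = list(rng.choice(sorted(assignment), 12, replace=False))
        res = pathway_ora(sel, ann, level="sub")
        assert (res["p_adj"] >= res["p"] - 1e-15).all()
        assert res["p"].is_monotonic_increasing

    def test_null_type_i_control(self, small_pair):
        """Random (unplanted) selections produce ~no BH-significant pathways."""
        _, _, truth = small_pair
        rng = np.random.default_rng(6)
        universe = list(truth.metabolites.index)
        n_hits = 0
        for _ in range(5):
            sel = rng.choice(universe, 30, replace=False)
            res = pathway_ora(sel, truth.annotation, level="sub")
            if not res.empty:
                n_hits += int((res["p_adj"] < 0.05).sum())
        assert n_hits == 0


class TestBHAdjust:
    def test_small_examples(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([0.005, 0.04, 0.04, 0.8]),
                                   [0.02, 0.04 * 4 / 3, 0.04 * 4 / 3, 0.8])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_step_up_oracle(self, pvals):
        """Independent textbook re-implementation of BH step-up."""
        p = np.asarray(pvals)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / np.arange(1, m + 1)
        adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(bh_adjust(p), oracle, rtol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30),
           st.floats(0.001, 0.2))
    def test_cutoff_order_preservation(self, pvals, cut):
        """Any BH-significant set at a cutoff is a down-set of the raw
        p-value ordering."""
        p = np.asarray(pvals)
        adj = bh_adjust(p)
        sig = adj <= cut
        if sig.any():
            assert p[sig].max() <= p[~sig].min() + 1e-12 if (~sig).any() else True

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])
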