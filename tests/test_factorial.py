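"""Design coding, OLS, BH adjustment, equation simplification, subgroups, merging."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from ferroglc.core import PipelineConfig, SampleRecord, canonical_conditions
from ferroglc.factorial import (
    EquationGroup,
    FactorialFit,
    TERMS,
    adjust_fdr,
    assign_subgroups,
    build_design,
    cross_validate_reduced,
    fit_full_model,
    fit_proteome,
    merge_groups,
    simplify_equation,
    simplify_proteome,
)

from conftest import full_design_log2, matrix_from_log2


def balanced_samples(n_reps=2):
    out = []
    for c in canonical_conditions(("WT", "hxk1-2")):
        for r in range(1, n_reps + 1):
            out.append(SampleRecord(f"{c.label}_r{r}", c.strain, c.fe, c.glc, r))
    return out


def _fit(betas: dict, pvals: dict, protein_id="p") -> FactorialFit:
    b = {t: betas.get(t, 0.0) for t in TERMS}
    p = {t: pvals.get(t, 1.0) for t in TERMS}
    return FactorialFit(protein_id, 0.0, b, p, pd.Series(dtype=float), 1.0, 8)


class TestDesign:
    def test_coding_of_wt_plus_plus(self):
        s = SampleRecord("x", "WT", 1, 1, 1)
        row = build_design([s] + balanced_samples()).loc["x"]
        assert list(row) == [1.0] + [1.0] * 7

    def test_coding_of_hxk_minus_minus(self):
        """Interaction signs are products: the triple term is (-1)^3 = -1."""
        s = SampleRecord("x", "hxk1-2", -1, -1, 9)
        row = build_design([s] + balanced_samples()).loc["x"]
        expected = {"intercept": 1, "Fe": -1, "Glc": -1, "strain": -1,
                    "Fe:Glc": 1, "strain:Glc": 1, "strain:Fe": 1,
                    "strain:Fe:Glc": -1}
        assert {k: int(v) for k, v in row.items()} == expected

    def test_balanced_design_is_orthogonal(self):
        X = build_design(balanced_samples()).to_numpy()
        gram = X.T @ X
        assert np.allclose(gram, np.diag(np.diag(gram)))

    def test_empty_cell_listed_in_error(self):
        samples = [s for s in balanced_samples() if s.condition.label != "WT-Fe+Glc"]
        with pytest.raises(ValueError, match="WT-Fe\\+Glc"):
            build_design(samples)

    def test_hxk1_1_rejected_from_design(self):
        samples = balanced_samples() + [SampleRecord("y", "hxk1-1", 1, 1, 1)]
        with pytest.raises(ValueError, match="hxk1-1"):
            build_design(samples)


class TestOls:
    def test_constant_response(self):
        samples = balanced_samples()
        design = build_design(samples)
        y = pd.Series(10.0, index=design.index)
        fit = fit_full_model(y, design)
        assert fit.alpha == pytest.approx(10.0)
        assert all(b == pytest.approx(0.0, abs=1e-12) for b in fit.betas.values())
        # zero-residual degenerate rule: nonzero betas get p=0, zero betas p=1
        assert all(p == 1.0 for p in fit.term_p.values())

    def test_exact_three_term_surface_recovered(self):
        samples = balanced_samples(n_reps=3)
        design = build_design(samples)
        y = pd.Series(
            5.0 + 2.0 * design["Fe"] + 1.0 * design["Glc"] - 0.5 * design["Fe:Glc"],
            index=design.index,
        )
        fit = fit_full_model(y, design)
        assert fit.betas["Fe"] == pytest.approx(2.0, abs=1e-10)
        assert fit.betas["Glc"] == pytest.approx(1.0, abs=1e-10)
        assert fit.betas["Fe:Glc"] == pytest.approx(-0.5, abs=1e-10)
        for t in ("strain", "strain:Glc", "strain:Fe", "strain:Fe:Glc"):
            assert fit.betas[t] == pytest.approx(0.0, abs=1e-10)
        assert fit.term_p["Fe"] == 0.0 and fit.term_p["strain"] == 1.0

    def test_balanced_beta_equals_half_contrast(self, rng):
        samples = balanced_samples(n_reps=3)
        design = build_design(samples)
        y = pd.Series(rng.normal(8, 1, len(design)), index=design.index)
        fit = fit_full_model(y, design)
        plus = y[design["Fe"] == 1].mean()
        minus = y[design["Fe"] == -1].mean()
        assert fit.betas["Fe"] == pytest.approx((plus - minus) / 2, abs=1e-12)
        assert fit.alpha == pytest.approx(y.mean(), abs=1e-12)

    def test_matches_statsmodels_on_noisy_unbalanced_data(self, rng):
        """Independent cross-check of coefficients and t-test p-values."""
        samples = balanced_samples(n_reps=3)
        design = build_design(samples)
        y = pd.Series(rng.normal(8, 1, len(design)), index=design.index)
        y.iloc[[0, 5, 11]] = np.nan  # unbalance the design
        fit = fit_full_model(y, design)
        mask = y.notna()
        ref = sm.OLS(y[mask], design[mask]).fit()
        for i, t in enumerate(TERMS):
            assert fit.betas[t] == pytest.approx(ref.params.iloc[i + 1], abs=1e-10)
            assert fit.term_p[t] == pytest.approx(ref.pvalues.iloc[i + 1], abs=1e-10)
        assert fit.r_squared == pytest.approx(ref.rsquared, abs=1e-10)

    def test_residual_mean_absorbed_by_intercept(self, rng):
        samples = balanced_samples(n_reps=2)
        design = build_design(samples)
        y = pd.Series(rng.normal(5, 2, len(design)), index=design.index)
        fit = fit_full_model(y, design)
        assert abs(fit.residuals.mean()) < 1e-9

    def test_too_few_samples_rejected(self):
        samples = balanced_samples(n_reps=1)
        design = build_design(samples)
        y = pd.Series(1.0, index=design.index)
        with pytest.raises(ValueError, match="more than 8"):
            fit_full_model(y, design)


class TestBenjaminiHochberg:
    @staticmethod
    def brute_force_bh(p, alpha):
        """Textbook step-up: reject 1..k for the largest k with p_(k) <= k*alpha/m."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        k_max = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * alpha / m:
                k_max = k
        reject = np.zeros(m, bool)
        reject[order[:k_max]] = True
        adj = np.empty(m)
        running = 1.0
        for k in range(m, 0, -1):
            running = min(running, p[order[k - 1]] * m / k)
            adj[order[k - 1]] = running
        return reject, adj

    def test_equal_spaced_example(self):
        p = pd.DataFrame({"t": [0.01, 0.02, 0.03, 0.04]})
        adj, mask = adjust_fdr(p, level=0.05)
        assert np.allclose(adj["t"], 0.04)
        assert mask["t"].all()

    def test_all_ones_nothing_significant(self):
        p = pd.DataFrame({"t": [1.0, 1.0, 1.0]})
        _, mask = adjust_fdr(p, level=0.05)
        assert not mask.any().any()

    def test_single_p_identity(self):
        p = pd.DataFrame({"t": [0.04]})
        adj, mask = adjust_fdr(p, level=0.05)
        assert adj.iloc[0, 0] == pytest.approx(0.04)
        assert bool(mask.iloc[0, 0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pooled_family_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = pd.DataFrame(rng.beta(0.5, 3, size=(40, 7)), columns=list(TERMS))
        adj, mask = adjust_fdr(p, level=0.05, family="pooled")
        reject_ref, adj_ref = self.brute_force_bh(p.to_numpy().ravel(), 0.05)
        assert np.allclose(adj.to_numpy().ravel(), adj_ref, atol=1e-12)
        assert (mask.to_numpy().ravel() == reject_ref).all()

    def test_adjusted_monotone_in_raw(self, rng):
        p = pd.DataFrame(rng.uniform(size=(30, 7)), columns=list(TERMS))
        adj, _ = adjust_fdr(p)
        flat = pd.DataFrame({"raw": p.to_numpy().ravel(), "adj": adj.to_numpy().ravel()})
        flat = flat.sort_values("raw")
        assert (np.diff(flat["adj"]) >= -1e-15).all()


class TestSimplifyEquation:
    def test_dominance_truncation_worked_example(self):
        """|4| >= 4*|0.25| breaks after Glc: '4Fe+4Glc+0.25strain+0.1strain:Glc' -> Fe, Glc."""
        fit = _fit({"Fe": 4.0, "Glc": 4.0, "strain": 0.25, "strain:Glc": 0.1},
                   {t: 0.0 for t in TERMS})
        eq = simplify_equation(fit, ["Fe", "Glc", "strain", "strain:Glc"])
        assert eq.group_key == frozenset({"Fe", "Glc"})
        assert eq.label == "+Fe+Glc"

    def test_effect_floor_empties_small_equations(self):
        fit = _fit({"Fe": 0.2, "Glc": 0.1}, {"Fe": 0.0, "Glc": 0.0})
        eq = simplify_equation(fit, ["Fe", "Glc"])
        assert eq.retained == () and eq.label == "none"

    def test_ratio_below_dominance_keeps_both(self):
        fit = _fit({"Fe": 1.0, "Glc": 0.3}, {"Fe": 0.0, "Glc": 0.0})
        eq = simplify_equation(fit, ["Fe", "Glc"])
        assert eq.group_key == frozenset({"Fe", "Glc"})

    def test_non_significant_terms_dropped_first(self):
        fit = _fit({"Fe": 4.0, "Glc": 4.0}, {"Fe": 0.0, "Glc": 0.5})
        eq = simplify_equation(fit, ["Fe"])
        assert eq.group_key == frozenset({"Fe"})

    def test_signs_recorded_in_subgroup_key(self):
        fit = _fit({"Fe": -1.0, "Glc": 0.5}, {"Fe": 0.0, "Glc": 0.0})
        eq = simplify_equation(fit, ["Fe", "Glc"])
        assert eq.label == "-Fe+Glc"
        assert eq.subgroup_key == (("Fe", -1), ("Glc", 1))

    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=7, max_size=7))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_idempotent_and_dominance_postcondition(self, beta_values):
        config = PipelineConfig()
        betas = dict(zip(TERMS, beta_values))
        fit = _fit(betas, {t: 0.0 for t in TERMS})
        eq = simplify_equation(fit, list(TERMS), config)
        # postcondition: no consecutive retained pair violates the dominance rule
        mags = [abs(b) for _, b in eq.retained]
        for a, b in zip(mags, mags[1:]):
            assert a < config.dominance_ratio * b
        # idempotence: simplifying the retained set again changes nothing
        again = simplify_equation(fit, [t for t, _ in eq.retained], config)
        assert again.retained == eq.retained


class TestSubgroupsAndMerging:
    def test_opposite_signs_share_group_but_not_subgroup(self):
        m = matrix_from_log2({
            "up": full_design_log2(lambda s, f, g: 8.0 + f),
            "down": full_design_log2(lambda s, f, g: 8.0 - f),
        })
        m = m.replace_values(m.values, imputed_mask=None)
        eq_up = simplify_equation(_fit({"Fe": 1.0}, {"Fe": 0.0}, "up"), ["Fe"])
        eq_down = simplify_equation(_fit({"Fe": -1.0}, {"Fe": 0.0}, "down"), ["Fe"])
        assert eq_up.group_key == eq_down.group_key == frozenset({"Fe"})
        assert eq_up.label != eq_down.label
        groups = assign_subgroups([eq_up, eq_down], m)
        assert len(groups) == 2

    def test_empty_equations_form_none_subgroup(self):
        m = matrix_from_log2({"p1": full_design_log2(lambda s, f, g: 8.0)})
        eq = simplify_equation(_fit({}, {}, "p1"), [])
        groups = assign_subgroups([eq], m)
        assert len(groups) == 1 and groups[0].label == "none"

    def test_identical_labels_pool_members(self):
        m = matrix_from_log2({
            pid: full_design_log2(lambda s, f, g: 8.0 + f) for pid in ("a", "b", "c")
        })
        eqs = [simplify_equation(_fit({"Fe": 1.0}, {"Fe": 0.0}, pid), ["Fe"])
               for pid in ("a", "b", "c")]
        groups = assign_subgroups(eqs, m)
        assert len(groups) == 1 and groups[0].size == 3

    @staticmethod
    def _group(label, members, profile):
        idx = [f"c{i}" for i in range(len(profile))]
        return EquationGroup(label, ((label, 1),), list(members),
                             pd.Series(profile, index=idx, dtype=float))

    def test_identical_profiles_merge_to_larger_name(self):
        g1 = self._group("big", ["a", "b", "c"], [1.0, -1.0, 0.5, -0.5])
        g2 = self._group("small", ["d"], [1.0, -1.0, 0.5, -0.5])
        merged = merge_groups([g1, g2], 0.9)
        assert len(merged) == 1
        assert merged[0].label == "big" and merged[0].size == 4

    def test_equal_size_tie_breaks_lexicographically(self):
        g1 = self._group("zeta", ["a"], [1.0, -1.0, 0.5, -0.5])
        g2 = self._group("alpha", ["b"], [1.0, -1.0, 0.5, -0.5])
        merged = merge_groups([g1, g2], 0.9)
        assert merged[0].label == "alpha"

    def test_low_correlation_pair_unchanged(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 0.0, 0.0])
        z = np.array([0.0, 0.0, 0.0, 0.0, 1.0, -1.0])
        y = 0.5 * x + np.sqrt(1 - 0.25) * z * np.std(x) / np.std(z)
        assert abs(np.corrcoef(x, y)[0, 1] - 0.5) < 1e-9
        merged = merge_groups([self._group("a", ["p"], x), self._group("b", ["q"], y)], 0.9)
        assert len(merged) == 2

    def test_three_mutually_correlated_groups_collapse(self, rng):
        base = rng.normal(0, 1, 8)
        groups = [
            self._group(name, [name], base + rng.normal(0, 0.05, 8))
            for name in ("g1", "g2", "g3")
        ]
        assert len(merge_groups(groups, 0.9)) == 1

    def test_merge_never_increases_count_and_order_invariant(self, rng):
        base = rng.normal(0, 1, 8)
        groups = [self._group(f"g{i}", [f"g{i}"], base + rng.normal(0, 2.0, 8))
                  for i in range(5)]
        merged_fwd = merge_groups(groups, 0.9)
        merged_rev = merge_groups(groups[::-1], 0.9)
        assert len(merged_fwd) <= 5
        assert sorted(g.label for g in merged_fwd) == sorted(g.label for g in merged_rev)

    def test_zero_variance_profile_excluded_with_warning(self):
        flat = self._group("flat", ["p"], [0.0, 0.0, 0.0, 0.0])
        live = self._group("live", ["q"], [1.0, -1.0, 0.5, -0.5])
        with pytest.warns(UserWarning, match="zero variance"):
            merged = merge_groups([flat, live], 0.9)
        assert len(merged) == 2


class TestCrossValidation:
    def test_noiseless_strain_independent_protein_has_zero_test_residuals(self):
        m = matrix_from_log2({
            "p1": full_design_log2(lambda s, f, g: 8.0 + f + 0.5 * g, n_replicates=3),
            "p2": full_design_log2(lambda s, f, g: 9.0 - 0.6 * f * g, n_replicates=3),
        })
        fits = fit_proteome(m)
        eqs, _ = simplify_proteome(fits)
        report, summary = cross_validate_reduced(m, eqs)
        assert (report["test_frac_lt_0.5"] == 1.0).all()
        assert summary["strain_independent"]["test_frac_lt_0.5"] == 1.0

    def test_strain_effect_shifts_test_residuals_by_two_beta(self):
        # true strain beta = 2: hxk1-2 samples sit 4 log2 below the WT surface
        m = matrix_from_log2({
            "p1": full_design_log2(lambda s, f, g: 8.0 + 2.0 * s, n_replicates=3),
        })
        report, _ = cross_validate_reduced(m, [])
        assert report.loc[0, "train_frac_lt_0.5"] == 1.0
        assert report.loc[0, "test_frac_lt_0.5"] == 0.0

    def test_train_test_agreement_for_strain_independent_cohort(self):
        rng = np.random.default_rng(42)
        vals = {}
        for i in range(60):
            beta_f, beta_g = rng.normal(0, 1), rng.normal(0, 1)
            noise = iter(rng.normal(0, 0.25, 100))
            vals[f"p{i}"] = {
                lbl: [v + next(noise) for v in reps]
                for lbl, reps in full_design_log2(
                    lambda s, f, g: 8.0 + beta_f * f + beta_g * g, n_replicates=3
                ).items()
            }
        m = matrix_from_log2(vals)
        fits = fit_proteome(m)
        eqs, _ = simplify_proteome(fits)
        report, summary = cross_validate_reduced(m, eqs)
        si = summary["strain_independent"]
        # train residuals shrink by sqrt(1-h) and test residuals inflate by
        # sqrt(1+h) (h = 4/12 here), so ~8 points is the expected 0.5-bin gap
        assert abs(si["train_frac_lt_0.5"] - si["test_frac_lt_0.5"]) < 0.10
        assert abs(si["train_frac_lt_1.0"] - si["test_frac_lt_1.0"]) < 0.02
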