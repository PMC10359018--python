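"""Fitness bookkeeping, omega recursion, medians and path comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import seqmut as sm
from seqmut.model import CASE_DECREASE, CASE_EQUAL, CASE_INCREASE

from conftest import neutral_assay_path, random_valid_path, two_type_sim


class TestMutationPath:
    def test_validation(self):
        with pytest.raises(ValueError, match="supercritical"):
            sm.MutationPath([1.0], [1.2], [0.0])
        with pytest.raises(ValueError, match="nonnegative"):
            sm.MutationPath([1.0], [-0.1], [0.0])
        with pytest.raises(ValueError, match="unreachable"):
            sm.MutationPath([1.0, 1.0], [0.0, 0.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="beta"):
            sm.MutationPath([1.0, 1.0], [0.0], [0.01, 0.0])

    def test_nu_may_omit_final_type(self):
        p = sm.MutationPath([1.0, 1.0], [0.0, 0.0], [0.01])
        assert p.nu == (0.01, 0.0)

    def test_one_based_accessors(self, fig1_path):
        assert fig1_path.rates_of(1) == (1.1, 0.8, 0.01)
        assert fig1_path.rates_of(3) == (1.1, 0.5, 0.0)
        with pytest.raises(IndexError):
            fig1_path.rates_of(4)


class TestFitnessProfile:
    def test_printed_three_type_rates(self, fig1_path):
        prof = sm.fitness_profile(fig1_path)
        assert np.allclose(prof.lam, [0.3, 0.1, 0.6])
        assert np.allclose(prof.delta, [0.3, 0.3, 0.6])
        assert list(prof.r) == [1, 1, 1]
        assert prof.case == (CASE_DECREASE, CASE_INCREASE)

    def test_neutral_path_attains_max_everywhere(self):
        p = neutral_assay_path(1e-3, n_types=5)
        prof = sm.fitness_profile(p)
        assert np.allclose(prof.delta, 1.0)
        assert list(prof.r) == [1, 2, 3, 4, 5]

    def test_tail_parameters_of_simulated_regimes(self):
        # increasing alpha_2 turns the tail from 1 down to 1/4
        for alpha2, tail in [(4.3, 0.25), (2.3, 0.5), (1.0, 1.0)]:
            prof = sm.fitness_profile(two_type_sim(alpha2))
            assert prof.tail(2) == pytest.approx(tail)
        # three-type: (1.0, 0.7, 2.0) -> delta (1, 1, 2), tails (1, 1, 0.5)
        p = sm.MutationPath((1.2, 1.0, 2.4), (0.2, 0.3, 0.4), (0.01, 0.001, 0.0))
        prof = sm.fitness_profile(p)
        assert np.allclose(prof.delta, [1.0, 1.0, 2.0])
        assert list(prof.r) == [1, 1, 1]
        assert [prof.tail(n) for n in (1, 2, 3)] == pytest.approx([1.0, 1.0, 0.5])

    def test_supercriticality_guard(self):
        p = sm.MutationPath([1.0, 1.0], [0.4, 0.0], [0.01, 0.0])
        object.__setattr__(p, "beta", (1.4, 0.0))  # bypass constructor check
        with pytest.raises(ValueError, match="supercriticality"):
            sm.fitness_profile(p)

    def test_mildly_deleterious_warning(self):
        p = sm.MutationPath([1.0, 0.99], [0.0, 0.02], [0.01, 0.0])
        with pytest.warns(RuntimeWarning, match="mildly deleterious"):
            prof = sm.fitness_profile(p)
        assert prof.warn_steps == (1,)

    @given(st.lists(st.floats(-2, 2), min_size=1, max_size=10),
           st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=200, derandomize=True)
    def test_delta_r_match_brute_force(self, lam_tail, seed):
        """delta/r agree with direct max-and-count over prefixes (values on
        a coarse grid so ties are exact, not borderline-within-tolerance)."""
        rng = np.random.default_rng(seed)
        lam = np.array([round(rng.uniform(0.1, 2.0), 3)]
                       + [round(v, 3) for v in lam_tail])
        alpha = np.abs(lam) + 0.5
        p = sm.MutationPath(alpha, alpha - lam, [1e-3] * len(lam))
        prof = sm.fitness_profile(p, compute_omega=False)
        for n in range(len(lam)):
            d = max(lam[: n + 1])
            assert prof.delta[n] == pytest.approx(d)
            assert prof.r[n] == sum(1 for v in lam[: n + 1] if v == d)


class TestOmegaRecursion:
    def test_base_case(self):
        prof = sm.fitness_profile(two_type_sim(1.0))
        assert prof.omega[0] == pytest.approx(1.2)  # alpha_1/lambda_1

    def test_deleterious_branch_hand_value(self, sim3_path):
        # nu/(delta_1 - lambda_2) * omega_1 = (0.01/0.3)*1.2
        prof = sm.fitness_profile(sim3_path)
        assert prof.omega[1] == pytest.approx(0.04)

    def test_neutral_closed_form(self):
        """omega_n = (alpha_1/lambda_1) nu^{n-1}/(n-1)! on a neutral path."""
        a, b, nu = 1.3, 0.3, 3e-3
        p = sm.MutationPath([a] * 6, [b] * 6, [nu] * 6)
        prof = sm.fitness_profile(p)
        expected = [a / (a - b) * nu ** k / math.factorial(k) for k in range(6)]
        assert np.allclose(prof.omega, expected, rtol=1e-12)

    def test_increase_branch_rejects_large_nu(self):
        p = sm.MutationPath([1.0, 2.0], [0.3, 0.3], [1.0, 0.0])
        with pytest.raises(sm.RegimeError, match="nu"):
            sm.fitness_profile(p)

    def test_omega_positive_on_random_paths(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            prof = sm.fitness_profile(random_valid_path(rng))
            assert (prof.omega > 0).all()


class TestMedians:
    def test_two_type_closed_form(self):
        """t_half(2) = log(lambda_1^2/(alpha_1 nu_1))/lambda_1."""
        p = sm.MutationPath((1.0, 1.4), (0.3, 0.3), (0.01, 0.0))
        prof = sm.fitness_profile(p)
        law = sm.median_arrival(prof, p, 2)
        assert law.median == pytest.approx(math.log(49) / 0.7, rel=1e-12)
        assert law.scale == pytest.approx(1 / 0.7)

    def test_doubling_nu_shifts_by_log2_over_lambda(self):
        p1 = sm.MutationPath((1.0, 1.4), (0.3, 0.3), (0.01, 0.0))
        p2 = sm.MutationPath((1.0, 1.4), (0.3, 0.3), (0.02, 0.0))
        m1 = sm.median_arrival(sm.fitness_profile(p1), p1, 2).median
        m2 = sm.median_arrival(sm.fitness_profile(p2), p2, 2).median
        assert m1 - m2 == pytest.approx(math.log(2) / 0.7, rel=1e-12)

    def test_recursion_equals_direct_formula(self):
        """The incremental recursion and the direct median formula are two
        independent routes to the same numbers, across all case branches."""
        rng = np.random.default_rng(42)
        branches = set()
        checked = 0
        while checked < 120:
            p = random_valid_path(rng)
            try:
                prof = sm.fitness_profile(p)
                rec = sm.median_recursion(prof, p)
                direct = [sm.median_arrival(prof, p, n).median
                          for n in range(2, p.n_types + 1)]
            except sm.RegimeError:
                continue
            assert np.allclose(rec, direct, rtol=1e-9)
            branches.update(prof.case)
            checked += 1
        assert branches == {CASE_DECREASE, CASE_EQUAL, CASE_INCREASE}

    def test_neutral_reduction(self):
        """On a neutral path the general recursion reduces to the closed-form
        neutral median used by the assay inference."""
        nu = 1e-3
        p = neutral_assay_path(nu, n_types=5)
        prof = sm.fitness_profile(p)
        rec = sm.median_recursion(prof, p)
        for n in range(2, 6):
            assert rec[n - 2] == pytest.approx(
                sm.neutral_median(nu, n, 1.0, 1.0), rel=1e-12)

    def test_constant_driver_increments_decrease(self):
        """Strictly increasing fitness with constant driver rate: increments
        are log(lam_n/nu)/lam_n - log(c_{n-1} lam_{n-1})/lam_{n-1} and
        shrink with n (evolution accelerates)."""
        lam = np.array([0.5, 1.0, 1.5, 2.0])
        nu = 1e-4
        p = sm.MutationPath(lam + 0.3, np.full(4, 0.3), [nu] * 4)
        prof = sm.fitness_profile(p)
        rec = sm.median_recursion(prof, p)
        inc = np.diff(rec)
        for i in range(2):  # increments t_half(3)-t_half(2), t_half(4)-t_half(3)
            n = i + 2
            ln, lp = lam[n - 1], lam[n - 2]  # lambda_n, lambda_{n-1} (1-based)
            expected = (math.log(ln / nu) / ln
                        - math.log(prof.kappa[n - 2] * lp) / lp)
            assert inc[i] == pytest.approx(expected, rel=1e-9)
        assert (inc[1:] < inc[:-1]).all()

    def test_median_decreasing_in_every_nu(self, fig1_path):
        prof = sm.fitness_profile(fig1_path)
        base = sm.median_arrival(prof, fig1_path, 3).median
        for i in range(2):
            nu = list(fig1_path.nu)
            nu[i] *= 1.5
            p = sm.MutationPath(fig1_path.alpha, fig1_path.beta, nu)
            assert sm.median_arrival(sm.fitness_profile(p), p, 3).median < base

    def test_median_increasing_in_deleterious_gap(self):
        meds = []
        for beta2 in (0.35, 0.5, 0.7):  # growing gap delta_1 - lambda_2
            p = sm.MutationPath((1.0, 1.0, 1.0), (0.3, beta2, 0.3),
                                (0.01, 0.01, 0.0))
            prof = sm.fitness_profile(p)
            meds.append(sm.median_arrival(prof, p, 3).median)
        assert meds[0] < meds[1] < meds[2]

    def test_regime_error_when_rates_too_large(self):
        p = sm.MutationPath((1.0, 1.0), (0.2, 0.2), (0.9, 0.0))
        prof = sm.fitness_profile(p)
        with pytest.raises(sm.RegimeError, match="non-positive"):
            sm.median_arrival(prof, p, 2)


class TestSurvivingLineage:
    def test_no_death_leaves_nu_unchanged(self):
        p = sm.MutationPath((1.0, 1.0), (0.2, 0.0), (0.01, 0.0))
        adj = sm.surviving_lineage_path(p)
        assert adj.nu == p.nu

    def test_half_survival_halves_nu(self):
        p = sm.MutationPath((1.0, 1.0), (0.2, 0.5), (0.01, 0.0))
        adj = sm.surviving_lineage_path(p)
        assert adj.nu[0] == pytest.approx(0.005)

    def test_adjusted_median_never_earlier(self, mixed_path):
        # lambda_3 <= 0 there, so adjust only the first step
        adj = sm.surviving_lineage_path(mixed_path, steps=1)
        m0 = sm.median_arrival(sm.fitness_profile(mixed_path), mixed_path, 2).median
        m1 = sm.median_arrival(sm.fitness_profile(adj), adj, 2).median
        assert m1 >= m0

    def test_subcritical_next_type_rejected(self, mixed_path):
        with pytest.raises(sm.RegimeError, match="extinct"):
            sm.surviving_lineage_path(mixed_path, steps=2)  # lambda_3 = -0.5


class TestComparePaths:
    def test_identical_paths_tie(self, fig1_path):
        out = sm.compare_paths([fig1_path, fig1_path], 3)
        assert out[0]["median"] == out[1]["median"]
        assert out[0]["rank"] == out[1]["rank"] == 1

    def test_smaller_nu2_arrives_later(self):
        def make(nu2):
            return sm.MutationPath((1.0, 1.0, 1.0), (0.3, 0.3, 0.3),
                                   (0.01, nu2, 0.0))
        out = sm.compare_paths([make(1e-3), make(1e-2)], 3,
                               labels=["slow", "fast"])
        assert [e["label"] for e in out] == ["fast", "slow"]

    def test_mini_vs_major_driver_matches_simulation(self):
        """A high-rate/low-advantage middle step vs a low-rate/high-advantage
        one: the analytic ranking of tau_3 medians agrees with brute-force
        simulated medians."""
        mini = sm.MutationPath((1.0, 1.1, 2.0), (0.3, 0.3, 0.3), (0.01, 5e-3, 0.0))
        major = sm.MutationPath((1.0, 2.0, 2.0), (0.3, 0.3, 0.3), (0.01, 5e-5, 0.0))
        out = sm.compare_paths([mini, major], 3, labels=["mini", "major"])
        sim_meds = {}
        for label, p in (("mini", mini), ("major", major)):
            _, arr, _ = sm.replicate_final_counts(
                p, 40.0, 500, seed=3, mode="hybrid", stop_at_type=3,
                condition_on_type1_survival=True)
            sim_meds[label] = np.median(arr[:, 2])
        analytic_order = [e["label"] for e in out]
        sim_order = sorted(sim_meds, key=sim_meds.get)
        assert analytic_order == sim_order


class TestParameterFiles:
    def test_json_and_toml_round_trip(self, tmp_path, fig1_path):
        f = tmp_path / "params.json"
        import json
        f.write_text(json.dumps(fig1_path.to_dict()))
        assert sm.MutationPath.from_file(f) == fig1_path
        g = tmp_path / "params.toml"
        g.write_text("alpha = [1.1, 1.0, 1.1]\nbeta = [0.8, 0.9, 0.5]\n"
                     "nu = [0.01, 0.01, 0.0]\n")
        assert sm.MutationPath.from_file(g) == fig1_path

    def test_missing_key_reported(self, tmp_path):
        f = tmp_path / "bad.json"
        f.write_text('{"alpha": [1.0]}')
        with pytest.raises(ValueError, match="missing keys"):
            sm.MutationPath.from_file(f)
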