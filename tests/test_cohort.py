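"""Cohort dynamics: seeding, aging, grouped prevalence, weighted rates,
forward simulation and projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quitrate.cohort import (
    AGE_MAX,
    AGE_MIN,
    N_AGES,
    AgeGroups,
    AgeYearSchedule,
    CessationParams,
    DomainError,
    InitiationSeries,
    ScheduleGapError,
    SmokerCounts,
    advance_cohorts,
    expand_params,
    group_prevalence,
    one_year_step,
    project_prevalence,
    seed_initiation,
    simulate_prevalence,
    weighted_average_rate,
)


def counts(arr_or_scalar, year=2009):
    c = np.full(N_AGES, float(arr_or_scalar)) if np.isscalar(arr_or_scalar) else arr_or_scalar
    return SmokerCounts(year=year, counts=c)


def flat_schedule(role, value, years):
    vals = np.full((len(years), N_AGES), value)
    return AgeYearSchedule(role, tuple(years), vals)


class TestSeedInitiation:
    @pytest.mark.parametrize(
        "gamma,pop,expected", [(0.0, 1000, 0.0), (0.2, 1000, 200.0), (1.0, 50, 50.0)]
    )
    def test_direct_product(self, gamma, pop, expected):
        assert seed_initiation(gamma, pop) == expected

    def test_out_of_range_gamma_names_year(self):
        with pytest.raises(DomainError, match="2013"):
            seed_initiation(1.5, 1000, year=2013)

    def test_round_trips_generator_entry_cohort(self, default_bundle):
        b = default_bundle
        for year in b.obs_years:
            expected = seed_initiation(
                b.initiation.at(year), b.population.at(AGE_MIN, year)
            )
            assert expected == b.initiation.at(year) * b.population.at(AGE_MIN, year)


class TestAdvanceCohorts:
    def test_lossless_aging_when_no_mortality_or_cessation(self):
        C = counts(np.linspace(10, 800, N_AGES))
        nxt = advance_cohorts(C, np.zeros(N_AGES), np.zeros(N_AGES))
        assert nxt.year == C.year + 1
        np.testing.assert_array_equal(nxt.counts[1:], C.counts[:-1])
        assert nxt.counts[0] == 0.0  # entry cohort left for seeding

    def test_total_quitting_empties_older_ages(self):
        nxt = advance_cohorts(counts(500.0), np.zeros(N_AGES), np.ones(N_AGES))
        np.testing.assert_array_equal(nxt.counts, 0.0)

    def test_single_age_product(self):
        C = np.zeros(N_AGES)
        C[40 - AGE_MIN] = 1000.0
        mu = np.zeros(N_AGES)
        theta = np.zeros(N_AGES)
        mu[40 - AGE_MIN] = 0.01
        theta[40 - AGE_MIN] = 0.04
        nxt = advance_cohorts(counts(C), mu, theta)
        assert nxt.counts[41 - AGE_MIN] == pytest.approx(1000 * 0.99 * 0.96)  # 950.4

    def test_rate_out_of_range_names_age(self):
        theta = np.zeros(N_AGES)
        theta[30 - AGE_MIN] = 1.2
        with pytest.raises(DomainError, match="age 30"):
            advance_cohorts(counts(10.0), np.zeros(N_AGES), theta)

    def test_conservation_under_thinning(self):
        rng = np.random.default_rng(0)
        C = counts(rng.uniform(0, 1000, N_AGES))
        nxt = advance_cohorts(
            C, rng.uniform(0, 1, N_AGES), rng.uniform(0, 1, N_AGES)
        )
        assert np.all(nxt.counts[1:] <= C.counts[:-1] + 1e-12)

    @given(alpha=st.floats(0, 5), beta=st.floats(0, 5), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_linear_in_counts(self, alpha, beta, seed):
        rng = np.random.default_rng(seed)
        c1, c2 = rng.uniform(0, 100, (2, N_AGES))
        mu, theta = rng.uniform(0, 1, (2, N_AGES))
        lhs = advance_cohorts(counts(alpha * c1 + beta * c2), mu, theta).counts
        rhs = (
            alpha * advance_cohorts(counts(c1), mu, theta).counts
            + beta * advance_cohorts(counts(c2), mu, theta).counts
        )
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-9)


class TestExpandParams:
    def test_constant_expansion(self):
        theta = expand_params(CessationParams([0.3, 0.3, 0.3]), AgeGroups())
        np.testing.assert_array_equal(theta, 0.3)

    @pytest.mark.parametrize("age,expected", [(50, 0.0246), (65, 0.0486), (25, 0.0498), (44, 0.0498), (45, 0.0246)])
    def test_group_membership_including_boundaries(self, age, expected):
        theta = expand_params(CessationParams([0.0498, 0.0246, 0.0486]), AgeGroups())
        assert theta[age - AGE_MIN] == expected

    def test_groups_must_cover_domain(self):
        with pytest.raises(DomainError):
            AgeGroups(((25, 44), (45, 64), (65, 99)))
        with pytest.raises(DomainError):
            AgeGroups(((25, 44), (46, 64), (65, 100)))


class TestGroupPrevalence:
    def test_everyone_smokes(self):
        P = np.full(N_AGES, 100.0)
        prev = group_prevalence(counts(100.0), P, AgeGroups())
        np.testing.assert_allclose(prev, 1.0)

    def test_nobody_smokes(self):
        prev = group_prevalence(counts(0.0), np.full(N_AGES, 100.0), AgeGroups())
        np.testing.assert_array_equal(prev, 0.0)

    def test_uniform_ratio(self):
        prev = group_prevalence(counts(20.0), np.full(N_AGES, 100.0), AgeGroups())
        np.testing.assert_allclose(prev, 0.2)

    def test_zero_group_population_rejected(self):
        P = np.full(N_AGES, 100.0)
        P[65 - AGE_MIN:] = 0.0
        with pytest.raises(DomainError, match="65"):
            group_prevalence(counts(1.0), P, AgeGroups())

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_in_unit_interval_when_smokers_below_population(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.uniform(1, 1000, N_AGES)
        C = P * rng.uniform(0, 1, N_AGES)
        prev = group_prevalence(counts(C), P, AgeGroups())
        assert np.all((prev >= 0) & (prev <= 1))


class TestWeightedAverageRate:
    def test_equal_rates_give_that_rate(self):
        assert weighted_average_rate([10, 5, 2], CessationParams([0.07, 0.07, 0.07])) == pytest.approx(0.07)

    def test_degenerate_weights_pick_one_group(self):
        assert weighted_average_rate([1, 0, 0], CessationParams([0.2, 0.5, 0.9])) == 0.2

    def test_hand_computed_dot_product(self):
        # (100*0.0498 + 300*0.0246 + 100*0.0486) / 500 = 17.22/500
        got = weighted_average_rate([100, 300, 100], CessationParams([0.0498, 0.0246, 0.0486]))
        assert got == pytest.approx(0.03444, abs=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(DomainError):
            weighted_average_rate([0, 0, 0], CessationParams([0.1, 0.1, 0.1]))

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_extreme_rates(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0, 100, 3)
        w[rng.integers(3)] += 1e-6  # ensure positive total
        eta = rng.uniform(0, 1, 3)
        avg = weighted_average_rate(w, CessationParams(eta))
        assert eta.min() - 1e-12 <= avg <= eta.max() + 1e-12


class TestSimulatePrevalence:
    def test_single_year_is_initial_grouped_prevalence(self):
        years = [2009]
        pop = flat_schedule("population", 100.0, years)
        mort = flat_schedule("mortality", 0.0, years)
        C0 = counts(20.0)
        out = simulate_prevalence(
            C0, pop, mort, InitiationSeries({2009: 0.2}), {}, AgeGroups()
        )
        assert list(out) == [2009]
        np.testing.assert_allclose(out[2009], 0.2)

    def test_stationary_conditions_converge_to_fixed_point(self):
        # No mortality, constant initiation and rates, stationary population:
        # the per-age counts converge to gamma*P*(1-eta)^(a-25), so grouped
        # prevalence converges; oracle = brute-force long run.
        years = list(range(2000, 2201))
        pop = flat_schedule("population", 1000.0, years)
        mort = flat_schedule("mortality", 0.0, years)
        gamma = InitiationSeries({y: 0.2 for y in years})
        eta = {y: CessationParams([0.05, 0.05, 0.05], year=y) for y in years[:-1]}
        C0 = counts(0.0, year=2000)
        out = simulate_prevalence(C0, pop, mort, gamma, eta, AgeGroups())
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
        fixed_counts = 0.2 * 1000.0 * (1 - 0.05) ** (ages - AGE_MIN)
        expected = AgeGroups().aggregate(fixed_counts) / AgeGroups().aggregate(
            np.full(N_AGES, 1000.0)
        )
        np.testing.assert_allclose(out[2200], expected, rtol=1e-10)
        # monotone approach from below (started from zero smokers)
        seq = np.array([out[y][0] for y in years])
        assert np.all(np.diff(seq) >= -1e-15)

    def test_round_trips_generator_noise_free_trajectory(self, default_bundle):
        b = default_bundle
        C0 = SmokerCounts(
            year=b.obs_years[0],
            counts=b.initial_prevalence * b.population.column(b.obs_years[0]),
        )
        eta = {
            int(y): CessationParams(row, year=int(y))
            for y, row in zip(
                sorted(b.truth["year"].unique()), b.true_eta_matrix()
            )
        }
        out = simulate_prevalence(
            C0, b.population, b.mortality, b.initiation, eta, b.config.groups
        )
        nf = b.noise_free.pivot(index="year", columns="group_index", values="prevalence")
        for y in b.obs_years:
            np.testing.assert_array_equal(out[y], nf.loc[y].to_numpy())

    def test_invariant_to_group_boundaries_when_rates_equal(self):
        years = list(range(2009, 2015))
        pop = flat_schedule("population", 500.0, years)
        mort = flat_schedule("mortality", 0.01, years)
        gamma = InitiationSeries({y: 0.15 for y in years})
        C0 = counts(60.0)
        outs = []
        for bounds in [((25, 44), (45, 64), (65, 100)), ((25, 30), (31, 90), (91, 100))]:
            g = AgeGroups(bounds)
            eta = {y: CessationParams([0.04] * 3, year=y) for y in years[:-1]}
            out = simulate_prevalence(C0, pop, mort, gamma, eta, g)
            # compare overall smoker mass via prevalence * group population
            gp = np.array([out[y] @ g.aggregate(np.full(N_AGES, 500.0)) for y in years])
            outs.append(gp)
        np.testing.assert_allclose(outs[0], outs[1], rtol=1e-12)

    def test_schedule_gap_is_reported(self):
        years = [2009, 2010]
        pop = flat_schedule("population", 100.0, years)
        mort = flat_schedule("mortality", 0.0, years)
        gamma = InitiationSeries({2009: 0.2, 2010: 0.2})
        eta = {2009: CessationParams([0.05] * 3), 2010: CessationParams([0.05] * 3)}
        with pytest.raises(ScheduleGapError, match="2011"):
            simulate_prevalence(counts(10.0), pop, mort, gamma, eta, AgeGroups())


class TestProjectPrevalence:
    def _setup(self):
        years = list(range(2017, 2031))
        pop = flat_schedule("population", 1000.0, years)
        mort = flat_schedule("mortality", 0.01, years)
        C0 = counts(150.0, year=2017)
        return C0, pop, mort

    def test_zero_covariance_gives_zero_width_interval(self):
        C0, pop, mort = self._setup()
        res = project_prevalence(
            C0, pop, mort, 0.15, np.array([0.04, 0.03, 0.05]), np.zeros((3, 3)),
            2030, AgeGroups(), n_draws=50, seed=1,
        )
        assert res.lo == pytest.approx(res.point, abs=1e-12)
        assert res.hi == pytest.approx(res.point, abs=1e-12)

    def test_same_seed_reproduces_interval(self):
        C0, pop, mort = self._setup()
        args = (C0, pop, mort, 0.15, np.array([0.04, 0.03, 0.05]),
                np.diag([1e-4, 1e-4, 1e-4]), 2030, AgeGroups())
        r1 = project_prevalence(*args, n_draws=200, seed=7)
        r2 = project_prevalence(*args, n_draws=200, seed=7)
        assert (r1.point, r1.lo, r1.hi) == (r2.point, r2.lo, r2.hi)

    def test_matches_independent_monte_carlo_reimplementation(self):
        # oracle: same draw sequence, straightforward year loop
        C0, pop, mort = self._setup()
        mean = np.array([0.045, 0.03, 0.055])
        cov = np.diag([4e-4, 4e-4, 4e-4])
        res = project_prevalence(C0, pop, mort, 0.15, mean, cov, 2030,
                                 AgeGroups(), n_draws=500, seed=3)
        rng = np.random.default_rng(3)
        draws = np.clip(rng.multivariate_normal(mean, cov, size=500), 0, 1)
        member = AgeGroups().membership()
        finals = []
        for d in draws:
            c = C0.counts.copy()
            for _ in range(2030 - 2017):
                new = np.zeros_like(c)
                new[1:] = c[:-1] * (1 - 0.01) * (1 - d[member][:-1])
                new[0] = 0.15 * 1000.0
                c = new
            finals.append(c.sum() / (1000.0 * N_AGES))
        lo, hi = np.percentile(finals, [2.5, 97.5])
        assert res.lo == pytest.approx(lo, abs=1e-12)
        assert res.hi == pytest.approx(hi, abs=1e-12)

    def test_horizon_before_base_year_rejected(self):
        C0, pop, mort = self._setup()
        with pytest.raises(DomainError):
            project_prevalence(C0, pop, mort, 0.15, np.full(3, 0.04),
                               np.zeros((3, 3)), 2016, AgeGroups())
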