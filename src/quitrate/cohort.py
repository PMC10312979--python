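"""Discrete cohort-component dynamics of current smokers by single year of age.

The model tracks the number of current smokers ``C[a, t]`` for ages 25..100.
Each year the entry cohort is seeded from the initiation proportion gamma_t
(the smoking prevalence of 25-year-olds), and every older cohort is the
previous year's cohort one age younger, thinned by smoker mortality mu and by
the net cessation rate theta:

    C[25, t] = gamma_t * P[25, t]
    C[a, t]  = C[a-1, t-1] * (1 - mu[a-1, t-1]) * (1 - theta[a-1, t-1])

Grouped smoking prevalence is the ratio of smokers to population summed over
an age group.  Cessation rates are piecewise constant in age: one rate eta_k
per age group, expanded to a per-age vector theta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

AGE_MIN = 25
AGE_MAX = 100
N_AGES = AGE_MAX - AGE_MIN + 1

DEFAULT_GROUP_BOUNDS: tuple[tuple[int, int], ...] = ((25, 44), (45, 64), (65, 100))


class DomainError(ValueError):
    """A quantity is outside its admissible range."""


class ScheduleGapError(KeyError):
    """An (age, year) cell required by the dynamics is missing."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeGroups:
    """Ordered, disjoint, inclusive age intervals jointly covering [25, 100]."""

    bounds: tuple[tuple[int, int], ...] = DEFAULT_GROUP_BOUNDS

    def __post_init__(self) -> None:
        b = tuple((int(lo), int(hi)) for lo, hi in self.bounds)
        object.__setattr__(self, "bounds", b)
        covered = []
        prev_hi = AGE_MIN - 1
        for lo, hi in b:
            if lo != prev_hi + 1 or hi < lo:
                raise DomainError(
                    f"age groups must be sorted, disjoint and contiguous; got {b}"
                )
            prev_hi = hi
            covered.append((lo, hi))
        if b[0][0] != AGE_MIN or b[-1][1] != AGE_MAX:
            raise DomainError(f"age groups must cover [{AGE_MIN}, {AGE_MAX}]; got {b}")

    @property
    def n_groups(self) -> int:
        return len(self.bounds)

    @property
    def labels(self) -> tuple[str, ...]:
        out = []
        for lo, hi in self.bounds:
            out.append(f"{lo}-{hi}" if hi < AGE_MAX else f"{lo}+")
        return tuple(out)

    def index_of(self, age: int) -> int:
        for k, (lo, hi) in enumerate(self.bounds):
            if lo <= age <= hi:
                return k
        raise DomainError(f"age {age} not covered by any group in {self.bounds}")

    def membership(self) -> np.ndarray:
        """Group index for every age 25..100, shape (76,)."""
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
        out = np.empty(N_AGES, dtype=int)
        for k, (lo, hi) in enumerate(self.bounds):
            out[(ages >= lo) & (ages <= hi)] = k
        return out

    def aggregate(self, values: np.ndarray) -> np.ndarray:
        """Sum a per-age vector within each group."""
        member = self.membership()
        return np.array(
            [values[member == k].sum() for k in range(self.n_groups)]
        )


@dataclass(frozen=True)
class AgeYearSchedule:
    """A quantity on the complete (age, year) grid: population counts or
    smoker mortality probabilities.

    ``values`` has shape (n_years, n_ages), rows indexed by calendar year in
    ``years`` order, columns by age 25..100.
    """

    role: str  # "population" | "mortality"
    years: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        object.__setattr__(self, "years", years)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.role not in ("population", "mortality"):
            raise DomainError(f"unknown schedule role {self.role!r}")
        if vals.shape != (len(years), N_AGES):
            raise ScheduleGapError(
                f"{self.role} schedule must be complete over ages "
                f"{AGE_MIN}..{AGE_MAX} and {len(years)} years; got shape {vals.shape}"
            )
        if list(years) != sorted(set(years)):
            raise DomainError(f"{self.role} schedule years must be sorted and unique")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise DomainError(f"{self.role} values must be finite and non-negative")
        if self.role == "mortality" and np.any(vals > 1):
            raise DomainError("mortality values must lie in [0, 1]")

    def column(self, year: int) -> np.ndarray:
        """The per-age slice for one calendar year."""
        try:
            i = self.years.index(int(year))
        except ValueError:
            raise ScheduleGapError(
                f"{self.role} schedule has no year {year} "
                f"(covers {self.years[0]}..{self.years[-1]})"
            ) from None
        return self.values[i]

    def at(self, age: int, year: int) -> float:
        return float(self.column(year)[age - AGE_MIN])

    def extended_to(self, year: int) -> "AgeYearSchedule":
        """Flat-extrapolate the final year forward to ``year`` (logged)."""
        last = self.years[-1]
        if year <= last:
            return self
        logger.warning(
            "flat-extrapolating %s schedule from %d to %d", self.role, last, year
        )
        extra = np.tile(self.values[-1], (year - last, 1))
        return AgeYearSchedule(
            role=self.role,
            years=self.years + tuple(range(last + 1, year + 1)),
            values=np.vstack([self.values, extra]),
        )


@dataclass(frozen=True)
class SmokerCounts:
    """Current smokers by single age for one calendar year."""

    year: int
    counts: np.ndarray  # shape (76,), ages 25..100

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", c)
        if c.shape != (N_AGES,):
            raise DomainError(f"counts must cover ages {AGE_MIN}..{AGE_MAX}")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise DomainError(f"smoker counts for year {self.year} must be >= 0")

    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class CessationParams:
    """One net cessation rate per age group; ``year`` labels the transition
    it governs (year t rates drive the t -> t+1 step)."""

    eta: np.ndarray
    year: int | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.eta, dtype=float)
        object.__setattr__(self, "eta", e)
        if np.any((e < 0) | (e > 1)) or not np.all(np.isfinite(e)):
            raise DomainError(
                f"cessation rates must lie in [0, 1]; got {e} (year {self.year})"
            )


@dataclass(frozen=True)
class InitiationSeries:
    """Smoking prevalence of 25-year-olds per calendar year (initiation proxy)."""

    gamma: Mapping[int, float]

    def __post_init__(self) -> None:
        g = {int(y): float(v) for y, v in dict(self.gamma).items()}
        object.__setattr__(self, "gamma", g)
        for y, v in g.items():
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"initiation proportion for year {y} is {v}, not in [0, 1]")

    def at(self, year: int) -> float:
        try:
            return self.gamma[int(year)]
        except KeyError:
            raise ScheduleGapError(f"initiation series has no year {year}") from None

    def extended_to(self, year: int) -> "InitiationSeries":
        last = max(self.gamma)
        if year <= last:
            return self
        logger.warning("flat-extrapolating initiation series from %d to %d", last, year)
        g = dict(self.gamma)
        for y in range(last + 1, year + 1):
            g[y] = g[last]
        return InitiationSeries(g)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def seed_initiation(gamma_t: float, pop_25_t: float, year: int | None = None) -> float:
    """Smokers entering at age 25: gamma_t * P[25, t]."""
    if not (0.0 <= gamma_t <= 1.0):
        raise DomainError(
            f"initiation proportion {gamma_t} out of [0, 1]"
            + (f" in year {year}" if year is not None else "")
        )
    if pop_25_t < 0:
        raise DomainError(f"population {pop_25_t} must be >= 0")
    return gamma_t * pop_25_t


def _check_rates(rates: np.ndarray, name: str) -> np.ndarray:
    rates = np.asarray(rates, dtype=float)
    bad = np.where((rates < 0) | (rates > 1) | ~np.isfinite(rates))[0]
    if bad.size:
        age = AGE_MIN + int(bad[0])
        raise DomainError(f"{name} rate {rates[bad[0]]} at age {age} out of [0, 1]")
    return rates


def advance_cohorts(
    C_prev: SmokerCounts, mu_prev: np.ndarray, theta_prev: np.ndarray
) -> SmokerCounts:
    """Age every cohort one year, thinning by mortality and cessation.

    Entry counts (age 25) are left at zero for ``seed_initiation`` to fill;
    smokers aged 100 in year t-1 exit the model.
    """
    mu_prev = _check_rates(mu_prev, "mortality")
    theta_prev = _check_rates(theta_prev, "cessation")
    new = np.zeros(N_AGES)
    new[1:] = C_prev.counts[:-1] * (1.0 - mu_prev[:-1]) * (1.0 - theta_prev[:-1])
    return SmokerCounts(year=C_prev.year + 1, counts=new)


def expand_params(eta: CessationParams, groups: AgeGroups) -> np.ndarray:
    """Per-age cessation rates theta_a = eta_k for the group containing a."""
    if len(eta.eta) != groups.n_groups:
        raise DomainError(
            f"{len(eta.eta)} rates for {groups.n_groups} groups"
        )
    return np.asarray(eta.eta, dtype=float)[groups.membership()]


def one_year_step(
    C_prev: SmokerCounts,
    mu_prev: np.ndarray,
    theta_prev: np.ndarray,
    gamma_next: float,
    pop25_next: float,
) -> SmokerCounts:
    """Full transition C_t -> C_{t+1}: aging/thinning plus entry seeding."""
    nxt = advance_cohorts(C_prev, mu_prev, theta_prev)
    counts = nxt.counts.copy()
    counts[0] = seed_initiation(gamma_next, pop25_next, year=nxt.year)
    return SmokerCounts(year=nxt.year, counts=counts)


def group_prevalence(
    C: SmokerCounts, P: np.ndarray, groups: AgeGroups
) -> np.ndarray:
    """Smoking prevalence per age group: sum(C) / sum(P) within the group."""
    P = np.asarray(P, dtype=float)
    num = groups.aggregate(C.counts)
    den = groups.aggregate(P)
    if np.any(den <= 0):
        k = int(np.where(den <= 0)[0][0])
        raise DomainError(
            f"zero population in age group {groups.labels[k]} (year {C.year})"
        )
    return num / den


def weighted_average_rate(
    smokers_per_group: np.ndarray, eta: CessationParams
) -> float:
    """Smoker-count-weighted mean of the group cessation rates at the start
    of a year."""
    w = np.asarray(smokers_per_group, dtype=float)
    if np.any(w < 0):
        raise DomainError("smoker counts must be >= 0")
    tot = w.sum()
    if tot <= 0:
        raise DomainError("total smokers must be > 0 for a weighted average")
    return float(w @ np.asarray(eta.eta, dtype=float) / tot)


def weighted_average_sd(smokers_per_group: np.ndarray, cov: np.ndarray) -> float:
    """Delta-method SD of the weighted average, weights treated as known."""
    w = np.asarray(smokers_per_group, dtype=float)
    w = w / w.sum()
    return float(np.sqrt(max(w @ np.asarray(cov) @ w, 0.0)))


def simulate_prevalence(
    C_init: SmokerCounts,
    population: AgeYearSchedule,
    mortality: AgeYearSchedule,
    gamma: InitiationSeries,
    eta_by_year: Mapping[int, CessationParams] | Sequence[CessationParams],
    groups: AgeGroups,
    end_year: int | None = None,
) -> dict[int, np.ndarray]:
    """Run the cohort model forward and return grouped prevalence per year.

    ``eta_by_year[t]`` governs the t -> t+1 transition.  The output covers the
    initial year through ``end_year`` (default: last transition year + 1);
    year-t prevalence uses year-t counts and year-t population.
    """
    if not isinstance(eta_by_year, Mapping):
        eta_by_year = {
            (p.year if p.year is not None else C_init.year + i): p
            for i, p in enumerate(eta_by_year)
        }
    if end_year is None:
        end_year = (max(eta_by_year) + 1) if eta_by_year else C_init.year
    out: dict[int, np.ndarray] = {}
    C = C_init
    out[C.year] = group_prevalence(C, population.column(C.year), groups)
    for t in range(C_init.year, end_year):
        theta = expand_params(eta_by_year[t], groups)
        C = one_year_step(
            C,
            mortality.column(t),
            theta,
            gamma.at(t + 1),
            population.at(AGE_MIN, t + 1),
        )
        out[C.year] = group_prevalence(C, population.column(C.year), groups)
    return out


@dataclass(frozen=True)
class ProjectionResult:
    """Point projection with a Monte-Carlo percentile interval."""

    target_year: int
    point: float  # overall 25+ prevalence at posterior-mean rates
    lo: float
    hi: float
    point_by_group: np.ndarray
    n_draws: int


def project_prevalence(
    C_base: SmokerCounts,
    population: AgeYearSchedule,
    mortality: AgeYearSchedule,
    gamma_held: float,
    eta_mean: np.ndarray,
    eta_cov: np.ndarray,
    target_year: int,
    groups: AgeGroups,
    n_draws: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> ProjectionResult:
    """Project overall smoking prevalence to ``target_year``.

    Rates and initiation are held constant over the horizon.  The point
    estimate propagates the posterior-mean rates; the interval is the
    percentile band over ``n_draws`` Gaussian draws of the rates, each
    clipped to [0, 1] and held constant.
    """
    if target_year <= C_base.year:
        raise DomainError(
            f"target year {target_year} must be after base year {C_base.year}"
        )
    if n_draws < 1:
        raise DomainError("n_draws must be >= 1")
    population = population.extended_to(target_year)
    mortality = mortality.extended_to(target_year)

    def run(eta_vec: np.ndarray) -> tuple[float, np.ndarray]:
        theta = np.asarray(eta_vec, dtype=float)[groups.membership()]
        C = C_base
        for t in range(C_base.year, target_year):
            C = one_year_step(
                C,
                mortality.column(t),
                theta,
                gamma_held,
                population.at(AGE_MIN, t + 1),
            )
        P = population.column(target_year)
        return C.total() / P.sum(), group_prevalence(C, P, groups)

    point, by_group = run(np.clip(eta_mean, 0.0, 1.0))
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(eta_mean, eta_cov, size=n_draws)
    draws = np.clip(draws, 0.0, 1.0)
    finals = np.array([run(d)[0] for d in draws])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(finals, [100 * alpha, 100 * (1 - alpha)])
    return ProjectionResult(
        target_year=target_year,
        point=float(point),
        lo=float(lo),
        hi=float(hi),
        point_by_group=by_group,
        n_draws=n_draws,
    )
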