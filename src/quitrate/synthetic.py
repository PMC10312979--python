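"""Synthetic input bundles with known ground-truth cessation rates.

The generator emulates the statistical structure of the real inputs the
estimation pipeline consumes — a smooth single-age population pyramid
(Census-style), Gompertz-shaped smoker mortality (CISNET-style), a slowly
declining entry-age smoking prevalence, and survey-style grouped prevalence
observations with Gaussian sampling noise at stated standard errors
(NHIS-scale, a few tenths of a percentage point) — while planting known
time-varying group cessation rates so estimation quality can be verified by
parameter recovery.

The default scenario mirrors the regime the estimation problem targets:
three age groups over ten observation years, rates starting near
(5.0%, 2.5%, 4.9%) with the middle group ramping from 2.5% to 4.2% over the
nine estimated years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import (
    AGE_MAX,
    AGE_MIN,
    N_AGES,
    AgeGroups,
    AgeYearSchedule,
    CessationParams,
    InitiationSeries,
    SmokerCounts,
    simulate_prevalence,
)

logger = logging.getLogger(__name__)


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class EtaTrajectory:
    """Ground-truth rate path for one group over the estimated years.

    kind: "constant" (value=start), "ramp" (linear start->end), or
    "changepoint" (start until change_index, then end).
    """

    kind: str
    start: float
    end: float | None = None
    change_index: int | None = None

    def values(self, n_years: int) -> np.ndarray:
        if self.kind == "constant":
            out = np.full(n_years, self.start)
        elif self.kind == "ramp":
            out = np.linspace(self.start, self.end, n_years)
        elif self.kind == "changepoint":
            out = np.full(n_years, self.start)
            out[self.change_index:] = self.end
        else:
            raise GenerationError(f"unknown trajectory kind {self.kind!r}")
        if np.any((out < 0) | (out > 1)):
            raise GenerationError(f"trajectory leaves [0, 1]: {out}")
        return out


DEFAULT_TRAJECTORIES = (
    EtaTrajectory("constant", 0.050),
    EtaTrajectory("ramp", 0.025, 0.042),
    EtaTrajectory("constant", 0.049),
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-condition knobs for a synthetic scenario.

    Defaults are chosen to resemble the US adult setting the estimator is
    built for: ~4 million people per single age at 25 thinning with age,
    smoker mortality rising Gompertz-style from ~0.4% at 25 to ~50% by 100,
    entry-age smoking prevalence starting at 20% and drifting down, and
    observation standard errors of 0.4-0.5 percentage points per group.
    """

    start_year: int = 2009
    n_obs_years: int = 10
    groups: AgeGroups = field(default_factory=AgeGroups)
    pop_base: float = 4.2e6  # population at age 25, first year
    pop_age_decline: float = 0.012  # exponential decline per year of age
    pop_annual_growth: float = 0.003
    mort_base: float = 0.004  # smoker mortality at age 25
    mort_slope: float = 0.065  # Gompertz log-slope per year of age
    gamma_start: float = 0.20
    gamma_drift: float = -0.004  # absolute change per year
    init_prev_young: float = 0.21  # initial single-age prevalence at 25
    init_prev_old: float = 0.08  # and at 100 (log-linear in between)
    eta_trajectories: tuple[EtaTrajectory, ...] = DEFAULT_TRAJECTORIES
    obs_se: tuple[float, ...] = (0.004, 0.004, 0.005)

    def __post_init__(self) -> None:
        if self.n_obs_years < 2:
            raise GenerationError("need at least 2 observation years")
        if len(self.eta_trajectories) != self.groups.n_groups:
            raise GenerationError("one trajectory per age group required")
        if len(self.obs_se) != self.groups.n_groups or any(s <= 0 for s in self.obs_se):
            raise GenerationError("obs_se must be positive, one per group")
        for p in (self.gamma_start, self.init_prev_young, self.init_prev_old):
            if not 0 <= p <= 1:
                raise GenerationError("prevalences must lie in [0, 1]")


@dataclass(frozen=True)
class ScenarioBundle:
    """A complete, internally consistent input set plus its ground truth."""

    config: ScenarioConfig
    seed: int
    population: AgeYearSchedule
    mortality: AgeYearSchedule
    initiation: InitiationSeries
    initial_prevalence: np.ndarray  # per age, first year
    observations: pd.DataFrame  # year, group_index, group, prevalence, se
    truth: pd.DataFrame  # year, group_index, group, true_eta
    noise_free: pd.DataFrame  # year, group_index, group, prevalence
    metadata: dict

    @property
    def obs_years(self) -> list[int]:
        return sorted(self.observations["year"].unique())

    def true_eta_matrix(self) -> np.ndarray:
        """(n_estimated_years, n_groups) ground-truth rates."""
        piv = self.truth.pivot(index="year", columns="group_index", values="true_eta")
        return piv.sort_index().to_numpy()


def _build_schedules(cfg: ScenarioConfig) -> tuple[AgeYearSchedule, AgeYearSchedule]:
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    years = tuple(range(cfg.start_year, cfg.start_year + cfg.n_obs_years))
    pyramid = cfg.pop_base * np.exp(-cfg.pop_age_decline * (ages - AGE_MIN))
    pop = np.vstack(
        [pyramid * (1.0 + cfg.pop_annual_growth) ** i for i in range(len(years))]
    )
    mort_curve = np.clip(cfg.mort_base * np.exp(cfg.mort_slope * (ages - AGE_MIN)), 0, 1)
    mort = np.tile(mort_curve, (len(years), 1))
    return (
        AgeYearSchedule("population", years, pop),
        AgeYearSchedule("mortality", years, mort),
    )


def _initial_prevalence(cfg: ScenarioConfig) -> np.ndarray:
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    frac = (ages - AGE_MIN) / (AGE_MAX - AGE_MIN)
    return np.exp(
        np.log(cfg.init_prev_young) * (1 - frac) + np.log(cfg.init_prev_old) * frac
    )


def generate_scenario(config: ScenarioConfig | None = None, seed=0) -> ScenarioBundle:
    """Build schedules, run the cohort model forward with the true rates, and
    emit noisy grouped observations (noise truncated to [0, 1], logged).

    ``seed`` may be an integer or an entropy sequence such as [master, i]
    (the counter scheme used for recovery-suite subseeds)."""
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pop, mort = _build_schedules(cfg)
    years = list(pop.years)
    y0, y_last = years[0], years[-1]

    gamma = InitiationSeries(
        {y: float(np.clip(cfg.gamma_start + cfg.gamma_drift * (y - y0), 0, 1))
         for y in years}
    )
    init_prev = _initial_prevalence(cfg)

    n_est = cfg.n_obs_years - 1
    eta_mat = np.column_stack(
        [traj.values(n_est) for traj in cfg.eta_trajectories]
    )
    eta_by_year = {
        y0 + i: CessationParams(eta_mat[i], year=y0 + i) for i in range(n_est)
    }

    C0 = SmokerCounts(year=y0, counts=init_prev * pop.column(y0))
    prev = simulate_prevalence(C0, pop, mort, gamma, eta_by_year, cfg.groups)
    if any(np.any((p < 0) | (p > 1)) for p in prev.values()):
        raise GenerationError("noise-free prevalence left [0, 1]; bad config")

    labels = cfg.groups.labels
    nf_rows, obs_rows, truth_rows = [], [], []
    se = np.asarray(cfg.obs_se)
    for y in years:
        clean = prev[y]
        noisy = clean + rng.normal(0.0, se)
        if np.any((noisy < 0) | (noisy > 1)):
            logger.warning("year %d: noisy observation truncated to [0, 1]", y)
            noisy = np.clip(noisy, 0.0, 1.0)
        for k in range(cfg.groups.n_groups):
            nf_rows.append(dict(year=y, group_index=k, group=labels[k],
                                prevalence=clean[k]))
            obs_rows.append(dict(year=y, group_index=k, group=labels[k],
                                 prevalence=noisy[k], se=se[k]))
    for i in range(n_est):
        for k in range(cfg.groups.n_groups):
            truth_rows.append(dict(year=y0 + i, group_index=k, group=labels[k],
                                   true_eta=eta_mat[i, k]))

    return ScenarioBundle(
        config=cfg,
        seed=seed,
        population=pop,
        mortality=mort,
        initiation=gamma,
        initial_prevalence=init_prev,
        observations=pd.DataFrame(obs_rows),
        truth=pd.DataFrame(truth_rows),
        noise_free=pd.DataFrame(nf_rows),
        metadata=dict(seed=seed, years=f"{y0}-{y_last}", n_obs_years=cfg.n_obs_years),
    )


def make_recovery_suite(
    config: ScenarioConfig | None = None, n_replicates: int = 200, seed: int = 0
) -> list[ScenarioBundle]:
    """Independent observation-noise replicates sharing one ground truth.

    Replicate i uses the derived seed SeedSequence([seed, i]); the schedules,
    initiation series and truth tables are byte-identical across replicates.
    """
    if n_replicates < 1:
        raise GenerationError("n_replicates must be >= 1")
    cfg = config or ScenarioConfig()
    out = []
    for i in range(n_replicates):
        bundle = generate_scenario(cfg, seed=[int(seed), i])
        meta = dict(bundle.metadata, replicate=i, subseed=[int(seed), i])
        out.append(replace(bundle, metadata=meta))
    return out
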