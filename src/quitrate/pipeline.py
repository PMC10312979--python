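"""Annual predict-update estimation cycle over the observation years.

The rate with year label t governs the t -> t+1 transition, so estimating it
needs both the year-t state and the year-(t+1) observed prevalence: N
observation years yield N-1 estimated years.  Smoker counts are propagated
between years with the posterior-mean rates (dual estimation; the cohort
dynamics are treated as deterministic given the rates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import cohort
from .cdkf import (
    FilterConfig,
    MeasurementSpec,
    ParamBelief,
    cdkf_update,
    expit,
    logit,
    predict_params,
)
from .cohort import (
    AgeGroups,
    AgeYearSchedule,
    CessationParams,
    InitiationSeries,
    SmokerCounts,
    group_prevalence,
    one_year_step,
    weighted_average_rate,
    weighted_average_sd,
)

logger = logging.getLogger(__name__)

WEIGHTED_LABEL = "weighted"


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class FilterTrace:
    """Per-estimated-year filter output (the published-table shape).

    Arrays are (n_years, n_groups) unless noted.  ``obs``/``obs_se`` hold the
    year t+1 observation each year-t estimate was updated against; ``fitted``
    is the model prevalence at t+1 under the posterior mean.  Entries may be
    NaN for traces rebuilt from a published table.
    """

    years: np.ndarray  # estimated years, shape (Y,)
    group_labels: tuple[str, ...]
    mean: np.ndarray  # posterior mean rates, proportions
    sd: np.ndarray
    weighted_mean: np.ndarray  # shape (Y,)
    weighted_sd: np.ndarray
    fitted: np.ndarray
    obs: np.ndarray
    obs_se: np.ndarray
    smokers: np.ndarray  # smokers per group at start of year t
    updated: np.ndarray  # bool, False for predict-only years
    final_belief: ParamBelief | None = None
    final_counts: SmokerCounts | None = None

    @property
    def n_years(self) -> int:
        return self.years.size

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    def year_index(self, year: int) -> int:
        idx = np.where(self.years == year)[0]
        if idx.size == 0:
            raise InputError(f"year {year} not in trace ({self.years[0]}..{self.years[-1]})")
        return int(idx[0])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (year, group) plus weighted rows."""
        rows = []
        for i, y in enumerate(self.years):
            for k, g in enumerate(self.group_labels):
                rows.append(
                    dict(
                        year=int(y),
                        group=g,
                        cr_mean=self.mean[i, k],
                        cr_sd=self.sd[i, k],
                        fitted_prev=self.fitted[i, k],
                        obs_prev=self.obs[i, k],
                        obs_se=self.obs_se[i, k],
                        smokers=self.smokers[i, k],
                        updated=bool(self.updated[i]),
                    )
                )
            rows.append(
                dict(
                    year=int(y),
                    group=WEIGHTED_LABEL,
                    cr_mean=self.weighted_mean[i],
                    cr_sd=self.weighted_sd[i],
                    fitted_prev=np.nan,
                    obs_prev=np.nan,
                    obs_se=np.nan,
                    smokers=self.smokers[i].sum(),
                    updated=bool(self.updated[i]),
                )
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_table(
        cls,
        years: Iterable[int],
        group_labels: Iterable[str],
        mean: np.ndarray,
        sd: np.ndarray | None = None,
        weighted_mean: np.ndarray | None = None,
        weighted_sd: np.ndarray | None = None,
        smokers: np.ndarray | None = None,
    ) -> "FilterTrace":
        """Build a trace from published/tabulated estimates (for the summary
        and reporting layer; dynamic fields are NaN)."""
        years = np.asarray(list(years), dtype=int)
        labels = tuple(group_labels)
        mean = np.asarray(mean, dtype=float)
        Y, K = mean.shape
        nan = np.full((Y, K), np.nan)

        def arr(x, shape):
            return np.full(shape, np.nan) if x is None else np.asarray(x, dtype=float)

        return cls(
            years=years,
            group_labels=labels,
            mean=mean,
            sd=arr(sd, (Y, K)),
            weighted_mean=arr(weighted_mean, Y),
            weighted_sd=arr(weighted_sd, Y),
            fitted=nan.copy(),
            obs=nan.copy(),
            obs_se=nan.copy(),
            smokers=arr(smokers, (Y, K)),
            updated=np.ones(Y, dtype=bool),
        )


def run_filter(
    population: AgeYearSchedule,
    mortality: AgeYearSchedule,
    initiation: InitiationSeries,
    initial_prevalence: np.ndarray,
    observations: pd.DataFrame,
    config: FilterConfig | None = None,
    groups: AgeGroups | None = None,
) -> FilterTrace:
    """Run the annual predict-update cycle over the observation span.

    Parameters
    ----------
    initial_prevalence
        Smoking prevalence by single age (25..100) in the first observation
        year; initial smoker counts are prevalence * population.
    observations
        Long table with columns year, group (index or label), prevalence, se.
        Years inside the span with no row get a predict-only year (flagged).
    """
    config = config or FilterConfig()
    groups = groups or AgeGroups()
    K = groups.n_groups

    obs_years = sorted(observations["year"].unique())
    if len(obs_years) < 2:
        raise InputError("need observations for at least 2 years")
    y0, y_last = int(obs_years[0]), int(obs_years[-1])

    obs_map: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for year, sub in observations.groupby("year"):
        if len(sub) != K:
            raise InputError(
                f"year {year}: expected {K} group observations, got {len(sub)}"
            )
        sub = sub.sort_values("group_index") if "group_index" in sub else sub
        obs_map[int(year)] = (
            sub["prevalence"].to_numpy(dtype=float),
            sub["se"].to_numpy(dtype=float),
        )

    init_prev = np.asarray(initial_prevalence, dtype=float)
    if np.any((init_prev < 0) | (init_prev > 1)):
        raise InputError("initial prevalence must lie in [0, 1] per age")
    C = SmokerCounts(year=y0, counts=init_prev * population.column(y0))

    use_logit = config.param_space == "logit"
    belief = config.initial_belief(year=y0)
    if use_logit:
        jac0 = belief.mean * (1.0 - belief.mean)
        belief = ParamBelief(
            mean=logit(belief.mean),
            cov=belief.cov / np.outer(jac0, jac0),
            year=y0,
        )

    est_years = list(range(y0, y_last))
    Y = len(est_years)
    mean = np.empty((Y, K))
    sd = np.empty((Y, K))
    fitted = np.full((Y, K), np.nan)
    obs_arr = np.full((Y, K), np.nan)
    se_arr = np.full((Y, K), np.nan)
    smokers = np.empty((Y, K))
    wmean = np.empty(Y)
    wsd = np.empty(Y)
    updated = np.zeros(Y, dtype=bool)

    for i, t in enumerate(est_years):
        if i > 0:
            belief = predict_params(belief, config.forgetting_lambda)
        smokers[i] = groups.aggregate(C.counts)

        mu_t = mortality.column(t)
        gamma_next = initiation.at(t + 1)
        pop25_next = population.at(cohort.AGE_MIN, t + 1)
        pop_next = population.column(t + 1)
        member = groups.membership()

        def measurement_fn(eta_vec: np.ndarray, _C=C, _mu=mu_t, _g=gamma_next,
                           _p25=pop25_next, _P=pop_next) -> np.ndarray:
            rates = expit(eta_vec) if use_logit else eta_vec
            theta = np.asarray(rates, dtype=float)[member]
            C_next = one_year_step(_C, _mu, theta, _g, _p25)
            return group_prevalence(C_next, _P, groups)

        if t + 1 in obs_map:
            d, se = obs_map[t + 1]
            spec = MeasurementSpec(observation=d, noise_sd=se, measurement_fn=measurement_fn)
            posterior = cdkf_update(
                belief,
                spec,
                h=config.cdkf_step_h,
                clip_bounds=None if use_logit else config.clip_bounds,
            )
            updated[i] = True
            obs_arr[i], se_arr[i] = d, se
        else:
            logger.warning("no observation for year %d: predict-only", t + 1)
            posterior = belief

        if use_logit:
            nat_mean = expit(posterior.mean)
            jac = nat_mean * (1.0 - nat_mean)
            nat_cov = posterior.cov * np.outer(jac, jac)
        else:
            nat_mean = np.clip(posterior.mean, 0.0, 1.0)
            nat_cov = posterior.cov
        mean[i] = nat_mean
        sd[i] = np.sqrt(np.clip(np.diag(nat_cov), 0.0, None))
        wmean[i] = weighted_average_rate(smokers[i], CessationParams(nat_mean, year=t))
        wsd[i] = weighted_average_sd(smokers[i], nat_cov)
        fitted[i] = measurement_fn(posterior.mean if use_logit else nat_mean)

        theta_post = nat_mean[member]
        C = one_year_step(C, mu_t, theta_post, gamma_next, pop25_next)
        logger.info(
            "year %d: posterior %s, weighted %.4f%s",
            t,
            np.array_str(nat_mean, precision=4),
            wmean[i],
            "" if updated[i] else " (predict-only)",
        )
        belief = posterior

    final_belief = ParamBelief(mean=mean[-1], cov=nat_cov, year=est_years[-1])
    return FilterTrace(
        years=np.asarray(est_years),
        group_labels=groups.labels,
        mean=mean,
        sd=sd,
        weighted_mean=wmean,
        weighted_sd=wsd,
        fitted=fitted,
        obs=obs_arr,
        obs_se=se_arr,
        smokers=smokers,
        updated=updated,
        final_belief=final_belief,
        final_counts=C,
    )


# ---------------------------------------------------------------------------
# Summaries (the abstract-style reductions of a trace)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SummaryStats:
    """Period means (percent, one decimal), percent changes (nearest integer)
    and per-year rates relative to the weighted average."""

    period_means: pd.DataFrame  # index period name, columns group labels + weighted
    percent_change: pd.Series  # per group, 100*(end/start - 1) rounded to int
    change_years: tuple[int, int]
    relative: pd.DataFrame  # index year, columns group labels


def relative_rates(trace: FilterTrace) -> pd.DataFrame:
    """Each group's rate divided by that year's weighted average rate."""
    if np.any(trace.weighted_mean <= 0):
        raise cohort.DomainError("weighted average rate must be > 0 for ratios")
    ratios = trace.mean / trace.weighted_mean[:, None]
    return pd.DataFrame(ratios, index=trace.years, columns=list(trace.group_labels))


def summarize_trace(
    trace: FilterTrace,
    periods: Mapping[str, Iterable[int]] | None = None,
    change_years: tuple[int, int] | None = None,
) -> SummaryStats:
    """Reduce a trace to period-mean rates and start-to-end percent changes.

    Period means are arithmetic means of the yearly posterior means, reported
    in percent to one decimal; the percent change is 100*(end/start - 1)
    rounded to the nearest integer.
    """
    if periods is None:
        periods = {"all": [int(y) for y in trace.years]}
    if change_years is None:
        change_years = (int(trace.years[0]), int(trace.years[-1]))

    cols = list(trace.group_labels) + [WEIGHTED_LABEL]
    rows = {}
    for name, yrs in periods.items():
        idx = [trace.year_index(int(y)) for y in yrs]
        vals = [round(100.0 * float(trace.mean[idx, k].mean()), 1)
                for k in range(trace.n_groups)]
        vals.append(round(100.0 * float(trace.weighted_mean[idx].mean()), 1))
        rows[name] = vals
    period_means = pd.DataFrame.from_dict(rows, orient="index", columns=cols)

    i0, i1 = trace.year_index(change_years[0]), trace.year_index(change_years[1])
    change = {}
    for k, g in enumerate(trace.group_labels):
        change[g] = int(round(100.0 * (trace.mean[i1, k] / trace.mean[i0, k] - 1.0)))
    change[WEIGHTED_LABEL] = int(
        round(100.0 * (trace.weighted_mean[i1] / trace.weighted_mean[i0] - 1.0))
    )
    return SummaryStats(
        period_means=period_means,
        percent_change=pd.Series(change),
        change_years=change_years,
        relative=relative_rates(trace),
    )
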