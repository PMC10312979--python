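"""CSV readers/validators/writers, config parsing and report rendering.

All on-disk quantities are decimal proportions (0.206, not 20.6) except the
human-facing estimates table, which renders percentages to two decimals.
Schemas (long format, comma-separated, header required):

    population.csv:          year, age, population
    mortality.csv:           year, age, mu
    initiation.csv:          year, gamma
    initial_prevalence.csv:  age, prevalence        (first year only)
    observed.csv:            year, group_lo, group_hi, prevalence, se
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cdkf import FilterConfig
from .cohort import AGE_MAX, AGE_MIN, N_AGES, AgeGroups, AgeYearSchedule, InitiationSeries
from .pipeline import WEIGHTED_LABEL, FilterTrace, SummaryStats

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

SCHEMAS = {
    "population.csv": ["year", "age", "population"],
    "mortality.csv": ["year", "age", "mu"],
    "initiation.csv": ["year", "gamma"],
    "initial_prevalence.csv": ["age", "prevalence"],
    "observed.csv": ["year", "group_lo", "group_hi", "prevalence", "se"],
}


class InputFileError(ValueError):
    """A schema file is missing, malformed, or out of range (file/row/column
    named in the message)."""


@dataclass(frozen=True)
class ValidatedInputBundle:
    """The five parsed input tables, cross-validated and ready to filter."""

    population: AgeYearSchedule
    mortality: AgeYearSchedule
    initiation: InitiationSeries
    initial_prevalence: np.ndarray
    observations: pd.DataFrame  # year, group_index, group, prevalence, se
    groups: AgeGroups
    first_year: int
    schema_version: str = SCHEMA_VERSION


def _read_table(path: Path, name: str) -> pd.DataFrame:
    f = path / name
    if not f.exists():
        raise InputFileError(f"{name}: file not found in {path}")
    try:
        df = pd.read_csv(f, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise InputFileError(f"{name}: could not parse ({exc})") from exc
    expected = SCHEMAS[name]
    if list(df.columns) != expected:
        raise InputFileError(
            f"{name}: header must be {','.join(expected)}; got {','.join(df.columns)}"
        )
    for col in expected:
        num = pd.to_numeric(df[col], errors="coerce")
        if num.isna().any():
            row = int(num.index[num.isna()][0]) + 2  # 1-based incl. header
            raise InputFileError(f"{name}: non-numeric cell at row {row}, column {col!r}")
        df[col] = num
    return df


def _check_range(df: pd.DataFrame, name: str, col: str, lo: float, hi: float) -> None:
    bad = df.index[(df[col] < lo) | (df[col] > hi)]
    if len(bad):
        row = int(bad[0]) + 2
        raise InputFileError(
            f"{name}: value {df.loc[bad[0], col]} at row {row}, column {col!r} "
            f"outside [{lo}, {hi}]"
        )


def _pivot_schedule(df: pd.DataFrame, name: str, value_col: str, role: str) -> AgeYearSchedule:
    years = sorted(df["year"].unique().astype(int))
    piv = df.pivot_table(index="year", columns="age", values=value_col, aggfunc="first")
    want_ages = list(range(AGE_MIN, AGE_MAX + 1))
    missing = [a for a in want_ages if a not in piv.columns]
    if missing or piv.isna().any().any():
        raise InputFileError(
            f"{name}: incomplete (age, year) grid; e.g. missing age "
            f"{missing[0] if missing else int(piv.columns[piv.isna().any()][0])}"
        )
    return AgeYearSchedule(role, tuple(years), piv.loc[years, want_ages].to_numpy())


def read_inputs(path: str | Path, groups: AgeGroups | None = None) -> ValidatedInputBundle:
    """Parse and validate the five input CSVs from a directory."""
    path = Path(path)
    pop_df = _read_table(path, "population.csv")
    _check_range(pop_df, "population.csv", "population", 0, np.inf)
    mort_df = _read_table(path, "mortality.csv")
    _check_range(mort_df, "mortality.csv", "mu", 0, 1)
    init_df = _read_table(path, "initiation.csv")
    _check_range(init_df, "initiation.csv", "gamma", 0, 1)
    prev_df = _read_table(path, "initial_prevalence.csv")
    _check_range(prev_df, "initial_prevalence.csv", "prevalence", 0, 1)
    obs_df = _read_table(path, "observed.csv")
    _check_range(obs_df, "observed.csv", "prevalence", 0, 1)
    _check_range(obs_df, "observed.csv", "se", np.nextafter(0, 1), 1)

    population = _pivot_schedule(pop_df, "population.csv", "population", "population")
    mortality = _pivot_schedule(mort_df, "mortality.csv", "mu", "mortality")
    initiation = InitiationSeries(dict(zip(init_df["year"].astype(int), init_df["gamma"])))

    prev_df = prev_df.sort_values("age")
    if list(prev_df["age"].astype(int)) != list(range(AGE_MIN, AGE_MAX + 1)):
        raise InputFileError(
            f"initial_prevalence.csv: ages must be exactly {AGE_MIN}..{AGE_MAX}"
        )
    initial_prevalence = prev_df["prevalence"].to_numpy()

    bounds = sorted(
        {(int(lo), int(hi)) for lo, hi in zip(obs_df["group_lo"], obs_df["group_hi"])}
    )
    inferred = AgeGroups(tuple(bounds))
    if groups is not None and groups.bounds != inferred.bounds:
        raise InputFileError(
            f"observed.csv groups {inferred.bounds} differ from configured {groups.bounds}"
        )
    groups = inferred
    obs = obs_df.assign(
        group_index=[groups.index_of(int(lo)) for lo in obs_df["group_lo"]],
        group=[groups.labels[groups.index_of(int(lo))] for lo in obs_df["group_lo"]],
        year=obs_df["year"].astype(int),
    )[["year", "group_index", "group", "prevalence", "se"]]

    obs_years = sorted(obs["year"].unique())
    first_year = int(obs_years[0])
    for sched in (population, mortality):
        for y in obs_years:
            sched.column(y)  # raises ScheduleGapError naming the year
    return ValidatedInputBundle(
        population=population,
        mortality=mortality,
        initiation=initiation,
        initial_prevalence=initial_prevalence,
        observations=obs.sort_values(["year", "group_index"]).reset_index(drop=True),
        groups=groups,
        first_year=first_year,
    )


def write_inputs(bundle, path: str | Path) -> None:
    """Write a bundle (ScenarioBundle or ValidatedInputBundle) to the five
    schema CSVs; scenario bundles additionally get truth.csv and metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pop, mort = bundle.population, bundle.mortality
    ages = np.arange(AGE_MIN, AGE_MAX + 1)

    def long(sched: AgeYearSchedule, col: str) -> pd.DataFrame:
        rows = []
        for i, y in enumerate(sched.years):
            for j, a in enumerate(ages):
                rows.append({"year": y, "age": a, col: sched.values[i, j]})
        return pd.DataFrame(rows)

    _write_csv(long(pop, "population"), path / "population.csv")
    _write_csv(long(mort, "mu"), path / "mortality.csv")
    _write_csv(
        pd.DataFrame(
            sorted(bundle.initiation.gamma.items()), columns=["year", "gamma"]
        ),
        path / "initiation.csv",
    )
    _write_csv(
        pd.DataFrame({"age": ages, "prevalence": bundle.initial_prevalence}),
        path / "initial_prevalence.csv",
    )
    groups = bundle.groups if hasattr(bundle, "groups") else bundle.config.groups
    obs = bundle.observations.copy()
    obs["group_lo"] = [groups.bounds[k][0] for k in obs["group_index"]]
    obs["group_hi"] = [groups.bounds[k][1] for k in obs["group_index"]]
    _write_csv(
        obs[["year", "group_lo", "group_hi", "prevalence", "se"]],
        path / "observed.csv",
    )
    if hasattr(bundle, "truth"):
        _write_csv(bundle.truth, path / "truth.csv")
        _write_csv(bundle.noise_free, path / "noise_free_prevalence.csv")
        with open(path / "metadata.yaml", "w") as fh:
            yaml.safe_dump(dict(bundle.metadata), fh)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InputFileError(f"{path}: config must be a key/value mapping")
    return cfg


def filter_config_from_dict(cfg: dict) -> FilterConfig:
    keys = (
        "forgetting_lambda",
        "cdkf_step_h",
        "prior_mean",
        "prior_sd",
        "param_space",
    )
    kwargs = {k: cfg[k] for k in keys if k in cfg}
    for k in ("prior_mean", "prior_sd"):
        if k in kwargs:
            kwargs[k] = tuple(float(v) for v in np.atleast_1d(kwargs[k]))
    return FilterConfig(**kwargs)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def render_reports(
    trace: FilterTrace, stats: SummaryStats | None, outdir: str | Path
) -> dict[str, Path]:
    """Write the human-facing estimates table (percent, two decimals), the
    fitted-vs-observed table with 95% bands, and the relative-rate table.

    Rendering is deterministic: identical traces give byte-identical files.
    """
    if trace.n_years == 0:
        raise InputFileError("cannot render an empty trace")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    rows = []
    for i, y in enumerate(trace.years):
        row: dict[str, object] = {"year": int(y)}
        for k, g in enumerate(trace.group_labels):
            row[f"CR ({g})"] = f"{100 * trace.mean[i, k]:.2f}%"
            row[f"SD ({g})"] = f"{100 * trace.sd[i, k]:.2f}%"
        row["CR (weighted average)"] = f"{100 * trace.weighted_mean[i]:.2f}%"
        row["SD (weighted average)"] = f"{100 * trace.weighted_sd[i]:.2f}%"
        rows.append(row)
    out["table"] = outdir / "estimates_table.csv"
    _write_csv(pd.DataFrame(rows), out["table"])

    fig2 = []
    for i, y in enumerate(trace.years):
        for k, g in enumerate(trace.group_labels):
            se = trace.obs_se[i, k]
            fig2.append(
                dict(
                    year=int(y) + 1,  # fitted/observed refer to the t+1 prevalence
                    group=g,
                    fitted_prev=trace.fitted[i, k],
                    obs_prev=trace.obs[i, k],
                    obs_lo=trace.obs[i, k] - 1.96 * se,
                    obs_hi=trace.obs[i, k] + 1.96 * se,
                )
            )
    out["fig2"] = outdir / "fig2_data.csv"
    _write_csv(pd.DataFrame(fig2), out["fig2"])

    from .pipeline import relative_rates

    rel = relative_rates(trace).round(3)
    rel.index.name = "year"
    out["fig3"] = outdir / "fig3_data.csv"
    _write_csv(rel.reset_index(), out["fig3"])

    if stats is not None:
        pm = stats.period_means.copy()
        pm.index.name = "period"
        out["summary"] = outdir / "summary.csv"
        _write_csv(pm.reset_index(), out["summary"])
    return out
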