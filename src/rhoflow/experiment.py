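"""Scenario grid, bias summaries and statistical analyses.

Runs the isolation-with-migration scenario grid (continuous gene flow vs
secondary contact x Nem x recombination change), estimates rho for both
populations at every sampling time, and aggregates the estimates into the
study's headline quantities: percent bias of the inferred rate against the
Nem = 0 baseline, the inferred between-population difference p2 - p1, a
variance-ratio test, and a standardized fixed-effects linear model.

The default "desk" preset shrinks the in-silico population to N_model = 200
(100 for single-population equilibrium work) and the genome to 20 kb while
preserving theta/site = 0.0378, rho/site = 0.1534 and all durations in
units of N, so the full pipeline runs on one CPU in minutes rather than
cluster-months.  The paper-scale preset (N = 1000, 100 kb) is available for
larger machines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scaling import (
    DEFAULT_MU_SITE,
    DEFAULT_NE_ACTUAL,
    DEFAULT_R_SITE,
    EventSchedule,
    MigrationSpec,
    ScaledParameters,
    build_schedule,
    rescale,
)
from .twolocus import LookupTable, build_lookup_table, default_rho_grid
from .estimate import composite_rho
from .stats import diversity, hudson_fst
from .wf import advance_generation, initialize_population, run_schedule

__all__ = [
    "ExperimentCell",
    "RunPreset",
    "desk_preset",
    "paper_preset",
    "small_ne_preset",
    "default_grid",
    "build_scenario_tables",
    "run_burn_in",
    "run_grid",
    "percent_bias",
    "population_difference",
    "variance_ratio_test",
    "standardized_lm",
]

NEM_GRID = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class ExperimentCell:
    """One cell of the scenario grid."""

    scenario: str  # "continuous" | "secondary"
    nem: float
    recomb_factor_p2: float = 1.0
    migration_mode: str = "symmetric"

    def label(self) -> str:
        tag = "" if self.migration_mode == "symmetric" else f"-{self.migration_mode}"
        return f"{self.scenario}-nem{self.nem:g}-f{self.recomb_factor_p2:g}{tag}"


@dataclass(frozen=True)
class RunPreset:
    """Scale preset: population/genome size plus estimator settings."""

    name: str
    ne_actual: float = DEFAULT_NE_ACTUAL
    mu_site: float = DEFAULT_MU_SITE
    r_site: float = DEFAULT_R_SITE
    n_model: int = 200
    L: int = 20_000
    n_sample: int = 25
    # singletons are retained at the estimator's subsample scale: the
    # migration-LD signal at low Nem lives in low-frequency immigrant alleles
    maf_min: float = 0.05
    d_max: float = 2_500
    table_n: int = 20
    table_mc: int = 20_000
    max_pairs: int = 1_500
    n_subsamples: int = 5

    @property
    def params(self) -> ScaledParameters:
        return rescale(self.ne_actual, self.mu_site, self.r_site, self.n_model, self.L)


def desk_preset(**overrides) -> RunPreset:
    return replace(RunPreset(name="desk"), **overrides)


def paper_preset(**overrides) -> RunPreset:
    return replace(
        RunPreset(name="paper", n_model=1000, L=100_000, table_mc=50_000), **overrides
    )


def small_ne_preset(**overrides) -> RunPreset:
    """Small effective size (Ne = 1,720): the robustness check grid."""
    return replace(
        RunPreset(name="small-ne", ne_actual=1720.0, n_model=172), **overrides
    )


def default_grid(
    scenarios=("continuous", "secondary"),
    nem_values=NEM_GRID,
    recomb_factors=(1.0, 2.0),
    migration_mode: str = "symmetric",
) -> list[ExperimentCell]:
    return [
        ExperimentCell(s, nem, f, migration_mode)
        for s in scenarios
        for f in recomb_factors
        for nem in nem_values
    ]


def _schedule_for(
    cell: ExperimentCell, preset: RunPreset, **duration_overrides
) -> tuple[EventSchedule, MigrationSpec]:
    mig = MigrationSpec.from_nem(
        cell.nem, preset.n_model, mode=cell.migration_mode
    )
    return build_schedule(
        cell.scenario,
        mig,
        cell.recomb_factor_p2,
        preset.params,
        n_sample=preset.n_sample,
        **duration_overrides,
    ), mig


def build_scenario_tables(
    preset: RunPreset, seed: int, scenarios=("equilibrium", "continuous", "secondary")
) -> dict[str, LookupTable]:
    """One lookup table per demographic context.

    All tables use the sampled population's contemporary size as reference:
    the equilibrium table has a constant history; the post-split tables have
    a doubling of size (back to the ancestral N) at a depth equal to the
    midpoint of the sampling window, measured in units of 2*N_sub model
    generations.  Building one table per scenario rather than per sampling
    time is a desk-scale simplification: across the 51,000-generation
    window the change-time varies by under 2% of the coalescent timescale.
    """
    params = preset.params
    n_sub = preset.n_model // 2
    theta = params.theta_site
    grid = default_rho_grid()
    tables: dict[str, LookupTable] = {}
    rng = np.random.SeedSequence(seed)
    seeds = {s: int(ss.generate_state(1)[0] % 2**31) for s, ss in
             zip(scenarios, rng.spawn(len(scenarios)))}
    for scen in scenarios:
        if scen == "equilibrium":
            history = [(0.0, 1.0)]
        else:
            cell = ExperimentCell(scen, 0.0)
            sched, _ = _schedule_for(cell, preset)
            depth = (sched.migration_onset_gen - sched.split_gen
                     + (sched.end_gen - sched.migration_onset_gen) / 2) / (2.0 * n_sub)
            history = [(0.0, 1.0), (depth, 2.0)]
        tables[scen] = build_lookup_table(
            preset.table_n, theta, grid, history, preset.table_mc, seeds[scen]
        )
    return tables


def run_burn_in(preset: RunPreset, seed, n_generations: int | None = None):
    """Evolve a single ancestral population to mutation-drift equilibrium."""
    params = preset.params
    mig = MigrationSpec.from_nem(0.0, preset.n_model)
    sched, _ = _schedule_for(ExperimentCell("continuous", 0.0), preset)
    state = initialize_population(params, seed)
    n_gens = sched.split_gen - 1 if n_generations is None else n_generations
    for _ in range(n_gens):
        advance_generation(state, mig, sched)
    return state


def _estimate_seed(base: int, rep: int, gen: int, pop: int) -> int:
    return int((base * 1_000_003 + rep * 8191 + gen * 131 + pop) % (2**31 - 1))


def run_grid(
    cells: list[ExperimentCell],
    preset: RunPreset,
    n_replicates: int,
    seed: int,
    tables: dict[str, LookupTable] | None = None,
    *,
    share_burn_in: bool = True,
    collect_diversity: bool = True,
) -> pd.DataFrame:
    """Simulate and estimate every cell x replicate x sampling time.

    Returns one row per (cell, replicate, generation, population) with the
    composite-likelihood estimate in both scaled (rho/site) and
    back-transformed (cM/Mb) units.  With ``share_burn_in`` each replicate
    runs one ancestral burn-in and branches every cell from a copy of that
    state (common random numbers), pairing cells with their Nem = 0
    baseline.  Per-replicate failures are recorded and skipped; a cell
    fails only if more than half its replicates do.
    """
    if n_replicates < 2:
        raise ValueError("need at least two replicates")
    if tables is None:
        tables = build_scenario_tables(preset, seed + 1)
    params = preset.params
    rows: list[dict] = []
    failures: list[tuple[str, int, str]] = []
    root = np.random.SeedSequence(seed)
    # stable integer per replicate: a fresh SeedSequence is derived from it
    # at every use, so shared and independent branches see identical streams
    rep_seeds = [int(ss.generate_state(1)[0] % 2**31) for ss in root.spawn(n_replicates)]
    ref_ne_sub = preset.ne_actual / 2.0

    for rep in range(n_replicates):
        burn_state = run_burn_in(preset, rep_seeds[rep]) if share_burn_in else None
        # cache the isolation phase per (scenario, factor): migration is
        # inactive before contact, so the trajectory (and RNG stream) is
        # identical across Nem values and branching at contact is exact
        iso_cache: dict[tuple, object] = {}
        for cell in cells:
            sched, mig = _schedule_for(cell, preset)
            try:
                if share_burn_in:
                    key = (cell.scenario, cell.recomb_factor_p2)
                    if sched.migration_onset_gen - sched.split_gen > 1:
                        if key not in iso_cache:
                            st = burn_state.copy()
                            while st.generation < sched.migration_onset_gen - 1:
                                advance_generation(st, mig, sched)
                            iso_cache[key] = st
                        state = iso_cache[key].copy()
                    else:
                        state = burn_state.copy()
                else:
                    state = None
                for s in run_schedule(
                    params, sched, mig, rep_seeds[rep], state=state, replicate_id=rep
                ):
                    pop = 0 if s.population in ("p1", "anc") else 1
                    table = tables[cell.scenario]
                    est = composite_rho(
                        s,
                        table,
                        preset.maf_min,
                        preset.d_max,
                        max_pairs=preset.max_pairs,
                        n_subsamples=preset.n_subsamples,
                        reference_Ne=ref_ne_sub,
                        seed=_estimate_seed(seed, rep, s.generation_model, pop),
                    )
                    row = {
                        "scenario": cell.scenario,
                        "nem": cell.nem,
                        "recomb_factor_p2": cell.recomb_factor_p2,
                        "migration_mode": cell.migration_mode,
                        "replicate": rep,
                        "generation_model": s.generation_model,
                        "time_since_onset": s.metadata.get("time_since_onset", 0),
                        "population": s.population,
                        "rho_site": est.rho_site,
                        "r_cmmb": est.r_cmmb,
                        "n_pairs": est.n_pairs,
                        "at_boundary": est.at_boundary,
                    }
                    if collect_diversity:
                        d = diversity(s)
                        row["pi_site"] = d.pi_per_site
                        row["segregating_sites"] = d.segregating_sites
                    rows.append(row)
            except Exception as exc:  # noqa: BLE001 - per-replicate fault isolation
                failures.append((cell.label(), rep, repr(exc)))
    if failures:
        by_cell: dict[str, int] = {}
        for label, _, _ in failures:
            by_cell[label] = by_cell.get(label, 0) + 1
        worst = max(by_cell.values())
        if worst > 0.5 * n_replicates:
            raise RuntimeError(
                f"cell failed in >50% of replicates: {by_cell}; first: {failures[0]}"
            )
    df = pd.DataFrame(rows)
    df.attrs["failures"] = failures
    return df


def percent_bias(
    results: pd.DataFrame, *, value: str = "r_cmmb"
) -> pd.DataFrame:
    """Percent bias of each cell against its Nem = 0 baseline.

    The baseline is the matched (scenario, recombination setting, migration
    mode, population) cell at Nem = 0; the pooled summary averages over
    populations, sampling times and replicates, mirroring the convention of
    summarizing across all generations against the no-gene-flow mean.
    """
    keys = ["scenario", "recomb_factor_p2", "migration_mode"]
    out = []
    for group_key, grp in results.groupby(keys):
        base = grp[grp["nem"] == 0]
        if base.empty:
            raise ValueError(f"missing Nem = 0 baseline for {group_key}")
        base_pooled = base[value].mean()
        base_per_pop = base.groupby("population")[value].mean()
        for nem, cell in grp.groupby("nem"):
            pooled = cell[value].mean()
            rec = dict(zip(keys, group_key))
            rec.update(
                nem=nem,
                mean=pooled,
                sd=cell[value].std(ddof=1),
                baseline_mean=base_pooled,
                bias_pct=100.0 * (pooled - base_pooled) / base_pooled,
                n=len(cell),
            )
            for pop, sub in cell.groupby("population"):
                rec[f"bias_pct_{pop}"] = (
                    100.0 * (sub[value].mean() - base_per_pop[pop]) / base_per_pop[pop]
                )
            out.append(rec)
    return pd.DataFrame(out).sort_values(keys + ["nem"]).reset_index(drop=True)


def population_difference(results: pd.DataFrame, *, value: str = "r_cmmb"):
    """Per-replicate inferred difference p2 - p1 at each sampling time.

    Returns ``(per_obs, summary)``: the paired differences and their
    mean +- SD per cell.
    """
    two_pop = results[results["population"].isin(["p1", "p2"])]
    keys = ["scenario", "nem", "recomb_factor_p2", "migration_mode",
            "replicate", "generation_model"]
    wide = two_pop.pivot_table(index=keys, columns="population", values=value)
    if wide.isna().any().any():
        raise ValueError("unmatched p1/p2 rows; cannot pair populations")
    per = wide.reset_index()
    per["difference"] = per["p2"] - per["p1"]
    cell_keys = ["scenario", "nem", "recomb_factor_p2", "migration_mode"]
    summary = (
        per.groupby(cell_keys)["difference"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return per, summary


def variance_ratio_test(group_a, group_b) -> dict:
    """Two-sided F-test for equality of variances (ratio s2_a / s2_b)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        raise ZeroDivisionError("zero variance in denominator group")
    F = va / vb
    dfn, dfd = len(a) - 1, len(b) - 1
    cdf = sps.f.cdf(F, dfn, dfd)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return {"F": float(F), "df": (dfn, dfd), "p": float(min(p, 1.0))}


def standardized_lm(results: pd.DataFrame, *, value: str = "r_cmmb") -> pd.DataFrame:
    """Standardized fixed-effect coefficients for gene-flow magnitude and
    the recombination-change indicator, per scenario.

    The random intercepts of the original mixed model (simulation replicate
    and generation) are absorbed as fixed group effects — a within-group
    centering approximation rather than REML — and all variables are
    z-scored first, so coefficients are comparable across predictors.
    Constant predictors raise a singular-fit error naming the column.
    """
    import statsmodels.formula.api as smf

    out = []
    for scen, grp in results.groupby("scenario"):
        df = grp.copy()
        df["z_y"] = _zscore(df[value], value)
        df["z_nem"] = _zscore(df["nem"], "nem")
        df["z_factor"] = _zscore(df["recomb_factor_p2"], "recomb_factor_p2")
        model = smf.ols(
            "z_y ~ z_nem + z_factor + C(replicate) + C(generation_model)", data=df
        ).fit()
        for term, label in (("z_nem", "gene_flow"), ("z_factor", "recomb_change")):
            out.append(
                {
                    "scenario": scen,
                    "term": label,
                    "coef": model.params[term],
                    "se": model.bse[term],
                    "t": model.tvalues[term],
                    "p": model.pvalues[term],
                    "n": int(model.nobs),
                    "note": "fixed-effects (within-group centering) approximation",
                }
            )
    return pd.DataFrame(out)


def _zscore(col: pd.Series, name: str) -> pd.Series:
    sd = col.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"predictor or response {name!r} is constant; cannot standardize")
    return (col - col.mean()) / sd
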