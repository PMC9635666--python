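"""Discrete-generation diploid Wright-Fisher simulator.

The simulator tracks a haplotype 0/1 matrix over the currently relevant
variant positions of a 0-based integer genome of length L.  Each generation
every offspring chooses two parents uniformly from its parental pool (with
probability ``m`` the pool is the other subpopulation — migration acts on
offspring parentage, matching the usual WF-model semantics of offspring
fractions), each gamete receives a Poisson number of crossovers placed
uniformly along the genome, and new mutations arise under an approximate
infinite-sites model (integer positions, redrawn on collision with a
currently segregating site).

Randomness is split into independent child streams (reproduction, mutation,
sampling) derived from one root seed, so that drawing genotype samples never
perturbs the evolutionary trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from ._kernels import assemble_gametes
from .scaling import EventSchedule, MigrationSpec, ScaledParameters

__all__ = [
    "PopulationState",
    "SampleSet",
    "initialize_population",
    "advance_generation",
    "run_schedule",
    "draw_sample",
    "draw_paired_sample",
]


@dataclass
class SampleSet:
    """A haplotype sample: the unit of exchange between pipeline stages.

    ``H`` is an ``n_hap x n_sites`` 0/1 matrix (0 ancestral, 1 derived) whose
    columns are sorted by ``positions`` (0-based bp).  Haplotypes from the
    same diploid are adjacent rows.  Columns are guaranteed to segregate
    within the union of haplotypes the sample was extracted with (for paired
    two-population draws that union spans both samples, so between-population
    fixed differences are retained).
    """

    positions: np.ndarray
    H: np.ndarray
    population: str
    L: int
    generation_model: int = 0
    generation_actual: float = 0.0
    replicate_id: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def n_hap(self) -> int:
        return self.H.shape[0]

    @property
    def n_sites(self) -> int:
        return self.H.shape[1]

    @property
    def pop_labels(self) -> np.ndarray:
        return np.full(self.n_hap, self.population)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.H = np.asarray(self.H, dtype=np.uint8)
        if self.H.ndim != 2 or self.H.shape[1] != len(self.positions):
            raise ValueError("haplotype matrix and positions are inconsistent")


@dataclass
class PopulationState:
    """Internal simulator state: one or two populations plus RNG streams."""

    params: ScaledParameters
    H: np.ndarray  # (total haplotypes) x (tracked sites), uint8
    positions: np.ndarray  # int64, sorted
    pop_sizes: list[int]  # diploids per population, haplotypes stored pop-by-pop
    r_factors: list[float]  # per-population recombination multiplier
    generation: int
    rng_repro: np.random.Generator
    rng_mut: np.random.Generator
    rng_sample: np.random.Generator
    seg_positions: np.ndarray  # segregating positions as of last generation
    substitutions: list = field(default_factory=list)
    purge_interval: int = 1

    @property
    def n_pops(self) -> int:
        return len(self.pop_sizes)

    @property
    def n_hap(self) -> int:
        return 2 * sum(self.pop_sizes)

    def hap_slice(self, pop: int) -> slice:
        start = 2 * sum(self.pop_sizes[:pop])
        return slice(start, start + 2 * self.pop_sizes[pop])

    def copy(self) -> "PopulationState":
        """Deep copy (RNG streams included) for branching scenarios off a
        shared burn-in."""
        import copy as _copy

        return PopulationState(
            params=self.params,
            H=self.H.copy(),
            positions=self.positions.copy(),
            pop_sizes=list(self.pop_sizes),
            r_factors=list(self.r_factors),
            generation=self.generation,
            rng_repro=_copy.deepcopy(self.rng_repro),
            rng_mut=_copy.deepcopy(self.rng_mut),
            rng_sample=_copy.deepcopy(self.rng_sample),
            seg_positions=self.seg_positions.copy(),
            substitutions=list(self.substitutions),
            purge_interval=self.purge_interval,
        )


def initialize_population(
    params: ScaledParameters, seed: int | np.random.SeedSequence
) -> PopulationState:
    """Monomorphic single population of ``N_model`` diploids.

    Mutation-drift equilibrium is reached during the burn-in; nucleotide
    diversity starts at zero.
    """
    if params.N_model < 2:
        raise ValueError("N_model must be >= 2")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    repro, mut, samp = [np.random.default_rng(s) for s in ss.spawn(3)]
    n_hap = 2 * params.N_model
    return PopulationState(
        params=params,
        H=np.empty((n_hap, 0), dtype=np.uint8),
        positions=np.empty(0, dtype=np.int64),
        pop_sizes=[params.N_model],
        r_factors=[1.0],
        generation=0,
        rng_repro=repro,
        rng_mut=mut,
        rng_sample=samp,
        seg_positions=np.empty(0, dtype=np.int64),
    )


def _draw_new_mutation_positions(
    rng: np.random.Generator, n_mut: int, L: int, occupied: np.ndarray
) -> np.ndarray:
    """Uniform integer positions, redrawn until distinct from each other and
    from currently segregating sites (approximate infinite sites)."""
    pos = rng.integers(0, L, size=n_mut)
    for _ in range(64):
        bad = np.isin(pos, occupied)
        # mark all but the first occurrence of each repeated value
        _, first = np.unique(pos, return_index=True)
        dup = np.ones(n_mut, dtype=bool)
        dup[first] = False
        bad |= dup
        if not bad.any():
            return pos
        pos = pos.copy()
        pos[bad] = rng.integers(0, L, size=int(bad.sum()))
    raise RuntimeError("could not place mutations without collision; L too small")


def advance_generation(
    state: PopulationState,
    migration: MigrationSpec,
    schedule: EventSchedule,
) -> PopulationState:
    """Advance the state by one generation (in place; returns the state).

    Scheduled events are applied at their generation before reproduction:
    at ``split_gen`` the offspring generation is divided into two pools of
    N/2 drawing parents from the ancestral population, and population 2's
    recombination rate is multiplied by ``recomb_factor_p2``; migration
    affects offspring born strictly after ``migration_onset_gen``.
    """
    params = state.params
    g_next = state.generation + 1
    rng = state.rng_repro

    # --- event: population split -------------------------------------------------
    if g_next == schedule.split_gen and state.n_pops == 1:
        n_sub = params.N_model // 2
        child_sizes = [n_sub, params.N_model - n_sub]
        child_r_factors = [1.0, schedule.recomb_factor_p2]
        splitting = True
    else:
        child_sizes = list(state.pop_sizes)
        child_r_factors = list(state.r_factors)
        splitting = False

    migration_active = (
        state.n_pops == 2
        and not splitting
        and migration.Nem > 0
        and g_next > schedule.migration_onset_gen
        and g_next > schedule.split_gen
    )

    n_sites = state.H.shape[1]
    L = params.L

    # --- choose parental pools and parents ----------------------------------------
    # per offspring pop: array of source-pop ids, then diploid parent indices
    gam_rows_a: list[np.ndarray] = []
    gam_rows_b: list[np.ndarray] = []
    gam_lambda: list[np.ndarray] = []
    pop_hap_offset = [2 * sum(state.pop_sizes[:p]) for p in range(state.n_pops)]

    for i, ni in enumerate(child_sizes):
        if splitting:
            src = np.zeros(ni, dtype=np.int64)
        elif migration_active:
            other = 1 - i
            if migration.mode == "unidirectional" and i != 0:
                src = np.full(ni, i, dtype=np.int64)  # only p1 receives p2 migrants
            else:
                mig = rng.random(ni) < migration.m_model
                src = np.where(mig, other, i)
        else:
            src = np.full(ni, min(i, state.n_pops - 1), dtype=np.int64)

        pool_sizes = np.array([state.pop_sizes[s] for s in src])
        pool_offs = np.array([pop_hap_offset[s] for s in src])
        # two parents per offspring, drawn independently (selfing possible)
        p1 = (rng.random(ni) * pool_sizes).astype(np.int64)
        p2 = (rng.random(ni) * pool_sizes).astype(np.int64)
        # one gamete from each parent; random leading haplotype per gamete
        start = rng.integers(0, 2, size=2 * ni)
        parent = np.empty(2 * ni, dtype=np.int64)
        parent[0::2] = pool_offs + 2 * p1
        parent[1::2] = pool_offs + 2 * p2
        gam_rows_a.append(parent + start)
        gam_rows_b.append(parent + (1 - start))
        # crossover intensity follows the *parent's* population rate
        r_src = params.r_site_model * np.array([state.r_factors[s] for s in src])
        lam = np.repeat(r_src * L, 2)
        gam_lambda.append(lam)

    row_a = np.concatenate(gam_rows_a)
    row_b = np.concatenate(gam_rows_b)
    lam = np.concatenate(gam_lambda)
    n_gam = len(row_a)

    # --- crossover breakpoints ----------------------------------------------------
    k = rng.poisson(lam)
    total_k = int(k.sum())
    if total_k:
        gam_ids = np.repeat(np.arange(n_gam, dtype=np.float64), k)
        # sorting composite keys sorts breakpoints within each gamete's block
        keys = np.sort(gam_ids * L + rng.random(total_k) * L)
        bp_vals = keys % L
        bp_cols = np.searchsorted(state.positions, bp_vals)
    else:
        bp_cols = np.empty(0, dtype=np.int64)
    bp_off = np.zeros(n_gam + 1, dtype=np.int64)
    np.cumsum(k, out=bp_off[1:])

    child_H = assemble_gametes(state.H, row_a, row_b, bp_cols, bp_off)

    # --- new mutations -------------------------------------------------------------
    rng_mut = state.rng_mut
    n_mut = int(rng_mut.poisson(n_gam * params.mu_site_model * L))
    if n_mut:
        new_pos = _draw_new_mutation_positions(rng_mut, n_mut, L, state.seg_positions)
        rows = rng_mut.integers(0, n_gam, size=n_mut)
        order = np.argsort(new_pos, kind="stable")
        new_pos = new_pos[order]
        rows = rows[order]
        new_cols = np.zeros((n_gam, n_mut), dtype=np.uint8)
        new_cols[rows, np.arange(n_mut)] = 1
        all_pos = np.concatenate([state.positions, new_pos])
        all_H = np.concatenate([child_H, new_cols], axis=1)
    else:
        all_pos = state.positions
        all_H = child_H

    # --- drop lost columns; purge fixed ones on schedule ---------------------------
    counts = all_H.sum(axis=0, dtype=np.int64)
    seg = (counts > 0) & (counts < n_gam)
    if g_next % state.purge_interval == 0:
        keep = seg
        fixed = counts == n_gam
        if fixed.any():
            for p in all_pos[fixed]:
                state.substitutions.append((g_next, int(p)))
    else:
        keep = counts > 0
    order = np.argsort(all_pos[keep], kind="stable")
    kept_idx = np.flatnonzero(keep)[order]
    state.H = np.ascontiguousarray(all_H[:, kept_idx])
    state.positions = all_pos[kept_idx]
    seg_idx = np.flatnonzero(seg)
    state.seg_positions = np.sort(all_pos[seg_idx])
    state.pop_sizes = child_sizes
    state.r_factors = child_r_factors
    state.generation = g_next
    return state


def _extract(
    state: PopulationState, pop: int, diploid_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    off = 2 * sum(state.pop_sizes[:pop])
    rows = np.empty(2 * len(diploid_idx), dtype=np.int64)
    rows[0::2] = off + 2 * diploid_idx
    rows[1::2] = off + 2 * diploid_idx + 1
    return rows, state.H[rows]


def _pop_name(state: PopulationState, pop: int) -> str:
    return "anc" if state.n_pops == 1 else f"p{pop + 1}"


def draw_sample(
    state: PopulationState,
    population_id: int,
    n_diploids: int,
    seed: int | None = None,
    **stamp,
) -> SampleSet:
    """Uniform sample of diploids without replacement from one population.

    Columns that do not segregate within the sample (including derived
    alleles fixed in it) are removed.
    """
    if population_id >= state.n_pops:
        raise ValueError(f"no population {population_id}")
    n_pop = state.pop_sizes[population_id]
    if n_diploids > n_pop:
        raise ValueError(f"cannot sample {n_diploids} diploids from {n_pop}")
    rng = np.random.default_rng(seed) if seed is not None else state.rng_sample
    idx = rng.choice(n_pop, size=n_diploids, replace=False)
    _, Hs = _extract(state, population_id, np.sort(idx))
    counts = Hs.sum(axis=0, dtype=np.int64)
    seg = (counts > 0) & (counts < Hs.shape[0])
    return SampleSet(
        positions=state.positions[seg],
        H=np.ascontiguousarray(Hs[:, seg]),
        population=_pop_name(state, population_id),
        L=state.params.L,
        generation_model=state.generation,
        **stamp,
    )


def draw_paired_sample(
    state: PopulationState, n_diploids: int, seed: int | None = None, **stamp
) -> tuple[SampleSet, SampleSet]:
    """One sample per population with a shared column set.

    Segregation is assessed on the union of the two samples, so sites fixed
    within one population but not the other (between-population differences)
    are kept in both — required for divergence statistics such as FST.
    """
    if state.n_pops != 2:
        raise ValueError("paired sampling requires two populations")
    rng = np.random.default_rng(seed) if seed is not None else state.rng_sample
    mats = []
    for pop in (0, 1):
        n_pop = state.pop_sizes[pop]
        if n_diploids > n_pop:
            raise ValueError(f"cannot sample {n_diploids} diploids from {n_pop}")
        idx = rng.choice(n_pop, size=n_diploids, replace=False)
        _, Hs = _extract(state, pop, np.sort(idx))
        mats.append(Hs)
    union = np.concatenate(mats, axis=0)
    counts = union.sum(axis=0, dtype=np.int64)
    seg = (counts > 0) & (counts < union.shape[0])
    out = []
    for pop, Hs in enumerate(mats):
        out.append(
            SampleSet(
                positions=state.positions[seg],
                H=np.ascontiguousarray(Hs[:, seg]),
                population=_pop_name(state, pop),
                L=state.params.L,
                generation_model=state.generation,
                **stamp,
            )
        )
    return out[0], out[1]


def run_schedule(
    params: ScaledParameters,
    schedule: EventSchedule,
    migration: MigrationSpec,
    seed: int | np.random.SeedSequence,
    *,
    state: PopulationState | None = None,
    replicate_id: int = 0,
) -> Iterator[SampleSet]:
    """Execute the full demographic schedule, yielding genotype samples.

    Yields one SampleSet per population at every sampling time (paired
    column sets once two populations exist).  Fully deterministic given the
    seed.  A pre-built ``state`` (e.g. a shared burn-in at ``split_gen - 1``
    or earlier) may be supplied to branch scenarios off a common ancestor.
    """
    if state is None:
        state = initialize_population(params, seed)
    if state.generation >= schedule.migration_onset_gen:
        raise ValueError("supplied state is already past the migration onset")
    if state.generation > schedule.split_gen and state.n_pops != 2:
        raise ValueError("state past the split must carry two populations")
    sampling_times = set(schedule.sampling_times)
    while state.generation < schedule.end_gen:
        advance_generation(state, migration, schedule)
        g = state.generation
        if g in sampling_times:
            actual = (g - schedule.split_gen) * params.Q
            stamp = dict(
                generation_actual=actual,
                replicate_id=replicate_id,
                metadata={
                    "scenario": schedule.scenario,
                    "nem": migration.Nem,
                    "recomb_factor_p2": schedule.recomb_factor_p2,
                    "time_since_onset": g - schedule.migration_onset_gen,
                },
            )
            if state.n_pops == 2:
                s1, s2 = draw_paired_sample(state, schedule.n_sample, **stamp)
                yield s1
                yield s2
            else:
                yield draw_sample(state, 0, schedule.n_sample, **stamp)
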