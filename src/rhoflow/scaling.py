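"""Parameter rescaling and demographic event schedules.

Forward-time simulation of a *Drosophila*-sized population (N_e on the order
of 10^6) is intractable generation-by-generation, so the standard rescaling
trick is used: simulate a much smaller population of ``N_model`` individuals
and inflate the per-generation mutation and crossover probabilities by
``Q = Ne_actual / N_model``.  All population-scaled quantities — θ = 4Nμ,
ρ = 4Nr, and N·m — are invariant under this transformation, and durations
expressed in "actual" generations shrink by the same factor Q.

The demographic design is an isolation-with-migration scenario: an ancestral
population of size N evolves to mutation–drift equilibrium during a burn-in,
splits into two daughter populations of size N/2, and the daughters exchange
migrants either from the moment of the split ("continuous" gene flow) or
only after a period of complete isolation ("secondary" contact).  Optionally
the crossover rate of population 2 is doubled at the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "ScaledParameters",
    "MigrationSpec",
    "EventSchedule",
    "rescale",
    "build_schedule",
    "InvalidScalingError",
    "DEFAULT_NE_ACTUAL",
    "DEFAULT_MU_SITE",
    "DEFAULT_R_SITE",
    "DEFAULT_DURATIONS_ACTUAL",
]

# Genome-wide averages for D. melanogaster used to parameterize every run.
DEFAULT_NE_ACTUAL = 1.72e6
DEFAULT_MU_SITE = 5.49e-9  # per site per generation
DEFAULT_R_SITE = 2.23e-8  # per site per generation (chromosome-arm average)

#: Default durations of the demographic phases, in actual generations.
DEFAULT_DURATIONS_ACTUAL = {
    "burn_in": 35e6,  # ~20 N_e, within the customary 10-20 N_e practice
    "isolation": 1.7e6,  # secondary contact only; calibrated to FST ~ 0.4
    "post_div": 51_000.0,  # span of the sampled phase
    "sampling_interval": 1_751.0,  # between successive genotype samples
}


class InvalidScalingError(ValueError):
    """Raised when rescaling pushes a per-site rate to >= 1 (N_model too small)."""


@dataclass(frozen=True)
class ScaledParameters:
    """Biological parameters plus their rescaled in-silico counterparts.

    Invariants: ``mu_site_model = mu_site_actual * Q`` (same for r), so that
    4·Ne_actual·mu_site_actual = 4·N_model·mu_site_model, i.e. θ/site (and
    ρ/site) are preserved by the rescaling.
    """

    Ne_actual: float
    N_model: int
    Q: float
    mu_site_actual: float
    mu_site_model: float
    r_site_actual: float
    r_site_model: float
    L: int

    @property
    def theta_site(self) -> float:
        """Population-scaled mutation rate per site, 4·N·μ (scale-invariant)."""
        return 4.0 * self.N_model * self.mu_site_model

    @property
    def rho_site(self) -> float:
        """Population-scaled recombination rate per site, 4·N·r (scale-invariant)."""
        return 4.0 * self.N_model * self.r_site_model

    def to_model_generations(self, actual_generations: float) -> int:
        """Convert a duration in actual generations to >= 1 model generations."""
        return max(1, round(actual_generations / self.Q))


@dataclass(frozen=True)
class MigrationSpec:
    """Scaled migration intensity between the two daughter populations.

    ``Nem`` is the product of the (actual) effective size of a daughter
    population and the per-generation migration rate.  The per-generation
    model probability that an offspring's parents are drawn from the other
    subpopulation is ``m_model = Nem / N_sub_model`` with
    ``N_sub_model = N_model / 2`` by default (each daughter has half the
    ancestral size); the denominator is configurable for island-model style
    parameterizations against the full size.
    """

    Nem: float
    m_model: float
    mode: str = "symmetric"  # "symmetric" | "unidirectional" (p2 -> p1 only)

    def __post_init__(self) -> None:
        if self.mode not in ("symmetric", "unidirectional"):
            raise ValueError(f"unknown migration mode {self.mode!r}")
        if not 0.0 <= self.m_model <= 1.0:
            raise ValueError(
                f"m_model = {self.m_model} outside [0, 1]; "
                "increase N_model or lower Nem"
            )
        if (self.Nem == 0) != (self.m_model == 0):
            raise ValueError("Nem = 0 iff m_model = 0 must hold")

    @classmethod
    def from_nem(
        cls,
        Nem: float,
        N_model: int,
        mode: str = "symmetric",
        denominator: str = "half",
    ) -> "MigrationSpec":
        if Nem < 0:
            raise ValueError("Nem must be non-negative")
        n_sub = N_model / 2 if denominator == "half" else float(N_model)
        return cls(Nem=Nem, m_model=Nem / n_sub if Nem > 0 else 0.0, mode=mode)


@dataclass(frozen=True)
class EventSchedule:
    """Timeline of demographic events, in model generations.

    Sampling times are anchored at the onset of (potential) migration:
    for continuous gene flow that is the split itself, so samples are taken
    from the split onward; for secondary contact the sampled phase follows
    the isolation period, which is when the estimation question arises.
    """

    burn_in_gens: int
    split_gen: int
    migration_onset_gen: int
    isolation_gens: int
    recomb_factor_p2: float
    sampling_interval_gens: int
    end_gen: int
    n_sample: int
    scenario: str = "continuous"

    def __post_init__(self) -> None:
        if not (
            self.burn_in_gens
            <= self.split_gen
            <= self.migration_onset_gen
            <= self.end_gen
        ):
            raise ValueError("schedule ordering violated")
        if self.recomb_factor_p2 <= 0:
            raise ValueError("recomb_factor_p2 must be positive")
        if self.sampling_interval_gens < 1:
            raise ValueError("sampling interval must be >= 1 model generation")

    @property
    def sampling_times(self) -> list[int]:
        """Model generations at which genotype samples are drawn."""
        return list(
            range(
                self.migration_onset_gen,
                self.end_gen + 1,
                self.sampling_interval_gens,
            )
        )


def rescale(
    Ne_actual: float,
    mu_actual: float,
    r_actual: float,
    N_model: int,
    L: int | float,
) -> ScaledParameters:
    """Rescale biological parameters onto a tractable model population.

    Raises :class:`InvalidScalingError` if a scaled per-site rate reaches 1,
    which signals that ``N_model`` is too small for the given rates.
    """
    if Ne_actual <= 0 or mu_actual <= 0 or r_actual <= 0:
        raise ValueError("rates and sizes must be positive")
    if N_model < 2:
        raise ValueError("N_model must be at least 2")
    if N_model > Ne_actual:
        raise ValueError("N_model must not exceed Ne_actual (Q >= 1 required)")
    L = int(L)
    if L < 1:
        raise ValueError("genome length must be >= 1 bp")
    Q = Ne_actual / N_model
    mu_model = mu_actual * Q
    r_model = r_actual * Q
    if mu_model >= 1.0 or r_model >= 1.0:
        raise InvalidScalingError(
            f"scaled per-site rate >= 1 (mu={mu_model:g}, r={r_model:g}); "
            "N_model too small for the requested rates"
        )
    return ScaledParameters(
        Ne_actual=float(Ne_actual),
        N_model=int(N_model),
        Q=Q,
        mu_site_actual=float(mu_actual),
        mu_site_model=mu_model,
        r_site_actual=float(r_actual),
        r_site_model=r_model,
        L=L,
    )


def build_schedule(
    scenario: str,
    migration: MigrationSpec,
    recomb_factor_p2: float,
    params: ScaledParameters,
    *,
    burn_in_actual: float | None = None,
    isolation_actual: float | None = None,
    post_div_actual: float | None = None,
    sampling_interval_actual: float | None = None,
    n_sample: int = 25,
) -> EventSchedule:
    """Build the event schedule for one scenario in model generations.

    Default durations (actual generations) follow the study design: 35e6
    burn-in, 1.7e6 isolation (secondary contact only), a 51,000-generation
    sampled phase, and samples every 1,751 generations.  Durations are
    converted by dividing by Q and rounding to the nearest integer >= 1.
    """
    if scenario not in ("continuous", "secondary"):
        raise ValueError(f"unknown scenario {scenario!r}")
    d = DEFAULT_DURATIONS_ACTUAL
    burn_in_actual = d["burn_in"] if burn_in_actual is None else burn_in_actual
    isolation_actual = d["isolation"] if isolation_actual is None else isolation_actual
    post_div_actual = d["post_div"] if post_div_actual is None else post_div_actual
    if sampling_interval_actual is None:
        sampling_interval_actual = d["sampling_interval"]
    for name, val in (
        ("burn_in_actual", burn_in_actual),
        ("isolation_actual", isolation_actual),
        ("post_div_actual", post_div_actual),
        ("sampling_interval_actual", sampling_interval_actual),
    ):
        if val < 0:
            raise ValueError(f"{name} must be non-negative")
    if n_sample < 1:
        raise ValueError("n_sample must be >= 1")

    burn_in = params.to_model_generations(burn_in_actual)
    split = burn_in
    if scenario == "secondary":
        isolation = params.to_model_generations(isolation_actual)
    else:
        isolation = 0
    onset = split + isolation
    end = onset + params.to_model_generations(post_div_actual)
    interval = params.to_model_generations(sampling_interval_actual)
    return EventSchedule(
        burn_in_gens=burn_in,
        split_gen=split,
        migration_onset_gen=onset,
        isolation_gens=isolation,
        recomb_factor_p2=float(recomb_factor_p2),
        sampling_interval_gens=interval,
        end_gen=end,
        n_sample=int(n_sample),
        scenario=scenario,
    )


def with_short_burn_in(schedule: EventSchedule, burn_in_gens: int) -> EventSchedule:
    """Return a copy of ``schedule`` with a different burn-in, shifting all
    later events accordingly (used for desk-scale presets and tests)."""
    delta = burn_in_gens - schedule.burn_in_gens
    return replace(
        schedule,
        burn_in_gens=burn_in_gens,
        split_gen=schedule.split_gen + delta,
        migration_onset_gen=schedule.migration_onset_gen + delta,
        end_gen=schedule.end_gen + delta,
    )
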