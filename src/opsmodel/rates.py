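"""Model parameters and probability-scale conversions.

The simulation advances in 30-minute steps, but almost every input rate is
quoted on an annual scale (treatment entry, relapse, overdose risk) or a
per-use scale (overdose risk per injection).  This module owns the
conversions between those scales and provides closed-form analytic
quantities -- the equilibrium treatment population and the mean-field
expectation of annual event counts -- that seed initial conditions and act
as independent oracles for the stochastic engine.

Conversion convention
---------------------
Annual probabilities are converted to per-step (or per-use) probabilities
by complement compounding,

    q = 1 - (1 - p_annual) ** (1 / n),

so that ``n`` independent per-step Bernoulli trials compound back to the
annual probability exactly: ``1 - (1 - q)**n = p_annual``.  Simple division
``p/n`` would overstate the per-step hazard and, in particular, would move
the equilibrium treatment population from ~13,000 to 16,500 under the
baseline entry/relapse rates.

Overdose risk is attached to *use events*, not to clock time: a person who
injects ``uses_per_day`` times a day faces ``uses_per_day * 365``
independent per-use Bernoulli overdose trials per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace


class ParameterError(ValueError):
    """Raised when a model parameter is outside its valid range."""


MINUTES_PER_DAY = 24 * 60
DAYS_PER_YEAR = 365


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must be a probability in [0, 1], got {value!r}")


def annual_to_step_prob(p_annual: float, steps_per_year: int) -> float:
    """Per-step probability whose compounding over a year equals ``p_annual``.

    Returns ``q`` such that ``1 - (1 - q)**steps_per_year == p_annual``.
    """
    _check_prob("p_annual", p_annual)
    if steps_per_year < 1:
        raise ParameterError(f"steps_per_year must be >= 1, got {steps_per_year!r}")
    if p_annual == 1.0:
        return 1.0
    return -math.expm1(math.log1p(-p_annual) / steps_per_year)


def per_use_od_prob(annual_od: float, uses_per_year: int) -> float:
    """Per-use overdose probability compounding to the annual rate.

    Identical algebra to :func:`annual_to_step_prob`, with the number of
    drug uses per year as the compounding denominator (baseline
    ``4 * 365 = 1460``).
    """
    return annual_to_step_prob(annual_od, uses_per_year)


def annual_od_fraction(count: float, population: float) -> float:
    """Annual overdose probability implied by an event count and population."""
    if population <= 0:
        raise ParameterError(f"population must be positive, got {population!r}")
    return count / population


def equilibrium_treatment_count(
    active: float,
    annual_in: float,
    annual_out: float,
    steps_per_year: int = 17_520,
) -> float:
    """Equilibrium size of the treatment/recovery pool.

    With ``active`` users entering treatment at per-step probability
    ``q_in`` and the treatment pool relapsing at per-step probability
    ``q_out``, the stationary pool size balances the per-step flows:
    ``T* = active * q_in / q_out``.  In the small-step limit this ratio is
    ``ln(1 - annual_in) / ln(1 - annual_out)``.  At the baseline
    (55,000 active, 15%/yr in, 50%/yr out) the result is ~12,896,
    i.e. close to 13,000.
    """
    _check_prob("annual_in", annual_in)
    _check_prob("annual_out", annual_out)
    if annual_out <= 0.0:
        raise ParameterError("annual_out must be positive: no equilibrium without outflow")
    q_in = annual_to_step_prob(annual_in, steps_per_year)
    q_out = annual_to_step_prob(annual_out, steps_per_year)
    return active * q_in / q_out


@dataclass(frozen=True)
class ModelParameters:
    """All scalar rates, counts, and site settings of the model.

    Defaults are the baseline study conditions: 55,000 regular opioid
    users, annual overdose probabilities of 6.9% (nonfatal) and 1.88%
    (fatal), 15%/year treatment entry, 50%/year relapse, 4 uses/day,
    30-minute steps, a site open 20 h/day, and ~3 new users entering the
    population per day.

    ``ops_capacity = 0`` means no overdose prevention site.
    ``ops_od_proportion`` scales the in-site per-use overdose probability
    relative to the outside total (fatal + nonfatal) per-use rate; 1.0
    means using inside is exactly as risky as outside except that every
    overdose is reversed.
    """

    n_users_initial: int = 55_000
    annual_nonfatal_od: float = 0.069
    annual_fatal_od: float = 0.0188
    annual_treatment_entry: float = 0.15
    annual_relapse: float = 0.50
    uses_per_day: int = 4
    step_minutes: int = 30
    ops_capacity: int = 0
    ops_hours_per_day: float = 20.0
    ops_od_proportion: float = 1.0
    ops_referral_prob: float = 0.0
    od_referral_prob: float = 0.0
    new_entrants_per_day: float = 3.0
    horizon_days: int = 365
    n_replicates: int = 3000
    base_visit_prob: float = 0.67
    #: explicit initial treatment-pool size; None seeds the pool at the
    #: equilibrium implied by the entry/relapse rates.  Scenario sweeps that
    #: change the entry rate mid-flight set this to the baseline equilibrium
    #: so every arm starts from the same population.
    initial_treatment_count: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "annual_nonfatal_od",
            "annual_fatal_od",
            "annual_treatment_entry",
            "annual_relapse",
            "base_visit_prob",
            "ops_referral_prob",
            "od_referral_prob",
        ):
            _check_prob(name, getattr(self, name))
        if self.n_users_initial < 0:
            raise ParameterError("n_users_initial must be nonnegative")
        if self.ops_capacity < 0:
            raise ParameterError("ops_capacity must be nonnegative")
        if self.new_entrants_per_day < 0:
            raise ParameterError("new_entrants_per_day must be nonnegative")
        if self.horizon_days < 1:
            raise ParameterError("horizon_days must be >= 1")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")
        if self.initial_treatment_count is not None and self.initial_treatment_count < 0:
            raise ParameterError("initial_treatment_count must be nonnegative")
        if self.uses_per_day < 0:
            raise ParameterError("uses_per_day must be nonnegative")
        if self.ops_od_proportion < 0:
            raise ParameterError("ops_od_proportion must be nonnegative")
        if self.step_minutes < 1 or MINUTES_PER_DAY % self.step_minutes != 0:
            raise ParameterError(
                f"step_minutes must divide {MINUTES_PER_DAY} evenly, got {self.step_minutes!r}"
            )
        if self.uses_per_day > self.steps_per_day:
            raise ParameterError(
                f"uses_per_day ({self.uses_per_day}) cannot exceed "
                f"steps_per_day ({self.steps_per_day})"
            )
        if not (0.0 <= self.ops_hours_per_day <= 24.0):
            raise ParameterError("ops_hours_per_day must be in [0, 24]")
        if self.ops_od_prob > 1.0:
            raise ParameterError(
                "ops_od_proportion too large: in-site overdose probability exceeds 1"
            )

    # ---- derived step bookkeeping -------------------------------------

    @property
    def steps_per_day(self) -> int:
        return MINUTES_PER_DAY // self.step_minutes

    @property
    def steps_per_year(self) -> int:
        return self.steps_per_day * DAYS_PER_YEAR

    @property
    def total_steps(self) -> int:
        return self.steps_per_day * self.horizon_days

    @property
    def open_steps_per_day(self) -> int:
        return round(self.ops_hours_per_day * 60 / self.step_minutes)

    @property
    def uses_per_year(self) -> int:
        return self.uses_per_day * DAYS_PER_YEAR

    # ---- derived probabilities ----------------------------------------

    @property
    def p_use_per_step(self) -> float:
        """Probability a not-currently-using person initiates a use this step."""
        return self.uses_per_day / self.steps_per_day

    @property
    def p_fatal_use(self) -> float:
        return per_use_od_prob(self.annual_fatal_od, self.uses_per_year) if self.uses_per_day else 0.0

    @property
    def p_nonfatal_use(self) -> float:
        return per_use_od_prob(self.annual_nonfatal_od, self.uses_per_year) if self.uses_per_day else 0.0

    @property
    def ops_od_prob(self) -> float:
        """Per-use overdose probability inside the site (always nonfatal)."""
        return self.ops_od_proportion * (self.p_fatal_use + self.p_nonfatal_use)

    @property
    def q_treatment_per_step(self) -> float:
        return annual_to_step_prob(self.annual_treatment_entry, self.steps_per_year)

    @property
    def q_relapse_per_step(self) -> float:
        return annual_to_step_prob(self.annual_relapse, self.steps_per_year)

    @property
    def entrants_per_step(self) -> float:
        return self.new_entrants_per_day / self.steps_per_day

    @property
    def equilibrium_treatment(self) -> float:
        """Equilibrium treatment pool implied by the entry/relapse rates."""
        if self.annual_relapse == 0.0:
            raise ParameterError("no treatment equilibrium when annual_relapse is 0")
        return equilibrium_treatment_count(
            self.n_users_initial,
            self.annual_treatment_entry,
            self.annual_relapse,
            self.steps_per_year,
        )

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def expected_annual_events_no_ops(params: ModelParameters) -> tuple[float, float]:
    """Mean-field expectation of annual (fatal, nonfatal) overdose counts.

    Iterates the expected-value recursion of the per-step dynamics over the
    horizon with no randomness.  Because every stage of the step update is
    linear in the compartment counts (and there is no capacity constraint
    without a site), this recursion equals the exact expectation of the
    stochastic engine and serves as its deterministic oracle.
    """
    if params.ops_capacity != 0:
        raise ParameterError("mean-field oracle requires ops_capacity == 0")
    p_use = params.p_use_per_step
    r_f = params.p_fatal_use
    r_nf = params.p_nonfatal_use
    q_t = params.q_treatment_per_step
    q_r = params.q_relapse_per_step
    ent = params.entrants_per_step

    s1 = float(params.n_users_initial)
    s5 = 0.0
    if params.initial_treatment_count is not None:
        tr = float(params.initial_treatment_count)
    elif params.annual_relapse > 0.0:
        tr = float(round(params.equilibrium_treatment))
    else:
        tr = 0.0
    fatal = nonfatal = 0.0
    for _ in range(params.total_steps):
        users = s1 * p_use
        s1 -= users
        f = users * r_f
        nf = users * r_nf
        s1 += users - f - nf  # survivors of this step's uses
        fatal += f
        nonfatal += nf
        s1 += s5 * (1.0 - params.od_referral_prob)
        tr += s5 * params.od_referral_prob
        s5 = nf
        tin = s1 * q_t
        rel = tr * q_r
        s1 += rel - tin
        tr += tin - rel
        s1 += ent
    return fatal, nonfatal
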