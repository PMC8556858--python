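"""Stochastic simulation engine for the six-state opioid-use model.

States
------
1. ``NOT_USING``   -- active users between uses (the default state),
2. ``USING_OUTSIDE`` -- using this step outside the site,
3. ``USING_OPS``   -- using this step inside the site (capacity limited),
4. ``TREATMENT``   -- in treatment/recovery, not using,
5. ``NONFATAL_OD`` -- overdosed nonfatally this step, recovering,
6. fatal overdose  -- absorbing; tracked as a cumulative counter.

Each 30-minute step applies, in order and per distance ring:

1. *Initiation*: each ``NOT_USING`` person starts a use with probability
   ``uses_per_day / steps_per_day``; if the site is open, an initiator
   attempts to go there with the ring's visit probability.
2. *Admission*: attempted entrants across all rings are admitted up to
   the site capacity; the excess -- a uniformly random subset, i.e. a
   multivariate hypergeometric draw over rings -- use outside instead.
3. *Resolution*: an outside use ends in a fatal overdose, a nonfatal
   overdose, or a return to ``NOT_USING``; an in-site use ends in a
   nonfatal overdose (with probability ``ops_od_proportion`` times the
   combined outside per-use rate -- never fatal, every overdose inside is
   reversed) or a return (optionally a treatment referral).
4. Last step's ``NONFATAL_OD`` occupants return to ``NOT_USING``
   (optionally referred to treatment).
5. *Treatment flows*: ``NOT_USING`` -> ``TREATMENT`` and back at the
   per-step converted entry/relapse hazards.
6. *Entrants*: Poisson arrivals into ``NOT_USING``, spread over rings by
   population proportion.

A use occupies exactly one step, so the using states are transient
within a step; the engine therefore stores only ``NOT_USING``,
``TREATMENT`` and ``NONFATAL_OD`` between steps and reports the using
states of the step just executed for inspection.

The engine advances integer counts per (state x ring) with exact
binomial/multinomial draws, vectorized across replicates -- this is
equal in distribution to simulating every person independently, and the
per-agent microsimulation (:func:`simulate_year_microsim`) exists to
verify that equivalence.

Alongside realized event counts the engine accumulates their
conditional expectations given the realized use/admission trajectory
(``*_expected`` fields).  These have the same means as the realized
counts but far smaller replicate variance, and they carry the in-run
counterfactual: each admitted use would, outside, have been fatal with
probability ``p_fatal_use`` and nonfatal with ``p_nonfatal_use``, which
yields the expected fatalities averted and the expected net change in
nonfatal overdoses without needing a paired baseline run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geography import RingProfile
from .rates import ModelParameters


class ConsistencyError(AssertionError):
    """Internal invariant violated (conservation, capacity, negativity)."""


def largest_remainder(total: int, proportions: np.ndarray) -> np.ndarray:
    """Apportion ``total`` integer units across cells by proportion.

    Floors the exact shares and hands the leftover units to the cells
    with the largest fractional remainders (ties broken by cell index),
    so the result always sums to ``total`` exactly.
    """
    p = np.asarray(proportions, dtype=float)
    exact = total * p / p.sum()
    base = np.floor(exact).astype(np.int64)
    short = int(total - base.sum())
    if short:
        order = np.lexsort((np.arange(len(p)), -(exact - base)))
        base[order[:short]] += 1
    return base


@dataclass
class StateCounts:
    """Per-ring occupancy of one replicate plus cumulative counters.

    ``using_outside`` / ``using_ops`` describe the uses in progress
    during the most recently executed step (both are all-zero at
    initialization); the other states are end-of-step occupancy.
    """

    not_using: np.ndarray
    using_outside: np.ndarray
    using_ops: np.ndarray
    treatment: np.ndarray
    nonfatal_od: np.ndarray
    fatal_events: int = 0
    nonfatal_events: int = 0
    ops_od_events: int = 0
    ops_visits: int = 0
    entrants: int = 0

    @property
    def alive_total(self) -> int:
        return int(self.not_using.sum() + self.treatment.sum() + self.nonfatal_od.sum())


@dataclass
class SimulationResult:
    """End-of-horizon tallies of one replicate."""

    fatal: int
    nonfatal: int
    ops_od: int
    averted_tagged: int
    ops_visits: int
    entrants: int
    fatal_expected: float
    nonfatal_expected: float
    averted_expected: float
    net_nonfatal_expected: float
    revived_by_ring: np.ndarray
    mean_ops_occupancy: float
    seed: int | None = None

    SCALAR_FIELDS = (
        "fatal",
        "nonfatal",
        "ops_od",
        "averted_tagged",
        "ops_visits",
        "entrants",
        "fatal_expected",
        "nonfatal_expected",
        "averted_expected",
        "net_nonfatal_expected",
        "mean_ops_occupancy",
    )


@dataclass
class ReplicateSummary:
    """Replicate table with Monte-Carlo means and standard errors."""

    params: ModelParameters
    n_reps: int
    seed: int | None
    table: pd.DataFrame
    revived: np.ndarray  # (n_reps, n_rings)

    def mean(self, column: str) -> float:
        return float(self.table[column].mean())

    def se(self, column: str) -> float:
        """Monte-Carlo standard error of the replicate mean."""
        if self.n_reps < 2:
            return float("nan")
        return float(self.table[column].std(ddof=1) / np.sqrt(self.n_reps))

    @property
    def means(self) -> dict[str, float]:
        return {c: self.mean(c) for c in self.table.columns}

    @property
    def standard_errors(self) -> dict[str, float]:
        return {c: self.se(c) for c in self.table.columns}

    def revived_mean_by_ring(self) -> np.ndarray:
        return self.revived.mean(axis=0)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def initialize(params: ModelParameters, profile: RingProfile) -> StateCounts:
    """Baseline state: all users not using, treatment pool at equilibrium.

    ``n_users_initial`` people are spread over rings by population
    proportion with largest-remainder rounding; the treatment pool is
    seeded at the rounded equilibrium implied by the entry/relapse rates
    and spread the same way.
    """
    props = profile.population_proportion
    s1 = largest_remainder(params.n_users_initial, props)
    if params.initial_treatment_count is not None:
        t_total = params.initial_treatment_count
    elif params.annual_relapse > 0:
        t_total = round(params.equilibrium_treatment)
    else:
        t_total = 0
    tr = largest_remainder(int(t_total), props)
    k = profile.n_rings
    zeros = np.zeros(k, dtype=np.int64)
    return StateCounts(
        not_using=s1,
        using_outside=zeros.copy(),
        using_ops=zeros.copy(),
        treatment=tr,
        nonfatal_od=zeros.copy(),
    )


def _admit_capacity(rng: np.random.Generator, attempts: np.ndarray, capacity) -> np.ndarray:
    """Admit up to ``capacity`` of the attempted entrants, per replicate.

    Exact multivariate-hypergeometric allocation over rings via
    sequential conditional hypergeometric draws: when demand exceeds
    capacity, the admitted subset is uniform over all attempters.
    ``capacity`` may be a scalar or a per-replicate array.
    """
    total = attempts.sum(axis=1)
    if np.all(total <= capacity):
        return attempts.copy()
    n_reps, k = attempts.shape
    admitted = np.zeros_like(attempts)
    remaining = np.minimum(total, capacity)
    tail = total
    for j in range(k):
        if not remaining.any():
            break  # capacity exhausted in every replicate; outer rings get none
        ngood = attempts[:, j]
        tail = tail - ngood
        pool = ngood + tail
        # dummy-safe arguments where the pool is empty or the draw is forced
        nsample = np.minimum(remaining, pool)
        safe_pool = pool > 0
        a = np.where(
            safe_pool,
            rng.hypergeometric(
                np.maximum(ngood, 0),
                np.where(safe_pool, tail, 1),
                np.where(safe_pool, nsample, 0),
            ),
            0,
        )
        admitted[:, j] = a
        remaining = remaining - a
    return admitted


class _Engine:
    """Vectorized batch of independent replicates of the count model.

    The optional ``cap``, ``ops_od_prob`` and ``q_treatment`` arrays let a
    single batch carry several sweep arms at once (each row keeps its own
    value of the swept parameter); every other parameter, the profile and
    the initial conditions are shared across the batch.
    """

    def __init__(
        self,
        params: ModelParameters,
        profile: RingProfile,
        n_reps: int,
        rng: np.random.Generator,
        check_every: int = 48,
        cap: np.ndarray | None = None,
        ops_od_prob: np.ndarray | None = None,
        q_treatment: np.ndarray | None = None,
    ):
        self.params = params
        self.profile = profile
        self.n_reps = n_reps
        self.rng = rng
        self.check_every = check_every
        k = profile.n_rings

        init = initialize(params, profile)
        self.s1 = np.tile(init.not_using, (n_reps, 1))
        self.tr = np.tile(init.treatment, (n_reps, 1))
        self.s5 = np.zeros((n_reps, k), dtype=np.int64)
        self.last_outside = np.zeros((n_reps, k), dtype=np.int64)
        self.last_ops = np.zeros((n_reps, k), dtype=np.int64)

        self.fatal = np.zeros(n_reps, dtype=np.int64)
        self.nonfatal = np.zeros(n_reps, dtype=np.int64)
        self.ops_od = np.zeros(n_reps, dtype=np.int64)
        self.averted_tagged = np.zeros(n_reps, dtype=np.int64)
        self.ops_visits = np.zeros(n_reps, dtype=np.int64)
        self.entrants = np.zeros(n_reps, dtype=np.int64)
        self.revived = np.zeros((n_reps, k), dtype=np.int64)
        self.fatal_expected = np.zeros(n_reps)
        self.nonfatal_expected = np.zeros(n_reps)
        self.averted_expected = np.zeros(n_reps)
        self.net_nonfatal_expected = np.zeros(n_reps)
        self.occupancy_sum = np.zeros(n_reps, dtype=np.int64)
        self.open_steps_seen = 0

        self.initial_alive = self.s1.sum(axis=1) + self.tr.sum(axis=1)

        # precomputed constants; the three swept quantities may be (R,) arrays
        self.p_use = params.p_use_per_step
        self.r_f = params.p_fatal_use
        self.r_nf = params.p_nonfatal_use
        self.p_nf_given_not_fatal = self.r_nf / (1.0 - self.r_f) if self.r_f < 1 else 0.0
        self.p_ops_od = params.ops_od_prob if ops_od_prob is None else np.asarray(ops_od_prob)
        self.q_t = params.q_treatment_per_step if q_treatment is None else np.asarray(q_treatment)
        self.q_r = params.q_relapse_per_step
        self.visit_p = profile.visit_probabilities
        self.lam_ring = params.entrants_per_step * profile.population_proportion
        self.cap = params.ops_capacity if cap is None else np.asarray(cap)
        self.open_per_day = params.open_steps_per_day
        self.spd = params.steps_per_day
        denom = self.r_f + self.r_nf
        self.p_cf_fatal = self.r_f / denom if denom > 0 else 0.0
        # column views for broadcasting against (R, K) count arrays
        self._p_od_col = self.p_ops_od if np.isscalar(self.p_ops_od) else self.p_ops_od[:, None]
        self._q_t_col = self.q_t if np.isscalar(self.q_t) else self.q_t[:, None]

    def ops_open(self, step_index: int) -> bool:
        """Site operates the first ``open_steps_per_day`` steps of each day."""
        return bool(np.max(self.cap) > 0) and (step_index % self.spd) < self.open_per_day

    def step(self, step_index: int) -> None:
        rng = self.rng
        params = self.params
        open_now = self.ops_open(step_index)

        # 1. initiation
        users = rng.binomial(self.s1, self.p_use) if self.p_use > 0 else np.zeros_like(self.s1)
        self.s1 -= users

        # 2. attendance attempt and capacity-limited admission
        if open_now:
            attempts = rng.binomial(users, self.visit_p[None, :])
            admitted = _admit_capacity(rng, attempts, self.cap)
            adm_tot = admitted.sum(axis=1)
            if np.any(adm_tot > self.cap):
                raise ConsistencyError("site occupancy exceeded capacity")
            self.ops_visits += adm_tot
            self.occupancy_sum += adm_tot
            self.open_steps_seen += 1
        else:
            admitted = np.zeros_like(users)
            adm_tot = np.zeros(self.n_reps, dtype=np.int64)
        outside = users - admitted

        # 3. use resolution -- outside: fatal / nonfatal / return
        f = rng.binomial(outside, self.r_f)
        nf = rng.binomial(outside - f, self.p_nf_given_not_fatal)
        returned = outside - f - nf
        #    use resolution -- inside: nonfatal (reversed) / return / referral
        if open_now:
            ops_od = rng.binomial(admitted, self._p_od_col)
            ops_returned = admitted - ops_od
            if params.ops_referral_prob > 0.0:
                referred = rng.binomial(ops_returned, params.ops_referral_prob)
                ops_returned = ops_returned - referred
                self.tr += referred
            oo_tot = ops_od.sum(axis=1)
            self.averted_tagged += rng.binomial(oo_tot, self.p_cf_fatal)
            self.revived += ops_od
            self.ops_od += oo_tot
        else:
            ops_od = np.zeros_like(users)
            ops_returned = ops_od
            oo_tot = np.zeros(self.n_reps, dtype=np.int64)

        # 4. last step's nonfatal overdoses recover
        od_pool = self.s5
        if params.od_referral_prob > 0.0:
            od_referred = rng.binomial(od_pool, params.od_referral_prob)
            self.tr += od_referred
            od_pool = od_pool - od_referred
        self.s1 += returned + ops_returned + od_pool
        self.s5 = nf + ops_od

        f_tot = f.sum(axis=1)
        nf_tot = nf.sum(axis=1)
        out_tot = outside.sum(axis=1)
        self.fatal += f_tot
        self.nonfatal += nf_tot + oo_tot
        self.fatal_expected += out_tot * self.r_f
        self.nonfatal_expected += out_tot * self.r_nf + adm_tot * self.p_ops_od
        self.averted_expected += adm_tot * self.r_f
        self.net_nonfatal_expected += adm_tot * (self.p_ops_od - self.r_nf)

        # 5. treatment entry and relapse
        tin = rng.binomial(self.s1, self._q_t_col) if np.max(self.q_t) > 0 else 0
        rel = rng.binomial(self.tr, self.q_r) if self.q_r > 0 else 0
        self.s1 += rel - tin
        self.tr += tin - rel

        # 6. new entrants
        if params.new_entrants_per_day > 0:
            ent = rng.poisson(lam=self.lam_ring, size=self.s1.shape)
            self.s1 += ent
            self.entrants += ent.sum(axis=1)

        self.last_outside = outside
        self.last_ops = admitted

        if self.check_every and (step_index % self.check_every == 0):
            self.check_conservation()

    def check_conservation(self) -> None:
        alive = self.s1.sum(axis=1) + self.tr.sum(axis=1) + self.s5.sum(axis=1)
        if np.any(self.s1 < 0) or np.any(self.tr < 0) or np.any(self.s5 < 0):
            raise ConsistencyError("negative compartment count")
        if np.any(alive + self.fatal != self.initial_alive + self.entrants):
            raise ConsistencyError("conservation violated: alive + dead != initial + entrants")

    def run(self) -> None:
        for t in range(self.params.total_steps):
            self.step(t)
        self.check_conservation()

    def results(self, seed: int | None = None) -> list[SimulationResult]:
        occ = np.zeros(self.n_reps) if self.open_steps_seen == 0 else (
            self.occupancy_sum / self.open_steps_seen
        )
        return [
            SimulationResult(
                fatal=int(self.fatal[i]),
                nonfatal=int(self.nonfatal[i]),
                ops_od=int(self.ops_od[i]),
                averted_tagged=int(self.averted_tagged[i]),
                ops_visits=int(self.ops_visits[i]),
                entrants=int(self.entrants[i]),
                fatal_expected=float(self.fatal_expected[i]),
                nonfatal_expected=float(self.nonfatal_expected[i]),
                averted_expected=float(self.averted_expected[i]),
                net_nonfatal_expected=float(self.net_nonfatal_expected[i]),
                revived_by_ring=self.revived[i].copy(),
                mean_ops_occupancy=float(occ[i]),
                seed=seed,
            )
            for i in range(self.n_reps)
        ]

    def summary(self, seed: int | None = None) -> ReplicateSummary:
        occ = np.zeros(self.n_reps) if self.open_steps_seen == 0 else (
            self.occupancy_sum / self.open_steps_seen
        )
        table = pd.DataFrame(
            {
                "fatal": self.fatal,
                "nonfatal": self.nonfatal,
                "ops_od": self.ops_od,
                "averted_tagged": self.averted_tagged,
                "ops_visits": self.ops_visits,
                "entrants": self.entrants,
                "fatal_expected": self.fatal_expected,
                "nonfatal_expected": self.nonfatal_expected,
                "averted_expected": self.averted_expected,
                "net_nonfatal_expected": self.net_nonfatal_expected,
                "mean_ops_occupancy": occ,
            }
        )
        return ReplicateSummary(
            params=self.params,
            n_reps=self.n_reps,
            seed=seed,
            table=table,
            revived=self.revived.copy(),
        )


def step(
    state: StateCounts,
    params: ModelParameters,
    profile: RingProfile,
    step_index: int,
    rng: np.random.Generator,
) -> StateCounts:
    """Advance a single replicate one half-hour step (public wrapper)."""
    eng = _Engine(params, profile, 1, rng, check_every=0)
    eng.s1 = state.not_using[None, :].astype(np.int64).copy()
    eng.tr = state.treatment[None, :].astype(np.int64).copy()
    eng.s5 = state.nonfatal_od[None, :].astype(np.int64).copy()
    eng.fatal[0] = state.fatal_events
    eng.nonfatal[0] = state.nonfatal_events
    eng.ops_od[0] = state.ops_od_events
    eng.ops_visits[0] = state.ops_visits
    eng.entrants[0] = state.entrants
    eng.initial_alive = eng.s1.sum(axis=1) + eng.tr.sum(axis=1) + eng.s5.sum(axis=1) \
        + eng.fatal - eng.entrants
    eng.step(step_index)
    eng.check_conservation()
    return StateCounts(
        not_using=eng.s1[0].copy(),
        using_outside=eng.last_outside[0].copy(),
        using_ops=eng.last_ops[0].copy(),
        treatment=eng.tr[0].copy(),
        nonfatal_od=eng.s5[0].copy(),
        fatal_events=int(eng.fatal[0]),
        nonfatal_events=int(eng.nonfatal[0]),
        ops_od_events=int(eng.ops_od[0]),
        ops_visits=int(eng.ops_visits[0]),
        entrants=int(eng.entrants[0]),
    )


def simulate_year(
    params: ModelParameters, profile: RingProfile, seed: int | np.random.SeedSequence
) -> SimulationResult:
    """One replicate over the full horizon; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    eng = _Engine(params, profile, 1, rng)
    eng.run()
    return eng.results(seed=seed if isinstance(seed, int) else None)[0]


def run_replicates(
    params: ModelParameters,
    profile: RingProfile,
    n_reps: int,
    seed: int | np.random.SeedSequence,
) -> ReplicateSummary:
    """Run ``n_reps`` independent replicates and summarize them.

    All replicates are advanced in one vectorized batch from a single
    generator seeded by the master seed; a replicate batch is exactly
    reproducible from ``(params, profile, n_reps, seed)``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    eng = _Engine(params, profile, n_reps, rng)
    eng.run()
    return eng.summary(seed=seed if isinstance(seed, int) else None)


#: parameters allowed to differ between arms sharing one stacked batch
_STACKABLE = ("ops_capacity", "ops_od_proportion", "annual_treatment_entry")


def run_replicates_stacked(
    arms: Sequence[ModelParameters],
    profile: RingProfile,
    n_reps: int,
    seed: int | np.random.SeedSequence,
) -> list[ReplicateSummary]:
    """Run several sweep arms as one vectorized batch.

    Arms may differ only in site capacity, in-site overdose proportion
    and annual treatment-entry rate; everything else -- including the
    initial conditions -- must be shared, so the batch advances a single
    (len(arms) * n_reps)-row state.  Rows are independent replicates;
    the per-step cost is nearly flat in batch width, which makes this
    far cheaper than running each arm separately.

    Returns one :class:`ReplicateSummary` per arm, in order.
    """
    if not arms:
        raise ValueError("need at least one arm")
    base = arms[0]
    entry_varies = False
    for arm in arms:
        diff = {k for k, v in base.to_dict().items() if arm.to_dict()[k] != v}
        extra = diff - set(_STACKABLE)
        if extra:
            raise ValueError(f"arms differ in non-stackable parameters: {sorted(extra)}")
        if arm.annual_treatment_entry != base.annual_treatment_entry:
            entry_varies = True
    if entry_varies and base.initial_treatment_count is None:
        raise ValueError(
            "arms with different treatment-entry rates need an explicit shared "
            "initial_treatment_count so they start from the same population"
        )
    n_arms = len(arms)
    cap = np.repeat([a.ops_capacity for a in arms], n_reps)
    pod = np.repeat([a.ops_od_prob for a in arms], n_reps)
    q_t = np.repeat([a.q_treatment_per_step for a in arms], n_reps)
    rng = np.random.default_rng(seed)
    eng = _Engine(base, profile, n_arms * n_reps, rng, cap=cap, ops_od_prob=pod, q_treatment=q_t)
    eng.run()
    big = eng.summary(seed=seed if isinstance(seed, int) else None)
    out = []
    for i, arm in enumerate(arms):
        rows = slice(i * n_reps, (i + 1) * n_reps)
        out.append(
            ReplicateSummary(
                params=arm,
                n_reps=n_reps,
                seed=big.seed,
                table=big.table.iloc[rows].reset_index(drop=True),
                revived=big.revived[rows],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Per-agent microsimulation oracle
# ---------------------------------------------------------------------------

_INACTIVE, _NOT_USING, _TREATMENT, _OD, _DEAD = 0, 1, 4, 5, 6


class _MicroEngine:
    """Per-agent reference implementation with identical transition rules.

    Every agent carries an explicit state and ring; all randomness is
    per-agent Bernoulli (one uniform per decision), which is the
    distributional ground truth the aggregated multinomial engine must
    match.  Intended for small populations (hundreds to a few thousand
    agents); the batch dimension vectorizes replicates.
    """

    def __init__(
        self,
        params: ModelParameters,
        profile: RingProfile,
        n_reps: int,
        n_agents: int,
        rng: np.random.Generator,
    ):
        self.params = params
        self.profile = profile
        self.n_reps = n_reps
        self.rng = rng
        k = profile.n_rings
        props = profile.population_proportion

        t_total = int(round(equilibrium_for(params, n_agents))) if params.annual_relapse > 0 else 0
        pool = int(
            params.new_entrants_per_day * params.horizon_days
            + 8 * np.sqrt(params.new_entrants_per_day * params.horizon_days + 1)
            + 16
        )
        total = n_agents + t_total + pool
        self.n_agents = n_agents
        self.pool_start = n_agents + t_total

        state = np.zeros((n_reps, total), dtype=np.int8)
        ring = np.zeros((n_reps, total), dtype=np.int16)
        active_rings = np.repeat(np.arange(k), largest_remainder(n_agents, props))
        treat_rings = np.repeat(np.arange(k), largest_remainder(t_total, props))
        state[:, :n_agents] = _NOT_USING
        ring[:, :n_agents] = active_rings[None, :]
        state[:, n_agents:self.pool_start] = _TREATMENT
        ring[:, n_agents:self.pool_start] = treat_rings[None, :]
        self.state = state
        self.ring = ring
        self.next_pool = np.full(n_reps, self.pool_start, dtype=np.int64)

        self.fatal = np.zeros(n_reps, dtype=np.int64)
        self.nonfatal = np.zeros(n_reps, dtype=np.int64)
        self.ops_od = np.zeros(n_reps, dtype=np.int64)
        self.averted_tagged = np.zeros(n_reps, dtype=np.int64)
        self.ops_visits = np.zeros(n_reps, dtype=np.int64)
        self.entrants = np.zeros(n_reps, dtype=np.int64)
        self.revived = np.zeros((n_reps, k), dtype=np.int64)
        self.fatal_expected = np.zeros(n_reps)
        self.nonfatal_expected = np.zeros(n_reps)
        self.averted_expected = np.zeros(n_reps)
        self.net_nonfatal_expected = np.zeros(n_reps)
        self.occupancy_sum = np.zeros(n_reps, dtype=np.int64)
        self.open_steps_seen = 0

        self.p_use = params.p_use_per_step
        self.r_f = params.p_fatal_use
        self.r_nf = params.p_nonfatal_use
        self.p_ops_od = params.ops_od_prob
        self.q_t = params.q_treatment_per_step
        self.q_r = params.q_relapse_per_step
        self.visit_p = profile.visit_probabilities
        self.cap = params.ops_capacity
        self.open_per_day = params.open_steps_per_day
        self.spd = params.steps_per_day
        denom = self.r_f + self.r_nf
        self.p_cf_fatal = self.r_f / denom if denom > 0 else 0.0

    def step(self, step_index: int) -> None:
        rng = self.rng
        params = self.params
        open_now = self.cap > 0 and (step_index % self.spd) < self.open_per_day
        st = self.state
        shape = st.shape

        s1 = st == _NOT_USING
        uses = s1 & (rng.random(shape) < self.p_use)

        if open_now:
            attempts = uses & (rng.random(shape) < self.visit_p[self.ring])
            # admit a uniformly random subset of attempters up to capacity
            scores = rng.random(shape)
            scores[~attempts] = np.inf
            order = np.argsort(scores, axis=1)
            rank = np.empty(shape, dtype=np.int64)
            rows = np.arange(shape[0])[:, None]
            rank[rows, order] = np.arange(shape[1])[None, :]
            admitted = attempts & (rank < self.cap)
            adm_tot = admitted.sum(axis=1)
            self.ops_visits += adm_tot
            self.occupancy_sum += adm_tot
            self.open_steps_seen += 1
        else:
            admitted = np.zeros(shape, dtype=bool)
            adm_tot = np.zeros(self.n_reps, dtype=np.int64)
        outside = uses & ~admitted

        # outside resolution: one uniform decides fatal / nonfatal / return
        u = rng.random(shape)
        died = outside & (u < self.r_f)
        od_out = outside & ~died & (u < self.r_f + self.r_nf)

        # inside resolution: always reversed
        od_in = admitted & (rng.random(shape) < self.p_ops_od)
        tagged = od_in & (rng.random(shape) < self.p_cf_fatal)
        ops_ret = admitted & ~od_in
        if params.ops_referral_prob > 0.0:
            ref = ops_ret & (rng.random(shape) < params.ops_referral_prob)
            st[ref] = _TREATMENT
            ops_ret &= ~ref

        # last step's overdoses recover
        prior_od = st == _OD
        if params.od_referral_prob > 0.0:
            ref5 = prior_od & (rng.random(shape) < params.od_referral_prob)
            st[ref5] = _TREATMENT
            prior_od &= ~ref5
        st[prior_od] = _NOT_USING

        st[died] = _DEAD
        st[od_out | od_in] = _OD

        self.fatal += died.sum(axis=1)
        self.nonfatal += od_out.sum(axis=1) + od_in.sum(axis=1)
        self.ops_od += od_in.sum(axis=1)
        self.averted_tagged += tagged.sum(axis=1)
        for rep in range(self.n_reps):
            if od_in[rep].any():
                self.revived[rep] += np.bincount(
                    self.ring[rep][od_in[rep]], minlength=self.profile.n_rings
                )
        out_tot = outside.sum(axis=1)
        self.fatal_expected += out_tot * self.r_f
        self.nonfatal_expected += out_tot * self.r_nf + adm_tot * self.p_ops_od
        self.averted_expected += adm_tot * self.r_f
        self.net_nonfatal_expected += adm_tot * (self.p_ops_od - self.r_nf)

        # treatment flows (uses resolved above are back in NOT_USING already)
        s1 = self.state == _NOT_USING
        tin = s1 & (rng.random(shape) < self.q_t)
        trm = self.state == _TREATMENT
        rel = trm & (rng.random(shape) < self.q_r)
        self.state[tin] = _TREATMENT
        self.state[rel] = _NOT_USING

        # entrants drawn from the inactive pool
        if params.new_entrants_per_day > 0:
            n_new = rng.poisson(params.entrants_per_step, size=self.n_reps)
            if np.any(self.next_pool + n_new > shape[1]):
                raise ConsistencyError("entrant pool exhausted; enlarge the microsim pool")
            for rep in range(self.n_reps):
                if n_new[rep]:
                    sl = slice(self.next_pool[rep], self.next_pool[rep] + n_new[rep])
                    self.state[rep, sl] = _NOT_USING
                    self.ring[rep, sl] = rng.choice(
                        self.profile.n_rings,
                        size=n_new[rep],
                        p=self.profile.population_proportion,
                    )
                    self.next_pool[rep] += n_new[rep]
            self.entrants += n_new

    def run(self) -> None:
        for t in range(self.params.total_steps):
            self.step(t)

    def results(self, seed: int | None = None) -> list[SimulationResult]:
        occ = np.zeros(self.n_reps) if self.open_steps_seen == 0 else (
            self.occupancy_sum / self.open_steps_seen
        )
        return [
            SimulationResult(
                fatal=int(self.fatal[i]),
                nonfatal=int(self.nonfatal[i]),
                ops_od=int(self.ops_od[i]),
                averted_tagged=int(self.averted_tagged[i]),
                ops_visits=int(self.ops_visits[i]),
                entrants=int(self.entrants[i]),
                fatal_expected=float(self.fatal_expected[i]),
                nonfatal_expected=float(self.nonfatal_expected[i]),
                averted_expected=float(self.averted_expected[i]),
                net_nonfatal_expected=float(self.net_nonfatal_expected[i]),
                revived_by_ring=self.revived[i].copy(),
                mean_ops_occupancy=float(occ[i]),
                seed=seed,
            )
            for i in range(self.n_reps)
        ]


def equilibrium_for(params: ModelParameters, n_active: int) -> float:
    """Treatment equilibrium for a scaled-down active population."""
    from .rates import equilibrium_treatment_count

    return equilibrium_treatment_count(
        n_active, params.annual_treatment_entry, params.annual_relapse, params.steps_per_year
    )


def simulate_year_microsim(
    params: ModelParameters,
    profile: RingProfile,
    seed: int | np.random.SeedSequence,
    n_agents: int,
) -> SimulationResult:
    """Per-agent oracle run of one replicate with ``n_agents`` active users."""
    if n_agents > 20_000:
        raise ValueError("microsim oracle is intended for small populations")
    rng = np.random.default_rng(seed)
    eng = _MicroEngine(params, profile, 1, n_agents, rng)
    eng.run()
    return eng.results(seed=seed if isinstance(seed, int) else None)[0]


def run_replicates_microsim(
    params: ModelParameters,
    profile: RingProfile,
    n_reps: int,
    seed: int | np.random.SeedSequence,
    n_agents: int,
) -> ReplicateSummary:
    """Batch of per-agent replicates, summarized like :func:`run_replicates`."""
    rng = np.random.default_rng(seed)
    eng = _MicroEngine(params, profile, n_reps, n_agents, rng)
    eng.run()
    table = pd.DataFrame(
        {
            "fatal": eng.fatal,
            "nonfatal": eng.nonfatal,
            "ops_od": eng.ops_od,
            "averted_tagged": eng.averted_tagged,
            "ops_visits": eng.ops_visits,
            "entrants": eng.entrants,
            "fatal_expected": eng.fatal_expected,
            "nonfatal_expected": eng.nonfatal_expected,
            "averted_expected": eng.averted_expected,
            "net_nonfatal_expected": eng.net_nonfatal_expected,
            "mean_ops_occupancy": (
                np.zeros(n_reps) if eng.open_steps_seen == 0
                else eng.occupancy_sum / eng.open_steps_seen
            ),
        }
    )
    return ReplicateSummary(
        params=params,
        n_reps=n_reps,
        seed=seed if isinstance(seed, int) else None,
        table=table,
        revived=eng.revived.copy(),
    )
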