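"""Scenario drivers: calibration, capacity sweep, safety sweep, treatment sweep.

Every experiment runs batches of replicate one-year simulations and
reports differences of replicate means against the appropriate baseline
(no site, or the baseline treatment-entry rate), with Monte-Carlo
standard errors.  Arms of a sweep share the same ring profile and the
same initial conditions; only the swept parameter differs.  A sweep
runs all of its arms as one stacked batch seeded by the master seed;
rows of the batch are statistically independent replicates.

Break-even location in the safety sweep additionally uses the engine's
in-run counterfactual diagnostic (``net_nonfatal_expected``): for every
admitted use it accrues the expected in-site overdoses minus the
nonfatal overdoses the same uses would have produced outside.  Its mean
equals the net change in nonfatal overdoses up to the (tiny)
population-feedback term, but its replicate variance is orders of
magnitude smaller than that of differences of raw counts, which makes
the zero crossing locatable at low capacities with desk-scale replicate
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geography import RingProfile
from .model import ReplicateSummary, run_replicates, run_replicates_stacked
from .rates import ModelParameters


@dataclass(frozen=True)
class ScenarioConfig:
    """Resolved configuration of one experiment invocation."""

    label: str = "scenario"
    n_replicates: int = 300
    seed: int = 0
    capacities: tuple[int, ...] = (0, 30, 60, 90, 120, 150, 180, 210, 240, 270, 300)
    proportions: tuple[float, ...] = (0.70, 0.75, 0.80, 0.85)
    treatment_rates: tuple[float, ...] = (0.15, 0.20, 0.25)
    pairing: str = "independent"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.capacities or not self.proportions or not self.treatment_rates:
            raise ValueError("sweep lists must be nonempty")
        if any(c < 0 for c in self.capacities):
            raise ValueError("capacities must be nonnegative")
        if any(not (0.0 < p <= 1.0) for p in self.proportions):
            raise ValueError("proportions must lie in (0, 1]")
        if any(not (0.0 <= r <= 1.0) for r in self.treatment_rates):
            raise ValueError("treatment rates must be probabilities")
        if self.pairing not in ("independent", "common-random-numbers"):
            raise ValueError("pairing must be 'independent' or 'common-random-numbers'")


def calibration_experiment(
    params: ModelParameters,
    profile: RingProfile,
    n_replicates: int,
    seed: int | np.random.SeedSequence,
) -> ReplicateSummary:
    """Replicate means of annual fatal/nonfatal counts with no site."""
    if params.ops_capacity != 0:
        raise ValueError("calibration runs without a site; set ops_capacity = 0")
    return run_replicates(params, profile, n_replicates, seed)


@dataclass
class CapacitySweepResult:
    """Per-capacity differences vs the no-site baseline and the fitted slope.

    Differences are reported twice: from raw event counts
    (``fatal_reduction`` / ``nonfatal_change``) and from the engine's
    conditional-expectation counts (``*_vr`` columns), which estimate the
    same quantities with much smaller Monte-Carlo error.  The fitted
    slope uses the variance-reduced series; ``slope_per_30_raw`` is the
    raw-count fit.
    """

    table: pd.DataFrame
    slope_per_30: float
    slope_se_per_30: float
    slope_per_30_raw: float
    slope_se_per_30_raw: float
    summaries: dict[int, ReplicateSummary] = field(repr=False, default_factory=dict)


def capacity_sweep(
    params: ModelParameters,
    profile: RingProfile,
    capacities: Sequence[int] = ScenarioConfig.capacities,
    n_replicates: int = 150,
    seed: int | np.random.SeedSequence = 0,
) -> CapacitySweepResult:
    """Direct effects: fatal reduction and nonfatal change vs capacity.

    Runs each capacity (always including 0 as the baseline) and reports
    the difference of replicate means against capacity 0, plus the
    least-squares slope of fatal reduction on capacity rescaled to
    "fatalities averted per 30 stations".
    """
    caps = list(dict.fromkeys([0, *capacities]))  # ensure baseline, keep order
    arms = [params.replace(ops_capacity=c) for c in caps]
    results = run_replicates_stacked(arms, profile, n_replicates, seed)
    summaries = dict(zip(caps, results))

    base = summaries[0]
    rows = []
    for cap in caps:
        sm = summaries[cap]
        d_se = lambda col: float(np.hypot(sm.se(col), base.se(col)))
        rows.append(
            {
                "capacity": cap,
                "mean_fatal": sm.mean("fatal"),
                "se_fatal": sm.se("fatal"),
                "mean_nonfatal": sm.mean("nonfatal"),
                "se_nonfatal": sm.se("nonfatal"),
                "fatal_reduction": base.mean("fatal") - sm.mean("fatal"),
                "se_fatal_reduction": 0.0 if cap == 0 else d_se("fatal"),
                "nonfatal_change": sm.mean("nonfatal") - base.mean("nonfatal"),
                "se_nonfatal_change": 0.0 if cap == 0 else d_se("nonfatal"),
                "fatal_reduction_vr": base.mean("fatal_expected") - sm.mean("fatal_expected"),
                "se_fatal_reduction_vr": 0.0 if cap == 0 else d_se("fatal_expected"),
                "nonfatal_change_vr": sm.mean("nonfatal_expected") - base.mean("nonfatal_expected"),
                "se_nonfatal_change_vr": 0.0 if cap == 0 else d_se("nonfatal_expected"),
                "averted_expected": sm.mean("averted_expected"),
                "mean_ops_occupancy": sm.mean("mean_ops_occupancy"),
            }
        )
    table = pd.DataFrame(rows)

    def _fit(y_col: str, se_col: str) -> tuple[float, float]:
        x = table["capacity"].to_numpy(float)
        y = table[y_col].to_numpy(float)
        xc = x - x.mean()
        sxx = float((xc**2).sum())
        slope = float((xc * y).sum() / sxx)
        se_y = table[se_col].to_numpy(float)
        slope_se = float(np.sqrt((xc**2 * se_y**2).sum()) / sxx)
        return 30.0 * slope, 30.0 * slope_se

    slope_vr, slope_vr_se = _fit("fatal_reduction_vr", "se_fatal_reduction_vr")
    slope_raw, slope_raw_se = _fit("fatal_reduction", "se_fatal_reduction")
    return CapacitySweepResult(
        table=table,
        slope_per_30=slope_vr,
        slope_se_per_30=slope_vr_se,
        slope_per_30_raw=slope_raw,
        slope_se_per_30_raw=slope_raw_se,
        summaries=summaries,
    )


@dataclass
class ProportionSweepResult:
    """Net nonfatal change over (capacity, in-site overdose proportion)."""

    table: pd.DataFrame
    break_even: pd.DataFrame
    summaries: dict[tuple[int, float], ReplicateSummary] = field(repr=False, default_factory=dict)


def _interpolate_zero(props: np.ndarray, values: np.ndarray) -> float | None:
    """Linear interpolation of the zero crossing; None if not bracketed."""
    for i in range(len(props) - 1):
        v0, v1 = values[i], values[i + 1]
        if v0 == 0.0:
            return float(props[i])
        if v0 < 0.0 <= v1 or v1 <= 0.0 < v0:
            return float(props[i] - v0 * (props[i + 1] - props[i]) / (v1 - v0))
    if values[-1] == 0.0:
        return float(props[-1])
    return None


def proportion_sweep(
    params: ModelParameters,
    profile: RingProfile,
    capacities: Sequence[int] = tuple(range(30, 301, 30)),
    proportions: Sequence[float] = ScenarioConfig.proportions,
    n_replicates: int = 30,
    seed: int | np.random.SeedSequence = 0,
) -> ProportionSweepResult:
    """Indirect effects: vary in-site overdose safety and locate break-even.

    For each capacity the in-site overdose proportion is swept and the
    proportion at which the net change in annual nonfatal overdoses
    crosses zero is located by linear interpolation of the in-run
    counterfactual diagnostic; the reported ``break_even_reduction`` is
    one minus that proportion.  Raw differences of replicate means
    against a shared no-site baseline are reported alongside.
    """
    caps = [c for c in capacities if c > 0]
    if not caps:
        raise ValueError("proportion sweep needs at least one positive capacity")
    props = sorted(set(float(p) for p in proportions))
    grid = [(c, p) for c in caps for p in props]
    arms = [params.replace(ops_capacity=0)] + [
        params.replace(ops_capacity=c, ops_od_proportion=p) for c, p in grid
    ]
    results = run_replicates_stacked(arms, profile, n_replicates, seed)
    base = results[0]

    summaries: dict[tuple[int, float], ReplicateSummary] = {}
    rows = []
    for (cap, prop), sm in zip(grid, results[1:]):
        summaries[(cap, prop)] = sm
        rows.append(
            {
                "capacity": cap,
                "proportion": prop,
                "net_nonfatal_expected": sm.mean("net_nonfatal_expected"),
                "se_net_nonfatal_expected": sm.se("net_nonfatal_expected"),
                "nonfatal_change_raw": sm.mean("nonfatal") - base.mean("nonfatal"),
                "se_nonfatal_change_raw": float(np.hypot(sm.se("nonfatal"), base.se("nonfatal"))),
                "fatal_reduction_raw": base.mean("fatal") - sm.mean("fatal"),
            }
        )
    table = pd.DataFrame(rows)

    be_rows = []
    for cap in caps:
        sub = table[table["capacity"] == cap].sort_values("proportion")
        crossing = _interpolate_zero(
            sub["proportion"].to_numpy(), sub["net_nonfatal_expected"].to_numpy()
        )
        be_rows.append(
            {
                "capacity": cap,
                "break_even_proportion": np.nan if crossing is None else crossing,
                "break_even_reduction": np.nan if crossing is None else 1.0 - crossing,
                "bracketed": crossing is not None,
            }
        )
    return ProportionSweepResult(
        table=table, break_even=pd.DataFrame(be_rows), summaries=summaries
    )


@dataclass
class TreatmentSweepResult:
    """Differences in annual events vs the baseline treatment-entry rate."""

    table: pd.DataFrame
    summaries: dict[float, ReplicateSummary] = field(repr=False, default_factory=dict)


def treatment_sweep(
    params: ModelParameters,
    profile: RingProfile,
    rates: Sequence[float] = ScenarioConfig.treatment_rates,
    n_replicates: int = 300,
    seed: int | np.random.SeedSequence = 0,
) -> TreatmentSweepResult:
    """Population-wide treatment-entry sweep (relapse held fixed).

    All arms start from the treatment-pool equilibrium of the *baseline*
    entry rate (the first rate, normally 15%/year): raising the entry
    rate mid-flight then relaxes the population toward its new
    equilibrium over the simulated year.
    """
    rates = list(dict.fromkeys(float(r) for r in rates))
    base_rate = rates[0]
    t0 = round(
        params.replace(annual_treatment_entry=base_rate).equilibrium_treatment
        if params.annual_relapse > 0
        else 0
    )
    arms = [
        params.replace(annual_treatment_entry=r, initial_treatment_count=int(t0)) for r in rates
    ]
    results = run_replicates_stacked(arms, profile, n_replicates, seed)
    summaries = dict(zip(rates, results))

    base = summaries[base_rate]
    rows = []
    for r in rates:
        sm = summaries[r]
        is_base = r == base_rate
        rows.append(
            {
                "annual_treatment_entry": r,
                "mean_fatal": sm.mean("fatal"),
                "se_fatal": sm.se("fatal"),
                "mean_nonfatal": sm.mean("nonfatal"),
                "se_nonfatal": sm.se("nonfatal"),
                "fewer_fatal": 0.0 if is_base else base.mean("fatal") - sm.mean("fatal"),
                "se_fewer_fatal": 0.0 if is_base else float(np.hypot(sm.se("fatal"), base.se("fatal"))),
                "fewer_nonfatal": 0.0 if is_base else base.mean("nonfatal") - sm.mean("nonfatal"),
                "se_fewer_nonfatal": 0.0
                if is_base
                else float(np.hypot(sm.se("nonfatal"), base.se("nonfatal"))),
                "fewer_fatal_vr": 0.0
                if is_base
                else base.mean("fatal_expected") - sm.mean("fatal_expected"),
                "se_fewer_fatal_vr": 0.0
                if is_base
                else float(np.hypot(sm.se("fatal_expected"), base.se("fatal_expected"))),
                "fewer_nonfatal_vr": 0.0
                if is_base
                else base.mean("nonfatal_expected") - sm.mean("nonfatal_expected"),
                "se_fewer_nonfatal_vr": 0.0
                if is_base
                else float(np.hypot(sm.se("nonfatal_expected"), base.se("nonfatal_expected"))),
            }
        )
    return TreatmentSweepResult(table=pd.DataFrame(rows), summaries=summaries)


def spatial_attribution(summary: ReplicateSummary, profile: RingProfile) -> dict:
    """Cumulative share of in-site revivals by distance from the site.

    Normalizes the replicate-mean revived counts per ring and reports the
    cumulative shares within 1 and 1.5 miles next to the corresponding
    population shares.  With zero revivals the shares are undefined and
    returned as NaN.
    """
    revived = summary.revived_mean_by_ring()
    total = float(revived.sum())
    if total == 0.0:
        share = np.full(profile.n_rings, np.nan)
        cum1 = cum15 = float("nan")
    else:
        share = revived / total
        cum1 = float(share[profile.hi <= 1.0 + 1e-12].sum())
        cum15 = float(share[profile.hi <= 1.5 + 1e-12].sum())
    return {
        "revived_share_by_ring": share,
        "revived_within_1mi": cum1,
        "revived_within_1p5mi": cum15,
        "population_within_1mi": profile.cumulative_population_within(1.0),
        "population_within_1p5mi": profile.cumulative_population_within(1.5),
        "mean_total_revived": total,
    }
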