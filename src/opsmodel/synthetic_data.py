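"""Synthetic overdose-record generator.

The record-level Philadelphia overdose dataset that parameterizes the
spatial side of the model is restricted (obtainable only by request from
the city health department).  Only a handful of its statistics are
public: the annual counts (1033 fatal, 3788 nonfatal events), the
cumulative shares of users living within 1 mile (~30%) and 1.5 miles
(~38%) of the candidate site, and the demographic marginals of the fatal
and nonfatal event tables.  This module generates synthetic record sets
that reproduce those published statistics exactly (in distribution), so
ring-proportion estimation and every downstream experiment run with no
restricted data.

Spatial model: distance from the site is drawn from a two-component
mixture -- an exponential "near-site" component plus a uniform far-field
component on (1.5, 10] miles.  The exponential rate and the mixture
weight are solved (two equations, two unknowns) so that the analytic CDF
passes through both cumulative-share targets exactly.  The far-field
shape beyond 1.5 miles is a modeling stand-in; nothing downstream
depends on it beyond the two calibrated shares.

Demographics are drawn independently of distance and of each other by
default, matching the published marginals; an optional distance gradient
tilts the White share upward toward the site for demonstrations of
placement inequity.  Nonfatal records carry no race/ethnicity (the
nonfatal table publishes none).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .geography import (
    TABLE_RING_EDGES,
    RingProfile,
    ring_proportions_from_records,
    table_profile,
)


class CalibrationError(ValueError):
    """Raised when spatial calibration targets are infeasible."""


#: Published demographic marginals of the fatal overdose table.
FATAL_SEX = {"male": 0.7348, "female": 0.2652}
FATAL_RACE = {"White": 0.6970, "Black": 0.2933, "other/unknown": 0.0097}
FATAL_ETHNICITY = {"Hispanic": 0.1278, "non-Hispanic": 0.8616, "unknown": 0.0106}
FATAL_MEAN_AGE = 43.91

#: Published demographic marginals of the nonfatal overdose table
#: (no race/ethnicity breakdown exists for nonfatal events).
NONFATAL_SEX = {"male": 0.7083, "female": 0.2759, "unknown": 0.0158}
NONFATAL_MEAN_AGE = 41.5

#: Annual event counts in the one-year study window.
N_FATAL_EVENTS = 1033
N_NONFATAL_EVENTS = 3788

AGE_SD = 12.0
AGE_LO, AGE_HI = 10.0, 100.0

DEFAULT_WITHIN_1MI = 0.30
DEFAULT_WITHIN_1P5MI = 0.38


@dataclass(frozen=True)
class OverdoseRecord:
    """One synthetic overdose event."""

    distance_miles: float
    fatal: bool
    sex: str
    race: str
    ethnicity: str
    age_years: float


@dataclass(frozen=True)
class SpatialMixture:
    """Exponential near-site + uniform far-field distance distribution.

    Density: ``weight * Expon(rate)`` on [0, inf) plus
    ``(1 - weight) * Uniform(far_lo, far_hi]``.
    """

    weight: float
    rate: float
    far_lo: float = 1.5
    far_hi: float = 10.0

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        exp_part = self.weight * -np.expm1(-self.rate * np.clip(x, 0.0, None))
        u = np.clip((x - self.far_lo) / (self.far_hi - self.far_lo), 0.0, 1.0)
        out = exp_part + (1.0 - self.weight) * u
        return out if out.shape else float(out)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        near = rng.random(n) < self.weight
        d = np.empty(n)
        d[near] = rng.exponential(1.0 / self.rate, size=int(near.sum()))
        d[~near] = rng.uniform(self.far_lo, self.far_hi, size=int((~near).sum()))
        return d


def calibrate_spatial_decay(
    target_within_1mi: float = DEFAULT_WITHIN_1MI,
    target_within_1p5mi: float = DEFAULT_WITHIN_1P5MI,
) -> SpatialMixture:
    """Solve the mixture so its CDF hits both cumulative-share targets.

    Below the far-field onset (1.5 mi) only the exponential component has
    mass, so the two targets give::

        weight * (1 - exp(-rate * 1.0)) = target_within_1mi
        weight * (1 - exp(-rate * 1.5)) = target_within_1p5mi

    The ratio eliminates ``weight`` and is monotone in ``rate``; a
    bracketed root solve recovers ``rate``, then ``weight`` follows.
    """
    t1, t15 = float(target_within_1mi), float(target_within_1p5mi)
    if not (0.0 < t1 < t15 < 1.0):
        raise CalibrationError(
            f"targets must satisfy 0 < within_1mi < within_1.5mi < 1, got ({t1}, {t15})"
        )
    ratio = t15 / t1
    if ratio >= 1.5:
        raise CalibrationError(
            f"within-1.5mi/within-1mi ratio {ratio:.4f} >= 1.5 is unreachable by an "
            "exponential component (its CDF ratio at 1.5 vs 1 miles is below 1.5)"
        )

    def f(rate: float) -> float:
        return -math.expm1(-1.5 * rate) / -math.expm1(-rate) - ratio

    lo, hi = 1e-9, 1e3
    rate = brentq(f, lo, hi, xtol=1e-13, rtol=1e-15)
    weight = t1 / -math.expm1(-rate)
    if not (0.0 < weight <= 1.0):
        raise CalibrationError(
            f"calibrated mixture weight {weight:.4f} outside (0, 1]; "
            "targets imply more near-site mass than a unit-weight exponential allows"
        )
    return SpatialMixture(weight=weight, rate=rate)


def _sample_categorical(
    rng: np.random.Generator, marginals: dict[str, float], n: int
) -> np.ndarray:
    labels = list(marginals)
    p = np.array([marginals[k] for k in labels], dtype=float)
    if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
        raise ValueError(f"marginals must be a probability vector, got {marginals}")
    return np.array(labels, dtype=object)[rng.choice(len(labels), size=n, p=p / p.sum())]


def _sample_age(rng: np.random.Generator, mean: float, n: int) -> np.ndarray:
    """Truncated-normal ages by rejection; the published tables give only means."""
    out = rng.normal(mean, AGE_SD, size=n)
    bad = (out <= AGE_LO) | (out >= AGE_HI)
    while bad.any():
        out[bad] = rng.normal(mean, AGE_SD, size=int(bad.sum()))
        bad = (out <= AGE_LO) | (out >= AGE_HI)
    return out


def _race_with_gradient(
    rng: np.random.Generator,
    marginals: dict[str, float],
    distances: np.ndarray,
    gradient: float,
) -> np.ndarray:
    """Race draws whose White share rises linearly toward the site.

    ``P(White | d) = clip(p_White + gradient * (mean_d - d), 0, 1)``, with
    the non-White categories rescaled to keep each row a distribution.
    With ``gradient = 0`` this reduces to the plain marginals.
    """
    labels = list(marginals)
    base = np.array([marginals[k] for k in labels], dtype=float)
    iw = labels.index("White")
    p_white = np.clip(base[iw] + gradient * (distances.mean() - distances), 0.0, 1.0)
    others = np.delete(base, iw)
    out = np.empty(len(distances), dtype=object)
    u = rng.random(len(distances))
    # inverse-CDF draw per record: White first, then the rescaled others
    cum = p_white.copy()
    out[:] = labels[iw]
    remaining = u >= cum
    other_labels = [l for i, l in enumerate(labels) if i != iw]
    scale = np.where(others.sum() > 0, (1.0 - p_white) / max(others.sum(), 1e-300), 0.0)
    for j, lab in enumerate(other_labels):
        nxt = cum + others[j] * scale
        out[remaining & (u < nxt)] = lab
        cum = nxt
        remaining = u >= cum
    return out


def generate_records(
    n_fatal: int = N_FATAL_EVENTS,
    n_nonfatal: int = N_NONFATAL_EVENTS,
    spatial: SpatialMixture | None = None,
    race_distance_gradient: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> list[OverdoseRecord]:
    """Draw a synthetic one-year overdose record set.

    Returns exactly ``n_fatal + n_nonfatal`` records, fatal events first.
    Identical seeds give identical record sets.
    """
    if n_fatal < 0 or n_nonfatal < 0:
        raise ValueError("record counts must be nonnegative")
    spatial = spatial or calibrate_spatial_decay()
    rng = np.random.default_rng(seed)
    records: list[OverdoseRecord] = []

    if n_fatal:
        d = spatial.sample(rng, n_fatal)
        sex = _sample_categorical(rng, FATAL_SEX, n_fatal)
        if race_distance_gradient > 0.0:
            race = _race_with_gradient(rng, FATAL_RACE, d, race_distance_gradient)
        else:
            race = _sample_categorical(rng, FATAL_RACE, n_fatal)
        eth = _sample_categorical(rng, FATAL_ETHNICITY, n_fatal)
        age = _sample_age(rng, FATAL_MEAN_AGE, n_fatal)
        records += [
            OverdoseRecord(float(d[i]), True, sex[i], race[i], eth[i], float(age[i]))
            for i in range(n_fatal)
        ]

    if n_nonfatal:
        d = spatial.sample(rng, n_nonfatal)
        sex = _sample_categorical(rng, NONFATAL_SEX, n_nonfatal)
        age = _sample_age(rng, NONFATAL_MEAN_AGE, n_nonfatal)
        records += [
            OverdoseRecord(float(d[i]), False, sex[i], "unknown", "unknown", float(age[i]))
            for i in range(n_nonfatal)
        ]
    return records


def records_to_frame(records: Sequence[OverdoseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "distance_miles": [r.distance_miles for r in records],
            "fatal": [r.fatal for r in records],
            "sex": [r.sex for r in records],
            "race": [r.race for r in records],
            "ethnicity": [r.ethnicity for r in records],
            "age_years": [r.age_years for r in records],
        }
    )


def records_from_frame(frame: pd.DataFrame) -> list[OverdoseRecord]:
    return [
        OverdoseRecord(
            float(row.distance_miles),
            bool(row.fatal),
            str(row.sex),
            str(row.race),
            str(row.ethnicity),
            float(row.age_years),
        )
        for row in frame.itertuples()
    ]


def write_records_csv(records: Sequence[OverdoseRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path) -> list[OverdoseRecord]:
    return records_from_frame(pd.read_csv(path))


def default_ring_profile(
    seed: int | np.random.SeedSequence = 0,
    n_records: int = 50_000,
    target_within_1mi: float = DEFAULT_WITHIN_1MI,
    target_within_1p5mi: float = DEFAULT_WITHIN_1P5MI,
    base_visit_prob: float = 0.67,
) -> RingProfile:
    """Standard synthetic ring profile for the baseline study conditions.

    Draws a large synthetic record set from the calibrated spatial
    mixture, bins it into the standard rings, and attaches the published
    visit scales.  Deterministic for a fixed seed.
    """
    spatial = calibrate_spatial_decay(target_within_1mi, target_within_1p5mi)
    rng = np.random.default_rng(seed)
    distances = spatial.sample(rng, n_records)
    k = len(TABLE_RING_EDGES) - 1
    binning_profile = table_profile(np.full(k, 1.0 / k))
    proportions = ring_proportions_from_records(distances, binning_profile)
    return table_profile(proportions, base_visit_prob=base_visit_prob)
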