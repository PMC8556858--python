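"""Ring geometry, visit probabilities, decay fitting, and record binning."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import opsmodel as om
from opsmodel.geography import (
    TABLE_RING_EDGES,
    TABLE_VISIT_SCALES,
    FitError,
    table_profile,
)


@pytest.fixture(scope="module")
def uniform_profile():
    k = len(TABLE_VISIT_SCALES)
    return table_profile(np.full(k, 1.0 / k))


class TestVisitProbability:
    def test_innermost_ring(self, uniform_profile):
        assert uniform_profile.visit_probability(0) == pytest.approx(0.67)

    def test_published_ring_values(self, uniform_profile):
        # (1.5, 2] is the sixth ring; the outermost is open-ended
        assert uniform_profile.visit_probability(5) == pytest.approx(0.67 * 0.29)
        last = uniform_profile.n_rings - 1
        assert uniform_profile.visit_probability(last) == pytest.approx(0.67 * 0.0027)

    def test_out_of_range_index(self, uniform_profile):
        with pytest.raises(IndexError):
            uniform_profile.visit_probability(uniform_profile.n_rings)

    def test_non_increasing_with_distance(self, uniform_profile):
        probs = uniform_profile.visit_probabilities
        assert np.all(np.diff(probs) <= 1e-12)


class TestRingIndex:
    @pytest.mark.parametrize(
        "distance,expected",
        [(0.0, 0), (0.25, 0), (0.26, 1), (1.5, 4), (6.0, 11), (6.01, 12), (100.0, 12)],
    )
    def test_boundary_convention(self, uniform_profile, distance, expected):
        assert uniform_profile.ring_index(distance) == expected

    @given(st.floats(0.0, 50.0, allow_nan=False))
    def test_exhaustive_and_exclusive(self, uniform_profile, d):
        """Every nonnegative distance maps to exactly one ring containing it."""
        idx = uniform_profile.ring_index(d)
        lo, hi = uniform_profile.lo[idx], uniform_profile.hi[idx]
        if idx == 0:
            assert lo <= d <= hi
        else:
            assert lo < d <= hi

    def test_negative_distance_rejected(self, uniform_profile):
        with pytest.raises(ValueError):
            uniform_profile.ring_index(-0.1)


class TestProfileValidation:
    def test_gap_in_rings_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            om.RingProfile(
                lo=np.array([0.0, 0.5]),
                hi=np.array([0.25, np.inf]),
                visit_scale=np.array([1.0, 0.5]),
                population_proportion=np.array([0.5, 0.5]),
            )

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            om.RingProfile(
                lo=np.array([0.0, 0.25]),
                hi=np.array([0.25, np.inf]),
                visit_scale=np.array([1.0, 0.5]),
                population_proportion=np.array([0.5, 0.6]),
            )

    def test_increasing_visit_scale_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            om.RingProfile(
                lo=np.array([0.0, 0.25]),
                hi=np.array([0.25, np.inf]),
                visit_scale=np.array([0.5, 1.0]),
                population_proportion=np.array([0.5, 0.5]),
            )


class TestDistanceDecayFit:
    def test_exact_exponential_two_points(self):
        fit = om.fit_distance_decay([1.0, 2.0], [math.exp(-1), math.exp(-2)])
        assert fit.rate == pytest.approx(1.0, rel=1e-12)

    def test_half_life_point(self):
        fit = om.fit_distance_decay([0.0, 1.0], [1.0, 0.5])
        assert fit.rate == pytest.approx(math.log(2), rel=1e-12)

    def test_published_scales_recovered(self):
        """The tabulated visit scales follow a ~0.8/mile exponential decay."""
        edges = np.array(TABLE_RING_EDGES)
        mids = (edges[:-2] + edges[1:-1]) / 2  # bounded rings only
        scales = np.array(TABLE_VISIT_SCALES[:-1])
        fit = om.fit_distance_decay(mids, scales)
        assert 0.5 < fit.rate < 1.2
        assert np.max(np.abs(fit.residuals(mids, scales))) < 0.15

    def test_degenerate_distances_rejected(self):
        with pytest.raises(FitError):
            om.fit_distance_decay([1.0, 1.0], [0.5, 0.4])

    def test_single_point_rejected(self):
        with pytest.raises(FitError):
            om.fit_distance_decay([1.0], [0.5])


class TestRingProportions:
    def test_all_records_in_first_ring(self, uniform_profile):
        props = om.ring_proportions_from_records([0.1] * 7, uniform_profile)
        assert props[0] == 1.0
        assert props[1:].sum() == 0.0

    def test_four_quartiles(self, uniform_profile):
        props = om.ring_proportions_from_records([0.1, 0.3, 5.5, 10.0], uniform_profile)
        expected = np.zeros(uniform_profile.n_rings)
        expected[[0, 1, 11, 12]] = 0.25
        np.testing.assert_allclose(props, expected)

    def test_boundary_record_goes_inward(self, uniform_profile):
        props = om.ring_proportions_from_records([0.25], uniform_profile)
        assert props[0] == 1.0

    def test_accepts_record_objects(self, uniform_profile):
        recs = om.generate_records(n_fatal=10, n_nonfatal=0, seed=3)
        props = om.ring_proportions_from_records(recs, uniform_profile)
        assert props.sum() == pytest.approx(1.0)

    def test_empty_rejected(self, uniform_profile):
        with pytest.raises(ValueError):
            om.ring_proportions_from_records([], uniform_profile)


class TestSerialization:
    def test_csv_round_trip(self, profile, tmp_path):
        path = tmp_path / "profile.csv"
        profile.to_csv(path)
        back = om.RingProfile.from_csv(path)
        np.testing.assert_allclose(back.lo, profile.lo)
        np.testing.assert_allclose(back.hi, profile.hi)
        np.testing.assert_allclose(back.visit_scale, profile.visit_scale)
        np.testing.assert_allclose(
            back.population_proportion, profile.population_proportion
        )


def test_default_profile_matches_published_cumulative_shares(profile):
    """~30% of users within 1 mile, ~38% within 1.5 miles of the site."""
    assert profile.cumulative_population_within(1.0) == pytest.approx(0.30, abs=0.01)
    assert profile.cumulative_population_within(1.5) == pytest.approx(0.38, abs=0.01)
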