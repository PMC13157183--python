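"""Band detection, region calibration, indexing and profile classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epoprofile.datasets.cohort import CohortSimParams, render_lane
from epoprofile.errors import (
    CalibrationError,
    ClassificationError,
    InsufficientBandsError,
    InvalidInputError,
    NoBandsError,
)
from epoprofile.gel import (
    Band,
    BandSet,
    LaneProfile,
    RegionMap,
    assign_regions_and_index,
    calibrate_regions,
    classify_profile,
    detect_bands,
    select_top3,
)

from conftest import gaussian_signal


def make_band(position, intensity, region=None, basic_index=None, width=0.02):
    return Band(
        position=position,
        intensity=intensity,
        left=position - width,
        right=position + width,
        region=region,
        basic_index=basic_index,
    )


def make_bandset(specs, lane_id="L"):
    """specs: iterable of (position, intensity[, region[, basic_index]])."""
    bands = tuple(make_band(*s) for s in sorted(specs))
    return BandSet(lane_id=lane_id, bands=bands)


# ---------------------------------------------------------------------------
# LaneProfile validation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "positions, intensities",
    [
        (np.linspace(0, 1, 20), np.ones(20)),  # too few points
        (np.linspace(0, 1, 100)[::-1], np.ones(100)),  # decreasing
        (np.linspace(0, 1, 100), -np.ones(100)),  # negative
        (np.linspace(0, 1, 100), np.full(100, np.nan)),  # non-finite
    ],
)
def test_lane_profile_rejects_bad_input(positions, intensities):
    with pytest.raises(InvalidInputError):
        LaneProfile("bad", "sample", positions, intensities)


# ---------------------------------------------------------------------------
# detect_bands
# ---------------------------------------------------------------------------


def test_zero_signal_raises_no_bands():
    x = np.linspace(0, 1, 500)
    with pytest.raises(NoBandsError) as err:
        detect_bands(LaneProfile("flat", "sample", x, np.zeros_like(x)))
    assert err.value.lane_id == "flat"


def test_single_gaussian_band_area_matches_closed_form():
    # integral of A * exp(-(x-c)^2 / 2 s^2) is A * s * sqrt(2 pi)
    x, y = gaussian_signal(0.5, 1.0, sigma=0.01)
    bands = detect_bands(LaneProfile("g", "sample", x, y))
    assert len(bands) == 1
    band = bands.bands[0]
    step = x[1] - x[0]
    assert abs(band.position - 0.5) <= step / 2 + 1e-12
    expected_area = 1.0 * 0.01 * np.sqrt(2 * np.pi)  # 0.025066...
    assert band.intensity == pytest.approx(expected_area, rel=0.02)


def test_two_gaussians_ordered_by_area():
    x, y = gaussian_signal([0.3, 0.7], [2.0, 1.0], sigma=0.01)
    bands = detect_bands(LaneProfile("g2", "sample", x, y))
    assert len(bands) == 2
    b_at = {round(b.position, 1): b for b in bands}
    assert b_at[0.3].intensity > b_at[0.7].intensity


def brute_force_local_maxima(y, threshold):
    """Oracle: every strict local maximum above the threshold."""
    idx = [
        i
        for i in range(1, len(y) - 1)
        if y[i] > y[i - 1] and y[i] > y[i + 1] and y[i] >= threshold
    ]
    return np.array(idx)


def test_detector_matches_brute_force_enumeration_on_sparse_signals():
    rng = np.random.default_rng(42)
    for _ in range(20):
        k = int(rng.integers(1, 6))
        centers = 0.08 + np.sort(rng.permutation(np.arange(7))[:k]) * 0.13
        centers = centers + rng.uniform(-0.02, 0.02, k)
        amps = rng.uniform(0.3, 1.0, k)
        sigma = float(rng.uniform(0.008, 0.015))
        x, y = gaussian_signal(centers, amps, sigma=sigma, n=1200)
        bands = detect_bands(LaneProfile("mix", "sample", x, y))
        oracle = brute_force_local_maxima(y, 0.05 * y.max())
        assert len(bands) == len(oracle)
        step = x[1] - x[0]
        for band, oi in zip(bands, oracle):
            assert abs(band.position - x[oi]) <= 2 * step


# ---------------------------------------------------------------------------
# calibrate_regions
# ---------------------------------------------------------------------------


def test_calibration_from_stated_band_supports():
    acidic = make_bandset([(0.05, 1.0), (0.20, 0.8)])
    basic = make_bandset([(0.70, 1.0), (0.95, 0.9)])
    regions = calibrate_regions(acidic, basic, margin=0.02)
    assert regions.acidic_max == pytest.approx(0.22)
    assert regions.basic_min == pytest.approx(0.68)


def test_calibration_rejects_inverted_references():
    acidic = make_bandset([(0.5, 1.0)])
    basic = make_bandset([(0.4, 1.0)])
    with pytest.raises(CalibrationError) as err:
        calibrate_regions(acidic, basic, margin=0.02)
    assert "0.52" in str(err.value) and "0.38" in str(err.value)


def test_region_map_partitions_unit_interval(regions):
    for x in np.linspace(0.001, 0.999, 97):
        assert regions.region_of(x) in ("acidic", "neutral", "basic")
    assert regions.region_of(regions.acidic_max) == "acidic"
    assert regions.region_of(regions.basic_min) == "basic"


# ---------------------------------------------------------------------------
# indexing and top-3 selection
# ---------------------------------------------------------------------------


def test_six_basic_bands_indexed_from_neutral_boundary():
    regions = RegionMap(acidic_max=0.2, basic_min=0.6)
    positions = np.linspace(0.62, 0.95, 6)
    bs = make_bandset([(p, 1.0) for p in positions])
    out = assign_regions_and_index(bs, regions)
    assert [b.basic_index for b in out] == [1, 2, 3, 4, 5, 6]
    # a seventh basic band stays unindexed
    bs7 = make_bandset([(p, 1.0) for p in np.linspace(0.61, 0.96, 7)])
    out7 = assign_regions_and_index(bs7, regions)
    assert [b.basic_index for b in out7] == [1, 2, 3, 4, 5, 6, None]


def test_lane_without_basic_bands_keeps_band_count():
    regions = RegionMap(acidic_max=0.2, basic_min=0.6)
    bs = make_bandset([(0.3, 1.0), (0.4, 2.0)])
    out = assign_regions_and_index(bs, regions)
    assert len(out) == 2
    assert all(b.region == "neutral" and b.basic_index is None for b in out)


def test_top3_selection_and_tie_break():
    bs = make_bandset([(0.3, 5.0), (0.5, 3.0), (0.6, 3.0), (0.8, 3.0), (0.9, 1.0)])
    top3 = select_top3(bs)
    assert [b.intensity for b in top3] == [5.0, 3.0, 3.0]
    # tie among the 3.0 bands resolved to the more basic positions
    assert {b.position for b in top3[1:]} == {0.8, 0.6}


def test_top3_requires_three_bands():
    with pytest.raises(InsufficientBandsError):
        select_top3(make_bandset([(0.3, 1.0), (0.5, 2.0)]))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

REGIONS = RegionMap(acidic_max=0.2, basic_min=0.6)


def basic_top3(indices):
    return tuple(
        make_band(0.6 + 0.05 * i, 10.0 - n, region="basic", basic_index=i)
        for n, i in enumerate(indices)
    )


@pytest.mark.parametrize(
    "indices, expected_class, expected_rule",
    [
        ((3, 4, 5), "foetal", "foetal_345"),
        ((2, 3, 4), "mixed", "mixed_234"),
        ((1, 2, 3), "mixed", "mixed_123"),
        ((4, 5, 6), "foetal", "fallback_foetal_median"),
        ((1, 2, 4), "mixed", "fallback_mixed_median"),
        ((2, 4, 5), "foetal", "fallback_foetal_median"),
    ],
)
def test_all_basic_top3_classification(indices, expected_class, expected_rule):
    call = classify_profile(basic_top3(indices), REGIONS, lane_id="x")
    assert call.profile_class == expected_class
    assert call.rule_fired == expected_rule


@pytest.mark.parametrize("region", ["neutral", "acidic"])
def test_any_nonbasic_top3_band_gives_adult(region):
    pos = 0.4 if region == "neutral" else 0.1
    top3 = (
        make_band(pos, 9.0, region=region),
        make_band(0.7, 8.0, region="basic", basic_index=2),
        make_band(0.75, 7.0, region="basic", basic_index=3),
    )
    call = classify_profile(top3, REGIONS)
    assert call.profile_class == "adult"
    assert call.rule_fired == "adult_nonbasic_top3"


def test_unindexed_dominant_basic_band_is_an_error():
    top3 = (
        make_band(0.99, 9.0, region="basic", basic_index=None),
        make_band(0.7, 8.0, region="basic", basic_index=2),
        make_band(0.75, 7.0, region="basic", basic_index=3),
    )
    with pytest.raises(ClassificationError, match="unindexed"):
        classify_profile(top3, REGIONS)


# ---------------------------------------------------------------------------
# invariance properties
# ---------------------------------------------------------------------------


@settings(max_examples=12, derandomize=True, deadline=None)
@given(
    scale=st.floats(min_value=1e-3, max_value=1e3),
    hw=st.sampled_from([0.0, 0.45, 1.0]),
)
def test_intensity_scale_invariance(scale, hw):
    """Multiplying the lane by any positive constant leaves the call unchanged."""
    params = CohortSimParams(lane_noise_sd=0.0)
    from epoprofile.datasets.cohort import simulate_reference_lanes
    from epoprofile.gel import ProfileClassifier

    clf = ProfileClassifier().fit(list(simulate_reference_lanes(params)))
    lane = render_lane(hw, params, lane_id="s")
    scaled = LaneProfile("s", "sample", lane.positions, lane.intensities * scale)
    assert clf.predict([lane])[0] == clf.predict([scaled])[0]


@settings(max_examples=10, derandomize=True, deadline=None)
@given(offset=st.floats(min_value=-0.05, max_value=0.05))
def test_translation_consistency(offset):
    """Shifting bands and region boundaries together preserves index and class."""
    regions = RegionMap(acidic_max=0.2, basic_min=0.6)
    shifted = RegionMap(acidic_max=0.2 + offset, basic_min=0.6 + offset)
    positions = np.linspace(0.62, 0.95, 6)
    intensities = [1.0, 2.0, 5.0, 4.5, 4.0, 1.5]
    bs = make_bandset(zip(positions, intensities))
    bs_shift = make_bandset(zip(positions + offset, intensities))
    call = classify_profile(
        select_top3(assign_regions_and_index(bs, regions)), regions
    )
    call_shift = classify_profile(
        select_top3(assign_regions_and_index(bs_shift, shifted)), shifted
    )
    assert call.profile_class == call_shift.profile_class == "foetal"
    assert call.rule_fired == call_shift.rule_fired


def test_end_to_end_purity(classifier, clean_params):
    lane = render_lane(0.45, clean_params, lane_id="p")
    calls = [classifier.predict_calls([lane])[0] for _ in range(2)]
    assert calls[0] == calls[1]
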