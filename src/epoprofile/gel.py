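"""IEF-PAGE lane densitometry: band detection, region calibration, profile calling.

Erythropoietin (EPO) glycoforms separate on an isoelectric-focusing gel
(pH 2-6 gradient) into 11-16 bands. A lane is represented here as a 1-D
densitometric signal over a normalised coordinate x in [0, 1], where x = 0 is
the most acidic end of the gel and x = 1 the most basic end. Two recombinant
reference drugs anchor the coordinate frame: darbepoetin alfa migrates in the
acidic region and epoetin alfa/beta in the basic region; the neutral region is
whatever lies between them. Bands in the basic area are indexed 1-6 starting
at the band nearest the neutral boundary and increasing toward the basic
extreme (a package convention; the direction is not dictated by the assay).

A lane's profile class summarises where its three most intense bands sit:

* ``foetal`` - all three in the basic area at indices {3, 4, 5}
  (hepatic-dominant EPO);
* ``mixed``  - all three basic at indices {2, 3, 4} or {1, 2, 3}
  (partial renal contribution);
* ``adult``  - at least one of the three in the neutral (or acidic) region
  (renal-dominant EPO, the healthy-adult pattern).

Top-3 index sets not enumerated above are resolved by a documented fallback:
median basic index >= 4 is called foetal, otherwise mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks, savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    CalibrationError,
    ClassificationError,
    InsufficientBandsError,
    InvalidInputError,
    NoBandsError,
)

__all__ = [
    "LaneProfile",
    "RegionMap",
    "Band",
    "BandSet",
    "ProfileCall",
    "detect_bands",
    "calibrate_regions",
    "assign_regions_and_index",
    "select_top3",
    "classify_profile",
    "call_profile",
    "BandDetector",
    "ProfileClassifier",
    "PROFILE_CLASSES",
    "LANE_KINDS",
]

PROFILE_CLASSES = ("foetal", "mixed", "adult")
LANE_KINDS = ("sample", "acidic_reference", "basic_reference")

#: default detection / calibration settings
DEFAULT_MIN_PROMINENCE = 0.05  # fraction of max corrected intensity
DEFAULT_MIN_SEPARATION = 0.015  # normalised coordinate units
DEFAULT_REGION_MARGIN = 0.02  # margin delta around reference band extremes


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LaneProfile:
    """One gel lane as a sampled densitometric signal.

    Parameters
    ----------
    lane_id : str
        Identifier, unique within a run.
    lane_kind : str
        One of ``sample``, ``acidic_reference``, ``basic_reference``.
    positions : ndarray
        Strictly increasing normalised coordinates in [0, 1]; >= 50 points.
    intensities : ndarray
        Non-negative finite intensities (arbitrary units), same length.
    """

    lane_id: str
    lane_kind: str
    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)
        if self.lane_kind not in LANE_KINDS:
            raise InvalidInputError(
                f"lane {self.lane_id!r}: unknown lane_kind {self.lane_kind!r}"
            )
        if pos.ndim != 1 or pos.shape != inten.shape:
            raise InvalidInputError(
                f"lane {self.lane_id!r}: positions and intensities must be "
                "1-D arrays of equal length"
            )
        if pos.size < 50:
            raise InvalidInputError(
                f"lane {self.lane_id!r}: need >= 50 sample points, got {pos.size}"
            )
        if not np.all(np.isfinite(pos)) or not np.all(np.isfinite(inten)):
            raise InvalidInputError(f"lane {self.lane_id!r}: non-finite values")
        if np.any(np.diff(pos) <= 0):
            raise InvalidInputError(
                f"lane {self.lane_id!r}: positions must be strictly increasing"
            )
        if pos[0] < 0 or pos[-1] > 1:
            raise InvalidInputError(
                f"lane {self.lane_id!r}: positions must lie in [0, 1]"
            )
        if np.any(inten < 0):
            raise InvalidInputError(
                f"lane {self.lane_id!r}: intensities must be non-negative"
            )


@dataclass(frozen=True)
class RegionMap:
    """Partition of [0, 1] into acidic [0, a], neutral (a, b), basic [b, 1]."""

    acidic_max: float
    basic_min: float
    margin: float = DEFAULT_REGION_MARGIN

    def __post_init__(self):
        if not (0.0 < self.acidic_max < self.basic_min < 1.0):
            raise CalibrationError(
                "invalid region boundaries: need 0 < a < b < 1, got "
                f"a={self.acidic_max:.4f}, b={self.basic_min:.4f}"
            )

    def region_of(self, position: float) -> str:
        if position <= self.acidic_max:
            return "acidic"
        if position < self.basic_min:
            return "neutral"
        return "basic"


@dataclass(frozen=True)
class Band:
    """A detected band: apex position, integrated area, peak bounds.

    ``region`` and ``basic_index`` are filled in by
    :func:`assign_regions_and_index`; ``basic_index`` is present only for
    basic-region bands of position rank <= 6.
    """

    position: float
    intensity: float
    left: float
    right: float
    region: str | None = None
    basic_index: int | None = None

    def __post_init__(self):
        if not (self.left < self.position < self.right):
            raise InvalidInputError(
                f"band bounds must bracket apex: {self.left} < "
                f"{self.position} < {self.right} fails"
            )
        if self.intensity <= 0:
            raise InvalidInputError("band intensity must be positive")


@dataclass(frozen=True)
class BandSet:
    """All bands detected in one lane, ordered by position."""

    lane_id: str
    bands: tuple[Band, ...]

    def __post_init__(self):
        bands = tuple(self.bands)
        object.__setattr__(self, "bands", bands)
        if len(bands) == 0:
            raise InvalidInputError(f"lane {self.lane_id!r}: empty band set")
        pos = [b.position for b in bands]
        if any(pos[i] >= pos[i + 1] for i in range(len(pos) - 1)):
            raise InvalidInputError(
                f"lane {self.lane_id!r}: bands must be sorted by position"
            )

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)


@dataclass(frozen=True)
class ProfileCall:
    """Foetal/mixed/adult call for one lane with its top-3 evidence."""

    lane_id: str
    profile_class: str
    top3: tuple[Band, Band, Band]
    rule_fired: str

    def __post_init__(self):
        if self.profile_class not in PROFILE_CLASSES:
            raise InvalidInputError(
                f"unknown profile class {self.profile_class!r}"
            )
        if len(self.top3) != 3:
            raise InvalidInputError("top3 must contain exactly 3 bands")


# ---------------------------------------------------------------------------
# band detection
# ---------------------------------------------------------------------------


def _estimate_baseline(intensities: np.ndarray, window: int) -> np.ndarray:
    """Rolling-minimum baseline, linearly smoothed over the same window.

    The moving average of the rolling minimum never exceeds the signal
    (every window element is itself a windowed minimum covering the centre
    point), so the corrected signal stays non-negative.
    """
    window = max(3, int(window))
    base = minimum_filter1d(intensities, size=window, mode="nearest")
    return uniform_filter1d(base, size=window, mode="nearest")


def detect_bands(
    lane: LaneProfile,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    smooth: bool = True,
) -> BandSet:
    """Detect bands in a lane profile.

    The signal is baseline-corrected (rolling minimum over a window of
    10 x ``min_separation``, then linear smoothing), optionally denoised with
    a short Savitzky-Golay filter for peak *location*, and scanned for local
    maxima with prominence >= ``min_prominence`` x max(corrected signal) and
    pairwise separation >= ``min_separation``. Band bounds are the flanking
    minima between adjacent peaks (or the lane ends); band intensity is the
    trapezoidal area of the *unsmoothed* baseline-corrected signal between
    the bounds.

    Raises
    ------
    NoBandsError
        If no peak passes the thresholds (carries ``lane_id``).
    """
    if not (0 < min_prominence < 1):
        raise InvalidInputError("min_prominence must be in (0, 1)")
    if min_separation <= 0:
        raise InvalidInputError("min_separation must be positive")

    x = lane.positions
    y = lane.intensities
    dx = float(np.median(np.diff(x)))

    base_window = int(round(10.0 * min_separation / dx))
    corrected = y - _estimate_baseline(y, base_window)
    np.clip(corrected, 0.0, None, out=corrected)

    if smooth:
        win = int(round(min_separation / dx))
        win = max(5, win + (win % 2 == 0))  # odd, >= 5
        if win < corrected.size:
            located = savgol_filter(corrected, window_length=win, polyorder=2)
            np.clip(located, 0.0, None, out=located)
        else:
            located = corrected
    else:
        located = corrected

    top = float(located.max())
    if top <= 0:
        raise NoBandsError(lane.lane_id)

    distance = max(1, int(round(min_separation / dx)))
    peaks, _ = find_peaks(
        located, prominence=min_prominence * top, distance=distance
    )
    if peaks.size == 0:
        raise NoBandsError(lane.lane_id)

    # bounds: lowest point of the located signal between adjacent peaks
    cuts = [0]
    for i in range(peaks.size - 1):
        lo, hi = peaks[i], peaks[i + 1]
        cuts.append(lo + int(np.argmin(located[lo : hi + 1])))
    cuts.append(x.size - 1)

    bands = []
    for i, pk in enumerate(peaks):
        li, ri = cuts[i], cuts[i + 1]
        if ri - li < 2:
            continue
        area = float(np.trapezoid(corrected[li : ri + 1], x[li : ri + 1]))
        if area <= 0:
            continue
        left = float(x[li]) if x[li] < x[pk] else float(x[pk]) - dx / 2
        right = float(x[ri]) if x[ri] > x[pk] else float(x[pk]) + dx / 2
        bands.append(
            Band(position=float(x[pk]), intensity=area, left=left, right=right)
        )
    if not bands:
        raise NoBandsError(lane.lane_id)
    return BandSet(lane_id=lane.lane_id, bands=tuple(bands))


# ---------------------------------------------------------------------------
# region calibration and indexing
# ---------------------------------------------------------------------------


def calibrate_regions(
    acidic_ref: BandSet,
    basic_ref: BandSet,
    margin: float = DEFAULT_REGION_MARGIN,
) -> RegionMap:
    """Derive the acidic/neutral/basic partition from the reference drugs.

    The acidic boundary is the most basic darbepoetin band position plus
    ``margin``; the basic boundary is the most acidic epoetin band position
    minus ``margin``; the neutral region is the open interval between them.
    """
    if margin < 0:
        raise InvalidInputError("margin must be non-negative")
    a = max(b.position for b in acidic_ref) + margin
    b = min(bb.position for bb in basic_ref) - margin
    if not (0.0 < a < b < 1.0):
        raise CalibrationError(
            "reference lanes overlap or are inverted: acidic boundary "
            f"candidate a={a:.4f}, basic boundary candidate b={b:.4f}"
        )
    return RegionMap(acidic_max=a, basic_min=b, margin=margin)


def assign_regions_and_index(bands: BandSet, regions: RegionMap) -> BandSet:
    """Label each band's region and index basic bands 1-6.

    Basic-region bands are sorted by position and numbered starting at the
    band nearest the neutral boundary (smallest basic coordinate), increasing
    toward the basic extreme; bands beyond the sixth stay unindexed.
    """
    labelled = [replace(b, region=regions.region_of(b.position)) for b in bands]
    basic = [b for b in labelled if b.region == "basic"]
    index_of = {
        id(b): i + 1
        for i, b in enumerate(sorted(basic, key=lambda b: b.position))
        if i < 6
    }
    out = [
        replace(b, basic_index=index_of.get(id(b))) if b.region == "basic" else b
        for b in labelled
    ]
    return BandSet(lane_id=bands.lane_id, bands=tuple(out))


def select_top3(bands: BandSet) -> tuple[Band, Band, Band]:
    """The three most intense bands, sorted by descending intensity.

    Ties in intensity are broken in favour of the more basic (larger
    coordinate) band; this keeps the rule deterministic on exactly tied
    areas.
    """
    if len(bands) < 3:
        raise InsufficientBandsError(
            f"lane {bands.lane_id!r}: need >= 3 bands for top-3 selection, "
            f"got {len(bands)}"
        )
    ranked = sorted(bands, key=lambda b: (-b.intensity, -b.position))
    return tuple(ranked[:3])


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_profile(
    top3: tuple[Band, Band, Band],
    regions: RegionMap,
    lane_id: str = "",
) -> ProfileCall:
    """Classify a lane from its three most intense bands.

    Decision order:

    1. any top-3 band outside the basic region (neutral or acidic) -> adult;
    2. all basic with index set {3,4,5} -> foetal; {2,3,4} or {1,2,3} -> mixed;
    3. any other all-basic set falls back to the median-index rule:
       median index >= 4 -> foetal, else mixed.

    A top-3 basic band without an index (position rank > 6) is an error.
    """
    if len(top3) != 3:
        raise InvalidInputError("top3 must contain exactly 3 bands")
    for band in top3:
        if band.region is None:
            raise ClassificationError(
                f"lane {lane_id!r}: top-3 band at {band.position:.3f} has no "
                "region label; run assign_regions_and_index first"
            )
    if any(b.region in ("neutral", "acidic") for b in top3):
        return ProfileCall(lane_id, "adult", tuple(top3), "adult_nonbasic_top3")

    # all three basic: classify on the index set
    for band in top3:
        if band.basic_index is None:
            raise ClassificationError(
                f"lane {lane_id!r}: unindexed dominant band at position "
                f"{band.position:.3f} (basic rank > 6)"
            )
    idx = frozenset(b.basic_index for b in top3)
    if idx == frozenset({3, 4, 5}):
        return ProfileCall(lane_id, "foetal", tuple(top3), "foetal_345")
    if idx == frozenset({2, 3, 4}):
        return ProfileCall(lane_id, "mixed", tuple(top3), "mixed_234")
    if idx == frozenset({1, 2, 3}):
        return ProfileCall(lane_id, "mixed", tuple(top3), "mixed_123")
    med = float(np.median(sorted(idx)))
    if med >= 4:
        return ProfileCall(lane_id, "foetal", tuple(top3), "fallback_foetal_median")
    return ProfileCall(lane_id, "mixed", tuple(top3), "fallback_mixed_median")


def call_profile(
    lane: LaneProfile,
    regions: RegionMap,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    smooth: bool = True,
) -> ProfileCall:
    """End-to-end call for one lane: detect, label, select top-3, classify."""
    bands = detect_bands(lane, min_prominence, min_separation, smooth=smooth)
    bands = assign_regions_and_index(bands, regions)
    top3 = select_top3(bands)
    return classify_profile(top3, regions, lane_id=lane.lane_id)


# ---------------------------------------------------------------------------
# scikit-learn style estimators
# ---------------------------------------------------------------------------


class BandDetector(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping lanes to detected band sets.

    Parameters mirror :func:`detect_bands`. ``transform`` accepts an iterable
    of :class:`LaneProfile` and returns a list of :class:`BandSet`.
    """

    def __init__(
        self,
        min_prominence: float = DEFAULT_MIN_PROMINENCE,
        min_separation: float = DEFAULT_MIN_SEPARATION,
        smooth: bool = True,
    ):
        self.min_prominence = min_prominence
        self.min_separation = min_separation
        self.smooth = smooth

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> list[BandSet]:
        return [
            detect_bands(
                lane, self.min_prominence, self.min_separation, smooth=self.smooth
            )
            for lane in X
        ]


class ProfileClassifier(BaseEstimator):
    """Foetal/mixed/adult lane classifier calibrated on reference lanes.

    ``fit`` takes the two reference lanes (any iterable of
    :class:`LaneProfile`; the acidic and basic references are recognised by
    ``lane_kind``), detects their bands and calibrates the region map.
    Alternatively a precomputed :class:`RegionMap` can be supplied via the
    ``regions`` parameter, in which case ``fit`` may be called with no data.

    Reference lanes are detected at the stricter ``ref_min_prominence``
    threshold: the recombinant calibration drugs produce only strong bands,
    and region boundaries must not be dragged by faint noise excursions in
    the otherwise empty stretches of a reference lane.

    Attributes
    ----------
    regions_ : RegionMap
        Calibrated acidic/neutral/basic partition.
    """

    def __init__(
        self,
        min_prominence: float = DEFAULT_MIN_PROMINENCE,
        min_separation: float = DEFAULT_MIN_SEPARATION,
        margin: float = DEFAULT_REGION_MARGIN,
        smooth: bool = True,
        regions: RegionMap | None = None,
        ref_min_prominence: float = 0.25,
    ):
        self.min_prominence = min_prominence
        self.min_separation = min_separation
        self.margin = margin
        self.smooth = smooth
        self.regions = regions
        self.ref_min_prominence = ref_min_prominence

    def fit(self, X=None, y=None):
        if self.regions is not None:
            self.regions_ = self.regions
            return self
        if X is None:
            raise InvalidInputError(
                "fit requires reference lanes when no RegionMap is supplied"
            )
        acidic = [l for l in X if l.lane_kind == "acidic_reference"]
        basic = [l for l in X if l.lane_kind == "basic_reference"]
        if len(acidic) != 1 or len(basic) != 1:
            raise InvalidInputError(
                "fit expects exactly one acidic_reference and one "
                f"basic_reference lane; got {len(acidic)} and {len(basic)}"
            )
        det = BandDetector(
            self.ref_min_prominence, self.min_separation, self.smooth
        )
        acidic_bands, basic_bands = det.transform([acidic[0], basic[0]])
        self.regions_ = calibrate_regions(acidic_bands, basic_bands, self.margin)
        return self

    def predict_calls(self, X) -> list[ProfileCall]:
        if not hasattr(self, "regions_"):
            raise InvalidInputError("ProfileClassifier is not fitted")
        return [
            call_profile(
                lane,
                self.regions_,
                self.min_prominence,
                self.min_separation,
                smooth=self.smooth,
            )
            for lane in X
        ]

    def predict(self, X) -> np.ndarray:
        return np.array([c.profile_class for c in self.predict_calls(X)])
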