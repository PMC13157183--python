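"""Synthetic neonatal cohort: ages, hepatic fraction, and rendered gel lanes.

The generator encodes the developmental model under study: the fraction of
circulating EPO of hepatic origin is a decreasing logistic function of
*developmental age* (gestational age in weeks plus chronological age in
days / 7) and, by construction, carries **zero** partial dependence on
chronological age given developmental age. Within each developmental-age
stratum, chronological age is drawn independently of developmental age (from
the widest day range feasible for every developmental age in the stratum
given the gestational-age limits), so any within-stratum association between
profile class and postnatal oxygen exposure is a pure false positive under
the default settings. The ``oxygen_effect`` switch breaks this on purpose:
with ``oxygen_effect = beta``, each week of postnatal (oxygen-exposed) life
advances the maturation clock by ``beta`` weeks, the alternative hypothesis
in which atmospheric oxygen drives the hepatic-to-renal switch.

Lane rendering is phenomenological: a lane is a sum of Gaussian bands on a
fixed canonical slot grid (2 acidic + 5 neutral + 6 basic slots) plus a
slowly varying polynomial baseline and truncated additive Gaussian noise.
The hepatic component concentrates its three heaviest bands at basic indices
3-5; as the renal fraction grows, the basic-band envelope slides toward the
neutral boundary (indices 2-4, then 1-3) while neutral mass rises, so that
intermediate hepatic fractions produce the mixed patterns and low fractions
the adult (neutral-dominant) pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import ConfigurationError, InvalidInputError
from ..gel import LaneProfile

__all__ = [
    "CohortSimParams",
    "hepatic_fraction",
    "render_lane",
    "simulate_reference_lanes",
    "simulate_cohort",
    "simulate_ct_table",
    "STRATUM_BOUNDS",
]

#: developmental-age sampling bounds per stratum (weeks), half-open (lo, hi]
#: matching the age groups <=37, (37,41], (41,49], >49. The outer limits 29
#: and 54 keep every stratum feasible for plausible gestational ages.
STRATUM_BOUNDS = ((29.0, 37.0), (37.0, 41.0), (41.0, 49.0), (49.0, 54.0))

#: hard physiological limits on gestational age (weeks of amenorrhoea)
GA_HARD_MIN, GA_HARD_MAX = 20.0, 45.0

# canonical band slot grid (normalised coordinate, acidic end at 0)
ACIDIC_SLOTS = np.array([0.08, 0.15])
NEUTRAL_SLOTS = np.array([0.28, 0.34, 0.40, 0.46, 0.52])
BASIC_SLOTS = np.array([0.62, 0.686, 0.752, 0.818, 0.884, 0.95])
ACIDIC_REF_SLOTS = np.array([0.06, 0.11, 0.16, 0.20])

# reference-drug band amplitudes
ACIDIC_REF_AMPS = np.array([0.7, 1.0, 0.9, 0.6])
BASIC_REF_AMPS = np.array([0.5, 0.8, 1.0, 0.9, 0.7, 0.5])

# fixed slot shapes/weights of the lane model (free parameters of the
# phenomenological template; see docs/methods.md)
NEUTRAL_SHAPE = np.array([0.60, 0.85, 1.00, 0.90, 0.65])
ACIDIC_WEIGHTS = np.array([0.08, 0.10])
BASIC_FLOOR = 0.12  # keeps every rendered basic slot detectable
BASIC_ENVELOPE_SIGMA = 1.1  # in index units


@dataclass(frozen=True)
class CohortSimParams:
    """Generative settings for one synthetic cohort.

    Defaults reproduce the study conditions: stratum sizes 34/27/16/12
    (total 89), maturation logistic midpoint 43 weeks and slope 0.5 per week,
    chronological ages 1-92 days.
    """

    n_per_group: tuple[int, int, int, int] = (34, 27, 16, 12)
    logistic_midpoint_m: float = 43.0
    logistic_slope_k: float = 0.5
    ca_range_days: tuple[int, int] = (1, 92)
    ga_range_weeks: tuple[float, float] = (25.0, 44.0)
    lane_noise_sd: float = 0.02
    band_sigma: float = 0.012
    seed: int = 0
    n_points: int = 600
    oxygen_effect: float = 0.0

    def __post_init__(self):
        if len(self.n_per_group) != 4 or any(n < 0 for n in self.n_per_group):
            raise ConfigurationError(
                "n_per_group must be 4 non-negative integers"
            )
        if self.logistic_slope_k <= 0:
            raise ConfigurationError("logistic_slope_k must be > 0")
        if self.band_sigma <= 0:
            raise ConfigurationError("band_sigma must be > 0")
        if self.lane_noise_sd < 0:
            raise ConfigurationError("lane_noise_sd must be >= 0")
        if self.ca_range_days[0] > self.ca_range_days[1]:
            raise ConfigurationError("ca_range_days must be a non-empty interval")
        if self.ga_range_weeks[0] > self.ga_range_weeks[1]:
            raise ConfigurationError("ga_range_weeks must be a non-empty interval")
        if self.n_points < 50:
            raise ConfigurationError("n_points must be >= 50")


def hepatic_fraction(da: float, params: CohortSimParams) -> float:
    """Fraction of circulating EPO of hepatic origin at developmental age ``da``.

    ``h(da) = 1 / (1 + exp(k * (da - m)))`` - strictly decreasing in ``da``
    (weeks) and a function of developmental age only.
    """
    da = float(da)
    if not math.isfinite(da) or da <= 0:
        raise InvalidInputError(
            f"developmental age must be finite and positive, got {da!r}"
        )
    k, m = params.logistic_slope_k, params.logistic_midpoint_m
    z = k * (da - m)
    # exp underflows harmlessly to 0 for very negative z; clamp only the top
    return 1.0 / (1.0 + math.exp(min(z, 700.0)))


def _slot_weights(hepatic_weight: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Band amplitudes on the canonical slot grid for a given hepatic fraction.

    The basic-band envelope is a Gaussian over the index axis whose centre
    slides from index ~4.3 (pure hepatic; top-3 at slots 3-5) down to ~2.5
    (pure renal; residual basic mass near the neutral boundary); neutral
    amplitude rises with the cube of the renal fraction.
    """
    hw = float(hepatic_weight)
    idx = np.arange(1, 7, dtype=float)
    mu = 2.52 + 1.78 * hw  # envelope centre: 4.30 at hw=1, 3.50 at hw=0.55
    env = np.exp(-((idx - mu) ** 2) / (2.0 * BASIC_ENVELOPE_SIGMA**2))
    basic_scale = 0.35 + 0.65 * hw
    basic = basic_scale * (BASIC_FLOOR + (1.0 - BASIC_FLOOR) * env)
    neutral_scale = 0.12 + 0.88 * (1.0 - hw) ** 3
    neutral = neutral_scale * NEUTRAL_SHAPE
    return ACIDIC_WEIGHTS.copy(), neutral, basic


def _render_signal(
    positions: np.ndarray,
    slot_positions: np.ndarray,
    amplitudes: np.ndarray,
    band_sigma: float,
    noise_sd: float,
    rng: np.random.Generator | None,
    baseline: bool = True,
) -> np.ndarray:
    diff = positions[None, :] - slot_positions[:, None]
    signal = amplitudes @ np.exp(-(diff**2) / (2.0 * band_sigma**2))
    if baseline:
        x = positions
        signal = signal + 0.04 + 0.05 * x - 0.04 * x**2
    if noise_sd > 0:
        if rng is None:
            raise InvalidInputError("noise_sd > 0 requires an rng")
        signal = signal + rng.normal(0.0, noise_sd, size=positions.size)
    return np.clip(signal, 0.0, None)


def render_lane(
    hepatic_weight: float,
    params: CohortSimParams,
    lane_id: str = "lane",
    rng: np.random.Generator | None = None,
) -> LaneProfile:
    """Render one sample lane for a given hepatic fraction.

    With zero noise the rendered lane has 11-13 detectable bands (of the 13
    canonical slots, the most basic slots fall below the detection threshold
    as the renal fraction grows); a pure hepatic lane places its three
    heaviest bands at basic indices 3-5 and a pure renal lane puts its
    dominant mass in the neutral region.
    """
    hw = float(hepatic_weight)
    if not math.isfinite(hw) or not (0.0 <= hw <= 1.0):
        raise InvalidInputError(
            f"hepatic_weight must be in [0, 1], got {hepatic_weight!r}"
        )
    if params.lane_noise_sd > 0 and rng is None:
        rng = np.random.default_rng(params.seed)
    acidic, neutral, basic = _slot_weights(hw)
    positions = np.linspace(0.0, 1.0, params.n_points)
    slots = np.concatenate([ACIDIC_SLOTS, NEUTRAL_SLOTS, BASIC_SLOTS])
    amps = np.concatenate([acidic, neutral, basic])
    intensities = _render_signal(
        positions, slots, amps, params.band_sigma, params.lane_noise_sd, rng
    )
    return LaneProfile(lane_id, "sample", positions, intensities)


def simulate_reference_lanes(
    params: CohortSimParams,
    rng: np.random.Generator | None = None,
) -> tuple[LaneProfile, LaneProfile]:
    """Render the darbepoetin (acidic) and epoetin (basic) calibration lanes.

    The two band supports are disjoint by construction, leaving a gap that
    calibration turns into the neutral region.
    """
    if params.lane_noise_sd > 0 and rng is None:
        rng = np.random.default_rng(params.seed)
    positions = np.linspace(0.0, 1.0, params.n_points)
    acidic = LaneProfile(
        "acidic_reference",
        "acidic_reference",
        positions,
        _render_signal(
            positions, ACIDIC_REF_SLOTS, ACIDIC_REF_AMPS,
            params.band_sigma, params.lane_noise_sd, rng,
        ),
    )
    basic = LaneProfile(
        "basic_reference",
        "basic_reference",
        positions,
        _render_signal(
            positions, BASIC_SLOTS, BASIC_REF_AMPS,
            params.band_sigma, params.lane_noise_sd, rng,
        ),
    )
    return acidic, basic


def _stratum_ca_bounds(
    stratum: int, params: CohortSimParams
) -> tuple[int, int]:
    """Chronological-age day range valid for *every* developmental age in the
    stratum, so chronological age can be drawn independently of developmental
    age within the stratum."""
    da_lo, da_hi = STRATUM_BOUNDS[stratum]
    ga_lo = max(params.ga_range_weeks[0], GA_HARD_MIN)
    ga_hi = min(params.ga_range_weeks[1], GA_HARD_MAX)
    lo = max(params.ca_range_days[0], int(math.ceil((da_hi - ga_hi) * 7.0)))
    hi = min(params.ca_range_days[1], int(math.floor((da_lo - ga_lo) * 7.0)))
    if lo > hi:
        raise ConfigurationError(
            f"stratum G{stratum + 1} (developmental age {da_lo}-{da_hi} weeks) "
            "is infeasible: no chronological age in "
            f"[{params.ca_range_days[0]}, {params.ca_range_days[1]}] days is "
            f"compatible with gestational ages in [{ga_lo}, {ga_hi}] weeks"
        )
    return lo, hi


def simulate_cohort(
    params: CohortSimParams,
) -> tuple[pd.DataFrame, list[LaneProfile], tuple[LaneProfile, LaneProfile]]:
    """Simulate a neonatal cohort: age records, sample lanes, reference lanes.

    Returns
    -------
    records : DataFrame
        Columns ``subject_id``, ``gestational_age_weeks``,
        ``chronological_age_days``, ``developmental_age_weeks``,
        ``age_group`` (1-4) and the generative truth
        ``true_hepatic_fraction`` (not visible to the analysis pipeline).
    lanes : list of LaneProfile
        One sample lane per subject, ``lane_id`` equal to ``subject_id``.
    references : (LaneProfile, LaneProfile)
        Acidic and basic reference lanes.
    """
    ca_bounds = [_stratum_ca_bounds(g, params) for g in range(4)]
    root = np.random.SeedSequence(params.seed)
    age_seq, ref_seq, lane_seq = root.spawn(3)
    age_rng = np.random.default_rng(age_seq)

    rows = []
    lanes: list[LaneProfile] = []
    lane_streams = lane_seq.spawn(int(sum(params.n_per_group))) if sum(
        params.n_per_group
    ) else []
    i = 0
    for g, n in enumerate(params.n_per_group):
        da_lo, da_hi = STRATUM_BOUNDS[g]
        ca_lo, ca_hi = ca_bounds[g]
        for _ in range(int(n)):
            da = float(age_rng.uniform(da_lo, da_hi))
            ca = int(age_rng.integers(ca_lo, ca_hi + 1))
            ga = da - ca / 7.0
            exposure_adjusted_da = da + params.oxygen_effect * ca / 7.0
            hw = hepatic_fraction(exposure_adjusted_da, params)
            subject_id = f"S{i + 1:03d}"
            rows.append(
                {
                    "subject_id": subject_id,
                    "gestational_age_weeks": round(ga, 4),
                    "chronological_age_days": ca,
                    "developmental_age_weeks": round(ga, 4) + ca / 7.0,
                    "age_group": g + 1,
                    "true_hepatic_fraction": hw,
                }
            )
            lanes.append(
                render_lane(
                    hw,
                    params,
                    lane_id=subject_id,
                    rng=np.random.default_rng(lane_streams[i]),
                )
            )
            i += 1

    records = pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "gestational_age_weeks",
            "chronological_age_days",
            "developmental_age_weeks",
            "age_group",
            "true_hepatic_fraction",
        ],
    )
    references = simulate_reference_lanes(
        params, rng=np.random.default_rng(ref_seq)
    )
    return records, lanes, references


# ---------------------------------------------------------------------------
# qPCR cycle-threshold table
# ---------------------------------------------------------------------------

REFERENCE_GENES = ("RPLP0", "ACTB", "RPL13A")
_REF_OFFSETS = (-0.5, 0.0, 0.5)


def simulate_ct_table(
    true_rel_expr: pd.DataFrame,
    ref_ct_base: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit a synthetic Ct table consistent with given relative expressions.

    ``true_rel_expr`` is samples x targets (2^-dCt scale, all positive).
    Three reference genes (RPLP0, ACTB, RPL13A) are emitted per sample around
    ``ref_ct_base``; each target's Ct is
    ``mean(reference Cts) - log2(relative expression) + noise``, so
    :func:`epoprofile.organoid.delta_ct` recovers the input exactly at zero
    noise.
    """
    vals = true_rel_expr.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise InvalidInputError(
            "relative expressions must be finite and strictly positive"
        )
    rng = np.random.default_rng(seed)
    n = len(true_rel_expr.index)
    ct = pd.DataFrame(index=true_rel_expr.index.copy())
    for gene, off in zip(REFERENCE_GENES, _REF_OFFSETS):
        ct[gene] = ref_ct_base + off + (
            rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
        )
    ref_mean = ct[list(REFERENCE_GENES)].mean(axis=1)
    for gene in true_rel_expr.columns:
        ct[gene] = ref_mean - np.log2(true_rel_expr[gene].to_numpy()) + (
            rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
        )
    ct.index.name = "sample_id"
    return ct
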