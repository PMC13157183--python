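"""End-to-end pipelines combining the generator and the analysis stages."""

from __future__ import annotations

import pandas as pd

from .cohort import (
    AssociationResult,
    add_age_groups,
    build_contingency,
    test_independence,
)
from .datasets.cohort import CohortSimParams, simulate_cohort
from .gel import ProfileClassifier

__all__ = ["classify_cohort", "cohort_pipeline", "headline_association"]


def classify_cohort(
    records: pd.DataFrame,
    lanes,
    references,
    min_prominence: float = 0.05,
    min_separation: float = 0.015,
    margin: float = 0.02,
) -> pd.DataFrame:
    """Attach profile classes to cohort records by calling every lane.

    The classifier is calibrated on the two reference lanes; sample lanes
    are joined to records on ``subject_id`` == ``lane_id``.
    """
    clf = ProfileClassifier(
        min_prominence=min_prominence,
        min_separation=min_separation,
        margin=margin,
    ).fit(list(references))
    calls = clf.predict_calls(lanes)
    call_df = pd.DataFrame(
        {
            "subject_id": [c.lane_id for c in calls],
            "profile_class": [c.profile_class for c in calls],
            "rule_fired": [c.rule_fired for c in calls],
        }
    )
    out = records.merge(call_df, on="subject_id", how="left")
    return add_age_groups(out)


def cohort_pipeline(
    params: CohortSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, AssociationResult]:
    """Simulate a cohort and run the full profile-calling analysis.

    Render lanes, detect bands, classify profiles, build the 4x3
    age-group x class contingency table and test independence.

    Returns (classified records, contingency table, association result).
    """
    records, lanes, references = simulate_cohort(params)
    classified = classify_cohort(records, lanes, references)
    table = build_contingency(classified)
    assoc = test_independence(table, seed=params.seed)
    return classified, table, assoc


def headline_association(seed: int, params: CohortSimParams | None = None) -> float:
    """P-value of the profile-by-age-group independence test for one
    simulated cohort at the default study conditions."""
    if params is None:
        params = CohortSimParams(seed=seed)
    else:
        params = CohortSimParams(**{**params.__dict__, "seed": seed})
    return cohort_pipeline(params)[2].p_value
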