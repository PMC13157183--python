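"""Reading and writing the package's delimited-text interchange formats.

Lanes travel as long-format TSV (lane_id, lane_kind, position, intensity);
cohort metadata as CSV (subject_id, gestational_age_weeks,
chronological_age_days); counts as a genes x samples TSV with sample
metadata TSV; Ct tables as CSV; marker catalogs and region boundaries as
YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError
from .gel import BandSet, LaneProfile, ProfileCall, RegionMap

__all__ = [
    "write_lanes_tsv",
    "read_lanes_tsv",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_meta_tsv",
    "read_meta_tsv",
    "read_marker_catalog",
    "write_marker_catalog",
    "read_regions_yaml",
    "write_bands_tsv",
    "write_calls_csv",
]


def write_lanes_tsv(lanes, path) -> None:
    frames = [
        pd.DataFrame(
            {
                "lane_id": lane.lane_id,
                "lane_kind": lane.lane_kind,
                "position": lane.positions,
                "intensity": lane.intensities,
            }
        )
        for lane in lanes
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_lanes_tsv(path) -> list[LaneProfile]:
    df = pd.read_csv(path, sep="\t")
    required = {"lane_id", "lane_kind", "position", "intensity"}
    if not required.issubset(df.columns):
        raise InvalidInputError(
            f"lane table must have columns {sorted(required)}"
        )
    lanes = []
    for lane_id, sub in df.groupby("lane_id", sort=False):
        kinds = sub["lane_kind"].unique()
        if len(kinds) != 1:
            raise InvalidInputError(f"lane {lane_id!r} has mixed lane_kind")
        sub = sub.sort_values("position")
        lanes.append(
            LaneProfile(
                str(lane_id),
                str(kinds[0]),
                sub["position"].to_numpy(dtype=float),
                sub["intensity"].to_numpy(dtype=float),
            )
        )
    return lanes


def write_cohort_csv(records: pd.DataFrame, path) -> None:
    cols = [
        c
        for c in (
            "subject_id",
            "gestational_age_weeks",
            "chronological_age_days",
            "developmental_age_weeks",
            "age_group",
            "profile_class",
        )
        if c in records.columns
    ]
    records[cols].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "gestational_age_weeks", "chronological_age_days"}
    if not required.issubset(df.columns):
        raise InvalidInputError(
            f"cohort table must have columns {sorted(required)}"
        )
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene").to_csv(path, sep="\t")


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise InvalidInputError("count matrix has negative entries")
    return df


def write_meta_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_meta_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "day", "condition", "replicate"}
    if not required.issubset(df.columns):
        raise InvalidInputError(
            f"sample metadata must have columns {sorted(required)}"
        )
    return df


def read_marker_catalog(path) -> dict[str, list[str]]:
    with open(path) as fh:
        catalog = yaml.safe_load(fh)
    if not isinstance(catalog, dict) or not all(
        isinstance(v, list) and v for v in catalog.values()
    ):
        raise InvalidInputError(
            "marker catalog must map set names to non-empty gene lists"
        )
    return {str(k): [str(g) for g in v] for k, v in catalog.items()}


def write_marker_catalog(catalog: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(catalog, fh, sort_keys=True)


def read_regions_yaml(path) -> RegionMap:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        return RegionMap(
            acidic_max=float(cfg["a"]),
            basic_min=float(cfg["b"]),
            margin=float(cfg.get("margin", 0.02)),
        )
    except (KeyError, TypeError) as exc:
        raise InvalidInputError(
            "regions YAML must define boundaries 'a' and 'b'"
        ) from exc


def write_bands_tsv(band_sets: list[BandSet], path) -> None:
    rows = [
        {
            "lane_id": bs.lane_id,
            "position": b.position,
            "left": b.left,
            "right": b.right,
            "intensity": b.intensity,
            "region": b.region,
            "basic_index": b.basic_index,
        }
        for bs in band_sets
        for b in bs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_calls_csv(calls: list[ProfileCall], path) -> None:
    rows = [
        {
            "lane_id": c.lane_id,
            "profile_class": c.profile_class,
            "rule_fired": c.rule_fired,
            "top3_positions": ";".join(f"{b.position:.4f}" for b in c.top3),
            "top3_basic_indices": ";".join(
                "-" if b.basic_index is None else str(b.basic_index)
                for b in c.top3
            ),
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
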