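"""Normalisation, trajectories, induction testing, 2^-dCt, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epoprofile.datasets.organoid import OrganoidSimParams, simulate_organoid_counts
from epoprofile.errors import InvalidInputError
from epoprofile.organoid import (
    SizeFactorError,
    SizeFactorNormalizer,
    delta_ct,
    epo_trajectory_summary,
    hypoxia_induction_test,
    markerset_trajectory,
    normalize_counts,
    pca_summary,
    size_factors,
    stabilize,
)


def counts_df(arr, genes=None, samples=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


def tiny_meta(samples, days, conditions, replicates=None):
    return pd.DataFrame(
        {
            "sample_id": samples,
            "day": days,
            "condition": conditions,
            "replicate": replicates or list(range(1, len(samples) + 1)),
        }
    )


# ---------------------------------------------------------------------------
# size factors / normalisation / stabilisation
# ---------------------------------------------------------------------------


def test_identical_samples_have_unit_factors():
    c = counts_df([[10, 10, 10], [5, 5, 5], [100, 100, 100]])
    assert np.allclose(size_factors(c), 1.0)


def test_doubled_sample_closed_form_factors():
    c = counts_df([[10, 20], [4, 8], [7, 14]])
    f = size_factors(c)
    assert f.iloc[0] == pytest.approx(1 / np.sqrt(2))
    assert f.iloc[1] == pytest.approx(np.sqrt(2))
    # normalising equalises the two samples exactly
    norm = normalize_counts(c, f)
    assert np.allclose(norm.iloc[:, 0], norm.iloc[:, 1])


def test_genes_with_zeros_excluded_from_reference():
    # the zero-containing gene would otherwise drag sample 2's median down
    c = counts_df([[10, 20], [4, 8], [1000, 0]])
    f = size_factors(c)
    assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0)


def test_no_zero_free_gene_is_an_error():
    c = counts_df([[0, 5], [5, 0]])
    with pytest.raises(SizeFactorError):
        size_factors(c)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(scale=st.floats(min_value=0.1, max_value=10.0))
def test_size_factor_scale_equivariance(scale):
    """Scaling one sample's counts by c scales its factor relative to every
    other sample by exactly c (factors are defined up to a common rescale)."""
    rng = np.random.default_rng(4)
    base = rng.integers(5, 200, size=(40, 4))
    c = counts_df(base)
    scaled = c.copy().astype(float)
    scaled.iloc[:, 2] *= scale
    f0, f1 = size_factors(c), size_factors(scaled)
    rel0 = f0.iloc[2] / f0.iloc[0]
    rel1 = f1.iloc[2] / f1.iloc[0]
    assert rel1 / rel0 == pytest.approx(scale, rel=1e-9)


def test_renormalisation_is_idempotent():
    rng = np.random.default_rng(9)
    c = counts_df(rng.integers(1, 500, size=(60, 5)))
    norm = normalize_counts(c, size_factors(c))
    assert np.allclose(size_factors(norm), 1.0, atol=1e-6)


@pytest.mark.parametrize("x, expected", [(0.0, 0.0), (1.0, 1.0), (7.0, 3.0)])
def test_stabilize_known_values(x, expected):
    assert stabilize(np.array([x]))[0] == pytest.approx(expected)


def test_size_factor_normalizer_estimator():
    c = counts_df([[10, 20], [4, 8], [7, 14]])
    est = SizeFactorNormalizer().fit(c)
    assert np.allclose(est.size_factors_, [1 / np.sqrt(2), np.sqrt(2)])
    out = est.transform(c)
    assert np.allclose(out.iloc[:, 0], out.iloc[:, 1])


# ---------------------------------------------------------------------------
# marker trajectories
# ---------------------------------------------------------------------------


def test_constant_geneset_gives_constant_trajectory():
    samples = ["a", "b", "c", "d"]
    meta = tiny_meta(samples, [0, 0, 2, 2], ["normoxia"] * 4, [1, 2, 1, 2])
    stab = counts_df([[3.0] * 4, [3.0] * 4], genes=["m1", "m2"], samples=samples)
    traj, warnings = markerset_trajectory(stab, meta, {"set": ["m1", "m2"]})
    assert np.allclose(traj["mean"], 3.0)
    assert np.allclose(traj["sd"], 0.0)
    assert warnings == []


def test_absent_gene_warns_and_absent_set_reported():
    samples = ["a", "b", "c"]
    meta = tiny_meta(samples, [0, 0, 2], ["normoxia"] * 3)
    stab = counts_df([[1.0, 2.0, 3.0]], genes=["m1"], samples=samples)
    traj, warnings = markerset_trajectory(
        stab, meta, {"present": ["m1", "ghost"], "empty": ["nope"]}
    )
    assert any("ghost" in w for w in warnings)
    assert any("empty" in w for w in warnings)
    assert set(traj["set"]) == {"present"}
    with pytest.raises(InvalidInputError):
        markerset_trajectory(stab, meta, {"empty": ["nope"]})


def test_synthetic_maturation_markers_increase():
    counts, meta = simulate_organoid_counts(OrganoidSimParams(seed=2))
    norm = normalize_counts(counts, size_factors(counts))
    traj, _ = markerset_trajectory(
        stabilize(norm), meta, {"maturation": ["ALB", "CYP3A4", "CYP3A7"]}
    )
    nor = traj[(traj["condition"] == "normoxia") & (traj["day"] >= 7)]
    means = nor.sort_values("day")["mean"].to_numpy()
    assert all(a < b for a, b in zip(means, means[1:]))


# ---------------------------------------------------------------------------
# EPO trajectory summary
# ---------------------------------------------------------------------------


def test_constant_gene_peaks_at_earliest_day():
    samples = [f"s{i}" for i in range(8)]
    meta = tiny_meta(
        samples,
        [0, 0, 5, 5, 0, 0, 5, 5],
        ["normoxia"] * 4 + ["hypoxia"] * 4,
        [1, 2, 1, 2, 1, 2, 1, 2],
    )
    norm = counts_df([[4.0] * 8], genes=["EPO"], samples=samples)
    s = epo_trajectory_summary(norm, meta, late_day=5)
    assert s.peak_day == {"normoxia": 0, "hypoxia": 0}
    assert s.decline_ratio["hypoxia"] == pytest.approx(1.0)
    assert not s.late_induction_flag


def test_absent_gene_is_an_error():
    samples = ["a", "b", "c"]
    meta = tiny_meta(samples, [0, 0, 2], ["normoxia"] * 3)
    norm = counts_df([[1.0, 2.0, 3.0]], genes=["x"], samples=samples)
    with pytest.raises(InvalidInputError, match="EPO"):
        epo_trajectory_summary(norm, meta)


def test_synthetic_epo_window():
    counts, meta = simulate_organoid_counts(OrganoidSimParams(seed=5))
    norm = normalize_counts(counts, size_factors(counts))
    s = epo_trajectory_summary(norm, meta)
    assert s.peak_day["hypoxia"] in (11, 13)
    assert s.decline_ratio["hypoxia"] < 0.1
    assert not s.late_induction_flag


# ---------------------------------------------------------------------------
# induction test
# ---------------------------------------------------------------------------


def test_identical_conditions_give_null_result():
    samples = ["h1", "h2", "n1", "n2"]
    meta = tiny_meta(
        samples, [19] * 4, ["hypoxia", "hypoxia", "normoxia", "normoxia"],
        [1, 2, 1, 2],
    )
    c = counts_df([[8, 8, 8, 8], [0, 0, 0, 0], [5, 7, 5, 7]], samples=samples)
    res = hypoxia_induction_test(c, meta, day=19)
    assert res.loc["g0", "log2fc"] == pytest.approx(0.0)
    assert res.loc["g0", "p_value"] == pytest.approx(1.0)
    assert not res.loc["g1", "tested"]
    assert np.isnan(res.loc["g1", "p_value"])


def test_missing_day_is_an_error():
    samples = ["h1", "h2", "n1", "n2"]
    meta = tiny_meta(
        samples, [5] * 4, ["hypoxia", "hypoxia", "normoxia", "normoxia"],
        [1, 2, 1, 2],
    )
    c = counts_df([[1, 2, 3, 4]], samples=samples)
    with pytest.raises(InvalidInputError, match="19"):
        hypoxia_induction_test(c, meta, day=19)


def test_bh_adjustment_monotone_and_bounded():
    counts, meta = simulate_organoid_counts(OrganoidSimParams(seed=3))
    res = hypoxia_induction_test(counts, meta, day=19)
    tested = res[res["tested"]].sort_values("p_value")
    assert (tested["p_adjusted"] >= tested["p_value"] - 1e-12).all()
    assert (tested["p_adjusted"] <= 1.0).all()
    assert tested["p_adjusted"].is_monotonic_increasing


def test_hif_targets_induced_epo_silent_single_run():
    counts, meta = simulate_organoid_counts(OrganoidSimParams(seed=0))
    res = hypoxia_induction_test(counts, meta, day=19)
    for g in ("VEGFA", "EGLN3", "NDRG1", "PDK1", "HK2"):
        assert res.loc[g, "p_adjusted"] < 0.05
        assert res.loc[g, "log2fc"] == pytest.approx(2.0, abs=0.5)
    assert abs(res.loc["EPO", "log2fc"]) < 0.5
    assert res.loc["EPO", "p_adjusted"] > 0.05


# ---------------------------------------------------------------------------
# delta Ct
# ---------------------------------------------------------------------------


def test_delta_ct_closed_form_examples():
    ct = pd.DataFrame(
        {
            "RPLP0": [20.0, 20.0, 20.0],
            "ACTB": [21.0, 21.0, 21.0],
            "RPL13A": [22.0, 22.0, 22.0],
            "EPO": [21.0, 22.0, 20.0],
        },
        index=["s1", "s2", "s3"],
    )
    rel = delta_ct(ct, targets=["EPO"])
    assert rel.loc["s1", "EPO"] == pytest.approx(1.0)  # Ct == mean ref
    assert rel.loc["s2", "EPO"] == pytest.approx(0.5)  # one cycle later
    assert rel.loc["s3", "EPO"] == pytest.approx(2.0)  # refs (20,21,22), Ct 20


def test_missing_reference_ct_names_sample_and_gene():
    ct = pd.DataFrame(
        {"RPLP0": [20.0], "ACTB": [np.nan], "RPL13A": [22.0], "EPO": [20.0]},
        index=["s1"],
    )
    with pytest.raises(InvalidInputError, match="ACTB.*s1"):
        delta_ct(ct)


# ---------------------------------------------------------------------------
# PCA summary
# ---------------------------------------------------------------------------


def test_rank_one_gradient_dominates_pc1():
    rng = np.random.default_rng(12)
    gradient = np.linspace(0, 1, 12)
    loadings = rng.normal(0, 1, 30)
    data = np.outer(loadings, gradient) + rng.normal(0, 0.01, (30, 12))
    samples = [f"s{i}" for i in range(12)]
    stab = counts_df(np.abs(data), samples=samples)
    meta = tiny_meta(samples, list(range(12)), ["normoxia"] * 12)
    out = pca_summary(stab, meta)
    assert out.explained_variance_ratio[0] > 0.9
    assert abs(out.pc1_day_spearman) > 0.95


def test_duplicated_samples_get_identical_scores():
    counts, meta = simulate_organoid_counts(
        OrganoidSimParams(seed=1, timepoints=(0, 9, 19))
    )
    stab = stabilize(normalize_counts(counts, size_factors(counts)))
    dup = stab.copy()
    dup["copycat"] = dup.iloc[:, 0]
    meta2 = pd.concat(
        [meta, meta.iloc[[0]].assign(sample_id="copycat", replicate=99)],
        ignore_index=True,
    )
    out = pca_summary(dup, meta2)
    assert np.allclose(
        out.scores.iloc[0].to_numpy(), out.scores.loc["copycat"].to_numpy()
    )


def test_pca_requires_three_samples():
    stab = counts_df([[1.0, 2.0]], samples=["a", "b"])
    meta = tiny_meta(["a", "b"], [0, 2], ["normoxia"] * 2)
    with pytest.raises(InvalidInputError):
        pca_summary(stab, meta)


def test_organoid_pca_orders_samples_by_day():
    counts, meta = simulate_organoid_counts(OrganoidSimParams(seed=7))
    stab = stabilize(normalize_counts(counts, size_factors(counts)))
    out = pca_summary(stab, meta)
    assert abs(out.pc1_day_spearman) > 0.8
    assert out.mean_within_group_distance < out.mean_between_group_distance
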