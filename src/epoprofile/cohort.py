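"""Cohort statistics: age groups, contingency analysis, decoupling test,
maturation-logistic recovery.

Developmental age is the sum of gestational age (weeks of amenorrhoea) and
chronological age (days since birth, divided by 7). Subjects are binned into
four ordered developmental-age groups, <=37 / (37,41] / (41,49] / >49 weeks,
and their foetal/mixed/adult profile classes are cross-tabulated. The
independence test is a Pearson chi-square without continuity correction; when
any expected count drops below 5 the method switches to an exact test
(Fisher for 2x2) or a seeded Monte-Carlo permutation null of the chi-square
statistic for larger tables.

The oxygen-decoupling test asks, within each developmental-age stratum,
whether the profile class carries information about chronological age (i.e.
about the duration of postnatal oxygen exposure): a rank-based comparison of
chronological age across the classes observed in the stratum. Under the
developmental hypothesis these within-stratum tests should reject at the
nominal rate only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import InvalidInputError

__all__ = [
    "AGE_GROUP_LABELS",
    "assign_age_group",
    "add_age_groups",
    "build_contingency",
    "AssociationResult",
    "test_independence",
    "proportions_by_group",
    "DecouplingReport",
    "test_oxygen_decoupling",
    "MaturationFit",
    "MaturationLogistic",
    "fit_maturation_logistic",
]

AGE_GROUP_LABELS = ("<=37", "(37,41]", "(41,49]", ">49")
_CLASS_ORDER = ("foetal", "mixed", "adult")


def assign_age_group(developmental_age_weeks: float) -> str:
    """Ordered developmental-age group of one subject.

    Half-open binning: da <= 37 -> "<=37"; 37 < da <= 41 -> "(37,41]";
    41 < da <= 49 -> "(41,49]"; da > 49 -> ">49".
    """
    da = float(developmental_age_weeks)
    if not np.isfinite(da) or da <= 0:
        raise InvalidInputError(
            f"developmental age must be positive and finite, got {da!r}"
        )
    if da <= 37:
        return AGE_GROUP_LABELS[0]
    if da <= 41:
        return AGE_GROUP_LABELS[1]
    if da <= 49:
        return AGE_GROUP_LABELS[2]
    return AGE_GROUP_LABELS[3]


def _developmental_age(records: pd.DataFrame) -> pd.Series:
    if "developmental_age_weeks" in records:
        da = records["developmental_age_weeks"].astype(float)
    else:
        da = (
            records["gestational_age_weeks"].astype(float)
            + records["chronological_age_days"].astype(float) / 7.0
        )
    bad = records.loc[~np.isfinite(da) | (da <= 0)]
    if len(bad):
        ids = ", ".join(map(str, bad.get("subject_id", bad.index)))
        raise InvalidInputError(f"invalid ages for subject(s): {ids}")
    return da


def add_age_groups(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with ``developmental_age_weeks`` and ``age_group`` columns."""
    out = records.copy()
    da = _developmental_age(out)
    out["developmental_age_weeks"] = da
    out["age_group"] = pd.Categorical(
        [assign_age_group(v) for v in da],
        categories=list(AGE_GROUP_LABELS),
        ordered=True,
    )
    return out


def build_contingency(records: pd.DataFrame) -> pd.DataFrame:
    """4x3 table of age group x profile class counts.

    Every record must carry a ``profile_class``; rows are the four ordered
    age groups (empty rows kept as zeros), columns foetal/mixed/adult.
    """
    if len(records) == 0:
        return pd.DataFrame(
            0,
            index=pd.Index(AGE_GROUP_LABELS, name="age_group"),
            columns=pd.Index(_CLASS_ORDER, name="profile_class"),
        )
    if "profile_class" not in records:
        raise InvalidInputError("records lack a profile_class column")
    missing = records.loc[
        records["profile_class"].isna()
        | ~records["profile_class"].isin(_CLASS_ORDER)
    ]
    if len(missing):
        ids = ", ".join(map(str, missing.get("subject_id", missing.index)))
        raise InvalidInputError(f"unclassified record(s): {ids}")
    recs = records if "age_group" in records else add_age_groups(records)
    table = pd.crosstab(recs["age_group"], recs["profile_class"])
    table = table.reindex(
        index=list(AGE_GROUP_LABELS), columns=list(_CLASS_ORDER), fill_value=0
    )
    table.index.name = "age_group"
    table.columns.name = "profile_class"
    return table


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of the profile-by-age-group independence test."""

    method: str  # "chi_square" or "fisher_exact_or_permutation"
    statistic: float
    degrees_of_freedom: int | None
    p_value: float
    expected_counts: pd.DataFrame
    min_expected: float
    n_permutations: int | None = None


def _chi_square_stat(observed: np.ndarray) -> tuple[float, np.ndarray]:
    total = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    return float(cells.sum()), expected


def test_independence(
    table: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> AssociationResult:
    """Chi-square test of independence with an exact/permutation fallback.

    Rows and columns with zero totals are dropped before testing. If the
    smallest expected count is below 5 the asymptotic chi-square is replaced
    by Fisher's exact test (2x2 tables) or a seeded Monte-Carlo permutation
    null of the chi-square statistic (>= ``n_permutations`` label
    permutations) for larger tables.
    """
    obs_df = table.loc[
        table.sum(axis=1) > 0, table.sum(axis=0).gt(0).to_numpy()
    ]
    observed = obs_df.to_numpy(dtype=float)
    if observed.sum() < 1:
        raise InvalidInputError("contingency table has a zero grand total")

    statistic, expected = _chi_square_stat(observed)
    expected_df = pd.DataFrame(
        expected, index=obs_df.index.copy(), columns=obs_df.columns.copy()
    )
    min_expected = float(expected.min()) if expected.size else 0.0
    r, c = observed.shape
    df = (r - 1) * (c - 1)

    if r < 2 or c < 2:
        # degenerate after dropping empty margins: nothing to test
        return AssociationResult(
            "chi_square", 0.0, 0, 1.0, expected_df, min_expected
        )

    if min_expected >= 5:
        p = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
        return AssociationResult(
            "chi_square", statistic, df, p, expected_df, min_expected
        )

    if (r, c) == (2, 2):
        _, p = stats.fisher_exact(observed.astype(int))
        return AssociationResult(
            "fisher_exact_or_permutation",
            statistic,
            None,
            float(p),
            expected_df,
            min_expected,
        )

    # Monte-Carlo permutation null of the chi-square statistic
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(
        np.arange(r), observed.sum(axis=1).astype(int)
    )
    col_labels = np.repeat(np.arange(c), observed.sum(axis=0).astype(int))
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(col_labels)
        counts = np.bincount(row_labels * c + perm, minlength=r * c).reshape(r, c)
        stat_perm, _ = _chi_square_stat(counts.astype(float))
        if stat_perm >= statistic - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return AssociationResult(
        "fisher_exact_or_permutation",
        statistic,
        None,
        float(p),
        expected_df,
        min_expected,
        n_permutations=n_permutations,
    )


def proportions_by_group(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-group class percentages (rows summing to 100).

    Groups with zero totals are excluded from the output and returned in the
    flag list.
    """
    totals = table.sum(axis=1)
    flagged = [str(g) for g in table.index[totals == 0]]
    kept = table.loc[totals > 0]
    pct = kept.div(kept.sum(axis=1), axis=0) * 100.0
    return pct, flagged


@dataclass(frozen=True)
class StratumTest:
    age_group: str
    n: int
    classes: tuple[str, ...]
    test: str  # "kruskal_wallis" or "wilcoxon_rank_sum"
    statistic: float
    p_value: float


@dataclass(frozen=True)
class DecouplingReport:
    """Per-stratum association of profile class with chronological age."""

    strata: tuple[StratumTest, ...]
    skipped: tuple[str, ...]
    alpha: float
    fraction_significant: float
    adjusted: bool


def test_oxygen_decoupling(
    records: pd.DataFrame,
    alpha: float = 0.05,
    bh_adjust: bool = False,
) -> DecouplingReport:
    """Test, within developmental-age strata, whether profile class tracks
    chronological age.

    Within each stratum with at least two observed classes, chronological
    age is compared across classes by a Kruskal-Wallis test (Wilcoxon
    rank-sum when exactly two classes are present). Strata with a single
    class are skipped with a notice. ``fraction_significant`` is the share
    of tested strata with p < ``alpha``; no multiplicity correction is
    applied unless ``bh_adjust`` is set.
    """
    recs = records if "age_group" in records else add_age_groups(records)
    if "profile_class" not in recs:
        raise InvalidInputError("records lack a profile_class column")
    sizes = recs.groupby("age_group", observed=True).size()
    if (sizes >= 4).sum() < 2:
        raise InvalidInputError(
            "need at least 2 strata with at least 4 records each"
        )

    tests: list[StratumTest] = []
    skipped: list[str] = []
    for group, sub in recs.groupby("age_group", observed=True):
        classes = [
            c for c in _CLASS_ORDER if (sub["profile_class"] == c).any()
        ]
        if len(classes) < 2 or len(sub) < 4:
            skipped.append(str(group))
            continue
        samples = [
            sub.loc[sub["profile_class"] == c, "chronological_age_days"]
            .astype(float)
            .to_numpy()
            for c in classes
        ]
        if len(classes) == 2:
            stat, p = stats.mannwhitneyu(
                samples[0], samples[1], alternative="two-sided"
            )
            name = "wilcoxon_rank_sum"
        else:
            stat, p = stats.kruskal(*samples)
            name = "kruskal_wallis"
        tests.append(
            StratumTest(
                str(group), len(sub), tuple(classes), name, float(stat), float(p)
            )
        )

    pvals = np.array([t.p_value for t in tests])
    if bh_adjust and len(pvals):
        pvals = multipletests(pvals, method="fdr_bh")[1]
    frac = float(np.mean(pvals < alpha)) if len(pvals) else float("nan")
    return DecouplingReport(
        tuple(tests), tuple(skipped), alpha, frac, bh_adjust
    )


# the test_* operation names follow the analysis vocabulary, not pytest's
test_independence.__test__ = False
test_oxygen_decoupling.__test__ = False


# ---------------------------------------------------------------------------
# maturation logistic recovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaturationFit:
    """Recovered parameters of the maturation logistic h(da)."""

    midpoint: float
    slope_k: float
    midpoint_ci: tuple[float, float] | None
    slope_ci: tuple[float, float] | None
    converged: bool
    separation: bool
    n: int


class MaturationLogistic(BaseEstimator):
    """Maximum-likelihood logistic fit of foetal status on developmental age.

    The generative model has P(foetal-like EPO) decreasing in developmental
    age as ``h(da) = 1 / (1 + exp(k (da - m)))``. Fitting
    ``P(foetal) = sigmoid(b0 + b1 da)`` gives ``k = -b1`` and
    ``m = -b0 / b1``; Wald confidence intervals for ``m`` come from the
    delta method.

    When the classes are (quasi-)separated in developmental age the MLE
    diverges; the fit is then flagged, confidence intervals are suppressed,
    and the midpoint is estimated as the centre of the error-minimising
    threshold interval (the ML step-function boundary).

    Attributes
    ----------
    midpoint_, slope_k_ : float
        Recovered logistic midpoint (weeks) and slope (per week).
    converged_, separation_ : bool
    midpoint_ci_, slope_ci_ : tuple or None
        95% Wald intervals (suppressed on separation).
    """

    def __init__(self, alpha: float = 0.05, max_abs_slope: float = 50.0):
        self.alpha = alpha
        self.max_abs_slope = max_abs_slope

    def fit(self, X, y):
        da = np.asarray(X, dtype=float).reshape(-1)
        foetal = np.asarray(y).astype(bool).astype(float)
        if da.shape[0] != foetal.shape[0]:
            raise InvalidInputError("X and y must have equal length")
        if da.shape[0] < 30:
            raise InvalidInputError("need >= 30 classified records")
        if da.max() - da.min() < 10:
            raise InvalidInputError(
                "records must span >= 10 weeks of developmental age"
            )
        self.n_ = int(da.shape[0])

        if foetal.min() == foetal.max():
            # single class: nothing to regress on
            self.converged_ = False
            self.separation_ = True
            self.midpoint_ = float("nan")
            self.slope_k_ = float("nan")
            self.midpoint_ci_ = None
            self.slope_ci_ = None
            return self

        design = sm.add_constant(da)
        separated = False
        params = cov = None
        converged = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(foetal, design).fit(disp=0, maxiter=200)
                params, cov = res.params, res.cov_params()
                converged = bool(res.mle_retvals.get("converged", False))
            except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
                separated = True

        if not separated:
            b0, b1 = float(params[0]), float(params[1])
            # a diverging or non-negative slope means the smooth fit failed
            usable = (
                np.isfinite(b0)
                and np.isfinite(b1)
                and b1 < 0
                and abs(b1) <= self.max_abs_slope
            )
            if usable:
                self.slope_k_ = -b1
                self.midpoint_ = -b0 / b1
                z = stats.norm.ppf(1 - self.alpha / 2)
                var_b0 = float(np.asarray(cov)[0, 0])
                var_b1 = float(np.asarray(cov)[1, 1])
                cov_b = float(np.asarray(cov)[0, 1])
                # delta method for m = -b0/b1
                gm = np.array([-1.0 / b1, b0 / b1**2])
                var_m = (
                    gm[0] ** 2 * var_b0
                    + gm[1] ** 2 * var_b1
                    + 2 * gm[0] * gm[1] * cov_b
                )
                se_m = float(np.sqrt(max(var_m, 0.0)))
                se_k = float(np.sqrt(max(var_b1, 0.0)))
                self.midpoint_ci_ = (self.midpoint_ - z * se_m, self.midpoint_ + z * se_m)
                self.slope_ci_ = (self.slope_k_ - z * se_k, self.slope_k_ + z * se_k)
                self.converged_ = converged
                self.separation_ = False
                return self

        # separation fallback: ML step-function boundary
        order = np.argsort(da)
        da_s, f_s = da[order], foetal[order]
        candidates = (da_s[1:] + da_s[:-1]) / 2.0
        # errors of the rule "foetal iff da <= t"
        best_t, best_err = candidates[0], np.inf
        cum_foetal = np.cumsum(f_s)
        total_foetal = cum_foetal[-1]
        for i, t in enumerate(candidates):
            n_le = i + 1
            err = (n_le - cum_foetal[i]) + (total_foetal - cum_foetal[i])
            if err < best_err:
                best_t, best_err = t, err
        self.converged_ = False
        self.separation_ = True
        self.midpoint_ = float(best_t)
        self.slope_k_ = float("inf")
        self.midpoint_ci_ = None
        self.slope_ci_ = None
        return self

    def result_(self) -> MaturationFit:
        return MaturationFit(
            midpoint=self.midpoint_,
            slope_k=self.slope_k_,
            midpoint_ci=self.midpoint_ci_,
            slope_ci=self.slope_ci_,
            converged=self.converged_,
            separation=self.separation_,
            n=self.n_,
        )


def fit_maturation_logistic(records: pd.DataFrame) -> MaturationFit:
    """Recover the maturation logistic from classified records.

    Regresses the binary response "foetal vs not" on developmental age; see
    :class:`MaturationLogistic`.
    """
    recs = records if "developmental_age_weeks" in records else add_age_groups(records)
    if "profile_class" not in recs:
        raise InvalidInputError("records lack a profile_class column")
    da = recs["developmental_age_weeks"].to_numpy(dtype=float)
    y = (recs["profile_class"] == "foetal").to_numpy()
    est = MaturationLogistic().fit(da, y)
    return est.result_()
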