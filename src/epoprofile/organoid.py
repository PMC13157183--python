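"""Organoid time-course expression analysis.

Counts are normalised by median-of-ratios size factors (per-gene geometric
mean pseudo-reference over zero-free genes), stabilised as
``log2(normalised + 1)``, and summarised three ways: marker-set mean
trajectories across days and conditions, an EPO competence-window summary
(peak day, decline ratio, late hypoxia inducibility), and a PCA of the
stabilised matrix with stage-vs-condition diagnostics. Differential hypoxia
induction at a fixed day is a per-gene Welch test on stabilised values with
Benjamini-Hochberg adjustment, with the log2 fold change computed on
normalised condition means (+0.5 pseudocount). qPCR quantification uses the
2^-dCt method against the mean of three reference genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import EpoProfileError, InvalidInputError

__all__ = [
    "size_factors",
    "normalize_counts",
    "stabilize",
    "SizeFactorNormalizer",
    "markerset_trajectory",
    "EpoTrajectorySummary",
    "epo_trajectory_summary",
    "hypoxia_induction_test",
    "delta_ct",
    "PcaSummary",
    "pca_summary",
    "DEFAULT_REFERENCE_GENES",
]

DEFAULT_REFERENCE_GENES = ("RPLP0", "ACTB", "RPL13A")


class SizeFactorError(EpoProfileError):
    """No gene is positive in every sample, so the median-of-ratios
    pseudo-reference is undefined. Consider supplying a pre-filtered matrix
    restricted to ubiquitously detected genes, or pooling replicates; no
    fallback is applied silently."""


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise InvalidInputError("duplicate gene or sample identifiers")
    vals = counts.to_numpy()
    if np.any(vals < 0):
        raise InvalidInputError("counts must be non-negative")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The pseudo-reference is the per-gene geometric mean over samples,
    computed only on genes with no zero count; each sample's factor is the
    median over those genes of count / reference, rescaled to unit geometric
    mean so that re-estimating factors on an already-normalised matrix
    returns factors of exactly 1.
    """
    _check_counts(counts)
    if counts.shape[1] < 2:
        raise InvalidInputError("need at least 2 samples")
    vals = counts.to_numpy(dtype=float)
    allpos = (vals > 0).all(axis=1)
    if not allpos.any():
        raise SizeFactorError(str(SizeFactorError.__doc__))
    logs = np.log(vals[allpos])
    log_ref = logs.mean(axis=1, keepdims=True)
    log_factors = np.median(logs - log_ref, axis=0)
    factors = np.exp(log_factors - log_factors.mean())
    return pd.Series(factors, index=counts.columns.copy(), name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    f = factors.reindex(counts.columns)
    if f.isna().any() or (f <= 0).any():
        raise InvalidInputError("size factors must be positive for all samples")
    return counts / f


def stabilize(normalized: pd.DataFrame | np.ndarray):
    """Variance-stabilising transform ``log2(x + 1)`` (monotone, 0 -> 0)."""
    arr = np.asarray(normalized, dtype=float)
    if np.any(arr < 0):
        raise InvalidInputError("stabilize expects non-negative input")
    out = np.log2(arr + 1.0)
    if isinstance(normalized, pd.DataFrame):
        return pd.DataFrame(out, index=normalized.index, columns=normalized.columns)
    return out


class SizeFactorNormalizer(BaseEstimator, TransformerMixin):
    """Estimator wrapper around median-of-ratios normalisation.

    ``fit`` learns per-sample factors (``size_factors_``); ``transform``
    returns the normalised matrix, stabilised to ``log2(x + 1)`` when
    ``stabilize=True``.
    """

    def __init__(self, stabilize: bool = False):
        self.stabilize = stabilize

    def fit(self, X: pd.DataFrame, y=None):
        self.size_factors_ = size_factors(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = normalize_counts(X, self.size_factors_)
        return stabilize(out) if self.stabilize else out


def _check_meta(counts: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    m = meta.set_index("sample_id") if "sample_id" in meta else meta
    missing = [s for s in counts.columns if s not in m.index]
    if missing:
        raise InvalidInputError(f"samples missing from metadata: {missing}")
    return m.loc[counts.columns]


def markerset_trajectory(
    stabilized: pd.DataFrame,
    meta: pd.DataFrame,
    catalog: dict[str, list[str]],
) -> tuple[pd.DataFrame, list[str]]:
    """Mean stabilised expression of each marker set per (day, condition).

    For each set the per-sample score is the mean over member genes present
    in the matrix; the trajectory reports mean, sd and n over replicates.
    Catalog genes absent from the matrix are excluded with a warning record;
    sets with no present gene are reported in the warnings, not silently
    dropped. An empty intersection for every set is an error.
    """
    m = _check_meta(stabilized, meta)
    warnings: list[str] = []
    rows = []
    any_present = False
    for set_name, genes in catalog.items():
        present = [g for g in genes if g in stabilized.index]
        absent = sorted(set(genes) - set(present))
        if absent:
            warnings.append(
                f"{set_name}: genes absent from matrix: {', '.join(absent)}"
            )
        if not present:
            warnings.append(f"{set_name}: no member genes present; set not reported")
            continue
        any_present = True
        score = stabilized.loc[present].mean(axis=0)
        for (day, cond), idx in m.groupby(["day", "condition"], observed=True).groups.items():
            vals = score.loc[idx].to_numpy(dtype=float)
            rows.append(
                {
                    "set": set_name,
                    "day": day,
                    "condition": cond,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "n": len(vals),
                }
            )
    if not any_present:
        raise InvalidInputError(
            "no catalog gene is present in the matrix for any set"
        )
    traj = pd.DataFrame(rows).sort_values(["set", "day", "condition"]).reset_index(
        drop=True
    )
    return traj, warnings


@dataclass(frozen=True)
class EpoTrajectorySummary:
    """Peak day, decline ratio and late-inducibility of one gene (EPO)."""

    gene: str
    peak_day: dict[str, int]
    decline_ratio: dict[str, float]
    late_day: int
    late_induction_flag: bool
    late_log2fc: float
    late_p_value: float


def epo_trajectory_summary(
    normalized: pd.DataFrame,
    meta: pd.DataFrame,
    gene: str = "EPO",
    late_day: int | None = None,
    alpha: float = 0.05,
) -> EpoTrajectorySummary:
    """Summarise the competence window of ``gene`` (default EPO).

    Per condition: ``peak_day`` is the day with maximal replicate-mean
    normalised expression (ties to the earliest day) and ``decline_ratio``
    the last-day mean divided by the peak mean. The late-induction flag
    reports whether hypoxia exceeds normoxia at ``late_day`` (default: the
    last day) by a single-gene Welch test on stabilised values.
    """
    if gene not in normalized.index:
        raise InvalidInputError(f"gene {gene!r} absent from matrix")
    m = _check_meta(normalized, meta)
    expr = normalized.loc[gene]
    days = np.sort(m["day"].unique())
    if late_day is None:
        late_day = int(days[-1])

    peak_day: dict[str, int] = {}
    decline: dict[str, float] = {}
    for cond, sub in m.groupby("condition", observed=True):
        cond_days = np.sort(sub["day"].unique())
        if len(cond_days) < 2:
            raise InvalidInputError(
                f"condition {cond!r} has fewer than 2 timepoints"
            )
        means = expr.loc[sub.index].groupby(sub["day"]).mean()
        means = means.loc[cond_days]
        peak = int(cond_days[int(np.argmax(means.to_numpy()))])  # argmax: first max
        peak_day[str(cond)] = peak
        peak_mean = float(means.loc[peak])
        last_mean = float(means.loc[cond_days[-1]])
        decline[str(cond)] = last_mean / peak_mean if peak_mean > 0 else float("nan")

    hyp = expr.loc[m.index[(m["day"] == late_day) & (m["condition"] == "hypoxia")]]
    nor = expr.loc[m.index[(m["day"] == late_day) & (m["condition"] == "normoxia")]]
    log2fc = float(np.log2((hyp.mean() + 0.5) / (nor.mean() + 0.5)))
    hs, ns = np.log2(hyp.to_numpy() + 1.0), np.log2(nor.to_numpy() + 1.0)
    if len(hs) >= 2 and len(ns) >= 2 and (np.ptp(hs) > 0 or np.ptp(ns) > 0):
        _, p = stats.ttest_ind(hs, ns, equal_var=False)
        p = float(p)
    else:
        p = 1.0
    flag = bool(hyp.mean() > nor.mean() and p < alpha)
    return EpoTrajectorySummary(
        gene=gene,
        peak_day=peak_day,
        decline_ratio=decline,
        late_day=int(late_day),
        late_induction_flag=flag,
        late_log2fc=log2fc,
        late_p_value=p,
    )


def hypoxia_induction_test(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    day: int = 19,
) -> pd.DataFrame:
    """Per-gene hypoxia-vs-normoxia induction test at a fixed day.

    Size factors are estimated on the full matrix; at the chosen day the
    log2 fold change is computed from normalised condition means with a 0.5
    pseudocount, and the p-value from a Welch two-sample test on stabilised
    values, adjusted across tested genes by Benjamini-Hochberg. Genes with
    all-zero counts in both groups are reported with ``tested = False`` and
    excluded from the adjustment.
    """
    m = _check_meta(counts, meta)
    if day not in set(m["day"]):
        raise InvalidInputError(f"day {day} absent from metadata")
    norm = normalize_counts(counts, size_factors(counts))
    hyp_cols = m.index[(m["day"] == day) & (m["condition"] == "hypoxia")]
    nor_cols = m.index[(m["day"] == day) & (m["condition"] == "normoxia")]
    if len(hyp_cols) < 2 or len(nor_cols) < 2:
        raise InvalidInputError(
            f"need >= 2 replicates per condition at day {day}"
        )

    h_counts = counts[hyp_cols].to_numpy()
    n_counts = counts[nor_cols].to_numpy()
    h_norm = norm[hyp_cols].to_numpy()
    n_norm = norm[nor_cols].to_numpy()
    tested = (h_counts.sum(axis=1) + n_counts.sum(axis=1)) > 0

    log2fc = np.log2((h_norm.mean(axis=1) + 0.5) / (n_norm.mean(axis=1) + 0.5))
    h_stab = np.log2(h_norm + 1.0)
    n_stab = np.log2(n_norm + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(h_stab, n_stab, axis=1, equal_var=False)
    pvals = np.asarray(pvals, dtype=float)
    # identical values in both groups carry no evidence: p = 1
    degenerate = np.isnan(pvals) & tested
    pvals[degenerate] = 1.0
    pvals[~tested] = np.nan

    padj = np.full_like(pvals, np.nan)
    if tested.any():
        padj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "log2fc": np.where(tested, log2fc, np.nan),
            "p_value": pvals,
            "p_adjusted": padj,
            "tested": tested,
        },
        index=counts.index.copy(),
    )
    out.index.name = "gene"
    return out


def delta_ct(
    ct: pd.DataFrame,
    targets: list[str] | None = None,
    reference_genes: tuple[str, str, str] = DEFAULT_REFERENCE_GENES,
) -> pd.DataFrame:
    """Relative expression by the 2^-dCt method.

    ``dCt = Ct_target - mean(Ct of the three reference genes)`` per sample;
    relative expression is ``2 ** -dCt``. ``ct`` is samples x genes.
    """
    if len(reference_genes) != 3:
        raise InvalidInputError("exactly three reference genes are required")
    for g in reference_genes:
        if g not in ct.columns:
            raise InvalidInputError(f"reference gene {g!r} missing from Ct table")
        bad = ct.index[ct[g].isna()]
        if len(bad):
            raise InvalidInputError(
                f"missing Ct for reference gene {g!r} in sample(s): "
                f"{', '.join(map(str, bad))}"
            )
    if targets is None:
        targets = [c for c in ct.columns if c not in reference_genes]
    for t in targets:
        if t not in ct.columns:
            raise InvalidInputError(f"target gene {t!r} missing from Ct table")
        bad = ct.index[ct[t].isna()]
        if len(bad):
            raise InvalidInputError(
                f"missing Ct for target {t!r} in sample(s): "
                f"{', '.join(map(str, bad))}"
            )
    ref_mean = ct[list(reference_genes)].mean(axis=1)
    rel = pd.DataFrame(index=ct.index.copy())
    for t in targets:
        rel[t] = 2.0 ** -(ct[t] - ref_mean)
    return rel


@dataclass(frozen=True)
class PcaSummary:
    """PCA of samples with stage-vs-condition diagnostics."""

    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame
    pc1_day_spearman: float
    mean_within_group_distance: float
    mean_between_group_distance: float


def pca_summary(
    stabilized: pd.DataFrame,
    meta: pd.DataFrame,
    n_components: int | None = None,
) -> PcaSummary:
    """PCA of gene-centred stabilised expression, samples as observations.

    Genes are centred but not scaled (the dominant trajectory structure is
    the signal of interest). Diagnostics: Spearman rank correlation of the
    PC1 score with day, and the mean within-(day, condition) replicate
    distance versus the mean between-group distance of group centroids, in
    the reported component space.
    """
    if stabilized.shape[1] < 3:
        raise InvalidInputError("need at least 3 samples for PCA")
    m = _check_meta(stabilized, meta)
    X = stabilized.to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    k = n_components or min(10, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    scores_df = pd.DataFrame(
        scores,
        index=stabilized.columns.copy(),
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    rho = stats.spearmanr(scores[:, 0], m["day"].to_numpy()).statistic

    groups = m.groupby(["day", "condition"], observed=True).groups
    within = []
    centroids = []
    for idx in groups.values():
        pts = scores_df.loc[idx].to_numpy()
        centroids.append(pts.mean(axis=0))
        if len(pts) > 1:
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            within.append(d[np.triu_indices(len(pts), 1)].mean())
    cen = np.asarray(centroids)
    dc = np.sqrt(((cen[:, None, :] - cen[None, :, :]) ** 2).sum(-1))
    between = float(dc[np.triu_indices(len(cen), 1)].mean()) if len(cen) > 1 else float("nan")
    return PcaSummary(
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=scores_df,
        pc1_day_spearman=float(rho),
        mean_within_group_distance=float(np.mean(within)) if within else float("nan"),
        mean_between_group_distance=between,
    )
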