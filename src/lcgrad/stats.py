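"""Cohort-level statistics on trend-surface parameters of group gradients.

Implements the group-based analysis scheme: per-year-of-age average gradients
regressed against age, a sliding-window analysis linking windowed gradients to
behavioral scores via nested F-tests and partial Spearman correlations,
per-subject gradient clusterability (1-D k-means + Calinski-Harabasz), and a
bootstrap MANOVA contrast between screening-defined groups, with
Benjamini-Hochberg FDR control over the trend-surface parameter family.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import trend
from .trend import TSM_TERMS

logger = logging.getLogger(__name__)

__all__ = [
    "rank_transform",
    "partial_spearman",
    "NestedFTestResult",
    "nested_f_test",
    "sliding_windows",
    "WindowBehaviorResult",
    "window_behavior_analysis",
    "AgeAnalysisResult",
    "per_year_age_analysis",
    "calinski_harabasz",
    "ClusterabilityResult",
    "clusterability_vs_age",
    "bh_fdr",
    "mann_whitney",
    "ManovaResult",
    "manova_oneway",
    "GroupComparisonResult",
    "bootstrap_group_comparison",
    "PARAM_NAMES",
]

PARAM_NAMES = tuple(f"{h}_{t}" for h in ("left", "right") for t in TSM_TERMS)


def rank_transform(x) -> np.ndarray:
    """Average ranks (ties share their mean rank), in [1, n]."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to rank")
    return sps.rankdata(x)


def _residualize(v: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    n = v.size
    X = np.ones((n, 1))
    if covariates is not None and covariates.size:
        X = np.column_stack([X, covariates])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_spearman(x, y, covariates=None) -> tuple[float, float]:
    """Spearman rank correlation after removing linear covariate effects.

    x, y and the covariates are rank-transformed; x and y ranks are each
    residualized on [intercept, covariate ranks] by least squares, and rho is
    the Pearson correlation of the residuals; p comes from the t distribution
    with n - 2 - n_covariates degrees of freedom. With no covariates this
    equals plain Spearman. If the covariates explain one variable completely
    (zero residual), the partial correlation is 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = None
    k = 0
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        C = np.column_stack([rank_transform(c) for c in C.T])
        k = C.shape[1]
    n = x.size
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} observations, got {n}")
    rx = rank_transform(x)
    ry = rank_transform(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant input after rank transform")
    ex = _residualize(rx, C)
    ey = _residualize(ry, C)
    denom = np.linalg.norm(ex) * np.linalg.norm(ey)
    if denom <= 1e-12 * n:
        return 0.0, 1.0
    rho = float(ex @ ey / denom)
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return rho, p


@dataclass
class NestedFTestResult:
    """Nested-model F-test with (adjusted) partial R-squared."""

    F: float
    p: float
    partial_r2: float
    adj_partial_r2: float
    df: tuple[int, int]
    rss_null: float
    rss_full: float


def _add_intercept(X: np.ndarray | None, n: int) -> np.ndarray:
    if X is None or np.size(X) == 0:
        return np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(n), X])


def nested_f_test(y, X_null, X_full) -> NestedFTestResult:
    """Compare a full linear model against a nested null model.

    Matrices are given without the intercept, which is added internally; the
    leading columns of X_full must equal X_null. F = [(RSS0 - RSS1)/(p1 - p0)]
    / [RSS1/(n - p1 - 1)]; partial R2 = (RSS0 - RSS1)/RSS0 and its adjusted
    version applies the Ezekiel-style small-sample penalty.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    Xn = _add_intercept(X_null, n)
    Xf = _add_intercept(X_full, n)
    p0 = Xn.shape[1] - 1
    p1 = Xf.shape[1] - 1
    if p1 <= p0:
        raise ValueError("X_full must add at least one column to X_null")
    if not np.allclose(Xf[:, : p0 + 1], Xn):
        raise ValueError("X_null columns must be the leading columns of X_full")
    if n <= p1 + 1:
        raise ValueError(f"need n > {p1 + 1} rows, got {n}")
    rank = np.linalg.matrix_rank(Xf)
    if rank < Xf.shape[1]:
        # name offending columns via the QR diagonal
        _, R = np.linalg.qr(Xf)
        bad = np.flatnonzero(np.abs(np.diag(R)) < 1e-10 * np.abs(np.diag(R)).max())
        raise ValueError(f"X_full is rank deficient; collinear columns (0-based, "
                         f"incl. intercept col 0): {bad.tolist()}")

    def _rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss0 = _rss(Xn)
    rss1 = _rss(Xf)
    d1 = p1 - p0
    d2 = n - p1 - 1
    if rss0 <= 0:
        raise ValueError("null model already fits perfectly; F undefined")
    partial_r2 = (rss0 - rss1) / rss0
    partial_r2 = float(np.clip(partial_r2, 0.0, 1.0))
    if rss1 <= max(1e-300, 1e-14 * rss0):
        F, p, partial_r2 = np.inf, 0.0, 1.0
    else:
        F = ((rss0 - rss1) / d1) / (rss1 / d2)
        F = float(max(F, 0.0))
        p = float(sps.f.sf(F, d1, d2))
    adj = 1.0 - (1.0 - partial_r2) * (n - p0 - 1) / (n - p1 - 1)
    return NestedFTestResult(F=F, p=p, partial_r2=partial_r2,
                             adj_partial_r2=float(adj), df=(d1, d2),
                             rss_null=rss0, rss_full=rss1)


def sliding_windows(scores: pd.Series, window_length: int = 20, step: int = 5):
    """Sorted sliding windows over subjects ordered by score.

    ``scores`` is indexed by subject id. Windows are consecutive blocks of
    ``window_length`` subjects in ascending score order (ties broken by id for
    determinism), starting every ``step`` subjects; trailing subjects not
    covered by a full window are dropped (logged). Returns a list of id lists.
    """
    if window_length < 2 or step < 1:
        raise ValueError("window_length must be >= 2 and step >= 1")
    s = scores.dropna()
    n = len(s)
    if n < window_length:
        raise ValueError(f"need at least window_length={window_length} subjects, got {n}")
    order = sorted(s.index, key=lambda i: (s[i], str(i)))
    n_windows = (n - window_length) // step + 1
    covered = (n_windows - 1) * step + window_length
    if covered < n:
        logger.info("sliding_windows: %d trailing subject(s) not covered", n - covered)
    return [order[w * step : w * step + window_length] for w in range(n_windows)]


def _window_tsm_params(cohort, ids) -> np.ndarray:
    g = cohort.group_gradient(ids)
    left, right = trend.fit_bilateral(g.values, cohort.coords)
    return np.concatenate([left.params, right.params])


@dataclass
class WindowBehaviorResult:
    ftest: NestedFTestResult
    table: pd.DataFrame          # per-parameter rho, p, p_fdr
    windows: list
    params: np.ndarray           # windows x 18
    score: str


def window_behavior_analysis(
    cohort,
    score_name: str,
    covariates: tuple = ("age", "sex", "education"),
    window_length: int = 20,
    step: int = 5,
) -> WindowBehaviorResult:
    """Sliding-window gradient-behavior analysis.

    Subjects are sorted by the score; per window the group gradient and its
    bilateral trend-surface parameters (18 = 9 left + 9 right) are computed
    along with window means of the score and nuisance covariates. Windows are
    then the rows of a nested F-test (null: covariates only; full: + the 18
    parameters) and of per-parameter partial Spearman correlations with the
    score, FDR-corrected across the 18-parameter family.
    """
    df = cohort.table.dropna(subset=[score_name, *covariates]).set_index("id")
    windows = sliding_windows(df[score_name], window_length, step)
    k_full = len(PARAM_NAMES) + len(covariates) + 1
    if len(windows) < k_full + 2:
        raise ValueError(
            f"only {len(windows)} windows for {k_full} full-model columns; "
            "increase the cohort size or reduce the parameter set"
        )
    P = np.array([_window_tsm_params(cohort, ids) for ids in windows])
    y = np.array([df.loc[ids, score_name].mean() for ids in windows])
    C = np.array([[df.loc[ids, c].mean() for c in covariates] for ids in windows])
    ftest = nested_f_test(y, C, np.column_stack([C, P]))
    rows = []
    for j, name in enumerate(PARAM_NAMES):
        rho, p = partial_spearman(P[:, j], y, C)
        rows.append((name, rho, p))
    table = pd.DataFrame(rows, columns=["parameter", "rho", "p"])
    table["p_fdr"] = bh_fdr(table["p"].to_numpy())
    return WindowBehaviorResult(ftest=ftest, table=table, windows=windows,
                                params=P, score=score_name)


@dataclass
class AgeAnalysisResult:
    ftest: NestedFTestResult
    table: pd.DataFrame
    years: np.ndarray
    params: np.ndarray


def per_year_age_analysis(cohort) -> AgeAnalysisResult:
    """Average gradient per integer year of age, regressed against age.

    Each year with at least one subject forms a bin; per bin the group
    gradient and its 18 bilateral trend-surface parameters are computed. The
    nested F-test asks whether those parameters explain age (the bin year)
    over and above bin-mean sex; per-parameter partial Spearman correlations
    with age (controlling sex) are FDR-corrected across the family.
    """
    df = cohort.table.dropna(subset=["age", "sex"]).set_index("id")
    years_all = np.floor(df["age"]).astype(int)
    bins = np.unique(years_all)
    if bins.size < 20:
        warnings.warn(f"only {bins.size} age bins; low statistical power")
    P, y, sex = [], [], []
    for yr in bins:
        ids = list(years_all.index[years_all == yr])
        P.append(_window_tsm_params(cohort, ids))
        y.append(float(yr))
        sex.append(df.loc[ids, "sex"].mean())
    P = np.asarray(P)
    y = np.asarray(y)
    sex = np.asarray(sex)[:, None]
    ftest = nested_f_test(y, sex, np.column_stack([sex, P]))
    rows = []
    for j, name in enumerate(PARAM_NAMES):
        rho, p = partial_spearman(P[:, j], y, sex)
        rows.append((name, rho, p))
    table = pd.DataFrame(rows, columns=["parameter", "rho", "p"])
    table["p_fdr"] = bh_fdr(table["p"].to_numpy())
    return AgeAnalysisResult(ftest=ftest, table=table, years=bins, params=P)


# ---------------------------------------------------------------------------
# Clusterability


def _kmeans_1d(values: np.ndarray, k: int, max_iter: int = 100):
    """Deterministic 1-D k-means with quantile seeding.

    Centers start at the (2i+1)/(2k) quantiles; for k=2 and a contiguous
    optimum this reliably finds it without random restarts.
    """
    q = (2 * np.arange(k) + 1) / (2 * k)
    centers = np.quantile(values, q)
    labels = np.zeros(values.size, dtype=int)
    for _ in range(max_iter):
        d = np.abs(values[:, None] - centers[None, :])
        new_labels = d.argmin(axis=1)
        for j in range(k):
            sel = new_labels == j
            if sel.any():
                centers[j] = values[sel].mean()
            else:  # re-seed an empty cluster at the farthest point
                centers[j] = values[d.min(axis=1).argmax()]
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return labels, centers


def calinski_harabasz(values: np.ndarray, k: int = 2) -> float:
    """Calinski-Harabasz criterion of the k-means solution on 1-D values.

    CH = [B/(k-1)] / [W/(n-k)] with B/W the between/within cluster sums of
    squares; higher = more clusterable (sharper gradient transition).
    """
    v = np.asarray(values, dtype=float).ravel()
    n = v.size
    if np.ptp(v) == 0:
        raise ValueError("all values identical; Calinski-Harabasz undefined")
    if np.unique(v).size < k:
        raise ValueError(f"need at least k={k} distinct values")
    labels, centers = _kmeans_1d(v, k)
    grand = v.mean()
    B = sum((labels == j).sum() * (centers[j] - grand) ** 2 for j in range(k))
    W = sum(((v[labels == j] - centers[j]) ** 2).sum() for j in range(k))
    if W == 0:
        return np.inf
    return float((B / (k - 1)) / (W / (n - k)))


@dataclass
class ClusterabilityResult:
    ch: pd.Series
    rho: float
    p: float


def clusterability_vs_age(cohort) -> ClusterabilityResult:
    """Per-subject gradient clusterability, rank-correlated with age.

    CH is computed on each subject's own dominant gradient values; the
    association with age is the partial Spearman correlation controlling for
    sex.
    """
    df = cohort.table.set_index("id")
    ch = pd.Series(
        {sid: calinski_harabasz(cohort.gradient(sid).values) for sid in df.index}
    )
    rho, p = partial_spearman(ch.to_numpy(), df["age"].to_numpy(),
                              df["sex"].to_numpy())
    return ClusterabilityResult(ch=ch, rho=rho, p=p)


# ---------------------------------------------------------------------------
# Multiple comparisons and group contrasts


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def _u_statistic(ranks_a_sum: float, n: int) -> float:
    return ranks_a_sum - n * (n + 1) / 2.0


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    Exact enumeration over all assignments (tie-aware) when both samples have
    at most 8 observations; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    if max(n, m) <= 8:
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        u_obs = _u_statistic(ranks[:n].sum(), n)
        us = np.array([
            _u_statistic(ranks[list(idx)].sum(), n)
            for idx in itertools.combinations(range(n + m), n)
        ])
        tol = 1e-9
        p_le = np.mean(us <= u_obs + tol)
        p_ge = np.mean(us >= u_obs - tol)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return float(u_obs), float(p)
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ManovaResult:
    pillai: float
    F: float
    df: tuple[float, float]
    p: float


def manova_oneway(groups) -> ManovaResult:
    """One-way MANOVA via Pillai's trace and its standard F approximation."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    p = groups[0].shape[1]
    if any(g.ndim != 2 or g.shape[1] != p for g in groups):
        raise ValueError("all groups must be 2D with the same number of parameters")
    if any(g.shape[0] <= p for g in groups):
        raise ValueError("each group needs more observations than parameters; "
                         "reduce the parameter set")
    N = sum(g.shape[0] for g in groups)
    gnum = len(groups)
    grand = np.vstack(groups).mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for g in groups:
        mg = g.mean(axis=0)
        d = (mg - grand)[:, None]
        H += g.shape[0] * (d @ d.T)
        r = g - mg
        E += r.T @ r
    try:
        pillai = float(np.trace(np.linalg.solve(H + E, H)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular SSCP matrix; reduce the parameter set") from exc
    s = min(p, gnum - 1)
    m_ = (abs(p - gnum + 1) - 1) / 2.0
    n_ = (N - gnum - p - 1) / 2.0
    df1 = s * (2 * m_ + s + 1)
    df2 = s * (2 * n_ + s + 1)
    if df2 <= 0:
        raise ValueError("not enough observations for the Pillai F approximation")
    denom = s - pillai
    F = (df2 / df1) * (pillai / denom) if denom > 1e-12 else np.inf
    p_val = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return ManovaResult(pillai=pillai, F=float(F), df=(df1, df2), p=p_val)


@dataclass
class GroupComparisonResult:
    manova: ManovaResult
    table: pd.DataFrame          # per-parameter U, p, p_fdr
    group_params: tuple          # (iterations x 18, iterations x 18)
    group_sizes: tuple


def bootstrap_group_comparison(
    cohort,
    groups: tuple | None = None,
    group_col: str = "hads",
    threshold: float = 7,
    draw: int = 20,
    iterations: int = 1000,
    seed: int = 0,
) -> GroupComparisonResult:
    """Bootstrap contrast of gradient parameters between two subject groups.

    By default groups are defined by the HADS screening rule (score > 7 =
    abnormal). Per iteration and group, ``draw`` subjects are sampled with
    replacement, their group gradient computed, and its 18 bilateral
    trend-surface parameters recorded. The two collections of parameter
    vectors are compared with a one-way MANOVA (Pillai), followed by
    per-parameter Mann-Whitney U tests with BH-FDR correction.
    """
    df = cohort.table.set_index("id")
    if groups is None:
        normal = list(df.index[df[group_col] <= threshold])
        abnormal = list(df.index[df[group_col] > threshold])
        groups = (normal, abnormal)
    ids_a, ids_b = list(groups[0]), list(groups[1])
    for name, ids in (("first", ids_a), ("second", ids_b)):
        if len(ids) < draw:
            raise ValueError(f"{name} group has {len(ids)} subjects; "
                             f"need at least draw={draw}")
    rng = np.random.default_rng(seed)
    stacks = []
    for ids in (ids_a, ids_b):
        ids = np.asarray(ids)
        vecs = []
        for _ in range(iterations):
            sample = rng.choice(ids, size=draw, replace=True)
            vecs.append(_window_tsm_params(cohort, sample))
        stacks.append(np.asarray(vecs))
    manova = manova_oneway(stacks)
    rows = []
    for j, name in enumerate(PARAM_NAMES):
        U, p = mann_whitney(stacks[0][:, j], stacks[1][:, j])
        rows.append((name, U, p))
    table = pd.DataFrame(rows, columns=["parameter", "U", "p"])
    table["p_fdr"] = bh_fdr(table["p"].to_numpy())
    return GroupComparisonResult(manova=manova, table=table,
                                 group_params=tuple(stacks),
                                 group_sizes=(len(ids_a), len(ids_b)))
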