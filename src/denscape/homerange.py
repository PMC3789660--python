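"""Home-range-scale selection analysis via Euclidean distance ratios.

For each den, 200 random points (default) are drawn uniformly in an 800 m
buffer — about 200 ha, midway between documented male and female annual home
ranges of the Indian fox — and for each of the seven features (six land-cover
classes and roads) a ratio is formed:

    r_ij = d(den_i, feature_j) / mean_k d(random_ik, feature_j)

with the zero-if-containing rule in the numerator.  Ratios below 1 indicate
selection of the feature, above 1 avoidance.  Inference:

* a one-sample MANOVA of the ratio vectors against (1, ..., 1), computed via
  Hotelling's T² (the one-sample case has a single non-zero eigenvalue, so
  Pillai's trace is the monotone transform T²/(T² + n - 1) with an exact F);
* percentile bootstrap CIs (1000 reps) for each feature's mean ratio;
* per-feature one-sample t-tests of (ratio - 1), two-sided;
* relative ranking across features via pairwise paired t-tests, summarized
  as a compact letter display (features sharing a letter are not
  significantly different).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geospatial import FEATURES, GeometryError, LandscapeMap, nearest_distances, sample_uniform_disc


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Distance-ratio matrix
# ---------------------------------------------------------------------------

def compute_distance_ratios(
    dens: pd.DataFrame,
    landscape: LandscapeMap,
    n_random: int = 200,
    radius_m: float = 800.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Dens x 7-features matrix of distance ratios.

    ``dens`` needs x, y columns.  Random points are drawn independently per
    den from per-den subseeds spawned off the master seed.  The denominator
    is the mean nearest distance of the den's own random points; 0/0 cells
    (all random points inside the focal class) are defined as 0.
    """
    if len(dens) == 0:
        raise AnalysisError("empty den list")
    if n_random < 1:
        raise AnalysisError(f"n_random must be >= 1, got {n_random}")
    for feat in FEATURES:
        if landscape._union(feat) is None:
            raise GeometryError(f"feature layer {feat!r} is empty")

    den_xy = dens[["x", "y"]].to_numpy(dtype=float)
    n = len(den_xy)
    subseeds = np.random.SeedSequence(seed).spawn(n)

    # Stack den + its random points per den, one vectorized distance pass
    # per feature over all points.
    all_pts = [den_xy]
    for i in range(n):
        all_pts.append(sample_uniform_disc(den_xy[i], radius_m, n_random, np.random.default_rng(subseeds[i])))
    pts = np.vstack(all_pts)

    ratios = np.empty((n, len(FEATURES)))
    for j, feat in enumerate(FEATURES):
        d = nearest_distances(pts, landscape, feat)
        num = d[:n]
        denom = d[n:].reshape(n, n_random).mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / denom
        r[(num == 0) & (denom == 0)] = 0.0
        if not np.all(np.isfinite(r)):
            raise AnalysisError(
                f"non-finite distance ratio for feature {feat!r}: all random points at "
                "distance 0 while the den is not; increase n_random or check the layer"
            )
        ratios[:, j] = r
    out = pd.DataFrame(ratios, columns=list(FEATURES), index=dens.index)
    out.attrs.update(n_random=n_random, radius_m=radius_m, seed=seed)
    return out


# ---------------------------------------------------------------------------
# One-sample MANOVA vs a vector of 1s (Hotelling's T²)
# ---------------------------------------------------------------------------

@dataclass
class ManovaResult:
    pillai_trace: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    hotelling_t2: float


def manova_vs_ones(matrix: pd.DataFrame) -> ManovaResult:
    """One-sample multivariate test of H0: mean ratio vector = (1, ..., 1).

    T² = n (x̄-1)' S⁻¹ (x̄-1);  F = (n-p) T² / (p (n-1)) with (p, n-p) df.
    Pillai's trace is reported as T²/(T² + n - 1).
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n <= p:
        raise AnalysisError(f"need more dens ({n}) than features ({p}) for the MANOVA")
    d = X - 1.0
    xbar = d.mean(axis=0)
    S = np.cov(d, rowvar=False, ddof=1)
    if np.linalg.cond(S) > 1e12:
        raise AnalysisError(
            "singular (or near-singular) covariance of the ratio matrix; "
            "consider removing a constant or collinear feature column"
        )
    t2 = float(n * xbar @ np.linalg.solve(S, xbar))
    f_stat = (n - p) / (p * (n - 1)) * t2
    p_value = float(stats.f.sf(f_stat, p, n - p))
    return ManovaResult(
        pillai_trace=t2 / (t2 + n - 1),
        f_stat=f_stat,
        df1=p,
        df2=n - p,
        p_value=p_value,
        hotelling_t2=t2,
    )


# ---------------------------------------------------------------------------
# Bootstrap CIs, t-tests, ranking
# ---------------------------------------------------------------------------

def bootstrap_ratio_cis(
    matrix: pd.DataFrame, reps: int = 1000, seed: int = 0, level: float = 0.95
) -> pd.DataFrame:
    """Percentile bootstrap CIs for each feature's mean ratio.

    Resamples dens (rows) with replacement ``reps`` times; returns a frame
    with feature, mean, lo, hi.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise AnalysisError("bootstrap needs at least 2 dens")
    if reps < 1:
        raise AnalysisError(f"reps must be >= 1, got {reps}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    boot_means = X[idx].mean(axis=1)  # reps x p
    a = (1.0 - level) / 2.0
    lo = np.quantile(boot_means, a, axis=0)
    hi = np.quantile(boot_means, 1.0 - a, axis=0)
    return pd.DataFrame(
        {"feature": list(matrix.columns), "mean": X.mean(axis=0), "lo": lo, "hi": hi}
    )


def ttest_vs_one(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature one-sample t-test of H0: mean ratio = 1 (two-sided)."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise AnalysisError("t-test needs at least 2 dens")
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [c for c, s in zip(matrix.columns, sds) if s == 0]
        raise AnalysisError(f"zero-variance ratio column(s): {bad}; t-test undefined")
    t, p = stats.ttest_1samp(X, popmean=1.0, axis=0)
    return pd.DataFrame({"feature": list(matrix.columns), "t": t, "p": p})


def rank_features(matrix: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Relative ranking of features by pairwise paired t-tests.

    Features are ordered by mean ratio (most-selected first) and given a
    compact letter display: features that are not significantly different
    (paired t, two-sided p > alpha) share a letter.  A zero-variance
    difference column (identical features) is treated as non-significant and
    logged via a warning.
    """
    cols = list(matrix.columns)
    if len(cols) < 2:
        raise AnalysisError("ranking needs at least 2 features")
    X = np.asarray(matrix, dtype=float)
    p_mat = _pairwise_paired_pvalues(X, cols)
    order = np.argsort(X.mean(axis=0), kind="stable")
    letters = _compact_letter_display(p_mat > alpha, order)
    return pd.DataFrame(
        {
            "feature": cols,
            "mean_ratio": X.mean(axis=0),
            "rank": [letters[j] for j in range(len(cols))],
        }
    ).sort_values("mean_ratio", ignore_index=True)


def _pairwise_paired_pvalues(X: np.ndarray, cols: list[str]) -> np.ndarray:
    k = X.shape[1]
    p_mat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            diff = X[:, i] - X[:, j]
            if diff.std(ddof=1) == 0:
                if not np.allclose(diff, 0):
                    warnings.warn(
                        f"constant non-zero difference between {cols[i]!r} and {cols[j]!r}; "
                        "treated as non-significant",
                        stacklevel=3,
                    )
                p = 1.0
            else:
                p = stats.ttest_rel(X[:, i], X[:, j]).pvalue
            p_mat[i, j] = p_mat[j, i] = p
    return p_mat


def _compact_letter_display(ns: np.ndarray, order: np.ndarray) -> dict[int, str]:
    """Letters from maximal cliques of the not-significantly-different graph.

    ``ns`` is a boolean symmetric matrix (True = not significantly
    different); ``order`` ranks features (best first) and fixes letter order.
    """
    import networkx as nx

    k = ns.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if ns[i, j]:
                g.add_edge(i, j)
    rank_of = {int(f): r for r, f in enumerate(order)}
    cliques = sorted(
        (sorted(c, key=lambda f: rank_of[f]) for c in nx.find_cliques(g)),
        key=lambda c: min(rank_of[f] for f in c),
    )
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    feat_letters: dict[int, list[str]] = {f: [] for f in range(k)}
    for letter, clique in zip(alphabet, cliques):
        for f in clique:
            feat_letters[f].append(letter)
    return {f: "".join(sorted(ls)) for f, ls in feat_letters.items()}


def selection_table(
    matrix: pd.DataFrame, reps: int = 1000, seed: int = 0, alpha: float = 0.05
) -> pd.DataFrame:
    """Combined per-feature summary: mean ratio, bootstrap CI, t, p, rank."""
    cis = bootstrap_ratio_cis(matrix, reps=reps, seed=seed)
    tt = ttest_vs_one(matrix)
    rk = rank_features(matrix, alpha=alpha)
    out = cis.merge(tt, on="feature").merge(rk[["feature", "rank"]], on="feature")
    return out.rename(columns={"mean": "ratio"})
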