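"""Temporal-profile clustering and archetype classification.

Profiles are per-gene expression values averaged over the samples
available at each timepoint, then mean-centered. Clustering uses a
Spearman-correlation distance realized exactly as Euclidean K-means on
rank z-scores: for tie-free vectors of length m, the squared Euclidean
distance between rank z-scores is proportional to 1 - rho_spearman, so
the usual K-means machinery (centroid updates, k-means++ seeding,
restarts) applies unchanged while respecting the stated distance.

Cluster centroids (or any centered profile) are classified into the
eight named temporal archetypes A-H by a deterministic rule cascade on
simple shape features (peak/trough position, interior local maxima,
plateau and endpoint-return flags); profiles matching no rule are
labeled OTHER.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .errors import UserInputError

DEFAULT_K = 25
DEFAULT_N_INIT = 50

#: |x(24) - x(0)| <= RETURN_TOL * range counts as "returned to baseline"
RETURN_TOL = 0.2
#: spread over the 2-6 h points <= PLATEAU_TOL * range counts as a plateau
PLATEAU_TOL = 0.15
#: |x(1) - x(0)| <= FLAT_TOL * range counts as "unchanged at 1 h"
FLAT_TOL = 0.15


# ---------------------------------------------------------------------------
# averaging and standardization


def average_profiles(matrix: pd.DataFrame, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Mean expression per timepoint, using only the samples present.

    Returns genes x timepoints (columns are the sorted hour values).
    """
    sheet = sample_sheet.set_index("sample_id")
    missing = [c for c in matrix.columns if c not in sheet.index]
    if missing:
        raise UserInputError(f"samples {missing[:3]} absent from sample sheet")
    times = sheet.loc[matrix.columns, "time_h"].astype(float)
    levels = sorted(times.unique())
    cols = {}
    for t in levels:
        sub = matrix.loc[:, (times == t).to_numpy()]
        if sub.shape[1] == 0:  # pragma: no cover - levels come from data
            raise UserInputError(f"no samples at timepoint {t}")
        cols[t] = sub.mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns.name = "time_h"
    return out


@dataclass
class StandardizedProfiles:
    """Mean-centered profiles and their rank z-scores.

    ``rank_z`` rows have mean 0 and population variance 1 except for
    fully tied (constant) profiles, which are flagged ``degenerate`` and
    left at zero.
    """

    centered: pd.DataFrame
    rank_z: pd.DataFrame
    degenerate: pd.Series


def rank_z_scores(values: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, z-scored with the population SD."""
    values = np.asarray(values, dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, values)  # average ties
    mu = ranks.mean(axis=1, keepdims=True)
    sd = ranks.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (ranks - mu) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return z


def standardize(profiles: pd.DataFrame) -> StandardizedProfiles:
    """Center each profile and compute its rank z-scores."""
    if profiles.shape[1] < 2:
        raise UserInputError("profiles need at least 2 timepoints")
    values = profiles.to_numpy(dtype=float)
    centered = values - values.mean(axis=1, keepdims=True)
    z = rank_z_scores(values)
    degenerate = (values.std(axis=1) == 0)
    return StandardizedProfiles(
        centered=pd.DataFrame(centered, index=profiles.index, columns=profiles.columns),
        rank_z=pd.DataFrame(z, index=profiles.index, columns=profiles.columns),
        degenerate=pd.Series(degenerate, index=profiles.index, name="degenerate"),
    )


def spearman_distance(x, y) -> float:
    """1 - Spearman rank correlation; in [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise UserInputError("inputs must be 1-d vectors of equal length >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UserInputError("Spearman distance undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(1.0 - rho)


# ---------------------------------------------------------------------------
# K-means in rank-z space


class SpearmanKMeans(ClusterMixin, BaseEstimator):
    """K-means under Spearman-correlation distance.

    Input rows are raw (or centered) temporal profiles; each row is
    transformed to rank z-scores, in which squared Euclidean distance is
    proportional to the Spearman distance, and standard K-means
    (k-means++ seeding, ``n_init`` restarts) is run there.

    Attributes: ``labels_`` (0-based), ``cluster_centers_`` (rank-z
    space), ``inertia_``, ``rank_z_``.
    """

    def __init__(self, n_clusters: int = DEFAULT_K, n_init: int = DEFAULT_N_INIT,
                 random_state: int | None = 0):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        values = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if values.ndim != 2 or values.shape[1] < 2:
            raise UserInputError("X must be profiles x timepoints with >= 2 timepoints")
        if self.n_clusters < 1:
            raise UserInputError("n_clusters must be >= 1")
        if values.shape[0] < self.n_clusters:
            raise UserInputError(
                f"K={self.n_clusters} exceeds the {values.shape[0]} profiles"
            )
        if np.any(values.std(axis=1) == 0):
            raise UserInputError(
                "constant profiles have undefined rank correlation; filter "
                "them out (see cluster_profiles)"
            )
        z = rank_z_scores(values)
        km = KMeans(
            n_clusters=self.n_clusters, n_init=self.n_init,
            random_state=self.random_state,
        ).fit(z)
        self.rank_z_ = z
        self.labels_ = km.labels_
        self.cluster_centers_ = km.cluster_centers_
        self.inertia_ = float(km.inertia_)
        return self


@dataclass
class ClusterResult:
    """Assignment of genes to temporal clusters (1-based indices)."""

    assignments: pd.Series          # gene -> cluster index 1..K (0 = excluded)
    centroids: pd.DataFrame         # K x timepoints, rank-z space
    inertia: float
    k: int
    seed: int | None
    n_init: int


def cluster_profiles(
    standardized: StandardizedProfiles,
    k: int = DEFAULT_K,
    seed: int | None = 0,
    n_init: int = DEFAULT_N_INIT,
) -> ClusterResult:
    """K-means on the rank z-scores; degenerate profiles are excluded
    (assignment 0) rather than clustered."""
    keep = ~standardized.degenerate
    usable = standardized.rank_z.loc[keep]
    est = SpearmanKMeans(n_clusters=k, n_init=n_init, random_state=seed)
    est.fit(usable.to_numpy())
    assignments = pd.Series(0, index=standardized.rank_z.index, name="cluster")
    assignments.loc[keep] = est.labels_ + 1
    centroids = pd.DataFrame(
        est.cluster_centers_, index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=standardized.rank_z.columns,
    )
    return ClusterResult(assignments=assignments, centroids=centroids,
                         inertia=est.inertia_, k=k, seed=seed, n_init=n_init)


# ---------------------------------------------------------------------------
# shape features and archetype rules


@dataclass(frozen=True)
class ShapeFeatures:
    """Machine-checkable description of a 6-point temporal profile.

    All features are computed on deviations from the 0 h value, which
    makes them invariant to mean-centering and to any additive shift.
    """

    peak_time: float                    # hour of the maximum deviation
    trough_time: float                  # hour of the minimum deviation
    n_interior_maxima: int              # strict local maxima on the grid
    interior_maxima_times: tuple[float, ...]
    initial_sign: int                   # sign of x(1h)-x(0h) beyond FLAT_TOL
    returns_to_baseline: bool           # |x(24)-x(0)| <= RETURN_TOL * range
    plateau_2_6: bool                   # spread over 2-6 h <= PLATEAU_TOL * range
    monotone_down: bool                 # non-increasing (FLAT_TOL slack), min at 24 h
    recovers: bool                      # endpoint strictly above the minimum
    goes_up: bool                       # max deviation exceeds RETURN_TOL * range
    goes_down: bool                     # min deviation below -RETURN_TOL * range
    value_range: float


def shape_features(profile, timepoints=(0.0, 1.0, 2.0, 3.0, 6.0, 24.0)) -> ShapeFeatures:
    """Features of a (centered) profile as deviations from its 0 h value."""
    x = np.asarray(profile, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if x.shape != t.shape:
        raise UserInputError("profile and timepoints must have equal length")
    dev = x - x[0]
    rng = float(x.max() - x.min())
    peak_time = float(t[int(np.argmax(dev))])
    trough_time = float(t[int(np.argmin(dev))])
    interior = tuple(
        float(t[i]) for i in range(1, len(x) - 1)
        if x[i] > x[i - 1] and x[i] > x[i + 1]
    )
    if rng == 0 or abs(dev[1]) <= FLAT_TOL * rng:
        initial = 0
    else:
        initial = 1 if dev[1] > 0 else -1
    returns = abs(dev[-1]) <= RETURN_TOL * rng if rng > 0 else True
    mid = dev[(t >= 2.0) & (t <= 6.0)]
    plateau = bool(mid.size and (mid.max() - mid.min()) <= PLATEAU_TOL * rng) if rng > 0 else True
    eps = FLAT_TOL * rng
    monotone_down = bool(
        rng > 0
        and np.all(np.diff(dev) <= eps)
        and int(np.argmin(dev)) == len(dev) - 1
    )
    return ShapeFeatures(
        peak_time=peak_time, trough_time=trough_time,
        n_interior_maxima=len(interior), interior_maxima_times=interior,
        initial_sign=initial, returns_to_baseline=bool(returns),
        plateau_2_6=plateau, monotone_down=monotone_down,
        recovers=bool(dev[-1] > dev.min()),
        goes_up=bool(rng > 0 and dev.max() > RETURN_TOL * rng),
        goes_down=bool(rng > 0 and dev.min() < -RETURN_TOL * rng),
        value_range=rng,
    )


def classify_archetype(features: ShapeFeatures) -> str:
    """First-match rule cascade mapping shape features to A-H or OTHER.

    Order matters: the two-peak shape D is tested before the single-peak
    shapes A/B/C, and the monotone decline F before the recovering
    declines E/G. A convenience overload accepts the profile itself.
    """
    if not isinstance(features, ShapeFeatures):
        features = shape_features(features)
    f = features
    if f.value_range == 0:
        return "OTHER"
    # D: interior maxima at both 2 h and 6 h (forcing the 3 h dip), transient
    if {2.0, 6.0} <= set(f.interior_maxima_times) and f.returns_to_baseline and f.goes_up:
        return "D"
    # F: monotone decline still falling at 24 h
    if f.goes_down and f.monotone_down:
        return "F"
    # H: below baseline at 1 h, then a positive maximum at 3 or 6 h
    if f.initial_sign < 0 and f.goes_up and f.peak_time in (3.0, 6.0) and f.returns_to_baseline:
        return "H"
    # A: hyperacute transient peak at 2 h
    if f.goes_up and f.peak_time == 2.0 and f.returns_to_baseline:
        return "A"
    # C: unchanged at 1 h, transient peak at 6 h
    if f.goes_up and f.peak_time == 6.0 and f.returns_to_baseline and f.initial_sign == 0:
        return "C"
    # B: immediate rise to a transient 6 h peak
    if f.goes_up and f.peak_time == 6.0 and f.returns_to_baseline and f.initial_sign > 0:
        return "B"
    # G: low plateau across 2-6 h with partial recovery at 24 h
    if f.goes_down and f.plateau_2_6 and f.trough_time in (2.0, 3.0, 6.0) and f.recovers:
        return "G"
    # E: trough at 6 h with partial recovery at 24 h
    if f.goes_down and f.trough_time == 6.0 and f.recovers:
        return "E"
    return "OTHER"


def label_clusters(result: ClusterResult) -> pd.Series:
    """Archetype label for each cluster, from its rank-z centroid."""
    times = tuple(float(c) for c in result.centroids.columns)
    return pd.Series(
        {
            idx: classify_archetype(shape_features(row.to_numpy(), times))
            for idx, row in result.centroids.iterrows()
        },
        name="archetype",
    )


def assign_archetypes(result: ClusterResult) -> pd.DataFrame:
    """Per-gene table: cluster index and the cluster's archetype label.

    Excluded (degenerate) genes get cluster 0 and label OTHER.
    """
    labels = label_clusters(result)
    arch = result.assignments.map(lambda c: labels.get(c, "OTHER"))
    return pd.DataFrame({"cluster": result.assignments, "archetype": arch})
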