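"""Smoothing, normalization and clustering of qPCR induction time courses.

The pipeline mirrors how high-temporal-resolution RT-PCR time courses of
activity-induced genes are analysed:

1. raw Ct values (optionally) become fold changes via the ddCt method;
2. each replica's trajectory is fitted with a cubic smoothing spline and
   evaluated on a dense minute grid;
3. each curve is min-max normalized to [0, 1], so clustering compares the
   *shape* of induction, not its magnitude;
4. the normalized replica curves of each gene are concatenated into one
   feature vector and clustered by Euclidean k-means;
5. the number of clusters is chosen unsupervised, as the minimum of
   ``Theta(N) = mean_scaled_intra_cluster_distance + alpha * N``, where
   ``dist(c_i)`` is the average squared member-to-centroid distance in
   cluster i scaled by the global average squared distance to the grand mean
   (dimensionless, in [0, 1]), the mean over clusters weights each cluster
   by its size (equivalently: within-cluster over total sum of squares,
   which is non-increasing in N), and ``alpha`` penalises fragmentation;
6. clustering quality is quantified by a permutation Z-score, and the
   co-clustering of paired control primers by a permutation/exact p-value.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from sklearn.cluster import KMeans

__all__ = [
    "TimeCourseSet",
    "Trajectory",
    "ClusterResult",
    "TrajectoryBundle",
    "ddct_fold_change",
    "smooth_trajectory",
    "normalize_unit_interval",
    "average_replicas",
    "build_trajectories",
    "kmeans_cluster",
    "theta_criterion",
    "clustering_zscore",
    "primer_consistency_pvalue",
]

#: default dense evaluation grid, minutes
GRID_SPAN = (10.0, 90.0)
GRID_STEP = 1.0

#: default spline roughness penalty; passes ~4 effective degrees of freedom
#: over a 12-point design, the complexity of the expected trend shapes.
#: GCV per curve is available (smoothing=None) but under-smooths short
#: noisy series, defeating trend extraction.
DEFAULT_SMOOTHING = 2500.0

#: default grain penalty of the Theta(N) cluster-number criterion,
#: calibrated once on planted-three-pattern synthetic data at the
#: generator's default noise so that Theta attains its minimum at the
#: planted cluster number (stable over the 0.08-0.12 range there).
DEFAULT_ALPHA = 0.10

_CONST_TOL = 1e-12


@dataclass(frozen=True)
class TimeCourseSet:
    """Per-gene, per-replica fold-change samples at common time stamps."""

    gene_ids: list[str]
    replica_ids: list[str]
    times: np.ndarray  # (T,) minutes, strictly increasing
    values: np.ndarray  # (genes, replicas, T) fold changes, > 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if v.shape != (len(self.gene_ids), len(self.replica_ids), t.size):
            raise ValueError(f"values shape {v.shape} inconsistent with ids/times")
        if not np.all(v > 0):
            raise ValueError("fold changes must be > 0")

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with columns gene, replica, time_min, fold_change."""
        g, r, t = np.meshgrid(
            np.arange(len(self.gene_ids)),
            np.arange(len(self.replica_ids)),
            np.arange(self.times.size),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "gene": np.asarray(self.gene_ids)[g.ravel()],
                "replica": np.asarray(self.replica_ids)[r.ravel()],
                "time_min": self.times[t.ravel()],
                "fold_change": self.values.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TimeCourseSet":
        need = {"gene", "replica", "time_min", "fold_change"}
        if not need.issubset(df.columns):
            raise ValueError(f"time-course table must have columns {sorted(need)}")
        genes = list(dict.fromkeys(df["gene"].astype(str)))
        replicas = list(dict.fromkeys(df["replica"].astype(str)))
        times = np.sort(df["time_min"].unique().astype(float))
        wide = df.set_index(["gene", "replica", "time_min"])["fold_change"]
        values = np.empty((len(genes), len(replicas), times.size))
        try:
            for i, g in enumerate(genes):
                for j, r in enumerate(replicas):
                    values[i, j] = wide.loc[g, r].reindex(times).to_numpy()
        except KeyError as exc:
            raise ValueError(f"incomplete time-course table: missing {exc}") from exc
        if np.isnan(values).any():
            raise ValueError("incomplete time-course table (missing samples)")
        return cls(genes, replicas, times, values)


@dataclass(frozen=True)
class Trajectory:
    """A smoothed curve for one gene on a dense minute grid."""

    gene_id: str
    grid: np.ndarray
    values: np.ndarray
    source: str = "average"  # replica id or "average"

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have the same length")


@dataclass
class ClusterResult:
    """Outcome of one k-means fit (labels are 1-based)."""

    k: int
    gene_ids: list[str]
    assignments: np.ndarray  # (genes,), labels in 1..k
    centroids: np.ndarray  # (k, features)
    inertia: float
    seed: int
    n_restarts: int
    theta_by_k: dict[int, float] | None = None
    z_score: float | None = None

    def labels_dict(self) -> dict[str, int]:
        return dict(zip(self.gene_ids, (int(c) for c in self.assignments)))


def ddct_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """qPCR relative quantification: fold change = 2**(-ddCt).

    ddCt = (Ct_target - Ct_ref) in the treated sample minus the same
    difference in the control sample; one PCR cycle is one doubling.
    """
    cts = (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return float(2.0 ** (-ddct))


def _make_grid(times: np.ndarray, grid_step: float, grid_span=GRID_SPAN) -> np.ndarray:
    lo = max(grid_span[0], float(times[0]))
    hi = min(grid_span[1], float(times[-1]))
    if hi <= lo:
        raise ValueError("time span does not overlap the evaluation grid span")
    n = int(round((hi - lo) / grid_step))
    return lo + grid_step * np.arange(n + 1)


def smooth_trajectory(
    times,
    values,
    smoothing: float | None = None,
    grid_step: float = GRID_STEP,
    grid_span: tuple[float, float] = GRID_SPAN,
    gene_id: str = "",
    source: str = "average",
) -> Trajectory:
    """Cubic smoothing spline on a dense minute grid (un-normalized).

    ``smoothing`` is the roughness-penalty weight lambda: 0 interpolates the
    data, larger values flatten the curve towards the best straight line;
    None selects lambda per curve by generalized cross-validation. Straight
    lines are in the penalty null space, so affine data are reproduced
    exactly for any lambda.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.size < 4:
        raise ValueError("need at least 4 time points to fit a smoothing spline")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if t.size != y.size:
        raise ValueError("times and values must have equal length")
    if smoothing is None and t.size < 5:
        raise ValueError("GCV smoothing selection needs at least 5 points")
    grid = _make_grid(t, grid_step, grid_span)
    if np.ptp(y) < _CONST_TOL * max(1.0, float(np.abs(y).max())):
        # constant data: the spline is the constant itself
        return Trajectory(gene_id, grid, np.full(grid.size, float(y[0])), source)
    spline = make_smoothing_spline(t, y, lam=smoothing)
    return Trajectory(gene_id, grid, spline(grid), source)


def normalize_unit_interval(traj: Trajectory) -> Trajectory:
    """Min-max normalization to [0, 1]; constant curves map to all-0.5.

    Idempotent, and invariant under any affine transform of the input.
    """
    v = traj.values
    rng = float(v.max() - v.min())
    if rng < _CONST_TOL * max(1.0, float(np.abs(v).max())):
        warnings.warn(
            f"constant trajectory {traj.gene_id!r}/{traj.source}: normalized to 0.5",
            stacklevel=2,
        )
        out = np.full(v.size, 0.5)
    else:
        out = (v - v.min()) / rng
    return Trajectory(traj.gene_id, traj.grid, out, traj.source)


def average_replicas(trajs: list[Trajectory]) -> Trajectory:
    """Pointwise mean of per-replica curves on a common grid."""
    if not trajs:
        raise ValueError("no trajectories to average")
    grid = trajs[0].grid
    for t in trajs[1:]:
        if t.grid.shape != grid.shape or not np.allclose(t.grid, grid):
            raise ValueError("replica trajectories are on different grids")
    mean = np.mean([t.values for t in trajs], axis=0)
    return Trajectory(trajs[0].gene_id, grid, mean, "average")


@dataclass(frozen=True)
class TrajectoryBundle:
    """Smoothed/normalized curves of a whole time-course set.

    ``features`` concatenates each gene's normalized replica curves
    (replica1 || replica2 || ...) — the vectors that are clustered;
    ``averages`` holds the per-gene mean curve used for reporting.
    """

    gene_ids: list[str]
    replica_ids: list[str]
    grid: np.ndarray
    curves: np.ndarray  # (genes, replicas, grid)
    features: np.ndarray  # (genes, replicas * grid)
    averages: np.ndarray  # (genes, grid)


def build_trajectories(
    tcs: TimeCourseSet,
    smoothing: float | None = DEFAULT_SMOOTHING,
    grid_step: float = GRID_STEP,
    grid_span: tuple[float, float] = GRID_SPAN,
) -> TrajectoryBundle:
    """Smooth and normalize every replica curve; assemble cluster features."""
    n_g, n_r = len(tcs.gene_ids), len(tcs.replica_ids)
    grid = _make_grid(tcs.times, grid_step, grid_span)
    curves = np.empty((n_g, n_r, grid.size))
    for i, g in enumerate(tcs.gene_ids):
        for j, r in enumerate(tcs.replica_ids):
            traj = smooth_trajectory(
                tcs.times, tcs.values[i, j], smoothing, grid_step, grid_span, g, r
            )
            curves[i, j] = normalize_unit_interval(traj).values
    features = curves.reshape(n_g, n_r * grid.size)
    averages = curves.mean(axis=1)
    return TrajectoryBundle(
        list(tcs.gene_ids), list(tcs.replica_ids), grid, curves, features, averages
    )


def kmeans_cluster(
    features: np.ndarray | TrajectoryBundle,
    k: int,
    seed: int = 0,
    n_restarts: int = 100,
    gene_ids: list[str] | None = None,
) -> ClusterResult:
    """Best-of-restarts Euclidean k-means on trajectory feature vectors.

    Deterministic given (seed, n_restarts); restarts use k-means++-style
    seeding and the solution with minimum within-cluster squared distance
    (inertia) is kept.
    """
    if isinstance(features, TrajectoryBundle):
        gene_ids = features.gene_ids
        X = features.features
    else:
        X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if gene_ids is None:
        gene_ids = [f"item{i}" for i in range(n)]
    if not 1 <= k <= n:
        raise ValueError(f"k = {k} out of range [1, {n}]")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
    return ClusterResult(
        k=k,
        gene_ids=list(gene_ids),
        assignments=km.labels_.astype(int) + 1,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        seed=seed,
        n_restarts=n_restarts,
    )


def _scaled_intra_distances(
    X: np.ndarray, labels: np.ndarray, centroids: np.ndarray
) -> np.ndarray:
    """Per-cluster mean squared member-centroid distance over global variance."""
    grand = X.mean(axis=0)
    global_msd = float(((X - grand) ** 2).sum(axis=1).mean())
    if global_msd <= 0:
        return np.zeros(centroids.shape[0])
    out = np.empty(centroids.shape[0])
    for c in range(centroids.shape[0]):
        members = X[labels == c + 1]
        if members.size == 0:
            raise RuntimeError(f"cluster {c + 1} is empty")
        out[c] = ((members - centroids[c]) ** 2).sum(axis=1).mean() / global_msd
    return out


def theta_criterion(
    features: np.ndarray | TrajectoryBundle,
    k_range=range(1, 9),
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    n_restarts: int = 100,
    max_retries: int = 3,
) -> tuple[dict[int, float], int, dict[int, ClusterResult]]:
    """Unsupervised cluster-number selection by minimizing Theta(N).

    Theta(N) = <dist(c_i)> + alpha * N, with dist(c_i) the scaled
    (dimensionless) intra-cluster distance and <.> the size-weighted mean
    over clusters — i.e. the within-cluster over total sum of squares. The
    first term is non-increasing in N given enough restarts; alpha*N
    penalises grain. The argmin of Theta over ``k_range`` is the selected
    cluster number.

    Returns (theta_by_k, k_opt, fits_by_k).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if isinstance(features, TrajectoryBundle):
        X = features.features
        gene_ids = features.gene_ids
    else:
        X = np.asarray(features, dtype=float)
        gene_ids = None
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1 or ks[-1] >= X.shape[0]:
        raise ValueError(f"k_range must lie within [1, {X.shape[0] - 1}]")
    theta: dict[int, float] = {}
    fits: dict[int, ClusterResult] = {}
    for k in ks:
        for attempt in range(max_retries + 1):
            fit = kmeans_cluster(X, k, seed + attempt, n_restarts, gene_ids)
            try:
                dists = _scaled_intra_distances(X, fit.assignments, fit.centroids)
            except RuntimeError:
                if attempt == max_retries:
                    raise
                continue
            break
        sizes = np.bincount(fit.assignments, minlength=k + 1)[1:]
        theta[k] = float(np.average(dists, weights=sizes) + alpha * k)
        fits[k] = fit
    k_opt = min(theta, key=lambda k: (theta[k], k))
    fits[k_opt].theta_by_k = dict(theta)
    return theta, k_opt, fits


def _inertia(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        members = X[labels == c]
        total += float(((members - members.mean(axis=0)) ** 2).sum())
    return total


def clustering_zscore(
    features: np.ndarray | TrajectoryBundle,
    assignments: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation Z-score of clustering tightness.

    Compares the observed total within-cluster squared distance I_obs with
    its distribution under random reassignment of items to clusters of the
    observed sizes: Z = (mean(I_null) - I_obs) / sd(I_null). Larger Z means
    tighter-than-random clustering.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = features.features if isinstance(features, TrajectoryBundle) else np.asarray(features)
    labels = np.asarray(assignments)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("assignments length must match number of items")
    i_obs = _inertia(X, labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = _inertia(X, rng.permutation(labels))
    sd = float(null.std())
    if sd == 0:
        warnings.warn("degenerate permutation null (zero variance); Z set to 0")
        return 0.0
    return float((null.mean() - i_obs) / sd)


def primer_consistency_pvalue(
    assignments,
    pairs: list[tuple[str, str]],
    n_permutations: int = 100_000,
    seed: int = 0,
    max_exact: int = 1_000_000,
) -> float:
    """Probability that all paired items co-cluster by chance.

    The null redistributes all clustered items uniformly at random into
    clusters of the observed sizes. When the pairs are disjoint and the
    number of pair-to-cluster configurations k**P is small (<= ``max_exact``)
    the probability is computed exactly by enumeration (summing products of
    falling factorials); otherwise it is estimated by Monte-Carlo label
    permutation with ``n_permutations`` draws.
    """
    if isinstance(assignments, dict):
        items = list(assignments)
        labels = np.asarray([assignments[i] for i in items])
        index = {g: i for i, g in enumerate(items)}
        pair_idx = []
        for a, b in pairs:
            if a not in index or b not in index:
                raise ValueError(f"pair member {a!r}/{b!r} not among clustered items")
            pair_idx.append((index[a], index[b]))
    else:
        labels = np.asarray(assignments)
        pair_idx = [(int(a), int(b)) for a, b in pairs]
        for a, b in pair_idx:
            if not (0 <= a < labels.size and 0 <= b < labels.size):
                raise ValueError("pair index out of range")
    if not pair_idx:
        return 1.0

    uniq, sizes = np.unique(labels, return_counts=True)
    M = int(labels.size)
    P = len(pair_idx)
    members = {m for p in pair_idx for m in p}
    disjoint = len(members) == 2 * P

    if disjoint and len(uniq) ** P <= max_exact:
        # exact: sum over assignments of the P pairs to clusters of the
        # probability that both members of each pair land there
        denom = 1.0
        for i in range(2 * P):
            denom *= M - i
        total = 0.0
        for combo in itertools.product(range(len(uniq)), repeat=P):
            used = np.zeros(len(uniq), dtype=int)
            num = 1.0
            for c in combo:
                num *= (sizes[c] - used[c]) * (sizes[c] - used[c] - 1)
                used[c] += 2
                if num == 0.0:
                    break
            total += num
        return total / denom

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if all(perm[a] == perm[b] for a, b in pair_idx):
            hits += 1
    return hits / n_permutations
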