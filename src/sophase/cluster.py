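"""Cluster-based permutation tests for ERP and time-frequency maps.

Pointwise paired (or one-sample) t statistics across subjects are thresholded
at a per-point alpha (default 0.01, two-tailed), contiguous suprathreshold
points of common sign are merged into clusters (grid neighbors along time and
frequency; user-supplied channel neighbor pairs), and each cluster's mass
(summed t) is referred to a permutation null built from random within-subject
condition swaps (equivalently, sign flips of the paired differences). The
Monte-Carlo p uses the +1/+1 correction and positive/negative clusters are
each tested against their own tail's max-mass distribution; with the default
alpha of 0.05 split two-sided, clusters are significant at p <= 0.025.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist

__all__ = [
    "ClusterConfig",
    "AdjacencySpec",
    "Cluster",
    "ClusterResult",
    "paired_cluster_test",
    "one_sample_cluster_test",
    "cluster_channel_heatmap",
    "one_sample_t",
    "one_sample_t_from_summary",
    "WAKE_WINDOWS",
    "SLEEP_WINDOWS",
]

#: Windows of interest for waking stimulus-related power (band Hz, window s).
WAKE_WINDOWS = {
    "theta": ((5.0, 14.0), (0.050, 0.300)),
    "alpha": ((7.0, 15.0), (0.500, 0.800)),
    "gamma": ((55.0, 75.0), (0.750, 1.100)),
}

#: Windows of interest for sleep stimulus-evoked power.
SLEEP_WINDOWS = {
    "theta": ((5.0, 10.0), (0.200, 0.800)),
    "spindle_beta": ((11.0, 27.0), (0.700, 1.200)),
}


@dataclass(frozen=True)
class ClusterConfig:
    n_permutations: int = 1000
    cluster_alpha: float = 0.01  # per-point threshold, two-tailed
    alpha_two_sided: float = 0.025  # per-tail cluster significance level
    analysis_window_s: tuple[float, float] = (-0.200, 1.500)
    seed: int = 0  # permutation seed is mandatory config for reproducibility


@dataclass
class AdjacencySpec:
    """Channel neighborhood; time/frequency adjacency is the implicit grid.

    ``pairs`` holds symmetric (i, j) channel-index pairs. Build from a
    neighbor name file with :meth:`from_name_pairs`.
    """

    n_channels: int
    pairs: frozenset = frozenset()

    def __post_init__(self) -> None:
        sym = set()
        for i, j in self.pairs:
            if not (0 <= i < self.n_channels and 0 <= j < self.n_channels):
                raise ValueError(f"channel pair {(i, j)} out of range")
            if i != j:
                sym.add((min(i, j), max(i, j)))
        object.__setattr__(self, "pairs", frozenset(sym))

    @classmethod
    def from_name_pairs(cls, name_pairs, channel_names) -> "AdjacencySpec":
        index = {name: i for i, name in enumerate(channel_names)}
        pairs = {(index[a], index[b]) for a, b in name_pairs}
        return cls(n_channels=len(channel_names), pairs=frozenset(pairs))


@dataclass
class Cluster:
    members: np.ndarray  # (n_points, ndim) coordinates into the map
    mass: float
    p_value: float
    sign: int


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    df: int
    map_shape: tuple[int, ...]
    n_permutations: int
    cluster_alpha: float
    alpha_two_sided: float

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= self.alpha_two_sided]


def _label_clusters(mask: np.ndarray, adjacency: AdjacencySpec) -> np.ndarray:
    """Label connected components of a channels x grid boolean mask.

    Grid axes use orthogonal (rook) connectivity; channels connect through the
    supplied neighbor pairs at identical grid coordinates. Returns an integer
    label array (0 = background).
    """
    n_ch = mask.shape[0]
    if n_ch == 1 or not adjacency.pairs:
        # no cross-channel merging: label each channel's grid independently
        structure = ndimage.generate_binary_structure(mask.ndim - 1, 1)
        labels = np.zeros(mask.shape, dtype=np.int32)
        offset = 0
        for ch in range(n_ch):
            lab, n = ndimage.label(mask[ch], structure=structure)
            lab = lab.astype(np.int32)
            lab[lab > 0] += offset
            labels[ch] = lab
            offset += n
        return labels

    idx = np.full(mask.shape, -1, dtype=np.int64)
    pts = np.argwhere(mask)
    idx[tuple(pts.T)] = np.arange(len(pts))
    rows, cols = [], []
    # grid-axis edges within each channel
    for axis in range(1, mask.ndim):
        sl_a = [slice(None)] * mask.ndim
        sl_b = [slice(None)] * mask.ndim
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        both = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        rows.append(idx[tuple(sl_a)][both])
        cols.append(idx[tuple(sl_b)][both])
    # channel edges at identical grid coordinates
    for i, j in adjacency.pairs:
        both = mask[i] & mask[j]
        rows.append(idx[i][both])
        cols.append(idx[j][both])
    if len(pts) == 0:
        return np.zeros(mask.shape, dtype=np.int32)
    rows = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    graph = coo_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(len(pts), len(pts))
    )
    _, comp = connected_components(graph, directed=False)
    labels = np.zeros(mask.shape, dtype=np.int32)
    labels[tuple(pts.T)] = comp + 1
    return labels


def _cluster_masses(
    t_map: np.ndarray, thresh: float, adjacency: AdjacencySpec, sign: int
):
    """Clusters of one sign: list of (member-coords, mass)."""
    mask = t_map > thresh if sign > 0 else t_map < -thresh
    if not mask.any():
        return []
    labels = _label_clusters(mask, adjacency)
    out = []
    for lab in range(1, labels.max() + 1):
        members = np.argwhere(labels == lab)
        mass = float(t_map[labels == lab].sum())
        out.append((members, mass))
    return out


def _max_masses(t_map, thresh, adjacency):
    pos = _cluster_masses(t_map, thresh, adjacency, +1)
    neg = _cluster_masses(t_map, thresh, adjacency, -1)
    max_pos = max((m for _, m in pos), default=0.0)
    min_neg = min((m for _, m in neg), default=0.0)
    return max_pos, min_neg


def _sign_flip_tmaps(diffs_flat: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-maps for many sign-flip permutations at once.

    Sign flips leave per-subject squares unchanged, so only the mean moves:
    var = (sum(x^2) - n*mean^2) / (n - 1).
    """
    n = diffs_flat.shape[0]
    ss = (diffs_flat**2).sum(axis=0)
    means = signs @ diffs_flat / n
    var = np.maximum((ss - n * means**2) / (n - 1), 1e-300)
    return means / np.sqrt(var / n)


def one_sample_cluster_test(
    maps: np.ndarray,
    adjacency: AdjacencySpec | None = None,
    cfg: ClusterConfig | None = None,
) -> ClusterResult:
    """Cluster-corrected one-sample test of per-subject maps against zero.

    ``maps`` is subjects x channels x grid (time, or frequency x time). The
    permutation null flips each subject's map sign at random.
    """
    maps = np.asarray(maps, dtype=float)
    n_sub = maps.shape[0]
    if n_sub < 2:
        raise ValueError("need at least two subjects")
    cfg = cfg or ClusterConfig()
    shape = maps.shape[1:]
    adjacency = adjacency or AdjacencySpec(n_channels=shape[0])
    df = n_sub - 1
    thresh = float(t_dist.ppf(1.0 - cfg.cluster_alpha / 2.0, df))

    flat = maps.reshape(n_sub, -1)
    t_obs = _sign_flip_tmaps(flat, np.ones((1, n_sub)))[0].reshape(shape)

    if cfg.n_permutations >= 2**n_sub:
        # small samples: enumerate every sign pattern exactly
        patterns = np.array(
            [[1.0 if (i >> j) & 1 else -1.0 for j in range(n_sub)]
             for i in range(2**n_sub)]
        )
        signs = patterns
    else:
        rng = np.random.default_rng(cfg.seed)
        signs = rng.choice([-1.0, 1.0], size=(cfg.n_permutations, n_sub))
    t_perm = _sign_flip_tmaps(flat, signs)
    n_perm = signs.shape[0]
    null_pos = np.empty(n_perm)
    null_neg = np.empty(n_perm)
    for p in range(n_perm):
        null_pos[p], null_neg[p] = _max_masses(
            t_perm[p].reshape(shape), thresh, adjacency
        )

    clusters = []
    for members, mass in _cluster_masses(t_obs, thresh, adjacency, +1):
        p = (np.sum(null_pos >= mass) + 1.0) / (n_perm + 1.0)
        clusters.append(Cluster(members, mass, float(p), +1))
    for members, mass in _cluster_masses(t_obs, thresh, adjacency, -1):
        p = (np.sum(null_neg <= mass) + 1.0) / (n_perm + 1.0)
        clusters.append(Cluster(members, mass, float(p), -1))
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterResult(
        clusters=clusters,
        t_map=t_obs,
        df=df,
        map_shape=shape,
        n_permutations=n_perm,
        cluster_alpha=cfg.cluster_alpha,
        alpha_two_sided=cfg.alpha_two_sided,
    )


def paired_cluster_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    adjacency: AdjacencySpec | None = None,
    cfg: ClusterConfig | None = None,
) -> ClusterResult:
    """Cluster-corrected paired test of two conditions across subjects.

    The per-point statistic is the paired t (a minus b); permutations swap
    conditions within subjects, which is exactly a sign flip of the paired
    differences.
    """
    cond_a, cond_b = np.asarray(cond_a, dtype=float), np.asarray(cond_b, dtype=float)
    if cond_a.shape != cond_b.shape:
        raise ValueError("conditions must have identical shapes")
    return one_sample_cluster_test(cond_a - cond_b, adjacency, cfg)


def cluster_channel_heatmap(
    result: ClusterResult, cluster_index: int = 0
) -> np.ndarray:
    """Number of channels a cluster involves at each time-frequency point.

    Only defined for time-frequency-channel results (3-D maps); ERP-shaped
    results raise.
    """
    if len(result.map_shape) != 3:
        raise ValueError("channel heat maps require channels x freq x time maps")
    counts = np.zeros(result.map_shape[1:], dtype=int)
    members = result.clusters[cluster_index].members
    for _, fi, ti in members:
        counts[fi, ti] += 1
    return counts


def one_sample_t(values, mu: float = 0.0) -> tuple[float, int, float]:
    """One-sample t test of per-subject scalars against ``mu``.

    Returns (t, df, p). Zero variance with mean != mu yields an infinite t
    (p = 0); zero variance with mean == mu yields t = 0, p = 1.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two values")
    mean = x.mean()
    sd = x.std(ddof=1)
    df = n - 1
    if sd == 0:
        if np.isclose(mean, mu):
            return 0.0, df, 1.0
        return float(np.sign(mean - mu)) * float("inf"), df, 0.0
    t_stat = (mean - mu) / (sd / np.sqrt(n))
    p = 2.0 * float(t_dist.sf(abs(t_stat), df))
    return float(t_stat), df, min(p, 1.0)


def one_sample_t_from_summary(
    mean: float, sd: float, n: int, mu: float = 0.0
) -> tuple[float, int, float]:
    """One-sample t from reported summary statistics (mean, SD, n)."""
    if n < 2 or sd <= 0:
        raise ValueError("need n >= 2 and sd > 0")
    t_stat = (mean - mu) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * float(t_dist.sf(abs(t_stat), df))
    return float(t_stat), df, min(p, 1.0)
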