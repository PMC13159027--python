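"""SNR difference maps and cluster-based permutation significance.

The SNR of two comparison levels is contrasted channel-wise on the
z-score scale (difference map dz = z_B - z_A, optionally |z_B| when the
B side is a cross-modal map whose sign carries physiology rather than
strength).  Contiguous channels beyond the 2.5th / 97.5th percentile of
the map's own dz distribution form candidate clusters; the maximum
cluster sum per tail is tested against surrogate SNR maps built from the
stored null draws of both sides, using the same thresholding and
clustering code path as the empirical map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import ChannelGeometry, stable_stream
from .surrogates import NullDistribution, ReliabilityMap

__all__ = [
    "AdjacencyGraph",
    "adjacency_from_coords",
    "snr_difference_map",
    "Cluster",
    "ClusterResult",
    "form_clusters",
    "cluster_permutation_test",
    "bh_reject",
]


@dataclass
class AdjacencyGraph:
    """Channel neighbourhood graph (symmetric, no self-edges)."""

    neighbors: list[np.ndarray]
    edges: np.ndarray  # (E, 2) with i < j
    max_dist_mm: float

    @property
    def n_channels(self) -> int:
        return len(self.neighbors)


def adjacency_from_coords(
    geom: ChannelGeometry, max_dist_mm: float | None = None
) -> AdjacencyGraph:
    """Edges between channels within ``max_dist_mm`` (Euclidean).

    The default threshold is 1.5x the median nearest-neighbour distance,
    which on a regular grid connects face and edge-diagonal neighbours.
    """
    n = geom.n_channels
    if n == 1:
        return AdjacencyGraph([np.empty(0, dtype=int)], np.empty((0, 2), dtype=int), 0.0)
    d = squareform(pdist(geom.coords))
    if max_dist_mm is None:
        np.fill_diagonal(d, np.inf)
        max_dist_mm = 1.5 * float(np.median(d.min(axis=1)))
        np.fill_diagonal(d, 0.0)
    if max_dist_mm <= 0:
        raise ValueError("max_dist_mm must be positive")
    iu, ju = np.triu_indices(n, k=1)
    keep = d[iu, ju] <= max_dist_mm
    edges = np.column_stack([iu[keep], ju[keep]])
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i, j in edges:
        neighbors[i].append(j)
        neighbors[j].append(i)
    return AdjacencyGraph(
        [np.asarray(sorted(nb), dtype=int) for nb in neighbors], edges, float(max_dist_mm)
    )


def snr_difference_map(
    map_a: ReliabilityMap, map_b: ReliabilityMap, abs_b: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """dz = (|z_B| if abs_b else z_B) - z_A, with the joint channel mask.

    Returns ``(dz, mask)``; masked channels hold NaN.
    """
    if map_a.z.shape != map_b.z.shape:
        raise ValueError("maps must share a channel support")
    band_a = map_a.meta.get("band")
    band_b = map_b.meta.get("band")
    if band_a is not None and band_b is not None and band_a != band_b:
        raise ValueError(f"band mismatch: {band_a!r} vs {band_b!r}")
    mask = map_a.channel_mask & map_b.channel_mask
    zb = np.abs(map_b.z) if abs_b else map_b.z
    dz = np.where(mask, zb - map_a.z, np.nan)
    return dz, mask


@dataclass
class Cluster:
    channels: np.ndarray
    total: float  # sum of member dz
    tail: str  # positive | negative

    @property
    def size(self) -> int:
        return len(self.channels)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold_lo: float
    threshold_hi: float
    dz: np.ndarray
    mask: np.ndarray
    p_values: dict = field(default_factory=dict)  # tail -> p of max cluster

    def max_cluster(self, tail: str) -> Cluster | None:
        cands = [c for c in self.clusters if c.tail == tail]
        return max(cands, key=lambda c: abs(c.total)) if cands else None


def _components(supra: np.ndarray, graph: AdjacencyGraph) -> list[np.ndarray]:
    """Connected components of the subgraph induced by the boolean mask."""
    seen = np.zeros(len(supra), dtype=bool)
    comps = []
    for start in np.nonzero(supra)[0]:
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            node = stack.pop()
            comp.append(node)
            for nb in graph.neighbors[node]:
                if supra[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(np.asarray(sorted(comp), dtype=int))
    return comps


def form_clusters(
    dz: np.ndarray,
    graph: AdjacencyGraph,
    mask: np.ndarray | None = None,
    pct_lo: float = 2.5,
    pct_hi: float = 97.5,
) -> ClusterResult:
    """Threshold a dz map at its own percentiles and label contiguous
    supra-threshold clusters.

    Positive clusters are connected components of {dz > hi percentile},
    negative clusters of {dz < lo percentile} (strict inequalities, so a
    constant map yields no clusters).  Each cluster carries the sum of its
    member dz values.
    """
    dz = np.asarray(dz, dtype=float)
    if mask is None:
        mask = np.isfinite(dz)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(dz)
    if not mask.any():
        return ClusterResult([], np.nan, np.nan, dz, mask)
    lo, hi = (float(v) for v in np.percentile(dz[mask], [pct_lo, pct_hi]))
    clusters: list[Cluster] = []
    for comp in _components(mask & (dz > hi), graph):
        clusters.append(Cluster(comp, float(dz[comp].sum()), "positive"))
    for comp in _components(mask & (dz < lo), graph):
        clusters.append(Cluster(comp, float(dz[comp].sum()), "negative"))
    return ClusterResult(clusters, lo, hi, dz, mask)


def cluster_permutation_test(
    null_a: NullDistribution,
    null_b: NullDistribution,
    empirical: ClusterResult,
    graph: AdjacencyGraph,
    n_maps: int = 10000,
    abs_b: bool = False,
    seed: int = 0,
    pct_lo: float = 2.5,
    pct_hi: float = 97.5,
) -> ClusterResult:
    """p-values for the empirical maximum clusters from surrogate SNR maps.

    Each surrogate map draws one stored GA null value per channel per side
    (independently across channels), standardizes it against that side's
    own null, forms dz (respecting ``abs_b``), thresholds at the surrogate
    map's own percentiles, and records the maximum absolute cluster sum
    per tail.  The p-value of an empirical maximum cluster is the add-one
    proportion of surrogate maximum absolute sums >= its absolute sum.
    """
    if null_a.draws.shape[1] != null_b.draws.shape[1]:
        raise ValueError("null distributions must share a channel support")
    rng = stable_stream(seed, "cluster-perm")
    C = null_a.draws.shape[1]
    mask = empirical.mask
    max_sums = {"positive": np.zeros(n_maps), "negative": np.zeros(n_maps)}
    idx_a = rng.integers(null_a.n_draws, size=(n_maps, C))
    idx_b = rng.integers(null_b.n_draws, size=(n_maps, C))
    cols = np.arange(C)

    def all_z(null: NullDistribution, idx: np.ndarray) -> np.ndarray:
        sigma = null.sigma
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (null.draws[idx, cols[None, :]] - null.mu) / sigma
        z[:, sigma == 0] = np.nan
        return z

    za_all = all_z(null_a, idx_a)
    zb_all = all_z(null_b, idx_b)
    dz_all = (np.abs(zb_all) if abs_b else zb_all) - za_all
    for m in range(n_maps):
        res = form_clusters(dz_all[m], graph, mask=mask, pct_lo=pct_lo, pct_hi=pct_hi)
        for tail in ("positive", "negative"):
            mc = res.max_cluster(tail)
            max_sums[tail][m] = abs(mc.total) if mc is not None else 0.0
    out = ClusterResult(
        empirical.clusters,
        empirical.threshold_lo,
        empirical.threshold_hi,
        empirical.dz,
        empirical.mask,
    )
    for tail in ("positive", "negative"):
        mc = empirical.max_cluster(tail)
        if mc is None:
            continue
        b = int((max_sums[tail] >= abs(mc.total)).sum())
        out.p_values[tail] = (b + 1) / (n_maps + 1)
    return out


def bh_reject(p_values: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg rejection mask at level ``q`` (helper for the
    per-band collection of max-cluster p-values)."""
    from statsmodels.stats.multitest import multipletests

    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject
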