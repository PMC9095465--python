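"""Global and nodal graph topology of thresholded connectomes.

Implements the weighted graph measures used at the cohort level:

* mean functional connectivity — arithmetic mean of retained edge weights;
* global efficiency — mean inverse weighted shortest-path length, with
  edge length 1/weight (the Brain Connectivity Toolbox convention);
* Newman modularity — spectral leading-eigenvector bisection with
  Kernighan–Lin-style refinement, Q by the standard weighted formula;
* eigenvector centrality — Perron vector of the weighted adjacency,
  unit Euclidean norm;
* wiring-distance proportions — retained edges binned by Euclidean
  centroid distance into short (<= 45 mm), middle (45–75 mm) and long
  (>= 75 mm) ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import pdist, squareform

from .connectome import ThresholdedNetwork
from .synthetic import ParcelAtlas

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "mean_connectivity",
    "global_efficiency",
    "modularity_newman",
    "modularity_q",
    "eigenvector_centrality",
    "distance_bin_proportions",
    "compute_global_metrics",
    "cohort_metrics_table",
]

#: Wiring-distance bin boundaries in mm: short <= 45, long >= 75.
DEFAULT_DISTANCE_BOUNDS = (45.0, 75.0)


@dataclass(frozen=True)
class GlobalMetrics:
    mean_fc: float
    global_efficiency: float
    modularity_q: float
    partition: np.ndarray
    prop_short: float
    prop_middle: float
    prop_long: float


@dataclass(frozen=True)
class NodalMetrics:
    """Per-parcel eigenvector centrality, unit Euclidean norm."""

    eigenvector_centrality: np.ndarray


def _edge_weights(net: ThresholdedNetwork) -> np.ndarray:
    iu = np.triu_indices(net.n_parcels, k=1)
    return net.weights[iu][net.mask[iu]]


def mean_connectivity(net: ThresholdedNetwork) -> float:
    """Mean weight across all retained edges (each undirected edge once)."""
    if net.edge_count < 1:
        raise ValueError("network has no edges")
    return float(_edge_weights(net).mean())


def global_efficiency(net: ThresholdedNetwork) -> float:
    """E = mean over ordered pairs of 1/d(i,j); edge length = 1/weight."""
    n = net.n_parcels
    w = np.where(net.mask, net.weights, 0.0)
    if np.any(w[net.mask] <= 0):
        raise ValueError("global efficiency requires strictly positive edge weights")
    lengths = np.zeros_like(w)
    lengths[net.mask] = 1.0 / w[net.mask]
    d = dijkstra(csr_matrix(lengths), directed=False)
    off = ~np.eye(n, dtype=bool)
    if np.isinf(d[off]).any():
        raise ValueError("network is disconnected; efficiency undefined")
    return float((1.0 / d[off]).mean())


# ---------------------------------------------------------------------------
# Newman spectral modularity
# ---------------------------------------------------------------------------


def modularity_q(weights: np.ndarray, labels: np.ndarray) -> float:
    """Standard weighted modularity Q = sum_m (e_mm - a_m^2) at resolution 1."""
    a = np.asarray(weights, dtype=float)
    m2 = a.sum()
    if m2 <= 0:
        return 0.0
    labels = np.asarray(labels)
    q = 0.0
    for lab in np.unique(labels):
        mask = labels == lab
        e_mm = a[np.ix_(mask, mask)].sum() / m2
        a_m = a[mask].sum() / m2
        q += e_mm - a_m * a_m
    return float(q)


def _kl_refine(bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan–Lin-style single-node sweeps maximizing s' Bg s.

    Each pass moves every node exactly once (the best available move at
    each step, ties broken by node index), then keeps the best prefix of
    moves; passes repeat while they improve the objective.
    """
    n = len(s)
    s = s.copy()
    # gains below cancellation noise (relative to the matrix scale) are ties
    tol = 1e-9 * n * max(1.0, float(np.abs(bg).max()))
    for _pass in range(200):
        bs = bg @ s
        moved = np.zeros(n, dtype=bool)
        gains = np.empty(n)
        order = np.empty(n, dtype=int)
        cum = 0.0
        for step in range(n):
            # gain of flipping i: -4 s_i (Bg s)_i + 4 Bg_ii
            g = -4.0 * s * bs + 4.0 * np.diag(bg)
            g[moved] = -np.inf
            i = int(np.argmax(g))
            cum += g[i]
            gains[step] = cum
            order[step] = i
            bs = bs - 2.0 * s[i] * bg[:, i]
            s[i] = -s[i]
            moved[i] = True
        best = int(np.argmax(gains))
        best_gain = gains[best]
        # revert moves after the best prefix
        for i in order[best + 1 :]:
            s[i] = -s[i]
        if best_gain <= tol:
            # revert the whole pass
            for i in order[: best + 1]:
                s[i] = -s[i]
            return s
    return s


def modularity_newman(
    net: ThresholdedNetwork | np.ndarray, weighted: bool = True
) -> tuple[float, np.ndarray]:
    """Partition by Newman's spectral method; returns (Q, module labels).

    Iterative bisection on the (generalized) modularity matrix's leading
    eigenvector, each split refined by Kernighan–Lin-style node sweeps; a
    split is kept only if it increases Q.  ``weighted=False`` binarizes
    the retained edges first.
    """
    if isinstance(net, ThresholdedNetwork):
        a = np.where(net.mask, net.weights, 0.0).astype(float)
    else:
        a = np.asarray(net, dtype=float)
    if not weighted:
        a = (a > 0).astype(float)
    if np.any(a < 0):
        raise ValueError("modularity requires nonnegative weights")
    n = a.shape[0]
    k = a.sum(axis=1)
    m2 = k.sum()
    labels = np.zeros(n, dtype=int)
    if m2 <= 0:
        return 0.0, labels

    b = a - np.outer(k, k) / m2
    next_label = 1
    stack = [np.arange(n)]
    while stack:
        g = stack.pop()
        if len(g) < 2:
            continue
        bg = b[np.ix_(g, g)].copy()
        np.fill_diagonal(bg, np.diag(bg) - bg.sum(axis=1))
        vals, vecs = np.linalg.eigh(bg)
        lead = vecs[:, -1]
        s = np.where(lead >= 0, 1.0, -1.0)
        s = _kl_refine(bg, s)
        delta_q = float(s @ bg @ s) / (2.0 * m2)
        if delta_q <= 1e-9 or np.all(s == s[0]):
            continue
        half = g[s < 0]
        labels[half] = next_label
        next_label += 1
        stack.append(g[s > 0])
        stack.append(half)

    # relabel modules to consecutive integers ordered by first occurrence
    _, labels = np.unique(labels, return_inverse=True)
    seen: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen)
        out[i] = seen[lab]
    return modularity_q(a, out), out


# ---------------------------------------------------------------------------
# eigenvector centrality
# ---------------------------------------------------------------------------


def eigenvector_centrality(
    net: ThresholdedNetwork | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> NodalMetrics:
    """Leading eigenvector of the weighted adjacency, unit Euclidean norm.

    Power iteration on A + I (the identity shift leaves the Perron vector
    unchanged and guarantees convergence on bipartite-like graphs such as
    stars).  Requires a connected nonnegative network.
    """
    if isinstance(net, ThresholdedNetwork):
        a = np.where(net.mask, net.weights, 0.0).astype(float)
    else:
        a = np.asarray(net, dtype=float)
    if np.any(a < 0):
        raise ValueError("eigenvector centrality requires nonnegative weights")
    n = a.shape[0]
    shifted = a + np.eye(n)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = shifted @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            raise ValueError("adjacency has no edges; centrality undefined")
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    else:
        raise RuntimeError(f"power iteration did not converge in {max_iter} iterations")
    if x.sum() < 0:
        x = -x
    x = np.clip(x, 0.0, None)
    x /= np.linalg.norm(x)
    return NodalMetrics(eigenvector_centrality=x)


# ---------------------------------------------------------------------------
# wiring distance bins
# ---------------------------------------------------------------------------


def distance_bin_proportions(
    net: ThresholdedNetwork,
    atlas: ParcelAtlas,
    bounds: tuple[float, float] = DEFAULT_DISTANCE_BOUNDS,
) -> tuple[float, float, float]:
    """Proportions of retained edges that are short-, middle- and long-range.

    Boundary conventions: short if distance <= bounds[0], long if
    distance >= bounds[1], middle strictly between.
    """
    if atlas.n_parcels != net.n_parcels:
        raise ValueError(
            f"atlas has {atlas.n_parcels} parcels but network has {net.n_parcels}"
        )
    lo, hi = bounds
    d = squareform(pdist(atlas.centroids))
    iu = np.triu_indices(net.n_parcels, k=1)
    keep = net.mask[iu]
    dist = d[iu][keep]
    k = dist.size
    if k == 0:
        raise ValueError("network has no edges")
    n_short = int((dist <= lo).sum())
    n_long = int((dist >= hi).sum())
    n_middle = k - n_short - n_long
    return n_short / k, n_middle / k, n_long / k


# ---------------------------------------------------------------------------
# cohort-level convenience
# ---------------------------------------------------------------------------


def compute_global_metrics(
    net: ThresholdedNetwork,
    atlas: ParcelAtlas,
    bounds: tuple[float, float] = DEFAULT_DISTANCE_BOUNDS,
    weighted_modularity: bool = True,
) -> GlobalMetrics:
    q, partition = modularity_newman(net, weighted=weighted_modularity)
    ps, pm, pl = distance_bin_proportions(net, atlas, bounds)
    return GlobalMetrics(
        mean_fc=mean_connectivity(net),
        global_efficiency=global_efficiency(net),
        modularity_q=q,
        partition=partition,
        prop_short=ps,
        prop_middle=pm,
        prop_long=pl,
    )


def cohort_metrics_table(
    networks: dict,
    atlas: ParcelAtlas,
    bounds: tuple[float, float] = DEFAULT_DISTANCE_BOUNDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject global metrics and nodal centralities.

    ``networks`` maps subject_id -> ThresholdedNetwork.  Returns a global
    metrics table (one row per subject) and a centrality table (subject x
    parcel).
    """
    rows = []
    cent = {}
    for sid, net in networks.items():
        gm = compute_global_metrics(net, atlas, bounds)
        rows.append(
            {
                "subject_id": sid,
                "mean_fc": gm.mean_fc,
                "global_efficiency": gm.global_efficiency,
                "modularity_q": gm.modularity_q,
                "n_modules": int(gm.partition.max()) + 1,
                "prop_short": gm.prop_short,
                "prop_middle": gm.prop_middle,
                "prop_long": gm.prop_long,
            }
        )
        cent[sid] = eigenvector_centrality(net).eigenvector_centrality
    global_df = pd.DataFrame(rows)
    cent_df = pd.DataFrame.from_dict(cent, orient="index")
    cent_df.columns = [f"p{j}" for j in range(atlas.n_parcels)]
    cent_df.index.name = "subject_id"
    return global_df, cent_df
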