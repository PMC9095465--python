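"""Independent reference implementations used to check the package.

Everything here is deliberately naive — exhaustive enumeration, hand
ANOVA arithmetic, literal textbook formulas — and shares no code with
the implementation it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# spanning trees
# ---------------------------------------------------------------------------


def _is_spanning_tree(n: int, edges) -> bool:
    if len(edges) != n - 1:
        return False
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri == rj:
            return False
        parent[ri] = rj
    return True


def best_spanning_tree_weight(weights: np.ndarray) -> float:
    """Maximum total weight over ALL spanning trees, by full enumeration."""
    n = weights.shape[0]
    all_edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = -np.inf
    for subset in combinations(all_edges, n - 1):
        if _is_spanning_tree(n, subset):
            w = sum(weights[i, j] for i, j in subset)
            best = max(best, w)
    return best


# ---------------------------------------------------------------------------
# shortest paths / efficiency
# ---------------------------------------------------------------------------


def brute_force_efficiency(weights: np.ndarray) -> float:
    """Global efficiency via exhaustive simple-path search (tiny graphs)."""
    n = weights.shape[0]
    lengths = {
        (i, j): 1.0 / weights[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and weights[i, j] > 0
    }

    def shortest(src, dst):
        best = [np.inf]

        def walk(node, visited, acc):
            if acc >= best[0]:
                return
            if node == dst:
                best[0] = acc
                return
            for nxt in range(n):
                if nxt not in visited and (node, nxt) in lengths:
                    walk(nxt, visited | {nxt}, acc + lengths[(node, nxt)])

        walk(src, {src}, 0.0)
        return best[0]

    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                total += 1.0 / shortest(i, j)
    return total / (n * (n - 1))


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------


def modularity_of(weights: np.ndarray, labels) -> float:
    a = np.asarray(weights, dtype=float)
    labels = np.asarray(labels)
    m2 = a.sum()
    q = 0.0
    for lab in np.unique(labels):
        mask = labels == lab
        q += a[np.ix_(mask, mask)].sum() / m2 - (a[mask].sum() / m2) ** 2
    return q


def _restricted_growth_strings(n: int, k_max: int):
    """All set partitions of n items into at most k_max blocks."""
    labels = np.zeros(n, dtype=int)

    def rec(pos, max_used):
        if pos == n:
            yield labels.copy()
            return
        for lab in range(min(max_used + 1, k_max - 1) + 1):
            labels[pos] = lab
            yield from rec(pos + 1, max(max_used, lab))

    yield from rec(1, 0)


def best_modularity_exhaustive(weights: np.ndarray, k_max: int = 3) -> float:
    """Max Q over every partition into at most k_max modules (N small)."""
    best = -np.inf
    for labels in _restricted_growth_strings(weights.shape[0], k_max):
        best = max(best, modularity_of(weights, labels))
    return best


# ---------------------------------------------------------------------------
# ICC by hand ANOVA
# ---------------------------------------------------------------------------


def icc1_by_hand(m: np.ndarray) -> float:
    m = np.asarray(m, dtype=float)
    e, w = m.shape
    grand = m.mean()
    ssb = 0.0
    for row in m:
        ssb += w * (row.mean() - grand) ** 2
    ssw = 0.0
    for row in m:
        for x in row:
            ssw += (x - row.mean()) ** 2
    bms = ssb / (e - 1)
    wms = ssw / (e * (w - 1))
    return (bms - wms) / (bms + (w - 1) * wms)


# ---------------------------------------------------------------------------
# rank statistics by hand
# ---------------------------------------------------------------------------


def kruskal_by_hand(samples) -> float:
    """H with tie correction from literal rank arithmetic."""
    pooled = np.concatenate([np.asarray(s, float) for s in samples])
    n = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average rank, 1-based
        i = j
    h = 0.0
    start = 0
    for s in samples:
        k = len(s)
        r = ranks[start : start + k].sum()
        h += r * r / k
        start += k
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    ties = ((counts**3 - counts).sum()) / (n**3 - n)
    return h / (1.0 - ties) if ties < 1 else 0.0


def partial_corr_by_hand(x, y, cov) -> float:
    """Residualize-then-correlate with explicit normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.column_stack([np.ones(len(x)), np.asarray(cov, float)])
    bx = np.linalg.solve(z.T @ z, z.T @ x)
    by = np.linalg.solve(z.T @ z, z.T @ y)
    rx, ry = x - z @ bx, y - z @ by
    return float(
        (rx - rx.mean()) @ (ry - ry.mean())
        / np.sqrt(((rx - rx.mean()) ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
    )


def bh_by_hand(p, q):
    """Step-up BH: reject mask via the i*q/m comparison, by hand."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


# ---------------------------------------------------------------------------
# NBS exact enumeration
# ---------------------------------------------------------------------------


def _components_max_size(edges, n) -> int:
    if not edges:
        return 0
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        parent[find(i)] = find(j)
    sizes: dict[int, int] = {}
    for i, j in edges:
        sizes[find(i)] = sizes.get(find(i), 0) + 1
    return max(sizes.values())


def exact_nbs_pvalue(edge_data: np.ndarray, na: int, n_nodes: int, edge_list,
                     p_threshold: float, observed_size: int, direction: int) -> float:
    """Exact permutation p for a max-component-size statistic.

    ``edge_data`` is (n_subjects, n_edges) with the first ``na`` rows the
    observed group A.  Enumerates every split of the pooled subjects.
    """
    from scipy import stats as sps

    n_subj = edge_data.shape[0]
    df = n_subj - 2
    t_crit = sps.t.isf(p_threshold / 2.0, df)
    count = 0
    total = 0
    for combo in combinations(range(n_subj), na):
        in_a = np.zeros(n_subj, dtype=bool)
        in_a[list(combo)] = True
        xa, xb = edge_data[in_a], edge_data[~in_a]
        ma, mb = xa.mean(0), xb.mean(0)
        va = ((xa - ma) ** 2).sum(0)
        vb = ((xb - mb) ** 2).sum(0)
        se = np.sqrt((va + vb) / df * (1 / na + 1 / (n_subj - na)))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, (ma - mb) / np.where(se > 0, se, 1), 0.0)
        keep = (np.abs(t) > t_crit) & (direction * t > 0)
        edges = [edge_list[k] for k in np.flatnonzero(keep)]
        if _components_max_size(edges, n_nodes) >= observed_size:
            count += 1
        total += 1
    return count / total
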