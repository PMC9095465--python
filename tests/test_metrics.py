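"""Graph topology: mean connectivity, efficiency, Newman modularity,
eigenvector centrality, and wiring-distance proportions."""

import numpy as np
import pytest

from fcpipe import (
    build_static_network,
    distance_bin_proportions,
    eigenvector_centrality,
    generate_atlas,
    global_efficiency,
    mean_connectivity,
    modularity_newman,
    modularity_q,
)
from fcpipe.synthetic import ParcelAtlas
from conftest import make_network
from oracles import (
    best_modularity_exhaustive,
    brute_force_efficiency,
    modularity_of,
)
import pandas as pd


def _sym_random(n, seed, lo=0.05, hi=1.0):
    rng = np.random.default_rng(seed)
    v = rng.uniform(lo, hi, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    return v


class TestMeanConnectivity:
    def test_constant_and_simple_mean(self):
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = 0.2
        v[1, 2] = v[2, 1] = 0.4
        v[2, 3] = v[3, 2] = 0.6
        assert mean_connectivity(make_network(v)) == pytest.approx(0.4)
        assert mean_connectivity(make_network(np.full((3, 3), 0.4) - 0.4 * np.eye(3))) \
            == pytest.approx(0.4)

    def test_matches_independent_summation(self):
        v = _sym_random(12, 0)
        net = make_network(v)
        iu = np.triu_indices(12, 1)
        expected = v[iu].sum() / len(iu[0])
        assert mean_connectivity(net) == pytest.approx(expected)


class TestGlobalEfficiency:
    def test_complete_unit_graph(self):
        v = np.ones((6, 6)) - np.eye(6)
        assert global_efficiency(make_network(v)) == pytest.approx(1.0)

    def test_three_node_path(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 1.0
        v[1, 2] = v[2, 1] = 1.0
        # distances {1, 1, 2} -> E = (1 + 1 + 0.5) / 3
        assert global_efficiency(make_network(v)) == pytest.approx(5.0 / 6.0)

    def test_matches_brute_force_path_search(self):
        rng = np.random.default_rng(7)
        v = _sym_random(8, 7)
        # sparsify a bit but keep connected (add a ring)
        keep = rng.random((8, 8)) < 0.4
        keep = keep | keep.T
        for i in range(8):
            keep[i, (i + 1) % 8] = keep[(i + 1) % 8, i] = True
        v = np.where(keep, v, 0.0)
        np.fill_diagonal(v, 0)
        assert global_efficiency(make_network(v)) == pytest.approx(
            brute_force_efficiency(v)
        )

    def test_disconnected_errors(self):
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = 0.5
        v[2, 3] = v[3, 2] = 0.5
        with pytest.raises(ValueError, match="disconnected"):
            global_efficiency(make_network(v))


class TestModularity:
    def test_two_cliques_with_vanishing_bridge(self):
        """Two 5-cliques joined by an epsilon bridge: Q -> 0.5 for the
        2-module split, and the algorithm finds it."""
        n = 10
        v = np.zeros((n, n))
        v[:5, :5] = 1.0
        v[5:, 5:] = 1.0
        np.fill_diagonal(v, 0)
        v[4, 5] = v[5, 4] = 1e-9
        q, labels = modularity_newman(make_network(v))
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[9]
        assert q == pytest.approx(0.5, abs=1e-6)

    def test_complete_graph_single_module(self):
        v = np.ones((8, 8)) - np.eye(8)
        q, labels = modularity_newman(make_network(v))
        assert q == 0.0
        assert len(set(labels)) == 1

    def test_beats_exhaustive_search_on_planted_modules(self):
        """12 nodes, 3 planted modules: found Q matches the exhaustive
        optimum over all partitions into <= 3 modules and is at least the
        planted partition's Q."""
        rng = np.random.default_rng(0)
        n = 12
        planted = np.repeat([0, 1, 2], 4)
        v = np.where(
            planted[:, None] == planted[None, :],
            rng.uniform(0.6, 1.0, (n, n)),
            rng.uniform(0.0, 0.15, (n, n)),
        )
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        q, labels = modularity_newman(make_network(v))
        assert q >= modularity_of(v, planted) - 1e-9
        assert q >= best_modularity_exhaustive(v, k_max=3) - 1e-9

    def test_q_formula_against_independent_implementation(self):
        v = _sym_random(10, 3)
        labels = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 0])
        assert modularity_q(v, labels) == pytest.approx(modularity_of(v, labels))

    def test_cross_module_edge_decreases_planted_q(self):
        """Adding a between-module edge never increases the fixed
        partition's Q."""
        v = np.zeros((8, 8))
        v[:4, :4] = 0.8
        v[4:, 4:] = 0.8
        np.fill_diagonal(v, 0)
        planted = np.repeat([0, 1], 4)
        q_before = modularity_q(v, planted)
        v2 = v.copy()
        v2[0, 7] = v2[7, 0] = 0.8
        assert modularity_q(v2, planted) < q_before

    def test_igraph_cross_check(self):
        """Our spectral+refinement Q is at least igraph's leading-eigenvector Q."""
        import igraph as ig

        v = _sym_random(25, 11, lo=0.0, hi=1.0)
        v[v < 0.5] = 0.0  # sparsify
        # make connected via ring
        for i in range(25):
            v[i, (i + 1) % 25] = max(v[i, (i + 1) % 25], 0.6)
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        q, _ = modularity_newman(make_network(v))
        g = ig.Graph.Weighted_Adjacency(v.tolist(), mode="undirected")
        ref = g.community_leading_eigenvector(weights="weight")
        assert q >= ref.modularity - 1e-9


class TestEigenvectorCentrality:
    def test_star_closed_form(self):
        v = np.zeros((5, 5))
        v[0, 1:] = 1.0
        v[1:, 0] = 1.0
        ec = eigenvector_centrality(make_network(v)).eigenvector_centrality
        assert ec[0] == pytest.approx(1 / np.sqrt(2), abs=1e-8)
        assert np.allclose(ec[1:], 1 / (2 * np.sqrt(2)), atol=1e-8)

    def test_ring_uniform(self):
        n = 8
        v = np.zeros((n, n))
        for i in range(n):
            v[i, (i + 1) % n] = v[(i + 1) % n, i] = 0.7
        ec = eigenvector_centrality(make_network(v)).eigenvector_centrality
        assert np.allclose(ec, 1 / np.sqrt(n), atol=1e-8)

    def test_matches_dense_eigensolver(self):
        v = _sym_random(10, 9)
        ec = eigenvector_centrality(make_network(v)).eigenvector_centrality
        w, vecs = np.linalg.eigh(v)
        ref = vecs[:, -1]
        ref = np.abs(ref) / np.linalg.norm(ref)
        assert np.allclose(ec, ref, atol=1e-8)

    def test_scale_invariance(self):
        v = _sym_random(9, 13)
        a = eigenvector_centrality(make_network(v)).eigenvector_centrality
        b = eigenvector_centrality(make_network(5.0 * v)).eigenvector_centrality
        assert np.allclose(a, b, atol=1e-9)

    def test_unit_norm_and_nonnegative(self):
        v = _sym_random(15, 21)
        ec = eigenvector_centrality(make_network(v)).eigenvector_centrality
        assert np.linalg.norm(ec) == pytest.approx(1.0)
        assert np.all(ec >= 0)


def _atlas_from_coords(coords, labels=None):
    n = len(coords)
    return ParcelAtlas(
        pd.DataFrame(
            {
                "parcel_id": np.arange(n),
                "parcel_name": [f"p{i}" for i in range(n)],
                "network_label": labels if labels is not None else ["net"] * n,
                "x": [c[0] for c in coords],
                "y": [c[1] for c in coords],
                "z": [c[2] for c in coords],
            }
        )
    )


class TestDistanceBins:
    def test_triangle_one_edge_per_bin(self):
        # pairwise distances 40 (0-1), 60 (0-2 along y via placement), 80
        coords = [(0, 0, 0), (40, 0, 0), (0, 60, 0)]
        d12 = np.hypot(40, 60)  # 72.1 -> middle
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 0.5
        v[0, 2] = v[2, 0] = 0.5
        v[1, 2] = v[2, 1] = 0.5
        atlas = _atlas_from_coords(coords)
        ps, pm, pl = distance_bin_proportions(make_network(v), atlas)
        assert d12 < 75
        assert (ps, pm, pl) == (pytest.approx(1 / 3), pytest.approx(2 / 3), 0.0)

    def test_exact_boundaries(self):
        # 45 mm is short; 75 mm is long
        coords = [(0, 0, 0), (45, 0, 0), (-75, 0, 0)]
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 0.5
        v[0, 2] = v[2, 0] = 0.5
        atlas = _atlas_from_coords(coords)
        ps, pm, pl = distance_bin_proportions(make_network(v), atlas)
        assert ps == pytest.approx(0.5)
        assert pm == 0.0
        assert pl == pytest.approx(0.5)

    def test_sums_to_one_and_matches_recount(self, small_atlas, small_cohort):
        _, series, _, _ = small_cohort
        atlas = generate_atlas(60, 6, seed=1)
        net = build_static_network(series[0], 0.2).network
        ps, pm, pl = distance_bin_proportions(net, atlas)
        assert ps + pm + pl == pytest.approx(1.0, abs=1e-12)
        # per-edge recount
        from scipy.spatial.distance import squareform, pdist

        d = squareform(pdist(atlas.centroids))
        i, j, _ = net.edge_array()
        dist = d[i, j]
        assert ps == pytest.approx((dist <= 45).mean())
        assert pl == pytest.approx((dist >= 75).mean())

    def test_size_mismatch(self, small_atlas):
        v = _sym_random(5, 0)
        with pytest.raises(ValueError, match="parcels"):
            distance_bin_proportions(make_network(v), small_atlas)


def test_uc_like_offset_raises_group_mean_fc():
    """A global connectivity offset shows up as higher mean retained-edge
    weight in the offset group (the 'higher global FC' pattern)."""
    from fcpipe import CohortConfig, generate_cohort

    cfg = CohortConfig(
        n_per_group=8,
        groups=("HC", "UC"),
        n_parcels=40,
        n_networks=4,
        group_fc_offset={"UC": 0.06},
        planted_delta={},
        stability_mean={"HC": 0.6, "UC": 0.6},
    )
    series, phen, _ = generate_cohort(cfg, seed=4)
    means = {}
    for g in ("HC", "UC"):
        ids = set(phen.loc[phen["group"] == g, "subject_id"])
        vals = [
            mean_connectivity(build_static_network(ts, 0.15).network)
            for ts in series
            if ts.subject_id in ids
        ]
        means[g] = np.mean(vals)
    assert means["UC"] > means["HC"]
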