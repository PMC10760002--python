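"""Contact probabilities, community partitioning, difference networks."""

import itertools

import networkx as nx
import numpy as np
import pytest

from protomerscope import (
    ContactMatrix,
    contact_probabilities,
    difference_network,
    partition_communities,
    stable_contacts,
)
from protomerscope.errors import AlignmentError
from protomerscope.network import CommunityPartition
from protomerscope.structure import TrajectoryEnsemble

from conftest import toy_structure


def two_residue_structure(gap_atoms=1):
    """Two CA-only residues, ids 10 and 20 (sequence-separated)."""
    return toy_structure(
        [
            (10, "GLY", "CA", "C", [0.0, 0.0, 0.0]),
            (20, "GLY", "CA", "C", [4.4, 0.0, 0.0]),
        ]
    )


def ensemble_from_offsets(structure, offsets):
    """One replica whose frames move the second residue along +x."""
    frames = []
    for off in offsets:
        c = structure.atoms.coord.copy()
        c[1, 0] = off
        frames.append(c)
    return TrajectoryEnsemble(structure, [np.stack(frames)], burn_in_fraction=0.0)


class TestContactProbabilities:
    def test_always_touching_pair_probability_one(self):
        s = two_residue_structure()
        ens = ensemble_from_offsets(s, [4.4] * 10)
        mat = contact_probabilities(ens)
        assert mat.probabilities[0, 1] == 1.0

    def test_alternating_frames_probability_half(self):
        s = two_residue_structure()
        ens = ensemble_from_offsets(s, [4.4, 4.6] * 5)
        mat = contact_probabilities(ens)
        assert mat.probabilities[0, 1] == 0.5

    def test_sequence_neighbours_excluded(self):
        s = toy_structure(
            [
                (10, "GLY", "CA", "C", [0.0, 0.0, 0.0]),
                (11, "GLY", "CA", "C", [3.0, 0.0, 0.0]),
                (13, "GLY", "CA", "C", [0.0, 3.0, 0.0]),
            ]
        )
        ens = TrajectoryEnsemble(s, [s.atoms.coord[None]], burn_in_fraction=0.0)
        mat = contact_probabilities(ens)
        idx = {r: i for i, r in enumerate(mat.residue_index)}
        assert mat.probabilities[idx[("A", 10)], idx[("A", 11)]] == 0.0  # |Δ|=1
        assert mat.probabilities[idx[("A", 10)], idx[("A", 13)]] == 1.0  # |Δ|=3

    def test_matches_bruteforce_counting(self):
        rng = np.random.default_rng(19)
        protein = []
        for rid in (10, 14, 18, 22):
            for name in ("CA", "CB"):
                protein.append((rid, "ALA", name, "C", rng.uniform(0, 10, 3)))
        s = toy_structure(protein)
        frames = np.stack(
            [s.atoms.coord + rng.normal(scale=2.0, size=s.atoms.coord.shape)
             for _ in range(20)]
        )
        ens = TrajectoryEnsemble(s, [frames], burn_in_fraction=0.0)
        mat = contact_probabilities(ens)
        res_ids = [10, 14, 18, 22]
        atoms_of = {
            rid: np.flatnonzero(s.atoms.res_id == rid) for rid in res_ids
        }
        for i, j in itertools.combinations(range(4), 2):
            count = 0
            for f in frames:
                d = np.linalg.norm(
                    f[atoms_of[res_ids[i]]][:, None] - f[atoms_of[res_ids[j]]][None],
                    axis=-1,
                )
                if d.min() <= 4.5:
                    count += 1
            assert mat.probabilities[i, j] == pytest.approx(count / 20, abs=1e-12)

    def test_invariant_to_frame_order(self):
        s = two_residue_structure()
        offsets = [4.4, 4.6, 4.4, 4.7, 4.2]
        a = contact_probabilities(ensemble_from_offsets(s, offsets))
        b = contact_probabilities(ensemble_from_offsets(s, offsets[::-1]))
        assert np.array_equal(a.probabilities, b.probabilities)


def matrix_from_edges(residues, edges):
    n = len(residues)
    p = np.zeros((n, n))
    idx = {r: i for i, r in enumerate(residues)}
    for (a, b), w in edges.items():
        p[idx[a], idx[b]] = p[idx[b], idx[a]] = w
    return ContactMatrix(residue_index=tuple(residues), probabilities=p)


class TestStableContacts:
    def test_boundary_inclusive(self):
        residues = [("A", 1), ("A", 5), ("A", 9)]
        mat = matrix_from_edges(
            residues, {(("A", 1), ("A", 5)): 0.7, (("A", 1), ("A", 9)): 0.699}
        )
        g = stable_contacts(mat)
        assert g.has_edge(("A", 1), ("A", 5))
        assert not g.has_edge(("A", 1), ("A", 9))
        assert g[("A", 1)][("A", 5)]["weight"] == pytest.approx(0.7)

    def test_empty_matrix_gives_empty_graph(self):
        residues = [("A", 1), ("A", 5)]
        g = stable_contacts(matrix_from_edges(residues, {}))
        assert g.number_of_edges() == 0

    def test_edges_equal_thresholded_support(self):
        rng = np.random.default_rng(23)
        residues = [("A", i) for i in range(0, 40, 4)]
        edges = {}
        for a, b in itertools.combinations(residues, 2):
            edges[(a, b)] = float(rng.random())
        mat = matrix_from_edges(residues, edges)
        g = stable_contacts(mat)
        want = {frozenset(e) for e, w in edges.items() if w >= 0.7}
        assert {frozenset(e) for e in g.edges} == want


def exhaustive_best_partition(graph, k):
    """Independent brute-force: best modularity over all k-partitions."""
    nodes = list(graph.nodes())
    best_q = -np.inf
    for labels in itertools.product(range(k), repeat=len(nodes)):
        if len(set(labels)) != k:
            continue
        blocks = [
            {n for n, l in zip(nodes, labels) if l == c} for c in range(k)
        ]
        q = nx.community.modularity(graph, blocks, weight="weight")
        best_q = max(best_q, q)
    return best_q


class TestPartition:
    def test_two_disjoint_cliques_split_exactly(self):
        g = nx.Graph()
        a = [("A", i) for i in (1, 5, 9)]
        b = [("A", i) for i in (20, 24, 28)]
        for grp in (a, b):
            for u, v in itertools.combinations(grp, 2):
                g.add_edge(u, v, weight=1.0)
        part = partition_communities(g, k=2)
        comms = part.communities()
        assert sorted(map(sorted, comms)) == sorted(map(sorted, [a, b]))

    def test_matches_exhaustive_optimum_on_small_graphs(self):
        rng = np.random.default_rng(29)
        for trial in range(8):
            n = int(rng.integers(5, 9))
            g = nx.Graph()
            nodes = [("A", 4 * i) for i in range(n)]
            g.add_nodes_from(nodes)
            for u, v in itertools.combinations(nodes, 2):
                if rng.random() < 0.5:
                    g.add_edge(u, v, weight=float(rng.uniform(0.7, 1.0)))
            if g.number_of_edges() == 0:
                continue
            k = 3
            part = partition_communities(g, k=k)
            # compare on the connected core the implementation partitions
            core = [m for m in nodes if g.degree(m) > 0]
            if len(core) < k:
                continue
            sub = g.subgraph(core)
            blocks = {}
            for m in core:
                blocks.setdefault(part.assignment[m], set()).add(m)
            q_impl = nx.community.modularity(sub, list(blocks.values()), weight="weight")
            q_best = exhaustive_best_partition(sub, k)
            assert q_impl >= q_best - 1e-9

    def test_four_lobe_dimer_recovered(self):
        # two protomers × two lobes, dense within a lobe, sparse across
        g = nx.Graph()
        lobes = {}
        rng = np.random.default_rng(31)
        for p, ids in (("A", range(0, 40, 4)), ("B", range(0, 40, 4))):
            n_lobe = [(p, i) for i in ids[:5]]
            c_lobe = [(p, i + 100) for i in ids[5:]]
            lobes[(p, "N")] = n_lobe
            lobes[(p, "C")] = c_lobe
            for grp in (n_lobe, c_lobe):
                for u, v in itertools.combinations(grp, 2):
                    g.add_edge(u, v, weight=1.0)
        # weak inter-lobe and inter-protomer links keep the graph connected
        g.add_edge(("A", 0), ("A", 120), weight=0.7)
        g.add_edge(("B", 0), ("B", 120), weight=0.7)
        g.add_edge(("A", 0), ("B", 0), weight=0.7)
        part = partition_communities(g, k=4)
        got = {frozenset(c) for c in part.communities()}
        want = {frozenset(v) for v in lobes.values()}
        assert got == want

    def test_invariant_under_graph_preserving_relabeling(self):
        rng = np.random.default_rng(37)
        g = nx.Graph()
        nodes = [("A", 4 * i) for i in range(8)]
        for u, v in itertools.combinations(nodes, 2):
            if rng.random() < 0.6:
                g.add_edge(u, v, weight=float(rng.uniform(0.7, 1.0)))
        part = partition_communities(g, k=3)
        # isomorphic copy: shift residue ids by a constant
        mapping = {(p, i): (p, i + 1000) for p, i in g.nodes}
        g2 = nx.relabel_nodes(g, mapping)
        part2 = partition_communities(g2, k=3)
        q1 = nx.community.modularity(g, [set(c) for c in part.communities()],
                                     weight="weight")
        q2 = nx.community.modularity(g2, [set(c) for c in part2.communities()],
                                     weight="weight")
        assert q1 == pytest.approx(q2, abs=1e-12)

    def test_k_larger_than_nodes_rejected(self):
        g = nx.Graph()
        g.add_edge(("A", 1), ("A", 5), weight=1.0)
        with pytest.raises(ValueError):
            partition_communities(g, k=3)


class TestDifferenceNetwork:
    def _setup(self):
        residues = [("A", 0), ("A", 10), ("B", 0), ("B", 10)]
        part = CommunityPartition(
            assignment={r: i for i, r in enumerate(residues)}, k=4
        )
        return residues, part

    def test_identical_ensembles_give_zero(self):
        residues, part = self._setup()
        mat = matrix_from_edges(residues, {(("A", 0), ("B", 0)): 0.9})
        diff = difference_network(mat, mat, part)
        assert all(v == 0.0 for v in diff.delta_contacts.values())
        assert diff.interprotomer_sum == 0.0

    def test_hand_computed_deltas(self):
        residues, part = self._setup()
        apo = matrix_from_edges(
            residues,
            {(("A", 0), ("B", 0)): 0.8, (("A", 0), ("A", 10)): 0.9},
        )
        holo = matrix_from_edges(
            residues,
            {(("A", 0), ("B", 0)): 0.95, (("A", 0), ("A", 10)): 0.75,
             (("A", 10), ("B", 10)): 0.85},
        )
        diff = difference_network(apo, holo, part)
        # each community is a single residue so mean == pair delta
        assert diff.delta_contacts[(0, 2)] == pytest.approx(0.15)
        assert diff.delta_contacts[(0, 1)] == pytest.approx(-0.15)
        assert diff.delta_contacts[(1, 3)] == pytest.approx(0.85)
        assert diff.interprotomer_sum == pytest.approx(0.15 + 0.85)

    def test_antisymmetry_under_ensemble_swap(self):
        residues, part = self._setup()
        rng = np.random.default_rng(41)
        edges_a, edges_h = {}, {}
        for pair in itertools.combinations(residues, 2):
            edges_a[pair] = float(rng.random())
            edges_h[pair] = float(rng.random())
        apo = matrix_from_edges(residues, edges_a)
        holo = matrix_from_edges(residues, edges_h)
        for mode in ("union", "per_ensemble"):
            for stat in ("mean", "sum"):
                fwd = difference_network(apo, holo, part, statistic=stat,
                                         stability_mode=mode)
                rev = difference_network(holo, apo, part, statistic=stat,
                                         stability_mode=mode)
                for key in fwd.delta_contacts:
                    assert fwd.delta_contacts[key] == pytest.approx(
                        -rev.delta_contacts[key], abs=1e-12
                    )
                assert fwd.interprotomer_sum == pytest.approx(
                    -rev.interprotomer_sum, abs=1e-12
                )

    def test_interprotomer_sum_is_sum_of_cross_pairs(self):
        residues, part = self._setup()
        rng = np.random.default_rng(43)
        edges = {p: float(rng.uniform(0.7, 1)) for p in
                 itertools.combinations(residues, 2)}
        apo = matrix_from_edges(residues, {p: 0.75 for p in edges})
        holo = matrix_from_edges(residues, edges)
        diff = difference_network(apo, holo, part)
        cross = sum(
            v for (a, b), v in diff.delta_contacts.items()
            if diff.community_protomer[a] != diff.community_protomer[b]
        )
        assert diff.interprotomer_sum == pytest.approx(cross, abs=1e-12)

    def test_index_mismatch_raises(self):
        residues, part = self._setup()
        other = [("A", 0), ("A", 10), ("B", 0), ("B", 99)]
        apo = matrix_from_edges(residues, {})
        holo = matrix_from_edges(other, {})
        with pytest.raises(AlignmentError):
            difference_network(apo, holo, part)
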