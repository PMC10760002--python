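"""Difference contact-network analysis of trajectory ensembles.

Pipeline: residue-pair contact probabilities per ensemble → stable-contact
graph (probability ≥ 0.7) → partition into a fixed number of communities
(k = 4 for a two-lobe dimer: N-lobe and C-lobe of each protomer) → signed
community-pair contact changes between two ensembles (e.g. holo − apo), with
the inter-protomer changes summed as a dimer-interface stability readout.

Contact definition: two residues are in contact in a frame when any pair of
their heavy atoms is within 4.5 Å; sequence neighbours (|Δresid| < 3 within
a protomer) are excluded, all inter-protomer pairs are eligible.  The
probability is the fraction of pooled post-burn-in frames with a contact.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import networkx as nx
from scipy.spatial import cKDTree

from .anchors import DEFAULT_THRESHOLDS, Thresholds
from .errors import AlignmentError
from .structure import TrajectoryEnsemble

#: minimum sequence separation for an intra-protomer pair to be eligible
MIN_SEQ_SEPARATION = 3

Residue = tuple[str, int]  # (protomer label, author residue id)


@dataclass
class ContactMatrix:
    """Symmetric residue-pair contact probabilities of one ensemble."""

    residue_index: tuple[Residue, ...]
    probabilities: np.ndarray
    ensemble_id: str = ""

    def __post_init__(self):
        p = self.probabilities
        n = len(self.residue_index)
        if p.shape != (n, n):
            raise ValueError("probability matrix shape does not match residue index")
        if not np.allclose(p, p.T):
            raise ValueError("contact matrix must be symmetric")
        if np.any(np.diag(p) != 0):
            raise ValueError("diagonal must be zero")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("entries must be probabilities")


def contact_probabilities(
    ensemble: TrajectoryEnsemble,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> ContactMatrix:
    """Fraction of analysis frames in which each eligible residue pair touches."""
    topo = ensemble.topology
    atoms = topo.atoms
    labels = topo.protomer_labels()

    # atom → residue slot
    residues: list[Residue] = []
    slot_of: dict[Residue, int] = {}
    atom_idx: list[int] = []
    atom_slot: list[int] = []
    for label in labels:
        mask = topo.protomer_mask(label) & topo.heavy_mask
        for i in np.flatnonzero(mask):
            key = (label, int(atoms.res_id[i]))
            if key not in slot_of:
                slot_of[key] = len(residues)
                residues.append(key)
            atom_idx.append(int(i))
            atom_slot.append(slot_of[key])
    atom_idx = np.asarray(atom_idx)
    atom_slot = np.asarray(atom_slot)
    n_res = len(residues)

    res_label = np.array([labels.index(r[0]) for r in residues])
    res_id = np.array([r[1] for r in residues])
    eligible = (res_label[:, None] != res_label[None, :]) | (
        np.abs(res_id[:, None] - res_id[None, :]) >= MIN_SEQ_SEPARATION
    )

    counts = np.zeros((n_res, n_res), dtype=np.int64)
    n_frames = 0
    for _, frame in ensemble.iter_analysis_frames():
        n_frames += 1
        tree = cKDTree(frame[atom_idx])
        pairs = tree.query_pairs(thresholds.contact_cutoff, output_type="ndarray")
        if pairs.size == 0:
            continue
        si = atom_slot[pairs[:, 0]]
        sj = atom_slot[pairs[:, 1]]
        keep = si != sj
        si, sj = si[keep], sj[keep]
        # a residue pair counts once per frame regardless of atom-pair count
        flat = np.unique(np.minimum(si, sj) * n_res + np.maximum(si, sj))
        counts.flat[flat] += 1
    probs = counts / max(n_frames, 1)
    probs = probs + probs.T
    probs[~eligible] = 0.0
    np.fill_diagonal(probs, 0.0)
    return ContactMatrix(
        residue_index=tuple(residues),
        probabilities=probs,
        ensemble_id=topo.source or "ensemble",
    )


def stable_contacts(
    matrix: ContactMatrix,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> nx.Graph:
    """Graph over residues with an edge for every contact of probability ≥ 0.7
    (inclusive), weighted by the probability."""
    g = nx.Graph()
    g.add_nodes_from(matrix.residue_index)
    n = len(matrix.residue_index)
    for i in range(n):
        for j in range(i + 1, n):
            p = matrix.probabilities[i, j]
            if p >= thresholds.contact_stability:
                g.add_edge(
                    matrix.residue_index[i], matrix.residue_index[j], weight=float(p)
                )
    return g


@dataclass(frozen=True)
class CommunityPartition:
    """Assignment of every residue to one of exactly k communities.

    Community ids are 0..k−1, ordered by each community's lowest member in
    the residue ordering, which makes the labelling deterministic.
    """

    assignment: dict[Residue, int]
    k: int

    def __post_init__(self):
        used = set(self.assignment.values())
        if used != set(range(self.k)):
            raise ValueError(f"expected exactly {self.k} non-empty communities")

    def communities(self) -> list[list[Residue]]:
        out: list[list[Residue]] = [[] for _ in range(self.k)]
        for node, c in self.assignment.items():
            out[c].append(node)
        return [sorted(c) for c in out]


def _canonical_labels(blocks, node_order) -> dict:
    """Relabel communities 0..k−1 by lowest member position."""
    pos = {n: i for i, n in enumerate(node_order)}
    ordered = sorted(blocks, key=lambda b: min(pos[n] for n in b))
    return {n: c for c, b in enumerate(ordered) for n in b}


def _weighted_modularity(graph: nx.Graph, blocks) -> float:
    return nx.community.modularity(graph, blocks, weight="weight")


def _exact_partition(graph: nx.Graph, k: int, node_order):
    """Optimal-modularity partition by exhaustive enumeration (small graphs).

    Enumerates restricted-growth strings with at most k blocks and keeps the
    best partition with exactly k non-empty blocks; ties broken by canonical
    (lexicographically smallest) block structure for determinism.
    """
    nodes = list(node_order)
    n = len(nodes)
    best = None

    def recurse(i, labels, n_used):
        nonlocal best
        if n - i < k - n_used:  # cannot reach k blocks any more
            return
        if i == n:
            if n_used != k:
                return
            blocks = [[] for _ in range(k)]
            for node, lab in zip(nodes, labels):
                blocks[lab].append(node)
            q = _weighted_modularity(graph, [frozenset(b) for b in blocks])
            key = (q, [tuple(b) for b in blocks])
            if best is None or q > best[0] + 1e-15:
                best = (q, key[1])
            return
        for lab in range(min(n_used + 1, k)):
            labels.append(lab)
            recurse(i + 1, labels, max(n_used, lab + 1))
            labels.pop()

    recurse(0, [], 0)
    assert best is not None
    return [set(b) for b in best[1]]


def _greedy_partition(graph: nx.Graph, k: int, node_order):
    """CNM-style greedy modularity agglomeration merged down to exactly k
    communities; ties broken by the lowest-index community pair."""
    pos = {n: i for i, n in enumerate(node_order)}
    m2 = 2.0 * sum(d.get("weight", 1.0) for _, _, d in graph.edges(data=True))
    if m2 == 0:
        # no edges: partition by node order into k contiguous groups
        chunks = np.array_split(np.arange(len(node_order)), k)
        return [{node_order[i] for i in c} for c in chunks if len(c)]
    comms = {i: {n} for i, n in enumerate(node_order)}
    degree = {i: graph.degree(n, weight="weight") for i, n in enumerate(node_order)}
    between: dict[tuple[int, int], float] = {}
    index_of = {n: i for i, n in enumerate(node_order)}
    for u, v, d in graph.edges(data=True):
        a, b = sorted((index_of[u], index_of[v]))
        between[(a, b)] = between.get((a, b), 0.0) + d.get("weight", 1.0)

    def min_pos(c):
        return min(pos[n] for n in comms[c])

    while len(comms) > k:
        best_gain, best_pair = None, None
        live = sorted(comms)
        candidates = list(between) or list(combinations(live, 2))
        for a, b in candidates:
            if a not in comms or b not in comms:
                continue
            e_ab = between.get((a, b), 0.0)
            gain = 2.0 * (e_ab / m2 - degree[a] * degree[b] / (m2 * m2))
            key = (min(min_pos(a), min_pos(b)), max(min_pos(a), min_pos(b)))
            if best_gain is None or gain > best_gain + 1e-15 or (
                abs(gain - best_gain) <= 1e-15 and key < best_key
            ):
                best_gain, best_pair, best_key = gain, (a, b), key
        a, b = best_pair
        # merge b into a
        comms[a] |= comms.pop(b)
        degree[a] += degree.pop(b)
        new_between = {}
        for (x, y), w in between.items():
            x = a if x == b else x
            y = a if y == b else y
            if x == y:
                continue
            key = (min(x, y), max(x, y))
            new_between[key] = new_between.get(key, 0.0) + w
        between = new_between
    return list(comms.values())


#: graphs at or below this size are partitioned by exhaustive enumeration
EXACT_PARTITION_MAX_NODES = 12


def partition_communities(graph: nx.Graph, k: int = 4) -> CommunityPartition:
    """Partition the stable-contact graph into exactly ``k`` communities by
    modularity maximization.

    Graphs with ≤ 12 nodes are solved exactly (exhaustive enumeration of
    k-partitions); larger graphs use deterministic greedy modularity
    agglomeration merged down to exactly k.  Isolated residues are attached
    to the community of their nearest-in-sequence non-isolated residue, so
    they never form spurious singleton communities.
    """
    nodes = sorted(graph.nodes())
    if k < 1 or k > len(nodes):
        raise ValueError(f"k={k} out of range for {len(nodes)} residues")
    isolated = [n for n in nodes if graph.degree(n) == 0]
    core = [n for n in nodes if graph.degree(n) > 0]
    if len(core) < k:
        # not enough connected residues: fall back to partitioning all nodes
        core, isolated = nodes, []
    sub = graph.subgraph(core)
    if len(core) <= EXACT_PARTITION_MAX_NODES:
        blocks = _exact_partition(sub, k, core)
    else:
        blocks = _greedy_partition(sub, k, core)
    assignment = _canonical_labels(blocks, core)
    for n in isolated:
        same = [
            m for m in core
            if m[0] == n[0]
        ]
        if same:
            nearest = min(same, key=lambda m: (abs(m[1] - n[1]), m[1]))
        else:
            nearest = core[0]
        assignment[n] = assignment[nearest]
    return CommunityPartition(assignment=assignment, k=k)


@dataclass(frozen=True)
class DifferenceNetwork:
    """Community-pair contact changes between two ensembles (second − first)."""

    community_pairs: tuple[tuple[int, int], ...]
    delta_contacts: dict[tuple[int, int], float]
    interprotomer_sum: float
    statistic: str
    community_protomer: dict[int, str]

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "delta_contacts": {f"{a}-{b}": v for (a, b), v in self.delta_contacts.items()},
            "interprotomer_sum": self.interprotomer_sum,
            "community_protomer": dict(self.community_protomer),
        }


def difference_network(
    apo: ContactMatrix,
    holo: ContactMatrix,
    partition: CommunityPartition,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    statistic: str = "mean",
    stability_mode: str = "union",
) -> DifferenceNetwork:
    """Signed per-community-pair contact change, holo − apo.

    ``stability_mode="union"`` (default) admits a residue pair when the
    larger of its two ensemble probabilities reaches the stability threshold,
    so contacts stable in *either* state contribute a signed change;
    ``"per_ensemble"`` thresholds each ensemble first and differences the
    thresholded values.  ``statistic`` is "mean" (default) or "sum" over the
    admitted residue pairs of each community pair.  Both choices make the
    result antisymmetric under swapping the two ensembles.

    The inter-protomer sum aggregates the changes over every community pair
    whose (majority-membership) protomers differ — for a two-lobe dimer the
    four pairs N:A↔N:B, N:A↔C:B, C:A↔C:B, C:A↔N:B.
    """
    if apo.residue_index != holo.residue_index:
        raise AlignmentError("contact matrices are indexed over different residues")
    if statistic not in ("mean", "sum"):
        raise ValueError("statistic must be 'mean' or 'sum'")
    if stability_mode not in ("union", "per_ensemble"):
        raise ValueError("stability_mode must be 'union' or 'per_ensemble'")
    residues = apo.residue_index
    thr = thresholds.contact_stability
    pa, ph = apo.probabilities, holo.probabilities
    if stability_mode == "union":
        admitted = np.maximum(pa, ph) >= thr
        delta_pair = np.where(admitted, ph - pa, 0.0)
    else:
        da = np.where(pa >= thr, pa, 0.0)
        dh = np.where(ph >= thr, ph, 0.0)
        admitted = (pa >= thr) | (ph >= thr)
        delta_pair = dh - da

    comm = np.array([partition.assignment[r] for r in residues])
    k = partition.k
    deltas: dict[tuple[int, int], float] = {}
    pairs = []
    for a in range(k):
        for b in range(a, k):
            ia = np.flatnonzero(comm == a)
            ib = np.flatnonzero(comm == b)
            block = delta_pair[np.ix_(ia, ib)]
            mask = admitted[np.ix_(ia, ib)]
            if a == b:  # count each unordered pair once
                tri = np.triu(np.ones_like(mask, dtype=bool), 1)
                mask = mask & tri
            vals = block[mask]
            if vals.size == 0:
                d = 0.0
            elif statistic == "mean":
                d = float(vals.mean())
            else:
                d = float(vals.sum())
            deltas[(a, b)] = d
            pairs.append((a, b))

    # majority protomer per community
    comm_protomer: dict[int, str] = {}
    for c in range(k):
        members = [r for r in residues if partition.assignment[r] == c]
        labels = [r[0] for r in members]
        comm_protomer[c] = max(sorted(set(labels)), key=labels.count)

    inter = sum(
        d for (a, b), d in deltas.items() if comm_protomer[a] != comm_protomer[b]
    )
    return DifferenceNetwork(
        community_pairs=tuple(pairs),
        delta_contacts=deltas,
        interprotomer_sum=float(inter),
        statistic=statistic,
        community_protomer=comm_protomer,
    )
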