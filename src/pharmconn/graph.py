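"""Fractionation of the DMN into sub-networks by signed community detection.

The rectangular DMN x other-networks difference matrix is turned into a
square signed graph over DMN nodes: each node's profile is its masked row of
paired t statistics (non-surviving cells zeroed), and the edge weight between
two DMN nodes is the cosine similarity of their profiles.  Nodes whose
connectivity responds to the drug in the same way are positively linked;
nodes with opposite responses are negatively linked, so modularity over the
signed graph separates increase- from decrease-responding sub-networks.

Community detection is a Louvain-style greedy two-phase maximisation of the
signed modularity

    Q = Q+ - (v-/(v+ + v-)) Q-,
    Q+- = (1/v+-) sum_{ij in same community} [W+-_ij - gamma s+-_i s+-_j / v+-],

where W+ and W- are the positive and negative parts of the weights, s the
node strengths and v the total strengths.  Positive weight inside communities
raises Q, negative weight inside communities lowers it, with the negative
term down-weighted by its share of total strength.  The optimiser visits
nodes in seeded random order — the stochastic element that makes repeated-run
NMI a meaningful stability probe.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging

import numpy as np

from .core import Parcellation
from .stats import DifferenceMatrix, NetworkTestResult, networkwise_tests

__all__ = [
    "DMNGraph",
    "Partition",
    "StabilityReport",
    "build_dmn_graph",
    "signed_modularity",
    "louvain_signed",
    "nmi",
    "stability_analysis",
    "gamma_sweep",
    "subnetwork_tests",
]

logger = logging.getLogger(__name__)

_TOL = 1e-12


@dataclasses.dataclass
class DMNGraph:
    """Signed, symmetric similarity graph over DMN nodes (zero diagonal)."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        self.nodes = np.asarray(self.nodes)
        n = self.nodes.size
        if w.shape != (n, n):
            raise ValueError("weights must be square over the node set")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.abs(np.diag(w)) > 1e-12):
            raise ValueError("diagonal must be zero")
        if np.any(np.abs(w) > 1 + 1e-9):
            raise ValueError("weights must lie in [-1, 1]")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.nodes.size


@dataclasses.dataclass
class Partition:
    """Community labels (contiguous from 0) with quality Q at resolution gamma."""

    nodes: np.ndarray
    labels: np.ndarray
    q_value: float
    gamma: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.nodes = np.asarray(self.nodes)
        if self.labels.size != self.nodes.size:
            raise ValueError("one label per node required")
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(uniq.size)):
            raise ValueError("labels must be contiguous from 0")

    @property
    def n_communities(self) -> int:
        return int(np.unique(self.labels).size)

    def members(self, label: int) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]


@dataclasses.dataclass
class StabilityReport:
    """Repeated-optimisation agreement plus a resolution sweep."""

    n_iterations: int
    min_pairwise_nmi: float
    mean_pairwise_nmi: float
    consensus: Partition
    gamma_sweep: list[tuple[float, float, int]] = dataclasses.field(default_factory=list)


def build_dmn_graph(
    diff: DifferenceMatrix,
    profile: str = "t",
    masked: bool = True,
    similarity: str = "cosine",
) -> DMNGraph:
    """Profile-similarity graph over DMN nodes.

    ``profile`` selects t statistics (default) or mean differences as the row
    profile; ``masked`` zeroes non-surviving cells first.  ``similarity`` is
    the uncentered cosine by default: two nodes whose drug response lives on
    disjoint column sets get weight ~0 and truly opposite responses weight
    < 0, which is what lets the signed modularity separate increase- from
    decrease-responding sub-networks.  (Centered Pearson similarity, kept as
    ``similarity="pearson"``, links disjoint-support profiles of opposite
    mean *positively* and cannot express that structure.)  Pairs where either
    profile is degenerate (all-zero, or constant for Pearson) get weight 0.
    """
    if diff.rows.size < 2:
        raise ValueError("need at least 2 DMN nodes to build a graph")
    source = diff.t if profile == "t" else diff.delta_mean
    profiles = np.where(np.isfinite(source), source, 0.0)
    if masked:
        profiles = np.where(diff.mask, profiles, 0.0)
    n = diff.rows.size
    w = np.zeros((n, n))
    if similarity == "cosine":
        norms = np.linalg.norm(profiles, axis=1)
        good = norms > 0.0
        if good.sum() >= 2:
            unit = profiles[good] / norms[good, None]
            w[np.ix_(good, good)] = unit @ unit.T
    elif similarity == "pearson":
        good = profiles.std(axis=1) > 0.0
        if good.sum() >= 2:
            w[np.ix_(good, good)] = np.corrcoef(profiles[good])
    else:
        raise ValueError("similarity must be 'cosine' or 'pearson'")
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return DMNGraph(nodes=diff.rows.copy(), weights=w)


def _split_signs(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.clip(weights, 0.0, None), np.clip(-weights, 0.0, None)


def signed_modularity(
    graph_or_weights, labels: np.ndarray, gamma: float = 1.0
) -> float:
    """Signed modularity Q of a partition (self-pairs included in the sums).

    Accepts a :class:`DMNGraph` or a raw symmetric weight matrix; for
    all-positive weights it reduces exactly to Newman weighted modularity.
    """
    w = graph_or_weights.weights if isinstance(graph_or_weights, DMNGraph) else np.asarray(
        graph_or_weights, dtype=float
    )
    labels = np.asarray(labels)
    if labels.size != w.shape[0]:
        raise ValueError("partition must cover every node")
    same = labels[:, None] == labels[None, :]
    pos, neg = _split_signs(w)
    v_pos, v_neg = pos.sum(), neg.sum()

    def _q_part(part: np.ndarray, v: float) -> float:
        if v <= 0:
            return 0.0
        s = part.sum(axis=1)
        null = gamma * np.outer(s, s) / v
        return float((part - null)[same].sum() / v)

    total = v_pos + v_neg
    if total <= 0:
        return 0.0
    return _q_part(pos, v_pos) - (v_neg / total) * _q_part(neg, v_neg)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel communities 0..k-1 in order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _quality_matrix(w: np.ndarray, gamma: float) -> np.ndarray:
    """Signed modularity matrix B with Q(partition) = sum of B over
    same-community pairs (i = j included).

    B = (W+ - gamma s+ s+^T / v+) / v+  -  (v-/(v+ + v-)) (W- - gamma s- s-^T / v-) / v-.
    Aggregating B by block sums preserves Q exactly for super-node
    partitions, which raw signed weights do not (their positive and negative
    parts mix under block summation).
    """
    pos, neg = _split_signs(w)
    v_pos, v_neg = pos.sum(), neg.sum()
    total = v_pos + v_neg
    b = np.zeros_like(w)
    if v_pos > 0:
        s = pos.sum(axis=1)
        b += (pos - gamma * np.outer(s, s) / v_pos) / v_pos
    if v_neg > 0:
        s = neg.sum(axis=1)
        b -= (v_neg / total) * (neg - gamma * np.outer(s, s) / v_neg) / v_neg
    return (b + b.T) / 2.0


def _partition_quality(b: np.ndarray, labels: np.ndarray) -> float:
    same = labels[:, None] == labels[None, :]
    return float(b[same].sum())


def _community_links(b: np.ndarray, comm: np.ndarray, i: int) -> np.ndarray:
    """Sum of B[i, j] per community, self excluded (it cancels in gains)."""
    row = b[i].copy()
    row[i] = 0.0
    return np.bincount(comm, weights=row, minlength=comm.size)


def _local_moves(
    b: np.ndarray, rng: np.random.Generator, init: np.ndarray
) -> np.ndarray:
    """Greedy single-node moves on the quality matrix until none improves Q.

    Candidate targets are every occupied community plus one empty community
    (so splits as well as merges are reachable); ties break to the lowest
    label.  Gain of moving i from a to c is 2 (k_c - k_a) with k the
    self-excluded link sums.
    """
    n = b.shape[0]
    comm = init.copy()
    sizes = np.bincount(comm, minlength=n)
    moved_any = True
    while moved_any:
        moved_any = False
        for i in rng.permutation(n):
            a = comm[i]
            k = _community_links(b, comm, i)
            occupied = np.nonzero(sizes > 0)[0]
            candidates = occupied
            if sizes[a] > 1:
                empty = np.nonzero(sizes == 0)[0]
                if empty.size:
                    candidates = np.append(occupied, empty[0])
            rel = 2.0 * (k[candidates] - k[a])
            best = rel.max()
            if best > _TOL:
                best_c = int(candidates[rel >= best - _TOL].min())
            else:
                best_c = a
            if best_c != a:
                moved_any = True
                sizes[a] -= 1
                sizes[best_c] += 1
                comm[i] = best_c
    return comm


def _kl_refine(b: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Kernighan-Lin-style refinement: force the best single move (even if it
    lowers Q) for each node at most once, then backtrack to the best prefix.
    Escapes local optima that no improving single move can leave."""
    n = b.shape[0]
    labels = labels.copy()
    base_q = _partition_quality(b, labels)
    while True:
        comm = labels.copy()
        sizes = np.bincount(comm, minlength=n)
        free = np.ones(n, dtype=bool)
        cur_q = base_q
        best_q, best_labels = base_q, labels.copy()
        for _ in range(n):
            move = None  # (gain, node, target)
            for i in np.nonzero(free)[0]:
                a = comm[i]
                k = _community_links(b, comm, i)
                occupied = np.nonzero(sizes > 0)[0]
                candidates = occupied
                if sizes[a] > 1:
                    empty = np.nonzero(sizes == 0)[0]
                    if empty.size:
                        candidates = np.append(occupied, empty[0])
                candidates = candidates[candidates != a]
                if candidates.size == 0:
                    continue
                rel = 2.0 * (k[candidates] - k[a])
                j = int(np.argmax(rel))
                if move is None or rel[j] > move[0] + _TOL:
                    move = (float(rel[j]), i, int(candidates[j]))
            if move is None:
                break
            gain, i, c = move
            sizes[comm[i]] -= 1
            sizes[c] += 1
            comm[i] = c
            free[i] = False
            cur_q += gain
            if cur_q > best_q + _TOL:
                best_q, best_labels = cur_q, comm.copy()
        if best_q > base_q + _TOL:
            labels = _canonical_labels(best_labels)
            base_q = _partition_quality(b, labels)
        else:
            return labels


def _forced_sweep(
    b: np.ndarray, labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Visit every node once in random order, forcing its best move (even if
    it lowers Q), and backtrack to the best prefix.  The randomised
    counterpart of the KL pass; different visit orders cross different
    barriers."""
    n = b.shape[0]
    comm = labels.copy()
    sizes = np.bincount(comm, minlength=n)
    base_q = _partition_quality(b, comm)
    cur_q = base_q
    best_q, best_labels = base_q, comm.copy()
    for i in rng.permutation(n):
        a = comm[i]
        k = _community_links(b, comm, i)
        occupied = np.nonzero(sizes > 0)[0]
        candidates = occupied
        if sizes[a] > 1:
            empty = np.nonzero(sizes == 0)[0]
            if empty.size:
                candidates = np.append(occupied, empty[0])
        candidates = candidates[candidates != a]
        if candidates.size == 0:
            continue
        rel = 2.0 * (k[candidates] - k[a])
        j = int(np.argmax(rel))
        c = int(candidates[j])
        sizes[a] -= 1
        sizes[c] += 1
        comm[i] = c
        cur_q += rel[j]
        if cur_q > best_q + _TOL:
            best_q, best_labels = cur_q, comm.copy()
    return best_labels if best_q > base_q + _TOL else labels


def _aggregate(b: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Block sums of the quality matrix; Q of a super-node partition on the
    result equals Q of its flat counterpart."""
    k = labels.max() + 1
    agg = np.zeros((k, k))
    for c in range(k):
        idx_c = labels == c
        for d in range(c, k):
            idx_d = labels == d
            agg[c, d] = agg[d, c] = b[np.ix_(idx_c, idx_d)].sum()
    return agg


def louvain_signed(
    graph: DMNGraph, gamma: float = 1.0, seed: int = 0, n_restarts: int = 4
) -> Partition:
    """Greedy two-phase (local moves + aggregation) maximisation of signed Q
    with Kernighan-Lin refinement, best of ``n_restarts`` seeded starts.

    Deterministic given ``seed``; distinct seeds explore distinct node
    orders, which is what makes repeated-run NMI a stability probe.
    """
    if n_restarts > 1:
        runs = [
            _louvain_single(graph, gamma, _derive_seed(seed, f"restart{r}"))
            for r in range(n_restarts)
        ]
        return max(runs, key=lambda p: p.q_value)  # first max wins ties
    return _louvain_single(graph, gamma, seed)


def _louvain_single(graph: DMNGraph, gamma: float, seed: int) -> Partition:
    """One seeded optimisation run: greedy phases alternating with KL
    refinement until neither improves Q.  Ties in the local move break to
    the lowest community label."""
    n = graph.n_nodes
    rng = np.random.default_rng(seed)
    b = _quality_matrix(graph.weights, gamma)
    labels = np.arange(n)
    q = _partition_quality(b, labels)
    while True:
        while True:
            # phase 1: single-node moves on the full quality matrix
            refined = _canonical_labels(_local_moves(b, rng, labels))
            q_refined = _partition_quality(b, refined)
            if q_refined > q + _TOL:
                labels, q = refined, q_refined
                continue
            labels = refined
            k = labels.max() + 1
            if k <= 1:
                break
            # phase 2: community-level moves on the aggregated matrix
            agg = _aggregate(b, labels)
            merged = _canonical_labels(_local_moves(agg, rng, np.arange(k)))
            candidate = _canonical_labels(merged[labels])
            q_candidate = _partition_quality(b, candidate)
            if q_candidate > q + _TOL:
                labels, q = candidate, q_candidate
            else:
                break
        # escape single-move local optima before accepting the partition
        refined = _kl_refine(b, labels)
        q_refined = _partition_quality(b, refined)
        if q_refined > q + _TOL:
            labels, q = _canonical_labels(refined), q_refined
            continue
        # randomised forced sweeps cross barriers the best-first pass cannot
        escaped = False
        for _ in range(8):
            candidate = _forced_sweep(b, labels, rng)
            candidate = _canonical_labels(_local_moves(b, rng, candidate))
            q_candidate = _partition_quality(b, candidate)
            if q_candidate > q + _TOL:
                labels, q = candidate, q_candidate
                escaped = True
                break
        if not escaped:
            break
    labels = _canonical_labels(labels)
    q = signed_modularity(graph, labels, gamma)
    return Partition(nodes=graph.nodes.copy(), labels=labels, q_value=q, gamma=gamma)


def nmi(a: Partition | np.ndarray, b: Partition | np.ndarray) -> float:
    """Normalised mutual information 2 I(A;B) / (H(A) + H(B)), natural logs.

    Returns 1.0 when both partitions are single-community (identical trivial
    clusterings); raises on mismatched node sets.
    """
    la = a.labels if isinstance(a, Partition) else np.asarray(a)
    lb = b.labels if isinstance(b, Partition) else np.asarray(b)
    if isinstance(a, Partition) and isinstance(b, Partition):
        if not np.array_equal(a.nodes, b.nodes):
            raise ValueError("partitions cover different node sets")
    if la.size != lb.size:
        raise ValueError("partitions cover different numbers of nodes")
    n = la.size
    ua, ia = np.unique(la, return_inverse=True)
    ub, ib = np.unique(lb, return_inverse=True)
    contingency = np.zeros((ua.size, ub.size))
    np.add.at(contingency, (ia, ib), 1.0)
    pij = contingency / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)

    def _entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    h_a, h_b = _entropy(pi), _entropy(pj)
    if h_a + h_b == 0.0:
        return 1.0
    # identical up to relabeling: one nonzero cell per row and per column
    if (
        ua.size == ub.size
        and np.all((contingency > 0).sum(axis=1) == 1)
        and np.all((contingency > 0).sum(axis=0) == 1)
    ):
        return 1.0
    nz = pij > 0
    mi = float((pij[nz] * np.log(pij[nz] / np.outer(pi, pj)[nz])).sum())
    value = 2.0 * mi / (h_a + h_b)
    return float(min(1.0, max(0.0, value)))


def _derive_seed(master: int, tag: str) -> int:
    digest = hashlib.sha256(f"{master}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stability_analysis(
    graph: DMNGraph,
    gamma: float = 1.0,
    n_iterations: int = 1000,
    seed: int = 0,
    gammas: np.ndarray | None = None,
) -> StabilityReport:
    """Repeat the optimisation with distinct derived seeds and compare runs.

    All pairwise NMIs among the partitions are computed; the consensus is the
    highest-Q partition (ties to the first found).  On strongly planted
    structure every run lands on the same optimum and min NMI is 1.
    """
    if n_iterations < 2:
        raise ValueError("need at least 2 iterations")
    partitions = [
        louvain_signed(graph, gamma, _derive_seed(seed, f"iter{i}"))
        for i in range(n_iterations)
    ]
    nmis = [
        nmi(partitions[i], partitions[j])
        for i in range(n_iterations)
        for j in range(i + 1, n_iterations)
    ]
    consensus = max(partitions, key=lambda p: p.q_value)  # first max wins ties
    sweep = (
        gamma_sweep(graph, gammas, seed, reference=consensus)
        if gammas is not None
        else []
    )
    return StabilityReport(
        n_iterations=n_iterations,
        min_pairwise_nmi=float(min(nmis)),
        mean_pairwise_nmi=float(np.mean(nmis)),
        consensus=consensus,
        gamma_sweep=sweep,
    )


def gamma_sweep(
    graph: DMNGraph,
    gammas,
    seed: int = 0,
    reference: Partition | None = None,
) -> list[tuple[float, float, int]]:
    """One optimisation per resolution; records (gamma, NMI vs the gamma=1
    reference partition, community count)."""
    gammas = list(gammas)
    if not gammas:
        raise ValueError("gamma list must be non-empty")
    if reference is None:
        reference = louvain_signed(graph, 1.0, _derive_seed(seed, "reference"))
    out = []
    for g in gammas:
        part = louvain_signed(graph, float(g), _derive_seed(seed, f"gamma{g:.6g}"))
        out.append((float(g), nmi(part, reference), part.n_communities))
    return out


def subnetwork_tests(
    diff: DifferenceMatrix,
    partition: Partition,
    parcellation: Parcellation,
    use_t_values: bool = False,
) -> list[NetworkTestResult]:
    """Network-wise one-sample tests restricted to each DMN sub-network's rows.

    Bonferroni factor = (number of target networks) x (number of
    sub-networks).
    """
    if not np.array_equal(partition.nodes, diff.rows):
        raise ValueError("partition nodes must match difference-matrix rows")
    n_targets = len(parcellation.target_networks)
    m = n_targets * partition.n_communities
    results: list[NetworkTestResult] = []
    for label in range(partition.n_communities):
        rows = partition.members(label)
        results.extend(
            networkwise_tests(
                diff,
                parcellation,
                rows=rows,
                bonferroni=m,
                use_t_values=use_t_values,
                subnetwork=label,
            )
        )
    return results
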