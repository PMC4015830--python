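"""Weighted random-walk agglomerative community detection.

The walk on a weighted graph with adjacency A moves from vertex i to j
with probability P_ij = A_ij / d(i), where d(i) = sum_j A_ij.  Rows of
P^t (t short, default 3) profile each vertex by where a t-step walker
ends up; structurally similar vertices have similar rows.  The distance
between vertices i and j is the degree-normalized L2 distance

    r_ij = sqrt( sum_k (P^t_ik - P^t_jk)^2 / d(k) ),

and the same form with community rows (the mean of member rows) defines
the distance between communities.  Starting from singletons, the pair of
*adjacent* communities whose merge minimizes the Ward-style cost

    delta_sigma(C1, C2) = (1/n) * |C1||C2| / (|C1|+|C2|) * r_{C1C2}^2

is merged at every step; the cost equals the increase in the mean squared
vertex-to-community distance sigma.  The full merge sequence is recorded
together with the weighted modularity Q after every step, and a partition
is then selected under a community-size cap by maximum modularity or by
maximum permutation module score.

The implementation keeps dense P^t rows, which is comfortably fast for
networks up to a few thousand vertices — the scale this package targets.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import networkx as nx
import numpy as np

from .expression import WeightedNetwork

__all__ = [
    "TransitionModel",
    "CommunityState",
    "MergeRecord",
    "MergeHistory",
    "StopConfig",
    "transition_model",
    "vertex_distance",
    "community_distance",
    "delta_sigma",
    "modularity",
    "run_merge",
    "select_partition",
    "partition_summary",
    "PartitionSummary",
    "write_merge_history",
    "write_partition",
]

log = logging.getLogger(__name__)

DEFAULT_WALK_LENGTH = 3
DEFAULT_MAX_SIZE = 200


def _as_graph(net: WeightedNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, WeightedNetwork) else net


@dataclass(frozen=True)
class TransitionModel:
    """t-step transition structure of the weighted walk.

    ``nodes`` fixes the vertex order for all matrices; ``A`` is the dense
    symmetric weight matrix, ``d`` the weighted degree vector and ``Pt``
    the dense matrix of t-step probability rows.
    """

    nodes: tuple
    A: np.ndarray
    d: np.ndarray
    t: int
    Pt: np.ndarray

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index(self, vertex) -> int:
        try:
            return self._index[vertex]
        except AttributeError:
            object.__setattr__(
                self, "_index", {v: i for i, v in enumerate(self.nodes)}
            )
            return self._index[vertex]


def transition_model(
    net: WeightedNetwork | nx.Graph,
    t: int = DEFAULT_WALK_LENGTH,
    self_loop_weight: float = 0.0,
) -> TransitionModel:
    """Build the t-step walk model for a connected, positively weighted graph.

    ``self_loop_weight`` adds that weight as a self-loop on every vertex
    (a lazy walk).  The default is 0: with t=3 and strictly positive
    weights the rows are never degenerate, so laziness is not needed.
    Some implementations of the same community search use a unit lazy
    walk; set 1.0 to reproduce that convention.
    """
    graph = _as_graph(net)
    if t < 1:
        raise ValueError("walk length t must be >= 1")
    if self_loop_weight < 0:
        raise ValueError("self_loop_weight must be nonnegative")
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(graph):
        raise ValueError("graph must be connected; extract the LCC first")
    nodes = tuple(sorted(graph.nodes))
    A = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    if np.any(A < 0):
        raise ValueError("negative edge weight")
    if self_loop_weight:
        A = A + self_loop_weight * np.eye(len(nodes))
    d = A.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError(
            "zero-degree vertex; apply a positive weight floor before the walk"
        )
    P = A / d[:, None]
    Pt = P.copy()
    for _ in range(t - 1):
        Pt = Pt @ P
    return TransitionModel(nodes=nodes, A=A, d=d, t=t, Pt=Pt)


def _row_distance(model: TransitionModel, row_i: np.ndarray, row_j: np.ndarray) -> float:
    return float(np.sqrt(np.sum((row_i - row_j) ** 2 / model.d)))


def vertex_distance(model: TransitionModel, i, j) -> float:
    """Degree-normalized L2 distance between the t-step rows of two vertices."""
    ii, jj = model.index(i), model.index(j)
    if ii == jj:
        return 0.0
    return _row_distance(model, model.Pt[ii], model.Pt[jj])


def community_row(model: TransitionModel, members: Sequence) -> np.ndarray:
    """P^t row of a community: mean of its member vertex rows."""
    idx = [model.index(v) for v in members]
    if not idx:
        raise ValueError("empty community")
    return model.Pt[idx].mean(axis=0)


def community_distance(model: TransitionModel, c1: Sequence, c2: Sequence) -> float:
    """Walk distance between two communities; reduces to
    :func:`vertex_distance` for singletons."""
    return _row_distance(model, community_row(model, c1), community_row(model, c2))


def _adjacent(model: TransitionModel, c1: Sequence, c2: Sequence) -> bool:
    i1 = [model.index(v) for v in c1]
    i2 = [model.index(v) for v in c2]
    return bool(np.any(model.A[np.ix_(i1, i2)] > 0))


def delta_sigma(model: TransitionModel, c1: Sequence, c2: Sequence) -> float:
    """Ward-style cost of merging two adjacent communities."""
    s1, s2 = len(c1), len(c2)
    if set(c1) & set(c2):
        raise ValueError("communities overlap")
    if not _adjacent(model, c1, c2):
        raise ValueError("only adjacent communities are merge candidates")
    r = community_distance(model, c1, c2)
    return (s1 * s2) / (s1 + s2) / model.n * r**2


def modularity(
    net: WeightedNetwork | nx.Graph,
    partition: Sequence[set],
    weighted: bool = True,
) -> float:
    """Newman modularity Q = sum_C (e_C - a_C^2) of a partition.

    ``e_C`` is the fraction of total edge weight inside community C and
    ``a_C`` the fraction of weighted degree attached to C.  With
    ``weighted=False`` every edge counts 1 regardless of its weight.
    """
    graph = _as_graph(net)
    nodes = set(graph.nodes)
    seen: set = set()
    for comm in partition:
        if seen & set(comm):
            raise ValueError("partition has overlapping communities")
        seen |= set(comm)
    if seen != nodes:
        raise ValueError("partition does not cover the vertex set")

    def w(u, v):
        return graph.edges[u, v].get("weight", 1.0) if weighted else 1.0

    total = sum(w(u, v) for u, v in graph.edges())
    if total == 0:
        return 0.0
    member = {v: k for k, comm in enumerate(partition) for v in comm}
    e = np.zeros(len(partition))
    a = np.zeros(len(partition))
    for u, v in graph.edges():
        wt = w(u, v)
        cu, cv = member[u], member[v]
        if cu == cv:
            e[cu] += wt
        a[cu] += wt / 2.0
        a[cv] += wt / 2.0
    e /= total
    a /= total
    return float(np.sum(e - a**2))


@dataclass(frozen=True)
class MergeRecord:
    step: int
    merged_a: int
    merged_b: int
    new_id: int
    delta_sigma: float
    Q: float        # modularity on walk weights
    Q_topo: float   # modularity on bare topology (each edge counts 1)
    max_size: int


@dataclass
class MergeHistory:
    """Dendrogram of community merges.

    Community ids follow the scipy linkage convention: vertices are
    0..n-1 (in ``nodes`` order) and the community created at step s gets
    id n - 1 + s.  Two modularity tracks are recorded per step: ``Q`` on
    the walk's edge weights and ``Q_topo`` on the bare topology (they
    coincide for unweighted graphs).  ``initial_Q``/``initial_Q_topo``
    belong to the all-singleton partition (step 0).
    """

    nodes: tuple
    records: list[MergeRecord]
    initial_Q: float
    initial_Q_topo: float

    @property
    def n(self) -> int:
        return len(self.nodes)

    def partition_at(self, step: int) -> list[set]:
        """Communities (as sets of vertex labels) after ``step`` merges."""
        if not 0 <= step <= len(self.records):
            raise ValueError(f"step must be in [0, {len(self.records)}]")
        comms: dict[int, set] = {i: {v} for i, v in enumerate(self.nodes)}
        for rec in self.records[:step]:
            comms[rec.new_id] = comms.pop(rec.merged_a) | comms.pop(rec.merged_b)
        return [comms[k] for k in sorted(comms)]

    def q_sequence(self, weighted: bool = True) -> np.ndarray:
        """Modularity after each step, starting with the singleton Q."""
        if weighted:
            return np.array([self.initial_Q] + [r.Q for r in self.records])
        return np.array([self.initial_Q_topo] + [r.Q_topo for r in self.records])


@dataclass(frozen=True)
class StopConfig:
    """Stopping/selection configuration for the merge process.

    ``max_size`` caps the community size considered acceptable (the merge
    loop stops once a merge exceeds it); the final partition is the step
    within the cap that maximizes modularity (``criterion="modularity"``)
    or the best permutation module score (``criterion="score"``).

    ``modularity_on`` picks which modularity track guides the selection:
    ``"topology"`` (default) judges partitions on the interaction
    structure itself, which keeps the community criterion independent of
    the expression weighting that already drives the merge order and is
    robust to floor-weighted (silent) regions; ``"walk_weights"`` uses
    the weighted modularity of the walk's edge weights instead.
    """

    max_size: int | None = DEFAULT_MAX_SIZE
    criterion: str = "modularity"
    modularity_on: str = "topology"

    def __post_init__(self):
        if self.criterion not in ("modularity", "score"):
            raise ValueError("criterion must be 'modularity' or 'score'")
        if self.modularity_on not in ("topology", "walk_weights"):
            raise ValueError("modularity_on must be 'topology' or 'walk_weights'")
        if self.max_size is not None and self.max_size < 1:
            raise ValueError("max_size must be positive")


def run_merge(
    net: WeightedNetwork | nx.Graph,
    t: int = DEFAULT_WALK_LENGTH,
    stop: StopConfig | None = None,
    model: TransitionModel | None = None,
    self_loop_weight: float = 0.0,
) -> MergeHistory:
    """Agglomerate singletons by repeatedly merging the adjacent community
    pair with minimal merge cost.

    Ties on the cost are broken toward the smaller (id, id) pair so runs
    are reproducible.  After each merge the new community's probability
    row is the size-weighted mean of its parents' rows and its distances
    to neighboring communities are recomputed exactly.  Recording stops
    once a merge exceeds ``stop.max_size`` (the offending step is kept in
    the history; partition selection filters it out).
    """
    graph = _as_graph(net)
    if model is None:
        model = transition_model(graph, t=t, self_loop_weight=self_loop_weight)
    n = model.n
    if n == 1:
        return MergeHistory(
            nodes=model.nodes, records=[], initial_Q=0.0, initial_Q_topo=0.0
        )

    # modularity bookkeeping always excludes self-loop weight, so Q equals
    # the standard modularity of the input graph even for a lazy walk
    W = model.A.copy()
    np.fill_diagonal(W, 0.0)
    w_deg = W.sum(axis=1)
    u_deg = (W > 0).sum(axis=1).astype(float)
    total_w = w_deg.sum() / 2.0  # sum of edge weights, each edge once
    total_u = u_deg.sum() / 2.0  # number of edges

    # community state, ids 0..n-1 for vertices, n-1+step for merged
    rows: dict[int, np.ndarray] = {i: model.Pt[i] for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    # inter-community [weight, edge count] per adjacent community pair
    between: dict[int, dict[int, list]] = {i: {} for i in range(n)}
    ii, jj = np.nonzero(np.triu(W, k=1))
    for a, b in zip(ii.tolist(), jj.tolist()):
        link = [float(W[a, b]), 1.0]
        between[a][b] = link
        between[b][a] = link

    inv_d = 1.0 / model.d

    def pair_cost(a: int, b: int) -> float:
        diff = rows[a] - rows[b]
        r2 = float(np.sum(diff * diff * inv_d))
        return sizes[a] * sizes[b] / (sizes[a] + sizes[b]) / n * r2

    heap: list[tuple[float, int, int]] = []
    for a in range(n):
        for b in between[a]:
            if a < b:
                heap.append((pair_cost(a, b), a, b))
    heapq.heapify(heap)

    a_frac = {i: float(w_deg[i]) / (2.0 * total_w) for i in range(n)}
    a_frac_u = {i: float(u_deg[i]) / (2.0 * total_u) for i in range(n)}
    # singleton partition: every e_C = 0, so Q = -sum a_C^2
    Q = -sum(v * v for v in a_frac.values())
    Q_topo = -sum(v * v for v in a_frac_u.values())
    initial_Q, initial_Q_topo = Q, Q_topo

    alive = set(range(n))
    records: list[MergeRecord] = []
    max_size = 1
    next_id = n
    step = 0
    cap = stop.max_size if stop is not None else None

    while len(alive) > 1 and heap:
        cost, a, b = heapq.heappop(heap)
        if a not in alive or b not in alive:
            continue
        step += 1
        c = next_id
        next_id += 1
        sa, sb = sizes[a], sizes[b]
        rows[c] = (sa * rows[a] + sb * rows[b]) / (sa + sb)
        sizes[c] = sa + sb
        w_ab, u_ab = between[a].get(b, (0.0, 0.0))
        # modularity update: e gains w_ab/total, a^2 gains 2*a_a*a_b
        Q += w_ab / total_w - 2.0 * a_frac[a] * a_frac[b]
        Q_topo += u_ab / total_u - 2.0 * a_frac_u[a] * a_frac_u[b]
        a_frac[c] = a_frac[a] + a_frac[b]
        a_frac_u[c] = a_frac_u[a] + a_frac_u[b]

        nbrs: dict[int, list] = {}
        for old in (a, b):
            for nb, link in between[old].items():
                if nb in (a, b):
                    continue
                if nb in nbrs:
                    nbrs[nb][0] += link[0]
                    nbrs[nb][1] += link[1]
                else:
                    nbrs[nb] = [link[0], link[1]]
                del between[nb][old]
        between[c] = nbrs
        for nb, link in nbrs.items():
            between[nb][c] = link
        for old in (a, b):
            del between[old], rows[old], sizes[old], a_frac[old], a_frac_u[old]
        alive.discard(a)
        alive.discard(b)
        alive.add(c)
        max_size = max(max_size, sizes[c])

        for nb in nbrs:
            lo, hi = (nb, c) if nb < c else (c, nb)
            heapq.heappush(heap, (pair_cost(lo, hi), lo, hi))

        records.append(
            MergeRecord(
                step=step,
                merged_a=a,
                merged_b=b,
                new_id=c,
                delta_sigma=cost,
                Q=Q,
                Q_topo=Q_topo,
                max_size=max_size,
            )
        )
        if cap is not None and max_size > cap:
            log.info("merge stopped at step %d: community size %d exceeds cap %d",
                     step, max_size, cap)
            break

    return MergeHistory(
        nodes=model.nodes,
        records=records,
        initial_Q=initial_Q,
        initial_Q_topo=initial_Q_topo,
    )


@dataclass(frozen=True)
class CommunityState:
    """A selected partition with its provenance in the merge sequence."""

    communities: tuple[frozenset, ...]
    step: int
    Q: float
    criterion: str

    def __iter__(self):
        return iter(self.communities)

    def __len__(self):
        return len(self.communities)


def select_partition(
    history: MergeHistory,
    stop: StopConfig | None = None,
    scorer: Callable[[list[set]], float] | None = None,
) -> CommunityState:
    """Pick the partition along the merge sequence per the stop criteria.

    Only steps whose largest community respects ``stop.max_size`` are
    candidates.  ``criterion="modularity"`` returns the candidate step of
    maximal Q on the track chosen by ``stop.modularity_on``;
    ``criterion="score"`` maximizes ``scorer(partition)`` (the best
    permutation module score of the partition).  If the very first merge
    already violates the cap, the all-singleton partition is returned
    with a warning.
    """
    stop = stop or StopConfig()
    if stop.criterion == "score" and scorer is None:
        raise ValueError("criterion='score' requires a scorer")
    cap = stop.max_size if stop.max_size is not None else float("inf")

    candidates = [0] + [r.step for r in history.records if r.max_size <= cap]
    if candidates == [0] and history.records:
        log.warning("first merge already exceeds the size cap; returning singletons")

    q = history.q_sequence(weighted=stop.modularity_on == "walk_weights")
    if stop.criterion == "modularity":
        objective = {s: q[s] for s in candidates}
    else:
        objective = {s: scorer(history.partition_at(s)) for s in candidates}

    best_step = max(candidates, key=lambda s: (objective[s], -s))
    parts = history.partition_at(best_step)
    return CommunityState(
        communities=tuple(frozenset(c) for c in parts),
        step=best_step,
        Q=float(q[best_step]),
        criterion=stop.criterion,
    )


@dataclass(frozen=True)
class PartitionSummary:
    singletons: int
    pairs: int
    triplets: int
    modules: int
    max_module_size: int

    @property
    def n_communities(self) -> int:
        return self.singletons + self.pairs + self.triplets + self.modules


def partition_summary(
    partition: Sequence[set] | CommunityState, cap: int | None = None
) -> PartitionSummary:
    """Count singletons, pairs, triplets and modules (size > 3, up to the
    cap) in a partition."""
    comms = list(partition)
    sizes = [len(c) for c in comms]
    singles = sum(1 for s in sizes if s == 1)
    pairs = sum(1 for s in sizes if s == 2)
    triplets = sum(1 for s in sizes if s == 3)
    limit = cap if cap is not None else max(sizes, default=0)
    modules = sum(1 for s in sizes if 3 < s <= limit)
    module_sizes = [s for s in sizes if 3 < s <= limit]
    return PartitionSummary(
        singletons=singles,
        pairs=pairs,
        triplets=triplets,
        modules=modules,
        max_module_size=max(module_sizes, default=0),
    )


def write_merge_history(history: MergeHistory, path: str | Path, meta: str = "") -> None:
    with Path(path).open("w") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        fh.write("step\tmerged_a\tmerged_b\tnew_id\tdelta_sigma\tQ\tQ_topo\tmax_size\n")
        for r in history.records:
            fh.write(
                f"{r.step}\t{r.merged_a}\t{r.merged_b}\t{r.new_id}\t"
                f"{r.delta_sigma:.12g}\t{r.Q:.12g}\t{r.Q_topo:.12g}\t{r.max_size}\n"
            )


def write_partition(
    partition: Sequence[set] | CommunityState, path: str | Path, meta: str = ""
) -> None:
    comms = sorted((sorted(map(str, c)) for c in partition), key=lambda c: (-len(c), c))
    with Path(path).open("w") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        fh.write("gene\tcommunity_id\n")
        for cid, members in enumerate(comms):
            for g in members:
                fh.write(f"{g}\t{cid}\n")
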