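"""Binary graph construction and the 74 graph-theoretic features.

Eight unweighted graphs are built per connectivity variant: the whole-brain
graph, binarized by keeping the top 10% of connections over the full matrix,
and one subgraph per network, re-binarized from that network's own
correlation submatrix at the same density.  From these, four measures:

* efficiency — mean inverse geodesic distance; 29 scopes on the whole-brain
  inverse-distance matrix + 7 "intra" efficiencies of the network subgraphs;
* clustering coefficient — node-wise on the whole-brain graph (whole-brain
  and per-network means) + mean clustering of each network subgraph;
* modularity — Newman Q of each of the 8 graphs (gamma = 1);
* participation coefficient — node-wise against the Newman communities,
  whole-brain and per-network means + subgraph means against each
  subgraph's own communities.

Total: 36 + 15 + 8 + 15 = 74 features per variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .blocks import FeatureBlock
from .community import CommunityAssignment, EdgelessGraphError, newman_modularity
from .connectivity import ConnectivityMatrix, scope_pair_masks
from .partition import NetworkPartition

DEFAULT_DENSITY = 0.10


@dataclass(frozen=True)
class BinaryGraph:
    adjacency: np.ndarray  # {0,1}, symmetric, zero diagonal
    density: float
    scope: str  # "whole_brain" or a network name

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(A).any():
            raise ValueError("adjacency must have a zero diagonal")
        object.__setattr__(self, "adjacency", A)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(round(self.adjacency.sum() / 2))


def binarize_at_density(values: np.ndarray | ConnectivityMatrix, density: float,
                        scope: str = "whole_brain") -> BinaryGraph:
    """Keep the ``round(density * P(P-1)/2)`` largest off-diagonal values.

    Ranking is by signed value over the whole matrix (one global cutoff);
    ties at the cutoff are broken by ascending (row, column) index of the
    upper-triangle pair.
    """
    if isinstance(values, ConnectivityMatrix):
        values = values.values
    M = np.asarray(values, dtype=float)
    P = M.shape[0]
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    n_pairs = P * (P - 1) // 2
    k = int(np.floor(density * n_pairs + 0.5))
    if k == 0:
        raise ValueError(f"density {density} yields 0 edges for {P} nodes")
    iu, ju = np.triu_indices(P, k=1)
    vals = (M[iu, ju] + M[ju, iu]) / 2.0
    # stable sort on descending value; equal values keep (row, col) order
    order = np.argsort(-vals, kind="stable")[:k]
    A = np.zeros((P, P))
    A[iu[order], ju[order]] = 1.0
    A += A.T
    return BinaryGraph(adjacency=A, density=density, scope=scope)


def shortest_paths(g: BinaryGraph) -> np.ndarray:
    """Unweighted geodesic distances; unreachable pairs are ``inf``."""
    return shortest_path(csr_matrix(g.adjacency), method="D", unweighted=True, directed=False)


def inverse_distance(g: BinaryGraph) -> np.ndarray:
    """1/d with 1/inf := 0 and a zero diagonal."""
    D = shortest_paths(g)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse distance over unordered node pairs."""
    n = g.n_nodes
    if n < 2:
        raise ValueError("efficiency needs >= 2 nodes")
    inv = inverse_distance(g)
    iu = np.triu_indices(n, k=1)
    return float(inv[iu].mean())


def clustering_coefficients(g: BinaryGraph) -> np.ndarray:
    """Binary clustering C_i = 2 t_i / (k_i (k_i - 1)); C_i = 0 for k_i < 2."""
    A = g.adjacency
    k = A.sum(axis=1)
    t = np.einsum("ij,jk,ki->i", A, A, A) / 2.0  # triangles through each node
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(denom > 0, 2.0 * t / denom, 0.0)
    return C


def participation_coefficients(g: BinaryGraph, communities: CommunityAssignment) -> np.ndarray:
    """P_i = 1 - sum_s (k_is / k_i)^2; isolated nodes get 0 by convention."""
    A = g.adjacency
    k = A.sum(axis=1)
    labels = communities.labels
    n_comm = int(labels.max()) + 1
    onehot = np.zeros((g.n_nodes, n_comm))
    onehot[np.arange(g.n_nodes), labels] = 1.0
    k_is = A @ onehot
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(k[:, None] > 0, k_is / k[:, None], 0.0)
    part = 1.0 - (frac**2).sum(axis=1)
    part[k == 0] = 0.0
    return part


# --------------------------------------------------------------------------- #
# Shared per-variant context (avoids recomputing graphs and communities)
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class GraphContext:
    """Binary graphs and community assignments shared by the four measures."""

    cm: ConnectivityMatrix
    partition: NetworkPartition
    density: float = DEFAULT_DENSITY
    gamma: float = 1.0

    @property
    def family(self) -> str:
        return f"graph_{self.cm.variant}"

    @cached_property
    def whole(self) -> BinaryGraph:
        return binarize_at_density(self.cm, self.density)

    @cached_property
    def subgraphs(self) -> dict[str, BinaryGraph]:
        subs: dict[str, BinaryGraph] = {}
        for net in self.partition.networks:
            idx = self.partition.indices(net)
            sub = self.cm.values[np.ix_(idx, idx)]
            try:
                subs[net] = binarize_at_density(sub, self.density, scope=net)
            except ValueError as err:
                raise ValueError(f"network {net!r}: {err}") from err
        return subs

    @cached_property
    def whole_communities(self) -> CommunityAssignment:
        try:
            return newman_modularity(self.whole.adjacency, self.gamma)
        except EdgelessGraphError as err:
            raise EdgelessGraphError(f"whole-brain graph: {err}") from err

    @cached_property
    def sub_communities(self) -> dict[str, CommunityAssignment]:
        out: dict[str, CommunityAssignment] = {}
        for net, sub in self.subgraphs.items():
            try:
                out[net] = newman_modularity(sub.adjacency, self.gamma)
            except EdgelessGraphError as err:
                raise EdgelessGraphError(f"network {net!r} subgraph: {err}") from err
        return out


def _ctx(cm: ConnectivityMatrix, partition: NetworkPartition, density: float,
         gamma: float = 1.0, ctx: GraphContext | None = None) -> GraphContext:
    if ctx is not None:
        return ctx
    return GraphContext(cm=cm, partition=partition, density=density, gamma=gamma)


def efficiency_features(cm: ConnectivityMatrix, partition: NetworkPartition,
                        density: float = DEFAULT_DENSITY, *,
                        ctx: GraphContext | None = None) -> FeatureBlock:
    """36 efficiency features (29 whole-brain-level + 7 intra-network)."""
    c = _ctx(cm, partition, density, ctx=ctx)
    inv = inverse_distance(c.whole)
    masks = scope_pair_masks(partition)
    names, values = [], []
    for scope, mask in masks.items():
        if mask.sum() < 1:
            raise ValueError(f"scope {scope!r} has no parcel pairs")
        names.append(f"{c.family}:eff:{scope}")
        values.append(float(inv[mask].mean()))
    for net, sub in c.subgraphs.items():
        names.append(f"{c.family}:intra_eff:{net}")
        values.append(global_efficiency(sub))
    return FeatureBlock(names=tuple(names), values=np.array(values), family=c.family)


def clustering_features(cm: ConnectivityMatrix, partition: NetworkPartition,
                        density: float = DEFAULT_DENSITY, *,
                        ctx: GraphContext | None = None) -> FeatureBlock:
    """15 clustering features (whole + 7 network means + 7 intra means)."""
    c = _ctx(cm, partition, density, ctx=ctx)
    C = clustering_coefficients(c.whole)
    names = [f"{c.family}:clust:whole"]
    values = [float(C.mean())]
    for net in partition.networks:
        names.append(f"{c.family}:clust:{net}")
        values.append(float(C[partition.indices(net)].mean()))
    for net, sub in c.subgraphs.items():
        names.append(f"{c.family}:intra_clust:{net}")
        values.append(float(clustering_coefficients(sub).mean()))
    return FeatureBlock(names=tuple(names), values=np.array(values), family=c.family)


def modularity_features(cm: ConnectivityMatrix, partition: NetworkPartition,
                        density: float = DEFAULT_DENSITY, gamma: float = 1.0, *,
                        ctx: GraphContext | None = None) -> FeatureBlock:
    """8 modularity features: Q of the whole-brain graph and of each subgraph."""
    c = _ctx(cm, partition, density, gamma, ctx)
    names = [f"{c.family}:modularity:whole"]
    values = [c.whole_communities.Q]
    for net in partition.networks:
        names.append(f"{c.family}:modularity:{net}")
        values.append(c.sub_communities[net].Q)
    return FeatureBlock(names=tuple(names), values=np.array(values), family=c.family)


def participation_features(cm: ConnectivityMatrix, partition: NetworkPartition,
                           density: float = DEFAULT_DENSITY, gamma: float = 1.0, *,
                           ctx: GraphContext | None = None) -> FeatureBlock:
    """15 participation features (whole + 7 network means + 7 intra means).

    Whole-brain values use the whole-brain Newman communities; each intra
    value uses the subgraph's own communities (mirroring the "Intra-" naming).
    """
    c = _ctx(cm, partition, density, gamma, ctx)
    part = participation_coefficients(c.whole, c.whole_communities)
    names = [f"{c.family}:part:whole"]
    values = [float(part.mean())]
    for net in partition.networks:
        names.append(f"{c.family}:part:{net}")
        values.append(float(part[partition.indices(net)].mean()))
    for net, sub in c.subgraphs.items():
        names.append(f"{c.family}:intra_part:{net}")
        values.append(float(participation_coefficients(sub, c.sub_communities[net]).mean()))
    return FeatureBlock(names=tuple(names), values=np.array(values), family=c.family)


def graph_feature_block(cm: ConnectivityMatrix, partition: NetworkPartition,
                        density: float = DEFAULT_DENSITY, gamma: float = 1.0) -> FeatureBlock:
    """All 74 graph features, ordered efficiency/clustering/modularity/participation."""
    c = GraphContext(cm=cm, partition=partition, density=density, gamma=gamma)
    blocks = [
        efficiency_features(cm, partition, density, ctx=c),
        clustering_features(cm, partition, density, ctx=c),
        modularity_features(cm, partition, density, gamma, ctx=c),
        participation_features(cm, partition, density, gamma, ctx=c),
    ]
    names: list[str] = []
    values: list[np.ndarray] = []
    for b in blocks:
        names.extend(b.names)
        values.append(b.values)
    return FeatureBlock(names=tuple(names), values=np.concatenate(values), family=c.family)
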