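"""Deterministic Newman leading-eigenvector community detection.

Divisive spectral partitioning on the modularity matrix
``B = A - gamma * k k^T / (2m)`` with Kernighan-Lin-style single-node
fine-tuning after every bisection.  All tie-breaks are by node index and
the eigensolver is a dense symmetric decomposition, so the partition is
a deterministic function of the adjacency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-10


class EdgelessGraphError(ValueError):
    """Modularity is undefined on a graph with no edges."""


@dataclass(frozen=True)
class CommunityAssignment:
    labels: np.ndarray  # community id per node, 0..n_communities-1
    Q: float
    gamma: float = 1.0

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1


def modularity_value(adjacency: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Q = sum_c (e_cc - gamma * a_c^2) for an undirected binary graph."""
    A = np.asarray(adjacency, dtype=float)
    m2 = A.sum()  # 2m
    if m2 <= 0:
        raise EdgelessGraphError("graph has no edges")
    k = A.sum(axis=1)
    Q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        e_cc = A[np.ix_(idx, idx)].sum() / m2
        a_c = k[idx].sum() / m2
        Q += e_cc - gamma * a_c**2
    return float(Q)


def _fine_tune(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """KL-style sweeps: flip each node once per pass, keep the best prefix."""
    n = s.size
    diag = np.diag(Bg)
    q = float(s @ Bg @ s)
    while True:
        s_work = s.copy()
        moved = np.zeros(n, dtype=bool)
        best_q, best_state = q, s.copy()
        Bs = Bg @ s_work
        for _ in range(n):
            gains = -4.0 * s_work * Bs + 4.0 * diag
            gains[moved] = -np.inf
            i = int(np.argmax(gains))  # argmax takes the lowest index on ties
            q_new = float(s_work @ Bg @ s_work) + gains[i]
            Bs = Bs - 2.0 * s_work[i] * Bg[:, i]
            s_work[i] = -s_work[i]
            moved[i] = True
            if q_new > best_q + _EPS:
                best_q, best_state = q_new, s_work.copy()
        if best_q > q + _EPS:
            q, s = best_q, best_state
        else:
            return s


def newman_modularity(adjacency: np.ndarray, gamma: float = 1.0) -> CommunityAssignment:
    """Leading-eigenvector divisive partitioning with KL fine-tuning.

    Recursively bisects groups using the leading eigenvector of the
    group's generalized modularity matrix; a group whose best (fine-tuned)
    bisection does not increase Q is left indivisible.  Returns the node
    labels (renumbered in order of first appearance) and the modularity of
    the returned partition.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    n = A.shape[0]
    m2 = A.sum()
    if m2 <= 0:
        raise EdgelessGraphError("graph has no edges")
    k = A.sum(axis=1)
    B = A - gamma * np.outer(k, k) / m2

    labels = np.zeros(n, dtype=int)
    stack = [np.arange(n)]
    next_label = 1
    while stack:
        nodes = stack.pop()
        if nodes.size < 2:
            continue
        Bg = B[np.ix_(nodes, nodes)]
        Bg = Bg - np.diag(Bg.sum(axis=1))  # generalized modularity matrix
        w, V = np.linalg.eigh(Bg)
        if w[-1] <= _EPS:
            continue  # indivisible
        v = V[:, -1]
        s = np.where(v >= 0, 1.0, -1.0)  # zero entries join the + side
        s = _fine_tune(Bg, s)
        dq = float(s @ Bg @ s)  # proportional to the Q gain (factor 1/(2m))
        if dq <= _EPS or np.all(s == s[0]):
            continue
        neg = nodes[s < 0]
        pos = nodes[s > 0]
        labels[neg] = next_label
        next_label += 1
        stack.append(pos)
        stack.append(neg)

    # renumber communities by first appearance for determinism
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return CommunityAssignment(labels=out, Q=modularity_value(A, out, gamma), gamma=gamma)
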