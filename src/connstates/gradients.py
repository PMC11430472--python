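"""Cortical gradients: affinity, diffusion-map embedding, Procrustes, features.

From the GSR connectivity matrix, connectivity profiles are Fisher
z-transformed and row-wise sparsified (top 10% of entries per row, weights
retained), a normalized-angle cosine affinity is computed, and a 3-component
diffusion-map embedding (anisotropy alpha = 0.5, multiscale t = 0 weighting
lambda/(1 - lambda)) places each parcel in a low-dimensional space of
connectivity styles.  Per-scan embeddings are aligned to a reference by
orthogonal Procrustes (rotation/reflection, no scaling) before 60 summary
features are taken: 24 ranges, 8 dispersions, 7 network eccentricities and
21 between-network centroid distances.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .blocks import FeatureBlock
from .connectivity import ConnectivityMatrix
from .partition import NetworkPartition

DEFAULT_ALPHA = 0.5
DEFAULT_DENSITY = 0.10
N_COMPONENTS = 3


class DisconnectedAffinityError(ValueError):
    """The affinity graph has more than one connected component."""


@dataclass(frozen=True)
class AffinityMatrix:
    values: np.ndarray  # symmetric, in [0, 1], unit diagonal
    alpha: float = DEFAULT_ALPHA
    sparsity_density: float = DEFAULT_DENSITY

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("affinity must be symmetric")
        if v.min() < -1e-10 or v.max() > 1 + 1e-10:
            raise ValueError("affinity entries must lie in [0, 1]")
        v = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(v, 1.0)
        object.__setattr__(self, "values", v)

    @property
    def parcel_count(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class GradientEmbedding:
    coords: np.ndarray  # P x 3
    eigenvalues: np.ndarray  # 3 nonneg reals, nonincreasing
    aligned: bool = False
    reference_id: str = ""
    disparity: float = float("nan")

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != N_COMPONENTS:
            raise ValueError(f"coords must be P x {N_COMPONENTS}")
        if not np.isfinite(c).all():
            raise ValueError("coords must be finite")
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "eigenvalues", np.asarray(self.eigenvalues, dtype=float))

    @property
    def parcel_count(self) -> int:
        return self.coords.shape[0]


# --------------------------------------------------------------------------- #
# Affinity construction
# --------------------------------------------------------------------------- #


def rowwise_sparsify(cm: ConnectivityMatrix, density: float = DEFAULT_DENSITY) -> np.ndarray:
    """Fisher-z profiles with only the top ``round(density * (P-1))`` entries per row.

    The diagonal is excluded and zeroed; retained entries keep their z
    weights; ties at the row cutoff are broken by ascending column index.
    The result need not be symmetric.
    """
    P = cm.parcel_count
    k = int(np.floor(density * (P - 1) + 0.5))
    if k == 0:
        raise ValueError(f"density {density} retains 0 entries per row for {P} parcels")
    r = np.clip(cm.values, -1 + 1e-7, 1 - 1e-7)
    z = np.arctanh(r)
    np.fill_diagonal(z, -np.inf)  # never retained
    out = np.zeros_like(z)
    for i in range(P):
        order = np.argsort(-z[i], kind="stable")[:k]  # stable: lower column wins ties
        out[i, order] = z[i, order]
    return out


def cosine_affinity(profiles: np.ndarray) -> AffinityMatrix:
    """Normalized-angle affinity 1 - acos(cosine(row_i, row_j)) / pi."""
    S = np.asarray(profiles, dtype=float)
    norms = np.linalg.norm(S, axis=1)
    bad = np.where(norms < 1e-12)[0]
    if bad.size:
        raise ValueError(f"parcel {bad[0]} has an all-zero connectivity profile")
    U = S / norms[:, None]
    cos = np.clip(U @ U.T, -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    np.fill_diagonal(aff, 1.0)
    return AffinityMatrix(values=np.clip(aff, 0.0, 1.0))


# --------------------------------------------------------------------------- #
# Diffusion-map embedding
# --------------------------------------------------------------------------- #


def diffusion_embedding(a: AffinityMatrix, alpha: float = DEFAULT_ALPHA,
                        n_components: int = N_COMPONENTS) -> GradientEmbedding:
    """Multiscale diffusion-map embedding of a connected affinity matrix.

    Density-normalized kernel W' = D^-alpha W D^-alpha, row-stochastic
    M = D'^-1 W'; the first ``n_components`` nontrivial eigenvectors are
    returned scaled by lambda/(1 - lambda) (the t = 0 multiscale
    convention), in descending eigenvalue order.  Component signs are fixed
    so each column's largest-magnitude entry is positive.
    """
    W = a.values
    P = W.shape[0]
    if P < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} parcels")
    n_comp, _ = connected_components(csr_matrix(W > 1e-12), directed=False)
    if n_comp != 1:
        raise DisconnectedAffinityError(f"affinity graph has {n_comp} components")

    d = W.sum(axis=1)
    Wp = W / np.outer(d**alpha, d**alpha)
    dp = Wp.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(dp)
    S = Wp * np.outer(inv_sqrt, inv_sqrt)  # symmetric conjugate of M
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(-evals)
    evals, evecs = evals[order], evecs[:, order]

    psi = evecs * inv_sqrt[:, None]
    psi = psi / psi[:, 0:1]  # trivial eigenvector becomes the constant 1
    lam = evals[1 : n_components + 1]
    coords = psi[:, 1 : n_components + 1] * (lam / (1.0 - lam))[None, :]
    for j in range(coords.shape[1]):  # deterministic sign convention
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return GradientEmbedding(coords=coords, eigenvalues=lam, aligned=False)


def embed_connectivity(cm: ConnectivityMatrix, density: float = DEFAULT_DENSITY,
                       alpha: float = DEFAULT_ALPHA) -> GradientEmbedding:
    """Full per-scan gradient computation: sparsify, affinity, embed."""
    return diffusion_embedding(cosine_affinity(rowwise_sparsify(cm, density)), alpha)


# --------------------------------------------------------------------------- #
# Procrustes alignment and group reference
# --------------------------------------------------------------------------- #


def procrustes_align(e: GradientEmbedding, ref: GradientEmbedding,
                     reference_id: str = "reference") -> GradientEmbedding:
    """Orthogonal (rotation/reflection, no scaling) alignment of ``e`` to ``ref``."""
    if e.coords.shape != ref.coords.shape:
        raise ValueError(
            f"shape mismatch: embedding {e.coords.shape} vs reference {ref.coords.shape}"
        )
    R, _ = orthogonal_procrustes(e.coords, ref.coords)
    aligned = e.coords @ R
    disparity = float(np.linalg.norm(aligned - ref.coords) ** 2)
    return replace(e, coords=aligned, aligned=True, reference_id=reference_id,
                   disparity=disparity)


def build_reference(embeddings: list[GradientEmbedding], n_iter: int = 2) -> GradientEmbedding:
    """Group-mean reference: align all embeddings to a tentative reference
    and average, iterating ``n_iter`` times (seeded by the first embedding)."""
    if not embeddings:
        raise ValueError("need at least one embedding to build a reference")
    ref = embeddings[0]
    for _ in range(n_iter):
        aligned = [procrustes_align(e, ref).coords for e in embeddings]
        mean = np.mean(aligned, axis=0)
        ref = GradientEmbedding(coords=mean,
                                eigenvalues=np.mean([e.eigenvalues for e in embeddings], axis=0))
    return replace(ref, reference_id="group-mean")


# --------------------------------------------------------------------------- #
# Gradient features
# --------------------------------------------------------------------------- #


def gradient_feature_block(e: GradientEmbedding, partition: NetworkPartition) -> FeatureBlock:
    """The 60 gradient features from an aligned 3-D embedding.

    24 ranges (max - min per gradient; whole brain + 7 networks), 8
    dispersions (sum of squared distances of member parcels to the scope
    centroid), 7 eccentricities (squared network-centroid-to-global-centroid
    distance) and 21 between-network squared centroid distances.
    """
    if e.parcel_count != partition.parcel_count:
        raise ValueError("embedding and partition disagree on parcel count")
    X = e.coords
    names: list[str] = []
    values: list[float] = []

    scopes: list[tuple[str, np.ndarray]] = [("whole", np.arange(partition.parcel_count))]
    scopes += [(net, partition.indices(net)) for net in partition.networks]

    for scope, idx in scopes:
        rng_ = X[idx].max(axis=0) - X[idx].min(axis=0)
        for d in range(N_COMPONENTS):
            names.append(f"gradient:range:{scope}:g{d + 1}")
            values.append(float(rng_[d]))

    centroids = {scope: X[idx].mean(axis=0) for scope, idx in scopes}
    for scope, idx in scopes:
        diff = X[idx] - centroids[scope]
        names.append(f"gradient:disp:{scope}")
        values.append(float((diff**2).sum()))

    c_whole = centroids["whole"]
    for net in partition.networks:
        names.append(f"gradient:ecc:{net}")
        values.append(float(((centroids[net] - c_whole) ** 2).sum()))

    for a, b in partition.network_pairs():
        names.append(f"gradient:dist:{a}-{b}")
        values.append(float(((centroids[a] - centroids[b]) ** 2).sum()))

    return FeatureBlock(names=tuple(names), values=np.array(values), family="gradient")
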