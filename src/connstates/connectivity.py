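"""Pearson functional connectivity and the 58 connectivity-profile features.

Two variants are computed per scan: ``noGSR`` (the parcel signals as
given) and ``GSR`` (the mean signal over all parcels regressed out of
every parcel by ordinary least squares before correlating).  From a
P x P correlation matrix, the mean and population SD of the off-diagonal
entries are taken over 29 scopes — the whole matrix, the 7 within-network
blocks, and the 21 between-network-pair blocks — each unordered parcel
pair counted once, giving 29 x 2 = 58 named features per variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import FeatureBlock
from .partition import NetworkPartition
from .timeseries import DegenerateSignalError, ParcelTimeSeries, standardize_columns


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix with its GSR variant tag."""

    values: np.ndarray
    variant: str  # "GSR" | "noGSR"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if np.abs(v).max() > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 1.0)
        object.__setattr__(self, "values", v)

    @property
    def parcel_count(self) -> int:
        return self.values.shape[0]


def global_signal_regress(ts: ParcelTimeSeries) -> ParcelTimeSeries:
    """Regress the cross-parcel mean time course out of every parcel.

    OLS with an intercept and the global mean as regressor; residual
    columns are re-standardized.  Raises :class:`DegenerateSignalError`
    if the global signal, or any residual, has zero variance (e.g. all
    parcels identical).
    """
    X = ts.data
    g = X.mean(axis=1)
    gc = g - g.mean()
    den = float(gc @ gc)
    if den < 1e-12:
        raise DegenerateSignalError("global signal has zero variance")
    Xc = X - X.mean(axis=0)
    beta = (gc @ Xc) / den
    resid = Xc - np.outer(gc, beta)
    try:
        resid = standardize_columns(resid, what="GSR residual for parcel")
    except DegenerateSignalError as err:
        raise DegenerateSignalError(f"degenerate residual after GSR: {err}") from err
    return ts.with_data(resid, variant="GSR")


def pearson_connectivity(ts: ParcelTimeSeries) -> ConnectivityMatrix:
    """Sample Pearson correlation of all parcel pairs, diagonal set to 1."""
    X = ts.data
    sd = X.std(axis=0)
    bad = np.where(sd < 1e-12)[0]
    if bad.size:
        raise DegenerateSignalError(f"parcel {bad[0]} has zero variance")
    r = np.corrcoef(X, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, variant=ts.variant)


# --------------------------------------------------------------------------- #
# Scope machinery shared with the graph features
# --------------------------------------------------------------------------- #


def scope_pair_masks(partition: NetworkPartition) -> dict[str, np.ndarray]:
    """Boolean P x P mask of the unordered parcel pairs in each of 29 scopes.

    Masks select the upper triangle only, so each pair is counted once and
    the diagonal never enters.
    """
    P = partition.parcel_count
    codes = partition.label_codes()
    upper = np.triu(np.ones((P, P), dtype=bool), k=1)
    masks: dict[str, np.ndarray] = {"whole": upper}
    for k, net in enumerate(partition.networks):
        inn = codes == k
        masks[net] = upper & np.outer(inn, inn)
    for a, b in partition.network_pairs():
        ia, ib = partition.networks.index(a), partition.networks.index(b)
        ma, mb = codes == ia, codes == ib
        cross = np.outer(ma, mb) | np.outer(mb, ma)
        masks[f"{a}-{b}"] = upper & cross
    return masks


def connectivity_features(cm: ConnectivityMatrix, partition: NetworkPartition) -> FeatureBlock:
    """The 58 connectivity features: mean and population SD per scope.

    Ordering: all 29 means (whole, 7 networks, 21 pairs), then the 29 SDs
    in the same scope order.  Names are ``conn_<variant>:<stat>:<scope>``.
    """
    if cm.parcel_count != partition.parcel_count:
        raise ValueError("connectivity matrix and partition disagree on parcel count")
    family = f"conn_{cm.variant}"
    masks = scope_pair_masks(partition)
    names: list[str] = []
    values: list[float] = []
    stats: dict[str, tuple[float, float]] = {}
    for scope, mask in masks.items():
        entries = cm.values[mask]
        if entries.size < 2:
            raise ValueError(f"scope {scope!r} has {entries.size} pair(s); SD needs >= 2")
        stats[scope] = (float(entries.mean()), float(entries.std()))  # population SD
    for stat_idx, stat in enumerate(("mean", "sd")):
        for scope in masks:
            names.append(f"{family}:{stat}:{scope}")
            values.append(stats[scope][stat_idx])
    return FeatureBlock(names=tuple(names), values=np.array(values), family=family)
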