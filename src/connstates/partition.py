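"""Parcel-to-network partition of a cortical parcellation.

Every parcel belongs to exactly one of seven canonical resting-state
networks: visual (VIS), somatomotor (SMN), dorsal attention (DAN),
ventral attention (VAN), limbic (LIM), frontoparietal (FPN) and
default-mode (DMN).  Feature scopes (whole brain, the 7 networks, the
21 unordered network pairs) are all derived from this partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Canonical network order used everywhere (features, couplings, scopes).
NETWORKS: tuple[str, ...] = ("VIS", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN")


class PartitionError(ValueError):
    """Raised when a parcel/network configuration is inconsistent."""


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of each parcel to one named functional network.

    Parameters
    ----------
    labels
        One network name per parcel, in parcel order.
    networks
        Ordered tuple of the network names (default: the canonical 7).
    """

    labels: tuple[str, ...]
    networks: tuple[str, ...] = NETWORKS

    def __post_init__(self) -> None:
        if len(set(self.networks)) != len(self.networks):
            raise PartitionError("network names must be unique")
        unknown = set(self.labels) - set(self.networks)
        if unknown:
            raise PartitionError(f"labels reference unknown networks: {sorted(unknown)}")
        counts = {n: 0 for n in self.networks}
        for lab in self.labels:
            counts[lab] += 1
        for name, c in counts.items():
            if c < 2:
                raise PartitionError(
                    f"network {name!r} has {c} parcel(s); every network needs >= 2"
                )

    @property
    def parcel_count(self) -> int:
        return len(self.labels)

    def indices(self, network: str) -> np.ndarray:
        """Parcel indices belonging to ``network``."""
        if network not in self.networks:
            raise PartitionError(f"unknown network {network!r}")
        return np.array([i for i, lab in enumerate(self.labels) if lab == network])

    def label_codes(self) -> np.ndarray:
        """Integer network code per parcel (position in ``networks``)."""
        code = {n: k for k, n in enumerate(self.networks)}
        return np.array([code[lab] for lab in self.labels])

    def sizes(self) -> dict[str, int]:
        return {n: int((self.label_codes() == k).sum()) for k, n in enumerate(self.networks)}

    def network_pairs(self) -> list[tuple[str, str]]:
        """The 21 unordered network pairs, in canonical order."""
        nets = self.networks
        return [(nets[i], nets[j]) for i in range(len(nets)) for j in range(i + 1, len(nets))]

    def pair_name(self, a: str, b: str) -> str:
        """Canonical ``A-B`` name of a network pair (declared order)."""
        ia, ib = self.networks.index(a), self.networks.index(b)
        if ia == ib:
            raise PartitionError("pair requires two distinct networks")
        if ia > ib:
            a, b = b, a
        return f"{a}-{b}"

    def scope_names(self) -> list[str]:
        """The 29 scope names: whole brain, 7 networks, 21 pairs."""
        return ["whole"] + list(self.networks) + [f"{a}-{b}" for a, b in self.network_pairs()]


def even_sizes(parcel_count: int, networks: Sequence[str] = NETWORKS) -> dict[str, int]:
    """Near-equal network sizes summing to ``parcel_count``.

    The first ``parcel_count % 7`` networks receive one extra parcel.
    """
    k = len(networks)
    base, extra = divmod(parcel_count, k)
    return {n: base + (1 if i < extra else 0) for i, n in enumerate(networks)}


def make_partition(
    parcel_count: int,
    sizes: Mapping[str, int] | None = None,
    networks: Sequence[str] = NETWORKS,
) -> NetworkPartition:
    """Deterministic contiguous-block partition in declared network order.

    Parameters
    ----------
    parcel_count
        Total number of parcels.
    sizes
        Parcel count per network; must cover exactly the declared networks
        and sum to ``parcel_count``.  Defaults to near-equal sizes.
    """
    if parcel_count <= 0:
        raise PartitionError("parcel_count must be positive")
    networks = tuple(networks)
    if sizes is None:
        sizes = even_sizes(parcel_count, networks)
    missing = set(networks) - set(sizes)
    extra = set(sizes) - set(networks)
    if missing:
        raise PartitionError(f"sizes missing networks: {sorted(missing)}")
    if extra:
        raise PartitionError(f"sizes name unknown networks: {sorted(extra)}")
    total = sum(sizes[n] for n in networks)
    if total != parcel_count:
        off = next(n for n in networks if sizes[n] > 0) if total > parcel_count else networks[-1]
        raise PartitionError(
            f"network sizes sum to {total}, expected {parcel_count} "
            f"(check e.g. network {off!r})"
        )
    labels: list[str] = []
    for n in networks:
        labels.extend([n] * sizes[n])
    return NetworkPartition(labels=tuple(labels), networks=networks)
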