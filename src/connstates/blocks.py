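"""Named feature blocks: ordered (name, value) records with a family tag."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical family order of the integrated 324-feature vector.
FAMILIES: tuple[str, ...] = ("conn_noGSR", "conn_GSR", "graph_noGSR", "graph_GSR", "gradient")


@dataclass(frozen=True)
class FeatureBlock:
    names: tuple[str, ...]
    values: np.ndarray
    family: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if len(self.names) != vals.shape[0] or vals.ndim != 1:
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.names)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name=self.family)


def concat_blocks(blocks: list[FeatureBlock], family: str = "all") -> FeatureBlock:
    names: list[str] = []
    values: list[np.ndarray] = []
    for b in blocks:
        names.extend(b.names)
        values.append(b.values)
    return FeatureBlock(names=tuple(names), values=np.concatenate(values), family=family)
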