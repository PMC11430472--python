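"""Parcellated BOLD time series container and column standardization."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

MIN_TIMEPOINTS = 30  # below this, Pearson correlations are too unstable to use


class DegenerateSignalError(ValueError):
    """A parcel time course has (numerically) zero variance."""


def standardize_columns(data: np.ndarray, *, what: str = "parcel") -> np.ndarray:
    """Return ``data`` with each column scaled to mean 0, unit variance.

    Raises :class:`DegenerateSignalError` naming the first offending column
    if any column is constant.
    """
    data = np.asarray(data, dtype=float)
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    bad = np.where(sd < 1e-12)[0]
    if bad.size:
        raise DegenerateSignalError(f"{what} {bad[0]} has zero variance")
    return (data - mean) / sd


@dataclass(frozen=True)
class ParcelTimeSeries:
    """T x P matrix of parcel signals plus scan metadata.

    Columns are z-scored (zero mean, unit variance) by construction for
    everything this pipeline produces; ``variant`` records whether the
    global signal has been regressed out ("GSR") or not ("noGSR").
    """

    data: np.ndarray
    subject_id: str
    state: str  # "baseline" | "atypical"
    condition: str
    variant: str = "noGSR"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError("data must be a 2-D (time x parcels) array")
        if arr.shape[0] < MIN_TIMEPOINTS:
            raise ValueError(
                f"need at least {MIN_TIMEPOINTS} time points, got {arr.shape[0]}"
            )
        if not np.isfinite(arr).all():
            raise ValueError("data contains non-finite values")
        if self.state not in ("baseline", "atypical"):
            raise ValueError(f"state must be 'baseline' or 'atypical', got {self.state!r}")
        object.__setattr__(self, "data", arr)

    @property
    def t_points(self) -> int:
        return self.data.shape[0]

    @property
    def parcel_count(self) -> int:
        return self.data.shape[1]

    @property
    def scan_id(self) -> str:
        return f"{self.subject_id}:{self.state}"

    def with_data(self, data: np.ndarray, variant: str | None = None) -> "ParcelTimeSeries":
        return replace(self, data=data, variant=variant or self.variant)
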