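"""Plain-text I/O: scan TSVs, cohort sidecar JSON, feature tables, references."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gradients import GradientEmbedding
from .partition import NetworkPartition
from .synth import CohortDataset
from .timeseries import ParcelTimeSeries


def parcel_names(P: int) -> list[str]:
    return [f"p{i:03d}" for i in range(P)]


def write_scan_tsv(path: Path | str, ts: ParcelTimeSeries) -> None:
    df = pd.DataFrame(ts.data, columns=parcel_names(ts.parcel_count))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_scan_tsv(path: Path | str, subject_id: str, state: str,
                  condition: str, variant: str = "noGSR") -> ParcelTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return ParcelTimeSeries(data=df.to_numpy(dtype=float), subject_id=subject_id,
                            state=state, condition=condition, variant=variant)


def write_cohort(directory: Path | str, cohort: CohortDataset) -> None:
    """One TSV per scan plus a ``cohort.json`` sidecar (partition, pairing, labels)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for scan in cohort.scans:
        fname = f"{scan.subject_id}_{scan.state}.tsv"
        write_scan_tsv(directory / fname, scan)
        files[scan.scan_id] = fname
    sidecar = {
        "condition": cohort.condition,
        "seed": cohort.seed,
        "networks": list(cohort.partition.networks),
        "labels": list(cohort.partition.labels),
        "pairing": {sub: [cohort.scans[i].scan_id for i in pair]
                    for sub, pair in cohort.pairing.items()},
        "files": files,
        "states": {scan.scan_id: scan.state for scan in cohort.scans},
    }
    (directory / "cohort.json").write_text(json.dumps(sidecar, indent=1))


def read_cohort(directory: Path | str) -> CohortDataset:
    directory = Path(directory)
    sidecar = json.loads((directory / "cohort.json").read_text())
    partition = NetworkPartition(labels=tuple(sidecar["labels"]),
                                 networks=tuple(sidecar["networks"]))
    scans = []
    index: dict[str, int] = {}
    for sub, (bid, aid) in sidecar["pairing"].items():
        for scan_id in (bid, aid):
            state = sidecar["states"][scan_id]
            ts = read_scan_tsv(directory / sidecar["files"][scan_id],
                               subject_id=sub, state=state,
                               condition=sidecar["condition"])
            index[scan_id] = len(scans)
            scans.append(ts)
    pairing = {sub: (index[b], index[a]) for sub, (b, a) in sidecar["pairing"].items()}
    return CohortDataset(scans=tuple(scans), partition=partition, pairing=pairing,
                         condition=sidecar["condition"], seed=int(sidecar["seed"]))


def write_reference(path: Path | str, ref: GradientEmbedding) -> None:
    """Reference embedding as a P x 3 TSV with parcel names."""
    df = pd.DataFrame(ref.coords, columns=["g1", "g2", "g3"],
                      index=parcel_names(ref.parcel_count))
    df.to_csv(path, sep="\t", index_label="parcel")


def read_reference(path: Path | str) -> GradientEmbedding:
    df = pd.read_csv(path, sep="\t", index_col="parcel")
    return GradientEmbedding(coords=df.to_numpy(dtype=float),
                             eigenvalues=np.full(3, np.nan), aligned=False,
                             reference_id=str(path))


def write_features(path: Path | str, features: pd.DataFrame, meta: pd.DataFrame) -> None:
    joined = meta.join(features)
    joined.to_csv(path, sep="\t", index_label="scan_id")


def read_features(path: Path | str) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", index_col="scan_id")
    meta_cols = ["subject", "state", "condition"]
    return df.drop(columns=meta_cols), df[meta_cols]
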