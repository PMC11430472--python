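"""Assembly of the integrated 324-feature vector per scan and per cohort.

Family order: conn_noGSR (58), conn_GSR (58), graph_noGSR (74),
graph_GSR (74), gradient (60).  Gradients are computed from the GSR
matrix only, and every scan's embedding is aligned to a shared reference
(by default the group-mean embedding of the cohort's baseline scans).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .blocks import FAMILIES, FeatureBlock, concat_blocks
from .connectivity import (
    ConnectivityMatrix,
    connectivity_features,
    global_signal_regress,
    pearson_connectivity,
)
from .gradients import (
    GradientEmbedding,
    build_reference,
    embed_connectivity,
    gradient_feature_block,
    procrustes_align,
)
from .graphs import DEFAULT_DENSITY, graph_feature_block
from .partition import NetworkPartition
from .synth import CohortDataset
from .timeseries import ParcelTimeSeries

N_FEATURES_TOTAL = 324


def feature_names(partition: NetworkPartition) -> list[str]:
    """Canonical ordered names of the integrated 324-feature vector."""
    scopes = partition.scope_names()
    names: list[str] = []
    for fam in ("conn_noGSR", "conn_GSR"):
        for stat in ("mean", "sd"):
            names += [f"{fam}:{stat}:{s}" for s in scopes]
    for fam in ("graph_noGSR", "graph_GSR"):
        names += [f"{fam}:eff:{s}" for s in scopes]
        names += [f"{fam}:intra_eff:{n}" for n in partition.networks]
        names += [f"{fam}:clust:whole"] + [f"{fam}:clust:{n}" for n in partition.networks]
        names += [f"{fam}:intra_clust:{n}" for n in partition.networks]
        names += [f"{fam}:modularity:whole"] + [f"{fam}:modularity:{n}" for n in partition.networks]
        names += [f"{fam}:part:whole"] + [f"{fam}:part:{n}" for n in partition.networks]
        names += [f"{fam}:intra_part:{n}" for n in partition.networks]
    for scope in ["whole"] + list(partition.networks):
        names += [f"gradient:range:{scope}:g{d}" for d in (1, 2, 3)]
    names += [f"gradient:disp:{s}" for s in ["whole"] + list(partition.networks)]
    names += [f"gradient:ecc:{n}" for n in partition.networks]
    names += [f"gradient:dist:{a}-{b}" for a, b in partition.network_pairs()]
    return names


def family_of(name: str) -> str:
    return name.split(":", 1)[0]


def scan_connectivity(ts: ParcelTimeSeries) -> dict[str, ConnectivityMatrix]:
    """Both connectivity variants of one scan."""
    return {
        "noGSR": pearson_connectivity(ts),
        "GSR": pearson_connectivity(global_signal_regress(ts)),
    }


def extract_scan_features(
    ts: ParcelTimeSeries,
    partition: NetworkPartition,
    reference: GradientEmbedding,
    density: float = DEFAULT_DENSITY,
) -> FeatureBlock:
    """The full named 324-entry feature vector of one scan."""
    cms = scan_connectivity(ts)
    blocks = [
        connectivity_features(cms["noGSR"], partition),
        connectivity_features(cms["GSR"], partition),
        graph_feature_block(cms["noGSR"], partition, density),
        graph_feature_block(cms["GSR"], partition, density),
    ]
    emb = procrustes_align(embed_connectivity(cms["GSR"], density), reference)
    blocks.append(gradient_feature_block(emb, partition))
    block = concat_blocks(blocks)
    if len(block) != N_FEATURES_TOTAL:
        raise AssertionError(f"expected {N_FEATURES_TOTAL} features, got {len(block)}")
    return block


def cohort_reference(cohort: CohortDataset, density: float = DEFAULT_DENSITY) -> GradientEmbedding:
    """Group-mean gradient reference from the cohort's baseline scans."""
    embeddings = []
    for scan in cohort.scans:
        if scan.state != "baseline":
            continue
        cm = pearson_connectivity(global_signal_regress(scan))
        embeddings.append(embed_connectivity(cm, density))
    return build_reference(embeddings)


def extract_cohort_features(
    cohort: CohortDataset,
    reference: GradientEmbedding | None = None,
    density: float = DEFAULT_DENSITY,
) -> tuple[pd.DataFrame, pd.DataFrame, GradientEmbedding]:
    """Feature table (scans x 324), metadata table, and the gradient reference used."""
    if reference is None:
        reference = cohort_reference(cohort, density)
    rows, meta = [], []
    for scan in cohort.scans:
        block = extract_scan_features(scan, cohort.partition, reference, density)
        rows.append(block.as_series())
        meta.append(
            {"scan_id": scan.scan_id, "subject": scan.subject_id,
             "state": scan.state, "condition": scan.condition}
        )
    features = pd.DataFrame(rows, index=[m["scan_id"] for m in meta])
    expected = feature_names(cohort.partition)
    if list(features.columns) != expected:
        raise AssertionError("feature columns deviate from the canonical order")
    meta_df = pd.DataFrame(meta).set_index("scan_id")
    return features, meta_df, reference


def family_columns(features: pd.DataFrame) -> dict[str, list[str]]:
    """Column names per base-model family, in canonical order."""
    out: dict[str, list[str]] = {fam: [] for fam in FAMILIES}
    for col in features.columns:
        out[family_of(col)].append(col)
    return out
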