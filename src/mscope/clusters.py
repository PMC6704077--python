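"""Gyrus-level clustering of above-threshold nodes (CMCD ranking).

Above-threshold nodes are grouped purely by anatomical label — one cluster
per (hemisphere, gyrus) — and each cluster's CMCD is the *sum* of its
members' field values, so both extent and intensity contribute.  Clusters
are ranked by descending CMCD (alphabetical gyrus label, then hemisphere,
breaks exact ties), and the top-ranked clusters name the cortical regions
a montage stimulates most.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import AtlasLabelTable, FieldVector, MscopeError
from .overlap import ThresholdedSet


@dataclass
class GyrusCluster:
    gyrus: str
    hemisphere: str
    n_nodes: int
    cmcd: float
    rank: int   # 1-based, by descending cmcd

    def to_dict(self) -> dict:
        return {"gyrus": self.gyrus, "hemisphere": self.hemisphere,
                "n_nodes": self.n_nodes, "cmcd": self.cmcd,
                "rank": self.rank}


def cluster_by_gyrus(thresholded: ThresholdedSet, field: FieldVector,
                     labels: AtlasLabelTable) -> list[GyrusCluster]:
    """One cluster per (hemisphere, gyrus) with at least one
    above-threshold node; cmcd = sum of member field values."""
    if not thresholded.node_ids:
        return []
    if not thresholded.node_ids <= set(labels.node_id.tolist()):
        raise MscopeError("thresholded nodes must all carry atlas labels")
    df = pd.DataFrame({"node_id": field.node_id, "value": field.value})
    df = df[df["node_id"].isin(thresholded.node_ids)]
    df = df.merge(labels.table, on="node_id", how="inner")
    agg = df.groupby(["hemisphere", "gyrus"], observed=True)["value"] \
        .agg(cmcd="sum", n_nodes="size").reset_index()
    agg = agg.sort_values(by=["cmcd", "gyrus", "hemisphere"],
                          ascending=[False, True, True],
                          kind="mergesort").reset_index(drop=True)
    return [
        GyrusCluster(gyrus=row["gyrus"], hemisphere=row["hemisphere"],
                     n_nodes=int(row["n_nodes"]), cmcd=float(row["cmcd"]),
                     rank=i + 1)
        for i, row in agg.iterrows()
    ]


def top_clusters(clusters: list[GyrusCluster], k: int) -> list[GyrusCluster]:
    """The first min(k, Cn) clusters by rank."""
    if k < 1:
        raise MscopeError("k must be at least 1")
    return sorted(clusters, key=lambda c: c.rank)[:k]
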