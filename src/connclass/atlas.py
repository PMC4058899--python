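"""Resting-state network atlas: 16 networks, 56 node regions.

The packaged atlas is the derived node table of a 16-network parcellation
(20-component group ICA with four artifactual components removed), reduced to
56 node regions.  Node centroids are Talairach millimetres and are carried as
metadata only; no geometric computation in this package depends on them.

The atlas fixes the three feature spaces used downstream:

* 56 REP features   — one per node (network representativeness),
* 120 B-RSN features — one per unordered network pair, C(16, 2),
* 119 W-RSN features — one per unordered within-network node pair.

Row order of the atlas file is the canonical feature order; feature names
encode node/network identity (e.g. ``W:ECN:9-11``) so that per-fold feature
selections are joinable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AtlasError",
    "Node",
    "NetworkAtlas",
    "load_atlas",
    "within_network_pairs",
    "network_pairs",
    "rep_feature_names",
    "brsn_feature_names",
    "wrsn_feature_names",
]

#: Canonical network order (packaged atlas row order) with display names.
NETWORK_NAMES = {
    "SM": "Sensorimotor",
    "AUD": "Auditory",
    "TC": "Thalamus/Caudate",
    "ECN": "Executive Control Network",
    "DMN": "Default Mode Network",
    "V1": "Visual-1",
    "V2": "Visual-2",
    "V3": "Visual-3",
    "V4": "Visual-4",
    "FRO": "Frontal",
    "CER": "Cerebellum",
    "FPL": "Frontoparietal (L)",
    "FPR": "Frontoparietal (R)",
    "HON1": "Higher Order Network-1",
    "HON2": "Higher Order Network-2",
    "HON3": "Higher Order Network-3",
}

_PACKAGED_NODES = 56
_PACKAGED_NETWORKS = 16


class AtlasError(ValueError):
    """Raised when an atlas file violates the atlas invariants."""


@dataclass(frozen=True)
class Node:
    """One node region: a contiguous cluster of a network's thresholded map."""

    id: int
    name: str
    network: str
    centroid: tuple[float, float, float]
    volume: int

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise AtlasError(f"node {self.id}: volume must be positive, got {self.volume}")


@dataclass
class NetworkAtlas:
    """Ordered networks and node regions, plus optional voxel geometry.

    ``voxel_membership`` maps node id -> voxel column indices and is attached
    by the synthetic cohort generator (or the NIfTI adapter); the packaged
    atlas itself ships no geometry.
    """

    networks: list[str]
    nodes: list[Node]
    voxel_membership: dict[int, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AtlasError(f"duplicate node ids: {dupes}")
        if len(set(self.networks)) != len(self.networks):
            raise AtlasError("duplicate network labels in network order")
        known = set(self.networks)
        for n in self.nodes:
            if n.network not in known:
                raise AtlasError(f"node {n.id}: unknown network label {n.network!r}")
        for net in self.networks:
            if not any(n.network == net for n in self.nodes):
                raise AtlasError(f"network {net!r} has no nodes")

    # -- accessors ----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    @property
    def node_ids(self) -> list[int]:
        return [n.id for n in self.nodes]

    def node(self, node_id: int) -> Node:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(f"no node with id {node_id}")

    def nodes_of(self, network: str) -> list[Node]:
        """Nodes of one network, in canonical (row) order."""
        return [n for n in self.nodes if n.network == network]

    def network_index(self, network: str) -> int:
        return self.networks.index(network)

    def node_voxels(self, node_id: int) -> np.ndarray:
        if self.voxel_membership is None:
            raise AtlasError("atlas carries no voxel membership")
        vox = np.asarray(self.voxel_membership.get(node_id, ()), dtype=int)
        if vox.size == 0:
            raise AtlasError(f"node {node_id} has an empty voxel set")
        return vox

    def network_voxels(self, network: str) -> np.ndarray:
        return np.concatenate([self.node_voxels(n.id) for n in self.nodes_of(network)])


def load_atlas(path: str | Path | None = None) -> NetworkAtlas:
    """Load a node-table TSV (``None`` -> the packaged 56-node atlas).

    Columns: node_id, node_name, network, x, y, z, volume.  Row order is
    preserved as the canonical feature order.  The packaged file must parse to
    exactly 56 nodes in 16 networks; any violation raises :class:`AtlasError`
    naming the problem.
    """
    packaged = path is None
    if packaged:
        path = resources.files("connclass.data") / "rsn16_nodes.tsv"
    df = pd.read_csv(path, sep="\t")
    required = ["node_id", "node_name", "network", "x", "y", "z", "volume"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AtlasError(f"atlas file missing columns: {missing}")

    nodes = [
        Node(
            id=int(r.node_id),
            name=str(r.node_name),
            network=str(r.network),
            centroid=(float(r.x), float(r.y), float(r.z)),
            volume=int(r.volume),
        )
        for r in df.itertuples()
    ]
    # network order = order of first appearance in the file
    networks = list(dict.fromkeys(str(net) for net in df["network"]))
    atlas = NetworkAtlas(networks=networks, nodes=nodes)
    if packaged:
        if atlas.n_nodes != _PACKAGED_NODES:
            raise AtlasError(
                f"packaged atlas must have {_PACKAGED_NODES} nodes, found {atlas.n_nodes}"
            )
        if atlas.n_networks != _PACKAGED_NETWORKS:
            raise AtlasError(
                f"packaged atlas must have {_PACKAGED_NETWORKS} networks, "
                f"found {atlas.n_networks}"
            )
    return atlas


def within_network_pairs(atlas: NetworkAtlas) -> list[tuple[int, int]]:
    """All unordered node pairs sharing a network.

    Ordered by (network order, lower node id, higher node id).  Single-node
    networks contribute no pairs, so for the packaged atlas the three
    single-node visual networks yield none and the total is 119.
    """
    pairs: list[tuple[int, int]] = []
    for net in atlas.networks:
        ids = sorted(n.id for n in atlas.nodes_of(net))
        pairs.extend(combinations(ids, 2))
    return pairs


def network_pairs(atlas: NetworkAtlas) -> list[tuple[str, str]]:
    """All unordered network pairs in canonical order (C(16,2) = 120 packaged)."""
    return list(combinations(atlas.networks, 2))


# -- canonical feature names ------------------------------------------------

def rep_feature_names(atlas: NetworkAtlas) -> list[str]:
    return [f"REP:{n.network}:{n.id}" for n in atlas.nodes]


def brsn_feature_names(atlas: NetworkAtlas) -> list[str]:
    return [f"B:{a}|{b}" for a, b in network_pairs(atlas)]


def wrsn_feature_names(atlas: NetworkAtlas) -> list[str]:
    by_id = {n.id: n for n in atlas.nodes}
    return [f"W:{by_id[i].network}:{i}-{j}" for i, j in within_network_pairs(atlas)]
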