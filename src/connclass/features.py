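"""The three network-centric connectivity feature families.

* REP (56 features): dual regression of the subject's data on the 16 network
  templates yields subject-specific network maps, standardized to Z; the REP
  feature of a node is the mean Z of its parent network's map over the node's
  voxels — how representative the node is of its network.
* B-RSN (120 features): Pearson correlation between each unordered pair of
  the 16 network time courses obtained from the spatial-regression stage.
* W-RSN (119 features): Pearson correlation between each unordered pair of
  node-mean time courses within the same network.

All correlations are computed on censored-row-deleted series; no Fisher
transform is applied (raw correlation coefficients are the features).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import (
    NetworkAtlas,
    brsn_feature_names,
    network_pairs,
    rep_feature_names,
    within_network_pairs,
    wrsn_feature_names,
)
from .preprocess import CensorMask
from .simulate import TemplateMaps

__all__ = [
    "SubjectMaps",
    "FeatureTable",
    "spatial_timecourses",
    "dual_regression",
    "rep_features",
    "brsn_features",
    "wrsn_features",
]


@dataclass
class SubjectMaps:
    """Subject-level network maps and time courses from dual regression."""

    zmaps: np.ndarray  # 16 x V
    timecourses: np.ndarray  # 16 x T


@dataclass
class FeatureTable:
    """Subjects x named features of one kind, with group labels."""

    kind: str  # "REP" | "B-RSN" | "W-RSN"
    names: list[str]
    values: np.ndarray  # n_subjects x n_features
    labels: np.ndarray  # n_subjects, in {0, 1}
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != (len(self.subject_ids), len(self.names)):
            raise ValueError("values shape must be (n_subjects, n_features)")
        if not np.isfinite(self.values).all():
            raise ValueError("feature table contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "") -> "FeatureTable":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("subject_id", "label")]
        if not kind and names:
            prefix = names[0].split(":", 1)[0]
            kind = {"REP": "REP", "B": "B-RSN", "W": "W-RSN"}.get(prefix, "unknown")
        return cls(
            kind=kind,
            names=names,
            values=df[names].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=int),
            subject_ids=[str(s) for s in df["subject_id"]],
        )


def _kept(x: np.ndarray, mask: CensorMask | None) -> np.ndarray:
    return x if mask is None else x[mask.keep]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float((a @ b) / denom)


def spatial_timecourses(maps: TemplateMaps, data: np.ndarray) -> np.ndarray:
    """Stage-1 dual regression: regress every volume on all template maps
    jointly, giving one time course per network (16 x T).

    The per-volume fits are row-independent, so all volumes are computed;
    correlation-stage consumers drop censored rows themselves.
    """
    A = maps.maps.T  # V x 16
    if np.linalg.cond(A) > 1e10:
        raise ValueError("collinear template maps (condition number > 1e10)")
    tc, *_ = np.linalg.lstsq(A, np.asarray(data, dtype=float).T, rcond=None)
    return tc  # 16 x T


def dual_regression(
    maps: TemplateMaps,
    data: np.ndarray,
    mask: CensorMask | None = None,
    standardize: str = "se",
) -> SubjectMaps:
    """Two-stage dual regression with Z-standardized subject maps.

    Stage 1: joint spatial regression of each volume on the 16 templates
    -> 16 time courses.  Stage 2: per-voxel temporal regression (with
    intercept, kept volumes only) of the voxel series on all 16 time courses
    -> 16 coefficient maps.

    ``standardize``:
      * ``"se"`` (default) — coefficient divided by its regression standard
        error, i.e. a per-voxel Z/t-statistic map;
      * ``"spatial"`` — (map - spatial mean) / spatial SD per map.
    """
    data = np.asarray(data, dtype=float)
    tc = spatial_timecourses(maps, data)
    K = tc.shape[0]
    Yk = _kept(data, mask)
    tck = _kept(tc.T, mask)  # T_kept x 16
    Tk = Yk.shape[0]
    if Tk <= K + 1:
        raise ValueError("kept volumes must exceed number of networks + 1")
    D = np.column_stack([np.ones(Tk), tck])
    if np.linalg.cond(D) > 1e10:
        raise ValueError("collinear stage-1 time courses")
    G = np.linalg.inv(D.T @ D)
    beta = G @ D.T @ Yk  # (K+1) x V
    coef = beta[1:]  # K x V
    if standardize == "se":
        resid = Yk - D @ beta
        dof = Tk - (K + 1)
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(np.outer(np.diag(G)[1:], sigma2))
        zmaps = coef / np.maximum(se, 1e-12)
    elif standardize == "spatial":
        mu = coef.mean(axis=1, keepdims=True)
        sd = coef.std(axis=1, keepdims=True)
        zmaps = (coef - mu) / np.maximum(sd, 1e-12)
    else:
        raise ValueError(f"unknown standardization {standardize!r}")
    return SubjectMaps(zmaps=zmaps, timecourses=tc)


def rep_features(subjmaps: SubjectMaps, atlas: NetworkAtlas) -> np.ndarray:
    """Mean Z of each node's parent-network map over the node's voxels,
    in canonical node order (56 features for the packaged atlas)."""
    out = np.empty(atlas.n_nodes)
    for idx, node in enumerate(atlas.nodes):
        vox = atlas.node_voxels(node.id)  # raises on empty set
        k = atlas.network_index(node.network)
        out[idx] = subjmaps.zmaps[k, vox].mean()
    return out


def brsn_features(
    maps: TemplateMaps,
    data: np.ndarray,
    mask: CensorMask | None,
    atlas: NetworkAtlas,
) -> np.ndarray:
    """Pearson correlations between network time-course pairs (120 packaged)."""
    tc = spatial_timecourses(maps, np.asarray(data, dtype=float))
    tck = _kept(tc.T, mask).T  # 16 x T_kept
    for k, net in enumerate(atlas.networks):
        if tck[k].std() == 0:
            raise ValueError(f"network {net!r} has a zero-variance time course")
    pairs = network_pairs(atlas)
    idx = {net: k for k, net in enumerate(atlas.networks)}
    return np.array([_pearson(tck[idx[a]], tck[idx[b]]) for a, b in pairs])


def node_timecourses(
    data: np.ndarray, atlas: NetworkAtlas, mask: CensorMask | None = None
) -> np.ndarray:
    """Voxel-mean time course per node (n_nodes x T_kept)."""
    data = _kept(np.asarray(data, dtype=float), mask)
    out = np.empty((atlas.n_nodes, data.shape[0]))
    for idx, node in enumerate(atlas.nodes):
        out[idx] = data[:, atlas.node_voxels(node.id)].mean(axis=1)
    return out


def wrsn_features(
    data: np.ndarray, mask: CensorMask | None, atlas: NetworkAtlas
) -> np.ndarray:
    """Pearson correlations between within-network node-pair time courses
    (119 packaged features)."""
    tc = node_timecourses(data, atlas, mask)
    row = {node.id: i for i, node in enumerate(atlas.nodes)}
    for node in atlas.nodes:
        if tc[row[node.id]].std() == 0:
            raise ValueError(f"node {node.id} has a zero-variance time course")
    return np.array(
        [_pearson(tc[row[i]], tc[row[j]]) for i, j in within_network_pairs(atlas)]
    )
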