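"""Synthetic resting-state cohorts with network-structured covariance.

The generator emulates the data structure the downstream analysis assumes:
two balanced groups of subjects, each with a T x V multi-voxel recording in
which every atlas node owns a small voxel ensemble, plus white-matter and CSF
nuisance ensembles and a 6-column motion trace with occasional
super-threshold spikes.

Signal model (per subject):

* node signals are band-limited (0.01-0.15 Hz) Gaussian processes with an
  exactly specified covariance: within a network every node pair has
  population correlation ``r0`` (of the voxel-averaged time courses) set by
  ``base_coupling``, cross-network correlation is zero; the signals are
  produced by Cholesky-mixing independent band-limited unit-variance
  latents, so the band-pass stage of preprocessing cannot destroy them;
* each voxel of node i records the node signal plus white noise of SD
  ``noise_sd``;
* WM/CSF voxels are linear mixtures of three dedicated latent signals per
  tissue plus white noise, so their leading principal components are
  well-defined;
* motion is a slow random walk (step SD 0.02, far below the 0.3 censoring
  threshold) with occasional step changes exceeding the threshold in one
  randomly chosen column.

Group effect: subjects of group 1 draw their node signals from a covariance
in which every edge (i, j) in ``effect_edges`` has its population
correlation raised from ``r0`` to ``r0 + effect_size`` (the baseline for
all other pairs is untouched).  The calibration accounts for the
voxel-noise attenuation of the voxel-averaged node time courses, so the
empirical group difference in sample correlations on those edges is
``effect_size`` in expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .atlas import NetworkAtlas, load_atlas

__all__ = [
    "SimulationConfig",
    "SubjectRecording",
    "TemplateMaps",
    "simulate_cohort",
    "make_noise_free_subject",
    "ecn_fp_effect_edges",
    "save_cohort",
    "load_cohort",
]

_BAND = (0.01, 0.15)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level knobs.  Defaults are the study conditions emulated here:

    21 subjects per group, 180 volumes at TR = 2 s (so that post-censoring
    counts land near the ~174-178 surviving volumes of a typical run),
    censor-threshold-exceeding motion spikes at 2% of TRs.
    """

    n_per_group: int = 21
    n_volumes: int = 180
    tr: float = 2.0
    voxels_per_node: int = 8
    n_wm_voxels: int = 30
    n_csf_voxels: int = 30
    base_coupling: float = 0.8
    effect_edges: tuple[tuple[int, int], ...] = ()
    effect_size: float = 0.0
    motion_spike_rate: float = 0.02
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 32:
            raise ValueError("n_volumes must be >= 32")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must be in [0, 1]")
        if self.voxels_per_node < 1:
            raise ValueError("voxels_per_node must be >= 1")


@dataclass
class SubjectRecording:
    """One subject: T x V data, voxel tissue labels, motion trace, group label.

    ``tissue`` entries are ``"node:<id>"``, ``"WM"`` or ``"CSF"``; it may be
    ``None`` only for idealized fixtures that never reach tissue-dependent
    stages.
    """

    data: np.ndarray  # T x V
    motion: np.ndarray  # T x 6 (3 translations mm, 3 rotations deg)
    tr: float
    label: int
    subject_id: str
    tissue: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        if not np.isfinite(self.data).all():
            raise ValueError(f"{self.subject_id}: data contains non-finite values")
        if self.motion.ndim != 2 or self.motion.shape[1] != 6:
            raise ValueError(f"{self.subject_id}: motion must have 6 columns")
        if self.motion.shape[0] != self.data.shape[0]:
            raise ValueError(f"{self.subject_id}: motion rows != data rows")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def tissue_voxels(self, kind: str) -> np.ndarray:
        """Voxel indices of one tissue class ('WM' or 'CSF')."""
        if self.tissue is None:
            raise ValueError("recording has no tissue labels")
        return np.flatnonzero(self.tissue == kind)


@dataclass
class TemplateMaps:
    """Group-level spatial templates: one V-vector of weights per network."""

    maps: np.ndarray  # 16 x V
    networks: list[str]

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.shape[0] != len(self.networks):
            raise ValueError("one map per network required")


def ecn_fp_effect_edges() -> tuple[tuple[int, int], ...]:
    """Ten within-network node pairs inside the executive-control and
    frontoparietal networks, used as the default perturbation set."""
    return (
        (9, 10), (9, 11), (10, 11), (12, 13),   # ECN
        (29, 30), (29, 31), (30, 31),            # FP (L)
        (33, 34), (33, 35), (34, 35),            # FP (R)
    )


# -- latent synthesis -------------------------------------------------------

def _bandlimited(rng: np.random.Generator, n_series: int, n_volumes: int,
                 tr: float, lo: float = _BAND[0], hi: float = _BAND[1]) -> np.ndarray:
    """Unit-variance Gaussian signals with all spectral power in [lo, hi] Hz."""
    freqs = np.fft.rfftfreq(n_volumes, tr)
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any():
        raise ValueError("no FFT bin falls inside the requested band")
    coefs = np.zeros((n_series, freqs.size), dtype=complex)
    coefs[:, band] = rng.standard_normal((n_series, band.sum())) + 1j * rng.standard_normal(
        (n_series, band.sum())
    )
    x = np.fft.irfft(coefs, n=n_volumes, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _simulate_motion(rng: np.random.Generator, n_volumes: int,
                     spike_rate: float) -> np.ndarray:
    """Slow 6-column drift plus occasional super-threshold step changes."""
    steps = rng.normal(scale=0.02, size=(n_volumes, 6))
    steps[0] = 0.0
    spike_at = rng.random(n_volumes) < spike_rate
    spike_at[0] = False
    for t in np.flatnonzero(spike_at):
        col = rng.integers(0, 6)
        steps[t, col] += rng.choice([-1.0, 1.0]) * rng.uniform(0.35, 0.6)
    return np.cumsum(steps, axis=0)


# -- effect calibration -----------------------------------------------------

def _node_covariance(cfg: SimulationConfig, atlas: NetworkAtlas,
                     with_effect: bool) -> np.ndarray:
    """Target covariance of the node signals (before voxel noise).

    Node-signal variance is ``a^2 + 1`` (shared network component plus
    node-unique component); voxel-averaging later adds ``noise_sd^2 / P``.
    Off-diagonal entries are chosen so the population correlation of the
    *voxel-averaged* node time courses is ``r0 = a^2 / v0`` for ordinary
    within-network pairs (the value the simple shared-latent model produces)
    and ``r0 + effect_size`` on the effect edges; cross-network covariance
    is zero.  Raises if the requested effect makes the matrix non-PSD.
    """
    a2 = cfg.base_coupling**2
    v_sig = a2 + 1.0
    v0 = v_sig + cfg.noise_sd**2 / cfg.voxels_per_node
    r0 = a2 / v0
    row = {node.id: i for i, node in enumerate(atlas.nodes)}
    C = np.eye(atlas.n_nodes) * v_sig
    for net in atlas.networks:
        ids = [n.id for n in atlas.nodes_of(net)]
        for a_id in ids:
            for b_id in ids:
                if a_id < b_id:
                    C[row[a_id], row[b_id]] = C[row[b_id], row[a_id]] = r0 * v0
    if with_effect and cfg.effect_size > 0:
        target = r0 + cfg.effect_size
        if target >= 1.0:
            raise ValueError(
                f"effect_size {cfg.effect_size} infeasible: "
                f"target correlation {target:.3f} >= 1"
            )
        for i, j in cfg.effect_edges:
            C[row[i], row[j]] = C[row[j], row[i]] = target * v0
    return C


def _mixing_matrix(C: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "effect configuration yields a non-positive-definite node "
            "covariance; reduce effect_size or the edge set"
        ) from exc


# -- cohort generation ------------------------------------------------------

def _attach_geometry(atlas: NetworkAtlas, cfg: SimulationConfig) -> tuple[NetworkAtlas, np.ndarray]:
    """Assign voxel columns: node blocks in canonical order, then WM, then CSF."""
    membership: dict[int, np.ndarray] = {}
    tissue: list[str] = []
    start = 0
    for node in atlas.nodes:
        membership[node.id] = np.arange(start, start + cfg.voxels_per_node)
        tissue.extend([f"node:{node.id}"] * cfg.voxels_per_node)
        start += cfg.voxels_per_node
    tissue.extend(["WM"] * cfg.n_wm_voxels)
    tissue.extend(["CSF"] * cfg.n_csf_voxels)
    geo_atlas = NetworkAtlas(
        networks=list(atlas.networks), nodes=list(atlas.nodes), voxel_membership=membership
    )
    return geo_atlas, np.array(tissue, dtype=object)


def _template_maps(atlas: NetworkAtlas, n_voxels: int) -> TemplateMaps:
    maps = np.zeros((atlas.n_networks, n_voxels))
    for k, net in enumerate(atlas.networks):
        maps[k, atlas.network_voxels(net)] = 1.0
    return TemplateMaps(maps=maps, networks=list(atlas.networks))


def _nuisance_ensemble(rng: np.random.Generator, n_voxels: int, n_volumes: int) -> np.ndarray:
    latents = rng.standard_normal((3, n_volumes))
    loadings = rng.standard_normal((n_voxels, 3)) * np.array([1.5, 1.0, 0.7])
    return (loadings @ latents + 0.3 * rng.standard_normal((n_voxels, n_volumes))).T


def simulate_cohort(
    config: SimulationConfig, atlas: NetworkAtlas | None = None
) -> tuple[list[SubjectRecording], TemplateMaps, NetworkAtlas]:
    """Generate a full cohort: group 0 (controls) then group 1 (perturbed).

    Fully reproducible from ``config.seed``; the effect edges must each lie
    within a single network of the atlas.
    """
    if atlas is None:
        atlas = load_atlas()
    by_id = {n.id: n for n in atlas.nodes}
    for i, j in config.effect_edges:
        if i not in by_id or j not in by_id:
            raise ValueError(f"effect edge ({i}, {j}) references unknown node ids")
        if by_id[i].network != by_id[j].network:
            raise ValueError(
                f"effect edge ({i}, {j}) spans networks "
                f"{by_id[i].network!r} and {by_id[j].network!r}"
            )

    geo_atlas, tissue = _attach_geometry(atlas, config)
    n_voxels = len(tissue)
    maps = _template_maps(geo_atlas, n_voxels)
    mixers = {
        0: _mixing_matrix(_node_covariance(config, atlas, with_effect=False)),
        1: _mixing_matrix(_node_covariance(config, atlas, with_effect=True)),
    }

    n_subjects = 2 * config.n_per_group
    seeds = np.random.SeedSequence(config.seed).spawn(n_subjects)

    recordings: list[SubjectRecording] = []
    for s in range(n_subjects):
        rng = np.random.default_rng(seeds[s])
        label = 0 if s < config.n_per_group else 1
        T = config.n_volumes

        z = _bandlimited(rng, atlas.n_nodes, T, config.tr)
        node_sig = mixers[label] @ z

        data = np.empty((T, n_voxels))
        for idx, node in enumerate(atlas.nodes):
            vox = geo_atlas.voxel_membership[node.id]
            noise = config.noise_sd * rng.standard_normal((vox.size, T))
            data[:, vox] = (node_sig[idx] + noise).T
        wm = slice(atlas.n_nodes * config.voxels_per_node,
                   atlas.n_nodes * config.voxels_per_node + config.n_wm_voxels)
        csf = slice(wm.stop, wm.stop + config.n_csf_voxels)
        data[:, wm] = _nuisance_ensemble(rng, config.n_wm_voxels, T)
        data[:, csf] = _nuisance_ensemble(rng, config.n_csf_voxels, T)

        motion = _simulate_motion(rng, T, config.motion_spike_rate)
        recordings.append(
            SubjectRecording(
                data=data,
                motion=motion,
                tr=config.tr,
                label=label,
                subject_id=f"sub-{s:03d}",
                tissue=tissue.copy(),
            )
        )
    return recordings, maps, geo_atlas


def make_noise_free_subject(
    maps: TemplateMaps,
    timecourses: np.ndarray,
    tr: float = 2.0,
    tissue: np.ndarray | None = None,
) -> SubjectRecording:
    """Idealized recording ``data = timecourses.T @ maps`` with zero noise and
    zero motion; a fixture for exact regression-recovery checks."""
    timecourses = np.asarray(timecourses, dtype=float)
    if timecourses.shape[0] != maps.maps.shape[0]:
        raise ValueError("timecourses rows must match number of template maps")
    data = timecourses.T @ maps.maps
    T = data.shape[0]
    return SubjectRecording(
        data=data,
        motion=np.zeros((T, 6)),
        tr=tr,
        label=0,
        subject_id="noise-free",
        tissue=tissue,
    )


# -- serialization ----------------------------------------------------------

def save_cohort(recordings: list[SubjectRecording], maps: TemplateMaps,
                outdir: str | Path) -> None:
    """Write per-subject TSV matrices plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"subjects": [], "networks": maps.networks}
    np.savetxt(outdir / "template_maps.tsv", maps.maps, delimiter="\t")
    for rec in recordings:
        np.savetxt(outdir / f"{rec.subject_id}_data.tsv", rec.data, delimiter="\t")
        np.savetxt(outdir / f"{rec.subject_id}_motion.tsv", rec.motion, delimiter="\t")
        manifest["subjects"].append(
            {
                "subject_id": rec.subject_id,
                "label": int(rec.label),
                "tr": rec.tr,
                "tissue": list(rec.tissue) if rec.tissue is not None else None,
            }
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest))


def load_cohort(indir: str | Path) -> tuple[list[SubjectRecording], TemplateMaps]:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    maps = TemplateMaps(
        maps=np.loadtxt(indir / "template_maps.tsv", delimiter="\t", ndmin=2),
        networks=list(manifest["networks"]),
    )
    recordings = []
    for sub in manifest["subjects"]:
        sid = sub["subject_id"]
        recordings.append(
            SubjectRecording(
                data=np.loadtxt(indir / f"{sid}_data.tsv", delimiter="\t", ndmin=2),
                motion=np.loadtxt(indir / f"{sid}_motion.tsv", delimiter="\t", ndmin=2),
                tr=float(sub["tr"]),
                label=int(sub["label"]),
                subject_id=sid,
                tissue=np.array(sub["tissue"], dtype=object) if sub["tissue"] else None,
            )
        )
    return recordings, maps
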