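"""Time-series cleaning: motion censoring, nuisance-PC regression, band-pass.

Pipeline order (fixed): censor detection -> nuisance regression -> band-pass
filtering -> censored-row removal by the correlation-stage consumers.  The
censoring and regression stages never change the number of rows; only code
that computes correlations drops censored rows.

Censoring follows a framewise rule: if any translation column changes by more
than ``thr_trans`` mm, or any rotation column by more than ``thr_rot`` deg,
between consecutive volumes, the *later* volume of the pair is discarded.
Nuisance regressors are the aCompCor-style top principal components of the
white-matter and CSF voxel ensembles (3 each by default) plus the six motion
parameters; PCs are computed on kept volumes only so spike variance cannot
leak into them.  The band-pass is an ideal frequency-mask filter (DC removed),
which makes pass/stop behavior exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SubjectRecording

__all__ = [
    "CensorMask",
    "NuisanceSet",
    "censor_from_motion",
    "nuisance_pcs",
    "regress_out",
    "bandpass",
    "rms_motion",
    "build_nuisance",
    "clean_recording",
]


@dataclass
class CensorMask:
    """Boolean keep-flag per volume."""

    keep: np.ndarray

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def n_total(self) -> int:
        return self.keep.size


@dataclass
class NuisanceSet:
    """T x K matrix of nuisance regressors (WM PCs, CSF PCs, motion)."""

    regressors: np.ndarray
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=float)
        if self.regressors.ndim != 2 or self.regressors.shape[1] < 1:
            raise ValueError("regressors must be a T x K matrix with K >= 1")
        if not np.isfinite(self.regressors).all():
            raise ValueError("nuisance regressors contain non-finite values")


def censor_from_motion(
    motion: np.ndarray, thr_trans: float = 0.3, thr_rot: float = 0.3
) -> CensorMask:
    """Flag volumes whose head position jumped beyond threshold.

    For each consecutive pair (t-1, t): if any of the first three (translation,
    mm) columns changed by more than ``thr_trans``, or any of the last three
    (rotation, deg) columns by more than ``thr_rot``, volume t is censored.
    Volume 0 is always kept.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be T x 6")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    if not np.isfinite(motion).all():
        raise ValueError("motion trace contains non-finite values")
    d = np.abs(np.diff(motion, axis=0))
    bad = (d[:, :3] > thr_trans).any(axis=1) | (d[:, 3:] > thr_rot).any(axis=1)
    keep = np.ones(motion.shape[0], dtype=bool)
    keep[1:] = ~bad
    return CensorMask(keep=keep)


def nuisance_pcs(
    ensemble: np.ndarray, k: int = 3, mask: CensorMask | None = None
) -> np.ndarray:
    """First ``k`` principal-component time courses of a tissue ensemble.

    Computed on kept volumes of the column-demeaned T x M ensemble and
    re-embedded with zeros at censored volumes.  Sign convention: the
    largest-magnitude spatial loading of each component is positive.
    """
    X = np.asarray(ensemble, dtype=float)
    if X.ndim != 2:
        raise ValueError("ensemble must be T x M")
    T, M = X.shape
    if M < k:
        raise ValueError(f"need at least k={k} voxels, got {M}")
    keep = np.ones(T, dtype=bool) if mask is None else mask.keep
    if keep.sum() <= k:
        raise ValueError("kept volumes must exceed k")
    Xk = X[keep]
    Xk = Xk - Xk.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xk, full_matrices=False)
    rank = int((s > s[0] * max(Xk.shape) * np.finfo(float).eps).sum()) if s.size else 0
    if rank < k:
        raise ValueError(f"ensemble rank {rank} < requested k={k}")
    # score time courses, deterministic sign
    flip = np.sign(Vt[np.arange(k), np.argmax(np.abs(Vt[:k]), axis=1)])
    scores = U[:, :k] * s[:k] * flip
    out = np.zeros((T, k))
    out[keep] = scores
    return out


def regress_out(
    series: np.ndarray, nuisance: NuisanceSet, mask: CensorMask | None = None
) -> np.ndarray:
    """OLS residuals of each column with respect to the nuisance set.

    The fit (with intercept) uses kept volumes only; residuals are formed for
    every row so the output keeps the input's shape.  Residuals at kept
    volumes are orthogonal to every regressor.
    """
    Y = np.asarray(series, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    T = Y.shape[0]
    keep = np.ones(T, dtype=bool) if mask is None else mask.keep
    R = nuisance.regressors
    if R.shape[0] != T:
        raise ValueError("nuisance rows must match series rows")
    if keep.sum() <= R.shape[1] + 1:
        raise ValueError("kept volumes must exceed number of regressors + 1")
    X = np.column_stack([np.ones(T), R])
    Xk = X[keep]
    if np.linalg.cond(Xk) > 1e10:
        raise ValueError("collinear nuisance regressors (condition number > 1e10)")
    beta, *_ = np.linalg.lstsq(Xk, Y[keep], rcond=None)
    resid = Y - X @ beta
    return resid[:, 0] if squeeze else resid


def bandpass(
    series: np.ndarray, lo: float = 0.01, hi: float = 0.15, tr: float = 2.0
) -> np.ndarray:
    """Ideal frequency-mask band-pass: DFT bins with |f| in [lo, hi] retained,
    all others (including DC) zeroed."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    nyquist = 1.0 / (2.0 * tr)
    if hi >= nyquist + 1e-12:
        raise ValueError(f"hi={hi} Hz must be below Nyquist {nyquist} Hz")
    Y = np.asarray(series, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    T = Y.shape[0]
    freqs = np.fft.rfftfreq(T, tr)
    band = (freqs >= lo) & (freqs <= hi)
    F = np.fft.rfft(Y, axis=0)
    F[~band] = 0.0
    out = np.fft.irfft(F, n=T, axis=0)
    return out[:, 0] if squeeze else out


def rms_motion(motion: np.ndarray) -> tuple[float, float]:
    """RMS of between-volume head-position changes, pooled over the three
    translation (mm) and three rotation (deg) columns respectively."""
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] < 2 or motion.shape[1] != 6:
        raise ValueError("motion must be T x 6 with T >= 2")
    d = np.diff(motion, axis=0)
    rms_trans = float(np.sqrt(np.mean(d[:, :3] ** 2)))
    rms_rot = float(np.sqrt(np.mean(d[:, 3:] ** 2)))
    return rms_trans, rms_rot


def build_nuisance(
    recording: SubjectRecording,
    mask: CensorMask,
    n_wm_pcs: int = 3,
    n_csf_pcs: int = 3,
) -> NuisanceSet:
    """Assemble the default 12-regressor set: WM PCs + CSF PCs + 6 motion."""
    wm = recording.data[:, recording.tissue_voxels("WM")]
    csf = recording.data[:, recording.tissue_voxels("CSF")]
    cols = [
        nuisance_pcs(wm, k=n_wm_pcs, mask=mask),
        nuisance_pcs(csf, k=n_csf_pcs, mask=mask),
        recording.motion,
    ]
    names = (
        [f"wm_pc{i+1}" for i in range(n_wm_pcs)]
        + [f"csf_pc{i+1}" for i in range(n_csf_pcs)]
        + [f"motion{i+1}" for i in range(6)]
    )
    return NuisanceSet(regressors=np.column_stack(cols), names=names)


def clean_recording(
    recording: SubjectRecording,
    thr_trans: float = 0.3,
    thr_rot: float = 0.3,
    lo: float = 0.01,
    hi: float = 0.15,
    n_wm_pcs: int = 3,
    n_csf_pcs: int = 3,
) -> tuple[np.ndarray, CensorMask]:
    """Full cleaning chain for one subject; returns (cleaned T x V, mask)."""
    mask = censor_from_motion(recording.motion, thr_trans, thr_rot)
    nuis = build_nuisance(recording, mask, n_wm_pcs, n_csf_pcs)
    resid = regress_out(recording.data, nuis, mask)
    return bandpass(resid, lo, hi, recording.tr), mask
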