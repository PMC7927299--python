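"""Frame-level preprocessing of registered 4D fMRI data.

Covers framewise-displacement (FD) computation and motion censoring,
nuisance regression (WM/CSF means, motion parameters, low-frequency
discrete-cosine components, optional global signal), spatial Gaussian
smoothing and temporal band-pass filtering.

The pipeline order is fixed: nuisance regression -> spatial smoothing ->
band-pass. Censoring masks are computed from the raw motion parameters but
applied only where frames are consumed downstream (seed z-scoring, frame
selection, connectivity); regression and filtering always see the full
time series so that filter transients are not re-introduced by gaps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

logger = logging.getLogger(__name__)

#: column order of the motion-parameter table (fMRIPrep confounds dialect):
#: translations in mm, rotations in radians.
MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")

#: head radius (mm) used to convert rotations to arc displacement
#: (Power et al. convention).
FD_HEAD_RADIUS_MM = 50.0

GAUSSIAN_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))  # = 1/2.3548


@dataclass
class Volume4D:
    """A masked 4D intensity series.

    Attributes
    ----------
    data : ndarray, shape (x, y, z, t)
        Intensity values.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform in mm.
    mask : ndarray of bool, shape (x, y, z)
        Brain mask; every analysis is restricted to it.
    tr : float
        Repetition time in seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.data.shape[3] < 1:
            raise ValueError("need at least one frame")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match spatial grid")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if abs(np.linalg.det(np.asarray(self.affine)[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm along each axis."""
        return np.sqrt((np.asarray(self.affine)[:3, :3] ** 2).sum(axis=0))

    def timeseries(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Return a (t, n_voxels) matrix over ``mask`` (default: brain mask)."""
        m = self.mask if mask is None else mask
        return self.data[m].T

    def with_data(self, data: np.ndarray) -> "Volume4D":
        return Volume4D(data=data, affine=self.affine, mask=self.mask, tr=self.tr)


@dataclass
class CensorInfo:
    """Per-frame motion summary and keep/drop decision."""

    fd: np.ndarray
    keep_mask: np.ndarray
    threshold_mm: float
    min_retained_seconds: float
    tr: float
    excluded: bool = field(default=False)

    @property
    def n_dropped(self) -> int:
        return int((~self.keep_mask).sum())

    @property
    def retained_seconds(self) -> float:
        return float(self.keep_mask.sum() * self.tr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self.fd)), "fd": self.fd, "keep": self.keep_mask.astype(int)}
        )


def compute_fd(motion: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Framewise displacement (Power et al.): sum of absolute backward
    differences of the six motion parameters, rotations (radians) mapped to
    mm as arc length on a 50 mm sphere. ``fd[0] = 0`` by convention.
    """
    if isinstance(motion, pd.DataFrame):
        missing = [c for c in MOTION_COLUMNS if c not in motion.columns]
        if missing:
            raise ValueError(f"motion table missing columns: {missing}")
        params = motion.loc[:, list(MOTION_COLUMNS)].to_numpy(dtype=float)
    else:
        params = np.asarray(motion, dtype=float)
        if params.ndim != 2 or params.shape[1] != 6:
            raise ValueError("motion array must have 6 columns (3 trans mm, 3 rot rad)")
    fd = np.zeros(params.shape[0])
    if params.shape[0] > 1:
        diffs = np.abs(np.diff(params, axis=0))
        fd[1:] = diffs[:, :3].sum(axis=1) + FD_HEAD_RADIUS_MM * diffs[:, 3:].sum(axis=1)
    return fd


def censor_frames(
    fd: np.ndarray,
    tr: float,
    threshold: float = 0.7,
    min_retained_seconds: float = 240.0,
) -> CensorInfo:
    """Drop every frame with FD above ``threshold`` together with its
    precedent and the two following frames; flag the subject excluded when
    less than ``min_retained_seconds`` of data survives.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("fd must be non-empty")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = fd.size
    keep = np.ones(n, dtype=bool)
    for t in np.flatnonzero(fd > threshold):
        keep[max(t - 1, 0) : min(t + 3, n)] = False
    info = CensorInfo(
        fd=fd,
        keep_mask=keep,
        threshold_mm=threshold,
        min_retained_seconds=min_retained_seconds,
        tr=tr,
    )
    info.excluded = info.retained_seconds < min_retained_seconds
    return info


def dct_basis(n_frames: int, tr: float, n_components: int = 3) -> np.ndarray:
    """The ``n_components`` lowest-frequency *nonzero* DCT-II basis vectors.

    Component ``j`` (1-based) oscillates at ``j / (2 * n_frames * tr)`` Hz;
    the constant (zero-frequency) vector is never included. Columns are
    orthonormal.
    """
    if n_components >= n_frames:
        raise ValueError("n_components must be smaller than n_frames")
    t = np.arange(n_frames)
    basis = np.empty((n_frames, n_components))
    for j in range(1, n_components + 1):
        col = np.cos(np.pi * j * (2 * t + 1) / (2 * n_frames))
        basis[:, j - 1] = col / np.linalg.norm(col)
    return basis


def dct_frequencies(n_frames: int, tr: float, n_components: int = 3) -> np.ndarray:
    """Frequencies (Hz) of the columns returned by :func:`dct_basis`."""
    return np.arange(1, n_components + 1) / (2.0 * n_frames * tr)


def regress_nuisance(ts: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each column of ``ts`` on ``confounds``.

    An intercept is always included; zero-variance confound columns are
    dropped with a warning. Residuals are orthogonal to every retained
    confound column.
    """
    ts = np.asarray(ts, dtype=float)
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != ts.shape[0]:
        raise ValueError("ts and confounds must have the same number of time points")
    if confounds.shape[1] >= ts.shape[0]:
        raise ValueError("more confounds than time points")
    keep = confounds.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance confound column(s)",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("regress_nuisance: dropped %d zero-variance confounds", (~keep).sum())
    design = np.column_stack([np.ones(ts.shape[0]), confounds[:, keep]])
    beta, *_ = np.linalg.lstsq(design, ts, rcond=None)
    return ts - design @ beta


def bandpass(ts: np.ndarray, tr: float, low: float = 0.01, high: float = 0.15) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the time axis.

    Applied forward and backward (``filtfilt``) with reflection padding, so
    the pass band is amplitude-preserving and phase-neutral.
    """
    nyquist = 0.5 / tr
    if not (0.0 < low < high < nyquist):
        raise ValueError(f"band limits must satisfy 0 < low < high < Nyquist ({nyquist:.3f} Hz)")
    b, a = signal.butter(4, [low / nyquist, high / nyquist], btype="bandpass")
    ts = np.asarray(ts, dtype=float)
    padlen = min(3 * (max(len(a), len(b)) - 1) * 4, ts.shape[0] - 1)
    return signal.filtfilt(b, a, ts, axis=0, padtype="even", padlen=padlen)


def smooth_spatial(vol: Volume4D, fwhm: float = 6.0) -> Volume4D:
    """Per-frame Gaussian smoothing with the stated full-width-at-half-maximum
    in mm; the per-axis sigma in voxels is read from the affine."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    sigma_vox = (fwhm * GAUSSIAN_FWHM_TO_SIGMA) / vol.voxel_sizes
    out = np.empty_like(vol.data, dtype=float)
    for t in range(vol.n_frames):
        out[..., t] = ndimage.gaussian_filter(
            vol.data[..., t].astype(float), sigma=sigma_vox, mode="nearest"
        )
    return vol.with_data(out)


def extract_global_signal(vol: Volume4D, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-frame mean intensity over ``mask`` (default: brain mask)."""
    m = vol.mask if mask is None else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    return vol.data[m].mean(axis=0)


def build_confounds(
    vol: Volume4D,
    motion: pd.DataFrame | np.ndarray,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    n_dct: int = 3,
    gsr: bool = False,
) -> np.ndarray:
    """Assemble the nuisance-regressor matrix: WM and CSF mean signals, six
    motion parameters, the lowest-frequency DCT components and, optionally,
    the global signal."""
    cols: list[np.ndarray] = []
    if wm_mask is not None and wm_mask.any():
        cols.append(extract_global_signal(vol, wm_mask))
    if csf_mask is not None and csf_mask.any():
        cols.append(extract_global_signal(vol, csf_mask))
    if isinstance(motion, pd.DataFrame):
        motion = motion.loc[:, list(MOTION_COLUMNS)].to_numpy(dtype=float)
    cols.extend(np.asarray(motion, dtype=float).T)
    cols.extend(dct_basis(vol.n_frames, vol.tr, n_dct).T)
    if gsr:
        cols.append(extract_global_signal(vol))
    return np.column_stack(cols)


def preprocess_volume(
    vol: Volume4D,
    motion: pd.DataFrame | np.ndarray,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    gsr: bool = False,
    fwhm: float = 6.0,
    band: tuple[float, float] = (0.01, 0.15),
    fd_threshold: float = 0.7,
    min_retained_seconds: float = 240.0,
    n_dct: int = 3,
    drop_initial_frames: int = 0,
) -> tuple[Volume4D, CensorInfo]:
    """Run the full frame-level pipeline on one scan.

    Order: (optional initial-frame drop) -> nuisance regression -> spatial
    smoothing -> temporal band-pass. The returned :class:`CensorInfo` is
    computed from the raw motion parameters and is *not* applied to the
    data; downstream measures consume it.
    """
    if drop_initial_frames:
        vol = vol.with_data(vol.data[..., drop_initial_frames:])
        if isinstance(motion, pd.DataFrame):
            motion = motion.iloc[drop_initial_frames:].reset_index(drop=True)
        else:
            motion = np.asarray(motion)[drop_initial_frames:]
    fd = compute_fd(motion)
    censor = censor_frames(
        fd, tr=vol.tr, threshold=fd_threshold, min_retained_seconds=min_retained_seconds
    )
    confounds = build_confounds(vol, motion, wm_mask, csf_mask, n_dct=n_dct, gsr=gsr)
    ts = vol.timeseries()  # (t, n_brain_voxels)
    resid = regress_nuisance(ts, confounds)
    cleaned = np.zeros_like(vol.data, dtype=float)
    cleaned[vol.mask] = resid.T
    out = vol.with_data(cleaned)
    out = smooth_spatial(out, fwhm=fwhm)
    filtered = bandpass(out.timeseries(), tr=vol.tr, low=band[0], high=band[1])
    data = np.zeros_like(out.data)
    data[vol.mask] = filtered.T
    return out.with_data(data), censor
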