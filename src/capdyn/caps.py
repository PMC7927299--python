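"""Seed-based co-activation pattern (CAP) analysis.

A seed time course (e.g. bilateral precuneus/posterior-cingulate spheres) is
z-scored over the motion-censored frames and thresholded at +1 SD to select
high-amplitude activation frames. Selected frames pooled over subjects are
clustered with k-means under a correlation distance; the z-scored centroids
are the CAPs. Per subject and session we compute each CAP's relative
temporal occurrence, mean duration, and frequency of expression, and
held-out frames (a post-intervention session) are classified into the
pre-established CAPs by maximal Pearson correlation.

The number of clusters is chosen by consensus clustering: co-clustering
stability across bootstrap subsamples, subject to every candidate CAP being
expressed in a minimum fraction of subjects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .preprocess import Volume4D

logger = logging.getLogger(__name__)

#: MNI coordinates (mm) of the left/right precuneus-posterior cingulate
#: sphere centers and their radius, the default seed of the analysis.
PRECUNEUS_CENTERS = ((-5.7, -54.3, 34.1), (7.5, -53.7, 31.2))
PRECUNEUS_RADIUS_MM = 6.25


@dataclass
class SeedSpec:
    """Seed definition: spheres in world coordinates, an explicit voxel
    mask, or the whole brain (global-signal mode)."""

    mode: str = "spheres"  # {"spheres", "mask", "global"}
    centers: tuple = PRECUNEUS_CENTERS
    radius: float = PRECUNEUS_RADIUS_MM
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("spheres", "mask", "global"):
            raise ValueError(f"unknown seed mode: {self.mode}")
        if self.mode == "spheres" and (self.radius <= 0 or len(self.centers) == 0):
            raise ValueError("spheres mode needs radius > 0 and at least one center")
        if self.mode == "mask" and self.mask is None:
            raise ValueError("mask mode needs a voxel mask")


@dataclass
class CapSet:
    """k z-scored cluster centroids over gray-matter voxels."""

    k: int
    centroids: np.ndarray  # (k, n_voxels), each row mean 0 / sd 1
    order: str = "descending_occurrence"
    training_frame_count: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")


@dataclass
class CapMetrics:
    """Temporal CAP statistics for one subject-session."""

    occurrence: np.ndarray  # fraction of selected frames per CAP (sums to 1)
    duration_s: np.ndarray  # mean consecutive-run length per CAP, seconds
    frequency_per_min: np.ndarray  # disjoint runs per retained minute
    n_active_frames: int
    active_fraction: float  # selected / kept frames
    flagged_empty: bool = field(default=False)


def resolve_seed(seed: SeedSpec, vol: Volume4D) -> np.ndarray:
    """Resolve a seed specification to a boolean voxel set on the volume's
    grid: union of spheres in world space, an explicit mask, or the brain
    mask in global mode."""
    if seed.mode == "global":
        return vol.mask.copy()
    if seed.mode == "mask":
        out = np.asarray(seed.mask, dtype=bool)
        if out.shape != vol.data.shape[:3]:
            raise ValueError("seed mask grid does not match the volume")
    else:
        shape = vol.data.shape[:3]
        ijk = np.indices(shape).reshape(3, -1)
        homog = np.vstack([ijk, np.ones(ijk.shape[1])])
        world = (np.asarray(vol.affine) @ homog)[:3]
        out = np.zeros(ijk.shape[1], dtype=bool)
        for c in seed.centers:
            d2 = ((world - np.asarray(c, dtype=float)[:, None]) ** 2).sum(axis=0)
            out |= d2 <= seed.radius**2
        out = out.reshape(shape)
    out &= vol.mask
    if not out.any():
        raise ValueError("seed resolves to an empty voxel set")
    return out


def seed_series(
    vol: Volume4D, seed_voxels: np.ndarray, keep_mask: np.ndarray | None = None
) -> np.ndarray:
    """Mean signal over the seed voxels for each kept frame."""
    seed_voxels = np.asarray(seed_voxels, dtype=bool)
    if not seed_voxels.any():
        raise ValueError("empty seed")
    series = vol.data[seed_voxels].mean(axis=0)
    if keep_mask is not None:
        series = series[np.asarray(keep_mask, dtype=bool)]
    return series


def select_active_frames(series: np.ndarray, z_thresh: float = 1.0, negative: bool = False) -> np.ndarray:
    """Indices (into ``series``) of high-amplitude events: z-score the series
    and keep frames with z > +z_thresh (and z < -z_thresh when ``negative``)."""
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        raise ValueError("need at least 3 kept frames")
    sd = series.std()
    if sd == 0:
        raise ValueError("seed series has zero variance")
    z = (series - series.mean()) / sd
    sel = z > z_thresh
    if negative:
        sel |= z < -z_thresh
    return np.flatnonzero(sel)


def coactivation_map(vol: Volume4D, frames: np.ndarray, gm_mask: np.ndarray) -> np.ndarray:
    """Voxel-wise mean over the selected frames on the gray-matter mask.

    Returns a 3D map, zero outside ``gm_mask``. With the global signal as
    seed time course the same operation yields the global-signal
    representation map.
    """
    frames = np.asarray(frames, dtype=int)
    if frames.size == 0:
        raise ValueError("no activations: empty frame set")
    gm_mask = np.asarray(gm_mask, dtype=bool)
    out = np.zeros(vol.data.shape[:3])
    out[gm_mask] = vol.data[gm_mask][:, frames].mean(axis=1)
    return out


def _row_standardize(frames: np.ndarray) -> np.ndarray:
    mu = frames.mean(axis=1, keepdims=True)
    sd = frames.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (frames - mu) / sd


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    return (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)


def cluster_caps(
    frames: np.ndarray,
    k: int,
    rng_seed: int,
    n_init: int = 20,
    max_iter: int = 300,
) -> tuple[CapSet, np.ndarray]:
    """K-means clustering of selected frames into k CAPs.

    Rows are standardized so that squared-Euclidean k-means is equivalent to
    clustering under correlation distance; k-means++ initialization,
    deterministic given ``rng_seed``. Clusters are relabeled by descending
    pooled occurrence (ties: lower original index first) and the reported
    centroids are z-scored over voxels.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] < max(k, 10 * k):
        raise ValueError(f"need at least {10 * k} frames to cluster k={k}")
    km = KMeans(
        n_clusters=k,
        n_init=n_init,
        max_iter=max_iter,
        init="k-means++",
        random_state=int(rng_seed) % (2**31 - 1),
    ).fit(_row_standardize(frames))
    counts = np.bincount(km.labels_, minlength=k)
    order = np.lexsort((np.arange(k), -counts))  # descending count, stable
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[km.labels_]
    centroids = _zscore_rows(km.cluster_centers_[order])
    caps = CapSet(
        k=k,
        centroids=centroids,
        training_frame_count=frames.shape[0],
        rng_seed=rng_seed,
    )
    return caps, labels


@dataclass
class ConsensusReport:
    """Per-k consensus-clustering summary."""

    table: pd.DataFrame  # columns: k, stability, expression_fraction, passes
    chosen_k: int | None
    consensus_matrices: dict  # k -> (n_ref, n_ref) consensus matrix


def consensus_select_k(
    frames: np.ndarray,
    k_range: range | list,
    rng_seed: int,
    n_boot: int = 100,
    subsample: float = 0.8,
    subject_ids: np.ndarray | None = None,
    expression_threshold: float = 0.9,
    max_reference_frames: int = 1500,
    boot_n_init: int = 4,
    stability_tol: float = 0.01,
) -> ConsensusReport:
    """Choose the number of CAPs by consensus clustering.

    For each candidate k, frames are repeatedly subsampled (fraction
    ``subsample`` without replacement) and re-clustered; the consensus
    matrix is the co-clustering frequency of frame pairs among subsamples
    containing both. Stability is the mean consensus within the clusters of
    the full-data solution. A k is admissible only if every CAP is expressed
    (>= 1 frame) in at least ``expression_threshold`` of subjects.

    The chosen k is the *largest* admissible k whose stability lies within
    ``stability_tol`` of the maximum. The tie-break toward larger k is
    essential: any k at or below the true number of states can reproduce
    its (merged) partition perfectly, so stability alone cannot separate
    them — it only degrades once k exceeds the true state count. Among
    equally reproducible solutions the finest partition is preferred.

    Consensus is accumulated on a random reference subset of at most
    ``max_reference_frames`` frames to bound memory.
    """
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    k_range = list(k_range)
    if any(k < 2 or k > n / 10 for k in k_range):
        raise ValueError("k_range must lie within [2, n_frames/10]")
    rng = np.random.default_rng(rng_seed)
    ref = (
        np.sort(rng.choice(n, size=max_reference_frames, replace=False))
        if n > max_reference_frames
        else np.arange(n)
    )
    ref_pos = np.full(n, -1)
    ref_pos[ref] = np.arange(len(ref))
    std_frames = _row_standardize(frames)

    rows = []
    consensus_mats = {}
    for k in k_range:
        caps_k, labels_full = cluster_caps(frames, k, rng_seed=int(rng.integers(2**31 - 1)), n_init=10)
        # expression check on the full-data solution
        if subject_ids is not None:
            subjects = np.unique(subject_ids)
            expressed = np.array(
                [
                    np.isin(np.arange(k), labels_full[subject_ids == s]).all()
                    for s in subjects
                ]
            )
            expression_fraction = float(expressed.mean())
        else:
            expression_fraction = 1.0
        passes = expression_fraction >= expression_threshold

        co = np.zeros((len(ref), len(ref)))
        both = np.zeros((len(ref), len(ref)))
        m = int(round(subsample * n))
        for _ in range(n_boot):
            idx = rng.choice(n, size=m, replace=False)
            km = KMeans(
                n_clusters=k,
                n_init=boot_n_init,
                max_iter=100,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(std_frames[idx])
            in_ref = ref_pos[idx] >= 0
            rpos = ref_pos[idx[in_ref]]
            lab = km.labels_[in_ref]
            onehot = np.zeros((len(rpos), k))
            onehot[np.arange(len(rpos)), lab] = 1.0
            present = np.zeros(len(ref))
            present[rpos] = 1.0
            coc = onehot @ onehot.T  # same-cluster indicator for sampled ref frames
            co[np.ix_(rpos, rpos)] += coc
            both += np.outer(present, present)
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(both > 0, co / both, np.nan)
        consensus_mats[k] = consensus
        lab_ref = labels_full[ref]
        same = lab_ref[:, None] == lab_ref[None, :]
        iu = np.triu_indices(len(ref), 1)
        within = consensus[iu][same[iu]]
        stability = float(np.nanmean(within)) if within.size else np.nan
        rows.append(
            {"k": k, "stability": stability, "expression_fraction": expression_fraction, "passes": passes}
        )

    table = pd.DataFrame(rows)
    admissible = table[table["passes"]]
    if admissible.empty:
        warnings.warn("no candidate k passes the expression check", RuntimeWarning, stacklevel=2)
        chosen = None
    else:
        best = admissible["stability"].max()
        near = admissible[admissible["stability"] >= best - stability_tol]
        chosen = int(near["k"].max())
    return ConsensusReport(table=table, chosen_k=chosen, consensus_matrices=consensus_mats)


def cap_metrics(
    labels: np.ndarray,
    selected: np.ndarray,
    keep_mask: np.ndarray,
    tr: float,
    k: int,
) -> CapMetrics:
    """Temporal CAP statistics from per-frame CAP labels.

    ``selected`` holds the original frame indices of seed-activation frames
    and ``labels`` (same length, values in 0..k-1) their CAP assignment.
    Runs are maximal sets of *consecutive* original-time indices with the
    same label: censored gaps and unselected frames break runs.

    occurrence_c  = #frames labeled c / #selected
    duration_c    = mean run length of c (frames) x tr, seconds
    frequency_c   = #runs of c per retained minute
    """
    selected = np.asarray(selected, dtype=int)
    labels = np.asarray(labels, dtype=int)
    keep_mask = np.asarray(keep_mask, dtype=bool)
    retained_minutes = keep_mask.sum() * tr / 60.0
    if selected.size == 0:
        return CapMetrics(
            occurrence=np.zeros(k),
            duration_s=np.zeros(k),
            frequency_per_min=np.zeros(k),
            n_active_frames=0,
            active_fraction=0.0,
            flagged_empty=True,
        )
    if labels.shape != selected.shape:
        raise ValueError("labels must be defined exactly on the selected frames")
    order = np.argsort(selected)
    selected, labels = selected[order], labels[order]

    occurrence = np.bincount(labels, minlength=k) / selected.size
    run_lengths: list[list[int]] = [[] for _ in range(k)]
    start = 0
    for i in range(1, selected.size + 1):
        if (
            i == selected.size
            or selected[i] != selected[i - 1] + 1
            or labels[i] != labels[i - 1]
        ):
            run_lengths[labels[start]].append(i - start)
            start = i
    duration = np.array([np.mean(r) if r else 0.0 for r in run_lengths]) * tr
    frequency = np.array([len(r) for r in run_lengths]) / retained_minutes
    return CapMetrics(
        occurrence=occurrence,
        duration_s=duration,
        frequency_per_min=frequency,
        n_active_frames=int(selected.size),
        active_fraction=float(selected.size / keep_mask.sum()),
    )


def assign_frames_to_caps(frames: np.ndarray, caps: CapSet) -> tuple[np.ndarray, np.ndarray]:
    """Classify frames into pre-established CAPs by maximal Pearson
    correlation with the centroids (ties: lowest CAP index). Returns
    (labels, correlation matrix); zero-variance frames get label -1."""
    frames = np.asarray(frames, dtype=float)
    if frames.shape[1] != caps.centroids.shape[1]:
        raise ValueError("frame and centroid voxel spaces differ")
    sd = frames.std(axis=1)
    bad = sd == 0
    z_frames = np.zeros_like(frames)
    z_frames[~bad] = _zscore_rows(frames[~bad])
    z_cent = _zscore_rows(caps.centroids)
    corr = z_frames @ z_cent.T / frames.shape[1]
    labels = corr.argmax(axis=1)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} zero-variance frame(s) left unassigned", RuntimeWarning, stacklevel=2
        )
        labels = labels.astype(int)
        labels[bad] = -1
    return labels, corr


def match_caps(reference: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Match two centroid sets by maximal correlation, solved as a linear
    assignment problem. Returns (column index into ``other`` for each
    reference centroid, the matched correlations)."""
    ref = _zscore_rows(np.asarray(reference, dtype=float))
    oth = _zscore_rows(np.asarray(other, dtype=float))
    corr = ref @ oth.T / ref.shape[1]
    n = min(corr.shape)
    rows, cols = linear_sum_assignment(-corr)
    matched = np.full(reference.shape[0], -1)
    matched_r = np.full(reference.shape[0], np.nan)
    for r, c in zip(rows, cols):
        matched[r] = c
        matched_r[r] = corr[r, c]
    return matched, matched_r
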