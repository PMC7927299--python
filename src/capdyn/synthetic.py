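"""Synthetic resting-state cohorts with known CAP ground truth.

The generator plants k latent co-activation maps on a gray-matter mask and
produces multi-subject, pre/post-session 4D series in which frames are
state-driven: at each TR a first-order Markov chain occupies one of the k
CAP states or a baseline state; state frames express the corresponding map
on top of nuisance structure (low-frequency drift, a global fluctuation,
WM/CSF compartment signals) and Gaussian noise. A designated seed region is
positive in every map, so seed high-amplitude events select state frames —
the generative counterpart of seed-based CAP analysis.

Group and session effects are planted directly in the state-occupancy
vectors; behavior scores are linear in the realized per-subject CAP
occupancies plus noise, so multivariate brain-behavior recovery has a known
answer. Motion tables contain slow wander plus single-frame displacement
jumps whose FD exceeds the censoring threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import GAUSSIAN_FWHM_TO_SIGMA, MOTION_COLUMNS, Volume4D

GROUPS = ("control", "patient")
SESSIONS = ("pre", "post")

#: default behavior domains and their loadings on CAP occupancies (k=3).
#: Rows are scores, columns CAP1..CAP3; chosen so each domain has one or two
#: strong, sign-mixed loadings (a gait-like block on CAP1/CAP2 and an
#: executive-like block on CAP1/CAP3).
DEFAULT_BEHAVIOR_LOADINGS = {
    "gait_stride_time": (4.0, -3.0, 0.0),
    "gait_speed": (-3.5, 3.0, 0.0),
    "exec_fluency": (3.5, 0.0, -4.0),
    "exec_trail": (-3.0, 0.0, 4.0),
    "memory_recall": (1.0, 0.5, -0.5),
    "attention_digit": (0.8, -0.4, 0.6),
}


@dataclass
class GroundTruth:
    """Latent CAP maps and the sampling law of the synthetic cohort."""

    cap_maps: np.ndarray  # (k, n_gm_voxels), z-scored over gray matter
    gm_mask: np.ndarray  # 3D bool
    seed_mask: np.ndarray  # 3D bool, subset of gm_mask
    wm_mask: np.ndarray  # 3D bool, disjoint from gm
    csf_mask: np.ndarray  # 3D bool, disjoint from gm and wm
    brain_mask: np.ndarray  # 3D bool, union of the compartments
    affine: np.ndarray
    occupancy: dict  # (group, session) -> length k+1 probabilities, baseline last
    behavior_loadings: pd.DataFrame  # score x k
    noise_sd: float = 0.5
    motion_spike_rate: float = 0.5  # spikes per minute
    persistence: float = 0.3  # Markov self-transition weight
    amplitude: float = 1.0  # map expression amplitude
    drift_amp: float = 0.3
    global_amp: float = 0.2
    compartment_amp: float = 0.5
    base_offset: float = 100.0
    rng_seed: int = 0

    @property
    def k(self) -> int:
        return self.cap_maps.shape[0]

    def map_volume(self, i: int) -> np.ndarray:
        """CAP map ``i`` as a 3D volume (zeros outside gray matter)."""
        out = np.zeros(self.gm_mask.shape)
        out[self.gm_mask] = self.cap_maps[i]
        return out


@dataclass
class CohortDesign:
    """Cohort structure: one pre session per control, pre+post per patient."""

    n_per_group: int = 20
    n_frames: int = 600
    tr: float = 1.0
    behavior_noise_sd: float = 0.5
    age_mean: float = 76.0
    age_sd: float = 6.0
    min_retained_seconds: float = 240.0

    def __post_init__(self) -> None:
        if self.n_frames * self.tr < self.min_retained_seconds:
            raise ValueError("scan shorter than the minimum retained duration")


@dataclass
class SubjectScan:
    subject_id: str
    group: str
    session: str
    volume: Volume4D
    motion: pd.DataFrame
    states: np.ndarray  # per-frame latent state, k = baseline


@dataclass
class Cohort:
    truth: GroundTruth
    design: CohortDesign
    scans: list[SubjectScan]
    phenotype: pd.DataFrame


def default_occupancy(k: int, baseline: float = 0.5) -> dict:
    """Planted occupancy vectors over {CAP_1..CAP_k, baseline}.

    Controls favor low-index CAPs, patients (pre) the reverse — the planted
    group effect; the post session moves patients part-way back toward the
    control profile with an extra boost of the middle CAP, the planted
    paired shift.
    """
    weights = np.linspace(1.2, 0.8, k)
    control = weights / weights.sum() * (1 - baseline)
    patient = control[::-1].copy()
    post = 0.5 * (control + patient)
    shift = 0.2 * post[-1]
    post[-1] -= shift
    post[min(1, k - 1)] += shift
    return {
        ("control", "pre"): np.append(control, baseline),
        ("patient", "pre"): np.append(patient, baseline),
        ("patient", "post"): np.append(post, baseline),
    }


def _default_loadings(k: int) -> pd.DataFrame:
    if k == 3:
        return pd.DataFrame(DEFAULT_BEHAVIOR_LOADINGS, index=["CAP1", "CAP2", "CAP3"]).T
    rng = np.random.default_rng(12345)
    vals = rng.normal(0, 2.0, size=(6, k))
    return pd.DataFrame(vals, index=list(DEFAULT_BEHAVIOR_LOADINGS), columns=[f"CAP{i+1}" for i in range(k)])


def _smooth_field(shape: tuple, sigma: float, rng: np.random.Generator) -> np.ndarray:
    field3d = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return field3d


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def generate_ground_truth(
    k: int,
    mask: np.ndarray,
    rng_seed: int,
    *,
    map_fwhm_vox: float = 3.0,
    seed_fraction: float = 0.02,
    seed_gain: float = 2.0,
    occupancy: dict | None = None,
    behavior_loadings: pd.DataFrame | None = None,
    affine: np.ndarray | None = None,
    **params,
) -> GroundTruth:
    """Generate ``k`` smooth, partially overlapping signed CAP maps on
    ``mask`` with a common positive seed region.

    Maps are Gaussian-smoothed random fields (FWHM ``map_fwhm_vox`` voxels),
    sequentially decorrelated and z-scored, then given a shared positive
    seed bump so that seed events select all states. Deterministic given
    ``rng_seed``; pairwise spatial |r| < 0.5 is enforced.
    """
    mask = np.asarray(mask, dtype=bool)
    if k < 2:
        raise ValueError("k must be at least 2")
    n_vox = int(mask.sum())
    if n_vox < max(2 * k, 8):
        raise ValueError("mask too small to carry distinguishable maps")
    rng = np.random.default_rng(rng_seed)
    sigma = map_fwhm_vox * GAUSSIAN_FWHM_TO_SIGMA

    # seed region: a blob of ~seed_fraction of gm voxels around the mask centroid
    coords = np.argwhere(mask)
    centroid = coords.mean(axis=0)
    d2 = ((coords - centroid) ** 2).sum(axis=1)
    n_seed = max(4, int(round(seed_fraction * n_vox)))
    seed_idx = np.argsort(d2)[:n_seed]
    seed_mask = np.zeros_like(mask)
    seed_mask[tuple(coords[seed_idx].T)] = True
    seed_in_gm = seed_mask[mask]

    for _attempt in range(25):
        maps = np.empty((k, n_vox))
        for i in range(k):
            m = _zscore(_smooth_field(mask.shape, sigma, rng)[mask])
            for j in range(i):  # decorrelate against previous maps
                m = m - (m @ maps[j]) / (maps[j] @ maps[j]) * maps[j]
            m = _zscore(m)
            # identical seed plateau in every map: seed events must sample
            # all states with the same selection probability
            m[seed_in_gm] = seed_gain
            maps[i] = (m - m[~seed_in_gm].mean()) / m[~seed_in_gm].std()
        cc = np.corrcoef(maps)
        if np.abs(cc[np.triu_indices(k, 1)]).max() < 0.5:
            break
    else:
        raise RuntimeError("could not generate sufficiently distinct maps")

    wm_mask = np.zeros_like(mask)
    csf_mask = np.zeros_like(mask)
    outside = np.argwhere(~mask)
    if outside.size:  # split non-gm voxels into WM / CSF compartments
        half = len(outside) // 2
        wm_mask[tuple(outside[:half].T)] = True
        csf_mask[tuple(outside[half:].T)] = True
    brain_mask = mask | wm_mask | csf_mask

    return GroundTruth(
        cap_maps=maps,
        gm_mask=mask,
        seed_mask=seed_mask,
        wm_mask=wm_mask,
        csf_mask=csf_mask,
        brain_mask=brain_mask,
        affine=np.diag([2.5, 2.5, 2.5, 1.0]) if affine is None else affine,
        occupancy=default_occupancy(k) if occupancy is None else occupancy,
        behavior_loadings=_default_loadings(k) if behavior_loadings is None else behavior_loadings,
        rng_seed=rng_seed,
        **params,
    )


def sample_states(
    occupancy: np.ndarray, n_frames: int, persistence: float, rng: np.random.Generator
) -> np.ndarray:
    """First-order Markov chain with transition matrix
    ``persistence * I + (1 - persistence) * 1 pi^T``; its stationary
    distribution is exactly ``pi = occupancy``. State ``k`` is baseline."""
    pi = np.asarray(occupancy, dtype=float)
    pi = pi / pi.sum()
    n_states = pi.size
    states = np.empty(n_frames, dtype=int)
    states[0] = rng.choice(n_states, p=pi)
    stay = rng.random(n_frames) < persistence
    jumps = rng.choice(n_states, size=n_frames, p=pi)
    for t in range(1, n_frames):
        states[t] = states[t - 1] if stay[t] else jumps[t]
    return states


def _simulate_motion(
    n_frames: int, tr: float, spike_rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Slow small-amplitude wander plus single-frame displacement jumps
    (1.2 mm on one translation axis) at ``spike_rate`` spikes per minute."""
    steps = np.column_stack(
        [rng.normal(0, 0.01, size=(n_frames, 3)), rng.normal(0, 2e-4, size=(n_frames, 3))]
    )
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    minutes = n_frames * tr / 60.0
    n_spikes = rng.poisson(spike_rate * minutes)
    if n_spikes > 0:
        # interior frames only, so the 1-back/2-forward rule is fully exercised
        lo, hi = 1, max(2, n_frames - 2)
        spike_frames = rng.choice(np.arange(lo, hi), size=min(n_spikes, hi - lo), replace=False)
        axes = rng.integers(0, 3, size=len(spike_frames))
        for t, ax in zip(spike_frames, axes):
            params[t, ax] += 1.2
    return pd.DataFrame(params, columns=list(MOTION_COLUMNS))


def simulate_subject(
    truth: GroundTruth,
    design: CohortDesign,
    group: str,
    session: str,
    rng_seed: int,
) -> tuple[Volume4D, pd.DataFrame, np.ndarray]:
    """Simulate one scan: state-driven frames plus nuisance and noise.

    Frame t equals ``amplitude * cap_map[state]`` on gray matter when the
    latent state is a CAP, zero otherwise, plus a spatially smooth
    low-frequency drift, a global fluctuation shared by all brain voxels,
    AR(1) compartment signals on WM and CSF voxels, a constant offset, and
    i.i.d. Gaussian noise of sd ``truth.noise_sd``.
    """
    key = (group, session)
    if key not in truth.occupancy:
        raise ValueError(f"unknown group/session combination: {key}")
    rng = np.random.default_rng(rng_seed)
    n, tr = design.n_frames, design.tr
    shape = truth.gm_mask.shape

    states = sample_states(truth.occupancy[key], n, truth.persistence, rng)
    data = np.zeros(shape + (n,), dtype=np.float32)

    gm = truth.gm_mask
    gm_ts = np.zeros((n, int(gm.sum())), dtype=np.float32)
    for s in range(truth.k):
        on = states == s
        if on.any():
            gm_ts[on] = (truth.amplitude * truth.cap_maps[s]).astype(np.float32)

    brain = truth.brain_mask
    n_brain = int(brain.sum())
    if truth.drift_amp > 0:
        t_ax = np.arange(n)
        f_drift = rng.uniform(0.002, 0.006)
        drift = truth.drift_amp * np.cos(2 * np.pi * f_drift * tr * t_ax + rng.uniform(0, 2 * np.pi))
        weights = _zscore(_smooth_field(shape, 2.0, rng)[brain])
        data[brain] += (weights[:, None] * drift[None, :]).astype(np.float32)
    if truth.global_amp > 0:
        g = _ar1(n, 0.9, rng) * truth.global_amp
        data[brain] += g.astype(np.float32)[None, :]
    if truth.compartment_amp > 0:
        if truth.wm_mask.any():
            data[truth.wm_mask] += (_ar1(n, 0.8, rng) * truth.compartment_amp).astype(np.float32)[None, :]
        if truth.csf_mask.any():
            data[truth.csf_mask] += (_ar1(n, 0.8, rng) * truth.compartment_amp).astype(np.float32)[None, :]
    data[gm] += gm_ts.T
    if truth.base_offset:
        data[brain] += truth.base_offset
    if truth.noise_sd > 0:
        data[brain] += rng.normal(0, truth.noise_sd, size=(n_brain, n)).astype(np.float32)

    vol = Volume4D(data=data, affine=truth.affine, mask=brain, tr=tr)
    motion = _simulate_motion(n, tr, truth.motion_spike_rate, rng)
    return vol, motion, states


def _ar1(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n) * np.sqrt(1 - rho**2)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + innov[t]
    return x


def simulate_cohort(truth: GroundTruth, design: CohortDesign) -> Cohort:
    """Simulate the full cohort: one pre session per control, pre and post
    sessions per patient, with phenotype covariates and behavior scores
    linear in the realized CAP occupancies."""
    master = np.random.SeedSequence(truth.rng_seed)
    n_scans = 3 * design.n_per_group  # controls: pre; patients: pre + post
    scan_seeds = master.spawn(n_scans + 1)
    pheno_rng = np.random.default_rng(scan_seeds[-1])

    scans: list[SubjectScan] = []
    rows = []
    scan_i = 0
    for group in GROUPS:
        for s in range(design.n_per_group):
            sid = f"{'hc' if group == 'control' else 'pt'}{s:03d}"
            age = pheno_rng.normal(design.age_mean, design.age_sd)
            gender = int(pheno_rng.random() < 0.5)
            education = int(pheno_rng.integers(1, 4))
            sessions = ("pre",) if group == "control" else ("pre", "post")
            for session in sessions:
                seed_int = int(np.random.default_rng(scan_seeds[scan_i]).integers(2**31 - 1))
                scan_i += 1
                vol, motion, states = simulate_subject(truth, design, group, session, seed_int)
                scans.append(SubjectScan(sid, group, session, vol, motion, states))
                active = states < truth.k
                occ = np.bincount(states[active], minlength=truth.k) / max(active.sum(), 1)
                means = truth.behavior_loadings.to_numpy() @ occ
                noise = pheno_rng.normal(0, design.behavior_noise_sd, size=means.size)
                row = {
                    "subject_id": sid,
                    "group": group,
                    "session": session,
                    "age": round(age, 1),
                    "gender": gender,
                    "education": education,
                }
                for name, mu, eps in zip(truth.behavior_loadings.index, means, noise):
                    row[name] = mu + (eps if design.behavior_noise_sd > 0 else 0.0)
                # biomarker analogue: linear in occ contrast, patients only
                row["ptau"] = (
                    60 + 40 * (occ[0] - occ[-1]) + pheno_rng.normal(0, 2.0) * (design.behavior_noise_sd > 0)
                    if group == "patient"
                    else np.nan
                )
                rows.append(row)
    phenotype = pd.DataFrame(rows)
    return Cohort(truth=truth, design=design, scans=scans, phenotype=phenotype)


def synthetic_parcellation(gm_mask: np.ndarray, n_regions: int, n_rsn: int, rng_seed: int = 0):
    """Partition the gray-matter mask into ``n_regions`` spatially compact
    regions (k-means on voxel coordinates) grouped into ``n_rsn`` networks
    by contiguous chunks of regions ordered along the first axis."""
    from sklearn.cluster import KMeans

    from .connectivity import Parcellation

    coords = np.argwhere(gm_mask).astype(float)
    if len(coords) < n_regions:
        raise ValueError("mask smaller than requested number of regions")
    km = KMeans(n_clusters=n_regions, n_init=4, random_state=rng_seed).fit(coords)
    label_volume = np.zeros(gm_mask.shape, dtype=int)
    label_volume[gm_mask] = km.labels_ + 1
    order = np.argsort(km.cluster_centers_[:, 0], kind="stable")
    rsn_of_region = np.empty(n_regions, dtype=int)
    for rank, reg in enumerate(order):
        rsn_of_region[reg] = rank * n_rsn // n_regions + 1
    table = pd.DataFrame(
        {
            "region_id": np.arange(1, n_regions + 1),
            "name": [f"region_{i+1}" for i in range(n_regions)],
            "rsn_id": rsn_of_region,
            "rsn_name": [f"RSN{r}" for r in rsn_of_region],
        }
    )
    return Parcellation(label_volume=label_volume, region_table=table)


# ---------------------------------------------------------------------------
# on-disk round trip (NIfTI + TSV + truth JSON)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write the cohort as NIfTI volumes, fMRIPrep-dialect motion TSVs, a
    phenotype TSV, masks and truth maps, plus a truth JSON with parameters."""
    import nibabel as nib

    out = Path(outdir)
    (out / "func").mkdir(parents=True, exist_ok=True)
    truth = cohort.truth
    aff = truth.affine
    for name, m in [
        ("gm_mask", truth.gm_mask),
        ("seed_mask", truth.seed_mask),
        ("wm_mask", truth.wm_mask),
        ("csf_mask", truth.csf_mask),
        ("brain_mask", truth.brain_mask),
    ]:
        nib.save(nib.Nifti1Image(m.astype(np.uint8), aff), out / f"{name}.nii")
    for i in range(truth.k):
        nib.save(nib.Nifti1Image(truth.map_volume(i), aff), out / f"truth_cap{i+1}.nii")
    for scan in cohort.scans:
        stem = f"{scan.subject_id}_{scan.session}"
        img = nib.Nifti1Image(scan.volume.data, aff)
        img.header.set_zooms((*scan.volume.voxel_sizes, scan.volume.tr))
        nib.save(img, out / "func" / f"{stem}_bold.nii")
        scan.motion.to_csv(out / "func" / f"{stem}_motion.tsv", sep="\t", index=False)
        pd.DataFrame({"frame": np.arange(len(scan.states)), "state": scan.states}).to_csv(
            out / "func" / f"{stem}_states.tsv", sep="\t", index=False
        )
    cohort.phenotype.to_csv(out / "phenotype.tsv", sep="\t", index=False)
    record = {
        "k": truth.k,
        "rng_seed": truth.rng_seed,
        "noise_sd": truth.noise_sd,
        "motion_spike_rate": truth.motion_spike_rate,
        "persistence": truth.persistence,
        "amplitude": truth.amplitude,
        "tr": cohort.design.tr,
        "n_frames": cohort.design.n_frames,
        "n_per_group": cohort.design.n_per_group,
        "behavior_noise_sd": cohort.design.behavior_noise_sd,
        "min_retained_seconds": cohort.design.min_retained_seconds,
        "occupancy": {f"{g}/{s}": list(map(float, v)) for (g, s), v in truth.occupancy.items()},
        "behavior_loadings": truth.behavior_loadings.to_dict(),
    }
    (out / "truth.json").write_text(json.dumps(record, indent=2))
    return out
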