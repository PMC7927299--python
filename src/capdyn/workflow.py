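"""End-to-end study orchestration.

One config drives: synthetic-cohort simulation (or loading a cohort from
disk), frame-level preprocessing with motion censoring, RSN connectivity
with group contrasts, seed CAP extraction with temporal metrics and
post-session frame classification, group/paired inference with optional
voxel-wise TFCE permutation testing, and PLSC brain-behavior analyses.
Every source of randomness fans out from a single master seed through a
named seed-splitting scheme, so each stage is independently reproducible
and a repeated run is numerically identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import caps as caps_mod
from . import plsc as plsc_mod
from . import stats as stats_mod
from .connectivity import fc_matrix, parcel_timeseries, rsn_aggregate
from .preprocess import preprocess_volume, extract_global_signal
from .synthetic import (
    Cohort,
    CohortDesign,
    SubjectScan,
    generate_ground_truth,
    simulate_cohort,
    synthetic_parcellation,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "connectivity", "caps", "stats", "plsc")


@dataclass
class StudyConfig:
    """Serializable configuration of a full study run."""

    # simulation
    simulate: bool = True
    input_dir: str | None = None
    grid_shape: tuple = (20, 20, 20)
    n_frames: int = 600
    tr: float = 1.0
    n_per_group: int = 20
    k_true: int = 3
    noise_sd: float = 0.5
    motion_spike_rate: float = 0.5
    behavior_noise_sd: float = 0.5
    # preprocessing
    gsr: bool = False
    fd_threshold: float = 0.7
    band_low: float = 0.01
    band_high: float = 0.15
    fwhm_mm: float = 6.0
    min_retained_seconds: float = 240.0
    n_dct: int = 3
    # connectivity
    n_regions: int = 32
    n_rsn: int = 8
    # caps
    z_thresh: float = 1.0
    k: int = 3
    k_range: tuple | None = None
    consensus_n_boot: int = 100
    # stats
    covariates: tuple = ("age", "gender", "education")
    n_perm: int = 200
    q_fdr: float = 0.05
    tfce_steps: int = 50
    min_cluster: int = 20
    voxelwise: bool = False
    # plsc
    plsc_n_perm: int = 200
    plsc_n_boot: int = 200
    # reproducibility
    rng_seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for key in ("grid_shape", "k_range", "covariates"):
            if d[key] is not None:
                d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key in ("grid_shape", "k_range", "covariates"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        h = hashlib.sha256(f"{self.rng_seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31 - 1)


@dataclass
class StudyState:
    """In-memory artifacts accumulated across stages."""

    config: StudyConfig
    cohort: Cohort | None = None
    processed: dict = field(default_factory=dict)  # (subject, session) -> Volume4D
    censors: dict = field(default_factory=dict)
    excluded: list = field(default_factory=list)  # dicts: subject, session, rule
    parcellation: object = None
    rsn_matrices: dict = field(default_factory=dict)
    rsn_contrasts: pd.DataFrame | None = None
    caps: caps_mod.CapSet | None = None
    consensus: caps_mod.ConsensusReport | None = None
    metrics: pd.DataFrame | None = None
    coact_maps: dict = field(default_factory=dict)  # (subject, session) -> 1D gm vector
    gs_maps: dict = field(default_factory=dict)
    group_contrasts: pd.DataFrame | None = None
    paired: pd.DataFrame | None = None
    voxel_result: stats_mod.VoxelTestResult | None = None
    plsc_results: dict = field(default_factory=dict)
    plsc_summary: pd.DataFrame | None = None


def _gm_box_mask(shape: tuple) -> np.ndarray:
    """Central-box gray-matter mask leaving a one-voxel shell of WM/CSF."""
    mask = np.zeros(shape, dtype=bool)
    sl = tuple(slice(1, s - 1) for s in shape)
    mask[sl] = True
    return mask


def stage_simulate(state: StudyState) -> None:
    cfg = state.config
    if not cfg.simulate:
        if cfg.input_dir is None or not Path(cfg.input_dir).exists():
            raise FileNotFoundError(
                f"stage simulate: input_dir {cfg.input_dir!r} missing and simulation disabled"
            )
        state.cohort = load_cohort(cfg.input_dir)
        return
    gm = _gm_box_mask(tuple(cfg.grid_shape))
    truth = generate_ground_truth(
        cfg.k_true,
        gm,
        rng_seed=cfg.stage_seed("simulate"),
        noise_sd=cfg.noise_sd,
        motion_spike_rate=cfg.motion_spike_rate,
    )
    design = CohortDesign(
        n_per_group=cfg.n_per_group,
        n_frames=cfg.n_frames,
        tr=cfg.tr,
        behavior_noise_sd=cfg.behavior_noise_sd,
        min_retained_seconds=min(cfg.min_retained_seconds, cfg.n_frames * cfg.tr),
    )
    state.cohort = simulate_cohort(truth, design)


def stage_preprocess(state: StudyState) -> None:
    cfg = state.config
    truth = state.cohort.truth
    for scan in state.cohort.scans:
        vol, censor = preprocess_volume(
            scan.volume,
            scan.motion,
            wm_mask=truth.wm_mask,
            csf_mask=truth.csf_mask,
            gsr=cfg.gsr,
            fwhm=cfg.fwhm_mm,
            band=(cfg.band_low, cfg.band_high),
            fd_threshold=cfg.fd_threshold,
            min_retained_seconds=min(cfg.min_retained_seconds, cfg.n_frames * cfg.tr),
        )
        key = (scan.subject_id, scan.session)
        state.censors[key] = censor
        if censor.excluded:
            state.excluded.append(
                {"subject": scan.subject_id, "session": scan.session, "rule": "motion_duration"}
            )
            logger.warning("excluded %s/%s: insufficient uncorrupted duration", *key)
            continue
        state.processed[key] = vol


def _scan_index(state: StudyState) -> dict:
    return {(s.subject_id, s.session): s for s in state.cohort.scans}


def stage_connectivity(state: StudyState) -> None:
    cfg = state.config
    truth = state.cohort.truth
    state.parcellation = synthetic_parcellation(
        truth.gm_mask, cfg.n_regions, cfg.n_rsn, rng_seed=cfg.stage_seed("parcellation")
    )
    pheno = state.cohort.phenotype.set_index(["subject_id", "session"])
    rows = []
    for key, vol in state.processed.items():
        if key[1] != "pre":
            continue
        ts = parcel_timeseries(vol, state.parcellation, state.censors[key].keep_mask)
        state.rsn_matrices[key] = rsn_aggregate(fc_matrix(ts), state.parcellation)
        rows.append(key)
    if not rows:
        return
    groups = np.array([pheno.loc[k, "group"] == "patient" for k in rows], dtype=float)
    if len(np.unique(groups)) < 2:
        return
    cov = pd.DataFrame([pheno.loc[k, list(cfg.covariates)] for k in rows]).astype(float).reset_index(drop=True)
    n_rsn = state.rsn_matrices[rows[0]].n_rsn
    recs = []
    for a in range(n_rsn):
        for b in range(a + 1):
            y = np.array([state.rsn_matrices[k].values[a, b] for k in rows])
            if np.isnan(y).any() or y.std() == 0:
                continue
            res = stats_mod.ancova_group_test(y, groups, cov, effect_name=f"RSN{a+1}-RSN{b+1}")
            recs.append(
                {"pair": res.effect_name, "a": a + 1, "b": b + 1, "F": res.statistic,
                 "p": res.p, "d": res.cohens_d}
            )
    table = pd.DataFrame(recs)
    if not table.empty:
        reject, p_adj = stats_mod.bh_fdr(table["p"].to_numpy(), q=cfg.q_fdr)
        table["fdr_significant"] = reject
        table["p_adjusted"] = p_adj
    state.rsn_contrasts = table


def stage_caps(state: StudyState) -> None:
    cfg = state.config
    truth = state.cohort.truth
    gm = truth.gm_mask
    seed_voxels = truth.seed_mask

    pooled_frames, pooled_subjects, per_scan = [], [], {}
    for key, vol in state.processed.items():
        keep = state.censors[key].keep_mask
        series = caps_mod.seed_series(vol, seed_voxels, keep)
        if series.std() == 0:
            state.excluded.append({"subject": key[0], "session": key[1], "rule": "zero_variance_seed"})
            logger.warning("excluded %s/%s: zero-variance seed series", *key)
            continue
        sel_kept = caps_mod.select_active_frames(series, z_thresh=cfg.z_thresh)
        kept_idx = np.flatnonzero(keep)
        selected = kept_idx[sel_kept]
        frames = vol.data[gm][:, selected].T  # (n_sel, n_gm)
        per_scan[key] = {"selected": selected, "frames": frames, "keep": keep}
        # co-activation and global-signal representation maps (pre sessions)
        if key[1] == "pre" and selected.size:
            state.coact_maps[key] = frames.mean(axis=0)
            gs = extract_global_signal(vol)[keep]
            gs_sel = kept_idx[caps_mod.select_active_frames(gs, z_thresh=cfg.z_thresh)]
            if gs_sel.size:
                state.gs_maps[key] = vol.data[gm][:, gs_sel].mean(axis=1)
        if key[1] == "pre":
            pooled_frames.append(frames)
            pooled_subjects.append(np.repeat(key[0], frames.shape[0]))

    train = np.vstack(pooled_frames)
    train_subjects = np.concatenate(pooled_subjects)

    k = cfg.k
    if cfg.k_range is not None:
        state.consensus = caps_mod.consensus_select_k(
            train,
            range(cfg.k_range[0], cfg.k_range[1] + 1),
            rng_seed=cfg.stage_seed("consensus"),
            n_boot=cfg.consensus_n_boot,
            subject_ids=train_subjects,
        )
        if state.consensus.chosen_k is not None:
            k = state.consensus.chosen_k
    state.caps, train_labels = caps_mod.cluster_caps(train, k, rng_seed=cfg.stage_seed("kmeans"))

    # per-scan metrics; pre sessions reuse training labels, post sessions are
    # classified into the pre-established CAPs by correlation
    offsets = np.cumsum([0] + [f.shape[0] for f in pooled_frames])
    pre_keys = [key for key in per_scan if key[1] == "pre"]
    rows = []
    for i, key in enumerate(pre_keys):
        info = per_scan[key]
        labels = train_labels[offsets[i] : offsets[i + 1]]
        rows.append((key, caps_mod.cap_metrics(labels, info["selected"], info["keep"], cfg.tr, k)))
    for key, info in per_scan.items():
        if key[1] == "pre":
            continue
        labels, _ = caps_mod.assign_frames_to_caps(info["frames"], state.caps)
        ok = labels >= 0
        rows.append(
            (key, caps_mod.cap_metrics(labels[ok], info["selected"][ok], info["keep"], cfg.tr, k))
        )
    recs = []
    for (sid, session), m in rows:
        for c in range(k):
            recs.append(
                {
                    "subject_id": sid,
                    "session": session,
                    "cap": c + 1,
                    "occurrence": m.occurrence[c],
                    "duration_s": m.duration_s[c],
                    "frequency_per_min": m.frequency_per_min[c],
                    "n_active": m.n_active_frames,
                    "active_fraction": m.active_fraction,
                }
            )
    state.metrics = pd.DataFrame(recs).sort_values(["subject_id", "session", "cap"]).reset_index(drop=True)


def stage_stats(state: StudyState) -> None:
    cfg = state.config
    pheno = state.cohort.phenotype.set_index(["subject_id", "session"])
    metrics = state.metrics
    k = state.caps.k

    pre = metrics[metrics.session == "pre"]
    subjects = pre.subject_id.unique()
    groups = np.array(
        [pheno.loc[(s, "pre"), "group"] == "patient" for s in subjects], dtype=float
    )
    cov = pd.DataFrame(
        [pheno.loc[(s, "pre"), list(cfg.covariates)] for s in subjects]
    ).astype(float).reset_index(drop=True)

    recs = []
    wide = pre.pivot_table(index="subject_id", columns="cap", values="occurrence").loc[subjects]
    for c in range(1, k + 1):
        res = stats_mod.ancova_group_test(
            wide[c].to_numpy(), groups, cov, effect_name=f"CAP{c}_occurrence"
        )
        recs.append(res)
    active = pre.groupby("subject_id")["active_fraction"].first().loc[subjects].to_numpy()
    recs.append(stats_mod.ancova_group_test(active, groups, cov, effect_name="active_fraction"))
    table = pd.DataFrame(
        {
            "effect": [r.effect_name for r in recs],
            "F": [r.statistic for r in recs],
            "df1": [r.df[0] for r in recs],
            "df2": [r.df[1] for r in recs],
            "p": [r.p for r in recs],
            "d": [r.cohens_d for r in recs],
            "direction": [r.direction for r in recs],
        }
    )
    reject, p_adj = stats_mod.bh_fdr(table["p"].to_numpy(), q=cfg.q_fdr)
    table["fdr_significant"] = reject
    table["p_adjusted"] = p_adj
    state.group_contrasts = table

    # paired pre/post on patients present in both sessions
    post = metrics[metrics.session == "post"]
    paired_subjects = sorted(set(pre.subject_id) & set(post.subject_id))
    paired_recs = []
    if len(paired_subjects) >= 3:
        wpre = pre.pivot_table(index="subject_id", columns="cap", values="occurrence").loc[paired_subjects]
        wpost = post.pivot_table(index="subject_id", columns="cap", values="occurrence").loc[paired_subjects]
        for c in range(1, k + 1):
            r = stats_mod.paired_t(
                wpre[c].to_numpy(), wpost[c].to_numpy(), effect_name=f"CAP{c}_occurrence"
            )
            paired_recs.append(
                {"effect": r.effect_name, "t": r.statistic, "df": r.df[0], "p": r.p,
                 "d": r.cohens_d, "direction": r.direction}
            )
    state.paired = pd.DataFrame(paired_recs)

    if cfg.voxelwise and state.coact_maps:
        keys = [(s, "pre") for s in subjects if (s, "pre") in state.coact_maps]
        maps = np.vstack([state.coact_maps[key] for key in keys])
        g = np.array([pheno.loc[key, "group"] == "patient" for key in keys], dtype=float)
        cv = pd.DataFrame([pheno.loc[key, list(cfg.covariates)] for key in keys]).astype(float)
        state.voxel_result = stats_mod.voxelwise_permutation_test(
            maps,
            g,
            state.cohort.truth.gm_mask,
            covariates=cv.reset_index(drop=True),
            n_perm=cfg.n_perm,
            rng_seed=cfg.stage_seed("voxelwise"),
            tfce_steps=cfg.tfce_steps,
            min_cluster=cfg.min_cluster,
        )


def stage_plsc(state: StudyState) -> None:
    cfg = state.config
    pheno = state.cohort.phenotype.set_index(["subject_id", "session"])
    metrics = state.metrics
    k = state.caps.k
    pre = metrics[metrics.session == "pre"]
    patients = [
        s for s in pre.subject_id.unique() if pheno.loc[(s, "pre"), "group"] == "patient"
    ]
    if len(patients) < 6:
        logger.warning("too few patients for PLSC; stage skipped")
        return
    occ = pre.pivot_table(index="subject_id", columns="cap", values="occurrence").loc[patients]
    occ.columns = [f"CAP{c}" for c in occ.columns]
    score_cols = [c for c in state.cohort.phenotype.columns if c.split("_")[0] in
                  ("gait", "exec", "memory", "attention")]
    domains = {}
    for prefix in ("gait", "exec", "memory", "attention"):
        cols = [c for c in score_cols if c.startswith(prefix)]
        if cols:
            domains[prefix] = pd.DataFrame(
                [pheno.loc[(s, "pre"), cols] for s in patients], index=patients
            ).astype(float)
    confounds = pd.DataFrame(
        [pheno.loc[(s, "pre"), list(cfg.covariates)] for s in patients], index=patients
    ).astype(float)
    state.plsc_results, state.plsc_summary = plsc_mod.run_plsc_domains(
        occ,
        domains,
        confounds=confounds,
        n_perm=cfg.plsc_n_perm,
        n_boot=cfg.plsc_n_boot,
        rng_seed=cfg.stage_seed("plsc"),
    )


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "connectivity": stage_connectivity,
    "caps": stage_caps,
    "stats": stage_stats,
    "plsc": stage_plsc,
}


def run_study(
    config: StudyConfig,
    outdir: str | Path | None = None,
    stages: tuple = STAGES,
    make_plots: bool = False,
) -> StudyState:
    """Run the configured stages in order and write their artifacts.

    Re-running with the same config and master seed reproduces all numeric
    outputs; every table is stamped with the config hash and seed through
    the accompanying report.json.
    """
    state = StudyState(config=config)
    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("running stage %s", stage)
        STAGE_FUNCS[stage](state)
    if outdir is not None:
        write_outputs(state, outdir, make_plots=make_plots)
    return state


def write_outputs(state: StudyState, outdir: str | Path, make_plots: bool = False) -> Path:
    import nibabel as nib

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = state.config
    cfg.to_yaml(out / "config.yaml")
    for key, censor in state.censors.items():
        (out / "censor").mkdir(exist_ok=True)
        censor.to_frame().to_csv(out / "censor" / f"{key[0]}_{key[1]}.tsv", sep="\t", index=False)
    if state.cohort is not None:
        state.cohort.phenotype.to_csv(out / "phenotype.tsv", sep="\t", index=False)
    if state.rsn_contrasts is not None:
        state.rsn_contrasts.to_csv(out / "rsn_contrasts.tsv", sep="\t", index=False)
    if state.metrics is not None:
        state.metrics.to_csv(out / "cap_metrics.tsv", sep="\t", index=False)
    if state.caps is not None:
        truth = state.cohort.truth
        for i in range(state.caps.k):
            vol = np.zeros(truth.gm_mask.shape)
            vol[truth.gm_mask] = state.caps.centroids[i]
            nib.save(nib.Nifti1Image(vol, truth.affine), out / f"cap{i+1}_centroid.nii")
    if state.consensus is not None:
        state.consensus.table.to_csv(out / "consensus.tsv", sep="\t", index=False)
    if state.group_contrasts is not None:
        state.group_contrasts.to_csv(out / "group_contrasts.tsv", sep="\t", index=False)
    if state.paired is not None and not state.paired.empty:
        state.paired.to_csv(out / "paired_prepost.tsv", sep="\t", index=False)
    if state.voxel_result is not None:
        nib.save(
            nib.Nifti1Image(state.voxel_result.corrected_p_map, state.cohort.truth.affine),
            out / "voxelwise_corrected_p.nii",
        )
        (out / "voxelwise_clusters.json").write_text(json.dumps(state.voxel_result.clusters, indent=2))
    if state.plsc_summary is not None:
        state.plsc_summary.to_csv(out / "plsc_summary.tsv", sep="\t", index=False)
        if make_plots:
            for domain, res in state.plsc_results.items():
                plsc_mod.plot_saliences(res, out / f"plsc_{domain}.png", title=f"PLSC: {domain}")
    report = {
        "config_hash": cfg.config_hash(),
        "rng_seed": cfg.rng_seed,
        "excluded": state.excluded,
        "chosen_k": state.consensus.chosen_k if state.consensus else cfg.k,
        "n_scans_processed": len(state.processed),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return out


def load_cohort(input_dir: str | Path) -> Cohort:
    """Load a cohort previously written by :func:`capdyn.synthetic.write_cohort`."""
    import nibabel as nib

    from .preprocess import Volume4D
    from .synthetic import GroundTruth, default_occupancy, _default_loadings

    src = Path(input_dir)
    if not src.exists():
        raise FileNotFoundError(f"cohort directory {src} does not exist")
    record = json.loads((src / "truth.json").read_text())

    def _mask(name: str) -> np.ndarray:
        f = src / f"{name}.nii"
        if not f.exists():
            raise FileNotFoundError(f"stage simulate: missing mask file {f}")
        return np.asarray(nib.load(str(f)).dataobj).astype(bool)

    gm = _mask("gm_mask")
    k = record["k"]
    maps = np.vstack(
        [np.asarray(nib.load(str(src / f"truth_cap{i+1}.nii")).dataobj)[gm] for i in range(k)]
    )
    affine = nib.load(str(src / "gm_mask.nii")).affine
    occupancy = {
        tuple(key.split("/")): np.asarray(v) for key, v in record["occupancy"].items()
    }
    truth = GroundTruth(
        cap_maps=maps,
        gm_mask=gm,
        seed_mask=_mask("seed_mask"),
        wm_mask=_mask("wm_mask"),
        csf_mask=_mask("csf_mask"),
        brain_mask=_mask("brain_mask"),
        affine=affine,
        occupancy=occupancy,
        behavior_loadings=pd.DataFrame(record["behavior_loadings"]),
        noise_sd=record["noise_sd"],
        motion_spike_rate=record["motion_spike_rate"],
        persistence=record["persistence"],
        amplitude=record["amplitude"],
        rng_seed=record["rng_seed"],
    )
    design = CohortDesign(
        n_per_group=record["n_per_group"],
        n_frames=record["n_frames"],
        tr=record["tr"],
        behavior_noise_sd=record.get("behavior_noise_sd", 0.5),
        min_retained_seconds=record.get(
            "min_retained_seconds", min(240.0, record["n_frames"] * record["tr"])
        ),
    )
    phenotype = pd.read_csv(src / "phenotype.tsv", sep="\t")
    scans = []
    for _, row in phenotype.iterrows():
        stem = f"{row.subject_id}_{row.session}"
        img = nib.load(str(src / "func" / f"{stem}_bold.nii"))
        vol = Volume4D(
            data=np.asarray(img.dataobj).astype(np.float32),
            affine=img.affine,
            mask=truth.brain_mask,
            tr=design.tr,
        )
        motion = pd.read_csv(src / "func" / f"{stem}_motion.tsv", sep="\t")
        states = pd.read_csv(src / "func" / f"{stem}_states.tsv", sep="\t")["state"].to_numpy()
        scans.append(SubjectScan(row.subject_id, row.group, row.session, vol, motion, states))
    return Cohort(truth=truth, design=design, scans=scans, phenotype=phenotype)


def sensitivity_suite(config: StudyConfig, outdir: str | Path | None = None) -> dict:
    """Robustness re-runs: alternative cluster number (k + 1), alternative
    parcellation resolution, and global-signal regression enabled; reports
    centroid-matching correlations and effect-size concordance."""
    base = run_study(config)
    report: dict = {}

    # k + 1 variant on the same data: every base centroid should keep a
    # well-matched counterpart
    alt_cfg = dataclasses.replace(config, k=config.k + 1, k_range=None)
    alt = run_study(alt_cfg, stages=("simulate", "preprocess", "caps"))
    _, matched_r = caps_mod.match_caps(base.caps.centroids, alt.caps.centroids)
    report["k_variant"] = {
        "k_base": base.caps.k,
        "k_alt": alt.caps.k,
        "centroid_match_r": [float(r) for r in matched_r],
    }

    # alternative parcellation resolution: planted contrast direction
    parc_cfg = dataclasses.replace(config, n_regions=config.n_regions * 2)
    parc = run_study(parc_cfg, stages=("simulate", "preprocess", "connectivity"))
    report["parcellation_variant"] = {
        "n_regions": parc_cfg.n_regions,
        "rsn_contrast_rows": 0 if parc.rsn_contrasts is None else len(parc.rsn_contrasts),
    }

    # GSR variant: effect-size concordance across RSN pairs and CAP contrasts
    gsr_cfg = dataclasses.replace(config, gsr=True)
    gsr = run_study(gsr_cfg)
    if base.rsn_contrasts is not None and gsr.rsn_contrasts is not None and len(base.rsn_contrasts):
        merged = base.rsn_contrasts.merge(gsr.rsn_contrasts, on="pair", suffixes=("_base", "_gsr"))
        if len(merged) >= 3 and merged["d_base"].std() > 0 and merged["d_gsr"].std() > 0:
            r, p, _ = stats_mod.pearson_corr(merged["d_base"], merged["d_gsr"])
            report["gsr_effect_size_concordance"] = {"r": r, "p": p, "n_pairs": len(merged)}
    if base.group_contrasts is not None and gsr.group_contrasts is not None:
        # CAP indices are ordered by pooled occurrence within each run, so
        # centroids must be matched across runs before comparing contrasts
        mapping, match_r = caps_mod.match_caps(base.caps.centroids, gsr.caps.centroids)
        d_base = base.group_contrasts.set_index("effect")["d"]
        d_gsr = gsr.group_contrasts.set_index("effect")["d"]
        signs = [
            np.sign(d_base[f"CAP{i + 1}_occurrence"])
            == np.sign(d_gsr[f"CAP{mapping[i] + 1}_occurrence"])
            for i in range(base.caps.k)
            if mapping[i] >= 0
        ]
        report["gsr_cap_contrast_sign_agreement"] = float(np.mean(signs))
        report["gsr_centroid_match_r"] = [float(r) for r in match_r]
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "sensitivity.json").write_text(json.dumps(report, indent=2))
    return report
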