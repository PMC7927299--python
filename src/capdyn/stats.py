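"""Group and paired inference.

ANCOVA with covariates (F test on the group term, Cohen's d from the
adjusted difference over the residual SD), paired t tests, Pearson
correlation, Benjamini-Hochberg FDR, threshold-free cluster enhancement
(TFCE), and a Freedman-Lane voxel-wise permutation engine with a max-TFCE
family-wise null — the contract of FSL randomise, re-implemented so the
whole pipeline is one importable library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    effect_name: str
    statistic: float
    df: tuple
    p: float
    cohens_d: float
    direction: str = ""


@dataclass
class VoxelTestResult:
    stat_map: np.ndarray  # 3D t map (group term)
    tfce_map: np.ndarray  # 3D, signed TFCE of the observed t map
    corrected_p_map: np.ndarray  # 3D, per-voxel FWE-corrected p (min over contrasts)
    corrected_p_pos: np.ndarray  # contrast group1 > group0
    corrected_p_neg: np.ndarray  # contrast group1 < group0
    clusters: list = field(default_factory=list)  # dicts: size, peak, p, direction
    n_perm: int = 0


def _design_with_covariates(
    group: np.ndarray, covariates: pd.DataFrame | np.ndarray | None
) -> tuple[np.ndarray, list]:
    group = np.asarray(group, dtype=float)
    cols = [np.ones_like(group), group]
    names = ["intercept", "group"]
    if covariates is not None:
        cov = (
            covariates.to_numpy(dtype=float)
            if isinstance(covariates, pd.DataFrame)
            else np.atleast_2d(np.asarray(covariates, dtype=float))
        )
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != group.size:
            cov = cov.T
        cov_names = (
            list(covariates.columns)
            if isinstance(covariates, pd.DataFrame)
            else [f"cov{i}" for i in range(cov.shape[1])]
        )
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            names.append(cov_names[j])
    X = np.column_stack(cols)
    # drop collinear columns (never intercept or group)
    keep = [0, 1]
    for j in range(2, X.shape[1]):
        sub = X[:, keep + [j]]
        if np.linalg.matrix_rank(sub) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear covariate {names[j]}", RuntimeWarning, stacklevel=3)
    return X[:, keep], [names[j] for j in keep]


def ancova_group_test(
    y: np.ndarray,
    group: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    effect_name: str = "group",
) -> StatResult:
    """OLS of y on intercept + group + covariates; F test (1, n - p) on the
    group term. Cohen's d is the adjusted group difference (group 1 minus
    group 0) divided by the residual SD."""
    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=float)
    if len(np.unique(group)) != 2:
        raise ValueError("group must have exactly two levels")
    X, _ = _design_with_covariates(group, covariates)
    n, p = X.shape
    if n < p + 2:
        raise ValueError("too few subjects for the design")
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dfe = n - p
    mse = resid @ resid / dfe
    if mse <= 0:
        raise ValueError("zero residual variance")
    se = np.sqrt(mse * xtx_inv[1, 1])
    t = beta[1] / se
    F = t**2
    p_val = float(stats.f.sf(F, 1, dfe))
    d = float(beta[1] / np.sqrt(mse))
    return StatResult(
        effect_name=effect_name,
        statistic=float(F),
        df=(1, dfe),
        p=p_val,
        cohens_d=d,
        direction="group1>group0" if beta[1] > 0 else "group1<group0",
    )


def cohens_d(
    y: np.ndarray, group: np.ndarray, covariates: pd.DataFrame | np.ndarray | None = None
) -> float:
    """Covariate-adjusted Cohen's d: adjusted mean difference over residual SD."""
    return ancova_group_test(y, group, covariates).cohens_d


def paired_t(pre: np.ndarray, post: np.ndarray, effect_name: str = "post-pre") -> StatResult:
    """One-sample t test on post - pre differences, df = n - 1;
    d = mean difference / SD of differences."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size < 3:
        raise ValueError("need paired samples with n >= 3")
    diff = post - pre
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return StatResult(effect_name, 0.0, (pre.size - 1,), 1.0, 0.0, "none")
        raise ValueError("zero-variance nonzero differences")
    t, p = stats.ttest_rel(post, pre)
    d = float(diff.mean() / sd)
    return StatResult(
        effect_name=effect_name,
        statistic=float(t),
        df=(pre.size - 1,),
        p=float(p),
        cohens_d=d,
        direction="increase" if diff.mean() > 0 else "decrease",
    )


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r with a two-sided t-based p value and df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), x.size - 2


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control at level q.

    Returns (rejection mask, adjusted p values with cumulative-min
    monotonicity enforced).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def tfce(
    stat_map: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    n_steps: int = 100,
    connectivity: int = 6,
) -> np.ndarray:
    """Threshold-free cluster enhancement.

    For each voxel v: sum over thresholds 0 < h <= value(v) of
    extent(cluster containing v at height h)^E * h^H * dh. Negative values
    are enhanced on the negated map and returned with negative sign.
    ``dh`` defaults to max/n_steps (n_steps=100 mirrors common practice).
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if stat_map.ndim != 3:
        raise ValueError("stat_map must be 3D")
    if dh is not None and dh <= 0:
        raise ValueError("dh must be positive")
    structure = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if structure is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    struct = ndimage.generate_binary_structure(3, structure)

    def _one_sided(m: np.ndarray) -> np.ndarray:
        vmax = m.max()
        if vmax <= 0:
            return np.zeros_like(m)
        step = dh if dh is not None else vmax / n_steps
        out = np.zeros_like(m)
        n_iter = int(np.floor(vmax / step + 1e-9))
        for i in range(1, n_iter + 1):
            h = i * step
            above = m >= h - 1e-12
            lab, n_lab = ndimage.label(above, structure=struct)
            if n_lab == 0:
                break
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            out += np.where(above, sizes[lab] ** E * h**H * step, 0.0)
        return out

    return _one_sided(stat_map) - _one_sided(-stat_map)


def _group_t_maps(X: np.ndarray, Y: np.ndarray, xtx_inv: np.ndarray, pinv_X: np.ndarray) -> np.ndarray:
    """Vectorized t statistic of the group column (index 1) for every map
    column of Y under the fixed design X."""
    n, p = X.shape
    beta = pinv_X @ Y
    resid = Y - X @ beta
    mse = (resid**2).sum(axis=0) / (n - p)
    se = np.sqrt(np.maximum(mse * xtx_inv[1, 1], 1e-300))
    return beta[1] / se


def voxelwise_permutation_test(
    maps: np.ndarray,
    group: np.ndarray,
    mask: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_perm: int = 1000,
    rng_seed: int = 0,
    tfce_E: float = 0.5,
    tfce_H: float = 2.0,
    tfce_steps: int = 100,
    min_cluster: int = 20,
    alpha: float = 0.05,
) -> VoxelTestResult:
    """Voxel-wise two-group comparison with Freedman-Lane permutation and a
    max-TFCE family-wise null.

    ``maps`` is (n_subjects, n_voxels) restricted to ``mask`` (3D bool, with
    mask.sum() == n_voxels). Covariates are handled by permuting the
    residuals of the reduced (covariates-only) model. Both contrasts are
    evaluated; per-voxel corrected p = (1 + #{perm max >= observed}) /
    (1 + n_perm). Clusters of corrected p < alpha larger than
    ``min_cluster`` voxels are reported.
    """
    maps = np.asarray(maps, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if maps.shape[1] != int(mask.sum()):
        raise ValueError("maps second dimension must equal mask voxel count")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse null", RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(rng_seed)
    group = np.asarray(group, dtype=float)
    X, _ = _design_with_covariates(group, covariates)
    n = X.shape[0]
    pinv_X = np.linalg.pinv(X)
    xtx_inv = np.linalg.pinv(X.T @ X)

    # reduced model: everything but the group column
    Xr = np.delete(X, 1, axis=1)
    pinv_Xr = np.linalg.pinv(Xr)
    fitted_r = Xr @ (pinv_Xr @ maps)
    resid_r = maps - fitted_r

    def _tfce_3d(t_flat: np.ndarray) -> np.ndarray:
        vol = np.zeros(mask.shape)
        vol[mask] = t_flat
        return tfce(vol, E=tfce_E, H=tfce_H, n_steps=tfce_steps)

    t_obs = _group_t_maps(X, maps, xtx_inv, pinv_X)
    tfce_obs = _tfce_3d(t_obs)
    obs_pos = np.where(tfce_obs > 0, tfce_obs, 0.0)[mask]
    obs_neg = np.where(tfce_obs < 0, -tfce_obs, 0.0)[mask]

    # single two-sided max-TFCE null: the family of tests spans both
    # contrasts, so the null maximum pools positive and negative excursions
    exceed_pos = np.ones_like(obs_pos)
    exceed_neg = np.ones_like(obs_neg)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Y_star = fitted_r + resid_r[perm]
        t_star = _group_t_maps(X, Y_star, xtx_inv, pinv_X)
        tf = _tfce_3d(t_star)
        max_abs = np.abs(tf).max()
        exceed_pos += max_abs >= obs_pos
        exceed_neg += max_abs >= obs_neg
    p_pos_flat = exceed_pos / (n_perm + 1)
    p_neg_flat = exceed_neg / (n_perm + 1)

    def _to_vol(flat: np.ndarray, fill: float = 1.0) -> np.ndarray:
        vol = np.full(mask.shape, fill)
        vol[mask] = flat
        return vol

    p_pos = _to_vol(p_pos_flat)
    p_neg = _to_vol(p_neg_flat)
    struct = ndimage.generate_binary_structure(3, 1)
    clusters = []
    for p_map, direction in ((p_pos, "group1>group0"), (p_neg, "group1<group0")):
        sig = (p_map < alpha) & mask
        lab, n_lab = ndimage.label(sig, structure=struct)
        for c in range(1, n_lab + 1):
            voxels = lab == c
            size = int(voxels.sum())
            if size <= min_cluster:
                continue
            peak = np.unravel_index(np.argmin(np.where(voxels, p_map, np.inf)), p_map.shape)
            clusters.append(
                {
                    "size": size,
                    "peak": tuple(int(i) for i in peak),
                    "p": float(p_map[voxels].min()),
                    "direction": direction,
                }
            )
    stat_vol = _to_vol(t_obs, fill=0.0)
    return VoxelTestResult(
        stat_map=stat_vol,
        tfce_map=tfce_obs,
        corrected_p_map=np.minimum(p_pos, p_neg),
        corrected_p_pos=p_pos,
        corrected_p_neg=p_neg,
        clusters=clusters,
        n_perm=n_perm,
    )
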