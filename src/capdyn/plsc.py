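"""Partial least squares correlation (PLSC) between CAP occurrences and
behavior-score blocks.

PLSC finds linear combinations of the brain block (CAP occurrences) and the
behavior block with maximal cross-subject covariance: both blocks are
column z-scored, the cross-block matrix R = Y'X / (n - 1) is decomposed by
SVD, and the singular vectors are the saliences (weights). Component
significance is assessed by permuting subject rows of one block; weight
reliability by bootstrap resampling of subjects with percentile intervals
(a weight is "robust" when its 95% interval excludes zero). Confounds are
removed beforehand by per-column forward stepwise regression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)


@dataclass
class PlscResult:
    singular_values: np.ndarray  # non-increasing
    brain_saliences: np.ndarray  # (p, n_comp), unit-norm columns
    behavior_saliences: np.ndarray  # (q, n_comp), unit-norm columns
    perm_p: np.ndarray | None = None
    brain_intervals: np.ndarray | None = None  # (p, n_comp, 2)
    behavior_intervals: np.ndarray | None = None
    brain_robust: np.ndarray | None = None
    behavior_robust: np.ndarray | None = None
    brain_names: list = field(default_factory=list)
    behavior_names: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.singular_values.size


def _zscore_cols(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    sd = a.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance column")
    return (a - a.mean(axis=0)) / sd


def _as_array(block) -> tuple[np.ndarray, list]:
    if isinstance(block, pd.DataFrame):
        return block.to_numpy(dtype=float), list(block.columns)
    a = np.asarray(block, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a, [f"v{i}" for i in range(a.shape[1])]


def residualize_confounds_stepwise(
    y_block,
    confounds: pd.DataFrame,
    entry_p: float = 0.05,
) -> tuple[np.ndarray, list]:
    """Per-column forward stepwise removal of confounds.

    For each column of ``y_block``, confounds enter one at a time: at every
    step the candidate with the smallest coefficient p value is added if
    p < ``entry_p`` (no removal step). The residuals of the selected model
    (always containing an intercept) are returned together with the
    per-column selection order.
    """
    Y, y_names = _as_array(y_block)
    C, c_names = _as_array(confounds)
    n = Y.shape[0]
    if n <= C.shape[1] + 2:
        raise ValueError("too few subjects for stepwise confound regression")
    resid = np.empty_like(Y)
    report = []
    for j in range(Y.shape[1]):
        y = Y[:, j]
        if y.std() == 0:
            warnings.warn(
                f"constant column {y_names[j]} left unchanged", RuntimeWarning, stacklevel=2
            )
            resid[:, j] = y
            report.append({"column": y_names[j], "selected": []})
            continue
        selected: list[int] = []
        while len(selected) < C.shape[1]:
            best_p, best_c = np.inf, None
            for c in range(C.shape[1]):
                if c in selected:
                    continue
                X = np.column_stack([np.ones(n), C[:, selected + [c]]])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                r = y - X @ beta
                dfe = n - X.shape[1]
                mse = r @ r / dfe
                xtx_inv = np.linalg.pinv(X.T @ X)
                se = np.sqrt(max(mse * xtx_inv[-1, -1], 1e-300))
                p_val = 2 * stats.t.sf(abs(beta[-1] / se), dfe)
                if p_val < best_p:
                    best_p, best_c = p_val, c
            if best_c is None or best_p >= entry_p:
                break
            selected.append(best_c)
        X = np.column_stack([np.ones(n)] + ([C[:, selected]] if selected else []))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid[:, j] = y - X @ beta
        report.append({"column": y_names[j], "selected": [c_names[c] for c in selected]})
        logger.info("stepwise %s: selected %s", y_names[j], [c_names[c] for c in selected])
    return resid, report


def plsc_fit(X, Y) -> PlscResult:
    """SVD of the z-scored cross-block covariance R = Zy' Zx / (n - 1).

    Columns of both blocks are z-scored (ddof = 1); components are ordered
    by decreasing singular value. Brain saliences are the right singular
    vectors, behavior saliences the left ones; each side is orthonormal.
    """
    Xa, x_names = _as_array(X)
    Ya, y_names = _as_array(Y)
    if Xa.shape[0] != Ya.shape[0] or Xa.shape[0] < 4:
        raise ValueError("blocks must share n >= 4 subjects")
    Zx, Zy = _zscore_cols(Xa), _zscore_cols(Ya)
    R = Zy.T @ Zx / (Xa.shape[0] - 1)
    if not np.any(R):
        raise ValueError("cross-block covariance is identically zero")
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    return PlscResult(
        singular_values=s,
        brain_saliences=Vt.T,
        behavior_saliences=U,
        brain_names=x_names,
        behavior_names=y_names,
    )


def plsc_permutation_p(X, Y, n_perm: int = 1000, rng_seed: int = 0) -> np.ndarray:
    """Per-component permutation p values: subject rows of the behavior
    block are permuted and each permuted singular value is compared with the
    observed one; p = (1 + #{s_perm >= s_obs}) / (1 + n_perm)."""
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse null", RuntimeWarning, stacklevel=2)
    Xa, _ = _as_array(X)
    Ya, _ = _as_array(Y)
    obs = plsc_fit(Xa, Ya).singular_values
    rng = np.random.default_rng(rng_seed)
    Zx, Zy = _zscore_cols(Xa), _zscore_cols(Ya)
    n = Xa.shape[0]
    exceed = np.ones_like(obs)
    for _ in range(n_perm):
        s = np.linalg.svd(Zy[rng.permutation(n)].T @ Zx / (n - 1), compute_uv=False)
        exceed += s[: obs.size] >= obs
    return exceed / (n_perm + 1)


def _align(result: PlscResult, ref: PlscResult) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match a resampled solution's components to the reference by maximal
    absolute correlation of brain saliences (linear assignment), then flip
    signs to agree with the reference."""
    corr = np.zeros((ref.n_components, result.n_components))
    for i in range(ref.n_components):
        for j in range(result.n_components):
            a, b = ref.brain_saliences[:, i], result.brain_saliences[:, j]
            denom = np.linalg.norm(a) * np.linalg.norm(b)
            corr[i, j] = (a @ b) / denom if denom > 0 else 0.0
    rows, cols = linear_sum_assignment(-np.abs(corr))
    brain = np.empty_like(ref.brain_saliences)
    behav = np.empty_like(ref.behavior_saliences)
    sv = np.empty(ref.n_components)
    for i, j in zip(rows, cols):
        sign = 1.0 if corr[i, j] >= 0 else -1.0
        brain[:, i] = sign * result.brain_saliences[:, j]
        behav[:, i] = sign * result.behavior_saliences[:, j]
        sv[i] = result.singular_values[j]
    return brain, behav, sv


def plsc_bootstrap(
    X,
    Y,
    n_boot: int = 1000,
    rng_seed: int = 0,
    ci: float = 0.95,
    max_redraws: int = 50,
) -> PlscResult:
    """Bootstrap reliability of PLSC weights.

    Subjects are resampled with replacement; each resampled solution is
    aligned (component matching by maximal correlation, sign flips) to the
    original; per-weight percentile intervals are formed and a weight is
    flagged robust when its interval excludes zero. Degenerate resamples
    (a constant column) are redrawn and counted.
    """
    Xa, _ = _as_array(X)
    Ya, _ = _as_array(Y)
    base = plsc_fit(Xa, Ya)
    rng = np.random.default_rng(rng_seed)
    n = Xa.shape[0]
    brain_draws = np.empty((n_boot,) + base.brain_saliences.shape)
    behav_draws = np.empty((n_boot,) + base.behavior_saliences.shape)
    n_redraws = 0
    for b in range(n_boot):
        for _attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            try:
                res = plsc_fit(Xa[idx], Ya[idx])
            except ValueError:
                n_redraws += 1
                continue
            break
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        brain_draws[b], behav_draws[b], _ = _align(res, base)
    if n_redraws:
        logger.info("plsc_bootstrap: %d degenerate resamples redrawn", n_redraws)
    lo, hi = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    b_int = np.stack(np.percentile(brain_draws, [lo, hi], axis=0), axis=-1)
    y_int = np.stack(np.percentile(behav_draws, [lo, hi], axis=0), axis=-1)
    base.brain_intervals = b_int
    base.behavior_intervals = y_int
    base.brain_robust = (b_int[..., 0] > 0) | (b_int[..., 1] < 0)
    base.behavior_robust = (y_int[..., 0] > 0) | (y_int[..., 1] < 0)
    return base


def run_plsc(
    X,
    Y,
    confounds: pd.DataFrame | None = None,
    n_perm: int = 1000,
    n_boot: int = 1000,
    rng_seed: int = 0,
) -> PlscResult:
    """Full PLSC analysis of one behavior domain: stepwise confound removal
    on both blocks, fit, permutation p values, bootstrap intervals."""
    Xa, x_names = _as_array(X)
    Ya, y_names = _as_array(Y)
    if confounds is not None:
        Xa, _ = residualize_confounds_stepwise(Xa, confounds)
        Ya, _ = residualize_confounds_stepwise(Ya, confounds)
    ss = np.random.SeedSequence(rng_seed).spawn(2)
    result = plsc_bootstrap(Xa, Ya, n_boot=n_boot, rng_seed=int(ss[1].generate_state(1)[0] % 2**31))
    result.perm_p = plsc_permutation_p(
        Xa, Ya, n_perm=n_perm, rng_seed=int(ss[0].generate_state(1)[0] % 2**31)
    )
    result.brain_names, result.behavior_names = x_names, y_names
    return result


def run_plsc_domains(
    occurrences: pd.DataFrame,
    behavior_blocks: dict,
    confounds: pd.DataFrame | None = None,
    n_perm: int = 1000,
    n_boot: int = 1000,
    rng_seed: int = 0,
    q: float = 0.05,
) -> tuple[dict, pd.DataFrame]:
    """One PLSC per behavior domain, with BH-FDR over the first-component
    permutation p values (family size = number of domains)."""
    from .stats import bh_fdr

    ss = np.random.SeedSequence(rng_seed).spawn(len(behavior_blocks))
    results = {}
    for s, (domain, block) in zip(ss, behavior_blocks.items()):
        results[domain] = run_plsc(
            occurrences,
            block,
            confounds=confounds,
            n_perm=n_perm,
            n_boot=n_boot,
            rng_seed=int(s.generate_state(1)[0] % 2**31),
        )
    p1 = np.array([results[d].perm_p[0] for d in behavior_blocks])
    reject, p_adj = bh_fdr(p1, q=q)
    summary = pd.DataFrame(
        {
            "domain": list(behavior_blocks),
            "component1_p": p1,
            "fdr_adjusted_p": p_adj,
            "significant": reject,
        }
    )
    return results, summary


def plot_saliences(result: PlscResult, path, component: int = 0, title: str = "") -> None:
    """Bar plot of brain and behavior saliences for one component with
    bootstrap intervals; robust weights are shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, names, sal, intervals, robust, label in (
        (
            axes[0],
            result.brain_names,
            result.brain_saliences,
            result.brain_intervals,
            result.brain_robust,
            "CAP occurrences",
        ),
        (
            axes[1],
            result.behavior_names,
            result.behavior_saliences,
            result.behavior_intervals,
            result.behavior_robust,
            "behavior scores",
        ),
    ):
        vals = sal[:, component]
        x = np.arange(len(vals))
        colors = ["gold" if robust is not None and robust[i, component] else "steelblue" for i in x]
        ax.bar(x, vals, color=colors)
        if intervals is not None:
            err = np.abs(intervals[:, component, :].T - vals)
            ax.errorbar(x, vals, yerr=err, fmt="none", ecolor="black", capsize=3)
        ax.axhline(0, color="gray", lw=0.5)
        ax.set_xticks(x)
        ax.set_xticklabels(names, rotation=45, ha="right", fontsize=7)
        ax.set_title(label, fontsize=9)
    fig.suptitle(title or f"PLSC component {component + 1}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
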