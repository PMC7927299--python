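import numpy as np
import pytest
from hypothesis import settings

from capdyn import caps as caps_mod
from capdyn import synthetic as syn

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_truth(seed=7, shape=(8, 8, 8), k=3, noiseless=False, **kw):
    """Small ground truth on a full-grid gray-matter mask; ``noiseless``
    turns off noise and every nuisance term."""
    mask = np.ones(shape, dtype=bool)
    params = dict(noise_sd=0.5, motion_spike_rate=0.0, drift_amp=0.0,
                  global_amp=0.0, compartment_amp=0.0, base_offset=0.0)
    if noiseless:
        params["noise_sd"] = 0.0
    params.update(kw)
    return syn.generate_ground_truth(k, mask, rng_seed=seed, **params)


def pooled_selected_frames(truth, n_subjects=40, n_frames=100, seed=1, z_thresh=1.0):
    """Simulate subjects, select seed-activation frames, pool them.

    Returns (frames, subject_ids, per-frame true states).
    """
    design = syn.CohortDesign(
        n_per_group=max(n_subjects // 2, 1), n_frames=n_frames, tr=1.0,
        min_retained_seconds=min(240.0, n_frames),
    )
    ss = np.random.SeedSequence(seed).spawn(n_subjects)
    frames, subj, states_sel = [], [], []
    for i in range(n_subjects):
        grp = "control" if i < n_subjects // 2 else "patient"
        sub_seed = int(np.random.default_rng(ss[i]).integers(2**31 - 1))
        vol, _, states = syn.simulate_subject(truth, design, grp, "pre", sub_seed)
        series = vol.data[truth.seed_mask].mean(axis=0)
        sel = caps_mod.select_active_frames(series, z_thresh=z_thresh)
        frames.append(vol.data[truth.gm_mask][:, sel].T)
        subj.append(np.repeat(i, sel.size))
        states_sel.append(states[sel])
    return np.vstack(frames), np.concatenate(subj), np.concatenate(states_sel)


@pytest.fixture(scope="session")
def small_truth():
    return make_truth()


@pytest.fixture(scope="session")
def noiseless_truth():
    return make_truth(noiseless=True)
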