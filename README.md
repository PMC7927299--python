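# capdyn

Seed-based **co-activation pattern (CAP) dynamics** for resting-state fMRI,
with a synthetic-cohort generator for end-to-end validation.

Static functional connectivity averages away the moment-to-moment
reconfiguration of brain networks. CAP analysis instead treats single fMRI
frames as samples of transient whole-brain states: frames acquired while a
seed region (here, the bilateral precuneus/posterior cingulate hub of the
default-mode network) is highly active are selected and clustered, and each
cluster centroid — a CAP — is a recurring co-activation configuration. The
temporal statistics of CAP expression (how often, how long, how frequently
each pattern occurs) are interpretable per subject and can be compared
between groups, across paired sessions (e.g. before/after an intervention
such as a CSF tap test in normal-pressure hydrocephalus), and related to
behavior. `capdyn` implements this pipeline for researchers who want a
tested, scriptable reference implementation that runs on synthetic cohorts
with known ground truth.

## Method

For each scan with frames $x_t \in \mathbb{R}^V$ (gray-matter voxels,
motion-censored), the seed series $s_t$ is z-scored and frames with
$z(s_t) > 1$ are selected. Pooled selected frames from all training
subjects are clustered by k-means under a correlation distance (rows
standardized, squared-Euclidean equivalence); the z-scored centroids
$c_1,\dots,c_k$ are the CAPs. Per subject-session, with $S$ the selected
frames and runs defined as maximal sets of consecutive frames sharing a
label:

- occurrence$_c$ = $|\{t \in S : \ell_t = c\}| / |S|$
- duration$_c$ = mean run length of $c$ × TR (seconds)
- frequency$_c$ = number of runs of $c$ per retained minute

The number of clusters is chosen by consensus clustering: co-clustering
frequency across bootstrap subsamples, with every candidate CAP required to
be expressed in ≥ 90 % of subjects; among admissible k the largest k whose
within-cluster consensus is within 0.01 of the maximum is chosen.
Held-out (post-intervention) frames are classified into the pre-established
CAPs by maximal Pearson correlation.

Inference: ANCOVA (age, gender, education covariates) with Cohen's *d* for
group contrasts; paired *t* for pre/post shifts; Benjamini–Hochberg FDR;
voxel-wise group maps tested with Freedman–Lane permutations and
threshold-free cluster enhancement (TFCE,
$\mathrm{tfce}(v)=\sum_{h} e_h(v)^{E} h^{H} \, dh$ with E = 0.5, H = 2)
under a max-statistic family-wise null. Brain–behavior coupling uses
partial least squares correlation (PLSC): SVD of the z-scored cross-block
covariance $R = Y^\top X/(n-1)$, permutation p-values per component, and
bootstrap reliability intervals for the saliences after stepwise confound
removal.

Preprocessing of the registered 4D data follows the standard order:
nuisance regression (WM/CSF means, 6 motion parameters, 3 lowest-frequency
DCT components, optional global signal) → 6 mm FWHM Gaussian smoothing →
0.01–0.15 Hz band-pass. Framewise displacement (FD) uses the Power
convention (rotations × 50 mm); frames with FD > 0.7 mm are censored
together with 1 preceding and 2 following frames, and subjects retaining
less than 4 minutes are excluded.

## Worked example

The default configuration simulates the standard synthetic study: a
20×20×20 grid, 600 frames at TR 1 s, 20 controls (one session) and 20
patients (pre and post sessions), three planted CAPs with group and
session occupancy differences, behavior scores linear in the true
occupancies, nuisance drifts and motion spikes.

```python
from capdyn import StudyConfig, run_study

config = StudyConfig(rng_seed=42, n_perm=200, plsc_n_perm=200,
                     plsc_n_boot=200, voxelwise=True, tfce_steps=50)
state = run_study(config, outdir="out")

print(state.group_contrasts[["effect", "F", "p", "d", "fdr_significant"]]
      .round(4).to_string(index=False))
print(state.paired[["effect", "t", "df", "p", "d"]].round(4).to_string(index=False))
print(state.plsc_summary.round(4).to_string(index=False))
```

Output (about 2 minutes on one CPU):

```
         effect       F      p       d  fdr_significant
CAP1_occurrence 12.7034 0.0011  1.1503             True
CAP2_occurrence 15.6816 0.0004 -1.2781             True
CAP3_occurrence  0.1715 0.6813 -0.1337            False
active_fraction  0.0203 0.8876  0.0460            False

         effect       t  df      p       d
CAP1_occurrence -5.3664  19 0.0000 -1.2000
CAP2_occurrence  2.1101  19 0.0483  0.4718
CAP3_occurrence  3.5750  19 0.0020  0.7994

   domain  component1_p  fdr_adjusted_p  significant
     gait        0.0100          0.0398         True
     exec        0.3632          0.3632        False
   memory        0.3383          0.3632        False
attention        0.1741          0.3483        False
```

Reading the tables: the two planted group differences in CAP occupancy are
recovered with large effect sizes (|d| ≈ 1.2–1.3) and survive FDR; CAP
labels are ordered by pooled occurrence, so which planted state maps to
which CAP index varies between runs. The paired table shows the planted
post-session occupancy shifts in patients (df = 19 → 20 paired subjects),
and the PLSC summary shows that the behavior domain with the strongest
planted loading on CAP occupancies (gait) yields a significant first
component after FDR over the four domain-wise analyses.

The same pipeline is scriptable from the shell:

```bash
capdyn run-all --seed 42 --out out/        # full study from the default config
capdyn simulate --seed 5 --out cohort/     # write a cohort as NIfTI + TSV
capdyn sensitivity --seed 42 --out sens/   # k+1, parcellation, GSR variants
```

## Layout

- `capdyn.synthetic` — ground-truth CAP maps and cohort simulation
- `capdyn.preprocess` — FD/censoring, nuisance regression, smoothing, band-pass
- `capdyn.connectivity` — parcel time series, FC matrices, RSN aggregation
- `capdyn.caps` — frame selection, clustering, consensus-k, CAP metrics
- `capdyn.stats` — ANCOVA, paired t, BH-FDR, TFCE, permutation testing
- `capdyn.plsc` — PLSC with permutation and bootstrap inference
- `capdyn.workflow` / `capdyn.cli` — end-to-end orchestration

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
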