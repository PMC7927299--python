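# Methods

This note documents the models, algorithmic choices, and defaults behind
`capdyn`, and what the synthetic validation does and does not establish.

## The analysis model

CAP analysis assumes that a meaningful part of resting-state dynamics is
carried by transient, recurring whole-brain configurations expressed at
moments of high seed activity. The pipeline operationalizes this as:

1. **Frame selection.** The seed series (mean preprocessed signal over the
   seed voxels; by default two 6.25 mm spheres at the bilateral
   precuneus/posterior-cingulate coordinates (−5.7, −54.3, 34.1) and
   (7.5, −53.7, 31.2) mm, averaged into one series) is z-scored over
   motion-censored frames and thresholded at +1 SD. Only positive
   excursions are selected by default — the target phenomenon is seed
   *activation*; selection of negative events is available behind a flag.
   Replacing the seed by the whole-brain mean produces global-signal
   representation maps with the same machinery.

2. **Clustering.** Selected frames pooled over all training subjects (both
   groups) are clustered by k-means. Distance is correlation distance,
   realized by standardizing each frame to mean 0 / SD 1 so that squared
   Euclidean distance is an affine function of (1 − r); k-means++
   initialization, 20 restarts, deterministic given the seed. Cluster
   indices are ordered by descending pooled occurrence with a stable
   tie-break, and reported centroids are z-scored over voxels. Because the
   ordering is by occurrence, the mapping between planted states and CAP
   indices is data-dependent; comparisons against ground truth use
   maximal-correlation matching (solved as a linear assignment problem).

3. **Temporal statistics.** Occurrence is the fraction of selected frames
   assigned to a CAP; duration is the mean length of maximal runs of
   consecutive frames with the same label (censored gaps and unselected
   frames break runs) times TR; frequency is the number of runs per
   retained minute. These satisfy the exact identity
   occurrence = (mean run length × number of runs) / number of selected
   frames, which the tests enforce on random label sequences.

4. **Held-out classification.** Post-session frames are assigned to the
   pre-established CAPs by maximal Pearson correlation with the centroids
   (ties to the lower index; zero-variance frames are left unassigned with
   a warning), so pre/post comparisons use a common state definition.

## Choosing k by consensus

For each candidate k, the pooled frames are subsampled (80 % without
replacement, 100 subsamples by default) and re-clustered; the consensus
matrix holds the co-clustering frequency of frame pairs among subsamples
containing both (accumulated on a ≤1,500-frame reference subset to bound
memory). Stability is the mean consensus within the clusters of the
full-data solution. A candidate k is admissible only if each of its CAPs is
expressed (≥ 1 frame) in at least 90 % of subjects.

**Tie-break toward larger k.** Stability alone cannot separate k values at
or below the true state count: a consistent merge of two true states at
k = 2 reproduces perfectly across subsamples, so its stability equals that
of the true k. Stability only degrades once k exceeds the true count and
clusters start splitting noise. The chosen k is therefore the *largest*
admissible k whose stability lies within 0.01 of the maximum — the finest
equally-reproducible partition. The 0.01 tolerance absorbs Monte-Carlo
noise of the consensus estimate at the default subsample counts; bootstrap
fits use 4 k-means restarts so that stability reflects partition
reproducibility rather than optimizer noise.

## Preprocessing

Order is fixed: nuisance regression → spatial smoothing → temporal
band-pass. Censoring masks are computed from raw motion parameters but
applied only where frames are consumed (seed z-scoring, frame selection,
connectivity); regression and filtering always see the full series so that
gaps do not create filter transients.

- **FD** (Power convention): sum of absolute backward differences of the
  six motion parameters, rotations (radians) mapped to mm as arc length on
  a 50 mm sphere; FD[0] = 0.
- **Censoring**: FD > 0.7 mm drops frames {t−1, t, t+1, t+2}; subjects with
  under 240 s retained are flagged excluded. Censoring is idempotent.
- **Nuisance regressors**: WM and CSF compartment means (extracted before
  smoothing), the six motion parameters, the three lowest-frequency nonzero
  DCT-II vectors (frequency j/(2·N·TR), i.e. ≈ 0.0008/0.0016/0.0024 Hz for
  a 594-frame scan at TR 1.057 s), and optionally the global signal. An
  intercept is always included; zero-variance columns are dropped with a
  warning.
- **Smoothing**: per-frame Gaussian, σ = FWHM/2.3548 per axis in mm read
  from the affine; default FWHM 6 mm.
- **Band-pass**: 4th-order Butterworth, zero-phase (forward–backward) with
  reflection padding, 0.01–0.15 Hz. The filter order is a package choice;
  zero-phase filtering preserves event timing.
- An optional `drop_initial_frames` flag reproduces dummy-volume removal;
  the synthetic data contain no dummy frames, so it defaults to 0.

## Group and paired inference

ANCOVA is OLS of the outcome on intercept + group + covariates, with the
F(1, n−p) test on the group term; Cohen's d is the adjusted group
difference divided by the residual SD (a partial d; without covariates it
reduces to the classical pooled-SD d, and F equals the squared two-sample
t). Education enters as ordinal 1/2/3 and gender as binary 0/1. Paired
comparisons use the one-sample t on post − pre differences with
d = mean/SD of differences. BH-FDR uses the step-up rule (via statsmodels)
and is verified against a literal enumeration oracle.

**Voxel-wise testing** re-implements the contract of FSL randomise:
Freedman–Lane permutation (residuals of the covariates-only model are
permuted and re-fitted under the full design), TFCE enhancement
(E = 0.5, H = 2, 6-neighborhood connectivity, dh = max/100 by default;
negative values enhanced on the negated map), and a **two-sided max-TFCE
null**: each permutation contributes the maximum |TFCE| over the mask, and
both one-sided contrasts are compared against this common null. Pooling the
signs is what keeps the family-wise error of "any corrected p < .05 in
either direction" at the nominal level; testing each direction against its
own one-sided null would double it. Corrected p = (1 + #{perm max ≥
observed})/(1 + n_perm), floored at 1/(n_perm+1). Clusters of corrected
p < .05 larger than 20 voxels are reported per direction.

## PLSC

Blocks are column z-scored (ddof = 1); R = Yᵀ X/(n−1) is decomposed by SVD;
saliences are the singular vectors. Significance: permutation of the
behavior block's rows, comparing each permuted singular value to the
observed one (no Procrustes re-alignment — adequate for the first
component, which is what the domain analyses report; p-values for later
components are conservative and should not be over-read). Reliability:
subjects resampled with replacement; each resample is aligned to the
original solution by maximal-|correlation| component matching with sign
flips; a weight is "robust" when its 95 % percentile interval excludes
zero. Percentile intervals need not contain the original point estimate
under component rotation — robustness flags, not interval coverage, are
the inferential output. Confounds are removed beforehand by per-column
forward stepwise regression (entry p < .05, no removal step), applied
symmetrically to both blocks. Four domain-wise analyses (gait, executive,
memory, attention) are corrected by BH-FDR over their four first-component
p-values.

## The synthetic cohort

The generator plants k z-scored, spatially smooth (FWHM 3 voxels) CAP maps
on a gray-matter mask, sequentially decorrelated (pairwise |r| < 0.5) with
an identical positive seed plateau in every map — so seed events sample all
states with equal probability, which is the design assumption of seed-based
CAP analysis. Latent states follow a first-order Markov chain with
transition matrix pI + (1−p)·1πᵀ, whose stationary distribution equals the
requested occupancy π exactly; the persistence default p = 0.3 gives short
(≈1.4-frame) events. State frames express the corresponding map at
amplitude 1 over nuisance structure: a spatially weighted low-frequency
drift, an AR(1) global fluctuation, AR(1) WM/CSF compartment signals, a
constant offset, and i.i.d. Gaussian noise (default SD 0.5 = half the map
amplitude). Motion tables combine a slow random walk with single-frame
1.2 mm displacement jumps at 0.5 spikes/minute (Poisson), exercising the
1-back/2-forward censoring rule. The default occupancy gives the baseline
(no-CAP) state probability 0.5 and splits the active mass (0.40/0.33/0.27
in controls, reversed in patients pre-intervention, partially normalized
with a planted middle-CAP boost post-intervention). Behavior scores are
linear in the realized per-subject CAP occupancies plus Gaussian noise
(SD 0.5), with gait- and executive-like domains carrying strong sign-mixed
loadings. Cohorts are fully reproducible from one master seed via named
seed splitting.

**What the synthetic validation does not show.** Frames are linear state
expressions without hemodynamic convolution, physiological waveforms, or
EPI artifacts; "registration" is perfect by construction; WM/CSF
compartments are geometric conveniences. Passing tests demonstrate that the
estimators recover what the generative model plants at realistic noise
levels — not that the pipeline is robust to the full artifact spectrum of
real fMRI. Two measurement-model effects are worth knowing when reading
pipeline-level numbers: (i) centroids estimated from smoothed data match
the *smoothed* truth maps (r ≈ 0.95–0.98) and are bounded near r ≈ 0.9
against the unsmoothed maps; (ii) the 0.01–0.15 Hz band-pass removes most
spectral energy of 1–2-frame events, so frame selection on fully
preprocessed data admits some baseline leakage and attenuates group
effects relative to the ground-truth occupancies — as it would with real
short-lived events.

## Problem sizes and numerical choices

Simulation-based tests use reduced but faithful sizes chosen so the whole
suite runs on one CPU: 8–12-voxel grids, 100–250 frames, 20–40 subjects,
200 permutations/bootstraps where the analysis default is 1,000. The
full-scale default study (20×20×20 grid, 600 frames, 40 subjects,
voxel-wise testing included) runs in under two minutes and ≈5 GB. Ties in
frame classification resolve to the lowest CAP index; degenerate inputs
(empty selections, zero-variance frames/columns, singleton RSNs, collinear
covariates) return flagged results or warnings rather than silent numbers.
Correlations are averaged directly in RSN aggregation (Fisher-z behind a
flag); within-RSN averages exclude self-pairs.

## Known limitations

- Permutation inference for PLSC components beyond the first is
  conservative (no re-alignment under permutation).
- The consensus stability tolerance (0.01) is a heuristic for Monte-Carlo
  noise; very close competing k values may require more subsamples.
- Paired-session analyses assume the same CAP basis pre/post (post frames
  are classified, not re-clustered) — by design, matching the
  pre-established-states approach.
- The voxel-wise engine evaluates a single binary group contrast with
  covariates; general design matrices are out of scope.
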