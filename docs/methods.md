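# Methods

`rlbold` implements a complete analysis chain for flexible go/no-go odor
discrimination in head-fixed mice: a trial-by-trial reinforcement-learning
model of choice, hierarchical Bayesian estimation of its parameters, and a
model-based fMRI arm that locates and characterizes brain signals tracking
the model's decision variable. Because the in-vivo recordings the chain
was designed for are not bundled with the package, a synthetic-data layer
generates behavior and BOLD volumes with the same structure, which is also
what the test suite exercises. This note records the models, the defaults
and their rationale, the numerical choices, and what the synthetic data do
and do not establish.

## Task and behavioral simulation

The task is organised in 50-trial blocks, 25 presentations of each of two
neutral odorants in pseudo-random order (a uniform permutation of the
25+25 multiset; an optional `max_run_length` caps consecutive repeats,
off by default since no such constraint is documented for the task).
Each trial lasts 2.5 s: a 1-s odor pulse and a 2-s response window from
odor onset. Licking the go odor delivers a ~2.5-ul water reward
immediately; licking the no-go odor is unrewarded and never punished.
Inter-trial intervals are uniform on 5-12.5 s. In the reversal phase the
go/no-go roles of the two odorants swap; an optional never-rewarded
control (nitrogen) odor is supported as a third stimulus (0% of trials by
default, since its true frequency in the task is not documented).

One timing subtlety: the blocks are nominally six minutes, but 50 trials
at a minimum onset-to-onset spacing of 7.5 s (trial + shortest ITI)
necessarily span slightly more than 360 s. The generator therefore treats
`block_duration` as nominal metadata and enforces it only on request
(`enforce_block_duration=True` raises a configuration error naming the
violated constraint).

## The Q-learning model

The agent maintains a value Q(odor, action) for every odor (go-odor,
no-go-odor, control) x action (lick, no-lick) pair — six values in all,
initialized at zero and carried across sessions and the reversal boundary
without reset. After each trial only the realized pair is updated:

    Q <- Q + alpha * (r - Q),        alpha in [0, 1]

with reward r = 1 for a rewarded lick and 0 otherwise (including withheld
licks: not licking is one of the two actions and its value is updated,
toward zero, whenever it is chosen). The decision variable of the
presented odor o is

    dV = Q(o, lick) - Q(o, nolick)

and choice follows the logistic policy

    P(lick) = logistic(beta0 + beta1 * dV)

where `beta0` is a lick-bias intercept and `beta1` an inverse temperature
(unconstrained in sign; its prior is symmetric). The control odor's dV is
computed identically — its values only ever see r = 0.

Two consequences of this parameterization worth knowing:

- With binary rewards and zero initialization every value stays in
  [0, 1]. After a reversal, both values of the formerly rewarded odor
  decay toward zero, so that odor's dV approaches zero *from above*; it
  does not go negative. The behavioral signature of reversal is the
  ordering flip between the two odors' dV trajectories.
- On a stationary (acquisition-only) schedule the likelihood is nearly
  flat in alpha above the value that produces convergence before the
  session ends: once values have converged there is no further learning
  to observe. alpha is well identified only when the schedule contains a
  contingency change. Parameter-recovery studies in this package
  therefore use schedules with a mid-run reversal.

The likelihood forward pass is vectorized: within the subsequence of
trials on which a given (odor, action) pair is realized, the update is a
first-order exponential filter, so each of the six streams is evaluated
with `scipy.signal.lfilter` and scattered back onto the trial axis. A
trial-by-trial reference loop in the test suite checks exact agreement.
Lick probabilities are clipped to [1e-12, 1 - 1e-12] inside the
likelihood so extreme parameter proposals cannot produce -inf during
sampling.

## Hierarchical Bayesian estimation

Subjects are split into acquisition-only and reversal groups and each
group is fit independently (pooling would let the reversal group's extra
volatility inflate the acquisition group's learning rates). Within a
group, each subject's `(beta0, beta1)` is drawn from a bivariate normal
with mean `mu_beta` and covariance `diag(tau_beta) Omega diag(tau_beta)`;
learning rates are pooled through `alpha_s ~ Beta(a1, a2)`. Hyperpriors:
`mu_beta ~ Normal(0, 5)` (5 = standard deviation), `tau_beta ~
HalfCauchy(2.5)`, `Omega ~ LKJCorr(2)`, and `a1, a2 ~ HalfNormal(5)` —
half-normal because Beta shapes must be positive.

The joint posterior is sampled with an adaptive Metropolis-within-Gibbs
scheme on unconstrained coordinates (logit alpha, log tau, atanh rho,
log shapes, with the corresponding Jacobians). Each subject's three
parameters are proposed jointly (target acceptance 0.25); the seven
group-level parameters are proposed singly (target 0.44). Proposal scales
adapt in batches of 50 iterations during warmup only, so the retained
chain is Markov. Chains initialize at a coarse per-subject grid MLE with
per-chain jitter; group-level parameters initialize at moments of the
subject initializations. Default bookkeeping is 4 chains x 2000
iterations with the first 1000 discarded — 4000 retained draws per
parameter. Convergence is summarized by the rank-normalized split R-hat
(via `arviz`) with a 1.05 flag threshold; threshold violations and
low-acceptance chains are recorded as warnings in the fit metadata, not
fatal errors. A random-walk sampler mixes more slowly than a
gradient-based one, so R-hat values modestly above 1.05 on weakly
identified subject parameters are common at the default chain length;
point estimates (posterior means, used for the downstream regressors —
the conventional Bayes estimate, configurable) are stable in the
package's recovery tests.

## Synthetic BOLD and the hemodynamic model

The mouse hemodynamic response is modeled as a configurable double-gamma
kernel, default time-to-peak 1.0 s, scale 0.3 s, undershoot mode at 3 s
with ratio 0.2, 8 s total duration — fast dynamics appropriate for the
mouse. The kernel is peak-normalized to 1 and sampled on a fine grid
(default 10 Hz) so that event regressors honor sub-TR onset jitter before
resampling at the TR (2.5 s).

The simulator plants, in each ROI voxel of a desk-scale grid (default
16 x 16 x 8; the acquisition matrix is much larger but geometry is
configurable), `amplitude x (dV-weighted zero-duration stick train
convolved with the HRF)` on top of a baseline of 100, and adds structured
nuisance shared across voxels — low-order cosine drift, an AR(1) global
fluctuation with per-voxel loadings, motion-correlated signal from a
random-walk motion trace — plus AR(1) Gaussian voxel noise (default
autocorrelation 0.3). Framewise displacement follows the standard sum of
absolute derivatives with a 5-mm rotation arc radius; spike volumes can
be injected at configurable times. The simulator and the GLM construct
regressors through the same routine, so the noiseless recovery loop is
exact by construction — that is a feature (it isolates estimator errors
from discretization differences), but it also means the tests do not
probe mismatch between an assumed and a true HRF.

## First-level GLM

Events are zero-duration sticks at stimulus onset (the slow TR and fast
mouse HRF make stimulus, choice and feedback inseparable, so a trial is
one event). The decision-variable covariate is mean-centered over trials
before stick weighting — centering keeps the modulator from absorbing
the main onset effect — and optionally orthogonalized against the onset
regressor (off by default). Nuisance columns: global signal, ventricle
signal, six motion parameters and their first derivatives, one one-hot
spike column per volume with FD > 0.2 mm (the voxel size), run constants
for all runs except the last when sessions are concatenated, and an
intercept. Scrubbing by spike regressor is algebraically identical to
volume deletion for the remaining coefficients, which the suite verifies.
Estimation is plain voxelwise OLS (no prewhitening by default); the
design is checked for rank and rank deficiencies are reported with the
offending columns (all-zero columns, e.g. a constant-dV modulator, are
flagged rather than fatal). The subject-level contrast defaults to
selecting the `dv_modulator` coefficient.

## Group inference

The parametric route is a voxelwise one-sample t map (df = n-1;
zero-variance voxels flagged NaN) with Bonferroni voxelwise FWE control
and a cluster-extent filter (default 5 voxels). Bonferroni is exact and
conservative at desk scale; random-field corrections are deliberately
out of scope.

The nonparametric route is the exhaustive sign-flip permutation test:
under the null, subject contrast maps are symmetric about zero, so all
2^n sign assignments (64 for n = 6) are equally likely; beyond a
configurable cap (default n = 20) a seeded random subsample is used. For
each assignment the pseudo-t map — the t statistic with the
variance image Gaussian-smoothed (FWHM in mm, kernel truncated at 3 SD,
renormalized within the mask; FWHM 0 reduces exactly to the t map) — is
thresholded at the cluster-defining threshold and the maximum
suprathreshold cluster size recorded. Corrected cluster p-values are the
fraction of assignments whose maximum reaches the observed size, with
the observed labeling included (so p >= 1/2^n); the critical STCS is the
smallest size with corrected p <= alpha. Cluster connectivity defaults
to the 18-neighborhood (faces + edges; 6 and 26 available). Calibration
note: the permutation distribution of cluster sizes is discrete, so with
a very high defining threshold on few subjects no clusters form under
the null and the test is trivially (degenerately) conservative; the
package's calibration checks run at a low defining threshold where
cluster sizes take many values and the empirical level lands at the
nominal 0.05.

## ROI FIR analysis

ROI series are spatial means over a boolean mask. The FIR design places
one delta column per time bin per outcome condition (Hit / FA / CR /
Miss), with onsets shifted 5 s earlier to expose the pre-trial baseline;
the default window is -5 s to +15 s in TR bins (8 bins). The AUC of a
condition is the mean coefficient over post-onset bins — restrictable to
an integration window; with the fast mouse HRF the evoked response is
over within ~7.5 s, and bins beyond that add only noise to the summary —
minus the mean of the pre-onset bins (baseline subtraction is this
package's choice, toggleable). Paired condition comparisons use exact
small-sample nulls: the Wilcoxon signed-rank statistic against full
enumeration of the 2^n sign assignments (zeros dropped before ranking,
midranks on ties, normal approximation only beyond n = 20) and the sign
test against the binomial; two-sided p is twice the smaller tail,
capped at 1. A Holm step-down helper is provided for post-hoc families;
repeated-measures ANOVA is intentionally left to external tools, fed by
the tidy per-session AUC table.

## Problem sizes in the validation suite

The packaged checks run at the following scales, chosen to exercise the
study's structure at desk scale: hierarchical fits on 6 subjects x 300
trials (bookkeeping) and 5 replicates of 6 subjects x 1000 trials with a
mid-run reversal (recovery of alpha = 0.3, beta0 = -1, beta1 = 5);
permutation calibration on 200 pure-noise datasets of 6 subjects on a
16 x 16 x 8 grid; FIR direction recovery on 100 simulated blocks of
25 + 25 events at response amplitude 1.5x the series noise SD.

## Known limitations

- The synthetic BOLD generator shares its regressor construction with
  the GLM and uses a known HRF; it does not emulate HRF misspecification,
  spatial smoothing, registration error, or physiological noise spectra.
- The sampler is a random-walk scheme: effective sample sizes per draw
  are far below a gradient-based sampler's, and R-hat flags should be
  taken seriously before interpreting group-level scale/correlation
  posteriors, which are weakly identified with 6 subjects.
- ROI masks for synthetic runs come from the generator's ground truth;
  on real data they would come from thresholded group maps, which are
  not independent of the ROI analysis — a caveat of the original design
  that this package documents rather than fixes.
- alpha is weakly identified on stationary schedules (see above); fits
  to acquisition-only groups constrain it mostly from the early learning
  trials.
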