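# Methods

This note records the models, the synthetic study design, the numerical
choices, and what the desk-scale experiments do and do not demonstrate.

## Signal models

All forward simulation and the network's physics layer share one code path
evaluating the ideal spin-echo and magnitude inversion-recovery spin-echo
equations voxel-wise (`qmrsynth.physics`).  Magnitude reconstruction is
used for IR-SE because clinical FLAIR images are magnitude images; it
keeps the signal nonnegative and continuous (with a kink) across the
inversion null `TI = T1·ln 2`.  No scanner gain, flip-angle, B0/B1 or
k-space effects are modeled; the simulated scanner has unit gain, so
proton density is absolutely identified — on real data PD would only be
known up to the scanner scale.

The default protocol (ms) mirrors a 1.5 T brain study: T1w and T1w-c are
short-TE/TR SE (10/500), T2w long-TE/long-TR SE (100/8000), FLAIR IR-SE
(140/9000, TI 2200).  The long T2w repetition time makes the T2w signal
essentially independent of T1 (`TR/T1 ≳ 6` for all tissue classes), which
both matches late-echo clinical practice and gives the planted survival
signal (below) a clean channel separation.  T1w-c is the T1w sequence
applied to maps whose enhancing-tumor T1 is shortened by a factor 0.55,
standing in for gadolinium enhancement; post-contrast synthesis itself is
out of scope.

## Phantom cohorts

Each subject is a deformed-ellipsoid "brain" (GM rind, WM interior, CSF
ventricles) plus a nested tumor (NET core, ET shell, ED halo) confined to
one hemisphere so that contralateral white matter always exists.  Tissue
T1/T2/PD means are 1.5 T literature-typical (WM 600/80/0.70, GM
1000/100/0.85, CSF 4000/2000/1.0, tumor classes with elevated T2/PD); they
are free parameters of the generator, not claims about patients.  Per
subject the class means get 4% log-normal jitter and the maps a 4% smooth
log-normal texture; `T1 ≥ T2` is enforced by clipping and background
voxels are exactly zero.  Acquired images are the forward simulations
corrupted by Rician noise `sqrt((S+e1)^2 + e2^2)`, the correct magnitude
statistic; sigma = 0 reproduces the ideal images bit-for-bit.

### The planted survival signal

Survival follows a log-normal accelerated-failure-time law

    ln T = ln 480 + 0.10 − 0.30·z(log WT volume) + 0.65·z(c) + 0.35·ε,

with 10% independent censoring and dichotomization at 480 days (strict
`>`).  The covariate `c ~ U(−0.8, 0.8)` is the *correlation between two
smooth edema texture fields*.  The fields perturb (ln T1, ln T2) along two
direction vectors chosen orthogonal, in log-sensitivity space at the edema
operating point, to the T2w and T1w sensitivity vectors respectively.
Consequences, exact to first order in the texture amplitude (default
0.12; 0.20 in the strongly-planted desk study):

- T1w (and T1w-c) see only the first field, T2w only the second; their
  per-channel texture variances are independent of `c` — no single
  remaining channel can read the signal after FLAIR is dropped;
- FLAIR responds strongly to both fields, so its edema texture energy is
  linear in `c`: first-order statistics and GLCM features of FLAIR carry
  the survival signal;
- the voxel-wise map (T1w, T2w) → (T1, T2) remains invertible, so a
  network that learns the physics inversion reproduces the FLAIR texture
  — including its `c`-dependence — from the two input contrasts.

This is precisely the regime in which the replacement claim is
non-trivial: the information exists in the inputs jointly, the fixed
radiomic feature bank cannot extract it from them per-channel, and the
synthesized FLAIR makes it accessible again.  Whole-tumor volume provides
a second, channel-independent covariate so the ablated system (Experiment
III) is better than chance but clearly weaker.

## Synthesis network

2-D slice-wise (axial) processing on the package's NumPy reverse-mode
autodiff engine: dual encoders (two 3x3 conv + ReLU blocks per level, 2x2
max-pool), pixel-wise max fusion of all latent levels, and three decoders
(1x1 channel reduction, nearest upsampling, skip concatenation, conv
block) ending in per-map heads.  Map activations are scaled sigmoids onto
physical ranges — log-spaced for T1 (50–5000 ms) and T2 (10–2500 ms),
linear for PD (0–1.2) — because relaxation times span orders of magnitude
and a log parameterization makes multiplicative accuracy uniform.

The physics layer applies the signal equations to the predicted maps for
each supervised contrast and contributes no trainable parameters.  By
default the loss averages the per-image masked MAE over *all* acquired
contrasts with known parameters (the two inputs and the target), each
through its own physics layer.  Supervising the inputs as well as the
target is what identifies the three maps — a target-only loss admits a
two-parameter family of map combinations with identical target signal —
and it uses only weighted images, never map ground truth.  A target-only
loss remains available via `loss_contrasts`.

Inputs are the reference-normalized images (see below); supervision
targets are the acquired images in native units.  Optimization is Adam;
the reference learning rate is 1e-4, and the desk-scale configurations use
3e-3 because they take only a few hundred optimizer steps (larger rates
destabilize the wider networks).  Early stopping monitors the validation
`L_syn` with patience and restores the best weights.  Training is
deterministic given the seed; reproducibility of loss curves is asserted
at 1e-4 (float32 kernels).

Leave-one-out protocol: one model per held-out subject, the remaining
subjects split ~80/20 into train/early-stop validation (18/5/1 for a
24-subject cohort).  All folds share one init/batch-schedule seed so that
fold models differ only through their training data — with the very short
desk-scale trainings, per-fold init noise would otherwise dominate the
per-subject differences the experiments measure.

## Radiomic system

Normalization divides each volume by the mean intensity of white matter
contralateral to the tumor (hemisphere split along the first axis); the
contralateral-WM mean is exactly 1 afterwards.  Features per (contrast,
ROI): 13 first-order statistics, 6 GLCM features (16 gray levels, the
three axis-aligned unit offsets, symmetric accumulation), and per-ROI
shape descriptors (volume, face-count surface corrected by the standard
3/2 voxelization factor, sphericity) — ~400 named features whose
`contrast|roi|family|feature` columns make channel replacement and
ablation exact operations on the table.  This bank is deliberately small
compared with filter-bank radiomics platforms; what matters here is the
provenance structure, not the census of features.

mRMR uses plug-in mutual information on 8-bin equal-frequency
discretizations, lexicographic tie-breaks.  Nested CV: mRMR re-ranked
inside every outer training split; inner folds score (family, k)
candidates by Brier; one candidate per outer fold; the winner by
outer-fold AUC is refit on all training rows.  `outer_auc_mean_` (the mean
of the per-fold outer AUCs) is the unbiased cross-validated summary; the
winner's own outer AUC is a max-of-k statistic and is reported but not
used as a performance estimate.  Empty-ROI features are NaN and imputed
with the training-fold median inside each pipeline; the probability
threshold is fixed at 0.5.  Censored subjects with follow-up short of 480
days are excluded from labeling (their follow-up is uninformative for the
dichotomy); censored past 480 days are labeled long survivors.

## Experiments and desk-scale choices

Experiment I/II/III orchestration enforces the firewall structurally: the
RS classes are fit on acquired-image features of the training cohort only;
synthesized volumes enter only through the test-time feature table of
Experiment II, and an id audit hard-fails if a test subject appears in its
own synthesis fold.  Experiments I and II differ only in columns tagged
with the replaced contrast.

The reference study scale mirrors the emulated cohorts (120 training, 24
test subjects, 64x64x32 grids).  The desk configuration used by the test
suite and the acceptance script is scaled for a single CPU and emulates a
steady single-protocol cohort: 96 training / 10 test subjects on 32x32x10
grids with a prominent edema halo, strong planted texture (amplitude
0.20), and modest between-subject class-mean spread (1.5%) — large
between-subject spread acts as errors-in-variables noise for any
cross-subject voxel-wise inversion and attenuates synthesized texture
amplitude, which is why single-protocol cohorts are the natural setting
for this method.  The desk synthesis network is the pointwise variant
(kernel size 1, width 16): voxel-wise inversion is the correct inductive
bias at this scale and cannot blur texture.  Each LOO fold warm-starts
from one model pretrained on a disjoint subset of the training cohort
(id-audited) and fine-tunes two epochs at 2e-4; all folds share one init
seed, so fold models differ only through their data.  Early stopping and
init selection monitor a lesion-restricted validation loss — the global
MAE is nearly blind to the tumor region that the downstream radiomics
reads.  The RS sweep uses outer/inner folds 3/5, mRMR with 4 bins and
k in {2, 4} (coarse bins keep chance-level mutual information below the
true feature's on ~90-subject cohorts), and a logistic-regression grid
at C = 0.5 (the five-family grid is exercised by the nested-CV contract
test).  Rician sigma is 0.005 in the replacement study — the noise level
is the difficulty knob of Experiment II: the synthesized volume is
noise-free, so at higher sigma the noise-floor mismatch between acquired
and synthesized texture statistics, not synthesis quality, dominates the
probability disagreement (white matter is dark in FLAIR, so the
reference-normalized noise floor is several times the nominal sigma).
Map-recovery runs use noiseless 64x64x16 phantoms, ten for training and
two held out, also with the pointwise variant (the noiseless inversion is
voxel-wise by construction; the 3x3 U-Net reaches the same accuracy given
several times the training budget but is markedly more init-sensitive).

## What passing does and does not show

The phantoms demonstrate internal consistency of the full chain —
physics, self-supervised identification of maps, feature plumbing,
selection hygiene, and the replacement ordering — under a generative model
whose difficulty is controlled and whose ground truth is known.  They do
not demonstrate clinical performance: real tissue is not piecewise
log-normal, real acquisition includes bias fields, partial volume and
registration error, real survival signals are weaker and confounded, and
the feature bank and network are far smaller than production systems.
Quantities with small test cohorts (per-seed AUC and ICC on ten subjects)
are individually noisy; conclusions are drawn from means and win-counts
over ten independent cohort seeds.

## Known limitations

- 2-D slice-wise synthesis; no 3-D context.
- Single acquisition-parameter setting per study; the physics layer makes
  each trained model specific to its protocol.
- The mRMR implementation is the only selector (a second selector hook is
  a natural extension).
- ICC is the two-way absolute-agreement single-measure form only.
- float32 training kernels; bitwise reproducibility is only guaranteed on
  one BLAS build.
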