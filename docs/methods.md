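# Methods

## Problem

Repeated-measures movement datasets — many recorded trials per child —
invite a subtle but consequential analysis error. When individual
movements (*records*) of the same child are split across training and
test sets (**record-wise cross-validation**), a classifier can learn each
child's idiosyncratic movement signature and read the diagnostic label
off the identity rather than off any group-discriminating structure.
Apparent diagnostic accuracy is then inflated, sometimes to 1.0, while
true generalization to unseen children is at chance. **Subject-wise
cross-validation** (all records of a child in exactly one fold)
neutralizes the leak. `prograsp` implements the full pipeline needed to
demonstrate, quantify and guard against this *identity confounding* in
reach-to-grasp kinematics: feature extraction from 3D hand-marker
trajectories, both fold schemes plus a hybrid, subject-block permutation
nulls, and a hierarchical synthetic movement generator that makes every
stage testable without clinical data.

## Kinematic feature extraction

A trial is the 100 Hz trajectory of 8 hand markers (index MCP and tip,
little-finger MCP and tip, thumb, wrist, dorsum, hand reference) in mm.
The pipeline is:

1. **Gap handling** (reader): markers missing on ≤ 100 ms are filled by
   cubic-spline interpolation; a trial with any marker missing on more
   than 10% of frames, or with a gap over 100 ms, is excluded and
   enumerated in an exclusion log. The thresholds are our
   operationalization of "poor marker reconstruction"; both are
   configurable in `prograsp.io`.
2. **Filtering**: 2nd-order Butterworth low-pass at a nominal 6 Hz
   cutoff, applied forward and backward (zero phase, `filtfilt`), without
   dual-pass cutoff correction — standard motion-analysis practice.
3. **Derivatives**: wrist speed is the magnitude of the 3D first
   derivative of position; acceleration and jerk are successive
   derivatives of the scalar speed. Central differences interior,
   one-sided at the ends.
4. **Grip aperture**: Euclidean thumb–index-tip distance. **Wrist
   height**: z-coordinate of the wrist marker.
5. **Movement bounds**: the movement is the sustained (≥ 50 ms)
   above-threshold (20 mm/s) speed episode containing the global speed
   maximum; onset is its first frame, offset the first subsequent frame
   opening a sustained below-threshold run. Anchoring on the peak makes
   the rule robust to filter edge transients and rest-period jitter that
   can briefly cross the threshold; on clean profiles it coincides with
   the plain first-sustained-crossing rule. Threshold and sustain time
   are configurable.
6. **Time normalization**: each of the five variables is linearly
   interpolated at 10%, 20%, …, 100% of movement duration (deciles, not
   11 points including 0%), giving the 5 × 10 = 50 feature vector in the
   fixed order velocity, acceleration, jerk, aperture, height.

Wrist "velocity" is 3D tangential speed, not a single-axis component.

## Synthetic movement generator

The generator emulates the hierarchical structure the analyses assume,
not the biomechanics of a hand. Wrist transport follows a beta-family
speed bell `v(τ) ∝ τ^(a−1)(1−τ)^(b−1)` with `a+b = 6` and mode placed at
the trial's landmark fraction `c` (`a = 1+4c`); at `c = 0.5` this is
exactly the minimum-jerk speed profile with closed-form peak speed
`15·d/(8·T)`, which the tests use as a free oracle. Grip aperture opens
and closes along a unit-peak bump of the same family; the wrist arcs
vertically; six markers ride rigidly on the wrist while thumb and index
tip sit symmetrically about a grasp point at a separation equal to the
aperture curve. Stationary rest padding (0.4 s) surrounds the movement so
onset/offset detection is genuinely exercised, and isotropic Gaussian
jitter (0.5 mm, optical-capture magnitude) is added per frame.

Three layers of variation:

* **Subject signatures** — Gaussian random effects on duration (SD
  0.08 s), amplitude (15 mm), peak-speed timing (0.02 of duration), peak
  aperture (8 mm), aperture timing (0.02), arc height (6 mm), rest
  aperture (4 mm) and baseline wrist height (10 mm). The last two encode
  hand-size and posture idiosyncrasies; they were included because
  real children differ stably in hand geometry, and without them the
  generator's identity signatures were weaker than the near-perfect
  identity classification the regime is meant to exhibit.
* **Group effect** — ASD-like subjects reach their speed landmarks later
  by `group_timing_shift` (default 0.05 of movement duration, a small
  effect), optionally restricted to specific intentions.
* **Intention modulation** — population-level offsets on peak aperture,
  duration and landmark timing per onward action (place / pour / pass),
  so intention is decodable from the reach.

Trial-to-trial parameter jitter defaults to one tenth of the subject SDs
(the 10:1 identity-signature regime); the full design is 2 × 20 subjects
× 4 blocks (place, pour, pass, pass) × 10 trials = 1600 movements, with
both pass blocks sharing one intention label. The true subject-to-group
variance ratio of clinical data is unknown; these defaults are chosen
once to reproduce the qualitative regime the analyses presuppose
(record-wise and identity accuracy saturate, subject-wise accuracy is
moderate) and are labelled as such.

What the generator does **not** emulate: finger articulation, object
interaction forces, fatigue or learning trends across blocks,
non-Gaussian or correlated marker noise, and heterogeneous within-group
subpopulations. Passing tests therefore show that the *analysis
machinery* behaves correctly in the regime the data model assumes, not
that clinical effect sizes are as configured.

## Classification and cross-validation

Three families: Gaussian-kernel SVM (`svm-g`, default), L1-regularized
linear SVM (`svm-lasso`) and random forest (`rf`). Feature z-scoring is
fit on training records only. Hyper-parameters are tuned by nested CV:
within each outer training set, grid points are scored by
leave-one-fold-out accuracy over inner folds of the same scheme
(record-wise outer folds are reused as inner folds) and the winner is
refit on the whole training set. Default grids: C ∈ {0.1, 1, 10, 100} ×
γ ∈ 5 points log-spaced 10⁻³…10 for `svm-g`; 7 penalties 10⁻³…10 for
`svm-lasso`; 500 trees × max-features {√p, p/3} for `rf`. Ties break
toward the least complex model (smallest C, then smallest γ). A
single-point "reduced" grid (C = 10, γ = 0.02 for `svm-g`) skips the
inner loop and is used inside permutation loops.

Record-wise folds deal each subject's records evenly across k folds (4
per subject at k = 10, 1 at k = 40); the intention task uses
intention-balanced folds (one record per subject × intention cell per
fold). Subject-wise folds are leave-one-subject-out (LOSO) by default or
a group-balanced k-fold. Hybrid CV tunes record-wise inside a LOSO outer
loop, measuring what record-wise tuning costs on unseen children.

For the binary group task, a subject's predicted group is ASD when the
mean posterior score of its held-out movements exceeds 0.5; an exact tie
goes to TD (deterministic, conservative toward non-diagnosis). SVM
posterior scores are a logistic squashing of the signed decision margin
— monotone in the margin and exactly 0.5 on the boundary — rather than
Platt scaling, which would add an internal CV and a calibration step
that the averaged-posterior decision rule does not need; random forests
use their vote fraction. Accuracy is the mean over folds of the fraction
of correctly classified test-fold subjects; sensitivity and specificity
come from the pooled per-subject predictions (all held-out records of a
subject averaged). Multi-class tasks (intention, identity) score at the
record level. SEMs are bootstrap SDs of per-fold accuracies (1000
resamples).

## Permutation statistics

Significance against chance uses permutation nulls with the add-one
estimator p = (1 + #{null ≥ observed}) / (1 + n_perm), one-sided, which
never reports exactly zero and gives p = 1/101 ≈ 0.0099 when the
observed accuracy beats all 100 permutations. Group-task nulls permute
the diagnosis label **subject-as-block** (all records of a child flip
together): this preserves the identity–label confound while destroying
any label–movement relationship, so a *record-wise* null centred above
0.5 is direct evidence of identity confounding, while the *subject-wise*
null stays at chance. Intention nulls permute labels record by record.
Folds are always drawn from the original dataset's structure —
permutation shuffles labels within the CV design, it does not rebuild
folds around shuffled labels (intention-balanced folds would otherwise
be undefined under permuted labels). The confounding report flags
identity confounding when a one-sided one-sample t-test places the
record-wise null mean above 0.5 at α = 0.05.

The paired comparisons between schemes use two-tailed exact sign tests
on matched per-subject correctness (ties dropped); this pairing unit is
defined for every scheme, including LOSO where per-fold pairing is not.

## Numerical and design choices

* Movement-bound threshold 20 mm/s sustained 50 ms; both configurable.
* Degenerate inputs raise: all-quiet speed ("no movement"), speed never
  returning to rest ("no offset"), single-class training folds, fold
  counts that do not divide per-subject record counts.
* Learning curves draw nested group-balanced training sets per repeat
  (the 4-subject set is inside the 10-subject set, etc.) to reduce
  between-size sampling variance; odd sizes assign the extra subject's
  group at random. The record-wise variant trains on half of every
  held-out subject's records and tests on the other half, which is what
  lets signatures leak; the subject-wise variant never sees test
  subjects.
* All randomness flows through explicit `numpy` `Generator` objects;
  every experiment is reproducible from (config, seed).

## Problem sizes used in the checks

The test suite exercises the full 40-subject × 40-record design for the
dissociation phenomena and the learning curve (8 repeats, sizes 4/10/
20/39), a 20-subject × 20-record design for the 100-permutation null
geometry, and 50 replicate 8-subject null datasets with 50 permutations
each for the type-I-error check; permutation loops use the reduced
single-point grid. The acceptance script regenerates the full design and
reports record-wise group accuracy (nested tuning over a 2 × 2 grid),
identity accuracy, and both 100-permutation subject-block null means.

## Known limitations

* The generator's group effect lives entirely in landmark timing; real
  group differences may involve amplitude, variability or coupling
  effects the simulation does not produce.
* Posterior scores are uncalibrated monotone margins; they support the
  averaged-posterior decision rule but are not probabilities.
* The LOSO permutation null has the usual slight below-chance bias of
  leave-one-out schemes under exchangeable labels (a held-out subject's
  training set under-represents its own permuted label); with 40
  subjects the bias is within Monte-Carlo error of 0.5.
* Exclusion thresholds for poor marker reconstruction are conventions;
  recorded datasets with different capture quality may need different
  settings.
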