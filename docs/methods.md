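# Methods

`nirserp` implements a simultaneous fNIRS-ERP analysis of auditory sentence
processing, together with a synthetic cohort generator that produces data
with the statistical structure the analysis assumes. This note documents
the models, the defaults and why they were chosen, the numerical decisions,
and what the synthetic validation does and does not establish.

## Study design being modelled

A passive-listening event-related run: 48 sentences in each of three
conditions — syntactically *correct* (NP VP NP PP), *incorrect* with the
verb-object order swapped, and a verb-less *filler* — interleaved with 147
silent null events and 5 pure-tone vigilance probes. All 296 events occupy
fixed 4 s slots, giving a 1184 s run. Stimulus order is a seeded uniform
shuffle of the slot sequence; the null events scattered through the run
supply the inter-stimulus jitter. This is a deliberate simplification of
design-optimisation schedulers that operate on the same fixed slot grid.

Each sentence carries four phrases with mean durations 607, 497, 625 and
1149 ms; the word-order violation (if any) begins at the second phrase, so
ERP epochs are locked there. Only the means are specified, so per-trial
phrase durations are jittered multiplicatively (default ±10%, uniform).

Cortical recordings: per hemisphere a 3×5 pad of alternating sources and
detectors at 3 cm spacing yields 22 source-detector channels (12 horizontal
+ 10 vertical adjacencies), sampled at 10 Hz at 695 and 830 nm; EEG from
five scalp electrodes (Fz, Cz, Pz, F5, F6), two earlobe references and an
EOG channel at 500 Hz.

## Haemodynamic model

The HRF is the double-gamma

    h(tau_p, t) = t^tau_p e^-t / Gamma(tau_p+1)
                - t^(tau_p+tau_d) e^-t / (A Gamma(tau_p+tau_d+1))

with first-peak latency `tau_p` (s), undershoot delay `tau_d` (s) and peak
ratio `A`; canonical values (6, 10, 6). Factorials are generalised through
the gamma function so non-integer latencies are legal; `h(0) = 0` exactly
and the kernel is truncated at 60 s, where it is below 1e-6 for all
latencies on the sweep grid.

The GLM regressors are condition boxcars (1 during the 4 s trial, half-open
`[onset, onset+duration)`) convolved with `h` sampled at 10 Hz, plus a
constant. Correct/incorrect/filler are regressors of interest, the tone
probes a nuisance regressor, and null events span the unmodelled baseline.
Estimation is ordinary least squares with per-regressor t statistics from
the residual variance and `inv(X'X)` diagonal.

### Latency sweep and selection

Because a canonical 6 s peak need not fit an adolescent population,
`tau_p` is swept over the integer grid 3-20 s (step 1 s — the grid is
described only by its endpoints, and the latency prior is coarse), the
whole GLM refit per latency, and amplitudes grand-averaged over subjects
and the three sentence conditions (tones and nulls excluded — they index
vigilance, not sentence processing). The optimal latency is the mean of the
argmax latencies of a reference channel (default channel 16, the channel
over auditory cortex) in the left and right hemispheres, rounded half-up to
the grid when fractional; argmax ties break toward the smaller latency.
The rule is trusted only when the reference channel sits within the top
10% of per-hemisphere peak amplitudes, and the selection report records
that check together with both hemisphere argmaxes and the rounding flag.

A property worth knowing: the kernel keeps unit *area*, not unit norm,
across the sweep, so a weak channel's amplitude-vs-latency argmax can sit
one grid step above the generating latency depending on the design
randomization. The reference-channel rule is robust to this in practice
(exact recovery in all seeded checks; the package's recovery criterion is
±1 s in ≥90% of replicates), but per-channel argmax maps should be read
with a one-step grain of salt, and sparse designs make it worse.

## Optical preprocessing

* **MBLL** — per channel and sample, the 2×2 linear system
  `dOD(lambda) = eps_oxy(lambda) dHbO + eps_deoxy(lambda) dHbR` is solved
  for the haemoglobin changes. Differential pathlength stays folded into
  the mM·mm output units, as continuous-wave instruments report. The
  packaged extinction table holds standard tabulated coefficients at
  695/830 nm; its condition number is checked at load.
* **Detrending** — default is a deterministic projection onto the
  complement of a low-frequency basis: DCT-II cosines below 1/128 Hz plus
  an explicit linear term. The linear term matters: the pure cosine basis
  leaves ~1% of a linear ramp at the series edges, while the augmented
  projection removes constant and linear drift exactly and is exactly
  idempotent. The alternative `wavelet_mdl` method subtracts the DWT
  approximation branch with the decomposition depth chosen by a
  minimum-description-length cost, `(n/2) log(RSS/n) + (k/2) log n`, over
  levels; because the approximation branch is only approximately a
  projection (boundary leakage), the removal is iterated four times at the
  chosen depth to reach near-idempotency. This is a documented stand-in
  for more elaborate wavelet-MDL detrending schemes: same purpose, simpler
  contract.
* **Precoloring** — both species are convolved with the unit-sum canonical
  HRF. The same kernel is applied to the design-matrix task columns
  (matched filtering), which keeps noiseless amplitude estimates exactly
  unbiased; a data-only mode is available but not default.

## ERP pipeline

Linked-earlobe re-reference (mean of the two earlobe channels subtracted
from every scalp channel), then run-wise EOG regression — per scalp
channel, subtract `b·EOG` with `b = cov/var` over the whole run; this is a
transparent replacement for vendor-proprietary ocular-reduction algorithms
and removes planted blink leakage to residual correlation < 0.05 in
simulation. The 30 Hz/12 dB low-pass is read as a second-order Butterworth
(12 dB/octave) applied forward-backward: zero phase, effective attenuation
doubled. The 0.1-100 Hz acquisition band-pass is assumed already applied
by the recording hardware.

Epochs run −200…+1000 ms around the second-phrase onset (600 samples at
500 Hz); the mean over the pre-onset window is subtracted per epoch and
channel. Epochs exceeding the recording bounds are dropped and counted.
Rejection (any scalp sample beyond ±100 μV) runs after filtering and
baseline correction — the ordering is a package decision; rejecting on raw
data would trip on blink leakage the EOG regression removes. Window means
use half-open `[start, end)` windows over phase 1 (100-300 ms), phase 2-a
(300-450 ms), phase 2-b (450-600 ms) and phase 3 (600-800 ms).

Group inference is a split-plot ANOVA — sex between subjects,
grammaticality (2) × electrode (5) within — computed by projecting each
subject's within-cell vector onto orthonormal (Helmert) contrasts per
effect and taking Type III sums of squares on the contrast scores, which
is exact for this balanced-within, unequal-group design and was verified
against an independent multivariate-model decomposition (R `car::Anova`,
type III univariate table) to printed precision. Greenhouse-Geisser
epsilon comes from the pooled within-group covariance of each effect's
contrast scores (equivalently, the double-centered level covariance),
clipped to `[1/(k−1), 1]`, and corrects every effect whose contrast space
has more than one dimension. Partial eta squared is
`SS_effect/(SS_effect+SS_error)`. Post hoc contrasts are paired t per sex
(incorrect − correct, averaged over electrodes) with pooled-SD Cohen's d,
and Welch t between sexes; no further multiplicity correction is applied
at the post hoc level.

## Channel-wise group statistics

Activation maps are one-sample t tests on per-subject amplitudes.
Proficiency maps are per-channel Pearson correlations of amplitude with
the grammar-listening percent score, computed per sex and condition;
partial-correlation maps control for the reading-span score through the
first-order formula `(r_xy − r_xz r_yz)/sqrt((1−r_xz²)(1−r_yz²))` with
`n−3` degrees of freedom (verified to 1e-10 against the
residual-on-residual construction).

Multiplicity over the 44 channels uses the Dubey/Armitage-Parmar boundary
`alpha_adj = 1 − (1−alpha)^(1/m^(1−r_bar))`, which interpolates Šidák
(`r_bar = 0`) and no correction (`r_bar = 1`). `r_bar` is the mean pairwise
Pearson correlation between channels' subject-level amplitude vectors,
pooled over conditions and sexes; negative pairwise correlations enter as
signed values and a negative mean is floored at zero for the formula (the
report flags flooring). At m = 44, `r_bar` = 0.385, alpha = 0.05 the
boundary gives 0.005.

ROIs grow from seed channels below the adjusted threshold to grid-adjacent
channels below a secondary 0.05 threshold, iteratively (secondary channels
adjacent to already-grown members join too), then merge into maximal
connected components. Adjacency is "the two channels share an optode" —
the combinatorial nearest-neighbour relation on the channel lattice, which
works for 2-D pads and degenerate 1-row layouts alike; hemispheres never
merge. The ROI-level statistic correlates the member-averaged amplitude
with the score (averaging amplitudes, then correlating — not averaging
member correlations; the alternative was considered and rejected as it has
no associated sample of subject-level values).

## Synthetic cohort generator

Defaults encode the study conditions: 31 boys and 22 girls; behavioral
percent means/SDs Grammar_L 54.44 ± 13.31, Grammar_R 75.60 ± 21.04, KET_L
43.25 ± 22.16, KET_RW 42.89 ± 19.02, reading span 51.89 ± 7.85 raw of 70;
girls-minus-boys standardised gaps 0.98 (Grammar_L), 0.76 (KET_L), 0.82
(RST), zero for the untested gaps; span-grammar correlation 0.672 in
girls, 0.042 in boys. Scores follow a one-factor model per sex (the
standardised grammar-listening score is the factor; the printed pooled
correlations serve as loadings), drawn from truncated normal families by
rejection resampling — resampling, not clipping, preserves the correlation
structure. Because rejection preferentially discards extreme rows and
thereby shifts every correlated test, the generating means are first
calibrated on a large internal draw (three fixed-point iterations on a
separate stream) so post-truncation means match the configured values.
The pooled SDs are used as within-sex SDs — the study prints no within-sex
decomposition. Raw scores are kept continuous (`percent × max/100`);
integer rounding would perturb the calibrated correlations.

True haemodynamic amplitudes:
`beta = base(condition) · gain(channel) + slope(sex, condition, region) ·
hemisphere_gain · z(Grammar_L) + subject noise`, with the slope sign map
boys-correct anterior-positive, boys-incorrect globally negative,
girls posterior-positive for both conditions (anterior/posterior is a
front/back split of the pad at the grid midline — a labelling convention,
not anatomy). `gain(channel)` is a Gaussian bump (boost 2.5, sigma 3 cm)
centred on the reference channel's lattice position: auditory stimulation
drives the channels over auditory cortex hardest, and without this profile
no channel could satisfy the top-10% reference check. Default magnitudes —
base 0.02 mM·mm, slope 0.015 per score SD, subject noise 0.008, left
hemisphere gain 1.0 vs right 0.7, deoxy = −0.3 × oxy — are in the range
typical of event-related oxy-Hb responses and were fixed once at design
time. fNIRS noise: cardiac 1.1 Hz, respiratory 0.25 Hz, Mayer 0.1 Hz
sinusoids with per-channel random phase and amplitude jitter, a random
linear drift plus random walk, and white noise. The forward MBLL model can
emit two-wavelength optical density for end-to-end runs.

EEG: pink (1/f) plus white background per scalp channel, a shared auditory
evoked response at every sentence onset (identical across conditions, so
it cancels in grammaticality contrasts), and a Hann-windowed negativity on
incorrect trials — boys spanning 100-800 ms post violation
(anterior-weighted, −2.5 μV), girls confined to 450-600 ms
(centro-parietally weighted, −2 μV). Blinks are Gaussian pulses on the EOG
channel leaking to frontal channels with fixed coefficients; a
configurable fraction of sentence trials (default 5%) carries a >100 μV
artifact burst for the rejection stage.

### What the synthetic validation shows — and does not

Passing tests establish that the pipeline recovers planted structure:
noiseless amplitudes exactly, the generating peak latency within ±1 s in
≥90% of replicates under structured noise, the planted correlation signs
on ≥80% of effect channels over 20 cohorts, and the sex-specific ERP phase
pattern at the study's sample size. They do not establish performance on
real data: the generator's noise is stationary and sinusoidal where real
physiology drifts and couples across channels; motion artifacts, optode
decoupling, and non-linear blink propagation are absent; the one-factor
behavioral model is a convenience; and the anterior/posterior split is a
grid convention, not anatomy. Problem sizes in the test-suite (20-subject
sweeps, 6-trial unit fixtures) were chosen as the smallest sizes at which
each property is comfortably identifiable.

## Numerical conventions

Time is in seconds, 0-based, half-open intervals throughout. Channel names
are `{L|R}-{1..22}`, row-major per hemisphere, so "channel 16" is
addressable on both sides. Seeds: every generator is a pure function of
(config, seed); cohort-level runs derive per-subject seeds from a
`SeedSequence` so subjects are independent but reproducible. Degenerate
inputs fail loudly: singular extinction matrices, rank-deficient design
matrices (with the collinear columns named), constant scores, covariates
collinear with a variable, and zero-variance t tests (flagged, with the
sign-appropriate degenerate p).

## Known limitations

No prewhitening or AR noise modelling (precoloring is the chosen
autocorrelation treatment); no subject-level latency estimation; no motion
correction or short-separation regression; no source localisation or
anatomical registration (region labels are grid conventions); SNIRF/EDF
containers are not read or written — the canonical interchange format is
wide TSV with a JSON sidecar.
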