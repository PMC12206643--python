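# Methods

This note documents the model, the synthetic study conditions, the numerical
choices, and the limits of what the bundled experiments demonstrate.

## Differential-entropy features

The feature of record is differential entropy (DE) per window, channel and
band. For a band-limited EEG window the signal is modelled as Gaussian, for
which DE has the closed form ½·ln(2πeσ²) (nats), σ² being the window's
sample variance (population normalization). The implementation *is* the
closed form; a histogram plug-in estimator of differential entropy exists in
the code base purely as a test oracle. A discrete Shannon sum over raw µV
values is not well defined without a binning rule, which is why the Gaussian
reading — standard in this literature — is used. Windows with variance below
1e−12 are rejected as degenerate rather than returning −∞.

Two identities anchor the tests: DE is strictly increasing in σ², and
DE(a·x) = DE(x) + ln|a| exactly.

Band edges are the conventional split: theta 4–8, alpha 8–13, beta 13–30,
gamma 30–45 Hz (configurable). Filtering is a 4th-order Butterworth,
applied forward-backward (zero phase). The 8×9 electrode grid follows the
convention row 0 = frontal, column 0 = left hemisphere; the shipped
62-channel assignment (10 empty cells) is this package's own documented
default — there is no canonical published table for the 8×9 arrangement.
The tensor axis order is (time step, row, column, band), i.e. an 8×9
spatial map with 4 band channels, stacked over T = 6 one-second windows.

**Fragmentation.** `assemble_4d` supports any stride; the default experiment
uses stride = T (non-overlapping 6-s fragments). Overlapping fragments share
windows, and under sample-level k-fold CV that would leak test information
into training; non-overlapping fragments keep folds independent.

**Normalization.** All of a subject's tensor values (electrode-backed cells
only) are z-scored with that subject's own mean and standard deviation;
structurally empty cells stay exactly zero. This targets inter-subject
amplitude/baseline differences and is applied identically in both
evaluation protocols (the test subject's statistics require no labels).

## The fusion network

Two streams read the same `(6, 8, 9, 4)` sample:

* **CNN-BiLSTM.** Each time-step map passes through conv(3×3, SAME) → ReLU
  → max-pool(2×2, ceil) blocks — the same parameters for all six steps
  (weight sharing is asserted by test) — then a bidirectional LSTM over the
  six step features. The standard gate recursion is used (forget/input/cell/
  output); the final forward and backward hidden states merge by
  concatenation (default), summation, or averaging. Average ≡ sum/2 by
  construction.
* **DC-IGN stream.** The sample is reshaped to an (8, 9, 24) volume (time
  folded into channels) and encoded by strided SAME convolutions into a
  diagonal Gaussian posterior q(z|x) = N(μ, σ²I), parameterized as
  (μ, log σ²). Sampling uses the reparameterization z = μ + σ⊙ε. The
  decoder mirrors the encoder: dense → nearest-neighbour upsampling →
  convolutions, back to the input volume. The original DC-IGN ladder (five
  5×5 stride-2 layers, channels 64–1024, a 7×7×1024 map, 256-d latent) is
  built for ~224×224 images and cannot act on an 8×9 grid; it remains
  expressible through `ModelConfig` for image-sized inputs, while the
  default is a scaled ladder of the same family.
* **Fusion.** concat(temporal feature, μ) → dense(ReLU) → softmax. Fusing
  the latent *mean* rather than a sample keeps evaluation deterministic;
  sampling happens only inside the training loss. Whether the probabilistic
  stream should see raw features or CNN outputs is an open design point;
  it sees the raw stacked features here, so the two streams are
  complementary rather than nested.

The loss is `CE + λ·MSE(x′, x) + β·KL(q‖N(0,I))` with λ = β = 1 by default:
MSE is averaged per element (so its scale matches CE on z-scored features)
and KL is the per-sample sum over latent dimensions, batch-averaged, in the
closed form ½Σ(μ² + σ² − 1 − ln σ²).

Everything is implemented directly on NumPy — forward passes, analytic
backpropagation, Adam (β₁ = 0.9, β₂ = 0.999) — and the gradients are
validated against central finite differences at relative error < 1e−4 on a
tiny configuration. The check runs at a generic parameter point: with
freshly initialised zero biases, entire ReLU pre-activation regions sit
exactly at the kink where the loss is genuinely non-differentiable, so the
parameters are jittered first.

## Learning-rate policies

Five closed-form policies, evaluated at epoch granularity (the simplest
reading of adjusting the rate "in different periods of training"):

| kind | lr(e) |
|---|---|
| constant | lr₀ |
| piecewise exponential | lr_enter(i) · γᵢ^(e−eᵢ) within segment i, continuous at boundaries |
| cosine annealing | lr_min + ½(lr₀−lr_min)(1 + cos(πe/T_max)) |
| stepped | lr₀ · γ^⌊e/s⌋ |
| linear | lr₀ + (lr_final−lr₀)·e/E |

No numeric schedule hyperparameters are canonical for this model family;
the defaults (lr₀ = 1e−3; piecewise boundaries at 40%/75% of the horizon
with per-epoch γ = 1.0/0.95/0.90; stepped γ = 0.5 every quarter; cosine
floor lr₀/100; linear floor lr₀/100) are this package's own and are fully
configurable. The schedule-comparison harness demonstrates a directional
property only: when lr₀ is set an order of magnitude above a well-tuned
value, the decaying policies end at a training loss no worse than the
constant policy.

## Synthetic study conditions

Each trial is a sum over bands of band-pass-filtered Gaussian noise, scaled
per channel so that band power equals

    base(band) · class multiplier(band, region) · exp(subject offset(band))
    · trial jitter,

plus white baseline noise, times a per-channel subject gain. Regions are
frontal / central / posterior row-blocks of the grid. Because the noise is
Gaussian and band-limited by the same filters the feature stage uses, the
Gaussian DE closed form is approximately exact on these signals, and
class-to-class band-power ratios are controlled analytically (verified by a
Welch-periodogram oracle to within 10%).

Default conditions: 8 subjects × 3 classes × 20 trials of 60 s at 200 Hz,
seed 42 → 480 trials → 4800 non-overlapping fragments. The three classes
have distinct region×band signatures (frontal β/γ emphasis with posterior α
suppression; flat; posterior α emphasis with frontal θ), multipliers 0.7–2.5.
A binary low/high-valence pair is also shipped, standing for a continuous
valence score thresholded at its midpoint.

Subject heterogeneity: per-channel lognormal gain (sd 0.4 in log), baseline
noise sd drawn from 1–3 µV, and a per-band log-power offset per subject.
The offset scale is the lever that separates the two protocols: it was set
(once) so that between-subject variability is comparable to the class
effect, the regime real EEG occupies — several-fold between-subject
band-power differences are routine. Under subject-dependent CV the model
sees every subject in training and absorbs these offsets; under LOSO it
cannot, so LOSO accuracy sits strictly and visibly below the
subject-dependent figure while the class signal remains recoverable. Trial
jitter (lognormal, sd 0.15) adds within-subject spread to both protocols.

What the generator does **not** emulate: 1/f spectral slopes, ocular/muscle
artifacts, electrode drift, volume-conduction correlation structure between
channels, or non-Gaussian waveforms. Passing the bundled experiments
therefore shows the pipeline recovers *engineered* band-power structure
under realistic subject/trial variability — it says nothing about accuracy
on recorded human EEG, and the headline accuracies reported for licensed
datasets in the literature are not reproducible from this package.

## Experiment sizes and determinism

The default experiment preset uses a compact network (CNN channels 16→32,
BiLSTM hidden 32, DC-IGN channels 16–32–64, latent 32, fusion 64) trained
for 8 epochs with batch 64 — sized for a single-CPU desktop run; the class
structure converges within 2–3 epochs at these conditions. The module-level
defaults are wider (32→64, latent 64, 80 epochs) and fully configurable.

Every experiment is a pure function of its config: the dataset derives from
the dataset seed through a spawned seed tree; fold assignment from the
split seed; initialization, batch order and VAE noise from a per-fold seed
derived from the train seed. Re-running a config reproduces the report and
all training histories bit for bit. Degenerate inputs (constant windows,
zero-variance subjects, empty splits, non-finite losses) raise typed errors
rather than propagating NaNs.

## Known limitations

* The analytic-gradient implementation targets clarity over speed; it is
  single-threaded NumPy and not suitable for image-scale DC-IGN configs.
* Adaptive per-subject feature recalibration (dynamically re-weighting
  features from subject-derived statistics) is not implemented — no
  concrete formulation exists to implement.
* LOSO accuracy on the synthetic conditions varies noticeably across
  subjects (the per-subject offset draw is the dominant factor), mirroring
  the large per-subject spread reported for real subject-independent EEG
  evaluation. The LOSO *mean* consequently also moves by several points
  across dataset seeds (roughly the high-70s to high-80s, %): eight
  subjects are few, and one or two hard offset draws dominate the average.
* Std is reported across CV folds; for LOSO this coincides with the
  across-subject spread, and the per-subject table is reported separately.
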