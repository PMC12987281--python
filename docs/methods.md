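# Methods

## The muscle–bladder pressure model

`pneumyo.bladder` models a looped air bladder worn circumferentially on the
distal thigh. Fully inflated, the bladder is idealized as a cylinder of
cross-sectional diameter *D* and axial loop length *L*, giving a gas volume
*V = πD²L/4*. With the default *D* = 20 mm and *L* = 300 mm this is
94,247.8 mm³.

The sensing principle rests on three assumptions:

1. **Shared cross-section.** Muscle and bladder together occupy a constant
   cross-sectional area, so a muscle contraction *dA_m* forces an equal and
   opposite bladder area change *dA_b = −dA_m*.
2. **Single contracting region.** At any instant one muscle group contracts;
   the bladder splits into a contracting region (area *A_b*, pressure *P_b*)
   and a rest region (*A_u*, *P_u*), connected through the bladder's
   interior so pressure equalizes quickly to a common *P_t + dP_t*.
3. **Isothermal gas.** The thin TPU wall sits against skin, a
   constant-temperature reservoir, and the thermal time constant is short
   relative to a movement cycle, so each region's trapped gas obeys
   *P·A* = const per unit length.

First-order expansion of the isothermal balance yields the linear maps

* *dA_b = −(A_b/P_b)·dP_b* (local) and *dA_b = −((A_b+A_u)/P_t)·dP_t* (total),
* hence *dP_b = P_b(A_b+A_u)/(P_t·A_b)·dP_t*,

and, with a series-elastic tendon of stiffness *k* and a muscle of initial
length *x* and cross-section *A_m*,

* *f_m = k·A_b·x/(P_b·A_m)·dP_b = k·(A_b+A_u)·x/(P_t·A_m)·dP_t*.

The flat-text source equations do not disambiguate operator grouping; the
grouping above is the unique one under which the total-pressure law is
*exactly* the local law composed with the total-to-local map, which the
test suite asserts to 1e−12 relative error. Because the laws use
area and pressure *ratios*, *k* (N/mm) times *x* (mm) carries the units and
the result is in newtons with no explicit kPa·mm² conversion.

`equilibrium_oracle` implements the exact (non-linearized) isothermal
redistribution *P_new = (P_b A_b + P_u A_u)/(A_b + A_u + dA_b)*. Relative to
this oracle the linearized *dP_t* has relative error exactly
|dA_b|/(A_b+A_u) for a uniform start, i.e. ≤ 1% for contractions up to 1% of
the total area, and the *absolute* error decays quadratically with
contraction size (log–log slope 2). Pressures are the model's gauge-offset
absolute values used multiplicatively, exactly as the algebra requires; no
atmospheric offset is added. This is a documented limitation, not an
oversight: adding 101.3 kPa would change every ratio and the model is
calibrated against the printed magnitudes as-is.

## Synthetic pressure traces

`pneumyo.synth` generates labeled 100 Hz pressure streams for six
locomotion modes on a 20 or 30 kPa baseline. The per-mode parameters are
**synthetic design choices** — the source measurements are qualitative
waveform shapes only — chosen to respect the qualitative ordering of
cadence and amplitude across modes:

| mode | cadence (Hz) | amplitude (kPa) | shape |
|---|---|---|---|
| standing | – | 0 | flat baseline |
| walking | 0.9 | 1.5 | sinusoid + 2nd harmonic |
| jogging | 1.4 | 3.0 | sinusoid + 2nd harmonic |
| uphill | 0.85 | 2.5 | strongly asymmetric (2nd+3rd harmonic) |
| stairs | 0.7 | 3.5 | surged cycle; landing cycles walking-like |
| squatting | 0.1 | 6.0 | 3 s raised-cosine surges, rest at baseline |

Stair streams are built cycle-by-cycle: each cycle is independently drawn
walking-like with probability `landing_fraction` (default 0.15), emulating
the walking strides across stair landings that contaminate stair-labeled
data. Landing cycles reuse the walking profile verbatim, so windows lying
fully inside them are *by construction* indistinguishable from walking —
the honest reading of "highly similar". Noise is additive white Gaussian
(default sd 0.1 kPa, a compensated MEMS sensor's stationary noise) plus an
optional linear drift (default 0 kPa/min). All draws derive from an
explicit seed; traces are bit-reproducible.

What the generator does **not** emulate: biomechanically calibrated
waveforms, stride-to-stride timing variability, subject differences, sensor
quantization, or motion artifacts. Passing classifier tests on these
streams therefore demonstrates that the pipeline and model are correct and
can exploit cadence/amplitude/shape differences; they say nothing about
accuracy on real recordings.

## Physiological processing

`pneumyo.physio` implements the sEMG linear-envelope chain — MVC
normalization, 20–500 Hz band-pass, full-wave rectification, 6 Hz low-pass
— with 4th-order Butterworth filters applied forward–backward
(zero-phase), the standard choice where only pass-bands are specified.
The EMG sampling rate defaults to 2000 Hz and must exceed twice the upper
band edge. Post-smoothing negative excursions are clipped at zero.

Net metabolic cost uses the Brockway energy equivalents: gross power =
(16.58 kJ/L·VO₂ + 4.51 kJ/L·VCO₂) per minute converted to watts, divided by
body mass, minus the standing baseline (W/kg). A respiratory exchange ratio
outside [0.6, 1.3] triggers a warning. The CLI averages the final 2 min of
a breath file by default, exposed as a windowing parameter. Gait-cycle
curves are linear resamplings of each cycle to 101 points (0–100%),
averaged across cycles with a per-point SD.

## Dataset pipeline

Streams become training data in this order: (1) a threshold filter applied
to squat-labeled samples only, removing values strictly below the static
baseline — it isolates active squats from between-repetition standing;
(2) sliding-window segmentation, 50-sample (500 ms) windows at a 5-sample
(50 ms) stride — the stride is unstated in the source and chosen to yield
datasets of a realistic size from feasible recording durations; (3) window
labels by majority vote (≥ 50%), windows without a majority dropped rather
than mislabeled; (4) per-class balancing to an exact target (seeded
down-sampling without replacement / up-sampling with replacement);
(5) a seeded per-class 80/20 stratified split (floor on the test side);
(6) global scalar Z-score standardization **fitted on the training portion
only** and applied unchanged to the test portion. Fitting before the split
would match the source's sentence order but leaks test statistics; for a
single global scalar the numerical difference is negligible and the
leak-free order is preferred.

## Classifier

`pneumyo.network` implements the lightweight hybrid network in pure numpy
(forward pass, analytic backpropagation, Adam): conv1d (48 filters, kernel
4, valid padding, ReLU) → max-pool 2 → LSTM 24 (full sequence) → dropout
0.3 → LSTM 12 (final state) → dropout 0.3 → dense softmax over 6 classes.
Conventions: Glorot-uniform kernels, orthogonal recurrent kernels,
forget-gate bias 1, gate order i/f/g/o, tanh/sigmoid activations, inverted
dropout active only in training, Adam at step size 0.001 (no early
stopping). Gradient correctness is enforced by central finite differences
in the test suite; training is deterministic given the seed.

Parameter accounting is closed-form — conv 240 + LSTM 7008 + 1776 + dense
78 = **9102** — and must agree exactly with the instantiated weight-array
sizes. The source prints 9104, two more than any standard convention
yields; the discrepancy is reported, not absorbed. Flat weight size is
count × 4 bytes (35.55 KiB). The MACC estimate uses a stated convention
(conv `out_len·filters·kernel·channels`, LSTM `steps·4·units·(input+units)`,
dense `in·out`; biases/activations/pooling excluded), totalling 207,816 for
the default spec; vendor toolchains count differently and no equality with
their figures is claimed.

## Reference experiment and problem sizes

`pneumyo.experiments.synthetic_classification_experiment` is the canned
end-to-end evaluation: six default profiles at 60 s per mode (150 s for
squatting, since the threshold filter discards its rest periods), balanced
to 600 windows per class, 50 training epochs — sizes chosen so a run
completes in under a minute on one CPU while leaving the task non-trivial.
At seed 42 it reaches 96.5% test accuracy with the characteristic
stairs→walking confusion: stairs recall (0.89) is the lowest of all
classes, because roughly 11% of stairs test windows consist mostly of
landing-cycle content that is exactly walking. That confusion floor is a
property of the generator's landing model, not of the classifier;
real stair recordings show the same structure at lower contamination.

## Known limitations

* The gas model is quasi-static and first-order: no airflow/valve
  transients, adiabatic effects, fabric elasticity, or multi-bladder
  arrays; simultaneous contractions must be composed sequentially.
* Synthetic waveforms are stylized (see above); reported accuracies
  characterize the pipeline, not field performance.
* The split is window-wise, not subject-wise; windows from the same stream
  share generator state, so accuracy estimates are optimistic relative to
  leave-one-subject-out evaluation.
* Embedded figures (flash/RAM/latency) depend on the vendor toolchain and
  are out of scope; only parameter count, flat size and the documented MACC
  convention are computed.
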