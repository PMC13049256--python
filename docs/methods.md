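# Methods

`jpresskit` implements a complete pipeline for quantifying brain-metabolite
concentrations and transverse relaxation times from multi-echo (J-resolved
PRESS, "JPRESS") time-domain MRS data: a quantum-mechanical basis simulator,
a fully labeled synthetic-data generator, a neural encoder-decoder that maps
the 32-echo FID stack directly to concentrations and metabolite-average T2s,
and a resampling procedure for prediction-sensitivity intervals.

## Spin simulation

Each metabolite is a set of proton groups (chemical shift, multiplicity,
subgroup label) with a scalar-coupling matrix between groups.  Groups with
no coupling path between them are factored into independent subsystems;
coupled groups are expanded into individual spins (each group pair coupled
with its J), with a hard cap of 8 spins (256-dimensional Hilbert space) per
subsystem.  The rotating-frame Hamiltonian is

    H = sum_i 2 pi nu_i I_iz + sum_{i<j} 2 pi J_ij (I_i . I_j),

with nu_i the offset from the carrier (water, 4.7 ppm) at 123.2 MHz (3 T).
The PRESS localization is collapsed to a single ideal spin echo of total
duration TE (90x - TE/2 - 180y - TE/2 - acquire): with ideal pulses this is
exactly equivalent to the double echo for weak coupling and a close
approximation for strong coupling, and no TE1/TE2 split needs to be
assumed.  Evolution is computed in the Hamiltonian eigenbasis; each
subsystem yields a coherence line list (amplitude, frequency) from which
the FID at any TE is synthesized on the acquisition grid.  The simulator is
verified in the test suite against an independent brute-force matrix-
exponential propagator (agreement ~1e-14) and against the product-operator
echo modulation cos(pi J TE) of a weakly coupled pair.  At moderate
separation (dnu/J ~ 50) the exact result deviates from the first-order
formula by up to ~2%; this is genuine strong-coupling physics, so the
first-order oracle is only asserted at dnu/J >= 200.

Normalization: a subgroup's unit-concentration FID has first-point
magnitude equal to its proton count at TE = 0.  Absolute calibration
against a water reference is out of scope; concentrations live on the
simulator's own mM scale throughout.

Default acquisition grid: 32 echoes, first TE 35 ms with uniform 10 ms
increments (the echo spacing is a configurable choice; only the ascending
order and the 35 ms first echo are fixed by the acquisition it emulates),
2048 complex points at 2500 Hz spectral width.

The bundled chemical shifts and couplings follow the standard published
proton tables for the 14 brain metabolites (NAA, NAAG, Cr, PCr, PCho,
GPCho, Glu, Gln, GSH, Tau, Asp, mI, GABA, Lac) plus water, with small
simplifications: exchangeable protons and the GPCho glycerol backbone are
omitted, and the choline ethylene systems are reduced to A2B2 with a single
inter-group coupling.

## Generative model of training data

Each sample is assembled as

    input = sum_c component_c + background        (exactly, by construction)

with twelve components: tNAA (= NAA + NAAG), tCr, tCho, Glu, Gln, GSH, Tau,
Asp, mI, GABA, Lac, and residual water.  Randomization per sample:

- **Concentrations**: uniform on [0, 2 x median] per metabolite; medians
  10 mM for NAA, Glu, Gln, GSH, Tau, Asp, mI, GABA, Lac and 5 mM for NAAG,
  Cr, PCr, PCho, GPCho; hard cap 20 mM.  Combined-component labels are the
  sums of their constituents.
- **T2s**: each subgroup's relaxation rate is 1/T2k = preset + delta1 +
  delta2, with delta1 uniform on [-1.3, 4.4] 1/s shared by all metabolites
  of a sample, water's delta1 independent on [1.3, 12.6] 1/s, and delta2
  uniform on [-0.63, 0.63] 1/s per subgroup.  Metabolite presets are drawn
  uniformly in rate between T2 164 and 276 ms, water's preset is fixed at
  0.044 1/s; these presets are chosen so the realized subgroup T2s span
  ~90-590 ms (metabolites) and ~75-1400 ms (water).  T2 attenuates both the
  echo delay and the acquisition window (exp(-(TE + t)/T2)); applying it to
  the acquisition as well as the echo is the physically motivated choice
  and is configurable.  The average-T2 label of a combined component is the
  proton-signal-weighted mean over its constituents' subgroups
  (configurable to the unweighted mean).
- **Lineshape**: one modified-Voigt envelope shared by all echoes of a
  sample, exp(-lam t - g t^2)(1 - b1 t - b2 t^2 - b3 t^3), lam in [pi, 8 pi]
  1/s, g in [9, 21] 1/s^2, b1 in [-1.5, 3] 1/s, b2 in [-3, 30] 1/s^2, b3 in
  [0, 210] 1/s^3.  The envelope equals 1 at t = 0 and may go negative at
  long t; it is retained unclipped (labels live upstream of the lineshape).
- **Phase/frequency**: phase uniform on [0, 360) deg and frequency offset
  uniform on [-5, 5] Hz drawn independently per echo; the residual water
  carries an entirely independent lineshape/phase/frequency set, so the
  model cannot infer metabolite phase from water.
- **Shift jitter**: each metabolite's spectrum is shifted by an independent
  uniform [-1, 1] Hz offset (applied over the acquisition only, since the
  echo refocuses chemical shift).
- **Residual water amplitude**: log-uniform between 0.5x and 50x the total
  metabolite first-point amplitude, emulating suppression quality that
  varies over orders of magnitude.  The water "concentration" label is the
  equivalent concentration on the simulator scale and is therefore much
  larger than the metabolite labels.
- **Background**: complex white Gaussian noise with sigma log-uniform in
  [0.2, 2.0] simulator units (first-echo NAA at 10 mM ~ 30 units, so
  per-point SNR spans roughly 15-150), plus 0-8 damped complex exponentials
  (frequency uniform over the spectral width, damping 5-100 1/s, amplitude
  up to 2x the largest metabolite first point, phase and amplitude
  re-drawn per echo) standing in for spurious echoes, outer-volume signals
  and unregistered resonances.  The exact artifact model matters less than
  its diversity: the network is trained to filter the background out, not
  to model it.

What the generator does **not** emulate: macromolecule baselines with
realistic J-evolution, tissue partial-volume effects, eddy-current phase
distortions beyond the polynomial envelope, frequency drift within one
echo, and scanner-specific filtering of the first points.  Tests passing on
this generator therefore demonstrate correctness of the pipeline and
learnability of the mapping under these study conditions, not in vivo
performance.

Reproducibility: sample i of a dataset is drawn from an RNG stream keyed
(seed, i), so datasets are order-independent and any sample can be
regenerated in isolation.

## Network

Input is the (n_te, n_points, 2) stack of complex FIDs as two real
channels, echoes in ascending TE order.  The encoder repeats
(per-echo gated dilated convolutions -> GRU across the TE axis) n_blocks
times at full sequence length:

- Convolutions have kernel 2 with taps at p and p + d, dilations 2^1 ..
  2^max (256 at full size: the longest single hop is 256 points), gated
  tanh x sigmoid activations, and a linear projection feeding both the
  residual stream and the skip path.  They are non-causal; causality serves
  autoregressive generation, which is not needed for fully observed FIDs.
- The GRU runs along the 32-echo axis independently at every time position
  with shared weights, fusing J-modulation and T2-decay information across
  echoes.
- Pooling-at-the-beginning (PAB) averages the final block's features over
  only the first 64 points (window/total = 1/32; 32 points in the scaled
  profile), where concentration information is concentrated and lineshape
  influence is minimal; setting the window to the full length reproduces
  the global-average-pooling ablation.  PAB is applied once after the last
  block: pooling inside each repeat would destroy the sequence the next
  repeat needs.
- The mean of the 32 TE-specific representations is the 128-dimensional
  JPRESS representation; dense heads (one hidden tanh layer each) map it to
  the 12 concentrations and 12 average T2s, a per-echo dense head maps each
  TE representation to that echo's 12 first-point amplitudes, and a decoder
  (1x1 convolution stack over the concatenation of the raw input, every
  block's output sequence, and the TE-specific representations broadcast
  along the position axis) reconstructs all 12 component FIDs at every
  echo.  The exact decoder inventory is a configuration choice; skip access
  to the raw input lets it recover lineshape and phase detail the pooled
  representation deliberately discards, while the broadcast representation
  supplies the global component content that a purely pointwise map lacks.

Numerical conditioning: the conv stack reads an arcsinh-compressed
featurization [asinh(re), asinh(im), asinh(|z|)] of the scaled input.
Residual water can sit two orders of magnitude above the metabolites and
saturates the gated units if fed raw; the magnitude channel is a
deterministic function of the two input channels, so the external input
contract is unchanged.  The decoder's skip keeps the raw channels so large
amplitudes remain reconstructable.  Per-component target scales (water
30x) bring all labels to order 1 for the shared MAE loss.

The network and its training loop are implemented in NumPy with explicit
backpropagation (gradient-checked against finite differences in the test
suite); layers are float32 throughout.

## Training

All four loss terms are mean absolute errors (concentrations, average T2s,
per-echo first-point amplitudes, FID reconstructions), weighted equally by
default; the weighting is exposed in configuration.  Negative predicted
concentrations and amplitudes are clipped to zero inside the loss, which
keeps clipping an optional post-processing step at test time; T2 and
reconstruction terms are not clipped.  Optimization is Adam under cosine
annealing of the learning rate; the scaled profile uses two annealing
cycles (warm restarts), because in very short single-cycle schedules the
weakest components can collapse to constant-median predictions -- an MAE
plateau -- and never escape once the rate has annealed, whereas a second
high-rate phase after the strong components' features have formed reliably
un-sticks them.  Training data are generated on the fly:
every epoch consumes fresh counter-derived samples and validation draws
from a disjoint counter range, so a run is reproducible from one seed and
never stores its training set.

Profiles:

- **full-scale profile**: 32 echoes x 2048 points, 14 metabolites + water,
  feature dim 128, 4 blocks, dilations to 256, PAB 64, 100 000 samples,
  18 epochs, max learning rate 5e-4.  This is accelerator-scale and is
  provided for completeness, not run in the tests.
- **smoke profile** (the package's scaled study condition, used by tests,
  examples and the acceptance script): 8 echoes spanning the full
  35-315 ms TE range (fewer echoes, same span, so the T2-decay and
  J-evolution information along the echo dimension is preserved) x 512
  points; NAA + Cr + GABA + water (4 output components; GABA included
  deliberately as the hard low-signal target); feature dim 14, 2 blocks,
  dilations 2-32, PAB 32; 20 epochs of 900 fresh samples in batches of 8,
  two cosine cycles.
  The optimization schedule is sized for a single CPU; the maximum
  learning rate (1e-2, cosine-annealed) is raised relative to the full-scale
  profile because the scaled run takes orders of magnitude fewer
  optimizer steps.  At this scale the strongest components train to the
  task's measurable information limit (residual-water amplitude, noise
  and spurious peaks bound what any learner can recover); the weaker
  coupled metabolites remain below full recovery, which is a scale
  limitation, not a pipeline defect.

## Sensitivity intervals and ablation

Given a prediction, the background is the input minus the sum of all 12
reconstructed component FIDs.  Resampled inputs are built as
sum_c factor_c x component_c + factor_bg x background with factors drawn
from Normal(1, sd) -- the target component's factor pinned at exactly 1 --
and re-predicted; the spread of the target's re-predictions over 30
resamples is its sensitivity interval (reported as the central 95%
percentile interval plus the relative sd; the quantile convention is the
package's choice).  Phase/frequency/lineshape are not re-perturbed, since
the model is trained to be invariant to them.  Negative scale factors
(probability ~4e-4 at sd 30%) are truncated at zero: negative component
scaling is unphysical.  The ablation test forces one component's factor to
0 (removed) or 1 (intact) across n regenerated datasets and compares the
two re-predicted concentration distributions; a removed component should
be re-predicted near zero.  How far removal actually drives the
re-prediction depends on how much of the component's energy the decoder
captures: at desk scale the reconstructions are directionally correct but
amplitude-shrunken, so much of the true component signal survives inside
the background term and the separation between the two distributions is
correspondingly weak (see Known limitations).

## Water preprocessing and rendering

The unsuppressed-water tool fits A(TE) = A_t exp(-TE/T2_t) +
A_c exp(-TE/T2_c) with T2_c constrained above T2_t (parameterized as
T2_t + dT2, dT2 > 0.05 s) via bounded least squares, returning the tissue
amplitude extrapolated to TE = 0 (the normalizer) and the CSF fraction.
Spectrum rendering applies no apodization by default; the TE-averaged
spectrum is the mean of the per-echo Fourier transforms.

## Numerical choices and degenerate inputs

- Coupled subsystems above 8 spins raise a dimension error rather than
  silently truncating; couplings below 0.5 Hz are dropped when factoring.
- A non-positive total relaxation rate in the T2 draw triggers a logged
  redraw of delta2.
- The conservation invariant input == sum(components) + background is
  asserted (bit-exactly, with the construction's summation order) for
  every generated sample.
- MAE subgradients at exact ties are taken as 0; negative-branch clipping
  passes gradient at exactly 0 predictions, and head biases are
  initialized positive so the clipped losses do not start dead.
- Finite-difference gradient checks use a smooth quadratic objective so
  MAE kinks do not confound them; float32 tolerances apply.

## Known limitations

- Desk-scale training (minutes on one CPU, thousands of samples) does not
  approach the full-scale regime (TPU-scale, 100k samples); recovery
  quality and invariance at the scaled size demonstrate that the pipeline
  learns the mapping, not the accuracy attainable at full scale.
- At the scaled size the decoder's component reconstructions carry the
  right waveforms but strongly shrunken amplitudes; experiments built on
  the predicted decomposition (component ablation, and to a lesser degree
  the sensitivity resampling) therefore understate the contrast a
  fully-trained decomposition would show.
- The ideal-pulse, single-echo PRESS approximation ignores RF profiles,
  spatial localization and the TE1/TE2 timing split.
- Absolute concentration calibration (water referencing to institutional
  units) is out of scope; all concentrations are on the simulator scale.
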