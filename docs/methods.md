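# Methods

This note records the modelling choices behind emgforge: what each stage
assumes, which parameters matter and why their defaults are what they are,
what the synthetic protocols emulate, and where the model's limits lie.

## Movement and the musculoskeletal surrogate

Movements live on a 24-degree-of-freedom schema (four wrist/arm DoFs, four
thumb DoFs, four DoFs per finger), each with a closed range in degrees.
Eight named poses (hand open/grasp, wrist flexion/extension, radial/ulnar
deviation, pronation/supination) plus a neutral pose span the common
hand/wrist repertoire; poses combine by key-wise summation (`"open+flex"`),
and movements are defined by a pose sequence with per-transition durations.

Interpolation between keyframes uses a half-cosine ramp,
`s(u) = (1 − cos πu)/2`, so angular velocity is zero at every keyframe.
This was a deliberate choice over linear interpolation (available via
`interpolation="linear"`): velocity discontinuities at keyframes would
propagate into abrupt fibre-length and torque transients that no voluntary
movement exhibits. Keyframe samples reproduce pose angles bit-exactly.

The muscle model is deliberately minimal: constant moment arms, rigid
tendons at fixed slack length. Musculotendon length is then affine in the
joint angles and the normalised fibre length follows by subtracting the
slack length. Fibre lengths are clipped to a physiological band (default
[0.5, 1.5] of optimal) and a warning is recorded if the raw value ever
becomes non-positive. The default muscle set is the nine superficial
forearm actuators (ECRL, ECRB, ED, ECU, both heads of FCU, PL, FDS, FCR);
their moment arms, optimal lengths and maximal forces are documented
stand-in constants chosen to make flexors shorten during flexion and
extensors lengthen. Absolute fibre-length values are therefore not
comparable to a full musculoskeletal reconstruction — only the qualitative
patterns (signs, relative modulation) are meaningful, and that is all the
downstream stages consume.

Activations come from static optimisation: at each sample, minimise the sum
of squared activations subject to torque equilibrium on every demanded DoF,
with activations bounded to [0, 1] and muscle force scaled by a Gaussian
force–length factor `exp(−((ℓ−1)/w)²)`, width `w = 0.45` by default. The
solver is SLSQP warm-started from the previous sample; when the demand
exceeds the muscles' capacity the sample falls back to the bounded
least-squares closest point and is flagged. The torque-demand helper models
a single-DoF rigid-body load `τ = I·q̈ + b·q̇ + k·q`. The elastic term `k·q`
(zero by default) is an extension we added for the regression case study:
moving against a spring-like load keeps flexors tonically active while the
joint is flexed, which is both a common experimental paradigm and the
regime in which EMG amplitude actually encodes joint angle. With `k = 0`
the antagonists brake the movement near peak excursion and amplitude
encodes angular acceleration instead.

## Parameter tracking

Muscle volume is taken as constant within a movement, so cross-sectional
area scales as `1/ℓ_s` (an exact invariant of the implementation) and
radius as `ℓ_s^(−1/2)`. Conduction velocity is scaled with the radius —
fibre diameter grows as `ℓ^(−1/2)` at constant fibre volume and CV grows
with diameter — and motor-unit depth likewise, as territories are carried
outward with the expanding cross-section. Only the *direction* of these
relations is physiologically established; the exponents are configuration
(`cv_exponent`, `depth_exponent`, default −0.5) so an area law (−1.0) is a
one-line change, and no claim is made that −0.5 reproduces any particular
measured magnitude.

## Motor-unit pools

Twitch amplitudes are exponential across ranks in the classical model
(`exp(ln RP · j/N)`, RP = 100) and follow the linear-exponential law
`0.81·(18.51 x + 104.10 x^4.83)`, `x = j/N`, in the LIF cohort. Fibre
counts are proportional to twitch amplitude, rounded by largest remainder
(ties to lower rank) so they sum exactly to the muscle's fibre total, with
a transfer step guaranteeing every unit at least one fibre.

Recruitment thresholds are exponential in rank with range RR = 30 and are
normalised so the *last* unit recruits at drive 1.0; drive is normalised
excitation in [0, 1], and muscle activation maps to drive as identity. The
classical rate code uses MFR = 8 Hz, peak rates falling from 35 Hz (first
unit) to 25 Hz (last), ISI coefficient of variation 0.2 (truncated at
±3.9 σ to exclude negative intervals), and gain 30 Hz per unit drive — the
classical "1 Hz per excitation unit" convention expressed on the
normalised drive axis (thresholds spanning [1/RR, 1] instead of [1, RR]).
These constants are conventional for this model family, not measurements;
all are configurable and none are hard-coded.

The LIF cohort integrates `dV/dt = (R·I − V)/τ` by forward Euler with
threshold `v_th`, reset to zero and absolute refractory `t_ref`. Membrane
parameters interpolate affinely between first-unit and last-unit endpoints
(R 2.0→0.7 MΩ, τ 6→7 ms, v_th 15 mV, t_ref 25→35 ms): larger motoneurons
have lower input resistance, and the refractory gradient enforces the
onion-skin ordering at saturation. The per-unit input scale is
`i_max = margin · v_th/(R·θ)` with a 1.15 suprathreshold margin, so the
cohort recruits at the same exponential thresholds as the classical model;
without the margin a unit at exactly threshold drive would approach `v_th`
only asymptotically and never fire. At constant drive the simulated ISI
matches the closed form `t_ref + τ·ln(RI/(RI − v_th))` within 1 % at
10 kHz, which fixes the recommended integration rate.

Conduction velocity is Normal (4.0 ± 0.35 m/s, clamped to 3–6 m/s) sorted
ascending in the classical model so CV pairs with size; the LIF cohort maps
normalised twitch amplitude affinely onto the same CV range, standing in
for the published CV–surface-area relations that live in cited literature
rather than in any single formula we could transcribe. Depth and
medial–lateral position are uniform in the circular muscle territory;
innervation zone (0.5 ± 0.05 of fibre length) and fibre length (optimal
± 5 mm) are truncated Normals. All per-unit draws come from hash-derived
child streams keyed by (seed, muscle, rank), so enlarging a pool never
perturbs existing units.

## The MUAP generator

The MUAP stage honours a seven-parameter conditioning interface — fat-layer
conductivity, fibre number, depth, medial–lateral position, innervation
zone, conduction velocity, fibre length, each a relative value in (0, 1]
mapped affinely to physical units — and realises it with a deterministic
analytical line-source volume conductor rather than a learned generator.
This is a deliberate design: a closed-form surrogate is exactly
reproducible, fast (≈2.5 ms per template), and testable against geometric
oracles, while the hierarchical HDF5 container (`/muscle/unit/keyframe`
with condition attributes) lets externally produced template tensors be
swapped in unchanged.

Geometry: 10 axial rows × 32 circumferential columns on a cylinder of
radius 40 mm, 10 mm axial pitch, channel index = row·32 + column. The
equivalent fibre sits at the conditioned depth and circumferential angle,
axially centred, innervation zone at the conditioned fraction of its
length. At discharge two dipoles (leading depolarisation pole, trailing
repolarisation pole ~1.2 ms behind) leave the IZ in opposite directions at
the conduction velocity and extinguish at the fibre ends over a 0.8-ms
ramp; each pole contributes `amplitude/(σ_eff · distance)` at every
electrode. Amplitude is exactly linear in fibre number and proportional to
fat conductivity; lower fat conductivity additionally widens a spatial
Gaussian blur (circular across columns), mimicking the low-pass effect of
a thicker/less conductive subcutaneous layer. The per-unit latent (a fixed
16-dimensional standard-Normal vector drawn once per unit) perturbs pole
amplitude by at most ±10 % and the IZ by at most ±5 % of fibre length —
bounded individuality that never masks the conditioning parameters.

Consequences used as test oracles: doubling fibre number doubles every
sample; shifting the medial–lateral position by k columns' angle rotates
the grid pattern by exactly k columns; doubling CV halves the IZ-to-end
travel time; depth increases attenuate amplitude and widen the spatial
spread; fibre length stretches the waveform; IZ shifts move the
earliest-activity row. Morphing scales fibre length, CV and depth of the
base condition multiplicatively along the tracked trajectories (clamped to
the valid range) at a configurable number of keyframes (default 16), with
the latent fixed; a prior-sampling mode that redraws the latent per
keyframe exists behind a flag.

## EMG synthesis

The interference signal is the superposition of each unit's template placed
at each discharge sample (rounded to the nearest sample; sub-sample
placement is out of scope). The template at a spike is the linear
interpolation of the two bracketing keyframe tensors — the resolution of
the continuous template change between keyframes is this package's choice;
a nearest-keyframe mode exists for speed. Synthesis is exactly linear and
superposable, and matches a dense brute-force convolution to floating-point
round-off. Additive white Gaussian noise is scaled per channel to a
requested SNR in dB; channel selection maps requested (row, column)
coordinates — fractional allowed, columns wrapping — to nearest grid
channels and records the mapping. Output units are arbitrary: the volume
conductor is uncalibrated, so amplitude comparisons are only meaningful
within a run.

## Similarity analysis

NMSE divides the mean square error by the average of the two templates'
mean squares, giving 0 for identity, 2 against silence and 4 for a sign
flip. Cropping keeps the minimal bounding rectangle of channels whose peak
absolute amplitude exceeds 0.75× the mean of channel peaks; because a
single application of that rule is not idempotent (re-cropping the cropped
grid can shrink the box again), the implementation iterates the rule to its
fixed point, which makes cropping idempotent by construction. Pairs are
compared on the union bounding box of the two individual crops, and the
average power in the NMSE denominator is taken over that cropped support.
"Maximum amplitude" is the maximum of the absolute value, as the waveforms
are biphasic. The windowed RMS features default to 200-ms windows with
50-ms *overlap*, i.e. a 150-ms step; because "50-ms overlap" could also be
read as a 50-ms step, `step_s` overrides the step directly.

## The synthetic regression study

The case study runs entirely on simulator output. The default protocol is a
15-s two-degree-of-freedom task (wrist flexion/extension followed by MCP
flexion/extension via grasp/open) with joint angles at 40 Hz and EMG at
2000 Hz, performed against an elastic load (k = 0.8 N·m/rad, b = 0.3,
I = 0.05). Six channels are read over the six demo muscles (FCR, FDS,
FCU(u), ECU, ED, ECRL) at the middle electrode row. Pools are scaled to 12
units and 2000 fibres per muscle and templates to 96 samples at 6 keyframes
so a full 320-channel trial synthesises in a few seconds; these sizes are
the package's default study conditions and all scale up by configuration.

Trials share one "subject" (pools and latents keyed by the root seed) and
differ by per-trial multiplicative drive jitter (log-normal, σ = 0.05) plus
additive noise at 25 dB SNR. The *real-like* regime emulates an
experimental arm without any data collection: independent and stronger
jitter (σ = 0.15), 15 dB SNR, and a channel-misplacement perturbation
(Gaussian, 2 columns) standing in for electrode-placement error. Because
the experimental arm is emulated, accuracies reported for regressors
applied to real recordings in the literature are not reproduction targets;
the study's self-consistency claims are the ones the tests state: a ridge
regressor trained on one synthetic trial reaches PCC ≥ 0.8 on a second
trial of the same protocol for both targets, and the ten-repeat
shuffled-label null averages within ±0.2 of zero.

Features are z-scored before the ridge penalty (channel RMS magnitudes
span orders of magnitude; an unscaled penalty is dominated by the loudest
channel); window labels are the mean joint angle within each RMS window;
the default ridge λ is 1.0 on the standardised features, with a
leave-one-trial-out selector over a log grid available. PCC against a
constant series is reported as NaN and flagged rather than guessed. The
augmentation experiment draws, per repeat, one held-out real-like test
trial, two real-like training trials and two synthetic trials, and reports
per-target paired PCCs with both paired and unpaired t-tests, since the
appropriate pairing structure across repeats is itself a modelling choice.

## Numerical choices and degenerate inputs

* Spike placement and window arithmetic round to the nearest sample; the
  classical spike generator requires fs ≥ 1 kHz, the LIF cohort warns
  below 10 kHz.
* ISIs have a 5-ms refractory floor after jitter.
* Static-optimisation infeasibility is detected by residual torque > 1e-6
  (relative) and answered with bounded least squares plus a flag, never an
  exception.
* An all-zero template crops to its (arbitrary) peak channel and is
  flagged degenerate; NMSE between two all-zero templates raises.
* Largest-remainder ties break toward lower rank for determinism.
* Duplicate channel-selection coordinates duplicate channels (documented
  behaviour, useful for montage emulation).

## Limitations

Tendon compliance, muscle wrapping, reflex and afferent dynamics, and
force-dependent discharge-pattern changes are all outside the model; the
pool models are isometric-contraction designs driven here through slowly
varying drives. The volume conductor is a single idealised cylinder — no
subject-specific anatomy, no electrode-position learning, and uncalibrated
amplitudes. The synthetic "real-like" regime captures noise, jitter and
electrode misplacement but not crosstalk structure, skin-impedance drift or
genuine inter-subject anatomical variation, so passing the regression tests
demonstrates internal consistency of the pipeline, not field performance on
human recordings.
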