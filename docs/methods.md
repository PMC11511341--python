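# Methods note

This note documents the computational model implemented by `cmjkit`, the
parameter choices, the design of the synthetic-jump generator, and the known
numerical limits. Nothing here is an empirical claim beyond what the test
suite and `scripts/acceptance.py` compute.

## Coordinate system and input data

All processing happens in the sagittal plane: X is the posterior–anterior
axis, Z is vertical; units are meters and seconds internally. A trial is a
set of equal-length coordinate series for up to 14 landmarks (left/right ×
shoulder, hip, knee, ankle, heel, small toe, big toe) at a fixed sampling
rate. Missing samples are NaN and must be interior; they are filled by
linear or local-polynomial interpolation (default maximum gap 0.1 s —
brief occlusions only; longer dropouts indicate tracking failure and
raise). Resampling onto a common rate uses linear interpolation, which is
exact for the piecewise-linear content of typical 100–300 Hz landmark
traces and reproduces grid-identical input bit-for-bit.

## Centre-of-mass model

The whole-body CoM uses the classic Dempster segment parameters restricted
to four segments per side:

| segment    | endpoints        | mass fraction | CoM position along segment |
|------------|------------------|---------------|----------------------------|
| foot       | heel → big toe   | 0.015         | 0.500                      |
| lower leg  | ankle → knee     | 0.0465        | 0.433                      |
| upper leg  | knee → hip       | 0.10          | 0.433                      |
| upper body | hip → shoulder   | 0.43          | 0.500                      |

The four fractions sum to 0.5915, so the weighted mean is renormalised by
that sum rather than forced to one. This makes the CoM a convex combination
of the segment CoMs (tested property) and gives the hand-checkable value
0.5853/0.5915 ≈ 0.98952 m for segment CoM heights of 0, 0.2, 0.6 and
1.2 m. The omitted head/arm mass is implicitly distributed over the trunk
term; this is the standard simplification when only lower-body plus trunk
landmarks are tracked.

CoM vertical velocity comes from central differences (`numpy.gradient`,
one-sided at the series edges). No differentiation-specific smoothing is
applied; smoothing, if any, is applied to the landmark coordinates before
every derived signal, so CoM, toe trace and joint angles see identical
filtering. Two smoothers are provided: a centred moving average with the
window clipped at the edges, and a zero-phase exponential moving average
(the first-order recursion run forward and backward and averaged). The
zero-phase construction matters: a single-pass exponential filter delays
every detected event by roughly `(1−α)/α` samples, which would bias all
phase durations in one direction.

## Event detection

Nine events bound the jump phases; the label *b* is historically unused.

* Baselines come from the first 0.5 s of quiet stance: the mean CoM height,
  the mean toe height, and the SD of the toe height (`noise_sd`).
* **Take-off (f) and touchdown (h)** are detected on the *unsmoothed*
  big-toe height: the longest run of samples above
  `toe_baseline + max(0.01 m, 5·noise_sd)` is the flight, and its ends are
  tracked outward to the last sample at ground level
  (`toe_baseline + 3·noise_sd`). The three-sigma ground margin keeps
  noise runs during quiet contact from dragging the crossing away from the
  true lift-off, while the toe's speed at lift-off (far above one noise SD
  per sample) keeps the detected crossing tight. Smoothing is deliberately
  avoided here because it spreads the threshold crossing by half a window
  and autocorrelates the residual noise. Multiple substantial
  supra-threshold excursions mean the recording holds more than one jump
  and raise an ambiguity error.
* **Countermovement bottom (d)** is the CoM minimum before take-off; **peak
  downward velocity (c)** the velocity minimum before d; **peak upward
  velocity (e)** the velocity maximum in (d, f].
* **Movement onset (a)** is found by walking backward from c to the first
  sample whose downward speed drops below 5% of a reference velocity. The
  "5% of the maximum velocity" convention is ambiguous about whether the
  reference is the peak upward or peak downward velocity; both are
  implemented (`onset_reference = "max_up"` (default) or `"max_down"`).
  The backward search makes onset robust to small pre-trial fidgeting.
* **Apex (g)** is the CoM maximum strictly inside (f, h); **landing bottom
  (i)** the CoM minimum at or after h.

The ordering `a < c < d < e ≤ f < g < h ≤ i` is enforced as a class
invariant; violations raise instead of producing silently wrong variables.

## Variables

Phase durations are event-index differences over the sampling rate, so the
additivity identities (eccentric = unweighting + braking; take-off =
eccentric + propulsive) hold exactly and are validated on construction.
Displacements are relative to the quiet-stance CoM height. Three ballistic
jump heights are reported alongside the displacement-based one: `g·t²/8`
from flight time and `v²/2g` from take-off and from maximum upward
velocity, with g = 9.81 m/s². CoM velocity extrema are restricted to the
ground-contact interval [a, f] so landing transients cannot masquerade as
movement velocities. Joint angles are interior angles at the vertex
landmark (180° = fully extended); push-off angles are sampled at d, landing
angles at i. Mapping interior angles onto anatomical flexion/dorsiflexion
conventions is left to the caller.

## Agreement statistics

* **Bland–Altman**: bias ± 1.96·SD limits of agreement; t-based CI on the
  bias; the classic `SE = SD·√(3/n)` approximation for the LoA CIs.
* **Pearson r** with Fisher-z 95% CI and the conventional magnitude labels
  (negligible < 0.3 ≤ low < 0.5 ≤ moderate < 0.7 ≤ high < 0.9 ≤ very high).
* **ICC(3,1)**: two-way mixed, consistency, single measures,
  `(BMS − EMS)/(BMS + (k−1)·EMS)`, with an F-bound CI. Consistency means a
  fixed offset between methods does not lower the coefficient.
* **Two-way fully repeated-measures ANOVA** (method × side) with the trial
  as the blocking unit; each within factor is tested against its own
  case × factor interaction mean square. The degrees of freedom therefore
  follow the trial-as-case design (df2 = levels−1 times cases−1); studies
  that treat all trial × side observations as one error stratum will report
  different df for the same data.
* **Cohen's d** standardised by the *harmonic* mean of the two group SDs,
  `2·s1·s2/(s1+s2)`, with a normal-approximation CI
  (`SE = √((n1+n2)/(n1·n2) + d²/(2(n1+n2)))`), magnitude labels
  (trivial < 0.2 ≤ small < 0.5 ≤ moderate < 0.8 ≤ large < 1.3 ≤ very
  large), and a clear/unclear call: unclear when the CI spans both −0.2 and
  +0.2.
* **Whole curves** are linearly time-normalised onto 101 stations (0–100%)
  and compared station-wise (across-trial means with t-based CI bands) and
  pooled (all stations of all trials as one paired sample). Pooling
  overweights slowly-varying curve segments and treats stations as
  exchangeable; it is a descriptive summary, not an inferential one.

Implementation choices are tested against independent oracles: brute-force
sums-of-squares decompositions, direct textbook formulas, and the
`pingouin` package (tests only; the library itself depends only on numpy,
scipy, pandas, pyyaml and typer).

## Synthetic jump generator

The generator works backward from a closed-form CoM height profile, so that
every event time and variable value has an exact analytic target.

The profile is piecewise with continuous position and velocity: quiet
stance; a cosine-eased unweighting (velocity 0 → peak downward velocity);
a braking segment with parabolic speed decay `v(s) = v_min·(1 − s²)`;
a push-off `v(s) = v_to·(1 − cos πs)/2 + B·sin πs` whose free harmonic `B`
is solved so that commanded duration, displacement and take-off velocity
are simultaneously honoured (feasibility requires the push-off duration
not to exceed `2·depth/v_to`); an exactly ballistic flight of duration
`2·v_to/g` starting from the standing CoM height; a parabolic-decay landing
descent; and a sine-velocity recovery back to standing.

Two design points deserve emphasis:

* **Sharp bottoms.** The braking and landing segments end with nonzero
  deceleration, so the CoM minimum is a well-defined point. A profile that
  eases into the bottom with zero acceleration has a flat minimum that *no*
  detector can localise under noise — the corresponding events would carry
  an irreducible multi-sample error that says nothing about the detector.
  The sharp bottom also matches the mechanics of a real jump, where
  leg-extensor force is highest at the turning point.
* **Exact ballistics.** The CoM returns exactly to its standing height at
  take-off, so the displacement, flight-time and take-off-velocity height
  estimators coincide analytically, and any disagreement in the analysis
  output is attributable to the pipeline, not the data.

Landmarks are back-generated through a hinged planar posture model (flat
feet; shank, thigh and trunk rotating with a single crouch parameter, with
segment lengths as standard stature fractions). The crouch parameter is
inverted per sample by bisection so the Dempster CoM of the generated
landmarks matches the target profile to ~1e−12 m; during flight the
take-off posture is translated rigidly along the ballistic path. The
measurement-error model adds seeded i.i.d. Gaussian noise and constant
per-landmark bias to the landmark coordinates (not to the CoM), so the
mass-weighted averaging of the CoM computation is exercised.

The ground-truth movement onset is computed analytically from the
unweighting shape with the same onset definition as the detector
(`s_a = arccos(1 + 2·thr/v_min)/π`), because the detected onset is a
threshold crossing, not the start of the commanded descent.

**What the generator does not emulate**: horizontal travel, arm swing,
inter-segment timing differences (all joints move with one crouch
parameter), soft-tissue artefact, pose-estimation outliers or dropout
bursts, and asymmetry (both sides are identical by construction). It is a
verification instrument for the analysis pipeline, not a biomechanical
forward model.

## Numerical limits

* Central differences carry a truncation error of `v''·h²/6`; inside the
  push-off (`v'' ≈ 240 m/s³` at 100 Hz) this is ≈ 4×10⁻³ m/s, and at
  acceleration discontinuities (take-off, touchdown) the one-sided error is
  `Δa·h/2`, up to ≈ 0.05 m/s. Velocity-derived quantities are therefore
  accurate to a few mm/s at 100 Hz, better at higher rates; tests assert
  the rate-dependent bounds (5×10⁻³ m/s at 100 Hz, 1×10⁻³ m/s at 300 Hz,
  away from segment boundaries).
* The take-off-velocity height estimate is biased low by the central
  difference straddling the take-off kink (≈ 6 mm at 100 Hz on a 0.27 m
  jump); the flight-time estimate is biased slightly high by the
  outward-tracking take-off/touchdown convention (about one sample of
  flight). Both effects shrink with the sampling rate and are part of the
  ≤ 0.01 m agreement budget of the three estimators at 100 Hz.
* Event indices are integer samples; all phase durations are quantised to
  the sampling period. At 100 Hz this dominates the error budget of the
  short phases (braking ≈ 0.18 s spans only 18 samples).
* The bisection posture inversion is run 60 iterations, far past float64
  resolution; CoM reconstruction error is < 1e−6 m by test (typically
  ~1e−15).

## Limitations

The event rules assume a single, well-executed countermovement jump with a
quiet-stance lead-in: recordings with multiple hops, a walk-in, or missing
flight raise typed errors rather than guessing. The Dempster fractions are
population averages; per-subject scaling is not attempted. Joint angles are
planar interior angles and will misstate out-of-plane motion. The
statistics module implements the consistency ICC only (ICC(3,1)); absolute
agreement variants are out of scope. The ANOVA requires a complete
crossed design (every trial observed in all method × side cells) and does
not handle missing cells.
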