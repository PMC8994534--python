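# Methods

## Scope and data model

Every assay stage consumes the same per-frame table: time `t` (s, strictly
increasing), animal centroid `x, y` (mm; NaN while untracked), optional
heading (rad), stimulus center and diameter (`stim_diam = 0` when nothing is
shown), and an integer `epoch_id` labeling stimulus presentations (−1
between epochs). Coordinates are metric: the circular watch glass has its
origin at the dish center; the rectangular dyad tank has its origin at the
corner where the divider meets the side wall, with y increasing toward the
wall opposite the divider. Recordings made in pixels are converted at read
time with a px/mm calibration factor supplied by the user — it is
configuration, never inferred. Frame timestamps are interval starts:
a per-frame quantity (displacement, heading) computed from frames i and
i+1 is attributed to `[t_i, t_i + 1/fps)`.

Tracking dropouts of at most `max_gap_frames` (default 3) consecutive
frames are filled by linear interpolation; longer runs stay NaN, and every
metric excludes NaN frames from both numerator and denominator. The NaN
itself is the flag — no extra column, so the CSV schema stays closed.

## The social index and its time-shifted null

For each stimulus epoch, frames with the dot on and the animal tracked are
compacted into paired animal/stimulus position sequences (dropping a frame
removes it from both sequences, so the observed and every shifted series
use identical frame counts). The observed mean distance IADr is averaged in
5-min chunks (one chunk per standard 300 s presentation; chunks with under
half their frames valid are excluded; multi-chunk epochs are combined with
frame-count weights). The null shifts the animal sequence circularly within
the epoch by 10 offsets evenly spaced strictly inside
(60 s, epoch − 60 s) and recomputes the mean distance; the mean over
offsets is mIADs and `SI = (mIADs − IADr)/mIADs`.

Two choices here were genuinely open:

* **Shift topology.** Shifts wrap circularly within the epoch rather than
  sliding across the whole multi-hour session. This preserves the marginal
  spatial distribution of both trajectories exactly, keeps the sample size
  constant across offsets, and makes a stationary animal score SI = 0
  identically. The choice is recorded in the result metadata
  (`offsets_used`).
* **Offset placement.** Only the count (10) and the lower bound (>60 s)
  are fixed by the assay definition; the offsets are placed evenly in the
  open interval so every offset exceeds 60 s and stays at least 60 s from
  the epoch end. Epochs shorter than 120 s plus one frame are rejected.

Degenerate cases: mIADs = 0 (animal and dot pinned to the same point under
every shift) raises an explicit error; a perfect tracker has IADr = 0 and
mIADs > 0, giving SI = 1 exactly, the upper bound.

## The bout-swimming agent

The simulators exist to give every metric a ground-truthed input with a
single controllable social drive. The agent is a bout-and-turn random
walk:

* inter-bout intervals are exponential at `bout_rate` (default 1 Hz),
  floored at the glide duration — a new bout cannot interrupt the
  propulsive phase of the previous one (a behavioral refractory);
* each bout turns the heading by a wrapped-normal angle: bias term plus
  noise of SD `turn_sd` (0.6 rad);
* the bout displacement is gamma-distributed (shape 2, mean
  `bout_disp_mean` = 1.5 mm, capped at `bout_disp_max` = 5 mm) and plays
  out as a straight glide of `glide_s` = 0.15 s at constant speed, so the
  per-frame speed is bounded by `bout_disp_max / glide_s`;
* endpoints outside the arena are mirrored back through the wall; both
  arena shapes are convex, so interpolated glide frames stay inside.

Social drive is one signed gain k (`attraction_gain`). With k > 0 the turn
bias is `w · (bearing-to-target − heading)` with saturating weight
`w = |k|/(1+|k|)`: a single monotone knob from asocial (k = 0, trajectory
independent of the stimulus by construction — the null the SI is
calibrated against) to near-deterministic tracking. With k < 0 the agent
performs a flight response: the bout is more vigorous
(`flight_vigor` = 2×) and its turn is biased toward the *refuge* — the
arena point farthest from the stimulus. Steering directly away from the
dot was tried first and fails in a bounded dish: the agent pins itself
against the wall, becomes quasi-stationary, and scores SI ≈ 0 rather than
negative; fleeing toward the far side is also what real escape maneuvers
accomplish. A `flight_zone` range limits avoidance to nearby stimuli
(default: unlimited).

Defaults (bout rate 1 Hz, 1.5 mm bouts, 5 mm body length, 20 mm dish
radius) describe a plausible 14 dpf larva; they are configuration, not
measurements.

The dot stimulus follows a closed Lissajous ("synthetic knot") path
`x = A_x sin(p·ω·t), y = A_y sin(q·ω·t + φ)` with p:q = 2:3, amplitudes
14 mm, period 120 s. In the default boutlike mode the dot advances along
this path in discrete Poisson-timed steps at 1 Hz and dwells in between,
i.e. it moves with the same bout-like kinetics as the agent (median step
≈ 1.2 mm); a smooth mode exists for geometric tests. The period was set so
the dot's mean speed (≈ 1.8 mm/s) is commensurate with the agent's —
a dot much faster than the animal can neither be followed nor avoided,
compressing the SI dynamic range toward 0.

In the split dyad, both agents run the same bout walk in mirrored 50 × 20
mm tanks at 10 fps. During the presocial (opaque-divider) phase there is no
coupling; after divider removal each agent's bouts are biased toward the
partner's mirrored position with its own gain, which drags its place
preference toward the divider. The simulation is event-driven in time
order, so each bout sees the partner's current frame.

In the looming session the agent swims asocially; the 20 s centering
grating is modeled only as a re-centering of the animal at the grating's
end, 10 s before each loom (that is the grating's experimental purpose).
At each loom the agent escapes with probability
`logistic(escape_slope · (final_diam − escape_p50))` (defaults: p50 =
6 mm, slope = 1 /mm); an escape is a straight 8 mm dart at `escape_speed`
= 100 mm/s directed away from the loom side (jittered within ±60°, with
more tangential fallbacks when the full dart would leave the dish), and the
planted flags and latencies are returned as ground truth. A cornered
animal — already pinned against the wall opposite the loom — occasionally
cannot produce a full-speed dart; those rare events are legitimately
missed by any speed-based detector.

## Dyad, open-field, and loom scoring

* **Heading** comes from frame-to-frame displacement (the streams carry
  centroids only); displacements under `min_step` (default body length/10)
  carry no orientation information and yield NaN.
* **Orienting** is the acute angle between the heading and the divider
  line, scored only for headings with a positive component toward the
  divider — without that restriction an animal facing directly away would
  also score 90°. The 45–90° band is inclusive on both ends (with a 1e-9°
  float tolerance so exact 45°/90° headings count). Toggle:
  `require_toward`.
* **Place preference** is the mean distance from the wall opposite the
  divider, normalized to tank length (1 = divider wall, 0.5 = uniform).
* **Motion**: a frame counts when the displacement is at least one-third
  body length (inclusive); animals under 10% whole-experiment motion are
  excluded (strict: exactly 10% is retained).
* **Thigmotaxis** is outer-third occupancy: the fraction of tracked frames
  with radial distance beyond 2/3 of the dish radius (uniform occupancy
  gives 5/9). The index is named, not defined, by the upstream assay
  literature; the definition used is recorded here and the cut radius is
  configurable.
* **Stunted** classification thresholds at the wild-type mean minus 1.5
  wild-type sample SD (ddof = 1), estimated from the wt stratum only;
  the cut is strict (a length exactly at threshold is not stunted).
* **Escape detection**: escaped iff the peak inter-frame speed within
  1.0 s of loom onset (0.5 s expansion + 0.5 s) exceeds a threshold of 5×
  the session's median *moving-frame* speed. The plain median is not used
  because bout-and-glide swimmers are stationary in most frames, which
  drives the plain median — and with it the threshold — to zero;
  restricting to positive-displacement frames anchors the threshold to the
  individual's routine bout speed (≈ 47 mm/s for default agents, between
  the routine per-frame maximum of 37.5 mm/s and the 100 mm/s escape).
  Window and threshold are parameters and appear in the scored output.

## Group comparisons

Tukey–Kramer HSD (studentized range with the unequal-n correction, via
statsmodels) covers the three-genotype contrasts; a permutation test (mean
difference, two-sided, add-one correction `p = (1 + #{|T*| ≥ |T|})/(B+1)`)
is the distribution-free alternative, with a paired (sign-flip) mode for
within-animal phase contrasts. The unpaired null permutes a *sorted* pool
and splits at the smaller group size, which makes the p-value exactly
invariant to exchanging the group labels. α = 0.05, two-sided, throughout.

## What the simulations do and do not show

The generator reproduces the statistical structure the metrics rely on —
bout-interval and displacement distributions, a monotone social-drive
knob, phase-locked dyad coupling, logistic loom psychometrics, planted
stunting rates — so passing tests show that the *pipeline* measures what
it claims on data whose ground truth is known. The agents have no
hydrodynamics, no visual physiology, no habituation or learning within a
session, no size-dependent kinematics, and dyads are limited to two
animals; absolute SI values from simulation therefore do not predict
absolute values in live recordings, only the ordering and null behavior.

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` use 300 s epochs at 30 Hz
(9,000 frames) with 100 seeds per attraction gain; 50 dyads of two 300 s
phases at 10 fps; 10,000-animal cohorts; and 10 looming sessions giving 60
events per stimulus size plus size-0 sessions for false positives. Oracle
comparisons (vectorized implementation vs. independent Python loops) are
required to agree to 1e-9 relative error on 1,000-frame instances.
Statistical checks use 99% binomial or 3-SE intervals around analytic
expectations. Boundary semantics (inclusive motion threshold, strict
exclusion and stunting cuts) are pinned by dedicated tests.

## Known limitations

* Heading is displacement-based; during dwell the orientation is unknown,
  so orienting percentages are conditioned on moving frames.
* The escape detector is purely speed-based; it does not classify C-start
  kinematics and will miss escapes of cornered animals (see above).
* `fill_gaps` interpolates linearly; curvature inside a gap is lost
  (bounded by the chord-sagitta error for smooth paths).
* The SI shift-null assumes within-epoch stationarity; slow drift (e.g.,
  progressive thigmotaxis) inflates neither IADr nor mIADs systematically
  under circular shifts but is not explicitly modeled.
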