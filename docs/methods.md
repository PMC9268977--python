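# Methods

## Disposable running statistics

The analytics core is a six-field accumulator (count, min, max, mean,
second- and third-central-moment auxiliaries) updated once per incoming
value. The mean and variance recursions are the classical one-pass
(Welford-style) forms; the third-moment auxiliary T is updated as

    T' = T − 3Δμ·V + ΔV·(x − μ' − Δμ),  Δμ = μ'−μ, ΔV = V'−V,

which is algebraically exact (we verify it against a brute-force batch
computation rather than proving it here). Derived statistics use the
unbiased conventions: sample SD √(V/(n−1)), reported as absent below
n = 2, and adjusted Fisher–Pearson skewness n·T/((n−1)(n−2)σ³), absent
below n = 3 or when σ = 0 (a constant stream has no defined skewness;
callers that prefer 0 can substitute it).

Two deliberate choices:

* **Extrema initialisation.** An empty accumulator holds *no* min/max;
  the first observation defines both. Seeding them with 0 would corrupt
  any stream that does not straddle zero (e.g. heart rates, or
  accelerations hovering around +g).
* **Numerics.** Plain double precision, no compensated summation. The
  oracle-equivalence property tests cover magnitudes 10⁻³–10³ and
  n up to 10⁴ at 10⁻⁹ relative tolerance, which is the regime the
  sensor pipeline actually produces; extreme cancellation regimes
  (mean ≫ SD by many orders) are out of scope.

The `batch_oracle` companion computes the same summary non-recursively
from the full array (numpy reductions, `scipy.stats.skew(bias=False)`)
and exists purely as the independent check of the recursion — both in
the unit tests and as the offline-analytics path of the policy engine,
where the agreement of the two routes is itself a tested contract.

## Privacy quantification

Privacy risk in one data context is a fuzzy membership of the
disclosure percentage x: sig(x; s, p) = 1/(1+e^−(x−p)/s), with p the
context's objective inflection point (risk 0.5) and s ∈ [1, 10] the
subjective sensitivity. Context privacy is 1 − sig, with hard overrides
P(0) = 1 and P(100) = 0: the sigmoid alone gives ≈0.998 at x = 0, and
the framework's semantics ("disclosing nothing is fully private") take
precedence over the asymptote. Independent contexts multiply.

Shipped defaults model a home-care deployment: storage (s = 8, p = 50)
is more tolerant because stored data remain at the user side;
transmission (s = 10, p = 30) uses the maximal sensitivity because
transmitted data leave the user's control. Disclosure ratings are
fixed per level: handshakes 10% (pessimistic — they reveal liveness
and identity), analytic results 30% (summaries are partially
invertible), raw data 100%. The s values would come from user
questionnaires in a deployment; here they are plain configuration.

## Scenario taxonomy and policy engine

Storage levels {nothing, analytic result, raw} × transmission levels
{nothing, handshake, analytic result, raw} yield ten named scenarios
A–J; the two corners that hoard raw data while sending nothing (or only
handshakes) are labelled impractical and score privacy 0.

Scenarios A–F are *disposable*: `process_session` walks the session one
sample at a time, updates per-channel running accumulators (ax, ay, az,
gx, gy, gz, and the acceleration magnitude), and never buffers the raw
stream — the outcome object can only ever contain summaries, handshake
codes, and an action-level audit log. Scenarios G–J accumulate raw data,
run the batch path, and then store/send/erase per policy; the erase
action is always audited. Note a summary *does* legitimately reveal the
stream's extrema (min/max are sample values by definition); the
leak-freedom tests therefore plant a mid-range sentinel sample and scan
every serialised payload for it.

Handshake payloads carry heartbeat codes (one per configurable period,
default 10 s of session time), the subject pseudo-ID, and predefined
alert codes. Alert thresholds are artifact defaults — the default rule
flags a running acceleration-magnitude maximum above 3 g (a fall-like
impact); deployments supply their own bounds. "Transmission" is
delivery to a sink object or directory, not a network stack: the
privacy contract concerns what crosses the local boundary.

## Synthetic sensor sessions

Axis convention: X anterior–posterior, Y medio-lateral, Z vertical;
g = 9.80665 m/s² converts the noise model's G units. Sessions are
100 Hz with quiet lead-in/lead-out padding (1.5–2 s) so onset detectors
have a baseline.

The iTUG generator builds trunk pitch as a raised-cosine excursion
spanning the stand-up phase (default peak 15°) and another spanning
sit-down (12°); yaw rate as raised-cosine bursts spanning the two turns
(defaults 150 and −120 °/s); gravity is rotated through the resulting
orientation, chair-transfer transients (≈2 m/s²) and Gaussian step
impacts (2.5 m/s², σ = 25 ms, evenly spaced, default 6 per bout) are
added on the vertical axis. Default phase durations (1.4, 2.6, 1.6,
2.6, 1.8, 1.5 s; total 11.5 s) describe a mildly slow performer. The
10 m walk places initial-contact bumps on the vertical axis and
final-contact bumps on the antero-posterior axis, one stance period
(default 60% of a stride) after the same foot's contact; left/right
step times follow the requested asymmetry ratio; the realised step
count is the rounded cadence × duration, and the returned ground truth
reports the realised values.

The noise model adds per-axis white Gaussian noise and constant offsets
to the accelerometer (RMS 0.0011/0.0011/0.0014 G, offsets
0.013/0.033/0.150 G), white noise to the gyroscope (1.12/1.42/1.41 °/s,
treated as zero-mean — the characterisation reports no gyro offset),
and a linear Euler drift (yaw 0, pitch 2.88·10⁻⁶, roll 1.60·10⁻⁵ °/s)
composed into the quaternions, which are renormalised. Everything is
driven by a single seeded generator and is bit-reproducible.

What the generator does *not* emulate: waveform realism (real lumbar
traces show oscillatory impact transients, postural sway, arm-swing
coupling), soft-tissue artefacts, sensor saturation, or orientation
error during dynamics. Passing recovery tests therefore demonstrates
that the detectors correctly invert this signal model at realistic
noise levels — not that they would match clinically validated systems
on real patients.

## Detectors

Segmentation uses two nearly orthogonal channels: trunk pitch (active
only during chair transfers) and smoothed yaw rate (active only during
turns). Activity intervals are found by an onset threshold —
max(25% of the channel peak, 6× a robust noise estimate, an absolute
floor) — and each edge is then refined outward until the signal falls
below max(0.2% of peak, 4× noise, floor). The noise estimate is the
scaled median absolute deviation of the whole channel, which tracks the
quiet baseline because activity is sparse. The six phases are cut at:
first posture interval (stand), gap to first turn (walk out), the two
turn intervals, the gap between them (walk back), and the last posture
interval (sit). A static or structureless signal (fewer than two
posture transients or turns) raises a segmentation failure rather than
a partial result.

Step/contact detection band-passes the acceleration (3–16 Hz,
zero-phase second-order Butterworth), rectifies and smooths (50 ms) to
an envelope, and picks peaks above 35% of the window maximum with a
250 ms minimum separation. Zero-phase filtering and the symmetric
envelope keep event-time bias below one or two samples.

Index conventions (open points resolved as package choices):

* Maximum inclination is measured from the session's *initial* pitch,
  not from gravity — robust to a tilted sensor mount.
* Stand/sit maximum acceleration is the deviation of the acceleration
  magnitude from its session median, robust to constant offsets.
* Fall-risk category from total test duration: Normal ≤ 10 s,
  Risk ≤ 13.5 s, High Risk above — configurable artifact defaults, not
  validated clinical cut-offs.
* Gait symmetry = |L − R| / (½(L + R)) on per-foot mean step times
  (0 = perfect). Foot labels alternate from the first contact; absolute
  left/right identity is not claimable from a single lumbar sensor.
* Single support = stride − stance, double support = 2·stance − stride
  (per-stride overlap); stance% + swing% = 100 by construction.
* The functional-mobility label bands walking speed at 0.4 and 0.8 m/s
  (household / limited community / community ambulation).

## Problem sizes

The recovery properties are established over 20 seeded sessions per
test (iTUG at the default profile; walks spanning cadences
80–140 steps/min), oracle equivalence over 200 random streams up to
n = 10⁴ across signs and magnitudes, and noise calibration at 10⁵
static samples. These sizes make the full suite run in a few seconds
while leaving the Monte-Carlo margins (worst boundary error ≈ 0.12 s
against a 0.15 s bound; worst contact-time error ≈ 5 ms against 50 ms)
comfortably visible.

## Known limitations

* Detector thresholds are tuned to the synthetic signal model; real
  recordings would need re-tuning and validation.
* No accumulator merging (parallel reduction), kurtosis, quantiles, or
  moving windows in the running-statistics core.
* The policy engine's movement-analysis hook runs only on the raw
  (non-disposable) path; a streaming reformulation of segmentation is
  future work.
* Impractical scenarios are refused by `process_session`; they exist
  in the taxonomy for completeness and score privacy 0.
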