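# Methods

## The measurement model

A transilluminated duct appears as a bright background crossed by two dark
wall bands. All quantities derive from a kymograph `K(s, t)`: the movie
resampled along a fixed line (position `s`, frame time `t = i·dt`,
bilinear interpolation at ≤ 1 px steps, optional averaging over parallel
1-px offsets). For a *transverse* line the two deepest intensity minima of
each time column are the walls; for a *longitudinal* (centerline) line the
column is the luminal content profile.

Wall minima are refined to subpixel positions by fitting a parabola
through the minimum and its two neighbours (the standard three-point
refinement; exact for a locally quadratic dip, and accurate to ≈ 0.01 px
for the Gaussian wall bands used in validation). The diameter trace is
`D(t) = s_bottom(t) − s_top(t)`. Time columns without two separable
minima (separation ≥ 4 px required) are *gaps*; a trace with more than
25 % gaps is rejected as untrackable rather than silently interpolated.

### Event detection

Contractions are transient *decreases* of `D`. Detection operates on
`depth(t) = B(t) − smooth₃(D)(t)` where `B` is a centered running median
(window 60 s — long against the ~3 s pulses, so pulses do not drag the
baseline) and `smooth₃` a 3-frame centered mean. Candidate events are
local maxima of `depth` with

* prominence ≥ `max(3 σ_noise, 0.03 · median(B))`, and
* pairwise spacing ≥ `min_interval_s` (default 3 s: the fastest observed
  spontaneous rate, 15 beats/min, has a 4 s period).

Conflicts are resolved greedily, deepest first, ties toward the earlier
event. Event times are refined to sub-frame resolution with the same
parabolic rule (this is what makes wave latencies resolvable at 7
frames/s), and events are never reported inside gap frames.

`σ_noise` is `1.4826 · MAD` of `D − B` with two sigma-clipping passes
(residuals beyond 3 σ excluded, then re-estimated). The clipping matters:
once contractions occupy a third or more of the recording, the plain MAD
absorbs the spikes themselves (measured ≈ 0.4 px against a true tracking
jitter of ≈ 0.15 px at 10 beats/min) and the threshold would swallow
small-amplitude events.

Frequency over `[a, b)` is `60 · N / (b − a)` beats/min with a half-open
window, so abutting windows partition events exactly.

### Wave speed

Events from ≥ 3 transverse stations are rank-matched (k-th event with
k-th event; stations whose event count deviates from the majority are
excluded — their sequences cannot be aligned). Each matched event's time
is regressed on axial station; the mean slope `ŝ` (s/px) across events
gives speed `1/ŝ`. If `|ŝ|` is below the resolvability bound — half a
frame interval across the station span — the pattern is classified
`global`; otherwise `propagating` when the pooled latency fit has
R² ≥ 0.5, else `incoherent`. When the total lag is within a few frame
intervals the estimate carries a note recommending 7 frames/s capture.

### Luminal flow

Consecutive centerline profiles are aligned by maximum normalized
cross-correlation (mean-subtracted, lags limited to a quarter of the
line, parabolic subsample refinement). The cumulative displacement series
is decomposed into a net drift (Theil–Sen slope, with a standard error
from its 95 % confidence band) and an oscillation amplitude
(`SD × √2` of the detrended series — the amplitude of the equivalent
sinusoid). Classification: `net_transport` iff
`|net| > max(0.5 px/s, 2·SE)`; otherwise `pendular` when the oscillation
amplitude is ≥ 1 px; otherwise `static`. A featureless lumen (median
profile contrast < 0.01 intensity units) is `static` with a warning, not
an error. These thresholds are package decisions — flow is described only
qualitatively in the source experiments — and are validated against the
simulator, where they separate the preset regimes by wide margins.

### Epoch statistics

For each drug addition at time `t`, frequency is measured in the paired
half-open windows `[t − 120, t)` and `[t + 10, t + 130)` s; the
spontaneous ("Spont") baseline is the pre-window of the *first* addition
only. Window violations (leaving the recording, overlapping the next
addition's windows) are reported as errors naming the addition.

The Friedman statistic is computed from within-segment mid-ranks:

    Q = [ 12/(n·k·(k+1)) · Σ_j R_j²  −  3·n·(k+1) ] / C ,
    C = 1 − Σ(t³ − t) / (n·(k³ − k))

summing over tie groups of size `t` within segments; p from χ² with
k − 1 df. A table whose every row is fully tied carries no ordering
information and returns Q = 0, p = 1 by convention. Dunn's post hoc uses
`z = (R̄_i − R̄_j)/√(k(k+1)/(6n))` with two-sided normal p-values,
Bonferroni-adjusted over the comparisons performed (Holm available);
stars mark p < 0.05 (`*`) and p < 0.01 (`**`).

`friedman_exact_p` enumerates all `k!^n` within-segment rank
permutations. Note that the χ² approximation is *not* uniformly close to
the exact permutation p at small n: at n = 5, k = 3 the two differ by up
to ≈ 0.14 in the mid-range (e.g. exact 0.69 vs χ² 0.55 at Q = 1.2),
agreeing only in the far tail. The exact option is the defensible choice
for the segment counts typical of these experiments; the χ² default
matches common software practice.

## The simulator

The generator renders the physics the analysis assumes, in continuous
time sampled at the frame grid:

* diameter `D(c, t) = D₀ · (1 − A · p(t − τ(c)))` with `p` a raised-cosine
  unit pulse (width `w`, repeating at the active regime's interval) and
  `τ(c) = (c − c₀)/v` for wave speed `v` (zero lag for "global");
* walls as Gaussian absorption bands (σ = 2 px) at `center ∓ D/2` on a
  bright background;
* intraluminal particles as dark Gaussian blobs advected by
  `x(t) = x₀ + u·t + a·sin(2πt/T)` through a periodic lumen;
* additive Gaussian intensity noise, then clipping to [0, 1] and
  quantization to the 16-bit grid — so an in-memory stack is bit-identical
  to one written to TIFF and read back, and identical parameters (seed
  included) give bit-identical movies.

Scheduled regime changes switch the pulse interval at the first onset at
or after the change time, so no pulse is truncated mid-contraction; the
ground truth records every onset per station and the per-epoch true
frequencies (60/interval).

Defaults: frame interval 1 s (alternatively 1/7 s), resting diameter
40 px, amplitude A = 0.2, pulse width 3 s, noise SD 0.01, background
0.85 / wall depth 0.55. The sources report neither contraction amplitude
nor pixel scale, only that amplitude "remained largely constant"; A = 0.2
with D₀ = 40 px gives spikes of the same visual scale as the published
kymographs while keeping both walls well inside the frame. Virtual
sections default to 1 px width (user-settable); all geometry stays in
pixel units unless a physical pixel size is supplied.

What the simulator deliberately omits: tissue texture and collagen
optics, curved or 3-D duct geometry, and any mechanochemical coupling of
flow to wall motion (particle kinematics are prescribed). Passing the
validation suite therefore demonstrates correctness of the measurement
chain on idealized duct images, not robustness to real-tissue confounds
such as drift, focus changes, or wall-intensity inhomogeneity.

## Validation conditions and problem sizes

The end-to-end suite simulates movies on a compact 64 × 128 px geometry
(diameter 28 px) to keep runs fast; the presets use 96 × 192 px.

* *Worked example*: the fig1 preset must yield exactly 7.5 beats/min from
  one midpoint section and from three auto-placed sections.
* *Frequency recovery*: true rates {1.5, 3, 5, 6, 10, 15} beats/min ×
  20 seeds, amplitudes 0.1/0.2, noise SD up to 0.02, 240 s recordings;
  ≥ 95 % of runs within ±0.5 beats/min. Capture follows the imaging
  protocol the method is built for: 1 frame/s up to the modal range and
  7 frames/s at 10–15 beats/min, where wall movements need finer time
  resolution. Pulse width is capped at 40 % of the period so fast regimes
  remain *phasic* (at the spec'd 3 s width a 15 beats/min duct would be
  contracting 75 % of the time — nearly tonic, and its residual ripple
  after 3-frame smoothing, ≈ 0.025·D₀, is unresolvable at 1 frame/s by
  any threshold).
* *False positives*: 100 zero-amplitude movies with noise SD 0.02 must
  yield zero events in ≥ 95 % of runs.
* *Wave/flow*: the peristaltic preset (50 px/s at 7 frames/s) within
  10 % with correct sign; the two flow presets classified correctly with
  net velocity within 10 %.
* *Statistics*: 200 random 5 × 3 tables against scipy's Friedman
  statistic (≤ 1e−9), a full brute-force permutation enumeration
  (≤ 0.02) and the closed-form Dunn z (≤ 1e−9); plus a power check
  (8 segments, 7.5 → 3.0 beats/min, adjusted p < 0.05) and a type-I
  control (no regime change: at most 1 of 10 replicates significant).

## Known limitations

* Straight-duct assumption: analysis lines are straight; strongly curved
  ducts need manually placed lines, and there is no motion-compensated
  reslicing.
* Wall tracking assumes exactly two dominant dark bands; crossing debris
  or out-of-focus walls become gaps rather than being disambiguated.
* Contractile force is out of scope: diameter change is a geometric
  read-out only.
* Flow estimation reports bulk profile displacement in px/s, not
  volumetric flux, and assumes trackable luminal texture.
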