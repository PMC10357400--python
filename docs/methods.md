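# Methods

## Model and assumptions

The package analyzes two-channel single-particle flow data from a
two-laser instrument: an upstream ("red") and a downstream ("blue")
excitation beam of widths ΔX2 and ΔX1 (μm), separated center-to-center
by ΔX3 (μm). All times are milliseconds, distances micrometers, speeds
μm/ms. Peak times are beam-center crossing times; a particle's transit
time (PT) across a beam is the full width at half maximum of its
fluorescence burst, so PT = beam width / speed. The FWHM convention is
used consistently by the trace renderer and the peak detector; users
who calibrate widths differently can rescale `pt_ms` before matching.

The colocalization model assumes each particle's speed is constant
while crossing a beam, and approximately constant (coarse shift) or
linearly summarized by the average of the two per-beam speeds (fine
shift) between beams. Speed changes that violate this (wall
interactions) are not modeled; the W2 acceptance window exists to
discard such particles rather than mis-pair them.

### Shift equations

For a red peak at t_red with transit time PT2:

* coarse: t′ = t_red + PT2·(ΔX3/ΔX2), i.e. travel time ΔX3/v2 with
  v2 = ΔX2/PT2;
* fine, against a candidate blue peak with transit time PT1:
  t′ = t_red + ΔX3/v_avg with v1 = ΔX1/PT1 and, by default,
  v_avg = (v1 + v2)/2.

The arithmetic mean is the default because it is the plain reading of
"average velocity between the beams"; the harmonic mean — the effective
speed of a constant-acceleration transit over a fixed distance — is
available via `velocity_average="harmonic"`. On error-free constant
speed data the two coincide.

### Conflict resolution

Accepted proposals (ΔT ≤ W2) are reduced to a one-to-one matching by
repeatedly fixing the globally smallest-ΔT proposal and discarding
competitors of its two peaks; displaced peaks remain in the pool with
their surviving candidates, so the procedure runs to a fixed point.
ΔT ties within `tie_tol` (default 10⁻⁶ ms, a double-precision guard;
no physical tolerance is implied) are broken by the smallest relative
transit-time change |PT1 − PT2|/PT2 — the particle whose speed changed
least between beams is the more plausible identity. The fixed point is
computed as a single sorted greedy sweep. Note this yields a *maximal*
matching under the local minimum-ΔT rule, which on adversarial chains
is not the matching maximizing total pair count; the local rule is the
method's definition, not an optimization shortcut.

## Simulator

`flowsim` draws arrivals at the red laser as a homogeneous Poisson
process (rates studied: 5, 35, 252 particles/s) over the acquisition.
Each particle gets an independent radial position, mapped through the
Poiseuille profile (v_max = 3 μm/ms, channel radius 1 μm by default);
its blue-crossing time is t_red + ΔX3/v exactly. Observed transit times
multiply the true ones by an independent per-laser random factor;
brightness is dim (intensity 1) or bright (intensity 3) with the
configured bright fraction (5% or 50% in the study conditions).

Two choices the study conditions leave open are fixed as follows:

* **Radial density.** Default `radial_sampling="flux"`: density
  ∝ r·v(r). Particles recorded crossing a detection plane in steady
  laminar flow arrive in proportion to their speed — the standard
  observation bias of flow velocimetry — which makes the observed speed
  density f(v) = 2v/v_max². `"area"` (density ∝ r, giving speeds
  uniform on (0, v_max]) models an instantaneous snapshot of the
  channel instead and is retained for sensitivity analysis.
* **Transit-time error.** Default `pt_error_model="uniform"`: a
  multiplicative factor uniform on [1 − c, 1 + c] with c = 0.10, the
  literal reading of "a 10% random error". A bounded model is also the
  only one consistent with near-total colocalization surviving at
  W2 = 4 ms while only a few percent is lost at W2 = 1 ms: unbounded
  Gaussian tails (available as `"gaussian"`, redrawn while nonpositive)
  lose an order of magnitude more at narrow windows for any speed
  distribution compatible with the wide-window behavior.

Radial positions with v < 10⁻³·v_max are resampled (such particles
never exit the channel within a realistic record). With a fixed seed
the generated ground truth is bit-identical across runs; every random
draw flows from the single `numpy` generator seeded by the config.

The benchmark pipeline feeds the simulator's *observed peak tables*
(exact crossing times, perturbed transit times) directly to the
matchers — transit-time randomization stands in for detection error, as
in the study design. Trace rendering (Gaussian pulses, FWHM = true PT,
plus additive baseline noise) and Gaussian-fit peak detection are
exercised separately by round-trip tests; at the default 10 kHz the
fastest particles (~0.33 ms transit) are covered by only ~3 samples, so
rendered-trace detection of fast particles is warned about and not part
of the benchmark path.

### What the synthetic benchmark does not show

The generator emulates a velocity *distribution*, Poisson traffic, a
bright/dim intensity mixture and transit-time measurement error. It
does not emulate mid-channel speed changes, wall interactions, photon
shot noise, detector dead time, coincident (coeluting) particles within
one beam, or the empirical, instrument-specific particle-position
distribution of real acquisitions. Passing benchmarks therefore
demonstrate algorithmic correctness under idealized Poiseuille
kinematics, not end-to-end instrument performance. In particular, the
published study drew particle locations from unpublished experimental
bead data; its Xcorr ΔT distributions imply a velocity density with a
tight fast core plus a heavy slow tail that no pure Poiseuille radial
density reproduces (a tight core is incompatible with the ~30%
low-density Xcorr loss under any radial scheme). Quantities dominated
by that distribution's shape — the high-density ΔT concentration
fractions of both methods — accordingly differ here by roughly ten
percentage points from the published ones, in opposite directions for
Scorr (more concentrated) and Xcorr (less), while window effects,
losses, mis-colocalization bounds and the Scorr/Xcorr fold increase
reproduce within the study's stochastic band.

## Baseline (Xcorr) conventions

The lag k maximizes the FFT-based discrete cross-correlation of the
two traces over |k| ≤ 60 ms by default (ties toward the smallest |k|);
when only peak tables exist, a Gaussian pulse train (amplitude = peak
height, FWHM = PT) is synthesized at the configured sample rate so the
intensity weighting of the trace-level definition — and hence its
sensitivity to bright contaminants — is preserved. Matching is greedy
in red-time order: each red peak claims the nearest unclaimed blue peak
within W of t_red + k. Exclusive claiming is the default (the charitable
baseline); `exclusive=False` exposes the double colocalization of fast
particles instead.

## Evaluation conventions

Percentages are relative to particles present in both channels (in the
simulator, all of them). This denominator is stated prominently because
it moves absolute values: "loss" here is 100 − (correctly and singly
matched %), and an alternative reading relative to wide-window match
counts can be computed from the sweep table. Mis-colocalization counts
only dim-with-bright wrong pairings (the damaging case for
immunophenotyping); all-cause wrong pairings are reported separately as
`wrong_pct`. Double colocalization counts downstream peaks claimed by
more than one upstream peak before conflict resolution. ΔT histograms
use 0.25 ms bins with cumulative fractions at 0.25 and 0.5 ms.

## Problem sizes

The acceptance script uses ten 120 s replicates per condition
(~30,000 particles per high-density replicate) and a three-replicate
factorial sweep for the fold-increase table; the test suite uses three
60 s replicates for the same quantities with the band widened by the
replicate standard error. Brute-force oracles (assignment enumeration,
per-lag correlation sums) run on instances of ≤ 12 peaks per channel.
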