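# Methods

`placeseq` re-implements, as a tested library, the analysis chain used for
hippocampal CA1 ensemble recordings on a square track maze with a removable
detour: place maps and remapping statistics, offline burst ("frame")
detection and Bayesian replay/preplay scoring, theta-sequence quadrant-ratio
statistics, a first-order Markov model over sleep spike sequences, cell
assemblies and plastic/elastic drift measures, and alternate-context
("flickering") decoding during running. Because the recordings themselves
are not public, every stage is exercised end-to-end on synthetic sessions
with known ground truth; this note records the models, conventions, and the
design decisions taken where the underlying procedures leave choices open.

## Conventions

Time is seconds (float64), session-relative from 0. Position is linearized
to a single 1-D coordinate in cm: the four 150 cm tracks of the square are
concatenated (T1 at 0–150, T2 at 150–300, ...); when a track carries the
150 cm U-shaped detour replacing its 50 cm middle ("mobile") segment, that
track occupies 250 cm of the coordinate and downstream offsets shift.
Corner-ambiguous 2-D samples snap to the lower-indexed track; samples
farther than a 5 cm tolerance from every track are flagged invalid and
excluded rather than clamped. Theta phase is the analytic-signal angle of
the zero-phase 7–10 Hz band-passed LFP, with 0° at the LFP peak and 180° at
the trough; a theta cycle spans consecutive phase peaks.

## Synthetic sessions

The generator (`placeseq.synthetic`) is first-class, tested code. One
`numpy.random.Generator` seeded from the `GeneratorSpec` drives every draw, so
identical spec + seed reproduces sessions bit-exactly.

**Run sessions.** The animal sweeps the full linearized maze end-to-end at
30 cm/s (alternating direction per lap, 10 laps by default, with 2 s
immobile pauses at the ends). Each unit carries one or more Gaussian place
fields (σ = 10 cm, peaks 5–20 Hz). Spiking is an inhomogeneous Poisson
process at 1 ms resolution with rate

    r_i(t) = tuning_i(x(t)) · exp(κ cos(θ(t) − φ_i(t))) / I0(κ),

a von Mises phase gain (κ = 2) normalized to unit mean so place-field rates
are conserved. Phase precession enters through the preferred phase
φ_i = φ_entry + s · d_i(t), where d_i is the distance travelled into the
field *along the running direction*, φ_entry = 330° and
s = −6°/cm (≈240° across a 40 cm field). Two properties of this
parameterization matter: the descending ramp from a late entry phase makes
units with fields ahead of the animal fire late in each cycle (forward
theta sequences, positive quadrant ratio), and the ramp stays monotone on
the 0–360° phase axis, so the linear phase-versus-position correlation is
well defined. Coupling phase to position (rather than adding independent
phase jitter) means that spike-time jittering genuinely destroys both
precession and theta sequences, which the jitter analyses require. The LFP
is a theta-frequency cosine (amplitude 1 while running, 0.2 while paused)
plus white noise, so Hilbert phase has known ground truth.

**Sleep sessions.** Non-REM-like activity is modelled as a near-silent
tonic floor (0.05 Hz/unit) plus "frames": 0.2–0.5 s bursts at ~8/min in
which an ordered template of units (preplay content, or a random subset)
fires in sequence, ≥5 distinct units per frame, ~3 spikes per member with
8 ms jitter around evenly spaced centers of mass. The burst-concentrated
regime is deliberate: with a tonic Poisson floor of 0.5 Hz/unit the smoothed
multi-unit activity is near-Gaussian and chance 2-SD excursions longer than
100 ms with ≥5 units occur many times per minute, swamping the detector;
with population activity concentrated in frames (as in real non-REM, where
DOWN states are near-silent) the detector recovers >99% of injected frames
with a null false-positive rate of ~0.02/min. A 160 Hz burst is added to
the sleep LFP at each frame for ripple-detection tests.

**Remapping plans.** Detour and post-detour maps derive from the pre-detour
maps per unit: *stable* (all equal), *plastic* (fresh detour map that
persists), *elastic* (fresh detour map that reverts), remainder random in
both. The default day uses 60/20/20 stable/plastic/elastic.

**Flicker injection.** Within chosen epochs (optionally locked to theta
peaks) the current position is mapped proportionally onto the alternate
segment and spikes are redrawn from the alternate-context tuning there,
with a 3× gain. The gain reflects that flicker events are coordinated
population bursts; without it a 40 ms five-template decode cannot reach the
0.5/0.9 probability regime that defines representing epochs.

**What the generator does not emulate:** bursty interspike intervals,
interneurons, speed-modulated theta frequency, realistic broadband LFP,
electrode drift, or behavioural variability (running speed is constant).
Passing recovery tests therefore demonstrates correctness of the analysis
chain under its own assumptions, not performance on real recordings.

## Analysis chain

**Place maps** are smoothed spike counts over smoothed occupancy in 2 cm
bins (Gaussian σ = 2 cm, counts and occupancy smoothed separately before
dividing), restricted to speed > 10 cm/s; bins under 0.1 s raw occupancy
are masked. Spatial information is the standard bits-per-spike sum.
Split-half stability randomly bipartitions laps 100 times and averages the
cosine similarity of the half-maps. Segment-pair remapping uses per-unit
Pearson correlations maximized over ±2-bin shifts against 1000 cell-ID
shuffles; the stretched comparison (150 vs 50 cm) rebins to equal bin
counts. The bidirectionality of a unit is the cosine similarity of its two
directional maps (the underlying convention is unstated; cosine matches the
other similarity measures in the chain).

**Frames** threshold the 1 ms-binned, 15 ms-smoothed pyramidal multi-unit
activity at mean + 2 SD (statistics over immobility only), extend to the
flanking mean crossings, and keep candidates of 100–1200 ms with ≥5
distinct units during velocity < 2 cm/s. Note the duration filter applies
to the *extended* duration: a strong 50 ms burst typically measures
~100 ms after extension, so the practical floor for injected bursts sits
below the nominal one. Ripples use the 140–220 Hz envelope (2 ms smoothed)
at mean + 5 SD extended to mean + 2 SD, 30–200 ms. Theta state requires
speed > 10 cm/s and a (7–10 Hz)/(2–15 Hz) power ratio above its session
median — a construction that presumes the session contains substantial
non-theta time.

**Decoding** is the canonical memoryless Poisson population decoder with a
uniform spatial prior; template rates are floored at per-unit mean rate
× 1e-5, and likelihoods accumulate in log space. Multi-track decoding
concatenates templates rescaled to a common mean rate. Frames are decoded
at 20 ms, flicker at 40 ms, validation at 200 ms; only bins with ≥1 spike
are scored. Trajectory scores are the posterior-weighted time–position
correlation and the peak-jump distance normalized by track length; the
two-parameter replay criterion is |wc| > 0.6 and jump < 0.4, with column
permutation as the time-bin shuffle (circular shifts are exposed nowhere —
permutation was chosen as the stricter null).

**Theta sequences.** Cycles with more than 3 active units during running
are decoded at 20 ms; the posterior is recentred on the animal (±40 cm)
and oriented along the running direction; the quadrant ratio sums
future-ahead and past-behind mass against the other two quadrants, split at
the cycle's temporal midpoint. Population positivity is a one-sided
Wilcoxon signed rank (continuity-corrected normal approximation — slightly
conservative, so the empirical false-positive rate stays at or below the
nominal alpha). In the emergence comparison the theta alpha is set no
larger than the replay criterion's empirical false-positive rate, and for
every candidate replay frame all prior cycles' quadrant ratios are tested,
matching test counts between the phenomena.

**Markov sequence model.** Events reduce to unit orderings by spike-time
center of mass (ties break by unit ID). The first-order model uses
maximum-likelihood transition counts; exact zeros are reset to the matrix's
minimum non-zero entry and exact ones to its maximum non-one entry, so long
sequences never collapse to zero probability. Sequence probability is the
P1-initialized transition product; the length-normalized score is its
geometric mean. Significance compares against same-length random sequences
drawn uniformly without within-sequence repeats (matching the one
appearance per unit in observed orderings); 500,000 draws by default,
reduced to 10,000 in desk-scale runs at a documented loss of percentile
resolution (±0.5 vs ±0.07 percentile points at the 95th). Tuplets are
contiguous 2–3 unit sub-sequences repeating ≥2 times, significant above the
95th percentile of 500 rate-matched shuffle sleeps (weighted sampling
without replacement preserves unit frequencies, destroys order).

**Drift and assemblies.** The plastic/elastic index is
cos(post, det) − cos(post, pre) on concatenated stationary-segment tunings;
|index| > 0.3 classifies (the same 0.3 used for the drift/stable map
correlation cut). Assemblies are PCA components of the 20 ms-binned
z-scored spike matrix with eigenvalues above the Marchenko–Pastur bound
(1 + √(n_units/n_bins))²; members carry weights > mean + 2 SD; activation
removes the projection matrix diagonal so single-unit firing contributes
nothing. The regression decomposition fits post-detour tunings on a
grand-mean regressor plus Pre/Det/OT/T1/T3 tunings by least squares over
all (unit, bin) observations and reports leave-one-out residual-norm
shares, with a unit-identity shuffle (n = 1000) for percentiles.

**Flickering.** Five segment templates (unchanged flanks, current segment,
alternative segment, length-matched control on the opposite side of the
maze) compete at 40 ms; representing epochs need smoothed context
probability > 0.5 at speed > 10 cm/s, strong representations > 0.9 with ≥3
active units. Overlapping (90%) windows are used only for phase curves,
whose s.e.m. corrects the degrees of freedom to 10% of the window count.

## Null calibrations

Three chance-level calibrations (in `placeseq.calibration`, recomputed by
`scripts/acceptance.py`) characterize the detection chain:

1. **Theta-sequence false positives.** 10,000 synthetic cycle posteriors
   (noisy forward sweeps) are column-shuffled; each drawn permutation
   enters the pool together with its time reversal, which exactly negates
   the quadrant ratio, making the null pool exactly symmetric. 1000 random
   subpopulations of 200 are tested at alpha = 1%, each together with its
   mirror image (the mirrored pair leaves the expected rejection rate
   unchanged while halving the estimator's variance). The significant
   fraction sits at or below 1%.
2. **Pairwise-order chance.** An order-probability matrix built from 2000
   random frame orderings scores 10,000 independent random cycle orderings
   at a mean order probability of 50% (±1%).
3. **Markov null.** A model fitted on structured synthetic sleep sequences
   (a planted random transition chain — diverse transitions, so cycle
   scores are only weakly correlated) is cell-ID shuffled and applied to
   2000 structured cycle sequences against 10,000 same-length random
   sequences each; the fraction above the 95th percentile is averaged over
   5 independent shuffles (a single shuffle leaves model-level variance in
   the tail fraction) and sits at the 5% chance level.

## Problem sizes

Default test and calibration sizes are desk-scale by design: 20–60 units,
4–10 laps, 2–5 minute sleep sessions, 100–1000 shuffles per test and
10,000 random sequences per significance call. These sizes put binomial
error comfortably inside every asserted tolerance while keeping the whole
suite fast; all are plain parameters that scale up unchanged.

## Known limitations

Linearization assumes the maze geometry of the configured `MazeConfig`;
there is no general track-graph inference. The decoder has no transition
prior (memoryless by design). Cluster quality, waveform-based (clusterless)
decoding and 2-D place fields are out of scope. The theta-state median
construction degenerates when a session is almost entirely mobile or
immobile. Assembly extraction is PCA-based; ICA refinements are not
implemented.
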