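# Methods

## Scope and model

`cargotrack` quantifies directed intracellular transport of endo-lysosomal
cargoes from fluorescence video-microscopy. The physical picture is
motor-driven motion along microtubules inside neuronal branches: a cargo
alternates *go* phases (processive runs at roughly constant speed) with
*stop* phases (pauses during which it only wiggles in place), and a
substantial fraction of cargoes never moves at all during a 2-minute
observation. The pipeline estimates, per trajectory, the velocity, run
length, pausing time and pausing frequency of this intermittent motion, plus
per-field-of-view counts and moving fractions, organelle sizes from spot
widths, and dynamic two-channel colocalization.

All spatial quantities are carried in pixel units and converted once,
through `pixel_size_nm` (default 80 nm) and `frame_rate_hz` (default 20 Hz),
at analysis time.

## Spot detection and linking

Frames are band-pass filtered (narrow Gaussian smooth minus a
spot-diameter-scale Gaussian background), candidate peaks are local maxima
exceeding five robust noise SDs, and sub-pixel centers are refined either by
an iterative background-subtracted weighted centroid (default; fast and
accurate to well under 0.15 px at high SNR) or by least squares against a
*pixel-integrated* 2-D Gaussian (`refine="gauss"`). The integrated model
matters for morphometry: a sensor averages the PSF over each pixel area, and
fitting a sampled Gaussian instead would inflate the fitted SD by about
`px²/12` in variance.

Linking is Crocker–Grier-style global nearest-neighbour assignment: per
frame transition, the particle-to-spot matching minimizing total squared
displacement is solved as a padded linear assignment problem in which not
linking costs the squared search radius (`max_displacement_px`, default
5 px). Tracks unmatched for at most `memory_frames` (default 3) frames keep
their identity. Trajectories shorter than `min_track_frames` (default 50
frames, 2.5 s at 20 Hz) are discarded as spurious. The per-FoV particle
count is the number of surviving trajectories, static ones included.

The default study geometry keeps particles on separate branch lanes (see
below), so the linker is never asked to disambiguate crossing trajectories;
multi-hypothesis or motion-predictive tracking is deliberately out of scope.

## Phase parsing

The confinement ratio of frame *i* is the net displacement between the ends
of a `window_frames`-frame window centered on *i*, divided by the summed
step lengths inside the window; windows are clipped at trajectory ends, and
trajectories shorter than the window use the whole-track ratio. Frames with
ratio above `confinement_threshold` (0.8) are *go*, the rest *stop*; runs
shorter than `min_phase_frames` are iteratively merged (earliest-shortest
first) into their neighbours.

**Window choice.** The window is the parser's resolution limit and its
noise filter at once, and the two pull in opposite directions:

* Too wide, and pauses comparable to the window are smeared away. With 1 s
  mean pauses at 20 Hz, a 21-frame (1.05 s) window inflates the mean
  detected pause duration by ~85% and suppresses the pausing frequency by
  ~35%; even 7 frames leaves a +20–27% pause bias.
* Too narrow, and pure localization noise reads as directed motion: the
  net-over-path ratio of a 2-step window exceeds 0.8 for ~40% of isotropic
  noise windows (the ratio is scale-free, so this cannot be fixed by
  lowering the noise), chopping static tracks into spurious phases.

The defaults, `window_frames = 5` and `min_phase_frames = 2`, are the
measured optimum of this trade-off under the package's standard study
conditions (1 µm/s, go 2 s / stop 1 s, 20 Hz, 10 nm jitter; five seeds of 60
moving particles, parsed on ground-truth positions): velocity bias +1.2%,
mean pausing time +9…15%, pausing frequency −7…−10%, with at most one rare
spurious go phase on a static track (such a phase never reaches the 1 µm
directed-displacement criterion, so moving/static classification is
unaffected). Both knobs are configurable; analyses of slower cargoes with
longer pauses can widen the window proportionally.

Residual, structural biases worth knowing about: pauses much shorter than
the window (≲0.15 s here) are invisible, which — pause durations being
memoryless — raises the mean detected pause by roughly the detection floor;
and detected pause boundaries are smeared by up to half a window. Both
effects are included in the recovery numbers above.

## Transport parameters

With each sample owning one frame interval (`1/frame_rate_hz`), phase
durations always sum to the trajectory duration. Per trajectory:

* **velocity** — total go-phase path length over total go-phase time
  (time-weighted; the per-phase-mean alternative is available via
  `velocity_mode="phase_mean"`),
* **run length** — mean go-phase path length (the per-phase net-displacement
  variant is also reported, as `run_length_net_um`),
* **pausing time** — mean stop-phase duration,
* **pausing frequency** — stop events per minute of the trajectory's full
  observed duration (so static and moving tracks are comparable),
* **total length** — sum of go-phase path lengths.

Velocity and run length are NaN-flagged when a trajectory has no go phase.
A trajectory is *moving* (directed) when at least one go phase achieves
`min_directed_displacement_um` (1 µm) of net displacement.

## Morphometry

A sub-resolution organelle imaged through a Gaussian PSF appears as a
Gaussian of SD `sigma_T**2 = sigma_psf**2 + sigma_L**2`; the organelle SD is
recovered in quadrature, and its diameter is reported as the FWHM
`2*sqrt(2 ln 2) * sigma_L`. The deconvolution PSF defaults to the measured
112 nm; the diffraction-theory alternative (`rho_A = 0.61*lambda/NA =
286 nm` at 700 nm / NA 1.49, `sigma = rho_A/3 = 95 nm`) is carried alongside
and selectable. Spots whose fitted SD does not exceed the PSF SD (possible
under noise) report size 0 with `resolvable=False` rather than an imaginary
number, keeping size tables totalizable. Per-trajectory sizes use the median
of per-spot fitted SDs, which is robust to occasional bad fits.

## Colocalization and ROI intensity

Colocalization is decided per trajectory pair: at least
`min_overlap_frames` (20) common frames and a median inter-channel distance
below `max_distance_nm` (320 nm = 4 px, about one diffraction radius in the
red channel). Each green (assembly) trajectory takes its nearest qualifying
red partner, and the reported fraction is computed over *moving* green
trajectories. Both criteria are declared assumptions — the track-level
median makes the decision robust to transient encounters, unlike frame-wise
pixel overlap. Dual-view sensors are split into a green (top) and red
(bottom) view registered by a rigid translation from configuration; full
affine registration is not attempted.

Branch fluorescence is the mean count per pixel over a polygonal ROI
(center-in-polygon inclusion) minus the mean over a user-drawn background
polygon; overlapping polygons warn and bias the value low.

## Statistics

Group comparisons use the two-tailed Wilcoxon–Mann–Whitney test: exact
enumeration when `n_a*n_b <= 400` and the pooled data are tie-free,
otherwise the normal approximation with tie and continuity corrections. A
variance-ratio F test is reported per comparison as a descriptive screen
only — it documents the variance heterogeneity that motivates a rank test
and never switches the method. Stars: * p<0.05, ** p<0.01, *** p<0.001; no
multiple-testing correction by default (a Holm option exists).

## Synthetic data: what it does and does not emulate

The generator produces the statistical structure the analysis assumes:
memoryless exponential go/stop switching (the simplest model of
alternating runs and pauses), constant-speed motion along branch polylines
with per-go-phase direction reversals, isotropic per-frame positional
jitter (default 10 nm SD — cargo wiggle plus localization-scale disorder),
a planted static fraction, and an imaging model of pixel-integrated
Gaussian spots (`sqrt(sigma_psf**2 + sigma_obj**2)`) under Poisson shot
noise, flat background and Gaussian read noise. By default each particle
occupies its own horizontal lane with guaranteed lateral spacing,
emulating cargoes on distinct neurites.

It deliberately omits: photobleaching and blinking (the tracer of interest
is photostable), EM-gain excess noise, axial defocus, heterogeneous
per-cargo speeds, crossing trajectories, and real branch morphology.
Passing recovery tests therefore demonstrates correctness of the analysis
chain under its stated assumptions — not robustness to crossing tracks,
blinking emitters or motion heterogeneity in real recordings.

## Problem sizes used in validation

The recovery experiments run at a reduced field of view chosen to keep one
lane per particle: 100 particles on 384×1024 px (≈31×82 µm), 2 min at
20 Hz, ~2000 detected photons per spot per frame over background 20
(peak-SNR ≈ 12). Morphometry uses 25 static emitters per object size on
256×256 px for 20 frames at 5000 photons; colocalization uses 50 green
trajectories, a planted 0.40 paired fraction with 50 nm binding jitter and
60 red distractors over 60 s; test calibration uses 1000 null datasets of
30+30 samples. Parser-reference equivalence is checked frame-for-frame on
1000 simulated trajectories spanning randomized kinetics and parser
settings.

## Known limitations

* The confinement-ratio parser is threshold-based; its pause statistics
  carry the structural biases quantified above, and the acceptance window
  default is tuned to ~1 s pauses at 20 Hz.
* Anterograde vs retrograde direction and axon vs dendrite attribution are
  not attempted.
* Trajectories are pooled across fields of view in statistics; no
  hierarchical (coverslip/culture) modelling.
* Channel registration is translation-only.
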