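# Methods

This note documents the models, parameter choices and numerical decisions
behind `trackmel`, in the spirit of a methods supplement: what is simulated,
what is estimated, and what the defaults mean.

## Excitation model

The excitation profile is one engineered PSF containing three Gaussian foci
placed on the perimeter of a circle of 2 µm diameter, with axial offsets
(−400, 0, +400) nm. Each focus is modeled as a separable Gaussian intensity
`exp(−2ρ²/w_l² − 2δz²/w_a²)` with lateral 1/e² radius `w_l = 250 nm` and
axial 1/e² half-length `w_a = 600 nm` by default. The instrument these
numbers idealize does not publish its measured waists; the defaults are
diffraction-limited-scale round numbers and are configurable
(`BeamGeometry`). Two consequences worth keeping in mind:

- An ideal Gaussian triplet carries **more** position information than a
  real SLM-engineered, aberrated profile measured through a camera. All
  resolution figures produced with the synthetic PSF are therefore
  information-limit figures, a few tens of percent better than an
  as-built instrument would measure. The pipeline accepts measured TIFF
  z-stacks (`load_psf_stack` + `interpolate_psf`) for realistic profiles.
- The default pair (250, 600) treats the lateral and axial widths as
  independent knobs; a physically consistent focused beam with
  `w_l = 250 nm` would have a somewhat longer axial extent.

A shot places one selected focus at a lateral target by displacing the whole
PSF; an aperture suppresses the other two foci (at ≥ 1 µm distance their
Gaussian tails are ≲ 1e−8 of peak, so the displaced full PSF is used
directly). The axial coordinate of a shot is carried by *which* focus is
selected, not by a physical z-move — this mirrors the optical design and
means the localization layer only ever sees PSF displacement vectors.

Measured stacks are resampled to 10 nm voxels with separable cubic splines
(z first, then xy). The instrument's own interpolation propagates a
phase-retrieved light field between planes; at camera sampling scales the
field is smooth, and a spline reproduces an analytically sampled Gaussian to
better than 2% — the substitution changes nothing the estimator can see.

## Tracking pattern

Per z-plane, 13 points: the center, an inner square at (±237.5, ±237.5) nm,
and an outer ring of 8 points on the square of side 950 nm. The inner
square is the slow-reporter (MINFLUX-like) unit; the outer ring extends
coverage to fast reporters. The exact instrument coordinates are not
published; this layout spans the stated 950 nm lateral volume and is
configurable (`PatternConfig.layout_xy`), as is the intra-plane visiting
order (default serpentine, minimizing large moves). Each plane's shots run
contiguously — one axial layer completes before the next, minimizing axial
moves — and each layer change costs one blank 20 µs slot. Totals: 42 slots,
3 blanks, 0.84 ms per pattern, with a 10 µs beam-move + 10 µs excitation
split within each slot.

## MAP localization

Per pattern, the cross-entropy negative log-likelihood is evaluated on a
10 nm lattice and minimized together with the priors:

- `T_c`: binary bound on the implied photon efficiency
  c̃(r) = Σnᵢ / ΣΦᵢ(r). Defaults c_min = 0, c_max = ∞ (the bound exists to
  exclude low-power regions in difficult data; by default it only removes
  voxels below the attainability floor).
- `G_c`: Gaussian penalty (ĉ − c̃(r))²/(2σ_c²) around the efficiency EWMA ĉ
  with weight γ_c = 0.05 (long tail, averages over blinking) and
  σ_c = 0.5·ĉ. Skipped until an efficiency history exists (ĉ > 0).
- `G_r`: per-axis Gaussian jump penalty around the position EWMA r̂ with
  weight γ_r = 0.5 (short tail) and width σ_r from a configured FWHM
  (default 470 nm on all axes, σ = FWHM/(2√(2 ln 2)) ≈ 199.6 nm). At the
  0.84 ms pattern period this corresponds to a diffusion ceiling
  σ²/(2Δt) ≈ 24 µm²/s. r̂ starts at the volume center.

The paper-facing prior weights (γ_c, σ_c, γ_r, c bounds) are not published;
the defaults above are deliberately weak and configurable, and the neutral
limit (γ_c = 1, σ_c → ∞, σ_r → ∞, c_max = ∞, r_tail = 1) provably reduces
the estimator to the plain cross-entropy MLE (asserted in the tests).

**Search.** Coarse-to-fine lattice search (80 nm → 10 nm) inside a window of
±600 nm around r̂ — wider than the 3σ reach of the jump prior, so the prior
rather than the window bounds admissible jumps — clipped to the
950 × 950 × 1390 nm reconstruction volume around the current pattern
center. The lattice is anchored at the world origin, so estimates are
reproducible voxel positions. Ties are broken toward r̂, then by lowest
linear index. Voxels with ΣΦ below 1e−6 of the PSF peak are unattainable;
a zero model intensity at a positive count makes a voxel impossible.
Correctness of the two-stage search is cross-checked against exhaustive
10 nm search in the tests.

**Likelihood tail averaging.** With ratio r_tail < 1 the raw likelihood grid
is exponentially averaged over patterns before priors are added, pooling an
effective 1/r_tail patterns of photons. The averaged grid lives on a fixed
lattice window that recenters only when r̂ leaves its inner half: voxels
freshly exposed by a window move have no history and a higher-variance
value, and letting them compete for the argmin every pattern biases the
estimate toward window faces (visible as inflated axial scatter). Anchored
recentering removes the artifact; fresh voxels are initialized with the
current likelihood. Default r_tail = 1 (no averaging).

**CRLB.** The ratio likelihood is multinomial with cell probabilities
pᵢ(r) = Φᵢ/ΣΦᵢ; Fisher information is computed by central finite
differences (δ = 2 nm) and inverted by eigendecomposition, reporting inf
for axes in the null space. The bound scales as 1/√N and is validated
against a hand-derived closed form for a 1D two-beam pattern (the cell
probability is logistic in x, giving I = N(8a/w²)² p(1−p)).

## Simulation

- **Stage paths**: xy circle (default radius 750 nm) plus an axial sinusoid
  (default 0.5 µm peak-to-peak), one cycle per second, optional pause —
  the bead-scan protocol used for resolution evaluation.
- **Cell geometry**: spherocylinder, cylinder length 2000 nm + radius
  400 nm hemispherical caps (a typical *E. coli* envelope; configurable).
  The membrane reflects: an out-of-bounds step is mirrored across the
  surface (iterated for pathological steps). Interior step statistics are
  verified unperturbed by a KS test.
- **State switching**: continuous-time Markov chain simulated exactly
  (Gillespie dwell times, then read off per 20 µs slot). The default
  three-state model is D = (0.1, 1.4, 6.0) µm²/s — long-lived binding,
  short-lived site interrogation, free diffusion — with generator rates
  chosen to give mean dwells of 23.9 / 5 / 10.8 ms and stationary
  occupancies ≈ 43 / 18 / 39%. The published experiment's exact rate
  matrix lives in unpublished supplementary material; these defaults
  reproduce its stated occupancies and its defining feature, an
  intermediate state too short-lived to resolve.
- **Photons**: independent Poisson draws per illuminated slot with mean
  c·Φ(r_p − rᵢ) plus optional constant background; blanks are always dark.
  The emitter position updates every 20 µs slot, so motion blur enters at
  single-shot granularity; motion within the 10 µs excitation window is
  ignored. The photon efficiency is calibrated so an emitter at the
  pattern center yields the configured detected rate (default 60 kHz,
  ≈ 50 counts per pattern).
- **Feedback**: photon-weighted centroid of the effective focus positions
  over a sliding window of two full patterns, fed to a discrete PI
  controller (K_p = 0.4, K_i = 0.05 per pattern) that moves the pattern
  center in all three axes once per pattern. The instrument splits this
  across an FPGA centroid, a tip/tilt piezo and a slow z-stage; collapsing
  it into one controller preserves the statistics the reconstruction sees
  (shot positions are known exactly either way). The default gains hold a
  6 µm²/s diffuser inside the tracking volume ≥ 90% of slots at 60 kHz.
- Bleaching (exponential lifetime) is off by default so tests are
  deterministic in length.

## Diffusion estimation

Displacements over lag j of a pure-diffusion track with localization error σ
and blur factor R have covariance 2D(j−2R)Δt + 2σ² on the diagonal,
2D(j−|k−k′|)Δt on the inner bands, 2DRΔt − σ² at |k−k′| = j and 0 beyond —
verified against ensemble simulations in every band. The ECVE uses the
first off-diagonal, which is σ-free for j ≥ 2: D̃ = ⟨Δ_{k,j}Δ_{k+1,j}⟩ /
(2Δt(j−1)); σ² then follows from the diagonal. Defaults j = 8 with 16
consecutive products per sliding window (stride 1); per-axis estimates are
averaged over the axes (the scalar-combination rule is not published;
averaging axes is the natural isotropic choice). Windows never straddle
localization gaps, and nothing is imputed. Negative small-sample σ²
estimates are reported as-is with a flag. The blur factor of the actual
shot schedule (39 × 10 µs windows spread over 0.84 ms) evaluates to
R ≈ 0.165, close to the uniform-shutter 1/6.

Caveat: sliding ECVE windows over a reconstructed track are autocorrelated,
and localization errors of consecutive patterns are weakly correlated
through the jump prior's EWMA — both inflate slow-state diffusion estimates
above the iid-noise theory. This is visible as a slow-state mean above its
ground truth in the end-to-end pipeline, consistent with the method's
published full-scale behavior.

## Diffusion-state HMM

Inverse-gamma emissions capture the positive support and heavy right tail
of windowed diffusion estimates. Baum–Welch EM with scaled
forward–backward; the M-step is exact (β = α/⟨1/x⟩ in closed form, α by
Brent root-finding on ln α − ψ(α) = ⟨ln x⟩ + ln⟨1/x⟩, which is nonnegative
by Jensen). Initialization by k-means on ln D̃ with sticky transitions;
20 random restarts by default, 500 iterations max, relative tolerance
1e−8; log-likelihood monotonicity is asserted per iteration. Non-positive
D̃ inputs are floored at 1e−4 µm²/s with a logged count. States are
reported sorted by emission mean (resolving label switching). Occupancy is
the Viterbi state fraction (posterior-weighted occupancy is available as an
option; the published convention is not stated, and the two agree for
well-separated states). Bootstrap SEs resample whole trajectories
(default B = 200), match states by sorted means, and exclude degenerate
refits with a logged count. The HMM consumes the stride-1 sliding ECVE
series, whose autocorrelation the emission model does not represent —
transition-rate estimates are therefore biased toward stickiness, and the
bootstrap (which resamples trajectories, not windows) is the honest
uncertainty measure.

## Problem sizes and determinism

The test suite and the acceptance script run everything from scratch with
seeded generators (`numpy.random.default_rng`; bit-identical photon streams
per seed). Ensemble sizes were chosen as the smallest that keep Monte-Carlo
slack well below the assertion tolerances: 400 × 400-step tracks for the
covariance oracle, 1e5-step tracks for estimator recovery, 100 × 200-point
chains for HMM recovery, 500 repeated patterns for the CRLB-efficiency
check, and 30 cell trajectories (of the experiment's 100, lengths
50–800 ms) for the end-to-end state-mixing property.

## Known limitations

- Ideal synthetic optics: no aberrations, no camera noise in the PSF, no
  detector dead time, no afterpulsing; resolution figures are
  information-limit values (see Excitation model).
- Photophysics is Poisson emission plus optional bleaching — no blinking
  model (the G_c prior exists to tolerate it, but the simulator does not
  generate it).
- The feedback stand-in has no piezo dynamics (instantaneous moves, no
  hysteresis or resonance), so stage-induced tracking errors are absent.
- No model selection over K beyond reported log-likelihood.
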