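# Methods

This note documents the models, estimators and numerical choices behind
`whiskmech`, what its synthetic data do and do not emulate, and the known
limitations of each stage.

## Beam model and FEM solution

A whisker shaft is a linearly tapered Euler-Bernoulli cantilever: radius
r(x) = r_b − (r_b − r_t)x/L, area A = πr², second moment J = πr⁴/4, with
Young's modulus E, density ρ, and Rayleigh damping (mass coefficient α in
1/s, stiffness coefficient β in s). The base is clamped but driven by an
imposed transverse displacement; the tip is free. Euler-Bernoulli theory is
appropriate because whiskers are extremely slender (L/r_b ≈ 500); shear
deformation, rotary inertia, intrinsic curvature, large deflections and
follicle compliance are all neglected.

**Discretisation.** Two-node Hermite-cubic beam elements (deflection +
rotation per node), 200 uniform elements by default. Element integrals use
6-point Gauss-Legendre quadrature, exact for the degree-8 integrands that
the quartic J(x) produces against the cubic shapes. The free-free stiffness
matrix retains its rigid-body null space until boundary conditions are
applied, and the rigid-translation mass equals the closed-form frustum mass
ρπL(r_b² + r_b r_t + r_t²)/3 to machine precision — both are regression
tests. Convergence: the first three modal frequencies change by < 10⁻⁴
relative from 100 to 200 elements, and for an untapered rod they agree with
the roots of cos λ cosh λ = −1 to better than 0.1%.

**Frequency-domain solve.** For each ω the complex banded system
[(s² + sα)M + (1 + sβ)K]u = 0, s = iω, is solved with the base deflection
constrained to 1 and base rotation to 0 (LAPACK banded LU; the two
constrained columns move to the right-hand side). Free-tip conditions are
natural in the weak form. H(0, ω) = 1 holds exactly by construction;
H → 1 everywhere as ω → 0 (rigid quasi-static translation). With zero
damping the system is singular at resonances; the solver detects the
non-finite solve and reports the offending frequency.

**Defaults.** D2-like geometry L = 30 mm, r_b = 60 µm, r_t = 3 µm;
E = 3 GPa, ρ = 1200 kg/m³ (keratin-like), α = 10 s⁻¹, β = 2×10⁻⁵ s. These
are literature-scale stand-ins, exposed in the config (`length_mm`,
`base_radius_um`, `tip_radius_um`, `E_GPa`, `rho_kg_m3`, `alpha_per_s`,
`beta_s`, `n_elements`, `f_min_hz`, `f_max_hz`, `df_hz`); every test
property is checked against closed forms or relative contrasts rather than
absolute resonance values. The default frequency grid is 1–1000 Hz at 1 Hz
(1000 Hz is the Nyquist frequency of a 2000 fps camera).

## Video tracking

Per frame: (1) pixels above threshold inside the ROI are the whisker
candidates — per-frame Otsu by default (invariant under global intensity
rescaling; a fixed absolute threshold is available); (2) a parametric cubic
B-spline is fitted to the point cloud (scipy `splprep`), with points
ordered by projection onto the cloud's first principal axis and weighted by
normalised intensity; (3) the curve is resampled at N = 25 positions
equally spaced in arclength (dense evaluation + monotone inversion of the
cumulative arclength), oriented base-first using the ROI edge nearest the
follicle. The deflection of sample i at frame t is its image-row coordinate
minus its temporal mean over the trial (the rest shape is not otherwise
defined), so the N×T deflection field is zero-mean per row; row 0 doubles
as the estimate of the shaker input.

The default spline smoothing bound is 0.25 per point, i.e. roughly
half-pixel RMS residuals from thresholding quantisation. Measured accuracy
on rendered ground truth: ≈ 0.04 px RMS for rigid translations; 0.1–0.3 px
at the distal samples of strongly bent shapes. Two known error sources grow
with deflection amplitude: spline end wobble (weakly constrained ends) and
the difference between arclength position on the deformed curve and
material position on the shaft, which scales with slope². Tracked videos
should therefore keep peak deflections small relative to the imaged length,
exactly as the physical experiment does by choosing the drive amplitude.

## Spectral estimation and the similarity fingerprint

Each shaft position is an LTI system driven by the base motion, so its
transfer function is estimated as H_i(f) = S_{xy_i}(f)/S_{xx}(f) (H1
estimator, unbiased under output noise), with Welch spectra: Hann window,
1024-sample segments, 50% overlap, constant detrend — a 4500-sample trial
gives ~7 segments. Magnitudes are formed per trial and averaged
arithmetically across trials (10 by default). The retained band is
1–900 Hz, excluding the DC bin and near-Nyquist bins. Zero input power in
any retained bin is an error, not a NaN.

Similarity of two fingerprints: both magnitude matrices are interpolated to
a common normalised-position grid (and to the first argument's frequency
grid if needed), log₁₀-transformed (floor 10⁻¹²), vectorised, and compared
by squared Pearson correlation. This equals the OLS coefficient of
determination of the simple linear regression between the vectors and is
symmetric by construction; a linear-magnitude variant is available via
`log=False`. Similarity matrices are exactly symmetric with unit diagonal;
θ_i is the mean of all entries at diagonal offset i.

**Behaviour of the metric across length disparity.** For simulated sets
with default damping, log-mFRF R² between two whiskers decays from ≈ 0.9 at
~5% length difference to ≈ 0.35–0.43 once their resonance structures no
longer overlap — but it does not decay to zero: all tapered whiskers share
a smooth growth of log |H| along the shaft, which sets a cross-whisker
"envelope floor". Consequently θ_i declines monotonically only while
pairwise similarity remains above that floor. The canonical length-ordered
ladder (`LENGTH_LADDER_MM`, 45–56 mm in ~4.5% geometric steps) sits in that
regime; over a 3:1 length span θ flattens near the floor and can tick
upward at extreme offsets. Simulated sets use an allometric taper rule,
r_b = 2 µm per mm of length (the 30 mm default has a 60 µm base) with a
3 µm tip.

## Synthetic data

The generators emulate the ex vivo experiment with seeded, bit-reproducible
randomness (multi-trial sets derive streams as seed + trial index):

* **Stimulus** — Gaussian white noise at 2 kHz, 2.25 s, shaped by a
  Gaussian transfer function with gain ½ at the 1 kHz cutoff (the "−6 dB"
  reading of a Gaussian low-pass, since the nominal cutoff equals Nyquist),
  de-meaned, scaled to a chosen standard deviation.
* **Deflection fields** — exact LTI synthesis: inverse FFT of the stimulus
  spectrum times H interpolated to each normalised position (H = 1 below
  the FRF grid, edge-held above); optional additive Gaussian "tracking"
  noise. Circular convolution is intentional — the Welch estimator sees a
  perfectly stationary LTI record.
* **Rendered videos** — an anti-aliased Gaussian-profile ridge (σ = 0.8 px)
  on a dark background with additive Gaussian noise, the rest curve
  displaced vertically by the frame's deflections. Intensity is a function
  of vertical distance to the curve, near-exact for the shallow slopes of a
  shaken whisker; curves must be column-monotone (near-horizontal). No
  photorealism, shot noise, motion blur or optics are modelled, so tracking
  accuracy measured here is an upper bound for real footage.
* **Treatments** — dye: uniform density increase (default +0.7%, the
  measured mass bound), geometry and stiffness unchanged; polish: a
  deliberately severe coating analog (+30% density, +200% E) used only for
  qualitative contrast. Real coatings are nonuniform films that also change
  geometry; neither analog attempts that.
* **Photobleaching** — exp(−t/τ) plus Gaussian noise, clipped positive;
  τ defaults to 50,000 s (≈ 13.9 h, the measured fluorescence decay scale),
  sampled every 60 s for 7 h (421 samples).
* **Behavioural sessions** — per trial, two position-noise stimuli
  (Butterworth low-pass, 150 Hz, order 4, zero-phase) with amplitudes drawn
  from [0.5, 2.0]; "mean speed" is the time-averaged absolute velocity and
  the rewarded side is the faster one; ties are resampled. Agents: random
  (coin flip), ideal (always correct), noisy (correct iff the observed
  speed difference plus Gaussian noise has the right sign). No whisking
  kinematics, learning or bias is modelled.

Because the generators share the beam model with the solver under test, the
round-trip checks validate the *estimation* chain (Welch/H1, averaging,
similarity), and the closed-form beam oracles validate the solver
independently; passing tests say nothing about un-modelled properties of
real video (lighting, whisker crossings, camera noise statistics).

## Workflows and problem sizes

`run_simulation_study` runs whisker configs → FEM FRF → synthesized trials
→ averaged mFRFs → length-ordered similarity matrix, θ bands and a JSON
report (config hash, versions, seeds) that makes a run exactly
regenerable. `run_video_analysis` does the same from tracked frame stacks,
dropping a whisker only if all of its trials fail. The test suite exercises
the video path with 0.9 s trials at 192×256 px and a moderately damped
fixture whisker (β = 3×10⁻⁴ s): with the default light damping the tip's
resonant gain (~50×) would push the base motion below a pixel whenever the
tip stays in frame, which corrupts the H1 denominator — the same trade-off
the physical experiment resolves by choosing its drive amplitude. The
simulation-path suites use the default 2.25 s × 10-trial protocol.

## Auxiliary quantifications

The photobleaching fit is nonlinear least squares of a·exp(−t/τ),
initialised from a log-linear regression; a non-decaying trace raises
instead of returning a divergent τ. τ divided by the 2 s trial duration
gives the "equivalent trials" reading (25,000 for the default constant).
Mass increment is 100·(m_after − m_before)/m_before; behavioural
performance is percent correct; the before/after comparison enumerates all
n_before × n_after pairwise differences (the permutation-difference
distribution) with quantile summaries, and is exactly antisymmetric under
argument exchange.
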