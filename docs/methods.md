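# Methods

## Physical picture and coordinate conventions

In diffracted X-ray tracking a nanocrystal rigidly attached to a surface-
immobilised protein is illuminated with a broadband ("white") X-ray beam.
Each lattice reflection of the crystal produces a Laue spot wherever Bragg's
law λ = 2d·sin θ_B is satisfied within the beam's energy band, so the spot
survives continuous crystal re-orientation as long as the reflection stays
inside the band.  Two rotational degrees of freedom are observable on a flat
detector:

* **twist χ** — rotation about the beam axis.  A twist of δ moves the spot
  azimuthally by δ, so χ is taken as the azimuth of the spot about the beam
  centre (counter-clockwise, zero along the +x detector axis).
* **tilt θ** — rotation of the lattice plane normal.  A tilt of δ changes
  the scattering angle by 2δ, so θ = ½·arctan(r·pitch/L), with r the radial
  spot distance in pixels, pitch the pixel size (default 0.172 mm, the
  PILATUS pitch) and L the sample–detector distance.

Both angles are stored in milliradians.  χ is defined modulo 2π·10³ mrad and
is unwrapped to the branch nearest the previous sample before displacements
are formed, so ring crossings of the ±π cut stay continuous.

Neither the camera length nor the energy band is fixed by the recording
geometry this package targets; both are configuration values (placeholder
defaults L is user-supplied, band 10–20 keV).  The ZnO reflection d-spacings
used for ring gating are derived from the wurtzite lattice constants
a = 3.2495 Å, c = 5.2069 Å via 1/d² = 4/3·(h²+hk+k²)/a² + l²/c², giving
d(110) = a/2 = 1.62475 Å and d(103) = 1.47726 Å.  They are configuration
values, not constants, so other nanocrystals can be described.

## Spot detection and linking

Frames are background-corrected with a rolling median over a window of
3 × `min_spot_diameter` pixels (spots occupy well under half the window, so
they do not bias their own background); negative residuals are clipped to
zero.  For integer count images the median is computed with a histogram-
based rank filter, which is exact and an order of magnitude faster than a
sorting median; float images fall back to the generic filter.

Detection takes local maxima above an absolute threshold and refines each to
an intensity-weighted centroid over a window of half-width
`min_spot_diameter`.  The window is deliberately wider than the PSF core: a
window that truncates the PSF tails biases the centroid toward the pixel
grid.  Consequently two spots closer than the window partially share pixels
and their centroids attract; the package targets the sparse-spot regime that
diffraction recordings actually produce (a handful of spots per ring).

Linking follows the Crocker–Grier formulation restricted to consecutive
frames: candidate pairs farther than `search_radius` are forbidden, and the
assignment minimising total squared displacement is found with the Hungarian
algorithm.  Forbidden pairs are encoded with a big-M cost, which makes the
solution maximise the number of feasible links first and minimise cost among
those — identical to the classic "unlinked costs r_max²" formulation because
every feasible link (cost ≤ r_max²) is cheaper than two terminations.
`memory = 0` by default: a trajectory's lifetime is its *continuous*
visibility, and bridging detection gaps would silently lengthen lifetimes;
gap bridging is available but off.  Tracks shorter than 2 frames are
dropped.

## Trajectories and displacement statistics

A trajectory's first sample defines its start time and angular origin; every
statistic below uses displacements **from the start**, not sliding-window
time averages.  (Sliding averages would mix time points at different ages of
the trajectory; the from-start convention matches how DXT trajectories are
anchored to the spot's emergence and makes the number of contributors per
lag explicit.)  A trajectory of lifetime T contributes exactly one
displacement to each lag Δt ≤ T and nothing beyond — so the per-lag count
`n_pairs` is non-increasing and no interpolation across missing frames is
ever performed.

* **MSD.**  MSD(Δt) is the mean of squared from-start displacements over
  all trajectories reaching Δt.  The 95 % band is a percentile bootstrap
  (default 1000 resamples, seeded) resampling whole trajectories — the
  trajectory, not the frame, is the independent unit.  A bootstrap was
  chosen over a normal-theory band because squared displacements are
  strongly skewed at small counts.
* **Diffusion coefficient.**  The DXT convention MSD = 4·D·t + A is fitted
  by ordinary least squares over the first five lags (0.1–0.5 s) by
  default; a single-lag "fit" cannot determine both slope and intercept,
  and five lags keep the fit inside the small-Δt regime the convention
  addresses.  For per-axis free diffusion with coefficient d the per-axis
  MSD is 2·d·t, so the fitted D equals d/2; the package keeps the 4Dt form
  because it is how DXT results are reported, and documents the factor
  instead of silently rescaling.  The intercept A absorbs static
  localisation error (white position noise adds a constant 2σ_loc² to every
  lag), which is why localisation noise does not bias D.
* **Displacement distributions.**  At each Δt the from-start displacements
  are fitted with a single Gaussian.  Default estimator: sample moments
  (mean, (n−1)-denominator SD) — the binning-free maximum-likelihood fit.
  A histogram least-squares variant (Freedman–Diaconis bins, nonlinear LSQ)
  is retained for fidelity to fitting plotted probability distributions;
  for Gaussian data the two coincide asymptotically.  μ(Δt) across the lag
  grid is the **mean transition** (rotational bias: for drift b, μ(Δt) =
  ∫₀^Δt b dt); σ(Δt) tracks broadening.  Grid points with fewer than 10
  samples are omitted, not extrapolated.
* **Lifetime groups.**  LT1 < 1.5 s ≤ LT2 < 4.0 s ≤ LT3 < 7.5 s ≤ LT4,
  lower bounds inclusive.  Lifetime is (n_frames − 1) × frame interval of
  the linked track.  Per-group statistics simply re-run the suite on the
  group's subset; groups with fewer than two usable trajectories report
  counts only.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes — it
is the package's test bed, not a physical diffraction simulator:

* Per axis, increments over one frame are exact Brownian steps:
  Normal(drift·Δt, 2·d·Δt).  No sub-stepping is needed because the
  coefficients are constant within a frame (piecewise drift changes only at
  frame boundaries in practice; the increment uses the integrated drift, so
  mid-interval breaks are also exact).
* Defaults mirror the target acquisition: frame interval 0.1 s, up to 500
  frames (50 s) per spot (5000 frames supported), d of order 0.1–10
  mrad²/s with χ motion typically exceeding θ, drift of order −3 mrad/s
  (−0.3 mrad per 0.1 s) when a bias preset is used.
* Lifetimes are Exponential(mean), discretized as
  n_steps = clip(floor(L/Δt), 1, max_frames − 1); the visible lifetime is
  n_steps·Δt.  The LT-group fractions of this law have a closed direct-
  summation form, used as the test oracle.
* One root seed drives everything; per-trajectory substreams are spawned by
  counter, so trajectory i is reproducible independently of ensemble size.
* The renderer places an isotropic Gaussian PSF (default σ 1.5 px,
  amplitude 1000 counts on a 10-count background) at each live trajectory's
  angles→pixels position and applies Poisson noise.  Spots mapping off the
  detector are an error, not a clip — silent clipping would corrupt
  recovered statistics.

What the generator does **not** emulate: polychromatic intensity variation
along the ring, spot-shape changes with Bragg angle, detector gaps and hot
pixels, intensity fluctuation from crystal wobble, or correlated multi-spot
motion from a shared molecule.  Passing the closed-loop tests therefore
demonstrates the correctness of the analysis chain on data satisfying its
own assumptions, not performance on raw beamline images.

## Problem sizes and numerical choices

* Recovery experiments use 1000–2000 trajectories of up to 500 frames;
  closed-loop experiments use twenty 50-spot movies of 100 frames at
  400×400 px (pooled n = 1000).  Fifty spots per ring keeps neighbour
  separation (≈ 18 px) beyond the centroid window, the sparse regime the
  detector geometry section assumes.
* With from-start displacements each trajectory contributes one sample per
  lag, so the relative standard error of a fitted MSD slope is ≈ √(3.1/n);
  n = 1000 gives ≈ 5.6 %.  Recovery tolerances in the tests (5–15 %) are
  read against this scaling.
* Lag grids must lie on the frame grid (tolerance 1e−9 s); off-grid lags
  are an error, never rounded silently.
* Table output uses 10 significant digits: byte-reproducible across runs
  and lossless to 1e−9 relative on read-back.
* Bootstrap percentiles are 2.5/97.5 with a fixed default seed; identical
  config + seed reproduces every pipeline output byte-for-byte (no
  timestamps enter file contents).

## Known limitations

* The tracker has no adaptive thresholding or ML detection; heavily
  overlapping spots merge (the brighter maximum wins).
* No anomalous-diffusion or confined-motion models; the MSD fit is strictly
  linear in t.
* No survival-analysis correction for lifetimes truncated by the recording
  window beyond the truncation itself.
* Whether published 95 % MSD bands are bootstrap or standard-error bands is
  generally unstated; the percentile bootstrap here is a documented choice,
  not a reproduction of any specific band construction.
* A time-averaged (sliding-window) MSD is not offered; the from-start
  convention is the single code path to keep contributor counts and
  censoring semantics unambiguous.
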