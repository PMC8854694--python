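# Methods note

Definitions, estimators and conventions implemented by `epiquant`. All
coordinates in track tables are micrometres in the midsagittal imaging
plane; image data use 0-based (row, col) pixel indexing with the origin at
the top-left; angles are degrees; lifetimes are nanoseconds.

## Daughter-cell kinematics (`epiquant.kinematics`)

**Jitter correction.** Rigid per-frame motion of the whole field (stage
drift, sample motion) shifts tracked points and the annotated
embryonic-region centre alike. `correct_jitter` expresses every position
relative to the per-frame centre, which removes any rigid translation
exactly (up to floating-point rounding) without modelling it.

**Displacement and direction.** For each division, the mother's position
immediately prior to division is the origin of two vectors: the *reference*
vector to the embryonic-region centre (the local apical direction in a
roughly circular tissue section) and each daughter's *movement* vector to
her final tracked position (optionally bounded by a follow-up horizon in
minutes). The net displacement *d* is the movement vector's length; the
direction angle θ ∈ [0°, 180°] is the angle between the two vectors.
θ < 90° is classified apical, θ > 90° basal; θ = 90° exactly is an event of
measure zero, assigned basal and flagged as a tie rather than dropped.

**Sibling labels.** Immediately after division the daughter nearer the
centre is the `apical_daughter`, her sister the `basal_daughter`; exact
ties are broken toward the lower track id and flagged.

**Division geometry.** The division-axis angle is the angle between the
inter-daughter vector and the midpoint-to-centre direction, folded to
[0°, 90°] because the axis is undirected, and binned as parallel (< 30°),
oblique (30–60°) or orthogonal (> 60°). The division position is the
distance from the mother's final position to the epiblast base, given as a
circle model, a point, or a polyline along the basement membrane.

Every analysis returns a report listing exclusions with reasons and tie
flags; nothing is silently dropped.

## Phasor-FLIM (`epiquant.flim`)

Decay stacks hold per-pixel photon histograms over N time bins spanning one
laser period T = 1/rep-rate (defaults: 20 MHz, N = 256, 135 nm pixels).
The pipeline is: sum non-overlapping k×k pixel blocks (default ×5, photon
counts ×25, pixel size ×5), mask pixels whose total count falls below a
background threshold, compute the first-harmonic phasor

G = Σ c(t) cos(ωt) / Σ c(t),  S = Σ c(t) sin(ωt) / Σ c(t)

with t at bin centres and ω = 2π/T, median-filter G and S over a w×w window
(default 5, NaN-aware: undefined pixels neither contribute nor get filled),
then invert to a lifetime per pixel. ROI statistics pool defined pixels
whose lifetime lies inside the probe's tension-sensitive window
(2.8–7 ns); pixels excluded by the window or the threshold are counted and
reported.

**Exact finite-bin-width lifetime inversion.** The textbook phase lifetime
τ = S/(ωG) is exact only in the continuous limit. A wrapped
mono-exponential integrated over N equal bins is a geometric sequence with
ratio r = exp(−Δ/τ), Δ = T/N, whose discrete phasor has phase

φ = ωΔ/2 + atan( r sin ωΔ / (1 − r cos ωΔ) ).

`lifetime_map` inverts this exactly: φ′ = atan2(S, G) − ωΔ/2,
r = sin φ′ / sin(ωΔ + φ′), τ = −Δ / ln r. With N = 256 the naive ratio
carries an O(1/N²) bias that reaches ≈ 1.3% at τ = 0.5 ns, while the exact
inversion recovers noiseless lifetimes to machine precision; the naive and
modulation estimators remain available as `method="phase_naive"` and
`"modulation"`. An optional complex calibration factor (from a reference of
known lifetime) applies the standard instrument phase/modulation
correction. Lifetimes approaching T/2π (≈ 7.96 ns at 20 MHz) enter the
phase-wrapping regime; the simulator warns when asked to generate them.

Lifetime TIFF I/O follows the vendor dialect of 0.01 ns per integer grey
level; float TIFFs are nanoseconds. Rendering clips to a display range
(default 3.75–4.75 ns) over a rainbow map with undefined pixels black —
display only, never used in statistics.

## Apical intensity profiles (`epiquant.profiles`)

Intensity is sampled along an annotated polyline with a configurable width
(default 3: the mean of three bilinear samples spaced one pixel apart along
the local perpendicular), the arc length is rescaled to percent of total
path length (the apical domain differs in absolute size between cells), and
intensities are divided by the mean inside the cell's nucleus polygon to
cancel depth-dependent attenuation — making profiles comparable across
cells and exactly invariant to global intensity scaling. Ensembles are
summarized either as per-position mean ± SD across junction paths on a
common percent grid, or as a LOWESS fit (default span 0.3) with a bootstrap
95% band that resamples cells with replacement within embryos, respecting
the experimental-unit structure (3 embryos × 5 cells per group).

## Migration metrics (`epiquant.migration`)

Per cell: movement = Σ segment lengths (µm); velocity = movement / elapsed
time (µm/min); directionality = movement / straight-line start-to-end
distance, which is ≥ 1 with 1 = perfectly straight. This is deliberately
the total/straight form (the reciprocal of the common "directionality
ratio"); `inverse=True` gives straight/total. A closed track has undefined
directionality and is reported with a note, not dropped.

## Statistics (`epiquant.stats`)

* **Fisher's exact test** (2×2, two-sided) uses the probability-mass
  definition — the sum of hypergeometric probabilities of all tables with
  the observed margins no more probable than the observed table — computed
  with exact integer numerators over a common denominator, so ties are
  handled without floating-point ambiguity.
* **Bonferroni** adjustment always takes the family size m explicitly
  (p → min(1, m·p)); raw and adjusted values are reported side by side.
* **Nested ANOVA** for measurements nested in units (embryos) nested in
  groups (genotypes) tests MS_group against MS_unit(group) with
  df = (g − 1, Σ units − g) — the correct error stratum when several
  measurements per embryo would otherwise pseudo-replicate. In balanced
  designs this equals one-way ANOVA on unit means.
* **One-way ANOVA + Tukey HSD**, pooled/Welch **t-tests**, and **box
  summaries** with min–max whiskers (the plotting convention used for small
  per-embryo samples) or Tukey 1.5·IQR fences with outliers listed.

Degenerate inputs (zero variance, empty margins) raise or are flagged
explicitly; every test result carries its statistic, df, raw p, adjusted p
and method.

## Synthetic data (`epiquant.synth`)

Generators produce raw-level data with recorded ground truth: division
track tables (INM-like apical approach of the mother, linear daughter
paths with drawn direction angles and displacements, per-daughter
apical/basal fates, optional rigid jitter and centre drift on a separate
random stream so geometry is identical with and without nuisance), FLIM
decay stacks (wrapped mono-exponential bin probabilities, Poisson shot
noise, uniform-in-time background), apical-pattern images (junctional
Gaussian spots versus a uniform ridge of matched integrated intensity,
nucleus filled at a known mean), and correlated-random-walk migration
tracks (von Mises turning increments). Ground-truth labels are recorded
before noise is applied, so they are invariant to it by construction. All
generators are deterministic given their seed.
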