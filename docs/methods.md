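# Methods

## The model

`blebsim` predicts where a migrating cell will bleb from the geometry of its
segmented outline.  A 2D cross-section of the cell is represented by two
closed polygons: the plasma membrane (N nodes at ~0.3 µm spacing) and the
actin cortex, an inward-parallel contour offset by the relaxed linker length
L₀ = 30 nm.  Corresponding membrane and cortex nodes are tied by linear
springs that stand for the local ensemble of membrane–cortex linker proteins
(Talin, ezrin-family).  The cortex is rigid on the blebbing timescale:
nucleation and early expansion are much faster than cortical remodeling, so
cortex nodes never move and broken linkers never rebind within a simulation.

The membrane energy is a discrete Helfrich-type functional,

    E = Σᵢ ½ (α/h)(ℓᵢ − x₀ᵢ)²                    (tension, per segment)
      + Σᵢ ½ β |xᵢ₊₁ − 2xᵢ + xᵢ₋₁|² / h³          (bending, per node)
      + Σᵢ ½ kᵢ (Lᵢ − L₀)²  over intact linkers    (membrane–cortex coupling)
      − Δp · A(membrane),                          (pressure work)

with ℓᵢ the segment lengths, x₀ᵢ the segment rest lengths, Lᵢ the linker
lengths, h the reference node spacing and A the enclosed area.  Intracellular
pressure acts on the membrane but not on the porous cortex; writing it as
−Δp·A makes its variational derivative an outward normal force of magnitude
Δp per unit contour length, which is the physics a bare constant term in the
integrand could not produce.

Two discretization choices matter and are deliberate:

* **Mesh consistency.**  Each discrete linker coarse-grains the linkers on
  one arc-length interval, so its spring constant is stiffness density ×
  spacing, kᵢ = k·h, and the tension prefactor is α/h.  With these scalings
  the energy is a Riemann sum of a fixed continuum density, and the
  sub-critical pressure and site ranking converge under mesh refinement
  (halving the spacing 0.3 → 0.15 → 0.075 µm changes p_sub by a few percent
  and preserves the order of the dominant sites).  A naive per-node constant
  k makes the linker stiffness density diverge as 1/h and roughly doubles
  p_sub at each refinement.
* **Tension-free start.**  x₀ᵢ is taken as the initial segment length
  (`x0_mode = initial`): the observed contour is the reference state and the
  readout is linker strain, not absolute tension.

Membrane movement is computed by minimizing E with gradient descent
(spatial derivatives by periodic finite differences, analytic energy
gradient, backtracking line search halving the step until the energy
decreases, step regrowth ×1.5 capped at `descent_step`).  Convergence is
declared when a full-size step would displace no node by more than
`grad_tol` (default 10⁻⁴ × spacing); the criterion is deliberately
step-independent so a recent line-search backtrack cannot fake convergence.
The energy is non-increasing at every accepted step, and the solver is fully
deterministic.

## Bleb-site prediction

Bleb propensity is read off at the **sub-critical pressure** — the largest
Δp at which relaxation stretches no linker beyond the critical extension
`L_crit`.  It is found by bisection: the bracket auto-doubles from `p_start`
(at most 12 doublings) and narrows to a relative width < 10⁻³, so relaxing
at the returned p_sub breaks nothing while 0.1% more pressure does.  At
p_sub the cyclic linker-extension profile is analysed: local maxima
(plateaus collapsing to their central node, round-down) are candidate
nucleation sites ranked by extension — rank 1 is the longest linker — and
each site's width spans the first local minima on either side of its peak.
Near-exact ties (relative difference ≤ 10⁻¹²) are broken by angular
proximity to the cell front, then by node index, so output is deterministic.
A perfect circle is a degenerate null: its profile is uniform and no site is
returned.

Because the maximum extension at a contour's own p_sub is pinned near
L_crit by construction, the "deeper notch ⇒ larger extension" monotonicity
is measured at one fixed pressure common to the notch family (0.8 × the
p_sub of the shallowest member), where it is a meaningful comparison.

The polarization axis is the major axis of a direct least-squares ellipse
fit (Halir–Flusser, via scikit-image), with the front end chosen by the mean
centroid displacement over the next 5 frames.  The optional front-to-rear
linker gradient multiplies stiffness by exp(λu), u ∈ [0,1] the normalized
projection onto the axis (0 = front) and λ = ln(1 + max_increase); the
default max_increase = 0.60 mirrors the measured ~60% front-to-rear increase
in membrane–cortex adhesion energy.  Stiffer rear linkers stretch less at a
given pressure, so the gradient demotes rear-flank sites and redirects the
top ranks to the cell front; only stiffness is graded, not L_crit, since the
evidence concerns linkage strength.

Early bleb expansion is overdamped: after linkers in a span have broken,
detached nodes move with velocity F/γ, γ = 6πηR the Stokes drag with R the
radius of a circular arc fitted (least-squares) to the detached span,
refitted each step and floored at one node spacing; attached nodes use the
floor radius.  Explicit time stepping halves dt whenever a step would raise
the energy, and stops once the motion achievable in the remaining time is
below 1% of the node spacing (forces balanced).

## Parameters

Defaults live in `src/blebsim/data/default_params.txt` (flat `key = value`)
and every run logs the full set.  Lengths are µm; α, β, k, Δp are model
units — only ratios, orderings and symmetry carry meaning, and every test
in the package is relative.  The geometric constants are physical:
spacing 0.3 µm, L₀ = 0.03 µm (30 nm).  `L_crit` = 0.015 µm is the critical
*extension* beyond L₀.  α = 1, β = 0.002, k = 1 were fixed once so that the
three energy scales compete on realistic shapes: with much larger β, deep
concave regions stretch linkers past L_crit by bending forces alone at zero
pressure (no finite sub-critical pressure exists); with much smaller β the
profile develops node-scale ripples.  η = 10⁻³ Pa·s is water.  Numerical
settings: descent_step 0.05, grad_tol 10⁻⁴ × spacing, max_iters 40 000,
dynamics dt 2×10⁻⁴ s, pressure bracket start 0.01.

## Bleb detection and evaluation

Observed blebs are found between consecutive frames: later-frame nodes are
classified against the earlier polygon (shapely; boundary points are not
"outside"), contiguous outside runs become candidates, and a candidate is a
bleb if its maximum point-to-boundary distance exceeds a threshold —
default 0.5 µm per 0.5 s frame, scaled linearly with the frame interval so
the criterion is an expansion *speed*.  Point-to-polygon distance (not
along normals) tolerates tangential drift.  The per-span protruded area is
the area of the polygon-difference component carrying the span.  Detections
carry a review flag in the output CSV in place of an interactive check.
Each bleb is matched to the predicted site whose width span contains the
earlier-contour node nearest the bleb apex; unmatched blebs are reported.

Evaluation compares the matched-rank distribution against the exact null in
which every site on a frame with n_f sites is equally likely (each bleb
contributes 1/n_f to ranks 1..n_f; a seeded Monte-Carlo mode exists for
resampling checks).  The global test is Pearson's χ² with class width 1,
tail classes pooled below expected count 5; per-class flags use
standardized residuals (O−E)/√E, two-sided at α = 0.001 with Bonferroni
correction over the pooled classes — the paper-style "***" marks are not a
specified procedure anywhere, so this documented choice is configurable.
Prediction quality is summarized by the area under the rank CDF as a
percentage of the theoretical maximum (100% = every bleb at rank 1;
uniform ranks over 1..R give 100·(R+1)/(2R)%).  Angular statistics use 15°
polar bins and the front-half fraction (angles in [0°,90°) ∪ (270°,360°),
0° = cell front).  The two-sample Kuiper test (V = max(F_a−F_b) +
max(F_b−F_a) on the circle, asymptotic p with effective n = n_a n_b/(n_a+n_b))
is implemented in-package; V is exactly invariant to a common rotation.
Mann–Whitney U uses exact enumeration for min(n) ≤ 8 without ties and the
tie-corrected normal approximation otherwise (scipy).

## Fluorescence

Per-node cortical intensities are min–max normalized per cell pooled over
all frames (constant signals map to 0.5 with a warning).  The front-to-rear
gradient is fitted as I = A·exp(B·|θ|/180°) + C on the angle folded about
the front (pooling both flanks; unfolded fitting is available).  The free
additive offset C is essential: per-cell normalization is affine, and only
with an offset is the rate B invariant under it (and under detector
background).  On noiseless synthetic data the fit recovers A and B to
machine precision; through the full normalize-then-fit pipeline B is exact
up to the small difference between the fitted axis and the generator's true
front.  Bleb–fluorescence correlation bins the normalized intensity at each
bleb's apex node into 10 equal-width bins and reports the Spearman rank
correlation between bin centre and bleb count.  With ten bins the Spearman
of a null (uniform) assignment has s.d. ≈ 1/3, so single-run values near
±0.3 are noise; conclusions should rest on constructions or datasets where
|ρ| is large (the front-concentrated construction used in the tests gives
ρ ≈ −0.8).

## Synthetic data

The generator supplies every fixture as a smooth polar curve r(φ) resampled
to 0.3 µm spacing: circles, ellipses, notched circles (Gaussian radial
indentation r = R − depth·exp(−(φ−φ₀)²/2w²), analytically differentiable so
curvature oracles are independent of the polygon), and polarized cells
(elongated ellipse, circularity < 0.6, with concave flank indentations;
front and rear flank depths can differ and extra dips can be planted).
Blebbing time series morph a base shape with slow drift (default 0.1
µm/frame), optional uniform scaling and a low-amplitude (0.03 µm)
three-mode radial wobble, all far below the 0.5 µm fast-expansion
threshold; planted blebs are single-frame outward bumps (default 1.2 µm
amplitude ≈ 2.4× threshold, 12° width) that persist in later frames as a
real bleb would, and pseudopods grow at 0.2 µm/frame.  Planted bumps have
compact support (Gaussian truncated at 3 widths): with infinite tails the
entire later contour sits microscopically outside the earlier one and
protrusion spans merge.  The fluorescence generator paints
A·exp(B|θ|/180°) + N(0, σ) about the generator's true front.  All
randomness flows from explicit `rng_seed` fields; identical (spec, seed)
reproduce outputs bit-for-bit.

What the generator does **not** emulate: segmentation noise correlated
along the contour, pixelation, uneven node spacing from real tracking,
cortex turnover, bleb retraction, or cells whose polarity axis turns during
the series.  Passing tests therefore demonstrate correctness of the
machinery and the claimed qualitative behaviors (curvature selectivity,
gradient redirection, detection logic, statistics), not performance on
microscope data.

## Numerical edge cases

* Contours are normalized CCW on input; an exactly repeated closing point
  is stripped; < 8 nodes, consecutive duplicates, zero area or (after
  resampling) self-intersection are rejected.
* The cortex offset is rejected if it self-intersects (pathological input
  at 30 nm this requires near-cusp geometry).
* A strictly uniform extension profile returns no sites (logged); the
  circle criterion instead bounds the profile spread.
* Kuiper p-values are clamped to [0, 1] and equal 1 below λ = 0.4.
* χ² expected counts are rescaled to the observed total before testing.
* The problem sizes used by the test-suite and the acceptance script
  (contours of 60–530 nodes, 3–25 frame series, 200 statistical
  replicates) were chosen as the smallest at which the measured quantities
  are stable; all are regenerated at run time from seeds.

## Known limitations

* Absolute pressures and energies are in model units; only the geometric
  lengths are physical.  Comparing p_sub across parameter files is
  meaningless unless α, β, k are held fixed.
* The 2D cross-section ignores out-of-plane curvature; the model is
  geometry-generic but calibrated for flattened (under-gel) cells.
* Gradient descent on fine meshes (0.075 µm) costs thousands of
  iterations; the solver favors robustness and determinism over speed.
* Single-linker stochastic unbinding kinetics are out of scope; linkers
  break deterministically at L_crit.
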