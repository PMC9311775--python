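# Methods

This note documents the models behind `spinetape`: what is computed, which
defaults matter, what the synthetic data do and do not emulate, and where
the design was genuinely open.

## Coordinates and units

Sagittal plane throughout: +x caudal along the mattress top, +y vertically
away from the mattress; lengths in mm, masses in kg, forces in N, pressures
in kPa, energies in N·mm. Curves are stored cranial end first with a
cumulative-arclength chart `s` (strictly increasing, `s[0] = 0`).

## Tape reconstruction

A tape element is three sagittal points (start, mid, end). It is classified
as a **line** when the midpoint's perpendicular distance to the start–end
chord is below 0.05 mm (an order of magnitude below plausible sensor
resolution, configurable), otherwise as an **arc** through the circumscribed
circle of the three points; the angular sweep is chosen to traverse the
midpoint. Element arclength is the chord length (line) or `R·|sweep|`
(arc).

Chaining samples each element at 20 points (≈1.5 mm spacing, well below
every stated tolerance) and concatenates them. Junctions are closed by
rigidly **translating** the later element — never rotating, because
inclination-sensing tapes measure orientation per segment and translation
preserves it. A warning is emitted when the original endpoint gap exceeds
0.5 mm (`gap_tol`); smaller gaps are closed silently. Whether the device
reports elements in one global frame or per-element frames is not
documented for such tapes; translation repair covers both readings.

Resampling redistributes points at equal arclength; the arclength chart is
carried over exactly, so resampling is idempotent and length-preserving by
construction.

## Spine parameters

Region boundaries along the tape are **not** anatomically fixed — the
device does not know where vertebral levels sit. They are arclength
fractions (head [0, 0.05), cervical [0.05, 0.20), thoracic [0.20, 0.55),
lumbar [0.55, 0.75), sacral [0.75, 0.90]), anthropometric estimates exposed
in `RegionPartition` and threaded through every API.

The torso-inclination (TI) line is the *common support line* of the
thoracic and sacral regions on the mattress side, computed from the lower
convex hull of the union of the two point sets: the hull edge with one
endpoint in each region. Supporting-line geometry makes the construction
exact and O(n log n); a brute-force pair search is kept as a test oracle.
"Lower" is taken in the package's global frame, which assumes curves are
oriented within the coordinate convention (support direction within 45° of
+x) — satisfied by construction for tape data laid along the mattress.

HD is the perpendicular distance of the cranial tape endpoint to the TI
line (the head landmark is the tape end; a vertex/occiput distinction is
not resolvable from tape data). CLD and LLD are regional *maxima* of
perpendicular distance (apex heights). Perpendicular rather than vertical
distance makes HD/CLD/LLD rigid-motion invariant; TI is reported as the
absolute angle to +x, folded into [0°, 90°). A head point below the support
line is physically odd for a supine posture; HD is clipped to zero with a
warning rather than raising.

## Synthetic profiles and cohorts

`make_profile` inverts the extraction: working in the frame where the
support line is the x-axis, it places knots at the target arclength
fractions — cranial endpoint at height HD, cervical apex at CLD,
thoracic tangent at 0, lumbar apex at LLD, sacral tangent at 0, flat tail —
and interpolates with a shape-preserving monotone cubic (PCHIP). PCHIP sets
zero derivatives at extrema knots, so the tangent points touch the baseline
exactly and the lobes peak exactly at the apex knots; no separate smoothing
pass is applied, because any averaging window would lower the apex heights
and defeat the exact round trip. An extra knot caps the cervical region at
CLD when HD > CLD. The spline is built over horizontal position and
iteratively reparametrized (≤40 fixed-point steps, 2·10⁻⁴ tolerance) so
that total arclength equals the requested length (default 870 mm) and knots
sit at their arclength fractions; the whole curve is then rotated by TI.
Round-trip error of construct→extract is below 0.01 mm / 0.001° in
practice, against the 1 mm / 0.2° contract.

**Feasibility.** Not every parameter quadruple admits a curve: the descent
from the head to the cervical apex must fit inside the head region's
arclength, and each lobe's rise/fall must fit its region. The rule
`|Δheight| ≤ 0.8 · Δarclength` between adjacent knots (slope ≈ 39°)
encodes this; `is_feasible` exposes it and `make_profile` raises on
violation. Heights are additionally capped at 35% of the curve length.

`sample_tape` cuts a curve into equal-arclength elements and takes each
piece's start/mid/end points, adding isotropic Gaussian noise per
coordinate (default SD 0.5 mm, a plausible sensor resolution). The tape is
one continuous strip, so the junction shared by adjacent elements receives
a single noise draw. Noise-free sampling followed by chaining reproduces
smooth (C²) curves to within 0.2 mm Hausdorff; profiles built by
`make_profile` have curvature jumps at knots that 3-point arcs cannot
represent, and can deviate by ≈0.25 mm locally — one reason extraction
tolerances are quoted at the millimetre, not micron, level.

Cohorts emulate a 16-participant, three-mattress randomized crossover. The
per-condition parameter means/SDs (soft SM, medium MM, hard HM) are the
package defaults, e.g. HD = 85.8 ± 21.5 mm on SM vs 55.3 ± 8.9 mm on MM.
Values are zero-truncated normal draws; a per-parameter participant random
effect shares a fraction ρ (default 0.5, configurable — marginal statistics
only are published, so inter-condition correlation is a free knob) of the
variance across conditions. Plain parameter tables use zero-truncation
only, preserving the stated marginals; when curves are materialized,
parameter vectors that fail the feasibility rule are re-drawn (up to 100
times), which perturbs the SM marginals by ~2% of an SD. With ρ = 1 and a
condition mean within ~1.5 SD of zero, the shared effect can make the
truncated draw unsatisfiable; the generator raises rather than silently
clipping. All randomness flows from a single integer seed; identical specs
yield byte-identical cohorts.

What the generator does **not** emulate: inter-parameter correlation beyond
the shared participant effect, sensor drift or breathing motion, the
physical coupling between mattress stiffness and an individual's curve
(conditions are drawn from their marginal distributions, not simulated
mechanically), and the soft foam supporter used under the tape on hard
mattresses (the tape is assumed to contact the back everywhere). Passing
tests therefore demonstrate the correctness of the *pipeline* — geometry,
statistics, mechanics — not fidelity to any individual human back.

## Foam materials and foundations

Stress–strain tables must start at (0, 0) with strictly increasing strain
and non-decreasing stress; they are interpolated with a monotone cubic
(exact at data points) and extended linearly beyond the last strain with
the terminal slope. The bundled tables are **synthetic**, as their
filenames state: smooth curves with the classic foam shape (exponential
elastic toe, plateau, `ε⁶` densification), scaled so the surrogate 25%
indentation load deflection on the standard 323 cm² (50 in²) indenter is
20 / 42 / 120 lbf for SM / MM / HM, and the pillow 5% above MM (the pillow
foam behaves like the medium mattress). The surrogate ILD is uniaxial —
`sigma(0.25) × area` — so only stiffness orderings, never absolute lbf,
should be read from it.

The near-zero Poisson ratio of these foams (ν = 0.01) justifies a
Winkler (independent-column) foundation: `p(w) = sigma(w / t)` for a slab
of thickness `t`. Layer stacks (pillow over mattress) compress in series:
the unique equal-stress split is found by monotone root solving (1e-6 kPa).
Deflection beyond 95% of stack thickness raises a densification error.

## Equilibrium mechanics

The body is a chain of 29 nodes (head, C1–C7, T1–T12, L1–L5, sacrum,
thigh, shank, heel) at stature-scaled x positions. Masses follow fixed
segment fractions (head 8.1%, trunk 59.7% including both arms — folded in
because the supine posture keeps arms parallel to the trunk — thighs 20%,
shanks 9.3%, feet 2.9%), with trunk mass weighted toward the caudal end;
node masses sum to total mass exactly. Each node has an effective contact
width (head 150, trunk 300, sacrum 350, calf 150, heel 80 mm …)
converting line loads to pressures and tributary spans to areas. Joints
carry axial springs (cervical 500, thoracic 1000, lumbar 1800, legs
5000 N/mm — literature-scale disc stiffnesses, config-overridable) and
bending springs at internal nodes; spinal ligaments add tension-only
skip-one springs with stiffness `E·A/L` from tabulated moduli. Those
moduli are kept in kPa *as tabulated* behind a `ligament_unit_scale`
config defaulting to 1: published ligament moduli are MPa-scale, so the
tabulated kPa values are likely a units slip, but at either scale the
ligament contribution is far below the joint springs in this loading
regime; a scale of 1000 restores MPa.

Only vertical nodal positions are unknowns (consistent with the columnar
foundation). Total potential energy = gravity + axial + bending + ligament
+ foundation strain energy (the integral of the column law over deflection,
per tributary area), with unilateral contact entering through the
`max(0, ·)` deflection. Foundation laws are tabulated once per solve on a
200-point grid so the piecewise-linear pressure and its piecewise-quadratic
energy stay exactly consistent (C¹) during minimization. L-BFGS-B with the
analytic gradient, a fixed initial guess (rest profile lowered to first
contact), `ftol` 1e-15, `gtol` 1e-7 and up to 200 line-search steps makes
the solve deterministic; the recorded energy trace is non-increasing. At
stationarity the internal forces telescope, so total contact force equals
body weight; a relative force-balance residual above 0.5% raises a
diagnostic error carrying the energy trace. The rigid-foundation limit
(laws scaled ×10⁶) converges to sub-micron deflections.

The cervical pillow is a 90 mm foam layer stacked on the mattress over a
350 mm extent at the head end (footprint 550 × 350 mm). This directly
encodes the load-spreading mechanism: a pillow stiffer than the mattress
beneath it acts as a plate, holding the craniocervical region up while the
torso sinks — visible in the model as the cervical disc-load proxy rising
monotonically with pillow stiffness. Pillow–mattress friction has no role
in a vertical-column model and is out of scope.

Outputs: per-node pressure and per-region peaks (occiput, cervical,
scapula, buttock, calf, heel); contact area above a 1 kPa threshold
(tributary area of qualifying nodes, split pillow/mattress); per-disc load
proxy `|F|/A + |M|·c/I` with circular-disc geometry from a shipped
literature-scale area table (C2-C3 230 mm² … L5-S1 1700 mm²), peak per
spinal region; and a torso-inclination proxy, the angle of the
chest-to-pelvis *deflection* line (deflections, not positions, so a
bridging non-contacting upper back reads zero).

**Scope statement.** This is a planar, lumped surrogate: no 3-D contact,
no shear or friction, no muscle activation (muscles assumed relaxed in
supine rest), no viscoelasticity, no lateral postures. Quantitative
agreement with pressure-mat or finite-element values is *not* claimed;
the model is built and tested for orderings (softer ⇒ larger contact area,
lower buttock peak; stiffer pillow ⇒ higher cervical disc load) and
conservation properties (force balance, energy descent).

## Statistics and reporting

Crossover contrasts use participant-wise paired differences per parameter
and condition pair: paired two-sided t-test (Wilcoxon signed-rank as a
config alternative — the choice cannot be settled from significance stars
alone), Holm-adjusted across the three pairs of each parameter. Degenerate
zero-variance differences are defined as p = 1 (identically zero) or p = 0
(nonzero), so SD-0 synthetic cohorts behave sensibly. Validation follows
the standard rule labelling Pearson r in [0.7, 1.0] a strong positive
linear relationship; the pipeline correlates parameters recovered through
the full measurement chain against the generator's ground truth, pooled
across the four parameters, and reaches r ≈ 0.99 at the default 0.5 mm
sensor noise.

The pipeline (`run_pipeline` / `spinetape run-all`) is deterministic from
one seed: cohort → tape simulation → reconstruction → extraction →
contrasts → validation → per-condition mechanics, written as JSON + CSV
with stable key ordering so repeated runs produce identical checksums.

## Problem sizes

Defaults keep every stage interactive on one core: 16-participant cohorts
(~0.1 s), 870-point curve reconstructions, 29-node equilibrium solves
(~1 s each), 20-scenario property sweeps (~1 min), 100-profile round-trip
suites (~10 s). Larger cohorts (n = 2000) are used for moment checks with
curve generation disabled.

## Known limitations

- Region boundaries are fixed arclength fractions; real vertebral levels
  vary between individuals, so extracted CLD/LLD are apex heights of
  *regions*, not of named vertebrae.
- The tangent-point construction assumes a single common support line; a
  reading with two separate tangent lines would differ for strongly
  kyphotic profiles.
- Synthetic profile curvature is only C¹ at knots; tape arcs smooth over
  the jumps (~0.25 mm locally).
- The contact discretization (29 nodes over ~1.7 m) makes contact areas
  coarse step functions of the scenario; only orderings are asserted.
- Absolute disc-load proxies depend on assumed joint stiffnesses and disc
  geometry; they are comparison quantities, not tissue stresses.
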