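# Model and methods

`samsce` simulates a two-dimensional longitudinal section of the central
region of a shoot apical meristem (SAM) with the subcellular-element (SCE)
method: each cell is a closed ring of *wall nodes* plus a set of internal
*cytoplasm nodes*, and all dynamics follow from pairwise potentials between
nodes. This note records the model, its parameters and units, the numerical
choices, what the reduced "desk-scale" study conditions do and do not show,
and known limitations.

## Mechanics

Node positions obey overdamped (first-order) dynamics

    eta_i dW/dt = -grad E,      eta_i dI/dt = -grad E,

integrated with an explicit Euler scheme at `dt` = 0.4 s. The printed
equations of motion carry damping but no thermal noise term, so the
integrator is deterministic; all stochasticity in the model enters through
behaviour draws and cycle-length draws. The potential is a sum of:

* **Wall springs (`E_WWS`)** — each ring edge is a single linear spring
  (stiffness `k_lin` = 8 nN/um, rest length `ell` = 0.4 um), and each wall
  node carries a rotational spring on the angle formed with its ring
  neighbours. Side nodes (see polarization below) use `k_bend_high` = 2.0
  nN·um/rad² with a flat equilibrium angle (pi); end nodes use
  `k_bend_low` = 0.3 with the regular-polygon angle pi(N-2)/N, so an
  unpolarized ring relaxes circular. We treat each edge as one spring of
  stiffness `k_lin` (not two stacked per-node springs) so that the wall
  stress measure below is exactly the spring force.
* **Turgor (`E_IW`, `E_II`)** — Morse interactions `U e^{-r/xi} - W
  e^{-r/gamma}` between a cell's internal nodes and its wall (U=0.3,
  W=0.02, xi=0.8, gamma=2.6) and among internal nodes (U=0.5, W=0.02,
  xi=0.7, gamma=2.2). Net short-range repulsion pressurises the cell; a
  cell's equilibrium area therefore grows with its internal-node count,
  which is how growth is driven.
* **Volume exclusion (`E_WWD`)** — a short-range Morse core between wall
  nodes of different cells (U=1.5, W=0.05, xi=0.12, gamma=0.9). Pairs are
  gathered on a k-d tree with cutoff `1.8 * max(xi, gamma)` (force < 0.01
  nN there), refreshed every 100 steps with a 0.6 um search margin.
* **Adhesion (`E_Adh`)** — linear springs (k=1.5 nN/um, rest 0.25 um)
  between adhered wall nodes of adjacent cells (the middle lamella).
  Partners are the mutual nearest foreign wall nodes within 0.8 um,
  re-derived after every topology change, which keeps the partnership
  symmetric and cross-cell by construction.

Damping is `eta` = 80 nN·s/um for ordinary cells and 100x that for the
bottom (stem) row, which acts as a quasi-static foundation. The explicit
scheme is stable when `dt * k_lin / eta <= 0.1`; the config loader enforces
this. None of the spring/Morse magnitudes are printed in the source study;
they were fixed once so that (i) an isolated relaxed cell has diameter ~5-6
um at 10 internal nodes, (ii) a polarized single cell reaches aspect ratio
> 1.1, (iii) a 50-cell tissue relaxes without wall folding, and analysis
metrics are ratios/angles/counts that do not depend on their absolute scale.

**Wall stress.** The in-plane tensile stress at wall node j is the mean
magnitude of the tangential projections of the two neighbour spring forces,
with the tangent taken along `W_{j+1} - W_{j-1}`. It is zero at rest
spacing and equals `k_lin * ell` for collinear neighbours at double spacing.

**Wall resolution maintenance.** A segment stretched beyond `1.4 ell` gets
a midpoint node (adding rest length: the wall yields to sustained tension,
which is how cell perimeter grows); a node whose two edges would merge into
an edge shorter than `1.2 ell` is dropped (compression sheds the excess rest
length instead of crumpling the ring). The two thresholds are separated so
insertion and removal cannot thrash.

## Signals and behaviour

WUS and CK are prescribed steady-state exponentials of distance from two
signal centres located 2 and 3 mean tunica-cell diameters below the centroid
of the apical-most L1 cell, recomputed every signal interval (6 simulated
minutes) so they track the growing dome. Defaults: peaks `wus0 = ck0 = 1`
a.u., decay `mu = 0.12 /um`, width scalings `alpha = 1` (wildtype). CK is
held at zero in L1/L2, which lack CK responsiveness. Conditions: *ectopic
WUS* lowers the WUS peak to 2/3 and halves `alpha_wus` (wider gradient);
*ectopic CK* halves `alpha_ck` only.

A cell's periclinal/anticlinal **behaviour** is a Bernoulli draw with
probability `1 / (1 + (K/lambda)^N)` in the ratio `lambda = [CK]/[WUS]`.
`K` is the ratio evaluated at the midpoint between the two signal centres
(depth 2.5 diameters), which makes behaviour a coin flip exactly there; `N`
= 4 (config-exposed; not printed in the source study). At `[WUS] = 0` the
continuity limit applies (periclinal iff CK > 0). The draw is made at birth
and cached until the cell's next division.

**Cycle lengths** are normal draws truncated at 10% of the mean, with mean
`18 + 18*[WUS]` hours — central, WUS-rich cells cycle slower, spanning
roughly 18-36 h across the tissue. A newborn cell adds internal nodes
linearly in time so that it reaches the mitotic trigger (30 nodes) after
one cycle.

## Polarized growth

Behaviour sets the elongation axis `v`: periclinal (CK-dominant) cells
polarize apical-basally, anticlinal (WUS-dominant) cells radially; boundary
cells grow isotropically (uniform rotational springs). Ring segments within
45 degrees of `v` mark their flanking nodes as *sides* (stiff, flat
equilibrium); the rest are *ends* (loose, circular equilibrium). Flat stiff
sides channel turgor-driven expansion along `v`.

## Division

A non-boundary, non-stem cell divides when it reaches the internal-node
trigger. Guards: the ring must have >= 12 nodes, be simple (untangled), and
the cell must exceed a 3.2 um² size checkpoint — otherwise the division
waits an interval. All planes must split the mother's area evenly
(larger/smaller <= 1.11). Candidate planes are chords between wall nodes;
the candidate areas are corrected for the thin strip each daughter cedes
when its new wall is offset (below), so the *realised* daughters satisfy
the window. If no node pair fits, edge midpoints join the candidate set (a
chosen midpoint becomes a real wall node); only if that also fails is the
window widened in steps of 0.05 with a flag on the event.

* **CAE-E** (Errera): shortest chord within the window.
* **CAE-M** (mechanical): first anchor at the maximally stressed wall node;
  the partner best balances the areas (ties: shortest chord). If no
  containable in-window partner exists the next-most-stressed anchors are
  tried; a fully relaxed ring falls back to the shortest wall.
* **CED** (chemical): horizontal plane when the cached behaviour is
  periclinal, vertical otherwise, placed to balance areas.
* **L1/L2**: always anticlinal, perpendicular to the segment joining the
  in-layer neighbours' centroids (local surface normal); classified
  anticlinal by construction.
* **combined**: apical-corpus lineages (initial layers 3-4) divide by
  CAE-M, basal-corpus lineages (5-7) by CED.

Daughters receive the mother's two wall arcs plus their own new wall built
along the plane at `new_wall_spacing` = 0.4 um, offset by half an adhesion
rest length toward each daughter so the two new walls sit at the adhesion
spring's rest separation; new-wall nodes adhere to their mirrors in the
sibling. Internal nodes are assigned by side of the plane (an on-plane node
goes to the smaller daughter); a daughter left empty gets one node at its
centroid. Daughters inherit lineage layer and flags, then draw fresh
behaviour, polarization and cycle length. A split that would create a
self-intersecting ring is aborted and retried at the next interval. A plane
within 45 degrees of horizontal is classified periclinal, otherwise
anticlinal.

## Tissue, runs and outputs

The initial tissue is 50 circular cells in 7 rows (8,8,7,7,7,7,6 from top),
staggered brick-like by alternating quarter-pitch shifts, with row pitch
1.8 cell radii. Row 1 is L1, row 2 L2, rows 3-4 apical corpus, 5-7 basal
corpus; the left/rightmost cell of each row is a non-dividing boundary
cell; the bottom row is the non-dividing, heavily damped stem. The initial
ring radius is `N ell / 2 pi` so the wall starts at rest spacing.

Stage one relaxes the tiling mechanically for 15 simulated minutes with
polarizations assigned but no growth. Stage two runs 40 hours: mechanics in
6-minute chunks, then signal/centre updates, growth, and divisions, with
snapshots every 30 minutes. Runs stop early at a 400-cell safety cap. One
root seed spawns independent child generators per subsystem (behaviour,
cycle, geometry), so runs are bitwise reproducible. Outputs are CSV node
and cell-summary snapshots, a CSV division log, the resolved YAML config
and a JSON metadata file; `samsce run/batch/metrics` expose this from the
shell.

## Desk scale

`desk_scale()` derives the reduced study conditions used by the test suite
and the acceptance script: mitotic trigger 8 (initial cells hold 3 internal
nodes), cycle means `1 + 1*[WUS]` h, 4 simulated hours (about 2.5-3
generations from 50 to ~200 cells), `dt` = 0.5 s with `eta` = 40 (the same
stability ratio; mechanics kinetics are scaled toward the compressed cycle
clock so growth and relaxation keep the same relative pacing as at full
scale). Everything else — tissue, fields, thresholds, the 0.9-1.11 window —
is unchanged. A 4-hour desk run takes tens of seconds on one CPU.

What desk runs show: division legality, the layer-specific behaviour of the
four plane mechanisms, strip formation under ectopic CK, and the relative
isotropy of Errera-divided tissue. What they do not show: absolute cell
sizes and cycle statistics of real meristems, long-horizon (40 h)
homeostasis, or any comparison against confocal data — the synthetic tissue
has a flat initial geometry, sharper boundaries and far fewer cells than a
real SAM section.

## Numerical choices and degenerate inputs

* Angle-bend forces skip the degenerate sin(theta) ~ 0 configuration (the
  gradient direction is undefined there); coincident adjacent nodes raise a
  degenerate-geometry error.
* Morse pairs at zero separation raise a singular-configuration error; the
  volume-exclusion kernel skips such pairs defensively (they arise only
  transiently at freshly built walls).
* Ties in the shortest-wall search break to the lowest ring index of the
  first anchor, making square cells divide deterministically.
* Aspect ratio construction: the short axis is the minimal even-splitting
  chord; the long axis joins the nodes nearest the short axis' perpendicular
  bisector on either side; if the "long" axis comes out shorter (nearly
  isotropic rings) the roles swap so the ratio stays >= 1.
* Non-finite positions abort a run with the offending step and node named.

## Limitations

* Strictly 2D; no out-of-plane stress or 3D division planes.
* Signal fields are prescribed steady states — no transport, no feedback
  from mechanics to signalling.
* The tissue boundary (non-dividing columns, damped stem row) is an
  artefact of the finite domain; analyses restrict to interior cells where
  it matters.
* At desk scale, third-generation cells are small relative to the wall
  resolution; the division guards above keep their divisions legal but a
  few rings transiently tangle in crowded regions (they are excluded from
  division until they relax).
* Exact parameter values from the source study's supplement are not
  reproduced; all comparisons in the test suite are therefore qualitative
  (rankings, fractions, thresholds), never absolute calibrated values.
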