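# Methods

`arborfractal` quantifies the fractal geometry of 3D neuron dendritic
arbors — specifically the mild multi-scale weave of individual dendrites
versus the much richer scaling of the whole arbor — and the consequences of
that geometry for the balance between a neuron's connectivity potential and
its material/metabolic costs. This note records the models, the numerical
choices, and the limits of what the synthetic tests demonstrate.

## Data model

An arbor is a rooted forest of cylindrical segments read from SWC (or an
equivalent plain-text segment list): node id, type, position (µm), radius
(µm), parent. Soma nodes (type 1) are stripped before analysis; each former
soma child becomes a stem root, and the soma centroid is retained so the
arbor radius R_A (maximum distance from the soma centroid to any dendrite
node) stays defined. A *branch* is any soma-to-tip path; distinct branches
share their proximal sections by construction. Branch polylines are used at
their raw node spacing (median ≈ 2.4 µm for the target preparation); no
resampling or smoothing is applied before branch-level analysis.

## Branch dimension, coastline (divider) method

A branch is measured with rulers of length `L_R`: a sphere of radius `L_R`
is centred on the soma-side end; the next ruler endpoint is the
branch–sphere intersection with the smallest arc length beyond the part
already segmented (the sphere–segment intersection is solved exactly as a
quadratic per segment — no sampling). When no intersection remains, a
truncated ruler joins the last endpoint to the tip and is counted as a
fraction `truncated/L_R`, so 12 full rulers plus a 2 µm remainder at
`L_R = 10 µm` count as N = 12.2. Tangency (zero discriminant) counts as an
intersection; the case has measure zero on real data.

`D_BC` is minus the OLS slope of log10 N against log10 L_R (base-10 logs
throughout). The default grid is 20 log-spaced rulers over 4–40 µm: below
≈4 µm a ruler probes the straight cylindrical segments rather than the
weave, and one order of magnitude is the widest window short branches can
support. Branches with `L_E < 40 µm` cannot hold the largest ruler and are
excluded from per-branch fits. The pooled estimate `D_BCN` refits all of an
arbor's branches together on the normalized scale `L_R/L_E`, restricted to
the normalized range where every branch contributes (the full intersection
of the per-branch spans — we do not trim it further).

## Branch dimension, tortuosity method

Tortuosity `T = L_P/L_D` compares a sub-path's curvilinear length with its
endpoint distance. All vertex-to-vertex sub-paths of every branch are
enumerated (no endpoint interpolation inside segments); sub-paths occurring
in several sibling branches via shared proximal sections are deduplicated
by their (arbor, unordered node pair) key. Records are binned in `L_P` with
12 log-spaced bins over 4–40 µm (matching the coastline window), the
arithmetic mean T is taken per bin, and the slope S of log10 mean-T against
log10 L_P maps to the dimension

    D_BT = 1 / (1 − S),        S < 1,

with stderr propagated by the delta method, stderr(D_BT) = D_BT² ·
stderr(S). Bins are equally weighted (no n-weighting); bin centres are the
geometric means of the edges. Straight branches give S = 0 and D_BT = 1
exactly; the two estimators give independent routes to the same branch
dimension and agree within joint uncertainty on pooled ensembles.

A caution on uncertainties: the nominal OLS stderr of a *single* branch's
binned fit understates its real noise, because the sub-paths within one
branch are strongly correlated and the binned curve is smooth. The spread
of per-branch `D_BT` estimates around the pooled value is the honest
measure of per-branch noise, and it exceeds the pooled stderr several-fold.

## Arbor dimension, box counting

The arbor centerline, resampled at min(box)/4 spacing, is inserted into a
cubic grid anchored at the bounding-box minimum corner; `N_box` cells
containing at least one point are counted and `D_A` is minus the log-log
slope of `N_box` against `L_box`. Dendrite radius is ignored: the ≈1.4 µm
branch width sits below the analysis window. The default grid is 15 sizes
spanning one order of magnitude of the *normalized* box size, up to
`L_box/L_grid = 1/4` (`L_grid` = largest bounding-box side). Tying the
window to `L_grid` rather than to absolute micrometres keeps a distortion
ensemble — whose members grow or shrink — probed at the same normalized
scales; for a natural ≈100 µm-radius arbor the window is ≈4.6–46 µm,
consistent with the fine-scale cut-off used for branches. No grid-offset
averaging is performed; rotation of an arbor moves `D_A` by well under
0.05 on the synthetic family.

## Angle-multiplier distortion

The arbor is decomposed losslessly into, per node: segment length, bend
angle (the weave angle θ at continuations, the fork angle ϕ for each child
of a branching node), and the azimuth of the bending plane expressed in a
parallel-transported frame. Multiplying every bend by a common factor α and
rebuilding positions depth-first yields the distorted arbor: lengths and
azimuths (torsion) are untouched, so every branch's path length `L_B` is
exactly invariant; stem-root positions and initial stem directions are
absolute and unchanged. α = 1 reproduces the input to 1e-6 µm; α = 0
straightens every branch (`L_E = L_B`); α > 1 makes branches curl up. At
collinear nodes the bending axis is undefined but the scaled bend is also
zero, so no axis is needed. Scaled bends are clipped to π − 1e-6 and the
clip count reported. Torsion is held fixed under distortion — re-randomized
torsion would be a different (stochastic) model and is deliberately not
used. A report of non-adjacent segment pairs closer than the sum of their
radii verifies that distorted geometries remain physically reasonable
(offending fraction ≲ 0.01% across α ∈ [0.5, 2] on the synthetic family).

## Connectivity and cost metrics

* **Profile area P** — the arbor is projected orthogonally along 64
  deterministic Fibonacci-sphere directions; each segment's silhouette is a
  stadium of half-width radius + 2 µm (the expansion accounts for the space
  into which spines can grow); the union area (exact polygon union of
  buffered segments, 32 quadrant segments per circular arc) is averaged
  over views. A single capsule reproduces the Cauchy mean-projection value
  (surface area / 4) to better than 1% at 256 views.
* **Surface area A_s** — per-segment lateral tessellation (16
  circumferential × 2 axial facets); triangles whose three corners lie
  strictly inside another segment's cylinder are junction interiors and are
  removed before summing.
* **Volume V_m** — sum of π r² L over segments. Junction overlaps are
  ignored; with ≈0.7 µm radii and ≈2.4 µm segments the bias is ≪1% and
  V_m is exactly invariant under α.
* **Hull A_b, V_b** — surface area and volume of the convex hull of the
  node positions (Qhull).

For a distortion ensemble the per-α means of `P/A_b`, `A_s/A_b`, `V_m/V_b`
are fit as quadratics in `D_A`, differentiated analytically, and the
balance ratios

    R_PA = d(P/A_b)/dD_A ÷ d(A_s/A_b)/dD_A
    R_PV = d(P/A_b)/dD_A ÷ d(V_m/V_b)/dD_A

are evaluated on a `D_A` grid. Grid points where the denominator derivative
crosses zero are masked, never interpolated.

## Synthetic morphology

The generator emulates CA1 pyramidal basal arbors so the full pipeline is
testable without any downloaded reconstruction. Target statistics, fixed
once: ≈32 soma-to-tip dendrites, 100 µm radial extent (R_A ≈ 100 µm),
lognormal segment lengths with 2.4 µm median, 0.7 µm radii, branch
dimension near 1.04 by both estimators.

Mechanism: stems leave the soma inside a 0.4 rad cone (basal dendrites
exit one side of the soma and fan into the neighbouring layer) and all
active tips grow in lockstep as correlated random walks — each step bends
by a folded-normal angle (mean 0.15 rad, σ = mean/3) about a uniformly
random torsion axis — with a soft repulsion (weight 0.3, range 12 µm) away
from dendrite already laid down. The repulsion implements self-avoidance:
it is what makes the natural (α = 1) geometry special, so that scaling the
angles *either way* pushes branches closer together and raises the arbor
dimension. Without it a random walk has no distinguished natural state and
the U-shaped D_A(α) response cannot arise. Paths bifurcate on first
crossing radial shells confined to the proximal 40% of the extent
(basal dendrites branch close to the soma and then run unbranched), with
the shell count per stem chosen so tips sum to the target: tip counts land
exactly on 32 for the default recipe across seeds. A per-node bifurcation
probability mode exists as an alternative (fork count capped at twice the
target). Everything is driven by one `numpy` Generator seed; identical
seeds give byte-identical SWC output.

Resulting natural statistics (8 seeds): ⟨D_BC⟩ = 1.045, pooled D_BT =
1.040 ± 0.004, mean branch length ≈ 125 µm, R_A ≈ 104 µm, D_A(α=1) ≈ 1.32,
D_A(0.5) ≈ 1.38, D_A(2) ≈ 1.47, D_A − ⟨D_BC⟩ ≈ 0.27. The free-standing
weave-branch generator uses a larger bend (0.25 rad) because it lacks the
repulsion deflections; that value is what brackets D_BT ≈ 1.04 for isolated
branches.

What the synthetic family does *not* capture: real arbors are denser
(their arbor dimension is ≈1.4 at α = 1 and their mean branch length
141 µm, vs ≈1.32 and ≈125 µm here), taper their radii, have heterogeneous
fork statistics, and live in tissue with extrinsic guidance cues. Passing
tests on this family therefore demonstrates correctness and qualitative
behaviour of the estimators and the distortion response — monotone branch
dimension in α, U-shaped arbor dimension with its minimum near the natural
geometry, arbor dimension well above branch dimension — not quantitative
agreement with any particular real population.

The H-tree fixture (deterministic, planar, dimension log 2/log(1/ratio))
provides a known-dimension target: box counting over its self-similar
window (4–40 µm at the default trunk length of 120 µm) recovers D = 1.5
within 0.1 for the level-8, ratio 2^(−2/3) tree.

## Numerical conventions and degenerate inputs

* Base-10 logarithms in every scaling fit; ordinary least squares via
  `scipy.stats.linregress`; fits require ≥3 points/bins in range.
* Ruler marching uses an arc-length frontier with a 1e-12 µm strict-progress
  guard; endpoints lie on the polyline to 1e-6 µm.
* Boxes: points exactly on the far grid boundary belong to the last cell,
  so an axis-aligned 64 µm rod in 8 µm boxes occupies exactly 8.
* Zero-length segments, loops/cycles, orphan parents, coplanar hulls, and
  empty arbors raise typed exceptions (`arborfractal.errors`) naming the
  offending node where possible.
* SWC floats are written with `%.17g`, so write→read round-trips are exact.

## Problem sizes used in the shipped checks

Test and reference computations run on the synthetic family at its natural
scale: arbors of ≈1000–1300 nodes (32 tips), ensembles of 5 seeds, and the
seven-step α grid reduced to five levels where only qualitative shape is
asserted. The reference script uses single constructed branches (≤101
points), where all three reported quantities are scale-independent and
exact.

## Known limitations

* `D_BCN`'s shared normalized range can be empty if branch lengths span
  more than the ruler grid's dynamic range (10×); the error lists the
  per-branch spans so the caller can supply per-branch grids.
* The interior-face removal in `A_s` tests triangle corners only; a face
  whose corners are inside two *different* cylinders is removed even if its
  centre pokes out — at the default tessellation this bias is below the 1%
  verification tolerance.
* Profile areas use exact polygon unions; cost grows with segment count ×
  views, so sweeps over large ensembles should lower `n_views` (the view
  average converges at a few dozen directions).
* Box counting uses a single anchored grid; offset averaging would reduce
  quantization noise at coarse scales but is intentionally omitted for
  determinism.
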