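# Methods

## Problem setting

An axial T1/T2 MRI slice through a lumbar intervertebral disc is assumed
to be segmented into six classes — 1 Unregistered, 2 IVD, 3 posterior
elements (PE), 4 thecal sac (TS), 5 the inter-element space (AAP),
6 Other — by any upstream source (manual annotation or a semantic
segmentation model).  The package's job is everything downstream of that
segmentation: refining the two clinically important boundaries, locating
the measurement landmarks, and converting them into foraminal widths, an
anteroposterior (AP) canal diameter and a herniation grade.  The slice
is required to be oriented anterior-at-top (row 0 anterior); pixel
spacing must be isotropic (a scalar mm/px).

Coordinates in the Python API are 0-based (row, column) floats with
pixel centers at integers.  Boundary-grid subscripts are 1-based so that
the parity rules below read naturally; grid cell (i, j) sits at
pixel-frame position ((i−1)/2, (j−1)/2) — interface cells at
half-integers, halfway between the two pixel centers they separate.

## Boundary model and contour evolution

A label image of shape H×W embeds in a (2H−1)×(2W−1) *Modified Boundary
Grid*: odd/odd cells carry the class labels; even-row/odd-column cells
sit between vertically adjacent pixels and carry the vertical image
gradient; odd-row/even-column cells carry the horizontal gradient;
even/even cells are empty.  Gradients are forward differences of the
Gaussian-smoothed intensity image (width σ, truncated at radius
⌈3σ⌉ and renormalized at borders), so the horizontal and vertical
gradient images have shapes H×(W−1) and (H−1)×W — one value per
interface.  A *Sparse Boundary Representation* indexes, for each
unordered pair of neighboring classes {a, b}, the interface cells whose
flanking labels are exactly a and b; the boundary set S to evolve is a
union of such entries (by default the five pairs (2,3), (2,4), (2,5),
(3,4), (3,5), i.e. the important IVD and PE boundaries).

One evolution sweep visits the cells of S in ascending subscript order
(a snapshot taken at sweep start; label edits apply immediately).  Each
interface cell is tested for relocation along its movement axis —
perpendicular to the interface, the only motion that changes the
segmentation — to the candidate interface within ±w label pixels whose
stored gradient has maximal absolute value.  Ties prefer the smallest
move, then the negative direction, so the update is deterministic.
Moving an interface by δ re-labels the crossed pixels with the class of
the region the interface moved away from; any candidate whose crossed
pixels include a third class is discarded, which prevents one region
from invading another through a junction.  Consequences worth knowing:

* no sweep ever introduces a class absent from the input;
* boundaries of pairs disjoint from the evolved set are bitwise
  preserved; junction pixels shared with an evolved pair can change
  *pair membership* (e.g. a pixel turning from 5 to 2 turns an adjacent
  5|6 interface into 2|6) — this is the unavoidable edge effect of
  selective evolution.

Sweeps repeat until the number of changed label cells, averaged over the
last n sweeps, falls strictly below τ.  Greedy per-cell updates admit
small limit cycles — two adjacent cells each improving their own feature
while undoing one another, typically at staircase corners of weakly
contrasted boundaries — so an exact fixed point is not generally
reached; τ is therefore tied to the working image size
(τ = max(1, 0.001·H·W) when not set explicitly), which terminates the
iteration once only this steady-state churn remains.  `max_sweeps`
(default 100) caps pathological cases; hitting it flags a warning in the
evolution history without discarding the result.

To pass the original pixel quantum, the image (bilinear) and label
(nearest-neighbor, i.e. 2×2 block replication) are upsampled by 2 after
each complete evolution, k times in total; gradients and the grid are
rebuilt at each level.  Under the pixel-area convention used for
upsampling, a level-ℓ coordinate u maps to the original frame by
applying u ← (u − 0.5)/2 ℓ times; interfaces map onto interfaces, and
after k rounds every boundary coordinate lies on the 2^−(k+1)-pixel
lattice of the original frame — the boundary is known to half the final
working pixel.  σ is kept constant in working pixels across levels.

### Boundary ordering and adaptive smoothing

The evolved boundary point set is ordered into a curve by a greedy
nearest-neighbor chain starting from the lexicographically smallest
point (distance ties resolve lexicographically).  A variable-width
moving average then smooths the curve: at each point the half-width w_p
interpolates linearly (rounded to nearest integer) between w_min and
w_max according to the local magnitude of the image's second derivative
— the absolute Laplacian of the Gaussian-smoothed image (width σ₂),
computed with exact central second differences so constants and ramps
give identically zero — sampled at the nearest pixel and min–max
normalized along the curve; a constant feature falls back to w_min
everywhere.  Only indices i with w_p < i < card(A) − w_p are replaced
(by the mean of their 2·w_p+1 neighbors from the unsmoothed curve);
endpoints pass through.  Defaults w_min = 2, w_max = 7: at sub-pixel
sampling (points every ~2^−(k+1) px along the curve) these windows span
roughly 2–7 original pixels of arc, enough to suppress staircase noise
without erasing the articular-horn-scale features the foraminal search
relies on.

## Landmarks and measurements

With the important boundaries A2 (disc) and A3 (PE top) as ordered,
smoothed curves:

* **T_L, B_L / T_R, B_R** — endpoints of the shortest segment between A2
  and A3 candidates on the left/right of the disc-centroid column, with
  candidates whose column falls inside the thecal-sac column extent
  (padded 1 px) excluded so the canal cannot win the minimum-distance
  search.  Distance ties prefer the smaller column offset, then the
  smaller T row.  A zero-width foramen (disc touching PE) is legal
  output.
* **B_M** — the maximal-row (most posterior) A3 point with column
  strictly between B_L and B_R; ties take the column nearest the
  interval midpoint.
* **D_C** — centroid of the largest connected component of class 2
  (smaller fragments are treated as segmentation noise).
* **q** — over the sub-arc M_IVD of A2 between T_L and T_R (of the two
  arcs the curve splits into, the one nearer B_M — the canal-facing
  side), the maximizer of (perpendicular distance to the infinite
  T_L–T_R line) − (Euclidean distance to B_M); first index wins ties.
* **p, q′** — intersection of the T_L–T_R and B_M–D_C infinite lines,
  and the orthogonal projection of q on the B_M–D_C line.  If p or q′
  falls outside its segment a warning is recorded; the pipeline degrades
  rather than halts on pathological segmentations.

Measurements: d_L = d(T_L,B_L)·mm/px, d_R likewise, AP diameter
d_AP = d(B_M,q′)·mm/px, and the dimensionless herniation ratio
r = d(B_M,q′)/d(B_M,p).  Grading: **normal** iff r ≥ 1.1, **severe** iff
r ≤ 0.8 (boundary inclusive), **minor** in between; both thresholds are
configurable and the three grades partition [0, ∞).  Left/right names
follow image columns by default; a `radiological_convention` flag swaps
them to patient-side naming at serialization.

Degenerate inputs raise typed errors: missing region 2 or 3, an
important boundary that is empty (region present but never adjacent to
the partner classes), no foramen candidates on a side, no A3 point
between B_L and B_R, coincident B_M and D_C, parallel chord and
bisecting line, or d(B_M,p) = 0.

## Pipeline

`run_slice` composes: schema validation → optional per-class
morphological closing (3×3 square element, class order (2,3,4,5), later
classes take precedence; closing only adds pixels to a class, so a
uniform image passes through and the operation is idempotent) →
sub-pixel evolution of the five important pairs → boundary extraction
(ordering + adaptive smoothing) → landmark location → measurement.  All
stage warnings propagate to the result.  The high-resolution centroid
and thecal-sac extent are mapped back to the original frame with the
same (u − 0.5)/2 rule as the boundary points.  Composites (T1,
registered T2, |T1 − T2|) are collapsed to one working image as the mean
of the first two channels.

## Evaluation metrics

* **Boundary F1 (BF-score)** at tolerance d_T: precision = fraction of
  predicted contour points strictly closer than d_T to the ground-truth
  contour; recall symmetric; F their harmonic mean.  Contours are the
  class pixels with a differing 4-neighbor or on the image border.  Two
  empty contours score 1 (absence correctly predicted); exactly one
  empty scores 0.
* **Landmark errors**: per-point Euclidean distance in mm, plus absolute
  errors of the derived widths and AP diameter.
* **Intra-rater variation**: mean distance of repeated placements of one
  point to their mean location, in mm (translation/rotation invariant).
* **Category agreement**: percentage of slices with matching herniation
  grades.

## The phantom: what it emulates, and what it does not

The generator rasterizes an analytic axial-slice geometry at disc level:

* a **kidney-shaped disc** — an ellipse (semi-axes `ivd_top`/`ivd_bot`
  anterior/posterior, `ivd_halfwidth` lateral) whose posterior boundary
  is indented by `indent·cos(πu/2)` (u the normalized lateral
  coordinate), carries two **posterolateral lobes** (Gaussian bumps,
  `lobe_height`, `lobe_sigma`) and an optional central posterior
  **herniation bump** of amplitude `hern_amp` and relative width
  `hern_width`;
* a **PE band** whose top boundary is a line through the two foraminal
  anchors, minus two **articular horns** (Gaussian, `horn_height`,
  `horn_sigma`) rising at ±`horn_pos`·halfwidth under the disc lobes,
  plus a central **canal arch** of depth `canal_depth`;
* an **AAP space** filling the rows between disc (or its equator row,
  laterally) and PE top across the band's extent, a **thecal-sac
  ellipse** centered in the canal gap (compressing when herniation
  narrows the gap), a class-1 frame and class-6 background.

The lobe/horn pairing is deliberate: the closest approach between A2 and
A3 on each side is tip-to-tip between two curved surfaces, so the
designed foraminal gap (`gap_left`/`gap_right`, in px) is both the
min-distance value and sharply localized laterally — rasterization at
integer pixels cannot smear the foraminal landmarks along a flat
plateau.  Intensities are per-class means for two pseudo-modalities
(defaults give the disc/AAP boundary low contrast and the PE/AAP
boundary high contrast, reproducing the easy and hard boundary cases of
real slices), plus a smooth quadratic bias field (`bias_amp`) and i.i.d.
Gaussian noise (`noise_sd`, default 0.02 against class contrasts of
0.14–0.6 on unit scale).

Ground truth is computed from the analytic curves sampled every 0.01 px
with the same geometric rules as the pipeline but independent code —
never by calling the measurement path — so end-to-end tests compare two
independent routes.  `solve_herniation_amplitude` inverts the analytic
ratio r(h) (monotone decreasing in the bump amplitude) by bracketed
root-finding, letting tests and cohorts dial an exact target ratio.
Cohorts draw per-slice substreams from (seed, study, level), jitter the
base geometry, and draw grades from a configurable category mix; the
default canvas is 320×320 at 0.5 mm/px, and `PhantomSpec.scaled(n)`
shrinks everything proportionally (with floors on the thinnest
structures) for fast tests — tests and the acceptance script use 64–200
px canvases.

The annotation-noise model jitters all region boundaries by up to
`jitter_px` (each of `jitter_px` passes flips boundary pixels to a
random differing 4-neighbor's class with probability 0.35 per
direction, bounding the boundary displacement by the amplitude) and
injects 1×1 holes at rate `hole_rate` per 100 important-boundary pixels.
Hole sites are pixels with a uniform 8-neighborhood within 2 px of an
important boundary: genuine isolated holes, all of which a 3×3 closing
provably removes — defects literally on staircase corners would be
corner nicks that closing cannot fill and that the closing step is not
claimed to fix.

What passing phantom tests shows — and does not.  The phantom exercises
every pipeline stage with known truth: boundary refinement against
analytic curves, landmark recovery to ~1 px, grade agreement, the
directional benefit of evolution on jittered labels.  It does not emulate
MRI texture, partial-volume effects, registration failure (class 1 is a
fixed frame), anisotropic voxels, or anatomically abnormal topologies;
accuracy numbers on phantoms are therefore upper bounds, not estimates,
of performance on clinical data.

## Parameter defaults

| parameter | default | meaning / rationale |
|---|---|---|
| w | 2 px | search width per sweep; small keeps the result close to the initial estimate |
| τ | max(1, 0.001·H·W) | convergence threshold on mean changed cells per sweep, tied to working image size |
| n | 3 sweeps | averaging window for the convergence test |
| k | 1 | upsampling rounds → boundary precision 2^−2 = 0.25 px |
| σ | 1.0 px | gradient smoothing width (working pixels, constant across levels) |
| max_sweeps | 100 | safety cap per level |
| w_min, w_max | 2, 7 points | adaptive smoothing half-width range |
| σ₂ | 1.0 px | smoothing width for the second-derivative feature |
| d_T | 1, 2, 3 px | BF-score tolerances reported by the CLI |
| thresholds | 0.8, 1.1 | severe / normal ratio cut-offs |
| class order | (2,3,4,5) | closing precedence: anatomical over background, smallest classes last |

## Known limitations

* The evolution's greedy per-cell update can cycle between equally
  supported configurations; termination relies on the averaged-change
  threshold, and on canvases much smaller than ~160 px the residual
  churn can exceed the image-size-tied τ, triggering the sweep cap
  (reported as a warning).  Defaults are tuned for the 160–320 px regime.
* Sub-pixel refinement cannot recover information lost at rasterization:
  upsampling sharpens the boundary representation, not the underlying
  evidence, so landmark accuracy on phantoms is bounded by the original
  pixel quantum (~0.5 px per boundary).
* Foraminal landmark localization assumes the closest IVD–PE approach is
  laterally well-defined; on segmentations where the gap function is
  flat over many columns the T/B columns are ambiguous within the
  plateau (their distance — the clinically reported width — is not).
* Only single slices are processed; slice selection from a 3-D study,
  T1↔T2 registration and bias-field correction happen upstream.
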