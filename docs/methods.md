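# Methods

This note documents the models, parameter choices and numerical decisions
behind `fretmap`: what the synthetic data emulate, how the estimators are
defined, and where genuinely open design questions were settled.

## Acceptor-photobleaching FRET model

A donor fluorophore within Förster distance (< ~10 nm) of an acceptor loses
a fraction *E* of its emission to energy transfer. The ground-truth
efficiency is defined on the de-quenching scale: at a complete acceptor
bleach, `E = 1 − D_pre / D_post`, where `D_pre`/`D_post` are the donor's
expected (noise-free) signals before and after the bleach pulse. Two
estimator conventions follow from the same per-pixel data:

- `increase_over_pre`: `e = 100·(post − pre)/pre`, the percentage increase
  in donor fluorescence after acceptor photobleaching (default, matching
  the verbal definition used with this assay);
- `dequench_over_post`: `e = 100·(post − pre)/post`, the classical transfer
  efficiency, whose noise-free fixed point is `E` itself.

On noise-free data the two are related exactly by
`e_pre = e_post / (1 − e_post/100)`; both are reported in output tables. At
*E* ≈ 10% the conventions differ by ~10% relative, which matters when
comparing absolute numbers across studies; within one convention all
classification results are unchanged. Which convention a given published
table used is often ambiguous — that ambiguity is why both are carried.

With a partial acceptor bleach (fraction β destroyed), the residual
acceptor keeps quenching: the post-bleach donor carries the factor
`1 − E·(1 − β)`, so the apparent efficiency is attenuated by roughly β. The
measured bleach fraction is recorded per cell and values below 0.5 are
QC-flagged, not dropped.

### Estimation pipeline

Per cell: (1) subtract the per-frame median of an extracellular background
region, clipping at zero; (2) average the 3–5 donor frames of each phase;
(3) set the intensity threshold to the mean cytoplasmic donor level of that
cell (on the averaged pre-bleach image); (4) average per-pixel efficiencies
over ROI pixels above the threshold in *both* averaged images (thresholding
the pre image only is a config option); (5) subtract the donor-only
baseline of the matched batch.

The threshold-both-images choice follows the thresholding behaviour of the
standard per-pixel FRET plugin workflow; the per-pixel loop is also
implemented as an explicit reference loop, and the vectorized path is
tested to match it bit for bit.

Zero-clipping in step (1) makes the *mean* of empty (extracellular) regions
positive by ~sd/√2π even when the subtraction is unbiased; validation
therefore checks medians and the subtracted constants, and the efficiency
estimator itself is unaffected (it only uses pixels far above zero).

### Donor-only baseline

Repeated donor acquisitions bleach the donor irreversibly ("structural"
photobleaching), so post-bleach frames are slightly dimmer than pre-bleach
frames even without FRET: donor-only cells read slightly negative (under
`increase_over_pre`) and the pipeline subtracts the mean apparent
efficiency of a donor-only batch acquired with identical settings.

The baseline batch is a *session-level pool* (default 60 cells serving all
pairs of a session) rather than one small batch per pair. This is a
deliberate statistical choice: subtracting a noisy baseline correlates the
corrected per-cell values, and the pair-level confidence interval cannot
see that shared error. With a 20-cell baseline the positivity rule's
false-positive rate inflates from its nominal ~2.5% to ~7–9%
(`P(Z > t/√2)`); with a 60-cell pool the measured rate is ~4.4%
(verified by a 200 000-resample bootstrap at the measurement level).

## Synthetic microscopy

The simulator emulates wide-field EMCCD acquisitions of yeast cells at
178 nm pixel size:

- **Scene**: an elliptical cell; 5–15 endocytic patches placed in a
  cortical annulus (sub-pixel centers, overlapping allowed — stalled sites
  cluster on diffraction-limited images); uniform cytoplasmic signal inside
  the cell; extracellular background everywhere.
- **PSF**: symmetric 2-D Gaussian, σ = 1.1 px (≈ 250 nm FWHM for a high-NA
  oil objective at this pixel size), rendered by exact per-pixel erf
  integration so patch photon totals are analytic.
- **Protocol**: 2 acceptor + 3–5 donor frames (0.5–1 s exposures), a 3–5 s
  bleach pulse, then 3–5 donor + 2 acceptor frames; donor frame *k* is
  scaled by `(1 − δ)^k` (structural photobleaching), acceptor post-bleach
  signal by `1 − β`.
- **Noise**: mean-preserving EM-scaled Poisson deviation plus Gaussian read
  noise — per-pixel variance `g²·mean + σ_read²` with the excess-noise
  factor g = √2 folded in, a standard high-gain EMCCD approximation that is
  adequate at the simulated photon counts (a full gain-register cascade
  adds nothing at these levels). Deterministic under a seed.

**Photon budget defaults** (donor patch 1200 photons/frame, acceptor 900,
cytoplasm 100/px, background 20/px, read noise 2 counts) were calibrated so
that simulated per-cell efficiency SDs are ~1 percentage point, i.e. 95%
CIs of ±0.5–1.0% at n = 10–40 cells — the CI magnitude scale of real
screens of this type. Defaults for the ground truth: β = 1 (the estimator's
complete-bleach assumption; partial bleach is an explicit setting) and
δ = 0.001/frame (donor-only baselines slightly negative, ~−0.5%).

What the generator does **not** emulate: spectral bleed-through and direct
acceptor excitation (irrelevant to acceptor photobleaching), 3-D optics and
axial structure, cell-to-cell expression variability, patch motion, and
fixation artifacts. Passing tests therefore demonstrate correctness of the
estimators and statistics under the stated imaging model, not robustness to
every property of real data.

**Bias budget.** The per-pixel ratio estimator carries a small Jensen bias
(`≈ CV²` of the averaged denominator pixel), ~0.1–0.3 points at the default
budget. Because donor-only cells are measured identically, the baseline
subtraction cancels it to first order; the end-to-end requirement (mean
corrected efficiency within 0.3 points of truth for E from 0 to 15%) holds
with margin (measured max |bias| ≈ 0.2 points at 200 cells/condition).

## Screen statistics

Per pair, the per-cell corrected efficiencies give a mean and a Student-t
95% CI (a seeded bootstrap CI is available). A pair is **FRET-positive**
iff the mean and both CI bounds are positive; there is no multiple-testing
correction by default — the per-pair CI rule is the published practice this
package reproduces — though a Benjamini–Hochberg helper exists. Group
comparisons use two-tailed Welch's t (Welch–Satterthwaite df); two
zero-variance samples with equal means give p = 1 by convention. Box-plot
summaries use linear (inclusive) quartile interpolation, whiskers at the
most extreme points within 1.5·IQR of the quartiles, and notch halfwidth
1.58·IQR/√n.

## Stage sorting

Patches are detected by Laplacian-of-Gaussian blobs at the PSF scale on the
max-normalized, background-subtracted pre-bleach image (response threshold
0.2, chosen for zero false positives at perfect recall on default-budget
scenes), intensity-ranked with a minimum separation. Each patch gets a
2-px-radius oval ROI (≈ 360 nm, covering the PSF-blurred spot; the choice
is ours — no ROI size is standard) and is measured only if ≥ 3 pixels
survive the threshold. Marker (Abp1) presence is a k-sigma rule: present
iff the ROI's mean marker intensity exceeds the cytoplasmic marker level by
3 of its SDs — a formalization of what is usually a visual call. Fixed-cell
acquisitions are assumed; no drift correction.

## FRAP

The bleached-spot trace and a large cytoplasmic reference trace are
background-subtracted, the bleach frame is auto-detected as the largest
single-frame fractional drop, and the double normalization
`F̃ = (spot/ref) / mean_pre(spot/ref)` removes acquisition photobleaching
(pre-bleach mean exactly 1). Recovery is fit by bounded least squares to a
single exponential, `F̃(t) = F₀ + M·(1 − F₀)·(1 − e^{−(t−t₀)/τ})`, with
M ∈ [0, 1.2], τ > 0, multiple τ starts, and half-time τ·ln 2. The single
exponential is the minimal standard; τ is an effective exchange time, not a
diffusion constant — no reaction–diffusion modelling is attempted.

Two FRAP-specific choices matter for recovery accuracy: the reference
region must be large (a patch-sized reference injects its own shot noise
into the normalized trace and roughly doubles parameter scatter), and the
FRAP photon budget is set an order of magnitude above the FRET-donor
default (spot 20 000 photons/frame, bleach depth 0.9) — the FRAP channel
images a bright tag with no FRET losses. The spot ROI also contains
unbleached cytoplasmic signal; this shifts the trace by an affine transform
under which the (M, τ) fit is invariant, so fits are compared to truth, and
trace-level tests are compared to the simulator's own expected stack. With
these settings the simulate→extract→normalize→fit round trip recovers M
and τ within 10% in ≥ 90% of replicates across M ∈ {0, 0.3, 0.7, 1} ×
τ ∈ {2, 5, 15} s (for immobile truth, τ is unidentifiable and the check is
fitted M ≤ 0.05).

## Proximity mapping

Positive pairs form an undirected graph over (protein, terminus, variant)
nodes. FRET magnitude is **not** converted to distance (fluorophore
orientation and stoichiometry are unknown); edges are binary ≤ d_max
(10 nm) proximity constraints, and magnitude enters only as a weak
tie-break. Connected components with ≥ 3 termini are "networks", size-2
components "isolated pairs".

Terminus orientation relative to a reference partner: the terminus with the
higher mean FRET is called closer, confidently only when Welch's p < 0.05
on per-cell values; without per-cell values the call is flagged
low-confidence.

Truncation rulers: when a full-length terminus shows no FRET to a marker
but a shortened construct does, the full-length terminus is bounded > d_max
from the marker and the shortened one < d_max. Contradictions (a longer
construct positive where a shorter one is negative) are reported, never
silently resolved.

### Axial embedding

Coordinates x (nm from the inner membrane leaflet) minimize

    Σ_pos  max(0, |xi−xj| − d_max)²
  + 0.1 · Σ_neg  max(0, d_max + 2 − |xi−xj|)²          (soft repulsion)
  + Σ_ruler hinge²                                      (weight 1)
  + 0.01 · Σ_pos (|xi−xj| − d_pref(E))²                 (magnitude tie-break)
  + anchor penalties (weight 50; hard point anchors are fixed)

Negative pairs are weak evidence (orientation/stoichiometry can abolish
FRET at short range), hence the low weight and 2 nm margin. The tie-break
distance `d_pref` decreases linearly with the edge's mean FRET; it resolves
orderings inside the flat ≤ d_max feasible set without overriding any
binary constraint. The optimizer is deterministic under a seed: multi-start
L-BFGS-B (including all-membrane-side and all-distal structured starts),
exact per-node 1-D grid coordinate descent (the restricted objective is
piecewise quadratic, so a grid scan hops basins that gradient steps
cannot), and a seeded dual-annealing stage with early stopping. On 5-node
instances the optimizer matches a 1-nm brute-force grid; on planted 12-node
geometries it recovers the true ordering with Kendall τ ≥ 0.94 across
seeds. Nodes not tied to any anchored node through at least one constraint
are reported unplaced rather than given arbitrary coordinates.

Anchors for the published map: the Sla2 N-terminus at 1.5 nm and C-terminus
at 33 nm (in-vitro positions of this membrane-anchored dimer), and the
clathrin subunits Chc1-C/Clc1-C as an ordered lattice-marker pair with soft
intervals 15–22 / 22–30 nm — the published evidence gives their ordering
(opposite lattice surfaces), not distances, so the intervals are a declared
assumption. Default layer labels: membrane-binding 0–3 nm, adaptor 3–15,
lattice 15–25, actin-regulatory 25–60.

### Encoding the published screen

The printed per-pair values, the two network membership lists, the
clathrin-marker results and the truncation contrasts are encoded as data in
`fretmap.published`. Where the text states a proximity without a value, the
pair is marked `inferred` and contributes connectivity only. Two published
subtleties required explicit decisions, recorded here as the package's own
reading:

1. The printed membership sentences place both End3 termini in both
   networks; taken literally as component input this merges the networks
   into one. The published orientation statement (End3-N toward the
   membrane-proximal network, End3-C toward the cytoplasmic one) resolves
   the assignment used here.
2. The weak cross-network End3 values (e.g. End3-N/Pan1-C 5.2%,
   Sla2-C/End3-N 1.9%) are *infeasible* as point-to-point ≤ 10 nm
   constraints on a single axis together with the ruler bounds — End3 is an
   extended rod spanning the lattice, and the published decomposition
   itself predates these refinement measurements. They are kept in the
   encoded table (category `bridge`) for orientation and ruler logic but
   excluded from the 1-D embedding; including them forces ~11 nm of
   constraint violation onto whichever side of the lattice the optimizer
   picks.

The same limitation in general form: a 1-D embedding of a 3-D protein
assembly can only honor axial information; in-plane structure is explicitly
not modelled, and any edge whose geometry is dominated by lateral offsets
will appear strained.

## Validation problem sizes

The end-to-end suite uses 200 cells per efficiency condition for bias, 400
replicates of 20-cell pairs (plus 60-cell baselines) for classification
calibration, 10⁴ replicates for Welch type-I error, 100/150 panels of 70+70
patches for stage-sorting power/null uniformity, 100 replicates per (M, τ)
grid point for FRAP, and 20 seeds of 12-node planted geometry — sizes at
which the Monte-Carlo error is comfortably below each acceptance margin
while the whole suite runs in minutes on one CPU.
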