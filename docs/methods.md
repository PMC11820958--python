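# Methods

This note documents the model, the numerical choices, the synthetic-data
generator and the known limitations of `somatrack`. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Intensity model

Each 2D slice `(k, t)` of the registered stack is binarized independently,
because fluorescence intensity and contrast fall off with depth and a
single global threshold cannot serve both superficial and deep slices.

**Pre-mask.** Somas occupy a tiny fraction of a slice, so the mixture is
fitted only to the candidate pixels at or above the `premask_percentile`
of the slice (default 99; astrocyte preset 98). Pixels strictly below the
cut are background. The retained intensities are min–max rescaled to
[0, 1] per slice and clamped to [1e−6, 1 − 1e−6]; the clamp is needed
because the beta density is unbounded or zero at the endpoints, and it is
far narrower than one 8-bit quantization step, so it cannot move a
threshold visibly. Rescaling is per slice, not per stack — this is what
makes the model depth-adaptive.

**Mixture and EM.** The rescaled candidates are modelled as
`p0·Beta(α0, β0) + (1−p0)·Beta(α1, β1)`, component 1 being the brighter
one (components are relabelled after fitting so that α1/(α1+β1) ≥
α0/(α0+β0)). The E-step computes posterior responsibilities in log space.
The M-step updates `p0` as the mean class-0 responsibility and each
component's shape parameters by maximizing its responsibility-weighted
beta log-likelihood with L-BFGS-B over (log α, log β), box-constrained to
α, β ∈ [1e−3, 1e3]. The weighted likelihood depends on the data only
through `Σ w·log y`, `Σ w·log(1−y)` and `Σ w`, so each objective
evaluation is O(1) and the per-iteration cost is dominated by the E-step.
If the optimizer ever proposes a worse point than the previous iterate,
the previous iterate is kept; together with exact E-steps this makes the
observed-data log-likelihood nondecreasing (tests assert a 1e−8
tolerance). Convergence is declared at |Δ log-likelihood| < 1e−6 or after
200 iterations.

**Initialization and restarts.** The first attempt assigns every value to
class 0 or 1 uniformly at random. This classic initialization has a
failure mode that matters here: for mixtures whose pooled histogram is
well approximated by a single beta density (e.g. the U-shaped
0.5·Beta(2,8) + 0.5·Beta(8,2)), the random halves give two near-identical
components, and the collapsed symmetric fit is a *stable* local maximum of
the likelihood — EM cannot leave it, at any iteration budget, because the
symmetric parameter manifold is EM-invariant and attracting. We verified
this numerically (deliberately split initializations up to 1.5× re-collapse,
while initializing at the true parameters yields a far higher likelihood).
Therefore, when an attempt collapses, up to `n_restarts` (default 2)
further attempts re-initialize by splitting the values at a random central
quantile (uniform in the 30th–70th), which starts the components separated;
the first converged, non-collapsed fit wins. On genuinely unimodal data the
split initialization re-merges and the slice is correctly declared
single-component.

**Collapse detection.** A fit is collapsed when `p0` leaves
[0.02, 0.98], when the component means differ by less than 0.02, or when
no attempt converges. All three constants are configurable.

**Threshold.** For a two-component fit the threshold is the root of
`g(y) = p0·f0(y) − (1−p0)·f1(y)` between the two component means: sign
changes are located on a 1024-point grid over that interval and refined
by Brent's method (xtol 1e−14); with several roots, the one nearest the
midpoint of the means is used. The comparison is inclusive: a pixel
exactly at the threshold is ROI. The rescaled threshold is mapped back to
raw intensity units (`raw_lo + τ·(raw_hi − raw_lo)`), and the slice's ROI
is simply `raw ≥ threshold_raw`; for intersection fits this is identical
to thresholding the rescaled candidates, since every pre-masked pixel
lies below the candidate minimum.

**Fallback.** When only one component is detected — or fewer than
`min_retained` (default 50) candidates exist, or the slice is constant —
the slice is thresholded at the `fallback_percentile` (default 80;
astrocyte preset 70) of its **whole raw intensity distribution**, and
voxels at or above it are ROI regardless of the pre-mask. The pre-mask
restricts only the fitting sample; in the fallback path there is no fit,
and applying an 80th-percentile threshold inside a top-1% candidate set
would be both self-contradictory (80 < 99) and would cap the ROI at 1% of
the slice, which no subsequent 11 × 11 × 3 majority filter could ever
retain (at most 3 × 1% of a 64 × 64 slice = 123 of the required 182
votes). A constant slice is labelled entirely background.

**Seeding.** Per-slice seeds derive deterministically from
`(global_seed, k, t)`, so serial and parallel executions are bit-identical
and slices can be processed in any order.

## Median filter

The binary median over an odd `wx × wy × wz` window is a strict majority
vote; the default 11 × 11 × 3 window holds 363 voxels, so ties are
impossible. It is computed per timepoint with separable integer box sums
(exact, no floating-point thresholding) and zero padding: out-of-volume
voxels count as background, so the filter never creates foreground at the
borders, at the price of eroding objects near them. Window geometry:
filaments are thin and mostly in-plane, somas are round, so a wide-in-XY,
shallow-in-Z window removes a 1-voxel filament of any length (it
contributes at most ~33 of 182 needed votes) while a radius-5 ball keeps a
~90-voxel core and a diameter-15 ball survives almost intact. Balls of
radius ≤ 4 are fully erased by the default window — the minimum resolvable
soma size is set by the window, not by the component-size filter.

## Tracking

**CCL.** Foreground voxels are partitioned under the default box kernel
[3, 3, 3, 3] (80-neighborhood) with `scipy.ndimage.label`; other odd
kernels use an in-package BFS (intended for small volumes). Labels are
renumbered by the lexicographic order of each component's minimal
(t, z, y, x) voxel, so labeling is deterministic and stable across runs.

**Split-merge.** Components merge when any voxel of one lies within the
per-axis spatial half-widths (default ±2 voxels) of a voxel of the other
at timepoints at most `merge_gap + 1` apart (default gap 1: one missing
frame is bridged). The search scales coordinates so the window becomes an
inf-norm unit ball and uses a k-d tree per component pair with a
bounding-box pre-filter; union–find closure makes the result independent
of processing order. With all half-widths 0 the graph is returned
unchanged. The right window size depends on registration quality and is
deliberately exposed rather than fixed.

**Size filter.** Components with fewer than 30 voxels — counted over the
whole 4D component, not per timepoint — are removed after merging
(order: CCL → merge → filter). The boundary is strict: 29 voxels is
removed, 30 is kept.

**Fates.** For each component, `first` and `last` are its first and last
timepoints with a detection. `n_total(t)` counts components whose
`[first, last]` span covers `t` — span-based presence, so a gap-merged
cell counts as tracked through its gap; this is also what makes the
conservation identity `n_total(t+1) = n_total(t) + n_new(t) − n_lost(t)`
hold unconditionally. `n_new(t)` counts components first detected at
`t+1`, `n_lost(t)` components last detected at `t` (for `t < T`): changes
are booked at the timepoint preceding their observation. Depth
stratification assigns each cell to a half-open bin by the z-centroid at
first detection times the z voxel size, measuring depth from slice z = 0;
this equals depth from the pial surface only if the stack starts there.

## Synthetic scenes

The generator renders what the tracker is designed for, with known ground
truth: a `Beta(2, 20)`-distributed background (×255), somas as solid balls
with a soft 1-voxel edge whose voxels draw from `Beta(20, 3)` scaled by a
peak intensity (default 230) and by depth attenuation `exp(−0.015·z)`,
and 1–2 voxel thick filaments at intermediate intensity (present at all
timepoints). Scenes are deterministic under their seed. Low-SNR
timepoints scale only the fluorescence signal, not the background draws:
the per-slice percentile thresholds are invariant to a global intensity
scale, so a session is only "lost" when its signal sinks beneath the
noise floor — which is exactly the physical failure mode (minimal emitted
signal over constant detector noise), and it makes recall monotone in the
scale factor.

Default scene conditions: the canonical recovery fixture is a
64 × 64 × 24 × 6 voxel scene with 15 radius-5 somas (10 present
throughout, 3 appearing at timepoint 4, 2 last seen at timepoint 2) and
two filaments; radius 5 is the smallest soma that survives the default
median window. At this slice size every slice takes the percentile
fallback path (a 64 × 64 slice retains at most ~41 candidates at the 99th
percentile, below `min_retained`); slices of ~160² pixels and up exercise
the mixture path, which the binarization tests cover separately. What
passing these tests shows — and does not show: exact fate recovery on
these scenes validates the pipeline's logic (thresholding, filtering,
4D connectivity, fate bookkeeping), not its performance on real tissue;
the generator has no optical PSF, no photon shot noise, no registration
error, and its somas are brighter and cleaner than GFP-labelled cells at
depth.

## Known limitations

- Two somas that touch in any frame form one 4D component and are tracked
  as one cell; there is no watershed splitting.
- Cells that drift farther than the merge window between sessions (e.g.
  registration failure) are reported as one lost plus one new cell.
- The minimum detectable soma diameter is set by the median window
  (~11 voxels in XY at the default); adjust `median_window` to the
  imaging resolution before adjusting anything else.
- Depth stratification assumes the stack's first slice is the anatomical
  surface.
- Low-SNR sessions are detected only indirectly (fallback thresholds in
  the diagnostics CSV); deciding whether to exclude a session remains the
  user's call.
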