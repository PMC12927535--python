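# Methods

## Coordinate and unit conventions

Image coordinates are (x right, y down), origin at the centre of the
top-left pixel, 0-based. Every metric quantity is converted to µm at the
measurement boundary using the user-supplied pixel size; there is no
default pixel size because acquisition optics vary. Volumes are stored in
nL (1 nL = 10⁻⁶ mL = 10⁶ µm³) and converted exactly once at module
boundaries; concentrations are cells/mL, laser energy µJ, DDR mm, loading
volume µL. Config files use unit-suffixed keys (`energy_uJ`, `x_um`)
because unit mistakes are the dominant failure mode in this kind of
pipeline.

## Droplet measurement and detection

Label masks (from any segmenter, or from the built-in detector) are
measured with scikit-image region properties. Equivalent diameter is
derived from area, 2·√(A/π), rather than from a bounding box, so it is
robust to non-circular spreading. Circularity is the Fiji definition
4πA/P² with the marching-squares perimeter estimator, clipped to [0, 1];
a zero-perimeter (single-pixel) object is treated as a perfect disk. The
perimeter estimator carries a pixelation bias of a few percent at radii
below ~20 px, which is why tests assert circularity bounds of 0.9–0.95
rather than 1 for rasterized disks.

The built-in detector is deliberately classical: Otsu threshold,
8-connected components, removal of components below a minimum area
(default 25 µm²). It replaces no segmentation research — externally
produced masks are first-class inputs, and pre-flagged satellites in them
are honoured.

## Satellite classification and the five-level grade

For each CAD target, the largest detection within a tolerance radius
(default a quarter of the nominal spacing — half the Nyquist distance
between targets, so no blob can claim two positions) becomes the main
droplet; area ties are broken by distance to the target. Everything else
is a satellite, spatially attributed to its nearest target.

The satellite grade lives on a fixed five-level scale
{0, 0.25, 0.5, 0.75, 1}. The verbal anchors (only satellites / a lot of
small / equally sized / some small / none) need numeric boundaries to be
computable; ours are: mean satellite area ≥ 0.5 of mean main area →
"equally sized" (0.5); satellite-to-main count ratio > 1 → "a lot"
(0.25); otherwise "some small" (0.75); the end points are exact (no
satellites → 1, no mains → 0). A manual override is first-class, since
this grade has historically been assigned by eye, and an optional
per-droplet corrections pathway mirrors manual curation of segmentations.
A print with neither mains nor satellites has no defined grade and
propagates the no-transfer state.

## Scoring and window maps

The four criteria are combined as a weighted mean with equal default
weights; only the diameter requires normalisation. We use the reciprocal
form min(1, d_ref/d): it is scale-free, needs no global maximum diameter,
equals 1 at the reference and decreases strictly beyond it. A linear
alternative 1 − (d − d_ref)/(d_max − d_ref) is available behind a config
switch for users who prefer a bounded-support ramp. The reference d_ref
is the 10th percentile (linear-interpolation, type-7 — the default of
mainstream numeric stacks) of a calibration distribution, pooled across
the calibration prints rather than computed per condition; the percentile
excludes small-end outliers while preserving "smaller is better".
At least 10 calibration diameters are required.

Acceptability uses a threshold of 0.5 on the overall score. No-transfer
is a categorical state distinct from a low score — a condition that
deposits nothing is physically different from one that deposits badly —
and unscreened grid cells are carried explicitly so maps show all three
states. Replicate prints of one condition are pooled before scoring:
diameters concatenated, efficiency as total matched over total expected
(3 replicate 4×4 grids → 48), circularity weighted by main count, and
the satellite grade recomputed from pooled counts.

Repeatability is summarised as the coefficient of variation of pooled
main-droplet diameters, with the sample (n−1) standard deviation because
replicate counts are small (3 prints).

## Content model

Droplet volume is estimated by counting: V = N_cells / (C_ink ·
N_droplets), independent of droplet spreading and hence of receiver
hydrophobicity. The spherical diameter d = (6V/π)^(1/3) converts volume
to an optically comparable size. Poisson prediction and fitting use
scipy; λ̂ is the sample mean (the MLE), and the goodness-of-fit test
pools bins from the upper tail until every bin has expected count ≥ 5,
with degrees of freedom bins − 2 (one estimated parameter). Histograms
that leave fewer than three usable bins are reported as degenerate rather
than tested. The concentration regime boundary is 10⁷ cells/mL, inclusive
on the low side; pattern-level cell totals are predicted under min/avg/max
volume models to bracket the volume variability seen at high
concentrations, optionally normalised to a reference condition's
avg-model total.

## Fidelity, coverage, retention

Fidelity evaluates inter-droplet distances over the design's adjacency
graph — pairs of targets at the nominal spacing ± 10%, which reproduces
"adjacent droplets" on grids without an explicit edge list. For every
pair with both ends matched, the absolute deviation between measured and
target distance is recorded; the headline percentage is
100·(1 − mean deviation / nominal spacing), floored at 0. Because the
field reports fidelity percentages without a canonical formula, the
per-pair-denominator variant and the raw deviations are always emitted
alongside. The statistic depends only on distances, so it is invariant to
print translation and rotation.

Coverage models each droplet as a disk of its equivalent diameter and
sums exact circle–rectangle intersection areas (shapely) over the ROI,
capped at 1.

Retention places square ROIs (default side 300 µm) normal to the CAD
centerline at offsets 0 and ±300 µm and reports mean gray values plus the
centre-to-flanks ratio. The ROI is a 300 µm **side** square, not a
300 µm² area: a ~17 µm box could not straddle a printed line at these
offsets, and the offset geometry implies box dimensions of the same
order. The side length is exposed as a parameter.

## Skeleton morphometrics

Binary network masks are skeletonized (scikit-image) and converted to an
8-connected pixel graph with √2-weighted diagonal steps; diagonal edges
short-circuited by an orthogonal neighbour are dropped so corners do not
form spurious triangles. Junction pixels (≥ 3 skeleton neighbours) are
merged within a 3 px radius — standard cleanup for thick-skeleton
artifacts, exposed as a parameter. Segments are the arcs remaining when
junction pixels are removed, plus their attachment edges; segments
shorter than 3 px are pruned. Reported metrics: total length, segment
count, average length, junction count. This is a re-implementation of
skeleton-based vessel quantification in the AngioTool style, not a
bit-exact clone — its pruning internals are unpublished — so synthetic
benchmarks assert exact junction counts but lengths only to the
few-percent level (skeletons shorten by roughly half the stroke thickness
at free ends).

Viability is two-channel particle counting, n_live/(n_live + n_dead)
with a minimum-area filter; cell-shape circularity reuses the droplet
measurement pipeline.

## Synthetic data

The generator plants known truth for every downstream module. Prints:
each target independently receives a main droplet with probability
`transfer_prob`; diameters are truncated-normal (resampled at ≤ 0, which
leaves the mean essentially unbiased for CV ≤ 0.3 — the paper-style
scatter); centroids get isotropic Gaussian jitter; satellites are
Poisson-distributed per realised droplet and placed in an annulus within
3 main radii of their parent — tied to the main droplet, never sitting on
a target. Overlapping draws are retried up to 100 times before the
density is declared degenerate. Ground truth (match indices, satellite
flags) rides on the returned record whose observations are measured off
the rasterized mask, so "truth" already includes pixelation.

Defaults emulate the reference aqueous printing condition: 4×4 grids at
500 µm spacing, 70 µm droplets, 10% diameter CV, 5 µm jitter, satellites
at 20% of the parent diameter, rasterized at 5 µm/px. The planted quality
surface used in window-recovery tests degrades monotonically with laser
energy past a designated optimum — transfer probability falls from ~1 to
≤ 0.25, droplets grow ≥ 2.3×, satellite rate rises to ≥ 2.5 per droplet —
giving inside/outside overall scores around 0.9 vs 0.4 so that recovery
is a property of the scoring machinery, not of a knife-edge margin.

What the generator does **not** emulate: uneven donor-film spreading,
optical vignetting and focus gradients, merged droplets bridging two
targets, non-Gaussian diameter tails, and segmentation errors of real
micrographs. Passing tests therefore demonstrate that the scoring,
matching and morphometric machinery is correct on well-posed inputs, not
that any particular segmenter will be accurate on real images.

Cell loadings are i.i.d. Poisson draws at λ = V·C; network images are
distance-rasterized strokes plus Gaussian noise with analytic length and
junction truth (a junction is any point where ≥ 3 branches meet, counting
interior crossings as two branches per crossing segment).

Reproducibility: a single seed fans out to per-print substreams via
`numpy.random.SeedSequence.spawn`, keyed by condition and replicate index
— identical seeds give bit-identical masks while conditions stay
statistically independent.

## Problem sizes

Test and acceptance workloads are desk-scale by design: window recovery
uses 6 energies × 2 DDR × 3 replicate 4×4 prints at 5 µm/px; Poisson
calibration uses 100 seeded runs of 300 droplets plus 500-seed λ-recovery
sweeps at n = 48 per λ; fidelity statistics use 30–40 seeded prints at
2 µm/px. These sizes give statistical bounds (3·SE, binomial tails) that
are already tight; larger canvases or replicate counts change nothing but
runtime.

## Known limitations

- Efficiency counts one match per target; a merged droplet spanning two
  targets matches only its nearest target, which may undercount transfers
  relative to manual grading (flagged via the satellite/unmatched output).
- The rubric's numeric boundaries (area fraction 0.5, count ratio 1) are
  one reasonable codification of verbal anchors; regrade manually where
  they bind.
- Skeleton lengths are estimator-dependent near junctions and free ends;
  compare like with like when benchmarking against other tools.
- The quality surface is phenomenological: it reproduces score geometry,
  not jet fluid dynamics. Only the dimensionless Weber number is
  computed.
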