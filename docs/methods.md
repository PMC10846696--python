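# Methods

hyphamap quantifies the growth of a filamentous fungal network (a
*thallus*) from a time series of assembled grayscale panoramas, borrowing
its spatial toolkit from geomatics: exact raster-to-vector conversion,
GIS-style line-density mapping, and natural-breaks classification.  A
synthetic growth simulator with exact ground truth closes the loop,
letting every measurement stage be validated end to end.

## 1. Synthetic mycelium (`hyphamap.simulate`)

Growth is an off-lattice branching random walk.  `initial_tips` hyphae
(default 3) germinate at the origin after a dormancy of `lag_time` hours.
Per time step `dt = min(frame_interval, 0.05)` h each active tip advances
`tip_speed * dt` micrometres along its heading (angular diffusion
`heading_sd` degrees per step) and branches with probability
`branch_rate * dt`; a branch inherits the parent position and deviates by
a signed angle drawn from N(`branch_angle_mean`, `branch_angle_sd`).
Because branching is a pure birth process on tips, the apex count doubles
every `tau = ln 2 / branch_rate` hours in expectation, independently of
`tip_speed`.  Optional anastomosis (radius > 0) fuses a tip that comes
within the radius of an older hypha and deactivates it, creating loops.

Six condition presets encode the qualitative behavior of a fungus grown
under different culture conditions as (target doubling time, lag,
tip speed): standard (2.09 h, 0.31 h, 250 um/h), low_nutrient
(2.91, 0.51, 180), osmotic (3.01, 0.58, 170), intense_light
(3.33, 2.67, 60), low_temp (3.66, 0.39, 100), high_temp
(2.00, 1.76, 200).

The simulator records every elementary segment with its birth time, every
branch/fusion event, and per-frame exact counts (`A_true`, `N_true`,
`L_true`), so any measured quantity can be compared against truth.

**Rasterization.** Segments are drawn into a panorama by covering every
pixel whose center lies within `hypha_width / 2` of a segment, at
`pixel_size` = 1.63 um/px, followed by optional Gaussian blur and additive
Gaussian noise.  The default stroke width is 5 px.  For the bundled
demonstration configuration we use a 2 px stroke: real hyphae are 2-3 um
in diameter, i.e. 1.5-2 px at this calibration, and wider strokes merge
neighboring parallel tips (at 5 px, roughly a third of late tips lie
within one stroke width of another hypha, producing a 25-30% apex
undercount that no threshold choice can undo; 2 px halves it).  A 1 px
stroke was also tried and rejected: after blurring, the strokes lose so
much contrast that automatic thresholding no longer separates hyphae from
noise.

**Realized doubling time.** The ground-truth apex doubling time actually
realized by one finite run is measured from successive-doubling crossing
times: the times at which the count first reaches `base * 2**k`
(log2-interpolated), plus the fractional final level, fitted by weighted
least squares of crossing time versus k with weights proportional to the
count at each level (the crossing interval from c to 2c has relative
spread ~ 1/sqrt(c), so early low-count doublings are noisier).

## 2. Vectorization (`hyphamap.vectorize`)

Each panorama is thresholded (fixed value or Otsu; the threshold value
itself belongs to the lower class, so dark-hyphae polarity keeps pixels
at or below it), speckles smaller than `min_speckle_px` are removed, and
the binary mask is converted into polygons *exactly*: one polygon per
connected component (foreground 8-connected, background 4-connected, the
standard dual pairing), tracing pixel edges so that geometric area equals
pixel count.  Pinch vertices (diagonal-only contacts) are resolved by
decomposing boundary cycles into simple loops.  The *thallus* is the
foreground polygon containing the germination center.

For a whole time series the automatic threshold is computed once, on the
last (most contrasted) frame, and applied to every frame: early frames
contain almost no foreground, and a per-frame Otsu threshold would split
the background noise distribution instead.

## 3. Intra-thallus areas (`hyphamap.areas`)

The intra-thallus areas `S_i` are the background regions completely
enclosed by hyphae: background polygons that do not touch the image
border and are enclosed by the thallus — inside its outer shell, or, for
holes pinched between diagonally-touching parts, bounded exclusively by
thallus pixels.  This matches a border flood-fill on the raster exactly.
Reported per frame: the individual `S_i`, their sum `S`, and their count.
`S` carries a bootstrap uncertainty (resampled sum of the `S_i`); the
count carries a Poisson sqrt(count).

## 4. Skeleton graph (`hyphamap.skeleton`)

The mask is thinned to a 1 px skeleton with a topology-preserving
sequential thinning (8-connected foreground simple points, with residual
2x2 block cleanup).  Skeleton pixels become a graph: degree-1 pixels are
*apexes* (hyphal tips, A), 8-connected clusters of degree >= 3 pixels
collapse into *nodes* (branch points, fusions or mere overlaps, N).
Length uses the chamfer metric (1 per orthogonal step, sqrt(2) per
diagonal), with a redundant-diagonal rule: a diagonal adjacency is
dropped whenever an orthogonal two-step path through a skeleton pixel
exists, so corners are not double counted.  Uncertainties:
`sigma_A = sqrt(A)`, `sigma_N = sqrt(N)`,
`sigma_L = sqrt(A + N) * <l>` with `<l> = L / (A + N)` the mean segment
length.

## 5. Line-density maps (`hyphamap.density`)

On a square grid of cells (default 50 px) the line density of a cell is
the total skeleton length inside a circle of `search_radius` (default
200 px) about the cell center, divided by the circle's area.  The
segment-circle clipped lengths are computed analytically (quadratic
chord clipping), not sampled.  The *envelope* is the set of cells with
nonzero density.  The density distribution is the normalized histogram
of nonzero cell values (bin 0.0024 by default), and maps are classified
for display with exact Fisher-Jenks natural breaks (dynamic programming,
provably minimal within-class variance; goodness reported as GVF).

## 6. Growth laws (`hyphamap.fits`)

Apexes, nodes and total length follow the doubling law
`X(t) = X0 * 2**((t + t0) / tau)`.  `tau` and `X0` are fitted by
weighted nonlinear least squares; `t0` is a fixed temporal offset (on a
single series `X0` and `t0` are exactly degenerate, so `t0` is either
supplied — the negative of the known lag — or chosen by `adjust_t0`,
which grid-searches the shared offset so fitted onset values land in
expected ranges).  Because count-type uncertainties evaluated at the
observed values correlate weights with noise and bias the fit low, the
fit iteratively re-evaluates the supplied error law at the model
(rescaling each sigma by sqrt(model/observed)); a Monte-Carlo pull study
with Poisson noise shows this removes a ~1.2-sd bias.  Uncertainties are
1 sd from the covariance (`absolute_sigma`), with the reduced chi-square
reported.

The total enclosed area `S(t)` grows linearly after its lag (OLS on a
window, R^2 reported).  The number of enclosed areas grows exponentially,
`count = beta * exp(alpha t)`, fitted log-linearly with Poisson weights
on counts within a window (default 5..336, the usable range before
extraction saturates).

## 7. Pipeline (`hyphamap.pipeline`, CLI `hyphamap`)

`run_pipeline(RunConfig)` chains simulate/load -> vectorize -> areas ->
skeleton -> density -> fits, writing every intermediate artifact (masks,
skeletons, GeoJSON polygons, CSV series, density TIFF + PNG, fit JSON)
and a `manifest.json`.  Reruns with the same config are bit-identical.
When frames were simulated, the manifest also carries the ground-truth
comparison (target and realized doubling times).  The `hyphamap` CLI
exposes every stage individually plus `run` and `report`.

## Known limitations

* At raster scale, parallel sibling hyphae closer than one stroke width
  merge, undercounting apexes in dense regions (about -10% median at
  2 px strokes) and slightly inflating fitted apex doubling times
  (+2..+7% per run).  Total length is much less affected (+2..+8%).
* Measured node counts include hyphal overlap crossings, so the node
  doubling time comes out systematically lower than the apex one — a
  property of planar imaging, reproduced deliberately.
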