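# Methods

## Coordinate contract

All arrays are indexed `(slice, row, col)` = `(z, y, x)`, 0-based. Physical
coordinates are nanometres; the centre of voxel `(k, j, i)` is at
`origin + (k·dz, j·dy, i·dx)`. The imaged plane of slice `k` is at
`z = k·dz`: the SEM images the freshly milled *surface*, not a slab centre.
A physical point on a voxel boundary belongs to the lower-index voxel.
Volumes round-trip bit-exactly through multi-page TIFF (via `tifffile`) and
a minimal hand-written MRC2014 reader/writer (modes 0/1/2/6); TIFF voxel
sizes are always supplied by the caller, never guessed from tags.

## Synthetic acquisition model

The phantom is an ellipsoidal cell spanning the whole milling depth (every
slice cuts the cell, as in a real acquisition) containing a spherical
nucleus, a heterochromatin shell of configurable thickness lining the
nuclear envelope, and a spherical nucleolus. Beads are a homogeneous Poisson
process per compartment; default densities are the measured values for the
Fab-conjugated probe — cytoplasm 4.7, euchromatin 24.4, nucleolus 7.5
beads/μm³ — with heterochromatin unlabelled (beads localize to the open
chromatin), all configurable.

Rendering follows a surface-imaging model. Slice `k` shows the compartment
base grey at its surface plane. A bead of diameter `d` centred at `z_p`
contributes a radially Gaussian spot (FWHM = `d`) on every plane with
`|k·dz − z_p| ≤ d/2 + p`, its amplitude scaled by the normalized chord
cross-section `1 − (max(|Δz|−p, 0)/(d/2))²` — the simplest model that
reproduces both the 4-section span at 5 nm slices and the depth-dependent
bead contrast. `p` is the back-scattered-electron penetration depth; its
default is 0 so that the simulated detectability matches the counting
arithmetic (`d/t` sections, `(t−d)/t` missed), which is what the observed
4-section / 20% numbers imply; a nonzero `p` (the physical range is
~5–10 nm) widens the window and is available for sensitivity studies, as is
an effective-diameter variant of the counting model. Note a consequence of
the chord model: a plane exactly tangent to the bead intersects it
geometrically but carries zero contrast, so image-level section spans run
slightly below `d/t` at any finite threshold.

Compartment base greys are deliberately compressed (0.05–0.45) relative to
the bead amplitude (1.0): amplified gold is by far the brightest structure
in the real data, and threshold detection relies on exactly that contrast.
Instrument imperfections: additive Gaussian noise (default σ = 10% of the
bead amplitude), per-slice multiplicative gain (±5%) and additive offset
(±2%) drift, and bounded integer per-slice lateral jitter (±2 px; slice 0
is never jittered and serves as the registration reference frame). One seed
determines everything; independent RNG substreams are derived per stage
(placement / jitter / drift / noise), so e.g. the jitter sequence can be
regenerated without re-rendering.

What the generator does **not** emulate: FIB curtaining and charging,
silver-enhancement size dispersion (all beads share one diameter), bead
aggregation, partial-staining texture inside compartments, and non-spherical
organelle shapes. Passing tests therefore demonstrate correctness of the
algorithms under the stated geometry/noise model, not robustness to every
real-world artefact.

## Preprocessing

Order: invert → drift removal → normalize → align → crop.

*Inversion* is an involution (`max − x` for integer data, `hi − x + lo` for
float). *Normalization* maps percentile bounds to [0, 1]; the default bounds
are the full min/max because robust clipping (e.g. 0.5/99.5%) saturates the
bead cores together with the brightest organelle voxels whenever the bright
compartments occupy more than the upper-tail allowance — flattening the
contrast the detector needs. Per-slice mode exists for stacks whose slices
need independent scaling. *Drift removal* anchors each slice's offset on the
embedding resin: the per-slice median of voxels inside a fixed global grey
window over the dark end of the histogram estimates the acquisition drift
independently of the z-varying cellular content. The correction is
offset-only and partial (gain drift anchored at the background perturbs the
brightest tissue by only its few-percent amplitude); its `background_fraction`
parameter is the approximate resin volume fraction.

*Alignment* is translation-only (FIB/SEM slice-to-slice motion is
translational drift). Each slice is registered to its predecessor (or to
slice 0) by FFT cross-correlation of mean-subtracted **gradient-magnitude**
images (Gaussian σ = 2 px, then Sobel), with the peak search restricted to a
small radius (default 16 px). This combination was chosen empirically on
phantoms: phase correlation whitens the spectrum and locks onto the noise
floor on texture-poor slices, while plain correlation of the raw images has
a degenerate flat peak; the constrained gradient correlator recovers
injected integer jitter exactly on noiseless finely-sectioned stacks and to
≤1 px under the default noise. With `reference="previous"` the pairwise
shifts are accumulated; on coarsely sectioned stacks the surface content
decorrelates between slices and small pairwise errors accumulate into a
staircase random walk, so the running median of the cumulative shifts
(window 15) is subtracted by default (`detrend=True`). Detrending also
removes genuine slow drift — disable it when that drift is real signal.
Sub-pixel registration (parabolic peak fit) is available; integer shifts are
the default and are applied with edge-value padding.

*Cropping* takes a centred window (odd margins split toward lower indices)
and updates the grid origin so physical coordinates are preserved.

## Segmentation

The workflow is semi-automatic, mirroring threshold-plus-trace operation:
the operator provides one seed voxel per compartment (including one in the
extracellular background). With explicit grey bands, a compartment is the
seed's connected component within the band (`trace_region`, topological
connectivity — anisotropy does not affect it). With bands set to `"auto"`,
all seeded compartments are segmented jointly by nearest-seed-level
classification: each voxel takes the compartment whose seed grey level
(local median around the seed) is closest, then only the component connected
to the seed is kept. The classifier was chosen over band growing because
under realistic noise a band either leaks through boundary intensity dips or
fragments into speckle, while the nearest-level rule partitions boundaries
at grey midpoints. Cleanup (binary closing, hole filling — except for the
hollow heterochromatin shell, whose enclosed cavity must survive — and
small-object removal) stands in for manual touch-up. Overlapping claims
resolve by fixed precedence nucleolus > heterochromatin > nucleus >
cytoplasm. A fully automatic mode (5-class Otsu mapped to compartments by
ascending grey) exists but is heuristic: Otsu weights classes by volume and
cannot resolve small compartments such as the nucleolus on realistic
histograms.

Volumes are voxel counts × `dz·dy·dx` in μm³; "whole nucleus" is labels
{2,3,4}, "nucleus without nucleoli" {2,4}, "cell total" {1,2,3,4}. On
noiseless phantoms traced volumes match the analytic geometry within 2%;
under the default noise the σ=2 px boundary blur costs up to ~6% on the
smallest compartment.

## Detection and localization

Candidate voxels are `I ≥ threshold`; 26-connectivity links the footprint of
one bead across consecutive planes into a single component, and the size
filter runs after linking (`min_voxels` 2; `max_voxels` defaults to the
voxel volume of a sphere of 3·d, rejecting membrane-adjacent aggregates). A
gap tolerance can bridge beads invisible on an intermediate slice; the
default is 0 (a split bead stays split). The automatic threshold is
`median + k·1.4826·MAD` of the euchromatin-region intensities (k = 6), a
robust version of "a high fixed offset above the nuclear level": the MAD
ignores the bead voxels themselves, and euchromatin is preferred as the
reference region because the whole-nucleus spread is dominated by the
nucleolus/heterochromatin base greys rather than noise.

Centroids are intensity-weighted centres of mass with the detection
threshold as background (weights `I − threshold`, clipped at 0), which
de-weights the flat super-threshold plateau of saturated beads; z
interpolates between member plane positions `k·dz`. Components whose
weights all vanish fall back to the unweighted centroid with a warning.
Each particle takes the compartment label of the voxel containing its
centroid (boundary points to the lower-index voxel); centroids outside the
grid are an error, label-0 (extracellular) particles are excluded from all
compartment statistics and reported separately.

Measured on 5 nm isotropic phantoms with the default noise model, jitter
and drift, the full pipeline localizes matched beads with an RMS 3D error of
~5 nm (≥99% of beads detected and matched at 250 beads per stack).

## Quantification

`CompartmentStats` rows (N, V, λ = N/V) are computed for cytoplasm, whole
nucleus, nucleus without nucleoli, nucleoli and the cell total; densities
are reported at full precision plus the 1-decimal rounding used in print.
Fold enrichments divide unrounded densities; the nucleus/cytoplasm and
nucleus/nucleolus ratios are emitted both for the whole nucleus and for the
nucleus without nucleoli (published prose is ambiguous about which
denominator some ratios use, so both are always available). The nuclear
fraction is `100·N_nucleus/N_cell`. Counts are corrected for beads lost
between sections by `N/(1 − miss)`. The labelled-molecule estimate is
λ_nucleus × (π/6)·D³ with D the physiological nuclear diameter (default
14 μm), reported at full precision and 2 significant figures; the labelled
fraction divides by an assumed total copy number that must be supplied
(there is no defensible default).

A reconstruction check recomputes the published per-compartment densities
from the published (N, V) pairs: every cell reproduces at 1 decimal except
the Fab whole-nucleus entry, where 1717/71.9 rounds to 23.9 against a
printed 23.8 — the recomputed value is kept and the discrepancy logged as a
warning, never silently patched. The published prose percentages of nuclear
particles (84%/79%) are similarly not derivable from the printed counts
(which give 89.8%/86.6%); the package reports what it computes.

## Spatial statistics

Nearest-neighbour distances use a k-d tree (verified against brute force).
`fraction_separated` uses a strict inequality ("separated by more than r");
ties at r count as close pairs. The clustering test simulates `n_reps`
(default 199, minimum 99) CSR patterns with the observed count uniformly
inside the observed compartment mask (uniform voxel choice plus uniform
within-voxel offset) and flags the pattern clustered when its mean NN
distance falls below the 2.5th percentile of the null. No edge correction
is applied: the null is simulated in the identical masked domain, so edge
effects cancel by construction. Unbounded-CSR closed forms
(mean NN = Γ(4/3)·(4πλ/3)^(−1/3), void probability exp(−λ·4πr³/3)) are used
as independent oracles in the tests, evaluated on interior points to avoid
edge bias.

## Problem sizes and numerical choices

Desk-scale defaults are used throughout: the default phantom is
120×256×256 voxels at (25, 5, 5) nm, the localization experiment
336×352×352 at 5 nm isotropic with 250 beads, the recovery experiment
300×320×320 at 5 nm with the default densities (a few tens of beads —
recovery is therefore asserted within 3 Poisson standard errors, the honest
resolution at this scale). Geometry scales down from the physiological cell;
densities stay physical. Monte-Carlo checks of the detectability closed
forms use ≥10⁵ samples. All stochastic tests fix their seeds; the pipeline
records the configuration hash and seed in every report so each number is
reproducible bit-for-bit.

## Known limitations

* Registration is translation-only; rotational or elastic distortions are
  out of scope.
* The drift correction removes per-slice offsets only; uncorrected gain
  drift of a few percent remains on bright structures.
* Detection undercounts beads whose best plane grazes the sphere whenever
  noise forces a high threshold — visible at 25 nm sections, where the
  geometric 80% detectability is an upper bound for any finite-contrast
  detector; at 5 nm sections detection is effectively complete.
* Touching beads are not split (no watershed); aggregates are rejected by
  the size filter instead.
* The labelled fraction depends entirely on the assumed total copy number.
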