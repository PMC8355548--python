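# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the `ciliaquant` toolkit. Empirical statements below are
limited to what the test suite and `scripts/acceptance.py` themselves
compute.

## Cilia beat frequency from bead movies (`beadcbf`)

**Model.** A bead attached to the apical membrane of a beating MCC oscillates
about a fixed rest position. The pipeline estimates the dominant frequency of
that oscillation per bead and summarises the movie by the median over beads.

**Background removal.** The per-pixel temporal median of the stack, computed
on a uniform subsample of at most 200 frames, is subtracted from every frame.
The median is robust to each bead's own transit and absorbs any constant
intensity offset; the pipeline is therefore invariant to global offsets and,
because all later steps are ratio- or position-based, to global linear
intensity rescaling.

**Bead recognition and tracking.** Two trackers are provided.

* *Activity-ROI tracking* (default, `tracking="roi"`). The per-pixel temporal
  standard deviation of the residual stack is compared against its noise
  floor (median of the activity map) plus `threshold_sd` (default 5) robust
  standard deviations; 8-connected components of at least `min_area`
  (default 4) pixels are the bead ROIs. Each bead's trajectory is the
  |residual|-weighted centroid within its ROI in *every* frame. This design
  matters for quasi-stationary beads whose oscillation amplitude is
  comparable to the bead radius: the bead then never fully leaves its own
  median footprint, its instantaneous residual periodically dips below any
  per-frame detection threshold (measured: ~40% per-frame visibility with
  dropouts of ~1/6 of a beat period at the default conditions), and
  frame-by-frame detection fragments. The temporal activity map has no such
  dropout. Its limitation: beads whose oscillation paths pass within a few
  bead radii of each other can merge into one ROI (their shared centroid
  still oscillates at the common frequency); beads that transit the field
  are not handled.
* *Detection + linking* (`tracking="link"`). Per frame, pixels whose
  residual magnitude exceeds `threshold_sd` times the frame's robust scale
  (1.4826 × MAD, floored at 0.1% of the frame's dynamic range so that a
  noise-free frame does not degenerate to a zero threshold) are grouped by
  8-connectivity; components ≥ `min_area` yield |residual|-weighted
  centroids, with a polarity switch for dark, bright or both-signed beads.
  Detections are linked greedily by nearest neighbour (links under
  `max_disp` = 8 px per frame step, conflicts resolved by ascending
  distance), gaps of up to 2 frames are linearly interpolated, and tracks
  whose gap-filled span covers less than `min_coverage` = 50% of the movie
  are discarded. Suitable for sparse transiting beads; not for dense
  crossing scenes.

The residual-weighted centroid carries a small systematic bias (≈1–1.5 px at
the default geometry) because the median footprint distorts the residual
blob. The bias is a periodic function of the beat phase, so it leaves the
fundamental frequency untouched; tests assert sub-2-px fidelity and exact
frequency recovery rather than sub-pixel positions.

**Spectral estimation.** Each axis series is linearly detrended (removing
slow drift), Hann-windowed, zero-padded to 4× its length, and the
periodogram peak is located in [`f_min`, fps/2) with three-point parabolic
refinement. `f_min` defaults to 0.5 Hz, below the slowest beating of
interest (~2 bps) but above DC/drift leakage. The reported `f_beat` is the
frequency of the axis with the larger peak power — both per-axis values are
always emitted so any other convention can be recomputed. The per-bead
quality ratio (peak power over median band power) gates the movie summary at
`quality_min` = 5. Frequencies are reported in "bps", numerically Hz.

With 20-s movies the spectral resolution is 1/duration = 0.05 Hz; the
acceptance script demonstrates median recovery within ~1e-4 Hz of the
simulated truth at both 15 bps and 2 bps (10 beads, 120 fps, amplitude 3 px,
SNR 10).

## Synthetic bead movies (`synthdata.make_movie`)

Bead *i*'s centre at frame *t* is
`rest_i + drift·t + A·sin(2π f_i t / fps + φ_i)·(cos θ_i, sin θ_i)`; beads
are Gaussian blobs of standard deviation `bead_radius` (default 2 px) with
signed contrast (default −50: dark beads on the bright background, as
magnetic beads appear in brightfield) on a constant background of 100
(optionally with a linear gradient so background removal is genuinely
exercised), plus i.i.d. Gaussian pixel noise (default sd 5, i.e. SNR
|contrast|/noise_sd = 10). Defaults follow the acquisition regime of the
assay: 120 fps, 20 s, 10 beads. The sinusoid is the minimal waveform
exposing a single dominant frequency — the quantity the pipeline claims to
measure; the 3-px amplitude is a free choice of plausible magnitude. Rest
positions are rejection-sampled with pairwise separation of at least
4×`bead_radius` plus the full oscillation diameter, so trajectories never
collide; the margin also accounts for drift. Not modelled: metachronal
waves, non-sinusoidal stroke asymmetry, optical PSF, photobleaching —
passing tests therefore validate frequency recovery, not waveform realism.

## Basal-body alignment (`bbalign`)

**Segmentation.** Within each cell of the label mask, pixels above a
per-cell Otsu threshold (or a fixed value) are grouped by 8-connectivity;
components under `min_area` = 3 px are dropped, and components straddling
cell borders are clipped by the mask. The threshold and minimum size are
documented free choices; the per-ROI table preserves everything needed to
re-aggregate differently.

**Minimum enclosing ellipse.** Each ROI's point set is the four corner
points of every member pixel — pixels have extent, so a single-pixel ROI
yields a finite circle (Mm ratio 1) and a one-pixel-wide row yields a valid
thin ellipse rather than a degenerate segment. The minimum-area enclosing
ellipse is the solution of the dual D-optimal design problem, computed by
Khachiyan's barycentric-coordinate iteration with Wolfe–Atwood away steps
(the away steps give linear convergence where the plain iteration is
sublinear), to relative optimality tolerance 1e-7 with a 10 000-iteration
cap. Points are centred and scaled to unit RMS first (absolute image
coordinates badly condition the lifted moment matrix). Exact-line-search
steps shrink with the optimality gap, so near machine precision the iterate
can plateau; a stall detector then accepts the best iterate provided its gap
is below 1e-4 (in practice ~5e-6). Finally the ellipse is scaled minimally
so that the farthest point lies exactly on the boundary — this guarantees
containment and preserves the axis ratio. Degenerate (collinear) inputs
raise a numerical error. Correctness is checked against the closed form for
rectangles (semi-axes √2 × half-widths) and against an independent
convex-program solution (log-det maximisation under containment
constraints, solved by SLSQP) on random point sets, with areas agreeing to
0.1%.

**Metrics and comparison.** Eccentricity = focal separation over major-axis
length = `sqrt(a² − b²)/a`; Mm ratio = `a/b`. Per-cell values are unweighted
means over the cell's ROIs (the per-ROI table allows count-weighted
re-aggregation); cells without ROIs are omitted with a log line. Group
comparison uses Welch's unequal-variance two-tailed t-test on the per-cell
means.

**Synthetic BB images** (`synthdata.make_bb_image`) place non-overlapping
disk-shaped cells on a jittered grid. Aligned cells receive
`rows_per_cell` = 3 parallel rows of `bbs_per_row` = 8 blobs (sd 1.5 px)
spaced 2 sigma along the row so neighbours merge into one elongated
component after thresholding, with perpendicular jitter `row_spread`
= 0.7 px; non-aligned cells receive the same blob budget in compact
isotropic clusters. With these defaults the per-cell mean Mm ratio separates
the two conditions (Mann-Whitney p < 0.01 per seed) and a simple Mm ≥ 2 rule
classifies the ground truth with ≥ 90% accuracy — a validation of the
metric's discriminative direction, not a biological claim. Rotational
polarity of basal feet and tissue-level planar polarity are out of scope.

## Mander's co-localization (`coloc`)

`M1 = Σ{red_i : red_i > t_red, green_i > t_green} / Σ{red_i : red_i > t_red}`
and symmetrically for `M2` — the thresholded-denominator convention; a flag
restores unthresholded denominators. Thresholds are per-channel Otsu by
default or user-fixed; both are recorded in the output. A channel with no
above-threshold signal yields NaN rather than an exception. Note that M1 is
monotone non-increasing in the *partner* threshold (raising `t_green` only
shrinks M1's numerator) but not in its own threshold, which also shrinks the
denominator.

**Shift null.** The green channel is displaced `shift_pixels` (default 5)
along +x and both channels are cropped to the overlap region — no
wrap-around, which would fabricate overlap at the seam. Across a batch of
image pairs, a paired two-tailed t-test compares each coefficient with its
shifted counterpart; identical pairs (zero-variance differences) return an
exact-tie marker with an undefined p-value. Calibration is checked on sets
of structure-free noise images (10 images of 128×128 per set): the
rejection rate at α = 0.05 is nominal within binomial error. With fewer,
smaller images per set the paired t-test becomes mildly anticonservative
because the per-image deltas are skewed — a limitation to keep in mind for
very small batches.

**Synthetic pairs** (`synthdata.make_coloc_pair`) render red spots with
minimum separation 4 sigma and green spots of which a fraction
`co_occupancy` sit exactly on randomly chosen red spots; the remainder are
kept at least 4 sigma away from every red spot. At matched Otsu thresholds
the measured `M2` tracks `co_occupancy` within ±0.05 (slight downward bias
from spot-edge pixels). Real confocal images with partial, sub-pixel overlap
are not emulated.

## Jam3 marker comparison (`scmarkers`)

Cells are split on the split gene (default `Jam3`): positive = at least one
read. Marker-panel scores are per-cell CPM (counts × 1e6 / library size; a
`fraction` mode omits the 1e6) averaged without weights over the panel's
present genes; absent genes are dropped with a warning, zero-depth cells get
NaN. Groups are compared per panel (deuterosomal, mature) and for the
reference gene (default `Foxj1`) with a two-sided Mann-Whitney test — chosen
over the t-test for sparse counts; per-gene outputs allow any other
aggregation. Marker lists are plain text files, one gene per line, supplied
by the user; the bundled defaults name canonical deuterosomal
(Ccno, Cdc20b, Deup1, Foxn4, Mcidas) and mature-MCC
(Tmem212, Fam183b, Dnali1, Tppp3, Sntn) genes for the synthetic workflow.

**Synthetic counts** (`synthdata.make_counts`) follow a gamma-Poisson
(negative binomial) model with dispersion 0.3. Defaults: 2000 genes, 500
cells, mean depth 5000, Jam3-positive fraction 0.5. Deuterosomal marker
means are multiplied by `effect_deutero` (default 3) in Jam3-*negative*
cells; mature markers and Foxj1 are identically distributed in both groups.
Marker genes sit at the filler-gene median abundance so the panels are a
realistically tiny fraction of each cell's library: a large marker share
would leak the deuterosomal effect into every other gene's CPM through
library-size normalisation (a compositional artifact this generator is
explicitly designed to avoid, mirroring real data where a 5-gene panel is a
negligible library fraction). Batch effects, dropout zero-inflation beyond
the NB, and cell-type mixtures are not modelled; the recovered pattern
(deuterosomal difference present, mature difference absent) is a
self-consistency check of the pipeline under its own generative model.

## Reproducibility and interfaces

Every generator and every CLI run is seeded and deterministic: identical
parameters and seed give bit-identical outputs. Each CLI run writes a
`run_manifest.json` with the tool version, the fully resolved configuration
(flag > YAML config > default) and SHA-256 digests of all input files.
Frame rate is always an explicit user argument, never read from file
metadata, because every frequency scales linearly with it. Movies are
multi-page TIFF (or directories of ordered single-page TIFFs; RGB frames are
converted by BT.601 luma); channel images are one single-channel TIFF per
channel; tables are CSV with alphabetical columns; count matrices are TSV or
MatrixMarket with label files. Proprietary microscope formats and video
containers are out of scope — convert to TIFF first.

## Problem sizes used in the validation suite

The acceptance checks run the full CBF pipeline on two 2400-frame 128×128
movies (10 beads each), the ellipse oracle on 100 random point sets, the
alignment separation on ten 40-cell 512×512 images, the shift-null
calibration on 200 ten-image sets, and the marker comparison on a
2000 × 500 matrix — sizes chosen so the entire suite completes in about a
minute on one CPU while leaving every statistical check well-powered.
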