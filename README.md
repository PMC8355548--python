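# ciliaquant

Quantification toolkit for imaging assays of multiciliated cells (MCCs) in
airway epithelial cultures. It implements, as a tested Python library plus a
`ciliaquant` command line, four analyses that are usually done with ad-hoc
interactive tools:

1. **Cilia beat frequency (CBF) from bead movies.** Magnetic beads dropped
   onto the apical surface of a differentiated culture ride the ciliary beat.
   From a high-speed movie (e.g. 120 fps, ~20 s) the pipeline removes the
   static background (per-pixel temporal median), recognises each beating
   bead as an ROI from the stack's temporal activity, extracts the bead's
   centroid trajectory in every frame, and estimates the dominant frequency
   of each axis by FFT (Hann window, 4x zero-padding, parabolic peak
   refinement). The reported per-bead frequency, in beats per second
   (numerically Hz), is the axis with the larger spectral peak; a movie-level
   median over quality-filtered beads summarises the culture.
2. **Basal-body (BB) alignment scoring.** In well-coordinated MCCs basal
   bodies sit in long parallel rows; misaligned ones form compact clusters.
   Each stained BB ROI inside a selected cell is summarised by its minimum
   enclosing (Löwner–John) ellipse, fitted to the ROI's pixel-corner points
   with a Khachiyan-type algorithm. Reported per ROI: eccentricity
   `sqrt(a² − b²)/a` and the **Mm ratio** `a/b` (major over minor semi-axis);
   per cell: the unweighted means; between groups (e.g. control vs
   knockdown): a Welch two-tailed t-test.
3. **Mander's co-localization with a pixel-shift null.** `M1` is the fraction
   of above-threshold red intensity co-occurring with green signal, `M2` the
   converse. As a chance-overlap control the green channel is displaced 5 px
   along x (cropping the non-overlapping strip) and the coefficients are
   recomputed; across a set of images a paired two-tailed t-test quantifies
   the drop.
4. **Jam3-positive/negative single-cell marker comparison.** MCCs from a
   genes × cells count matrix are split on Jam3 expression (positive = at
   least one read); per-cell CPM scores of deuterosomal-stage and mature-MCC
   marker panels are compared between the groups with a two-sided
   Mann-Whitney test.

A first-class synthetic-data module (`ciliaquant.synthdata`, also exposed as
`ciliaquant simulate movie|bb|coloc|counts`) generates seeded inputs with
known ground truth for every stage, so the whole toolkit can be validated
end-to-end without microscope data. See `docs/methods.md` for models,
parameters and limitations.

## Worked example

Simulate a 20-second, 120-fps movie of 10 beads beating at 15 bps (the rate
of a healthy untreated culture) and recover the frequency:

```sh
$ printf 'duration: 20.0\nn_beads: 10\nf_true: 15.0\n' > movie.yaml
$ ciliaquant simulate movie --params movie.yaml --seed 1 --out sim
wrote synthetic movie data to sim
$ ciliaquant cbf --movie sim/movie.tif --fps 120 --out cbf_results
median f_beat = 15.000 bps over 9 beads
$ cat cbf_results/cbf_summary.json
{
  "iqr_f_beat": 0.00022738206124905957,
  "median_f_beat": 14.999935406446914,
  "n_beads_total": 9,
  "n_beads_used": 9
}
```

The movie simulated 10 beads; two oscillation paths fell close enough to
merge into one activity ROI, so 9 trajectories were analysed. All 9 passed
the spectral-quality filter and their median recovered frequency, 14.99994
bps, matches the simulated 15 bps to well within the spectral resolution
(1/duration = 0.05 Hz). `cbf_results/cbf_per_bead.csv` holds the per-bead
per-axis frequencies and peak powers, `trajectories.csv` the raw centroid
series, and `run_manifest.json` the full resolved configuration and input
digests for reproducibility.

The other assays follow the same pattern, e.g.:

```sh
ciliaquant simulate bb --seed 7 --out bbsim
ciliaquant bbalign --image bbsim/bb.tif --mask bbsim/cells.tif --group control --out bb_results
ciliaquant bbalign-compare control/cells.csv knockdown/cells.csv --out comparison
ciliaquant coloc --red red.tif --green green.tif --shift 5 --out coloc_results
ciliaquant scmarkers --counts counts.tsv --deutero deutero.txt --mature mature.txt --out sc_results
```

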