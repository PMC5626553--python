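# filotrack

Filopodia — thin, actin-rich protrusions that neuronal growth cones and many
other motile cells extend to probe their environment — live at the limit of
what fluorescence time-lapse imaging resolves: a few hundred nanometres wide,
microns long, extending and retracting within seconds. `filotrack` is a
Python library and command-line tool that reconstructs filopodia from
two-channel time-lapse movies (a membrane "mapping" channel for geometry, an
optional "measurement" channel for a labelled protein), tracks each
filopodium over time, measures its shape and movement together with tip and
base fluorescence, and tests whether protein accumulation and tip movement
are genuinely coupled.

It is intended for cell biologists quantifying filopodial dynamics (growth
cones, tracheal cells, leading-edge cells, dendritic filopodia) and for
methodologists who need a fully scriptable, ground-truth-testable
reimplementation of this measurement pipeline.

## What it computes

**Segmentation.** Each mapping frame is convolved with a
Laplacian-of-Gaussian kernel

```
f(x, y) = -1/(pi sigma^4) (1 - (x^2+y^2)/(2 sigma^2)) exp(-(x^2+y^2)/(2 sigma^2))
```

binarised with an auto-threshold method (Renyi entropy, Huang, Otsu,
Triangle, ...), and the largest object is taken as the cell. `n` binary
erosions followed by `n` dilations delete thin protrusions from the mask;
subtracting the opened mask leaves the filopodia, each assigned a base
(contact with the body boundary) and a tip (farthest pixel from the base).

**Tracking.** Frame-to-frame identity is a one-step Hungarian assignment
with cost

```
cost = (dist(base1, base2) + dist(tip1, tip2)) / overlap_area * dT
```

followed by threshold filters (minimum frames, maximum length reached,
length change, mean waviness) that separate real filopodia from boundary
noise, plus a programmatic editing API (delete / delete-range / relink) that
replays from a CSV file.

**Morphodynamics.** Length is `perimeter/2` with a capsule end-correction;
straightness is `D(tip, base)/length`. Movement is reported as
direction-corrected tip movement (DCTM) and base movement (DCBM): the tip
(base) displacement projected onto the current base→tip axis, in nm/s —
insensitive to lateral swinging. Cleaned series (0.5–99.5 percentile filter,
5-point rolling mean) are classified into extending / stalling / retracting
states at ±32.5 nm/s (one 65-nm pixel per 2-s frame) over 10-s windows, and
tip persistence is the first zero crossing of the movement autocorrelation.
Fluorescence is measured in the protrusion, tip, Otsu-thresholded tip, base
and body regions, background-subtracted and normalised to the body; for
newly formed filopodia the base position is back-projected onto earlier
boundaries to read out pre-formation protein accumulation.

**Coupling statistics.** Per track, the cross-correlation function (CCF)
between normalised tip fluorescence and smoothed DCTM is computed over ±6 s
offsets (negative offset = fluorescence precedes movement); tracks are
hierarchically clustered on their CCFs and the "responding" subcluster
(maximal zero-offset CCF) is tested against two nulls: block randomization
(movement reshuffled in blocks of 8 frames, reclustered, subcluster size
matched to ±15%, 1000 accepted randomizations) and independent Markov
chains fitted to each series binned into nine equal-width states (10,000
simulated pairs per track).

A synthetic-movie generator (`filotrack.synthetic`) renders
growth-cone-like bodies with capsule-shaped, kinetically scripted
protrusions plus tip-localised fluorescence, with exact analytic ground
truth — every stage of the pipeline is testable without microscope data.

## Worked example

```python
from filotrack import PipelineConfig, io, pipeline
from filotrack.synthetic import benchmark_movie_spec, generate_movie

spec = benchmark_movie_spec(n_frames=60, seed=4)   # 6 scripted filopodia
movie, truth = generate_movie(spec)
io.write_timelapse("movie.tif", movie)

cfg = PipelineConfig(measurement_channel=1, seed=4, output_dir="out")
manifest = pipeline.run_pipeline(cfg, "movie.tif")
print(io.read_table("out/track_summaries.csv")[
    ["track_id", "max_length_um", "median_tip_extension_rate",
     "frac_extending", "frac_stalling", "tip_persistence_s"]].round(2))
```

prints one row per reconstructed filopodium:

```
 track_id  max_length_um  median_tip_extension_rate  frac_extending  frac_stalling  tip_persistence_s
        0           4.12                      37.57            0.42           0.33              27.99
        1           3.90                      33.61            0.29           0.71              24.40
        2           3.62                      34.12            0.04           0.96              24.19
        3           2.91                      33.64            0.13           0.87              16.70
        4           3.62                      36.14            0.42           0.38              21.82
        5           3.23                      34.83            0.20           0.76              16.88
```

All six scripted filopodia are recovered; maximum lengths sit in the
scripted 2.9–4.2 µm range, median extension rates are a little above the
32.5 nm/s threshold (the schedules oscillate at 30–36 nm/s, so tips hover
between stalling and extending, which the state fractions reflect), and
persistence is tens of seconds, matching the scripted extension
half-periods. The output directory also contains per-frame label masks,
boundary polygons, the long-format per-frame metrics table, the analysis
report (CCF clusters and any null-model results), the resolved
configuration and a run log.

The same pipeline is available from the shell:

```sh
filotrack simulate --out movie.tif --seed 4
filotrack run movie.tif --out results --seed 4
filotrack analyze results/metrics.csv --randomization --markov --out results
```

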