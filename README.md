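# cellfoam

Quantitative image analysis for foam-like (honeycomb) cellularization:
a tested, reusable re-implementation of the measurement pipeline for
time-lapse fluorescence microscopy of cellularizing sporangia, together
with a fully seeded synthetic-scene generator that stands in for the
microscopy data.

## What it does

| Module | Analysis |
| --- | --- |
| `cellfoam.geometry` | direct least-squares ellipse fitting, concentric-ellipse ("donut/disk") constructions, polar/log-polar unwrapping, elliptical band line-scans, tri-furrow vertex-angle metrology |
| `cellfoam.nuclei` | nuclear segmentation (multi-Otsu + watershed), the cortical nuclear ratio time series, peak alignment, loess smoothing with pointwise CIs |
| `cellfoam.foam` | peak-to-peak daughter-diameter estimation, coefficient of variation, gray-level co-occurrence Angular Second Moment (relative homogeneity) |
| `cellfoam.ablation` | FFT cross-correlation PIV with SNR filtering, radial velocity decomposition about an ablation site, bootstrap-CI distance/time summaries, kymographs, receding-tip distance curves and exponential recoil fits |
| `cellfoam.resampling` | one-tailed permutation test of the difference of means (exact or Monte-Carlo), percentile bootstrap CIs |
| `cellfoam.synthetic` | seeded generators with ground truth: Lloyd-relaxed Voronoi foam sections, artificial tri-furrows, cortical-migration movies, post-ablation recoil movies (with blank ablation frames), tip-recoil movies, network-dissolution movies, peripheral daughter rings |
| `cellfoam.pipeline` / `cellfoam.cli` | orchestration, config serialization, phenotype tallies, CSV/TIFF/JSON I/O |

## CLI

A single `cellfoam` command with one subcommand per stage. Every run
writes a `config.yaml` into its output directory; re-running from that
config reproduces the outputs byte-for-byte.

```sh
# generate a synthetic post-ablation recoil movie with ground truth
cellfoam simulate recoil --out results/sim --seed 21 --shape 160,160

# PIV + radial decomposition + binned bootstrap summary
cellfoam piv --stack results/sim/stack.tif \
    --ablation-x 79.5 --ablation-y 79.5 \
    --ablation-start 3.5 --ablation-end 5.5 --px 0.11 --out results/piv

# cortical nuclear ratio of a nuclei stack
cellfoam cortical-ratio --stack nuclei.tif --boundary-factor 0.70 \
    --interval-min 1 --out results/ratio

# other stages
cellfoam angles --annotations vertices.csv
cellfoam unwrap --stack mem.tif --mode log
cellfoam daughter-size --stack mem.tif --factor 0.85 --band-px 3
cellfoam texture --stack actin.tif --ref-frame 11
cellfoam kymo --stack actin.tif --line 10,32,54,32 --width 20
cellfoam tips --stack actin.tif --line 10,32,90,32 --width 10
cellfoam permtest --a a.csv --b b.csv --alternative less --seed 7
cellfoam tally --counts counts.csv
```

## Conventions

- Coordinates: 0-based pixel indices, `(x = column, y = row)`, pixel
  centers at integers; angles from the +x axis, counter-clockwise in
  image coordinates.
- The elliptical "radius" of a point is the factor `f` placing it on the
  fitted ellipse scaled by `f`; the equal-area donut/disk boundary is
  `f = sqrt(1/2)`, with `f = 0.70` as the conventional default.
- Radial velocity sign: positive = motion away from the ablation site
  (recoil), negative = toward it (repair).
- All randomness is seeded; identical configs give bit-identical stacks.

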