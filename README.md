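# gliaquant

Quantification of microglial dynamics from fluorescence and electron
microscopy — the measurement side of experiments on microglia during
ocular dominance plasticity in visual cortex.

Microglia, the brain's resident immune cells, continuously extend and
retract fine processes and interact with synapses. Studying how their
behaviour changes during experience-dependent plasticity (e.g. monocular
deprivation during the visual critical period) requires a battery of image
quantifications, most of which were historically done with one-off ImageJ /
Matlab scripts. `gliaquant` packages those procedures as tested, reusable
library functions with a thin CLI:

- **Sholl morphometry** (`gliaquant.morphology`) — process-arbor
  ramification as the number of crossings of concentric circles centered on
  the soma; plus soma area / background-subtracted intensity and cell
  density per imaged area.
- **Pixel-classification motility** (`gliaquant.motility`) — consecutive
  thresholded time-lapse projections are compared per pixel (stable /
  extended / retracted, the red–green–yellow overlay convention). Per
  overlay, the motility index is (extension + retraction pixels) / stable
  pixels, averaged across overlays; extension and retraction indices are
  the two components. The stability index is the fraction of newly extended
  pixels still present in the next overlay; the instability index is the
  fraction of stable pixels lost in the next overlay; the stability
  histogram tracks survival of newly stabilized pixels over subsequent
  overlays. A traced-process mode computes mean |ΔL|/Δt from manually
  measured process lengths.
- **Laser-ablation response** (`gliaquant.ablation`) — chemotaxis toward a
  focal injury, R(t) = (Rx(t) − Rx(0)) / Ry(0), where Rx counts thresholded
  process pixels inside an inner disc (~40 µm) and Ry(0) counts the outer
  annulus (~40–80 µm) at time zero.
- **Engulfment scoring** (`gliaquant.colocalization`) — two-channel
  confocal stacks are triangle-thresholded, multiplied, and connected
  components larger than one pixel are counted as internalized puncta,
  normalized by the microglial area (puncta/µm²).
- **Ocular dominance index** (`gliaquant.ios`) — per-pixel Fourier
  amplitude of intrinsic-signal recordings at the stimulus frequency
  (normalized 2·|X[k]|/N), ROI-averaged per eye over both stimulus
  directions, then ODI = (C − I)/(C + I).
- **EM event statistics** (`gliaquant.em_stats`) — per-process synaptic
  contact / inclusion counts normalized by process area (events/µm²), a
  single pass of Grubbs' outlier test, and per-animal → per-group
  aggregation (animals are the unit of replication).
- **Synthetic data** (`gliaquant.synthetic`) — seeded generators with exact
  ground truth for every stage (arbors with analytic Sholl profiles, movies
  with known extension/retraction pixel sets, converging ablation movies,
  planted puncta, exact-bin sinusoidal sessions, Poisson event tables), so
  the whole pipeline is verifiable without animal data.

## Worked example

Generate a 12-frame time-lapse (4-min intervals) of a synthetic arbor with
10% of foreground pixels extending and retracting per interval, add
realistic acquisition noise, and run the full pipeline (registration,
thresholding, pixel classification):

```python
from gliaquant import synthetic as syn
from gliaquant.motility import analyze_movie

arbor = syn.generate_arbor(n_branches=6, branch_radii=[5, 10, 15, 20], seed=7)
movie = syn.generate_timelapse(arbor, T=12, extension_fraction=0.10,
                               retraction_fraction=0.10, frame_interval=4.0,
                               seed=8, noise_sd=25.5)
result, overlays = analyze_movie(movie.frames)
print(f"motility index    : {result.motility_index:.3f}")
print(f"extension index   : {result.extension_index:.3f}")
print(f"retraction index  : {result.retraction_index:.3f}")
print(f"stability index   : {result.stability_index:.3f}")
print(f"instability index : {result.instability_index:.3f}")
```

prints

```
motility index    : 0.202
extension index   : 0.110
retraction index  : 0.092
stability index   : 0.508
instability index : 0.036
```

The motility index of 0.202 recovers the planted 0.10 + 0.10 change per
interval (extension and retraction each contribute their fraction of stable
pixels, with small deviations because fractional pixel counts round and
tips can run out); about half of newly extended pixels persist into the
next overlay, and ~4% of stable pixels destabilize per interval.

The same analyses are available from the shell, e.g.

```sh
gliaquant simulate timelapse --seed 8 --out sim/
gliaquant motility sim/timelapse.tif --interval 4 --out motility.json
gliaquant sholl arbor.tif profile.csv --center 32,32 --step 5 --max 20
gliaquant emstats events.csv --alpha 0.05 --out summary.csv
```

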