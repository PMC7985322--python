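# punctakit

Quantification of biomolecular condensate disruption in live-cell
fluorescence microscopy.

Many proteins (FUS, huntingtin exon 1, engineered optogenetic clusters…)
phase-separate into bright condensates — a dense phase suspended in the
dilute cytosolic pool.  Experiments that dissolve or block these condensates
(chemically induced recruitment of a disrupting ligand, light-switchable
clustering, and similar perturbations) are read out from timelapse images,
and the numbers that matter are surprisingly convention-laden: how the dense
phase is thresholded, how background is handled, what "fraction in
condensates" means, and how a characteristic time is extracted.  punctakit
implements that analysis as a tested, scriptable pipeline for experimentalists
and image analysts, together with a synthetic movie generator with exact
ground truth so every stage is validated by parameter recovery.

## The statistics at the core

With background-subtracted intensities inside a cell mask:

- condensate fraction
  `F = Area_dense · (MeanI_dense − MeanI_dilute) / TotalIntegratedDensity`
- percent disruption efficiency `100 · (F_pre − F_post) / F_pre`
- dense/dilute ratio `MeanI_dense / MeanI_dilute` and its regression against
  efficiency across cells
- condensate intensity ratio: integrated intensity inside condensates over
  total cell integrated density (endpoint formation/blocking assays)
- dissolution kinetics: least-squares fits of
  `v(t) = base + amplitude/(1 + exp((t − t_half)/τ))` (sigmoid) or
  `v(t) = base + amplitude·exp(−(t − t_start)/τ)` (exponential), reporting
  the characteristic time τ with standard errors
- FRAP recovery: region/total-cell ratio traces mapped to [0, 1] with 0 at
  the bleach point and 1 at the pre-bleach average; the plateau estimates the
  mobile fraction

Condensate masks come from ImageJ-convention histogram thresholds (Otsu or
Kapur maximum-entropy, 256 bins over [min, max], strictly-greater masks),
cell masks from the Mean threshold.  See `docs/methods.md` for every
convention and the reasoning behind it.

## Worked example

Simulate a dissolution movie (8 condensates at partition coefficient 6 over
a 40 photon/px dilute pool, sigmoid dissolution with τ = 30 s starting at
t = 60 s, shot + read noise) and run the full pipeline on it:

```python
from punctakit import RunConfig, SimulationConfig, run_pipeline

config = RunConfig(
    out_dir="demo_run", seed=7,
    simulation=SimulationConfig(seed=7, kinetics_model="sigmoid_decay",
                                tau_s=30.0, onset_s=60.0, n_frames=120,
                                frame_interval_s=2.5))
summary = run_pipeline(config).summary
for k, v in summary.items():
    print(f"{k}: {v:.4g}" if isinstance(v, float) else f"{k}: {v}")
```

prints

```
fraction_pre: 0.273
fraction_post: 0.001578
efficiency_percent: 99.42
true_efficiency_percent: 99.27
tau_s: 30.11
fit_converged: True
true_tau_s: 30
```

i.e. 27.3% of the cell's scaffold signal started in condensates, essentially
all of it was released (99.4% measured vs 99.3% true disruption efficiency),
and the fitted dissolution time constant (30.1 s) recovers the generating
τ = 30 s to 0.4%.  `demo_run/` holds the masks (TIFF), the per-frame
partition table, the disruption and fit tables (CSV), a data+fit overlay
plot, and a JSON manifest with the config hash for reproducibility.

The same stages are available from the shell:

```sh
punctakit simulate dissolution --out scene --seed 7
punctakit segment --in scene/movie.tif --out masks --condensate-method otsu
punctakit run --config run.yaml --seed 7
punctakit frap --in trace.csv --bleach-frame 10 --out frap_out
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's headline computations from
scratch at a given seed — a sigmoid-dissolution pipeline run (τ and
efficiency recovery), an exponential-dissolution run, and a FRAP
mobile-fraction recovery — printing recovered values next to the generating
ones, and writes its results JSON to `--out`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
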