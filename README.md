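# regenquant

Quantification toolkit for adult CNS axon-regeneration assays:

- **`simgen`** — synthetic microscopy generators with exact ground truth:
  cleared-nerve projections with labelled fibers whose survival past a crush
  site decays exponentially, explant images with radiating neurites, and
  time-lapse movies of punctate organelles moving under a two-state
  (moving/paused) Markov chain. Named presets capture the intact/post-lesion
  lysosome and mitochondria transport regimes.
- **`nerve_regen`** — regeneration index along a cleared optic nerve:
  maximum z-projection, manual injury line, orthogonal intensity profiles at
  fixed distances, width-normalized integrated intensity, max-normalization
  and background subtraction. An advisory injury-site detector is included
  but never substitutes for the manual annotation.
- **`explant_sholl`** — Sholl-style neurite intersection counting measured
  from the explant **border** (distance transform, 50 μm steps), the
  no-growth exclusion rule (0 or 1 axon), condition summary tables with
  half-up percentage rounding, and growth-cone collapse scoring
  (collapsed ⇔ fewer than 2 filopodia and no lamellipodia).
- **`kymo_transport`** — kymograph construction along an axon path,
  automatic punctum tracking (peak detection + gap-tolerant nearest-neighbour
  linking), per-interval motion classification with an inclusive minimum-speed
  threshold (0.02 μm/s), and transport kinetics: directional velocities
  Vma/Vmr, organelle direction counts, pausing fraction averaged per axon,
  and linear flow rate Q = Vma·n_antero + Vmr·n_retro.
- **`framework`** — TIFF/CSV/JSON/YAML I/O, the normality-gated statistical
  dispatch rule (Shapiro–Wilk at α = 0.01; t-test/ANOVA vs
  Mann-Whitney/Kruskal-Wallis), and the CLI.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance checks (exact
table arithmetic, Sholl oracle equivalence, regeneration-curve properties,
kinetics formula checks, stochastic parameter recovery on the transport
presets, and dispatch reliability).

## CLI

```bash
# synthetic data (also available as the standalone `simgen` entry point)
regenquant simgen nerve   --seed 1 --out runs/nerve
regenquant simgen explant --seed 1 --out runs/explant
regenquant simgen movie   --preset intact_lysosome --seed 1 --out runs/movie

# analyses
regenquant nerve    --image nerve.tif --annotations annotations.json --out runs/regen
regenquant explant  --image explant.tif --pixel-size 2.0 --out runs/sholl
regenquant collapse --annotations cones.csv --out runs/collapse
regenquant kymo     --movie movie.tif --path path.json --pixel-size 0.2 --out runs/kymo
regenquant stats    --data grouped.csv --out runs/stats
```

The nerve annotation JSON looks like:

```json
{
  "injury_line": [[80.0, 0.0], [80.0, 119.0]],
  "axial_direction_sign": 1,
  "background_distance_um": 2000.0,
  "distances_um": [200, 500, 750, 1000, 1500],
  "pixel_size_um": 5.0
}
```

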