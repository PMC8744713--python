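# espsim

Ecological security patterns and ESP-constrained urban-growth simulation.

`espsim` is a Python toolkit for a question city planners keep running
into: **how much urban expansion does a protected ecological network
actually prevent?** It re-implements, as a reusable and fully testable
pipeline, the workflow used to answer that question for a rapidly
urbanizing metropolitan area:

1. **Ecological security pattern (ESP) construction** from a 6-class
   land-use raster (arable, woodland, grassland, water, construction,
   unused; 30 m cells):
   - *morphological spatial pattern analysis (MSPA)* splits the ecological
     foreground (woodland + grassland) into core, islet, perforation,
     edge, bridge, loop and branch with 8-connectivity;
   - large cores are ranked by the *probability of connectivity*,
     PC = Σᵢⱼ p*ᵢⱼ aᵢaⱼ / AL², with p*ᵢⱼ the best-path product of
     negative-exponential dispersal probabilities (p(1500 m) = 0.5); cores
     whose removal loses more than 1 % of PC (dPC > 1), plus large
     non-river water bodies, become **ecological sources**;
   - **corridors** are least-cost paths over a resistance surface
     (land-use score × 0.7 + topographic-relief score × 0.3), ranked by a
     gravity model G = [ln Sᵢ/Pᵢ][ln Sⱼ/Pⱼ](L_max/Lᵢⱼ)², buffered 100 m,
     with long/wide rivers added; smaller "stepping-stone" cores become
     **nodes**. Sources ∪ corridors ∪ nodes is the ESP.
2. **Future land-use simulation** (CA-Markov + FLUS-style allocation):
   per-class demand comes from a Markov transition matrix estimated
   between two observed epochs; a single-hidden-layer neural network maps
   nine driving factors (elevation, slope, relief, distances to
   river/road/railway/residential, night light, population density) to
   per-class occurrence probabilities; roulette-wheel competition with
   neighborhood effects, adaptive inertia, 0/1 transfer constraints and a
   restricted-area mask allocates the demand spatially. The *natural*
   scenario runs unconstrained; the *ecological-security* scenario
   forbids conversions out of woodland/grassland and freezes every cell
   inside the ESP.
3. **Expansion metrics**: construction-land proportion, the annual
   increase index AI = (A_end − A_start)/d (km²/yr) and the average annual
   growth rate AGR = 100·((A_end/A_start)^(1/d) − 1) (%/yr), tabulated by
   quadrant and by 5-km rings around the construction-land center of
   gravity, plus kappa/confusion-matrix validation of hindcasts.

Because the original CNLUCC/DEM inputs are not publicly deposited, the
package ships a seeded synthetic-landscape generator (`espsim.synthetic`)
that reproduces the statistical structure the method assumes — spatially
autocorrelated class mosaics, epochs evolving under a known transition
matrix, and driving factors that genuinely correlate with class occurrence
— so every stage runs and is verified without any download.

## Worked example

```python
from espsim import pipeline, metrics

# published construction-land areas of the study area, km²
print(round(metrics.compute_ai(411.52, 660.08, 10), 2))   # 24.86 km²/yr
print(round(metrics.compute_agr(411.52, 660.08, 10), 2))  # 4.84 %/yr

manifest = pipeline.run_all(pipeline.PipelineConfig(seed=1))
print(manifest["esp"])
print(manifest["validation"])
print(manifest["scenarios"])
```

which prints (exactly, for seed 1):

```
24.86
4.84
{'n_core_patches': 2, 'n_sources': 3, 'source_area_km2': 5.2866,
 'n_corridors': 3, 'n_nodes': 3, 'restricted_area_km2': 6.5565}
{'kappa': 0.8900..., 'overall_accuracy': 0.91375}
{'natural':    {'construction_km2': 8.4879, 'converged': True,  ...},
 'ecological': {'construction_km2': 8.2692, 'converged': False, ...}}
```

Reading: on a 200×200 synthetic study area (36 km²), three ecological
sources totalling 5.29 km² are linked by three gravity-ranked corridors;
the hindcast (fit on epochs t0→t1, simulate t2, score against the true
t2) reaches kappa 0.89; and one decade ahead the ESP-constrained scenario
builds 0.22 km² less construction land than the unconstrained one, with
zero converted cells inside the ESP — the restriction effect the method
is designed to measure. `converged: False` on the ecological run is
informative, not an error: the Markov demand extrapolated from an
unconstrained past is not fully attainable once woodland conversion is
banned, and the allocator reports the shortfall instead of violating a
constraint.

A command-line interface mirrors the library:

```bash
espsim synth --seed 1 --outdir out/          # epochs + factor rasters
espsim esp --seed 1 --outdir out/            # ESP summary json
espsim simulate --scenario ecological --seed 1 --outdir out/
espsim metrics --start 411.52 --end 660.08 --years 10
espsim all --seed 1 --outdir out/            # everything + manifest
```

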