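# provdiv

Marine diversity gradients filtered through biogeographic provinces: an
end-to-end, tested pipeline from point occurrence records to the question
*"does richness track the environment directly, or is it mediated by
biogeographic province structure?"*

## The scientific problem

Latitudinal diversity gradients are classically explained by the
species–energy hypothesis: warmer places hold more species because
temperature (or energy availability) directly controls richness.  An
alternative reading is that the proximate control is *biogeography*: the
coastline is partitioned into faunal provinces with distinct species pools,
richness is a property of the province, and the apparent temperature effect
is inherited from the correlation between provinces and climate.

Distinguishing these requires a chain of machinery, and this package
implements each link as a separately tested module:

1. **`ingest`** — parse Darwin-Core-like occurrence records (keeping the
   *textual* coordinates so decimal precision can be policed), reject
   records without a binomial species name, out-of-range or low-precision
   coordinates, grid the survivors into 0.5° cells, and drop cells with
   fewer than 10 species or 150 records.
2. **`diversity`** — per-cell sampling-standardized diversity: Fisher's
   log-series α, unbiased Simpson's D, Chao1, first-order and corrected
   jackknife extrapolators, and analytic coverage-based rarefaction
   (SQS/CBR) with a Monte-Carlo cross-check.
3. **`bioregion`** — Q-mode varimax factor analysis of the binarized
   cell-by-cell correlation matrix, giving each cell a continuous *loading*
   on each province; factor count chosen by parallel analysis; PAM
   (k-medoids) clustering and correspondence analysis as discrete/ordination
   companions.
4. **`models`** — a varimax factor analysis of the 8-variable environmental
   table (3 abiotic factors), then general linear models with a spatial
   autoregressive (SAR) error companion for each diversity metric: an
   abiotic-only layout and a combined provinces + abiotic layout.  A
   path-regression suite relates key environmental variables, province
   loadings and diversity as a signed directed graph.
5. **`nullmodel`** — a temperature-range null: rebuild presence–absence
   worlds where each species is confined to cells within its observed
   thermal range and each cell keeps its observed richness, then re-run the
   bioregionalization and regressions to see what "provinces" look like
   when only the thermal niche is real.
6. **`synth`** — a synthetic-world generator with *planted* provinces,
   transition zones, environmental fields, richness gradients, log-uniform
   sampling effort and record-level noise, so every stage above is testable
   as a parameter-recovery problem.  Within-cell abundances follow an exact
   log-series (Hoppe-urn sampling), so Fisher's α is the planted diversity.
7. **`pipeline` / `cli`** — one-command orchestration with a manifest of
   SHA-256 hashes for every output.

## Worked example

Everything below is reproducible; the numbers are from the default
synthetic world with seed 1 (5 provinces planted on a 120-cell coastline).

```python
import numpy as np
from provdiv import (SynthConfig, generate_world, filter_records,
                     grid_records, filter_cells, build_matrix,
                     diversity_table, parallel_analysis, cell_correlation,
                     varimax_fa)

world = generate_world(SynthConfig(seed=1))
len(world.records)                  # 167530 records (6701 of them noise)

kept = filter_records(world.records)
retained, excluded = filter_cells(grid_records(kept))
matrix, env = build_matrix(retained, world.env)
matrix.shape                        # (120, 422): 120 cells x 422 species

div = diversity_table(matrix)       # n, raw_S, fisher_alpha, simpson_D,
                                    # chao1, cJ1, sqs per cell
round(div["fisher_alpha"].mean(), 1)   # 14.5

sol = varimax_fa(cell_correlation(matrix), 5)
labels = world.truth.labels.loc[matrix.index]
core = labels != "transition"
dom = sol.loadings.abs().idxmax(axis=1)
# dominant factor reproduces every core province exactly (ARI = 1.0);
# transition cells have depressed maximum loadings:
round(sol.loadings.abs().max(axis=1)[core].mean(), 2)    # 0.89
round(sol.loadings.abs().max(axis=1)[~core].mean(), 2)   # 0.68
```

The mediation question, in miniature — on a world where richness is a pure
step function of province identity, adding province loadings to the
abiotic-factor model raises adjusted R² by ≈ 0.60 with no abiotic term
significant, while on a world where richness is a smooth function of
temperature the temperature-dominated abiotic factor is significant at
p < 10⁻⁴⁰.

### Command line

```bash
provdiv synth --scenario province_mediated --seed 1 --out world/
provdiv run --config run.yaml      # full pipeline + manifest.json
```

A minimal `run.yaml`:

```yaml
outdir: run_output
seed: 3
null_reps: 100
```

## Reproduction

```bash
pytest                                   # unit + integration suite
pytest tests/test_acceptance.py          # the 8 acceptance properties
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes the headline quantities from scratch
(cells retained, factors retained, core-recovery ARI, loading contrasts,
mediation ΔR², null-model significant fractions, estimator cross-checks)
and writes them as JSON.

Two acceptance clauses fail honestly on the current generator: parallel
analysis retains 6–8 factors rather than exactly 5 (log-uniform sampling
effort creates genuine within-province sampling-depth structure), and
transition-zone mean loadings sit near 0.67 rather than below 0.6 (the
outer cells of a 4-cell linear transition are 80% one province).  See
`docs/methods.md` for the analysis.
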