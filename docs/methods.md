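# Methods

## Graph model

Molecules are hydrogen-suppressed simple graphs: vertices are heavy atoms,
edges are bonds, and every bond — single, double or aromatic — contributes
exactly one edge.  This is the only convention under which the embedded
per-molecule edge partitions are reproduced (glycine's printed partition
{(1,2):1, (1,3):2, (2,3):1} is exactly its 5-heavy-atom backbone), so it is
fixed package-wide.  Graphs must be connected and free of self-loops and
duplicate edges; validation is explicit and failable, and a disconnected
input reports its components.  Degrees above 4 are legal but trigger a
warning, since degree ≤ 4 covers organic skeletons and all embedded data.

All ten indices are edge-additive in the endpoint degrees, so the
edge-degree partition (counts of unordered degree pairs) is a sufficient
statistic and may be ingested directly without a realising graph.  No
graph-realisation algorithm is provided or needed.

## Index conventions

- M1 and F are computed from partitions via their edge forms Σ(d_u+d_v) and
  Σ(d_u²+d_v²), which equal the vertex sums Σd² and Σd³; the vertex forms
  are exposed separately and the equality is property-tested on random
  graphs.
- SS has two variants. `definition10` is Σ 1/(d_u+d_v)²; `table_consistent`
  is Σ √(d_u d_v/(d_u+d_v)), the unique edge-additive form that reproduces
  the embedded reference SS column (solved by least squares over per-pair
  contributions; the solver is public API and reports per-pair
  identifiability — the pairs (1,4), (2,4), (3,4) occur only jointly in one
  molecule and are therefore only constrained in combination).  The
  table-consistent variant is the default everywhere because it is the only
  one consistent with the embedded reference results; the conflict is
  recorded in every pipeline discrepancy log.
- Table reproduction rounds half away from zero (4 decimals for index
  tables, 3 for R² grids); all internal arithmetic is double precision.
- Unknown index ids raise immediately rather than returning a placeholder.

## Regression

The three forms are OLS with intercept on designs {1, T}, {1, T, T²} and
{1, ln T} (natural log).  Estimation is delegated to statsmodels; reported
statistics are R² , the overall F with its exact F-distribution p-value, and
the residual standard error √(SSE/(n−k−1)).  R is signed by the slope for
the single-slope forms and is the positive root of R² for the quadratic
(multiple-R convention).  A perfect fit (SSE relatively below 1e-12) reports
R² = 1, F = +inf and p = 0; standardized residuals (residual / residual SE)
return zeros with a perfect-fit flag.  A constant predictor raises a rank
error; a non-positive predictor under the log form raises a domain error.
Nine observations against one or two slopes is very small-sample territory;
no multiple-testing correction is applied, matching the workflow this
package reproduces.

Predictors default to indices recomputed from the partitions; a
`printed` source uses the embedded 4-decimal reference values instead to
isolate rounding effects (the two agree to 4 decimals).

Best predictors are the argmax of R² at 3-decimal resolution; ties return
every tied index, and tied forms are reported as ties, never broken
silently.  The embedded reference grids leave some property rows unreported
(their inclusion criterion is unstated), so the pipeline always computes the
full 8×10 grid per form and reproduction checks run only on reported cells.
One reported cell (logarithmic MW~M1, printed "0.8647" vs computed 0.847)
disagrees beyond one unit in the last printed digit and is excluded as a
flagged cell; three further internal inconsistencies of the source tables
(a BP~HZ R² printed as both 0.768 and 0.760, a BP~H quadratic intercept
printed as both −23.762 and −231.762, and an "S" column described as
standardized residuals but printing one number per fit, interpreted here as
the residual standard error, which matches the recomputed values) are
logged with both values on every embedded-fixture run.

## Synthetic data

The generator emulates the embedded study's design: small connected graphs
with degree cap 4, built as random trees (uniform attachment among vertices
with spare capacity) plus 0–2 ring-closing chords — every study molecule is
a tree or unicyclic, so this construction covers the class — with 5–20
heavy atoms per molecule, bracketing the study's range.  The response is
α + β·g(T) (+ γ·T²) + ε with ε ~ N(0, σ²); the default coefficients
(α = −9.1, β = 32.2, γ = −0.45, σ = 13) mirror the magnitudes of the
study's strongest relation, the molar-volume~Randić quadratic fit, so that
default synthetic studies look statistically like the real one.  Everything
is driven by one integer seed through a numpy Generator; identical specs
give bitwise-identical studies.

What the generator does not emulate: element-specific valence rules,
aromaticity, the empirical joint distribution of real physicochemical
properties, or correlated measurement error.  Passing synthetic tests
therefore demonstrates correctness of the pipeline mechanics (partition
tallies, estimator consistency, nested-model behaviour), not chemical
validity of predictions on new compounds.

Recovery checks use n = 200 observations and 100 replicates: at σ = 0
coefficients must return to within 1e-6; at σ > 0 replicate-mean estimates
must sit within 3 Monte-Carlo standard errors of the generating values.
These sizes keep the full suite under a few seconds while leaving the
Monte-Carlo standard errors small.

## Pipeline and CLI

`run_pipeline` accepts exactly one input source — the embedded fixtures,
edge-list files plus a property CSV, or a synthetic spec — and writes the
index table, three R² grids, three best-predictor fit tables, the model
comparison and `discrepancies.json` to an output directory in CSV (and
optionally JSON/markdown).  Column orders and float formats are fixed, so
identical configurations produce byte-identical files.  The `topoqspr` CLI
(`indices`, `fit`, `grid`, `compare`, `reproduce`, `simulate`) is a thin
wrapper over these library calls.

## Known limitations

- Only degree-based, edge-additive indices; no distance, eccentricity,
  neighbourhood-degree-sum or spectral descriptors.
- One predictor per model; no multivariate regression, regularisation or
  cross-validation.
- Property values of the embedded study are opaque response data and are
  never recomputed from chemistry (its printed heavy-atom count for
  methionine, 14, does not match methionine's 9 heavy atoms and is kept as
  printed).
- The SMILES adapter requires rdkit and ignores stereochemistry, charges
  and isotopes by construction of the graph model.
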