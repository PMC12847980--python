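# topoqspr

Degree-based topological indices and QSPR regression modelling for small
molecules.

Quantitative structure–property relationship (QSPR) studies connect a
molecule's graph structure to its measured physicochemical behaviour.  This
package implements one complete, reproducible QSPR workflow for an embedded
nine-compound study (linolenic acid, serine, methionine, tyrosine, cystine,
succinic acid, N-acetylglucosamine, glutamic acid, glycine): it computes ten
classical degree-based topological indices from hydrogen-suppressed
molecular graphs, regresses eight physicochemical properties (boiling point,
molar volume, molar refraction, molecular weight, heavy-atom count,
complexity, enthalpy of vaporization, melting point) on each index under
three one-predictor model forms, and compares the forms by coefficient of
determination.  It is aimed at cheminformatics practitioners and students
who want these descriptors and this model-comparison workflow as a tested
library rather than a spreadsheet.

## The descriptors and the models

A molecule is a simple connected graph G whose vertices are heavy atoms and
whose edges are bonds (bond order ignored).  With d_u the degree of vertex
u, the ten indices are edge-additive sums over bonds uv — Randić
RI = Σ 1/√(d_u d_v), harmonic H = Σ 2/(d_u+d_v), second Zagreb
M2 = Σ d_u d_v, atom-bond connectivity ABC = Σ √((d_u+d_v−2)/(d_u d_v)),
geometric-arithmetic GA = Σ 2√(d_u d_v)/(d_u+d_v), sum-connectivity
SC = Σ 1/√(d_u+d_v), hyper-Zagreb HZ = Σ (d_u+d_v)² — plus the vertex sums
M1 = Σ d_v² and F = Σ d_v³ (equal to the edge sums Σ (d_u+d_v) and
Σ (d_u²+d_v²)), and the "Schultz second" index SS, which ships in two
variants (see below).  All of them depend on the graph only through its
*edge-degree partition* — the count of edges per unordered degree pair
(a, b) — which the package therefore treats as a first-class input.

Each property P is fitted against each index T by ordinary least squares
under three forms:

    linear        P = α + β·T
    quadratic     P = α + β·T + γ·T²
    logarithmic   P = α + β·ln T

and per property the best predictor is the index with the highest R²; the
best form is the one whose best predictor attains the highest R².  On the
embedded study data the quadratic form wins for all eight properties.

### The SS index: two variants

The textbook-style definition SS = Σ 1/(d_u+d_v)² is inconsistent with the
published per-molecule SS results this package embeds (glycine: 0.2761 vs
the printed 3.6440).  Solving the linear system over unknown per-pair
contributions defined by the nine printed SS values and the nine edge
partitions yields f(a,b) = √(ab/(a+b)) — e.g. f(2,2) = 1 exactly — which
reproduces every printed SS value to four decimals.  Both variants are
implemented (`definition10` and `table_consistent`); the table-consistent
one is the pipeline default, and the solver
(`topoqspr.infer_edge_contributions`) is part of the public API.

## Worked example

```python
>>> from topoqspr import DescriptorRegression, compute_all, data
>>> compute_all(data.drug_partition("glycine")).rounded()
{'M1': 16.0, 'M2': 14.0, 'H': 2.0667, 'F': 38.0, 'SS': 3.644, 'ABC': 3.0472,
 'RI': 2.2701, 'SC': 2.0246, 'GA': 3.6547, 'HZ': 66.0}
>>> print(DescriptorRegression.from_study("MV", "RI", "linear").fit().summary())
Regression equation  MV = 26.866(RI) + 4.223
Form                 linear
N                    9
alpha                4.223
beta                 26.866
F                    202.946
p                    2e-06
R                    0.983
R^2                  0.967
Resid. SE            12.634
```

The first call computes glycine's ten indices from its 5-heavy-atom edge
partition.  The second fits molar volume against the Randić index: the slope
26.866 cm³/mol per Randić unit explains 96.7 % of the molar-volume variance
across the nine compounds (F = 202.9, p ≈ 2·10⁻⁶).

The same pipeline runs from the shell:

```
$ topoqspr reproduce -o report/
wrote report tables to report (4 logged source-table discrepancies)
BP: best model quadratic (H, R^2=0.849)
MV: best model quadratic (RI, R^2=0.968)
...
MP: best model quadratic (H, R^2=0.760)
```

writing the index table, the three R² grids, the best-predictor fit tables,
the model comparison and a discrepancy log as CSV.

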