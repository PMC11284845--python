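# confsel

Untangle transition-state conformer ensembles and compute reaction
selectivity under Curtin-Hammett conditions.

Conformer-generation workflows hand you big TS ensembles that conceal two
error sources: **repeated conformers** (the same TS counted twice, often
with permuted indices of symmetry-equivalent atoms) and **interconversion
errors** (treating non-interconvertible conformers as one Boltzmann pool,
or vice versa). `confsel` addresses both:

* **Clustering** — pairwise dissimilarities from symmetry-corrected
  heavy-atom RMSD (minimized over all bond-graph isomorphisms), torsion
  angle circular distances, and energy differences are min-max normalized
  and averaged into a compound matrix; multidimensional scaling embeds it,
  the silhouette score picks the number of k-means clusters, and each
  cluster's lowest-energy member becomes its representative.
* **Selectivity** — three treatments of two competing pathways: Boltzmann
  weighting of each pathway as one interconvertible pool, summation of
  Eyring rate constants over fully parallel conformers, and the hybrid
  *cluster-resolved* scheme (Boltzmann ensemble energy per cluster, rate
  constants summed across clusters, product ratio from the total rates).
* **Synthetic ensembles** — a planted-family generator (torsional families
  with energy offsets, coordinate jitter, and automorphism-permuted atom
  indices) so the whole pipeline is testable without external data.

## CLI

```bash
# generate a two-family synthetic ensemble
confsel simulate --family 0:0:10 --family 180:3.2:10 --seed 1 --out sim/

# cluster a multi-frame XYZ ensemble (energies read from comment lines)
confsel cluster sim/ensemble.xyz --out run/
# -> run/labels.csv, run/representatives.xyz, run/compound_matrix.csv, run/run_log.json

# selectivity from a per-conformer energy table
confsel selectivity energies.csv --method all --json report.json
```

The energy table is a CSV with columns `label, product, cluster,
energy_kcal_mol` (the `cluster` column may instead be joined from a
`labels.csv` produced by `confsel cluster` via `--labels`). Exactly two
product labels are required. All energies are free energies in kcal/mol
relative to one shared reference intermediate.

XYZ comment lines may carry energies as a bare float, `Energy= X`, or
`E = X`; magnitudes above 100 are auto-detected as Hartree and converted
(override with `--energy-unit`).

Every run writes `run_log.json` (config, seed, library versions,
silhouette trace, warnings) so outputs are exactly reproducible.

## Python API

```python
from confsel import (PlantedSpec, generate, cluster, ClusterConfig,
                     PathwayEnergies, selectivity)

ensemble, truth = generate(PlantedSpec([(0.0, 13.4, 10), (180.0, 17.5, 10)], seed=1))
result = cluster(ensemble, ClusterConfig(seed=1))

report = selectivity(
    PathwayEnergies("2a", [[15.3]]),
    PathwayEnergies("2b", [[13.4], [17.5]]),
    method="cluster_resolved",
)
print(report.percent_a, report.percent_b)   # 4 96
```

## Notes

* RMSD uses heavy atoms only and proper rotations only (mirror-image TSs
  are distinct pathways and are never superimposed).
* Symmetry handling enumerates bond-graph isomorphisms up to a cap
  (default 10,000); on truncation a warning is emitted and the identity
  map is always included.
* Degeneracy numbers are not applied automatically: listing a conformer
  twice *is* the repeated-conformer pitfall, so deliberate degeneracy must
  be expressed explicitly by the user.
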