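# qsarpipe

A tested, reusable pipeline for small-molecule cytotoxicity QSAR: compute the
seven molecular descriptors used by the published per-cell-line models
(GETAWAY R-indices, Moran 2D autocorrelations, a radial distribution
function value, the lopping centric index, and an aromatic-ester count),
prepare activity datasets (IC50 → pIC50, activity classes, inactive-record
exclusion), select features and fit multiple-linear-regression models with
leave-one-out cross-validation, and apply the four published equations to
score and rank candidate compounds against the HuCCA-1, HepG2, A549 and
MOLT-3 cell lines.

## Layout

| module | contents |
| --- | --- |
| `qsarpipe.chem` | molecule model, SDF/SMILES/XYZ readers, SDF writer, seeded 3D embedding, topological distances, carbon-scaled atomic property weights |
| `qsarpipe.descriptors` | the seven model descriptors (`R5e+`, `nArCOOR`, `RDF105m`, `MATS7m`, `MATS8v`, `Lop`, `R7m`) and their composition into a named vector |
| `qsarpipe.activity` | pIC50 conversion, experimental/predicted activity classes, modeling-table assembly |
| `qsarpipe.modeling` | correlation filter, stepwise MLR selection, OLS fitting, LOO-CV, R/RMSE metrics, the four published equations, candidate ranking |
| `qsarpipe.synthetic` | seeded linear descriptor/activity tables with known ground truth; random valence-respecting toy molecules |
| `qsarpipe.fixtures` | machine-readable transcription of the published activity/model tables (every value carries a citation string) |
| `qsarpipe.cli` | `qsarpipe` command-line interface |

## CLI

```bash
# descriptor table from structures (SDF with 3D coordinates; SMILES get a
# deterministic seeded embedding)
qsarpipe descriptors --structures mols.sdf --format sdf --out descriptors.csv

# per-cell-line feature selection + MLR + LOO-CV
qsarpipe train --activities activities.csv --descriptors descriptors.csv \
    --cell-line HepG2 --out-dir run/

# score a descriptor table with a published or fitted model
qsarpipe predict --model published:HuCCA-1 --descriptors descriptors.csv \
    --out predictions.csv

# recompute the published headline numbers from the bundled fixtures
qsarpipe reproduce --target all --out verdicts.json
```

The activity table is delimited text with columns
`compound_id, cell_line, ic50_uM, inactive`; descriptor tables use the
header `compound_id, R5e+, nArCOOR, RDF105m, MATS7m, MATS8v, Lop, R7m`.
Optional YAML config (`--config`) exposes `rdf_beta`,
`include_hydrogens_3d`, `property_table_path`, `corr_threshold`,
`p_enter` and `p_remove`.

## Notes

- Quantum-chemical geometry optimisation is out of scope: descriptors are
  computed from user-supplied 3D coordinates (SDF/XYZ) or from a
  deterministic distance-geometry embedding, so exact reproduction of the
  original software's compound-level descriptor values is not claimed.
- The per-element constants behind the `m`/`e`/`v` weighting schemes ship
  as a delimited text file (`qsarpipe/data/atomic_properties.csv`, sources
  cited inline) and can be overridden by the user.
- The HepG2 equation intercept is stored as −1.7524; the source prints
  both signs in different places and only the negative one is consistent
  with the published predicted-activity range (documented in the model's
  `notes` field).
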