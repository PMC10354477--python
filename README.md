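# kincomp

Kinship composition of same-sex social units from pedigree data, plus the
comparative phylogenetic machinery to analyse it across species.

Mean relatedness summarizes a group with one number; kinship composition asks
the complementary dyadic question — do adult same-sex group members comprise
only kin dyads (*related*), only non-kin dyads (*unrelated*) or both
(*mix-related*)?  `kincomp` implements that pipeline end to end:

* **`kincomp.pedigree`** — validated pedigree model (TSV I/O, cycle
  detection, auto-created founders), depth-2 ancestry queries, and exact
  pedigree relatedness via the tabular kinship recursion.
* **`kincomp.kin`** — the two-generation categorical criterion: a dyad is
  kin if parent–offspring, grandparent–grandoffspring, or sharing a known
  parent or grandparent; `strict` vs `permissive` policies govern when
  missing ancestry blocks a non-kin verdict.
* **`kincomp.composition`** — social-unit filtering (≥2 adults of one sex),
  categorical + continuous composition, mean relatedness, and the weaker
  genetic-cluster route that can certify mix-relatedness from noisy dyadic
  estimates plus matriline labels.
* **`kincomp.dataset`** — a packaged transcription of the published
  species-level table (22 sex/species rows, 18 species) with recomputed
  summaries and a crosscheck that surfaces the published totals'
  discrepancies instead of hiding them.
* **`kincomp.simulate`** — forward-time social-unit pedigree simulator with
  known ground-truth composition, marker-style noisy relatedness estimates,
  and binary-trait simulation on trees.
* **`kincomp.phylo`** — from-scratch symmetric 2-state Mk likelihood
  (Felsenstein pruning), ML rate estimation, stochastic character mapping
  (conditional node sampling + uniformization branch paths), and Bayesian
  Bernoulli regression with a phylogenetic random effect
  (Metropolis-within-Gibbs).

## Command line

```sh
kincomp classify-dyads pedigree.tsv --ids A,H,C --policy permissive
kincomp compose pedigree.tsv units.csv --out composition.csv
kincomp relatedness-matrix pedigree.tsv --out r.csv
kincomp simulate --females 2 --generations 2 --seed 1 --out simdir/
kincomp dataset-summary
kincomp mkfit tree.nwk states.csv
kincomp simmap tree.nwk states.csv --seed 1 --nsim 10000 --out-prefix map
kincomp phyloglm tree.nwk data.csv --seed 1 --config cfg.txt --out draws.csv
```

Pedigree TSV: columns `id`, `dam`, `sire`, `sex`, `birth_unit`; `.` or empty
means unknown.  Unit membership CSV: `unit_id, period, individual_id, sex,
age_class`.  `--config` files are `key=value` lines (e.g. `chains=2`,
`draws=2000`).

## Library example

```python
from kincomp import (Pedigree, PedigreeRecord, SocialUnit,
                     classify_composition, mean_relatedness)

ped = Pedigree([
    PedigreeRecord("GM"), PedigreeRecord("GF"),
    PedigreeRecord("D1", "GM", "GF"), PedigreeRecord("D3", "GM", "GF"),
    PedigreeRecord("D2"), PedigreeRecord("S"), PedigreeRecord("SC"),
    PedigreeRecord("A", "D1", "S"),   # focal
    PedigreeRecord("H", "D2", "S"),   # paternal half-sibling
    PedigreeRecord("C", "D3", "SC"),  # maternal first cousin
])
unit = SocialUnit("u1", "2020", "F", ("A", "H", "C"))
mean_relatedness(ped, unit)                     # 0.125
classify_composition(ped, unit, "permissive")   # MIX_RELATED, 2/3 kin dyads
```

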