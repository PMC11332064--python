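# endemap

Gridded phylogenetic endemism, CANAPE classification of centers of
endemism, and greedy spatial conservation prioritization — a tested,
reusable Python implementation of the full analysis chain, with a
synthetic-landscape generator so every stage runs without restricted
field data.

The package is written for spatial phylogeneticists and conservation
planners who have (i) a rooted phylogeny with branch lengths and (ii)
species occurrence records or a presence/absence matrix on a regular
grid, and who want to find where recently diversified, range-restricted
lineages (neo-endemism) and ancient, range-contracted lineages
(paleo-endemism) concentrate — and how to rank the landscape so that both
are protected.

## The metrics and the method

For a grid with cells *i* and a rooted tree with branches *b* of length
*L<sub>b</sub>*, with *R<sub>b</sub>* the set of cells occupied by any
descendant tip of *b*:

- **SR(i)** — species richness, the number of species present in cell *i*.
- **PD(i)** = Σ<sub>b ∋ i</sub> *L<sub>b</sub>* — Faith's phylogenetic
  diversity, summed over the branches on root-to-tip paths of the species
  in *i*.
- **PE(i)** = Σ<sub>b ∋ i</sub> *L<sub>b</sub>* / |*R<sub>b</sub>*| —
  phylogenetic endemism; each branch's length is divided by its range
  size, so branches confined to few cells contribute most. Summed over
  all cells, PE equals the total tree length (a conservation law the test
  suite asserts to 1e−9).
- **RPE(i)** = PE(i) / PE<sub>alt</sub>(i), where PE<sub>alt</sub> is PE
  on a topology-identical *alternate tree* whose branch lengths are all
  set to the mean. RPE < 1 means the endemism in *i* is carried by
  shorter-than-average (young) branches, RPE > 1 by longer-than-average
  (old) ones.

**CANAPE** classifies cells by randomizing the presence matrix under a
fixed-fixed null (cell richness and species occupancies both held exactly,
sampled with a curveball Markov chain), ranking observed PE, PE_alt and
RPE among 999 null replicates with two-tailed tests (α = 0.05): cells with
significant PE are centers of **paleo**-endemism if RPE is significantly
high, **neo**-endemism if significantly low, **mixed** if PE and PE_alt
are both significant but the ratio is not, and **super** if both are
significant at α = 0.01. Empty cells and cells holding only a designated
widespread species are relabeled non-significant (masked).

**Prioritization** ranks cells by iteratively removing the cell with the
lowest marginal loss δ<sub>i</sub> = max<sub>j</sub>(w<sub>j</sub>
q<sub>ij</sub>)/c<sub>i</sub>, where q<sub>ij</sub> is the fraction of
feature *j*'s remaining distribution in cell *i* (the core-area removal
rule). Three feature sets are built in: **Tx** (one unit-weight feature
per taxon), **Br** (one feature per branch, weight *L<sub>b</sub>*/ΣL,
distribution = union of descendant ranges) and **BrCE** (Br plus one
unit-weight feature per center class among neo/mixed/super — paleo
centers are left to the long branches that already represent them).
Solutions are evaluated at the 17% and 30% landscape fractions against
centers of endemism and a protected-area mask (a cell counts as protected
at ≥ 25% coverage).

## Worked example

```python
from endemap import PresenceMatrix, Grid, compute_cell_metrics
from endemap.gridio import read_newick

tree = read_newick("((A:1,B:1):1,C:2);", from_path=False)
presence = PresenceMatrix.from_cell_sets(
    Grid(0, 0, 1.0, 2, 2), {"A": [0], "B": [0, 1], "C": [0, 1, 2, 3]})
print(compute_cell_metrics(presence, tree).round(4).to_string(index=False))
```

```
 cell_id  SR  PD  PE  PE_alt    RPE
       0   3 5.0 2.5  2.8125 0.8889
       1   2 4.0 1.5  1.5625 0.9600
       2   1 2.0 0.5  0.3125 1.6000
       3   1 2.0 0.5  0.3125 1.6000
```

Cell 0 holds all three species, so PD = 5 is the whole tree and
PE(0) = 1/1 + 1/2 + 1/2 + 2/4 = 2.5. RPE < 1 in cell 0 — its endemism
comes from the short sister branches A and B — while cells 2–3 hold only
the long branch of C, pushing RPE to 1.6: old, range-restricted lineage.

The `examples/` directory has one short script per capability
(simulation, metrics, CANAPE, prioritization, gap analysis, the full
pipeline, and range estimation from occurrence records); each prints what
it computes and what the numbers mean. On a default synthetic landscape
(`examples/03_canape_classification.py`) the planted neo blocks and
paleo relicts are recovered at 100%:

```
class counts:
non_significant    388
neo                  8
paleo                4
planted neo cells recovered as neo: 100% (8 cells)
planted paleo cells recovered as paleo: 100% (4 cells)
```

## Command line

```bash
endemap simulate --seed 1 --out demo/
endemap run --config pipeline.yml --seed 1
endemap canape --presence m.csv --tree t.nwk --rows 20 --cols 20 --out canape.csv
```

`endemap run` executes simulate/load → metrics → CANAPE → prioritize →
evaluate from one YAML config and writes a manifest with per-file
checksums; identical config + seed reproduces every output byte for byte.

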