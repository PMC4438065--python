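# anna — anatomical network analysis of skull bone-contact networks

`anna` models a skull as an undirected, unweighted network — bones are
nodes, physical contacts (sutures and synchondroses) are links — and asks
how its modular organization relates to its morphological complexity
across a phylogeny. It is aimed at comparative morphologists working with
bone-contact (adjacency) matrices coded from specimens.

The pipeline has three stages:

1. **Connectivity modules.** Pairwise bone similarity is the topological
   overlap `TO_ij = J(n_i, n_j) / min_k(i, j)` (shared neighbors over the
   lower connectivity of the pair; 1 for identical connection patterns, 0
   for disjoint ones). Bones are clustered hierarchically on `1 − TO`,
   every dendrogram cut is scored with Newman's modularity

   `Q = (1/2K) Σ_ij [A_ij − k_i k_j / 2K] δ(m_i, m_j)`,

   and the highest-Q cut defines the connectivity modules. Modularity
   strength is summarized as `M = (number of modules) × Q`. The
   two-cluster cut (the dendrogram's first split) gives the two
   *macromodules* (in skulls, facial and cranial regions); helper
   routines flag left/right *specular* module pairs and assign
   module-type labels (neurocranial, midfacial, palatal, premaxillary)
   from anchor bones.
2. **Complexity.** Five per-network parameters: bones `N`, contacts `K`,
   density `D = 2K/(N(N−1))`, mean clustering coefficient `C`, and degree
   heterogeneity `H` (variance/mean of the degree sequence by default).
3. **Comparative tests.** Phylogenetic signal of each parameter by
   Abouheif's Cmean (and Blomberg's K) with permutation p-values, and
   Pearson correlations of phylogenetic independent contrasts (through
   the origin) between `M` and each complexity parameter — a direct test
   of whether modularity and complexity co-evolve, as the
   near-decomposability hypothesis predicts.

A seeded synthetic-data module generates bilaterally symmetric skull-like
networks, pure-birth trees, and Brownian-motion traits, so the whole
pipeline is testable and calibratable without external data.

## Worked example

```python
from anna import (StudyConfig, run_study)
from anna.synthetic_data import generate_study_corpus, generate_tree

networks = generate_study_corpus(n_taxa=20, seed=1)   # 21-24 bone skulls
tree = generate_tree(20, seed=2)                      # unit-height Yule tree
report = run_study(StudyConfig(networks=networks, tree=tree,
                               n_permutations=999, seed=1))
print(report.summary.round(4))
print([(c.y, round(c.r, 3), round(c.p_value, 4)) for c in report.correlations])
```

prints

```
             M      N      K       D       C       H
min     0.0000  21.00  41.00  0.1952  0.1839  0.3722
q1      0.0856  21.00  57.25  0.2411  0.2537  0.6026
median  0.3964  22.00  61.50  0.2554  0.2969  0.8415
mean    0.3747  22.25  61.80  0.2604  0.3067  0.7716
q3      0.5907  23.00  65.75  0.2822  0.3650  0.9129
max     0.8572  24.00  89.00  0.3238  0.4603  1.2109
[('N', 0.383, 0.0956), ('K', 0.352, 0.128), ('D', 0.218, 0.3564),
 ('C', 0.681, 0.001), ('H', -0.453, 0.0451)]
```

The summary table gives the six order statistics of each network
parameter across the 20 taxa (e.g. skulls average 22.25 bones and 61.8
contacts, with about a quarter of all possible contacts realized,
`D ≈ 0.26`). Each correlation row is the through-origin Pearson `r` of
the independent contrasts of modularity strength `M` against one
complexity parameter, with its two-sided p-value on 19 contrasts — a
positive, significant `r` would support a modularity–complexity feedback
for that parameter.

The same stages are exposed on the command line:

```bash
anna simulate skull --seed 1 --out skull.csv
anna complexity skull.csv
anna modules skull.csv --linkage average --to-convention open_neighborhood
anna signal --tree tree.nwk --traits traits.tsv --method abouheif --nperm 1000 --seed 42
anna pic --tree tree.nwk --traits traits.tsv --x M --y N
```

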