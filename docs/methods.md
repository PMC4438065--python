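# Methods

## Network model

A skull is represented as a simple, undirected, unweighted graph: nodes
are bones, links are physical contacts (craniofacial sutures and
synchondroses). On disk this is a labeled binary adjacency matrix
(`A_ij = 1` iff bones i and j touch). Validation enforces symmetry, a
zero diagonal, strict 0/1 entries, unique bone labels and connectivity.
Connectivity is an error, not a warning: an articulated skull is a single
unit, and every downstream quantity (topological overlap, modularity Q)
assumes one component, so a disconnected matrix signals a coding mistake.
Paired bilateral bones carry `_l`/`_r` suffixes; unpaired midline bones a
bare base name. External deposits with other label conventions can be
renamed at read time through an explicit `label_map`.

## Module identification

Pairwise bone similarity is the topological overlap
`TO_ij = J(n_i, n_j) / min_k(i, j)` — the number of shared neighbors over
the lower connectivity of the pair. The literature leaves open whether
the pair itself counts toward the neighborhoods, so three conventions are
implemented:

- `open_neighborhood` (default): numerator and denominator both exclude
  the pair. This is the only variant under which both boundary statements
  hold simultaneously — two bones with identical connection patterns
  score exactly 1 (including mutually adjacent mirror-image bones), and
  bones with disjoint neighborhoods score 0.
- `raw_degree`: shared neighbors over `min(k_i, k_j)` with raw degrees.
- `gtom1`: the Yip–Horvath generalized TOM with one-step neighborhoods,
  `(J_ij + A_ij) / (min(k_i, k_j) + 1 − A_ij)`.

Bones are clustered on the dissimilarity `1 − TO` by agglomerative
linkage (default: average/UPGMA, the standard companion of TOM
clustering; complete and single selectable). Rather than free modularity
optimization, the partition search space is exactly the dendrogram's
cuts: the tree is cut at every cluster count 1..N (cutting by count, not
height, so degenerate dendrograms with tied merge heights still expose
every cardinality), each partition is scored with Newman's

    Q = (1/2K) Σ_ij [A_ij − k_i k_j / 2K] δ(m_i, m_j)
      = Σ_c (e_c − a_c²),

and the maximum-Q cut is returned. Ties (within 1e−12) break toward
fewer modules, i.e. the lower cut; the procedure is fully deterministic.
Stochastic community detection (Louvain, Infomap, spin-glass) is
deliberately out of scope. Modularity strength is `M = n_modules × Q`;
`M = 0` exactly when the optimal partition is the trivial single module.

The two-cluster cut of the same dendrogram — its first split — defines
the two macromodules; each connectivity module is reported as contained
in one macromodule, or flagged as straddling if the optimal partition is
not a refinement of the first split. Specular (left/right mirror) module
pairs are detected by checking whether two modules' sided bone sets map
onto each other under the `_l`↔`_r` swap; unpaired midline bones are
excluded from the matching and reported as arbitrarily assigned, since
they connect equally to both sides. Module-type labels come from anchor
bones — occipital → neurocranial, ethmoid → midfacial, both palatines →
palatal, premaxilla → premaxillary — applied in that priority order, with
conflicts logged; a one-sided module (≥ 2 sided bones, all on one side)
gets a side suffix on its label.

## Complexity metrics

Five per-network parameters: node count N, link count K, density
`D = 2K/(N(N−1))`, mean clustering coefficient C, and degree
heterogeneity H.

C is the Watts–Strogatz average local clustering coefficient,
`c_i = 2 τ_i / (k_i (k_i − 1))` with τ_i the number of triangles through
node i, averaged over **all** nodes; nodes of degree < 2 contribute 0
rather than being dropped, keeping N as the denominator.

H is the ratio of a dispersion of the degree sequence to its mean. The
default is population variance / mean; because part of the
anatomical-network literature defines heterogeneity as σ/μ with σ the
standard deviation, an `sd_over_mean` option (and a sample-variance
option) is provided, and the pipeline's provenance block records which
convention a run used.

## Comparative stage

**Abouheif's Cmean.** The proximity of two tips is one over the product
of the numbers of direct descendants of every interior node on the path
between them (tips excluded, MRCA included) — a topology-only measure.
With the proximity matrix row-normalized to W and the trait centered to
x, the statistic is `Cmean = xᵀWx / xᵀx`. Significance comes from
shuffling trait values across tips: `p = (b + 1)/(m + 1)` where b counts
permuted statistics at least as large as the observed one. The test is
one-sided for positive autocorrelation by default (the field's
convention); `less` and `two-sided` are selectable. Every result records
the statistic, p, permutation count and seed, and is exactly reproducible
given (seed, n_perm).

**Blomberg's K.** With C the Brownian-motion covariance implied by the
tree (shared root-to-MRCA path lengths) and â the GLS mean,
`K = [(MSE0/MSE)_obs] / [(tr C − n/(1ᵀC⁻¹1))/(n − 1)]` where
`MSE0 = (x−â)ᵀ(x−â)/(n−1)` and `MSE = (x−â)ᵀC⁻¹(x−â)/(n−1)`. K ≈ 1 under
Brownian evolution; the permutation test mirrors Abouheif's. Constant
traits raise a degenerate-trait error; positive branch lengths are
required.

**Independent contrasts and their correlation.** Felsenstein's pruning:
each internal node yields the contrast `(x₁ − x₂)/√(v₁ + v₂)`, passes up
the variance-weighted mean, and extends its branch by `v₁v₂/(v₁+v₂)`.
Polytomies are rejected outright (the intended use is fully bifurcating
calibrated trees) as are nonpositive branches. Because contrast signs are
arbitrary, the correlation of two contrast vectors is computed through
the origin, `r = Σuw / √(Σu² Σw²)`, with a t test on `n_contrasts − 1`
degrees of freedom; two-sided by default (negative correlations are
reportable), with one-sided options and a with-intercept variant for
sensitivity analysis.

## Synthetic data

The generators define the conditions under which the pipeline is
validated:

- **Skull networks.** 8–9 bilateral bone pairs plus 5–6 midline bones
  (21–24 nodes — the size range of real mammalian skulls) with contacts
  sampled per *mirror orbit* (a left edge and its right image are added
  together), so networks are exactly bilaterally symmetric; an
  asymmetry-injection rate (default 0) supports robustness tests.
  Without a layout, orbits are added in random order until a target
  density (default 0.25, about what real skulls show) is met. With a
  planted layout, each orbit is kept with probability `p_within` or
  `p_between` according to its endpoints' blocks. The study corpus uses
  a two-region cranial/facial layout at 0.40/0.10, which yields overall
  density ≈ 0.25 and a recoverable but not caricatured module structure.
  Components are bridged with minimal mirrored contacts rather than
  rejected, keeping low-density generation fast.
- **Trees.** A unit-rate pure-birth (Yule) process run to the requested
  tip count, rescaled to unit root-to-tip height by default so that
  signal-test calibrations are comparable across seeds.
- **Traits.** Brownian motion: each branch adds a normal increment of
  variance `σ² × branch length`.

All generators are bit-reproducible given their seeds. What the
synthetic data does **not** emulate: real suture geometry, anatomically
faithful bone-specific contact patterns, correlated evolution between
network structure and the tree (networks are drawn independently of the
phylogeny), and bone loss/fusion along lineages. Passing calibrations
therefore demonstrate the statistical machinery is correct and properly
sized — not that any biological conclusion about real taxa follows.

## Numerical choices and degenerate inputs

- TO entries are clipped to [0, 1] and symmetrized against floating
  drift; the diagonal is fixed at 1.
- A pair of bones connected only to each other (possible only as a
  2-bone network) has TO 1 by vacuous identity of neighborhoods; pairs
  with an empty pair-excluded neighborhood otherwise score 0.
- Q ties break toward fewer modules; dendrogram cuts are by cluster
  count, so tied merge heights cannot hide partitions.
- Permutation p-values use the add-one convention, so p = 0 is
  impossible; with m = 199 permutations the achievable size at
  α = 0.05 is exact under exchangeability.
- |r| = 1 in the contrasts correlation maps to t = ±∞ and p = 0.
- Quartiles in summary tables use linear interpolation (R type 7), the
  convention of the standard statistical environments this kind of data
  is summarized in.
- Degenerate inputs raise typed errors: constant traits
  (`DegenerateTraitError`), metrics on < 2 bones
  (`UndefinedMetricError`), polytomies and nonpositive branches for
  contrasts, disconnected or non-binary matrices at validation.

## Problem sizes used in the validation suite

Calibration checks run at sizes chosen to make the statistics stable:
signal-test size on 1000 white-noise replicates (20 tips, 199
permutations each, α = 0.05, expected rejection 0.05); PIC type-I error
over 1000 independent tree + trait-pair draws; Brownian tip variance
over 10⁴ replicates (tolerance 3 SE); planted-partition recovery over
100 seeded 24-node two-block networks at 0.9/0.05 densities; exhaustive
Q-oracle agreement on all partitions of graphs up to 7 nodes.

## Known limitations

- The optimal partition is the best *dendrogram cut*, not the global Q
  optimum over all partitions; this is intentional (the method is
  hclust-then-Q) but means Q values are conservative.
- `M = n_modules × Q` confounds module count and partition quality by
  construction; it is reported alongside its factors.
- Abouheif's test uses topology only; branch-length information is
  ignored (use Blomberg's K when branch lengths are trusted).
- The through-origin reading of the contrasts correlation is an
  interpretive choice (it is the standard requirement for contrasts);
  the with-intercept variant is provided for sensitivity analysis.
- Anchor-based module labels are heuristics tied to the standard bone
  abbreviations (occ, eth, pal, pmx); networks using other nomenclature
  need a label map at ingestion.
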