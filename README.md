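# coextdiv

Stochastic plant–pollinator coextinction cascades and the decline of
plant **functional diversity (FD)** and **phylogenetic diversity (PD)**.

Pollinator declines can trigger cascades of secondary extinctions in
mutualistic communities: plants lose their pollinators, starving further
pollinators, and so on. `coextdiv` simulates such cascades on
quantitative visitation networks and asks how fast the plant
assemblage's functional and phylogenetic diversity erode compared with
best-case, worst-case and random extinction orderings. It is aimed at
ecologists studying network robustness and at anyone who needs a tested
reference implementation of the underlying primitives (stochastic
coextinction model, tree-based diversity metrics, quadratic-entropy
originality, Moran's correlograms).

## The model

A quantitative network is a matrix `a_ij` counting visits of pollinator
*i* to plant *j*. The **dependence** of species *i* on partner *j* is
`d_ij = a_ij / Σ_k a_ik`, recomputed from the shrinking matrix as the
simulation proceeds. When species *j* goes extinct, each surviving
partner *i* falls with probability

```
P_ij = R_i · d_ij
```

where `R_i ∈ [0, 1]` is the intrinsic dependence of *i* on the
mutualism (default `R = 1`: fully dependent). A simulated sequence
repeats primary extinction episodes until no pollinator remains: one
pollinator is removed, chosen with probability proportional to the
inverse of its current total interaction frequency (rare visitors die
first); cascades then alternate between the plant and pollinator sides
until no further species fall, after which the surviving plant set is
scored.

Diversity of the survivors is measured on fixed trees: FD on a UPGMA
dendrogram of Euclidean LHS-trait distances (specific leaf area, canopy
height, seed mass), PD on the dated phylogeny. Both are the summed
branch length connecting the surviving species; FD excludes the path
above their most recent common ancestor (one species ⇒ FD = 0), PD
includes the root path. Each species' **originality** is its weight in
the vector maximizing Rao's quadratic entropy on the tree's cophenetic
distances — weights are nonnegative and sum to 1. Decline curves of
metric value versus the proportion of plants lost are averaged over
10⁴-style ensembles and compared with plants removed directly in
ascending originality (best case), descending originality (worst case)
or uniformly at random.

## Worked example

```python
import coextdiv as cd

model = cd.CoextinctionModel.from_synthetic(cd.SynthConfig(seed=42))
res = model.fit(n_runs=500, reference_runs=500, seed=7)
print(res.summary())
```

```
Plant-pollinator coextinction analysis
======================================================
plants (after trait filter):     18
pollinators:                     30
plants removed (<2 traits):       2  (10.0%)
pollinators removed:              0
connectance:                     0.198
simulation runs:                500   (R_plant=1.0, R_animal=1.0)
------------------------------------------------------
Deviation from random expectation at 50% plant loss:
  FD                               +7.5%
  PD                               +7.5%
------------------------------------------------------
Spearman tests (mean persistence vs originality):
  functional     rs = +0.098   p = 0.699   (n = 18)
  phylogenetic   rs = -0.013   p = 0.958   (n = 18)
Moran's I, first distance class:
  persistence_on_functional_distance           I = -0.127  p = 0.489
  persistence_on_phylogenetic_distance         I = -0.193  p = 0.181
  functional_originality_on_phylogenetic_distance I = -0.236  p = 0.013
```

Two of the twenty synthetic plants had fewer than two LHS traits and
were dropped (any pollinator left without interactions would go too).
At the point where half the plants are lost, the coextinction
trajectory retains 7.5% more FD and 7.5% more PD than random plant
removal — on this community, coextinctions spare disproportionately
original plants. Neither originality measure correlates significantly
with persistence, and neither persistence correlogram shows significant
clustering of risk among functionally or phylogenetically similar
plants.

`res.plot_decline("FD")` draws the decline curve against the three
references; `res.curves_frame()`, `res.persistence()` and
`res.statistics` expose everything as DataFrames.

The same analysis runs from the shell:

```bash
coextdiv synth --n-plants 20 --n-pollinators 30 --seed 42 --out-dir inputs/
coextdiv run --config config.yaml        # full pipeline with manifest
coextdiv prep|diversity|simulate|curves|stats --help   # stage by stage
```

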