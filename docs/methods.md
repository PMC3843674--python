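# Methods

## The coextinction model

The simulation substrate is a quantitative bipartite network: integer
counts `a_ij` of visits by pollinator *i* to plant *j*. Visit counts
serve two roles — as the interaction-frequency proxy for abundance
(hence primary extinction risk) and as the basis of mutual dependences.
The dependence of species *i* on partner *j* is

    d_ij = a_ij / Σ_k a_ik ,

with the sum over *i*'s partners that are still alive; dependences are
recomputed from the current (zeroed-out) matrix after every cascade
wave, so a species' reliance concentrates on its surviving partners as
the community collapses. Species never form new interactions.

A single coextinction event is Bernoulli: after losing partner *j*,
species *i* goes extinct with probability `P_ij = R_i · d_ij`, where
`R_i ∈ [0, 1]` is *i*'s intrinsic dependence on the mutualism
(pollination for plants, floral food for pollinators). The default
`R = 1` describes fully dependent communities; `R < 1` lets species
survive partner loss outright.

An extinction **sequence** iterates primary episodes until no
pollinator remains:

1. One pollinator is removed, sampled with probability proportional to
   the inverse of its current total interaction frequency.
2. All surviving plants are exposed to the loss; any that fall expose
   the surviving pollinators, and so on, sides alternating, until a
   wave produces no extinction. Dependences used within a wave are
   those of the state at the wave's start (the newly lost species still
   count in the normalization; their loss is what the wave responds
   to).
3. The community is then at equilibrium; the surviving plant set is
   recorded and the next episode begins.

A plant's **persistence** is the number of completed episodes before
its loss; plants alive at the end keep the total episode count.

### Simultaneous partner loss

The per-event probability is defined for a single lost partner. When a
wave removes several partners of species *i* at once the implementation
combines them as independent hazards, `P_i = 1 − Π_j (1 − R_i·d_ij)`,
which reduces exactly to `P_ij` for one loss. One corner needs care:
if a wave removes *all* of *i*'s remaining partners, the independent-
hazard product evaluates to less than `R_i` (e.g. two partners at
d = ½ each give `1 − ¼ = ¾` rather than 1 at R = 1), so a fully
dependent species could outlive its entire partner set — contradicting
the model's premise that at R = 1 a species cannot persist without
partners, and leaving sequences that never fully terminate. The
implementation therefore scores a complete partner loss as the loss of
the species' whole dependence (d = 1): `P_i = R_i`, exactly what the
single-event rule gives for a sole surviving partner. With any partner
surviving, the product rule applies unchanged. Consequently at R = 1
every sequence ends with both sides empty, while for R < 1 species can
be stranded alive without partners; stranded plants are recorded as
never lost, and stranded pollinators (zero current frequency, hence
unbounded inverse-frequency weight) are deterministically chosen first
in subsequent primary episodes.

### Randomness

`run_ensemble` draws each run from its own `SeedSequence` substream of
the ensemble seed, so ensembles are reproducible and order-independent.
One uniform draw decides each species' fate per wave. The pipeline
fans a single master seed out to named substreams (synthesis,
simulation, random reference, permutation tests).

## Diversity metrics

FD and PD are both "summed branch length needed to connect the
survivors" on a fixed tree, evaluated via a precomputed edge-by-leaf
incidence matrix: an edge contributes to PD when at least one extant
leaf descends from it (the root path is therefore included), and to FD
additionally only when it lies below the survivors' most recent common
ancestor. This makes FD of a single species 0 while PD of a single
species is its root-to-leaf distance — the one behavioural difference
between the metrics. Trees are never reconstructed during a sequence.

The functional tree is a UPGMA dendrogram of Euclidean distances over
the three LHS traits. Because SLA (mm²/mg), canopy height (m) and seed
mass (mg) live on incommensurate scales, traits are z-scored by default
before the distance; per-trait log10 transforms are available and
recommended for these right-skewed traits. Missing values are handled
pairwise: the squared differences are summed over traits present in
both species and rescaled by `sqrt(3 / t_shared)`; a pair sharing no
trait is an error (upstream filtering guarantees ≥2 traits per
species, so a shared trait always exists among three). The z-scoring
uses the sample (ddof = 1) standard deviation. UPGMA places each merge
at half the average linkage distance and breaks ties by the
lexicographically lowest label pair, so dendrograms are identical
across platforms.

**Originality** is the weight vector on the probability simplex
maximizing Rao's quadratic entropy `w'Δw / 2` for the tree's cophenetic
distance matrix Δ — each species' relative contribution to the tree's
diversity, summing to 1. For ultrametric trees the problem is concave
and is solved by an equality-constrained active-set method: solve the
KKT system on the current support, drop the most negative weight,
re-admit any excluded species whose gradient exceeds the multiplier.
Solutions are validated in the test suite against dense simplex grid
search and an SLSQP cross-check during development. Originality is
computed once, on the full pre-extinction assemblage.

## Decline curves and reference scenarios

Curves live on the grid `p_k = k/S` of proportions of the S plants
lost. A simulated sequence yields a right-continuous step curve (the
metric after the last episode with cumulative loss ≤ k); curves are
averaged pointwise over the ensemble with a pointwise standard
deviation. Reference scenarios remove plants directly, one per grid
step, pollinators playing no role: *best case* in increasing order of
originality (functional originality for FD-type curves, phylogenetic
for PD-type; ties lexicographic), *worst case* in decreasing order, and
*random* as the mean over uniformly random orders. The relative
deviation `100·(coextinction − random)/random` is reported per grid
point (undefined where the random curve is 0, i.e. the FD endpoint)
and summarized at the smallest grid point ≥ 0.5, without
interpolation.

A caveat the test suite makes explicit: the greedy originality
orderings are heuristics, not pointwise optima. Because quadratic-
entropy originality scores species individually, the "best" order can
retain two individually original sister species whose joint
contribution is largely shared, and the random mean curve then exceeds
the "best" curve at interior grid points (observed on about a third of
small Yule-tree fixtures, mostly for PD). The best/worst curves should
be read as named removal strategies, not as proven envelopes.

## Synthetic communities

The generator supplies all three inputs with controllable structure;
defaults are chosen once to emulate a mid-sized temperate pollination
web and are used by the tests and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| `n_plants` / `n_pollinators` | 20 / 30 | community size |
| `connectance` | 0.2 | fraction of realized links |
| `count_mu`, `count_sigma` | 1.0, 1.0 | lognormal visit counts, rounded up to ≥1 (heavy-tailed; both 0 ⇒ all counts 1) |
| `birth_rate` | 1.0 | Yule speciation rate (arbitrary time units) |
| `trait_model` | `brownian` | Brownian motion along the tree vs iid |
| `trait_sigma` | 0.5 | diffusion (or iid sd) of latent log10 traits |
| `missing_rate` | 0.2 | per-value missingness ⇒ ≈10% of plants fail the ≥2-trait rule |

Networks fix the link count at `round(connectance · cells)`, cover
every row and column with a randomized cyclic assignment, and place the
remaining links uniformly — so no species starts empty and realized
connectance matches the target up to rounding. Phylogenies are
pure-birth (Yule) trees grown to n tips plus a final `Exp(n·λ)`
interval, hence ultrametric with no zero-length terminal branch.
Traits evolve on the log10 scale (from a root value of 0) and are
mapped to measurement units as `baseline · 10^latent` with baselines
20 mm²/mg (SLA), 0.5 m (height), 1 mg (seed mass), keeping stored trait
tables strictly positive as the format requires; the latent values are
exposed separately for calibration. Missingness is completely at
random.

What the generator does **not** emulate: degree distributions fitted to
any particular empirical web, sampling effort artefacts (rare species'
interactions are observed exactly), trait measurement error,
non-random missingness, and non-Yule tree shapes. Passing tests
therefore demonstrate internal correctness and calibration of the
machinery under idealized conditions, not agreement with any field
data.

## Statistics

Spearman rank correlations (average ranks for ties) test mean
persistence against each originality; for n ≤ 10 the two-sided p comes
from exhaustive enumeration of all n! pairings, otherwise from the
usual t approximation. Moran's I correlograms use equal-frequency
distance classes (default 4) on the cophenetic distances of the
dendrogram or phylogeny, binary within-class weights, and a two-sided
permutation test (default 999 permutations, observed value included in
the null set); a distance equal to an internal class edge is assigned
to the upper class so that heavily tied ultrametric distances still
partition. The expected value under no autocorrelation is −1/(n−1).
The third correlogram — functional originality on phylogenetic
distances — probes phylogenetic signal in functional uniqueness. A
calibration caveat established by the test suite: even under pure
Brownian traits the quadratic-entropy originality transform attenuates
phylogenetic signal strongly (first-class detection near 50–60% where
the raw traits give ~95%), so a non-significant originality correlogram
is weak evidence against trait conservatism.

## Problem sizes and numerical choices

Default analyses use 10⁴ simulation and reference runs; the test suite
and `scripts/acceptance.py` scale to 10²–10³ runs on communities of
8–20 plants, and to 10⁵ runs on the 2×2 enumeration checks, sizes at
which Monte-Carlo error is well inside the asserted 3·SE bounds.
Tolerances: exact tree-metric identities at 1e−9; originality grid
agreement at 2e−3 per component; ultrametricity at 1e−9 relative.
Degenerate inputs: constant persistence or constant correlogram values
are reported as degenerate rather than producing numbers; empty extant
sets give FD = PD = 0; a network with a single species pair is valid.

## Known limitations

- Primary extinctions target pollinators only; plants die only through
  cascades. No rewiring or partner switching.
- Binary (presence/absence) networks are supported only as counts of 1,
  which makes dependences uniform.
- The ≥2-trait filter follows the main preprocessing rule only; no
  taxonomy reconciliation or trait harmonization is attempted.
- Originality is the quadratic-entropy-maximizing definition only; the
  best/worst reference orders inherit its limitations (see above).
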