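# Methods

## The model

`crmnet` couples three layers: a combinatorial layer that encodes a signed
interaction network as consumer-resource rules, a dynamical layer (the
microbial consumer-resource model, MiCRM) that turns those rules into
abundance trajectories, and an observation layer that turns abundances
into sequencing counts.

### Interaction semantics

An entry `A[i,j] = +1` means taxon `i` produces a metabolite that taxon
`j` consumes (commensalism/feeding); a mutual `A[i,j] = A[j,i] = −1` pair
means the two taxa consume a common metabolite (competition). Negative
edges are always mutual, self-interactions are disallowed, and
interactions whose sign would depend on metabolite availability (e.g.
competitors that also feed each other) are excluded by construction, so
every edge has a fixed, unambiguous sign.

Because a consumer-resource model has no notion of *which* taxon produced
a given metabolite molecule, all consumers of a metabolite share its
by-product rules. Two competing taxa with different positive
out-neighbours would therefore be indistinguishable from two competing
taxa that share them — two different networks, one `(C, D)` pair. The
**disambiguation transform** removes this: for every competitive pair the
positive out-neighbour sets are replaced by their union, iterated to a
fixed point. Edges are only ever added into zero entries; an existing
negative edge is never overwritten (if the union would point a competitor
at its own partner, the competition stands). After this transform the map
from network to `(C, D)` is invertible, which the round-trip oracle
`reconstruct_network` checks property-wise in the tests. When
reconstructing, shared consumption (competition) takes precedence over
positive evidence arising from the shared by-product rules of competitor
chains — the exact inverse of the fill-zeros-only forward rule.

### Environment closure

Energy conservation requires every taxon to consume and produce
something. The ENV node supplies a nutrient to each taxon with no
in-edges and absorbs waste from each taxon with no positive out-edge. The
closure is production/consumption-aware: a negative edge marks its
endpoints as consumers (they eat the contested metabolite) but not as
producers, so a taxon whose only edges are competitive still gets a waste
edge to ENV. A sign-blind closure would let such taxa consume without
producing and leak energy.

### Metabolite allocation

Three deterministic passes (ascending node order, so results are
bit-reproducible):

1. every nonempty set of positive in-edges of a taxon shares one fresh
   metabolite (a taxon is fed by one niche, possibly by several
   producers); every competitive pair gets a private metabolite
   (preventing spurious co-regulation between unconnected competitions);
   the waste metabolite `w` is allocated last and stamped on all edges
   into ENV. `w` exists even when no taxon secretes it, so the metabolite
   count is always `M = #{taxa with a positive in-edge} +
   #{competitive pairs} + 1`.
2. for a positive edge the source produces and the target consumes the
   edge metabolite; for a negative edge both endpoints consume it.
3. `C` is the consumption incidence over taxa (ENV's row is dropped — the
   environment is not a consumer in the ODEs; external supply models its
   role), and `D[β,α] = 1` whenever some taxon consumes `α` and produces
   `β`. Nonzero columns of `D` are normalised to sum one, making `d_βα`
   the fraction of energy leaked from consuming `α` that reappears as
   `β`. ENV is excluded from the `D` loop: including it would create
   rules recycling waste back into nutrients, contradicting the waste
   definition.

Binary `C`/`D` entries can optionally be resampled (truncated-normal,
gamma, or Dirichlet over each row/column's support) to introduce
quantitative heterogeneity; the sparsity pattern — and hence the encoded
network — is never altered, and `D` is re-normalised column-wise.

## Dynamics

With `S` taxa and `M` metabolites,

    dN_i/dt = g N_i ( (1−l) w_e Σ_α c_iα σ(R_α) − m_c )
    dR_α/dt = κ_α(R) − Σ_i N_i c_iα σ(R_α) + l Σ_i Σ_β d_αβ N_i c_iβ σ(R_β)

Parameters (defaults in parentheses): `g` energy-to-growth conversion
(1 per energy), `m_c` maintenance cost (1 energy/time), `l` leakage
fraction (0.8), `w_e` energy per unit resource (1), `R0` intrinsic
equilibrium resource abundance (1000 mass/volume), `tau` supply timescale
(1 time unit). The uptake response `σ` is linear (`σ(R) = R`, default) or
a Hill type-III response `σ(R) = σ_max R^n / (K^n + R^n)` with defaults
`σ_max = 5`, `n = 2`. `K_half` is not fixed by the model definition; it
defaults to 20 and is exposed as a parameter. With uniform `w_e` the
energy ratio between secreted and consumed metabolites is one, so `w_e`
cancels from the secretion term.

Supply modes: **constant** (`κ = R0/tau` on the supplied set — the
default), **bolus** (`κ = 0`; resources enter only through the initial
condition) and **logistic** (`κ = (R0 − R)/tau`, intrinsic replenishment
towards `R0`). The supplied set is `round(fr·(M−1))` non-waste metabolites
drawn uniformly; `fr = 0.05 / 0.5 / 1` represent poor / moderately rich /
rich environments. Initial resources are `R0` on the supplied set (the
environment equilibrates before taxa are introduced); initial abundances
default to log-normal(μ=0, σ=2) — a synthetic heavy-tailed stand-in for
abundance distributions observed in real 16S count tables (it reproduces
their strong right skew but not, e.g., their taxon-rank correlation
structure across cohorts).

### Numerics

Integration uses LSODA with an analytic Jacobian, relative tolerance
1e−8, in chunks of `t_chunk = 100` time units up to `t_max = 1e5`. At
each chunk boundary negative round-off is clipped and taxa below the
extinction threshold (1e−6, absolute) are set to zero — extinct taxa stay
extinct, including across sample perturbations. The community is declared
steady when `max |dx/dt| / (|x| + 1e−8) < 1e−6` over all taxa **and over
all resources that still have a surviving consumer**. Resources without
consumers — the waste sink and any supplied-but-unconsumed nutrient —
accumulate linearly under constant supply by construction, never feed
back on the community, and are therefore excluded from the criterion;
with a full-state criterion a community secreting waste would never
register as steady. Non-convergence by `t_max` is reported via a flag
(and per-sample flags in the sample matrix), never silently accepted.

The single-consumer system has the closed form `R* = m_c/((1−l) w_e)` and
`N* = κ/R*` (linear response, constant supply), used as an analytic
anchor in the tests together with the zero-growth condition
`(1−l) w_e Σ_α c_iα σ(R*_α) = m_c` for every survivor.

## Samples and sequencing

Each of the `B` biological samples perturbs the converged environment:
`fp ~ U(0,1)` picks the fraction of perturbable resources (those with
nonzero supply in constant mode, nonzero steady-state concentration in
bolus mode), `ps ~ U(2,10)` the scale factor, and a fair coin the
direction (multiply or divide). Re-integration starts from the
unperturbed steady state — the perturbation alters the environment of an
established community, not a re-assembly from scratch. All samples share
`C` and `D`, hence the same ground-truth network.

Counts follow `Y_k ~ MultHyper(n = l_k, m = round(pool_scale · X_k))`,
drawn by sequential conditional univariate hypergeometric sampling.
Library sizes `l_k` are user-specified, constant, or log-normal
(`meanlog = log(5·10^4)`, `sdlog = 0.3` — depths typical of 16S runs).
Quantisation rounds half-to-even for cross-platform determinism and
preserves zeros exactly, so structural absences can never gain reads;
sampling without replacement can only add zeros, so sparsity never
decreases. `pool_scale` controls the finite-pool size: 1 treats the
abundances themselves as the molecule pool; `"auto"` (the pipeline
default) rescales so the smallest column total is ≥ 100× the largest
library, approaching the multinomial regime — the convention matters only
when abundances are comparable to read depths, and is recorded in the
output config for provenance.

## Benchmark harness

The zero-aware clr transform divides the nonzero entries of a sample by
the geometric mean of the nonzero entries and passes zeros through. The
transform is defined as this ratio; for Pearson input the log of the
transformed nonzero entries is used (zeros stay 0), because correlations
of raw ratios from heavy-tailed compositions are dominated by single
outliers. Ratio mode is available via `log=False`.

The baseline inference method computes pairwise Pearson correlations of
the transformed table and calibrates them with an empirical permutation
test: each taxon's samples are shuffled independently (`n_perm = 1000` by
default), two-sided `p = (1 + #{|r_perm| ≥ |r_obs|})/(1 + n_perm)`, then
Benjamini–Hochberg at `α = 0.05`. The shuffle scheme, sidedness and
correction are recorded in the inferred network's metadata. Zero-variance
taxa are assigned `p = 1`. Since cross-sectional methods infer undirected
networks, the directed signed truth is collapsed to a symmetric binary
adjacency (ENV removed) before scoring.

Edge recovery is scored with the Matthews correlation coefficient over
unordered taxon pairs (zero denominator ⇒ 0, the random-classifier
value). Topology descriptors use these conventions on disconnected
graphs: diameter = maximum component diameter; radius = minimum component
radius, undefined when an isolated node exists; mean distance =
ordered-pair average, undefined unless the graph is connected; clustering
coefficient averaged over all nodes with degree < 2 contributing 0;
betweenness unnormalised over unordered pairs excluding the focal node.
Undefined metrics are reported as explicit markers (`None` in the API,
`undefined` in report files), never as 0.

## Design choices and limitations

- **Directed scale-free generator**: preferential attachment with `k`
  seed nodes; every new node makes `k` attachments to distinct targets
  chosen proportionally to total degree, each oriented out / in / both
  with probability 1/3. `nneg` converts `round(nneg · #connected pairs)`
  uniformly chosen pairs to competition, sampled without replacement.
- **Randomness** is hierarchical: one master seed spawns an independent,
  named stream per stage, so regenerating one stage never consumes
  another stage's draws and every artifact is reproducible from the
  config file alone.
- **End-to-end study conditions in the tests** use the linear uptake
  response. Under the default energy budget (`l = 0.8`, `m_c = 1`,
  `w_e = 1`) a Hill response with `σ_max = 5` gives a taxon consuming a
  single metabolite a maximum energy surplus of exactly zero, so
  communities where most taxa occupy single-metabolite niches are only
  viable with the unbounded linear response; the Hill response remains
  fully supported and unit-tested.
- Problem sizes in the test suite (e.g. 20 replicates of the
  sample-size comparison at S = 50, B = 300 with 200 permutations;
  exhaustive topology-oracle checks on ≤ 5-node graphs plus sampled 6–7
  node graphs) were chosen to give stable statistics on a single CPU.
- One `D` for the whole community: metabolite conversion is
  taxon-independent by model structure, which is why disambiguation is
  needed at all; taxon-specific metabolic rules are out of scope.
- Not modelled: toxicity and other non-metabolic interactions (quorum
  sensing, contact-dependent inhibition), 16S copy-number variation and
  amplification bias, longitudinal sampling, and biological variability
  beyond the resource perturbations themselves (the hypergeometric layer
  adds technical noise only).
- Passing tests show the machinery is self-consistent (exact
  combinatorics, analytic dynamical limits, correct sampling moments) and
  that the simulator reproduces the expected qualitative ecology; they do
  not certify that any particular real community behaves like a MiCRM.
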