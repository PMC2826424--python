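# Methods

## The allele-interaction calculus

A biallelic locus is described by five genotypic values: homozygotes `x11`,
`x22`, heterozygote `x12`, and hemizygotes `h1`, `h2` (one allele deleted).
Phenotypes here are equilibrium expression levels, non-negative by
construction. Alleles are labelled canonically so that `x11 ≤ x22`; the
relabelling swaps `(x11, h1) ↔ (x22, h2)` jointly, and ties on the
homozygotes are broken by `h1 ≤ h2`, then input order.

The allele interaction value of genotype *ij* is
`δ_ij = x_ij − (h_i + h_j)`. The classical decomposition is
`a = (x22 − x11)/2`, `d = x12 − (x11 + x22)/2`, with the exact identity
`d = δ12 − (δ11 + δ22)/2`. Dominance classes: additive (d = 0 after
zero-calling), positive/negative dominance (0 < |d| ≤ a), positive/negative
overdominance (|d| > a, i.e. the heterozygote strictly outside the homozygote
range).

**Zero-calling.** Measured or simulated values are never exactly additive, so
each δ is called zero when the hemizygote sum differs from the biallelic
value by less than `tol` (default 0.05) times the biallelic value, and `d` is
called zero when the heterozygote differs from the homozygote mean by less
than `tol` times that mean. Both comparisons are one-sided relative
differences with strict `<`; `tol = 0` recovers the exact calculus used in
the algebraic identities. The reference value (biallelic phenotype for δ, the
homozygote mean for d) is the quantity being explained in each case; a
symmetric relative difference changes none of the qualitative results. The
scaled dominance `d/a` is reported only when `a > 0` and `a ≥ tol·m`
(`m` the homozygote mean); below that, the ratio is noise and is flagged
undefined rather than clipped.

**Sign motifs.** The called triplet `(s11, s12, s22)` is reduced modulo
allele relabelling, which reverses the triplet. The canonical representative
is the lexicographic minimum of the triplet and its reversal under the symbol
order `0 < + < −`; this order reproduces the conventional printed
orientations (e.g. `[0 0 +]`, `[+ 0 −]`). The 27 raw triplets collapse to 18
canonical motifs. For each motif, the set of dominance signs achievable over
strictly positive magnitudes follows a closed symbolic rule (`d` can be
positive iff `s12 = +` or a homozygote sign is `−`; negative symmetrically;
zero iff the heterozygote term can be matched exactly by the homozygote
mean). The rule is verified in the tests and in the acceptance script against
brute-force enumeration over a dyadic magnitude grid — dyadic so that the
exact-zero case (a 2:1 magnitude ratio) is realized without floating-point
residue. Eleven motifs have a unique dominance sign, seven are
magnitude-dependent, and six of the unique ones carry a nonzero heterozygote
sign equal to the dominance sign.

## The gene-regulatory model

Each allele *i* of an autoregulated locus follows

    dx_i/dt = α_i · R_i(u) − γ_i · x_i,     u = Σ_j w_j x_j,

summed over the alleles present (two in biallelic genotypes, one in
hemizygotes). `α` is the maximal transcription rate, `γ` the relative decay
rate, and `R ∈ [0, 1]` the dose-response of transcription to the gene's own
total product — the aggregate of the whole chain from transcript to active
regulator, modelled as if the product were its own transcription factor. The
weights `w` model coding variation: allele products with different binding
affinities contribute unequally to the regulatory input (`w = 1` without
coding variation). Response shapes:

* `hill_up`   `u^p/(u^p + θ^p)` — positive autoregulation;
* `hill_down` `θ^p/(u^p + θ^p)` — negative autoregulation;
* `bump_up`   `exp(−(u−μ)²/2σ²)` — peak-shaped (activating at low, inhibiting
  at high concentration), maximum 1 at `u = μ`;
* `bump_down` the complementary trough shape;
* a constant value in [0, 1] — constitutive control (no feedback).

The phenotype of a genotype is the total concentration at the stable
equilibrium reached from a random initial condition. At equilibrium
`x_i = (α_i/γ_i) R_i(u)`, so all equilibria are roots of the scalar function

    g(u) = Σ_i w_i (α_i/γ_i) R_i(u) − u        on [0, Σ_i w_i α_i/γ_i],

and stability is decided by the eigenvalues of the full per-allele Jacobian
(threshold Re λ < −1e−9). Constant responses yield strict additivity
(δ ≡ 0); an active Hill-down (Hill-up) feedback makes every beyond-tolerance
δ negative (positive) — both facts are enforced as tests over sampled
parameter sets, alongside: no overdominance at all under noncoding Hill-down
variation, and no positive overdominance under Hill-up.

**Two-locus loops.** A polymorphic locus 1 (alleles produced at
`α_i R_i(y_total)`, unit decay) is coupled to a nonpolymorphic locus 2 (two
identical copies produced at `β S(x_total)`, unit decay). Action signs are
encoded by the response kinds; the loop sign is their product. Hemizygotes
delete one locus-1 allele; locus 2 stays biallelic. Both loci are assayed
across the five locus-1 genotype configurations. For the locus-2 quintet the
hemizygote entries are **per-gene-copy** values (half the locus-2 total in
each hemizygous background): locus 2 contributes two identical copies in
every configuration, so the raw difference `y_ij − (y_hi + y_hj)` would be
≈ −y even for an inactive loop, classifying every uncoupled replicate as
negatively interacting. With the per-copy reference, locus-2 interaction
vanishes exactly when the loop is inactive and measures the loop-mediated
dose response otherwise; this reproduces the characteristic family swap (the
nonpolymorphic locus displays the motif family of the *opposite* feedback
sign when the loop consists of two inhibitions, or when it inhibits the
polymorphic locus).

## Monte-Carlo experiments

One replicate samples two allele parameter sets independently (cis
variation), builds the five genotype systems, solves each to its stable
equilibrium, and classifies the resulting quintet. Filters and calls:

* **null-allele filter** — replicates in which a homozygote configuration
  settles below 0.01 are discarded (both loci's homozygote configurations in
  two-locus runs);
* **convergence filter** — replicates whose dynamics have not met the rate
  criterion by `t_max = 1e4` time units (e.g. sustained oscillation, possible
  for nonmonotonic heterozygotes with unequal decay rates) are discarded;
* **zero-calling** at 5% relative, as above;
* **motif pruning** — motifs under 1% frequency among valid replicates are
  dropped from the summary tables (raw records keep them). `n_shown` counts
  the valid replicates whose motif survives pruning — the datasets a
  motif-frequency plot would display; `n_valid` counts all filter survivors.

**Sampling ranges** (uniform, config-first, overridable per experiment):

| parameter | range | used in | rationale |
|---|---|---|---|
| α (and β) | (1, 300) | all | production from nearly silent to strongly expressed |
| θ | (1, 300) | monotonic, two-locus | thresholds spanning the reachable expression range (up to 2α/γ), from permanently-off to constitutively-on feedback |
| p | (1, 4) | monotonic, two-locus | non-cooperative to moderately cooperative binding; steeper response makes inactive-feedback additivity common enough to distort the motif families |
| w | (0.5, 2) | coding variation | symmetric two-fold affinity change either way; wider spread inflates overdominance beyond the few-percent regime |
| μ | (1, 300) | nonmonotonic | peak/trough location across the expression range |
| σ | (1, 100) | nonmonotonic | narrow to broad response curves |
| γ | 1 (monotonic); (1, 5) (nonmonotonic) | — | time unit fixed by decay in monotonic runs (rescaling makes γ redundant there); the nonmonotonic experiments include decay-rate polymorphism with a five-fold half-life spread |

**Initial conditions.** One random initial condition is drawn per parameter
set and shared by its five genotype systems: a uniform unit draw per
gene-copy slot, scaled to each system's invariant box `[0, α_i/γ_i]`
coordinate-wise. Sharing matters wherever positive feedback makes systems
multistable: it keeps basin choices consistent across the genotypes of one
replicate (a heterozygote never starts below its own hemizygotes), which
eliminates spurious mixed-sign motifs such as `[+ − +]` that arise when each
system is restarted independently. The per-system scaling keeps the draw
inside the region the dynamics can actually reach. Discarded replicates
consume their draws, so the stream position is deterministic.

**Numerics.** Genotype systems with equal decay rates are solved exactly by
scalar-flow root bracketing: the weighted input obeys the autonomous flow
`du/dt = Σ w_i α_i R_i(u) − γu`, so the attractor reached from `u0` is the
nearest root of g in the direction of `sign(g(u0))` — identical to time
integration, without discretization error. The bracketing scan is geometric
near `u0` and linear toward the far end (384 points), followed by 60–80
bisection steps; an attractor pair hiding entirely inside one scan cell would
be missed, which at this resolution is negligible for Hill/bump shapes.
Heterozygotes with unequal decay rates and all two-locus systems are
integrated by a batched exponential-Euler scheme (exact linear decay,
explicit production; unconditionally stable and sharing its fixed points with
the continuous dynamics) with steps 0.05–0.25 up to `t_max`, then snapped to
the nearest root of g; an end state further than 5% from any root is a
convergence failure. A per-replicate LSODA reference path
(`grn.steady_state`) exists alongside the batched engine, and the
oracle-equivalence tests check integration against the fixed-point reduction
to 1e−6 relative on over a thousand sampled systems.

**Experiment sizes.** The acceptance script runs the monotonic experiments at
n = 50000 per feedback sign, the nonmonotonic ones at n = 10000 per shape,
and the coding-variation experiment at n = 50000. The test-suite uses
n = 10000 for the single-locus family checks and n = 4000 per two-locus loop
type; the motif-family and fraction statistics it asserts are scale-free.

## What the generator emulates — and what it does not

The synthetic experiments emulate *regulatory* genetic variation: allele
pairs differing in production rate and response-shape parameters (and, with
coding variation, input weights), with the phenotype read off as a
deterministic equilibrium. They do not model measurement error or biological
noise beyond the 5% zero-call band, transcription–translation delay,
stochastic (molecular-number) kinetics, environment dependence, or linkage to
other segregating loci. Passing tests therefore show that the *mapping* from
regulatory architecture to motif/dominance distributions behaves as derived;
they do not show that real expression data are free of the additional
variance components listed above.

## Known limitations and open edges

* The exact sampling ranges for θ, p, w, μ, σ are design choices of this
  package (the table above); the qualitative results — family memberships,
  sign exclusions, the 16-of-18 coverage — are robust across the ranges
  explored, but the exact shown-dataset counts shift by a few percent with
  them.
* Under negative autoregulation the Hill-down equilibrium is bounded below by
  ≈ 2α/γ whenever it sits below θ, so with α ≥ 1 and γ = 1 the null-allele
  filter never fires and the shown fraction is governed entirely by motif
  pruning (~1.5% of replicates); the valid fraction is 100%.
* Three-or-more-element loops are out of scope; the two-element loop results
  suggest the families are generic, but this package does not test it.
* Tangential (saddle-node) double roots of g can be missed by the bracketing
  scan or mis-snapped by the polish step; both events are measure-zero in the
  sampled parameter space.
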