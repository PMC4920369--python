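# Methods

## The model

Two habitats exchange migrants at rates `m_ji` (habitat `i` to `j`). Each
habitat holds many social groups. A group in habitat `i` is founded by `N_i`
haploid individuals drawn at random from the habitat's dispersal pool; the
founders then reproduce asexually, each of the `N_i` offspring group members
being an independent copy of a uniformly chosen founder. Two offspring group
members are therefore identical by descent since founding with probability
`r_i = 1/N_i` — the within-group relatedness. The reference parameter set
uses `N_1 = 20` (r = 0.05) and `N_2 = 2` (r = 0.5): the habitats differ only
in relatedness.

Offspring group members play a public-goods game. An individual investing
`z ∈ [0, 1]` in a group with mean investment `z̄` earns

    w_i(z, z̄) = W_i + b_i z̄ − c_i z²,

with reference values `W = 0.5`, `b = 3.0`, `c = 1.5` in both habitats.
Payoff is a fecundity and is clamped at zero where the raw expression goes
negative (possible only for extreme `(z, z̄)` combinations far from any
equilibrium; a warning-free clamp, since the equilibria of interest sit in
strictly positive-payoff regions).

The life cycle, from the census (groups formed, game about to start):
(i) the game and offspring production proportional to payoff, (ii) migration
of offspring into per-habitat dispersal pools, (iii) a brief sexual phase —
random mating in the pool, recombination between the cue locus and modifier
loci at rate `ρ`, mutation at gamete formation — and (iv) group founding,
which regulates each habitat back to a fixed capacity, followed by the
asexual generation. `φ_j`, the ratio of habitat `j`'s capacity to its pool
size, is the per-pool-member founding probability.

Phenotypes are set by a genetic cue: two alleles `x_1, x_2` (allelic effects
−1, +1; a symmetric coding that keeps `a0` interpretable as the liability
midpoint) at a cue locus are mapped through the liability sigmoid
`z = 1/(1 + exp(−a0 − ag·x))`. Epistatic modifier loci control `a0` and
`ag`, so a resident dimorphism is a phenotype pair `(z_1, z_2)` induced by
the two cue alleles.

## Analytical engine

**Expected payoffs.** For a rare mutant (a single mutant founder among
`N−1` residents), the expected payoff of a randomly chosen mutant player is
obtained by size-biasing over the mutant founder's offspring count
`K ~ Binomial(N, 1/N)`:

    E[z̄ | focal mutant] = s z' + (1 − s) z̃_i ,   s = (2N−1)/N²,

where `z̃_i` is the mean resident phenotype in the habitat. Because the
benefit is linear in `z̄`, this closed form is exact; the package carries an
independent combinatorial enumeration of the founding/copying process
(`N ≤ 8`) used purely as a test oracle, and the derivative of the expected
mutant payoff reproduces `d_ik = (b/N)(1 + (N−1) r) − 2 c z_k`. The same
size-biasing gives the expected payoff of a random resident of either cue
class, which drives the resident dynamics.

**Resident equilibrium.** Class abundances `n_ik` (habitat × cue allele)
follow the deterministic infinite-population limit of the life cycle;
habitat totals are regulated to capacity at founding. The fixed point is
found by damped iteration accelerated with a stability-checked quasi-Newton
solve; extinction of an allele is declared when its frequency falls below
1e−10, when a sustained geometric decay extrapolates there, or when the only
interior fixed point is dynamically unstable and the iterate drifts
boundary-ward. A Newton root on the boundary is never taken as evidence of
extinction — the monomorphic states are always fixed points. Near-neutral
dimorphisms (z_1 ≈ z_2) are quasi-degenerate: the equilibrium frequencies
become ill-conditioned as the phenotypes merge, which motivates the
diagonal handling in the search (below).

**Invasion fitness.** A rare mutant modifier that changes the phenotype
induced by `x_k` from `z_k` to `z'_k` is tracked over the four classes
(habitat, linked cue allele). One cycle gives the projection matrix

    M[(j,l),(i,k)] = φ_j · m_ji · w̄'_i(z'_k) · h_jlk ,
    h_jlk = (1 − ρ) δ_lk + ρ p_jl ,

with `p_jl` the dispersal-pool cue frequencies (mating is random with
respect to the pool). Invasion fitness is `F = log λ` of the leading
eigenvalue. Two structural identities anchor the construction and are
enforced as tests: the resident equilibrium vector is a right eigenvector of
the resident-valued matrix with `λ = 1` exactly, and the eigenvalue
perturbation `v·(∂M/∂z'_k)·u` with `u = n*/Σn*` reproduces the
reproductive-value decomposition of the selection gradient

    ∂F/∂z'_k = V_1k d_1k p_k q_1k + V_2k d_2k p_k q_2k ,

where `q_ik` is the habitat probability conditional on carrying `x_k`,
`p_k` the allele's overall frequency (dilution factor), and `V_ik` the
offspring reproductive value assembled from the left eigenvector,
`φ`, `h` and `m`. The gradient is verified against central finite
differences of `F` to 1e−6 across randomized parameter draws.

At exactly `ρ = 0` the matrix is block-diagonal over cue-allele lineages and
the dimorphic resident's eigenvalue 1 is degenerate (both lineages replace
themselves). The gradient is then computed per block: component `k` is
`p_k` times the derivative of the allele-`k` lineage's `log λ`, with the
block's left eigenvector normalized against the allele's own habitat
distribution. This is the natural reading of a fully linked modifier, whose
fate is decided entirely on the background it arises on.

**Coexistence and equilibria.** A phenotype pair is a protected dimorphism
when each cue allele invades a monomorphism of the other; because a cue
allele is fully linked to itself, this uses the 2-class (habitat-only)
matrix and is independent of `ρ`. Evolutionary equilibria of the modifier
dynamics are found by following the selection gradient through
`(z_1, z_2)`-space, re-solving the resident equilibrium at every step.
Numerical choices:

* steps `Δz = η g` with `η` halved when the gradient direction reverses
  between steps (overshoot detection) — near a branching-type equilibrium
  invasion fitness is positive on both sides, so a fitness-sign test cannot
  control the step size;
* a rate-limited quasi-Newton polish of the gradient root once `|g| < 1e−3`,
  accepted only if the root is a local attractor (gradient-field Jacobian
  eigenvalues ≤ 0). The diagonal `z_1 = z_2` is a stationary line of the
  dynamics, so saddles on it must be rejected; a rejected saddle is escaped
  along its unstable eigenvector;
* a divergence floor of 2e−3: pairs closer than this are quasi-neutral and
  numerically unresolvable, and persistent gradient pressure onto the
  diagonal is classified as collapse of the dimorphism (the alleles become
  phenotypically equivalent, leaving a neutral, unprotected polymorphism).
  Equilibria with true divergence below this floor are therefore reported
  as monomorphic outcomes — the resolution limit of the search;
* convergence at gradient norm < 1e−6; boundary-pinned phenotypes flagged.

The monomorphic singular strategy — the equilibrium of gradual evolution in
a monomorphic population — is the bracketed root of the 2-class gradient.
For the reference set it equals `b[(2N_1−1)/N_1² + (2N_2−1)/N_2²]/(4c) =
0.42375`, independent of `m` and `ρ`.

**Collapse threshold.** With the life cycle above, mutual invasibility
alone keeps a non-empty coexistence region for any `m < 0.5`: the pair of
habitat optima satisfies `G(z_1*) = G(z_2*)` exactly for the mixed-habitat
invasion potential `G(z) = b(s_1 + s_2) z − 2 c z²`, so it lies inside the
region for all sub-mixing migration rates. What disappears as `m` grows is
the *dimorphic evolutionary equilibrium*: the modifier gradient contracts
the divergence onto the diagonal, after which the neutral polymorphism is
lost. The package therefore determines the maintenance threshold from the
evolutionary outcome — the smallest scanned `m` at which every gradient
path, for every tested `ρ`, ends in a monomorphism. With the reference
parameters this threshold is 0.15 (dimorphic attractors exist up to
`m = 0.125`; at `m = 0.10, ρ = 0.5` the attractor's divergence is already
below the resolution floor, consistent with unlinked modifiers favoring
near-zero divergence).

## Individual-based simulator

The simulator executes the identical life cycle stochastically: multinomial
offspring draws proportional to clamped payoff (pool-wide within each
habitat, one offspring slot per census individual), independent per-offspring
migration, random pairing in the destination pool with one gamete per
founder slot, per-locus recombination against the cue locus, mutation at
gamete formation, and uniform founder copying within groups. Populations are
stored as flat arrays (groups contiguous), so a cycle at the default scale
(4000 individuals) costs ~2 ms.

Mutation defaults — unstated in the analytical model and chosen once for the
simulator: per-locus rate 0.005 per gamete with a zero-mean Gaussian kernel
(sd 0.2) on modifier values, and a cue-allele flip rate of 1e−4. These are
small enough not to distort the equilibria yet supply enough variation to
reach them within a few thousand cycles at the default scale.

Architectures: **A** — one `ag` locus at recombination `ρ` to the cue,
`a0` fixed at the logit of the monomorphic singular strategy (placing the
sigmoid midpoint at the `m`- and `ρ`-independent reference point); **B** —
one locus each for `a0` and `ag`; **C** — `a0` from 5 positive- plus 5
negative-effect unlinked loci (expression clamped at zero), `ag` from 5
unlinked additive loci; **D** — as C with two unlinked evolvable thresholds,
`a0 = min(S⁺, T⁺) − min(S⁻, T⁻)`, a concrete reading of threshold-limited
gene expression. `ag` starts at 1.5 in all architectures so the cue
polymorphism is phenotypically expressed — and hence protected — from the
first cycle.

Default problem sizes are 4000 individuals (2000 per habitat) and 5000
cycles with 10 replicates; the `--scale paper` flag raises this to 40000 ×
40000 for full-scale runs.

**What the simulator does and does not emulate.** It reproduces the model's
own stochastic finite-population version — drift, mutation-limited
adaptation, linkage. It does not add biological realism beyond the model:
no overlapping generations, no spatially explicit groups, no diploid
selection (diploidy exists only during the pooled sexual phase). Agreement
between simulator and analytical engine therefore validates the two
implementations against each other under the model's assumptions; it says
nothing about organisms whose life cycle departs from those assumptions.

At reduced scale, two finite-population effects matter for interpretation:
replicate-to-replicate spread of final mean phenotypes is ~0.01–0.05, so
comparisons with the analytical equilibria use replicate means; and once the
cue locus fixes (as in the polymorphism-transfer experiment), `ag` becomes
confounded with `a0` in the liability and its mean drifts neutrally — the
"`ag` became small" part of the transfer signature is therefore checked on
the trajectory (its transient minimum) and through variance attribution
(the allelic variance residing at `a0`), not on the end-state mean.

## Information metrics

The cue-habitat association is summarized by the conditional probabilities
`q_ik` and the mutual information (bits) of the habitat × allele table. For
continuous architectures the liability is discretized into 20 equal-width
bins over its observed range before computing MI — the binned-liability MI
is this package's operationalization of "information in the genotype",
chosen because it is directly comparable across architectures and
estimable from population dumps. Logistic regressions of habitat-1
membership on the liability use maximum likelihood; complete separation
(expected for clear-cut polymorphisms, which approach step-function
regressions) is handled by capping the slope at ±50 and re-estimating the
intercept with the slope fixed, flagged on the result.

## Known limitations

* The coexistence region is computed by numerical mutual invasibility on a
  grid, not in closed form; region boundaries are resolved only to the grid
  step.
* Dimorphic equilibria with divergence below 2e−3 are indistinguishable
  from monomorphic outcomes.
* The gradient machinery assumes the leading eigenvalue is simple; the
  `ρ = 0` degeneracy is handled per block, but other exact degeneracies
  (e.g. fully symmetric habitats with symmetric phenotypes) can make
  eigenvector-based quantities ill-defined — eigenvalues and invasion
  fitness remain valid there.
* Two habitats and two cue alleles throughout; containers are length-2 by
  construction.
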