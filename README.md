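# genecue

Social evolution with **genetic cues of relatedness** in a two-habitat
environment: an analytical adaptive-dynamics engine paired with a
forward-time individual-based simulator.

## The problem

Many social traits — investment in a public good, helping, virulence — are
genetically polymorphic, yet classical social-evolution theory treats the
evolving trait as monomorphic reaction norms over phenotypic states. When
nearby habitats favor different traits and migration connects them,
selection maintains allele-frequency differences between habitats; an allele
at such a polymorphic locus then *predicts* its carrier's environment,
including the relatedness of its social partners. It is a **genetic cue**,
and modifier loci can evolve to condition the phenotype on it, like a
Bayesian decision maker using prior and likelihood.

This package implements that framework for a concrete model: two habitats
whose social groups are founded by `N_1 = 20` vs `N_2 = 2` haploid
founders (within-group relatedness `r_i = 1/N_i`, so 0.05 vs 0.5), a
public-goods game with payoff `w_i(z, z̄) = W_i + b_i z̄ − c_i z²`, migration
at rate `m` between habitats, and a cue locus whose alleles `x_1, x_2`
induce investments `z_1, z_2` through the liability sigmoid
`z = 1/(1 + exp(−a0 − ag·x))`. Modifier loci controlling `a0` and `ag`
recombine with the cue locus at rate `ρ`.

The central quantities:

* **Invasion fitness** `F = log λ` of a rare mutant modifier, from a 4×4
  projection matrix over (habitat × linked cue allele) classes built on the
  resident's demographic equilibrium.
* **Selection gradient** `∂F/∂z'_k = V_1k d_1k p_k q_1k + V_2k d_2k p_k q_2k`
  — reproductive values `V_ik`, payoff derivatives
  `d_ik = (b_i/N_i)(1 + (N_i−1) r_i) − 2 c_i z_k`, the habitat probabilities
  `q_ik` conditional on the cue allele, and the allele's dilution factor
  `p_k`.
* **Protected dimorphisms** by mutual invasibility at the cue locus, and
  equilibrium dimorphisms by gradient ascent through `(z_1, z_2)`-space.
* **Information metrics**: `q_ik`, cue–habitat mutual information in bits,
  and logistic regressions of habitat on the liability.

The headline effect: the genetic linkage between cue and modifier shapes the
outcome. Tightly linked modifiers behave like habitat specialists (large
divergence `|z_2 − z_1|`), unlinked modifiers like generalists (small
divergence) — a genetic conflict whose loser can even hand its polymorphism
to another locus (the simulator's polymorphism-transfer experiments).

## Worked example

```python
from genecue import (ModelParams, Dimorphism, ascend_to_equilibrium,
                     monomorphic_singular_strategy)
from genecue.resident import find_resident_equilibrium
from genecue.info import empirical_cue_information

params = ModelParams.reference(m=0.05, rho=0.0)   # N=(20,2), W=0.5, b=3, c=1.5
res = ascend_to_equilibrium(Dimorphism(0.2, 0.7), params)
print(f"equilibrium dimorphism: z1 = {res.dim.z1:.4f}, z2 = {res.dim.z2:.4f}")
print(f"monomorphic reference:  z* = {monomorphic_singular_strategy(params):.5f}")

eq = find_resident_equilibrium(res.dim, params)
info = empirical_cue_information(eq.n)
print(f"P(habitat 1 | x1) = {info.q[0,0]:.3f}, P(habitat 2 | x2) = {info.q[1,1]:.3f}")
print(f"cue information: {info.mi_bits:.3f} bits")
```

prints

```
equilibrium dimorphism: z1 = 0.1064, z2 = 0.7411
monomorphic reference:  z* = 0.42375
P(habitat 1 | x1) = 0.919, P(habitat 2 | x2) = 0.865
cue information: 0.505 bits
```

With fully linked modifiers at `m = 0.05`, the two cue alleles settle near
the habitat-specific optima (0.0975 and 0.75 in the no-dispersal limit):
allele `x_1` marks the low-relatedness habitat and induces low investment,
`x_2` the high-relatedness habitat and high investment — far apart from the
compromise `z* = 0.42375` a cue-blind monomorphic population would reach.
Carrying `x_1` raises the probability of being in habitat 1 from the prior
0.5 to 0.92: the allele is worth about half a bit of habitat information.
Raising `ρ` shrinks the divergence (try `rho=0.5`), and for `m ≥ 0.15` the
polymorphism is not maintained at all.

## Command line

```bash
genecue equilibrium --out runs/eq          # gradient-path equilibrium search
genecue region --out runs/region           # coexistence mask over (z1, z2)
genecue sweep --out runs/sweep             # equilibria over an (m, rho) grid
genecue simulate --seed 1 --out runs/sim   # individual-based simulation
genecue info --seed 1 --out runs/info      # information metrics of a run
```

Each accepts `--config run.toml` (TOML or JSON; see `genecue.config` for the
schema — defaults reproduce the reference parameter set) and writes CSV/TSV
tables plus a JSON manifest (parameters, seed, version, timing) sufficient
to reproduce the run. Column semantics are documented in
[docs/output_schema.md](docs/output_schema.md); the scientific background in
[docs/methods.md](docs/methods.md).

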