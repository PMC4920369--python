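# Output file schema

All tables are plain text with a header row; CSV for result tables, TSV for
grids and class/genome dumps. Phenotypes `z` and frequencies are
dimensionless in [0, 1]; migration and recombination rates are
probabilities per cycle; payoffs/fecundities are dimensionless offspring
weights; mutual information is in bits.

## manifest.json (every run)
- `config` — the full resolved run configuration
- `version` — package version
- `mode`, `seconds` — dispatched mode and wall time
- mode-specific flags (`region_empty`, `collapsed`)

## gradient.csv (mode=gradient)
| column | meaning |
|---|---|
| z1, z2 | resident dimorphism |
| g1, g2 | selection gradient dF/dz'_k at the resident |
| monomorphic | surviving allele index if the pair is unprotected, else empty |

## equilibrium.tsv (modes gradient/fixtures; one row per class)
| column | meaning |
|---|---|
| habitat, allele | class labels (1-based) |
| n | equilibrium class abundance |
| p | within-habitat allele frequency p_ik |
| q_habitat | habitat prior q_i |
| q_given_allele | habitat probability conditional on the allele, q_ik |
| p_allele | overall allele frequency (dilution factor) p_k |
| phi | founding probability of the habitat's pool |
| pool_p | post-migration pool composition |

## equilibrium.csv (mode=equilibrium)
`z1, z2` (equilibrium dimorphism), `grad_norm`, `converged`, `collapsed`
(true when the polymorphism cannot be maintained; z then reports the
collapse point).

## region.tsv (mode=region)
Square 0/1 matrix; row index = z1 grid value, column = z2 grid value;
1 = the pair is a protected dimorphism (mutually invasible at the cue
locus).

## sweep.csv (mode=sweep)
`m, rho, z1, z2, z_mono, converged, coexists` — equilibrium dimorphism per
grid cell (NaN z's = monomorphic outcome), the m/ρ-independent monomorphic
singular strategy, and whether the reported pair is protected.

## trajectory.csv (modes simulate/info; one row per cycle × habitat × allele)
| column | meaning |
|---|---|
| cycle | life-cycle index (0 = initial census) |
| habitat, allele | class labels (1-based) |
| n | class count |
| mean_z, sd_z | investment phenotype moments within the class |
| mean_a0, mean_ag | liability-parameter means within the class |
| replicate | replicate index |

## summary.csv (modes simulate/info; one row per replicate)
`mean_z_allele{1,2}` (final-epoch, count-weighted mean phenotype per cue
allele), `freq_allele{1,2}`, `final_mean_ag`.

## information.csv (mode=info; one row per replicate)
`mi_cue_bits` (cue-locus × habitat mutual information of the final census),
`mi_liability_bits` (binned-liability × habitat mutual information).

## population.tsv (fixtures)
`habitat, individual, cue_allele, ag` — miniature deterministic population.
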