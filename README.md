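# sisevol

Eco-evolutionary adaptive dynamics of **sex-specific immune defences** in a
diploid, sexually reproducing host with SIS (susceptible–infected–
susceptible) pathogen dynamics.

Why do males and females often differ in how they cope with infection?
Beyond physiology, life-history theory suggests the answer lies in
sex-specific selective pressures — but the benefit of immunity is not a
constant: it depends on how much infection is circulating, which in turn
depends on what both sexes evolve.  `sisevol` is a toolkit for exploring
exactly this feedback.  It is aimed at theoretical ecologists and
evolutionary epidemiologists who want to compute, rather than intuit, how
ecological feedbacks shape sexually dimorphic defence.

## The model

A host population carries two diploid loci with additive allelic effects:
one determines a trait x_f ∈ (0,1) expressed only in females, the other a
trait x_m expressed only in males.  Each trait buys immune defence at a
life-history cost under one of three trade-off models:

* **(i)** recovery rate γ ↑ with death rate d ↑ (resistance, constitutive cost),
* **(ii)** fecundity during infection φ ↑ with death rate d ↑ (tolerance, constitutive cost),
* **(iii)** recovery rate γ ↑ with fecundity during infection φ ↓ (resistance, facultative cost).

Ecology is a genotype-resolved SIS system with density-dependent (mass
action) transmission and density-dependent births limited by female
fecundity; males compete for paternity in proportion to their effective
reproductive weight (Bateman's principle):

    dS^i/dt = B_i/2 − d^i S^i − β S^i I + γ^i I^i
    dI^i/dt = β S^i I − (d^i + α + γ^i) I^i          (per sex, per genotype)

    B_i = b(1 − qN) Σ_{j,k} δ_{i,j,k} F_j M_k / Σ_u M_u

with Mendelian offspring proportions δ and free recombination.  The
invasion fitness of a rare mutant allele is the dominant eigenvalue of the
linearized dynamics of its heterozygote carriers at the resident's
ecological equilibrium; joint evolutionarily stable strategies
(x_f\*, x_m\*) are located by alternating best responses with a
selection-gradient polish, and certified against a fine mutant grid.
A brute-force module cross-validates every eigenvalue verdict by
simulating the full nonlinear polymorphic system.  See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

Find the joint ESS for the resistance model at the default parameters
(b=1, q=0.01, d₀=0.25, γ₀=2, β=0.2, α=0.75):

```
$ sisevol ess find --model i
{
  "status": "interior-ESS",
  "x_f_star": 0.3879573729963088,
  "x_m_star": 0.3879573735589293,
  "gamma_f": 1.2677462512556958,
  "gamma_m": 1.267746254259573,
  "phi_f": 1.0,
  "phi_m": 1.0,
  "d_f": 0.29429454344492195,
  "d_m": 0.29429454359615753,
  "prevalence_f": 0.18025886440264724,
  "prevalence_m": 0.1802588642009998,
  "N": 14.102261650618523,
  "certificate": -1.610659575324025e-06
}
```

With both sexes equally exposed and affected, the two loci evolve to the
same strategy (x_f\* = x_m\* ≈ 0.388): an ES recovery rate of ≈ 1.27 paid
for by a death rate of ≈ 0.294 (18 % above baseline).  At that strategy
the pathogen is endemic with 18 % prevalence in each sex, and no mutant on
a 101-point grid at either locus can invade (the `certificate` is the
largest mutant eigenvalue found — at or below neutrality).

Things change once the sexes differ.  Sweep male susceptibility with
female susceptibility fixed at its default:

```
$ sisevol ess sweep --model i --axis1 beta_m:0.2:3.0:8 --out sweep.csv
wrote 8 rows to sweep.csv
```

The `gamma_m` column rises from 1.27 to a maximum of ≈ 2.36 near
β_m ≈ 1.0 — where male prevalence crosses 50 % — and then falls to 1.39 by
β_m = 3.0, dropping *below* the female value: males so exposed that they
are reinfected as fast as they recover gain little from recovery and
evolve lower immunocompetence than females.

Other entry points: `sisevol repro fig2|fig3|fig4` regenerate the
symmetric sweeps and the (β_f, β_m) / (α_f, α_m) ESS surfaces as CSV
tables with run manifests; `sisevol oracle-check` cross-validates the
eigenvalue criterion against nonlinear rare-mutant simulations.  The same
functionality is available as a library (`sisevol.find_ess`,
`sisevol.sweep`, `sisevol.invasion_fitness`, ...).

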