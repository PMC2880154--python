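# Methods

## The model

`sisevol` studies the joint evolution of female- and male-limited immune
defences in a diploid, sexually reproducing host exposed to a directly
transmitted pathogen.

### Ecology

Hosts of each genotype *i* and sex are tracked as susceptible and infected
densities (S_f^i, I_f^i, S_m^i, I_m^i) obeying
susceptible–infected–susceptible (SIS) dynamics:

    dS_f^i/dt = B_i/2 − d_f^i S_f^i − β_f S_f^i I + γ_f^i I_f^i
    dI_f^i/dt = β_f S_f^i I − (d_f^i + α_f + γ_f^i) I_f^i

and symmetrically for males, with I = Σ_j (I_f^j + I_m^j).  Transmission is
density dependent (mass action) and infectivity is independent of the sex
and genotype of the infected host; recovery confers no immunity; virulence
α adds mortality while infected.  Susceptibility β and virulence α are
sex-specific but genotype-independent; death rate d, recovery γ and
relative fecundity during infection φ are sex- and genotype-specific.

### Reproduction

Births follow Bateman's principle.  The total birth rate is limited by
effective female density and by crowding,

    B_i = b (1 − qN) Σ_j Σ_k δ_{i,j,k} F_j (M_k / Σ_u M_u),

where F_j = S_f^j + φ_f^j I_f^j is the effective fecund density of mothers
of genotype j, M_k = S_m^k + φ_m^k I_m^k is the effective reproductive
weight of fathers of genotype k (males compete for paternity shares, so
only their relative weight matters), and δ_{i,j,k} are Mendelian offspring
proportions for the cross (j, k) with free recombination between the two
loci.  The factor 1 − qN is clamped at zero above the crowding density
1/q, and offspring are split 1:1 between the sexes.  Two consequences used
as test oracles: total births never depend on male genotype composition,
and the disease-free carrying capacity K = (1 − 2 d_f/b)/q is set by
female mortality alone, the sexes splitting K in inverse proportion to
their death rates.

### Genetics

Both sexes carry two autosomal loci with additive allelic effects.  The
female locus determines a proxy trait x_f ∈ (0, 1) expressed in females
only; the male locus determines x_m expressed in males only (sex-limited
expression).  A heterozygote's trait is the mean of its two allele values.

### Trade-offs

A single trait per sex buys defence at a life-history cost:

| model | benefit (rises with x)         | cost                      | fixed     |
|-------|--------------------------------|---------------------------|-----------|
| (i)   | recovery γ = γ₀·x/(1−x)        | death d = d₀/(1−x²)       | φ = φ₀    |
| (ii)  | fecundity in infection φ = x   | death d = d₀/(1−x²)       | γ = γ₀    |
| (iii) | recovery γ = γ₀·√(2x)          | fecundity φ = 1 − x²      | d = d₀    |

Recovery is a form of *resistance* (it cuts the pathogen's infectious
period); maintained fecundity during infection is a form of *tolerance*.
Models (i) and (ii) pay a *constitutive* cost (shorter lifespan regardless
of infection status); model (iii) pays a *facultative* cost (reduced
fecundity only while infected).

The shapes are this package's choice, constrained by three requirements:
the stated monotonicity of each pair, reachability of the baseline values
γ₀ and d₀ (both Γ shapes are anchored so Γ(1/2) = γ₀), and a marginal cost
that accelerates in the benefit so that interior ESSs exist.  Model (iii)
deliberately uses a *saturating* benefit: with a facultative cost, both
the benefit and the cost of resistance scale with the force of infection,
and an unbounded accelerating benefit like γ₀·x/(1−x) makes additional
resistance asymptotically free — selection then drives the pathogen
extinct, after which the trait is neutral.  A saturating benefit with an
accelerating cost restores an interior optimum with the pathogen endemic.
All shapes are injectable callables on `TradeoffModel`, so alternative
families need no code change.

## Invasion fitness

A monomorphic resident (x_f, x_m) is equilibrated ecologically (4 ODEs).
A rare mutant allele at one locus initially resides almost exclusively in
heterozygotes at that locus; mutant homozygotes and double heterozygotes
are second order in rarity and excluded.  The four heterozygote classes
(S_f, I_f, S_m, I_m) grow linearly with operator

    J = births(het) ⊕ deaths ⊕ infection at the resident equilibrium,

where the linearized birth inflow is B_het = b(1−qN̄)[F_het/2 + F̄·M_het/(2M̄)]
— heterozygote mothers pass the mutant to half their offspring, and
heterozygote fathers claim paternity in proportion to their relative
effective weight, again transmitting to half.  The invasion fitness is the
dominant eigenvalue λ of this 4×4 operator; the mutant invades iff
λ > ε_neutral.  When mutant = resident the resident equilibrium state is an
exact null vector of J, so self-invasion is neutral to machine precision —
no calibration involved.

The `oracle` module validates the criterion without linearizing: it
integrates the full 12-equation three-genotype system from the resident
equilibrium perturbed by heterozygotes at allele frequency 10⁻⁶ and reads
the verdict off the slope of log mutant-allele frequency (final third of
the horizon, or the overall change when the run exits early after an
e³-fold move).  Randomized (resident, mutant, parameters) triples agree
with the eigenvalue sign in ≥98 % of cases outside the neutral band.

## ESS search

The joint ESS (x_f*, x_m*) is a strategy no rare mutant at either locus
can invade.  It is found as a fixed point of alternating best responses:

1. equilibrate the resident;
2. at each locus in turn, maximise λ over a 21-point candidate grid and
   refine the best cell with bounded Brent search (ties break toward the
   resident: if no mutant exceeds the neutral band the best response *is*
   the resident);
3. move the resident halfway toward the best response (damping 0.5 guards
   against overshoot cycles) until the undamped best response at both loci
   is within tol = 10⁻⁴ of the resident;
4. polish the fixed point by zeroing the selection gradient (central
   difference, step 5·10⁻⁴) with Brent root finding per locus — the
   gradient is far better conditioned than the argmax on the flat peak,
   and sharpens the fixed point to ~10⁻⁸;
5. certify: scan a 101-point mutant grid at both loci and record the
   maximum eigenvalue.  "interior-ESS" requires the certificate to be
   neutral-or-negative.

Reported statuses: `interior-ESS`, `boundary` (within 2·tol of the search
domain edge), `not-found` (iteration exhausted or certificate violated),
and `neutral` — the resident equilibrium is disease-free and the entire
mutant grid sits inside the neutral band, i.e. selection vanished with the
pathogen (this happens when host evolution or low β eradicates it; the
stall point carries no information).  Convergence stability can optionally
be checked by the sign of the selection gradient on either side of the
fixed point.  Multistart (centre plus four off-centre points) is available
to detect multiple singular strategies; none were found at the default
parameters.

## Parameters and study conditions

Defaults (arbitrary time/density units): b = 1, q = 0.01, d₀ = 0.25,
γ₀ = 2, β_f = β_m = 0.2, α_f = α_m = 0.75, φ₀ = 1, giving K = 50 and
R₀ = 10/3 for the baseline phenotype.  Sweep ranges bracket these
defaults: β ∈ [0.05, 0.4] and α ∈ [0.2, 2.0] for the figure-style
surfaces (8×8 reduced grids by default, configurable).  Directional
tests use joint-β sweeps over [0.1, 0.4], where the pathogen remains
endemic at the ESS for all three models (at β = 0.05 model (iii)
eradicates it and the search correctly reports `neutral`).  The male
recovery turning-point analysis sweeps β_m ∈ [0.2, 3.0] at β_f = 0.2: the
turning point sits deep in the male-biased regime under these trade-off
shapes, and the γ_m*-reversal below the female ESS value requires
male-to-female susceptibility ratios well above the ~4:1 that a coarser
trade-off family might need.

## Numerical choices

- Equilibria: chunked LSODA integration (rtol 10⁻⁹, atol 10⁻¹²) with a
  Newton polish on the derivative map once the residual is below 10⁻⁴;
  convergence declared at max |dX/dt| < 10⁻⁹; non-convergence is reported,
  never interpolated.
- Extinction threshold 10⁻⁸ density units; equilibrium states are clipped
  at zero (transients may brush the axes).
- Neutral band ε_neutral = 10⁻⁶ in eigenvalue units; ties count as
  non-invasion.
- Search domain [0.01, 0.99]: the trade-off shapes diverge (model i) or
  flatten (model iii) at the boundary and nothing of interest lives
  outside it.
- Oracle verdicts: |slope| < 10⁻⁴ per unit time is neutral; horizon 2000
  time units in 40 chunks with early exit after an e³-fold frequency
  change; initial mutant frequency 10⁻⁶ (runs at 5·10⁻⁷ give the same
  verdicts, confirming the linear regime).
- Everything is deterministic given the inputs; randomness appears only in
  randomized validation tests, which are seeded.

## Known limitations

- The ES tolerance of model (ii) declines monotonically with joint
  virulence here: tolerance restores fecundity but gives no protection
  against the disease-induced mortality that rises with α, so both factors
  of its marginal benefit (probability of being infected, value of
  fecundity while infected) fall as α grows, at every resident.  A
  rise-then-fall response to virulence in the tolerance model would
  require a mechanism outside this reconstruction.
- Best-response dynamics with damping converge to continuously stable
  strategies; a genuinely convergence-unstable singular point (repellor)
  would be reported as `not-found` rather than located.
- Mutual invasibility regions, evolutionary branching and
  trait-substitution sequences are out of scope; PIPs report sign maps
  only.
- Sweep resolutions are reduced (5–8 points per axis by default); turning
  points are located to grid resolution, not root-polished along the
  sweep axis.
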