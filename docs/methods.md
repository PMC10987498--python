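# Methods

## Scope

`grmdesign` simulates gene regulatory mechanisms (GRMs) on a 2D cell
grid and designs them automatically for a given target expression
pattern. A GRM is a directed network: two (or more) input morphogen
genes whose concentration fields are fixed exponential gradients,
optional intermediate genes, and reporter genes that are regulated but
regulate nothing. The designed object carries full mechanistic detail —
network topology, regulation signs and groupings, and all kinetic
constants — so it can be integrated as a PDE system, unlike
topology-only network inference.

## Regulation kinetics

Each regulation contributes a Hill term `t = (K·c)^η` with binding
constant `K ∈ [1, 100]` (1/concentration; the half-effect threshold is
`1/K`) and Hill coefficient `η ∈ [1, 10]` (sharpness; `η = 10` with
large `K` approximates a step response). Terms compose into a single
dimensionless strength

```
Dn = Π over all regulators (1 + t_i)
S  = Π over sufficient activators (1 + t_i) − 1     (S ≡ 1 if none)
P  = Π over necessary activators t_i                (P ≡ 1 if none)
N  = basal + S·P  if any activator exists, else basal
strength = N / Dn ∈ [0, 1]
```

The empty-group conventions (`S ≡ 1`, `P ≡ 1`) are forced by requiring
the general rule to reduce exactly to the six one- and two-regulator
special cases (single activation/inhibition, AND, OR, NOR, NIMPLY);
the test suite verifies this equivalence against independently
hand-coded forms of those cases at 1e-12 relative error. Inhibitors
only ever appear in the denominator (AND-style combination).

Numerically, `S` is accumulated incrementally (`s ← s·(1+t) + t`),
which reproduces the expanded polynomial (`t1·t2 + t1 + t2 + …`) with
only positive additions — no catastrophic cancellation for small
terms, which a literal `Π(1+t) − 1` would suffer. If the direct ratio
`N/Dn` overflows (only possible when many near-maximal terms stack),
the affected entries are recomputed with an algebraically identical
product of factors that each lie in [0, 1], so the result is finite
and correctly bounded for any non-negative inputs.

A gene's basal level is derived, not stored: 0 if it has at least one
activator, 1 otherwise (a constitutive promoter that inhibitors can
shut off). Inputs have no rate law at all.

## Simulation

- Domain: `w × h` cells (default 64×64), 0-based `(i, j)` with `i` the
  column and the origin at the top-left. The green input grades from
  the left (`d^i`), the red input from the top (`d^j`), `d = 0.93`;
  mirrored orientations support anti-parallel input pairs.
- Integration: explicit Euler, `x ← max(0, x + dt·(ρ·strength − λ·x))`,
  synchronous across genes, 100 steps with `dt = 1` by default, from
  zero initial concentrations for all non-input genes. The clamp at 0
  makes non-negativity unconditional (within the sampled parameter
  ranges, `dt·λ ≤ 1` already prevents undershoot except through float
  rounding).
- Diffusion constants are zero throughout (products confined to their
  cells), which makes every cell independent; the 5-point Laplacian
  with zero-flux mirror boundaries (the standard closed-tissue
  assumption) is implemented and used whenever a nonzero `D` is set.
- Equilibrium measure: `Δ` = per-gene maximum absolute concentration
  change per unit time at the final step, recorded for reporters by
  default (`delta_scope="all"` tightens this to every non-input gene).
  `Δ` is defined per unit time; with the default `dt = 1` this equals
  the per-step change.

Two precision paths share one code base. Direct simulation accumulates
concentrations in extended precision (`np.longdouble`) and returns
float64, so last-step changes — tiny differences between order-1
fields — match closed forms to ~1e-15 relative; in pure float64 a
single rounding of `λ·x` bounds that agreement near ~1e-11, which is
why the extended path is the default. The evolutionary search instead
passes `dtype=np.float64` (SIMD speed); its tolerances (`α` of order
0.1) are ~10 orders of magnitude above the difference between paths.
On platforms where `np.longdouble` is an alias of float64, only the
closed-form agreement of `Δ` degrades to the ~1e-11 floor.

The per-GRM simulation plan is compiled once: Hill terms of
regulations sourced by input genes are constant in time and are folded
into per-gene static partial products (computed on 1D row/column
profiles and broadcast), so each Euler step evaluates only the terms
of regulations sourced by dynamic genes; a gene with purely static
regulators gets a precomputed constant strength field.

## Fitness error

Both developed and target channels are blurred with a `k × k` box
kernel (`k` odd, default 5), compared per cell with tolerance band
`α` (default 0.1), averaged with `ln(1 + (·)⁺)`, and the equilibrium
excess `(Δ − β)⁺` (default `β = 10⁻³`) is added; multi-channel errors
are summed per channel, each reporter bound to one channel.

Blur normalization is a genuinely open design point: a literal
`(1/k)·J_k` kernel scales a constant image by `k`, which would make
larger kernels *stricter* — the opposite of their stated role as a
tolerance dial. The default therefore normalizes by the number of
in-domain kernel cells (constant-preserving, no boundary padding
bias); the literal variant is retained behind
`blur_normalization="literal"` for audits. The logarithm is natural;
the base only rescales nonzero errors and cannot affect the zero-error
condition. With area normalization the zero-error band is exact: any
developed pattern within `α` of the target pointwise (and settled
below `β`) scores exactly 0, because a blur that averages with weights
summing to 1 cannot amplify a bounded perturbation.

## Evolutionary search

Population: `islands × island_size` (defaults 32 × 64) random GRMs:
the fixed backbone (inputs + reporters), 0–3 random intermediates,
each permissible ordered gene pair carrying a regulation with
probability 0.3 (one regulation per ordered pair, as the kinetics
composes one term per regulator; intermediate self-loops allowed), and
every parameter uniform in its range: Hill coefficient (1,10), binding
constant (1,100), decay (0.1,1), production (0,0.1); input production
is fixed at 0.

Per generation and island, individuals are paired by a random perfect
matching. With probability 0.75 a pair crosses over — the parents'
intermediate genes, each carrying its incoming regulations and
untouched parameters, are distributed uniformly between two children,
while each child keeps its like-indexed parent's input/reporter copies
and the regulations targeting them; regulations whose source gene
ended up in the other child are dropped (the minimal rule that
preserves validity without inventing rewiring). Name collisions from
shared-lineage parents are disambiguated deterministically. Otherwise
the children are clones. Mutation then redraws each kinetic parameter
independently with probability 0.01 and fires at most one structural
event per category per offspring: link addition (p = 0.01), de-novo
intermediate gene with one random incoming and one outgoing link
(p = 0.01), link deletion (p = 0.075), intermediate deletion with its
incident links (p = 0.075). Inputs and reporters are never removed.
The deletion rates deliberately exceed the addition rates to bias the
search toward simple mechanisms (anti-bloat). Per-offspring structural
granularity keeps the expected topology change small; the per-category
rates are the printed ones.

Selection is deterministic crowding: each child competes against its
genotypically closest parent — distance = symmetric difference of
ordered regulation pairs plus symmetric difference of gene-name sets,
a cheap deterministic metric chosen because "closest" needs one —
under the pairing minimizing total distance (ties keep the identity
pairing). A child replaces its parent iff its error is equal or
better, with exact error ties resolved toward lower complexity. The
tie rule complements the deletion-biased mutation as anti-bloat:
exactly-neutral complexifications — dead-end subgraphs, or regulations
whose Hill term underflows to zero — would otherwise ratchet into the
population and multiply simulation cost. A variant accepting
equal-error children unconditionally (pure neutral drift) was
evaluated on the square design task: it let the population bloat
severalfold within a few hundred generations without descending to
any better optimum, so the stricter tie stands. Between zero-error
individuals the same rule makes the post-convergence phase actively
simplify, giving the 250-generation stop window something to measure.
Islands are randomly
paired and their members repartitioned every 250 generations. The run
stops once a zero-error mechanism exists and its complexity (links +
3 × genes, all nodes counted — inputs included for monotonicity; only
consistency matters, no absolute complexity value is asserted
anywhere) has not decreased for `stop_window` generations, or at the
generation cap, returning the simplest zero-error mechanism (or the
best-error one, flagged non-converged).

Every stochastic choice draws from per-island RNG streams spawned from
one seed, so runs are exactly reproducible; evaluation is sequential
(per-island streams would keep a parallel evaluation path
order-independent, but none is implemented). Candidates are evaluated
on their reporter-ancestor subgraph: genes with no regulatory path to
a reporter cannot influence the reporter fields or their equilibrium
measure, so pruning them is exact, and it substantially cuts the cost
of scoring bloated candidates. A candidate whose simulation produces a
non-finite error is assigned worst fitness and logged.

## Fixture generator

Targets are generated programmatically: square, circle, triangle,
diamond, stripes, checkerboard, linear gradients, and glyphs rendered
from small embedded bitmaps (not fonts, for determinism). Shapes are
binary rasters at configurable foreground/background levels; the
generator refuses geometry that does not fit the domain. A synthetic
gap-gene-like fixture provides anti-parallel exponential inputs
(anterior/posterior) and four smooth, mutually exclusive
anterior-posterior bands bound to four reporters. It emulates only the
qualitative geometry of the gap-gene layout — it is not measured
expression data, and results on it say nothing about fitting real
embryo concentrations; it exists to exercise the multi-channel
pipeline (anti-parallel inputs, per-channel Δ, summed errors).

## Problem sizes used in the checks, and what desk scale can reach

The full-scale searches this method targets (32 × 64 populations run
for thousands of generations) are cluster-scale computations of order
10⁷–10⁸ candidate evaluations. The package's own end-to-end checks run
scaled-down designs chosen to finish on one CPU: the square target on
the full 64×64 domain with 4 islands × 32 individuals at the forgiving
tolerance (`k = 7, α = 0.25`, a 2000-generation cap ≈ 2.6 × 10⁵
evaluations), and the gene-cap study on a 32×32 diamond with the same
population over 800 generations and caps {3, 5, 8}.

What that budget reaches depends strongly on the target's fitness
landscape. Targets matchable by stepwise single-link improvement — the
linear gradient is the clean example, where one soft input inhibition
of the reporter already scores zero — are designed within a few
hundred generations (the linear-gradient design test demonstrates the
loop end to end). Targets that need a multi-gene assembly (the
square needs a 4-gene, 5-link mechanism: two sharp input repressions
for the high-morphogen edges plus an input-AND intermediate for the
low-morphogen edges; such zero-error parameterizations exist and are
verified directly in the test suite) expose a deep local optimum at
desk scale: a *uniform* reporter level equal to the tolerance α puts
the entire background inside the tolerance band, and no single
regulation added to that mechanism improves the error — every partial
assembly of the square machinery scores worse until nearly complete.
Scaled-down populations converge onto this "optimal uniform gray"
(error ≈ 0.082 for the square, ≈ 0.030 for the 32×32 diamond) and stay
there; by the same token the gene-number cap stops mattering, since
intermediate genes never engage. Ironically the *more forgiving*
tolerance deepens this trap — the band that is meant to simplify
designs also rewards featureless patterns. The full-scale budget
escapes it by brute parallel diversity, roughly two orders of
magnitude more lineages and generations than a desk run; the
corresponding end-to-end design checks in the test suite therefore
document the scaled-down behaviour (convergence for
stepwise-reachable targets, the uniform plateau for multi-gene ones)
rather than full-scale convergence.

## Known limitations

- Explicit Euler with fixed `dt`; no implicit or adaptive integration.
  With the sampled ranges (`λ ≤ 1`, `dt = 1`) the scheme is stable,
  but user-supplied `λ·dt > 2` would oscillate.
- Two-dimensional domains only; no diffusible intermediates, hence no
  self-organized (Turing-type) patterning — spatial information enters
  only through the input gradients.
- The search returns a single mechanism per run; it does not enumerate
  the set of distinct mechanisms producing the same pattern.
- Crossover name disambiguation appends a suffix; over very long runs
  names of frequently exchanged genes can grow (cosmetic only).
- The literal blur normalization is provided for fidelity audits but
  makes the zero-error band narrower than `α` near boundaries; the
  area normalization is the supported default.
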