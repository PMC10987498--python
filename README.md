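# grmdesign

Automatic design of **gene regulatory mechanisms (GRMs)** that develop a
target two-dimensional spatial expression pattern from two static
orthogonal morphogen gradients.

Synthetic developmental biology aims to engineer genetic circuits that
pattern a field of cells. Every cell in a rectangular tissue or culture
domain carries the same circuit and reads two positional signals: a
"red" morphogen graded from the top edge and a "green" morphogen graded
from the left edge (concentration `d**distance`, `d = 0.93`). The
circuit — input genes, optional intermediate genes, and one or more
non-regulating reporter genes — processes these signals through
Hill-equation kinetics so that the reporter's steady-state expression
draws a desired picture (a square, a circle, a glyph, a set of gap-gene
bands). `grmdesign` both **simulates** such mechanisms and
**designs** them automatically with an island-model evolutionary
algorithm that evolves the network topology and all kinetic parameters
until a zero-error mechanism is found.

## The model

Each gene `a` evolves per cell by

```
∂a/∂t = ρ_a · strength(regulators) − λ_a · a + D_a ∇²a
```

where the regulation strength ∈ [0, 1] composes the Hill terms
`t_i = (K_i c_i)^η_i` of its regulators:

```
strength = (β + [Π_suff(1+t_i) − 1] · Π_nec t_i) / Π_all(1+t_i)
```

Necessary activators combine as AND logic, sufficient activators as OR
logic, inhibitors multiply into the denominator, and the basal level β
is 1 for a gene with no activators (a constitutive promoter that can be
inhibited) and 0 otherwise. The system is integrated by explicit Euler
(100 steps, dt = 1) from zero initial concentrations; diffusion is zero
(products stay intracellular), so the inputs alone carry spatial
information.

A candidate mechanism is scored against the target `T` with a
blur-tolerant error: both the developed reporter pattern `D` and `T`
are box-blurred with a `k × k` kernel, compared per cell with a
tolerance band `α`, and penalized if the dynamics have not settled:

```
error = mean_cells ln(1 + (|ω*D − ω*T| − α)⁺) + (Δ_D − β_eq)⁺
```

Zero error is reachable by construction, and the triple `(k, α, β_eq)`
dials the trade-off between mechanism complexity and pattern fidelity.

The evolutionary search runs islands of candidates with crossover
(genes and their incoming links distributed between two children),
parameter/topology mutations biased toward deletion to prevent bloat,
deterministic crowding selection, periodic island shuffling, and a
stopping rule that waits for the zero-error mechanism's complexity
(links + 3 × genes) to stop decreasing.

## Worked example

Design a mechanism for a left-to-right linear expression gradient on
the default 64×64 domain:

```sh
grmdesign fixtures --shape linear_gradient --out gradient.pgm
grmdesign design --target gradient.pgm --out run/ \
    --islands 4 --pop 32 --k 5 --alpha 0.25 --generations 2000 --seed 1
```

which prints, for this seed:

```
converged: error 0.0, complexity 10, 632 generations
```

meaning the search found a mechanism whose blurred reporter pattern
lies within α = 0.25 of the blurred target at every cell and whose
dynamics have settled (Δ ≤ 10⁻³) — the zero-error condition — and then
spent 250 further generations failing to simplify it (the stopping
rule). Complexity 10 is 3 genes + 1 link: the designer discovered that
a single soft inhibition of the reporter by the left-sourced morphogen
(`green ⊣ blue`, η ≈ 1.4, K ≈ 3.2, reporter ρ/λ ≈ 0.82) already
develops a smooth left-low, right-high ramp within tolerance of the
linear target. `run/` then contains `best.json` (the mechanism),
`best.dot` (the network diagram), `history.csv` (per-generation best
error and complexity), `final_blue.pgm` (the developed pattern) and
`manifest.json` (exact config + seed for replay). Inspect any saved
mechanism with:

```sh
grmdesign simulate --grm run/best.json --out frames/
grmdesign score --grm run/best.json --target gradient.pgm --k 5 --alpha 0.25
```

Harder targets need more search: shapes whose edges are oblique to the
gradients (triangles, diamonds) or tight tolerances (`k=5, α=0.1`)
required populations of 32 × 64 over thousands of generations in the
original full-scale experiments, and desk-scale runs of this package
should be expected to deliver approximate (nonzero-error) mechanisms
for them; see `docs/methods.md` for the search dynamics and their
limitations.

The same machinery handles multi-reporter targets: the
`fixtures --shape gapgene` subcommand emits a synthetic four-channel
anterior-posterior banded fixture with anti-parallel input gradients,
emulating the layout of the *Drosophila* gap-gene system.

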