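"""Island-model evolutionary design of GRM topology and parameters.

A population of candidate GRMs is split into islands that evolve
independently and are randomly paired and reshuffled at a fixed period.
Each generation, every island partitions its members into random parent
pairs; each pair produces two children by crossover (genes and their
incoming regulations distributed randomly between the children, no
parameter changes) or cloning, followed by mutation (uniform parameter
redraws, link/gene additions, and — with a deliberately higher rate —
link/gene deletions to bias the search toward simple mechanisms).
Children are simulated, scored with the blur-tolerant pattern error, and
placed back by deterministic crowding: each child competes only against
its genotypically closest parent and replaces it when its error is equal
or better (error ties resolved toward lower complexity, which drives the
post-convergence simplification phase).

The run stops once a zero-error mechanism has been found and its
complexity has not decreased for ``stop_window`` further generations, or
at ``generation_cap``.  Every stochastic choice flows from one seed
through per-island RNG streams, so runs are exactly reproducible.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import grm as grm_mod
from .fitness import ErrorParams, TargetPattern, score_simulation
from .grm import (
    BIND_RANGE, DECAY_RANGE, HILL_RANGE, PRODUCTION_RANGE,
    GRM, GeneSpec, RegulationSpec, complexity, validate,
)
from .simulator import DomainGrid, simulate

__all__ = [
    "EAConfig", "Individual", "EvolutionState", "EvolutionResult",
    "NetworkTemplate", "default_template", "random_grm", "crossover",
    "mutate", "crowding_replace", "genotype_distance", "shuffle_islands",
    "check_stop", "evolve", "write_history",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EAConfig:
    """Meta-parameters of the evolutionary search.

    Defaults follow the full-scale search setup: 32 islands of 64
    individuals, crossover 75%, parameter mutation 1%, link/gene
    addition 1%, link/gene deletion 7.5%, island shuffling and the
    zero-error simplification window both every 250 generations.
    """

    islands: int = 32
    island_size: int = 64
    crossover_rate: float = 0.75
    param_mutation_rate: float = 0.01
    addition_rate: float = 0.01
    deletion_rate: float = 0.075
    shuffle_period: int = 250
    stop_window: int = 250
    generation_cap: int = 5000
    seed: int = 0
    hill_range: tuple[float, float] = HILL_RANGE
    bind_range: tuple[float, float] = BIND_RANGE
    decay_range: tuple[float, float] = DECAY_RANGE
    production_range: tuple[float, float] = PRODUCTION_RANGE
    max_genes: int | None = None
    allowed_hill_coeffs: tuple[float, ...] | None = None
    n_init_intermediates: int = 3
    link_prob: float = 0.3
    steps: int = 100
    dt: float = 1.0
    delta_scope: str = "reporters"

    def __post_init__(self):
        for name in ("crossover_rate", "param_mutation_rate",
                     "addition_rate", "deletion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.island_size % 2:
            raise ValueError("island_size must be even (parent pairing)")


@dataclass
class Individual:
    grm: GRM
    error: float
    complexity: int


@dataclass
class EvolutionState:
    islands: list[list[Individual]]
    generation: int = 0
    archive: Individual | None = None          # simplest zero-error GRM
    archive_generation: int = 0                # last complexity improvement
    best: Individual | None = None             # best-error individual


@dataclass
class EvolutionResult:
    best: Individual
    converged: bool
    generations: int
    history: list[tuple[int, float, int, int]]
    state: EvolutionState


@dataclass(frozen=True)
class NetworkTemplate:
    """The fixed backbone every candidate shares: input genes with their
    gradient orientations and reporter names bound to target channels."""

    inputs: tuple[GeneSpec, ...]
    reporter_names: tuple[str, ...]

    @property
    def n_fixed(self) -> int:
        return len(self.inputs) + len(self.reporter_names)


def default_template(n_reporters: int = 1, decay_base: float = 0.93) -> NetworkTemplate:
    """Two orthogonal inputs: red from the top, green from the left."""
    inputs = (
        GeneSpec("red", "input", orientation="from_top", gradient_decay=decay_base),
        GeneSpec("green", "input", orientation="from_left", gradient_decay=decay_base),
    )
    names = ("blue",) if n_reporters == 1 else tuple(
        f"reporter{i}" for i in range(n_reporters)
    )
    return NetworkTemplate(inputs=inputs, reporter_names=names)


# -- random construction -------------------------------------------------

def _uniform(rng, lo_hi):
    return float(rng.uniform(lo_hi[0], lo_hi[1]))


def _draw_hill(rng, config: EAConfig) -> float:
    if config.allowed_hill_coeffs:
        return float(rng.choice(np.asarray(config.allowed_hill_coeffs, float)))
    return _uniform(rng, config.hill_range)


def _random_regulation(source, target, rng, config) -> RegulationSpec:
    sign = "positive" if rng.random() < 0.5 else "negative"
    grouping = "necessary"
    if sign == "positive" and rng.random() < 0.5:
        grouping = "sufficient"
    return RegulationSpec(
        source=source, target=target, sign=sign, grouping=grouping,
        hill_coeff=_draw_hill(rng, config),
        bind_const=_uniform(rng, config.bind_range),
    )


def _fresh_name(rng) -> str:
    return f"g{int(rng.integers(1, 2**62))}"


def _permissible_pairs(grm: GRM) -> list[tuple[str, str]]:
    sources = [g.name for g in grm.genes if g.role != "reporter"]
    targets = [g.name for g in grm.genes if g.role != "input"]
    return [(s, t) for s in sources for t in targets]


def random_grm(
    config: EAConfig,
    rng: np.random.Generator,
    template: NetworkTemplate | None = None,
) -> GRM:
    """A random valid GRM: the fixed backbone, 0..n_init_intermediates
    intermediate genes, each permissible link present with probability
    ``link_prob``, all parameters uniform in their ranges."""
    template = template or default_template()
    genes = [replace(g) for g in template.inputs]
    bindings = {}
    for ch, name in enumerate(template.reporter_names):
        genes.append(GeneSpec(
            name, "reporter",
            production=_uniform(rng, config.production_range),
            decay=_uniform(rng, config.decay_range),
        ))
        bindings[name] = ch

    max_inter = config.n_init_intermediates
    if config.max_genes is not None:
        max_inter = min(max_inter, max(config.max_genes - template.n_fixed, 0))
    n_inter = int(rng.integers(0, max_inter + 1))
    for _ in range(n_inter):
        genes.append(GeneSpec(
            _fresh_name(rng), "intermediate",
            production=_uniform(rng, config.production_range),
            decay=_uniform(rng, config.decay_range),
        ))

    out = GRM(genes=genes, regulations=[], reporter_bindings=bindings)
    for s, t in _permissible_pairs(out):
        if rng.random() < config.link_prob:
            out.regulations.append(_random_regulation(s, t, rng, config))
    return out


# -- crossover -----------------------------------------------------------

def _dedup_name(name: str, taken: set[str], rng) -> str:
    # fresh short id: appending suffixes instead would grow names without
    # bound over generations of clone crossovers
    fresh = name
    while fresh in taken:
        if rng is None:
            fresh += "~"
        else:
            fresh = f"g{int(rng.integers(1, 2**62))}"
    return fresh


def _assemble_child(fixed_genes, fixed_regs, inter_entries, bindings,
                    rng=None) -> GRM:
    """Build one child from fixed-gene copies plus assigned intermediates
    (each with its incoming regulations); rename colliding intermediate
    names, then drop regulations with missing sources and duplicate
    (source, target) pairs."""
    genes = [replace(g) for g in fixed_genes]
    regs = [replace(r) for r in fixed_regs]
    taken = {g.name for g in genes}
    for gene, incoming in inter_entries:
        g = replace(gene)
        new_name = _dedup_name(g.name, taken, rng)
        for r in incoming:
            r2 = replace(r)
            r2.target = new_name
            if r.source == gene.name and new_name != gene.name:
                r2.source = new_name        # self-loop follows the rename
            regs.append(r2)
        g.name = new_name
        taken.add(new_name)
        genes.append(g)

    names = {g.name for g in genes}
    seen: set[tuple[str, str]] = set()
    kept = []
    for r in regs:
        if r.source not in names:
            continue
        if (r.source, r.target) in seen:
            continue
        seen.add((r.source, r.target))
        kept.append(r)
    return GRM(genes=genes, regulations=kept, reporter_bindings=dict(bindings))


def crossover(p1: GRM, p2: GRM, rng: np.random.Generator) -> tuple[GRM, GRM]:
    """Distribute the parents' intermediate genes (with their incoming
    regulations and unchanged parameters) randomly between two children.

    Each child keeps its like-indexed parent's input/reporter gene
    copies together with the regulations that target them; regulations
    whose source gene did not travel to the same child are dropped.
    """
    parents = (p1, p2)
    fixed_roles = ("input", "reporter")
    child_inter: tuple[list, list] = ([], [])
    for parent in parents:
        for gene in parent.intermediates:
            side = int(rng.integers(0, 2))
            incoming = [r for r in parent.regulations if r.target == gene.name]
            child_inter[side].append((gene, incoming))
    children = []
    for idx, parent in enumerate(parents):
        fixed_genes = [g for g in parent.genes if g.role in fixed_roles]
        fixed_names = {g.name for g in fixed_genes}
        fixed_regs = [r for r in parent.regulations if r.target in fixed_names]
        children.append(_assemble_child(
            fixed_genes, fixed_regs, child_inter[idx],
            parent.reporter_bindings, rng,
        ))
    return children[0], children[1]


# -- mutation ------------------------------------------------------------

def mutate(grm: GRM, config: EAConfig, rng: np.random.Generator) -> GRM:
    """Return a mutated copy: per-parameter uniform redraws, then at most
    one link addition, one de-novo gene addition, one link deletion and
    one intermediate-gene deletion, each gated by its own rate.  Inputs
    and reporters are never removed; the result is always valid."""
    out = grm.copy()
    p = config.param_mutation_rate

    for g in out.genes:
        if g.role == "input":
            continue
        if rng.random() < p:
            g.production = _uniform(rng, config.production_range)
        if rng.random() < p:
            g.decay = _uniform(rng, config.decay_range)
    for r in out.regulations:
        if rng.random() < p:
            r.hill_coeff = _draw_hill(rng, config)
        if rng.random() < p:
            r.bind_const = _uniform(rng, config.bind_range)

    # link addition
    if rng.random() < config.addition_rate:
        existing = {(r.source, r.target) for r in out.regulations}
        free = [pr for pr in _permissible_pairs(out) if pr not in existing]
        if free:
            s, t = free[int(rng.integers(len(free)))]
            out.regulations.append(_random_regulation(s, t, rng, config))

    # de-novo intermediate gene with one incoming and one outgoing link
    if rng.random() < config.addition_rate:
        if config.max_genes is None or len(out.genes) < config.max_genes:
            gene = GeneSpec(
                _fresh_name(rng), "intermediate",
                production=_uniform(rng, config.production_range),
                decay=_uniform(rng, config.decay_range),
            )
            out.genes.append(gene)
            sources = [g.name for g in out.genes if g.role != "reporter"]
            targets = [g.name for g in out.genes if g.role != "input"]
            src = sources[int(rng.integers(len(sources)))]
            out.regulations.append(
                _random_regulation(src, gene.name, rng, config))
            existing = {(r.source, r.target) for r in out.regulations}
            free_out = [t for t in targets if (gene.name, t) not in existing]
            if free_out:
                tgt = free_out[int(rng.integers(len(free_out)))]
                out.regulations.append(
                    _random_regulation(gene.name, tgt, rng, config))

    # link deletion
    if rng.random() < config.deletion_rate and out.regulations:
        del out.regulations[int(rng.integers(len(out.regulations)))]

    # intermediate-gene deletion (inputs and reporters are protected)
    if rng.random() < config.deletion_rate:
        inters = out.intermediates
        if inters:
            victim = inters[int(rng.integers(len(inters)))].name
            out.genes = [g for g in out.genes if g.name != victim]
            out.regulations = [
                r for r in out.regulations
                if r.source != victim and r.target != victim
            ]
    return out


# -- selection -----------------------------------------------------------

def genotype_distance(g1: GRM, g2: GRM) -> int:
    """Symmetric difference of ordered regulation pairs plus symmetric
    difference of gene-name sets."""
    e1 = {(r.source, r.target) for r in g1.regulations}
    e2 = {(r.source, r.target) for r in g2.regulations}
    n1 = set(g1.gene_names())
    n2 = set(g2.gene_names())
    return len(e1 ^ e2) + len(n1 ^ n2)


def _beats(child: Individual, parent: Individual) -> bool:
    """Equal-or-better replacement; exact error ties go to the simpler
    mechanism.

    The tie rule is the anti-bloat complement of the deletion-biased
    mutation: exactly-neutral complexifications (dead-end subgraphs,
    regulations whose Hill term underflows to zero) would otherwise
    ratchet into the population and inflate simulation cost without
    measurably widening the search (an unconditional equal-error
    acceptance variant was tried: it bloated the population several-fold
    and found no better optima).  Between zero-error individuals the
    same rule is what makes the post-convergence phase actively
    simplify."""
    if child.error < parent.error:
        return True
    return child.error == parent.error and child.complexity <= parent.complexity


def crowding_replace(
    parents: tuple[Individual, Individual],
    children: tuple[Individual, Individual],
) -> tuple[Individual, Individual]:
    """Deterministic crowding: pair children with their genotypically
    closest parents (minimum total distance, ties toward the identity
    pairing), then each child replaces its parent iff its error is equal
    or better (equal errors resolved toward lower complexity)."""
    p1, p2 = parents
    c1, c2 = children
    straight = (genotype_distance(c1.grm, p1.grm)
                + genotype_distance(c2.grm, p2.grm))
    crossed = (genotype_distance(c1.grm, p2.grm)
               + genotype_distance(c2.grm, p1.grm))
    if crossed < straight:
        s2 = c1 if _beats(c1, p2) else p2
        s1 = c2 if _beats(c2, p1) else p1
    else:
        s1 = c1 if _beats(c1, p1) else p1
        s2 = c2 if _beats(c2, p2) else p2
    return s1, s2


def shuffle_islands(
    islands: list[list[Individual]], rng: np.random.Generator
) -> list[list[Individual]]:
    """Randomly pair islands and repartition each pair's union into two
    equal islands; with an odd count the unpaired island is unchanged."""
    n = len(islands)
    order = list(rng.permutation(n))
    out: list[list[Individual] | None] = [None] * n
    k = 0
    while k + 1 < n:
        a, b = order[k], order[k + 1]
        union = islands[a] + islands[b]
        perm = rng.permutation(len(union))
        half = len(union) // 2
        out[a] = [union[i] for i in perm[:half]]
        out[b] = [union[i] for i in perm[half:]]
        k += 2
    if k < n:
        out[order[k]] = list(islands[order[k]])
    return out  # type: ignore[return-value]


def check_stop(state: EvolutionState, config: EAConfig) -> bool:
    """Stop once a zero-error GRM exists and its complexity has not
    decreased for ``stop_window`` generations, or at the generation cap."""
    if state.generation >= config.generation_cap:
        return True
    return (
        state.archive is not None
        and state.generation - state.archive_generation >= config.stop_window
    )


# -- the main loop -------------------------------------------------------

def _evaluation_subgraph(grm: GRM) -> GRM:
    """Restrict to genes with a regulatory path to a reporter (plus all
    inputs).  Genes outside this set cannot influence the reporter
    fields or their equilibrium measure, so the restriction is exact."""
    keep = {g.name for g in grm.reporters} | {g.name for g in grm.inputs}
    frontier = {g.name for g in grm.reporters}
    incoming: dict[str, list[str]] = {}
    for r in grm.regulations:
        incoming.setdefault(r.target, []).append(r.source)
    while frontier:
        nxt = set()
        for name in frontier:
            for src in incoming.get(name, ()):
                if src not in keep:
                    keep.add(src)
                    nxt.add(src)
        frontier = nxt
    if len(keep) == len(grm.genes):
        return grm
    return GRM(
        genes=[g for g in grm.genes if g.name in keep],
        regulations=[
            r for r in grm.regulations
            if r.source in keep and r.target in keep
        ],
        reporter_bindings=dict(grm.reporter_bindings),
    )


def _grm_equal(a: GRM, b: GRM) -> bool:
    """Structural and parametric identity (order-sensitive, exact)."""
    if len(a.genes) != len(b.genes) or len(a.regulations) != len(b.regulations):
        return False
    if a.reporter_bindings != b.reporter_bindings:
        return False
    for x, y in zip(a.genes, b.genes):
        if (x.name != y.name or x.role != y.role
                or x.production != y.production or x.decay != y.decay
                or x.diffusion != y.diffusion
                or x.orientation != y.orientation
                or x.gradient_decay != y.gradient_decay):
            return False
    for x, y in zip(a.regulations, b.regulations):
        if (x.source != y.source or x.target != y.target
                or x.sign != y.sign or x.grouping != y.grouping
                or x.hill_coeff != y.hill_coeff
                or x.bind_const != y.bind_const):
            return False
    return True


def _evaluate(grm, target, error_params, grid, config, input_overrides) -> Individual:
    # strict equilibrium mode scores every gene's delta, so nothing may
    # be pruned; the default reporter scope allows the exact restriction
    sub = grm if config.delta_scope == "all" else _evaluation_subgraph(grm)
    try:
        result = simulate(
            sub, grid, steps=config.steps, dt=config.dt,
            delta_scope=config.delta_scope, input_overrides=input_overrides,
            dtype=np.float64,
        )
        err = score_simulation(result, sub, target, error_params)
    except FloatingPointError as exc:      # pragma: no cover - defensive
        logger.warning("non-finite simulation, assigning worst fitness: %s", exc)
        err = math.inf
    if not math.isfinite(err):
        logger.warning("non-finite error for candidate, assigning worst fitness")
        err = math.inf
    return Individual(grm=grm, error=err, complexity=complexity(grm))


def _update_archive(state: EvolutionState) -> None:
    for island in state.islands:
        for ind in island:
            if state.best is None or ind.error < state.best.error or (
                ind.error == state.best.error
                and ind.complexity < state.best.complexity
            ):
                state.best = ind
            if ind.error == 0.0:
                if state.archive is None or ind.complexity < state.archive.complexity:
                    state.archive = ind
                    state.archive_generation = state.generation


def evolve(
    target: TargetPattern,
    error_params: ErrorParams,
    config: EAConfig,
    grid: DomainGrid | None = None,
    template: NetworkTemplate | None = None,
    input_overrides=None,
) -> EvolutionResult:
    """Design a GRM for ``target`` by island-model evolutionary search.

    Returns the simplest zero-error mechanism found (or the best-error
    one if the generation cap is hit first) along with the per-generation
    history of (generation, best error, best complexity, island of the
    best individual).
    """
    h, w = target.shape
    grid = grid or DomainGrid(width=w, height=h)
    if grid.shape != target.shape:
        raise ValueError("target pattern does not match the grid")
    template = template or default_template(n_reporters=len(target.channels))

    seedseq = np.random.SeedSequence(config.seed)
    children = seedseq.spawn(config.islands + 1)
    island_rngs = [np.random.default_rng(s) for s in children[:config.islands]]
    master_rng = np.random.default_rng(children[-1])

    state = EvolutionState(islands=[])
    for i in range(config.islands):
        rng = island_rngs[i]
        state.islands.append([
            _evaluate(random_grm(config, rng, template), target, error_params,
                      grid, config, input_overrides)
            for _ in range(config.island_size)
        ])
    _update_archive(state)
    history = [_history_row(state)]

    while not check_stop(state, config):
        state.generation += 1
        for i, island in enumerate(state.islands):
            rng = island_rngs[i]
            perm = rng.permutation(config.island_size)
            for t in range(config.island_size // 2):
                a, b = int(perm[2 * t]), int(perm[2 * t + 1])
                pa, pb = island[a], island[b]
                if rng.random() < config.crossover_rate:
                    g1, g2 = crossover(pa.grm, pb.grm, rng)
                else:
                    g1, g2 = pa.grm.copy(), pb.grm.copy()
                g1 = mutate(g1, config, rng)
                g2 = mutate(g2, config, rng)
                # evaluation is deterministic, so an offspring identical
                # to a parent inherits its score without re-simulating
                if _grm_equal(g1, pa.grm):
                    ca = Individual(g1, pa.error, pa.complexity)
                elif _grm_equal(g1, pb.grm):
                    ca = Individual(g1, pb.error, pb.complexity)
                else:
                    ca = _evaluate(g1, target, error_params, grid, config,
                                   input_overrides)
                if _grm_equal(g2, pb.grm):
                    cb = Individual(g2, pb.error, pb.complexity)
                elif _grm_equal(g2, pa.grm):
                    cb = Individual(g2, pa.error, pa.complexity)
                else:
                    cb = _evaluate(g2, target, error_params, grid, config,
                                   input_overrides)
                island[a], island[b] = crowding_replace((pa, pb), (ca, cb))
        _update_archive(state)
        history.append(_history_row(state))
        if state.generation % 100 == 0:
            gen, err, cplx, _ = history[-1]
            logger.info("generation %d: best error %.6g, complexity %d",
                        gen, err, cplx)
        if (
            config.shuffle_period
            and state.generation % config.shuffle_period == 0
            and not check_stop(state, config)
        ):
            state.islands = shuffle_islands(state.islands, master_rng)

    best = state.archive if state.archive is not None else state.best
    return EvolutionResult(
        best=best,
        converged=state.archive is not None,
        generations=state.generation,
        history=history,
        state=state,
    )


def _history_row(state: EvolutionState) -> tuple[int, float, int, int]:
    best_isl, best = 0, None
    for i, island in enumerate(state.islands):
        for ind in island:
            if best is None or ind.error < best.error or (
                ind.error == best.error and ind.complexity < best.complexity
            ):
                best, best_isl = ind, i
    return (state.generation, best.error, best.complexity, best_isl)


def write_history(path, history: Sequence[tuple[int, float, int, int]]) -> None:
    """Per-generation run log as CSV."""
    with open(path, "w") as fh:
        fh.write("generation,best_error,best_complexity,island\n")
        for gen, err, cplx, isl in history:
            fh.write(f"{gen},{err!r},{cplx},{isl}\n")


# -- checkpointing -------------------------------------------------------

def save_checkpoint(path, state: EvolutionState) -> None:
    doc = {
        "generation": state.generation,
        "archive_generation": state.archive_generation,
        "islands": [
            [
                {"grm": grm_mod.serialize(ind.grm), "error": ind.error,
                 "complexity": ind.complexity}
                for ind in island
            ]
            for island in state.islands
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_checkpoint(path) -> EvolutionState:
    with open(path) as fh:
        doc = json.load(fh)
    islands = [
        [
            Individual(
                grm=grm_mod.deserialize(d["grm"]),
                error=float(d["error"]),
                complexity=int(d["complexity"]),
            )
            for d in island
        ]
        for island in doc["islands"]
    ]
    state = EvolutionState(
        islands=islands,
        generation=int(doc["generation"]),
        archive_generation=int(doc["archive_generation"]),
    )
    _update_archive(state)
    return state
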