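import collections

import numpy as np
import pytest

from grmdesign import (
    EAConfig,
    ErrorParams,
    GeneSpec,
    Individual,
    RegulationSpec,
    check_stop,
    complexity,
    crossover,
    crowding_replace,
    default_template,
    evolve,
    genotype_distance,
    mutate,
    random_grm,
    shuffle_islands,
    validate,
)
from grmdesign.evolution import EvolutionState, load_checkpoint, save_checkpoint
from grmdesign.fixtures import ShapeSpec, render_target
from conftest import make_backbone


SMALL = EAConfig(islands=2, island_size=8, seed=7, generation_cap=5,
                 stop_window=0)


def small_target():
    return render_target(ShapeSpec("square", width=12, height=12, size=6))


class TestRandomGrm:
    def test_seeded_calls_are_identical(self):
        g1 = random_grm(SMALL, np.random.default_rng(5))
        g2 = random_grm(SMALL, np.random.default_rng(5))
        from grmdesign import serialize
        assert serialize(g1) == serialize(g2)

    def test_always_valid(self, rng):
        for _ in range(50):
            assert validate(random_grm(SMALL, rng)) == []

    def test_max_genes_three_forces_no_intermediates(self, rng):
        cfg = EAConfig(islands=2, island_size=8, seed=0, max_genes=3)
        for _ in range(20):
            g = random_grm(cfg, rng)
            assert g.intermediates == []

    def test_parameters_within_ranges(self, rng):
        for _ in range(30):
            g = random_grm(SMALL, rng)
            for r in g.regulations:
                assert 1 <= r.hill_coeff <= 10
                assert 1 <= r.bind_const <= 100
            for gene in g.genes:
                if gene.role != "input":
                    assert 0 <= gene.production <= 0.1
                    assert 0.1 <= gene.decay <= 1

    def test_allowed_hill_set_respected(self, rng):
        cfg = EAConfig(islands=2, island_size=8, seed=0,
                       allowed_hill_coeffs=(1, 2, 4, 8, 10))
        for _ in range(20):
            g = random_grm(cfg, rng)
            for r in g.regulations:
                assert r.hill_coeff in (1, 2, 4, 8, 10)


class TestCrossover:
    def test_intermediate_multiset_is_conserved(self, rng):
        for _ in range(25):
            p1 = random_grm(SMALL, rng)
            p2 = random_grm(SMALL, rng)
            c1, c2 = crossover(p1, p2, rng)
            before = collections.Counter(
                g.name for g in p1.intermediates + p2.intermediates)
            after = collections.Counter(
                g.name for g in c1.intermediates + c2.intermediates)
            assert before == after
            assert validate(c1) == [] and validate(c2) == []

    def test_no_intermediates_children_equal_parents(self, rng):
        p1 = make_backbone(production=0.05, decay=0.3)
        p1.regulations = [
            RegulationSpec("red", "blue", "negative", hill_coeff=2, bind_const=5)]
        p2 = make_backbone(production=0.09, decay=0.8)
        c1, c2 = crossover(p1, p2, rng)
        from grmdesign import serialize
        assert serialize(c1) == serialize(p1)
        assert serialize(c2) == serialize(p2)

    def test_dangling_source_links_are_dropped(self):
        # Child receives p1's a and b (with a->b) and p2's copy of b
        # (with c->b); c stayed with the other child, so its outgoing
        # link cannot resolve and is dropped.  The colliding name is
        # renamed deterministically.
        from grmdesign.evolution import _assemble_child

        p1 = make_backbone()
        a = GeneSpec("a", "intermediate", 0.05, 0.5)
        b1 = GeneSpec("b", "intermediate", 0.05, 0.5)
        a_to_b = RegulationSpec("a", "b", "positive", "necessary", 2, 5)
        p2_b = GeneSpec("b", "intermediate", 0.07, 0.6)
        c_to_b = RegulationSpec("c", "b", "positive", "necessary", 3, 7)

        fixed = [g for g in p1.genes if g.role != "intermediate"]
        child = _assemble_child(
            fixed, [],
            [(a, []), (b1, [a_to_b]), (p2_b, [c_to_b])],
            p1.reporter_bindings,
        )
        edges = {(r.source, r.target) for r in child.regulations}
        assert ("a", "b") in edges                    # source travelled along
        assert not any(s == "c" for s, _ in edges)    # dangling source dropped
        assert {g.name for g in child.intermediates} == {"a", "b", "b~"}
        assert validate(child) == []

    def test_crossover_never_alters_parameters(self, rng):
        p1 = random_grm(SMALL, rng)
        p2 = random_grm(SMALL, rng)
        params_before = {
            (r.source, r.target): (r.hill_coeff, r.bind_const)
            for g in (p1, p2) for r in g.regulations
        }
        c1, c2 = crossover(p1, p2, rng)
        for child in (c1, c2):
            for r in child.regulations:
                key = (r.source.rstrip("~"), r.target.rstrip("~"))
                if key in params_before:
                    assert (r.hill_coeff, r.bind_const) == params_before[key]


class TestMutate:
    def test_zero_rates_is_identity(self, rng):
        cfg = EAConfig(islands=2, island_size=8, seed=0,
                       param_mutation_rate=0, addition_rate=0, deletion_rate=0)
        g = random_grm(SMALL, rng)
        from grmdesign import serialize
        assert serialize(mutate(g, cfg, rng)) == serialize(g)

    def test_parameter_redraws_stay_in_ranges(self, rng):
        cfg = EAConfig(islands=2, island_size=8, seed=0,
                       param_mutation_rate=1.0, addition_rate=0,
                       deletion_rate=0)
        g = random_grm(SMALL, rng)
        seen = 0
        for _ in range(1200):
            g = mutate(g, cfg, rng)
            for r in g.regulations:
                assert 1 <= r.hill_coeff <= 10
                assert 1 <= r.bind_const <= 100
                seen += 2
            for gene in g.genes:
                if gene.role != "input":
                    assert 0 <= gene.production <= 0.1
                    assert 0.1 <= gene.decay <= 1
                    seen += 2
        assert seen >= 10_000

    def test_protected_genes_survive_heavy_deletion(self, rng):
        cfg = EAConfig(islands=2, island_size=8, seed=0,
                       param_mutation_rate=0, addition_rate=0,
                       deletion_rate=1.0)
        g = random_grm(SMALL, rng)
        for _ in range(30):
            g = mutate(g, cfg, rng)
            assert {x.name for x in g.inputs} == {"red", "green"}
            assert [x.name for x in g.reporters] == ["blue"]
            assert validate(g) == []
        assert g.intermediates == [] and g.regulations == []

    def test_max_genes_cap_respected(self, rng):
        cfg = EAConfig(islands=2, island_size=8, seed=0,
                       addition_rate=1.0, deletion_rate=0, max_genes=5)
        g = random_grm(cfg, rng)
        for _ in range(50):
            g = mutate(g, cfg, rng)
            assert len(g.genes) <= 5
            assert validate(g) == []


class TestCrowding:
    def _ind(self, grm, error, cplx=None):
        return Individual(grm, error, cplx if cplx is not None else complexity(grm))

    def test_better_child_replaces_closest_parent(self, rng):
        p = random_grm(SMALL, rng)
        q = random_grm(SMALL, rng)
        child_of_p = mutate(p, SMALL, rng)
        s1, s2 = crowding_replace(
            (self._ind(p, 1.0), self._ind(q, 1.0)),
            (self._ind(child_of_p, 0.5), self._ind(q.copy(), 2.0)),
        )
        assert s1.error == 0.5          # child paired with p, better
        assert s2.error == 1.0          # other child worse, q survives

    def test_both_children_worse_parents_survive(self, rng):
        p, q = random_grm(SMALL, rng), random_grm(SMALL, rng)
        pi, qi = self._ind(p, 0.1), self._ind(q, 0.2)
        s1, s2 = crowding_replace(
            (pi, qi), (self._ind(p.copy(), 0.5), self._ind(q.copy(), 0.6)))
        assert (s1, s2) == (pi, qi)

    def test_equal_error_simpler_child_wins(self, rng):
        p = random_grm(SMALL, rng)
        child = p.copy()
        if child.regulations:
            del child.regulations[0]
        pi = self._ind(p, 0.0)
        ci = self._ind(child, 0.0)
        assert ci.complexity < pi.complexity
        s1, _ = crowding_replace((pi, pi), (ci, ci))
        assert s1 is ci

    def test_equal_error_more_complex_child_loses(self, rng):
        # anti-bloat: exactly-neutral complexifications never ratchet in
        p = random_grm(SMALL, rng)
        child = p.copy()
        child.genes.append(GeneSpec("extra", "intermediate", 0.05, 0.5))
        pi, ci = self._ind(p, 0.3), self._ind(child, 0.3)
        s1, _ = crowding_replace((pi, pi), (ci, ci))
        assert s1 is pi

    def test_distance_metric(self, rng):
        g = random_grm(SMALL, rng)
        assert genotype_distance(g, g) == 0
        h = g.copy()
        h.genes.append(GeneSpec("zz", "intermediate", 0.05, 0.5))
        assert genotype_distance(g, h) == 1
        h.regulations.append(
            RegulationSpec("zz", "blue", "positive", "necessary", 2, 5))
        assert genotype_distance(g, h) == 2


class TestShuffleAndStop:
    def test_shuffle_conserves_population(self, rng):
        islands = [
            [Individual(random_grm(SMALL, rng), float(i * 10 + k), 9)
             for k in range(4)]
            for i in range(4)
        ]
        out = shuffle_islands(islands, rng)
        assert sorted(ind.error for isl in out for ind in isl) == sorted(
            ind.error for isl in islands for ind in isl)
        assert [len(isl) for isl in out] == [4, 4, 4, 4]

    def test_shuffle_deterministic(self, rng):
        islands = [
            [Individual(random_grm(SMALL, rng), float(k), 9) for k in range(4)]
            for _ in range(2)
        ]
        a = shuffle_islands(islands, np.random.default_rng(3))
        b = shuffle_islands(islands, np.random.default_rng(3))
        assert [[i.error for i in isl] for isl in a] == \
               [[i.error for i in isl] for isl in b]

    def test_single_island_is_noop(self, rng):
        islands = [[Individual(random_grm(SMALL, rng), 1.0, 9)]]
        out = shuffle_islands(islands, rng)
        assert out[0] == islands[0]

    def test_stop_window_logic(self, rng):
        g = random_grm(SMALL, rng)
        cfg = EAConfig(islands=2, island_size=8, seed=0, stop_window=250,
                       generation_cap=10_000)
        zero = Individual(g, 0.0, complexity(g))
        st = EvolutionState(islands=[], generation=500, archive=zero,
                            archive_generation=300)
        assert not check_stop(st, cfg)          # 200 < 250 since improvement
        st.generation = 550
        assert check_stop(st, cfg)              # window elapsed
        st.archive_generation = 400             # complexity dropped later
        assert not check_stop(st, cfg)          # window restarted
        st.archive = None
        st.generation = 10_000
        assert check_stop(st, cfg)              # cap reached


class TestEvolve:
    def test_history_best_error_non_increasing_and_reproducible(self):
        target = small_target()
        cfg = EAConfig(islands=2, island_size=8, seed=11, generation_cap=12,
                       stop_window=0, shuffle_period=5)
        params = ErrorParams(kernel_size=5, conc_tol=0.25)
        r1 = evolve(target, params, cfg)
        errs = [row[1] for row in r1.history]
        assert all(b <= a for a, b in zip(errs, errs[1:]))
        r2 = evolve(target, params, cfg)
        assert r1.history == r2.history

    def test_trivial_target_converges_at_generation_zero(self):
        # a constitutive reporter (rho/lambda = 1) within tolerance of an
        # all-ones target can be sampled in the initial population
        target = render_target(ShapeSpec(
            "square", width=8, height=8, size=8, center=(4, 4)))
        cfg = EAConfig(islands=4, island_size=16, seed=2, generation_cap=50,
                       stop_window=0)
        params = ErrorParams(kernel_size=3, conc_tol=0.35)
        res = evolve(target, params, cfg)
        assert res.converged
        assert res.best.error == 0.0

    def test_structural_closure_of_variation_cycles(self, rng):
        cfg = EAConfig(islands=2, island_size=8, seed=0)
        pool = [random_grm(cfg, rng) for _ in range(8)]
        for k in range(250):
            i, j = rng.integers(len(pool)), rng.integers(len(pool))
            c1, c2 = crossover(pool[i], pool[j], rng)
            c1, c2 = mutate(c1, cfg, rng), mutate(c2, cfg, rng)
            assert validate(c1) == [] and validate(c2) == []
            pool[i % len(pool)] = c1
            pool[j % len(pool)] = c2

    def test_gradient_target_designs_to_zero_error(self):
        """A linear expression gradient is reachable by stepwise search
        (a single soft input inhibition of the reporter suffices), so
        the full design loop finds a zero-error mechanism."""
        target = render_target(ShapeSpec("linear_gradient",
                                         axis="horizontal"))
        cfg = EAConfig(islands=4, island_size=32, seed=1,
                       generation_cap=2000, stop_window=0)
        params = ErrorParams(kernel_size=5, conc_tol=0.25)
        res = evolve(target, params, cfg)
        assert res.converged
        assert res.best.error == 0.0
        assert validate(res.best.grm) == []

    def test_multi_channel_gapgene_pipeline(self):
        from grmdesign.fixtures import gapgene_fixture, gapgene_template
        inputs, target = gapgene_fixture(width=20, height=10)
        cfg = EAConfig(islands=2, island_size=8, seed=4, generation_cap=3,
                       stop_window=0)
        params = ErrorParams(kernel_size=3, conc_tol=0.25)
        res = evolve(target, params, cfg, template=gapgene_template(),
                     input_overrides=inputs)
        assert res.best.error >= 0
        grm = res.best.grm
        assert {g.name for g in grm.inputs} == {"Bcd", "Cad"}
        assert set(grm.reporter_bindings) == {"Gt", "Hb", "Kni", "Kr"}
        assert validate(grm) == []

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = EAConfig(islands=2, island_size=4, seed=0)
        state = EvolutionState(
            islands=[
                [Individual(random_grm(cfg, rng), 0.5, 9) for _ in range(4)]
                for _ in range(2)
            ],
            generation=7,
            archive_generation=3,
        )
        p = tmp_path / "ckpt.json"
        save_checkpoint(p, state)
        back = load_checkpoint(p)
        assert back.generation == 7
        assert back.archive_generation == 3
        from grmdesign import serialize
        assert [[serialize(i.grm) for i in isl] for isl in back.islands] == \
               [[serialize(i.grm) for i in isl] for isl in state.islands]
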