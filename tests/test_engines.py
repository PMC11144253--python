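import itertools

import numpy as np
import pytest

from hypoge.engines import (
    DSGEGenotype,
    EvolutionConfig,
    Individual,
    InvalidIndividualError,
    SGEGenotype,
    crossover,
    decode_dsge,
    decode_ge,
    decode_sge,
    default_generations,
    evolve,
    mutate_integer_flip,
    random_sge_genotype,
    tournament_select,
)
from hypoge.grammar import compute_stats, parse_bnf, remove_recursion
from oracles import rewrite_decode_sge


def all_genotypes(stats):
    """Every genotype over the exact list lengths and value ranges."""
    nts = sorted(stats.max_references)
    spaces = [
        list(
            itertools.product(
                range(stats.production_count[nt]),
                repeat=stats.max_references[nt],
            )
        )
        for nt in nts
    ]
    for combo in itertools.product(*spaces):
        yield SGEGenotype({nt: list(vals) for nt, vals in zip(nts, combo)})


class TestDecodeGE:
    def test_modulus_rule_hand_trace(self):
        g = parse_bnf("<v> ::= x | y")
        assert decode_ge([5], g) == "y"  # 5 mod 2 = 1
        assert decode_ge([4], g) == "x"

    def test_single_production_grammar_ignores_codons(self):
        g = parse_bnf("<s> ::= a <v> b\n<v> ::= m")
        for codons in ([0], [7, 3], [123]):
            assert decode_ge(codons, g) == "amb"

    def test_codon_exhaustion_beyond_wraps_is_invalid(self):
        g = parse_bnf("<e> ::= <e> x | y")
        # all-zero codons always choose the recursive production
        with pytest.raises(InvalidIndividualError):
            decode_ge([0, 0], g, max_wraps=2)

    def test_agrees_with_sge_when_each_nonterminal_used_once(self):
        g = parse_bnf("<s> ::= <a> <b>\n<a> ::= p | q\n<b> ::= u | v | w")
        for a, b in itertools.product(range(2), range(3)):
            geno = SGEGenotype({"s": [0], "a": [a], "b": [b]})
            assert decode_sge(geno, g)[0] == decode_ge([0, a, b], g)


class TestDecodeSGE:
    def test_hand_traces(self):
        g = parse_bnf("<s> ::= <v> + <v>\n<v> ::= x | y")
        assert decode_sge(SGEGenotype({"s": [0], "v": [0, 1]}), g)[0] == "x+y"
        assert decode_sge(SGEGenotype({"s": [0], "v": [1, 1]}), g)[0] == "y+y"

    def test_decoding_is_deterministic(self):
        g = parse_bnf("<s> ::= <v> + <v>\n<v> ::= x | y")
        geno = SGEGenotype({"s": [0], "v": [1, 0]})
        assert decode_sge(geno, g) == decode_sge(geno, g)

    def test_out_of_range_gene_rejected(self):
        g = parse_bnf("<v> ::= x | y")
        with pytest.raises(InvalidIndividualError, match="out of range"):
            decode_sge(SGEGenotype({"v": [2]}), g)

    def test_matches_rewriting_interpreter_exhaustively(self, toy_grammars):
        for g in toy_grammars:
            stats = compute_stats(g)
            for geno in all_genotypes(stats):
                assert decode_sge(geno, g)[0] == rewrite_decode_sge(
                    geno.lists, g
                )

    def test_sized_genotypes_never_exhaust_lists(self, toy_grammars, rng):
        # genotypes sized by max_references always decode
        for g in toy_grammars:
            stats = compute_stats(g)
            for _ in range(200):
                geno = random_sge_genotype(stats, rng)
                phenotype, used = decode_sge(geno, g)
                assert phenotype
                for nt, n in used.items():
                    assert n <= stats.max_references[nt]


class TestDecodeDSGE:
    def test_empty_genotype_is_repaired_reproducibly(self):
        g = parse_bnf("<v> ::= x | y")
        out1 = decode_dsge(DSGEGenotype.empty(g), g, 3, np.random.default_rng(9))
        out2 = decode_dsge(DSGEGenotype.empty(g), g, 3, np.random.default_rng(9))
        assert out1[0] in ("x", "y")
        assert out1[0] == out2[0]
        assert out1[1].appended == {"v": [0]}

    def test_sufficient_genes_need_no_repair(self):
        g = parse_bnf("<s> ::= <v> + <v>\n<v> ::= x | y")
        geno = DSGEGenotype({"s": [0], "v": [1, 0]})
        phenotype, repaired, used = decode_dsge(
            geno, g, 5, np.random.default_rng(0)
        )
        assert phenotype == "y+x"
        assert repaired.appended == {}
        assert used == {"s": 1, "v": 2}

    def test_depth_cap_forces_shortest_completion(self):
        g = parse_bnf("<e> ::= <e> x | y")
        geno = DSGEGenotype({"e": [0] * 10})
        phenotype, repaired, _ = decode_dsge(geno, g, 3, np.random.default_rng(0))
        # recursion count never exceeds the cap: at most 3 'x' suffixes
        assert phenotype == "y" + "x" * 3
        # the forced escape was written back into the genotype
        assert repaired.lists["e"][3] == 1

    def test_termination_and_validity_on_fuzzed_recursive_grammars(self, rng):
        from hypoge.grammar import recursive_nonterminals

        for trial in range(300):
            g = _random_recursive_grammar(rng)
            assert recursive_nonterminals(g)
            genes = {
                nt: [
                    int(rng.integers(len(g.rules[nt])))
                    for _ in range(int(rng.integers(0, 6)))
                ]
                for nt in g.rules
            }
            phenotype, repaired, used = decode_dsge(
                DSGEGenotype(genes), g, 5, rng
            )
            assert isinstance(phenotype, str) and phenotype
            for nt, positions in repaired.appended.items():
                assert all(p < len(repaired.lists[nt]) for p in positions)


def _random_recursive_grammar(rng) -> "Grammar":
    n = int(rng.integers(2, 5))
    names = [f"r{i}" for i in range(n)]
    lines = []
    for i, name in enumerate(names):
        prods = [str(rng.choice(list("abc")))]  # guaranteed terminal escape
        for _ in range(int(rng.integers(1, 3))):
            toks = []
            for _ in range(int(rng.integers(1, 4))):
                if rng.random() < 0.5:
                    toks.append(f"<{names[int(rng.integers(n))]}>")
                else:
                    toks.append(str(rng.choice(list("abcxyz"))))
            prods.append(" ".join(toks))
        lines.append(f"<{name}> ::= " + " | ".join(prods))
    # force at least one self-loop so the grammar is recursive
    lines[0] += f" | <{names[0]}> z"
    return parse_bnf("\n".join(lines))


class TestVariation:
    def setup_method(self):
        self.g = parse_bnf("<s> ::= <v> + <v> | <v>\n<v> ::= x | y | z")
        self.stats = compute_stats(self.g)

    def _individual(self, rng):
        geno = random_sge_genotype(self.stats, rng)
        phenotype, used = decode_sge(geno, self.g)
        return Individual(geno, phenotype, 0.5, used)

    def test_mutation_probability_boundaries(self, rng):
        ind = self._individual(rng)
        same = mutate_integer_flip(ind, 0.0, self.g, rng)
        assert same.genotype.lists == ind.genotype.lists
        flipped = mutate_integer_flip(ind, 1.0, self.g, rng)
        for nt, genes in flipped.genotype.lists.items():
            assert all(0 <= v < self.stats.production_count[nt] for v in genes)

    def test_mutation_rate_matches_binomial_expectation(self, rng):
        p = 0.05
        trials, flips, total = 2000, 0, 0
        for _ in range(trials):
            ind = self._individual(rng)
            out = mutate_integer_flip(ind, p, self.g, rng)
            for nt in ind.genotype.lists:
                for a, b in zip(
                    ind.genotype.lists[nt], out.genotype.lists[nt]
                ):
                    total += 1
                    flips += a != b
        # a resampled gene keeps its old value 1/options of the time, so the
        # observable flip rate is p*(1 - 1/options), mixed over the gene pool
        n_s = self.stats.max_references["s"]
        n_v = self.stats.max_references["v"]
        exp_flip = (n_s * p * (1 - 1 / 2) + n_v * p * (1 - 1 / 3)) / (n_s + n_v)
        se = (exp_flip * (1 - exp_flip) / total) ** 0.5
        assert abs(flips / total - exp_flip) < 3 * se

    def test_crossover_boundaries_and_gene_conservation(self, rng):
        cfg = EvolutionConfig(algorithm="SGE", crossover_prob=1.0,
                              crossover_change_prob=0.0)
        a, b = self._individual(rng), self._individual(rng)
        ca, cb = crossover(a, b, cfg, rng)
        assert ca.genotype.lists == a.genotype.lists
        assert cb.genotype.lists == b.genotype.lists

        cfg_full = EvolutionConfig(algorithm="SGE", crossover_prob=1.0,
                                   crossover_change_prob=1.0)
        ca, cb = crossover(a, b, cfg_full, rng)
        assert ca.genotype.lists == b.genotype.lists
        assert cb.genotype.lists == a.genotype.lists

        cfg_half = EvolutionConfig(algorithm="SGE", crossover_prob=1.0,
                                   crossover_change_prob=0.5)
        for _ in range(50):
            a, b = self._individual(rng), self._individual(rng)
            ca, cb = crossover(a, b, cfg_half, rng)
            for nt in a.genotype.lists:
                parents = sorted(
                    [a.genotype.lists[nt], b.genotype.lists[nt]]
                )
                children = sorted(
                    [ca.genotype.lists[nt], cb.genotype.lists[nt]]
                )
                assert parents == children  # multiset conserved per nt

    def test_crossover_rejects_mismatched_parents(self, rng):
        other = parse_bnf("<q> ::= a | b")
        a = self._individual(rng)
        b = Individual(SGEGenotype({"q": [0]}), "a", 0.5, {"q": 1})
        with pytest.raises(ValueError, match="share grammar"):
            crossover(a, b, EvolutionConfig(algorithm="SGE"), rng)


class TestTournament:
    def test_population_of_one(self, rng):
        ind = Individual(SGEGenotype({}), "p", 0.3)
        assert tournament_select([ind], 2, rng) is ind

    def test_binary_tournament_win_probability(self, rng):
        # fitnesses {0.1, 0.9}: the better one wins 3 of the 4 draw pairs
        pop = [
            Individual(SGEGenotype({}), "a", 0.1),
            Individual(SGEGenotype({}), "b", 0.9),
        ]
        wins = sum(
            tournament_select(pop, 2, rng).fitness == 0.1 for _ in range(20000)
        )
        se = (0.75 * 0.25 / 20000) ** 0.5
        assert abs(wins / 20000 - 0.75) < 4 * se

    def test_full_pressure_favors_best(self, rng):
        pop = [Individual(SGEGenotype({}), str(i), f) for i, f in
               enumerate([0.2, 0.4, 0.6, 0.8])]
        counts = {0.2: 0, 0.4: 0, 0.6: 0, 0.8: 0}
        for _ in range(4000):
            counts[tournament_select(pop, 4, rng).fitness] += 1
        assert counts[0.2] >= max(counts[0.4], counts[0.6], counts[0.8])

    def test_unevaluated_individual_rejected(self, rng):
        pop = [Individual(SGEGenotype({}))]
        with pytest.raises(ValueError, match="unevaluated"):
            tournament_select(pop, 2, rng)


class TestEvolve:
    def test_zero_generations_returns_best_of_initial_population(
        self, planted_split, rule_grammar
    ):
        train, *_ = planted_split
        cfg = EvolutionConfig(algorithm="DSGE", population_size=15,
                              generations=0, seed=3)
        best, trace = evolve(train, rule_grammar, cfg)
        assert len(trace) == 1
        assert best.fitness == trace[0]

    def test_trace_is_non_increasing_and_reproducible(
        self, quick_evolved, planted_split, rule_grammar
    ):
        best, trace = quick_evolved
        assert all(b <= a for a, b in zip(trace, trace[1:]))
        train, *_ = planted_split
        cfg = EvolutionConfig(algorithm="DSGE", population_size=30,
                              generations=20, runs=1, seed=5)
        best2, trace2 = evolve(train, rule_grammar, cfg)
        assert trace2 == trace
        assert best2.phenotype == best.phenotype

    def test_sge_run_decodes_valid_individuals_throughout(
        self, planted_split, rule_grammar
    ):
        train, *_ = planted_split
        cfg = EvolutionConfig(algorithm="SGE", population_size=20,
                              generations=10, seed=2)
        best, trace = evolve(train, rule_grammar, cfg)
        assert best.phenotype
        assert all(b <= a for a, b in zip(trace, trace[1:]))

    def test_single_class_training_set_rejected(self, planted_split, rule_grammar):
        train, *_ = planted_split
        degenerate = train.subset(np.flatnonzero(train.y))
        cfg = EvolutionConfig(algorithm="DSGE", population_size=5, generations=1)
        with pytest.raises(ValueError, match="single-class"):
            evolve(degenerate, rule_grammar, cfg)

    def test_separable_training_set_reaches_zero_fitness(
        self, planted_split, rule_grammar
    ):
        # the planted concept is expressible, so fitness 0.0 is attainable;
        # expect most short runs to reach it
        train, *_ = planted_split
        hits = 0
        for run in range(5):
            cfg = EvolutionConfig(algorithm="DSGE", population_size=50,
                                  generations=100, seed=200 + run)
            best, _ = evolve(train, rule_grammar, cfg)
            hits += best.fitness == 0.0
        assert hits >= 4

    def test_default_generation_budget_by_horizon(self):
        assert default_generations(30) == 500
        assert default_generations(60) == 500
        assert default_generations(90) == 800
        assert default_generations(120) == 800
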