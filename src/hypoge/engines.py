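"""SGE and DSGE: genotypes, genotype->phenotype decoding, variation and the
evolution loop.

Both engines encode an individual as one integer list per nonterminal of
the grammar; each gene selects a production of its nonterminal, read in
leftmost depth-first derivation order.

SGE works on the recursion-removed grammar: every list has a fixed length
(the worst-case reference count of its nonterminal), so any gene vector is
a valid individual and unused tail genes are simply never read.

DSGE works on the original, possibly recursive grammar and grows lists on
demand: whenever decoding needs a gene that is not there, a uniformly
random valid one is appended (the repair genes are recorded on the returned
genotype).  Recursion is capped by a maximum derivation-tree depth; at the
cap, recursive nonterminals are forced onto their shortest terminal
completion and the forced index is written back into the genotype.

The loop is a generational elitist (mu + lambda) scheme: tournament
selection, per-nonterminal list-swap crossover, integer-flip mutation, and
replacement by the best ``population_size`` of parents plus offspring
(offspring preferred on fitness ties).  Fitness is 1 - WA of the decoded
rule on the training windows; lower is better, 0 is a perfect split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import metrics
from .expressions import RuleModel, parse_phenotype
from .grammar import (
    Grammar,
    GrammarStats,
    compute_stats,
    detokenize,
    recursive_nonterminals,
    remove_recursion,
    shortest_terminal_production,
)

__all__ = [
    "SGEGenotype",
    "DSGEGenotype",
    "Individual",
    "EvolutionConfig",
    "InvalidIndividualError",
    "decode_ge",
    "decode_sge",
    "decode_dsge",
    "random_sge_genotype",
    "mutate_integer_flip",
    "crossover",
    "tournament_select",
    "evolve",
    "dataset_fitness",
    "default_generations",
]

logger = logging.getLogger(__name__)


class InvalidIndividualError(ValueError):
    """A genotype that cannot be decoded (GE codon exhaustion, bad gene)."""


@dataclass
class SGEGenotype:
    """Fixed-length per-nonterminal expansion lists."""

    lists: dict[str, list[int]]

    def copy(self) -> "SGEGenotype":
        return SGEGenotype({nt: list(v) for nt, v in self.lists.items()})


@dataclass
class DSGEGenotype:
    """Growable per-nonterminal expansion lists.

    ``appended`` records, per nonterminal, the gene positions that were
    created by repair during the most recent decode.
    """

    lists: dict[str, list[int]]
    appended: dict[str, list[int]] = field(default_factory=dict)

    def copy(self) -> "DSGEGenotype":
        return DSGEGenotype(
            {nt: list(v) for nt, v in self.lists.items()},
            {nt: list(v) for nt, v in self.appended.items()},
        )

    @classmethod
    def empty(cls, g: Grammar) -> "DSGEGenotype":
        return cls({nt: [] for nt in g.rules})


@dataclass
class Individual:
    genotype: SGEGenotype | DSGEGenotype
    phenotype: str | None = None
    fitness: float | None = None
    # genes per nonterminal actually read during the last decode; mutation
    # of a DSGE individual only touches these.
    used: dict[str, int] | None = None

    def copy(self) -> "Individual":
        return Individual(
            genotype=self.genotype.copy(),
            phenotype=self.phenotype,
            fitness=self.fitness,
            used=dict(self.used) if self.used else None,
        )


@dataclass
class EvolutionConfig:
    """Hyperparameters of one evolutionary run.

    Defaults are the study settings: population 100, 500 generations for the
    30/60-minute horizons (800 for 90/120, see :func:`default_generations`),
    integer-flip mutation at 0.05, crossover at 0.7 with per-nonterminal
    change probability 0.6 (SGE, "structured") or 0.2 (DSGE, "uniform"),
    binary tournaments, recursive depth 3 and tree depth 7, 30 runs.
    """

    algorithm: str = "DSGE"  # "SGE" or "DSGE"
    population_size: int = 100
    generations: int = 500
    mutation_prob: float = 0.05
    crossover_prob: float = 0.7
    crossover_change_prob: float | None = None  # default depends on algorithm
    tournament_pressure: int = 2
    recursive_depth: int = 3
    tree_depth: int = 7
    runs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        self.algorithm = self.algorithm.upper()
        if self.algorithm not in ("SGE", "DSGE"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.crossover_change_prob is None:
            self.crossover_change_prob = 0.6 if self.algorithm == "SGE" else 0.2


def default_generations(ph: int) -> int:
    """Study generation budget per horizon: 500 for 30/60 min, 800 beyond."""
    return 500 if ph <= 60 else 800


# ---------------------------------------------------------------------------
# Decoders
# ---------------------------------------------------------------------------

def decode_ge(
    codon_list: Sequence[int], g: Grammar, max_wraps: int = 2
) -> str:
    """Classic GE decoding with the modulus rule; kept as a reference oracle.

    Leftmost depth-first expansion from the start symbol; each nonterminal
    consumes the next codon modulo its option count, wrapping around the
    codon list at most ``max_wraps`` times.
    """
    if len(codon_list) == 0:
        raise InvalidIndividualError("empty codon list")
    out: list[str] = []
    # explicit worklist of symbols to expand, leftmost first
    from .grammar import Symbol

    stack = [Symbol(g.start, is_terminal=False)]
    ptr = 0
    wraps = 0
    expansions = 0
    while stack:
        sym = stack.pop(0)
        if sym.is_terminal:
            out.append(sym.name)
            continue
        if ptr >= len(codon_list):
            wraps += 1
            if wraps > max_wraps:
                raise InvalidIndividualError(
                    f"codons exhausted after {max_wraps} wraps"
                )
            ptr = 0
        options = g.rules[sym.name]
        choice = codon_list[ptr] % len(options)
        ptr += 1
        expansions += 1
        if expansions > 100_000:
            raise InvalidIndividualError("derivation did not terminate")
        stack = list(options[choice].symbols) + stack
    return detokenize(out)


def decode_sge(geno: SGEGenotype, g: Grammar) -> tuple[str, dict[str, int]]:
    """Deterministic SGE decoding on a recursion-free grammar.

    Returns the phenotype string and the per-nonterminal count of genes
    actually consumed (unused tail genes are permitted).  Raises
    :class:`InvalidIndividualError` on an out-of-range or missing gene.
    """
    ptr = {nt: 0 for nt in g.rules}
    out: list[str] = []

    def expand(nt: str) -> None:
        i = ptr[nt]
        genes = geno.lists.get(nt, ())
        if i >= len(genes):
            raise InvalidIndividualError(
                f"genotype list for <{nt}> exhausted at index {i}"
            )
        gene = genes[i]
        ptr[nt] = i + 1
        options = g.rules[nt]
        if not (0 <= gene < len(options)):
            raise InvalidIndividualError(
                f"gene {gene} out of range for <{nt}> ({len(options)} options)"
            )
        for sym in options[gene]:
            if sym.is_terminal:
                out.append(sym.name)
            else:
                expand(sym.name)

    expand(g.start)
    return detokenize(out), {nt: n for nt, n in ptr.items() if n}


def decode_dsge(
    geno: DSGEGenotype,
    g: Grammar,
    tree_depth: int,
    rng: np.random.Generator,
) -> tuple[str, DSGEGenotype, dict[str, int]]:
    """DSGE decoding with on-demand repair and a derivation-depth cap.

    Always produces a valid phenotype.  Missing genes are appended uniformly
    at random and recorded in the returned genotype's ``appended`` map; when
    the derivation depth reaches ``tree_depth``, recursive nonterminals are
    forced onto their shortest terminal completion and the forced gene is
    written into the genotype.  Returns (phenotype, repaired genotype,
    per-nonterminal used-gene counts).
    """
    if tree_depth < 1:
        raise ValueError("tree_depth must be >= 1")
    recursive = recursive_nonterminals(g)
    lists = {nt: list(geno.lists.get(nt, [])) for nt in g.rules}
    appended: dict[str, list[int]] = {nt: [] for nt in g.rules}
    ptr = {nt: 0 for nt in g.rules}
    out: list[str] = []

    def expand(nt: str, depth: int) -> None:
        i = ptr[nt]
        ptr[nt] = i + 1
        options = g.rules[nt]
        if depth >= tree_depth and nt in recursive:
            choice = shortest_terminal_production(g, nt, rng)
            if i < len(lists[nt]):
                lists[nt][i] = choice  # overwrite: bloat control
            else:
                lists[nt].append(choice)
                appended[nt].append(i)
        elif i < len(lists[nt]):
            choice = lists[nt][i] % len(options)  # defensive re-ranging
            lists[nt][i] = choice
        else:
            choice = int(rng.integers(len(options)))
            lists[nt].append(choice)
            appended[nt].append(i)
        for sym in options[choice]:
            if sym.is_terminal:
                out.append(sym.name)
            else:
                expand(sym.name, depth + 1)

    expand(g.start, 0)
    repaired = DSGEGenotype(
        lists={nt: v for nt, v in lists.items()},
        appended={nt: v for nt, v in appended.items() if v},
    )
    return detokenize(out), repaired, {nt: n for nt, n in ptr.items() if n}


# ---------------------------------------------------------------------------
# Initialisation and variation
# ---------------------------------------------------------------------------

def random_sge_genotype(
    stats: GrammarStats, rng: np.random.Generator
) -> SGEGenotype:
    """Uniformly random fixed-length genotype sized by ``max_references``."""
    return SGEGenotype(
        {
            nt: [
                int(rng.integers(stats.production_count[nt]))
                for _ in range(stats.max_references[nt])
            ]
            for nt in stats.production_count
        }
    )


def mutate_integer_flip(
    ind: Individual,
    p: float,
    g: Grammar,
    rng: np.random.Generator,
) -> Individual:
    """Integer-flip mutation: each eligible gene is independently replaced,
    with probability ``p``, by a uniform random valid value.

    For SGE every gene is eligible; for DSGE only genes read during the last
    decode (``ind.used``) are — mutating never-read tail genes would be
    silent.  A DSGE individual with unknown usage (fresh from crossover)
    treats its whole lists as eligible: every gene in a dynamic genotype
    exists because some decode consumed it.
    """
    child = ind.copy()
    geno = child.genotype
    for nt, genes in geno.lists.items():
        n_options = g.production_count(nt)
        if n_options <= 0 or not genes:
            continue
        limit = len(genes)
        if isinstance(geno, DSGEGenotype) and ind.used is not None:
            limit = min(limit, ind.used.get(nt, 0))
        for i in range(limit):
            if rng.random() < p:
                genes[i] = int(rng.integers(n_options))
    child.phenotype = None
    child.fitness = None
    return child


def crossover(
    parent_a: Individual,
    parent_b: Individual,
    cfg: EvolutionConfig,
    rng: np.random.Generator,
) -> tuple[Individual, Individual]:
    """Per-nonterminal list-swap crossover.

    Applied with probability ``crossover_prob`` (else the children are
    copies).  For each nonterminal, with probability
    ``crossover_change_prob`` the parents' whole lists for that nonterminal
    are exchanged — the "structured" operator over fixed SGE lists and the
    "uniform" operator over growable DSGE lists are the same mask-based
    swap, differing only in the change probability.
    """
    ga, gb = parent_a.genotype, parent_b.genotype
    if type(ga) is not type(gb) or set(ga.lists) != set(gb.lists):
        raise ValueError("parents must share grammar and algorithm")
    child_a, child_b = parent_a.copy(), parent_b.copy()
    if rng.random() < cfg.crossover_prob:
        for nt in ga.lists:
            if rng.random() < cfg.crossover_change_prob:
                child_a.genotype.lists[nt], child_b.genotype.lists[nt] = (
                    child_b.genotype.lists[nt],
                    child_a.genotype.lists[nt],
                )
        for child in (child_a, child_b):
            child.phenotype = None
            child.fitness = None
            child.used = None
            if isinstance(child.genotype, DSGEGenotype):
                child.genotype.appended = {}
    return child_a, child_b


def tournament_select(
    pop: Sequence[Individual], pressure: int, rng: np.random.Generator
) -> Individual:
    """Draw ``pressure`` individuals with replacement; lowest fitness wins,
    ties broken uniformly at random among the drawn tied entrants."""
    if not pop:
        raise ValueError("empty population")
    draws = [pop[int(i)] for i in rng.integers(len(pop), size=pressure)]
    for ind in draws:
        if ind.fitness is None:
            raise ValueError("tournament over unevaluated individuals")
    best = min(ind.fitness for ind in draws)
    tied = [ind for ind in draws if ind.fitness == best]
    return tied[int(rng.integers(len(tied)))] if len(tied) > 1 else tied[0]


# ---------------------------------------------------------------------------
# Fitness and the evolution loop
# ---------------------------------------------------------------------------

def dataset_fitness(train) -> Callable[[str], float]:
    """Fitness closure over a labeled training set: 1 - WA of the rule.

    ``train`` is a :class:`~hypoge.glucodata.LabeledDataset` (or anything
    with ``arrays()`` and ``y``).
    """
    data = train.arrays()
    y = np.asarray(train.y, dtype=bool)
    if y.size == 0:
        raise ValueError("empty training set")
    if y.all() or not y.any():
        raise ValueError("single-class training set; balance the data first")

    def fitness(phenotype: str) -> float:
        model = parse_phenotype(phenotype)
        preds = model.predict(data)
        return metrics.confusion(y, preds).fitness

    return fitness


def evolve(
    train,
    g: Grammar,
    cfg: EvolutionConfig,
    fitness_fn: Callable[[str], float] | None = None,
) -> tuple[Individual, list[float]]:
    """Run one evolutionary search; returns (best individual, fitness trace).

    The trace holds the best fitness of the population after initialisation
    and after every generation; elitist replacement makes it non-increasing.
    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    if fitness_fn is None:
        fitness_fn = dataset_fitness(train)
    cache: dict[str, float] = {}

    def evaluated(ind: Individual) -> Individual:
        _decode(ind)
        if ind.phenotype not in cache:
            cache[ind.phenotype] = fitness_fn(ind.phenotype)
        ind.fitness = cache[ind.phenotype]
        return ind

    if cfg.algorithm == "SGE":
        flat = remove_recursion(g, cfg.recursive_depth)
        stats = compute_stats(flat)

        def _decode(ind: Individual) -> None:
            if ind.phenotype is None:
                ind.phenotype, ind.used = decode_sge(ind.genotype, flat)

        def _spawn() -> Individual:
            return Individual(random_sge_genotype(stats, rng))

        variation_grammar = flat
    else:

        def _decode(ind: Individual) -> None:
            if ind.phenotype is None:
                pheno, repaired, used = decode_dsge(
                    ind.genotype, g, cfg.tree_depth, rng
                )
                ind.phenotype = pheno
                ind.genotype = repaired
                ind.used = used

        def _spawn() -> Individual:
            return Individual(DSGEGenotype.empty(g))

        variation_grammar = g

    population = [evaluated(_spawn()) for _ in range(cfg.population_size)]
    best = min(population, key=lambda ind: ind.fitness)
    trace = [best.fitness]
    logger.info(
        "gen 0: best=%.4f mean=%.4f", trace[0],
        float(np.mean([i.fitness for i in population])),
    )

    for gen in range(1, cfg.generations + 1):
        offspring: list[Individual] = []
        while len(offspring) < cfg.population_size:
            pa = tournament_select(population, cfg.tournament_pressure, rng)
            pb = tournament_select(population, cfg.tournament_pressure, rng)
            ca, cb = crossover(pa, pb, cfg, rng)
            for child in (ca, cb):
                if len(offspring) >= cfg.population_size:
                    break
                child = mutate_integer_flip(
                    child, cfg.mutation_prob, variation_grammar, rng
                )
                offspring.append(evaluated(child))
        # mu+lambda truncation; offspring (origin=0) preferred on ties
        pool = [(ind.fitness, 0, k, ind) for k, ind in enumerate(offspring)]
        pool += [(ind.fitness, 1, k, ind) for k, ind in enumerate(population)]
        pool.sort(key=lambda t: (t[0], t[1], t[2]))
        population = [t[3] for t in pool[: cfg.population_size]]
        best = population[0] if population[0].fitness <= best.fitness else best
        trace.append(min(ind.fitness for ind in population))
        if gen % 50 == 0 or gen == cfg.generations:
            logger.info(
                "gen %d: best=%.4f mean=%.4f", gen, trace[-1],
                float(np.mean([i.fitness for i in population])),
            )
    best = min(population, key=lambda ind: ind.fitness)
    return best, trace
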