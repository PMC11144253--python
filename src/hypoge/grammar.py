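"""Context-free grammars in BNF and the structural transforms used by
structured grammatical evolution.

A grammar here is the usual BNF object: an ordered mapping from nonterminal
names to ordered lists of productions, with the first rule's head as the
start symbol.  Production order matters — it defines the integer expansion
indices that genotypes refer to.

Three transforms drive the evolutionary engines:

* :func:`remove_recursion` rewrites every recursive rule into depth-indexed
  copies up to a fixed recursive depth, yielding an acyclic grammar whose
  language is exactly the sub-language of the original derivable with at most
  that many nested recursive expansions.
* :func:`compute_stats` sizes SGE genotypes: for each nonterminal of an
  acyclic grammar it computes the maximum number of times the nonterminal can
  be expanded in any single complete derivation.
* :func:`shortest_terminal_production` picks, for a nonterminal, the
  production with the minimum derivation height to an all-terminal string —
  the completion DSGE forces once the tree-depth cap is reached.

Dialect: ``::=`` separates head and body, ``|`` (as a stand-alone token)
separates alternatives, tokens are whitespace separated, ``<name>`` tokens
are nonterminals and everything else is a terminal.  ``#`` starts a comment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "Symbol",
    "Production",
    "Grammar",
    "GrammarStats",
    "GrammarError",
    "parse_bnf",
    "render",
    "remove_recursion",
    "compute_stats",
    "shortest_terminal_production",
    "min_production_heights",
    "recursive_nonterminals",
    "detokenize",
]

_NONTERMINAL_RE = re.compile(r"^<([^<>\s]+)>$")

# Level-copy separator for recursion removal; never occurs in user grammars
# because it is rejected at parse time.
_LEVEL_SEP = "@"


class GrammarError(ValueError):
    """Malformed grammar source or an invalid structural operation."""


@dataclass(frozen=True)
class Symbol:
    """One token of a production: a terminal literal or a nonterminal name."""

    name: str
    is_terminal: bool

    def __repr__(self) -> str:  # compact, for test failure messages
        return self.name if self.is_terminal else f"<{self.name}>"


@dataclass(frozen=True)
class Production:
    """A non-empty ordered sequence of symbols."""

    symbols: tuple[Symbol, ...]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise GrammarError("empty production")

    def __iter__(self):
        return iter(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def nonterminals(self) -> list[str]:
        return [s.name for s in self.symbols if not s.is_terminal]


@dataclass
class Grammar:
    """Rules in source order plus the start symbol (head of the first rule)."""

    rules: dict[str, list[Production]]
    start: str

    def __post_init__(self) -> None:
        if self.start not in self.rules:
            raise GrammarError(f"start symbol <{self.start}> has no rule")
        for head, prods in self.rules.items():
            for prod in prods:
                for nt in prod.nonterminals():
                    if nt not in self.rules:
                        raise GrammarError(f"undefined nonterminal <{nt}>")

    def production_count(self, nt: str) -> int:
        return len(self.rules[nt])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Grammar):
            return NotImplemented
        return (
            self.start == other.start
            and list(self.rules.items()) == list(other.rules.items())
        )


@dataclass
class GrammarStats:
    """Structural quantities that size SGE genotypes.

    ``production_count[nt]`` is the number of alternatives of ``nt``;
    ``max_references[nt]`` is the maximum number of expansions of ``nt``
    across any single complete derivation from the start symbol.
    """

    production_count: dict[str, int] = field(default_factory=dict)
    max_references: dict[str, int] = field(default_factory=dict)


def _classify(token: str) -> Symbol:
    m = _NONTERMINAL_RE.match(token)
    if m:
        name = m.group(1)
        if _LEVEL_SEP in name:
            raise GrammarError(
                f"nonterminal name {token!r} may not contain {_LEVEL_SEP!r}"
                " (reserved for recursion-removal level copies)"
            )
        return Symbol(name, is_terminal=False)
    return Symbol(token, is_terminal=True)


def parse_bnf(text: str) -> Grammar:
    """Parse BNF source into a :class:`Grammar`.

    One rule per line; ``#`` comments and blank lines are ignored.  The head
    of the first rule is the start symbol.  Raises :class:`GrammarError` on
    empty productions, duplicate heads, or references to undefined
    nonterminals.
    """
    rules: dict[str, list[Production]] = {}
    start: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "::=" not in line:
            raise GrammarError(f"line {lineno}: missing '::=' in {raw!r}")
        head_txt, body = line.split("::=", 1)
        head_sym = _classify(head_txt.strip())
        if head_sym.is_terminal:
            raise GrammarError(
                f"line {lineno}: rule head {head_txt.strip()!r} is not <...>"
            )
        head = head_sym.name
        if head in rules:
            raise GrammarError(f"line {lineno}: duplicate rule for <{head}>")
        prods: list[Production] = []
        for alt in _split_alternatives(body.split()):
            if not alt:
                raise GrammarError(f"line {lineno}: empty production for <{head}>")
            prods.append(Production(tuple(_classify(tok) for tok in alt)))
        if not prods:
            raise GrammarError(f"line {lineno}: no productions for <{head}>")
        rules[head] = prods
        if start is None:
            start = head
    if start is None:
        raise GrammarError("no rules found")
    return Grammar(rules=rules, start=start)


def _split_alternatives(tokens: list[str]) -> list[list[str]]:
    alts: list[list[str]] = [[]]
    for tok in tokens:
        if tok == "|":
            alts.append([])
        else:
            alts[-1].append(tok)
    return alts


def render(g: Grammar) -> str:
    """Serialize a grammar back to the BNF dialect; inverse of parse_bnf."""
    lines = []
    for head, prods in g.rules.items():
        alts = " | ".join(
            " ".join(repr(sym) for sym in prod) for prod in prods
        )
        lines.append(f"<{head}> ::= {alts}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Recursion analysis and removal
# ---------------------------------------------------------------------------

def _reference_graph(g: Grammar) -> dict[str, set[str]]:
    return {
        head: {nt for prod in prods for nt in prod.nonterminals()}
        for head, prods in g.rules.items()
    }


def recursive_nonterminals(g: Grammar) -> set[str]:
    """Nonterminals on a cycle of the reference graph (direct or mutual)."""
    cached = getattr(g, "_recursive_cache", None)
    if cached is not None:
        return cached
    graph = _reference_graph(g)
    # Tarjan-free approach: nt is recursive iff nt is reachable from itself.
    reach: dict[str, set[str]] = {}
    for src in graph:
        seen: set[str] = set()
        stack = list(graph[src])
        while stack:
            nt = stack.pop()
            if nt in seen:
                continue
            seen.add(nt)
            stack.extend(graph[nt])
        reach[src] = seen
    result = {nt for nt in graph if nt in reach[nt]}
    # Grammars are treated as immutable once built; memoise on the instance.
    g._recursive_cache = result
    return result


def _components(g: Grammar, recursive: set[str]) -> dict[str, frozenset[str]]:
    """Map each recursive nonterminal to its cycle component (SCC)."""
    graph = _reference_graph(g)
    reach: dict[str, set[str]] = {}
    for src in recursive:
        seen: set[str] = set()
        stack = [nt for nt in graph[src] if nt in recursive]
        while stack:
            nt = stack.pop()
            if nt in seen:
                continue
            seen.add(nt)
            stack.extend(x for x in graph[nt] if x in recursive)
        reach[src] = seen
    comp: dict[str, frozenset[str]] = {}
    for nt in recursive:
        comp[nt] = frozenset(
            x for x in recursive if x in reach[nt] and nt in reach[x]
        )
    return comp


def remove_recursion(g: Grammar, recursive_depth: int) -> Grammar:
    """Rewrite recursive rules into depth-indexed copies.

    Each rule on a reference cycle is replicated into levels ``1..depth``;
    same-component references at level ``i`` point to level ``i+1`` copies,
    and the deepest copy keeps only the productions that do not re-enter the
    component.  Non-recursive rules are kept as written, with references to
    recursive rules redirected to their level-1 copies.  The output grammar
    is acyclic and generates exactly the derivations of ``g`` that nest at
    most ``recursive_depth`` recursive expansions.
    """
    if recursive_depth < 1:
        raise GrammarError("recursive_depth must be >= 1")
    recursive = recursive_nonterminals(g)
    if not recursive:
        return Grammar(
            rules={h: list(ps) for h, ps in g.rules.items()}, start=g.start
        )
    comp = _components(g, recursive)

    def level_name(nt: str, level: int) -> str:
        return f"{nt}{_LEVEL_SEP}{level}"

    def map_symbol(sym: Symbol, component: frozenset[str], level: int) -> Symbol:
        if sym.is_terminal or sym.name not in recursive:
            return sym
        if sym.name in component:
            return Symbol(level_name(sym.name, level + 1), is_terminal=False)
        return Symbol(level_name(sym.name, 1), is_terminal=False)

    new_rules: dict[str, list[Production]] = {}
    for head, prods in g.rules.items():
        if head not in recursive:
            new_rules[head] = [
                Production(
                    tuple(map_symbol(s, frozenset(), 0) for s in prod)
                )
                for prod in prods
            ]
            continue
        component = comp[head]
        for level in range(1, recursive_depth + 1):
            if level < recursive_depth:
                copies = [
                    Production(
                        tuple(map_symbol(s, component, level) for s in prod)
                    )
                    for prod in prods
                ]
            else:
                copies = [
                    Production(
                        tuple(map_symbol(s, frozenset(), 0) for s in prod)
                    )
                    for prod in prods
                    if not any(nt in component for nt in prod.nonterminals())
                ]
                if not copies:
                    raise GrammarError(
                        f"recursive rule <{head}> has no non-recursive"
                        " production; its language is empty at finite depth"
                    )
            new_rules[level_name(head, level)] = copies

    start = level_name(g.start, 1) if g.start in recursive else g.start
    # Preserve source order: non-recursive heads keep their place, level
    # copies appear where the original rule was.
    ordered: dict[str, list[Production]] = {}
    for head in g.rules:
        if head in recursive:
            for level in range(1, recursive_depth + 1):
                name = level_name(head, level)
                ordered[name] = new_rules[name]
        else:
            ordered[head] = new_rules[head]
    return Grammar(rules=ordered, start=start)


def base_name(nt: str) -> str:
    """Strip the recursion-removal level suffix from a nonterminal name."""
    return nt.split(_LEVEL_SEP, 1)[0]


# ---------------------------------------------------------------------------
# Genotype sizing
# ---------------------------------------------------------------------------

def compute_stats(g: Grammar, tree_depth: int | None = None) -> GrammarStats:
    """Production counts and worst-case reference counts of an acyclic grammar.

    ``max_references[nt]`` is the maximum, over all complete derivations from
    the start symbol, of the number of expansions of ``nt``.  It is the exact
    list length an SGE genotype needs for ``nt``.  ``tree_depth`` is accepted
    for interface symmetry with the engines but is not needed: the acyclic
    grammar already bounds every derivation.
    """
    if recursive_nonterminals(g):
        raise GrammarError("compute_stats requires a recursion-free grammar")

    production_count = {nt: len(prods) for nt, prods in g.rules.items()}
    max_references: dict[str, int] = {}
    for target in g.rules:
        memo: dict[str, int] = {}

        def count(nt: str) -> int:
            if nt in memo:
                return memo[nt]
            best = 0
            for prod in g.rules[nt]:
                total = sum(count(x) for x in prod.nonterminals())
                best = max(best, total)
            result = (1 if nt == target else 0) + best
            memo[nt] = result
            return result

        max_references[target] = count(g.start)
    return GrammarStats(
        production_count=production_count, max_references=max_references
    )


# ---------------------------------------------------------------------------
# Shortest terminal completion
# ---------------------------------------------------------------------------

def min_production_heights(g: Grammar) -> dict[str, list[float]]:
    """Minimum derivation height of every production, by fixed-point iteration.

    The height of a nonterminal is ``1 + max`` over symbols of the minimum
    production height below it; terminals have height 0.  Works on recursive
    grammars (unreachable completions stay at ``inf``).
    """
    nt_height: dict[str, float] = {nt: float("inf") for nt in g.rules}
    changed = True
    while changed:
        changed = False
        for nt, prods in g.rules.items():
            for prod in prods:
                h = 1.0 + max(
                    (nt_height[s.name] for s in prod if not s.is_terminal),
                    default=0.0,
                )
                if h < nt_height[nt]:
                    nt_height[nt] = h
                    changed = True
    return {
        nt: [
            1.0
            + max(
                (nt_height[s.name] for s in prod if not s.is_terminal),
                default=0.0,
            )
            for prod in prods
        ]
        for nt, prods in g.rules.items()
    }


def shortest_terminal_production(g: Grammar, nt: str, rng=None) -> int:
    """Index of the production of ``nt`` with minimal derivation height.

    Ties are broken uniformly at random via ``rng`` (a numpy Generator);
    with ``rng=None`` the lowest index wins, which keeps the choice
    deterministic for callers that do not thread a generator.
    """
    if nt not in g.rules:
        raise GrammarError(f"unknown nonterminal <{nt}>")
    table = getattr(g, "_heights_cache", None)
    if table is None:
        table = min_production_heights(g)
        g._heights_cache = table
    heights = table[nt]
    best = min(heights)
    if best == float("inf"):
        raise GrammarError(f"<{nt}> derives no terminal string")
    ties = [i for i, h in enumerate(heights) if h == best]
    if len(ties) == 1 or rng is None:
        return ties[0]
    return ties[int(rng.integers(len(ties)))]


# ---------------------------------------------------------------------------
# Phenotype assembly
# ---------------------------------------------------------------------------

def detokenize(terminals: list[str]) -> str:
    """Concatenate emitted terminal literals into the phenotype string."""
    return "".join(terminals)
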