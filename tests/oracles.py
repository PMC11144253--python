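"""Independent reference implementations used as test oracles.

Everything here is deliberately written by a different route than the
package code it checks: string-rewriting instead of recursive descent,
exhaustive enumeration instead of closed forms, iterative deepening instead
of fixed points.
"""

from __future__ import annotations

import itertools
from collections import Counter

from hypoge.grammar import Grammar


def rewrite_decode_sge(lists: dict[str, list[int]], g: Grammar) -> str:
    """SGE decoding by leftmost sentential-form rewriting (not recursion)."""
    form = [("nt", g.start)]
    ptr = {nt: 0 for nt in g.rules}
    while any(kind == "nt" for kind, _ in form):
        i = next(k for k, (kind, _) in enumerate(form) if kind == "nt")
        nt = form[i][1]
        gene = lists[nt][ptr[nt]]
        ptr[nt] += 1
        prod = g.rules[nt][gene]
        replacement = [
            ("t", s.name) if s.is_terminal else ("nt", s.name) for s in prod
        ]
        form = form[:i] + replacement + form[i + 1 :]
    return "".join(name for _, name in form)


def enumerate_language(g: Grammar, max_strings: int = 100_000) -> set[str]:
    """Full language of an acyclic grammar by recursive enumeration."""
    memo: dict[str, set[str]] = {}

    def lang(nt: str) -> set[str]:
        if nt in memo:
            return memo[nt]
        out: set[str] = set()
        for prod in g.rules[nt]:
            parts = [
                {s.name} if s.is_terminal else lang(s.name) for s in prod
            ]
            for combo in itertools.product(*parts):
                out.add("".join(combo))
                if len(out) > max_strings:
                    raise RuntimeError("language too large to enumerate")
        memo[nt] = out
        return out

    return lang(g.start)


def enumerate_depth_bounded_language(
    g: Grammar, recursive: set[str], components: dict[str, frozenset[str]], d: int
) -> set[str]:
    """Strings of ``g`` derivable with at most ``d`` nested recursive
    expansions per cycle component (the sublanguage recursion removal at
    depth ``d`` must generate exactly)."""

    def expand(nt: str, depths: dict[frozenset[str], int]) -> set[str]:
        if nt in recursive:
            comp = components[nt]
            level = depths.get(comp, 0) + 1
            if level > d:
                return set()
            depths = {**depths, comp: level}
        out: set[str] = set()
        for prod in g.rules[nt]:
            parts = []
            for s in prod:
                if s.is_terminal:
                    parts.append({s.name})
                else:
                    sub = expand(s.name, depths)
                    parts.append(sub)
            if any(not p for p in parts):
                continue
            for combo in itertools.product(*parts):
                out.add("".join(combo))
        return out

    return expand(g.start, {})


def max_reference_counts(g: Grammar) -> dict[str, int]:
    """Worst-case expansion counts by enumerating all complete derivations."""

    def derivations(nt: str) -> list[Counter]:
        out = []
        for prod in g.rules[nt]:
            partials = [Counter({nt: 1})]
            for s in prod:
                if s.is_terminal:
                    continue
                partials = [
                    a + b for a in partials for b in derivations(s.name)
                ]
            out.extend(partials)
        return out

    derivs = derivations(g.start)
    return {
        nt: max((c.get(nt, 0) for c in derivs), default=0) for nt in g.rules
    }


def min_derivation_height(g: Grammar, nt: str, limit: int = 50) -> int:
    """Smallest h such that ``nt`` derives an all-terminal string in h
    levels, by iterative deepening."""

    def can(sym: str, h: int) -> bool:
        if h <= 0:
            return False
        for prod in g.rules[sym]:
            if all(can(s.name, h - 1) for s in prod if not s.is_terminal):
                return True
        return False

    for h in range(1, limit + 1):
        if can(nt, h):
            return h
    raise RuntimeError(f"<{nt}> derives nothing within {limit} levels")


def min_production_height(g: Grammar, nt: str, index: int, limit: int = 50) -> int:
    """Minimum derivation height when forced to use production ``index``."""
    prod = g.rules[nt][index]
    sub = [
        min_derivation_height(g, s.name, limit)
        for s in prod
        if not s.is_terminal
    ]
    return 1 + (max(sub) if sub else 0)


def brute_force_window_count(df, ph_steps: int, lag_steps: int) -> int:
    """O(n*w) scan counting complete windows with a present target."""
    import numpy as np

    values = df[["gluc", "hr", "steps", "cal"]].to_numpy()
    n = len(values)
    count = 0
    for t in range(n):
        if t - lag_steps < 0 or t + ph_steps >= n:
            continue
        if np.isnan(values[t - lag_steps : t + 1]).any():
            continue
        if np.isnan(values[t + ph_steps, 0]):
            continue
        count += 1
    return count
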