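import numpy as np
import pytest

from hypoge.engines import EvolutionConfig, evolve
from hypoge.expressions import default_grammar, parse_phenotype
from hypoge.glucodata import (
    LabeledDataset,
    SplitSpec,
    build_windows,
    stratified_split,
    undersample_balance,
)
from hypoge.grammar import parse_bnf
from hypoge.synthetic import SyntheticConfig, generate_cohort_with_planted_rule

PLANTED_RULE_TEXT = "steps_0>150.000"


@pytest.fixture(scope="session")
def rule_grammar():
    return default_grammar()


@pytest.fixture(scope="session")
def toy_grammars():
    """Small recursion-free grammars for exhaustive decoder checks."""
    sources = [
        "<s> ::= <v> + <v>\n<v> ::= x | y",
        "<s> ::= <a> <b> | <b>\n<a> ::= p | q | r\n<b> ::= <c> <c>\n<c> ::= 0 | 1",
        "<s> ::= <a> | <a> <a>\n<a> ::= m <b> | n\n<b> ::= u | v | w",
    ]
    return [parse_bnf(src) for src in sources]


@pytest.fixture(scope="session")
def planted_split():
    """Two synthetic patients labeled by a planted activity rule, windowed,
    split 70/30 and balanced — the shared substrate for recovery tests.

    Two patients at 14 days keep the balanced training pool in the
    hundreds of windows while staying fast enough for a default test run.
    """
    cfg = SyntheticConfig(n_patients=2, days_per_patient=14, seed=7)
    rule = parse_phenotype(PLANTED_RULE_TEXT)
    cohort, _ = generate_cohort_with_planted_rule(cfg, rule, ph=30)
    trains, tests = [], []
    for series in cohort:
        ds = build_windows(series, 30)
        tr, te = stratified_split(ds, SplitSpec(seed=7))
        trains.append(undersample_balance(tr, seed=7))
        tests.append(te)
    return (
        LabeledDataset.concat(trains),
        LabeledDataset.concat(tests),
        rule,
        cohort,
    )


@pytest.fixture(scope="session")
def quick_evolved(planted_split, rule_grammar):
    """One small DSGE run on the planted data, reused by cheap assertions."""
    train, _test, _rule, _cohort = planted_split
    cfg = EvolutionConfig(
        algorithm="DSGE", population_size=30, generations=20, runs=1, seed=5
    )
    best, trace = evolve(train, rule_grammar, cfg)
    return best, trace


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
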