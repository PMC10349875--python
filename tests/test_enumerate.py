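"""Genome-wide gMCS enumeration, verification and minimality."""

import pytest

from regmcs.boolean import parse_gpr
from regmcs.enumerate import (
    SolverConfig,
    check_minimality,
    enumerate_gmcs,
    verify_cut_set,
)
from regmcs.gmatrix import GFMatrices, build_g_matrix
from regmcs.io import RegulatoryNetwork, model_from_records
from regmcs.rules import EGPRRuleSet, extend_rules_one_layer
from regmcs.synthetic import ToySpec, brute_force_gmcs, generate_random_integrated_model

import numpy as np


def _linear_toy():
    """r1 (g1) -> r2 (g2 or g3) -> biomass."""
    records = [
        {"reaction": "EX", "equation": "-> A", "lower_bound": 0},
        {"reaction": "r1", "equation": "A -> B", "gpr": "g1"},
        {"reaction": "r2", "equation": "B -> C", "gpr": "g2 or g3"},
        {"reaction": "r_bio", "equation": "C ->"},
    ]
    model = model_from_records(records, target="r_bio").canonicalise()
    return model, EGPRRuleSet.from_model(model)


def test_linear_toy_gmcs():
    model, rules = _linear_toy()
    gf = build_g_matrix(model, rules, max_size=4)
    result = enumerate_gmcs(model, gf, SolverConfig(max_length=4), rules=rules)
    assert result.gene_sets() == {frozenset({"g1"}), frozenset({"g2", "g3"})}
    assert all(g.verified_blocking and g.verified_minimal for g in result.gmcs)


def test_linear_toy_with_single_activator_layer():
    model, rules = _linear_toy()
    rules = extend_rules_one_layer(rules, RegulatoryNetwork([("gR", "g1", 1)]))
    gf = build_g_matrix(model, rules, max_size=4)
    result = enumerate_gmcs(model, gf, SolverConfig(max_length=4), rules=rules)
    assert result.gene_sets() == {
        frozenset({"g1"}),
        frozenset({"gR"}),
        frozenset({"g2", "g3"}),
    }


def test_zero_rows_give_empty_list():
    model, rules = _linear_toy()
    gf = GFMatrices(
        F_rows=[], G_rows=[], d=np.zeros(0, dtype=int), reactions=list(model.reactions)
    )
    result = enumerate_gmcs(model, gf, SolverConfig(max_length=3), rules=rules)
    assert result.gmcs == []


def test_lengths_nondecreasing_and_objective_matches_set_size():
    model, rules = _linear_toy()
    gf = build_g_matrix(model, rules, max_size=4)
    result = enumerate_gmcs(model, gf, SolverConfig(max_length=4), rules=rules)
    lengths = [g.length for g in result.gmcs]
    assert lengths == sorted(lengths)
    for g in result.gmcs:
        assert g.length == len(g.genes)


def test_determinism_same_seed_same_sets():
    model, rules = generate_random_integrated_model(ToySpec(seed=5))
    gf = build_g_matrix(model, rules, max_size=3)
    cfg = SolverConfig(max_length=3, seed=7)
    a = enumerate_gmcs(model, gf, cfg, rules=rules)
    b = enumerate_gmcs(model, gf, cfg, rules=rules)
    assert a.gene_sets() == b.gene_sets()
    assert [g.genes for g in a.gmcs] == [g.genes for g in b.gmcs]


# -- verification helpers ----------------------------------------------------


def test_verify_empty_set_is_not_a_cut(toy):
    model, rules = toy
    assert not verify_cut_set(model, rules, set())


def test_every_enumerated_gmcs_verifies(toy_regulated):
    model, rules = toy_regulated
    gf = build_g_matrix(model, rules, max_size=4)
    result = enumerate_gmcs(model, gf, SolverConfig(max_length=4), rules=rules)
    assert result.gmcs
    for g in result.gmcs:
        assert verify_cut_set(model, rules, g.genes)


def test_superset_monotonicity_for_negation_free_rules(toy):
    model, rules = toy
    assert verify_cut_set(model, rules, {"g1"})
    for extra in rules.genes():
        assert verify_cut_set(model, rules, {"g1", extra})


def test_superset_can_unblock_under_negation():
    """A documented counterexample: with inhibitor chains, supersets of a cut
    set need not cut (adaptation re-enables the pathway)."""
    from regmcs.boolean import Not, Var

    records = [
        {"reaction": "EX", "equation": "-> A", "lower_bound": 0},
        {"reaction": "r1", "equation": "A -> B", "gpr": "g1"},
        {"reaction": "r_bio", "equation": "B ->"},
    ]
    model = model_from_records(records, target="r_bio").canonicalise()
    rules = EGPRRuleSet(
        reaction_rules=dict(model.gpr),
        equations={"g1": Not(Var("g2")), "g2": Not(Var("a"))},
        layer_index={"g1": 0, "g2": 1, "a": 2},
    )
    assert verify_cut_set(model, rules, {"a"})
    assert not verify_cut_set(model, rules, {"a", "g2"})


def test_check_minimality_examples():
    model, rules = _linear_toy()
    assert check_minimality(model, rules, {"g2", "g3"})
    assert not check_minimality(model, rules, {"g1", "g2"})
    assert check_minimality(model, rules, {"g1"})


def test_oracle_equivalence_small_batch():
    """Full pipeline equals brute force on random integrated models (spot
    batch; the full-size batch runs in the acceptance suite)."""
    for seed in range(6):
        model, rules = generate_random_integrated_model(
            ToySpec(n_metabolites=4, n_reactions=6, n_genes=4, n_layers=2, seed=seed)
        )
        gf = build_g_matrix(model, rules, max_size=4)
        got = enumerate_gmcs(model, gf, SolverConfig(max_length=4), rules=rules)
        want = {s for s in brute_force_gmcs(model, rules, 4).minimal if len(s) <= 4}
        assert got.gene_sets() == want, seed


def test_base_gmcs_preserved_in_integrated_model(toy, toy_regulated):
    model, base_rules = toy
    _, reg_rules = toy_regulated
    gf = build_g_matrix(model, base_rules, max_size=4)
    base = enumerate_gmcs(model, gf, SolverConfig(max_length=4), rules=base_rules)
    assert base.gmcs
    for g in base.gmcs:
        assert verify_cut_set(model, reg_rules, g.genes)
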