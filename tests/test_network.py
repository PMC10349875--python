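"""eGPR network compilation, ON/OFF splitting and cycle detection."""

import itertools

import numpy as np
import pytest

from regmcs._solve import solve_lp
from regmcs.boolean import Not, Var, parse_gpr
from regmcs.model import FLUX_TOL
from regmcs.network import (
    check_acyclic,
    compile_egpr_network,
    graph_cycle_check,
    circulation_lp_check,
    max_on_flux,
)
from regmcs.rules import EGPRRuleSet
from regmcs.synthetic import (
    generate_random_rule_system,
    oracle_reaction_blocked,
)


def _rules(rule: str, equations=None, layers=None):
    return EGPRRuleSet(
        reaction_rules={"rx": parse_gpr(rule)},
        equations={g: parse_gpr(e) for g, e in (equations or {}).items()},
        layer_index=layers or {},
    )


def test_single_gene_chain():
    net = compile_egpr_network(_rules("g1"), "rx")
    # R_ON producible iff the y_ON exchange is open
    assert max_on_flux(net, set()) > FLUX_TOL
    assert max_on_flux(net, {"g1"}) < FLUX_TOL


def test_and_rule_de_morgan_structure():
    net = compile_egpr_network(_rules("g1 and g2"), "rx")
    by_id = dict(net.reactions)
    on = by_id["x_R__rx_ON"]
    assert on["g1_ON"] == -1 and on["g2_ON"] == -1
    # OFF side: two alternative producers, one per conjunct
    off_producers = [
        coeffs
        for rid, coeffs in net.reactions
        if coeffs.get("R__rx_OFF") == 1.0
    ]
    assert len(off_producers) == 2
    off_subs = {next(s for s, v in c.items() if v < 0) for c in off_producers}
    assert off_subs == {"g1_OFF", "g2_OFF"}


def test_species_count_doubles_nodes():
    # 3 genes + 3 y nodes + 1 intermediate OR node + 1 reaction node -> x2
    net = compile_egpr_network(_rules("g1 and (g2 or g3)"), "rx")
    assert len(net.species) == 2 * (3 + 3 + 1 + 1)


def test_free_off_exchanges_exactly_for_input_genes():
    rules = _rules(
        "g1 and g2",
        equations={"g1": "t1 or not t2"},
        layers={"g1": 0, "g2": 0, "t1": 1, "t2": 1},
    )
    net = compile_egpr_network(rules, "rx")
    assert set(net.free_off) == net.input_genes == {"g2", "t1", "t2"}
    # every gene contributes exactly one y_ON and one y_OFF exchange
    assert set(net.y_on) == set(net.y_off) == net.b_genes


def test_every_internal_reaction_has_one_product():
    rules = _rules(
        "(g1 or g2) and g3",
        equations={"g3": "t1 or not t2"},
        layers={"g1": 0, "g2": 0, "g3": 0, "t1": 1, "t2": 1},
    )
    net = compile_egpr_network(rules, "rx")
    for rid, coeffs in net.reactions:
        if rid in net.exchanges:
            continue
        prods = [v for v in coeffs.values() if v > 0]
        subs = [v for v in coeffs.values() if v < 0]
        assert len(prods) == 1 and prods[0] == 1.0
        assert len(subs) >= 1


def test_network_flux_matches_token_oracle_exhaustively():
    """Compiled-network blocking (LP) equals the derivability oracle for every
    knockout pattern, on a batch of random rule systems."""
    for seed in range(20):
        rules = generate_random_rule_system(
            seed, n_metabolic_genes=2, n_layers=1, max_total_genes=6
        )
        net = compile_egpr_network(rules, "rx")
        genes = sorted(net.b_genes)
        for k in range(len(genes) + 1):
            for combo in itertools.combinations(genes, k):
                lp_blocked = max_on_flux(net, set(combo)) < FLUX_TOL
                assert lp_blocked == oracle_reaction_blocked(
                    rules, "rx", set(combo)
                ), (seed, combo)


# -- cycle detection ---------------------------------------------------------


def test_self_inhibition_token_loop_detected():
    rules = EGPRRuleSet(
        reaction_rules={"rx": Var("g1")},
        equations={"g1": Not(Var("g1"))},
        layer_index={"g1": 0},
    )
    net = compile_egpr_network(rules, "rx", with_knockouts=False)
    report = check_acyclic(net)
    assert report.cyclic
    assert set(report.witness) == {"x_g1_ON", "x_g1_OFF"}
    assert graph_cycle_check(net)


def test_chain_is_acyclic():
    rules = _rules("g1", equations={"g1": "g2"}, layers={"g1": 0, "g2": 1})
    net = compile_egpr_network(rules, "rx", with_knockouts=False)
    assert not check_acyclic(net).cyclic
    assert not graph_cycle_check(net)


def test_relaxed_exchanges_make_lp_feasible():
    """Through-flux exists when the exchange-sealing mask is not applied,
    guarding that the cycle LP actually seals the boundary."""
    rules = _rules("g1", equations={"g1": "g2"}, layers={"g1": 0, "g2": 1})
    net = compile_egpr_network(rules, "rx", with_knockouts=False)
    n = len(net.reactions)
    res = solve_lp(
        np.ones(n),
        A_ub=-np.ones((1, n)),
        b_ub=np.array([-1.0]),
        A_eq=net.S,
        b_eq=np.zeros(len(net.species)),
        bounds=[(0.0, 1e3)] * n,  # exchanges left open
    )
    assert res.status == "optimal"


def test_lp_and_graph_oracle_agree_on_random_systems():
    for seed in range(60):
        rules = generate_random_rule_system(
            seed, n_layers=1, plant_self_inhibition=(seed % 3 == 0)
        )
        net = compile_egpr_network(rules, "rx", with_knockouts=False)
        assert circulation_lp_check(net).cyclic == graph_cycle_check(net), seed


def test_compile_requires_a_rule(toy):
    _, rules = toy
    with pytest.raises(ValueError):
        compile_egpr_network(rules, "EX_A")
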