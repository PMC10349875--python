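"""Expression thresholding, essentiality calling and adaptation filtering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from regmcs.boolean import Not, Var, parse_gpr
from regmcs.essentiality import (
    AdaptationQuery,
    BooleanEncoding,
    call_essential_genes,
    check_adaptation,
    compute_gmcsTH5,
    enumerate_consistent_states,
    evaluate_predictions,
    filter_adaptation,
)
from regmcs.rules import EGPRRuleSet
from regmcs.synthetic import generate_random_rule_system


def _expr(values: dict[str, float], sample="s1") -> pd.DataFrame:
    return pd.DataFrame({sample: pd.Series(values, dtype=float)})


# -- gmcsTH5 -----------------------------------------------------------------


def test_threshold_lower_empirical_quantile():
    gmcs = [frozenset("AB"), frozenset("CD"), frozenset("E")]
    expr = _expr({"A": 8, "B": 2, "C": 5, "D": 1, "E": 12})
    th = compute_gmcsTH5(gmcs, expr, "s1")
    assert th.genes == ["A", "C", "E"]
    assert sorted(th.values) == [5, 8, 12]
    assert th.threshold == 5  # lower empirical quantile is an observed value


def test_threshold_single_gmcs():
    th = compute_gmcsTH5([frozenset("AB")], _expr({"A": 10, "B": 3}), "s1")
    assert th.genes == ["A"]
    assert th.threshold == 10


def test_threshold_repeated_max_gene_counted_once():
    gmcs = [frozenset("AB"), frozenset("AC")]
    th = compute_gmcsTH5(gmcs, _expr({"A": 9, "B": 1, "C": 2}), "s1")
    assert th.genes == ["A"]
    assert len(th.values) == 1


def test_threshold_empty_list_errors():
    with pytest.raises(ValueError):
        compute_gmcsTH5([], _expr({"A": 1}), "s1")


def test_threshold_shift_equivariance():
    gmcs = [frozenset("AB"), frozenset("CD"), frozenset("E")]
    vals = {"A": 8, "B": 2, "C": 5, "D": 1, "E": 12}
    th0 = compute_gmcsTH5(gmcs, _expr(vals), "s1")
    th1 = compute_gmcsTH5(
        gmcs, _expr({g: v + 3.5 for g, v in vals.items()}), "s1"
    )
    assert th1.threshold == pytest.approx(th0.threshold + 3.5)


# -- calling -----------------------------------------------------------------


def test_partner_low_pattern_called():
    """A gene in two pair gMCSs is called when one partner is silent."""
    gmcs = [frozenset({"TXN2", "TXN"}), frozenset({"TXN2", "PPARD"})]
    expr = _expr({"TXN": 8.0, "TXN2": 7.0, "PPARD": 0.05, "ZZZ": 6.0})
    th = compute_gmcsTH5(gmcs + [frozenset({"ZZZ"})], expr, "s1")
    calls = call_essential_genes(gmcs, expr, "s1", th)
    by_gene = {c.gene: c for c in calls}
    assert set(by_gene) == {"TXN2"}
    assert by_gene["TXN2"].explaining == [frozenset({"TXN2", "PPARD"})]


def test_no_call_when_both_members_high():
    gmcs = [frozenset({"A", "B"})]
    expr = _expr({"A": 9.0, "B": 8.0, "C": 0.1})
    th = compute_gmcsTH5(gmcs + [frozenset({"C"})], expr, "s1")
    assert call_essential_genes(gmcs, expr, "s1", th) == []


def test_length_one_gmcs_called_in_every_sample():
    gmcs = [frozenset({"E2F1"}), frozenset({"A", "B"})]
    expr = pd.DataFrame(
        {"s1": {"E2F1": 0.0, "A": 9.0, "B": 9.0}, "s2": {"E2F1": 50.0, "A": 9.0, "B": 9.0}}
    )
    for sample in ("s1", "s2"):
        th = compute_gmcsTH5(gmcs, expr, sample)
        calls = call_essential_genes(gmcs, expr, sample, th)
        assert "E2F1" in {c.gene for c in calls}


# -- adaptation (ILP) --------------------------------------------------------


def test_pure_metabolic_gmcs_retained(toy):
    _, rules = toy
    obj, discarded = check_adaptation(
        rules, AdaptationQuery("g2", frozenset({"g2", "g3"}))
    )
    assert obj == 0 and not discarded


def test_inhibitor_rescue_discards():
    rules = EGPRRuleSet(
        reaction_rules={"r1": parse_gpr("T or gB")},
        equations={"gB": Not(Var("T"))},
        layer_index={"T": 0, "gB": 0},
    )
    obj, discarded = check_adaptation(rules, AdaptationQuery("T", frozenset({"T", "gB"})))
    assert obj == 1 and discarded


def test_inhibitor_branch_rescue_with_free_input():
    rules = EGPRRuleSet(
        reaction_rules={"r1": parse_gpr("T or gB")},
        equations={"gB": parse_gpr("gC or not T")},
        layer_index={"T": 0, "gB": 0, "gC": 1},
    )
    obj, discarded = check_adaptation(rules, AdaptationQuery("T", frozenset({"T", "gB"})))
    assert obj == 1 and discarded


def test_filter_adaptation_statuses():
    rules = EGPRRuleSet(
        reaction_rules={"r1": parse_gpr("T or gB")},
        equations={"gB": Not(Var("T"))},
        layer_index={"T": 0, "gB": 0},
    )
    from regmcs.essentiality import EssentialityCall

    calls = [
        EssentialityCall("s1", "T", "essential", [frozenset({"T", "gB"})]),
    ]
    out = filter_adaptation(rules, calls)
    assert out[0].status == "discarded_adaptation"
    assert out[0].adaptation_objective == 1


# -- encoding faithfulness ---------------------------------------------------


def _assert_encoding_faithful(rules: EGPRRuleSet):
    enc = BooleanEncoding(rules)
    genes = sorted(rules.layer_index)
    for k in range(len(genes) + 1):
        for knocked in itertools.combinations(genes, k):
            knocked = set(knocked)
            consistent = {
                tuple(bool(s[g]) for g in genes)
                for s in enumerate_consistent_states(rules, knocked)
            }
            feasible = set()
            for bits in itertools.product([False, True], repeat=len(genes)):
                state = dict(zip(genes, bits))
                x = enc.assignment_vector(state, knocked)
                if enc.satisfies(x):
                    feasible.add(bits)
            assert feasible == consistent, (knocked, feasible ^ consistent)


def test_encoding_feasible_set_equals_consistent_states_small_batch():
    for seed in range(8):
        rules = generate_random_rule_system(
            seed, n_metabolic_genes=2, n_layers=1, max_total_genes=5
        )
        _assert_encoding_faithful(rules)


def test_adaptation_soundness_exhaustive():
    """discarded=True implies every consistent state with the target knocked
    keeps some partner gene active."""
    for seed in range(8):
        rules = generate_random_rule_system(
            seed + 100, n_metabolic_genes=2, n_layers=1, max_total_genes=5
        )
        genes = sorted(rules.layer_index)
        target = genes[0]
        partners = frozenset(genes[:3])
        obj, discarded = check_adaptation(rules, AdaptationQuery(target, partners))
        states = enumerate_consistent_states(rules, {target})
        min_active = min(
            sum(bool(s[g]) for g in partners if g != target) for s in states
        )
        assert obj == min_active
        assert discarded == (min_active > 0)


# -- evaluation --------------------------------------------------------------


def _mk_calls(sample, genes):
    from regmcs.essentiality import EssentialityCall

    return [EssentialityCall(sample, g, "essential") for g in genes]


def test_ppv_arithmetic():
    report = evaluate_predictions(_mk_calls("s1", ["A", "B"]), {"s1": {"A"}})
    row = report.per_sample.iloc[0]
    assert row.TP == 1 and row.FP == 1 and row.PPV == 0.5


def test_ppv_missing_without_predictions():
    report = evaluate_predictions([], {"s1": {"A"}})
    assert np.isnan(report.per_sample.iloc[0].PPV)


def test_ppv_perfect():
    report = evaluate_predictions(
        _mk_calls("s1", ["A", "B", "C"]), {"s1": {"A", "B", "C"}}
    )
    assert report.per_sample.iloc[0].PPV == 1.0
    assert report.macro_ppv == 1.0


def test_uncovered_predictions_excluded():
    report = evaluate_predictions(
        _mk_calls("s1", ["A", "B", "X"]),
        {"s1": {"A"}},
        covered={"s1": {"A", "B"}},
    )
    row = report.per_sample.iloc[0]
    assert row.TP == 1 and row.FP == 1
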