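"""Batch cross-validation of the enumerators against their brute-force oracles.

Each function runs one property check on a batch of seeded random instances
and returns (number agreeing, batch size).  These are the checks behind the
package's correctness claims: the dual MILPs are validated against exhaustive
enumeration, the flux-based cycle detector against the combinatorial oracle,
the dependency weights against the exact gene-count identity on hierarchical
row families, and the Boolean ILP encoding against exhaustive state
enumeration.  The same functions drive the acceptance script and the
acceptance test suite.
"""

from __future__ import annotations

import itertools

import numpy as np

from .enumerate import SolverConfig, enumerate_gmcs, verify_cut_set
from .essentiality import (
    BooleanEncoding,
    call_essential_genes,
    compute_gmcsTH5,
    enumerate_consistent_states,
    evaluate_predictions,
)
from .gmatrix import GFMatrices, build_g_matrix, compute_dependencies
from .network import compile_egpr_network, graph_cycle_check, circulation_lp_check
from .synthetic import (
    ToySpec,
    brute_force_gmcs,
    brute_force_reaction_mcs,
    generate_random_integrated_model,
    generate_random_rule_system,
    random_hierarchical_f_rows,
)


def _seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) // 2]  # keep below 2^31


def reaction_mcs_oracle_agreement(
    n_systems: int = 100, seed: int = 0, max_size: int = 4
) -> tuple[int, int]:
    """Per-reaction MILP enumeration vs exhaustive knockout search."""
    ok = 0
    for s in _seeds(seed, n_systems):
        rules = generate_random_rule_system(
            s, n_metabolic_genes=3, n_layers=2, max_total_genes=10
        )
        net = compile_egpr_network(rules, "rx")
        got = enumerate_reaction_mcs_sets(net, max_size)
        want = brute_force_reaction_mcs(rules, "rx", max_size).minimal
        ok += got == want
    return ok, n_systems


def enumerate_reaction_mcs_sets(net, max_size):
    from .reaction_mcs import enumerate_reaction_mcs

    return enumerate_reaction_mcs(net, max_size).as_sets()


def gmcs_pipeline_oracle_agreement(
    n_models: int = 50, seed: int = 0, max_length: int = 4
) -> tuple[int, int]:
    """Full pipeline (G/F build + genome-wide MILP) vs brute-force gMCSs."""
    ok = 0
    for s in _seeds(seed, n_models):
        model, rules = generate_random_integrated_model(
            ToySpec(
                n_metabolites=4,
                n_reactions=6,
                n_genes=4,
                n_layers=2,
                max_total_genes=12,
                seed=s,
            )
        )
        gf = build_g_matrix(model, rules, max_size=max_length)
        got = enumerate_gmcs(
            model, gf, SolverConfig(max_length=max_length), rules=rules
        ).gene_sets()
        want = {
            m
            for m in brute_force_gmcs(model, rules, max_length).minimal
            if len(m) <= max_length
        }
        ok += got == want
    return ok, n_models


def cycle_detection_agreement(n_systems: int = 200, seed: int = 0) -> tuple[int, int]:
    """Flux-based cycle verdict (LP) vs combinatorial token-cycle oracle,
    including planted self-inhibitions."""
    ok = 0
    for i, s in enumerate(_seeds(seed, n_systems)):
        rules = generate_random_rule_system(
            s, n_layers=1, plant_self_inhibition=(i % 2 == 0)
        )
        net = compile_egpr_network(rules, "rx", with_knockouts=False)
        ok += circulation_lp_check(net).cyclic == graph_cycle_check(net)
    return ok, n_systems


def dependency_weight_identity(n_families: int = 100, seed: int = 0) -> tuple[int, int]:
    """Weighted row sums count distinct genes for every dependency-closed
    activation, on hierarchical F-row families (exhaustive over activations)."""
    ok = 0
    for s in _seeds(seed, n_families):
        rng = np.random.default_rng(s)
        rows = random_hierarchical_f_rows(rng)
        gf = compute_dependencies(
            GFMatrices(
                F_rows=rows,
                G_rows=[{f"r{i}"} for i in range(len(rows))],
                d=np.ones(len(rows), dtype=int),
                reactions=[f"r{i}" for i in range(len(rows))],
            )
        )
        holds = True
        for bits in itertools.product([0, 1], repeat=gf.n_rows):
            if not all(bits[sub] >= bits[sup] for sub, sup in gf.dependencies):
                continue
            active = [i for i in range(gf.n_rows) if bits[i]]
            union: set[str] = set()
            for i in active:
                union |= gf.F_rows[i]
            if int(sum(gf.d[i] for i in active)) != len(union):
                holds = False
                break
        ok += holds
    return ok, n_families


def encoding_faithfulness(n_systems: int = 100, seed: int = 0) -> tuple[int, int]:
    """ILP encoding feasible set vs exhaustive consistent-state enumeration,
    for every knockout pattern."""
    ok = 0
    for s in _seeds(seed, n_systems):
        rules = generate_random_rule_system(
            s, n_metabolic_genes=2, n_layers=1, max_total_genes=5
        )
        enc = BooleanEncoding(rules)
        genes = sorted(rules.layer_index)
        holds = True
        for k in range(len(genes) + 1):
            for knocked in itertools.combinations(genes, k):
                knocked = set(knocked)
                consistent = {
                    tuple(bool(st[g]) for g in genes)
                    for st in enumerate_consistent_states(rules, knocked)
                }
                feasible = set()
                for bits in itertools.product([False, True], repeat=len(genes)):
                    x = enc.assignment_vector(dict(zip(genes, bits)), knocked)
                    if enc.satisfies(x):
                        feasible.add(bits)
                if feasible != consistent:
                    holds = False
                    break
            if not holds:
                break
        ok += holds
    return ok, n_systems


def base_gmcs_preservation(n_models: int = 20, seed: int = 0) -> tuple[int, int]:
    """Every gMCS of the unregulated model still cuts the task after the
    regulatory layers are added."""
    ok = 0
    for s in _seeds(seed, n_models):
        model, rules = generate_random_integrated_model(
            ToySpec(
                n_metabolites=4,
                n_reactions=6,
                n_genes=4,
                n_layers=2,
                max_total_genes=12,
                seed=s,
            )
        )
        from .rules import EGPRRuleSet

        base_rules = EGPRRuleSet.from_model(model)
        gf = build_g_matrix(model, base_rules, max_size=3)
        base = enumerate_gmcs(
            model, gf, SolverConfig(max_length=3), rules=base_rules
        )
        ok += all(verify_cut_set(model, rules, g.genes) for g in base.gmcs)
    return ok, n_models


def partner_silencing_pattern() -> dict[str, float]:
    """Worked essentiality pattern: a gene kept essential by one silent
    partner, plus an always-essential single-gene gMCS.

    Returns the per-sample PPV of the calls against the planted truth and the
    call indicators the pattern requires.
    """
    import pandas as pd

    gmcs = [
        frozenset({"TXN2", "TXN"}),
        frozenset({"TXN2", "PPARD"}),
        frozenset({"E2F1"}),
    ]
    expr = pd.DataFrame(
        {
            "partner_low": {"TXN": 8.0, "TXN2": 7.0, "PPARD": 0.1, "E2F1": 0.2},
            "partner_high": {"TXN": 8.0, "TXN2": 7.0, "PPARD": 9.0, "E2F1": 0.2},
        }
    )
    gold = {
        "partner_low": {"TXN2", "E2F1"},
        "partner_high": {"E2F1"},
    }
    all_calls = []
    results: dict[str, float] = {}
    for sample in expr.columns:
        th = compute_gmcsTH5(gmcs, expr, sample)
        calls = call_essential_genes(gmcs, expr, sample, th)
        all_calls.extend(calls)
        called = {c.gene for c in calls}
        results[f"called_{sample}"] = float(called == gold[sample])
    report = evaluate_predictions(all_calls, gold)
    results["ppv"] = float(report.macro_ppv)
    return results
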