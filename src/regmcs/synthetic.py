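"""Synthetic fixtures, random integrated models and brute-force oracles.

Everything enumerative in the package (per-reaction knockout sets, gMCSs,
cycle verdicts, the adaptation ILP) is validated against exhaustive oracles
defined here.  The oracle Boolean semantics is the single source of truth:
for a knockout set K, a token (g, ON) is derivable iff g is unknocked and
(g is an input or its equation is ON-derivable); (g, OFF) is derivable iff
g is knocked, or g is an input (free OFF state), or its equation is
OFF-derivable under De Morgan duality.  A reaction is blocked iff its rule
is not ON-derivable; a gene set cuts the metabolic task iff removing the
blocked reactions leaves no task flux (LP).  The oracle uses an iterative
fixpoint (no MILP, no recursion shared with the enumerators).

Random integrated models are built layer-wise so that regulatory layers are
acyclic by construction: layer-l regulators are fresh genes that only point
at layer-(l-1) targets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boolean import And, BooleanExpr, Not, Or, Var
from .io import RegulatoryNetwork, model_from_records
from .model import FLUX_TOL, MetabolicModel
from .rules import EGPRRuleSet, extend_rules_one_layer


@dataclass
class ToySpec:
    n_metabolites: int = 6
    n_reactions: int = 8
    n_genes: int = 6
    gpr_depth: int = 2
    n_layers: int = 1
    regulators_per_gene: int = 2
    activation_prob: float = 0.7
    max_total_genes: int = 12
    seed: int = 0


@dataclass
class OracleResult:
    #: minimal blocking sets up to the length bound
    minimal: set[frozenset[str]]
    #: blocking verdict for every tested subset
    blocked: dict[frozenset[str], bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# deterministic example fixture
# ---------------------------------------------------------------------------


def make_example_toy(n_layers: int = 0) -> tuple[MetabolicModel, EGPRRuleSet]:
    """Five-reaction, five-gene toy with a biomass task.

    One gene (g2) participates in two reactions so that a single G row blocks
    both.  With ``n_layers=1`` a three-gene regulatory layer is added for g4
    (g4 = g6 OR NOT g7 OR g8), introducing one inhibitory interaction.
    """
    records = [
        {"reaction": "EX_A", "equation": "-> A", "lower_bound": 0, "upper_bound": 1000},
        {"reaction": "r1", "equation": "A -> B", "gpr": "g1"},
        {"reaction": "r2", "equation": "B -> C", "gpr": "g2"},
        {"reaction": "r3", "equation": "B -> D", "gpr": "g2 and g3"},
        {"reaction": "r4", "equation": "C -> E", "gpr": "g2 or g4"},
        {"reaction": "r_bio", "equation": "D + E ->", "gpr": "g5"},
    ]
    model = model_from_records(records, target="r_bio").canonicalise()
    rules = EGPRRuleSet.from_model(model)
    for _ in range(n_layers):
        rules = extend_rules_one_layer(rules, example_regulatory_network())
    return model, rules


def example_regulatory_network() -> RegulatoryNetwork:
    return RegulatoryNetwork(
        [("g6", "g4", 1), ("g7", "g4", -1), ("g8", "g4", 1)]
    )


# ---------------------------------------------------------------------------
# oracle semantics (iterative fixpoint; independent of the enumerators)
# ---------------------------------------------------------------------------


def _expr_on(expr: BooleanExpr, tokens: set[tuple[str, str]]) -> bool:
    if isinstance(expr, Var):
        return (expr.name, "ON") in tokens
    if isinstance(expr, Not):
        return _expr_off(expr.arg, tokens)
    if isinstance(expr, And):
        return all(_expr_on(a, tokens) for a in expr.args)
    return any(_expr_on(a, tokens) for a in expr.args)


def _expr_off(expr: BooleanExpr, tokens: set[tuple[str, str]]) -> bool:
    if isinstance(expr, Var):
        return (expr.name, "OFF") in tokens
    if isinstance(expr, Not):
        return _expr_on(expr.arg, tokens)
    if isinstance(expr, And):
        return any(_expr_off(a, tokens) for a in expr.args)
    return all(_expr_off(a, tokens) for a in expr.args)


def derivable_tokens(
    eqs: dict[str, BooleanExpr], genes: set[str], knocked: set[str]
) -> set[tuple[str, str]]:
    tokens: set[tuple[str, str]] = set()
    for g in genes:
        if g in knocked:
            tokens.add((g, "OFF"))
        elif g not in eqs:
            tokens.add((g, "ON"))
            tokens.add((g, "OFF"))
    changed = True
    while changed:
        changed = False
        for g in genes:
            if g in knocked or g not in eqs:
                continue
            if (g, "ON") not in tokens and _expr_on(eqs[g], tokens):
                tokens.add((g, "ON"))
                changed = True
            if (g, "OFF") not in tokens and _expr_off(eqs[g], tokens):
                tokens.add((g, "OFF"))
                changed = True
    return tokens


def oracle_reaction_blocked(
    rules: EGPRRuleSet, reaction: str, knocked: set[str]
) -> bool:
    rule = rules.reaction_rules.get(reaction)
    if rule is None:
        return False
    genes = rules.genes_for_reaction(reaction)
    eqs = {
        g: e for g, e in rules.effective_equations(reaction).items() if g in genes
    }
    tokens = derivable_tokens(eqs, genes, set(knocked) & genes)
    return not _expr_on(rule, tokens)


def brute_force_reaction_mcs(
    rules: EGPRRuleSet, reaction: str, max_size: int
) -> OracleResult:
    """Exhaustive minimal knockout sets blocking one reaction's eGPR rule."""
    genes = sorted(rules.genes_for_reaction(reaction))
    if len(genes) > 14:
        raise ValueError("oracle limited to <= 14 genes")
    blocked: dict[frozenset[str], bool] = {}
    for k in range(0, max_size + 1):
        for combo in itertools.combinations(genes, k):
            s = frozenset(combo)
            blocked[s] = oracle_reaction_blocked(rules, reaction, set(s))
    minimal = {
        s
        for s, b in blocked.items()
        if b
        and s
        and not any(
            blocked[frozenset(sub)]
            for k in range(0, len(s))
            for sub in itertools.combinations(sorted(s), k)
        )
    }
    return OracleResult(minimal, blocked)


def brute_force_gmcs(
    model: MetabolicModel, rules: EGPRRuleSet, max_len: int
) -> OracleResult:
    """Exhaustive minimal gene-knockout sets blocking the metabolic task."""
    genes = sorted(rules.layer_index)
    if len(genes) > 14:
        raise ValueError("oracle limited to <= 14 genes")

    def is_blocked(subset: frozenset[str]) -> bool:
        disabled = {
            rid
            for rid in rules.reaction_rules
            if oracle_reaction_blocked(rules, rid, set(subset))
        }
        return model.max_task_flux(disabled=disabled) < FLUX_TOL

    if is_blocked(frozenset()):
        raise ValueError("task infeasible without knockouts")
    blocked: dict[frozenset[str], bool] = {frozenset(): False}
    for k in range(1, max_len + 1):
        for combo in itertools.combinations(genes, k):
            s = frozenset(combo)
            blocked[s] = is_blocked(s)
    minimal = {
        s
        for s, b in blocked.items()
        if b
        and not any(
            blocked[frozenset(sub)]
            for k in range(1, len(s))
            for sub in itertools.combinations(sorted(s), k)
        )
    }
    return OracleResult(minimal, blocked)


# ---------------------------------------------------------------------------
# random generators
# ---------------------------------------------------------------------------


def _random_gpr(rng: np.random.Generator, pool: list[str], depth: int) -> BooleanExpr:
    if depth <= 0 or rng.random() < 0.45:
        return Var(pool[rng.integers(len(pool))])
    op = And if rng.random() < 0.5 else Or
    k = int(rng.integers(2, 4))
    args = [_random_gpr(rng, pool, depth - 1) for _ in range(k)]
    return op(*args)


def _random_layers(
    rng: np.random.Generator,
    rules: EGPRRuleSet,
    n_layers: int,
    regulators_per_gene: int,
    activation_prob: float,
    max_total_genes: int = 12,
) -> EGPRRuleSet:
    for layer in range(1, n_layers + 1):
        frontier = sorted(
            g
            for g, lv in rules.layer_index.items()
            if lv == layer - 1 and g not in rules.equations
        )
        edges = []
        fresh = 0
        n_genes = len(rules.layer_index)
        for g in frontier:
            k = int(rng.integers(0, regulators_per_gene + 1))
            for _ in range(k):
                if n_genes + fresh >= max_total_genes:
                    break
                reg = f"t{layer}_{fresh}"
                fresh += 1
                sign = 1 if rng.random() < activation_prob else -1
                edges.append((reg, g, sign))
        rules = extend_rules_one_layer(rules, RegulatoryNetwork(edges))
    return rules


def generate_random_integrated_model(
    spec: ToySpec,
) -> tuple[MetabolicModel, EGPRRuleSet]:
    """Random linear-pathway metabolic model with random GPRs and acyclic
    regulatory layers; biomass is reachable by construction (verified by LP).
    """
    rng = np.random.default_rng(spec.seed)
    nm = max(spec.n_metabolites, 2)
    records = [
        {
            "reaction": "EX_in",
            "equation": "-> M0",
            "lower_bound": 0,
            "upper_bound": 1000,
        }
    ]
    pool = [f"g{i + 1}" for i in range(spec.n_genes)]
    for i in range(1, nm):
        records.append(
            {
                "reaction": f"r{i}",
                "equation": f"M{i - 1} -> M{i}",
                "gpr": _random_gpr(rng, pool, spec.gpr_depth).to_string(),
            }
        )
    n_extra = max(0, spec.n_reactions - nm)
    for j in range(n_extra):
        i = int(rng.integers(1, nm))
        records.append(
            {
                "reaction": f"alt{j}",
                "equation": f"M{i - 1} -> M{i}",
                "gpr": _random_gpr(rng, pool, spec.gpr_depth).to_string(),
            }
        )
    records.append(
        {"reaction": "r_bio", "equation": f"M{nm - 1} ->", "gpr": pool[0]}
    )
    model = model_from_records(records, target="r_bio").canonicalise()
    if model.max_task_flux() < FLUX_TOL:  # pragma: no cover - by construction
        raise RuntimeError("generated model cannot reach biomass")
    rules = EGPRRuleSet.from_model(model)
    rules = _random_layers(
        rng,
        rules,
        spec.n_layers,
        spec.regulators_per_gene,
        spec.activation_prob,
        spec.max_total_genes,
    )
    return model, rules


def generate_random_rule_system(
    seed: int,
    n_metabolic_genes: int = 3,
    gpr_depth: int = 2,
    n_layers: int = 1,
    regulators_per_gene: int = 2,
    activation_prob: float = 0.7,
    max_total_genes: int = 10,
    plant_self_inhibition: bool = False,
) -> EGPRRuleSet:
    """A single-reaction eGPR rule system (reaction id "rx").

    With ``plant_self_inhibition`` one gene of the rule gets the equation
    g = NOT g (sole regulator), the minimal cyclic feedback.
    """
    rng = np.random.default_rng(seed)
    pool = [f"g{i + 1}" for i in range(n_metabolic_genes)]
    rule = _random_gpr(rng, pool, gpr_depth)
    rules = EGPRRuleSet(reaction_rules={"rx": rule})
    rules = _random_layers(
        rng, rules, n_layers, regulators_per_gene, activation_prob, max_total_genes
    )
    if plant_self_inhibition:
        victims = sorted(rule.genes())
        victim = victims[int(rng.integers(len(victims)))]
        equations = dict(rules.equations)
        equations[victim] = Not(Var(victim))
        rules = EGPRRuleSet(
            reaction_rules=dict(rules.reaction_rules),
            equations=equations,
            layer_index=dict(rules.layer_index),
        )
    return rules


def random_hierarchical_f_rows(
    rng: np.random.Generator,
    n_base: int = 4,
    n_super: int = 4,
    max_rows: int = 12,
) -> list[frozenset[str]]:
    """Random F-row family in which every overlap between rows is covered by
    common subset rows (base rows are disjoint; supersets are unions of
    existing rows plus fresh genes), the regime in which the exclusive-count
    weighting d is an exact gene counter."""
    rows: list[frozenset[str]] = []
    gene_counter = 0

    def fresh() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"p{gene_counter}"

    for _ in range(n_base):
        rows.append(frozenset(fresh() for _ in range(int(rng.integers(1, 3)))))
    for _ in range(n_super):
        k = int(rng.integers(1, min(3, len(rows)) + 1))
        picked = rng.choice(len(rows), size=k, replace=False)
        union: set[str] = set()
        for i in picked:
            union |= rows[int(i)]
        n_fresh = int(rng.integers(1, 3))
        union |= {fresh() for _ in range(n_fresh)}
        candidate = frozenset(union)
        if candidate not in rows:
            rows.append(candidate)
    return rows[:max_rows]


# ---------------------------------------------------------------------------
# expression fixtures
# ---------------------------------------------------------------------------


def generate_expression_fixture(
    genes: list[str],
    samples: list[str],
    essential_design: dict[str, dict[str, set[str]]],
    seed: int = 0,
    low_value: float = 0.05,
    high_value: float = 50.0,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Lognormal expression matrix with planted low/high genes per sample.

    ``essential_design[sample]`` maps "low"/"high" to gene sets and
    "essential" to the genes the plan makes essential (the gold labels).
    """
    rng = np.random.default_rng(seed)
    values = rng.lognormal(mean=1.5, sigma=1.0, size=(len(genes), len(samples)))
    df = pd.DataFrame(values, index=genes, columns=samples)
    gold: dict[str, set[str]] = {}
    for sample, plan in essential_design.items():
        for g in plan.get("low", set()):
            df.loc[g, sample] = low_value
        for g in plan.get("high", set()):
            df.loc[g, sample] = high_value
        gold[sample] = set(plan.get("essential", set()))
    return df, gold
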