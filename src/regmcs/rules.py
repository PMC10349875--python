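"""Extended GPR rule sets: regulatory layers over metabolic GPR rules.

A rule set holds, per metabolic reaction, its (negation-free) GPR rule and,
per gene, an optional regulatory Boolean equation (an OR over signed
regulator literals, contributed by a regulatory layer).  Genes without an
equation are *inputs*: their state is free.  Layers are added one at a time:
layer 1 regulates the metabolic genes, layer 2 regulates the genes introduced
in layer 1, and so on.  Additions that would create cyclic dependencies are
reverted per reaction and counted.

The module also implements the conservative token semantics of the compiled
ON/OFF networks at the rule level: for a knockout set K,

* a knocked gene can only be OFF;
* an unknocked input gene can supply both its ON and its OFF token (its state
  is free, and both polarities are simultaneously available to different
  branches of a rule);
* an unknocked regulated gene is ON iff its equation is ON-derivable and OFF
  iff its equation is OFF-derivable (De Morgan dual).

A reaction is blocked iff its rule is not ON-derivable.  Because of NOT
literals, blocking is *not* monotone in K: knocking an inhibitor's inhibitor
can re-enable a reaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .boolean import And, BooleanExpr, Not, Or, Var
from .model import MetabolicModel

logger = logging.getLogger(__name__)


@dataclass
class EGPRRuleSet:
    #: reaction id -> GPR rule (over genes; negation-free)
    reaction_rules: dict[str, BooleanExpr]
    #: gene -> regulatory Boolean equation (OR of signed literals); absent = input
    equations: dict[str, BooleanExpr] = field(default_factory=dict)
    #: gene -> layer at which it entered the model (0 = metabolic)
    layer_index: dict[str, int] = field(default_factory=dict)
    #: reaction id -> genes whose equations are masked (reverted) for that reaction
    reaction_masks: dict[str, set[str]] = field(default_factory=dict)
    #: per-layer count of reactions reverted due to cycles
    reverted_per_layer: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.layer_index:
            self.layer_index = {
                g: 0 for rule in self.reaction_rules.values() for g in rule.genes()
            }
        for g, eq in self.equations.items():
            missing = eq.genes() - set(self.layer_index)
            if missing:
                raise ValueError(f"equation of {g} references unknown genes {missing}")
            if g not in self.layer_index:
                raise ValueError(f"equation for unknown gene {g}")

    @classmethod
    def from_model(cls, model: MetabolicModel) -> "EGPRRuleSet":
        return cls(reaction_rules=dict(model.gpr))

    @property
    def current_layer(self) -> int:
        return max(self.layer_index.values(), default=0)

    def genes(self) -> list[str]:
        return sorted(self.layer_index)

    def is_input(self, gene: str, reaction: str | None = None) -> bool:
        if gene not in self.equations:
            return True
        if reaction is not None and gene in self.reaction_masks.get(reaction, set()):
            return True
        return False

    def effective_equations(self, reaction: str) -> dict[str, BooleanExpr]:
        mask = self.reaction_masks.get(reaction, set())
        return {g: eq for g, eq in self.equations.items() if g not in mask}

    def genes_for_reaction(self, reaction: str) -> set[str]:
        """B(k): transitive closure of the reaction's rule through equations."""
        rule = self.reaction_rules.get(reaction)
        if rule is None:
            return set()
        eqs = self.effective_equations(reaction)
        seen: set[str] = set()
        stack = list(rule.genes())
        while stack:
            g = stack.pop()
            if g in seen:
                continue
            seen.add(g)
            if g in eqs:
                stack.extend(eqs[g].genes() - seen)
        return seen

    def inputs_for_reaction(self, reaction: str) -> set[str]:
        """L(k): genes of B(k) without an (unmasked) equation."""
        eqs = self.effective_equations(reaction)
        return {g for g in self.genes_for_reaction(reaction) if g not in eqs}

    def genes_per_layer(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for _, layer in self.layer_index.items():
            out[layer] = out.get(layer, 0) + 1
        return out


# ---------------------------------------------------------------------------
# conservative token semantics (rule-level derivability)
# ---------------------------------------------------------------------------


def _derivable(
    eqs: dict[str, BooleanExpr], knocked: frozenset[str], gene: str, want_on: bool, memo
) -> bool:
    key = (gene, want_on)
    if key in memo:
        return memo[key]
    if want_on:
        if gene in knocked:
            result = False
        elif gene not in eqs:
            result = True  # input gene: y_ON exchange open
        else:
            result = _expr_derivable(eqs, knocked, eqs[gene], True, memo)
    else:
        if gene in knocked or gene not in eqs:
            result = True  # y_OFF (knocked) or free-OFF exchange (input)
        else:
            result = _expr_derivable(eqs, knocked, eqs[gene], False, memo)
    memo[key] = result
    return result


def _expr_derivable(eqs, knocked, expr: BooleanExpr, want_on: bool, memo) -> bool:
    if isinstance(expr, Var):
        return _derivable(eqs, knocked, expr.name, want_on, memo)
    if isinstance(expr, Not):
        return _expr_derivable(eqs, knocked, expr.arg, not want_on, memo)
    if isinstance(expr, And):
        combine = all if want_on else any
    else:
        combine = any if want_on else all
    return combine(_expr_derivable(eqs, knocked, a, want_on, memo) for a in expr.args)


def reaction_blocked(rules: EGPRRuleSet, reaction: str, knocked: set[str]) -> bool:
    """True iff the reaction's eGPR rule is not ON-derivable under the knockouts.

    Reactions without a GPR rule cannot be blocked by gene knockouts.
    """
    rule = rules.reaction_rules.get(reaction)
    if rule is None:
        return False
    eqs = rules.effective_equations(reaction)
    memo: dict = {}
    return not _expr_derivable(eqs, frozenset(knocked), rule, True, memo)


def blocked_reactions(rules: EGPRRuleSet, knocked: set[str]) -> set[str]:
    return {
        rid for rid in rules.reaction_rules if reaction_blocked(rules, rid, knocked)
    }


# ---------------------------------------------------------------------------
# layer extension
# ---------------------------------------------------------------------------


def gene_dependency_graph(eqs: dict[str, BooleanExpr]) -> nx.DiGraph:
    """Digraph with an edge regulator -> regulated gene for each equation."""
    g = nx.DiGraph()
    for gene, eq in eqs.items():
        g.add_node(gene)
        for reg in eq.genes():
            g.add_edge(reg, gene)
    return g


def _cyclic_genes(eqs: dict[str, BooleanExpr], restrict: set[str]) -> set[str]:
    graph = gene_dependency_graph({g: e for g, e in eqs.items() if g in restrict})
    out: set[str] = set()
    for comp in nx.strongly_connected_components(graph):
        if len(comp) > 1:
            out |= comp
        else:
            (node,) = comp
            if graph.has_edge(node, node):
                out.add(node)
    return out


def extend_rules_one_layer(
    rules: EGPRRuleSet, net: "RegulatoryNetwork"
) -> EGPRRuleSet:
    """Add one regulatory layer to the rule set.

    Frontier genes (those introduced by the previous layer, or the metabolic
    genes for the first layer) that have at least one signed regulator get a
    Boolean equation: an OR over their regulators, inhibitors as NOT literals.
    Regulators not yet in the model enter as inputs of the new layer.  Any
    reaction whose dependency structure becomes cyclic reverts the offending
    additions (the new equations on its cycle genes are masked for that
    reaction) and the event is counted.
    """
    layer = rules.current_layer + 1
    frontier = [
        g
        for g, lv in rules.layer_index.items()
        if lv == layer - 1 and g not in rules.equations
    ]
    equations = dict(rules.equations)
    layer_index = dict(rules.layer_index)
    added: set[str] = set()
    for g in sorted(frontier):
        regs = sorted(net.regulators_of(g))
        if not regs:
            continue
        lits = [Var(s) if sign > 0 else Not(Var(s)) for s, sign in regs]
        equations[g] = lits[0] if len(lits) == 1 else Or(*lits)
        added.add(g)
        for s, _ in regs:
            if s not in layer_index:
                layer_index[s] = layer
    new_rules = EGPRRuleSet(
        reaction_rules=dict(rules.reaction_rules),
        equations=equations,
        layer_index=layer_index,
        reaction_masks={r: set(m) for r, m in rules.reaction_masks.items()},
        reverted_per_layer=dict(rules.reverted_per_layer),
    )
    if not added:
        return new_rules
    n_reverted = 0
    for rid in sorted(new_rules.reaction_rules):
        reverted_here = False
        while True:
            bk = new_rules.genes_for_reaction(rid)
            eqs = {
                g: e
                for g, e in new_rules.effective_equations(rid).items()
                if g in bk
            }
            cyclic = _cyclic_genes(eqs, bk)
            if not cyclic:
                break
            offending = cyclic & added
            if not offending:  # pre-existing cycle: mask everything cyclic
                offending = cyclic & set(eqs)
            if not offending:
                break
            new_rules.reaction_masks.setdefault(rid, set()).update(offending)
            reverted_here = True
        if reverted_here:
            n_reverted += 1
    if n_reverted:
        logger.info(
            "layer %d: reverted additions for %d reactions due to cycles",
            layer,
            n_reverted,
        )
    new_rules.reverted_per_layer[layer] = n_reverted
    return new_rules
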