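"""Compilation of eGPR rules into artificial ON/OFF token networks.

Each Boolean node X is split into two token species ``X_ON`` / ``X_OFF``
(De Morgan complement), so negation disappears from the rule system and the
logic can be modelled as an irreversible reaction network: a conjunction
becomes one reaction consuming one token of each conjunct and producing one
token of the head; each disjunct becomes an alternative producing reaction.

Per gene g of the rule set, an auxiliary knockout node y_g gates the gene
(``g = y_g AND f_g``; ``g = y_g`` for input genes), with input exchanges for
``y_g_ON`` and ``y_g_OFF`` (the set Y(k)); removing the ON exchange knocks
the gene out without affecting the network upstream.  Input genes
additionally get a free input exchange for their OFF token (their state is
free), and the target reaction node gets output exchanges for both tokens.

Cycle detection asks for a non-zero steady-state flux with every
exchange sealed.  Because every reaction here consumes k >= 1 tokens and
produces exactly 1, summing the balance over all species shows that a sealed
circulation can only be supported on single-substrate reactions; a directed
cycle in the token-passing digraph of those reactions is therefore an exact
combinatorial characterisation of the LP's feasibility, and is used as the
independent graph oracle.  The knockout (y) gates would seal every such cycle
(each ON producer consumes an exchange-fed y token), so the cycle check runs
on the network compiled without knockout nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

from ._solve import solve_lp
from .boolean import And, BooleanExpr, Not, Or, Var, to_nnf
from .model import FLUX_CAP, FLUX_TOL
from .rules import EGPRRuleSet


@dataclass
class EGPRNetwork:
    reaction_id: str
    species: list[str]
    #: (artificial reaction id, {species: stoichiometric coefficient})
    reactions: list[tuple[str, dict[str, float]]]
    #: gene -> input exchange id of its y_ON / y_OFF token (the set Y(k))
    y_on: dict[str, str]
    y_off: dict[str, str]
    #: input gene -> free input exchange of its OFF token
    free_off: dict[str, str]
    out_on: str
    out_off: str
    #: all input+output exchange reaction ids (the set E^k)
    exchanges: set[str]
    b_genes: set[str]
    input_genes: set[str]
    extra_input_exchanges: set[str] = field(default_factory=set)

    _S: sp.csc_matrix | None = None

    @property
    def species_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.species)}

    @property
    def reaction_ids(self) -> list[str]:
        return [rid for rid, _ in self.reactions]

    @property
    def S(self) -> sp.csc_matrix:
        if self._S is None:
            idx = self.species_index
            rows, cols, vals = [], [], []
            for j, (_, coeffs) in enumerate(self.reactions):
                for s, v in coeffs.items():
                    rows.append(idx[s])
                    cols.append(j)
                    vals.append(v)
            self._S = sp.csc_matrix(
                (vals, (rows, cols)), shape=(len(self.species), len(self.reactions))
            )
        return self._S


@dataclass
class CycleReport:
    reaction_id: str
    cyclic: bool
    #: artificial reactions carrying flux in the circulation-LP solution, if cyclic
    witness: list[str] | None = None


class _Builder:
    def __init__(self):
        self.species: list[str] = []
        self._seen: set[str] = set()
        self.reactions: list[tuple[str, dict[str, float]]] = []
        self._rids: set[str] = set()

    def sp(self, name: str) -> str:
        if name not in self._seen:
            self._seen.add(name)
            self.species.append(name)
        return name

    def add(self, rid: str, consumes: list[str], produces: str) -> str:
        coeffs: dict[str, float] = {}
        for s in consumes:
            coeffs[self.sp(s)] = coeffs.get(s, 0.0) - 1.0
        coeffs[self.sp(produces)] = coeffs.get(produces, 0.0) + 1.0
        if rid in self._rids:
            raise ValueError(f"duplicate artificial reaction id {rid}")
        self._rids.add(rid)
        self.reactions.append((rid, coeffs))
        return rid


def _atom_species(atom, positive: bool) -> str:
    kind = atom[0]
    if kind == "node":
        return f"{atom[1]}_{'ON' if positive else 'OFF'}"
    _, gene, pos = atom
    return f"{gene}_{'ON' if positive == pos else 'OFF'}"


def _emit(b: _Builder, head: str, expr: BooleanExpr, counter: list[int]) -> None:
    """Emit producing reactions for head_ON and head_OFF from an NNF expr."""

    def atomify(child: BooleanExpr):
        if isinstance(child, Var):
            return ("lit", child.name, True)
        if isinstance(child, Not):
            if not isinstance(child.arg, Var):  # pragma: no cover - NNF guard
                raise ValueError("expression not in NNF")
            return ("lit", child.arg.name, False)
        name = f"{head}_s{counter[0]}"
        counter[0] += 1
        _emit(b, name, child, counter)
        return ("node", name)

    if isinstance(expr, (Var, Not)):
        atom = atomify(expr)
        b.add(f"x_{head}_ON", [_atom_species(atom, True)], f"{head}_ON")
        b.add(f"x_{head}_OFF", [_atom_species(atom, False)], f"{head}_OFF")
        return
    atoms = [atomify(c) for c in expr.args]
    if isinstance(expr, And):
        b.add(
            f"x_{head}_ON",
            [_atom_species(a, True) for a in atoms],
            f"{head}_ON",
        )
        for i, a in enumerate(atoms):
            b.add(f"x_{head}_OFF_{i}", [_atom_species(a, False)], f"{head}_OFF")
    else:  # Or
        for i, a in enumerate(atoms):
            b.add(f"x_{head}_ON_{i}", [_atom_species(a, True)], f"{head}_ON")
        b.add(
            f"x_{head}_OFF",
            [_atom_species(a, False) for a in atoms],
            f"{head}_OFF",
        )


def compile_egpr_network(
    rules: EGPRRuleSet, reaction_id: str, with_knockouts: bool = True
) -> EGPRNetwork:
    """Compile the eGPR rule of one reaction into its token network.

    With ``with_knockouts=False`` the y gates and their exchanges are omitted
    (input genes get plain ON/OFF input exchanges instead); this is the
    variant used for cycle detection.
    """
    rule = rules.reaction_rules.get(reaction_id)
    if rule is None:
        raise ValueError(f"reaction {reaction_id!r} has no GPR rule")
    b_genes = rules.genes_for_reaction(reaction_id)
    inputs = rules.inputs_for_reaction(reaction_id)
    eqs = {
        g: e
        for g, e in rules.effective_equations(reaction_id).items()
        if g in b_genes
    }
    unknown = rule.genes() - b_genes
    if unknown:  # pragma: no cover - genes_for_reaction starts from the rule
        raise ValueError(f"rule references unknown genes {unknown}")

    b = _Builder()
    y_on: dict[str, str] = {}
    y_off: dict[str, str] = {}
    free_off: dict[str, str] = {}
    extra_inputs: set[str] = set()
    counter = [0]

    for g in sorted(b_genes):
        if with_knockouts:
            y_node = f"{g}_y"
            b.sp(f"{y_node}_ON")
            b.sp(f"{y_node}_OFF")
            y_on[g] = b.add(f"EX_y_{g}_ON", [], f"{y_node}_ON")
            y_off[g] = b.add(f"EX_y_{g}_OFF", [], f"{y_node}_OFF")
            if g in eqs:
                _emit_gene_with_y(b, g, y_node, eqs[g], counter)
            else:
                b.add(f"x_{g}_ON", [f"{y_node}_ON"], f"{g}_ON")
                b.add(f"x_{g}_OFF", [f"{y_node}_OFF"], f"{g}_OFF")
        else:
            if g in eqs:
                _emit(b, g, to_nnf(eqs[g]), counter)
            else:
                extra_inputs.add(b.add(f"EX_in_{g}_ON", [], f"{g}_ON"))
        if g in inputs:
            free_off[g] = b.add(f"EX_off_{g}", [], f"{g}_OFF")

    head = f"R__{reaction_id}"
    _emit(b, head, to_nnf(rule), counter)
    out_on, out_off = "EX_out_ON", "EX_out_OFF"
    b.reactions.append((out_on, {b.sp(f"{head}_ON"): -1.0}))
    b.reactions.append((out_off, {b.sp(f"{head}_OFF"): -1.0}))

    exchanges = (
        set(y_on.values())
        | set(y_off.values())
        | set(free_off.values())
        | {out_on, out_off}
        | extra_inputs
    )
    return EGPRNetwork(
        reaction_id=reaction_id,
        species=b.species,
        reactions=b.reactions,
        y_on=y_on,
        y_off=y_off,
        free_off=free_off,
        out_on=out_on,
        out_off=out_off,
        exchanges=exchanges,
        b_genes=b_genes,
        input_genes=inputs,
        extra_input_exchanges=extra_inputs,
    )


def _emit_gene_with_y(
    b: _Builder, gene: str, y_node: str, eq: BooleanExpr, counter: list[int]
) -> None:
    """Emit g = y_g AND f_g with the OFF side y_g_OFF OR f_g_OFF."""
    nnf = to_nnf(eq)
    if isinstance(nnf, (Var, Not)):
        atom = (
            ("lit", nnf.name, True)
            if isinstance(nnf, Var)
            else ("lit", nnf.arg.name, False)
        )
        on_sp = _atom_species(atom, True)
        off_sp = _atom_species(atom, False)
    else:
        sub = f"{gene}_s{counter[0]}"
        counter[0] += 1
        _emit(b, sub, nnf, counter)
        on_sp, off_sp = f"{sub}_ON", f"{sub}_OFF"
    b.add(f"x_{gene}_ON", [f"{y_node}_ON", on_sp], f"{gene}_ON")
    b.add(f"x_{gene}_OFF_y", [f"{y_node}_OFF"], f"{gene}_OFF")
    b.add(f"x_{gene}_OFF_f", [off_sp], f"{gene}_OFF")


# ---------------------------------------------------------------------------
# cycle detection
# ---------------------------------------------------------------------------


def circulation_lp_check(net: EGPRNetwork) -> CycleReport:
    """Circulation LP: minimise total flux s.t. total flux >= 1, steady state, exchanges
    sealed, fluxes >= 0.  Feasible iff the network supports a sealed
    circulation, i.e. has cycles."""
    n = len(net.reactions)
    exch = [j for j, (rid, _) in enumerate(net.reactions) if rid in net.exchanges]
    bounds = [(0.0, FLUX_CAP)] * n
    for j in exch:
        bounds[j] = (0.0, 0.0)
    A_ub = -np.ones((1, n))
    res = solve_lp(
        np.ones(n),
        A_ub=A_ub,
        b_ub=np.array([-1.0]),
        A_eq=net.S,
        b_eq=np.zeros(len(net.species)),
        bounds=bounds,
    )
    if res.status == "optimal":
        witness = [
            net.reactions[j][0] for j in np.nonzero(res.x > FLUX_TOL)[0]
        ]
        return CycleReport(net.reaction_id, True, witness)
    if res.status == "infeasible":
        return CycleReport(net.reaction_id, False, None)
    raise RuntimeError(f"circulation LP solver failure: {res.message}")


def graph_cycle_check(net: EGPRNetwork) -> bool:
    """Independent combinatorial oracle: a sealed circulation exists iff the
    token-passing digraph of single-substrate non-exchange reactions has a
    directed cycle (multi-substrate reactions cannot carry sealed steady-state
    flux because every reaction nets at most zero tokens)."""
    g = nx.DiGraph()
    for rid, coeffs in net.reactions:
        if rid in net.exchanges:
            continue
        subs = [(s, v) for s, v in coeffs.items() if v < 0]
        prods = [s for s, v in coeffs.items() if v > 0]
        if len(subs) == 1 and subs[0][1] == -1.0 and len(prods) == 1:
            g.add_edge(subs[0][0], prods[0])
    try:
        nx.find_cycle(g)
        return True
    except nx.NetworkXNoCycle:
        return False


def check_acyclic(net: EGPRNetwork) -> CycleReport:
    """Flux-based cycle verdict for a compiled network (circulation LP)."""
    return circulation_lp_check(net)


# ---------------------------------------------------------------------------
# network-level knockout evaluation
# ---------------------------------------------------------------------------


def max_on_flux(net: EGPRNetwork, knocked: set[str]) -> float:
    """Maximum flux through the R_ON output exchange under a knockout pattern.

    Knocked genes have their y_ON input exchange sealed; unknocked genes their
    y_OFF exchange (the two are coupled: a gene is either knocked out or not).
    """
    n = len(net.reactions)
    bounds = [(0.0, FLUX_CAP)] * n
    rid_index = {rid: j for j, (rid, _) in enumerate(net.reactions)}
    for g in net.b_genes:
        sealed = net.y_on[g] if g in knocked else net.y_off[g]
        bounds[rid_index[sealed]] = (0.0, 0.0)
    c = np.zeros(n)
    c[rid_index[net.out_on]] = -1.0
    res = solve_lp(c, A_eq=net.S, b_eq=np.zeros(len(net.species)), bounds=bounds)
    if res.status != "optimal":
        return 0.0
    return -res.objective
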