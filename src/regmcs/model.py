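"""Metabolic model container, canonicalisation and flux LPs.

The gMCS framework treats the metabolic network as a flux cone: after
canonicalisation every reaction is irreversible (lower bound 0) and each
originally reversible reaction is represented by a forward/backward column
pair (``_fwd``/``_rev`` suffixes).  A metabolic *task* is a reaction that must
be able to carry flux (typically biomass production); a gene-knockout set is a
cut set when the task flux drops to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from ._solve import solve_lp
from .boolean import BooleanExpr, contains_not, parse_gpr

#: numeric cap standing in for an unbounded flux in LP solves
FLUX_CAP = 1e3
#: fluxes below this are considered zero
FLUX_TOL = 1e-6

FWD_SUFFIX = "_fwd"
REV_SUFFIX = "_rev"


@dataclass(frozen=True)
class TaskSpec:
    """A metabolic task: the target reaction must carry at least min_flux."""

    target_reaction: str
    min_flux: float = 1.0

    def __post_init__(self):
        if self.min_flux <= 0:
            raise ValueError("min_flux must be positive")


@dataclass
class MetabolicModel:
    metabolites: list[str]
    reactions: list[str]
    stoichiometry: sp.csc_matrix  # m x n
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    gpr: dict[str, BooleanExpr]  # reaction id -> rule (absent = no GPR)
    task: TaskSpec | None = None
    #: canonical (split) reaction id -> original reaction id
    original_id: dict[str, str] = field(default_factory=dict)

    # -- construction -----------------------------------------------------
    def __post_init__(self):
        self.stoichiometry = sp.csc_matrix(self.stoichiometry)
        m, n = self.stoichiometry.shape
        if m != len(self.metabolites) or n != len(self.reactions):
            raise ValueError("stoichiometry shape does not match labels")
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        if not self.original_id:
            self.original_id = {r: r for r in self.reactions}
        unknown = set(self.gpr) - set(self.reactions)
        if unknown:
            raise ValueError(f"GPR rules for unknown reactions: {sorted(unknown)}")
        for rid, rule in self.gpr.items():
            for g in rule.genes():
                if not g:
                    raise ValueError(f"zero-length gene id in GPR of {rid}")

    @property
    def gene_list(self) -> list[str]:
        genes: set[str] = set()
        for rule in self.gpr.values():
            genes |= rule.genes()
        return sorted(genes)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def reaction_index(self, rid: str) -> int:
        return self.reactions.index(rid)

    def is_exchange(self, rid: str) -> bool:
        col = self.stoichiometry.getcol(self.reaction_index(rid))
        return bool((col.data >= 0).all() or (col.data <= 0).all()) and col.nnz > 0

    def is_input_exchange(self, rid: str) -> bool:
        """An exchange that only produces metabolites (an uptake)."""
        col = self.stoichiometry.getcol(self.reaction_index(rid))
        return col.nnz > 0 and bool((col.data > 0).all())

    def exchange_reactions(self) -> list[str]:
        return [r for r in self.reactions if self.is_exchange(r)]

    def is_canonical(self) -> bool:
        return bool((self.lower_bounds >= 0).all())

    # -- canonicalisation -------------------------------------------------
    def canonicalise(self) -> "MetabolicModel":
        """Split reversible reactions into forward/backward irreversible pairs."""
        if self.is_canonical():
            return self
        cols = []
        reactions: list[str] = []
        lbs: list[float] = []
        ubs: list[float] = []
        gpr: dict[str, BooleanExpr] = {}
        original: dict[str, str] = {}
        S = self.stoichiometry
        for j, rid in enumerate(self.reactions):
            lb, ub = self.lower_bounds[j], self.upper_bounds[j]
            col = S.getcol(j)
            rule = self.gpr.get(rid)
            if lb >= 0:
                reactions.append(rid)
                cols.append(col)
                lbs.append(lb)
                ubs.append(ub)
                original[rid] = self.original_id.get(rid, rid)
                if rule is not None:
                    gpr[rid] = rule
            else:
                fwd, rev = rid + FWD_SUFFIX, rid + REV_SUFFIX
                reactions.extend([fwd, rev])
                cols.extend([col, -col])
                lbs.extend([0.0, 0.0])
                ubs.extend([max(ub, 0.0), -lb])
                orig = self.original_id.get(rid, rid)
                original[fwd] = orig
                original[rev] = orig
                if rule is not None:
                    gpr[fwd] = rule
                    gpr[rev] = rule
        task = self.task
        if task is not None and task.target_reaction not in reactions:
            # target was split; point the task at the forward direction
            task = replace(task, target_reaction=task.target_reaction + FWD_SUFFIX)
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=reactions,
            stoichiometry=sp.hstack(cols, format="csc"),
            lower_bounds=np.array(lbs),
            upper_bounds=np.array(ubs),
            gpr=gpr,
            task=task,
            original_id=original,
        )

    # -- flux LPs ---------------------------------------------------------
    def max_task_flux(self, disabled: set[str] | None = None) -> float:
        """Maximise flux through the task reaction (bounds capped at FLUX_CAP).

        ``disabled`` reactions (canonical ids) are fixed to zero flux.
        """
        if self.task is None:
            raise ValueError("model has no task")
        disabled = disabled or set()
        n = self.n_reactions
        lb = np.maximum(self.lower_bounds, 0.0)
        ub = np.minimum(self.upper_bounds, FLUX_CAP)
        for rid in disabled:
            j = self.reaction_index(rid)
            lb[j] = 0.0
            ub[j] = 0.0
        c = np.zeros(n)
        c[self.reaction_index(self.task.target_reaction)] = -1.0
        res = solve_lp(
            c,
            A_eq=self.stoichiometry,
            b_eq=np.zeros(len(self.metabolites)),
            bounds=list(zip(lb, ub)),
        )
        if res.status != "optimal":
            return 0.0
        return -res.objective

    def fva_max(self, rid: str) -> float:
        """Maximum flux a single reaction can carry (irreversible model)."""
        n = self.n_reactions
        lb = np.maximum(self.lower_bounds, 0.0)
        ub = np.minimum(self.upper_bounds, FLUX_CAP)
        c = np.zeros(n)
        c[self.reaction_index(rid)] = -1.0
        res = solve_lp(
            c,
            A_eq=self.stoichiometry,
            b_eq=np.zeros(len(self.metabolites)),
            bounds=list(zip(lb, ub)),
        )
        if res.status != "optimal":
            return 0.0
        return -res.objective

    def drop_reactions(self, to_drop: set[str]) -> "MetabolicModel":
        keep = [j for j, r in enumerate(self.reactions) if r not in to_drop]
        reactions = [self.reactions[j] for j in keep]
        if self.task is not None and self.task.target_reaction not in reactions:
            raise ValueError("simplification would remove the task reaction")
        S = self.stoichiometry[:, keep]
        # drop orphan metabolites
        used = np.asarray((S != 0).sum(axis=1)).ravel() > 0
        return MetabolicModel(
            metabolites=[m for m, u in zip(self.metabolites, used) if u],
            reactions=reactions,
            stoichiometry=S[used.nonzero()[0], :],
            lower_bounds=self.lower_bounds[keep],
            upper_bounds=self.upper_bounds[keep],
            gpr={r: e for r, e in self.gpr.items() if r in reactions},
            task=self.task,
            original_id={r: self.original_id[r] for r in reactions},
        )


def validate_plain_gpr(model: MetabolicModel) -> None:
    """Plain metabolic GPR rules must be negation-free."""
    for rid, rule in model.gpr.items():
        if contains_not(rule):
            raise ValueError(f"GPR of {rid} contains NOT; plain GPRs are negation-free")


def parse_gpr_map(raw: dict[str, str]) -> dict[str, BooleanExpr]:
    return {rid: parse_gpr(text) for rid, text in raw.items() if text and text.strip()}
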