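"""Enumeration of genetic minimal cut sets (gMCSs) via the dual MILP.

A gMCS is a minimal set of gene knockouts that blocks the model's metabolic
task.  The primal flux problem (steady state, irreversibility, task flux,
and the gene-knockout constraints G r <= 0 for a chosen set of G rows) is a
cone, so it is infeasible exactly when a Farkas certificate exists:

    S^T u + G^T v - t w >= 0,   v >= 0 (supported on chosen rows),  w >= c.

Binary row indicators z are linked to v (alpha z <= v <= M z); dependency
constraints activate every strict-subset row of an active row; per-gene
indicator binaries q (q_p >= z_i whenever gene p is in F(i)) make the
objective an exact count of distinct knocked genes.  Solutions are therefore
proposed in nondecreasing knockout count.

Because eGPR rules may contain negation, blocking is not monotone in the
knockout set and the composition of per-reaction rows can propose candidates
whose simultaneous knockout does not actually block every claimed reaction.
Every candidate is therefore verified against the primal (token-semantics
blocking + LP on the metabolic network) and checked for minimality; verified
minimal candidates are reported and their supersets excluded, while failed
candidates are excluded individually (their supersets may still be genuine
gMCSs).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._solve import solve_milp
from .gmatrix import GFMatrices
from .model import FLUX_TOL, MetabolicModel
from .rules import EGPRRuleSet, blocked_reactions

logger = logging.getLogger(__name__)


@dataclass
class SolverConfig:
    alpha: float = 1e-3
    big_m: float = 1e3
    c: float = 1.0
    r_star: float = 1.0
    time_limit_s: float = 300.0
    max_length: int = 5
    seed: int = 0
    solver: str = "highs"
    #: safety valve on the number of MILP proposals per enumeration
    max_candidates: int = 5000

    def __post_init__(self):
        if self.alpha <= 0 or self.c <= 0 or self.r_star <= 0:
            raise ValueError("alpha, c and r_star must be positive")
        if self.big_m <= self.alpha:
            raise ValueError("big_m must exceed alpha")


@dataclass
class GMCS:
    genes: frozenset[str]
    source_rows: tuple[int, ...]
    verified_blocking: bool
    verified_minimal: bool

    @property
    def length(self) -> int:
        return len(self.genes)


@dataclass
class EnumerationResult:
    gmcs: list[GMCS]
    complete: bool = True
    n_candidates: int = 0

    def gene_sets(self) -> set[frozenset[str]]:
        return {g.genes for g in self.gmcs}


def verify_cut_set(
    model: MetabolicModel, rules: EGPRRuleSet, genes: set[str] | frozenset[str]
) -> bool:
    """Primal check of the gMCS definition, independent of any certificate.

    Reactions whose eGPR rule is not ON-derivable under the knockouts are
    removed and the task flux is maximised by LP; the set cuts iff the
    remaining cone admits no task flux.
    """
    disabled = blocked_reactions(rules, set(genes))
    return model.max_task_flux(disabled=disabled) < FLUX_TOL


def check_minimality(
    model: MetabolicModel, rules: EGPRRuleSet, genes: set[str] | frozenset[str]
) -> bool:
    """True iff no proper subset of ``genes`` is itself a cut set.

    Blocking is not monotone under negation, so all proper subsets are
    tested (not just leave-one-out) when the set is small.
    """
    genes = set(genes)
    if len(genes) <= 1:
        return True
    if len(genes) <= 8:
        candidates = itertools.chain.from_iterable(
            itertools.combinations(sorted(genes), k) for k in range(1, len(genes))
        )
    else:  # pragma: no cover - large sets: leave-one-out approximation
        candidates = itertools.combinations(sorted(genes), len(genes) - 1)
    return not any(verify_cut_set(model, rules, set(sub)) for sub in candidates)


def enumerate_gmcs(
    model: MetabolicModel,
    gf: GFMatrices,
    cfg: SolverConfig | None = None,
    rules: EGPRRuleSet | None = None,
    verify: bool = True,
) -> EnumerationResult:
    """Enumerate gMCSs of the model task in increasing knockout count.

    ``rules`` supplies the eGPR system used for primal verification; when
    omitted it is reconstructed from the model's plain GPR rules.
    """
    cfg = cfg or SolverConfig()
    if model.task is None:
        raise ValueError("model has no task")
    if rules is None:
        rules = EGPRRuleSet.from_model(model)
    if gf.n_rows == 0:
        return EnumerationResult([], complete=True)
    if gf.reactions != model.reactions:
        raise ValueError("G matrix reaction universe differs from the model")

    S = model.stoichiometry
    m, n = S.shape
    l = gf.n_rows
    genes = gf.genes
    g_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    t = np.zeros(n)
    t[model.reaction_index(model.task.target_reaction)] = 1.0
    G = gf.G()

    # variable layout: [u (m) | v (l) | w (1) | z (l) | q (n_genes)]
    iv, iw, iz, iq = m, m + l, m + l + 1, m + l + 1 + l
    n_var = iq + n_genes

    dual_block = sp.hstack(
        [
            S.T,
            G.T,
            sp.csc_matrix(-t.reshape(-1, 1)),
            sp.csc_matrix((n, l + n_genes)),
        ]
    )
    I_l = sp.eye(l, format="csc")
    link_lo = sp.hstack(
        [
            sp.csc_matrix((l, m)),
            I_l,
            sp.csc_matrix((l, 1)),
            -cfg.alpha * I_l,
            sp.csc_matrix((l, n_genes)),
        ]
    )
    link_hi = sp.hstack(
        [
            sp.csc_matrix((l, m)),
            I_l,
            sp.csc_matrix((l, 1)),
            -cfg.big_m * I_l,
            sp.csc_matrix((l, n_genes)),
        ]
    )
    # dependency constraints: z_subset >= z_superset
    dep_rows, dep_cols, dep_vals = [], [], []
    for r, (sub, sup) in enumerate(gf.dependencies):
        dep_rows.extend([r, r])
        dep_cols.extend([iz + sub, iz + sup])
        dep_vals.extend([1.0, -1.0])
    deps = sp.csc_matrix(
        (dep_vals, (dep_rows, dep_cols)), shape=(len(gf.dependencies), n_var)
    )
    # gene coverage: q_p >= z_i for every p in F(i)
    cov_rows, cov_cols, cov_vals = [], [], []
    r = 0
    for i, f in enumerate(gf.F_rows):
        for p in f:
            cov_rows.extend([r, r])
            cov_cols.extend([iq + g_index[p], iz + i])
            cov_vals.extend([1.0, -1.0])
            r += 1
    coverage = sp.csc_matrix((cov_vals, (cov_rows, cov_cols)), shape=(r, n_var))
    atleast = np.zeros(n_var)
    atleast[iz : iz + l] = 1.0

    A_rows = [
        dual_block,
        link_lo,
        link_hi,
        deps,
        coverage,
        sp.csc_matrix(atleast.reshape(1, -1)),
    ]
    lb = np.concatenate(
        [
            np.zeros(n),
            np.zeros(l),
            np.full(l, -np.inf),
            np.zeros(len(gf.dependencies)),
            np.zeros(r),
            [1.0],
        ]
    )
    ub = np.full(len(lb), np.inf)
    ub[n : n + l] = np.inf
    ub[n + l : n + 2 * l] = 0.0  # v - M z <= 0

    bounds_lo = np.concatenate(
        [np.full(m, -np.inf), np.zeros(l), [cfg.c], np.zeros(l + n_genes)]
    )
    bounds_hi = np.concatenate(
        [np.full(m, np.inf), np.full(l, cfg.big_m), [cfg.big_m], np.ones(l + n_genes)]
    )
    integrality = np.concatenate(
        [np.zeros(m + l + 1, dtype=int), np.ones(l + n_genes, dtype=int)]
    )
    objective = np.zeros(n_var)
    objective[iq:] = 1.0

    found: list[GMCS] = []
    cuts: list[sp.csc_matrix] = []
    cut_ub: list[float] = []
    complete = True
    n_candidates = 0
    while n_candidates < cfg.max_candidates:
        A = sp.vstack(A_rows + cuts, format="csr")
        full_lb = np.concatenate([lb, np.full(len(cuts), -np.inf)])
        full_ub = np.concatenate([ub, np.array(cut_ub)]) if cuts else ub
        res = solve_milp(
            objective,
            A,
            full_lb,
            full_ub,
            integrality,
            bounds_lo,
            bounds_hi,
            time_limit_s=cfg.time_limit_s,
        )
        if res.status == "infeasible":
            break
        if res.status != "optimal":
            complete = False
            break
        n_candidates += 1
        q = res.x[iq:]
        z = res.x[iz : iz + l]
        support = frozenset(genes[i] for i in range(n_genes) if q[i] > 0.5)
        if len(support) > cfg.max_length:
            break
        active_rows = tuple(int(i) for i in range(l) if z[i] > 0.5)
        if verify:
            blocking = verify_cut_set(model, rules, support)
            minimal = blocking and check_minimality(model, rules, support)
        else:
            blocking = minimal = True
        row = np.zeros(n_var)
        if blocking and minimal:
            found.append(GMCS(support, active_rows, blocking, minimal))
            # superset-excluding cut on the gene indicators
            for g in support:
                row[iq + g_index[g]] = 1.0
            cuts.append(sp.csc_matrix(row.reshape(1, -1)))
            cut_ub.append(float(len(support) - 1))
        else:
            # exact no-good cut: exclude this gene set only
            for i, g in enumerate(genes):
                row[iq + i] = 1.0 if g in support else -1.0
            cuts.append(sp.csc_matrix(row.reshape(1, -1)))
            cut_ub.append(float(len(support) - 1))
    else:  # pragma: no cover - candidate safety valve
        complete = False
        logger.warning("enumeration stopped at max_candidates")
    found.sort(key=lambda g: (g.length, tuple(sorted(g.genes))))
    return EnumerationResult(found, complete=complete, n_candidates=n_candidates)
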