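"""Per-reaction minimal knockout sets via the Farkas-dual MILP.

The primal question for a knockout pattern K over the genes B(k) of one
eGPR network: seal the y_ON exchange of every gene in K and the y_OFF
exchange of every other gene; can the R_ON output still carry flux?  The
network is a flux cone, so the task is blocked iff the cone admits no flux
with positive output, iff a Farkas certificate exists:

    S^T u + sum over sealed exchanges of v_j e_j - t w >= 0,
    v >= 0, w >= c > 0

with t the indicator of the R_ON output column.  The MILP couples the
certificate to binary seal decisions z (alpha z <= v <= M z), enforces the
knocked/not-knocked coupling z_on + z_off = 1 per gene, requires at least one
knockout, and minimises the number of knocked genes.  Support-exclusion cuts
on the z_on variables enumerate solutions in nondecreasing size while
forbidding supersets, which yields exactly the irreducible (minimal) knockout
sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._solve import solve_milp
from .network import EGPRNetwork, graph_cycle_check


@dataclass
class ReactionMCSSet:
    reaction_id: str
    mcs: list[frozenset[str]]
    #: per-solution solver status ("optimal" or "time_limit")
    statuses: list[str] = field(default_factory=list)
    #: False if enumeration stopped early (time limit)
    complete: bool = True

    def as_sets(self) -> set[frozenset[str]]:
        return set(self.mcs)


def enumerate_reaction_mcs(
    net: EGPRNetwork,
    max_size: int,
    time_limit_s: float | None = 300.0,
    alpha: float = 1e-3,
    big_m: float = 1e3,
    c_min: float = 1.0,
) -> ReactionMCSSet:
    """Enumerate the minimal gene-knockout sets blocking R_ON, up to max_size."""
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    if graph_cycle_check(net):
        raise ValueError(f"eGPR network of {net.reaction_id} is cyclic")
    genes = sorted(net.b_genes)
    n_genes = len(genes)
    if n_genes == 0:
        return ReactionMCSSet(net.reaction_id, [])
    m, n_rxn = net.S.shape
    rid_index = {rid: j for j, (rid, _) in enumerate(net.reactions)}
    y_cols = []  # (network column, v/z index) per y exchange; order: on,off per gene
    for i, g in enumerate(genes):
        y_cols.append((rid_index[net.y_on[g]], 2 * i))
        y_cols.append((rid_index[net.y_off[g]], 2 * i + 1))
    n_y = 2 * n_genes

    # variable layout: [u (m) | v (n_y) | w (1) | z (n_y)]
    iu, iv, iw, iz = 0, m, m + n_y, m + n_y + 1
    n_var = m + n_y + 1 + n_y

    t = np.zeros(n_rxn)
    t[rid_index[net.out_on]] = 1.0

    # dual feasibility: S^T u + V v - t w >= 0
    V = sp.csc_matrix(
        (np.ones(n_y), ([col for col, _ in y_cols], [k for _, k in y_cols])),
        shape=(n_rxn, n_y),
    )
    dual_block = sp.hstack(
        [net.S.T, V, sp.csc_matrix(-t.reshape(-1, 1)), sp.csc_matrix((n_rxn, n_y))]
    )
    # v - alpha z >= 0 ; v - M z <= 0
    I_v = sp.eye(n_y, format="csc")
    link_lo = sp.hstack(
        [sp.csc_matrix((n_y, m)), I_v, sp.csc_matrix((n_y, 1)), -alpha * I_v]
    )
    link_hi = sp.hstack(
        [sp.csc_matrix((n_y, m)), I_v, sp.csc_matrix((n_y, 1)), -big_m * I_v]
    )
    # z_on + z_off = 1 per gene
    pair_rows, pair_cols = [], []
    for i in range(n_genes):
        pair_rows.extend([i, i])
        pair_cols.extend([2 * i, 2 * i + 1])
    pairs = sp.hstack(
        [
            sp.csc_matrix((n_genes, m + n_y + 1)),
            sp.csc_matrix(
                (np.ones(n_y), (pair_rows, pair_cols)), shape=(n_genes, n_y)
            ),
        ]
    )
    # at least one knockout
    z_on_mask = np.zeros(n_var)
    for i in range(n_genes):
        z_on_mask[iz + 2 * i] = 1.0
    atleast = sp.csc_matrix(z_on_mask.reshape(1, -1))

    A_rows = [dual_block, link_lo, link_hi, pairs, atleast]
    lb = np.concatenate(
        [
            np.zeros(n_rxn),
            np.zeros(n_y),
            np.full(n_y, -np.inf),
            np.ones(n_genes),
            [1.0],
        ]
    )
    ub = np.concatenate(
        [
            np.full(n_rxn, np.inf),
            np.full(n_y, np.inf),
            np.zeros(n_y),
            np.ones(n_genes),
            [np.inf],
        ]
    )

    bounds_lo = np.concatenate(
        [np.full(m, -np.inf), np.zeros(n_y), [c_min], np.zeros(n_y)]
    )
    bounds_hi = np.concatenate(
        [np.full(m, np.inf), np.full(n_y, big_m), [big_m], np.ones(n_y)]
    )
    integrality = np.concatenate(
        [np.zeros(m + n_y + 1, dtype=int), np.ones(n_y, dtype=int)]
    )
    objective = z_on_mask.copy()

    found: list[frozenset[str]] = []
    statuses: list[str] = []
    cuts: list[sp.csc_matrix] = []
    cut_ub: list[float] = []
    complete = True
    while True:
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
            time_limit_s=time_limit_s,
        )
        if res.status == "infeasible":
            break
        if res.status != "optimal":
            complete = False
            break
        z = res.x[iz:]
        support = frozenset(genes[i] for i in range(n_genes) if z[2 * i] > 0.5)
        if len(support) > max_size:
            break
        found.append(support)
        statuses.append("optimal")
        row = np.zeros(n_var)
        for i, g in enumerate(genes):
            if g in support:
                row[iz + 2 * i] = 1.0
        cuts.append(sp.csc_matrix(row.reshape(1, -1)))
        cut_ub.append(float(len(support) - 1))
    return ReactionMCSSet(net.reaction_id, found, statuses, complete)
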