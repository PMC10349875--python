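"""Assembly of the genome-wide gene-knockout constraint system (G, F, d).

Each row i pairs an irreducible gene set F(i) (a minimal knockout set that
blocks at least one reaction on its own) with the set G(i) of reactions it
blocks.  Identical gene sets arising from different reactions merge into one
row.  The dependency weight d_i counts the gene deletions exclusively
provided by row i, i.e. the genes of F(i) not already covered by its strict
subset rows; together with the dependency constraints (activating a row
activates all its strict-subset rows) this makes the weighted sum of active
rows count the distinct genes of hierarchically structured row families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .model import MetabolicModel
from .network import compile_egpr_network
from .reaction_mcs import enumerate_reaction_mcs
from .rules import EGPRRuleSet

logger = logging.getLogger(__name__)


@dataclass
class GFMatrices:
    #: row i -> irreducible gene set F(i)
    F_rows: list[frozenset[str]]
    #: row i -> reactions G(i) blocked by deleting F(i)
    G_rows: list[set[str]]
    #: exclusive gene-deletion count per row
    d: np.ndarray
    #: all reaction ids of the model (column universe of G)
    reactions: list[str]
    #: strict-superset dependency pairs (subset_row, superset_row)
    dependencies: list[tuple[int, int]] = field(default_factory=list)
    #: reactions whose per-reaction enumeration hit a time limit
    incomplete_reactions: set[str] = field(default_factory=set)

    @property
    def n_rows(self) -> int:
        return len(self.F_rows)

    @property
    def genes(self) -> list[str]:
        out: set[str] = set()
        for row in self.F_rows:
            out |= row
        return sorted(out)

    def G(self) -> sp.csr_matrix:
        ridx = {r: j for j, r in enumerate(self.reactions)}
        rows, cols = [], []
        for i, g_set in enumerate(self.G_rows):
            for r in g_set:
                rows.append(i)
                cols.append(ridx[r])
        return sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(self.n_rows, len(self.reactions)),
        )

    def F(self) -> sp.csr_matrix:
        gidx = {g: j for j, g in enumerate(self.genes)}
        rows, cols = [], []
        for i, f_set in enumerate(self.F_rows):
            for g in f_set:
                rows.append(i)
                cols.append(gidx[g])
        return sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(self.n_rows, len(gidx))
        )


def _row_order_key(f: frozenset[str]):
    return (len(f), tuple(sorted(f)))


def build_g_matrix(
    model: MetabolicModel,
    rules: EGPRRuleSet,
    max_size: int = 5,
    time_limit_s: float | None = 300.0,
) -> GFMatrices:
    """Enumerate per-reaction minimal knockout sets and assemble G and F.

    Reactions without a GPR rule contribute nothing.  Reactions with an
    identical eGPR system share one enumeration.  Dependency weights are
    computed on the assembled rows.
    """
    merged: dict[frozenset[str], set[str]] = {}
    incomplete: set[str] = set()
    cache: dict[tuple, "object"] = {}
    for rid in model.reactions:
        rule = rules.reaction_rules.get(rid)
        if rule is None:
            continue
        key = (
            rule.to_string(),
            tuple(sorted(rules.reaction_masks.get(rid, set()))),
        )
        if key in cache:
            result = cache[key]
        else:
            net = compile_egpr_network(rules, rid)
            result = enumerate_reaction_mcs(net, max_size, time_limit_s=time_limit_s)
            cache[key] = result
        if not result.complete:
            incomplete.add(rid)
        for mcs in result.mcs:
            merged.setdefault(mcs, set()).add(rid)
    f_rows = sorted(merged, key=_row_order_key)
    gf = GFMatrices(
        F_rows=f_rows,
        G_rows=[merged[f] for f in f_rows],
        d=np.ones(len(f_rows), dtype=int),
        reactions=list(model.reactions),
        incomplete_reactions=incomplete,
    )
    logger.info("G matrix: %d rows x %d reactions", gf.n_rows, len(gf.reactions))
    return compute_dependencies(gf)


def compute_dependencies(gf: GFMatrices) -> GFMatrices:
    """Recompute strict-superset dependency pairs and exclusive counts d.

    d_i = |F(i) \\ union of all strict-subset rows of F(i)|.  On families in
    which overlaps between rows are themselves covered by subset rows, the
    weighted sum of a dependency-closed activation equals the size of the
    union of its active gene sets.
    """
    rows = gf.F_rows
    deps: list[tuple[int, int]] = []
    d = np.zeros(len(rows), dtype=int)
    for i, fi in enumerate(rows):
        covered: set[str] = set()
        for j, fj in enumerate(rows):
            if i != j and fj < fi:
                deps.append((j, i))
                covered |= fj
        d[i] = len(fi - covered)
    gf.dependencies = deps
    gf.d = d
    return gf


def simplify_g_matrix(gf: GFMatrices, max_len: int) -> GFMatrices:
    """Drop rows whose gene set exceeds max_len; recompute dependencies/d."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    keep = [i for i, f in enumerate(gf.F_rows) if len(f) <= max_len]
    out = GFMatrices(
        F_rows=[gf.F_rows[i] for i in keep],
        G_rows=[set(gf.G_rows[i]) for i in keep],
        d=gf.d[keep] if len(keep) else np.zeros(0, dtype=int),
        reactions=list(gf.reactions),
        incomplete_reactions=set(gf.incomplete_reactions),
    )
    return compute_dependencies(out)


# ---------------------------------------------------------------------------
# persistence: MatrixMarket + label files + d TSV
# ---------------------------------------------------------------------------


def save_gf(gf: GFMatrices, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(str(directory / "G.mtx"), sp.coo_matrix(gf.G()))
    mmwrite(str(directory / "F.mtx"), sp.coo_matrix(gf.F()))
    (directory / "reactions.txt").write_text("\n".join(gf.reactions) + "\n")
    genes = gf.genes
    (directory / "genes.txt").write_text("\n".join(genes) + ("\n" if genes else ""))
    pd.DataFrame({"row": range(gf.n_rows), "d": gf.d}).to_csv(
        directory / "d.tsv", sep="\t", index=False
    )
    if gf.incomplete_reactions:
        (directory / "incomplete_reactions.txt").write_text(
            "\n".join(sorted(gf.incomplete_reactions)) + "\n"
        )


def load_gf(directory) -> GFMatrices:
    directory = Path(directory)
    G = sp.csr_matrix(mmread(str(directory / "G.mtx")))
    F = sp.csr_matrix(mmread(str(directory / "F.mtx")))
    reactions = (directory / "reactions.txt").read_text().splitlines()
    genes = (directory / "genes.txt").read_text().splitlines()
    d = pd.read_csv(directory / "d.tsv", sep="\t")["d"].to_numpy()
    f_rows = [
        frozenset(genes[j] for j in F[i].indices) for i in range(F.shape[0])
    ]
    g_rows = [
        {reactions[j] for j in G[i].indices} for i in range(G.shape[0])
    ]
    incomplete: set[str] = set()
    inc_path = directory / "incomplete_reactions.txt"
    if inc_path.exists():
        incomplete = set(inc_path.read_text().splitlines())
    gf = GFMatrices(
        F_rows=f_rows,
        G_rows=g_rows,
        d=d,
        reactions=reactions,
        incomplete_reactions=incomplete,
    )
    return compute_dependencies(gf)
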