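"""Context-specific gene essentiality from expression data and gMCSs.

A gene is potentially essential in a sample when some gMCS contains it as the
unique highly expressed member and every other member is lowly expressed:
the cell then relies on that single gene to keep the cut set open.  The
high/low boundary is the gmcsTH5 threshold: for every gMCS take its
maximum-expression gene (deduplicating genes), and use the 5% lower empirical
quantile of those expression values.  Genes in length-1 gMCSs are essential
in every sample.

Regulatory (eGPR) rules contain negation, so knocking a candidate out may
*activate* another member of its explaining gMCS (an adaptation pathway).
The adaptation check encodes the whole Boolean rule system as linear
constraints over binaries, forces the candidate's knockout node to
zero and minimises the number of active partner genes; a positive optimum
means the gMCS cannot be kept closed and the essentiality call is discarded.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._solve import solve_milp
from .boolean import And, BooleanExpr, Not, Or, Var, to_nnf
from .rules import EGPRRuleSet, gene_dependency_graph

logger = logging.getLogger(__name__)


@dataclass
class ThresholdResult:
    sample: str
    threshold: float
    #: per-gMCS maximum-expression genes (deduplicated) and their values
    genes: list[str]
    values: np.ndarray


@dataclass
class EssentialityCall:
    sample: str
    gene: str
    status: str  # "essential" | "discarded_adaptation" | "not_essential"
    explaining: list[frozenset[str]] = field(default_factory=list)
    adaptation_objective: int | None = None


@dataclass
class EvaluationReport:
    per_sample: pd.DataFrame  # columns sample, TP, FP, PPV
    macro_ppv: float


def compute_gmcsTH5(
    gmcs_list: list[frozenset[str]],
    expr: pd.DataFrame,
    sample: str,
    quantile: float = 0.05,
    missing: str = "zero",
) -> ThresholdResult:
    """Per-sample expression threshold from the gMCS maximum-expression genes.

    Ties at a gMCS's maximum are broken towards the lexicographically
    smallest gene id; repeated genes across gMCSs are counted once.  The
    threshold is the lower empirical (type-1) quantile of the resulting
    values, so it is always an observed expression value.
    """
    if not gmcs_list:
        raise ValueError("empty gMCS list")
    col = expr[sample]

    def value(g: str) -> float:
        if g in col.index:
            return float(col[g])
        if missing == "zero":
            logger.info("gene %s missing from expression; treated as zero", g)
            return 0.0
        raise KeyError(f"gene {g} missing from expression matrix")

    best: dict[str, float] = {}
    for gmcs in gmcs_list:
        members = sorted(gmcs)
        vals = [value(g) for g in members]
        top = members[int(np.argmax(vals))]  # argmax takes the first = lexicographic
        best[top] = max(vals)
    genes = sorted(best)
    values = np.array([best[g] for g in genes])
    threshold = float(np.quantile(values, quantile, method="inverted_cdf"))
    return ThresholdResult(sample, threshold, genes, values)


def call_essential_genes(
    gmcs_list: list[frozenset[str]],
    expr: pd.DataFrame,
    sample: str,
    th: ThresholdResult,
    missing: str = "zero",
) -> list[EssentialityCall]:
    """Candidate essential genes for one sample (before adaptation filtering).

    Highly expressed means strictly above the threshold.  A gene is called
    when some gMCS has it as the unique highly expressed member with all
    other members lowly expressed; single-gene gMCSs call their gene in every
    sample regardless of expression.
    """
    col = expr[sample]

    def value(g: str) -> float:
        if g in col.index:
            return float(col[g])
        if missing == "zero":
            return 0.0
        raise KeyError(g)

    explaining: dict[str, list[frozenset[str]]] = {}
    for gmcs in gmcs_list:
        members = sorted(gmcs)
        if len(members) == 1:
            explaining.setdefault(members[0], []).append(gmcs)
            continue
        high = [g for g in members if value(g) > th.threshold]
        if len(high) == 1:
            explaining.setdefault(high[0], []).append(gmcs)
    return [
        EssentialityCall(sample=th.sample, gene=g, status="essential", explaining=p)
        for g, p in sorted(explaining.items())
    ]


# ---------------------------------------------------------------------------
# adaptation pathways (integer programming)
# ---------------------------------------------------------------------------


@dataclass
class AdaptationQuery:
    target: str
    explaining: frozenset[str]


class BooleanEncoding:
    """Linear-constraint encoding of an acyclic eGPR rule system.

    Variables: one binary x per gene, per knockout node y and per internal
    operator node.  Gene g with equation f is encoded as g = y_g AND f; input
    genes as g = y_g AND s_g with s_g a free binary (the free initial state).
    The feasible 0/1 points are exactly the consistent Boolean states of the
    system for the knockout pattern fixed through the y variables.
    """

    def __init__(self, rules: EGPRRuleSet):
        graph = gene_dependency_graph(rules.equations)
        import networkx as nx

        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("rule system has cyclic gene dependencies")
        self.rules = rules
        self.var_names: list[str] = []
        self._index: dict[str, int] = {}
        self.rows: list[dict[int, float]] = []
        self.lo: list[float] = []
        self.hi: list[float] = []
        self.y_index: dict[str, int] = {}
        self.gene_index: dict[str, int] = {}
        self.s_index: dict[str, int] = {}
        #: operator-node definitions in creation order: (var, "and"/"or", lits)
        self.op_defs: list[tuple[int, str, list[tuple[int, bool]]]] = []
        self._counter = 0
        for g in sorted(rules.layer_index):
            self.y_index[g] = self._new(f"y[{g}]")
        for g in sorted(rules.layer_index):
            xg = self._new(f"x[{g}]")
            self.gene_index[g] = xg
        for g in sorted(rules.layer_index):
            y = self.y_index[g]
            eq = rules.equations.get(g)
            if eq is None:
                state = self._new(f"s[{g}]")
                self.s_index[g] = state
                self._encode_and(self.gene_index[g], [(y, True), (state, True)])
            else:
                sub = self._encode_expr(to_nnf(eq), g)
                self._encode_and(self.gene_index[g], [(y, True), sub])

    def _new(self, name: str) -> int:
        self._index[name] = len(self.var_names)
        self.var_names.append(name)
        return self._index[name]

    @property
    def n_var(self) -> int:
        return len(self.var_names)

    def _lit(self, idx: int, positive: bool) -> tuple[float, float]:
        """coefficient and constant such that value = coeff*x + const."""
        return (1.0, 0.0) if positive else (-1.0, 1.0)

    def _encode_and(self, head: int, lits: list[tuple[int, bool]]) -> None:
        # head <= lit_i ; head >= sum(lit_i) - (k-1)
        k = len(lits)
        for idx, pos in lits:
            coeff, const = self._lit(idx, pos)
            # lit - head >= 0  ->  coeff*x + const - head >= 0
            self.rows.append({idx: coeff, head: -1.0})
            self.lo.append(-const)
            self.hi.append(np.inf)
        row: dict[int, float] = {head: -1.0}
        const_sum = 0.0
        for idx, pos in lits:
            coeff, const = self._lit(idx, pos)
            row[idx] = row.get(idx, 0.0) + coeff
            const_sum += const
        # sum(lit) - head <= k-1
        self.rows.append(row)
        self.lo.append(-np.inf)
        self.hi.append(k - 1 - const_sum)

    def _encode_or(self, head: int, lits: list[tuple[int, bool]]) -> None:
        for idx, pos in lits:
            coeff, const = self._lit(idx, pos)
            # head >= lit  ->  head - coeff*x >= const
            self.rows.append({head: 1.0, idx: -coeff})
            self.lo.append(const)
            self.hi.append(np.inf)
        row: dict[int, float] = {head: 1.0}
        const_sum = 0.0
        for idx, pos in lits:
            coeff, const = self._lit(idx, pos)
            row[idx] = row.get(idx, 0.0) - coeff
            const_sum += const
        # head <= sum(lit)  ->  head - sum(coeff x) <= sum(const)
        self.rows.append(row)
        self.lo.append(-np.inf)
        self.hi.append(const_sum)

    def _encode_expr(self, expr: BooleanExpr, context: str) -> tuple[int, bool]:
        """Return a literal (variable index, polarity) equal to the expression."""
        if isinstance(expr, Var):
            return (self.gene_index[expr.name], True)
        if isinstance(expr, Not):
            idx, pos = self._encode_expr(expr.arg, context)
            return (idx, not pos)
        lits = [self._encode_expr(a, context) for a in expr.args]
        head = self._new(f"op[{context}.{self._counter}]")
        self._counter += 1
        if isinstance(expr, And):
            self._encode_and(head, lits)
            self.op_defs.append((head, "and", lits))
        else:
            self._encode_or(head, lits)
            self.op_defs.append((head, "or", lits))
        return (head, True)

    _matrix_cache = None

    def constraint_matrix(self):
        if self._matrix_cache is not None:
            return self._matrix_cache
        import scipy.sparse as sp

        rows, cols, vals = [], [], []
        for r, row in enumerate(self.rows):
            for cidx, v in row.items():
                rows.append(r)
                cols.append(cidx)
                vals.append(v)
        A = sp.csc_matrix((vals, (rows, cols)), shape=(len(self.rows), self.n_var))
        self._matrix_cache = (A, np.array(self.lo), np.array(self.hi))
        return self._matrix_cache

    def assignment_vector(
        self, gene_values: dict[str, bool], knocked: set[str]
    ) -> np.ndarray:
        """The canonical full variable assignment for a candidate gene state.

        Operator nodes are determined by the gene values; free-state variables
        of unknocked inputs equal the gene value, those of knocked inputs are
        set to zero.  The candidate state is a consistent Boolean state iff
        the returned vector satisfies the encoding.
        """
        x = np.zeros(self.n_var)
        for g, yi in self.y_index.items():
            x[yi] = 0.0 if g in knocked else 1.0
        for g, gi in self.gene_index.items():
            x[gi] = 1.0 if gene_values.get(g, False) else 0.0
        for g, si in self.s_index.items():
            x[si] = 0.0 if g in knocked else x[self.gene_index[g]]
        for head, kind, lits in self.op_defs:
            vals = [x[idx] if pos else 1.0 - x[idx] for idx, pos in lits]
            x[head] = min(vals) if kind == "and" else max(vals)
        return x

    def satisfies(self, x: np.ndarray) -> bool:
        A, lo, hi = self.constraint_matrix()
        ax = A @ x
        return bool(np.all(ax >= lo - 1e-9) and np.all(ax <= hi + 1e-9))


def check_adaptation(
    rules: EGPRRuleSet, query: AdaptationQuery
) -> tuple[int, bool]:
    """Adaptation ILP: can the explaining gMCS stay fully inactive when the target is
    knocked out?  Returns (objective, discarded)."""
    enc = BooleanEncoding(rules)
    A, lo, hi = enc.constraint_matrix()
    n = enc.n_var
    bounds_lo = np.zeros(n)
    bounds_hi = np.ones(n)
    for g, yi in enc.y_index.items():
        if g == query.target:
            bounds_lo[yi] = bounds_hi[yi] = 0.0
        else:
            bounds_lo[yi] = bounds_hi[yi] = 1.0
    c = np.zeros(n)
    for g in query.explaining:
        if g == query.target:
            continue
        c[enc.gene_index[g]] = 1.0
    res = solve_milp(
        c, A, lo, hi, np.ones(n, dtype=int), bounds_lo, bounds_hi
    )
    if res.status != "optimal":
        raise RuntimeError(f"adaptation ILP not optimal: {res.status}")
    objective = int(round(res.objective))
    return objective, objective > 0


def filter_adaptation(
    rules: EGPRRuleSet, calls: list[EssentialityCall]
) -> list[EssentialityCall]:
    """Discard calls whose every explaining gMCS admits an adaptation pathway.

    Adaptation verdicts per (gene, gMCS) pair are cached across samples.
    """
    cache: dict[tuple[str, frozenset[str]], tuple[int, bool]] = {}
    out: list[EssentialityCall] = []
    for call in calls:
        objectives = []
        retained = False
        for p in call.explaining:
            key = (call.gene, p)
            if key not in cache:
                cache[key] = check_adaptation(rules, AdaptationQuery(call.gene, p))
            obj, discarded = cache[key]
            objectives.append(obj)
            if not discarded:
                retained = True
        status = "essential" if retained else "discarded_adaptation"
        out.append(
            EssentialityCall(
                sample=call.sample,
                gene=call.gene,
                status=status,
                explaining=call.explaining,
                adaptation_objective=min(objectives) if objectives else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# consistent-state oracle (used by faithfulness tests)
# ---------------------------------------------------------------------------


def enumerate_consistent_states(
    rules: EGPRRuleSet, knocked: set[str]
) -> list[dict[str, bool]]:
    """All consistent Boolean gene states of an acyclic rule system.

    Input genes range over free values (knocked inputs are forced off);
    regulated genes are determined by their equations with knocked genes
    forced off.
    """
    import networkx as nx

    graph = gene_dependency_graph(rules.equations)
    for g in rules.layer_index:
        graph.add_node(g)
    order = list(nx.topological_sort(graph))
    inputs = [g for g in order if g not in rules.equations]
    states: list[dict[str, bool]] = []
    for values in itertools.product([False, True], repeat=len(inputs)):
        state: dict[str, bool] = {}
        for g, v in zip(inputs, values):
            state[g] = False if g in knocked else v
        for g in order:
            if g in rules.equations:
                val = rules.equations[g].evaluate(state)
                state[g] = False if g in knocked else val
        states.append(dict(state))
    # deduplicate (knocked inputs collapse assignments)
    seen = set()
    unique = []
    for s in states:
        key = tuple(sorted(s.items()))
        if key not in seen:
            seen.add(key)
            unique.append(s)
    return unique


# ---------------------------------------------------------------------------
# evaluation against gold standards
# ---------------------------------------------------------------------------


def evaluate_predictions(
    calls: list[EssentialityCall],
    gold: dict[str, set[str]],
    covered: dict[str, set[str]] | None = None,
) -> EvaluationReport:
    """TP/FP/PPV per sample against gold-standard essential gene sets.

    ``covered`` restricts scoring to labelled genes; predictions outside it
    are excluded (and counted in the log).  PPV is missing when TP+FP = 0.
    """
    rows = []
    samples = sorted({c.sample for c in calls} | set(gold))
    for sample in samples:
        predicted = {
            c.gene for c in calls if c.sample == sample and c.status == "essential"
        }
        if covered is not None and sample in covered:
            dropped = predicted - covered[sample]
            if dropped:
                logger.info(
                    "sample %s: %d predictions outside gold coverage excluded",
                    sample,
                    len(dropped),
                )
            predicted &= covered[sample]
        ess = gold.get(sample, set())
        tp = len(predicted & ess)
        fp = len(predicted - ess)
        ppv = tp / (tp + fp) if (tp + fp) else np.nan
        rows.append({"sample": sample, "TP": tp, "FP": fp, "PPV": ppv})
    df = pd.DataFrame(rows)
    macro = float(df["PPV"].mean(skipna=True)) if len(df) else float("nan")
    return EvaluationReport(df, macro)
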