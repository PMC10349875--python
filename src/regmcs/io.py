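"""Readers/writers for models, regulatory tables and expression matrices.

Two metabolic-model dialects are supported:

* a tabular dialect (TSV with columns ``reaction``, ``equation``,
  ``lower_bound``, ``upper_bound``, ``gpr``; metabolites are implicit in the
  equation strings, e.g. ``"A + 2 B -> C"`` or ``"A <=> B"``), convenient for
  fixtures and CLI runs;
* SBML level 3 (fbc), read through cobra/libsbml.

Regulatory interaction tables are TSVs with columns ``source``, ``target``,
``sign``; unsigned and contradictory rows are dropped (and counted) at read
time, self-loops are removed, matching the cleaning applied to curated
interaction databases before building integrated models.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .boolean import parse_gpr
from .model import FLUX_TOL, MetabolicModel, TaskSpec

logger = logging.getLogger(__name__)

_POSITIVE = {"1", "+1", "activation", "activator", "+", "a"}
_NEGATIVE = {"-1", "−1", "inhibition", "inhibitor", "-", "i", "repression"}


@dataclass
class RegulatoryNetwork:
    """Signed regulator -> target interactions (sign in {+1, -1})."""

    edges: list[tuple[str, str, int]] = field(default_factory=list)

    def regulators_of(self, gene: str) -> list[tuple[str, int]]:
        return [(s, sign) for s, t, sign in self.edges if t == gene]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for s, t, _ in self.edges:
            out.add(s)
            out.add(t)
        return out

    def clean(self) -> "RegulatoryNetwork":
        return clean_regulatory_network(self)


def clean_regulatory_network(net: RegulatoryNetwork) -> RegulatoryNetwork:
    """Drop contradictory duplicates and self-edges; deduplicate.

    Cleaning is idempotent: pairs seen with both signs are removed entirely.
    """
    signs: dict[tuple[str, str], set[int]] = {}
    for s, t, sign in net.edges:
        signs.setdefault((s, t), set()).add(sign)
    edges = []
    n_contradictory = 0
    n_self = 0
    for (s, t), ss in signs.items():
        if len(ss) > 1:
            n_contradictory += 1
            continue
        if s == t:
            n_self += 1
            continue
        edges.append((s, t, next(iter(ss))))
    if n_contradictory:
        logger.info("dropped %d contradictory interaction pairs", n_contradictory)
    if n_self:
        logger.info("dropped %d self-interactions", n_self)
    edges.sort()
    return RegulatoryNetwork(edges)


def read_regulatory_table(path, strict: bool = False) -> RegulatoryNetwork:
    """Read a signed interaction TSV (source, target, sign) and clean it."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise ValueError("regulatory table needs >= 3 columns (source, target, sign)")
    src, tgt, sgn = df.columns[:3]
    edges: list[tuple[str, str, int]] = []
    n_unsigned = 0
    for _, row in df.iterrows():
        raw = row[sgn]
        raw = "" if pd.isna(raw) else str(raw).strip().lower()
        if raw in _POSITIVE:
            sign = 1
        elif raw in _NEGATIVE:
            sign = -1
        elif raw in ("", "na", "nan", "0", "unknown", "none"):
            n_unsigned += 1
            continue
        else:
            if strict:
                raise ValueError(f"unrecognised sign value {raw!r}")
            n_unsigned += 1
            continue
        edges.append((str(row[src]), str(row[tgt]), sign))
    if n_unsigned:
        logger.info("dropped %d unsigned interactions", n_unsigned)
    return clean_regulatory_network(RegulatoryNetwork(edges))


# ---------------------------------------------------------------------------
# tabular metabolic model dialect
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "<->", "->", "=>")


def _parse_side(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    text = text.strip()
    if not text:
        return out
    for part in text.split("+"):
        part = part.strip()
        if not part:
            continue
        m = re.match(r"^(\d+(?:\.\d+)?)\s+(.+)$", part)
        if m:
            coeff, met = float(m.group(1)), m.group(2).strip()
        else:
            coeff, met = 1.0, part
        out[met] = out.get(met, 0.0) + coeff
    return out


def parse_reaction_equation(eq: str) -> tuple[dict[str, float], bool]:
    """Return metabolite coefficients (substrates negative) and reversibility."""
    for arrow in _ARROWS:
        if arrow in eq:
            lhs, rhs = eq.split(arrow, 1)
            reversible = arrow in ("<=>", "<->")
            coeffs: dict[str, float] = {}
            for met, c in _parse_side(lhs).items():
                coeffs[met] = coeffs.get(met, 0.0) - c
            for met, c in _parse_side(rhs).items():
                coeffs[met] = coeffs.get(met, 0.0) + c
            return coeffs, reversible
    raise ValueError(f"no reaction arrow found in equation {eq!r}")


def model_from_records(
    records: list[dict],
    target: str | None = None,
    min_flux: float = 1.0,
) -> MetabolicModel:
    """Build a model from dicts with keys reaction/equation/lower_bound/upper_bound/gpr."""
    metabolites: list[str] = []
    met_index: dict[str, int] = {}
    rows, cols, vals = [], [], []
    reactions, lbs, ubs = [], [], []
    gpr = {}
    for j, rec in enumerate(records):
        rid = str(rec["reaction"])
        coeffs, reversible = parse_reaction_equation(str(rec["equation"]))
        lb = float(rec.get("lower_bound", -1000.0 if reversible else 0.0))
        ub = float(rec.get("upper_bound", 1000.0))
        rule = rec.get("gpr")
        if rule is not None and str(rule).strip() and not pd.isna(rule):
            gpr[rid] = parse_gpr(str(rule))
        reactions.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        for met, c in coeffs.items():
            if met not in met_index:
                met_index[met] = len(metabolites)
                metabolites.append(met)
            rows.append(met_index[met])
            cols.append(j)
            vals.append(c)
    S = sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(metabolites), len(reactions))
    )
    task = TaskSpec(target, min_flux) if target else None
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        stoichiometry=S,
        lower_bounds=np.array(lbs),
        upper_bounds=np.array(ubs),
        gpr=gpr,
        task=task,
    )
    if task is not None and target not in reactions:
        raise ValueError(f"target reaction {target!r} not in model")
    return model


def read_tabular_model(path, target: str | None = None, min_flux: float = 1.0) -> MetabolicModel:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"reaction", "equation"}
    if not required <= set(df.columns):
        raise ValueError(f"tabular model needs columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        rec = {"reaction": row["reaction"], "equation": row["equation"]}
        if "lower_bound" in df.columns and row["lower_bound"] != "":
            rec["lower_bound"] = row["lower_bound"]
        if "upper_bound" in df.columns and row["upper_bound"] != "":
            rec["upper_bound"] = row["upper_bound"]
        if "gpr" in df.columns and row["gpr"] != "":
            rec["gpr"] = row["gpr"]
        records.append(rec)
    return model_from_records(records, target=target, min_flux=min_flux)


def write_tabular_model(model: MetabolicModel, path) -> None:
    rows = []
    S = model.stoichiometry.tocsc()
    for j, rid in enumerate(model.reactions):
        col = S.getcol(j).tocoo()
        subs, prods = [], []
        for i, v in zip(col.row, col.data):
            met = model.metabolites[i]
            txt = met if abs(abs(v) - 1.0) < 1e-12 else f"{abs(v):g} {met}"
            (subs if v < 0 else prods).append(txt)
        arrow = "<=>" if model.lower_bounds[j] < 0 else "->"
        eq = f"{' + '.join(subs)} {arrow} {' + '.join(prods)}".strip()
        rule = model.gpr.get(rid)
        rows.append(
            {
                "reaction": rid,
                "equation": eq,
                "lower_bound": model.lower_bounds[j],
                "upper_bound": model.upper_bounds[j],
                "gpr": rule.to_string() if rule is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sbml_model(path, target: str | None = None, min_flux: float = 1.0) -> MetabolicModel:
    """Read an SBML (fbc) model via cobra and convert to a MetabolicModel."""
    from cobra.io import read_sbml_model as _read

    cmodel = _read(str(path))
    metabolites = [m.id for m in cmodel.metabolites]
    met_index = {m: i for i, m in enumerate(metabolites)}
    reactions, lbs, ubs = [], [], []
    rows, cols, vals = [], [], []
    gpr = {}
    for j, rxn in enumerate(cmodel.reactions):
        reactions.append(rxn.id)
        lbs.append(rxn.lower_bound)
        ubs.append(rxn.upper_bound)
        for met, c in rxn.metabolites.items():
            rows.append(met_index[met.id])
            cols.append(j)
            vals.append(float(c))
        rule = rxn.gene_reaction_rule
        if rule and rule.strip():
            gpr[rxn.id] = parse_gpr(rule)
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(metabolites), len(reactions)))
    task = TaskSpec(target, min_flux) if target else None
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        stoichiometry=S,
        lower_bounds=np.array(lbs),
        upper_bounds=np.array(ubs),
        gpr=gpr,
        task=task,
    )


def read_metabolic_model(
    path, dialect: str = "tabular", target: str | None = None, min_flux: float = 1.0
) -> MetabolicModel:
    if dialect == "tabular":
        return read_tabular_model(path, target=target, min_flux=min_flux)
    if dialect == "sbml":
        return read_sbml_model(path, target=target, min_flux=min_flux)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# medium constraint and model simplification
# ---------------------------------------------------------------------------


def apply_medium_and_simplify(
    model: MetabolicModel,
    medium: list[str],
    fva_prune: bool = False,
) -> MetabolicModel:
    """Close uptake exchanges outside the growth medium and prune the model.

    Input (uptake) exchanges not listed in ``medium`` get upper bound zero;
    reactions whose bounds are fixed to zero are then removed.  With
    ``fva_prune`` set, reactions unable to carry any flux (flux variability
    maximum below tolerance) are removed as well.  The task reaction must
    survive simplification.
    """
    model = model.canonicalise()
    for rid in medium:
        if rid not in model.reactions and rid + "_fwd" not in model.reactions:
            raise ValueError(f"medium reaction {rid!r} not in model")
    medium_orig = set(medium)
    ub = model.upper_bounds.copy()
    for j, rid in enumerate(model.reactions):
        if model.is_input_exchange(rid):
            if rid not in medium_orig and model.original_id[rid] not in medium_orig:
                ub[j] = 0.0
    model = MetabolicModel(
        metabolites=list(model.metabolites),
        reactions=list(model.reactions),
        stoichiometry=model.stoichiometry,
        lower_bounds=model.lower_bounds.copy(),
        upper_bounds=ub,
        gpr=dict(model.gpr),
        task=model.task,
        original_id=dict(model.original_id),
    )
    blocked = {
        rid
        for j, rid in enumerate(model.reactions)
        if model.upper_bounds[j] <= 0.0 and model.lower_bounds[j] >= 0.0
    }
    if model.task is not None and model.task.target_reaction in blocked:
        raise ValueError("medium constraint blocks the task reaction")
    model = model.drop_reactions(blocked)
    if fva_prune:
        dead = {rid for rid in model.reactions if model.fva_max(rid) < FLUX_TOL}
        if model.task is not None and model.task.target_reaction in dead:
            raise ValueError("simplification would remove the task reaction")
        model = model.drop_reactions(dead)
    logger.info(
        "simplified model: %d metabolites, %d reactions",
        len(model.metabolites),
        len(model.reactions),
    )
    return model


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def read_expression(path, missing: str = "error") -> pd.DataFrame:
    """Read a genes x samples expression matrix (TSV/CSV, first column = gene).

    ``missing`` is either "error" or "zero" (impute missing values as zero,
    logged).  Values must be non-negative.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        if missing == "zero":
            logger.info("imputed %d missing expression values as zero", n_missing)
            df = df.fillna(0.0)
        else:
            raise ValueError(f"{n_missing} missing values in expression matrix")
    if (df.values < 0).any():
        raise ValueError("expression values must be non-negative")
    df.index = df.index.astype(str)
    return df
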