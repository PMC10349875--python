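"""Model reading, canonicalisation, regulatory cleaning and simplification."""

import numpy as np
import pandas as pd
import pytest

from regmcs.io import (
    RegulatoryNetwork,
    apply_medium_and_simplify,
    clean_regulatory_network,
    model_from_records,
    read_regulatory_table,
    read_sbml_model,
    read_tabular_model,
    write_tabular_model,
)
from regmcs.model import FLUX_TOL


def test_toy_model_shape(toy):
    model, _ = toy
    assert len(model.reactions) == 6  # 5 GPR'd reactions + uptake
    assert model.gene_list == ["g1", "g2", "g3", "g4", "g5"]
    assert model.is_canonical()


def test_tabular_roundtrip(tmp_path, toy):
    model, _ = toy
    path = tmp_path / "model.tsv"
    write_tabular_model(model, path)
    back = read_tabular_model(path, target="r_bio")
    assert back.reactions == model.reactions
    assert back.metabolites == model.metabolites
    assert (back.stoichiometry != model.stoichiometry).nnz == 0
    assert {r: e.to_string() for r, e in back.gpr.items()} == {
        r: e.to_string() for r, e in model.gpr.items()
    }


def test_reversible_reaction_splits_into_two_columns():
    records = [
        {"reaction": "EX", "equation": "-> A", "lower_bound": 0},
        {"reaction": "rrev", "equation": "A <=> B", "gpr": "g1"},
        {"reaction": "out", "equation": "B ->"},
    ]
    model = model_from_records(records, target="out")
    assert not model.is_canonical()
    canon = model.canonicalise()
    assert canon.n_reactions == model.n_reactions + 1
    assert "rrev_fwd" in canon.reactions and "rrev_rev" in canon.reactions
    j_f = canon.reaction_index("rrev_fwd")
    j_r = canon.reaction_index("rrev_rev")
    Sf = canon.stoichiometry.getcol(j_f).toarray().ravel()
    Sr = canon.stoichiometry.getcol(j_r).toarray().ravel()
    assert np.allclose(Sf, -Sr)
    assert canon.gpr["rrev_fwd"].to_string() == "g1"
    assert canon.original_id["rrev_rev"] == "rrev"
    assert (canon.lower_bounds >= 0).all()


def test_task_flux_preserved_by_canonicalisation():
    records = [
        {"reaction": "EX", "equation": "-> A", "lower_bound": 0, "upper_bound": 7},
        {"reaction": "rrev", "equation": "B <=> A", "gpr": "g1"},
        {"reaction": "out", "equation": "B ->"},
    ]
    model = model_from_records(records, target="out")
    canon = model.canonicalise()
    # original model: flux must run B <- A through the reverse direction
    assert canon.max_task_flux() == pytest.approx(7.0, abs=1e-6)


def test_sbml_roundtrip_matches_tabular(tmp_path, toy):
    cobra = pytest.importorskip("cobra")
    model, _ = toy
    cm = cobra.Model("toy")
    mets = {m: cobra.Metabolite(m, compartment="c") for m in model.metabolites}
    for j, rid in enumerate(model.reactions):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lower_bounds[j])
        rxn.upper_bound = float(model.upper_bounds[j])
        cm.add_reactions([rxn])
        col = model.stoichiometry.getcol(j).tocoo()
        rxn.add_metabolites(
            {mets[model.metabolites[i]]: v for i, v in zip(col.row, col.data)}
        )
        rule = model.gpr.get(rid)
        if rule is not None:
            rxn.gene_reaction_rule = rule.to_string()
    path = tmp_path / "toy.xml"
    cobra.io.write_sbml_model(cm, str(path))
    back = read_sbml_model(path, target="r_bio")
    assert set(back.reactions) == set(model.reactions)
    for rid in model.gpr:
        assert back.gpr[rid] == model.gpr[rid]
    for rid in model.reactions:
        ja, jb = model.reaction_index(rid), back.reaction_index(rid)
        a = model.stoichiometry.getcol(ja).todok()
        b = back.stoichiometry.getcol(jb).todok()
        assert {model.metabolites[i]: v for (i, _), v in a.items()} == {
            back.metabolites[i]: v for (i, _), v in b.items()
        }


# -- regulatory tables -------------------------------------------------------


def test_contradictory_pairs_dropped(tmp_path):
    path = tmp_path / "reg.tsv"
    pd.DataFrame(
        [
            ("a", "b", "+1"),
            ("a", "b", "-1"),
            ("c", "b", "+1"),
        ],
        columns=["source", "target", "sign"],
    ).to_csv(path, sep="\t", index=False)
    net = read_regulatory_table(path)
    assert net.edges == [("c", "b", 1)]


def test_single_edge_identity(tmp_path):
    path = tmp_path / "reg.tsv"
    pd.DataFrame([("a", "b", "+1")], columns=["source", "target", "sign"]).to_csv(
        path, sep="\t", index=False
    )
    assert read_regulatory_table(path).edges == [("a", "b", 1)]


def test_unsigned_row_dropped(tmp_path):
    path = tmp_path / "reg.tsv"
    pd.DataFrame(
        [("a", "b", ""), ("c", "d", "activation"), ("e", "f", "inhibition")],
        columns=["source", "target", "sign"],
    ).to_csv(path, sep="\t", index=False)
    net = read_regulatory_table(path)
    assert net.edges == [("c", "d", 1), ("e", "f", -1)]


def test_strict_mode_rejects_garbage_sign(tmp_path):
    path = tmp_path / "reg.tsv"
    pd.DataFrame([("a", "b", "sideways")], columns=["source", "target", "sign"]).to_csv(
        path, sep="\t", index=False
    )
    with pytest.raises(ValueError):
        read_regulatory_table(path, strict=True)


def test_cleaning_is_idempotent():
    net = RegulatoryNetwork(
        [("a", "b", 1), ("a", "b", -1), ("x", "x", 1), ("c", "d", -1), ("c", "d", -1)]
    )
    once = clean_regulatory_network(net)
    twice = clean_regulatory_network(once)
    assert once.edges == twice.edges == [("c", "d", -1)]


# -- medium constraint and simplification ------------------------------------


def _branched_model():
    records = [
        {"reaction": "EX_A", "equation": "-> A", "lower_bound": 0},
        {"reaction": "EX_X", "equation": "-> X", "lower_bound": 0},
        {"reaction": "r1", "equation": "A -> B", "gpr": "g1"},
        {"reaction": "dead1", "equation": "X -> Y", "gpr": "g2"},
        {"reaction": "dead2", "equation": "Y -> B", "gpr": "g3"},
        {"reaction": "out", "equation": "B ->"},
    ]
    return model_from_records(records, target="out")


def test_medium_closes_and_prunes_dead_chain():
    model = _branched_model()
    simplified = apply_medium_and_simplify(model, ["EX_A"], fva_prune=True)
    assert "EX_X" not in simplified.reactions
    assert "dead1" not in simplified.reactions
    assert "dead2" not in simplified.reactions
    assert simplified.max_task_flux() == pytest.approx(
        model.max_task_flux(), abs=1e-6
    )


def test_medium_all_exchanges_is_identity():
    model = _branched_model()
    out = apply_medium_and_simplify(model, ["EX_A", "EX_X"], fva_prune=False)
    assert out.reactions == model.canonicalise().reactions


def test_simplification_never_changes_task_flux():
    model = _branched_model()
    for medium in (["EX_A"], ["EX_A", "EX_X"]):
        out = apply_medium_and_simplify(model, medium, fva_prune=True)
        # the dead branch never carried task flux, so the optimum is unchanged
        assert out.max_task_flux() == pytest.approx(
            model.max_task_flux(), abs=1e-6
        )


def test_removing_task_reaction_errors():
    records = [
        {"reaction": "EX_A", "equation": "-> A", "lower_bound": 0},
        {"reaction": "out", "equation": "A ->"},
    ]
    model = model_from_records(records, target="out")
    with pytest.raises(ValueError):
        apply_medium_and_simplify(model, [], fva_prune=True)


def test_expression_reader_missing_policy(tmp_path):
    from regmcs.io import read_expression

    path = tmp_path / "expr.csv"
    pd.DataFrame(
        {"s1": [1.0, None], "s2": [2.0, 3.0]}, index=["gA", "gB"]
    ).to_csv(path)
    with pytest.raises(ValueError):
        read_expression(path)
    df = read_expression(path, missing="zero")
    assert df.loc["gB", "s1"] == 0.0
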