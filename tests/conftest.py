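import pandas as pd
import pytest

from regmcs.io import write_tabular_model
from regmcs.synthetic import example_regulatory_network, make_example_toy


@pytest.fixture(scope="session")
def toy():
    """Base five-reaction/five-gene toy (no regulation)."""
    return make_example_toy()


@pytest.fixture(scope="session")
def toy_regulated():
    """Toy with one regulatory layer (g4 = g6 OR NOT g7 OR g8)."""
    return make_example_toy(n_layers=1)


@pytest.fixture()
def toy_files(tmp_path, toy):
    """Toy model + regulatory table written in the tabular dialect."""
    model, _ = toy
    model_path = tmp_path / "model.tsv"
    write_tabular_model(model, model_path)
    reg_path = tmp_path / "reg.tsv"
    pd.DataFrame(
        example_regulatory_network().edges, columns=["source", "target", "sign"]
    ).to_csv(reg_path, sep="\t", index=False)
    return model_path, reg_path
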