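import numpy as np
import pandas as pd
import pytest

import tcrhla as t
from tcrhla import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_pth_table() -> pd.DataFrame:
    """Six raw rows: 1 murine, 1 missing HLA, 1 two-HLA, 1 missing CDR3, 2 clean."""
    return pd.DataFrame(
        {
            "species": ["Mouse", "Human", "Human", "Human", "Human", "Human"],
            "cdr3b": ["CASSL", "CASSF", "CASSG", None, "CASSD", "CASSE"],
            "v_gene": ["TRBV05-01", "V05-01", "V06-01", "V05-01", "V05-01", "V06-01"],
            "j_gene": ["J02", "J02", "J01", "J02", "J01", "J02"],
            "hla": ["A*02:01", None, "A*02:01,B*07:02", "A*02:01", "A*02:01", "B*07:02"],
        }
    )


@pytest.fixture(scope="session")
def catalog() -> t.FrequencyCatalog:
    return t.FrequencyCatalog(
        hla_completions={"A*02": "A*02:01", "B*07": "B*07:02"},
        v_completions={"V05": "V05-01", "V13": "V13-01"},
    )


@pytest.fixture(scope="session")
def counts_8228_pairs() -> list:
    """The 8/2/2/8 contingency toy: (h1,v1):8 (h1,v2):2 (h2,v1):2 (h2,v2):8."""
    h1, h2 = t.HLAAllele("A", "01", "01"), t.HLAAllele("A", "02", "01")
    def mk(v, h):
        return t.PairExample(tcr=t.TCRBeta("CASSF", v, "J01"), hla=h, label=1)
    return ([mk("V01-01", h1)] * 8 + [mk("V02-01", h1)] * 2
            + [mk("V01-01", h2)] * 2 + [mk("V02-01", h2)] * 8)


@pytest.fixture(scope="session")
def small_planted_spec() -> sd.GeneratorSpec:
    """8x8 allele/V-gene universe with a strong planted association."""
    return sd.GeneratorSpec(
        n_tcrs=2000,
        hla_pool=sd.default_hla_pool(4, 4),
        v_pool=sd.default_v_pool(8),
        association=sd.planted_association(8, 8, strength=0.9),
        seed=42,
    )


@pytest.fixture(scope="session")
def fast_config() -> t.BindingModelConfig:
    """Reduced-size training config for unit tests."""
    return t.BindingModelConfig(
        learning_rate=0.003, max_epochs=10, patience=10, ae_epochs=5,
        ae_hidden=64, max_len=21, batch_size=256, seed=0,
    )


@pytest.fixture(scope="session")
def tiny_trained_binding(small_planted_spec, fast_config):
    """One small trained binding model shared by inference-contract tests."""
    pairs = sd.generate_pth(small_planted_spec)
    return t.BindingModel(pairs, config=fast_config).fit(), pairs
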