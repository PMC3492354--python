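import numpy as np
import pandas as pd
import pytest

import methcall as mc


@pytest.fixture(scope="session")
def ccnd1():
    """Deterministic 17-probe single-gene fixture (beta, annotation, sheet)."""
    return mc.make_ccnd1_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic dataset with fully penetrant planted signal."""
    cfg = mc.SyntheticConfig(
        n_genes=120,
        n_planted_hyper=3,
        n_planted_hypo=6,
        planted_case_fraction=1.0,
        bad_sample_count=1,
        n_failed_probes=4,
        seed=7,
    )
    return mc.generate(cfg)


@pytest.fixture
def tiny_beta():
    """3 probes x 4 samples, hand-written values."""
    df = pd.DataFrame(
        {
            "s1": [0.10, 0.90, 0.50],
            "s2": [0.15, 0.85, 0.55],
            "s3": [0.80, 0.20, 0.45],
            "s4": [0.85, 0.10, np.nan],
        },
        index=["p1", "p2", "p3"],
    )
    return mc.BetaMatrix(df)


def case_and_refs(sheet):
    case = list(sheet.index[sheet["group"] == "NB"])
    refs = mc.reference_groups(sheet)
    return case, refs
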