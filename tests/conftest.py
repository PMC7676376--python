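import numpy as np
import pandas as pd
import pytest

from megex import MegaSimConfig, StudyDataset, generate_collection


@pytest.fixture(scope="session")
def small_collection():
    """A small 16-study collection with 5 planted down-regulated genes."""
    cfg = MegaSimConfig(
        seed=20260926, n_genes=60, n_planted=5, planted_lfc=-1.8, tau2=0.05
    )
    studies, truth = generate_collection(cfg)
    return cfg, studies, truth


@pytest.fixture()
def tiny_study():
    """3 genes x 5 samples, hand-enterable values."""
    mat = pd.DataFrame(
        [[4.0, 4.0, 4.0, 2.0, 2.0],
         [1.0, 1.0, 1.0, 1.0, 1.0],
         [3.0, 6.0, 12.0, 2.0, 4.0]],
        index=["DOUBLE", "FLAT", "MIXED"],
        columns=["s1", "s2", "s3", "s4", "s5"],
    )
    return StudyDataset(
        study_id="TINY",
        matrix=mat,
        groups=["case", "case", "case", "control", "control"],
        country="USA",
        study_age=5.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
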