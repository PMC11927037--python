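import numpy as np
import pandas as pd
import pytest

from mrcascade.sumstats import HarmonizedPairs


def make_pairs(beta_exp, beta_out, se_out, se_exp=None) -> HarmonizedPairs:
    """Build a HarmonizedPairs table from plain arrays."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.broadcast_to(np.asarray(se_out, dtype=float), beta_exp.shape)
    if se_exp is None:
        se_exp = np.full_like(beta_exp, 0.01)
    else:
        se_exp = np.broadcast_to(np.asarray(se_exp, dtype=float), beta_exp.shape)
    return HarmonizedPairs(
        pd.DataFrame(
            {
                "snp": [f"rs{i:04d}" for i in range(len(beta_exp))],
                "beta_exp": beta_exp,
                "se_exp": se_exp,
                "beta_out": beta_out,
                "se_out": se_out,
                "eaf": 0.3,
                "action": "kept",
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def sumstats_tsv(tmp_path):
    """A small, well-formed summary-statistics TSV."""
    path = tmp_path / "ss.tsv"
    pd.DataFrame(
        {
            "snp": ["rs1", "rs2", "rs3"],
            "chr": ["1", "1", "2"],
            "pos": [1000, 2000, 3000],
            "ea": ["A", "C", "G"],
            "oa": ["G", "T", "T"],
            "eaf": [0.2, 0.4, 0.5],
            "beta": [0.1, -0.2, 0.05],
            "se": [0.02, 0.03, 0.01],
            "p": [1e-6, 3e-11, 0.02],
            "n": [1000, 1000, 1000],
        }
    ).to_csv(path, sep="\t", index=False)
    return path
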