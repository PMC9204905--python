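import numpy as np
import pandas as pd
import pytest

from methmark.arrays import ProbeBetaMatrix


@pytest.fixture
def tiny_matrix() -> ProbeBetaMatrix:
    """Two genes x (2 tumors + 2 normals), hand-set betas for exact checks.

    GENE_A: tumor probes at 0.6/0.6, normal at 0.1/0.1 (delta 0.5).
    GENE_B: flat 0.2 everywhere (delta 0).
    """
    probes = pd.DataFrame(
        {
            "gene": ["GENE_A", "GENE_A", "GENE_B"],
            "region": ["promoter", "exon1", "promoter"],
        },
        index=pd.Index(["pA1", "pA2", "pB1"], name="probe_id"),
    )
    samples = pd.DataFrame(
        {
            "role": ["tumor", "tumor", "adjacent_normal", "adjacent_normal"],
            "pair_id": ["P1", "P2", "P1", "P2"],
            "response": ["CR", "PD", "none", "none"],
            "tissue": "breast",
        },
        index=pd.Index(["T1", "T2", "N1", "N2"], name="sample_id"),
    )
    beta = pd.DataFrame(
        [[0.6, 0.6, 0.1, 0.1], [0.6, 0.6, 0.1, 0.1], [0.2, 0.2, 0.2, 0.2]],
        index=probes.index,
        columns=samples.index,
    )
    return ProbeBetaMatrix(beta, probes, samples)
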