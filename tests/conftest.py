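import numpy as np
import pandas as pd
import pytest

from coexpatlas import SimulationDesign, simulate_expression
from coexpatlas.simulate import simulate_annotations, simulate_counts


@pytest.fixture(scope="session")
def default_bundle():
    """One default-design synthetic atlas shared by read-only tests."""
    design = SimulationDesign(seed=11)
    tpm, samples, truth = simulate_expression(design)
    counts = simulate_counts(tpm, 2e7, seed=12)
    go_map = simulate_annotations(truth, seed=13)
    return {"design": design, "tpm": tpm, "samples": samples, "truth": truth,
            "counts": counts, "go_map": go_map}


@pytest.fixture()
def tiny_tpm():
    """A hand-sized matrix: 4 genes x 6 samples over 3 tissues."""
    genes = ["gA", "gB", "gC", "gD"]
    cols = ["t1_a", "t1_b", "t2_a", "t2_b", "t3_a", "t3_b"]
    data = np.array([
        [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],      # flat
        [2.0, 4.0, 6.0, 2.0, 4.0, 6.0],      # variable
        [0.5, 0.9, 0.0, 0.2, 0.8, 0.3],      # never reaches 1 TPM
        [40.0, 38.0, 1.0, 1.2, 1.1, 0.9],    # tissue-1 biased
    ])
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"), columns=cols)


@pytest.fixture()
def tiny_samples():
    return pd.DataFrame({
        "sample_id": ["t1_a", "t1_b", "t2_a", "t2_b", "t3_a", "t3_b"],
        "tissue": ["leaf", "leaf", "root", "root", "pollen", "pollen"],
        "clade": ["aerial", "aerial", "underground", "underground",
                  "pollen", "pollen"],
    })
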