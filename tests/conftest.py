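import numpy as np
import pandas as pd
import pytest

import lowph


@pytest.fixture(scope="session")
def zero_noise_sim():
    """Noise-free simulation: fold changes equal the planted values exactly."""
    cfg = lowph.SimulationConfig(noise_cv=0.0, seed=7)
    matrix, truth = lowph.simulate_expression(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def noisy_sim():
    """Default simulation: 200 planted genes, log-normal noise at CV 0.1."""
    cfg = lowph.SimulationConfig(seed=3)
    matrix, truth = lowph.simulate_expression(cfg)
    return cfg, matrix, truth


@pytest.fixture()
def hand_matrix():
    """A 4-gene, 16-sample matrix with spreadsheet-checkable values."""
    genes = ["gA", "gB", "gC", "gD"]
    rows = []
    cols = {}
    base = {"gA": 10.0, "gB": 50.0, "gC": 100.0, "gD": 8.0}
    # mutant multipliers at (stress, control); KF-7 stays at baseline
    mult = {
        "B3": {"gA": (4.0, 1.0), "gB": (0.13, 0.52), "gC": (1.0, 1.0), "gD": (2.0, 2.0)},
        "C3": {"gA": (1.0, 1.0), "gB": (1.0, 1.0), "gC": (3.0, 1.5), "gD": (1.0, 1.0)},
        "BC3": {"gA": (1.0, 1.0), "gB": (1.0, 1.0), "gC": (1.0, 1.0), "gD": (0.25, 0.5)},
    }
    for strain in lowph.STRAINS:
        for cond_i, cond in enumerate(lowph.CONDITIONS):
            for rep in (1, 2):
                sid = f"{strain}_{cond}_r{rep}"
                vals = []
                for g in genes:
                    m = 1.0 if strain == "KF-7" else mult[strain][g][cond_i]
                    vals.append(base[g] * m)
                cols[sid] = vals
                rows.append((sid, strain, cond, rep))
    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "strain", "condition", "replicate"]
    ).set_index("sample_id")
    return lowph.ExpressionMatrix(values=values, samples=samples), mult
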