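import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from phosphopipe import pipeline, syndata
from phosphopipe.io import PhosphoSiteTable, PipelineConfig


@pytest.fixture(scope="session")
def default_sim():
    """One simulated experiment at the emulated study conditions (seed 1)."""
    return syndata.simulate_experiment(syndata.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Preprocessing + differential statistics + classification on the
    default simulation; shared across tests that probe planted truth."""
    cfg = PipelineConfig(seed=1)
    pre = pipeline.preprocess_table(default_sim.table, default_sim.design, cfg)
    diff = pipeline.differential(pre.matrix, default_sim.design, pre.sv)
    cls = pipeline.classification(diff, cfg)
    return {"config": cfg, "pre": pre, "diff": diff, "cls": cls}


@pytest.fixture
def tiny_table():
    """3 sites x 4 samples with one missing value."""
    meta = pd.DataFrame(
        {
            "gene": ["AKT2", "AKT2", "GSK3B"],
            "residue": ["S", "T", "S"],
            "position": [474, 451, 9],
            "window": ["RPHFPQFSYSASGTA", "RPRHLNSTTDLYLTA", "RARTSSFSEPGGGGG"],
            "localization_probability": [0.99, 0.80, 0.60],
        },
        index=pd.Index(["AKT2_S474", "AKT2_T451", "GSK3B_S9"], name="site_id"),
    )
    inten = pd.DataFrame(
        {
            "s1": [1024.0, 64.0, 256.0],
            "s2": [2048.0, np.nan, 128.0],
            "s3": [512.0, 32.0, 512.0],
            "s4": [4096.0, 16.0, 64.0],
        },
        index=meta.index,
    )
    return PhosphoSiteTable(meta=meta, intensities=inten)
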