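import numpy as np
import pandas as pd
import pytest

from glycoferm import pipeline, simulate


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study shared by read-only tests."""
    cfg = simulate.SimConfig(seed=11, n_glycans=20, n_donors=4)
    plate, truth = simulate.generate_plate_timeseries(cfg)
    taxa, meta, effects = simulate.generate_taxa_tables(cfg)
    return {"config": cfg, "plate": plate, "truth": truth,
            "taxa": taxa, "meta": meta, "effects": effects}


@pytest.fixture(scope="session")
def phenotyped(small_study):
    cfg = small_study["config"]
    per_rep, per_glycan = pipeline.phenotype_plate(small_study["plate"], cfg.ph_model)
    return per_rep, per_glycan


def logistic(t, k, r, tm, od0=0.0):
    return od0 + k / (1.0 + np.exp(-r * (np.asarray(t, dtype=float) - tm)))
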