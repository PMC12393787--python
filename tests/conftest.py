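import numpy as np
import pytest

import kneemamba as km


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic 64x64x2 phantom (image, labels)."""
    spec = km.PhantomSpec(size=(64, 64, 2), seed=7)
    return km.generate_phantom_volume(spec)


@pytest.fixture(scope="session")
def smoke_run():
    """Train the reduced full model once per session on 32 phantoms.

    32 single-slice 64x64 phantoms, 200 AdamW steps; 8 extra phantoms are
    held out for evaluation.  Shared by the pipeline and end-to-end tests.
    """
    spec = km.PhantomSpec(size=(64, 64, 1))
    train_cohort = km.generate_cohort(32, spec, seed=101)
    holdout = km.generate_cohort(8, spec, seed=202)
    train_cohort = [(km.zscore_normalize(v), m) for v, m in train_cohort]
    holdout = [(km.zscore_normalize(v), m) for v, m in holdout]
    cfg = km.smoke_config(seed=0, max_steps=200)
    model, log = km.train_model(cfg, train_cohort)
    return {"model": model, "log": log, "holdout": holdout,
            "train_cohort": train_cohort, "config": cfg}
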