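import numpy as np
import pandas as pd
import pytest

from translatome.de import DEConfig
from translatome.ingest import CountMatrix, align_samples, validate_sample_meta
from translatome.pipeline import RunConfig, run_all
from translatome.simulate import paperlike_preset, simulate_dataset


def make_counts(arr, assay="mRNA", genes=None, samples=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(
        counts=pd.DataFrame(arr, index=genes, columns=samples), assay=assay
    )


def make_meta(samples, species="spX", assay="mRNA", conditions=None, replicates=None):
    n = len(samples)
    if conditions is None:
        half = n // 2
        conditions = ["diapause"] * half + ["developing"] * (n - half)
    if replicates is None:
        reps, seen = [], {}
        for c in conditions:
            seen[c] = seen.get(c, 0) + 1
            reps.append(seen[c])
        replicates = reps
    return validate_sample_meta(
        pd.DataFrame(
            {
                "sample_id": samples,
                "species": species,
                "condition": conditions,
                "replicate": replicates,
                "assay": assay,
            }
        )
    )


def make_aligned(arr, assay="mRNA", species="spX", n_dia=None):
    """Aligned toy experiment; first n_dia columns diapause, rest developing."""
    cm = make_counts(arr, assay=assay)
    n = cm.n_samples
    n_dia = n_dia if n_dia is not None else n // 2
    conds = ["diapause"] * n_dia + ["developing"] * (n - n_dia)
    meta = make_meta(cm.sample_ids, species=species, assay=assay, conditions=conds)
    return align_samples(cm, meta)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced draw of the calibrated preset for fast integration tests."""
    cfg = paperlike_preset()
    cfg.n_genes = 1200
    cfg.seed = 42
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def paperlike_report():
    """Full-size pipeline run on the calibrated preset (shared across tests)."""
    cfg = paperlike_preset()
    cfg.seed = 1
    return run_all(RunConfig(simulate=cfg, seed=1))


@pytest.fixture(scope="session")
def paperlike_dataset():
    cfg = paperlike_preset()
    cfg.seed = 1
    return simulate_dataset(cfg)
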