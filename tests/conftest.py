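import numpy as np
import pytest

from molfusion.synthetic_data import SyntheticSpec, make_benchmark


@pytest.fixture(scope="session")
def balanced_bench():
    """Small balanced planted-rule benchmark shared across tests."""
    spec = SyntheticSpec(n_compounds=700, seed=11)
    compounds, manifest = make_benchmark(spec, "balanced")
    return compounds, manifest


@pytest.fixture(scope="session")
def severe_bench():
    """Severely imbalanced (~4:1) benchmark."""
    spec = SyntheticSpec(n_compounds=700, seed=19)
    compounds, manifest = make_benchmark(spec, "severe")
    return compounds, manifest


@pytest.fixture(scope="session")
def bench_features(balanced_bench):
    """ECFP4 features + labels + true family ids for the balanced benchmark."""
    from molfusion.featurize import compute_fingerprint

    compounds, manifest = balanced_bench
    smiles = [c.canonical_smiles for c in compounds]
    labels = np.array([c.label for c in compounds])
    families = np.array([manifest["family_id"][s] for s in smiles])
    ecfp = compute_fingerprint(smiles, "ECFP4")
    return {"smiles": smiles, "labels": labels, "families": families, "ecfp": ecfp,
            "activity_um": np.array([c.activity_um for c in compounds])}
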