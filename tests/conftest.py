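import numpy as np
import pandas as pd
import pytest

from mtselect import MitoGenomeModel, MutationCatalog, annotate_catalog


@pytest.fixture(scope="session")
def model():
    return MitoGenomeModel.bundled()


def make_catalog(model, positions, n_samples=100, vafs=None, sample_ids=None):
    """Annotated catalog from reference-consistent transition calls."""
    positions = np.asarray(positions, dtype=int)
    refs = [model.ref_base(p) for p in positions]
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    alts = [transition[r] for r in refs]
    n = len(positions)
    df = pd.DataFrame(
        {
            "sample_id": sample_ids if sample_ids is not None else ["S0"] * n,
            "position": positions,
            "ref": refs,
            "alt": alts,
            "t_alt_fwd": 10,
            "t_alt_rev": 10,
            "t_depth": 1000,
            "t_vaf": vafs if vafs is not None else 0.05,
            "n_vaf": 0.0,
        }
    )
    return annotate_catalog(MutationCatalog(df, n_samples=n_samples), model)


@pytest.fixture(scope="session")
def ctr_positions(model):
    return np.where(model.mask("mtCTR"))[0]
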