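import numpy as np
import pandas as pd
import pytest

from silacswap.model import CANONICAL_COLS, RATIO_SLOTS, ExposureDataset


def make_dataset(
    treated,
    control,
    intensity=None,
    n_peptides=5,
    decoy=None,
    contaminant=None,
    gene_symbols=None,
    cell_line="TEST",
    emf_type="synthetic",
):
    """Build an ExposureDataset from raw ratio arrays (log2, NaN = missing)."""
    treated = np.atleast_2d(np.asarray(treated, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    n = treated.shape[0]
    assert treated.shape == (n, 4) and control.shape == (n, 2)
    rec = pd.DataFrame(
        {
            "group_id": [f"G{i:04d}" for i in range(n)],
            "accession": [f"A{i:04d}" for i in range(n)],
            "gene_symbol": gene_symbols if gene_symbols is not None
            else [f"SYM{i:04d}" for i in range(n)],
            "species": "human",
            "is_decoy": decoy if decoy is not None else [False] * n,
            "is_contaminant": contaminant if contaminant is not None else [False] * n,
            "n_peptides": n_peptides if np.ndim(n_peptides) else [n_peptides] * n,
            "intensity": intensity if intensity is not None else np.full(n, 1e6),
        }
    )
    block = np.hstack([treated, control])
    for j, slot in enumerate(RATIO_SLOTS):
        rec[slot] = block[:, j]
    for slot in RATIO_SLOTS:
        rec[f"nq_{slot}"] = np.where(np.isnan(rec[slot]), 0, 2)
    rec = rec.loc[:, list(CANONICAL_COLS)]
    return ExposureDataset(cell_line=cell_line, emf_type=emf_type, records=rec)


@pytest.fixture
def tiny_dataset():
    """Three proteins: clear up, clear down, inconsistent."""
    treated = [
        [0.5, 0.6, 0.4, 0.5],
        [-0.8, -0.7, -0.9, -0.8],
        [0.5, 0.3, -0.1, 0.4],
    ]
    control = [
        [0.05, -0.05],
        [0.1, -0.1],
        [0.02, 0.01],
    ]
    return make_dataset(treated, control)
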