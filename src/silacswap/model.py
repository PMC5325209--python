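"""Internal data model for triplex-SILAC double-label-swap datasets.

A dataset is a table of quantified protein groups, each carrying six
oriented log2 SILAC ratios: four "treated" ratios (exposed vs sham, two
per reciprocal labeling experiment) and two "control" ratios (same-state
channel pairs measuring technical variation only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Oriented treated slots: replicate 1 mixes sham L0/M0 with exposed H1
#: (ratios H1/L0, H1/M0); replicate 2 mixes exposed L1/M1 with sham H0
#: (ratios L1/H0, M1/H0).  All stored as log2(exposed/sham).
TREATED_SLOTS = ("treated_r1_HL", "treated_r1_HM", "treated_r2_LH", "treated_r2_MH")

#: Control slots: same-state channel pairs (M0/L0 and M1/L1), log2.
CONTROL_SLOTS = ("control_r1", "control_r2")

RATIO_SLOTS = TREATED_SLOTS + CONTROL_SLOTS

#: Quantitation-event count columns matching each ratio slot.
NQ_COLS = tuple(f"nq_{slot}" for slot in RATIO_SLOTS)

#: Label pair exercised by each treated slot (H-L or H-M swap).
SLOT_PAIR = {
    "treated_r1_HL": "H-L",
    "treated_r1_HM": "H-M",
    "treated_r2_LH": "H-L",
    "treated_r2_MH": "H-M",
}

META_COLS = (
    "group_id",
    "accession",
    "gene_symbol",
    "species",
    "is_decoy",
    "is_contaminant",
    "n_peptides",
    "intensity",
)

#: Canonical column order for the tab-delimited on-disk form.
CANONICAL_COLS = META_COLS + RATIO_SLOTS + NQ_COLS


@dataclass
class ExposureDataset:
    """One exposure experiment: a protein-group table plus provenance.

    ``records`` holds one row per protein group with the columns in
    :data:`CANONICAL_COLS`.  Ratio slots are oriented log2 values with
    NaN marking a missing quantification.  ``normalization_offsets``
    records the per-column median shift applied by
    :func:`silacswap.io.normalize_ratios` (log2 units).
    """

    cell_line: str
    emf_type: str
    records: pd.DataFrame
    normalization_offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing required columns: {missing}")
        if self.records["group_id"].duplicated().any():
            dupes = self.records.loc[self.records["group_id"].duplicated(), "group_id"]
            raise ValueError(f"duplicate group_ids: {sorted(set(dupes))[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    # -- convenience views -------------------------------------------------

    def treated_matrix(self) -> np.ndarray:
        """(n, 4) array of oriented treated log2 ratios (NaN = missing)."""
        return self.records.loc[:, list(TREATED_SLOTS)].to_numpy(dtype=float)

    def control_matrix(self) -> np.ndarray:
        """(n, 2) array of control log2 ratios (NaN = missing)."""
        return self.records.loc[:, list(CONTROL_SLOTS)].to_numpy(dtype=float)

    def complete_mask(self) -> np.ndarray:
        """Boolean mask of protein groups with all six ratios present."""
        ratios = self.records.loc[:, list(RATIO_SLOTS)].to_numpy(dtype=float)
        return ~np.isnan(ratios).any(axis=1)

    def subset(self, mask) -> "ExposureDataset":
        """New dataset restricted to ``mask`` rows; offsets are carried over."""
        return ExposureDataset(
            cell_line=self.cell_line,
            emf_type=self.emf_type,
            records=self.records.loc[mask].reset_index(drop=True),
            normalization_offsets=dict(self.normalization_offsets),
        )


def empty_records() -> pd.DataFrame:
    """An empty records frame with the canonical schema."""
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in CANONICAL_COLS})
    for c in RATIO_SLOTS + ("intensity",):
        df[c] = df[c].astype(float)
    for c in NQ_COLS + ("n_peptides",):
        df[c] = df[c].astype(int)
    for c in ("is_decoy", "is_contaminant"):
        df[c] = df[c].astype(bool)
    return df
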