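"""Reading, validating, filtering and normalizing protein-group tables.

The on-disk input is a MaxQuant-style tab-delimited ``proteinGroups``
table.  Column names vary between dialects, so the reader takes a
:class:`ColumnMap` describing which file column fills which role and
which raw ratio columns must be reciprocal-reoriented so that every
treated slot stores log2(exposed/sham).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import yaml

from .model import (
    CANONICAL_COLS,
    NQ_COLS,
    RATIO_SLOTS,
    ExposureDataset,
)

__all__ = [
    "ColumnMap",
    "read_protein_groups",
    "write_protein_groups",
    "read_canonical",
    "filter_quality",
    "normalize_ratios",
    "quantitation_summary",
]


@dataclass
class RatioColumn:
    """One raw ratio column: its header and whether the stored linear
    ratio is the reciprocal of the exposed/sham orientation."""

    column: str
    invert: bool = False


@dataclass
class ColumnMap:
    """Mapping from dialect column headers to canonical roles."""

    accession: str
    gene_symbol: str
    peptides: str
    intensity: str
    reverse: str
    contaminant: str
    ratios: dict[str, RatioColumn]
    ratio_counts: dict[str, str] = field(default_factory=dict)
    group_id: str | None = None
    species: str | None = None
    species_value: str = "other"

    def __post_init__(self) -> None:
        missing = [s for s in RATIO_SLOTS if s not in self.ratios]
        if missing:
            raise ValueError(f"column_map lacks ratio slots: {missing}")

    @classmethod
    def default_maxquant(cls) -> "ColumnMap":
        """The dialect emitted by :func:`silacswap.simulate.write_maxquant_like`.

        Replicate-2 H/L and H/M columns hold sham-over-exposed ratios
        (H0 is the sham channel there), hence ``invert=True``.
        """
        return cls(
            group_id="id",
            accession="Majority protein IDs",
            gene_symbol="Gene names",
            species="Species",
            peptides="Razor + unique peptides",
            intensity="Intensity",
            reverse="Reverse",
            contaminant="Potential contaminant",
            ratios={
                "treated_r1_HL": RatioColumn("Ratio H/L normalized 1"),
                "treated_r1_HM": RatioColumn("Ratio H/M normalized 1"),
                "treated_r2_LH": RatioColumn("Ratio H/L normalized 2", invert=True),
                "treated_r2_MH": RatioColumn("Ratio H/M normalized 2", invert=True),
                "control_r1": RatioColumn("Ratio M/L normalized 1"),
                "control_r2": RatioColumn("Ratio M/L normalized 2"),
            },
            ratio_counts={
                "treated_r1_HL": "Ratio H/L count 1",
                "treated_r1_HM": "Ratio H/M count 1",
                "treated_r2_LH": "Ratio H/L count 2",
                "treated_r2_MH": "Ratio H/M count 2",
                "control_r1": "Ratio M/L count 1",
                "control_r2": "Ratio M/L count 2",
            },
        )

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnMap":
        ratios = {
            slot: RatioColumn(**spec) if isinstance(spec, dict) else RatioColumn(spec)
            for slot, spec in d["ratios"].items()
        }
        kwargs = {k: v for k, v in d.items() if k != "ratios"}
        return cls(ratios=ratios, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ColumnMap":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = {
            "accession": self.accession,
            "gene_symbol": self.gene_symbol,
            "peptides": self.peptides,
            "intensity": self.intensity,
            "reverse": self.reverse,
            "contaminant": self.contaminant,
            "ratios": {
                s: {"column": rc.column, "invert": rc.invert}
                for s, rc in self.ratios.items()
            },
            "ratio_counts": dict(self.ratio_counts),
            "species_value": self.species_value,
        }
        if self.group_id is not None:
            d["group_id"] = self.group_id
        if self.species is not None:
            d["species"] = self.species
        return d


def _parse_ratio_column(raw: pd.Series, invert: bool, column: str) -> np.ndarray:
    """Linear ratio text -> oriented log2 values with NaN for missing.

    Zero, NaN and empty cells all mean "not quantified" in the MaxQuant
    dialect; non-numeric cells raise a record-level warning.
    """
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} non-numeric cell(s) in ratio column {column!r} "
            "treated as missing",
            stacklevel=3,
        )
    arr = values.to_numpy(dtype=float)
    arr[arr == 0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.log2(arr)
    out[~np.isfinite(out)] = np.nan
    return -out if invert else out


def read_protein_groups(
    path,
    column_map: ColumnMap | None = None,
    *,
    cell_line: str = "",
    emf_type: str = "synthetic",
) -> ExposureDataset:
    """Read a tab-delimited protein-group table into an :class:`ExposureDataset`.

    Ratio columns are log2-transformed on read and reciprocal-reoriented
    to exposed/sham where the column map declares ``invert``.  A missing
    mapped column is a hard error naming the column.
    """
    cmap = column_map or ColumnMap.default_maxquant()
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    raw = raw.replace({"": None})

    required = [cmap.accession, cmap.gene_symbol, cmap.peptides, cmap.intensity,
                cmap.reverse, cmap.contaminant]
    required += [rc.column for rc in cmap.ratios.values()]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise KeyError(f"input table lacks mapped column(s): {missing}")

    n = len(raw)
    out = pd.DataFrame(index=range(n))
    if cmap.group_id is not None and cmap.group_id in raw.columns:
        out["group_id"] = raw[cmap.group_id].to_numpy()
    else:
        out["group_id"] = [str(i) for i in range(n)]
    out["accession"] = raw[cmap.accession].fillna("").to_numpy()
    out["gene_symbol"] = raw[cmap.gene_symbol].fillna("").to_numpy()
    if cmap.species is not None and cmap.species in raw.columns:
        out["species"] = raw[cmap.species].fillna(cmap.species_value).to_numpy()
    else:
        out["species"] = cmap.species_value
    out["is_decoy"] = (raw[cmap.reverse] == "+").to_numpy()
    out["is_contaminant"] = (raw[cmap.contaminant] == "+").to_numpy()
    out["n_peptides"] = (
        pd.to_numeric(raw[cmap.peptides], errors="coerce").fillna(0).astype(int).to_numpy()
    )
    out["intensity"] = (
        pd.to_numeric(raw[cmap.intensity], errors="coerce").fillna(0.0).to_numpy()
    )
    for slot in RATIO_SLOTS:
        rc = cmap.ratios[slot]
        out[slot] = _parse_ratio_column(raw[rc.column], rc.invert, rc.column)
    for slot in RATIO_SLOTS:
        col = cmap.ratio_counts.get(slot)
        if col is not None and col in raw.columns:
            out[f"nq_{slot}"] = (
                pd.to_numeric(raw[col], errors="coerce").fillna(0).astype(int).to_numpy()
            )
        else:
            out[f"nq_{slot}"] = 0
    out = out.loc[:, list(CANONICAL_COLS)]
    return ExposureDataset(cell_line=cell_line, emf_type=emf_type, records=out)


def write_protein_groups(ds: ExposureDataset, path) -> None:
    """Write the canonical tab-delimited form (fixed column order, UTF-8)."""
    ds.records.loc[:, list(CANONICAL_COLS)].to_csv(
        path, sep="\t", index=False, na_rep=""
    )


def read_canonical(path, *, cell_line: str = "", emf_type: str = "synthetic") -> ExposureDataset:
    """Read back a table written by :func:`write_protein_groups`."""
    df = pd.read_csv(path, sep="\t", dtype={"group_id": str, "gene_symbol": str,
                                            "accession": str, "species": str},
                     keep_default_na=True)
    for c in ("gene_symbol", "accession", "species"):
        df[c] = df[c].fillna("")
    for c in RATIO_SLOTS:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in NQ_COLS + ("n_peptides",):
        df[c] = pd.to_numeric(df[c], errors="coerce").fillna(0).astype(int)
    for c in ("is_decoy", "is_contaminant"):
        df[c] = df[c].astype(bool)
    return ExposureDataset(cell_line=cell_line, emf_type=emf_type,
                           records=df.loc[:, list(CANONICAL_COLS)])


def filter_quality(
    ds: ExposureDataset, min_peptides: int = 2
) -> tuple[ExposureDataset, dict[str, int]]:
    """Drop decoys, contaminants and under-supported groups.

    Returns the retained subset plus counts removed per reason.  A record
    failing several criteria is counted once, in the order decoy >
    contaminant > peptides, so the counts sum to input - output size.
    """
    rec = ds.records
    decoy = rec["is_decoy"].to_numpy(dtype=bool)
    contam = rec["is_contaminant"].to_numpy(dtype=bool) & ~decoy
    few = (
        (rec["n_peptides"].to_numpy() < min_peptides) & ~decoy
        & ~rec["is_contaminant"].to_numpy(dtype=bool)
    )
    keep = ~(decoy | contam | few)
    removed = {
        "decoy": int(decoy.sum()),
        "contaminant": int(contam.sum()),
        "min_peptides": int(few.sum()),
    }
    if not keep.any():
        warnings.warn("filter_quality removed every record", stacklevel=2)
    return ds.subset(keep), removed


def normalize_ratios(ds: ExposureDataset, min_values: int = 3) -> ExposureDataset:
    """Median-center each of the six log2 ratio columns.

    Offsets accumulate in ``normalization_offsets`` so that a repeat
    application is a no-op (idempotent).  Columns with fewer than
    ``min_values`` non-missing entries are skipped with a warning.
    """
    rec = ds.records.copy()
    offsets = dict(ds.normalization_offsets)
    for slot in RATIO_SLOTS:
        col = rec[slot].to_numpy(dtype=float)
        finite = np.isfinite(col)
        if finite.sum() < min_values:
            warnings.warn(
                f"ratio column {slot!r} has <{min_values} values; not normalized",
                stacklevel=2,
            )
            continue
        shift = float(np.median(col[finite]))
        rec[slot] = col - shift
        offsets[slot] = offsets.get(slot, 0.0) + shift
    return ExposureDataset(
        cell_line=ds.cell_line,
        emf_type=ds.emf_type,
        records=rec,
        normalization_offsets=offsets,
    )


def quantitation_summary(ds: ExposureDataset) -> dict[str, float]:
    """Counts/percentages of groups quantified in replicate 1, replicate 2
    and completely (all six ratios), relative to identified groups."""
    rec = ds.records
    r1_slots = ["treated_r1_HL", "treated_r1_HM", "control_r1"]
    r2_slots = ["treated_r2_LH", "treated_r2_MH", "control_r2"]
    n = len(rec)
    r1 = rec.loc[:, r1_slots].notna().any(axis=1).sum()
    r2 = rec.loc[:, r2_slots].notna().any(axis=1).sum()
    complete = rec.loc[:, list(RATIO_SLOTS)].notna().all(axis=1).sum()
    pct = lambda k: 100.0 * k / n if n else float("nan")  # noqa: E731
    return {
        "n_identified": n,
        "n_quant_r1": int(r1),
        "n_quant_r2": int(r2),
        "n_complete": int(complete),
        "pct_quant_r1": pct(r1),
        "pct_quant_r2": pct(r2),
        "pct_complete": pct(complete),
    }
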