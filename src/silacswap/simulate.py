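"""Synthetic triplex-SILAC double-swap data with known ground truth.

The generator emulates the measurement structure of a reciprocal-label
exposure experiment: per-protein log-intensities, a small regulated
fraction with modest fold changes, label-specific per-protein bias
(stronger for the H-L channel pair than H-M), intensity-dependent ratio
noise, per-slot missingness, and decoy/contaminant records.  A matching
term-annotation generator feeds the protein-set analysis stage.

Per protein the six oriented log2 ratios are built as::

    treated_r1_HL = d + b_HL + e      treated_r2_LH = d - b_HL + e
    treated_r1_HM = d + b_HM + e      treated_r2_MH = d - b_HM + e
    control_r1    = (b_HM - b_HL) * kappa + e
    control_r2    = (b_HM - b_HL) * kappa + e

with d the true log2 fold change (0 for unregulated proteins),
b_HL ~ N(0, s_HL^2), b_HM ~ N(0, s_HM^2) per-protein label effects,
each e an independent N(0, sigma(I)^2) draw, and
sigma(I) = sigma0 * exp(-slope * (logI - median logI)).

The label bias enters the two replicates with opposite signs, which is
what produces the negative reciprocal-ratio correlations seen when bias
dominates treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ColumnMap
from .model import CANONICAL_COLS, RATIO_SLOTS, ExposureDataset

__all__ = [
    "SimulationParams",
    "simulate_exposure",
    "write_maxquant_like",
    "simulate_annotations",
]

LOG2_12 = float(np.log2(1.2))
LOG2_28 = float(np.log2(2.8))


@dataclass
class SimulationParams:
    """Knobs for :func:`simulate_exposure`; defaults give a realistic
    bias-dominated dataset with ~1% regulated proteins."""

    n_proteins: int = 3000
    frac_regulated: float = 0.01
    effect_log2fc_range: tuple[float, float] = (LOG2_12, LOG2_28)
    noise_sd_base: float = 0.1
    noise_intensity_slope: float = 0.15
    label_bias_sd_hl: float = 0.3
    label_bias_sd_hm: float = 0.15
    control_coupling: float = 1.0  # kappa: how much label bias leaks into controls
    missing_rate: float = 0.0
    n_decoys: int = 0
    n_contaminants: int = 0
    intensity_log_mean: float = 16.0
    intensity_log_sd: float = 1.5
    species: str = "human"
    cell_line: str = "SIM"
    emf_type: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_regulated <= 1.0:
            raise ValueError("frac_regulated must be in [0, 1]")
        if self.label_bias_sd_hl < self.label_bias_sd_hm or self.label_bias_sd_hm < 0:
            raise ValueError("require label_bias_sd_hl >= label_bias_sd_hm >= 0")
        if self.noise_sd_base < 0:
            raise ValueError("noise_sd_base must be >= 0")
        lo, hi = self.effect_log2fc_range
        if not (0 < lo <= hi):
            raise ValueError("effect_log2fc_range lower bound must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def _ratio_block(rng, n, d, s_hl, s_hm, kappa, sigma):
    """Six oriented log2 ratio columns for n proteins (no missingness)."""
    b_hl = rng.normal(0.0, s_hl, n)
    b_hm = rng.normal(0.0, s_hm, n)
    eps = rng.normal(0.0, 1.0, (n, 6)) * sigma[:, None]
    cols = np.empty((n, 6))
    cols[:, 0] = d + b_hl + eps[:, 0]  # treated_r1_HL
    cols[:, 1] = d + b_hm + eps[:, 1]  # treated_r1_HM
    cols[:, 2] = d - b_hl + eps[:, 2]  # treated_r2_LH
    cols[:, 3] = d - b_hm + eps[:, 3]  # treated_r2_MH
    cols[:, 4] = (b_hm - b_hl) * kappa + eps[:, 4]  # control_r1
    cols[:, 5] = (b_hm - b_hl) * kappa + eps[:, 5]  # control_r2
    return cols


def simulate_exposure(params: SimulationParams) -> tuple[ExposureDataset, pd.DataFrame]:
    """Generate one exposure dataset plus its truth table.

    The truth table has one row per target protein (decoys and
    contaminants excluded) with columns ``group_id``, ``regulated``,
    ``true_log2fc`` and ``true_intensity``.  Deterministic under
    ``params.seed``: a single numpy Generator is consumed in a fixed
    order (intensities, effects, ratios, missingness, extras).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_proteins

    log_i = rng.normal(p.intensity_log_mean, p.intensity_log_sd, n)
    intensity = np.exp(log_i)

    n_reg = int(round(p.frac_regulated * n))
    if p.frac_regulated > 0 and n_reg == 0:
        warnings.warn("frac_regulated * n_proteins < 1: no regulated proteins")
    regulated = np.zeros(n, dtype=bool)
    regulated[rng.choice(n, size=n_reg, replace=False)] = True
    d = np.zeros(n)
    lo, hi = p.effect_log2fc_range
    mag = rng.uniform(lo, hi, n_reg)
    sign = rng.choice([-1.0, 1.0], size=n_reg)
    d[regulated] = sign * mag

    sigma = p.noise_sd_base * np.exp(
        -p.noise_intensity_slope * (log_i - np.median(log_i))
    )
    ratios = _ratio_block(
        rng, n, d, p.label_bias_sd_hl, p.label_bias_sd_hm, p.control_coupling, sigma
    )
    if p.missing_rate > 0:
        ratios[rng.random((n, 6)) < p.missing_rate] = np.nan

    # intensity-linked peptide-count model; some groups fall under the
    # two-peptide quality threshold on purpose
    pep_mean = np.exp(1.0 + 0.6 * (log_i - np.median(log_i)))
    n_pep = 1 + rng.poisson(pep_mean)
    nq = rng.poisson(np.maximum(n_pep, 1)[:, None] * np.ones((1, 6)))
    nq[np.isnan(ratios)] = 0

    sym_prefix = "GENE" if p.species == "human" else "Gene"
    rec = pd.DataFrame(
        {
            "group_id": [f"P{i:05d}" for i in range(n)],
            "accession": [f"ACC{i:05d}" for i in range(n)],
            "gene_symbol": [f"{sym_prefix}{i:05d}" for i in range(n)],
            "species": p.species,
            "is_decoy": False,
            "is_contaminant": False,
            "n_peptides": n_pep,
            "intensity": intensity,
        }
    )
    for j, slot in enumerate(RATIO_SLOTS):
        rec[slot] = ratios[:, j]
    for j, slot in enumerate(RATIO_SLOTS):
        rec[f"nq_{slot}"] = nq[:, j]

    extras = []
    for kind, count in (("decoy", p.n_decoys), ("contaminant", p.n_contaminants)):
        if count == 0:
            continue
        e_log_i = rng.normal(p.intensity_log_mean, p.intensity_log_sd, count)
        e_sigma = p.noise_sd_base * np.exp(
            -p.noise_intensity_slope * (e_log_i - np.median(log_i))
        )
        e_ratios = _ratio_block(
            rng, count, np.zeros(count), p.label_bias_sd_hl, p.label_bias_sd_hm,
            p.control_coupling, e_sigma,
        )
        if p.missing_rate > 0:
            e_ratios[rng.random((count, 6)) < p.missing_rate] = np.nan
        tag = "REV" if kind == "decoy" else "CON"
        ext = pd.DataFrame(
            {
                "group_id": [f"{tag}{i:05d}" for i in range(count)],
                "accession": [f"{tag}__ACC{i:05d}" for i in range(count)],
                "gene_symbol": "" if kind == "decoy" else f"{tag}GENE",
                "species": p.species,
                "is_decoy": kind == "decoy",
                "is_contaminant": kind == "contaminant",
                "n_peptides": 1 + rng.poisson(2.0, count),
                "intensity": np.exp(e_log_i),
            }
        )
        for j, slot in enumerate(RATIO_SLOTS):
            ext[slot] = e_ratios[:, j]
        for j, slot in enumerate(RATIO_SLOTS):
            e_nq = rng.poisson(2.0, count)
            e_nq[np.isnan(e_ratios[:, j])] = 0
            ext[f"nq_{slot}"] = e_nq
        extras.append(ext)

    if extras:
        rec = pd.concat([rec] + extras, ignore_index=True)
    rec = rec.loc[:, list(CANONICAL_COLS)]

    truth = pd.DataFrame(
        {
            "group_id": [f"P{i:05d}" for i in range(n)],
            "regulated": regulated,
            "true_log2fc": d,
            "true_intensity": intensity,
        }
    )
    ds = ExposureDataset(cell_line=p.cell_line, emf_type=p.emf_type, records=rec)
    return ds, truth


def write_maxquant_like(
    ds: ExposureDataset, path, column_map: ColumnMap | None = None
) -> None:
    """Serialize a dataset in the raw dialect the reader expects.

    Ratio slots are converted back to linear scale and, for columns the
    map declares inverted, to their raw (sham/exposed) orientation.
    Missing slots serialize as empty cells; flags use "+"/"".
    """
    cmap = column_map or ColumnMap.default_maxquant()
    rec = ds.records
    out = pd.DataFrame(index=rec.index)
    if cmap.group_id is not None:
        out[cmap.group_id] = rec["group_id"]
    out[cmap.accession] = rec["accession"]
    out[cmap.gene_symbol] = rec["gene_symbol"]
    if cmap.species is not None:
        out[cmap.species] = rec["species"]
    out[cmap.peptides] = rec["n_peptides"]
    out[cmap.intensity] = rec["intensity"]
    out[cmap.reverse] = np.where(rec["is_decoy"], "+", "")
    out[cmap.contaminant] = np.where(rec["is_contaminant"], "+", "")
    for slot in RATIO_SLOTS:
        rc = cmap.ratios[slot]
        log2v = rec[slot].to_numpy(dtype=float)
        linear = np.exp2(-log2v if rc.invert else log2v)
        out[rc.column] = linear
    for slot, col in cmap.ratio_counts.items():
        out[col] = rec[f"nq_{slot}"]
    out.to_csv(path, sep="\t", index=False, na_rep="")


def simulate_annotations(
    n_terms: int,
    n_items: int,
    items_per_term=20,
    n_active: int = 1,
    alpha: float = 0.05,
    beta: float = 0.2,
    seed: int = 0,
):
    """Bipartite term->item annotations with a noisy observed study set.

    Hidden item state is the OR over its active annotating terms; the
    observed study set includes a hidden-off item with probability
    ``alpha`` and drops a hidden-on item with probability ``beta``.
    ``items_per_term`` may be an int (fixed size) or a (lo, hi) tuple
    (uniform inclusive).  Returns ``(annotations, active_terms,
    study_set)`` where annotations maps term id -> frozenset of items.
    """
    if not (0 <= alpha < 0.5 and 0 <= beta < 0.5):
        raise ValueError("alpha and beta must be in [0, 0.5)")
    if n_active > n_terms:
        raise ValueError("n_active exceeds n_terms")
    rng = np.random.default_rng(seed)
    items = [f"item{i:04d}" for i in range(n_items)]
    annotations: dict[str, frozenset[str]] = {}
    for t in range(n_terms):
        if isinstance(items_per_term, tuple):
            k = int(rng.integers(items_per_term[0], items_per_term[1] + 1))
        else:
            k = int(items_per_term)
        k = max(1, min(k, n_items))
        chosen = rng.choice(n_items, size=k, replace=False)
        annotations[f"term{t:03d}"] = frozenset(items[i] for i in chosen)
    active = sorted(
        f"term{t:03d}" for t in rng.choice(n_terms, size=n_active, replace=False)
    )
    hidden = set()
    for t in active:
        hidden |= annotations[t]
    study = set()
    for it in items:
        if it in hidden:
            if rng.random() >= beta:
                study.add(it)
        else:
            if rng.random() < alpha:
                study.add(it)
    return annotations, active, study
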