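"""Swap diagnostics: reciprocal-ratio correlation, quadrant classes and
paired comparison of the two label-swap types.

Plotting the replicate-1 oriented treated ratio against the replicate-2
oriented treated ratio for the same channel pair separates treatment
effect from label bias: a shared treatment effect pushes the scatter
toward the identity line (r > 0) while a per-protein label effect enters
the two replicates with opposite signs and pulls r negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import ExposureDataset

__all__ = [
    "CorrelationSummary",
    "PairedTResult",
    "SWAP_PAIR_SLOTS",
    "reciprocal_correlation",
    "classify_quadrants",
    "compare_swap_bias",
]

#: (replicate-1 slot, replicate-2 slot) per label-swap pair.
SWAP_PAIR_SLOTS = {
    "H-L": ("treated_r1_HL", "treated_r2_LH"),
    "H-M": ("treated_r1_HM", "treated_r2_MH"),
}


@dataclass
class CorrelationSummary:
    swap_pair: str
    n: int
    r: float
    ci95: tuple[float, float]
    p_value: float


@dataclass
class PairedTResult:
    n: int
    mean_diff: float
    ci95: tuple[float, float]
    t: float
    df: int
    p_value: float


def _pair_values(ds: ExposureDataset, swap_pair: str) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    if swap_pair not in SWAP_PAIR_SLOTS:
        raise ValueError(f"unknown swap pair {swap_pair!r}; use 'H-L' or 'H-M'")
    s1, s2 = SWAP_PAIR_SLOTS[swap_pair]
    sub = ds.records.loc[:, ["group_id", s1, s2]].dropna()
    return (
        sub[s1].to_numpy(dtype=float),
        sub[s2].to_numpy(dtype=float),
        pd.Index(sub["group_id"]),
    )


def reciprocal_correlation(ds: ExposureDataset, swap_pair: str = "H-L") -> CorrelationSummary:
    """Pearson correlation of the two oriented treated ratios of one
    swap pair, with Fisher-z 95% CI and two-tailed p.

    Missing slots are handled by pairwise-complete deletion; the n used
    is reported.  Fewer than 3 complete pairs, or a zero-variance axis,
    is an error.
    """
    x, y, _ = _pair_values(ds, swap_pair)
    n = len(x)
    if n < 3:
        raise ValueError(f"need >=3 complete pairs for {swap_pair}; got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance on one axis; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    # two-tailed p from the t transform of r
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (-1.0, 1.0)
    return CorrelationSummary(swap_pair=swap_pair, n=n, r=r, ci95=ci, p_value=p)


def classify_quadrants(ds: ExposureDataset, swap_pair: str = "H-L") -> pd.Series:
    """Per-protein scatter class for one swap pair.

    consistent-up: both oriented treated ratios > 0; consistent-down:
    both < 0; otherwise inconsistent (-a when x >= 0 >= y, -b when
    x <= 0 <= y).  Exact zeros land in the inconsistent classes.  The
    mapping of classes onto display quadrant numerals is a presentation
    concern and deliberately not fixed here.
    """
    x, y, idx = _pair_values(ds, swap_pair)
    labels = np.where(
        (x > 0) & (y > 0),
        "consistent-up",
        np.where(
            (x < 0) & (y < 0),
            "consistent-down",
            np.where((x >= 0) & (y <= 0), "inconsistent-a", "inconsistent-b"),
        ),
    )
    return pd.Series(labels, index=idx, name=f"quadrant_{swap_pair}")


def compare_swap_bias(pairs) -> PairedTResult:
    """Paired two-tailed t-test on |r_HL| - |r_HM| across experiments.

    ``pairs`` is a sequence of (|r_HL|, |r_HM|) tuples (absolute
    correlations may also be passed as CorrelationSummary pairs).  A
    positive mean difference says the H-L swap carries the stronger
    label bias.
    """
    vals = []
    for a, b in pairs:
        ra = abs(a.r) if isinstance(a, CorrelationSummary) else abs(float(a))
        rb = abs(b.r) if isinstance(b, CorrelationSummary) else abs(float(b))
        vals.append((ra, rb))
    n = len(vals)
    if n < 2:
        raise ValueError("need >=2 experiments for a paired comparison")
    diffs = np.array([a - b for a, b in vals])
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    df = n - 1
    se = sd / np.sqrt(n)
    if se == 0:
        t = 0.0 if mean == 0 else float(np.inf) * np.sign(mean)
        p = 1.0 if mean == 0 else 0.0
        ci = (mean, mean)
    else:
        t = mean / se
        p = float(2.0 * stats.t.sf(abs(t), df=df))
        half = float(stats.t.ppf(0.975, df=df)) * se
        ci = (mean - half, mean + half)
    return PairedTResult(n=n, mean_diff=mean, ci95=ci, t=float(t), df=df, p_value=p)
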