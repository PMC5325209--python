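"""Design-aware consistency/composite filters and MAD signal-to-noise.

The reciprocal design supports two Boolean filters: "consistent" keeps
proteins whose four treated ratios agree in sign across both labeling
experiments, and "composite" additionally requires the treated ratios to
dominate the control ratios.  Filter quality is summarized by the MAD of
pooled treated vs pooled control ratios; their ratio is the S/N of the
detection problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ExposureDataset

__all__ = [
    "FilterReport",
    "ConsistencySplit",
    "mad",
    "consistency_filter",
    "composite_filter",
    "signal_to_noise",
]

MAD_SCALE = 1.4826  # consistency constant vs the normal SD


@dataclass
class FilterReport:
    filter_name: str
    n_in: int
    n_out: int
    mad_treated: float
    mad_control: float
    snr: float  # NaN when mad_control == 0


@dataclass
class ConsistencySplit:
    consistent: ExposureDataset
    inconsistent: ExposureDataset
    n_excluded: int  # lacked one or more treated slots
    report_consistent: FilterReport
    report_inconsistent: FilterReport


def mad(values, scaled: bool = True) -> float:
    """Median absolute deviation; * 1.4826 when ``scaled``."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("mad of empty input is undefined")
    m = float(np.median(np.abs(arr - np.median(arr))))
    return m * MAD_SCALE if scaled else m


def signal_to_noise(ds: ExposureDataset, filter_name: str = "unfiltered",
                    n_in: int | None = None) -> FilterReport:
    """Pool treated slots across proteins -> MAD_treated; pool control
    slots -> MAD_control; S/N is their ratio (scaling constant cancels).
    """
    treated = ds.treated_matrix().ravel()
    control = ds.control_matrix().ravel()
    treated = treated[np.isfinite(treated)]
    control = control[np.isfinite(control)]
    mad_t = mad(treated) if treated.size else float("nan")
    mad_c = mad(control) if control.size else float("nan")
    snr = mad_t / mad_c if mad_c and np.isfinite(mad_c) and mad_c > 0 else float("nan")
    return FilterReport(
        filter_name=filter_name,
        n_in=len(ds) if n_in is None else n_in,
        n_out=len(ds),
        mad_treated=mad_t,
        mad_control=mad_c,
        snr=snr,
    )


def consistency_filter(ds: ExposureDataset) -> ConsistencySplit:
    """Split proteins with all four treated slots into sign-consistent
    vs inconsistent; proteins lacking a treated slot are excluded from
    both and counted.  Exact zeros break strict-sign consistency.
    """
    treated = ds.treated_matrix()
    have_all = ~np.isnan(treated).any(axis=1)
    with np.errstate(invalid="ignore"):
        consistent = have_all & (
            (treated > 0).all(axis=1) | (treated < 0).all(axis=1)
        )
    inconsistent = have_all & ~consistent
    ds_con = ds.subset(consistent)
    ds_inc = ds.subset(inconsistent)
    return ConsistencySplit(
        consistent=ds_con,
        inconsistent=ds_inc,
        n_excluded=int((~have_all).sum()),
        report_consistent=signal_to_noise(ds_con, "consistent", n_in=len(ds)),
        report_inconsistent=signal_to_noise(ds_inc, "inconsistent", n_in=len(ds)),
    )


def composite_filter(
    ds: ExposureDataset, rule: str = "strict"
) -> tuple[ExposureDataset, FilterReport]:
    """Keep complete six-ratio proteins whose treated ratios are
    sign-consistent AND dominate the control ratios.

    ``rule='strict'`` (default) requires min |treated| > max |control|;
    ``rule='mean'`` requires mean |treated| > mean |control|.
    """
    if rule not in ("strict", "mean"):
        raise ValueError("rule must be 'strict' or 'mean'")
    complete = ds.complete_mask()
    treated = ds.treated_matrix()
    control = ds.control_matrix()
    with np.errstate(invalid="ignore"):
        consistent = (treated > 0).all(axis=1) | (treated < 0).all(axis=1)
        if rule == "strict":
            dominate = np.nanmin(np.abs(treated), axis=1) > np.nanmax(
                np.abs(control), axis=1
            )
        else:
            dominate = np.nanmean(np.abs(treated), axis=1) > np.nanmean(
                np.abs(control), axis=1
            )
    passes = complete & consistent & dominate
    sub = ds.subset(passes)
    return sub, signal_to_noise(sub, "composite", n_in=len(ds))
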