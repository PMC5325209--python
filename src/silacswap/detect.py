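"""Six differential-regulation detectors, BH adjustment and the
ensemble union.

Three outlier detectors work on the per-protein mean oriented treated
log2 ratio: the standard Z-score, its robust median/MAD counterpart
(M-score) and an intensity-binned percentile-calibrated outlier p
(significance-B style).  Two rank-based detectors (rank product with a
permutation null, and a fold-change rank-ordering statistic calibrated
against a normal null centered at 0.5) work on the four treated ratio
columns.  The sixth detector fits a per-protein linear model separating
the treatment effect from the control (label) effect and applies an
empirical-Bayes moderated test against a fold-change threshold.

Each detector returns a :class:`MethodResult`; the ensemble union
combines calls across detectors at configurable fold-change / p-value
stringency tiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .model import TREATED_SLOTS, ExposureDataset

__all__ = [
    "MethodResult",
    "EnsembleResult",
    "fold_change_estimate",
    "fold_change_method",
    "z_score_test",
    "m_score_test",
    "significance_b",
    "rank_product",
    "fcros",
    "moderated_treat",
    "bh_adjust",
    "ensemble_union",
    "run_detectors",
]

RESULT_COLS = ["fc", "direction", "statistic", "p_raw", "p_adj"]


@dataclass
class MethodResult:
    """Per-protein output of one detector.

    ``table`` is indexed by group_id with columns ``fc`` (linear-scale
    fold-change magnitude, >= 1), ``direction`` ('up'/'down'),
    ``statistic`` (method-specific), ``p_raw`` and ``p_adj`` (BH).
    The non-statistical FC method carries NaN p-values.
    """

    method: str
    table: pd.DataFrame

    def tier_mask(
        self,
        fc_tier: float | None = None,
        p_tier: float | None = None,
        use_adjusted: bool = False,
    ) -> pd.Series:
        """Boolean call mask at the given stringency tier."""
        mask = pd.Series(True, index=self.table.index)
        if fc_tier is not None:
            mask &= self.table["fc"] > fc_tier
        if p_tier is not None:
            col = "p_adj" if use_adjusted else "p_raw"
            mask &= self.table[col] < p_tier
        return mask


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    finite = np.isfinite(arr)
    if not finite.any():
        return arr.astype(float).copy()
    vals = arr[finite]
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    n = vals.size
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.full(arr.shape, np.nan)
    tmp = np.empty(n)
    tmp[order] = np.minimum(adj, 1.0)
    out[finite] = tmp
    return out


# ---------------------------------------------------------------------------
# shared helpers

def _mean_treated(ds: ExposureDataset) -> tuple[np.ndarray, pd.Index]:
    """Per-protein mean of the four oriented treated log2 ratios for
    proteins with all four slots present."""
    treated = ds.treated_matrix()
    have = ~np.isnan(treated).any(axis=1)
    x = treated[have].mean(axis=1)
    idx = pd.Index(ds.records.loc[have, "group_id"])
    return x, idx

def _base_table(x: np.ndarray, idx: pd.Index, statistic: np.ndarray,
                p_raw: np.ndarray, direction: np.ndarray | None = None) -> pd.DataFrame:
    fc = np.exp2(np.abs(x))
    if direction is None:
        direction = np.where(x >= 0, "up", "down")
    return pd.DataFrame(
        {
            "fc": fc,
            "direction": direction,
            "statistic": statistic,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
        },
        index=idx,
    )


def fold_change_estimate(rs) -> tuple[float, str]:
    """Fold change from one six-ratio record (mapping or Series).

    Returns (magnitude on the linear scale, 'up'/'down') based on the
    mean of the four oriented treated log2 ratios; undefined (NaN) if a
    treated slot is missing.
    """
    vals = np.array([float(rs[s]) for s in TREATED_SLOTS])
    if np.isnan(vals).any():
        return float("nan"), "undefined"
    m = vals.mean()
    return float(np.exp2(abs(m))), "up" if m >= 0 else "down"


# ---------------------------------------------------------------------------
# detectors

def fold_change_method(ds: ExposureDataset) -> MethodResult:
    """Plain fold-change call (no p-value); thresholded by FC tiers only."""
    x, idx = _mean_treated(ds)
    nan = np.full(x.shape, np.nan)
    tab = _base_table(x, idx, statistic=np.exp2(np.abs(x)), p_raw=nan)
    tab["p_adj"] = np.nan
    return MethodResult("FC", tab)


def z_score_test(ds: ExposureDataset) -> MethodResult:
    """Standard Z-score of per-protein mean treated ratios; two-tailed
    normal p.  |Z| > 1.65/1.96/2.58 corresponds to p < 0.1/0.05/0.01."""
    x, idx = _mean_treated(ds)
    if x.size < 3:
        raise ValueError("need >=3 proteins with complete treated ratios")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation; Z-score undefined")
    z = (x - x.mean()) / sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    return MethodResult("Z", _base_table(x, idx, z, p))


def m_score_test(ds: ExposureDataset) -> MethodResult:
    """Robust Z: 0.6745 * (x - median) / unscaled MAD; two-tailed normal p."""
    x, idx = _mean_treated(ds)
    if x.size < 3:
        raise ValueError("need >=3 proteins with complete treated ratios")
    med = np.median(x)
    mad0 = np.median(np.abs(x - med))
    if mad0 == 0:
        raise ValueError("zero MAD; M-score undefined")
    m = 0.6745 * (x - med) / mad0
    p = 2.0 * stats.norm.sf(np.abs(m))
    return MethodResult("M", _base_table(x, idx, m, p))


def significance_b(ds: ExposureDataset, min_bin: int = 300) -> MethodResult:
    """Intensity-binned percentile-calibrated outlier test.

    Proteins are sorted by intensity and cut into consecutive bins of at
    least ``min_bin`` (single bin when n < 2*min_bin).  Within each bin
    the 15.87/50/84.13 percentiles of the mean treated ratio calibrate
    asymmetric tail z-scores; the one-sided tail p is doubled into
    ``p_raw`` so that tiers are two-tailed comparable (the one-sided
    tail is kept in column ``p_tail``).
    """
    treated = ds.treated_matrix()
    have = ~np.isnan(treated).any(axis=1)
    x = treated[have].mean(axis=1)
    idx = pd.Index(ds.records.loc[have, "group_id"])
    intensity = ds.records.loc[have, "intensity"].to_numpy(dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need >=3 proteins")

    order = np.argsort(intensity, kind="mergesort")
    n_bins = max(1, n // min_bin)
    bounds = [i * min_bin for i in range(n_bins)] + [n]
    z = np.empty(n)
    for b in range(n_bins):
        sel = order[bounds[b]:bounds[b + 1]]
        xb = x[sel]
        r_lo, r0, r_hi = np.percentile(xb, [15.87, 50.0, 84.13])
        if r_hi <= r0 or r0 <= r_lo:
            raise ValueError(
                f"degenerate ratio percentiles in intensity bin {b}: spread too "
                "small; lower min_bin or inspect the ratio distribution"
            )
        zb = np.where(xb > r0, (xb - r0) / (r_hi - r0), (r0 - xb) / (r0 - r_lo))
        z[sel] = zb
    p_tail = stats.norm.sf(z)
    p_two = np.minimum(1.0, 2.0 * p_tail)
    tab = _base_table(x, idx, z, p_two)
    tab["p_tail"] = p_tail
    return MethodResult("sigB", tab)


def _pooled_null_counts(
    obs_up: np.ndarray,
    obs_dn: np.ndarray,
    obs_min: np.ndarray,
    n: int,
    k: int,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled permutation-null counts for the up, down and two-sided
    (min of both orientations) log rank-product statistics.

    Each iteration permutes every column's ranks independently; a
    permuted row's down-orientation rank is n+1-rank, so both one-sided
    nulls and the joint min-statistic null come from the same draws.
    """
    log_up = np.log(np.arange(1, n + 1) / n)
    log_dn = log_up[::-1].copy()  # rank r maps to n+1-r
    c_up = np.zeros(obs_up.size, dtype=np.int64)
    c_dn = np.zeros(obs_dn.size, dtype=np.int64)
    c_min = np.zeros(obs_min.size, dtype=np.int64)
    chunk = max(1, min(n_perm, 1_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        null_up = np.zeros((m, n))
        null_dn = np.zeros((m, n))
        for _ in range(k):
            perms = np.argsort(rng.random((m, n)), axis=1)
            null_up += log_up[perms]
            null_dn += log_dn[perms]
        null_up /= k
        null_dn /= k
        null_min = np.minimum(null_up, null_dn).ravel()
        for flat, obs, acc in (
            (null_up.ravel(), obs_up, c_up),
            (null_dn.ravel(), obs_dn, c_dn),
            (null_min, obs_min, c_min),
        ):
            flat.sort()
            acc += np.searchsorted(flat, obs, side="right")
        done += m
    return c_up, c_dn, c_min


def rank_product(
    ds: ExposureDataset,
    n_perm: int = 10000,
    seed: int | None = None,
    slots: tuple[str, ...] = TREATED_SLOTS,
    exact: bool = False,
) -> MethodResult:
    """Rank product over the treated ratio columns with a permutation null.

    For up-regulation each column is ranked descending (rank 1 = most
    up) and RP = (prod_k rank_k / n)^(1/k); the null is built by
    independently permuting each column's ranks ``n_perm`` times and
    pooling all permuted RP values, so p_up is the pooled fraction <=
    the observed RP.  Down-regulation uses ascending ranks.  The
    two-sided ``p_raw`` is NOT the naive 2*min(p_up, p_down): because a
    protein's up- and down-RP are imperfectly anticorrelated (k > 1)
    that combination is visibly non-uniform under the null, so the
    two-sided p is instead calibrated against the permutation null of
    min(RP_up, RP_down) computed jointly on the same draws, which is
    uniform by construction.  ``exact=True`` replaces the permutation
    null by exact enumeration over all n^k equally likely rank tuples
    (small n only).  Ties get average ranks.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation p")
    cols = ds.records.loc[:, list(slots)].to_numpy(dtype=float)
    have = ~np.isnan(cols).any(axis=1)
    data = cols[have]
    idx = pd.Index(ds.records.loc[have, "group_id"])
    n, k = data.shape
    if n < 2:
        raise ValueError("need >=2 complete proteins")

    ranks_up = np.column_stack(
        [stats.rankdata(-data[:, j], method="average") for j in range(k)]
    )
    ranks_dn = np.column_stack(
        [stats.rankdata(data[:, j], method="average") for j in range(k)]
    )
    log_rp_up = np.log(ranks_up / n).mean(axis=1)
    log_rp_dn = np.log(ranks_dn / n).mean(axis=1)
    log_rp_min = np.minimum(log_rp_up, log_rp_dn)

    if exact:
        if n**k > 2_000_000:
            raise ValueError("exact enumeration infeasible: n^k too large")
        grids = np.meshgrid(*([np.arange(1, n + 1)] * k), indexing="ij")
        ranks = np.stack([g.ravel() for g in grids]).astype(float)
        null_up = np.log(ranks / n).mean(axis=0)
        null_dn = np.log((n + 1 - ranks) / n).mean(axis=0)
        null_min = np.minimum(null_up, null_dn)
        total = null_up.size
        null_up.sort()
        null_dn.sort()
        null_min.sort()
        p_up = np.searchsorted(null_up, log_rp_up, side="right") / total
        p_dn = np.searchsorted(null_dn, log_rp_dn, side="right") / total
        p_two = np.searchsorted(null_min, log_rp_min, side="right") / total
    else:
        rng = np.random.default_rng(seed)
        total = n_perm * n
        c_up, c_dn, c_min = _pooled_null_counts(
            log_rp_up, log_rp_dn, log_rp_min, n, k, n_perm, rng
        )
        p_up = c_up / total
        p_dn = c_dn / total
        p_two = c_min / total

    up_wins = p_up <= p_dn
    rp = np.exp(np.where(up_wins, log_rp_up, log_rp_dn))
    x = data.mean(axis=1)
    tab = _base_table(x, idx, rp, p_two,
                      direction=np.where(up_wins, "up", "down"))
    tab["p_up"] = p_up
    tab["p_down"] = p_dn
    return MethodResult("RankProd", tab)


def fcros(
    ds: ExposureDataset,
    trim_central: float = 0.8,
    slots: tuple[str, ...] = TREATED_SLOTS,
) -> MethodResult:
    """Fold-change rank-ordering statistic.

    Per column the ascending rank fraction rank/(n+1) is computed; the
    per-protein mean rank fraction is calibrated against a normal null
    with mean fixed at 0.5 and sigma estimated from the central
    ``trim_central`` interquantile range of the observed means.
    """
    if not 0 < trim_central < 1:
        raise ValueError("trim_central must be in (0, 1)")
    cols = ds.records.loc[:, list(slots)].to_numpy(dtype=float)
    have = ~np.isnan(cols).any(axis=1)
    data = cols[have]
    idx = pd.Index(ds.records.loc[have, "group_id"])
    n, k = data.shape
    if n < 20:
        warnings.warn("n < 20: fcros sigma estimate is unstable")
    rho = np.column_stack(
        [stats.rankdata(data[:, j], method="average") for j in range(k)]
    ) / (n + 1)
    rbar = rho.mean(axis=1)
    lo_q = (1 - trim_central) / 2
    hi_q = 1 - lo_q
    q_lo, q_hi = np.quantile(rbar, [lo_q, hi_q])
    denom = stats.norm.ppf(hi_q) - stats.norm.ppf(lo_q)
    sigma = (q_hi - q_lo) / denom
    if sigma <= 0:
        raise ValueError("degenerate rank-fraction spread; sigma estimate <= 0")
    f = stats.norm.cdf((rbar - 0.5) / sigma)
    p = 2.0 * np.minimum(f, 1.0 - f)
    x = data.mean(axis=1)
    tab = _base_table(x, idx, f, p,
                      direction=np.where(rbar >= 0.5, "up", "down"))
    return MethodResult("FCROS", tab)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y <= 0:
        return float(np.inf)
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def _fit_prior_variance(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Moment-match (d0, s0^2) to the scaled-F distribution of sample
    variances via digamma/trigamma relations on log s^2."""
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    if e.size < 2:
        return float(np.inf), float(np.exp(np.mean(e)))
    evar = np.var(e, ddof=1) - float(special.polygamma(1, d / 2.0))
    if not np.isfinite(evar) or evar <= 0:
        return float(np.inf), float(np.exp(np.mean(e)))
    half_d0 = _trigamma_inverse(evar)
    d0 = 2.0 * half_d0
    s02 = float(np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s02


def moderated_treat(ds: ExposureDataset, tau: float = 1.2) -> MethodResult:
    """Empirical-Bayes moderated test of |treatment - control effect|
    against a fold-change threshold.

    Per protein the six ratios are modeled with a treatment mean (four
    treated slots) and a control mean (two control slots), leaving 4
    residual df.  Variances are shrunk toward a prior fitted across
    proteins by moment matching on log s^2; the contrast theta - gamma
    is then tested against the threshold log2(tau) with the
    two-one-sided construction: p = P(T > (|c|-thr)/se) + P(T >
    (|c|+thr)/se) on d0 + d df.  ``tau=1`` reduces to the ordinary
    two-sided moderated t.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    complete = ds.complete_mask()
    treated = ds.treated_matrix()[complete]
    control = ds.control_matrix()[complete]
    idx = pd.Index(ds.records.loc[complete, "group_id"])
    n = treated.shape[0]
    if n < 2:
        raise ValueError("need >=2 complete six-ratio proteins")

    theta = treated.mean(axis=1)
    gamma = control.mean(axis=1)
    d = 4  # 6 observations - 2 fitted means
    rss = ((treated - theta[:, None]) ** 2).sum(axis=1) + (
        (control - gamma[:, None]) ** 2
    ).sum(axis=1)
    s2 = rss / d

    positive = s2[s2 > 0]
    if positive.size < 2:
        warnings.warn("variance moment fit degenerate; using pooled variance")
        d0, s02 = float(np.inf), float(max(np.mean(s2), np.finfo(float).tiny))
    else:
        d0, s02 = _fit_prior_variance(np.maximum(s2, np.finfo(float).tiny), d)
        if not (np.isfinite(s02) and s02 > 0):
            warnings.warn("variance moment fit non-finite; using pooled variance")
            d0, s02 = float(np.inf), float(np.mean(s2))
    if np.isfinite(d0):
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d
    else:
        s2_post = np.full_like(s2, s02)
        df_total = 1e6  # effectively normal

    c = theta - gamma
    u = np.sqrt(1.0 / 4 + 1.0 / 2)  # unscaled sd of the contrast
    se = u * np.sqrt(s2_post)
    thr = np.log2(tau)
    t_right = (np.abs(c) - thr) / se
    t_left = (np.abs(c) + thr) / se
    p = stats.t.sf(t_right, df_total) + stats.t.sf(t_left, df_total)
    p = np.minimum(p, 1.0)
    tab = _base_table(c, idx, t_right, p,
                      direction=np.where(c >= 0, "up", "down"))
    tab["s2_post"] = s2_post
    return MethodResult("ModeratedTREAT", tab)


# ---------------------------------------------------------------------------
# ensemble

@dataclass
class EnsembleResult:
    """Union of detector calls with per-method provenance.

    ``table`` is indexed by group_id over all proteins any detector
    scored, with columns ``member``, ``direction``, ``n_methods``,
    ``methods`` (comma-joined supporting detectors), ``conflicted``.
    """

    table: pd.DataFrame
    tiers: dict

    @property
    def members(self) -> pd.Index:
        return self.table.index[self.table["member"]]


def ensemble_union(
    results: list[MethodResult],
    fc_tier: float | None = 1.2,
    p_tier: float | None = 0.05,
    use_adjusted: bool = False,
    require_fc: bool = False,
) -> EnsembleResult:
    """Union of per-method calls at one stringency tier.

    The pure fold-change method is thresholded on ``fc_tier`` alone;
    statistical methods are thresholded on ``p_tier`` and, when
    ``require_fc``, additionally on ``fc_tier``.  Direction comes from
    each method's own call; proteins with disagreeing supporting
    directions are flagged conflicted.
    """
    if not results:
        raise ValueError("need at least one MethodResult")
    all_idx = results[0].table.index
    for r in results[1:]:
        all_idx = all_idx.union(r.table.index)
    member = pd.Series(False, index=all_idx)
    methods = {gid: [] for gid in all_idx}
    directions = {gid: set() for gid in all_idx}
    for r in results:
        if r.method == "FC" or r.table["p_raw"].isna().all():
            mask = r.tier_mask(fc_tier=fc_tier)
            tier_desc = f"FC>{fc_tier}"
        else:
            mask = r.tier_mask(
                fc_tier=fc_tier if require_fc else None,
                p_tier=p_tier,
                use_adjusted=use_adjusted,
            )
            tier_desc = f"p<{p_tier}" + (f",FC>{fc_tier}" if require_fc else "")
        for gid in r.table.index[mask]:
            member[gid] = True
            methods[gid].append(f"{r.method}({tier_desc})")
            directions[gid].add(r.table.at[gid, "direction"])
    direction = []
    conflicted = []
    for gid in all_idx:
        dirs = directions[gid]
        conflicted.append(len(dirs) > 1)
        direction.append(dirs.pop() if len(dirs) == 1 else ("conflict" if dirs else ""))
    table = pd.DataFrame(
        {
            "member": member,
            "direction": direction,
            "n_methods": [len(methods[g]) for g in all_idx],
            "methods": [",".join(methods[g]) for g in all_idx],
            "conflicted": conflicted,
        },
        index=all_idx,
    )
    tiers = {
        "fc_tier": fc_tier,
        "p_tier": p_tier,
        "use_adjusted": use_adjusted,
        "require_fc": require_fc,
    }
    return EnsembleResult(table=table, tiers=tiers)


def run_detectors(
    ds: ExposureDataset,
    methods=("fc", "z", "m", "sigb", "rankprod", "fcros", "treat"),
    seed: int | None = None,
    n_perm: int = 2000,
    tau: float = 1.2,
    min_bin: int = 300,
) -> list[MethodResult]:
    """Run the requested detectors on one dataset."""
    dispatch = {
        "fc": lambda: fold_change_method(ds),
        "z": lambda: z_score_test(ds),
        "m": lambda: m_score_test(ds),
        "sigb": lambda: significance_b(ds, min_bin=min_bin),
        "rankprod": lambda: rank_product(ds, n_perm=n_perm, seed=seed),
        "fcros": lambda: fcros(ds),
        "treat": lambda: moderated_treat(ds, tau=tau),
    }
    out = []
    for name in methods:
        key = name.strip().lower()
        if key not in dispatch:
            raise ValueError(f"unknown method {name!r}")
        out.append(dispatch[key]())
    return out
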