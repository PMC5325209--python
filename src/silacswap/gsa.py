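"""Model-based protein-set analysis.

Terms are binary on/off switches; an item's hidden state is the OR of
its active annotating terms, and the observed study-set membership is a
noisy readout with false-positive rate alpha and false-negative rate
beta.  alpha, beta and the prior term-activation probability p live on
discrete grids and are integrated over.  Marginal posterior term
activations come from either exact enumeration (small models; the
oracle) or a Metropolis sampler run several times independently so the
between-run SD quantifies Monte Carlo error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "GsaModel",
    "GsaResult",
    "mgsa_enumerate",
    "mgsa_mcmc",
    "perturbed_terms",
    "export_association_network",
    "write_graphml",
]

ENUM_MAX_TERMS = 15


def _default_grid(lo: float, hi: float, k: int = 10) -> tuple[float, ...]:
    return tuple(np.linspace(lo, hi, k))


@dataclass
class GsaModel:
    """Term-item annotation structure plus inference grids.

    ``annotations`` maps term id -> set of item ids; ``items`` is the
    universe (all quantified proteins); ``study_set`` the regulated
    ones.  Annotations are restricted to the universe on construction;
    terms left with no items are dropped with a warning.
    """

    annotations: dict[str, frozenset[str]]
    items: tuple[str, ...]
    study_set: frozenset[str]
    alpha_grid: tuple[float, ...] = field(default_factory=lambda: _default_grid(0.01, 0.3))
    beta_grid: tuple[float, ...] = field(default_factory=lambda: _default_grid(0.01, 0.3))
    p_grid: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        universe = set(self.items)
        if len(universe) != len(self.items):
            raise ValueError("duplicate items in universe")
        stray = set(self.study_set) - universe
        if stray:
            raise ValueError(f"study_set items outside universe: {sorted(stray)[:5]}")
        clipped = {}
        for term, its in self.annotations.items():
            within = frozenset(its) & universe
            if not within:
                warnings.warn(f"term {term!r} annotates no universe item; dropped")
                continue
            clipped[term] = frozenset(within)
        self.annotations = clipped
        if not clipped:
            raise ValueError("no usable terms")
        if self.p_grid is None:
            self.p_grid = _default_grid(1.0 / max(len(clipped), 4), 0.3)
        for grid, name in ((self.alpha_grid, "alpha"), (self.beta_grid, "beta"),
                           (self.p_grid, "p")):
            arr = np.asarray(grid, dtype=float)
            if arr.min() <= 0 or arr.max() >= 1:
                raise ValueError(f"{name}_grid values must lie in (0, 1)")

    # index-based internal view ------------------------------------------

    def _arrays(self):
        terms = sorted(self.annotations)
        item_index = {it: i for i, it in enumerate(self.items)}
        term_items = [
            np.array(sorted(item_index[it] for it in self.annotations[t]), dtype=np.intp)
            for t in terms
        ]
        obs = np.zeros(len(self.items), dtype=bool)
        for it in self.study_set:
            obs[item_index[it]] = True
        return terms, term_items, obs


@dataclass
class GsaResult:
    """Marginal posterior activation per term (mean over runs, SD across
    runs; SD is 0 for exact enumeration)."""

    terms: list[str]
    posterior: np.ndarray
    run_sd: np.ndarray
    n_runs: int
    n_steps: int
    seed: int | None = None
    method: str = "mcmc"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"posterior": self.posterior, "run_sd": self.run_sd},
            index=pd.Index(self.terms, name="term"),
        ).sort_values("posterior", ascending=False)


def _grid_logliks(model: GsaModel):
    a = np.asarray(model.alpha_grid, dtype=float)
    b = np.asarray(model.beta_grid, dtype=float)
    p = np.asarray(model.p_grid, dtype=float)
    return (
        (np.log(a), np.log1p(-a)),
        (np.log(b), np.log1p(-b)),
        (np.log(p), np.log1p(-p)),
    )


def mgsa_enumerate(model: GsaModel) -> GsaResult:
    """Exact marginal posteriors by summing the joint over all 2^T term
    states and all grid values.  Limited to small term counts; serves as
    the ground-truth oracle for the sampler.

    The alpha, beta and p sums factorize given the per-state confusion
    counts, so each state costs only three small logsumexps.
    """
    terms, term_items, obs = model._arrays()
    t_count = len(terms)
    if t_count > ENUM_MAX_TERMS:
        raise ValueError(
            f"{t_count} terms exceeds the enumeration limit ({ENUM_MAX_TERMS}); "
            "use mgsa_mcmc"
        )
    (la, l1a), (lb, l1b), (lp, l1p) = _grid_logliks(model)
    n_items = obs.size
    n_obs = int(obs.sum())

    log_w = np.empty(2 ** t_count)
    active_mask = np.zeros((2 ** t_count, t_count), dtype=bool)
    for state in range(2 ** t_count):
        bits = [(state >> t) & 1 for t in range(t_count)]
        hidden = np.zeros(n_items, dtype=bool)
        for t, bit in enumerate(bits):
            if bit:
                hidden[term_items[t]] = True
                active_mask[state, t] = True
        n11 = int((hidden & obs).sum())
        n10 = int(hidden.sum()) - n11
        n01 = n_obs - n11
        n00 = n_items - n11 - n10 - n01
        a = sum(bits)
        log_w[state] = (
            logsumexp(n01 * la + n00 * l1a)
            + logsumexp(n10 * lb + n11 * l1b)
            + logsumexp(a * lp + (t_count - a) * l1p)
        )
    log_z = logsumexp(log_w)
    w = np.exp(log_w - log_z)
    posterior = w @ active_mask
    return GsaResult(
        terms=terms,
        posterior=posterior,
        run_sd=np.zeros(t_count),
        n_runs=1,
        n_steps=2 ** t_count,
        method="enumeration",
    )


def _mcmc_single_run(term_items, obs, grids, n_steps, rng, p_toggle=0.75):
    (la, l1a), (lb, l1b), (lp, l1p) = grids
    t_count = len(term_items)
    n_items = obs.size
    n_obs = int(obs.sum())
    ga, gb, gp = la.size, lb.size, lp.size

    active = np.zeros(t_count, dtype=bool)
    cnt = np.zeros(n_items, dtype=np.int32)
    n11 = 0
    n10 = 0
    ia, ib, ip = rng.integers(ga), rng.integers(gb), rng.integers(gp)

    def loglik(n11_, n10_, a_, ia_, ib_, ip_):
        n01_ = n_obs - n11_
        n00_ = n_items - n11_ - n10_ - n01_
        return (
            n01_ * la[ia_] + n00_ * l1a[ia_]
            + n10_ * lb[ib_] + n11_ * l1b[ib_]
            + a_ * lp[ip_] + (t_count - a_) * l1p[ip_]
        )

    a_count = 0
    cur = loglik(n11, n10, a_count, ia, ib, ip)
    burn = n_steps // 5
    freq = np.zeros(t_count, dtype=np.int64)
    kept = 0

    unif = rng.random(n_steps)
    moves = rng.random(n_steps)
    term_choice = rng.integers(0, t_count, n_steps)
    param_choice = rng.integers(0, 3, n_steps)
    param_new = rng.random(n_steps)

    for step in range(n_steps):
        if moves[step] < p_toggle:
            t = term_choice[step]
            items = term_items[t]
            if active[t]:
                sub = cnt[items]
                dying = items[sub == 1]
                d11 = int(obs[dying].sum())
                new_n11 = n11 - d11
                new_n10 = n10 - (dying.size - d11)
                new_a = a_count - 1
            else:
                sub = cnt[items]
                born = items[sub == 0]
                d11 = int(obs[born].sum())
                new_n11 = n11 + d11
                new_n10 = n10 + (born.size - d11)
                new_a = a_count + 1
            prop = loglik(new_n11, new_n10, new_a, ia, ib, ip)
            if prop - cur >= 0 or unif[step] < np.exp(prop - cur):
                if active[t]:
                    cnt[items] -= 1
                else:
                    cnt[items] += 1
                active[t] = ~active[t]
                n11, n10, a_count, cur = new_n11, new_n10, new_a, prop
        else:
            which = param_choice[step]
            if which == 0:
                cand = int(param_new[step] * ga)
                prop = loglik(n11, n10, a_count, cand, ib, ip)
            elif which == 1:
                cand = int(param_new[step] * gb)
                prop = loglik(n11, n10, a_count, ia, cand, ip)
            else:
                cand = int(param_new[step] * gp)
                prop = loglik(n11, n10, a_count, ia, ib, cand)
            if prop - cur >= 0 or unif[step] < np.exp(prop - cur):
                if which == 0:
                    ia = cand
                elif which == 1:
                    ib = cand
                else:
                    ip = cand
                cur = prop
        if step >= burn:
            freq += active
            kept += 1
    return freq / kept


def mgsa_mcmc(
    model: GsaModel,
    n_runs: int = 20,
    n_steps: int = 1_000_000,
    seed: int | None = None,
) -> GsaResult:
    """Metropolis sampling of the joint (term states, alpha, beta, p).

    Proposals toggle a uniformly chosen term (75% of moves) or resample
    one grid parameter uniformly (25%); both are symmetric.  Each of the
    ``n_runs`` independent chains discards a 20% burn-in; the reported
    posterior is the mean activation frequency over runs with the
    between-run SD.  Deterministic per seed.
    """
    terms, term_items, obs = model._arrays()
    grids = _grid_logliks(model)
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    per_run = np.empty((n_runs, len(terms)))
    for r in range(n_runs):
        rng = np.random.default_rng(seeds[r])
        per_run[r] = _mcmc_single_run(term_items, obs, grids, int(n_steps), rng)
    posterior = per_run.mean(axis=0)
    run_sd = per_run.std(axis=0, ddof=1) if n_runs > 1 else np.zeros(len(terms))
    if (run_sd > 0.2).any():
        bad = [terms[i] for i in np.flatnonzero(run_sd > 0.2)]
        warnings.warn(f"possible non-mixing: between-run SD > 0.2 for {bad}")
    return GsaResult(
        terms=terms,
        posterior=posterior,
        run_sd=run_sd,
        n_runs=n_runs,
        n_steps=int(n_steps),
        seed=seed,
    )


def perturbed_terms(result: GsaResult, threshold: float = 0.5) -> list[tuple[str, float]]:
    """Terms with marginal posterior above ``threshold``, sorted
    descending by posterior."""
    hits = [
        (t, float(p)) for t, p in zip(result.terms, result.posterior) if p > threshold
    ]
    return sorted(hits, key=lambda tp: -tp[1])


def combine_study_sets(
    universes: list[tuple[str, ...]],
    study_sets: list[frozenset[str]],
    universe_mode: str = "union",
) -> tuple[tuple[str, ...], frozenset[str]]:
    """Pool regulated sets across exposures for a combined analysis.

    Study sets are always unioned; the universe is either the union
    (items quantified in any exposure) or the intersection (items
    quantified in all of them) of the per-exposure universes, with the
    study set clipped accordingly.
    """
    if universe_mode not in ("union", "intersection"):
        raise ValueError("universe_mode must be 'union' or 'intersection'")
    sets = [set(u) for u in universes]
    uni = set.union(*sets) if universe_mode == "union" else set.intersection(*sets)
    study = frozenset(set.union(*[set(s) for s in study_sets]) & uni)
    return tuple(sorted(uni)), study


def export_association_network(
    study_set,
    annotations: dict[str, frozenset[str]],
    evidence: dict[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """Bipartite protein-term edge list for the regulated set.

    One row per (protein, term) association; proteins in the study set
    annotated by no term appear as isolated rows with an empty term.
    ``evidence`` optionally labels edges keyed by (protein, term).
    """
    evidence = evidence or {}
    rows = []
    covered = set()
    for term in sorted(annotations):
        for prot in sorted(annotations[term]):
            if prot in study_set:
                rows.append(
                    {"protein": prot, "term": term,
                     "evidence": evidence.get((prot, term), "")}
                )
                covered.add(prot)
    for prot in sorted(set(study_set) - covered):
        rows.append({"protein": prot, "term": "", "evidence": ""})
    return pd.DataFrame(rows, columns=["protein", "term", "evidence"])


def write_graphml(edges: pd.DataFrame, path) -> None:
    """Serialize the edge list as GraphML-like XML (UTF-8)."""
    root = ET.Element("graphml")
    key = ET.SubElement(root, "key", id="evidence", attrib={"for": "edge"})
    key.set("attr.name", "evidence")
    graph = ET.SubElement(root, "graph", edgedefault="undirected")
    nodes = set()
    for _, row in edges.iterrows():
        for node, kind in ((row["protein"], "protein"), (row["term"], "term")):
            if node and node not in nodes:
                el = ET.SubElement(graph, "node", id=str(node))
                el.set("kind", kind)
                nodes.add(node)
    for _, row in edges.iterrows():
        if not row["term"]:
            continue
        e = ET.SubElement(graph, "edge", source=str(row["protein"]),
                          target=str(row["term"]))
        if row["evidence"]:
            d = ET.SubElement(e, "data", key="evidence")
            d.text = str(row["evidence"])
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)
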