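"""End-to-end pipeline driver, configuration and report rendering.

``run_pipeline`` chains ingest/simulate -> quality filter -> ratio
normalization -> swap diagnostics -> design filters -> detectors ->
ensemble -> (optional) protein-set analysis, and writes table-shaped
TSVs plus a metrics JSON into the output directory.  Every artifact
records the config hash and seed; deterministic stages reproduce
bit-exact on rerun.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detect, filters, gsa, studydata, swap
from .io import ColumnMap, filter_quality, normalize_ratios, quantitation_summary, read_protein_groups, write_protein_groups
from .simulate import SimulationParams, simulate_exposure

logger = logging.getLogger("silacswap")

__all__ = ["PipelineConfig", "run_pipeline", "render_table4", "reference_table4"]


@dataclass
class PipelineConfig:
    """Schema-validated pipeline settings; fully serialized into every
    output directory for provenance."""

    seed: int = 0
    outdir: str = "silacswap_out"
    # either an input table + column map, or simulation overrides
    input_path: str | None = None
    column_map_path: str | None = None
    cell_line: str = "SIM"
    emf_type: str = "synthetic"
    simulation: dict = field(default_factory=dict)
    min_peptides: int = 2
    composite_rule: str = "strict"
    detection: dict = field(default_factory=dict)
    gsa: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # output location does not affect results
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _detection_settings(cfg: PipelineConfig) -> dict:
    d = {
        "methods": ["fc", "z", "m", "sigb", "rankprod", "fcros", "treat"],
        "n_perm": 2000,
        "tau": 1.2,
        "min_bin": 300,
        "fc_tier": 1.2,
        "p_tier": 0.05,
        "use_adjusted": False,
        "require_fc": True,
        "mode": "filter_first",
    }
    d.update(cfg.detection)
    if d["mode"] not in ("filter_first", "detector_first"):
        raise ValueError("detection.mode must be filter_first or detector_first")
    return d


def _gsa_settings(cfg: PipelineConfig) -> dict:
    d = {
        "enabled": True,
        "n_terms": 8,
        "items_per_term": 20,
        "n_runs": 4,
        "n_steps": 20000,
    }
    d.update(cfg.gsa)
    return d


class _StageTracker:
    current = ""


def _stage(name):
    _StageTracker.current = name
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the metrics dict that is also
    written to ``metrics.json``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    metrics: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    try:
        with open(out / "config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

        _stage("ingest")
        if config.input_path:
            cmap = (
                ColumnMap.from_yaml(config.column_map_path)
                if config.column_map_path
                else ColumnMap.default_maxquant()
            )
            ds = read_protein_groups(
                config.input_path, cmap,
                cell_line=config.cell_line, emf_type=config.emf_type,
            )
            truth = None
        else:
            sim_kwargs = dict(config.simulation)
            sim_kwargs.setdefault("seed", config.seed)
            sim_kwargs.setdefault("cell_line", config.cell_line)
            sim_kwargs.setdefault("emf_type", config.emf_type)
            params = SimulationParams(**sim_kwargs)
            ds, truth = simulate_exposure(params)
            truth.to_csv(out / "truth.tsv", sep="\t", index=False)

        _stage("quality filter")
        ds, removed = filter_quality(ds, min_peptides=config.min_peptides)
        metrics["removed"] = removed

        _stage("normalize")
        ds = normalize_ratios(ds)
        metrics["normalization_offsets"] = {
            k: float(v) for k, v in ds.normalization_offsets.items()
        }
        write_protein_groups(ds, out / "protein_groups.tsv")

        qsum = quantitation_summary(ds)
        metrics["quantitation"] = qsum
        pd.DataFrame([qsum]).to_csv(out / "quantitation_summary.tsv", sep="\t", index=False)

        _stage("swap diagnostics")
        swap_rows = []
        for pair in ("H-L", "H-M"):
            try:
                cs = swap.reciprocal_correlation(ds, pair)
                swap_rows.append(
                    {"swap_pair": pair, "n": cs.n, "r": cs.r,
                     "ci_lo": cs.ci95[0], "ci_hi": cs.ci95[1], "p_value": cs.p_value}
                )
            except ValueError as exc:
                logger.warning("swap pair %s skipped: %s", pair, exc)
        pd.DataFrame(swap_rows).to_csv(out / "swap_diagnostics.tsv", sep="\t", index=False)
        metrics["swap"] = swap_rows

        _stage("design filters")
        split = filters.consistency_filter(ds)
        composite_ds, rep_composite = filters.composite_filter(ds, rule=config.composite_rule)
        reports = [
            filters.signal_to_noise(ds, "unfiltered"),
            split.report_consistent,
            split.report_inconsistent,
            rep_composite,
        ]
        metrics["filters"] = [dataclasses.asdict(r) for r in reports]
        with open(out / "filter_reports.json", "w", encoding="utf-8") as fh:
            json.dump(metrics["filters"], fh, indent=2, sort_keys=True, default=float)

        _stage("detectors")
        det = _detection_settings(config)
        detect_ds = composite_ds if det["mode"] == "filter_first" else ds
        results: list[detect.MethodResult] = []
        if det["methods"]:
            results = detect.run_detectors(
                detect_ds,
                methods=det["methods"],
                seed=config.seed,
                n_perm=det["n_perm"],
                tau=det["tau"],
                min_bin=det["min_bin"],
            )
            for r in results:
                r.table.to_csv(out / f"method_{r.method}.tsv", sep="\t",
                               index_label="group_id")

        _stage("ensemble")
        if results:
            ens = detect.ensemble_union(
                results,
                fc_tier=det["fc_tier"],
                p_tier=det["p_tier"],
                use_adjusted=det["use_adjusted"],
                require_fc=det["require_fc"],
            )
            if det["mode"] == "detector_first":
                allowed = set(composite_ds.records["group_id"])
                ens.table["member"] &= ens.table.index.isin(allowed)
            members = list(ens.members)
            symbols = ds.records.set_index("group_id")["gene_symbol"]
            table4 = render_table4(ens, results, symbols,
                                   emf=ds.emf_type, cell_line=ds.cell_line)
            table4.to_csv(out / "ensemble_table.tsv", sep="\t", index=False)
            ens.table.to_csv(out / "ensemble.tsv", sep="\t", index_label="group_id")
        else:
            ens, members = None, []
            logger.warning("no detectors configured: ensemble empty")
            pd.DataFrame(
                columns=["member", "direction", "n_methods", "methods", "conflicted"]
            ).to_csv(out / "ensemble.tsv", sep="\t", index_label="group_id")
        metrics["ensemble"] = {"n_members": len(members), "members": sorted(members)}

        _stage("protein-set analysis")
        g = _gsa_settings(config)
        if not g["enabled"] or not members:
            logger.warning("GSA skipped (%s)",
                           "disabled" if not g["enabled"] else "empty ensemble")
            metrics["gsa"] = {"skipped": True}
        else:
            universe = tuple(ds.records.loc[ds.complete_mask(), "group_id"])
            rng = np.random.default_rng(config.seed + 1)
            annotations = {}
            study_pool = [m for m in members if m in set(universe)]
            for t in range(int(g["n_terms"])):
                k = min(int(g["items_per_term"]), len(universe))
                chosen = set(rng.choice(len(universe), size=k, replace=False))
                items = {universe[i] for i in chosen}
                if study_pool:
                    items.add(study_pool[int(rng.integers(len(study_pool)))])
                annotations[f"term{t:03d}"] = frozenset(items)
            model = gsa.GsaModel(
                annotations=annotations,
                items=universe,
                study_set=frozenset(study_pool),
            )
            res = gsa.mgsa_mcmc(model, n_runs=int(g["n_runs"]),
                                n_steps=int(g["n_steps"]), seed=config.seed)
            res.to_frame().to_csv(out / "gsa_posteriors.tsv", sep="\t")
            edges = gsa.export_association_network(set(study_pool), annotations)
            edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
            gsa.write_graphml(edges, out / "network.graphml")
            metrics["gsa"] = {
                "skipped": False,
                "perturbed": [
                    {"term": t, "posterior": p} for t, p in gsa.perturbed_terms(res)
                ],
            }

        with open(out / "metrics.json", "w", encoding="utf-8") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True, default=float)
        return metrics
    except Exception as exc:  # annotate the failing stage and re-raise
        stage = _StageTracker.current
        logger.error("pipeline aborted at stage %r: %s", stage, exc)
        (out / "STALE").write_text(
            f"pipeline aborted at stage {stage!r}; partial outputs are stale\n"
        )
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# table rendering


def _annotate(sym: str, fc_tier, strong: bool) -> str:
    marks = []
    if fc_tier == 1:
        marks.append("fc>1.2")
    elif fc_tier == 2:
        marks.append("fc>1.5")
    if strong:
        marks.append("p<0.01")
    return f"{sym}({','.join(marks)})" if marks else sym


def render_table4(
    ensemble: detect.EnsembleResult,
    method_results: list[detect.MethodResult],
    gene_symbols: pd.Series,
    emf: str = "",
    cell_line: str = "",
    fc_tiers: tuple[float, float] = (1.2, 1.5),
) -> pd.DataFrame:
    """One table row per (exposure, cell line): per-method call lists
    with explicit tier annotations, the combined union set split by
    direction, and the member count.  Conflicted-direction proteins are
    listed under both directions with a '!' marker."""
    row: dict = {"EMF": emf, "cell_line": cell_line}
    for r in method_results:
        if r.method == "FC" or r.table["p_raw"].isna().all():
            mask = r.tier_mask(fc_tier=fc_tiers[0])
        else:
            mask = r.tier_mask(p_tier=ensemble.tiers["p_tier"],
                               fc_tier=fc_tiers[0] if ensemble.tiers["require_fc"] else None,
                               use_adjusted=ensemble.tiers["use_adjusted"])
        calls = []
        for gid in r.table.index[mask]:
            fc = r.table.at[gid, "fc"]
            tier = 2 if fc > fc_tiers[1] else (1 if fc > fc_tiers[0] else None)
            strong = (
                not np.isnan(r.table.at[gid, "p_raw"]) and r.table.at[gid, "p_raw"] < 0.01
                if "p_raw" in r.table
                else False
            )
            calls.append(_annotate(str(gene_symbols.get(gid, gid)), tier, strong))
        row[r.method] = ", ".join(calls) if calls else "-"
    up, down = [], []
    for gid in ensemble.members:
        sym = str(gene_symbols.get(gid, gid))
        direction = ensemble.table.at[gid, "direction"]
        if direction == "up":
            up.append(sym)
        elif direction == "down":
            down.append(sym)
        else:
            up.append(sym + "!")
            down.append(sym + "!")
    row["combined_up"] = ", ".join(up) if up else "-"
    row["combined_down"] = ", ".join(down) if down else "-"
    row["n_proteins"] = int(ensemble.table["member"].sum())
    return pd.DataFrame([row])


def reference_table4() -> pd.DataFrame:
    """The packaged published regulated-protein summary rendered in the
    same shape as :func:`render_table4` output."""
    rows = []
    for emf in studydata.EXPOSURES:
        for cell in studydata.CELL_LINES:
            entry = studydata.REGULATED_CALLS[(emf, cell)]
            row = {"EMF": emf, "cell_line": cell}
            for method, calls in entry["methods"].items():
                row[method] = (
                    ", ".join(_annotate(s, t, b) for s, t, b in calls) if calls else "-"
                )
            row["combined_up"] = ", ".join(entry["up"]) if entry["up"] else "-"
            row["combined_down"] = ", ".join(entry["down"]) if entry["down"] else "-"
            row["n_proteins"] = len(entry["up"]) + len(entry["down"])
            rows.append(row)
    return pd.DataFrame(rows)
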