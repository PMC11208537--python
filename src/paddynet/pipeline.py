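"""End-to-end orchestration: tables -> pollution -> diversity ->
association -> network, driven by one YAML config, with per-stage
seeds, structured logging and a machine-readable JSON report.

Stage seeds derive from the master seed by fixed offsets so any stage
can be rerun independently; any stage failure is recorded and
independent stages still run.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association, diversity, network, pollution, tables_io

logger = logging.getLogger(__name__)

STAGE_SEED_OFFSETS = {"diversity": 101, "association": 202, "network": 303}

_DEFAULTS = {
    "min_prevalence": 0.9,
    "scan": {"t_min": 0.3, "t_max": 0.99, "step": 0.01},
    "permutations": 999,
    "nulls": 100,
    "seed": 0,
    "nmds_restarts": 20,
}

_KNOWN_KEYS = {"otu", "soil", "metals", "backgrounds", "outdir",
               "min_prevalence", "scan", "permutations", "nulls", "seed",
               "nmds_restarts", "stages"}


@dataclass
class PipelineConfig:
    otu: str | None
    soil: str | None
    metals: str | None
    backgrounds: str | None
    outdir: str
    min_prevalence: float = 0.9
    scan: dict = field(default_factory=lambda: dict(_DEFAULTS["scan"]))
    permutations: int = 999
    nulls: int = 100
    seed: int = 0
    nmds_restarts: int = 20
    stages: list[str] = field(default_factory=lambda: [
        "pollution", "diversity", "association", "network"])

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if not 0 < self.min_prevalence <= 1:
            raise ValueError("min_prevalence must be in (0, 1]")
        if self.scan.get("step", 0.01) <= 0:
            raise ValueError("scan step must be > 0")
        if self.permutations < 99 or self.nulls < 1:
            raise ValueError("bad permutations/nulls")
        needs = {"pollution": ("metals", "backgrounds", "soil"),
                 "diversity": ("otu",),
                 "association": ("otu", "soil", "metals", "backgrounds"),
                 "network": ("otu",)}
        for stage in self.stages:
            if stage not in needs:
                raise ValueError(f"unknown stage {stage!r}")
            for key in needs[stage]:
                if getattr(self, key) is None:
                    raise ValueError(
                        f"stage {stage!r} requires config key {key!r}")

    def stage_seed(self, stage: str) -> int:
        return self.seed + STAGE_SEED_OFFSETS.get(stage, 0)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config, fill defaults, reject unknown keys."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    merged = {**_DEFAULTS, **raw}
    merged.setdefault("outdir", "paddynet_out")
    for k in ("otu", "soil", "metals", "backgrounds"):
        merged.setdefault(k, None)
    if "stages" not in merged:
        merged["stages"] = [s for s, reqs in (
            ("pollution", ("metals", "backgrounds", "soil")),
            ("diversity", ("otu",)),
            ("association", ("otu", "soil", "metals", "backgrounds")),
            ("network", ("otu",)),
        ) if all(merged.get(r) for r in reqs)]
    cfg = PipelineConfig(**merged)
    for key in ("otu", "soil", "metals", "backgrounds"):
        p = getattr(cfg, key)
        if p is not None and not Path(p).exists():
            raise ValueError(f"input path for {key!r} does not exist: {p}")
    return cfg


def _stage_pollution(cfg: PipelineConfig, outdir: Path, inputs: dict) -> dict:
    table = pollution.assess_table(inputs["metals"], inputs["backgrounds"],
                                   inputs["soil"])
    path = outdir / "pollution.tsv"
    table.to_csv(path, sep="\t", float_format="%.6g")
    return {"output": str(path), "n_samples": len(table),
            "n_polluted": int(table["polluted"].sum())}


def _stage_diversity(cfg: PipelineConfig, outdir: Path, inputs: dict) -> dict:
    otu = inputs["otu"]
    alpha = diversity.alpha_diversity_table(otu)
    alpha.to_csv(outdir / "alpha.tsv", sep="\t", float_format="%.6g")
    bray = diversity.bray_curtis_matrix(otu)
    pd.DataFrame(bray.data, index=list(bray.ids), columns=list(bray.ids)
                 ).to_csv(outdir / "bray.tsv", sep="\t", float_format="%.6g")
    ord_ = diversity.nmds(bray, k=2, restarts=cfg.nmds_restarts,
                          seed=cfg.stage_seed("diversity"),
                          depths=otu.counts.sum(axis=1).to_numpy())
    ord_.coordinates.to_csv(outdir / "nmds.tsv", sep="\t",
                            float_format="%.6g")
    inputs["_alpha"] = alpha
    inputs["_bray"] = bray
    inputs["_nmds"] = ord_
    return {"output": str(outdir / "alpha.tsv"), "stress": ord_.stress}


def _env_frame(inputs: dict) -> pd.DataFrame:
    soil = inputs["soil"].data
    metals = inputs["metals"]
    env = soil.join(metals.total.add_prefix("T_"))
    env = env.join(metals.dtpa.add_prefix("A_"))
    return env.dropna()


def _stage_association(cfg: PipelineConfig, outdir: Path,
                       inputs: dict) -> dict:
    otu = inputs["otu"]
    alpha = inputs.get("_alpha")
    if alpha is None:
        alpha = diversity.alpha_diversity_table(otu)
    env = _env_frame(inputs)
    common = alpha.index.intersection(env.index)
    alpha, env = alpha.loc[common], env.loc[common]
    seed = cfg.stage_seed("association")

    regs = []
    for var in ("ph", "tn", "ap"):
        for degree in (1, 2):
            fit = association.fit_polynomial(env[var], alpha["shannon"],
                                            degree=degree)
            regs.append({"x": var, "y": "shannon", "degree": degree,
                         "r_squared": fit.r_squared, "p": fit.p_value,
                         "vertex_x": fit.vertex_x})
    pd.DataFrame(regs).to_csv(outdir / "regressions.tsv", sep="\t",
                              index=False, float_format="%.6g")

    bray = inputs.get("_bray")
    if bray is None:
        bray = diversity.bray_curtis_matrix(otu)
    bray = bray.filter(list(common))
    from scipy.spatial.distance import pdist, squareform
    from skbio import DistanceMatrix
    mantel_rows = []
    for var in env.columns:
        v = env[var].to_numpy(dtype=float)
        if v.std() == 0:
            continue
        z = (v - v.mean()) / v.std()
        d_env = DistanceMatrix(squareform(pdist(z[:, None])),
                               ids=list(common))
        res = association.mantel(bray, d_env, method="spearman",
                                 permutations=cfg.permutations, seed=seed)
        mantel_rows.append({"variable": var, "r": res.r, "p": res.p_value})
    pd.DataFrame(mantel_rows).to_csv(outdir / "mantel.tsv", sep="\t",
                                     index=False, float_format="%.6g")

    soil_block = env[["ph", "cec", "tn", "ap", "ak"]]
    metal_block = env[[c for c in env.columns if c.startswith("T_")]]
    vpa = association.variation_partition(otu.counts.loc[common],
                                          soil_block, metal_block)
    with open(outdir / "vpa.tsv", "w", encoding="utf-8") as fh:
        fh.write("fraction\tvalue\n")
        for k in ("a", "b", "c", "residual"):
            fh.write(f"{k}\t{getattr(vpa, k):.6g}\n")

    imp = association.forest_importance(env, alpha["shannon"],
                                        trees=500, seed=seed)
    imp.to_csv(outdir / "importance.tsv", sep="\t", float_format="%.6g")

    phyla = tables_io.aggregate_phylum(otu).loc[common]
    grid = association.spearman_grid(phyla, env)
    grid.to_csv(outdir / "spearman_grid.tsv", sep="\t", index=False,
                float_format="%.6g")
    return {"output": str(outdir), "n_mantel": len(mantel_rows)}


def _stage_network(cfg: PipelineConfig, outdir: Path, inputs: dict) -> dict:
    otu = inputs["otu"]
    seed = cfg.stage_seed("network")
    core = network.prevalence_filter(otu, cfg.min_prevalence)
    corr = network.correlation_matrix(core)
    scan = network.rmt_threshold(corr, **cfg.scan)
    scan.table.to_csv(outdir / "scan.tsv", sep="\t", index=False,
                      float_format="%.6g")
    g = network.build_network(corr, scan.selected_st)
    modules = network.detect_modules(g)
    topo = network.network_topology(g, modules)
    with open(outdir / "topology.json", "w", encoding="utf-8") as fh:
        json.dump({**vars(topo), "st": scan.selected_st}, fh, indent=1)
    pd.Series(modules.membership, name="module").rename_axis("otu_id").to_csv(
        outdir / "modules.tsv", sep="\t")
    roles = network.node_roles(g, modules)
    pd.DataFrame([vars(r) for r in roles]).to_csv(
        outdir / "roles.tsv", sep="\t", index=False, float_format="%.6g")
    nulls = network.null_model_ensemble(g, n_random=cfg.nulls, seed=seed)
    nulls.metrics.to_csv(outdir / "nullstats.tsv", sep="\t",
                         float_format="%.6g")
    if inputs.get("soil") is not None and inputs.get("metals") is not None:
        env = _env_frame(inputs).loc[lambda d:
                                     d.index.isin(core.sample_ids)]
        mm = network.module_environment_mantel(
            core, modules, env, permutations=cfg.permutations, seed=seed,
            module_ids=modules.dominant(8))
        mm.to_csv(outdir / "module_mantel.tsv", sep="\t", index=False,
                  float_format="%.6g")
    network.export_network(g, modules, roles, outdir / "network.gexf",
                           fmt="gexf", taxonomy=core.taxonomy)
    return {"output": str(outdir), "st": scan.selected_st,
            "n_nodes": topo.n_nodes, "n_links": topo.n_links,
            "modularity": topo.modularity_q}


_STAGE_FUNCS = {"pollution": _stage_pollution, "diversity": _stage_diversity,
                "association": _stage_association, "network": _stage_network}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured stages; returns (and writes) the report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: dict = {}
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        if cfg.otu:
            inputs["otu"] = tables_io.read_otu_table(cfg.otu)
        if cfg.soil:
            inputs["soil"] = tables_io.read_soil_table(cfg.soil)
        if cfg.metals:
            inputs["metals"] = tables_io.read_metal_table(cfg.metals)
        if cfg.backgrounds:
            inputs["backgrounds"] = tables_io.read_background_table(
                cfg.backgrounds)
        report = {"stages": {}, "seeds": {s: cfg.stage_seed(s)
                                          for s in cfg.stages},
                  "config": {k: v for k, v in vars(cfg).items()},
                  "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
        for stage in cfg.stages:
            t0 = time.time()
            try:
                info = _STAGE_FUNCS[stage](cfg, outdir, inputs)
                report["stages"][stage] = {"status": "ok", **info,
                                           "seconds": round(time.time() - t0,
                                                            2)}
            except Exception as exc:  # stage isolation: record, continue
                logger.exception("stage %s failed", stage)
                report["stages"][stage] = {"status": "failed",
                                           "error": str(exc)}
        caught = [str(w.message) for w in wlist]
    report["warnings"] = caught
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
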