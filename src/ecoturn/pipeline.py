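"""End-to-end orchestration: simulate/ingest -> rarefy -> distances ->
ordination & permutation statistics -> turnover -> assembly partition ->
networks -> report bundle.

Every stochastic stage derives its seed deterministically from the run seed,
so a config fully determines every number in the output directory (re-runs
are byte-identical).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly, dissimilarity, multivariate, network, tables, turnover
from .simulate import SimConfig, generate_dataset
from .tables import CommunityTable

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``simulate`` holds generator parameters, or ``otu_table`` /
    ``metadata`` / ``environment`` point to TSV inputs.
    """

    out_dir: str = "ecoturn_out"
    seed: int = 0
    simulate: dict | None = None
    otu_table: str | None = None
    metadata: str | None = None
    environment: str | None = None
    rarefaction_depth: int | None = None
    metric: str = "bray_curtis"
    permanova_formula: str = "site + day + site:day"
    n_perm: int = 999
    n_boot: int = 1000
    n_null: int = 199
    network_min_prevalence: float = 0.5
    network_scan: tuple[float, float, float] = (0.30, 0.99, 0.01)
    dominant_threshold: float = 0.01

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "network_scan" in raw:
            raw["network_scan"] = tuple(raw["network_scan"])
        if raw.get("simulate") and "sampling_days" in raw["simulate"]:
            raw["simulate"]["sampling_days"] = tuple(raw["simulate"]["sampling_days"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return json.loads(o.to_json(orient="index"))
    raise TypeError(f"not serializable: {type(o)}")


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk).

    Any stage failure raises with the stage named; outputs of completed
    stages are retained in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": []}
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2 ** 31)

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self
            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    manifest["stages"][name] = {"status": "failed",
                                                "error": str(exc)}
                    _write_manifest()
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                manifest["stages"][name] = {
                    "status": "ok",
                    "seconds": round(time.perf_counter() - self.t0, 3)}
                return False
        return _Stage()

    def emit(name, frame_or_text):
        path = out / name
        if isinstance(frame_or_text, pd.DataFrame):
            frame_or_text.to_csv(path, sep="\t")
        else:
            path.write_text(frame_or_text)
        manifest["outputs"].append(name)

    def _write_manifest():
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=_json_default))

    # ---- ingest / simulate
    with stage("input"):
        if config.simulate is not None:
            sim_cfg = SimConfig(**{**config.simulate, "seed": int(seeds[0])})
            table, meta, env = generate_dataset(sim_cfg)
            table.to_tsv(out / "otu_table.tsv")
            meta.to_csv(out / "metadata.tsv", sep="\t")
            env.to_csv(out / "environment.tsv", sep="\t")
            manifest["outputs"] += ["otu_table.tsv", "metadata.tsv",
                                    "environment.tsv"]
        else:
            if not (config.otu_table and config.metadata):
                raise ValueError("need either simulate parameters or input paths")
            table = CommunityTable.from_tsv(config.otu_table)
            meta = pd.read_csv(config.metadata, sep="\t", index_col=0)
            env = (pd.read_csv(config.environment, sep="\t", index_col=0)
                   if config.environment else None)

    # ---- rarefaction
    with stage("rarefy"):
        if config.rarefaction_depth:
            table = tables.rarefy(table, config.rarefaction_depth,
                                  seed=int(seeds[1]))
            meta = meta.loc[table.sample_ids]
            if env is not None:
                env = env.loc[table.sample_ids]
            table.to_tsv(out / "rarefied_table.tsv")
            manifest["outputs"].append("rarefied_table.tsv")

    # ---- distances + ordination
    with stage("dissimilarity"):
        dm = dissimilarity.distance_matrix(table, config.metric)
        emit("distance_matrix.tsv",
             pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)))
        emit("alpha_diversity.tsv", dissimilarity.alpha_diversity(table))

    with stage("ordination"):
        ord_res = multivariate.pcoa(dm)
        emit("pcoa_coordinates.tsv", ord_res.coordinates)
        emit("pcoa_eigenvalues.tsv", pd.DataFrame({
            "eigenvalue": ord_res.eigenvalues,
            "proportion_explained": ord_res.proportion_explained}))

    # ---- PERMANOVA / ANOSIM
    with stage("permanova"):
        perm = multivariate.permanova(dm, meta, config.permanova_formula,
                                      n_perm=config.n_perm, seed=int(seeds[2]))
        emit("permanova.tsv", perm.table)
        an = multivariate.anosim(dm, meta["site"].to_numpy(),
                                 n_perm=config.n_perm, seed=int(seeds[2]))
        emit("anosim.json", json.dumps(an, indent=2, default=_json_default))

    # ---- DistLM
    with stage("distlm"):
        if env is not None:
            dl = multivariate.distlm(dm, env, n_perm=config.n_perm,
                                     seed=int(seeds[3]))
            emit("distlm_marginal.tsv", dl.marginal)
            emit("distlm_sequential.tsv", dl.sequential)
            emit("distlm_stop_reason.txt", dl.stop_reason + "\n")

    # ---- turnover
    with stage("turnover"):
        sites = list(pd.unique(meta["site"]))
        tdr_summary = {}
        lag_tables = []
        for site in sites:
            pairs = turnover.similarity_lag_pairs(dm, meta, group=site)
            fit = turnover.tdr_fit(pairs)
            test = turnover.slope_test_zero(fit, pairs, n_perm=config.n_perm,
                                            n_boot=config.n_boot,
                                            seed=int(seeds[4]))
            tdr_summary[site] = {
                "slope": fit.slope, "intercept": fit.intercept, "w": fit.w,
                "r_squared": fit.r_squared, "p_slope_zero": test["p"],
                "boot_ci": list(test["boot_ci"]),
            }
            lag_tables.append(pairs.assign(site=site))
        emit("tdr_pairs.tsv", pd.concat(lag_tables, ignore_index=True))
        if len(sites) == 2:
            comp = turnover.compare_slopes(dm, meta, tuple(sites),
                                           n_perm=config.n_perm,
                                           seed=int(seeds[4]))
            tdr_summary["comparison"] = {"delta_w": comp["delta_w"],
                                         "p": comp["p"]}
            wg = turnover.within_group_similarity(dm, meta,
                                                  n_perm=config.n_perm,
                                                  seed=int(seeds[4]))
            tdr_summary["within_group_similarity"] = wg
        emit("tdr_summary.json",
             json.dumps(tdr_summary, indent=2, default=_json_default))

    # ---- assembly partition
    with stage("assembly"):
        parts = {}
        for site in sites:
            ids = [s for s in table.sample_ids if meta.loc[s, "site"] == site]
            sub = table.select_samples(ids)
            sub_dm = dm.filter(ids)
            pairs = assembly.within_group_pairs(meta.loc[ids], group_col="site")
            parts[site] = assembly.partition(sub, sub_dm, pairs,
                                             n_null=config.n_null,
                                             seed=int(seeds[5]),
                                             metric=config.metric)
            emit(f"assembly_pairs_{site}.tsv", parts[site].pairs)
        summary = pd.concat({s: p.summary for s, p in parts.items()})
        emit("assembly_summary.tsv", summary)
        if len(sites) == 2:
            contrast = assembly.determinism_contrast(parts[sites[1]],
                                                     parts[sites[0]])
            emit("assembly_contrast.json",
                 json.dumps({k: v for k, v in contrast.items()},
                            indent=2, default=_json_default))

    # ---- networks
    with stage("network"):
        lo, hi, step = config.network_scan
        scan = np.round(np.arange(lo, hi + step / 2, step), 10)
        net_summary = {}
        for site in sites:
            ids = [s for s in table.sample_ids if meta.loc[s, "site"] == site]
            core = tables.core_otus(table.select_samples(ids),
                                    config.network_min_prevalence)
            corr = network.correlation_matrix(core)
            rmt = network.rmt_threshold(corr, scan=scan)
            st = rmt.st if rmt.st is not None else float(scan[-1])
            try:
                net = network.build_network(corr, st)
            except ValueError:
                net_summary[site] = {"st": st, "error": "no edges at threshold"}
                continue
            topo = network.topology(net)
            modules = topo.pop("modules")
            base = network.random_baseline(net, n_rand=50, seed=int(seeds[6]))
            net_summary[site] = {"st": st, "rmt_failed": rmt.failed,
                                 "topology": topo, "random_baseline": base}
            emit(f"network_edges_{site}.tsv", net.edges)
            emit(f"network_modules_{site}.tsv",
                 pd.DataFrame({"module": pd.Series(modules)}))
        emit("network_summary.json",
             json.dumps(net_summary, indent=2, default=_json_default))

    # ---- dominant taxa
    with stage("dominant_taxa"):
        level = table
        if table.taxonomy is not None:
            level = tables.aggregate_rank(table, "family")
        rel = tables.relative_abundance(level)
        dom = tables.dominant_taxa(rel, config.dominant_threshold)
        emit("dominant_taxa.tsv",
             rel.data.loc[dom].mean(axis=1).rename("mean_relative_abundance")
             .to_frame())

    _write_manifest()
    manifest["outputs"].append("manifest.json")
    return manifest
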