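"""End-to-end analysis pipeline: survey data -> tables of results.

One call runs the full chain the package is built for: per-community
diversity indices, per-period bipartite networks with their structural
metrics, node metric series with temporal CVs, the temporal beta
partition for every period pair, the species-vs-patch CV comparison, and
a keystone-patch ranking. All outputs are deterministic TSV tables plus a
JSON manifest that fully determines them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._errors import ConfigError, UndefinedMetricError, ValidationError
from .diversity import diversity_profile
from .io_model import (SurveySet, chronological_periods, read_survey_table,
                       to_abundance_matrix, write_table)
from .network import (build_network, connectance, modularity, nodf,
                      node_metric_series, rank_sum_compare)
from .synthetic import (REGIME_ORDER, ScenarioConfig, SpeciesPool,
                        patch_attribute_table, scenario_suite)
from .temporal_beta import beta_matrix

log = logging.getLogger("metapatch")

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {},          # ScenarioConfig.default / SpeciesPool.default kwargs
    "input": None,           # or {"survey": path, "delimiter": "\t", ...}
    "network": {"presence_threshold": 1, "n_random": 100, "restarts": 20},
    "keystone": {"cnodf_percentile": 75.0, "cv_percentile": 75.0},
    "output": {"directory": "metapatch_out"},
}

_KNOWN_KEYS = set(DEFAULT_CONFIG)


def load_config(path_or_dict) -> dict:
    """Load and validate a pipeline configuration (YAML file or dict)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict or {})
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in raw.items():
        if isinstance(cfg.get(k), dict) and isinstance(v, dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    if cfg["network"]["presence_threshold"] < 1:
        raise ConfigError("network.presence_threshold must be >= 1")
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_or_simulate(cfg: dict, seed: int):
    """Return (SurveySet, patch attribute DataFrame or None, digests)."""
    digests = {}
    if cfg.get("input"):
        inp = cfg["input"]
        path = Path(inp["survey"])
        survey = read_survey_table(
            path, delimiter=inp.get("delimiter", "\t"),
            column_map=inp.get("column_map"),
            period_order=inp.get("period_order"))
        if not inp.get("period_order"):
            survey.periods = chronological_periods(survey.periods)
        digests[str(path)] = _digest(path)
        return survey, None, digests
    sim = dict(cfg.get("simulate") or {})
    pool_keys = ("n_species", "median_population", "population_sigma",
                 "median_min_area", "min_area_sigma")
    pool_kwargs = {k: sim.pop(k) for k in pool_keys if k in sim}
    scen = ScenarioConfig.default(seed=seed, **sim)
    pool = SpeciesPool.default(seed=seed + 1, **pool_kwargs)
    survey = scenario_suite(scen, pool, seed=seed + 2)
    return survey, patch_attribute_table(scen), digests


def _diversity_table(survey: SurveySet) -> pd.DataFrame:
    df = survey.to_dataframe()
    rows = []
    for level, key in (("patch", "patch_id"), ("subregion", "subregion")):
        grouped = df.groupby(["period", key, "species"])["count"].sum()
        for (period, unit), block in grouped.groupby(level=[0, 1]):
            prof = diversity_profile(block.to_numpy())
            rows.append({
                "level": level, "period": period, "unit": unit,
                "abundance": prof.abundance, "richness": prof.richness,
                "shdi": prof.shdi,
                "pielou": np.nan if prof.pielou is None else prof.pielou,
            })
    return pd.DataFrame(rows)


def _network_tables(survey: SurveySet, net_cfg: dict, seed: int):
    nets = []
    net_rows = []
    for period in survey.periods:
        m = to_abundance_matrix(survey, period)
        net = build_network(m, net_cfg["presence_threshold"])
        nets.append(net)
        q, partition = modularity(net, seed=seed,
                                  restarts=net_cfg["restarts"])
        net_rows.append({
            "period": period,
            "n_species": len(net.species_nodes),
            "n_patches": len(net.patch_nodes),
            "n_links": net.n_links,
            "connectance": connectance(net),
            "nodf": nodf(net),
            "modularity_q": q,
            "n_modules": len(set(partition.values())),
        })
    series = node_metric_series(nets, n_random=net_cfg["n_random"], seed=seed)
    node_rows = []
    for s in series:
        row = {"node_id": s.node_id, "node_class": s.node_class}
        for period in survey.periods:
            row[f"degree_{period}"] = s.degree_by_period.get(period, np.nan)
            row[f"cnodf_{period}"] = s.cnodf_by_period.get(period, np.nan)
        row["cv_degree"] = np.nan if s.cv_degree is None else s.cv_degree
        row["cv_cnodf"] = np.nan if s.cv_cnodf is None else s.cv_cnodf
        node_rows.append(row)
    return nets, pd.DataFrame(net_rows), pd.DataFrame(node_rows), series


def _beta_table(nets) -> pd.DataFrame:
    rows = []
    for bp in beta_matrix(nets):
        rows.append({
            "pair": f"{bp.pair[0]}->{bp.pair[1]}",
            "beta_temporal": bp.beta_temporal,
            "beta_extinction": bp.beta_extinction,
            "beta_colonization": bp.beta_colonization,
            "beta_local": bp.beta_local,
            "beta_regional": bp.beta_regional,
            "beta_landscape": bp.beta_landscape,
            "beta_rl": bp.beta_rl,
        })
    return pd.DataFrame(rows)


def _cv_comparison(node_df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for metric in ("cv_degree", "cv_cnodf"):
        species = node_df.loc[node_df.node_class == "species", metric].dropna()
        patches = node_df.loc[node_df.node_class == "patch", metric].dropna()
        row = {"metric": metric, "n_species": len(species),
               "n_patches": len(patches)}
        try:
            u, z, p = rank_sum_compare(patches, species)
            row.update({"u_patches": u, "z": z, "p": p})
        except (UndefinedMetricError, ValidationError):
            row.update({"u_patches": np.nan, "z": np.nan, "p": np.nan})
        rows.append(row)
    return pd.DataFrame(rows)


def _keystone_table(node_df: pd.DataFrame, cfg: dict) -> pd.DataFrame:
    patches = node_df[node_df.node_class == "patch"].copy()
    cnodf_cols = [c for c in patches.columns if c.startswith("cnodf_")]
    patches["mean_abs_cnodf"] = patches[cnodf_cols].abs().mean(axis=1)
    cn_cut = np.nanpercentile(patches["mean_abs_cnodf"],
                              cfg["cnodf_percentile"])
    cv_cut = np.nanpercentile(patches["cv_degree"].dropna(),
                              cfg["cv_percentile"])
    patches["keystone"] = patches["mean_abs_cnodf"] > cn_cut
    patches["high_variability"] = patches["cv_degree"] > cv_cut
    out = patches[["node_id", "mean_abs_cnodf", "cv_degree", "cv_cnodf",
                   "keystone", "high_variability"]]
    out = out.sort_values("mean_abs_cnodf", ascending=False,
                          kind="mergesort", ignore_index=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def run_pipeline(config, out_dir: str | Path | None = None,
                 seed: int | None = None) -> Path:
    """Run the full analysis and write result tables plus a manifest.

    *config* is a YAML path or dict (see :data:`DEFAULT_CONFIG`). Returns
    the output directory. Identical configurations produce byte-identical
    outputs.
    """
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir or cfg["output"]["directory"])
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    master = int(cfg["seed"])

    survey, patch_attrs, digests = _load_or_simulate(cfg, master)
    log.info("stage=input periods=%d records=%d (%.2fs)",
             len(survey.periods), len(survey.records), time.perf_counter() - t0)

    tables: dict[str, pd.DataFrame] = {}
    tables["diversity.tsv"] = _diversity_table(survey)
    log.info("stage=diversity rows=%d (%.2fs)",
             len(tables["diversity.tsv"]), time.perf_counter() - t0)

    nets, net_df, node_df, _ = _network_tables(survey, cfg["network"],
                                               master + 10)
    tables["network_metrics.tsv"] = net_df
    tables["node_metrics.tsv"] = node_df
    log.info("stage=network periods=%d nodes=%d (%.2fs)",
             len(net_df), len(node_df), time.perf_counter() - t0)

    tables["beta_partition.tsv"] = _beta_table(nets)
    tables["cv_comparison.tsv"] = _cv_comparison(node_df)
    tables["keystone_patches.tsv"] = _keystone_table(node_df, cfg["keystone"])
    log.info("stage=beta pairs=%d (%.2fs)",
             len(tables["beta_partition.tsv"]), time.perf_counter() - t0)

    if patch_attrs is not None:
        tables["patch_attributes.tsv"] = patch_attrs

    for name, df in tables.items():
        write_table(df, out / name)

    manifest = {
        "package": "metapatch",
        "version": __version__,
        "seed": master,
        "config": cfg,
        "input_digests": digests,
        "row_counts": {name: int(len(df)) for name, df in tables.items()},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8")
    log.info("stage=done outputs=%d (%.2fs)",
             len(tables) + 1, time.perf_counter() - t0)
    return out


def plot_summary(out_dir: str | Path) -> list[Path]:
    """Render the two summary figures from a pipeline output directory:
    stacked beta-component bars per period pair and network-metric lines
    per period. Returns the written file paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    written = []

    beta = pd.read_csv(out / "beta_partition.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(7, 4))
    bottom = np.zeros(len(beta))
    for comp in ("beta_local", "beta_regional", "beta_landscape", "beta_rl"):
        ax.bar(beta["pair"], beta[comp], bottom=bottom,
               label=comp.replace("beta_", ""))
        bottom += beta[comp].to_numpy()
    ax.set_ylabel("temporal beta diversity of links")
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = out / "beta_components.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    net = pd.read_csv(out / "network_metrics.tsv", sep="\t")
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, col in zip(axes, ("connectance", "nodf", "modularity_q")):
        ax.plot(net["period"], net[col], marker="o")
        ax.set_title(col)
    fig.tight_layout()
    p = out / "network_metrics.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
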