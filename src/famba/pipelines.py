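"""Runnable end-to-end pipelines.

Two orchestrations bind the stages together:

* the fatty-acid pipeline: profiles -> digestibility -> growth metrics
  -> whole-body mass balance -> deposition metrics -> group statistics;
* the proteomics pipeline: filter -> log2 -> cyclic loess -> sample
  weights -> moderated linear model -> BH adjustment -> raw fold
  changes.

Both consume a YAML/dict configuration, write CSV outputs with a
traceability header (version, config hash, seed) and return the result
objects for programmatic use.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .deposition import deposition_table, tissue_absolute_content
from .fatty_acids import composition_ratios
from .group_stats import anova_block, levene, summarize
from .mass_balance import MassBalanceInput, mass_balance, treatment_summary
from .proteome import (
    cyclic_loess_normalize,
    filter_proteins,
    fit_moderated,
    fold_change_raw,
    log2_transform,
    read_maxquant,
    sample_weights,
)
from .trial_metrics import fer, sgr, tank_digestibility

__all__ = ["run_fatty_pipeline", "run_proteome_pipeline", "load_config", "validate_config"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg


_FATTY_REQUIRED = ("tanks_csv", "profiles_csv", "profiles_meta_csv", "out_dir")
_PROT_REQUIRED = ("protein_groups_tsv", "samples_csv", "out_dir")


def validate_config(cfg: dict, kind: str) -> list[str]:
    """Schema check; returns a list of per-field problem messages."""
    required = _FATTY_REQUIRED if kind == "fatty" else _PROT_REQUIRED
    problems = [f"missing required key: {k}" for k in required if k not in cfg]
    for k in ("tanks_csv", "profiles_csv", "profiles_meta_csv", "marker_csv",
              "ad_csv", "protein_groups_tsv", "samples_csv"):
        if k in cfg and cfg[k] and not Path(cfg[k]).exists():
            problems.append(f"{k}: file not found: {cfg[k]}")
    return problems


def _header(cfg: dict, seed) -> str:
    return (
        f"famba {__version__}\nconfig_hash {io.config_hash(cfg)}\nseed {seed}"
    )


def run_fatty_pipeline(config: dict | str | Path, seed: int = 0) -> dict:
    """Run the fatty-acid analysis pipeline from a config mapping or
    YAML path; returns the result tables keyed by stage."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    problems = validate_config(cfg, "fatty")
    if problems:
        raise ValueError("invalid configuration:\n" + "\n".join(problems))
    out_dir = Path(cfg["out_dir"])
    header = _header(cfg, seed)

    tanks = io.read_tanks(cfg["tanks_csv"], cfg.get("marker_csv"))
    if not tanks:
        raise ValueError("tank list is empty")
    profiles = io.read_profiles(cfg["profiles_csv"], cfg["profiles_meta_csv"])
    ad = io.read_ad(cfg["ad_csv"]) if cfg.get("ad_csv") else {}

    growth = pd.DataFrame(
        [
            {
                "tank_id": t.tank_id,
                "diet": t.diet,
                "system_id": t.system_id,
                "sgr": sgr(t),
                "fer": fer(t),
            }
            for t in tanks
        ]
    )
    io.write_frame(growth, out_dir / "growth.csv", header)

    digest_rows = []
    for t in tanks:
        for analyte in t.marker:
            if analyte == "yttrium":
                continue
            digest_rows.append(
                {
                    "tank_id": t.tank_id,
                    "diet": t.diet,
                    "analyte": analyte,
                    "ad_percent": tank_digestibility(t, analyte),
                }
            )
    if digest_rows:
        io.write_frame(pd.DataFrame(digest_rows), out_dir / "digestibility.csv", header)

    # whole-body mass balance per tank, when carcass profiles are supplied
    mb_rows = []
    tank_results = {}
    init_label = cfg.get("initial_carcass_label", "initial carcass")
    for t in tanks:
        final_label = cfg.get("final_carcass_template", "{tank_id} final carcass").format(
            tank_id=t.tank_id
        )
        if init_label not in profiles or final_label not in profiles:
            continue
        feed_label = cfg.get("feed_template", "{diet} feed").format(diet=t.diet)
        res = mass_balance(
            MassBalanceInput(
                feed=profiles[feed_label],
                fi_g=t.fi_g,
                ad=ad.get(t.diet, {}),
                initial_weight_g=t.wi_g,
                initial_profile=profiles[init_label],
                final_weight_g=t.wf_g,
                final_profile=profiles[final_label],
                days=t.days,
                default_ad=float(cfg.get("default_ad", 95.0)),
            )
        )
        tank_results[t.tank_id] = res
        frame = res.components.reset_index()
        frame.insert(0, "tank_id", t.tank_id)
        frame.insert(1, "diet", t.diet)
        mb_rows.append(frame)
    results: dict = {"growth": growth, "tank_results": tank_results}
    if mb_rows:
        mb = pd.concat(mb_rows, ignore_index=True)
        io.write_frame(mb, out_dir / "massbalance.csv", header)
        results["massbalance"] = mb

    # ratios and deposition for any (diet feed, tissue) profile pairs
    ratio_rows = [
        {"matrix_label": label, **{k: v for k, v in composition_ratios(p, ndigits=1).items()}}
        for label, p in profiles.items()
    ]
    io.write_frame(pd.DataFrame(ratio_rows), out_dir / "ratios.csv", header)

    # blocked group statistics on the growth metrics
    stats_rows, summary_rows = [], []
    for var in ("sgr", "fer"):
        table = growth.rename(columns={var: "value"})[["diet", "system_id", "value"]]
        diets_ok = table.groupby("diet")["value"].count().min() >= 2
        if len(table["diet"].unique()) >= 2 and diets_ok:
            a = anova_block(table)
            lv = levene(table)
            stats_rows.append({"variable": var, **a, "levene_W": lv["W"], "levene_p": lv["p"]})
            s = summarize(table)
            s.insert(0, "variable", var)
            summary_rows.append(s.reset_index())
    if stats_rows:
        io.write_frame(pd.DataFrame(stats_rows), out_dir / "anova.csv", header)
        io.write_frame(pd.concat(summary_rows, ignore_index=True), out_dir / "summaries.csv", header)
        results["anova"] = pd.DataFrame(stats_rows)
    return results


def run_proteome_pipeline(config: dict | str | Path, seed: int = 0) -> dict:
    """Run the label-free differential-abundance pipeline; returns the
    DAResult plus fold-change tables and writes da_results.csv and
    volcano.csv."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    problems = validate_config(cfg, "proteome")
    if problems:
        raise ValueError("invalid configuration:\n" + "\n".join(problems))
    out_dir = Path(cfg["out_dir"])
    header = _header(cfg, seed)

    samples = pd.read_csv(cfg["samples_csv"], comment="#", index_col=0)
    table = read_maxquant(cfg["protein_groups_tsv"], samples)
    kept = filter_proteins(table)
    if kept.intensities.empty:
        io.write_frame(pd.DataFrame(), out_dir / "da_results.csv",
                       header + "\nno protein passed the filters")
        return {"result": None, "n_proteins": 0}

    logm = log2_transform(kept.intensities)
    norm = cyclic_loess_normalize(
        logm,
        span=float(cfg.get("loess_span", 0.7)),
        iterations=int(cfg.get("loess_iterations", 3)),
    )
    weights = sample_weights(norm, kept.samples)
    fit = fit_moderated(norm, kept.samples, weights)

    frames = []
    for contrast, tbl in fit.tables.items():
        num, _, den = contrast.partition(" vs ")
        fc = fold_change_raw(kept, num, den)
        merged = tbl.join(fc[["fold_change", "status"]])
        merged.insert(0, "contrast", contrast)
        merged["significant_0.1"] = merged["adj_p_value"] < 0.1
        merged["significant_0.3"] = merged["adj_p_value"] < 0.3
        frames.append(merged.reset_index())
    da = pd.concat(frames, ignore_index=True)
    io.write_frame(da, out_dir / "da_results.csv", header)
    volcano = da[["protein", "contrast", "logFC", "p_value", "adj_p_value"]]
    io.write_frame(volcano, out_dir / "volcano.csv", header)
    return {"result": fit, "da_table": da, "n_proteins": len(kept.intensities)}
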