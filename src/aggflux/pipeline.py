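"""End-to-end workflow: simulate -> measure -> gate -> quantify -> partition.

Runs the whole platform on a config (dict or YAML file): per chaperone arm
and replicate it simulates a cell population, synthesizes cytometer events
with untransfected / unstained / diffuse-control references, derives a gate
set, computes the population metrics (death rates, inclusion fraction,
PFR,ni, reporter ratio, cell density), pools a lysate, pushes it through
the chromatogram and 2 M sucrose scan simulators, fits the monomer /
oligomer / inclusion partition, and finally compares arms by ANOVA with
Holm-Sidak correction.  Every output is a headered CSV; a run manifest
(config hash, seed, file list) makes reruns traceable and, for fixed seed,
byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gating, metrics, sva
from .gel_filtration import decompose_pools
from .instrument import (SUCROSE_SCAN_TIMES, ColumnConfig, PanelConfig, SvaGeometry,
                         cells_to_events, make_diffuse_control,
                         simulate_chromatogram, simulate_radial_scans)
from .partitioning import combine_partition
from .popsim import SimConfig, pool_lysate, simulate_population

__all__ = ["DEFAULT_PIPELINE_CONFIG", "run_pipeline"]

log = logging.getLogger("aggflux")

DEFAULT_PIPELINE_CONFIG: dict = {
    "seed": 0,
    "outdir": "aggflux_run",
    "polyq_length": 72,
    "arms": ["alone", "hsp40", "hsp70", "hsp40+hsp70"],
    "n_cells": 1500,
    "replicates": 3,
    "time_points": [46.0],
    "analysis_time": 46.0,
    "acquired_volume": 1.0,   # arbitrary volume units per replicate
    "inclusion_s_sucrose": 900.0,  # effective s of inclusions in 2 M sucrose
    "scan_noise_sd": 0.02,
    "chromatogram_noise_sd": 0.05,
    "write_fcs": False,
}


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def run_pipeline(config: dict | str | Path | None = None) -> dict:
    """Run every stage and write CSV outputs plus a run manifest.

    Returns the manifest dict.  The config is validated (including arm
    names) before any simulation starts.
    """
    if config is None:
        config = {}
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_PIPELINE_CONFIG, **config}
    unknown = set(cfg) - set(DEFAULT_PIPELINE_CONFIG)
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    # validate arms before simulating anything
    SimConfig(arm="alone", seed=0)  # also validates defaults
    probe = SimConfig(seed=0)
    for arm in cfg["arms"]:
        if arm not in probe.chaperone_mods:
            raise ValueError(f"unknown arm {arm!r}; known: "
                             f"{sorted(probe.chaperone_mods)}")

    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    rng_seq = np.random.SeedSequence(seed)
    panel = PanelConfig()
    t_star = float(cfg["analysis_time"])
    outputs: list[str] = []

    log.info("stage: references")
    diffuse_ctrl = make_diffuse_control(panel, n=3000, seed=seed + 901)
    untransfected = _reference_events(panel, 3000, seed + 902)
    unstained = untransfected

    metric_rows, partition_rows, stat_rows = [], [], []
    density_ref = None
    arm_totals: dict[str, list[float]] = {}

    for arm in cfg["arms"]:
        for rep in range(int(cfg["replicates"])):
            sub = int(rng_seq.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            sim = SimConfig(polyq_length=int(cfg["polyq_length"]),
                            n_cells=int(cfg["n_cells"]),
                            time_points=tuple(cfg["time_points"]),
                            arm=arm, seed=sub)
            log.info("stage: simulate arm=%s rep=%d", arm, rep)
            pop = simulate_population(sim)
            cells = pop.at(t_star)
            events = cells_to_events(cells, panel, seed=sub + 1)
            if cfg["write_fcs"]:
                from .fcs import write_fcs
                fp = outdir / f"events_{arm.replace('+', '-')}_r{rep}.fcs"
                write_fcs(events, fp)
                outputs.append(str(fp))

            gs = gating.derive_gateset(events, untransfected, unstained)
            labels = gating.apply_gates(events, gs, diffuse_ctrl, diffuse_ctrl)

            dr_all = metrics.death_rate(labels, "all")
            dr_i = metrics.death_rate(labels, "i")
            dr_ni = metrics.death_rate(labels, "ni")
            tr = int(labels["transfected"].sum())
            i_frac = float((labels["pulsa"] == "i").sum() / max(tr, 1))
            pfr = metrics.pfr_ni_fraction(labels)
            dens = metrics.cell_density(tr, float(cfg["acquired_volume"]))
            if density_ref is None:
                density_ref = dens
            metric_rows.append({
                "arm": arm, "replicate": rep, "polyq": cfg["polyq_length"],
                "time": t_star, "n_transfected": tr,
                "death_rate_all": dr_all.rate, "death_rate_i": dr_i.rate,
                "death_rate_ni": dr_ni.rate, "i_fraction": i_frac,
                "pfr_ni_fraction": pfr["fraction"],
                "relative_density": dens / density_ref,
            })

            log.info("stage: biochemistry arm=%s rep=%d", arm, rep)
            lysate = pool_lysate(cells)
            chrom = simulate_chromatogram(
                lysate, ColumnConfig(),
                noise_sd=float(cfg["chromatogram_noise_sd"]), seed=sub + 2)
            pools = decompose_pools(chrom, ColumnConfig().mono_center_ml,
                                    ColumnConfig().olig_center_ml)
            scans = simulate_radial_scans(
                [(0.0, (1 - lysate.p_inc) * lysate.total_signal / 1000.0),
                 (float(cfg["inclusion_s_sucrose"]),
                  lysate.p_inc * lysate.total_signal / 1000.0)],
                SvaGeometry(), scan_times=SUCROSE_SCAN_TIMES,
                noise_sd=float(cfg["scan_noise_sd"]), seed=sub + 3)
            inc = sva.inclusion_fraction(scans)
            part = combine_partition(pools, inc.p_inc,
                                     inc.total_loading * 1000.0)
            arm_totals.setdefault(arm, []).append(part.total_abundance)
            partition_rows.append({
                "arm": arm, "replicate": rep, "p_mono": part.p_mono,
                "p_olig": part.p_olig, "p_inc": part.p_inc,
                "total_abundance": part.total_abundance,
                "truth_p_mono": lysate.p_mono, "truth_p_olig": lysate.p_olig,
                "truth_p_inc": lysate.p_inc, "split_method": pools.method,
            })

    metrics_df = pd.DataFrame(metric_rows)
    partition_df = pd.DataFrame(partition_rows)
    for name, df in (("metrics.csv", metrics_df),
                     ("partition.csv", partition_df)):
        fp = outdir / name
        df.to_csv(fp, index=False, float_format="%.8g")
        outputs.append(str(fp))

    log.info("stage: statistics")
    if len(cfg["arms"]) > 1 and int(cfg["replicates"]) >= 2:
        for col in ("death_rate_all", "i_fraction"):
            res = metrics.anova_holm_sidak(
                metrics_df.rename(columns={col: "value"}), design="one-way",
                control_arm=cfg["arms"][0])
            for _, row in res["pairwise"].iterrows():
                stat_rows.append({"metric": col, "arm": row["arm"],
                                  "p_raw": row["p_raw"],
                                  "p_adj": row["p_adj"],
                                  "omnibus_p_arm": res["omnibus"]["arm"]})
        fp = outdir / "stats.csv"
        pd.DataFrame(stat_rows).to_csv(fp, index=False, float_format="%.8g")
        outputs.append(str(fp))

    manifest = {
        "config": cfg, "config_hash": _config_hash(cfg), "seed": seed,
        "inputs": [], "outputs": sorted(outputs),
        "package_version": _version(),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("pipeline complete: %d outputs in %s", len(outputs), outdir)
    return manifest


def _version() -> str:
    from importlib.metadata import version
    try:
        return version("aggflux")
    except Exception:
        return "unknown"


def _reference_events(panel: PanelConfig, n: int, seed: int) -> pd.DataFrame:
    """Untransfected, unstained reference acquisition (background only)."""
    from .popsim import STATUS_LIVE
    rng = np.random.default_rng(seed)
    cells = pd.DataFrame({
        "id": np.arange(n), "time": 0.0, "arm": "untransfected", "polyq": 0,
        "E_htt": 0.0, "E_mkate": 0.0, "f_mono": 1.0, "f_olig": 0.0,
        "f_inc": 0.0, "has_inclusion": False, "status": STATUS_LIVE,
    })
    clean = dataclasses.replace(panel, frac_untransfected=0.0,
                                frac_small_particles=0.0, doublet_rate=0.0)
    return cells_to_events(cells, clean, seed=rng)
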