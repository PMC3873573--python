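#!/usr/bin/env python
"""Measure the band quantities that the frozen simulator defaults target.

The simulator's death hazards and chaperone-arm modifiers were tuned once
against the qualitative bands the platform is meant to reproduce (reference
72Q arm at 46 h: inclusion-population death rate 50-75%, no-inclusion
15-30%; hsp40 cutting the all-cell inclusion fraction by 20-30% relative;
hsp70 lowering inclusion-population death by ~15 points; the combined arm
raising no-inclusion death by 5-10 points; ~0.5% PFR,ni for 46Q) and then
frozen in aggflux.popsim (DEFAULTS_VERSION).  This script re-measures those
quantities for the current defaults -- optionally overriding individual
modifiers from the command line -- so any retuning is reproducible.

Example:  python scripts/tune_defaults.py --n-cells 15000 --seeds 2 11
          python scripts/tune_defaults.py --hsp40-nuc 0.65
"""

from __future__ import annotations

import argparse
import dataclasses

import numpy as np

import aggflux as ag
from aggflux.metrics import death_rate, pfr_ni_fraction
from aggflux.pipeline import _reference_events
from aggflux.popsim import SimConfig, default_arm_modifiers


def run(panel, untr, ctrl, arm, polyq, n, seed, mods):
    cfg = SimConfig(polyq_length=polyq, n_cells=n, seed=seed, arm=arm,
                    time_points=(46.0,), chaperone_mods=mods)
    cells = ag.simulate_population(cfg).at(46.0)
    events = ag.cells_to_events(cells, panel, seed=seed + 1)
    gs = ag.derive_gateset(events, untr, untr)
    labels = ag.apply_gates(events, gs, ctrl, ctrl)
    tr = int(labels["transfected"].sum())
    return {
        "death_i": death_rate(labels, "i").rate,
        "death_ni": death_rate(labels, "ni").rate,
        "i_frac": (labels["pulsa"] == "i").sum() / tr,
        "pfr_ni": pfr_ni_fraction(labels)["fraction"],
    }


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-cells", type=int, default=12000)
    ap.add_argument("--seeds", type=int, nargs="+", default=[2, 11, 41])
    ap.add_argument("--hsp40-nuc", type=float, default=None)
    ap.add_argument("--hsp70-death-i", type=float, default=None)
    ap.add_argument("--pair-death-ni", type=float, default=None)
    args = ap.parse_args()

    mods = default_arm_modifiers()
    if args.hsp40_nuc is not None:
        for arm in ("hsp40", "hsp40+hsp70"):
            mods[arm] = dataclasses.replace(mods[arm], nuc=args.hsp40_nuc)
    if args.hsp70_death_i is not None:
        mods["hsp70"] = dataclasses.replace(mods["hsp70"],
                                            death_i=args.hsp70_death_i)
    if args.pair_death_ni is not None:
        mods["hsp40+hsp70"] = dataclasses.replace(
            mods["hsp40+hsp70"], death_ni=args.pair_death_ni)

    panel = ag.PanelConfig()
    untr = _reference_events(panel, 3000, 7)
    ctrl = ag.make_diffuse_control(panel, 3000, 8)

    acc: dict[str, list[dict]] = {a: [] for a in mods}
    pfr46 = []
    for seed in args.seeds:
        for arm in mods:
            acc[arm].append(run(panel, untr, ctrl, arm, 72, args.n_cells,
                                seed, mods))
        pfr46.append(run(panel, untr, ctrl, "alone", 46, args.n_cells,
                         seed + 1, mods)["pfr_ni"])

    mean = {a: {k: float(np.mean([r[k] for r in rows]))
                for k in rows[0]} for a, rows in acc.items()}
    alone = mean["alone"]
    print(f"{'arm':14s} {'death_i':>8s} {'death_ni':>9s} {'i_frac':>7s}")
    for arm, m in mean.items():
        print(f"{arm:14s} {m['death_i']:8.3f} {m['death_ni']:9.3f} "
              f"{m['i_frac']:7.3f}")
    print("\ntargets:")
    print(f"  alone death_i in [0.50, 0.75]        -> {alone['death_i']:.3f}")
    print(f"  alone death_ni in [0.15, 0.30]       -> {alone['death_ni']:.3f}")
    red = (alone["i_frac"] - mean["hsp40"]["i_frac"]) / alone["i_frac"]
    print(f"  hsp40 relative i reduction 0.20-0.30 -> {red:.3f}")
    drop = alone["death_i"] - mean["hsp70"]["death_i"]
    print(f"  hsp70 death_i drop ~0.15             -> {drop:.3f}")
    rise = mean["hsp40+hsp70"]["death_ni"] - alone["death_ni"]
    print(f"  hsp40+hsp70 death_ni rise 0.05-0.10  -> {rise:.3f}")
    print(f"  46Q PFR,ni fraction ~0.005           -> {np.mean(pfr46):.4f}")


if __name__ == "__main__":
    main()
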