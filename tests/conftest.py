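"""Shared fixtures: one default 72Q chain run reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import aggflux as ag
from aggflux.pipeline import _reference_events


@pytest.fixture(scope="session")
def panel():
    return ag.PanelConfig()


@pytest.fixture(scope="session")
def untransfected_ref(panel):
    return _reference_events(panel, 3000, 7)


@pytest.fixture(scope="session")
def diffuse_control(panel):
    return ag.make_diffuse_control(panel, 3000, 8)


@pytest.fixture(scope="session")
def default_run(panel, untransfected_ref, diffuse_control):
    """Default 72Q 'alone' population at 46 h pushed through the full chain."""
    cfg = ag.SimConfig(polyq_length=72, n_cells=12000, seed=2,
                       time_points=(46.0,))
    pop = ag.simulate_population(cfg)
    cells = pop.at(46.0)
    events = ag.cells_to_events(cells, panel, seed=3)
    gateset = ag.derive_gateset(events, untransfected_ref, untransfected_ref)
    labels = ag.apply_gates(events, gateset, diffuse_control, diffuse_control)
    return {"config": cfg, "pop": pop, "cells": cells, "events": events,
            "gateset": gateset, "labels": labels}


def truth_labels(cells: pd.DataFrame, sytox_miss_leached=0.6,
                 sytox_miss_debris=0.6, seed=0) -> pd.DataFrame:
    """Oracle labels from simulator truth plus SYTOX staining chemistry.

    Intact dead cells always stain; leached/debris stain with the
    configured miss probability; live cells never stain.
    """
    rng = np.random.default_rng(seed)
    status = cells["status"].to_numpy()
    pop = np.where(status == "leached", "L",
                   np.where(status == "lysed_debris", "D", "M"))
    stain = np.zeros(len(cells), dtype=bool)
    stain[status == "dead_intact"] = True
    for st, miss in (("leached", sytox_miss_leached),
                     ("lysed_debris", sytox_miss_debris)):
        sel = status == st
        stain[sel] = rng.random(sel.sum()) >= miss
    inc = cells["has_inclusion"].to_numpy()
    pulsa = np.where(pop == "M", np.where(inc, "i", "ni"), "n/a")
    return pd.DataFrame({
        "pregate": True, "transfected": True, "pop": pop,
        "sytox": np.where(stain, "+", "-"), "pulsa": pulsa, "flash": "n/a",
    }, index=pd.RangeIndex(len(cells), name="event_index"))
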