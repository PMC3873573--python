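"""Gating tree: references, thresholds, M/D/L, SYTOX, PulSA, FlAsH."""

import numpy as np
import pandas as pd
import pytest

import aggflux as ag
from aggflux import gating
from aggflux.gating import (GateSet, classify_MDL, flash_gate, pregate,
                            pulsa_gate, sytox_gate, transfection_gate)


def _min_events(n, **over):
    base = {c: np.full(n, 100.0) for c in (
        "FSC-H", "FSC-A", "FSC-W", "BV421-H", "BV421-A", "BV421-W",
        "FITC-H", "FITC-A", "FITC-W", "PE-TxRed-H", "PE-TxRed-A",
        "PE-TxRed-W", "APC-H", "APC-A", "APC-W")}
    base.update(over)
    return pd.DataFrame(base)


class TestPregate:
    def test_floor_is_exclusive(self):
        gs = GateSet(size_floor=6.0, doublet_max=10.0)
        ev = _min_events(3, **{"FSC-H": np.array([6.0 - 1e-9, 6.0, 6.1]),
                               "FSC-A": np.array([10.0, 10.0, 10.0])})
        assert list(pregate(ev, gs)) == [False, False, True]

    def test_background_removed_cells_kept(self, default_run):
        ev, lab = default_run["events"], default_run["labels"]
        particles = ev["truth_kind"] == "particle"
        cells = (ev["truth_kind"] == "cell") & ~ev["truth_doublet"]
        assert (~lab["pregate"][particles]).mean() >= 0.95
        assert (~lab["pregate"][cells]).mean() <= 0.01

    def test_identical_in_range_events_all_pass(self):
        ev = _min_events(5, **{"FSC-H": np.full(5, 50.0),
                               "FSC-A": np.full(5, 120.0)})
        assert pregate(ev, GateSet()).all()

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            pregate(_min_events(0))


class TestTransfectionGate:
    def test_constant_reference_threshold(self):
        ref = _min_events(100, **{"BV421-A": np.full(100, 100.0),
                                  "PE-TxRed-A": np.full(100, 50.0)})
        ev = _min_events(10, **{
            "BV421-A": np.array([101.0, 99.0] + [150.0] * 8),
            "PE-TxRed-A": np.zeros(10)})
        thr, mask = transfection_gate(ev, ref)
        assert thr == pytest.approx(100.0)
        assert list(mask) == [True, False] + [True] * 8

    def test_either_channel_rule_keeps_leached(self):
        ref = _min_events(100, **{"BV421-A": np.full(100, 10.0),
                                  "PE-TxRed-A": np.full(100, 10.0)})
        leached = _min_events(1, **{"BV421-A": np.array([0.5]),
                                    "PE-TxRed-A": np.array([400.0])})
        _, mask = transfection_gate(leached, ref)
        assert mask.all()

    def test_accuracy_on_simulation(self, default_run):
        ev, lab = default_run["events"], default_run["labels"]
        live = (ev["truth_kind"] == "cell") & (ev["truth_status"] == "live") \
            & lab["pregate"]
        untr = (ev["truth_kind"] == "untransfected") & lab["pregate"]
        assert lab["transfected"][live].mean() >= 0.99
        assert lab["transfected"][untr].mean() <= 0.002

    def test_mislabelled_controls_raise(self, default_run):
        ev = default_run["events"]
        with pytest.raises(ValueError, match="mislabelled"):
            transfection_gate(ev, ev)  # sample used as its own reference


class TestClassifyMDL:
    def test_live_population_is_major(self, default_run):
        ev, lab = default_run["events"], default_run["labels"]
        live = (ev["truth_kind"] == "cell") & (ev["truth_status"] == "live") \
            & lab["transfected"]
        assert (lab["pop"][live] == "M").mean() >= 0.98

    def test_debris_and_leached_examples(self):
        rng = np.random.default_rng(0)
        n = 300
        cer = np.exp(rng.normal(np.log(500), 0.5, n))
        ev = _min_events(n, **{"BV421-A": cer, "PE-TxRed-A": 0.4 * cer})
        # one debris-like event (Cerulean 100x the band prediction) and one
        # leached-like event (Cerulean dark, mKate2 bright)
        ev.loc[0, ["BV421-A", "PE-TxRed-A"]] = (50000.0, 3.0)
        ev.loc[1, ["BV421-A", "PE-TxRed-A"]] = (1.0, 800.0)
        labels, _ = classify_MDL(ev, transfection_threshold=15.0)
        assert labels.iloc[0] == "D"
        assert labels.iloc[1] == "L"
        assert (labels.iloc[2:] == "M").mean() > 0.98

    def test_too_few_events_raise(self):
        with pytest.raises(ValueError, match="fewer than 50"):
            classify_MDL(_min_events(10), transfection_threshold=10.0)


class TestSytoxGate:
    def test_reference_percentile_threshold(self):
        ref = _min_events(1000, **{"APC-A": np.full(1000, 50.0)})
        ev = _min_events(2, **{"APC-A": np.array([60.0, 40.0])})
        thr, labels = sytox_gate(ev, ref)
        assert thr == pytest.approx(50.0)
        assert list(labels) == ["+", "-"]

    def test_dead_intact_detected(self, default_run):
        ev, lab = default_run["events"], default_run["labels"]
        dead = (ev["truth_status"] == "dead_intact") & lab["transfected"]
        assert (lab["sytox"][dead] == "+").mean() >= 0.95

    def test_leached_mostly_negative(self, default_run):
        ev, lab = default_run["events"], default_run["labels"]
        leached = (ev["truth_status"] == "leached") & lab["transfected"]
        assert (lab["sytox"][leached] == "-").mean() > 0.5


class TestPulsaGate:
    def _matched_events(self, panel, punct_share, n=1000, seed=5):
        from dataclasses import replace
        rng = np.random.default_rng(seed)
        E = np.exp(rng.normal(np.log(1000), 0.8, n))
        cells = pd.DataFrame({
            "id": np.arange(n), "E_htt": E, "E_mkate": 0.5 * E,
            "f_mono": 1.0 - punct_share, "f_olig": 0.0,
            "f_inc": punct_share, "has_inclusion": punct_share > 0,
            "status": "live"})
        clean = replace(panel, frac_untransfected=0.0,
                        frac_small_particles=0.0, doublet_rate=0.0)
        return ag.cells_to_events(cells, clean, seed=seed + 1)

    def test_diffuse_events_called_ni(self, panel, diffuse_control):
        ev = self._matched_events(panel, 0.0)
        labels = pulsa_gate(ev, diffuse_control)
        assert (labels == "i").mean() <= 0.05

    def test_punctate_misclassification_below_5pct(self, panel,
                                                   diffuse_control):
        ev = self._matched_events(panel, 0.9)
        labels = pulsa_gate(ev, diffuse_control)
        assert (labels == "ni").mean() <= 0.05

    def test_boundary_monotone_in_width(self, panel, diffuse_control):
        ev = self._matched_events(panel, 0.9, n=200)
        labels = pulsa_gate(ev, diffuse_control)
        narrower = ev.copy()
        narrower["BV421-W"] *= 0.5
        labels2 = pulsa_gate(narrower, diffuse_control)
        # lowering width at fixed height can never flip i -> ni
        assert not ((labels == "i") & (labels2 == "ni")).any()

    def test_small_calibration_raises(self, panel, diffuse_control):
        with pytest.raises(ValueError, match="500"):
            pulsa_gate(diffuse_control, diffuse_control.head(100))


class TestFlashGate:
    def test_monomeric_events_high_flash(self, panel, diffuse_control):
        labels = flash_gate(diffuse_control, diffuse_control)
        assert (labels == "PFR").mean() <= 0.015

    def test_aggregated_events_pfr(self, panel, diffuse_control):
        from dataclasses import replace
        rng = np.random.default_rng(6)
        n = 500
        E = np.exp(rng.normal(np.log(1000), 0.8, n))
        cells = pd.DataFrame({
            "id": np.arange(n), "E_htt": E, "E_mkate": 0.5 * E,
            "f_mono": 0.05, "f_olig": 0.95, "f_inc": 0.0,
            "has_inclusion": False, "status": "live"})
        clean = replace(panel, frac_untransfected=0.0,
                        frac_small_particles=0.0, doublet_rate=0.0)
        ev = ag.cells_to_events(cells, clean, seed=7)
        labels = flash_gate(ev, diffuse_control)
        assert (labels == "PFR").mean() > 0.9

    def test_missing_channel_raises(self, diffuse_control):
        with pytest.raises(ValueError, match="FITC"):
            flash_gate(diffuse_control.drop(columns=["FITC-A"]),
                       diffuse_control)


class TestGateTree:
    def test_partition_at_every_level(self, default_run):
        lab = default_run["labels"]
        n = len(lab)
        n_pre = int(lab["pregate"].sum())
        assert (~lab["pregate"]).sum() + n_pre == n
        n_tr = int(lab["transfected"].sum())
        assert (lab["pregate"] & ~lab["transfected"]).sum() + n_tr == n_pre
        pops = lab.loc[lab["transfected"], "pop"].value_counts()
        assert pops.sum() == n_tr
        assert set(pops.index) <= {"M", "D", "L"}
        sytox = lab.loc[lab["transfected"], "sytox"].value_counts()
        assert sytox.sum() == n_tr
        n_m = int((lab["pop"] == "M").sum())
        pulsa = lab.loc[lab["pulsa"] != "n/a", "pulsa"].value_counts()
        assert pulsa.sum() == n_m
        flash = lab.loc[lab["flash"] != "n/a", "flash"].value_counts()
        assert flash.sum() == n_m

    def test_end_to_end_pulsa_accuracy(self, default_run):
        ev, lab = default_run["events"], default_run["labels"]
        m = lab["pop"] == "M"
        inc = ev["truth_has_inclusion"] & m
        diffuse = ~ev["truth_has_inclusion"] & m \
            & (ev["truth_kind"] == "cell") & ~ev["truth_doublet"]
        assert (lab["pulsa"][inc] == "i").mean() >= 0.9
        assert (lab["pulsa"][diffuse] == "i").mean() <= 0.05

    def test_labels_bit_for_bit_reproducible(self, default_run, panel,
                                             diffuse_control):
        ev, gs = default_run["events"], default_run["gateset"]
        a = ag.apply_gates(ev, gs, diffuse_control, diffuse_control)
        b = ag.apply_gates(ev, gs, diffuse_control, diffuse_control)
        pd.testing.assert_frame_equal(a, b)

    def test_gateset_json_round_trip(self, default_run, tmp_path):
        gs = default_run["gateset"]
        path = tmp_path / "gates.json"
        gs.to_json(path)
        back = GateSet.from_json(path)
        assert back.transfection_threshold == gs.transfection_threshold
        assert back.mdl_sigma == gs.mdl_sigma

    def test_apply_gates_requires_derived_threshold(self, default_run):
        with pytest.raises(ValueError, match="transfection threshold"):
            ag.apply_gates(default_run["events"], GateSet())
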