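"""Population metrics: death rates, binned kinetics, PFR, ANOVA/Holm-Sidak."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import aggflux as ag
from aggflux import metrics
from aggflux.metrics import (anova_holm_sidak, bin_by_expression,
                             cell_density, death_rate, holm_sidak_adjust,
                             intensity_histogram, pfr_ni_fraction,
                             reporter_ratio)


def make_labels(n_m=0, m_pos=0, n_l=0, l_pos=0, n_d=0, d_pos=0,
                m_pulsa=None):
    """Hand-built label table: counts per population and SYTOX+ within."""
    rows = []
    for i in range(n_m):
        rows.append(("M", "+" if i < m_pos else "-",
                     m_pulsa[i] if m_pulsa else "ni"))
    for i in range(n_l):
        rows.append(("L", "+" if i < l_pos else "-", "n/a"))
    for i in range(n_d):
        rows.append(("D", "+" if i < d_pos else "-", "n/a"))
    df = pd.DataFrame(rows, columns=["pop", "sytox", "pulsa"])
    df["pregate"] = True
    df["transfected"] = True
    df["flash"] = "n/a"
    return df


class TestDeathRate:
    def test_hand_countable_example(self):
        """M=850 (50 SYTOX+), L=100 (20+), D=50 (5+) -> exactly 0.200."""
        labels = make_labels(n_m=850, m_pos=50, n_l=100, l_pos=20,
                             n_d=50, d_pos=5)
        res = death_rate(labels, "all")
        assert res.n_sytox_pos == 75
        assert res.n_leached_sytox_neg == 80
        assert res.n_debris_sytox_neg == 45
        assert res.denominator == 1000
        assert res.rate == 0.200

    def test_no_deaths_rate_zero(self):
        labels = make_labels(n_m=100)
        assert death_rate(labels, "all").rate == 0.0

    def test_subpopulation_scopes(self):
        pulsa = ["i"] * 40 + ["ni"] * 60
        labels = make_labels(n_m=100, m_pos=10, n_l=20, l_pos=5, n_d=10,
                             d_pos=2, m_pulsa=pulsa)
        # scope i: SYTOX+ among i (all 10 SYTOX+ are labelled i here)
        res_i = death_rate(labels, "i")
        assert res_i.denominator == 40 + 10
        assert res_i.n_debris_sytox_neg == 8
        res_ni = death_rate(labels, "ni")
        assert res_ni.denominator == 60 + 20
        assert res_ni.n_leached_sytox_neg == 15
        # switchable attribution
        res_i2 = death_rate(labels, "i", attribute_D_to_i=False)
        assert res_i2.denominator == 40

    def test_zero_denominator_raises(self):
        labels = make_labels(n_m=10)
        labels["transfected"] = False
        with pytest.raises(ZeroDivisionError):
            death_rate(labels, "all")

    def test_unknown_scope_raises(self):
        with pytest.raises(ValueError, match="scope"):
            death_rate(make_labels(n_m=10), "weird")

    def test_row_permutation_invariant(self):
        labels = make_labels(n_m=50, m_pos=7, n_l=9, l_pos=2, n_d=4, d_pos=1)
        shuffled = labels.sample(frac=1.0, random_state=0)
        assert death_rate(labels, "all").rate == \
            death_rate(shuffled, "all").rate

    def test_monte_carlo_calibration(self):
        """Counting rule is exactly calibrated against simulator truth."""
        from conftest import truth_labels
        diffs = []
        for rep in range(50):
            cfg = ag.SimConfig(polyq_length=72, n_cells=400, seed=5000 + rep,
                               time_points=(46.0,))
            cells = ag.simulate_population(cfg).at(46.0)
            labels = truth_labels(cells, seed=rep)
            est = death_rate(labels, "all").rate
            truth = (cells["status"] != "live").mean()
            diffs.append(est - truth)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) <= max(2 * se, 1e-12)


class TestBinnedInclusionCurve:
    def test_all_ni_gives_zero_fractions(self):
        ev = pd.DataFrame({"BV421-A": np.geomspace(10, 1e4, 200)})
        lab = pd.DataFrame({"pulsa": ["ni"] * 200})
        curve = bin_by_expression(ev, lab)
        occupied = curve.counts > 0
        assert (curve.i_fraction[occupied] == 0).all()

    def test_sparse_bins_flagged(self):
        ev = pd.DataFrame({"BV421-A": np.geomspace(10, 1e4, 8)})
        lab = pd.DataFrame({"pulsa": ["i", "ni"] * 4})
        curve = bin_by_expression(ev, lab, n_bins=8)
        assert curve.sparse.all()
        occ = curve.counts == 1
        assert set(curve.i_fraction[occ]) <= {0.0, 1.0}

    def test_fraction_monotone_for_97q(self, panel, untransfected_ref,
                                       diffuse_control):
        cfg = ag.SimConfig(polyq_length=97, n_cells=8000, seed=13,
                           time_points=(46.0,))
        cells = ag.simulate_population(cfg).at(46.0)
        ev = ag.cells_to_events(cells, panel, seed=14)
        gs = ag.derive_gateset(ev, untransfected_ref, untransfected_ref)
        lab = ag.apply_gates(ev, gs, diffuse_control, diffuse_control)
        curve = bin_by_expression(ev, lab)
        frac = curve.i_fraction[~curve.sparse]
        # non-decreasing up to estimation noise in adjacent bins
        assert (np.diff(frac) >= -0.05).all()
        assert frac[-1] > frac[0]

    def test_counts_partition_parent(self, default_run):
        ev, lab = default_run["events"], default_run["labels"]
        curve = bin_by_expression(ev, lab)
        scoped = lab["pulsa"].isin(["i", "ni"]).sum()
        # bins cover the central 99%, so up to 1% of events fall outside
        assert curve.counts.sum() >= 0.98 * scoped


class TestReporterMetrics:
    def _labelled(self, ratio, n=100):
        ev = pd.DataFrame({"BV421-A": np.full(n, 100.0),
                           "PE-TxRed-A": np.full(n, 100.0 * ratio)})
        lab = pd.DataFrame({"pregate": True, "transfected": True, "pop": "M",
                            "sytox": "-", "pulsa": "ni", "flash": "n/a"},
                           index=range(n))
        return ev, lab

    def test_constant_ratio(self):
        ev, lab = self._labelled(2.0)
        res = reporter_ratio(ev, lab, "ni")
        assert res["mean"] == pytest.approx(2.0)
        assert res["n"] == 100

    def test_empty_scope_raises(self):
        ev, lab = self._labelled(2.0)
        with pytest.raises(ValueError, match="no live M events"):
            reporter_ratio(ev, lab, "i")
        with pytest.raises(ValueError, match="scope"):
            reporter_ratio(ev, lab, "all")

    def test_chaperone_pair_raises_ratio(self, panel, untransfected_ref,
                                         diffuse_control):
        """Raised turnover + mKate2 yield shifts mKate2/Cerulean up."""
        means = {}
        for arm in ("alone", "hsp40+hsp70"):
            cfg = ag.SimConfig(polyq_length=72, n_cells=5000, seed=15,
                               arm=arm, time_points=(46.0,))
            cells = ag.simulate_population(cfg).at(46.0)
            ev = ag.cells_to_events(cells, panel, seed=16)
            gs = ag.derive_gateset(ev, untransfected_ref, untransfected_ref)
            lab = ag.apply_gates(ev, gs, diffuse_control, diffuse_control)
            means[arm] = reporter_ratio(ev, lab, "ni")["mean"]
        assert means["hsp40+hsp70"] > means["alone"]

    def test_intensity_histogram(self):
        ev, lab = self._labelled(1.0)
        hist = intensity_histogram(ev, lab, "BV421-A", n_bins=5,
                                   edges=np.array([1, 10, 99.5, 100.5, 1e3]))
        assert (hist["density"] > 0).sum() == 1
        lab2 = lab.copy()
        lab2["transfected"] = False
        with pytest.raises(ValueError, match="no transfected"):
            intensity_histogram(ev, lab2)


class TestCellDensity:
    def test_examples(self):
        assert cell_density(100, 1.0, reference_density=100.0) == 1.0
        assert cell_density(100, 0.5, reference_density=100.0) == 2.0
        with pytest.raises(ValueError):
            cell_density(100, 0.0)


class TestPfrNiFraction:
    def test_edge_cases(self):
        lab = pd.DataFrame({"transfected": [True] * 10, "pulsa": "ni",
                            "flash": "high"})
        assert pfr_ni_fraction(lab)["fraction"] == 0.0
        lab["flash"] = "PFR"
        assert pfr_ni_fraction(lab)["fraction"] == 1.0
        lab["transfected"] = False
        with pytest.raises(ValueError):
            pfr_ni_fraction(lab)


class TestHolmSidak:
    def test_closed_form_example(self):
        adj = holm_sidak_adjust([0.01, 0.03, 0.04])
        np.testing.assert_allclose(np.round(adj, 4),
                                   [0.0297, 0.0591, 0.0591])

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(rng.integers(1, 10))
            adj = holm_sidak_adjust(p)
            assert (adj >= p - 1e-12).all()
            order = np.argsort(p, kind="stable")
            assert (np.diff(adj[order]) >= -1e-12).all()
            assert (adj <= 1.0).all()

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_properties_hold_for_arbitrary_pvalues(self, pvals):
        adj = holm_sidak_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        assert (adj <= 1.0).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak_adjust([0.5, 1.5])


class TestAnova:
    def _table(self, shift=0.0, sd=1.0, n=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for arm, mu in (("alone", 0.0), ("hsp40", shift)):
            for _ in range(n):
                rows.append({"arm": arm, "value": rng.normal(mu, sd)})
        return pd.DataFrame(rows)

    def test_two_groups_f_equals_t_squared(self):
        from scipy.stats import ttest_ind
        table = self._table(shift=1.0)
        res = anova_holm_sidak(table, design="one-way", control_arm="alone")
        t = ttest_ind(table.loc[table.arm == "hsp40", "value"],
                      table.loc[table.arm == "alone", "value"],
                      equal_var=True)
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm
        f = anova_lm(ols("value ~ C(arm)", data=table).fit(),
                     typ=2).loc["C(arm)", "F"]
        assert f == pytest.approx(t.statistic ** 2, rel=1e-9)
        assert res["pairwise"]["p_raw"].iloc[0] == pytest.approx(t.pvalue,
                                                                 rel=1e-9)

    def test_zero_variance_rejected(self):
        table = self._table(sd=1.0)
        table["value"] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            anova_holm_sidak(table, design="one-way", control_arm="alone")

    def test_three_way_design(self):
        rng = np.random.default_rng(1)
        rows = []
        for arm in ("alone", "hsp40", "hsp70"):
            for q in (46, 72):
                for t in (30, 46):
                    for _ in range(3):
                        rows.append({"arm": arm, "polyq": q, "time": t,
                                     "value": rng.normal(
                                         0.1 * (arm != "alone") + 0.01 * q
                                         + 0.002 * t, 0.05)})
        res = anova_holm_sidak(pd.DataFrame(rows), design="three-way",
                               control_arm="alone")
        assert set(res["omnibus"]) == {"arm", "polyq", "time"}
        assert res["omnibus"]["polyq"] < 0.01
        assert len(res["pairwise"]) == 2
        assert (res["pairwise"]["p_adj"] >= res["pairwise"]["p_raw"]).all()

    def test_single_replicate_cell_rejected(self):
        table = self._table(n=1)
        with pytest.raises(ValueError, match="2 replicates"):
            anova_holm_sidak(table, design="one-way", control_arm="alone")

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            anova_holm_sidak(self._table(), design="one-way",
                             control_arm="mock")
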