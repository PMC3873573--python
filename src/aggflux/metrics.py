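"""Population-level quantities computed from gated event tables.

Implements the platform's summary statistics: expression-binned inclusion
kinetics, the composite death-rate estimator, reporter ratios and intensity
histograms, the flow-rate cell-density proxy, the PFR,ni (oligomer-enriched,
no-inclusion) fraction, and fixed-effects ANOVA with Holm-Sidak step-down
pairwise comparisons against a control arm.

The death-rate estimator counts every SYTOX-positive event, plus
SYTOX-negative leached ghosts (L) and SYTOX-negative free-inclusion debris
(D) -- each D event taken to be the remnant of exactly one cell -- over all
transfected events.  For the subpopulation scopes, D events are attributed
to the inclusion-bearing (i) pool and L events to the no-inclusion (ni)
pool; this attribution is a documented modelling choice (see
docs/methods.md) and is switchable via the ``attribute_D_to_i`` /
``attribute_L_to_ni`` flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "BinnedInclusionCurve", "DeathRateResult", "bin_by_expression",
    "death_rate", "reporter_ratio", "intensity_histogram", "cell_density",
    "pfr_ni_fraction", "holm_sidak_adjust", "anova_holm_sidak",
]


# --------------------------------------------------------------------------
# expression-binned inclusion kinetics
# --------------------------------------------------------------------------

@dataclass
class BinnedInclusionCurve:
    """Per-expression-bin inclusion fraction with Wilson intervals."""

    bin_edges: np.ndarray        # Cerulean-A, log-spaced
    counts: np.ndarray
    i_fraction: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    sparse: np.ndarray           # bins with < min_count events
    arm: str = ""
    polyq: int | None = None
    time: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo": self.bin_edges[:-1], "bin_hi": self.bin_edges[1:],
            "count": self.counts, "i_fraction": self.i_fraction,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "sparse": self.sparse,
        })


def bin_by_expression(events: pd.DataFrame, labels: pd.DataFrame,
                      n_bins: int = 8, min_count: int = 20,
                      arm: str = "", polyq: int | None = None,
                      time: float | None = None) -> BinnedInclusionCurve:
    """Inclusion fraction vs Httex1 expression (Cerulean-A), log-spaced bins.

    Bins span the central 99% of Cerulean-A among PulSA-labelled events;
    each bin reports the i-population proportion with a Wilson interval, and
    bins with fewer than ``min_count`` events are flagged as sparse.
    """
    scoped = labels["pulsa"].isin(["i", "ni"]).to_numpy()
    if not scoped.any():
        raise ValueError("no PulSA-labelled events")
    cer = events.loc[scoped, "BV421-A"].to_numpy(dtype=float)
    is_i = (labels.loc[scoped, "pulsa"] == "i").to_numpy()
    lo, hi = np.percentile(cer, [0.5, 99.5])
    lo = max(lo, 1e-6)
    edges = np.geomspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, cer, side="right") - 1, 0, n_bins - 1)
    inside = (cer >= lo) & (cer <= hi)
    counts = np.bincount(idx[inside], minlength=n_bins)
    hits = np.bincount(idx[inside], weights=is_i[inside], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        frac = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    ci_lo, ci_hi = proportion_confint(hits, np.maximum(counts, 1),
                                      method="wilson")
    return BinnedInclusionCurve(edges, counts, frac, np.asarray(ci_lo),
                                np.asarray(ci_hi), counts < min_count,
                                arm, polyq, time)


# --------------------------------------------------------------------------
# death rate
# --------------------------------------------------------------------------

@dataclass
class DeathRateResult:
    """Composite death-rate estimate and its numerator components."""

    scope: str
    n_sytox_pos: int
    n_leached_sytox_neg: int
    n_debris_sytox_neg: int
    denominator: int
    rate: float = field(init=False)

    def __post_init__(self):
        for c in (self.n_sytox_pos, self.n_leached_sytox_neg,
                  self.n_debris_sytox_neg, self.denominator):
            if c < 0:
                raise ValueError("negative count")
        if self.denominator == 0:
            raise ZeroDivisionError("empty denominator for death rate")
        num = (self.n_sytox_pos + self.n_leached_sytox_neg
               + self.n_debris_sytox_neg)
        if num > self.denominator:
            raise ValueError("death-rate numerator exceeds denominator")
        self.rate = num / self.denominator


def death_rate(labels: pd.DataFrame, scope: str = "all",
               attribute_D_to_i: bool = True,
               attribute_L_to_ni: bool = True) -> DeathRateResult:
    """Death rate from gated populations.

    scope="all": numerator |SYTOX+| + |SYTOX- and L| + |SYTOX- and D| over
    all transfected events (|M|+|L|+|D|), each D event counting as one cell.
    scope="i": (|SYTOX+ and i| + |SYTOX- and D|) / (|i| + |D|).
    scope="ni": (|SYTOX+ and ni| + |SYTOX- and L|) / (|ni| + |L|).

    The three numerator terms are disjoint by construction (the L/D terms
    require SYTOX-), which is asserted on every call.
    """
    tr = labels["transfected"].to_numpy(dtype=bool)
    pop = labels["pop"].to_numpy()
    sy = labels["sytox"].to_numpy()
    pos = tr & (sy == "+")
    neg = tr & (sy == "-")
    L = tr & (pop == "L")
    D = tr & (pop == "D")
    assert not (pos & neg & L).any() and not (pos & neg & D).any()

    if scope == "all":
        n_pos = int(pos.sum())
        n_L = int((neg & L).sum())
        n_D = int((neg & D).sum())
        denom = int(tr.sum())
    elif scope == "i":
        i = tr & (labels["pulsa"].to_numpy() == "i")
        n_pos = int((pos & i).sum())
        n_L = 0
        n_D = int((neg & D).sum()) if attribute_D_to_i else 0
        denom = int(i.sum()) + (int(D.sum()) if attribute_D_to_i else 0)
    elif scope == "ni":
        ni = tr & (labels["pulsa"].to_numpy() == "ni")
        n_pos = int((pos & ni).sum())
        n_L = int((neg & L).sum()) if attribute_L_to_ni else 0
        n_D = 0
        denom = int(ni.sum()) + (int(L.sum()) if attribute_L_to_ni else 0)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return DeathRateResult(scope, n_pos, n_L, n_D, denom)


# --------------------------------------------------------------------------
# reporter ratios, histograms, density, PFR-ni
# --------------------------------------------------------------------------

def reporter_ratio(events: pd.DataFrame, labels: pd.DataFrame,
                   scope: str = "ni") -> dict:
    """Mean per-event mKate2/Cerulean area ratio over live M events.

    ``scope`` selects the i or ni subpopulation (PulSA labels required).
    """
    if scope not in ("i", "ni"):
        raise ValueError("scope must be 'i' or 'ni'")
    sel = (labels["transfected"] & (labels["pop"] == "M")
           & (labels["sytox"] == "-") & (labels["pulsa"] == scope)).to_numpy()
    if not sel.any():
        raise ValueError(f"no live M events in scope {scope!r}")
    ratio = (events.loc[sel, "PE-TxRed-A"].to_numpy(dtype=float)
             / np.maximum(events.loc[sel, "BV421-A"].to_numpy(dtype=float),
                          1e-12))
    return {"scope": scope, "mean": float(ratio.mean()),
            "median": float(np.median(ratio)), "n": int(sel.sum())}


def intensity_histogram(events: pd.DataFrame, labels: pd.DataFrame,
                        channel: str = "BV421-A", n_bins: int = 40,
                        edges: np.ndarray | None = None) -> pd.DataFrame:
    """Log-spaced intensity density over transfected events (one sample)."""
    sel = labels["transfected"].to_numpy(dtype=bool)
    if not sel.any():
        raise ValueError("no transfected events")
    x = events.loc[sel, channel].to_numpy(dtype=float)
    x = x[x > 0]
    if edges is None:
        edges = np.geomspace(x.min(), x.max(), n_bins + 1)
    dens, _ = np.histogram(x, bins=edges, density=True)
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:],
                         "density": dens})


def replicate_histograms(per_replicate: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean +/- SD bands across replicate histograms on shared bins."""
    if not per_replicate:
        raise ValueError("no replicates")
    dens = np.stack([h["density"].to_numpy() for h in per_replicate])
    out = per_replicate[0][["bin_lo", "bin_hi"]].copy()
    out["mean"] = dens.mean(axis=0)
    out["sd"] = dens.std(axis=0, ddof=1) if len(per_replicate) > 1 else 0.0
    return out


def cell_density(transfected_count: int, acquired_volume: float,
                 reference_density: float | None = None) -> float:
    """Transfected events per unit acquired volume (flow-rate proxy).

    With ``reference_density`` the result is normalized to that (reference
    arm) density, giving the relative cell number in culture.
    """
    if acquired_volume <= 0:
        raise ValueError("acquired volume must be positive")
    dens = transfected_count / acquired_volume
    if reference_density is not None:
        if reference_density <= 0:
            raise ValueError("reference density must be positive")
        dens = dens / reference_density
    return float(dens)


def pfr_ni_fraction(labels: pd.DataFrame) -> dict:
    """Proportion of transfected events that are PFR and ni, with Wilson CI.

    These are the cells whose Httex1 is biochemically self-aggregated (poor
    FlAsH reactivity) without a microscopically visible inclusion -- the
    oligomer-enriched intermediate stage.
    """
    tr = labels["transfected"].to_numpy(dtype=bool)
    n = int(tr.sum())
    if n == 0:
        raise ValueError("no transfected events")
    hit = int((tr & (labels["pulsa"] == "ni").to_numpy()
               & (labels["flash"] == "PFR").to_numpy()).sum())
    lo, hi = proportion_confint(hit, n, method="wilson")
    return {"fraction": hit / n, "count": hit, "n": n,
            "ci_low": float(lo), "ci_high": float(hi)}


# --------------------------------------------------------------------------
# ANOVA + Holm-Sidak
# --------------------------------------------------------------------------

def holm_sidak_adjust(pvalues) -> np.ndarray:
    """Holm-Sidak step-down adjustment, in the input order.

    Sort raw p ascending; adj_p(j) = max over j' <= j of
    1 - (1 - p(j'))^(k - j' + 1), clipped to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(k)
    running = 0.0
    for j, idx in enumerate(order):
        step = 1.0 - (1.0 - p[idx]) ** (k - j)
        running = max(running, step)
        adj_sorted[j] = min(running, 1.0)
    out = np.empty(k)
    out[order] = adj_sorted
    return out


def anova_holm_sidak(table: pd.DataFrame, value: str = "value",
                     design: str = "three-way",
                     control_arm: str = "alone") -> dict:
    """Fixed-effects ANOVA plus Holm-Sidak-adjusted arm-vs-control t tests.

    ``table`` holds one row per replicate with columns ``value``, ``arm``
    and, for the three-way design, ``polyq`` and ``time``.  The omnibus step
    is the standard sums-of-squares decomposition (type-II, main effects
    reported).  Pairwise comparisons pool over the other factors: each
    non-control arm vs ``control_arm`` by two-sample equal-variance t test,
    then Holm-Sidak step-down.
    """
    if design not in ("one-way", "three-way"):
        raise ValueError("design must be 'one-way' or 'three-way'")
    if control_arm not in set(table["arm"]):
        raise ValueError(f"control arm {control_arm!r} not present")
    counts = table.groupby(
        ["arm", "polyq", "time"] if design == "three-way" else ["arm"],
        observed=True)[value].count()
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates in every design cell")
    if np.allclose(table[value].var(ddof=1), 0.0):
        raise ValueError("zero variance across all groups; F undefined")

    if design == "one-way":
        model = ols(f"{value} ~ C(arm)", data=table).fit()
        tab = anova_lm(model, typ=2)
        omnibus = {"arm": float(tab.loc["C(arm)", "PR(>F)"])}
    else:
        model = ols(f"{value} ~ C(arm) + C(polyq) + C(time)"
                    " + C(arm):C(polyq) + C(arm):C(time) + C(polyq):C(time)",
                    data=table).fit()
        tab = anova_lm(model, typ=2)
        omnibus = {k: float(tab.loc[f"C({k})", "PR(>F)"])
                   for k in ("arm", "polyq", "time")}

    from scipy.stats import ttest_ind
    ctrl = table.loc[table["arm"] == control_arm, value].to_numpy()
    arms = [a for a in pd.unique(table["arm"]) if a != control_arm]
    raw = np.array([ttest_ind(table.loc[table["arm"] == a, value].to_numpy(),
                              ctrl, equal_var=True).pvalue for a in arms])
    adj = holm_sidak_adjust(raw) if len(raw) else np.array([])
    pairwise = pd.DataFrame({"arm": arms, "p_raw": raw, "p_adj": adj})
    return {"omnibus": omnibus, "pairwise": pairwise, "model": model}
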