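"""Deterministic, auditable gating tree for the cytometry event tables.

Reproduces the full classification hierarchy used throughout the platform:

1. pregate -- drop sub-cellular particles (size floor) and clumps (doublet
   bound on the size channel's area/height ratio);
2. transfection gate -- threshold at the 99.9th percentile of an
   untransfected reference, passing events bright in *either* reporter
   channel so Cerulean-dark leached ghosts are retained via mKate2;
3. M / D / L split -- robust (Theil-Sen) line through the correlated
   Cerulean x mKate2 cloud in log-log space; M within +/- k robust sigma of
   the line, L = Cerulean-dark / mKate2-bright ghosts, D = the remainder
   (free-inclusion debris, Cerulean-bright);
4. SYTOX dead stain -- threshold at the 99.9th percentile of an unstained
   reference;
5. PulSA -- inclusion (i) vs no-inclusion (ni) from the Cerulean pulse
   width-height envelope of a diffuse (25Q-like) calibration control;
6. FlAsH reactivity -- poor-FlAsH-reactive (PFR) vs high, from the lower
   envelope of the monomeric control's FlAsH/Cerulean ratio.

Every threshold is derived from an explicit reference event set by a stated
quantile rule and stored with provenance in :class:`GateSet`, replacing the
hand-drawn gates of interactive cytometry software with reproducible ones.
Gates are pure functions of (events, GateSet): identical inputs reproduce
identical labels bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GateSet", "pregate", "transfection_gate", "classify_MDL", "sytox_gate",
    "pulsa_gate", "flash_gate", "derive_gateset", "apply_gates", "log_signal",
]

_MDL_FIT_SUBSAMPLE = 1500  # Theil-Sen is O(n^2); fit on a fixed subsample


def log_signal(x, offset: float = 1.0):
    """log10(signal + offset); negative signals are clamped to zero first.

    Returns (log values, number of clamped events).
    """
    x = np.asarray(x, dtype=float)
    clamped = int((x < 0).sum())
    return np.log10(np.maximum(x, 0.0) + offset), clamped


@dataclass
class GateSet:
    """All gate parameters plus a record of how each was derived."""

    size_floor: float = 6.0           # FSC-H, exclusive lower bound
    doublet_max: float = 3.6          # FSC-A / FSC-H upper bound
    transfection_threshold: float = float("nan")
    sytox_threshold: float = float("nan")
    mdl_slope: float = float("nan")
    mdl_intercept: float = float("nan")
    mdl_sigma: float = float("nan")   # 1.4826 * MAD of band residuals
    mdl_k: float = 3.0
    pulsa_height_edges: list = field(default_factory=list)
    pulsa_width_bounds: list = field(default_factory=list)
    flash_cer_edges: list = field(default_factory=list)
    flash_ratio_bounds: list = field(default_factory=list)
    log_offset: float = 1.0
    provenance: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        doc = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_json(cls, doc_or_path) -> "GateSet":
        try:
            raw = json.loads(doc_or_path)
        except (ValueError, TypeError):
            with open(doc_or_path) as fh:
                raw = json.load(fh)
        return cls(**raw)


# --------------------------------------------------------------------------
# individual gates
# --------------------------------------------------------------------------

def pregate(events: pd.DataFrame, gateset: GateSet | None = None) -> np.ndarray:
    """Boolean mask keeping single-cell-sized events.

    Keeps events strictly above ``size_floor`` in FSC-H and with
    FSC-A / FSC-H at or below ``doublet_max``.
    """
    if events.empty:
        raise ValueError("empty event table")
    gs = gateset or GateSet()
    h = events["FSC-H"].to_numpy(dtype=float)
    a = events["FSC-A"].to_numpy(dtype=float)
    ratio = np.divide(a, h, out=np.full_like(a, np.inf), where=h > 0)
    return (h > gs.size_floor) & (ratio <= gs.doublet_max)


def transfection_gate(events: pd.DataFrame, reference: pd.DataFrame,
                      percentile: float = 99.9) -> tuple[float, np.ndarray]:
    """Threshold from an untransfected reference; pass on either reporter.

    The threshold is the ``percentile`` of the per-event max of Cerulean-A
    and mKate2-A in the reference.  An event passes if it exceeds the
    threshold in either channel (so leached, Cerulean-dark cells are kept
    via their membrane mKate2-F).  Raises if the reference looks as bright
    as the sample (mislabelled control).
    """
    if reference.empty:
        raise ValueError("empty untransfected reference")
    ref_max = np.maximum(reference["BV421-A"].to_numpy(dtype=float),
                         reference["PE-TxRed-A"].to_numpy(dtype=float))
    threshold = float(np.percentile(ref_max, percentile))
    samp_max = np.maximum(events["BV421-A"].to_numpy(dtype=float),
                          events["PE-TxRed-A"].to_numpy(dtype=float))
    overlap = float((samp_max <= threshold).mean()) if len(events) else 0.0
    if overlap > 0.20:
        raise ValueError(
            f"untransfected reference overlaps {overlap:.0%} of the sample; "
            "controls look mislabelled")
    mask = (events["BV421-A"].to_numpy(dtype=float) > threshold) \
        | (events["PE-TxRed-A"].to_numpy(dtype=float) > threshold)
    return threshold, mask


def _theil_sen(x: np.ndarray, y: np.ndarray):
    if x.size > _MDL_FIT_SUBSAMPLE:
        idx = np.random.default_rng(0).choice(x.size, _MDL_FIT_SUBSAMPLE,
                                              replace=False)
        x, y = x[idx], y[idx]
    slope, intercept, *_ = stats.theilslopes(y, x)
    return float(slope), float(intercept)


def _clipped_sigma(resid: np.ndarray):
    # iteratively clipped MAD: the raw MAD is inflated by the off-band D/L
    # populations, so re-estimate scale on the central cloud
    sel = np.ones_like(resid, dtype=bool)
    sigma = np.inf
    for _ in range(6):
        med = float(np.median(resid[sel]))
        sigma = 1.4826 * float(np.median(np.abs(resid[sel] - med)))
        sel = np.abs(resid - med) <= 2.0 * max(sigma, 1e-6)
    # the converged 2-sigma clipped MAD of a normal core reads 0.927 sd
    return sigma / 0.927


def _fit_mdl_band(log_cer: np.ndarray, log_mk: np.ndarray, log_thr: float):
    # L (Cerulean-dark) and D (mKate2-dark) events sit at opposite
    # high-leverage corners and would attenuate the slope, so the line is
    # fitted on the both-channels-bright core, then refined once on the
    # events inside the provisional band
    core = (log_cer > log_thr) & (log_mk > log_thr)
    if core.sum() < 50:
        core = np.ones_like(log_cer, dtype=bool)
    slope, intercept = _theil_sen(log_cer[core], log_mk[core])
    resid = log_mk - (intercept + slope * log_cer)
    sigma = _clipped_sigma(resid[core])
    keep = core & (np.abs(resid) <= 3.0 * sigma)
    if keep.sum() >= 50:
        slope, intercept = _theil_sen(log_cer[keep], log_mk[keep])
        resid = log_mk - (intercept + slope * log_cer)
        sigma = _clipped_sigma(resid[keep])
    return slope, intercept, sigma, resid


def classify_MDL(events: pd.DataFrame, transfection_threshold: float,
                 k: float = 3.0, gateset: GateSet | None = None,
                 log_offset: float = 1.0) -> tuple[pd.Series, GateSet]:
    """Partition transfected events into Major / Debris / Leached.

    A Theil-Sen line is fitted through log Cerulean x log mKate2 (robust to
    the off-band D/L events).  M = within +/- k robust-sigma of the line
    (sigma = normal-consistent scaled MAD of the residuals).  Off-band
    events with Cerulean below the transfection threshold are L (they passed
    the gate via mKate2 only); the remaining off-band events, bright in
    Cerulean, are D.  Returns labels plus a GateSet updated with the fitted
    band for auditability.
    """
    if len(events) < 50:
        raise ValueError("fewer than 50 events; M/D/L fit is unstable")
    log_cer, nc1 = log_signal(events["BV421-A"], log_offset)
    log_mk, nc2 = log_signal(events["PE-TxRed-A"], log_offset)
    if gateset is not None and np.isfinite(gateset.mdl_slope):
        slope, intercept = gateset.mdl_slope, gateset.mdl_intercept
        sigma, kk = gateset.mdl_sigma, gateset.mdl_k
        resid = log_mk - (intercept + slope * log_cer)
    else:
        slope, intercept, sigma, resid = _fit_mdl_band(
            log_cer, log_mk, np.log10(transfection_threshold + log_offset))
        # a band narrower than the instrument noise floor is meaningless
        sigma = max(sigma, 0.02)
        kk = k
    in_band = np.abs(resid) <= kk * sigma
    log_thr = np.log10(transfection_threshold + log_offset)
    labels = np.where(in_band, "M",
                      np.where(log_cer < log_thr, "L", "D"))
    gs = gateset or GateSet()
    gs.mdl_slope, gs.mdl_intercept, gs.mdl_sigma, gs.mdl_k = (
        slope, intercept, sigma, kk)
    gs.provenance.setdefault("mdl", {}).update(
        {"rule": "Theil-Sen band +/- k*1.4826*MAD in log10(x+1) space",
         "n_clamped": nc1 + nc2})
    return pd.Series(labels, index=events.index, name="pop"), gs


def sytox_gate(events: pd.DataFrame, unstained_reference: pd.DataFrame,
               percentile: float = 99.9) -> tuple[float, pd.Series]:
    """SYTOX +/- at the 99.9th percentile of an unstained reference (APC-A)."""
    if "APC-A" not in events:
        raise ValueError("APC channel missing")
    if unstained_reference.empty:
        raise ValueError("empty unstained reference")
    threshold = float(np.percentile(
        unstained_reference["APC-A"].to_numpy(dtype=float), percentile))
    labels = np.where(events["APC-A"].to_numpy(dtype=float) > threshold,
                      "+", "-")
    return threshold, pd.Series(labels, index=events.index, name="sytox")


def _quantile_envelope(x_cal, y_cal, x_ev, q: float, n_bins: int = 10):
    """Per-x-decile lower envelope of y from a calibration cloud.

    Returns (bin edges, per-bin bounds, per-event bound).  Events outside
    the calibration range use the nearest bin, keeping the boundary monotone
    in the sense that lowering y at fixed x can never cross back above it.
    """
    edges = np.quantile(x_cal, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    nb = len(edges) - 1
    bounds = np.empty(nb)
    idx_cal = np.clip(np.searchsorted(edges, x_cal, side="right") - 1, 0, nb - 1)
    for b in range(nb):
        sel = idx_cal == b
        bounds[b] = np.percentile(y_cal[sel], q) if sel.any() else -np.inf
    idx_ev = np.clip(np.searchsorted(edges, x_ev, side="right") - 1, 0, nb - 1)
    return edges, bounds, bounds[idx_ev]


def pulsa_gate(events: pd.DataFrame, calibration: pd.DataFrame,
               scope: np.ndarray | None = None,
               width_percentile: float = 0.5) -> pd.Series:
    """Label events i / ni from the Cerulean width-height envelope.

    The calibration events come from a known-diffuse (25Q-like) control.
    Within each height decile of the control, the boundary is the
    ``width_percentile``-th percentile of pulse width; an event narrower
    than the boundary at its matched height decile is called "i"
    (fluorescence concentrated in an inclusion).  ``scope`` restricts
    labelling (events outside get "n/a"), matching the convention that
    PulSA labels apply only to transfected M events.
    """
    if len(calibration) < 500:
        raise ValueError("PulSA calibration needs >= 500 events")
    h_cal = calibration["BV421-H"].to_numpy(dtype=float)
    w_cal = calibration["BV421-W"].to_numpy(dtype=float)
    h_ev = events["BV421-H"].to_numpy(dtype=float)
    w_ev = events["BV421-W"].to_numpy(dtype=float)
    _, _, bound = _quantile_envelope(h_cal, w_cal, h_ev, width_percentile)
    labels = np.where(w_ev < bound, "i", "ni")
    # below the calibration's height support the envelope is undefined;
    # make no inclusion call there (dim events default to ni)
    h_floor = np.percentile(h_cal, width_percentile)
    labels = np.where(h_ev < h_floor, "ni", labels)
    if scope is not None:
        labels = np.where(np.asarray(scope, dtype=bool), labels, "n/a")
    return pd.Series(labels, index=events.index, name="pulsa")


def flash_gate(events: pd.DataFrame, reference: pd.DataFrame,
               scope: np.ndarray | None = None,
               ratio_percentile: float = 1.0,
               log_offset: float = 1.0) -> pd.Series:
    """Label events PFR / high from the monomeric control's FlAsH envelope.

    In log FlAsH vs log Cerulean space the boundary is, per Cerulean decile
    of the reference (a 25Q-like all-monomer control), the
    ``ratio_percentile``-th percentile of the log FlAsH/Cerulean ratio.
    Events below the envelope are poor-FlAsH-reactive (PFR): most of their
    Httex1 no longer binds the biarsenical dye, i.e. is self-aggregated.
    """
    for col in ("FITC-A", "BV421-A"):
        if col not in events or col not in reference:
            raise ValueError(f"channel {col} missing")
    lc_ref, _ = log_signal(reference["BV421-A"], log_offset)
    lf_ref, _ = log_signal(reference["FITC-A"], log_offset)
    lc_ev, _ = log_signal(events["BV421-A"], log_offset)
    lf_ev, _ = log_signal(events["FITC-A"], log_offset)
    _, _, bound = _quantile_envelope(lc_ref, lf_ref - lc_ref, lc_ev,
                                     ratio_percentile)
    labels = np.where((lf_ev - lc_ev) < bound, "PFR", "high")
    if scope is not None:
        labels = np.where(np.asarray(scope, dtype=bool), labels, "n/a")
    return pd.Series(labels, index=events.index, name="flash")


# --------------------------------------------------------------------------
# full tree
# --------------------------------------------------------------------------

def derive_gateset(sample_events: pd.DataFrame,
                   untransfected_reference: pd.DataFrame,
                   unstained_reference: pd.DataFrame,
                   mdl_k: float = 3.0) -> GateSet:
    """Derive the scalar thresholds and M/D/L band for a run."""
    gs = GateSet(mdl_k=mdl_k)
    pg = pregate(sample_events, gs)
    thr, mask = transfection_gate(sample_events[pg], untransfected_reference)
    gs.transfection_threshold = thr
    gs.sytox_threshold, _ = sytox_gate(sample_events[pg],
                                       unstained_reference)
    sub = sample_events[pg][mask]
    _, gs = classify_MDL(sub, thr, k=mdl_k, gateset=gs)
    gs.provenance.update({
        "transfection": "99.9th pct of max(Cerulean-A, mKate2-A), "
                        "untransfected reference",
        "sytox": "99.9th pct of APC-A, unstained reference",
        "pregate": "fixed size floor / doublet bound (panel defaults)",
    })
    return gs


def apply_gates(events: pd.DataFrame, gateset: GateSet,
                pulsa_calibration: pd.DataFrame | None = None,
                flash_reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Run the whole gating tree; returns one label row per event.

    Columns: ``pregate`` and ``transfected`` booleans; ``pop`` in
    {M, D, L, ""}; ``sytox`` in {+, -, ""}; ``pulsa`` in {i, ni, n/a};
    ``flash`` in {PFR, high, n/a}.  Labels below a failed parent gate stay
    empty, so child counts sum exactly to their parent count at each level.
    """
    labels = pd.DataFrame(index=events.index)
    labels["pregate"] = pregate(events, gateset)
    thr = gateset.transfection_threshold
    if not np.isfinite(thr):
        raise ValueError("gateset has no transfection threshold; "
                         "derive it first (derive_gateset)")
    samp_pass = ((events["BV421-A"].to_numpy(dtype=float) > thr)
                 | (events["PE-TxRed-A"].to_numpy(dtype=float) > thr))
    labels["transfected"] = labels["pregate"] & samp_pass

    tr = labels["transfected"].to_numpy()
    labels["pop"] = ""
    if tr.any():
        pop, _ = classify_MDL(events[tr], thr, gateset=gateset)
        labels.loc[tr, "pop"] = pop

    labels["sytox"] = ""
    sy = np.where(events["APC-A"].to_numpy(dtype=float)
                  > gateset.sytox_threshold, "+", "-")
    labels.loc[tr, "sytox"] = sy[tr]

    m_scope = tr & (labels["pop"].to_numpy() == "M")
    labels["pulsa"] = "n/a"
    labels["flash"] = "n/a"
    if pulsa_calibration is not None:
        labels["pulsa"] = pulsa_gate(events, pulsa_calibration, scope=m_scope)
    if flash_reference is not None:
        labels["flash"] = flash_gate(events, flash_reference, scope=m_scope)
    return labels
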