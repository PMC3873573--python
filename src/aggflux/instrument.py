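"""Measurement-modality simulators: cytometer pulses, AUC scans, chromatograms.

Converts simulated cell populations (:mod:`aggflux.popsim`) into the three
kinds of raw data the analysis stages consume, each with configurable noise
and with simulator-truth labels carried alongside so gating and fitting can
be validated against ground truth.

* Flow cytometry: each cell transits a Gaussian laser beam.  Diffuse
  fluorescence spreads over the cell diameter while an inclusion is a
  near-point source, so concentrating signal into a punctum raises the pulse
  height and narrows the pulse width at fixed area -- the physical basis of
  pulse-shape analysis (PulSA).  Width is time above a fixed absolute
  detector threshold (instrument-style), recorded in the panel config.
* Sedimentation velocity: non-diffusing species at sedimentation coefficient
  ``s`` form a step boundary at ``r = r_m * exp(omega^2 s t)`` whose plateau
  dilutes radially as ``exp(-2 omega^2 s t)``.  A small logistic smoothing
  (default 0.005 cm) mimics diffusion so fits are non-degenerate.
* Gel filtration: monomers elute as a narrow Gaussian, oligomers as an
  earlier ~3x broader peak, and inclusions are occluded by the column
  entirely (their signal never appears in the chromatogram).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .popsim import (
    LysateComposition,
    STATUS_DEAD_INTACT,
    STATUS_DEBRIS,
    STATUS_LEACHED,
    STATUS_LIVE,
)

__all__ = [
    "PanelConfig", "SvaGeometry", "ColumnConfig", "RadialScan", "Chromatogram",
    "synthesize_pulse", "cells_to_events", "simulate_radial_scans",
    "simulate_chromatogram", "make_diffuse_control", "EVENT_CHANNELS",
    "SVEDBERG", "SUCROSE_SCAN_TIMES",
]

SVEDBERG = 1e-13  # seconds per svedberg

# scan schedule for the high-viscosity (2 M sucrose) low-speed runs: short
# enough that micrometre-scale inclusions (hundreds to thousands of S
# apparent) do not pellet before the last scan
SUCROSE_SCAN_TIMES = (600.0, 2000.0, 4000.0, 6000.0, 8000.0, 10000.0, 12000.0)

# channel -> (detector name, biology)
EVENT_CHANNELS = {
    "FSC": "size scatter surrogate",
    "BV421": "Cerulean (Httex1 fusion)",
    "FITC": "FlAsH (monomer biosensor)",
    "PE-TxRed": "mKate2 (bicistronic reporter)",
    "APC": "SYTOX Red Dead",
}


# --------------------------------------------------------------------------
# flow cytometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelConfig:
    """Cytometer panel: brightness constants, optics, noise and stain chemistry.

    Brightness ratios between channels are arbitrary fixed constants (no
    spectral spillover is modelled).  ``sytox_miss_leached``/``_debris`` are
    the probabilities that a membrane-compromised ghost or free-inclusion
    debris fails to stain (nucleic acids lost by leaching); intact dead cells
    retain their nuclei and stain reliably.
    """

    brightness_cerulean: float = 1.0
    brightness_flash: float = 0.6
    brightness_mkate: float = 0.8
    sytox_stain_level: float = 800.0

    beam_sigma: float = 0.3            # laser beam width (time units)
    shape_coeff: float = 0.10          # diffuse transit sd per unit diameter
    inclusion_scale: float = 0.10      # punctum transit sd (<< cell diameter)
    width_threshold: float = 1.0       # absolute detector floor for width
    noise_sd: float = 0.5              # additive pulse noise (a.u.)
    signal_noise_dex: float = 0.10     # multiplicative log10 signal noise
    autofluor_mean: float = 3.0        # per-channel background signal

    cell_diameter: float = 10.0        # a.u., lognormal median for cells
    diameter_log_sd: float = 0.06
    debris_diameter: float = 5.0       # free inclusions are smaller
    particle_diameter: float = 0.8     # sub-cellular junk

    sytox_miss_leached: float = 0.6
    sytox_miss_debris: float = 0.6
    sytox_miss_dead_intact: float = 0.0
    sytox_fp_live: float = 0.0

    frac_untransfected: float = 0.10   # background events, relative to n cells
    frac_small_particles: float = 0.05
    doublet_rate: float = 0.01


def synthesize_pulse(diffuse_signal, punctate_signal, cell_diameter,
                     beam_sigma, noise_sd=0.0, *, shape_coeff=0.10,
                     inclusion_scale=0.10, threshold=1.0,
                     relative_threshold=False, rng=None):
    """Synthesize (height, area, width) for one or many transit pulses.

    The transit profile is the sum of two centred Gaussians: the diffuse
    component with sd ``sqrt((shape_coeff*diameter)^2 + beam_sigma^2)`` and
    the punctate component with sd ``sqrt(inclusion_scale^2 + beam_sigma^2)``.
    Height is the profile maximum, area its integral, and width the duration
    the profile spends above ``threshold`` (absolute a.u. by default; with
    ``relative_threshold=True`` the threshold is ``threshold * height``).
    Additive Gaussian noise of sd ``noise_sd`` is applied to all three.
    """
    D = np.asarray(diffuse_signal, dtype=float)
    P = np.asarray(punctate_signal, dtype=float)
    diam = np.asarray(cell_diameter, dtype=float)
    scalar = D.ndim == 0 and P.ndim == 0 and diam.ndim == 0
    D, P, diam = np.atleast_1d(D), np.atleast_1d(P), np.atleast_1d(diam)
    D, P, diam = np.broadcast_arrays(D, P, diam)
    if (D < 0).any() or (P < 0).any():
        raise ValueError("signals must be >= 0")
    if beam_sigma <= 0:
        raise ValueError("beam_sigma must be > 0")
    if noise_sd == 0 and np.all(D + P == 0):
        raise ValueError("degenerate pulse: zero signal and zero noise")

    sd_d = np.sqrt((shape_coeff * diam) ** 2 + beam_sigma ** 2)
    sd_p = np.sqrt(inclusion_scale ** 2 + beam_sigma ** 2)
    norm = 1.0 / np.sqrt(2.0 * np.pi)

    def profile(t):
        return (D * norm / sd_d * np.exp(-0.5 * (t / sd_d) ** 2)
                + P * norm / sd_p * np.exp(-0.5 * (t / sd_p) ** 2))

    height = profile(np.zeros_like(D))
    area = D + P
    theta = threshold * height if relative_threshold else np.full_like(height,
                                                                       threshold)
    # profile is even and unimodal at 0: width = 2 t* with f(t*) = theta
    lo = np.zeros_like(height)
    hi = 10.0 * np.maximum(sd_d, sd_p) * np.ones_like(height)
    above = height > theta
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        gt = profile(mid) > theta
        lo = np.where(gt, mid, lo)
        hi = np.where(gt, hi, mid)
    width = np.where(above, 2.0 * 0.5 * (lo + hi), 0.0)

    if noise_sd > 0:
        rng = np.random.default_rng(rng) if not isinstance(
            rng, np.random.Generator) else rng
        height = height + rng.normal(0.0, noise_sd, height.shape)
        area = area + rng.normal(0.0, noise_sd, area.shape)
        width = width + rng.normal(0.0, 0.05 * noise_sd, width.shape)
        height, area, width = (np.maximum(x, 0.0) for x in (height, area, width))
    if scalar:
        return float(height[0]), float(area[0]), float(width[0])
    return height, area, width


def cells_to_events(cells: pd.DataFrame, panel: PanelConfig | None = None,
                    seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Convert one population snapshot into a cytometer event table.

    Per-status rules:

    * live / intact-dead cells: Cerulean proportional to ``E_htt`` with
      punctate share ``f_inc``; FlAsH proportional to the monomer pool
      ``f_mono * E_htt`` (the biarsenical dye binds monomeric Httex1 only);
      mKate2 diffuse/membrane; SYTOX positive for intact dead cells.
    * leached ghosts: membrane mKate2-F retained, Cerulean at background,
      SYTOX mostly negative (nucleic acids lost).
    * free-inclusion debris: one event per dead cell, bright punctate
      Cerulean, low mKate2, SYTOX mostly negative.

    Untransfected cells and small-particle background events are appended at
    the configured rates.  Truth columns (``truth_*``) describe the source;
    gating never reads them.
    """
    panel = panel or PanelConfig()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if cells.empty:
        raise ValueError("empty cell table")
    unknown = set(cells["status"].unique()) - {
        STATUS_LIVE, STATUS_DEAD_INTACT, STATUS_LEACHED, STATUS_DEBRIS}
    if unknown:
        raise ValueError(f"unknown status values: {sorted(unknown)}")

    n = len(cells)
    status = cells["status"].to_numpy()
    E_htt = cells["E_htt"].to_numpy(dtype=float)
    E_mk = cells["E_mkate"].to_numpy(dtype=float)
    f_mono = cells["f_mono"].to_numpy(dtype=float)
    f_inc = cells["f_inc"].to_numpy(dtype=float)

    is_debris = status == STATUS_DEBRIS
    is_leached = status == STATUS_LEACHED
    is_dead_intact = status == STATUS_DEAD_INTACT
    is_live = status == STATUS_LIVE

    def jitter(x, rows):
        return x * 10.0 ** rng.normal(0.0, panel.signal_noise_dex, rows)

    def bg(rows):
        return np.exp(rng.normal(np.log(panel.autofluor_mean), 0.5, rows))

    diam = panel.cell_diameter * np.exp(rng.normal(0, panel.diameter_log_sd, n))
    diam[is_debris] = panel.debris_diameter * np.exp(
        rng.normal(0, panel.diameter_log_sd, int(is_debris.sum())))

    cer_total = jitter(panel.brightness_cerulean * E_htt, n) + bg(n)
    cer_punct_share = np.where(is_debris, 1.0, f_inc)
    flash_total = jitter(panel.brightness_flash * f_mono * E_htt, n) + bg(n)
    mk_total = jitter(panel.brightness_mkate * E_mk, n) + bg(n)

    stained = np.zeros(n, dtype=bool)
    u = rng.random(n)
    stained[is_dead_intact] = u[is_dead_intact] >= panel.sytox_miss_dead_intact
    stained[is_leached] = u[is_leached] >= panel.sytox_miss_leached
    stained[is_debris] = u[is_debris] >= panel.sytox_miss_debris
    stained[is_live] = u[is_live] < panel.sytox_fp_live
    sytox_total = np.where(
        stained, jitter(np.full(n, panel.sytox_stain_level), n), 0.0) + bg(n)

    truth = pd.DataFrame({
        "truth_cell_id": cells["id"].to_numpy(),
        "truth_status": status,
        "truth_has_inclusion": cells["has_inclusion"].to_numpy(),
        "truth_sytox": stained,
        "truth_kind": "cell",
        "truth_doublet": False,
    })

    blocks = [_event_block(panel, rng, diam, cer_total, cer_punct_share,
                           flash_total, mk_total, sytox_total, truth)]

    n_un = int(round(panel.frac_untransfected * n))
    if n_un:
        d = panel.cell_diameter * np.exp(rng.normal(0, panel.diameter_log_sd, n_un))
        tr = pd.DataFrame({
            "truth_cell_id": -1, "truth_status": "live",
            "truth_has_inclusion": False, "truth_sytox": False,
            "truth_kind": "untransfected", "truth_doublet": False,
        }, index=range(n_un))
        blocks.append(_event_block(panel, rng, d, bg(n_un), np.zeros(n_un),
                                   bg(n_un), bg(n_un), bg(n_un), tr))
    n_sp = int(round(panel.frac_small_particles * n))
    if n_sp:
        d = panel.particle_diameter * np.exp(rng.normal(0, 0.3, n_sp))
        tr = pd.DataFrame({
            "truth_cell_id": -1, "truth_status": "live",
            "truth_has_inclusion": False, "truth_sytox": False,
            "truth_kind": "particle", "truth_doublet": False,
        }, index=range(n_sp))
        blocks.append(_event_block(panel, rng, d, 0.3 * bg(n_sp), np.zeros(n_sp),
                                   0.3 * bg(n_sp), 0.3 * bg(n_sp),
                                   0.3 * bg(n_sp), tr))

    events = pd.concat(blocks, ignore_index=True)

    if panel.doublet_rate > 0:
        dbl = rng.random(len(events)) < panel.doublet_rate
        for ch in EVENT_CHANNELS:
            events.loc[dbl, f"{ch}-A"] *= 2.0
            events.loc[dbl, f"{ch}-H"] *= 1.15
            events.loc[dbl, f"{ch}-W"] *= 1.7
        events.loc[dbl, "truth_doublet"] = True

    events.index.name = "event_index"
    return events


def _event_block(panel, rng, diam, cer_total, cer_punct_share, flash_total,
                 mk_total, sytox_total, truth) -> pd.DataFrame:
    rows = len(diam)
    out = {}
    specs = {
        "FSC": (diam ** 2, np.zeros(rows)),
        "BV421": (cer_total * (1 - cer_punct_share), cer_total * cer_punct_share),
        "FITC": (flash_total, np.zeros(rows)),
        "PE-TxRed": (mk_total, np.zeros(rows)),
        "APC": (sytox_total, np.zeros(rows)),
    }
    for ch, (diffuse, punct) in specs.items():
        h, a, w = synthesize_pulse(
            diffuse, punct, diam, panel.beam_sigma, panel.noise_sd,
            shape_coeff=panel.shape_coeff, inclusion_scale=panel.inclusion_scale,
            threshold=panel.width_threshold, rng=rng)
        out[f"{ch}-H"], out[f"{ch}-A"], out[f"{ch}-W"] = h, a, w
    block = pd.DataFrame(out)
    return pd.concat([block, truth.reset_index(drop=True)], axis=1)


def make_diffuse_control(panel: PanelConfig | None = None, n: int = 2000,
                         seed: int = 1234,
                         expression_log_mean: float = float(np.log(1000.0)),
                         expression_log_sd: float = 0.8,
                         flash_staining_dex: float = 0.12) -> pd.DataFrame:
    """Simulate a 25Q-like all-live, all-diffuse, all-monomer control.

    Used to calibrate the PulSA and FlAsH gate envelopes, mirroring the
    practice of deriving gates from a non-aggregating construct.  The
    control is an independent transfection and FlAsH staining session, so
    its FITC channel carries extra session-to-session staining variability
    (``flash_staining_dex``, log10 units) on top of the panel noise; this
    makes the FlAsH envelope appropriately generous, as control-derived
    gates are in practice.
    """
    rng = np.random.default_rng(seed)
    E = np.exp(rng.normal(expression_log_mean, expression_log_sd, n))
    cells = pd.DataFrame({
        "id": np.arange(n), "time": 0.0, "arm": "control", "polyq": 25,
        "E_htt": E, "E_mkate": 0.5 * E * np.exp(rng.normal(0, 0.3, n)),
        "f_mono": 1.0, "f_olig": 0.0, "f_inc": 0.0,
        "has_inclusion": False, "status": STATUS_LIVE,
    })
    panel = panel or PanelConfig()
    clean = replace(panel, frac_untransfected=0.0, frac_small_particles=0.0,
                    doublet_rate=0.0)
    events = cells_to_events(cells, clean, seed=rng)
    if flash_staining_dex > 0:
        stain = 10.0 ** rng.normal(0.0, flash_staining_dex, len(events))
        events["FITC-A"] *= stain
        events["FITC-H"] *= stain
    return events


# --------------------------------------------------------------------------
# sedimentation velocity
# --------------------------------------------------------------------------

@dataclass
class SvaGeometry:
    """Cell geometry and temperature for a sedimentation-velocity run."""

    meniscus_cm: float = 6.0
    base_cm: float = 7.2
    n_points: int = 150
    temp_C: float = 11.0

    def __post_init__(self):
        if not self.meniscus_cm < self.base_cm:
            raise ValueError("meniscus must lie above (inside of) the base")


@dataclass
class RadialScan:
    """One radial absorbance/fluorescence scan: signal vs radius at a time."""

    radius_cm: np.ndarray
    signal: np.ndarray
    time_s: float
    rotor_rpm: float
    meniscus_cm: float
    base_cm: float
    temp_C: float = 20.0

    def __post_init__(self):
        self.radius_cm = np.asarray(self.radius_cm, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if not (np.diff(self.radius_cm) > 0).all():
            raise ValueError("radii must be strictly increasing")
        if not self.meniscus_cm < self.base_cm:
            raise ValueError("meniscus must be < base radius")
        if not np.isfinite(self.signal).all():
            raise ValueError("non-finite signal")


def boundary_radius(s_svedberg: float, time_s: float, rpm: float,
                    meniscus_cm: float) -> float:
    """Boundary midpoint of a non-diffusing species: ``r_m exp(omega^2 s t)``."""
    omega = 2.0 * np.pi * rpm / 60.0
    return meniscus_cm * np.exp(omega ** 2 * s_svedberg * SVEDBERG * time_s)


def simulate_radial_scans(species, geometry: SvaGeometry | None = None,
                          rotor_rpm: float = 3000.0,
                          scan_times=(2000, 6000, 10000, 14000, 18000,
                                      22000, 26000, 30000),
                          noise_sd: float = 0.0, seed: int = 0,
                          smoothing_cm: float = 0.005) -> list[RadialScan]:
    """Simulate step-boundary scans for non-diffusing species.

    ``species`` is a list of ``(s_svedberg, loading_signal)`` pairs.  Each
    contributes ``c * exp(-2 omega^2 s t)`` behind its boundary at
    ``r_m exp(omega^2 s t)`` (radial-dilution law).  Boundary edges get a
    logistic smoothing of width ``smoothing_cm`` (0 restores hard steps).  A
    species whose boundary passes the base radius within the scan window is
    reported with a warning (it pellets and leaves the observable column).
    """
    geometry = geometry or SvaGeometry()
    scan_times = np.asarray(scan_times, dtype=float)
    if not (np.diff(scan_times) > 0).all():
        raise ValueError("scan times must be increasing")
    for s, _c in species:
        if s < 0:
            raise ValueError("sedimentation coefficients must be >= 0")
        if boundary_radius(s, scan_times[-1], rotor_rpm,
                           geometry.meniscus_cm) > geometry.base_cm:
            warnings.warn(
                f"species at {s:g} S pellets before the last scan "
                "(boundary beyond base radius)", stacklevel=2)
    rng = np.random.default_rng(seed)
    omega = 2.0 * np.pi * rotor_rpm / 60.0
    r = np.linspace(geometry.meniscus_cm, geometry.base_cm, geometry.n_points)
    scans = []
    for t in scan_times:
        sig = np.zeros_like(r)
        for s, c in species:
            if s == 0:          # non-sedimenting: uniform from the meniscus
                sig = sig + c
                continue
            rb = geometry.meniscus_cm * np.exp(omega ** 2 * s * SVEDBERG * t)
            plateau = c * np.exp(-2.0 * omega ** 2 * s * SVEDBERG * t)
            if smoothing_cm > 0:
                z = np.clip((r - rb) / smoothing_cm, -500.0, 500.0)
                edge = 1.0 / (1.0 + np.exp(-z))
            else:
                edge = (r >= rb).astype(float)
            sig = sig + plateau * edge
        if noise_sd > 0:
            sig = sig + rng.normal(0.0, noise_sd, sig.shape)
        scans.append(RadialScan(r.copy(), sig, float(t), rotor_rpm,
                                geometry.meniscus_cm, geometry.base_cm,
                                geometry.temp_C))
    return scans


# --------------------------------------------------------------------------
# gel filtration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnConfig:
    """Sephacryl-S1000-like column: calibrated elution centres and widths.

    Oligomers (tens of nm) elute earlier and ~3x broader than monomers;
    inclusions (micrometre scale) never enter the resin.
    """

    void_ml: float = 8.0
    total_ml: float = 24.0
    mono_center_ml: float = 18.0
    mono_sd_ml: float = 0.7
    olig_center_ml: float = 11.0
    olig_sd_ml: float = 2.1
    baseline: float = 0.5
    dv_ml: float = 0.25

    def __post_init__(self):
        for c in (self.mono_center_ml, self.olig_center_ml):
            if not (0.0 < c < self.total_ml):
                raise ValueError("peak centres must lie inside the column volume")
        if self.olig_center_ml >= self.mono_center_ml:
            raise ValueError("oligomer peak must elute before the monomer peak")


@dataclass
class Chromatogram:
    """Gel-filtration trace: fluorescence density (a.u./ml) vs elution volume."""

    elution_ml: np.ndarray
    fluorescence: np.ndarray
    column: ColumnConfig | None = None

    def __post_init__(self):
        self.elution_ml = np.asarray(self.elution_ml, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if not (np.diff(self.elution_ml) > 0).all():
            raise ValueError("elution volumes must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"elution_ml": self.elution_ml,
                             "fluorescence": self.fluorescence})


def simulate_chromatogram(lysate: LysateComposition,
                          column: ColumnConfig | None = None,
                          noise_sd: float = 0.0,
                          seed: int = 0) -> Chromatogram:
    """Elute a lysate: monomer + oligomer Gaussians, inclusions occluded.

    The loaded (recovered) signal is ``(1 - p_inc) * total_signal``; the
    inclusion pool never appears.  Fluorescence is reported as a density so
    that a trapezoidal integral over elution volume returns signal in a.u.
    """
    column = column or ColumnConfig()
    rng = np.random.default_rng(seed)
    v = np.arange(0.0, column.total_ml + 1e-9, column.dv_ml)
    m_amt = lysate.p_mono * lysate.total_signal
    o_amt = lysate.p_olig * lysate.total_signal

    def gauss(center, sd):
        return np.exp(-0.5 * ((v - center) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))

    sig = (m_amt * gauss(column.mono_center_ml, column.mono_sd_ml)
           + o_amt * gauss(column.olig_center_ml, column.olig_sd_ml)
           + column.baseline)
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, sig.shape)
    return Chromatogram(v, sig, column)
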