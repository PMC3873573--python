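"""Stochastic simulator of Httex1-transfected Neuro2a-like cell populations.

The simulator produces the ground truth for every downstream stage of the
platform: per-cell huntingtin-exon-1 (Httex1) abundance, the intracellular
partition of those molecules between monomer / oligomer / inclusion pools,
inclusion nucleation, cell death and its terminal fates (intact corpse,
cytosol-leached ghost, free-inclusion debris), degradation, and division.

Model sketch
------------
Each cell carries an Httex1 abundance ``E_htt`` (arbitrary molecules, drawn
log-normally at transfection) and a bicistronic mKate2 reporter abundance.
Dynamics are discrete-time hazard steps (default ``dt`` = 0.5 h):

* inclusion nucleation with hazard
  ``k_nuc * min((E/E_ref)**h_exp, exp_cap) * q_gain(Q) * mod_nuc(arm)``,
  where ``q_gain(Q) = max(0, (Q - 36)/10)**gamma`` vanishes for the
  non-pathogenic 25-glutamine construct and grows with polyQ length;
* after nucleation the inclusion absorbs soluble material by first-order
  conversion at rate ``k_conv``;
* a rare "oligomer burst" (hazard ``k_olig``, pathogenic polyQ only) converts
  most of a cell's monomer pool to dispersed oligomers without forming an
  inclusion -- the cells detected downstream as poor-FlAsH-reactive,
  no-inclusion (PFR,ni);
* death with hazard ``mu_i`` (inclusion-bearing) or ``mu_ni`` otherwise, each
  scaled by the chaperone-arm modifier; dead cells resolve to an intact
  corpse, a leached ghost (cytosolic Httex1 lost, membrane mKate2-F kept) or
  -- inclusion-bearing cells only -- free-inclusion debris;
* first-order Httex1 degradation at ``k_deg`` and division at
  ``growth_rate`` (daughters start inclusion-free).

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ArmModifiers",
    "SimConfig",
    "PopulationResult",
    "LysateComposition",
    "DEFAULTS_VERSION",
    "STATUS_LIVE",
    "STATUS_DEAD_INTACT",
    "STATUS_LEACHED",
    "STATUS_DEBRIS",
    "STATUS_NAMES",
    "q_gain",
    "default_arm_modifiers",
    "simulate_population",
    "pool_lysate",
]

# Version tag for the frozen default parameter set (see scripts/tune_defaults.py).
DEFAULTS_VERSION = "2026.09-1"

STATUS_LIVE = "live"
STATUS_DEAD_INTACT = "dead_intact"
STATUS_LEACHED = "leached"
STATUS_DEBRIS = "lysed_debris"
STATUS_NAMES = (STATUS_LIVE, STATUS_DEAD_INTACT, STATUS_LEACHED, STATUS_DEBRIS)

_LIVE, _INTACT, _LEACHED, _DEBRIS = 0, 1, 2, 3

SNAPSHOT_COLUMNS = [
    "id", "time", "arm", "polyq", "E_htt", "E_mkate",
    "f_mono", "f_olig", "f_inc", "has_inclusion", "status",
]


@dataclass(frozen=True)
class ArmModifiers:
    """Multiplicative hazard/rate modifiers for one chaperone co-expression arm.

    ``nuc`` scales inclusion nucleation, ``death_i``/``death_ni`` the death
    hazards of cells with/without inclusions, ``deg`` Httex1 degradation,
    ``growth`` the division hazard, and ``mkate_yield`` the folding yield of
    the bicistronic mKate2 reporter.
    """

    nuc: float = 1.0
    death_i: float = 1.0
    death_ni: float = 1.0
    deg: float = 1.0
    growth: float = 1.0
    mkate_yield: float = 1.0


def default_arm_modifiers() -> dict[str, ArmModifiers]:
    """Frozen per-arm modifiers for the four chaperone treatments.

    The reference arm ("alone", Httex1 with an inert DNA filler) has all
    modifiers 1.  hsp40 (DNAJB1) suppresses nucleation so the all-cell
    inclusion fraction at 46 h drops by roughly a quarter relative to the
    reference; hsp70 (HSPA1A) leaves nucleation alone but lowers the death
    hazard of inclusion-bearing cells by about 15 percentage points of death
    rate at 46 h; the combined arm keeps the hsp40 nucleation effect, loses
    the hsp70 survival benefit, raises no-inclusion death by a few points,
    and additionally boosts Httex1 turnover, mKate2 folding yield and growth.
    Values were tuned once (scripts/tune_defaults.py) and frozen.
    """
    return {
        "alone": ArmModifiers(),
        "hsp40": ArmModifiers(nuc=0.70, death_i=1.05, death_ni=1.05,
                              deg=1.10, growth=1.10, mkate_yield=1.15),
        "hsp70": ArmModifiers(nuc=1.0, death_i=0.47, death_ni=1.0,
                              deg=1.10, growth=1.10, mkate_yield=1.15),
        "hsp40+hsp70": ArmModifiers(nuc=0.70, death_i=1.0, death_ni=1.75,
                                    deg=2.0, growth=1.25, mkate_yield=1.5),
    }


def q_gain(polyq: float, gamma: float = 1.5) -> float:
    """PolyQ-length scaling of the nucleation hazard.

    Zero at and below the 36-glutamine pathogenicity threshold, then
    ``((Q - 36)/10)**gamma`` so that 46 < 72 < 97 in aggressiveness.
    """
    return float(max(0.0, (polyq - 36.0) / 10.0) ** gamma)


@dataclass
class SimConfig:
    """Parameters of one simulated transfection/treatment condition.

    Hazards are per hour.  Defaults are the frozen study conditions
    (``DEFAULTS_VERSION``); see docs/methods.md for the rationale of each.
    """

    polyq_length: int = 72
    n_cells: int = 5000
    time_points: tuple[float, ...] = (18.0, 25.0, 30.0, 46.0)
    arm: str = "alone"
    seed: int = 0

    # expression law: ln E_htt ~ Normal(log_mean, log_sd)
    expression_log_mean: float = float(np.log(1000.0))
    expression_log_sd: float = 0.8
    expression_ref: float = 1000.0       # E_ref in the nucleation hazard

    # reporter law: E_mkate = slope * E_htt * exp(Normal(0, log_sd)) * yield
    reporter_slope: float = 0.5
    reporter_log_sd: float = 0.3

    # hazards and rates (h^-1 unless noted)
    k_nuc: float = 0.0015                # baseline nucleation hazard
    h_exp: float = 1.5                   # expression cooperativity exponent
    exp_cap: float = 12.0                # cap on (E/E_ref)**h_exp (saturation)
    gamma: float = 1.5                   # q_gain exponent
    k_conv: float = 0.40                 # soluble -> inclusion conversion
    nucleation_seed_frac: float = 0.5    # soluble share captured at nucleation
    k_olig: float = 0.00005              # oligomer-burst hazard (pathogenic Q)
    olig_burst_frac: float = 0.95        # monomer share converted by a burst
    init_olig_beta: tuple[float, float] = (3.0, 100.0)  # initial f_olig, Q>36
    mu_ni: float = 0.0068                # death hazard, no inclusion
    mu_i: float = 0.095                  # death hazard, inclusion-bearing
    p_leach: float = 0.25                # dead -> leached ghost
    p_debris: float = 0.45               # dead+inclusion -> free-inclusion debris
    k_deg: float = 0.005                 # Httex1 degradation
    growth_rate: float = 0.020           # division hazard
    debris_mkate_retention: float = 0.08 # mKate2 left on debris remnants

    dt: float = 0.5                      # hazard step (h)
    max_step_prob: float = 0.2           # guard: per-step hazard*dt ceiling

    chaperone_mods: Mapping[str, ArmModifiers] = field(
        default_factory=default_arm_modifiers)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        hazards = dict(k_nuc=self.k_nuc, k_conv=self.k_conv, k_olig=self.k_olig,
                       mu_ni=self.mu_ni, mu_i=self.mu_i, k_deg=self.k_deg,
                       growth_rate=self.growth_rate)
        for name, h in hazards.items():
            if not np.isfinite(h) or h < 0:
                raise ValueError(f"hazard {name} must be finite and >= 0, got {h}")
        if self.p_leach < 0 or self.p_debris < 0 or self.p_leach + self.p_debris > 1:
            raise ValueError("need p_leach, p_debris >= 0 and p_leach + p_debris <= 1")
        if self.arm not in self.chaperone_mods:
            raise ValueError(
                f"unknown arm {self.arm!r}; known: {sorted(self.chaperone_mods)}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if q_gain(25.0, self.gamma) != 0.0:
            raise ValueError("q_gain(25) must be 0")

    @property
    def modifiers(self) -> ArmModifiers:
        return self.chaperone_mods[self.arm]

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        """Load a config from a YAML key-value file (unknown keys rejected)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "time_points" in kwargs:
            kwargs["time_points"] = tuple(float(t) for t in kwargs["time_points"])
        if "chaperone_mods" in kwargs and not isinstance(
                next(iter(kwargs["chaperone_mods"].values())), ArmModifiers):
            kwargs["chaperone_mods"] = {
                k: ArmModifiers(**v) for k, v in kwargs["chaperone_mods"].items()}
        return cls(**kwargs)


@dataclass
class LysateComposition:
    """Population-pooled molecular fractions of Httex1 in a lysate."""

    p_mono: float
    p_olig: float
    p_inc: float
    total_signal: float

    def __post_init__(self) -> None:
        fr = np.array([self.p_mono, self.p_olig, self.p_inc])
        if (fr < -1e-12).any():
            raise ValueError("lysate fractions must be >= 0")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("lysate fractions must sum to 1")


@dataclass
class PopulationResult:
    """Output of :func:`simulate_population`.

    ``snapshots`` has one row per cell per requested time point (dead cells
    persist with their state frozen at death); ``accounting`` is the per-step
    bookkeeping used to assert population-size conservation.
    """

    snapshots: pd.DataFrame
    accounting: pd.DataFrame
    config: SimConfig

    def at(self, time: float) -> pd.DataFrame:
        out = self.snapshots[self.snapshots["time"] == time]
        if out.empty:
            raise KeyError(f"no snapshot at t={time}; have "
                           f"{sorted(self.snapshots['time'].unique())}")
        return out

    def to_csv(self, path) -> None:
        self.snapshots.to_csv(path, index=False)


def _renormalize(f_mono, f_olig, f_inc):
    tot = f_mono + f_olig + f_inc
    return f_mono / tot, f_olig / tot, f_inc / tot


def simulate_population(config: SimConfig) -> PopulationResult:
    """Run the discrete-time hazard simulation and snapshot at each time point.

    Raises ``ValueError`` if any per-step hazard probability would exceed
    ``config.max_step_prob`` (the step size is then too coarse for the
    small-probability approximation the scheme relies on).
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    mods = cfg.modifiers
    n0 = int(cfg.n_cells)
    if n0 <= 0:
        raise ValueError("n_cells must be positive")

    E0 = np.exp(rng.normal(cfg.expression_log_mean, cfg.expression_log_sd, n0))
    E_htt = E0.copy()
    E_mkate = (cfg.reporter_slope * E0 * mods.mkate_yield
               * np.exp(rng.normal(0.0, cfg.reporter_log_sd, n0)))
    pathogenic = cfg.polyq_length > 36
    if pathogenic:
        f_olig = rng.beta(*cfg.init_olig_beta, n0)
    else:
        f_olig = np.zeros(n0)
    f_mono = 1.0 - f_olig
    f_inc = np.zeros(n0)
    has_inc = np.zeros(n0, dtype=bool)
    status = np.zeros(n0, dtype=np.int8)
    next_id = n0
    ids = np.arange(n0)

    qg = q_gain(cfg.polyq_length, cfg.gamma)
    t_max = max(cfg.time_points)
    n_steps = int(round(t_max / cfg.dt))
    if abs(n_steps * cfg.dt - t_max) > 1e-9:
        n_steps += 1
    snap_steps = {int(round(t / cfg.dt)): t for t in cfg.time_points}
    if 0 in snap_steps and 0.0 not in cfg.time_points:
        raise ValueError("time points must be positive multiples of dt")

    snapshots: list[pd.DataFrame] = []
    acct_rows: list[dict] = []

    def take_snapshot(t: float) -> None:
        snapshots.append(pd.DataFrame({
            "id": ids.copy(), "time": t, "arm": cfg.arm, "polyq": cfg.polyq_length,
            "E_htt": E_htt.copy(), "E_mkate": E_mkate.copy(),
            "f_mono": f_mono.copy(), "f_olig": f_olig.copy(),
            "f_inc": f_inc.copy(),
            "has_inclusion": has_inc.copy(),
            "status": np.array(STATUS_NAMES)[status],
        }))

    if 0 in snap_steps:
        take_snapshot(snap_steps[0])

    conv_delta = -np.expm1(-cfg.k_conv * cfg.dt)

    for step in range(1, n_steps + 1):
        n_before = ids.size
        live = status == _LIVE

        # --- inclusion nucleation -------------------------------------------
        lam_nuc = np.zeros(ids.size)
        cand = live & ~has_inc
        if qg > 0 and cand.any():
            drive = np.minimum(
                (E_htt[cand] / cfg.expression_ref) ** cfg.h_exp, cfg.exp_cap)
            lam_nuc[cand] = cfg.k_nuc * drive * qg * mods.nuc
        _check_step(lam_nuc, cfg, "nucleation")
        nucleate = cand & (rng.random(ids.size) < -np.expm1(-lam_nuc * cfg.dt))
        has_inc |= nucleate
        if nucleate.any():
            seized = cfg.nucleation_seed_frac * (f_mono[nucleate]
                                                 + f_olig[nucleate])
            f_inc[nucleate] += seized
            f_mono[nucleate] *= 1.0 - cfg.nucleation_seed_frac
            f_olig[nucleate] *= 1.0 - cfg.nucleation_seed_frac

        # --- oligomer burst (PFR,ni precursor) ------------------------------
        if pathogenic and cfg.k_olig > 0:
            burst_cand = live & ~has_inc
            lam_b = np.where(burst_cand, cfg.k_olig, 0.0)
            _check_step(lam_b, cfg, "oligomer burst")
            burst = burst_cand & (rng.random(ids.size) < -np.expm1(-lam_b * cfg.dt))
            if burst.any():
                moved = cfg.olig_burst_frac * f_mono[burst]
                f_olig[burst] += moved
                f_mono[burst] -= moved

        # --- inclusion growth (absorbing conversion of soluble pools) -------
        grow = live & has_inc
        if grow.any():
            f_inc[grow] += conv_delta * (f_mono[grow] + f_olig[grow])
            f_mono[grow] *= 1.0 - conv_delta
            f_olig[grow] *= 1.0 - conv_delta

        # --- death and terminal fate ----------------------------------------
        mu = np.where(has_inc, cfg.mu_i * mods.death_i, cfg.mu_ni * mods.death_ni)
        mu = np.where(live, mu, 0.0)
        _check_step(mu, cfg, "death")
        dies = live & (rng.random(ids.size) < -np.expm1(-mu * cfg.dt))
        if dies.any():
            u = rng.random(ids.size)
            die_i = dies & has_inc
            die_ni = dies & ~has_inc
            # inclusion-bearing: debris possible (the D population is free
            # inclusions with remnants); otherwise only intact or leached.
            status[die_i & (u < cfg.p_debris)] = _DEBRIS
            status[die_i & (u >= cfg.p_debris)
                   & (u < cfg.p_debris + cfg.p_leach)] = _LEACHED
            status[die_i & (u >= cfg.p_debris + cfg.p_leach)] = _INTACT
            status[die_ni & (u < cfg.p_leach)] = _LEACHED
            status[die_ni & (u >= cfg.p_leach)] = _INTACT

            leached = dies & (status == _LEACHED)
            E_htt[leached] = 0.0          # cytosolic contents lost
            debris = dies & (status == _DEBRIS)
            if debris.any():              # the free inclusion carries only f_inc
                E_htt[debris] *= f_inc[debris]
                E_mkate[debris] *= cfg.debris_mkate_retention
                f_mono[debris] = 0.0
                f_olig[debris] = 0.0
                f_inc[debris] = 1.0

        # --- degradation ----------------------------------------------------
        live = status == _LIVE
        E_htt[live] *= np.exp(-cfg.k_deg * mods.deg * cfg.dt)

        # --- division -------------------------------------------------------
        lam_div = np.where(live, cfg.growth_rate * mods.growth, 0.0)
        _check_step(lam_div, cfg, "division")
        divides = live & (rng.random(ids.size) < -np.expm1(-lam_div * cfg.dt))
        n_born = int(divides.sum())
        if n_born:
            idx = np.where(divides)[0]
            ids = np.concatenate([ids, np.arange(next_id, next_id + n_born)])
            next_id += n_born
            E_htt = np.concatenate([E_htt, E_htt[idx]])
            E_mkate = np.concatenate([E_mkate, E_mkate[idx]])
            # daughters start soluble and inclusion-free
            d_olig = f_olig[idx] / (f_olig[idx] + f_mono[idx] + 1e-300)
            f_mono = np.concatenate([f_mono, 1.0 - d_olig])
            f_olig = np.concatenate([f_olig, d_olig])
            f_inc = np.concatenate([f_inc, np.zeros(n_born)])
            has_inc = np.concatenate([has_inc, np.zeros(n_born, dtype=bool)])
            status = np.concatenate([status, np.zeros(n_born, dtype=np.int8)])

        counts = np.bincount(status, minlength=4)
        acct_rows.append({
            "step": step, "time": step * cfg.dt, "n_before": n_before,
            "births": n_born, "n_after": ids.size,
            "live": int(counts[_LIVE]), "dead_intact": int(counts[_INTACT]),
            "leached": int(counts[_LEACHED]), "lysed_debris": int(counts[_DEBRIS]),
        })
        if step in snap_steps:
            take_snapshot(snap_steps[step])

    snaps = pd.concat(snapshots, ignore_index=True)[SNAPSHOT_COLUMNS]
    _assert_snapshot_invariants(snaps)
    return PopulationResult(snapshots=snaps,
                            accounting=pd.DataFrame(acct_rows), config=cfg)


def _check_step(lam: np.ndarray, cfg: SimConfig, what: str) -> None:
    if not np.isfinite(lam).all():
        raise ValueError(f"non-finite {what} hazard")
    worst = float(lam.max(initial=0.0)) * cfg.dt
    if worst > cfg.max_step_prob:
        raise ValueError(
            f"{what} hazard * dt = {worst:.3f} exceeds {cfg.max_step_prob}; "
            "reduce dt (stepping too coarse)")


def _assert_snapshot_invariants(snaps: pd.DataFrame) -> None:
    fsum = snaps[["f_mono", "f_olig", "f_inc"]].to_numpy().sum(axis=1)
    if not np.allclose(fsum, 1.0, atol=1e-9):
        raise AssertionError("per-cell fractions do not sum to 1")
    inc = snaps["f_inc"].to_numpy() > 0
    if not (snaps["has_inclusion"].to_numpy() == inc).all():
        raise AssertionError("has_inclusion inconsistent with f_inc > 0")


def pool_lysate(cells: pd.DataFrame) -> LysateComposition:
    """Abundance-weighted pooling of per-cell fractions into a lysate.

    Lysis pools Httex1 from live, intact-dead and debris sources (leached
    cells contributed their cytosol to the medium, not the harvested pellet;
    their ``E_htt`` is already zero).  Each cell contributes its molecular
    fractions weighted by its Httex1 abundance.
    """
    if len(cells) == 0:
        raise ValueError("empty population")
    w = cells["E_htt"].to_numpy(dtype=float)
    if w.sum() <= 0:
        raise ValueError("all-zero E_htt; lysate has no Httex1 signal")
    total = float(w.sum())
    p_mono = float((w * cells["f_mono"].to_numpy()).sum() / total)
    p_olig = float((w * cells["f_olig"].to_numpy()).sum() / total)
    p_inc = float((w * cells["f_inc"].to_numpy()).sum() / total)
    # exact renormalization against accumulated rounding
    s = p_mono + p_olig + p_inc
    return LysateComposition(p_mono / s, p_olig / s, p_inc / s, total)
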