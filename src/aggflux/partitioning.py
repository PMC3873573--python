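"""Three-class molecular partition of Httex1: monomer / oligomer / inclusion.

Combines the two orthogonal biochemical measurements: gel filtration
quantitates monomers and oligomers but occludes inclusions, while
sedimentation velocity in 2 M sucrose at low speed quantitates the
inclusion share and the total loading signal.  The combination applies the
gel-filtration monomer:oligomer ratio to the non-inclusion share from SVA:

    p_mono = (1 - p_inc) * m / (m + o)
    p_olig = (1 - p_inc) * o / (m + o)

with total abundance carried from the SVA loading signal.  The rule is
scale-invariant in (m, o), so the two instruments need no shared intensity
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .gel_filtration import PoolAmounts

__all__ = ["PartitionResult", "combine_partition", "compare_total_abundance"]


@dataclass
class PartitionResult:
    """Proportions of Httex1 molecules per aggregation class, plus total."""

    p_mono: float
    p_olig: float
    p_inc: float
    total_abundance: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for p in (self.p_mono, self.p_olig, self.p_inc):
            if p < -1e-12:
                raise ValueError("fractions must be >= 0")
        if abs(self.p_mono + self.p_olig + self.p_inc - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def combine_partition(pools: PoolAmounts, p_inc: float,
                      total: float, provenance: dict | None = None
                      ) -> PartitionResult:
    """Merge gel-filtration pools with the SVA inclusion fraction."""
    if not 0.0 <= p_inc <= 1.0:
        raise ValueError("p_inc must lie in [0, 1]")
    m, o = pools.monomer, pools.oligomer
    if m + o <= 0:
        if p_inc < 1.0:
            raise ValueError(
                "inconsistent inputs: empty gel-filtration pools but SVA "
                "reports non-inclusion signal (p_inc < 1)")
        return PartitionResult(0.0, 0.0, 1.0, total, provenance or {})
    share = (1.0 - p_inc) / (m + o)
    return PartitionResult(share * m, share * o, p_inc, total,
                           provenance or {})


def compare_total_abundance(results: dict[str, list[float]],
                            control_arm: str = "alone") -> pd.DataFrame:
    """Replicate totals per arm, normalized to the control arm's mean.

    ``results`` maps arm name to a list of replicate total abundances.
    Returns mean +/- SD of the normalized totals per arm.
    """
    if control_arm not in results:
        raise ValueError(f"control arm {control_arm!r} missing")
    ctrl = pd.Series(results[control_arm], dtype=float)
    if ctrl.mean() <= 0:
        raise ValueError("control arm mean must be positive")
    rows = []
    for arm, totals in results.items():
        norm = pd.Series(totals, dtype=float) / ctrl.mean()
        rows.append({"arm": arm, "mean": norm.mean(),
                     "sd": norm.std(ddof=1) if len(norm) > 1 else 0.0,
                     "n": len(norm)})
    return pd.DataFrame(rows)
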