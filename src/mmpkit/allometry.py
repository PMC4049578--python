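"""Allometric metabolic-rate transforms and the F-sweep.

Within an animal group the basal metabolic rate follows BMR = C * M**alpha.
Dividing by mass gives the mass-specific rate

    msBMR = C * M**-(1 - alpha)

and dividing further by the mass-dependence of mitochondrial density gives
the rate per unit mitochondrion, parameterized here with a single
scaling-adjustment parameter F >= 1:

    mtBMR = C * M**(-(1 - alpha) / F)

F = 1 recovers msBMR exactly; F = inf removes the mass dependence entirely,
leaving mtBMR = C.  The mitochondrial-density proportionality constant is
fixed at 1, so mtBMR is in the (relative) units of C; only logarithms enter
the downstream correlations, via the exact identity

    ln(mtBMR) = ln(C) - (1 - alpha) * ln(M) / F.

``f_sweep`` scans a grid of F values (including inf) and reports the squared
Pearson correlation between a per-group trait (typically STC, the Ser+Thr
percentage) and ln(mtBMR) at each F, plus the argmax.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_io import GroupMetadata

#: Default F grid; inf is a legal value meaning "no mass dependence".
#: F = 3.0 (an earlier mammalian calibration) is included as a named preset.
DEFAULT_F_GRID: tuple[float, ...] = (
    1.0, 1.25, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 7.5, 10.0, 20.0, 50.0, 100.0, math.inf,
)

F_MAMMALIAN_PRESET = 3.0


def _check(C: float, alpha: float, M: float) -> None:
    if not M > 0:
        raise ValueError(f"M must be > 0, got {M}")
    if not C > 0:
        raise ValueError(f"C must be > 0, got {C}")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")


def msbmr(C: float, alpha: float, M: float) -> float:
    """Mass-specific basal metabolic rate C * M**-(1-alpha)."""
    _check(C, alpha, M)
    return C * M ** -(1.0 - alpha)


def mtbmr(C: float, alpha: float, M: float, F: float) -> float:
    """Per-mitochondrion rate C * M**(-(1-alpha)/F); F=inf returns C exactly."""
    _check(C, alpha, M)
    if not F >= 1:
        raise ValueError(f"F must be >= 1 (or inf), got {F}")
    if math.isinf(F):
        return C
    return C * M ** (-(1.0 - alpha) / F)


def ln_mtbmr(C: float, alpha: float, M: float, F: float) -> float:
    """ln(C) - (1-alpha)*ln(M)/F — the overflow-safe log form."""
    _check(C, alpha, M)
    if not F >= 1:
        raise ValueError(f"F must be >= 1 (or inf), got {F}")
    if math.isinf(F):
        return math.log(C)
    return math.log(C) - (1.0 - alpha) * math.log(M) / F


@dataclass
class SweepResult:
    """F-sweep outcome: the full R^2(F) curve and its argmax."""

    grid: list[float]
    r2: list[float]
    best_F: float
    best_r2: float
    mtbmr_at_best: dict[str, float] = field(default_factory=dict)
    n: int = 0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"F": self.grid, "r2": self.r2, "n": self.n})


def f_sweep(
    metadata: Sequence[GroupMetadata],
    trait_by_group: Mapping[str, float],
    grid: Sequence[float] = DEFAULT_F_GRID,
    trait_name: str = "STC",
) -> SweepResult:
    """Scan F and correlate the trait with ln(mtBMR) across groups.

    Only groups present in both inputs enter the correlation (>=3 required).
    R^2 is the squared Pearson correlation; it is NaN for an F where either
    variable is degenerate (zero variance).  Ties in the argmax break toward
    larger F.
    """
    meta = {m.group: m for m in metadata}
    groups = sorted(set(meta) & set(trait_by_group))
    if len(groups) < 3:
        raise ValueError(
            f"need >= 3 groups with both {trait_name} and metadata, have {len(groups)}"
        )
    trait = np.array([trait_by_group[g] for g in groups])
    grid = sorted(grid)
    r2s: list[float] = []
    for F in grid:
        ln_vals = np.array([ln_mtbmr(meta[g].C, meta[g].alpha, meta[g].M, F) for g in groups])
        if np.ptp(ln_vals) == 0 or np.ptp(trait) == 0:
            r2s.append(float("nan"))
            continue
        r, _ = stats.pearsonr(trait, ln_vals)
        r2s.append(float(r * r))
    finite = [(F, r2) for F, r2 in zip(grid, r2s) if not math.isnan(r2)]
    if not finite:
        raise ValueError("R^2 undefined on the entire grid (degenerate inputs)")
    best_r2 = max(r2 for _, r2 in finite)
    # ties toward larger F: grid is ascending, take the last attaining max
    best_F = [F for F, r2 in finite if r2 == best_r2][-1]
    per_group = {
        g: mtbmr(meta[g].C, meta[g].alpha, meta[g].M, best_F) for g in groups
    }
    return SweepResult(
        grid=list(grid), r2=r2s, best_F=best_F, best_r2=best_r2,
        mtbmr_at_best=per_group, n=len(groups),
    )
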