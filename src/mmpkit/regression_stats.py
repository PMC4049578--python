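"""Correlation and regression battery over group-level trait tables.

The analysis relates composition variables (TC, STC, CC), hydropathy (HYD)
and total site number (TSN) to each other and to ln(mtBMR), ln(msBMR),
ln(MLS) and ln(mtBMR*MLS) across animal groups:

* squared Pearson correlations with the sign of the association (P/N),
  per protein set — the correlation table;
* ordinary least-squares lines, fitted separately for the deuterostome
  and non-deuterostome subsets where the two lineages split;
* the power law TC = a * HYD**b, fitted both by nonlinear least squares on
  the original scale (headline) and by log-log OLS (reported alongside);
* a two-predictor OLS of ln(mtBMR) on STC and HYD.

Group means are the default regression input; species-level raw mode is a
flag upstream.  No multiple-testing correction is applied — every cell
carries its n instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import allometry
from .sequence_io import GroupMetadata, ProteinRecord
from . import composition as comp
from . import hydropathy


class DegenerateData(ValueError):
    """Zero variance (or otherwise undefined) input to a correlation/fit."""


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, str]:
    """Squared Pearson correlation plus the sign of the raw correlation.

    Returns ``(r2, sign)`` with sign 'P' (positive) or 'N' (negative).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateData("zero variance")
    r, _ = stats.pearsonr(x, y)
    return float(r * r), ("P" if r >= 0 else "N")


@dataclass
class RegressionFit:
    model: str  # "linear" or "power"
    params: dict[str, float]
    r2: float
    n: int
    subset: str = "all"
    flags: list[str] = field(default_factory=list)


def fit_linear(
    x: Sequence[float], y: Sequence[float], subset: str = "all"
) -> RegressionFit:
    """OLS line y = slope*x + intercept with squared-Pearson R^2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    if np.ptp(x) == 0:
        raise DegenerateData("zero variance in x")
    res = stats.linregress(x, y)
    return RegressionFit(
        model="linear",
        params={"slope": float(res.slope), "intercept": float(res.intercept)},
        r2=float(res.rvalue**2),
        n=int(x.size),
        subset=subset,
    )


def fit_power(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Fit y = a * x**b.

    Nonlinear least squares on the original scale is the headline fit,
    initialized from the log-log OLS solution; the log-log coefficients are
    reported alongside (``a_loglog``, ``b_loglog``).  R^2 is 1 - SSres/SStot
    on the original scale and may go negative (flagged).  Falls back to the
    log-log solution (flag ``nonconvergent``) if the optimizer fails.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("power-law fit requires strictly positive x and y")
    ll = stats.linregress(np.log(x), np.log(y))
    a0, b0 = math.exp(ll.intercept), ll.slope
    flags: list[str] = []
    try:
        popt, _ = optimize.curve_fit(
            lambda t, a, b: a * np.power(t, b), x, y, p0=(a0, b0), maxfev=20000
        )
        a, b = float(popt[0]), float(popt[1])
    except RuntimeError:
        a, b = a0, b0
        flags.append("nonconvergent")
    resid = y - a * x**b
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sstot if sstot > 0 else float("nan")
    if not math.isnan(r2) and r2 < 0:
        flags.append("negative_r2")
    return RegressionFit(
        model="power",
        params={
            "a": a,
            "b": b,
            "a_loglog": float(a0),
            "b_loglog": float(b0),
            "r2_loglog": float(ll.rvalue**2),
        },
        r2=r2,
        n=int(x.size),
        flags=flags,
    )


def multi_linear(
    y: Sequence[float], x1: Sequence[float], x2: Sequence[float]
) -> RegressionFit:
    """Two-predictor OLS y ~ x1 + x2 (e.g. ln(mtBMR) on STC and HYD).

    R^2 never falls below either single-predictor R^2 (OLS nesting).
    Near-collinear predictors are flagged.
    """
    y = np.asarray(y, float)
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if y.size < 4:
        raise ValueError("need n >= 4")
    X = np.column_stack([np.ones_like(y), x1, x2])
    flags: list[str] = []
    if np.linalg.matrix_rank(X) < 3:
        raise DegenerateData("collinear predictors")
    if np.linalg.cond(X) > 1e8:
        flags.append("near_collinear")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sstot if sstot > 0 else float("nan")
    return RegressionFit(
        model="linear",
        params={"intercept": float(beta[0]), "b1": float(beta[1]), "b2": float(beta[2])},
        r2=r2,
        n=int(y.size),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Correlation tables
# ---------------------------------------------------------------------------

def build_table1(
    records: Sequence[ProteinRecord],
    scale: hydropathy.HydropathyScale,
    iterations: int = hydropathy.DEFAULT_ITERATIONS,
    domain: str = comp.FULL_SEQUENCE,
    mode: str = "group_mean",
) -> pd.DataFrame:
    """Per-gene HYD-TC and TC-CC correlations across animal groups.

    ``mode='group_mean'`` (default) correlates group means of the per-species
    values; ``mode='species'`` uses the raw species-level points.
    Returns one row per gene with r2/sign/n for each variable pair, sorted by
    descending HYD-TC r2.
    """
    rows = []
    for gene in comp.CANONICAL_GENES:
        gene_set = comp.ProteinSet(gene, (gene,))
        sp = comp.species_table(records, gene_set, scale, iterations, domain)
        if sp.empty:
            continue
        pts = comp.group_mean(sp) if mode == "group_mean" else sp
        if len(pts) < 3:
            continue
        row: dict = {"gene": gene, "n": len(pts)}
        for pair in (("HYD", "TC"), ("TC", "CC")):
            try:
                r2, sign = pearson_r2(pts[pair[0]], pts[pair[1]])
            except DegenerateData:
                r2, sign = float("nan"), "-"
            row[f"{pair[0]}-{pair[1]}_r2"] = r2
            row[f"{pair[0]}-{pair[1]}_sign"] = sign
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("HYD-TC_r2", ascending=False, ignore_index=True)


#: Variable pairs of the cross-set correlation table.  ``ln_*`` columns are
#: appended from metadata; TSN pairs are evaluated with deuterostomes
#: excluded (the lineages split there).
TABLE2_PAIRS: tuple[tuple[str, str], ...] = (
    ("TC", "HYD"),
    ("TC", "CC"),
    ("HYD", "CC"),
    ("HYD", "STC"),
    ("STC", "CC"),
    ("TSN", "TC"),
    ("TSN", "HYD"),
    ("STC", "ln_mtBMR"),
    ("TC", "ln_mtBMR"),
    ("HYD", "ln_mtBMR"),
    ("CC", "ln_mtBMR"),
    ("STC", "ln_msBMR"),
    ("STC", "ln_MLS"),
    ("CC", "ln_MLS"),
    ("STC", "ln_mtBMR_MLS"),
)

_TSN_PAIRS = {("TSN", "TC"), ("TSN", "HYD")}


def _augment_with_metadata(
    group_df: pd.DataFrame, metadata: Sequence[GroupMetadata], F: float
) -> pd.DataFrame:
    meta = {m.group: m for m in metadata}
    df = group_df[group_df["group"].isin(meta)].copy()
    ln_mt, ln_ms, ln_mls, clade = [], [], [], []
    for g in df["group"]:
        m = meta[g]
        ln_mt.append(allometry.ln_mtbmr(m.C, m.alpha, m.M, F))
        ln_ms.append(allometry.ln_mtbmr(m.C, m.alpha, m.M, 1.0))
        ln_mls.append(math.log(m.MLS))
        clade.append(m.clade)
    df["ln_mtBMR"] = ln_mt
    df["ln_msBMR"] = ln_ms
    df["ln_MLS"] = ln_mls
    # ln of the product, computed as the sum of logs
    df["ln_mtBMR_MLS"] = df["ln_mtBMR"] + df["ln_MLS"]
    df["clade"] = clade
    return df


def build_table2(
    group_tables: Mapping[str, pd.DataFrame],
    metadata: Sequence[GroupMetadata],
    F: float,
    pairs: Sequence[tuple[str, str]] = TABLE2_PAIRS,
) -> pd.DataFrame:
    """Cross-set correlation table (variable pair x protein set).

    ``group_tables`` maps protein-set name -> group-level composition table
    (from :func:`mmpkit.composition.group_mean`).  ``F`` fixes the mtBMR
    transform (use the sweep's best F).  Output is long format: one row per
    (pair, set) with r2, sign and n, plus per-pair ``mean`` rows holding the
    arithmetic row mean of r2 across sets.
    """
    rows = []
    for set_name, gdf in group_tables.items():
        df = _augment_with_metadata(gdf, metadata, F)
        for vx, vy in pairs:
            sub = df[df["clade"] != "deuterostome"] if (vx, vy) in _TSN_PAIRS else df
            sub = sub.dropna(subset=[vx, vy])
            try:
                r2, sign = pearson_r2(sub[vx], sub[vy])
            except (DegenerateData, ValueError):
                r2, sign = float("nan"), "-"
            rows.append(
                {
                    "pair": f"{vx}-{vy}",
                    "protein_set": set_name,
                    "r2": r2,
                    "sign": sign,
                    "n": len(sub),
                }
            )
    long = pd.DataFrame(rows)
    means = (
        long.groupby("pair", sort=False)["r2"]
        .mean()
        .reset_index()
        .assign(protein_set="mean", sign="-", n=0)
    )
    return pd.concat([long, means], ignore_index=True)


def table2_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long correlation table to pairs x sets (r2 values)."""
    return long.pivot(index="pair", columns="protein_set", values="r2")


def split_linear_fits(
    group_df: pd.DataFrame,
    metadata: Sequence[GroupMetadata],
    xvar: str,
    yvar: str,
) -> dict[str, RegressionFit]:
    """OLS fits of yvar on xvar for all groups, deuterostomes, and the rest.

    The deuterostome/other split partitions the groups exactly (clade labels
    come from the metadata file).
    """
    df = _augment_with_metadata(group_df, metadata, F=1.0)
    out: dict[str, RegressionFit] = {}
    subsets = {
        "all": df,
        "deuterostome": df[df["clade"] == "deuterostome"],
        "other": df[df["clade"] != "deuterostome"],
    }
    for name, sub in subsets.items():
        sub = sub.dropna(subset=[xvar, yvar])
        if len(sub) >= 3:
            out[name] = fit_linear(sub[xvar], sub[yvar], subset=name)
    return out
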