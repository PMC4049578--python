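"""Hydropathy profiling: per-site scores, iterated smoothing, hydrophobic mask.

Each residue gets a scalar hydrophobicity score from a configurable scale
(default: the Cowan–Whittaker pH 7.5 HPLC scale).  The raw profile is then
smoothed by repeatedly replacing every site with the mean of the 3-site
window {n-1, n, n+1} (truncated at the termini, where only 2 values exist).
The hydrophobic domain is the set of sites where the smoothed profile S(n)
is strictly positive, and the scalar summary HYD is the mean of S(n) over
that domain — pooled across proteins when a protein set is profiled.

Sites carrying ambiguity codes (X, B, Z, U) have no scale value; they are
excluded from scoring and bridged in smoothing (the window simply spans the
remaining scored neighbors).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .sequence_io import AMBIGUITY_CODES, CANONICAL_RESIDUES, ProteinRecord

DEFAULT_ITERATIONS = 10


class NoHydrophobicDomain(ValueError):
    """Smoothed profile has no site with S(n) > 0; HYD is undefined, not 0."""


@dataclass(frozen=True)
class HydropathyScale:
    """A residue -> hydrophobicity score lookup covering the 20 canonical residues."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = CANONICAL_RESIDUES - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


def load_scale(path: str | Path, name: str | None = None) -> HydropathyScale:
    """Load a two-column (residue, score) TSV scale file."""
    values: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        residue, score = line.split("\t")
        values[residue.strip().upper()] = float(score)
    return HydropathyScale(name or Path(path).stem, values)


def _builtin(fname: str, name: str) -> HydropathyScale:
    values: dict[str, float] = {}
    for line in resources.files("mmpkit.data").joinpath(fname).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        residue, score = line.split("\t")
        values[residue.strip().upper()] = float(score)
    return HydropathyScale(name, values)


def cowan_whittaker() -> HydropathyScale:
    """The Cowan–Whittaker (1990) pH 7.5 scale — the pipeline default."""
    return _builtin("cowan_whittaker_ph75.tsv", "cowan_whittaker_ph75")


def kyte_doolittle() -> HydropathyScale:
    """The Kyte–Doolittle (1982) hydropathy index, for cross-checks."""
    return _builtin("kyte_doolittle.tsv", "kyte_doolittle")


@dataclass
class HydropathyProfile:
    """Scored profile of one protein.

    Arrays cover scored (canonical-residue) sites only; ``positions`` maps
    each entry back to its 1-based site in the full sequence so excluded
    ambiguity sites remain identifiable.
    """

    positions: np.ndarray  # 1-based site indices of scored residues
    raw: np.ndarray
    smoothed: np.ndarray
    mask: np.ndarray  # True iff smoothed > 0
    iterations_used: int

    @property
    def hyd(self) -> float:
        return hyd_value(self)


def raw_profile(
    record: ProteinRecord | str, scale: HydropathyScale
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site scores for the canonical residues of a sequence.

    Returns ``(scores, positions)`` where positions are 1-based indices into
    the full sequence; ambiguity-code sites are absent from both (bridged).
    Raises ``ValueError`` if no canonical residue exists.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    scores, positions = [], []
    for i, ch in enumerate(seq, start=1):
        if ch in CANONICAL_RESIDUES:
            scores.append(scale[ch])
            positions.append(i)
        elif ch not in AMBIGUITY_CODES:
            raise ValueError(f"unknown residue {ch!r} at position {i}")
    if not scores:
        raise ValueError("sequence has no canonical residues to score")
    return np.asarray(scores, dtype=float), np.asarray(positions, dtype=int)


def smooth(raw: np.ndarray, iterations: int) -> np.ndarray:
    """Iterated 3-site moving average with truncated terminal windows.

    One pass maps x[n] -> mean(x[n-1], x[n], x[n+1]); the first and last
    sites average the 2 available values.  ``iterations=0`` returns the
    input unchanged.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    x = np.asarray(raw, dtype=float)
    if x.ndim != 1:
        raise ValueError("profile must be 1-D")
    if x.size <= 1:
        return x.copy()
    counts = np.full(x.size, 3.0)
    counts[0] = counts[-1] = 2.0
    for _ in range(iterations):
        # full convolution trimmed by one at each end gives the 3-site window
        # sum at every position for any profile length
        x = np.convolve(x, [1.0, 1.0, 1.0], mode="full")[1:-1] / counts
    return x


def smooth_to_convergence(
    raw: np.ndarray, tol: float = 0.01, max_iterations: int = 1000
) -> tuple[np.ndarray, int]:
    """Smooth until the largest per-site change falls below ``tol``.

    Returns the smoothed profile and the number of passes applied.
    """
    x = np.asarray(raw, dtype=float)
    for k in range(max_iterations):
        nxt = smooth(x, 1)
        if np.max(np.abs(nxt - x), initial=0.0) < tol:
            return nxt, k + 1
        x = nxt
    return x, max_iterations


def hyd_value(profile: HydropathyProfile) -> float:
    """Mean of S(n) over the hydrophobic domain (sites with S(n) > 0)."""
    if not profile.mask.any():
        raise NoHydrophobicDomain("no site with S(n) > 0")
    return float(profile.smoothed[profile.mask].mean())


def pooled_hyd(profiles: Iterable[HydropathyProfile]) -> float:
    """Protein-set HYD: concatenate hydrophobic-domain sites of several
    proteins before averaging (per-species, per-set summary)."""
    pools = [p.smoothed[p.mask] for p in profiles]
    values = np.concatenate(pools) if pools else np.empty(0)
    if values.size == 0:
        raise NoHydrophobicDomain("no site with S(n) > 0 in any profile")
    return float(values.mean())


def profile_protein(
    record: ProteinRecord | str,
    scale: HydropathyScale,
    iterations: int = DEFAULT_ITERATIONS,
    convergence_tol: float | None = None,
) -> HydropathyProfile:
    """Score, smooth and mask one protein.

    If ``convergence_tol`` is given, smoothing stops when the largest
    per-site change drops below it (capped at ``iterations`` passes is NOT
    applied in that mode; the cap is 1000); otherwise exactly ``iterations``
    passes are run.
    """
    raw, positions = raw_profile(record, scale)
    if convergence_tol is not None:
        smoothed, used = smooth_to_convergence(raw, tol=convergence_tol)
    else:
        smoothed, used = smooth(raw, iterations), iterations
    return HydropathyProfile(
        positions=positions,
        raw=raw,
        smoothed=smoothed,
        mask=smoothed > 0.0,
        iterations_used=used,
    )


def profile_frame(record: ProteinRecord, profile: HydropathyProfile):
    """Per-site dump (position, residue, raw, smoothed, masked) as a DataFrame."""
    import pandas as pd

    residues = [record.sequence[p - 1] for p in profile.positions]
    return pd.DataFrame(
        {
            "position": profile.positions,
            "residue": residues,
            "raw": profile.raw,
            "smoothed": profile.smoothed,
            "masked": profile.mask,
        }
    )
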