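"""Synthetic sequence cohorts and metadata with the structure the analysis assumes.

The generator emulates a multi-group metazoan dataset: 13 animal groups,
>= 20 species each, 13 mitochondrially encoded membrane-protein genes per
species.  Sequences are drawn residue-by-residue from a per-group
multinomial whose frequencies are tuned so that

* expected Thr/Ser/Cys percentages hit the group targets, and
* the *measured* HYD (mean of the iterated-moving-average profile over its
  positive part) hits the group target, via a Gaussian approximation of the
  smoothed-score distribution (see ``_calibrate_raw_mean``).

Group targets follow a prescribed inverse TC-HYD relation (power law by
default) plus log-normal relation noise, deuterostome groups carry higher
TC/STC and longer genes (higher TSN) than the rest, and the metadata links
ln(C) and ln(MLS) affinely to STC — the statistical structure the
correlation battery and F-sweep are designed to detect.  Every generator
parameter is recorded in a ground-truth dict sufficient to regenerate the
cohort bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from . import hydropathy
from .reference import HUMAN_MT_PROTEIN_LENGTHS
from .sequence_io import (
    CANONICAL_GENES,
    GroupMetadata,
    ProteinRecord,
    write_fasta,
    write_metadata,
)

RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")

# Two residue pools besides the targeted T/S/C: a hydrophobic pool with high
# Cowan-Whittaker scores and a polar remainder.  Within a pool residues are
# equally weighted.
HYDROPHOBIC_POOL = ("I", "L", "V", "F", "M", "A", "W")
POLAR_POOL = ("G", "N", "Q", "H", "K", "R", "D", "E", "P", "Y")


@dataclass(frozen=True)
class GroupSimSpec:
    """Fully resolved simulation targets for one animal group."""

    name: str
    clade: str
    n_species: int
    gene_lengths: dict[str, int]
    target_hyd: float  # measured HYD (mean of S(n) > 0)
    target_tc: float   # percent
    target_sc: float   # percent
    target_cc: float   # percent
    M: float
    C: float
    alpha: float
    MLS: float

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species >= 1 required")
        if min(self.gene_lengths.values()) < 30:
            raise ValueError("gene lengths must be >= 30")
        for p in (self.target_tc, self.target_sc, self.target_cc):
            if p < 0:
                raise ValueError("target percents must be >= 0")
        if self.target_tc + self.target_sc + self.target_cc >= 100:
            raise ValueError("target percents exceed 100")


@dataclass(frozen=True)
class CohortSimSpec:
    groups: tuple[GroupSimSpec, ...]
    seed: int
    smoothing_iterations: int = hydropathy.DEFAULT_ITERATIONS


@dataclass
class SimulatedCohort:
    records: list[ProteinRecord]
    metadata: list[GroupMetadata]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "cohort.faa",
            "metadata": outdir / "metadata.tsv",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.records, paths["fasta"])
        write_metadata(self.metadata, paths["metadata"])
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True) + "\n")
        return paths


# ---------------------------------------------------------------------------
# Residue-frequency calibration
# ---------------------------------------------------------------------------

def _smoothing_weight_norm(iterations: int) -> float:
    """Sum of squared weights of the iterated 3-site smoother at an interior
    site — the variance-shrink factor for iid inputs."""
    size = 4 * iterations + 9
    impulse = np.zeros(size)
    impulse[size // 2] = 1.0
    w = hydropathy.smooth(impulse, iterations)
    return float((w**2).sum())


def _frequencies_for_raw_mean(
    raw_mean: float, f_t: float, f_s: float, f_c: float,
    scale: hydropathy.HydropathyScale,
) -> np.ndarray:
    """Multinomial frequencies over the 20 residues with fixed T/S/C shares
    and hydrophobic/polar pool split chosen to hit ``raw_mean``."""
    rem = 1.0 - f_t - f_s - f_c
    if rem <= 0:
        raise ValueError("target percents leave no room for the residue pools")
    mu_h = float(np.mean([scale[r] for r in HYDROPHOBIC_POOL]))
    mu_p = float(np.mean([scale[r] for r in POLAR_POOL]))
    base = f_t * scale["T"] + f_s * scale["S"] + f_c * scale["C"]
    h = (raw_mean - base - rem * mu_p) / (mu_h - mu_p)
    if not 0.0 <= h <= rem:
        raise ValueError(
            f"infeasible hydropathy target: hydrophobic-pool fraction {h:.3f} "
            f"outside [0, {rem:.3f}]"
        )
    freqs = np.zeros(len(RESIDUES))
    idx = {r: i for i, r in enumerate(RESIDUES)}
    freqs[idx["T"]] = f_t
    freqs[idx["S"]] = f_s
    freqs[idx["C"]] = f_c
    for r in HYDROPHOBIC_POOL:
        freqs[idx[r]] = h / len(HYDROPHOBIC_POOL)
    for r in POLAR_POOL:
        freqs[idx[r]] = (rem - h) / len(POLAR_POOL)
    return freqs


def _calibrate_raw_mean(
    target_hyd: float, f_t: float, f_s: float, f_c: float,
    scale: hydropathy.HydropathyScale, iterations: int,
) -> float:
    """Raw-score mean whose smoothed profile has E[S(n) | S(n)>0] = target.

    Under the iid residue model the smoothed score at an interior site is
    approximately Normal(m, v*w2) with v the residue-score variance and w2
    the smoother's squared-weight norm; the positive-part mean is then
    m + s*phi(m/s)/Phi(m/s).  Solved for m by a bracketing root-find.
    """
    if target_hyd <= 0:
        raise ValueError("target HYD must be > 0")
    w2 = _smoothing_weight_norm(iterations)
    scores = np.array([scale[r] for r in RESIDUES])

    def positive_part_mean(m: float) -> float:
        f = _frequencies_for_raw_mean(m, f_t, f_s, f_c, scale)
        mean = float(f @ scores)
        var = float(f @ (scores - mean) ** 2)
        s = math.sqrt(var * w2)
        a = mean / s
        return mean + s * stats.norm.pdf(a) / stats.norm.cdf(a)

    lo, hi = target_hyd - 4.0, target_hyd
    # widen the lower bracket if the pools cannot reach that low
    for _ in range(20):
        try:
            if positive_part_mean(lo) < target_hyd:
                break
        except ValueError:
            pass
        lo += 0.2
        if lo >= hi:
            raise ValueError("cannot bracket the hydropathy calibration")
    return float(optimize.brentq(lambda m: positive_part_mean(m) - target_hyd, lo, hi))


def group_frequencies(
    spec: GroupSimSpec, iterations: int, scale: hydropathy.HydropathyScale | None = None
) -> np.ndarray:
    """Calibrated residue frequencies for one group."""
    scale = scale or hydropathy.cowan_whittaker()
    raw_mean = _calibrate_raw_mean(
        spec.target_hyd, spec.target_tc / 100, spec.target_sc / 100,
        spec.target_cc / 100, scale, iterations,
    )
    return _frequencies_for_raw_mean(
        raw_mean, spec.target_tc / 100, spec.target_sc / 100,
        spec.target_cc / 100, scale,
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(spec: CohortSimSpec) -> SimulatedCohort:
    """Draw the full cohort: FASTA records, metadata and ground truth.

    Identical spec + seed gives byte-identical output (per-group random
    streams are derived deterministically from the master seed).
    """
    scale = hydropathy.cowan_whittaker()
    records: list[ProteinRecord] = []
    metadata: list[GroupMetadata] = []
    truth_groups = []  # ordered: the spawn order of per-group random streams
    master = np.random.SeedSequence(spec.seed)
    children = master.spawn(len(spec.groups))
    for gspec, child in zip(spec.groups, children):
        rng = np.random.default_rng(child)
        freqs = group_frequencies(gspec, spec.smoothing_iterations, scale)
        for k in range(gspec.n_species):
            species = f"{gspec.name}_sp{k:03d}"
            for gene in CANONICAL_GENES:
                length = gspec.gene_lengths[gene]
                seq = "".join(
                    RESIDUES[i] for i in rng.choice(len(RESIDUES), size=length, p=freqs)
                )
                records.append(
                    ProteinRecord(
                        species_id=species, group=gspec.name, gene=gene, sequence=seq
                    )
                )
        metadata.append(
            GroupMetadata(
                group=gspec.name, clade=gspec.clade, M=gspec.M, C=gspec.C,
                alpha=gspec.alpha, MLS=gspec.MLS,
            )
        )
        truth_groups.append(
            {
                **dataclasses.asdict(gspec),
                "residue_frequencies": dict(zip(RESIDUES, freqs.tolist())),
            }
        )
    truth = {
        "seed": spec.seed,
        "smoothing_iterations": spec.smoothing_iterations,
        "groups": truth_groups,
    }
    return SimulatedCohort(records=records, metadata=metadata, truth=truth)


def spec_from_truth(truth: dict) -> CohortSimSpec:
    """Rebuild the cohort spec from a ground-truth dict (regeneration)."""
    groups = []
    gspec_fields = {f.name for f in dataclasses.fields(GroupSimSpec)}
    for g in truth["groups"]:
        groups.append(GroupSimSpec(**{k: v for k, v in g.items() if k in gspec_fields}))
    return CohortSimSpec(
        groups=tuple(groups),
        seed=truth["seed"],
        smoothing_iterations=truth["smoothing_iterations"],
    )


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: 13 metazoan groups with their clade assignment (deuterostome =
#: echinoderms + vertebrates; basal = sponges and cnidarians) and a
#: realistic mean body mass in grams, spanning ~7 orders of magnitude.
DEFAULT_GROUPS: tuple[tuple[str, str, float], ...] = (
    ("Porifera", "basal", 0.5),
    ("Cnidaria", "basal", 2.0),
    ("Platyhelminthes", "protostome", 0.05),
    ("Nematoda", "protostome", 0.001),
    ("Mollusca", "protostome", 5.0),
    ("Crustacea", "protostome", 1.0),
    ("Hexapoda", "protostome", 0.02),
    ("Chelicerata", "protostome", 0.1),
    ("Echinodermata", "deuterostome", 20.0),
    ("Fishes", "deuterostome", 500.0),
    ("Amphibia", "deuterostome", 30.0),
    ("Eutheria", "deuterostome", 30000.0),
    ("Aves", "deuterostome", 800.0),
)

#: Group HYD targets: deuterostomes low (toward Aves), basal groups and
#: protostomes high — the two contrasting pathways.
DEFAULT_HYD_TARGETS: dict[str, float] = {
    "Aves": 0.560, "Eutheria": 0.575, "Amphibia": 0.610, "Fishes": 0.625,
    "Echinodermata": 0.645, "Cnidaria": 0.660, "Mollusca": 0.665,
    "Crustacea": 0.675, "Chelicerata": 0.680, "Hexapoda": 0.685,
    "Porifera": 0.690, "Platyhelminthes": 0.695, "Nematoda": 0.700,
}

#: TC-HYD relation of the default cohort (power law on the measured scale).
DEFAULT_POWER_A = 0.429
DEFAULT_POWER_B = -4.2045
#: Log-scale sd of the relation noise, set so the group-level TC-HYD
#: correlation lands near R^2 ~ 0.9.
DEFAULT_RELATION_NOISE = 0.09


def default_cohort_spec(
    seed: int,
    n_species: int = 20,
    gene_length_scale: float = 1.0,
    power_a: float = DEFAULT_POWER_A,
    power_b: float = DEFAULT_POWER_B,
    relation_noise: float = DEFAULT_RELATION_NOISE,
    smoothing_iterations: int = hydropathy.DEFAULT_ITERATIONS,
) -> CohortSimSpec:
    """Resolve the default 13-group study conditions into a concrete spec.

    ``gene_length_scale`` < 1 shrinks every gene proportionally (problem-size
    control for quick runs); targets and relations are unchanged.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0407)))
    groups = []
    for name, clade, mass in DEFAULT_GROUPS:
        hyd = DEFAULT_HYD_TARGETS[name]
        tc = power_a * hyd**power_b * math.exp(rng.normal(0.0, relation_noise))
        sc = 0.5 + 0.5 * tc
        cc = max(0.2, 1.6 - 0.25 * tc + rng.normal(0.0, 0.25))
        stc = tc + sc
        # TSN gradient: within each lineage gene length rises with TC, and the
        # deuterostome range sits strictly above the protostome/basal range
        # (the Fig-3-like clade split the cohort is meant to encode)
        if clade == "deuterostome":
            factor = 0.93 + 0.015 * (tc - 3.0)
        else:
            factor = 0.72 + 0.05 * tc
        factor *= gene_length_scale
        gene_lengths = {
            g: max(30, round(HUMAN_MT_PROTEIN_LENGTHS[g] * factor))
            for g in CANONICAL_GENES
        }
        alpha = float(np.clip(rng.normal(0.72, 0.03), 0.65, 0.80))
        ln_c = -1.0 + 0.67 * (stc - 5.5) + rng.normal(0.0, 0.30)
        ln_mls = 0.3 + 0.45 * stc + rng.normal(0.0, 0.35)
        groups.append(
            GroupSimSpec(
                name=name, clade=clade, n_species=n_species,
                gene_lengths=gene_lengths, target_hyd=hyd, target_tc=tc,
                target_sc=sc, target_cc=cc, M=mass, C=math.exp(ln_c),
                alpha=alpha, MLS=math.exp(ln_mls),
            )
        )
    return CohortSimSpec(
        groups=tuple(groups), seed=seed, smoothing_iterations=smoothing_iterations
    )


def fixture_cohort_spec(seed: int = 7) -> CohortSimSpec:
    """Small 3-group x 3-species cohort for unit tests and smoke runs."""
    spec = default_cohort_spec(seed, n_species=3, gene_length_scale=0.35)
    keep = {"Nematoda", "Fishes", "Aves"}
    return CohortSimSpec(
        groups=tuple(g for g in spec.groups if g.name in keep),
        seed=seed,
        smoothing_iterations=spec.smoothing_iterations,
    )


# ---------------------------------------------------------------------------
# Allometry-only simulation (exercises the F-sweep)
# ---------------------------------------------------------------------------

def simulate_allometry(
    F_true: float,
    seed: int,
    n_groups: int = 13,
    slope: float = 2.0,
    intercept: float = 6.0,
    sigma: float = 0.0,
    mass_orders: float = 5.0,
    sd_ln_c: float = 1.0,
    alpha_range: tuple[float, float] = (0.65, 0.80),
) -> tuple[list[GroupMetadata], dict[str, float], dict]:
    """Metadata plus STC targets constructed affine in ln(mtBMR(F_true)).

    STC_g = intercept + slope * ln(C_g * M_g**(-(1-alpha_g)/F_true)) + eps,
    eps ~ N(0, sigma).  Masses are log-spaced over ``mass_orders`` orders of
    magnitude; ln(C) is drawn independently so finite and infinite F remain
    distinguishable.  Returns (metadata, stc_by_group, ground truth).
    """
    if n_groups < 5:
        raise ValueError("need >= 5 groups")
    if mass_orders < 3:
        warnings.warn("mass range below 3 orders of magnitude is degenerate")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA110)))
    masses = np.logspace(0.0, mass_orders, n_groups)
    alphas = rng.uniform(*alpha_range, size=n_groups)
    ln_cs = rng.normal(0.0, sd_ln_c, size=n_groups)
    metadata: list[GroupMetadata] = []
    stc: dict[str, float] = {}
    from .allometry import ln_mtbmr  # local import to avoid cycle

    for i in range(n_groups):
        name = f"G{i:02d}"
        C = math.exp(ln_cs[i])
        m = GroupMetadata(
            group=name, clade="protostome", M=float(masses[i]), C=C,
            alpha=float(alphas[i]), MLS=10.0,
        )
        metadata.append(m)
        x = ln_mtbmr(C, m.alpha, m.M, F_true)
        stc[name] = intercept + slope * x + float(rng.normal(0.0, sigma))
    truth = {
        "F_true": F_true, "slope": slope, "intercept": intercept,
        "sigma": sigma, "seed": seed, "n_groups": n_groups,
        "mass_orders": mass_orders, "sd_ln_c": sd_ln_c,
    }
    return metadata, stc, truth
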