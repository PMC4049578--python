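"""Amino-acid composition statistics over nested protein sets.

Computes, per species (and aggregated to animal-group means):

* TC  — Thr percentage of amino-acid sites
* SC  — Ser percentage
* STC — Ser+Thr percentage (STC = TC + SC by construction)
* CC  — Cys percentage
* TSN — total site number: summed canonical-residue length of a protein set
* HYD — pooled hydrophobic-domain mean of the smoothed hydropathy profile

Percentages are pooled across the genes of a set (concatenation, matching
TSN's definition as a pooled site count) and computed over canonical
residues only; ambiguity codes are excluded from numerator and denominator.
The composition domain is either the full sequence (default) or only the
sites inside the hydrophobic mask S(n) > 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import hydropathy
from .sequence_io import CANONICAL_GENES, CANONICAL_RESIDUES, ProteinRecord

FULL_SEQUENCE = "full_sequence"
HYDROPHOBIC_MASK = "hydrophobic_mask"


@dataclass(frozen=True)
class ProteinSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = set(self.genes) - set(CANONICAL_GENES)
        if unknown:
            raise ValueError(f"unknown genes in set {self.name!r}: {sorted(unknown)}")


# The five nested sets built around the proton-pumping subunits, plus all 13.
PROTEIN_SETS: dict[str, ProteinSet] = {
    "set3": ProteinSet("set3", ("ND4", "ND5", "ND2")),
    "set4": ProteinSet("set4", ("ND4", "ND5", "ND2", "ND1")),
    "set5": ProteinSet("set5", ("ND4", "ND5", "ND2", "CO1", "CO3")),
    "set6": ProteinSet("set6", ("ND4", "ND5", "ND2", "CO1", "CO3", "ND1")),
    "set7": ProteinSet("set7", ("ND4", "ND5", "ND2", "CO1", "CO3", "ND1", "CYTB")),
    "all13": ProteinSet("all13", CANONICAL_GENES),
}

NESTED_SETS = ("set3", "set4", "set5", "set6", "set7")


class MissingGene(ValueError):
    """A unit lacks a gene required by the requested protein set."""


def _domain_residues(
    record: ProteinRecord,
    domain: str,
    profile: hydropathy.HydropathyProfile | None,
) -> Iterable[str]:
    canonical = (ch for ch in record.sequence if ch in CANONICAL_RESIDUES)
    if domain == FULL_SEQUENCE:
        return canonical
    if domain == HYDROPHOBIC_MASK:
        if profile is None:
            raise ValueError("hydrophobic_mask domain requires a profile")
        seq = record.sequence
        return (seq[p - 1] for p in profile.positions[profile.mask])
    raise ValueError(f"unknown composition domain {domain!r}")


def residue_counts(
    records: Sequence[ProteinRecord],
    domain: str = FULL_SEQUENCE,
    profiles: Mapping[str, hydropathy.HydropathyProfile] | None = None,
) -> Counter:
    """Pooled canonical-residue counts for one unit across its records."""
    counts: Counter = Counter()
    for r in records:
        profile = profiles.get(r.gene) if profiles else None
        counts.update(_domain_residues(r, domain, profile))
    return counts


def residue_percent(
    records: Sequence[ProteinRecord],
    residues: Iterable[str],
    domain: str = FULL_SEQUENCE,
    profiles: Mapping[str, hydropathy.HydropathyProfile] | None = None,
) -> float:
    """100 x (sites in ``residues``) / (all canonical sites), pooled."""
    if not records:
        raise ValueError("no records supplied")
    counts = residue_counts(records, domain, profiles)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty composition denominator")
    subset = sum(counts[r] for r in set(residues))
    return 100.0 * subset / total


def tsn(records: Sequence[ProteinRecord], protein_set: ProteinSet) -> int:
    """Total site number: summed canonical-residue length over the set's genes."""
    by_gene = {r.gene: r for r in records}
    total = 0
    for gene in protein_set.genes:
        if gene not in by_gene:
            raise MissingGene(f"gene {gene} missing for this unit")
        total += by_gene[gene].canonical_length
    return total


def species_composition(
    records: Sequence[ProteinRecord],
    protein_set: ProteinSet,
    scale: hydropathy.HydropathyScale,
    iterations: int = hydropathy.DEFAULT_ITERATIONS,
    domain: str = FULL_SEQUENCE,
) -> dict:
    """TC/SC/STC/CC/TSN/HYD for one species over one protein set.

    ``records`` are all records of one species; genes outside the set are
    ignored.  Raises ``MissingGene`` if the set is incomplete.
    """
    wanted = [r for r in records if r.gene in protein_set.genes]
    have = {r.gene for r in wanted}
    missing = set(protein_set.genes) - have
    if missing:
        raise MissingGene(f"missing gene(s) {sorted(missing)}")
    profiles = {
        r.gene: hydropathy.profile_protein(r, scale, iterations) for r in wanted
    }
    kwargs = dict(domain=domain, profiles=profiles)
    tc = residue_percent(wanted, ["T"], **kwargs)
    sc = residue_percent(wanted, ["S"], **kwargs)
    cc = residue_percent(wanted, ["C"], **kwargs)
    try:
        hyd = hydropathy.pooled_hyd(profiles.values())
    except hydropathy.NoHydrophobicDomain:
        hyd = np.nan
    return {
        "TC": tc,
        "SC": sc,
        "STC": tc + sc,
        "CC": cc,
        "TSN": tsn(wanted, protein_set),
        "HYD": hyd,
    }


def species_table(
    records: Sequence[ProteinRecord],
    protein_set: ProteinSet,
    scale: hydropathy.HydropathyScale,
    iterations: int = hydropathy.DEFAULT_ITERATIONS,
    domain: str = FULL_SEQUENCE,
    drop_incomplete: bool = True,
) -> pd.DataFrame:
    """Species-level composition table for one protein set.

    Species lacking any gene of the set are dropped (and reported in the
    frame's ``attrs['dropped']``) — the default missing-gene policy — or
    raise ``MissingGene`` when ``drop_incomplete`` is False.
    """
    by_species: dict[str, list[ProteinRecord]] = {}
    group_of: dict[str, str] = {}
    for r in records:
        by_species.setdefault(r.species_id, []).append(r)
        group_of[r.species_id] = r.group
    rows, dropped = [], []
    for sp in sorted(by_species):
        try:
            stats = species_composition(
                by_species[sp], protein_set, scale, iterations, domain
            )
        except MissingGene:
            if drop_incomplete:
                dropped.append(sp)
                continue
            raise
        rows.append({"species_id": sp, "group": group_of[sp], **stats})
    df = pd.DataFrame(
        rows, columns=["species_id", "group", "TC", "SC", "STC", "CC", "TSN", "HYD"]
    )
    df.attrs["protein_set"] = protein_set.name
    df.attrs["domain"] = domain
    df.attrs["dropped"] = dropped
    return df


VARIABLES = ("TC", "SC", "STC", "CC", "TSN", "HYD")


def group_mean(species_df: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-group arithmetic means with sd and n.

    Returns one row per group with mean columns named as the variables and
    companion ``sd_*`` columns plus ``n`` (species count).
    """
    grouped = species_df.groupby("group")
    means = grouped[list(VARIABLES)].mean()
    sds = grouped[list(VARIABLES)].std(ddof=1).add_prefix("sd_")
    out = means.join(sds)
    out["n"] = grouped.size()
    out = out.reset_index()
    out.attrs.update(species_df.attrs)
    return out
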