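"""Sequence and metadata I/O with gene-name normalization.

Mitochondrially encoded membrane proteins (MMPs) are annotated inconsistently
across taxa (``COX1``/``COI``/``MT-CO1`` all name the same gene), so every
record entering the pipeline is normalized to a 13-symbol canonical vocabulary
before anything downstream sees it.  Malformed records are collected into a
reject report rather than silently dropped.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_GENES = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "CYTB", "CO1", "CO2", "CO3", "ATP6", "ATP8",
)

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUITY_CODES = frozenset("XBZU")

CLADES = ("deuterostome", "protostome", "basal")

_METADATA_COLUMNS = ("group", "clade", "M", "C", "alpha", "MLS")


class SequenceIOError(ValueError):
    """Raised for unrecoverable input problems (empty file, bad metadata)."""


def _load_synonym_table() -> dict[str, str]:
    table: dict[str, str] = {}
    text = resources.files("mmpkit.data").joinpath("gene_synonyms.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        canonical, synonyms = line.split("\t")
        for syn in synonyms.split(","):
            table[syn.strip().upper()] = canonical
    return table


_SYNONYMS = _load_synonym_table()


def normalize_gene(name: str) -> str:
    """Map a gene name or synonym to its canonical symbol.

    Raises ``KeyError`` with the offending name if it is not recognized.
    Matching is case-insensitive and tolerates a leading ``MT-``/``MT_``
    prefix and internal dashes/underscores.
    """
    key = name.strip().upper()
    for candidate in (key, key.replace("-", "").replace("_", "")):
        if candidate in _SYNONYMS:
            return _SYNONYMS[candidate]
        stripped = re.sub(r"^MT[-_]?", "", candidate)
        if stripped in _SYNONYMS:
            return _SYNONYMS[stripped]
    raise KeyError(name)


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence tagged with species, animal group and gene."""

    species_id: str
    group: str
    gene: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - CANONICAL_RESIDUES - AMBIGUITY_CODES
        if bad:
            raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
        if self.gene not in CANONICAL_GENES:
            raise ValueError(f"gene {self.gene!r} is not canonical")

    @property
    def canonical_length(self) -> int:
        """Number of sites with a canonical (unambiguous) residue."""
        return sum(1 for ch in self.sequence if ch in CANONICAL_RESIDUES)


@dataclass(frozen=True)
class GroupMetadata:
    """Per-animal-group allometric and life-history parameters.

    ``M`` (grams) and ``MLS`` (years) are group means over individual species;
    ``C`` and ``alpha`` parameterize the within-group allometric law
    BMR = C * M**alpha.  ``C`` is treated as relative (units of the source
    metabolic-rate data) since only correlations of log values are consumed.
    """

    group: str
    clade: str
    M: float
    C: float
    alpha: float
    MLS: float

    def __post_init__(self) -> None:
        if self.clade not in CLADES:
            raise ValueError(f"clade must be one of {CLADES}, got {self.clade!r}")
        if not self.M > 0:
            raise ValueError(f"M must be > 0, got {self.M}")
        if not self.C > 0:
            raise ValueError(f"C must be > 0, got {self.C}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not self.MLS > 0:
            raise ValueError(f"MLS must be > 0, got {self.MLS}")


@dataclass
class RejectEntry:
    header: str
    reason: str


@dataclass
class ReadResult:
    records: list[ProteinRecord]
    rejects: list[RejectEntry] = field(default_factory=list)

    def reject_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.header, r.reason) for r in self.rejects],
            columns=["header", "reason"],
        )


DEFAULT_HEADER_REGEX = r"^(?P<species>[^|]+)\|(?P<group>[^|]+)\|(?P<gene>[^|]+)$"


def read_fasta(path: str | Path, header_regex: str = DEFAULT_HEADER_REGEX) -> ReadResult:
    """Read a protein FASTA whose headers encode species|group|gene.

    An alternative ``header_regex`` with named groups ``species``, ``group``
    and ``gene`` may be supplied for externally sourced files.  Records whose
    header does not parse, whose gene is unknown, or whose sequence contains
    non-amino-acid characters are returned as rejects with a reason.
    """
    pattern = re.compile(header_regex)
    records: list[ProteinRecord] = []
    rejects: list[RejectEntry] = []
    n_seen = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_seen += 1
        header = rec.description
        m = pattern.match(header)
        if m is None:
            rejects.append(RejectEntry(header, "unparseable header"))
            continue
        try:
            gene = normalize_gene(m.group("gene"))
        except KeyError:
            rejects.append(RejectEntry(header, f"unknown gene synonym {m.group('gene')!r}"))
            continue
        try:
            records.append(
                ProteinRecord(
                    species_id=m.group("species").strip(),
                    group=m.group("group").strip(),
                    gene=gene,
                    sequence=str(rec.seq).upper(),
                )
            )
        except ValueError as exc:
            rejects.append(RejectEntry(header, str(exc)))
    if n_seen == 0:
        raise SequenceIOError(f"no FASTA records in {path}")
    return ReadResult(records=records, rejects=rejects)


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records using the canonical ``species|group|gene`` header dialect."""
    seqrecords = [
        SeqRecord(
            Seq(r.sequence),
            id=f"{r.species_id}|{r.group}|{r.gene}",
            description="",
        )
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta-2line")


def read_metadata(path: str | Path) -> list[GroupMetadata]:
    """Read the per-group metadata TSV (group, clade, M, C, alpha, MLS)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SequenceIOError(f"metadata missing column(s): {', '.join(missing)}")
    dup = df["group"][df["group"].duplicated()].tolist()
    if dup:
        raise SequenceIOError(f"duplicate metadata rows for group(s): {sorted(set(dup))}")
    out = []
    for row in df.itertuples(index=False):
        try:
            out.append(
                GroupMetadata(
                    group=str(row.group), clade=str(row.clade),
                    M=float(row.M), C=float(row.C),
                    alpha=float(row.alpha), MLS=float(row.MLS),
                )
            )
        except ValueError as exc:
            raise SequenceIOError(f"group {row.group!r}: {exc}") from exc
    return out


def write_metadata(metadata: Iterable[GroupMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [(m.group, m.clade, m.M, m.C, m.alpha, m.MLS) for m in metadata],
        columns=list(_METADATA_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


def validate_dataset(
    records: Sequence[ProteinRecord],
    metadata: Sequence[GroupMetadata],
    required_genes: Sequence[str] = CANONICAL_GENES,
) -> dict:
    """Cross-check sequences against metadata; purely reporting, never raises.

    Returns a JSON-serializable report listing groups absent from the
    metadata, undersized groups, species missing genes of the requested set,
    and duplicate (species, gene) pairs.
    """
    meta_groups = {m.group for m in metadata}
    by_species: dict[str, set[str]] = {}
    species_group: dict[str, str] = {}
    seen: set[tuple[str, str]] = set()
    duplicates: list[list[str]] = []
    for r in records:
        key = (r.species_id, r.gene)
        if key in seen:
            duplicates.append(list(key))
        seen.add(key)
        by_species.setdefault(r.species_id, set()).add(r.gene)
        species_group[r.species_id] = r.group
    fasta_groups = set(species_group.values())
    missing_genes = {
        sp: sorted(set(required_genes) - genes)
        for sp, genes in sorted(by_species.items())
        if set(required_genes) - genes
    }
    group_sizes: dict[str, int] = {}
    for sp, grp in species_group.items():
        group_sizes[grp] = group_sizes.get(grp, 0) + 1
    return {
        "n_records": len(records),
        "n_species": len(by_species),
        "groups_in_fasta": sorted(fasta_groups),
        "groups_missing_metadata": sorted(fasta_groups - meta_groups),
        "metadata_groups_without_sequences": sorted(meta_groups - fasta_groups),
        "undersized_groups": sorted(g for g, n in group_sizes.items() if n < 1),
        "species_missing_genes": missing_genes,
        "duplicate_records": duplicates,
    }


def write_validation_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
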