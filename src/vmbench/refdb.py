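"""Reference databases of annotated sequences and incompleteness scenarios.

A reference database is a set of 16S or genome sequences labelled with a
species/genus/family taxonomy. Incomplete databases are built by deleting
whole taxa at a chosen rank (simulating missing genomic knowledge), and
representation scenarios retain family subsets whose cumulative abundance
in a target microbiome is as close as possible to 50% or 25%.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from vmbench._errors import InvalidParameterError, VmbenchError
from vmbench.ecology import VirtualMicrobiome, aggregate_abundance

IUPAC_ALPHABET = set("ACGTUNRYSWKMBDHV")

__all__ = [
    "SeqRecord",
    "ReferenceDatabase",
    "ScenarioSpec",
    "read_fasta_db",
    "write_fasta_db",
    "make_incomplete_db",
    "build_representation_scenario",
    "db_overlap",
]


@dataclass(frozen=True)
class SeqRecord:
    """One annotated reference sequence (a 16S gene or a genome)."""

    record_id: str
    sequence: str
    marker: str  # "16S" or "genome"
    species: str
    genus: str
    family: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidParameterError(f"empty sequence for {self.record_id}")
        bad = set(self.sequence.upper()) - IUPAC_ALPHABET
        if bad:
            raise InvalidParameterError(
                f"non-IUPAC characters {sorted(bad)} in {self.record_id}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceDatabase:
    """A collection of reference records sharing one marker type.

    A species may carry several records; read simulation picks uniformly
    among them so no single deposited sequence dominates.
    """

    records: list[SeqRecord]
    marker: str
    provenance: str = ""

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.marker != self.marker:
                raise InvalidParameterError(
                    f"record {rec.record_id} has marker {rec.marker}, "
                    f"database is {self.marker}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def taxa(self, level: str) -> set[str]:
        if level not in ("species", "genus", "family"):
            raise InvalidParameterError(f"unknown rank {level!r}")
        return {getattr(r, level) for r in self.records}

    def records_for_species(self, species: str) -> list[SeqRecord]:
        return [r for r in self.records if r.species == species]

    def subset_by_taxa(self, level: str, keep: set[str],
                       provenance: str = "") -> "ReferenceDatabase":
        records = [r for r in self.records if getattr(r, level) in keep]
        return ReferenceDatabase(records, self.marker,
                                 provenance or f"{self.provenance}|subset:{level}")


@dataclass
class ScenarioSpec:
    """Manifest of one incompleteness/representation scenario."""

    representation: float
    variant: str
    removal_level: str
    removed_taxa: list[str] = field(default_factory=list)
    achieved_fraction: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioSpec":
        return cls(**json.loads(text))


def read_fasta_db(path: str | Path, taxonomy_path: str | Path,
                  marker: str) -> ReferenceDatabase:
    """Load a FASTA plus sidecar taxonomy TSV (record_id, species, genus, family).

    Every FASTA ID must appear in the taxonomy table; unannotated IDs are a
    hard error listing the offenders.
    """
    tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str)
    required = {"record_id", "species", "genus", "family"}
    if not required <= set(tax.columns):
        raise InvalidParameterError(
            f"taxonomy table must have columns {sorted(required)}"
        )
    by_id = tax.set_index("record_id")
    records: list[SeqRecord] = []
    missing: list[str] = []
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id not in by_id.index:
            missing.append(bio.id)
            continue
        row = by_id.loc[bio.id]
        records.append(SeqRecord(
            record_id=bio.id, sequence=str(bio.seq).upper(), marker=marker,
            species=row["species"], genus=row["genus"], family=row["family"],
        ))
    if missing:
        raise VmbenchError(
            f"FASTA IDs missing from taxonomy table: {', '.join(missing)}"
        )
    if not records:
        warnings.warn(f"no records read from {path}", stacklevel=2)
    return ReferenceDatabase(records, marker, provenance=str(path))


def write_fasta_db(db: ReferenceDatabase, fasta_path: str | Path,
                   taxonomy_path: str | Path) -> None:
    """Write the database as FASTA plus taxonomy TSV (round-trip of read_fasta_db)."""
    bios = [
        BioSeqRecord(Seq(r.sequence), id=r.record_id, description="")
        for r in db.records
    ]
    SeqIO.write(bios, str(fasta_path), "fasta")
    pd.DataFrame(
        [(r.record_id, r.species, r.genus, r.family) for r in db.records],
        columns=["record_id", "species", "genus", "family"],
    ).to_csv(taxonomy_path, sep="\t", index=False)


def make_incomplete_db(db: ReferenceDatabase, level: str, fraction_removed: float,
                       rng: np.random.Generator) -> tuple[ReferenceDatabase, ScenarioSpec]:
    """Delete floor(fraction * count) taxa at a rank, records and all.

    Removing a family removes every genus and species under it (records
    carry their full lineage, so the cascade is automatic). The removed
    taxa are chosen by a seeded shuffle and reported in the manifest.
    """
    if not 0 <= fraction_removed < 1:
        raise InvalidParameterError("fraction_removed must be in [0, 1)")
    taxa = sorted(db.taxa(level))
    n_remove = int(np.floor(fraction_removed * len(taxa)))
    if n_remove == 0:
        spec = ScenarioSpec(1.0, "complete", level, [])
        return ReferenceDatabase(list(db.records), db.marker, db.provenance), spec
    if n_remove >= len(taxa):
        raise VmbenchError("removal would empty the database")
    removed = sorted(rng.permutation(taxa)[:n_remove].tolist())
    keep = set(taxa) - set(removed)
    reduced = db.subset_by_taxa(level, keep)
    if not reduced.records:
        raise VmbenchError("removal would empty the database")
    spec = ScenarioSpec(1.0 - fraction_removed, "random", level, removed)
    return reduced, spec


def build_representation_scenario(
    vm: VirtualMicrobiome, db: ReferenceDatabase, target_fraction: float,
    tolerance: float = 0.10,
) -> list[tuple[ReferenceDatabase, ScenarioSpec]]:
    """Build databases whose retained families cover ~target_fraction of abundance.

    Enumerates family subsets (exhaustively up to 20 families, greedily
    beyond) and keeps those whose cumulative mean abundance in ``vm`` is
    closest to ``target_fraction``; returns 2 variants (A, B) for the 50%
    target and 4 (A-D) for 25%, ordered by |achieved - target|.
    """
    if target_fraction not in (0.5, 0.25):
        raise InvalidParameterError("target_fraction must be 0.5 or 0.25")
    k = 2 if target_fraction == 0.5 else 4
    fam_matrix = aggregate_abundance(vm, "family")
    mean_ab = dict(zip(fam_matrix.taxon_ids, fam_matrix.values.mean(axis=0)))
    db_families = sorted(db.taxa("family"))
    missing = set(mean_ab) - set(db_families)
    if missing:
        raise VmbenchError(
            f"microbiome families absent from database: {sorted(missing)}"
        )
    families = sorted(mean_ab)
    n = len(families)

    candidates: list[tuple[float, frozenset[str]]] = []
    if n <= 20:
        for r in range(1, n):
            for keep in itertools.combinations(families, r):
                achieved = sum(mean_ab[f] for f in keep)
                candidates.append((achieved, frozenset(keep)))
    else:
        # greedy: grow subsets from each single family toward the target
        for start in families:
            keep = {start}
            achieved = mean_ab[start]
            rest = sorted(set(families) - keep, key=lambda f: -mean_ab[f])
            for f in rest:
                if achieved + mean_ab[f] <= target_fraction + tolerance:
                    keep.add(f)
                    achieved += mean_ab[f]
            candidates.append((achieved, frozenset(keep)))

    scored = sorted(
        {fs: ach for ach, fs in candidates}.items(),
        key=lambda item: (abs(item[1] - target_fraction), sorted(item[0])),
    )
    within = [(fs, ach) for fs, ach in scored
              if abs(ach - target_fraction) <= tolerance]
    if not within:
        best = scored[0][1] if scored else float("nan")
        raise VmbenchError(
            f"no family subset within {tolerance:.0%} of target "
            f"{target_fraction:.0%}; closest achievable is {best:.1%}"
        )
    out: list[tuple[ReferenceDatabase, ScenarioSpec]] = []
    for (keep, achieved), variant in zip(within[:k], "ABCD"):
        removed = sorted(set(families) - keep)
        reduced = db.subset_by_taxa("family", set(keep))
        spec = ScenarioSpec(target_fraction, variant, "family", removed,
                            achieved_fraction=float(achieved))
        out.append((reduced, spec))
    return out


def db_overlap(db_a: ReferenceDatabase, db_b: ReferenceDatabase,
               level: str) -> tuple[int, int, int]:
    """Shared / A-only / B-only counts of distinct taxon labels at a rank."""
    a, b = db_a.taxa(level), db_b.taxa(level)
    return len(a & b), len(a - b), len(b - a)
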