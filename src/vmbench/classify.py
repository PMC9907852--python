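"""Taxonomic classification of simulated reads.

The built-in classifier is a deliberately simple exact k-mer best-hit
scheme with lowest-common-ancestor tie resolution. It exists so the whole
benchmark loop (generate -> sequence -> classify -> evaluate) runs offline
and its failure modes are fully understood; it is not a reimplementation
of any production profiler. Results from external tools can be imported
as abundance tables instead and scored with the same metric suite.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from vmbench._errors import InvalidParameterError, VmbenchError
from vmbench.readsim import ReadSet, reverse_complement
from vmbench.refdb import ReferenceDatabase

__all__ = [
    "KmerIndex",
    "Assignment",
    "ClassificationResult",
    "build_kmer_index",
    "classify_pair",
    "classify_readset",
    "profile_from_assignments",
    "import_abundance_table",
]

RANKS = ("species", "genus", "family")


def _canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerIndex:
    """Canonical k-mer postings over a reference database.

    ``postings`` maps each canonical k-mer to the set of species whose
    records contain it (either strand); ``taxonomy`` carries each indexed
    species' genus and family so ties can fall back to an LCA rank.
    """

    k: int
    postings: dict[str, frozenset[str]]
    taxonomy: dict[str, tuple[str, str]]  # species -> (genus, family)
    db_manifest: str = ""

    @property
    def species(self) -> set[str]:
        return set(self.taxonomy)


def build_kmer_index(db: ReferenceDatabase, k: int = 31) -> KmerIndex:
    """Index every canonical k-mer of every record in the database.

    k = 31 (default) gives species-level specificity on the synthetic
    universe; values below ~11 are only useful for toy inspection.
    """
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    if not db.records:
        raise VmbenchError("cannot index an empty database")
    shortest = min(len(r.sequence) for r in db.records)
    if k > shortest:
        raise InvalidParameterError(
            f"k={k} exceeds the shortest record ({shortest} bp)"
        )
    postings: dict[str, set[str]] = {}
    taxonomy: dict[str, tuple[str, str]] = {}
    for rec in db.records:
        taxonomy[rec.species] = (rec.genus, rec.family)
        seq = rec.sequence.upper()
        for i in range(len(seq) - k + 1):
            kmer = _canonical(seq[i:i + k])
            postings.setdefault(kmer, set()).add(rec.species)
    frozen = {kmer: frozenset(sps) for kmer, sps in postings.items()}
    return KmerIndex(k=k, postings=frozen, taxonomy=taxonomy,
                     db_manifest=db.provenance)


@dataclass(frozen=True)
class Assignment:
    """Rank-resolved call for one read pair."""

    rank: str  # "species", "genus", "family" or "unclassified"
    taxon: str  # empty when unclassified


UNCLASSIFIED = Assignment("unclassified", "")


def _pair_hits(seq1: str, seq2: str, index: KmerIndex) -> Counter:
    hits: Counter = Counter()
    k = index.k
    postings = index.postings
    for seq in (seq1, seq2):
        seen: set[str] = set()
        for i in range(len(seq) - k + 1):
            kmer = _canonical(seq[i:i + k])
            if kmer in seen:
                continue
            seen.add(kmer)
            sps = postings.get(kmer)
            if sps:
                for sp in sps:
                    hits[sp] += 1
    return hits


def classify_pair(seq1: str, seq2: str, index: KmerIndex,
                  min_hits: int = 10) -> Assignment:
    """Assign a read pair by k-mer vote.

    The species with the most distinct k-mer hits over both mates wins if
    it reaches ``min_hits`` and strictly beats the runner-up; tied top
    species collapse to their lowest common ancestor (genus if they share
    one, else family, else unclassified). No hits -> unclassified.
    """
    hits = _pair_hits(seq1, seq2, index)
    if not hits:
        return UNCLASSIFIED
    best = max(hits.values())
    if best < min_hits:
        return UNCLASSIFIED
    top = [sp for sp, n in hits.items() if n == best]
    if len(top) == 1:
        return Assignment("species", top[0])
    genera = {index.taxonomy[sp][0] for sp in top}
    if len(genera) == 1:
        return Assignment("genus", genera.pop())
    families = {index.taxonomy[sp][1] for sp in top}
    if len(families) == 1:
        return Assignment("family", families.pop())
    return UNCLASSIFIED


@dataclass
class ClassificationResult:
    """Per-read assignments and/or per-taxon abundance profiles.

    ``profile[rank]`` maps taxon -> estimated relative abundance over the
    classified reads (unclassified reads are excluded from the simplex).
    Imported results carry profiles only; ``assignments`` is None then.
    """

    method_tag: str
    assignments: dict[str, Assignment] | None = None  # pair_id -> Assignment
    profiles: dict[str, dict[str, float]] = field(default_factory=dict)
    taxonomy: dict[str, tuple[str, str]] | None = None

    def detected_taxa(self, rank: str) -> set[str]:
        return {t for t, a in self.profiles.get(rank, {}).items() if a > 0}


def _ancestor(taxon_rank: str, taxon: str, target_rank: str,
              taxonomy: dict[str, tuple[str, str]]) -> str | None:
    """Name of ``taxon``'s ancestor at ``target_rank``, None if above it."""
    order = {r: i for i, r in enumerate(RANKS)}
    if order[taxon_rank] > order[target_rank]:
        return None  # assignment is less specific than the requested rank
    if taxon_rank == target_rank:
        return taxon
    if taxon_rank == "species":
        genus, family = taxonomy[taxon]
        return genus if target_rank == "genus" else family
    if taxon_rank == "genus":
        for genus, family in taxonomy.values():
            if genus == taxon:
                return family
    return None


def profile_from_assignments(result: ClassificationResult,
                             rank: str) -> dict[str, float]:
    """Relative abundance per taxon at a rank from per-read assignments.

    Counts at the requested rank include reads assigned exactly there and
    reads assigned deeper (a species call contributes to its genus and
    family); shallower calls cannot be placed and are skipped.
    """
    if rank not in RANKS:
        raise InvalidParameterError(f"unknown rank {rank!r}")
    if result.assignments is None:
        raise VmbenchError("result carries no per-read assignments")
    if result.taxonomy is None:
        raise VmbenchError("result carries no taxonomy for rank roll-up")
    counts: Counter = Counter()
    for assignment in result.assignments.values():
        if assignment.rank == "unclassified":
            continue
        name = _ancestor(assignment.rank, assignment.taxon, rank,
                         result.taxonomy)
        if name is not None:
            counts[name] += 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {t: n / total for t, n in counts.items()}


def classify_readset(rs: ReadSet, index: KmerIndex,
                     min_hits: int = 10) -> ClassificationResult:
    """Classify every pair of a read set and build profiles at all ranks."""
    assignments = {
        p.pair_id: classify_pair(p.seq1, p.seq2, index, min_hits=min_hits)
        for p in rs.pairs
    }
    result = ClassificationResult(
        method_tag="builtin",
        assignments=assignments,
        taxonomy=dict(index.taxonomy),
    )
    result.profiles = {rank: profile_from_assignments(result, rank)
                       for rank in RANKS}
    return result


# ---- import of external abundance tables ---------------------------------

_KRAKEN_RANK = {"S": "species", "G": "genus", "F": "family"}


def _import_generic_tsv(path: Path) -> dict[str, dict[str, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"taxon": str, "rank": str})
    required = {"taxon", "rank", "count"}
    if not required <= set(df.columns):
        raise VmbenchError(
            f"generic table needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    profiles: dict[str, dict[str, float]] = {}
    for i, row in df.iterrows():
        rank = str(row["rank"]).lower()
        if rank == "unclassified":
            continue
        if rank not in RANKS:
            raise VmbenchError(f"row {i + 2}: unknown rank {row['rank']!r}")
        try:
            count = float(row["count"])
        except (TypeError, ValueError) as exc:
            raise VmbenchError(f"row {i + 2}: bad count {row['count']!r}") from exc
        profiles.setdefault(rank, {})
        profiles[rank][str(row["taxon"])] = (
            profiles[rank].get(str(row["taxon"]), 0.0) + count
        )
    for rank, prof in profiles.items():
        total = sum(prof.values())
        if total > 0:
            profiles[rank] = {t: c / total for t, c in prof.items()}
    return profiles


def _import_kraken2_report(path: Path) -> dict[str, dict[str, float]]:
    """Parse the 6-column kraken2-style report (direct counts per taxon)."""
    profiles: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise VmbenchError(f"{path}: line {lineno}: expected 6 columns")
            _, _, direct, rank_code, _, name = parts[:6]
            rank = _KRAKEN_RANK.get(rank_code.strip()[:1])
            if rank is None:
                continue  # other ranks (D, P, C, O, U...) are not evaluated
            try:
                count = float(direct)
            except ValueError as exc:
                raise VmbenchError(
                    f"{path}: line {lineno}: bad count {direct!r}") from exc
            if count <= 0:
                continue
            profiles.setdefault(rank, {})
            taxon = name.strip()
            profiles[rank][taxon] = profiles[rank].get(taxon, 0.0) + count
    for rank, prof in profiles.items():
        total = sum(prof.values())
        profiles[rank] = {t: c / total for t, c in prof.items()}
    return profiles


def import_abundance_table(path: str | Path,
                           dialect: str = "generic_tsv") -> ClassificationResult:
    """Load an externally produced abundance table for auditing.

    ``generic_tsv`` expects columns (taxon, rank, count); ``kraken2_report``
    the standard 6-column report, using direct (not clade) counts at
    species/genus/family ranks. Imported profiles are normalized over
    classified rows only and otherwise trusted as-is; per-read assignments
    are not available for imported results.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise VmbenchError(f"abundance table {path} is missing or empty")
    if dialect == "generic_tsv":
        profiles = _import_generic_tsv(path)
    elif dialect == "kraken2_report":
        profiles = _import_kraken2_report(path)
    else:
        raise InvalidParameterError(f"unknown dialect {dialect!r}")
    return ClassificationResult(
        method_tag=f"imported:{path.name}", assignments=None, profiles=profiles
    )
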