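"""In-silico sequencing of virtual microbiomes.

Two modes mirror common Illumina workflows:

* **amplicon** -- the 16S V3-V4 region is located by in-silico PCR with
  degenerate primers, 300 bp paired reads are drawn from ~550 bp inserts
  (50 bp mate overlap), unidirectionally;
* **wgs** -- 150 bp paired reads from ~400 bp inserts anywhere on the
  genome, both strands.

Reads per species are proportional to abundance. Species whose 16S gene
fails PCR contribute no amplicon reads; their share is redistributed over
the amplifiable species according to the abundance distribution, so total
depth is conserved. Sequencing errors (substitutions, insertions,
deletions) occur at per-position rates following a 4th-degree polynomial
in the cycle number, emulating the error ramp-up along Illumina reads;
qualities are two-level, good (Q30) except at introduced substitutions or
insertions (Q10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from vmbench._errors import (
    DegenerateInputError,
    InvalidParameterError,
    VmbenchError,
)
from vmbench.refdb import ReferenceDatabase, SeqRecord

__all__ = [
    "ReadSimConfig",
    "PrimerPair",
    "ReadPair",
    "ReadSet",
    "V3V4_PRIMERS",
    "reverse_complement",
    "allocate_reads",
    "in_silico_pcr",
    "redistribute_failed",
    "sample_fragment",
    "make_pair",
    "apply_poly4_errors",
    "simulate_reads",
    "write_fastq",
    "read_fastq",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """Degenerate PCR primers; both given 5'->3' on their own strands."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p:
                raise InvalidParameterError(f"{name} primer is empty")
            bad = set(p.upper()) - set(IUPAC_SETS)
            if bad:
                raise InvalidParameterError(
                    f"{name} primer has non-IUPAC characters {sorted(bad)}"
                )


#: Standard V3-V4 16S primers (341F / 805R).
V3V4_PRIMERS = PrimerPair(forward="CCTACGGGNGGCWGCAG",
                          reverse="GGACTACHVGGGTATCTAATCC")


@dataclass
class ReadSimConfig:
    """Sequencing-run parameters.

    Amplicon defaults: 300 bp reads, 550 +- 55 bp inserts, unidirectional.
    WGS defaults: 150 bp reads, 400 +- 40 bp inserts, bidirectional.
    ``error_a``/``error_b`` are the polynomial error-rate coefficients in
    percent: rate(i) = (error_a + error_b * i^4) / 100 at 1-based cycle i,
    clamped to [0, 1]. ``total_reads`` counts read PAIRS.
    """

    mode: str = "amplicon"
    total_reads: int = 100_000
    read_length: int = 300
    insert_mean: float = 550.0
    insert_sd: float = 55.0
    orientation: str = "unidirectional"
    qual_good: int = 30
    qual_bad: int = 10
    error_a: float = 3e-3
    error_b: float = 3.3e-8
    error_ratio: tuple[float, float, float] = (0.8, 0.1, 0.1)  # sub/ins/del
    max_mismatches: int = 0
    seed: int | None = None

    @classmethod
    def amplicon(cls, **kw) -> "ReadSimConfig":
        return cls(mode="amplicon", **kw)

    @classmethod
    def wgs(cls, **kw) -> "ReadSimConfig":
        defaults = dict(mode="wgs", total_reads=60_000, read_length=150,
                        insert_mean=400.0, insert_sd=40.0,
                        orientation="bidirectional")
        defaults.update(kw)
        return cls(**defaults)

    def validate(self) -> None:
        if self.mode not in ("amplicon", "wgs"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if self.total_reads < 1:
            raise InvalidParameterError("total_reads must be >= 1")
        if self.read_length > self.insert_mean:
            raise InvalidParameterError("read_length must be <= insert_mean")
        if self.orientation not in ("unidirectional", "bidirectional"):
            raise InvalidParameterError(f"bad orientation {self.orientation!r}")
        if abs(sum(self.error_ratio) - 1.0) > 1e-9 or min(self.error_ratio) < 0:
            raise InvalidParameterError("error_ratio must be a 3-way simplex")

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["error_ratio"] = list(self.error_ratio)
        return d


@dataclass
class ReadPair:
    """One simulated pair with its true source."""

    pair_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    species: str
    record_id: str
    start: int = -1
    end: int = -1
    strand: str = "+"


@dataclass
class ReadSet:
    """A collection of simulated read pairs with per-pair truth labels."""

    pairs: list[ReadPair]
    config: ReadSimConfig | None = None

    def __len__(self) -> int:
        return len(self.pairs)

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.pair_id, p.species, p.record_id, p.start, p.end, p.strand)
             for p in self.pairs],
            columns=["pair_id", "species", "record_id", "start", "end", "strand"],
        )

    def sampled_species(self) -> set[str]:
        return {p.species for p in self.pairs}


# ---- allocation ---------------------------------------------------------


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    floors = np.floor(quotas).astype(int)
    short = total - int(floors.sum())
    if short > 0:
        remainders = quotas - floors
        order = np.argsort(-remainders, kind="stable")
        floors[order[:short]] += 1
    return floors


def allocate_reads(abundances: np.ndarray, total_reads: int,
                   method: str = "largest_remainder",
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Integer read counts per species, proportional to abundance.

    ``largest_remainder`` (default) is deterministic and conserves the
    total exactly; ``multinomial`` draws counts stochastically, modelling
    the sampling noise of a real sequencing run (requires ``rng``).
    """
    ab = np.asarray(abundances, dtype=float)
    if ab.size == 0:
        raise InvalidParameterError("empty abundance vector")
    if np.any(ab < 0) or ab.sum() <= 0:
        raise InvalidParameterError("abundances must be non-negative, sum > 0")
    if total_reads < 1:
        raise InvalidParameterError("total_reads must be >= 1")
    p = ab / ab.sum()
    if method == "largest_remainder":
        return _largest_remainder(p * total_reads, total_reads)
    if method == "multinomial":
        if rng is None:
            raise InvalidParameterError("multinomial allocation needs an rng")
        return rng.multinomial(total_reads, p)
    raise InvalidParameterError(f"unknown allocation method {method!r}")


# ---- in-silico PCR ------------------------------------------------------


def _match_at(seq: str, pos: int, primer_sets: list[frozenset[str]],
              max_mm: int) -> bool:
    mm = 0
    for offset, allowed in enumerate(primer_sets):
        if seq[pos + offset] not in allowed:
            mm += 1
            if mm > max_mm:
                return False
    return True


def _find_primer(seq: str, primer_sets: list[frozenset[str]], max_mm: int,
                 start: int = 0) -> int:
    """First position >= start where the primer matches, or -1."""
    span = len(primer_sets)
    for pos in range(start, len(seq) - span + 1):
        if _match_at(seq, pos, primer_sets, max_mm):
            return pos
    return -1


def _primer_sets(primer: str) -> list[frozenset[str]]:
    return [IUPAC_SETS[c] for c in primer.upper()]


def in_silico_pcr(seq: str, primers: PrimerPair,
                  max_mismatches: int = 0) -> tuple[int, int] | None:
    """Locate the amplicon bracketed by a degenerate primer pair.

    The forward primer is matched on the given strand (5'-most hit wins);
    the reverse primer, supplied 5'->3' on the opposite strand, is matched
    as its reverse complement downstream of the forward site (nearest hit).
    Degeneracy is honoured on the primer side only: a sequence base matches
    iff it belongs to the primer symbol's IUPAC set. Returns the 0-based
    half-open interval spanning both primer sites, or None if either site
    is absent (amplification failure is a value, not an error).
    """
    seq = seq.upper()
    fwd = _primer_sets(primers.forward)
    rev = _primer_sets(reverse_complement(primers.reverse))
    if len(seq) < len(fwd) + len(rev):
        return None
    fwd_start = _find_primer(seq, fwd, max_mismatches)
    if fwd_start < 0:
        return None
    rev_start = _find_primer(seq, rev, max_mismatches, start=fwd_start + len(fwd))
    if rev_start < 0:
        return None
    return fwd_start, rev_start + len(rev)


def redistribute_failed(counts: np.ndarray, abundances: np.ndarray,
                        amplifiable: np.ndarray) -> np.ndarray:
    """Reassign reads of non-amplifiable species to amplifiable ones.

    The failed species' total is split over amplifiable species in
    proportion to their abundances (largest-remainder rounding), conserving
    the overall read count; failed species end at zero.
    """
    counts = np.asarray(counts, dtype=int)
    ab = np.asarray(abundances, dtype=float)
    ok = np.asarray(amplifiable, dtype=bool)
    if counts.shape != ab.shape or counts.shape != ok.shape:
        raise InvalidParameterError("counts/abundances/flags length mismatch")
    if ok.all():
        return counts.copy()
    if not ok.any():
        raise VmbenchError("no amplifiable species to receive redistributed reads")
    total = int(counts.sum())
    failed_total = int(counts[~ok].sum())
    share = ab[ok] / ab[ok].sum()
    quotas = counts[ok] + share * failed_total
    out = np.zeros_like(counts)
    out[ok] = _largest_remainder(quotas, total)
    return out


# ---- fragments, pairs, errors -------------------------------------------


def sample_fragment(record: SeqRecord, config: ReadSimConfig,
                    region: tuple[int, int] | None,
                    rng: np.random.Generator) -> tuple[int, int, str]:
    """Draw one fragment (insert) inside a region of the record.

    Insert length ~ Normal(insert_mean, insert_sd), clamped to
    [read_length, region length]; start uniform; strand forward when
    unidirectional, fair coin otherwise. Returns (start, end, strand) in
    record coordinates.
    """
    lo, hi = region if region is not None else (0, len(record.sequence))
    region_len = hi - lo
    if region_len < config.read_length:
        raise DegenerateInputError(
            f"region of {record.record_id} shorter than read length"
        )
    insert = int(round(rng.normal(config.insert_mean, config.insert_sd)))
    insert = max(config.read_length, min(insert, region_len))
    start = lo + int(rng.integers(0, region_len - insert + 1))
    if config.orientation == "unidirectional":
        strand = "+"
    else:
        strand = "+" if rng.integers(0, 2) == 0 else "-"
    return start, start + insert, strand


def make_pair(fragment: str, config: ReadSimConfig) -> tuple[str, str]:
    """Mates from a fragment: mate1 its 5' end, mate2 the reverse
    complement of its 3' end; a 550 bp fragment with 300 bp reads gives a
    50 bp mate overlap (2L - fragment length)."""
    L = config.read_length
    if len(fragment) < L:
        raise InvalidParameterError("fragment shorter than read length")
    return fragment[:L], reverse_complement(fragment[-L:])


def _error_probabilities(length: int, config: ReadSimConfig) -> np.ndarray:
    i = np.arange(1, length + 1, dtype=float)
    return np.clip((config.error_a + config.error_b * i**4) / 100.0, 0.0, 1.0)


def _draw_error_positions(length: int, config: ReadSimConfig,
                          rng: np.random.Generator) -> np.ndarray:
    return np.flatnonzero(rng.random(length) < _error_probabilities(length, config))


_BASES = "ACGT"


_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def apply_poly4_errors(read: str, config: ReadSimConfig,
                       rng: np.random.Generator) -> tuple[str, str]:
    """Mutate a read under the polynomial Illumina error model.

    Each 1-based position i errs with probability
    (error_a + error_b * i^4)/100; an error is a substitution, insertion
    or deletion with the configured ratio. Positions carrying a
    substitution or insertion get ``qual_bad``, all others ``qual_good``;
    the read is re-trimmed (or padded with random bad-quality bases) to the
    configured read length after indels.
    """
    if not read:
        raise InvalidParameterError("empty read")
    L = config.read_length
    good, bad = np.uint8(config.qual_good + 33), np.uint8(config.qual_bad + 33)
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    quals = np.full(len(arr), good, dtype=np.uint8)

    err_pos = _draw_error_positions(len(read), config, rng)
    p_sub, p_ins, _ = config.error_ratio
    if err_pos.size:
        u = rng.random(err_pos.size)
        sub_pos = err_pos[u < p_sub]
        ins_pos = err_pos[(u >= p_sub) & (u < p_sub + p_ins)]
        del_pos = err_pos[u >= p_sub + p_ins]
        if sub_pos.size:
            # shift within ACGT by 1-3: always a different base
            cur = np.searchsorted(_BASE_ARR, arr[sub_pos])
            cur[cur > 3] = 0  # non-ACGT template bases: substitute from A
            shift = rng.integers(1, 4, size=sub_pos.size)
            arr[sub_pos] = _BASE_ARR[(cur + shift) % 4]
            quals[sub_pos] = bad
    else:
        ins_pos = del_pos = np.empty(0, dtype=int)

    if ins_pos.size or del_pos.size:
        # splice segments around indels, left to right
        events = sorted([(int(p), "I") for p in ins_pos] +
                        [(int(p), "D") for p in del_pos])
        seg_a: list[np.ndarray] = []
        seg_q: list[np.ndarray] = []
        prev = 0
        ins_bases = _BASE_ARR[rng.integers(0, 4, size=len(events))]
        for n_ev, (pos, kind) in enumerate(events):
            seg_a.append(arr[prev:pos])
            seg_q.append(quals[prev:pos])
            if kind == "I":  # random base inserted before the template base
                seg_a.append(ins_bases[n_ev:n_ev + 1])
                seg_q.append(np.array([bad], dtype=np.uint8))
                prev = pos
            else:  # deletion: skip the template base
                prev = pos + 1
        seg_a.append(arr[prev:])
        seg_q.append(quals[prev:])
        arr = np.concatenate(seg_a)
        quals = np.concatenate(seg_q)

    if len(arr) < L:
        pad = L - len(arr)
        arr = np.concatenate([arr, _BASE_ARR[rng.integers(0, 4, size=pad)]])
        quals = np.concatenate([quals, np.full(pad, bad, dtype=np.uint8)])
    return arr[:L].tobytes().decode(), quals[:L].tobytes().decode()


# ---- full simulation ----------------------------------------------------


def _usable_records(
    db: ReferenceDatabase, species: list[str], config: ReadSimConfig,
    primers: PrimerPair | None,
) -> dict[str, list[tuple[SeqRecord, tuple[int, int] | None]]]:
    """Per species, the records a fragment can be drawn from.

    Amplicon mode: records whose in-silico PCR succeeds with an amplicon at
    least one read long. WGS mode: records at least one read long.
    """
    by_species: dict[str, list[SeqRecord]] = {}
    for rec in db.records:
        by_species.setdefault(rec.species, []).append(rec)
    usable: dict[str, list[tuple[SeqRecord, tuple[int, int] | None]]] = {}
    for sp in species:
        entries: list[tuple[SeqRecord, tuple[int, int] | None]] = []
        for rec in by_species.get(sp, []):
            if config.mode == "amplicon":
                if primers is None:
                    raise InvalidParameterError("amplicon mode needs primers")
                interval = in_silico_pcr(rec.sequence, primers,
                                         config.max_mismatches)
                if interval and interval[1] - interval[0] >= config.read_length:
                    entries.append((rec, interval))
            else:
                if len(rec.sequence) >= config.read_length:
                    entries.append((rec, None))
        usable[sp] = entries
    return usable


def simulate_reads(vm, community_index: int, db: ReferenceDatabase,
                   config: ReadSimConfig,
                   primers: PrimerPair | None = None,
                   rng: np.random.Generator | None = None) -> ReadSet:
    """Simulate one community's sequencing run against the complete universe.

    Pipeline: allocate reads by abundance -> (amplicon: in-silico PCR per
    record, redistribute reads of non-amplifying species) -> per read pick
    a usable record uniformly -> sample a fragment -> build the mate pair
    -> apply the polynomial error model. Emits exactly
    ``config.total_reads`` pairs, each labelled with its true source.

    The generation database must cover every species with a nonzero
    allocation; incomplete databases belong to classification, not here.
    """
    config.validate()
    if config.mode == "amplicon" and primers is None:
        primers = V3V4_PRIMERS
    if rng is None:
        rng = np.random.default_rng(config.seed)

    species = list(vm.species_ids)
    abundances = np.asarray(vm.community(community_index), dtype=float)
    counts = allocate_reads(abundances, config.total_reads)

    present = [sp for sp, c in zip(species, counts) if c > 0]
    by_species: dict[str, list] = {r.species: None for r in db.records}
    missing = [sp for sp in present if sp not in by_species]
    if missing:
        raise VmbenchError(
            "species without any reference record (generation universe must "
            f"be complete): {', '.join(missing[:5])}"
        )

    usable = _usable_records(db, species, config, primers)
    ok = np.array([len(usable[sp]) > 0 for sp in species])
    if not ok.all() and counts[~ok].sum() > 0:
        if config.mode == "wgs":
            warnings.warn(
                "species with no record long enough for WGS reads; "
                "their reads were redistributed", stacklevel=2)
        counts = redistribute_failed(counts, abundances, ok)

    pairs: list[ReadPair] = []
    n_pair = 0
    for sp_idx, sp in enumerate(species):
        c = int(counts[sp_idx])
        if c == 0:
            continue
        entries = usable[sp]
        picks = rng.integers(0, len(entries), size=c)
        for pick in picks:
            rec, interval = entries[int(pick)]
            start, end, strand = sample_fragment(rec, config, interval, rng)
            fragment = rec.sequence[start:end]
            if strand == "-":
                fragment = reverse_complement(fragment)
            m1, m2 = make_pair(fragment, config)
            s1, q1 = apply_poly4_errors(m1, config, rng)
            s2, q2 = apply_poly4_errors(m2, config, rng)
            pairs.append(ReadPair(
                pair_id=f"pair{n_pair:06d}|{sp}|{rec.record_id}",
                seq1=s1, qual1=q1, seq2=s2, qual2=q2,
                species=sp, record_id=rec.record_id,
                start=start, end=end, strand=strand,
            ))
            n_pair += 1
    return ReadSet(pairs, config=config)


# ---- FASTQ IO -----------------------------------------------------------


def write_fastq(rs: ReadSet, path_r1: str | Path, path_r2: str | Path) -> None:
    """Write paired Phred+33 FASTQ; truth labels ride in the read IDs."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for p in rs.pairs:
            f1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def _parse_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    out = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise VmbenchError(f"{path}: truncated FASTQ near line {len(lines)}")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i:i + 4]
        if not header.startswith("@") or not plus.startswith("+"):
            raise VmbenchError(f"{path}: malformed FASTQ record at line {i + 1}")
        if len(seq) != len(qual):
            raise VmbenchError(
                f"{path}: sequence/quality length mismatch at line {i + 1}")
        out.append((header[1:], seq, qual))
    return out


def read_fastq(path_r1: str | Path, path_r2: str | Path) -> ReadSet:
    """Read a pair of FASTQ files written by :func:`write_fastq`."""
    r1, r2 = _parse_fastq(path_r1), _parse_fastq(path_r2)
    if len(r1) != len(r2):
        raise VmbenchError("R1 and R2 have different numbers of records")
    pairs = []
    for (h1, s1, q1), (h2, s2, q2) in zip(r1, r2):
        pid = h1.split()[0].rsplit("/", 1)[0]
        fields = pid.split("|")
        species = fields[1] if len(fields) >= 3 else "unknown"
        record_id = fields[2] if len(fields) >= 3 else "unknown"
        pairs.append(ReadPair(pair_id=pid, seq1=s1, qual1=q1, seq2=s2, qual2=q2,
                              species=species, record_id=record_id))
    return ReadSet(pairs)
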