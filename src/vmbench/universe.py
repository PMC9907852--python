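"""Synthesis of a self-contained reference sequence universe.

Real benchmarks draw 16S genes and genomes from public databases; here the
whole universe is generated so every pipeline stage runs offline with exact
ground truth. Sequences diverge hierarchically -- a root per family, genus
ancestors mutated from it, species sequences mutated from those -- under
independent per-site substitution (no indels, so primer offsets and
amplicon coordinates stay exact). Each 16S gene carries intact V3-V4
primer sites bracketing a ~430 bp variable region, except a configurable
fraction of species whose forward site is deliberately broken, emulating
the amplification failures degenerate primers show on real 16S genes.
Genome records embed the species' 16S gene in random flanking sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from vmbench._errors import InvalidParameterError, VmbenchError
from vmbench.ecology import TaxonomyMap, VirtualMicrobiome, group_taxa
from vmbench.readsim import IUPAC_SETS, PrimerPair, V3V4_PRIMERS
from vmbench.refdb import ReferenceDatabase, SeqRecord

__all__ = ["UniverseSpec", "generate_universe", "bind_ecology_to_universe"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Families whose species typically populate gut microbiome references.
DEFAULT_FAMILY_NAMES = (
    "Clostridiaceae", "Flavobacteriaceae", "Enterococcaceae",
    "Pseudomonadaceae", "Acetobacteraceae", "Lactobacillaceae",
    "Enterobacteriaceae", "Streptococcaceae",
)


@dataclass
class UniverseSpec:
    """Shape and divergence parameters of the synthetic reference universe.

    Divergences are per-site substitution probabilities applied on the step
    from the shared root to family ancestors, family to genus, and genus to
    species; they must decrease down the hierarchy so that within-genus
    sequences are more alike than cross-family ones. ``primer_fail_prob``
    is the chance a species' forward primer site carries enough
    substitutions to resist in-silico PCR.
    """

    n_species: int = 300
    n_genera: int = 40
    n_families: int = 8
    mu_group: float = 0.0
    sigma_group: float = 1.0
    genome_length: int = 100_000
    gene_16s_length: int = 1_500
    divergence_family: float = 0.25
    divergence_genus: float = 0.10
    divergence_species: float = 0.02
    within_species_divergence: float = 0.005
    primer_fail_prob: float = 0.10
    records_per_species: int = 1
    primers: PrimerPair = field(default_factory=lambda: V3V4_PRIMERS)
    forward_offset: int = 80
    variable_region_length: int = 430
    seed: int | None = None

    @classmethod
    def matching(cls, vm: VirtualMicrobiome, **kw) -> "UniverseSpec":
        """A spec whose taxonomy counts match an existing microbiome."""
        p = vm.params
        return cls(n_species=p.n_species, n_genera=p.n_genera,
                   n_families=p.n_families, **kw)

    def validate(self) -> None:
        divs = (self.divergence_family, self.divergence_genus,
                self.divergence_species)
        if not all(0 <= d <= 1 for d in divs):
            raise InvalidParameterError("divergences must be in [0, 1]")
        if not (self.divergence_family >= self.divergence_genus
                >= self.divergence_species):
            raise InvalidParameterError(
                "divergences must decrease family -> genus -> species"
            )
        if not 0 <= self.primer_fail_prob <= 1:
            raise InvalidParameterError("primer_fail_prob must be in [0, 1]")
        if self.records_per_species < 1:
            raise InvalidParameterError("records_per_species must be >= 1")
        if not (self.n_species >= self.n_genera >= self.n_families >= 1):
            raise InvalidParameterError("need n_species >= n_genera >= n_families")
        fwd, rev = len(self.primers.forward), len(self.primers.reverse)
        needed = self.forward_offset + fwd + self.variable_region_length + rev
        if needed > self.gene_16s_length:
            raise InvalidParameterError(
                f"16S layout needs {needed} bp, gene is {self.gene_16s_length}"
            )
        if self.genome_length < self.gene_16s_length:
            raise InvalidParameterError("genome shorter than the 16S gene")

    @property
    def amplicon_interval(self) -> tuple[int, int]:
        """Designed amplicon coordinates within every intact 16S gene."""
        start = self.forward_offset
        end = (start + len(self.primers.forward)
               + self.variable_region_length + len(self.primers.reverse))
        return start, end


def _random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator,
            protected: np.ndarray | None = None) -> np.ndarray:
    """Independent per-site substitution at ``rate``, sparing protected sites."""
    out = seq.copy()
    if rate <= 0:
        return out
    hit = rng.random(len(seq)) < rate
    if protected is not None:
        hit &= ~protected
    idx = np.flatnonzero(hit)
    if idx.size:
        # shift each hit base by 1-3 positions in ACGT: always a real change
        offsets = rng.integers(1, 4, size=idx.size)
        current = np.searchsorted(_BASES, out[idx])
        out[idx] = _BASES[(current + offsets) % 4]
    return out


def _realize_primer(primer: str, rng: np.random.Generator) -> str:
    """One concrete sequence compatible with a degenerate primer."""
    return "".join(
        sorted(IUPAC_SETS[c])[int(rng.integers(0, len(IUPAC_SETS[c])))]
        for c in primer.upper()
    )


def _break_forward_site(gene: np.ndarray, spec: UniverseSpec,
                        rng: np.random.Generator) -> None:
    """Substitute 3 concrete-base primer positions so PCR cannot match."""
    fwd = spec.primers.forward.upper()
    concrete = [i for i, c in enumerate(fwd) if len(IUPAC_SETS[c]) < 4]
    positions = rng.permutation(concrete)[:3]
    for p in positions:
        allowed = {b.encode()[0] for b in IUPAC_SETS[fwd[p]]}
        choices = [b for b in _BASES.tolist() if b not in allowed]
        gene[spec.forward_offset + p] = choices[int(rng.integers(0, len(choices)))]


def generate_universe(
    spec: UniverseSpec, rng: np.random.Generator | None = None,
) -> tuple[ReferenceDatabase, ReferenceDatabase, TaxonomyMap]:
    """Generate the complete 16S and genome databases plus their taxonomy."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    sp_to_ge = group_taxa(spec.n_species, spec.n_genera,
                          spec.mu_group, spec.sigma_group, rng)
    ge_to_fa = group_taxa(spec.n_genera, spec.n_families,
                          spec.mu_group, spec.sigma_group, rng)
    if spec.n_families == len(DEFAULT_FAMILY_NAMES):
        families = list(DEFAULT_FAMILY_NAMES)
    else:
        families = [f"Family{i:02d}" for i in range(spec.n_families)]
    genera = [f"Genus{j:03d}" for j in range(spec.n_genera)]
    species = [f"Species{k:04d}" for k in range(spec.n_species)]
    taxonomy = TaxonomyMap(
        {species[k]: genera[sp_to_ge[k]] for k in range(spec.n_species)},
        {genera[j]: families[ge_to_fa[j]] for j in range(spec.n_genera)},
    )

    # primer sites: one concrete realization, conserved across the universe
    fwd_site = np.frombuffer(
        _realize_primer(spec.primers.forward, rng).encode(), dtype=np.uint8
    ).copy()
    from vmbench.readsim import reverse_complement
    rev_site = np.frombuffer(
        reverse_complement(_realize_primer(spec.primers.reverse, rng)).encode(),
        dtype=np.uint8,
    ).copy()
    a_start, a_end = spec.amplicon_interval
    protected = np.zeros(spec.gene_16s_length, dtype=bool)
    protected[a_start:a_start + len(fwd_site)] = True
    protected[a_end - len(rev_site):a_end] = True

    def stamp_primers(gene: np.ndarray) -> None:
        gene[a_start:a_start + len(fwd_site)] = fwd_site
        gene[a_end - len(rev_site):a_end] = rev_site

    root = _random_seq(spec.gene_16s_length, rng)
    stamp_primers(root)
    fam_anc = {}
    for fam in families:
        fam_anc[fam] = _mutate(root, spec.divergence_family, rng, protected)
    gen_anc = {}
    for j, ge in enumerate(genera):
        fam = families[ge_to_fa[j]]
        gen_anc[ge] = _mutate(fam_anc[fam], spec.divergence_genus, rng, protected)

    fail_set = set(
        np.flatnonzero(rng.random(spec.n_species) < spec.primer_fail_prob)
    )

    recs_16s: list[SeqRecord] = []
    recs_gen: list[SeqRecord] = []
    for k, sp in enumerate(species):
        ge = genera[sp_to_ge[k]]
        fam = families[ge_to_fa[sp_to_ge[k]]]
        base_gene = _mutate(gen_anc[ge], spec.divergence_species, rng, protected)
        if k in fail_set:
            _break_forward_site(base_gene, spec, rng)
        for r in range(spec.records_per_species):
            gene = base_gene if r == 0 else _mutate(
                base_gene, spec.within_species_divergence, rng, protected
            )
            gene_str = gene.tobytes().decode()
            recs_16s.append(SeqRecord(
                record_id=f"{sp}_16S_r{r}", sequence=gene_str, marker="16S",
                species=sp, genus=ge, family=fam,
            ))
            flank_total = spec.genome_length - spec.gene_16s_length
            pos = int(rng.integers(0, flank_total + 1))
            genome = np.concatenate([
                _random_seq(pos, rng), gene,
                _random_seq(flank_total - pos, rng),
            ])
            recs_gen.append(SeqRecord(
                record_id=f"{sp}_gen_r{r}", sequence=genome.tobytes().decode(),
                marker="genome", species=sp, genus=ge, family=fam,
            ))
    db_16s = ReferenceDatabase(recs_16s, "16S", provenance="synthetic-universe-16S")
    db_gen = ReferenceDatabase(recs_gen, "genome",
                               provenance="synthetic-universe-genome")
    return db_16s, db_gen, taxonomy


def bind_ecology_to_universe(vm: VirtualMicrobiome,
                             taxonomy: TaxonomyMap) -> VirtualMicrobiome:
    """Relabel a microbiome with the universe's taxon names.

    The universe taxonomy becomes authoritative (it is what the reference
    databases are annotated with); the microbiome's species are mapped onto
    it in order. Counts at every rank must match. Binding is idempotent.
    """
    uni_species = taxonomy.species
    uni_genera = taxonomy.genera
    uni_families = taxonomy.families
    vm_species = vm.species_ids
    counts_vm = (len(vm_species), len(vm.taxonomy.genera),
                 len(vm.taxonomy.families))
    counts_uni = (len(uni_species), len(uni_genera), len(uni_families))
    if counts_vm != counts_uni:
        raise VmbenchError(
            f"taxonomy shape mismatch: microbiome has {counts_vm} "
            f"(species, genera, families), universe has {counts_uni}"
        )
    if vm_species == uni_species:
        new_matrix = vm.abundances
    else:
        from vmbench.ecology import AbundanceMatrix
        new_matrix = AbundanceMatrix(
            vm.abundances.values.copy(),
            vm.abundances.community_ids,
            list(uni_species),
        )
    new_trends = None
    if vm.trends is not None:
        new_trends = {new: vm.trends[old]
                      for old, new in zip(vm_species, uni_species)}
    return VirtualMicrobiome(
        params=vm.params,
        mad=vm.mad,
        abundances=new_matrix,
        taxonomy=taxonomy,
        alpha_diversity=vm.alpha_diversity,
        alpha_mean=vm.alpha_mean,
        beta=vm.beta,
        taylor_r=vm.taylor_r,
        diversity_class=vm.diversity_class,
        attempts=vm.attempts,
        taylor_skipped=vm.taylor_skipped,
        trends=new_trends,
    )
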