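"""Generation of virtual microbiomes with realistic macroecological structure.

A virtual microbiome is a set of communities (samples) over a fixed species
pool whose abundances obey three empirical laws of microbial macroecology:

* the mean abundance of species across communities follows a lognormal
  distribution (the MAD, mean abundance distribution);
* the abundance of a single species across communities follows a gamma
  distribution (the AFD, abundance fluctuation distribution);
* the per-species variance of abundance scales as a power of its mean
  (Taylor's law), enforced here as a rejection filter on the log-log
  Pearson correlation between means and variances.

Species are nested into genera and genera into families, with group sizes
drawn from lognormal weights, so that classification results can be scored
at any of the three ranks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from vmbench._errors import (
    DegenerateInputError,
    GenerationFailureError,
    InvalidParameterError,
)

SIMPLEX_TOL = 1e-9

__all__ = [
    "EcologyParams",
    "AbundanceMatrix",
    "TaxonomyMap",
    "VirtualMicrobiome",
    "generate_mad",
    "generate_afd",
    "generate_abundance_matrix",
    "test_taylors_law",
    "shannon_alpha",
    "beta_diversity",
    "group_taxa",
    "generate_ecology",
    "aggregate_abundance",
    "perturb_abundances",
]


@dataclass
class EcologyParams:
    """Parameters of the community generator.

    Defaults give a 300-species, 20-community microbiome from a lognormal
    MAD (``mu_mad``, ``sigma_mad``) and a gamma AFD (``shape_afd``,
    ``scale_afd``); the gamma scale cancels under normalization and only
    the shape controls fluctuation strength. ``taylor_r_min`` is the
    acceptance threshold on the Taylor's-law correlation.
    """

    n_species: int = 300
    n_genera: int = 40
    n_families: int = 8
    n_communities: int = 20
    mu_mad: float = 0.0
    sigma_mad: float = 1.5
    shape_afd: float = 2.0
    scale_afd: float = 1.0
    mu_genus: float = 0.0
    sigma_genus: float = 1.0
    mu_family: float = 0.0
    sigma_family: float = 1.0
    taylor_r_min: float = 0.95
    ks_alpha: float = 0.01
    max_attempts: int = 1000
    seed: int | None = None

    def validate(self) -> None:
        if not (self.n_species >= self.n_genera >= self.n_families >= 1):
            raise InvalidParameterError(
                "need n_species >= n_genera >= n_families >= 1, got "
                f"{self.n_species}/{self.n_genera}/{self.n_families}"
            )
        if self.n_communities < 1:
            raise InvalidParameterError("n_communities must be >= 1")
        for name in ("sigma_mad", "sigma_genus", "sigma_family"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.shape_afd <= 0 or self.scale_afd <= 0:
            raise InvalidParameterError("gamma shape and scale must be > 0")
        if not 0 < self.taylor_r_min <= 1:
            raise InvalidParameterError("taylor_r_min must be in (0, 1]")
        if self.max_attempts < 1:
            raise InvalidParameterError("max_attempts must be >= 1")


@dataclass
class AbundanceMatrix:
    """Relative abundances, communities in rows and taxa in columns."""

    values: np.ndarray
    community_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("abundance matrix must be 2-D")
        if self.values.shape != (len(self.community_ids), len(self.taxon_ids)):
            raise InvalidParameterError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.community_ids)} communities x {len(self.taxon_ids)} taxa"
            )
        if np.any(self.values < 0):
            raise InvalidParameterError("abundances must be non-negative")

    @property
    def n_communities(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def row_normalized(self) -> "AbundanceMatrix":
        sums = self.values.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise DegenerateInputError("cannot normalize an all-zero community")
        return AbundanceMatrix(self.values / sums, self.community_ids, self.taxon_ids)


@dataclass
class TaxonomyMap:
    """Nested species -> genus -> family assignment."""

    species_to_genus: dict[str, str]
    genus_to_family: dict[str, str]

    @property
    def species(self) -> list[str]:
        return list(self.species_to_genus)

    @property
    def genera(self) -> list[str]:
        return list(self.genus_to_family)

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for fam in self.genus_to_family.values():
            seen.setdefault(fam)
        return list(seen)

    def family_of_species(self, sp: str) -> str:
        return self.genus_to_family[self.species_to_genus[sp]]

    def validate(self) -> None:
        genera_used = set(self.species_to_genus.values())
        if genera_used != set(self.genus_to_family):
            raise InvalidParameterError("empty genus or unmapped genus in taxonomy")

    def relabel(self, species_names: list[str], genus_names: list[str],
                family_names: list[str]) -> "TaxonomyMap":
        """Rename taxa at all ranks, preserving the nesting structure."""
        sp_map = dict(zip(self.species, species_names, strict=True))
        ge_map = dict(zip(self.genera, genus_names, strict=True))
        fa_map = dict(zip(self.families, family_names, strict=True))
        return TaxonomyMap(
            {sp_map[s]: ge_map[g] for s, g in self.species_to_genus.items()},
            {ge_map[g]: fa_map[f] for g, f in self.genus_to_family.items()},
        )


@dataclass
class VirtualMicrobiome:
    """A generated community set: the ground truth of every benchmark."""

    params: EcologyParams
    mad: np.ndarray
    abundances: AbundanceMatrix
    taxonomy: TaxonomyMap
    alpha_diversity: np.ndarray
    alpha_mean: float
    beta: float | None
    taylor_r: float | None
    diversity_class: str
    attempts: int = 1
    taylor_skipped: bool = False
    trends: dict[str, str] | None = None

    @property
    def species_ids(self) -> list[str]:
        return self.abundances.taxon_ids

    def community(self, index: int) -> np.ndarray:
        """Relative abundance vector of one community (sums to 1)."""
        return self.abundances.values[index]

    # ---- serialization -------------------------------------------------

    def write(self, directory: str | Path) -> None:
        """Write abundance TSV, taxonomy TSV and params JSON to a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ab = pd.DataFrame(
            self.abundances.values,
            index=self.abundances.community_ids,
            columns=self.abundances.taxon_ids,
        )
        ab.to_csv(directory / "abundances.tsv", sep="\t", index_label="community")
        rows = [
            (sp, ge, self.taxonomy.genus_to_family[ge])
            for sp, ge in self.taxonomy.species_to_genus.items()
        ]
        pd.DataFrame(rows, columns=["species_id", "genus", "family"]).to_csv(
            directory / "taxonomy.tsv", sep="\t", index=False
        )
        meta = {
            "params": asdict(self.params),
            "taylor_r": self.taylor_r,
            "beta": self.beta,
            "alpha_mean": self.alpha_mean,
            "diversity_class": self.diversity_class,
            "attempts": self.attempts,
            "taylor_skipped": self.taylor_skipped,
            "trends": self.trends,
        }
        (directory / "params.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def read(cls, directory: str | Path) -> "VirtualMicrobiome":
        directory = Path(directory)
        ab = pd.read_csv(directory / "abundances.tsv", sep="\t", index_col="community")
        tax = pd.read_csv(directory / "taxonomy.tsv", sep="\t")
        meta = json.loads((directory / "params.json").read_text())
        params = EcologyParams(**meta["params"])
        taxonomy = TaxonomyMap(
            dict(zip(tax["species_id"], tax["genus"])),
            dict(zip(tax.drop_duplicates("genus")["genus"],
                     tax.drop_duplicates("genus")["family"])),
        )
        matrix = AbundanceMatrix(
            ab.to_numpy(float), [str(c) for c in ab.index], list(ab.columns)
        )
        alpha, alpha_mean = shannon_alpha(matrix)
        mad = matrix.values.mean(axis=0)
        return cls(
            params=params,
            mad=mad,
            abundances=matrix,
            taxonomy=taxonomy,
            alpha_diversity=alpha,
            alpha_mean=alpha_mean,
            beta=meta["beta"],
            taylor_r=meta["taylor_r"],
            diversity_class=meta["diversity_class"],
            attempts=meta["attempts"],
            taylor_skipped=meta["taylor_skipped"],
            trends=meta.get("trends"),
        )


# ---- primitive draws ---------------------------------------------------


def generate_mad(mu: float, sigma: float, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw a mean abundance distribution: lognormal, normalized to sum 1."""
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if sigma < 0:
        raise InvalidParameterError("sigma must be >= 0")
    raw = rng.lognormal(mu, sigma, n)
    return raw / raw.sum()


def generate_afd(shape: float, scale: float, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw an abundance fluctuation distribution: gamma, normalized to sum 1."""
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if shape <= 0 or scale <= 0:
        raise InvalidParameterError("gamma shape and scale must be > 0")
    raw = rng.gamma(shape, scale, n)
    return raw / raw.sum()


def _species_ids(n: int) -> list[str]:
    return [f"sp{i:04d}" for i in range(n)]


def _community_ids(n: int) -> list[str]:
    return [f"comm{i:03d}" for i in range(n)]


def generate_abundance_matrix(
    params: EcologyParams, rng: np.random.Generator,
    _raw_out: dict | None = None,
) -> tuple[np.ndarray, AbundanceMatrix]:
    """Build the raw abundance matrix from MAD and per-species AFDs.

    Column i is ``mad[i] * afd_i * n_communities`` where ``afd_i`` is the
    species' normalized fluctuation vector, so the mean of each column over
    communities equals exactly ``mad[i]``. Rows are NOT normalized here;
    :func:`generate_ecology` renormalizes them for downstream use.

    ``_raw_out``, if given, receives the pre-normalization lognormal and
    gamma draws for goodness-of-fit testing.
    """
    params.validate()
    n_s, n_c = params.n_species, params.n_communities
    raw_mad = rng.lognormal(params.mu_mad, params.sigma_mad, n_s)
    mad = raw_mad / raw_mad.sum()
    raw_gamma = rng.gamma(params.shape_afd, params.scale_afd, (n_s, n_c))
    afd = raw_gamma / raw_gamma.sum(axis=1, keepdims=True)
    values = (mad[:, None] * afd * n_c).T
    if _raw_out is not None:
        _raw_out["mad"] = raw_mad
        _raw_out["gamma"] = raw_gamma.ravel()
    matrix = AbundanceMatrix(values, _community_ids(n_c), _species_ids(n_s))
    return mad, matrix


def test_taylors_law(ab: AbundanceMatrix) -> float:
    """Pearson correlation between log10 mean and log10 variance per species.

    Taylor's law predicts variance proportional to a power of the mean, a
    straight line in log-log space; the correlation measures how well the
    matrix follows it. Species with zero variance are excluded.
    """
    if ab.n_communities < 3:
        raise DegenerateInputError(
            "Taylor's-law test needs >= 3 communities for a meaningful variance"
        )
    means = ab.values.mean(axis=0)
    variances = ab.values.var(axis=0, ddof=1)
    keep = (variances > 0) & (means > 0)
    if keep.sum() < 2:
        raise DegenerateInputError(
            "fewer than 2 species with positive variance"
        )
    r, _ = stats.pearsonr(np.log10(means[keep]), np.log10(variances[keep]))
    return float(r)


def shannon_alpha(ab: AbundanceMatrix) -> tuple[np.ndarray, float]:
    """Shannon index H = -sum(p ln p) in nats per community, plus the mean."""
    sums = ab.values.sum(axis=1)
    if np.any(sums <= 0):
        raise DegenerateInputError("all-zero community row")
    p = ab.values / sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1)
    return h, float(h.mean())


def beta_diversity(ab: AbundanceMatrix) -> float:
    """Mean pairwise Bray-Curtis dissimilarity between communities."""
    if ab.n_communities < 2:
        raise DegenerateInputError("beta diversity needs >= 2 communities")
    rows = ab.row_normalized().values
    return float(pdist(rows, metric="braycurtis").mean())


def _largest_remainder(target: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative quotas to integers summing to ``total``.

    Floors each quota, then hands the remaining units to the largest
    fractional parts; ties go to the lower index (stable sort).
    """
    target = np.asarray(target, dtype=float)
    floors = np.floor(target).astype(int)
    short = total - int(floors.sum())
    if short < 0:
        raise InvalidParameterError("quotas exceed total")
    if short > 0:
        remainders = target - floors
        order = np.argsort(-remainders, kind="stable")
        floors[order[:short]] += 1
    return floors


def group_taxa(n_children: int, n_parents: int, mu: float, sigma: float,
               rng: np.random.Generator) -> np.ndarray:
    """Partition children among parents with lognormal group-size weights.

    Returns an array of length ``n_children`` giving each child's parent
    index. Weights are normalized lognormal draws converted to integer
    counts by largest-remainder rounding; empty parents are repaired by
    moving one child from the currently largest group.
    """
    if n_children < n_parents:
        raise InvalidParameterError(
            f"cannot group {n_children} children into {n_parents} parents"
        )
    if n_parents < 1:
        raise InvalidParameterError("need at least one parent")
    weights = rng.lognormal(mu, sigma, n_parents)
    quotas = weights / weights.sum() * n_children
    counts = _largest_remainder(quotas, n_children)
    # minimum-one repair: every parent must receive at least one child
    while np.any(counts == 0):
        counts[int(np.argmax(counts))] -= 1
        counts[int(np.argmin(counts))] += 1
    parents = np.repeat(np.arange(n_parents), counts)
    return parents


def _build_taxonomy(params: EcologyParams, rng: np.random.Generator) -> TaxonomyMap:
    sp_to_ge = group_taxa(params.n_species, params.n_genera,
                          params.mu_genus, params.sigma_genus, rng)
    ge_to_fa = group_taxa(params.n_genera, params.n_families,
                          params.mu_family, params.sigma_family, rng)
    species = _species_ids(params.n_species)
    genera = [f"ge{i:03d}" for i in range(params.n_genera)]
    families = [f"fa{i:02d}" for i in range(params.n_families)]
    return TaxonomyMap(
        {species[i]: genera[sp_to_ge[i]] for i in range(params.n_species)},
        {genera[j]: families[ge_to_fa[j]] for j in range(params.n_genera)},
    )


def _ks_ok(raw: np.ndarray, dist: str, args: tuple, alpha: float) -> bool:
    """One-sample KS test of raw draws against the generating law."""
    if len(raw) < 8:
        return True  # KS has no power at tiny n; accept
    _, p = stats.kstest(raw, dist, args=args)
    return p > alpha


def generate_ecology(params: EcologyParams,
                     rng: np.random.Generator | None = None) -> VirtualMicrobiome:
    """Generate a virtual microbiome passing the macroecological filters.

    Matrices are redrawn until (a) the Taylor's-law correlation of the raw
    matrix meets ``params.taylor_r_min`` (skipped and flagged when fewer
    than 3 communities make variance meaningless) and (b) one-sample
    Kolmogorov-Smirnov tests do not reject the raw lognormal MAD draws and
    the raw gamma AFD draws at ``params.ks_alpha``. The accepted matrix is
    row-renormalized to relative abundances, and taxonomy plus diversity
    summaries are attached.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    ln_args = (params.sigma_mad, 0.0, float(np.exp(params.mu_mad)))
    ga_args = (params.shape_afd, 0.0, params.scale_afd)
    last_reason = "no attempt made"
    for attempt in range(1, params.max_attempts + 1):
        raws: dict = {}
        mad, raw_matrix = generate_abundance_matrix(params, rng, _raw_out=raws)
        taylor_skipped = params.n_communities < 3
        if taylor_skipped:
            taylor_r = None
        else:
            taylor_r = test_taylors_law(raw_matrix)
            if taylor_r < params.taylor_r_min:
                last_reason = f"taylor_r {taylor_r:.4f} < {params.taylor_r_min}"
                continue
        if params.sigma_mad > 0 and not _ks_ok(
            raws["mad"], "lognorm", ln_args, params.ks_alpha
        ):
            last_reason = "KS rejected lognormal MAD draws"
            continue
        if not _ks_ok(raws["gamma"], "gamma", ga_args, params.ks_alpha):
            last_reason = "KS rejected gamma AFD draws"
            continue
        break
    else:
        raise GenerationFailureError(
            f"no matrix accepted in {params.max_attempts} attempts; "
            f"last failure: {last_reason}"
        )

    matrix = raw_matrix.row_normalized()
    taxonomy = _build_taxonomy(params, rng)
    alpha, alpha_mean = shannon_alpha(matrix)
    beta = beta_diversity(matrix) if params.n_communities >= 2 else None
    threshold = np.log(params.n_species) / 2.0
    return VirtualMicrobiome(
        params=params,
        mad=mad,
        abundances=matrix,
        taxonomy=taxonomy,
        alpha_diversity=alpha,
        alpha_mean=alpha_mean,
        beta=beta,
        taylor_r=taylor_r,
        diversity_class="high" if alpha_mean > threshold else "low",
        attempts=attempt,
        taylor_skipped=taylor_skipped,
    )


def aggregate_abundance(vm: VirtualMicrobiome, level: str) -> AbundanceMatrix:
    """Sum species abundances up to genus or family; species is the identity."""
    if level == "species":
        return vm.abundances
    if level not in ("genus", "family"):
        raise InvalidParameterError(f"unknown rank {level!r}")
    if level == "genus":
        parent = {sp: vm.taxonomy.species_to_genus[sp] for sp in vm.species_ids}
    else:
        parent = {sp: vm.taxonomy.family_of_species(sp) for sp in vm.species_ids}
    taxa: list[str] = []
    for sp in vm.species_ids:
        if parent[sp] not in taxa:
            taxa.append(parent[sp])
    col = {t: i for i, t in enumerate(taxa)}
    out = np.zeros((vm.abundances.n_communities, len(taxa)))
    for j, sp in enumerate(vm.species_ids):
        out[:, col[parent[sp]]] += vm.abundances.values[:, j]
    return AbundanceMatrix(out, vm.abundances.community_ids, taxa)


def perturb_abundances(vm: VirtualMicrobiome, fraction_changed: float,
                       effect_log2: float,
                       rng: np.random.Generator) -> VirtualMicrobiome:
    """Create a paired microbiome with a known set of abundance changes.

    A fixed number of species -- fraction_changed rounded half-up -- are
    multiplied by 2**(+-effect_log2), the sign drawn per species; rows are
    then renormalized. The pre-normalization trend of each species
    (up/down/unchanged) is recorded on the returned microbiome, providing
    the ground truth for trend-detection scoring.
    """
    if not 0 <= fraction_changed <= 1:
        raise InvalidParameterError("fraction_changed must be in [0, 1]")
    n = len(vm.species_ids)
    n_changed = int(np.floor(fraction_changed * n + 0.5))
    chosen = rng.choice(n, size=n_changed, replace=False) if n_changed else np.array([], int)
    multipliers = np.ones(n)
    trends = {sp: "unchanged" for sp in vm.species_ids}
    if effect_log2 != 0:
        signs = rng.choice([-1.0, 1.0], size=n_changed)
    else:
        signs = np.zeros(n_changed)
    for idx, sign in zip(chosen, signs):
        multipliers[idx] = 2.0 ** (sign * effect_log2)
        sp = vm.species_ids[int(idx)]
        trends[sp] = "up" if sign > 0 else ("down" if sign < 0 else "unchanged")
    values = vm.abundances.values * multipliers[None, :]
    matrix = AbundanceMatrix(
        values, vm.abundances.community_ids, vm.abundances.taxon_ids
    ).row_normalized()
    alpha, alpha_mean = shannon_alpha(matrix)
    beta = beta_diversity(matrix) if matrix.n_communities >= 2 else None
    threshold = np.log(vm.params.n_species) / 2.0
    return VirtualMicrobiome(
        params=vm.params,
        mad=matrix.values.mean(axis=0),
        abundances=matrix,
        taxonomy=vm.taxonomy,
        alpha_diversity=alpha,
        alpha_mean=alpha_mean,
        beta=beta,
        taylor_r=vm.taylor_r,
        diversity_class="high" if alpha_mean > threshold else "low",
        attempts=vm.attempts,
        taylor_skipped=vm.taylor_skipped,
        trends=trends,
    )
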