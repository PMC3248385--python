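"""Significance machinery for the co-occurrence network.

Covers four families of analyses:

* clustering of gene sets on correlog groups — exact mean/variance of the
  number of distinct groups hit under random mapping, and the resulting
  Z score;
* functional coherence of correlog groups and category-overlap ratios,
  with cardinality-matched permutation nulls;
* pair-set comparisons of association weights against resampled null pair
  sets, optionally stratified by shortest-path distance in an external
  interaction graph;
* the phylum-level dispersion slope Z based on surrogate profiles with
  per-gene permuted presences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sp_stats

from .association import association_pipeline
from .network import CorrelogGroupSet, coupling_strengths
from .profile_io import ProfileMatrix

__all__ = [
    "AnnotationMap",
    "ClusterStat",
    "PairSet",
    "PairComparison",
    "DispersionResult",
    "clustering_expectation",
    "clustering_z",
    "clustering_bounds",
    "functional_coherence",
    "coherence_null_z",
    "category_overlap",
    "category_overlap_p",
    "pairset_w_comparison",
    "shortest_path_strata",
    "dispersion_slope",
    "phylum_dispersion_z",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class AnnotationMap:
    """Multi-label gene -> functional-category mapping.

    Genes absent from ``labels`` are unannotated.  The category universe is
    the union of all labels unless given explicitly.
    """

    labels: dict[str, frozenset[str]]
    categories: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        self.labels = {g: frozenset(c) for g, c in self.labels.items() if c}
        for cats in self.labels.values():
            if any(not c for c in cats):
                raise ValueError("category labels must be non-empty strings")
        universe = frozenset().union(*self.labels.values()) if self.labels else frozenset()
        self.categories = frozenset(self.categories) | universe

    @classmethod
    def from_tsv(cls, path) -> "AnnotationMap":
        labels: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                gene, cat = line.split("\t")
                labels.setdefault(gene, set()).add(cat)
        return cls({g: frozenset(c) for g, c in labels.items()})


@dataclass
class ClusterStat:
    """Observed vs expected number of distinct correlog groups hit.

    ``z`` is None when the analytic standard deviation is zero (the
    statistic is degenerate, e.g. at full saturation).
    """

    n: int
    eta: float
    sigma: float
    z: float | None
    n_mapped: int
    unmapped_genes: list[str] = field(default_factory=list)


@dataclass
class PairSet:
    """Unordered gene pairs, optionally tagged with a stratum label each."""

    pairs: list[tuple[str, str]]
    strata: list[object] | None = None

    def __post_init__(self) -> None:
        norm = []
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r}")
            norm.append((a, b) if a <= b else (b, a))
        self.pairs = norm
        if self.strata is not None and len(self.strata) != len(self.pairs):
            raise ValueError("strata must align with pairs")


@dataclass
class PairComparison:
    """Observed mean weight vs a resampled null of equal-size pair sets."""

    observed_mean: float
    null_mean: float
    null_sd: float
    z: float | None
    p_gaussian: float | None
    p_empirical: float
    per_stratum_mean: dict[object, float]
    null_means: np.ndarray = field(repr=False)


@dataclass
class DispersionResult:
    """Slope of coupling strength against phylum spread, with surrogate Z."""

    slope: float
    normalized_slope: float
    z: float
    null_mean: float
    null_sd: float
    n_genes_used: int


# ---------------------------------------------------------------------------
# clustering statistics


def _hit_probabilities(
    sizes: Sequence[int], n_mapped: int, with_replacement: bool
) -> tuple[list[Fraction], "callable"]:
    """Per-group hit probability p_g and a pair-miss term for q_gh, exact."""
    m = int(sum(sizes))
    if with_replacement:
        def miss(total_size: int) -> Fraction:
            return Fraction(m - total_size, m) ** n_mapped
    else:
        cm = comb(m, n_mapped)

        def miss(total_size: int) -> Fraction:
            return Fraction(comb(m - total_size, n_mapped), cm)

    p = [1 - miss(s) for s in sizes]
    return p, miss


def clustering_expectation(
    group_sizes: Sequence[int],
    n_mapped: int,
    with_replacement: bool = False,
) -> tuple[float, float]:
    """Exact mean and sd of the number of distinct groups hit by a random set.

    ``n_mapped`` gene slots are drawn uniformly without replacement from the
    ``M = sum(group_sizes)`` slots (the with-replacement variant draws
    ``n_mapped`` independent uniform slots).  With p_g the probability that
    group g receives at least one draw,

        eta    = sum_g p_g
        sigma^2 = sum_g p_g(1-p_g) + sum_{g != h} (q_gh - p_g p_h)

    where q_gh is the probability both g and h are hit.  All arithmetic is
    exact rational; only the final square root is floating point.
    """
    sizes = [int(s) for s in group_sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("all group sizes must be >= 1")
    m = sum(sizes)
    if not 0 <= n_mapped <= m and not with_replacement:
        raise ValueError(f"n_mapped={n_mapped} exceeds the {m} available gene slots")
    if with_replacement and n_mapped < 0:
        raise ValueError("n_mapped must be >= 0")
    p, miss = _hit_probabilities(sizes, n_mapped, with_replacement)
    eta = sum(p, Fraction(0))
    var = sum((pg * (1 - pg) for pg in p), Fraction(0))
    for g in range(len(sizes)):
        for h in range(g + 1, len(sizes)):
            q_gh = 1 - (1 - p[g]) - (1 - p[h]) + miss(sizes[g] + sizes[h])
            var += 2 * (q_gh - p[g] * p[h])
    return float(eta), math.sqrt(max(float(var), 0.0))


def clustering_z(
    groups: CorrelogGroupSet,
    gene_set: Iterable[str],
    with_replacement: bool = False,
) -> ClusterStat:
    """Z score of how many distinct correlog groups a gene set touches.

    Genes absent from the group partition are dropped (and reported in
    ``unmapped_genes``).  Negative Z means the set is more clustered on few
    groups than a random mapping of the same size.
    """
    genes = list(dict.fromkeys(gene_set))
    mapped = [g for g in genes if g in groups.group_of]
    unmapped = [g for g in genes if g not in groups.group_of]
    if not mapped:
        raise ValueError("no gene in the set maps to the correlog groups")
    n = len({groups.group_of[g] for g in mapped})
    sizes = [groups.sizes[gid] for gid in sorted(groups.members)]
    eta, sigma = clustering_expectation(sizes, len(mapped), with_replacement)
    z = (n - eta) / sigma if sigma > 0 else None
    return ClusterStat(n, eta, sigma, z, len(mapped), unmapped)


def clustering_bounds(
    group_sizes: Sequence[int], n_mapped: int
) -> tuple[int, int]:
    """Attainable (n_min, n_max) distinct groups for ``n_mapped`` genes.

    n_max spreads genes one per group; n_min packs them into the largest
    groups first.
    """
    sizes = sorted(int(s) for s in group_sizes)
    m = sum(sizes)
    if not 1 <= n_mapped <= m:
        raise ValueError(f"n_mapped={n_mapped} must lie in [1, {m}]")
    n_max = min(n_mapped, len(sizes))
    remaining = n_mapped
    n_min = 0
    for s in reversed(sizes):
        if remaining <= 0:
            break
        remaining -= s
        n_min += 1
    return n_min, n_max


# ---------------------------------------------------------------------------
# functional coherence and category overlap


def functional_coherence(
    groups: CorrelogGroupSet, ann: AnnotationMap
) -> tuple[dict[int, dict[str, float]], float | None]:
    """Per-group category fractions f_c^g and the perfect-coherence summary.

    For group g, f_c^g is the fraction of its annotated genes carrying
    category c.  Groups with no annotated gene are excluded.  The summary is
    the fraction of groups with more than one annotated gene in which some
    category covers every annotated gene (max_c f_c^g = 1); None when no
    group qualifies.
    """
    table: dict[int, dict[str, float]] = {}
    multi = 0
    coherent = 0
    for gid, members in groups.members.items():
        annotated = [g for g in members if g in ann.labels]
        if not annotated:
            continue
        counts: dict[str, int] = {}
        for g in annotated:
            for c in ann.labels[g]:
                counts[c] = counts.get(c, 0) + 1
        n_ann = len(annotated)
        table[gid] = {c: k / n_ann for c, k in counts.items()}
        if n_ann > 1:
            multi += 1
            if max(counts.values()) == n_ann:
                coherent += 1
    summary = coherent / multi if multi else None
    return table, summary


def _permute_annotations(
    ann: AnnotationMap, genes: Sequence[str], rng: np.random.Generator
) -> AnnotationMap:
    """Shuffle annotation sets among genes with equal annotation-set size.

    Unannotated genes never enter the shuffle; each gene keeps its number of
    affiliated categories.
    """
    by_card: dict[int, list[str]] = {}
    for g in genes:
        if g in ann.labels:
            by_card.setdefault(len(ann.labels[g]), []).append(g)
    new_labels = dict(ann.labels)  # genes outside `genes` keep their labels
    for card, members in by_card.items():
        perm = rng.permutation(len(members))
        sets = [ann.labels[g] for g in members]
        for idx, g in zip(perm, members):
            new_labels[g] = sets[idx]
    return AnnotationMap(new_labels, ann.categories)


def coherence_null_z(
    groups: CorrelogGroupSet,
    ann: AnnotationMap,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float | None, float | None, float, float]:
    """Permutation Z for the perfect-coherence summary fraction.

    Returns (z, observed, null_mean, null_sd); ``z`` is None when the null
    is degenerate (sd = 0).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    _, observed = functional_coherence(groups, ann)
    if observed is None:
        raise ValueError("no group with more than one annotated gene")
    genes = sorted(groups.group_of)
    null = np.empty(n_perm)
    for b in range(n_perm):
        _, frac = functional_coherence(
            groups, _permute_annotations(ann, genes, rng)
        )
        null[b] = np.nan if frac is None else frac
    null = null[~np.isnan(null)]
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if null.size > 1 else 0.0
    z = (observed - mean) / sd if sd > 0 else None
    return z, observed, mean, sd


def category_overlap(
    groups: CorrelogGroupSet, ann: AnnotationMap, c1: str, c2: str
) -> float | None:
    """Overlap ratio of two categories across correlog groups.

    Y = (# groups containing both a c1 gene and a c2 gene)
        / (# groups containing a c1 gene or a c2 gene).

    Returns None when neither category occurs in any group.  Y = 1 for a
    category with itself whenever it occurs.
    """
    for c in (c1, c2):
        if c not in ann.categories:
            raise ValueError(f"unknown category {c!r}")
    both = either = 0
    for members in groups.members.values():
        has1 = any(c1 in ann.labels.get(g, ()) for g in members)
        has2 = any(c2 in ann.labels.get(g, ()) for g in members)
        both += has1 and has2
        either += has1 or has2
    if either == 0:
        return None
    return both / either


def category_overlap_p(
    groups: CorrelogGroupSet,
    ann: AnnotationMap,
    c1: str,
    c2: str,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """One-sided permutation P for the category-overlap ratio.

    The null shuffles annotation sets among genes of equal annotation count;
    P = (1 + #{null Y >= observed Y}) / (1 + n_perm), so P is never zero.
    Returns (p, observed_Y).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    observed = category_overlap(groups, ann, c1, c2)
    if observed is None:
        raise ValueError(f"neither {c1!r} nor {c2!r} occurs in any group")
    genes = sorted(groups.group_of)
    exceed = 0
    for _ in range(n_perm):
        y = category_overlap(groups, _permute_annotations(ann, genes, rng), c1, c2)
        if y is not None and y >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_perm), observed


# ---------------------------------------------------------------------------
# pair-set comparisons


def shortest_path_strata(
    edges: Iterable[tuple[str, str]], gene_ids: Sequence[str]
) -> PairSet:
    """All connected pairs among ``gene_ids`` labeled by shortest-path length.

    Pairs in different components are unreachable and excluded.  Edges whose
    endpoints fall outside ``gene_ids`` still contribute to path lengths.
    """
    g = nx.Graph()
    g.add_edges_from(edges)
    present = [gid for gid in gene_ids if gid in g]
    if not present:
        raise ValueError("no gene of interest appears in the interaction graph")
    wanted = set(present)
    pairs: list[tuple[str, str]] = []
    strata: list[int] = []
    for src, dists in nx.all_pairs_shortest_path_length(g):
        if src not in wanted:
            continue
        for dst, d in dists.items():
            if dst in wanted and src < dst:
                pairs.append((src, dst))
                strata.append(d)
    return PairSet(pairs, strata)


def pairset_w_comparison(
    matrix: np.ndarray,
    gene_ids: Sequence[str],
    pairs: PairSet,
    population: PairSet,
    n_draws: int = 1000,
    seed: int | None = None,
) -> PairComparison:
    """Compare the mean weight of a designated pair set against random pair sets.

    The null draws ``n_draws`` pair sets of the same size (and the same
    per-stratum composition, when strata are present) from ``population``
    and records their mean weights.  Z = (observed - null mean)/null sd and
    the one-sided upper-tail Gaussian P mirror a central-limit argument; the
    empirical add-one P is retained alongside for audit.

    A stratum smaller than the number of pairs it must supply is resampled
    with replacement (a warning is emitted).  When the pair set exhausts the
    population the null is a point mass and Z = 0; any other zero-sd null is
    flagged (Z = None).
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    index = {g: i for i, g in enumerate(gene_ids)}
    if n_draws < 1:
        raise ValueError("n_draws must be positive")

    def mean_w(pair_list: list[tuple[str, str]]) -> float:
        vals = [matrix[index[a], index[b]] for a, b in pair_list]
        return float(np.mean(vals))

    for a, b in pairs.pairs + population.pairs:
        if a not in index or b not in index:
            raise ValueError(f"pair references unknown gene {a!r}/{b!r}")

    obs_strata = pairs.strata if pairs.strata is not None else [None] * len(pairs.pairs)
    pop_strata = (
        population.strata
        if population.strata is not None
        else [None] * len(population.pairs)
    )
    pop_by_stratum: dict[object, list[tuple[str, str]]] = {}
    for pair, s in zip(population.pairs, pop_strata):
        pop_by_stratum.setdefault(s, []).append(pair)
    need: dict[object, int] = {}
    for s in obs_strata:
        need[s] = need.get(s, 0) + 1
    for s, k in need.items():
        if s not in pop_by_stratum:
            raise ValueError(f"stratum {s!r} absent from the null population")
        if len(pop_by_stratum[s]) < k:
            warnings.warn(
                f"stratum {s!r} has {len(pop_by_stratum[s])} pairs but "
                f"{k} are required; resampling with replacement",
                stacklevel=2,
            )

    per_stratum: dict[object, float] = {}
    for s in need:
        vals = [
            matrix[index[a], index[b]]
            for (a, b), t in zip(pairs.pairs, obs_strata)
            if t == s
        ]
        per_stratum[s] = float(np.mean(vals))
    observed = mean_w(pairs.pairs)

    rng = np.random.default_rng(seed)
    null_means = np.empty(n_draws)
    for b in range(n_draws):
        sample: list[tuple[str, str]] = []
        for s, k in need.items():
            pool = pop_by_stratum[s]
            replace = len(pool) < k
            idx = rng.choice(len(pool), size=k, replace=replace)
            sample.extend(pool[i] for i in idx)
        null_means[b] = mean_w(sample)

    null_mean = float(null_means.mean())
    null_sd = float(null_means.std(ddof=1)) if n_draws > 1 else 0.0
    if null_sd <= 1e-12 * max(1.0, abs(null_mean)):  # numerically degenerate
        null_sd = 0.0
    if null_sd > 0:
        z = (observed - null_mean) / null_sd
        p_gauss = float(sp_stats.norm.sf(z))
    else:
        exhausts = all(
            sorted(set(p for p, t in zip(pairs.pairs, obs_strata) if t == s))
            == sorted(set(pop_by_stratum[s]))
            for s in need
        ) and set(need) == set(pop_by_stratum)
        z = 0.0 if exhausts else None
        p_gauss = 0.5 if exhausts else None
    p_emp = float((1 + np.sum(null_means >= observed)) / (1 + n_draws))
    return PairComparison(
        observed, null_mean, null_sd, z, p_gauss, p_emp, per_stratum, null_means
    )


# ---------------------------------------------------------------------------
# phylum-level dispersion


def _phyla_counts(
    pm: ProfileMatrix, taxonomy: Mapping[str, str]
) -> np.ndarray:
    missing = [s for s in pm.species_ids if s not in taxonomy]
    if missing:
        raise ValueError(f"species {missing[0]!r} missing from the taxonomy")
    phyla = sorted({taxonomy[s] for s in pm.species_ids})
    ph_index = {p: j for j, p in enumerate(phyla)}
    ind = np.zeros((pm.n_species, len(phyla)))
    for k, s in enumerate(pm.species_ids):
        ind[k, ph_index[taxonomy[s]]] = 1.0
    return ((pm.x @ ind) > 0).sum(axis=1)


def dispersion_slope(
    n_phyla: np.ndarray, s_p: np.ndarray, n_phyla_max: int = 7
) -> tuple[float, float, int]:
    """OLS slope of coupling strength on phylum count, plus a scale-free variant.

    Only genes with ``n_phyla < n_phyla_max`` enter the regression.  The
    normalized slope multiplies by sd(n_phyla)/sd(S_p); any linear
    normalization cancels in the surrogate Z, which is the comparable
    quantity.  Returns (slope, normalized_slope, n_genes_used).
    """
    n_phyla = np.asarray(n_phyla, dtype=np.float64)
    s_p = np.asarray(s_p, dtype=np.float64)
    mask = n_phyla < n_phyla_max
    xs, ys = n_phyla[mask], s_p[mask]
    if len(np.unique(xs)) < 3:
        raise ValueError(
            f"need at least 3 distinct phylum counts below {n_phyla_max}, "
            f"got {len(np.unique(xs))}"
        )
    slope = float(np.polyfit(xs, ys, 1)[0])
    sy = float(ys.std(ddof=1))
    normalized = slope * float(xs.std(ddof=1)) / sy if sy > 0 else 0.0
    return slope, normalized, int(mask.sum())


def _dispersion_slope(
    pm: ProfileMatrix,
    taxonomy: Mapping[str, str],
    x_th: int,
    n_phyla_max: int,
    lambda_override: float | None,
) -> tuple[float, float, int]:
    result, _ = association_pipeline(pm, x_th=x_th, lambda_override=lambda_override)
    kept = pm.subset_genes(result.gene_ids)
    s_pos = coupling_strengths(result.w, result.gene_ids).s_pos
    n_phyla = _phyla_counts(kept, taxonomy)
    return dispersion_slope(n_phyla, s_pos, n_phyla_max)


def phylum_dispersion_z(
    pm: ProfileMatrix,
    taxonomy: Mapping[str, str],
    x_th: int = 80,
    n_phyla_max: int = 7,
    n_perm: int = 100,
    seed: int | None = None,
    lambda_override: float | None = None,
) -> DispersionResult:
    """Z score of the coupling-strength-vs-phylum-spread regression slope.

    The slope of S_i^p against the number of distinct phyla hosting gene i
    (restricted to genes below ``n_phyla_max``) is normalized by
    sd(n_phyla)/sd(S_p) — the normalization cancels in Z, which is the only
    scale-free quantity.  The null ensemble permutes each gene's presence
    vector independently across species (preserving every E_i) and reruns
    the whole pipeline.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    slope, norm_slope, n_used = _dispersion_slope(
        pm, taxonomy, x_th, n_phyla_max, lambda_override
    )
    null = np.empty(n_perm)
    for b in range(n_perm):
        x = pm.x.copy()
        for i in range(x.shape[0]):
            rng.shuffle(x[i])
        surrogate = ProfileMatrix(list(pm.gene_ids), list(pm.species_ids), x)
        _, ns, _ = _dispersion_slope(
            surrogate, taxonomy, x_th, n_phyla_max, lambda_override
        )
        null[b] = ns
    sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    mean = float(null.mean())
    z = (norm_slope - mean) / sd if sd > 0 else 0.0
    return DispersionResult(slope, norm_slope, z, mean, sd, n_used)
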