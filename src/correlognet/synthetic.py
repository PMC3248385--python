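"""Synthetic profile generator with planted module structure.

Species are modeled as independent draws: each planted module is switched
on with its own activity probability, mutually exclusive ("anti-paired")
modules are deconflicted by deactivating one of the two at random, and
presence calls are corrupted by false-positive / false-negative noise.
Companion generators emit annotations, interaction graphs, and organism
gene sets aligned with the planted truth, so every downstream analysis can
be exercised without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profile_io import ProfileMatrix
from .statistics import AnnotationMap

__all__ = [
    "PlantedModel",
    "generate_profiles",
    "generate_annotations",
    "generate_interactions",
    "generate_organism_sets",
]


@dataclass
class PlantedModel:
    """Generative specification for synthetic profiles.

    Attributes
    ----------
    n_species : int
    modules : list of list of str
        Disjoint gene-id lists; genes of one module share an activity state
        per species.
    module_activity : float or list of float
        Activation probability per module (scalar broadcast to all).
    anti_pairs : list of (int, int)
        Module-index pairs constrained to be mutually exclusive per species.
    fp_rate, fn_rate : float
        Presence despite inactive module / absence despite active module.
    background_genes : list of str
        Genes with i.i.d. Bernoulli(background_prob) presence.
    seed : int
    """

    n_species: int
    modules: list[list[str]]
    module_activity: float | list[float] = 0.5
    anti_pairs: list[tuple[int, int]] = field(default_factory=list)
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    background_genes: list[str] = field(default_factory=list)
    background_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        flat = [g for mod in self.modules for g in mod]
        if len(set(flat)) != len(flat):
            raise ValueError("modules must be disjoint with unique gene ids")
        if set(flat) & set(self.background_genes):
            raise ValueError("background genes overlap module genes")
        for rate in (self.fp_rate, self.fn_rate, self.background_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for a, b in self.anti_pairs:
            if a == b:
                raise ValueError("anti-pair must reference two distinct modules")
            if not (0 <= a < len(self.modules) and 0 <= b < len(self.modules)):
                raise ValueError("anti-pair index out of range")
        pis = self.activity_vector()
        if np.any(pis < 0) or np.any(pis > 1):
            raise ValueError("module activity probabilities must lie in [0, 1]")

    def activity_vector(self) -> np.ndarray:
        if np.isscalar(self.module_activity):
            return np.full(len(self.modules), float(self.module_activity))
        pis = np.asarray(self.module_activity, dtype=np.float64)
        if pis.shape != (len(self.modules),):
            raise ValueError("module_activity must match the number of modules")
        return pis

    @classmethod
    def regular(
        cls,
        n_modules: int,
        genes_per_module: int,
        n_species: int,
        anti_paired: bool = True,
        **kwargs,
    ) -> "PlantedModel":
        """Uniform model: modules m00, m01, ... with genes ``m00_g0`` etc.

        With ``anti_paired`` the modules are coupled consecutively
        (0,1), (2,3), ...
        """
        modules = [
            [f"m{m:02d}_g{g}" for g in range(genes_per_module)]
            for m in range(n_modules)
        ]
        anti = (
            [(m, m + 1) for m in range(0, n_modules - 1, 2)] if anti_paired else []
        )
        return cls(n_species=n_species, modules=modules, anti_pairs=anti, **kwargs)

    def module_of(self) -> dict[str, int | None]:
        """Planted label per gene (None for background genes)."""
        out: dict[str, int | None] = {}
        for m, mod in enumerate(self.modules):
            for g in mod:
                out[g] = m
        for g in self.background_genes:
            out[g] = None
        return out


def generate_profiles(
    model: PlantedModel,
) -> tuple[ProfileMatrix, dict[str, int | None]]:
    """Draw a profile matrix from the planted model.

    Per species: each module activates independently with its probability;
    for every anti-pair with both members active, one is deactivated
    uniformly at random; a module gene is present iff its module is active
    and escapes false-negative dropout, or the module is inactive and a
    false positive fires.  Fully reproducible from ``model.seed``.

    Returns the matrix (module genes first, then background genes) and the
    planted gene -> module-index labels.
    """
    rng = np.random.default_rng(model.seed)
    n_sp = model.n_species
    pis = model.activity_vector()
    active = rng.random((n_sp, len(model.modules))) < pis[None, :]
    for a, b in model.anti_pairs:
        both = active[:, a] & active[:, b]
        drop_a = rng.random(n_sp) < 0.5
        active[both & drop_a, a] = False
        active[both & ~drop_a, b] = False

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    for m, mod in enumerate(model.modules):
        u = rng.random((len(mod), n_sp))
        on = active[:, m][None, :]
        present = np.where(on, u >= model.fn_rate, u < model.fp_rate)
        gene_ids.extend(mod)
        rows.append(present)
    if model.background_genes:
        u = rng.random((len(model.background_genes), n_sp))
        gene_ids.extend(model.background_genes)
        rows.append(u < model.background_prob)
    x = np.concatenate(rows, axis=0).astype(np.int8)
    species_ids = [f"s{k:04d}" for k in range(n_sp)]
    return ProfileMatrix(gene_ids, species_ids, x), model.module_of()


def generate_annotations(
    model: PlantedModel, purity: float = 1.0, seed: int | None = None
) -> AnnotationMap:
    """One category per module; each gene keeps its own with prob ``purity``.

    With probability 1 - purity a gene is relabeled with a category chosen
    uniformly among all module categories.  Background genes stay
    unannotated.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError("purity must lie in [0, 1]")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    cats = [f"C{m:02d}" for m in range(len(model.modules))]
    labels: dict[str, frozenset[str]] = {}
    for m, mod in enumerate(model.modules):
        for g in mod:
            if rng.random() < purity:
                labels[g] = frozenset({cats[m]})
            else:
                labels[g] = frozenset({cats[rng.integers(len(cats))]})
    return AnnotationMap(labels, frozenset(cats))


def generate_interactions(
    model: PlantedModel,
    within_prob: float = 0.8,
    between_prob: float = 0.02,
    seed: int | None = None,
) -> list[tuple[str, str]]:
    """Random undirected graph denser inside planted modules.

    Every unordered gene pair (modules and background alike) receives an
    edge with ``within_prob`` if both genes share a module, else
    ``between_prob``.
    """
    for p in (within_prob, between_prob):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    labels = model.module_of()
    genes = sorted(labels)
    edges: list[tuple[str, str]] = []
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            same = labels[a] is not None and labels[a] == labels[b]
            p = within_prob if same else between_prob
            if rng.random() < p:
                edges.append((a, b))
    return edges


def generate_organism_sets(
    model: PlantedModel,
    n_organisms: int,
    modules_per_organism: int,
    dropout: float = 0.0,
    seed: int | None = None,
) -> list[list[str]]:
    """Organism gene sets: union of randomly chosen modules with dropout.

    Each organism picks ``modules_per_organism`` distinct modules and keeps
    each of their genes with probability 1 - dropout.
    """
    if modules_per_organism > len(model.modules):
        raise ValueError("modules_per_organism exceeds the number of modules")
    if not 0.0 <= dropout <= 1.0:
        raise ValueError("dropout must lie in [0, 1]")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    organisms: list[list[str]] = []
    for _ in range(n_organisms):
        chosen = rng.choice(len(model.modules), size=modules_per_organism, replace=False)
        genes = [g for m in chosen for g in model.modules[m]]
        kept = [g for g in genes if rng.random() >= dropout]
        organisms.append(sorted(kept))
    return organisms
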