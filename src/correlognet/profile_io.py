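"""Reading, validation, summarization and filtering of binary phylogenetic profiles.

A profile matrix records presence (1) or absence (0) of each gene across a
set of species.  Rows are genes, columns are species.  Two on-disk dialects
are supported: a full 0/1 matrix with a header of species identifiers, and a
two-column (gene, species) occurrence list as shipped by ortholog databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ProfileFormatError",
    "ProfileMatrix",
    "FilterReport",
    "read_profile_matrix",
    "write_profile_matrix",
    "filter_by_prevalence",
    "balance_distribution",
    "write_filter_report",
]


class ProfileFormatError(ValueError):
    """Raised when an input file violates the profile-matrix contract."""


@dataclass
class ProfileMatrix:
    """Binary gene-by-species occurrence matrix.

    Attributes
    ----------
    gene_ids : list of str
        Row labels, unique, order preserved from the source.
    species_ids : list of str
        Column labels, unique.
    x : ndarray of shape (n_genes, n_species), dtype int8
        Entries are exactly 0 or 1.
    """

    gene_ids: list[str]
    species_ids: list[str]
    x: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int8)
        if self.x.ndim != 2:
            raise ProfileFormatError("profile matrix must be two-dimensional")
        if self.x.shape != (len(self.gene_ids), len(self.species_ids)):
            raise ProfileFormatError(
                f"matrix shape {self.x.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.species_ids)} species"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ProfileFormatError("duplicate gene identifiers")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ProfileFormatError("duplicate species identifiers")
        bad = (self.x != 0) & (self.x != 1)
        if bad.any():
            i, k = np.argwhere(bad)[0]
            raise ProfileFormatError(
                f"non-binary entry at gene {self.gene_ids[i]!r}, "
                f"species {self.species_ids[k]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_species(self) -> int:
        """Total number of species N."""
        return len(self.species_ids)

    @property
    def presence_counts(self) -> np.ndarray:
        """Per-gene presence count E_i = sum_k x_ki."""
        return self.x.sum(axis=1).astype(np.int64)

    @property
    def balance(self) -> np.ndarray:
        """Per-gene balance X_i = min(E_i, N - E_i)."""
        e = self.presence_counts
        return np.minimum(e, self.n_species - e)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ProfileMatrix":
        """Return a new matrix restricted to ``gene_ids`` (in the given order)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ProfileMatrix(list(gene_ids), list(self.species_ids), self.x[rows])


@dataclass
class FilterReport:
    """Outcome of the prevalence-balance filter."""

    kept_gene_ids: list[str]
    dropped_gene_ids: list[str]
    threshold: int


def _read_matrix_dialect(path: Path) -> ProfileMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ProfileFormatError(f"{path}: empty file")
        species_ids = header.split("\t")[1:]
        if not species_ids:
            raise ProfileFormatError(f"{path}: header contains no species columns")
        gene_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            gene, cells = parts[0], parts[1:]
            if len(cells) != len(species_ids):
                raise ProfileFormatError(
                    f"{path}:{lineno}: gene {gene!r} has {len(cells)} cells, "
                    f"expected {len(species_ids)}"
                )
            row = []
            for k, cell in enumerate(cells):
                if cell not in ("0", "1"):
                    raise ProfileFormatError(
                        f"{path}:{lineno}: non-binary cell {cell!r} for gene "
                        f"{gene!r}, species {species_ids[k]!r}"
                    )
                row.append(int(cell))
            if gene in gene_ids:
                raise ProfileFormatError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            gene_ids.append(gene)
            rows.append(row)
    if not gene_ids:
        raise ProfileFormatError(f"{path}: matrix contains no gene rows")
    return ProfileMatrix(gene_ids, species_ids, np.array(rows, dtype=np.int8))


def _read_pairs_dialect(path: Path, species: Sequence[str] | None) -> ProfileMatrix:
    occurrences: set[tuple[str, str]] = set()
    gene_order: list[str] = []
    species_order: list[str] = []
    seen_genes: set[str] = set()
    seen_species: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ProfileFormatError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            gene, sp = parts
            occurrences.add((gene, sp))
            if gene not in seen_genes:
                seen_genes.add(gene)
                gene_order.append(gene)
            if sp not in seen_species:
                seen_species.add(sp)
                species_order.append(sp)
    if not occurrences:
        raise ProfileFormatError(f"{path}: no occurrences found")
    if species is not None:
        unknown = seen_species - set(species)
        if unknown:
            raise ProfileFormatError(
                f"{path}: species {sorted(unknown)[0]!r} not in the supplied universe"
            )
        species_order = list(species)
    x = np.zeros((len(gene_order), len(species_order)), dtype=np.int8)
    sp_index = {s: k for k, s in enumerate(species_order)}
    g_index = {g: i for i, g in enumerate(gene_order)}
    for gene, sp in occurrences:
        x[g_index[gene], sp_index[sp]] = 1
    return ProfileMatrix(gene_order, species_order, x)


def read_profile_matrix(
    path: str | Path,
    dialect: str = "matrix",
    species: Sequence[str] | None = None,
) -> ProfileMatrix:
    """Load a profile matrix from a TSV file.

    Parameters
    ----------
    path : path-like
        Input file.
    dialect : {"matrix", "pairs"}
        ``matrix``: header row of species ids, one gene row per line with 0/1
        cells.  ``pairs``: two columns (gene_id, species_id), one occurrence
        per line; duplicated pairs collapse to a single presence.
    species : sequence of str, optional
        Explicit species universe for the pairs dialect.  Species never
        mentioned in the file get all-absent columns.

    Raises
    ------
    ProfileFormatError
        On non-binary cells, duplicate gene ids, or an empty matrix.
    """
    path = Path(path)
    if not path.exists():
        raise ProfileFormatError(f"no such file: {path}")
    if dialect == "matrix":
        if species is not None:
            raise ValueError("species universe only applies to the pairs dialect")
        return _read_matrix_dialect(path)
    if dialect == "pairs":
        return _read_pairs_dialect(path, species)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_profile_matrix(pm: ProfileMatrix, path: str | Path) -> None:
    """Write ``pm`` in the matrix dialect (round-trips bit-exactly)."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(pm.species_ids) + "\n")
        for i, gene in enumerate(pm.gene_ids):
            fh.write(gene + "\t" + "\t".join(str(int(v)) for v in pm.x[i]) + "\n")


def filter_by_prevalence(
    pm: ProfileMatrix, x_th: int = 80
) -> tuple[ProfileMatrix, FilterReport]:
    """Keep genes whose balance X_i = min(E_i, N - E_i) is at least ``x_th``.

    Genes that are too rare or too ubiquitous carry little co-occurrence
    signal; the balance threshold removes both tails at once.  Order of the
    surviving genes and the species set are preserved.

    Raises
    ------
    ValueError
        If ``x_th`` is negative or no gene survives.
    """
    if x_th < 0:
        raise ValueError("x_th must be non-negative")
    keep = pm.balance >= x_th
    kept = [g for g, k in zip(pm.gene_ids, keep) if k]
    dropped = [g for g, k in zip(pm.gene_ids, keep) if not k]
    if not kept:
        raise ValueError(f"empty after filtering: no gene has X_i >= {x_th}")
    out = ProfileMatrix(kept, list(pm.species_ids), pm.x[keep])
    return out, FilterReport(kept, dropped, x_th)


def balance_distribution(pm: ProfileMatrix) -> list[tuple[int, int]]:
    """Tabulate (balance value, gene count), sorted by balance.

    Diagnostic used to pick a filtering threshold by inspecting where the
    tail of the distribution decays.
    """
    values, counts = np.unique(pm.balance, return_counts=True)
    return [(int(v), int(c)) for v, c in zip(values, counts)]


def write_filter_report(
    report: FilterReport, pm: ProfileMatrix, path: str | Path
) -> None:
    """Write per-gene (E_i, X_i, kept) rows for the genes of ``pm``."""
    e = pm.presence_counts
    x = pm.balance
    kept = set(report.kept_gene_ids)
    with open(path, "w") as fh:
        fh.write("gene_id\tE\tX\tkept\n")
        for i, g in enumerate(pm.gene_ids):
            fh.write(f"{g}\t{e[i]}\t{x[i]}\t{int(g in kept)}\n")
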