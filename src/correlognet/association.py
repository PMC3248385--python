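"""Pairwise co-occurrence measures and shrinkage partial correlation.

Pipeline: Pearson correlation of the binary profiles -> analytic shrinkage
intensity (Ledoit-Wolf / Schaefer-Strimmer, identity target) -> shrunk
correlation matrix -> partial correlation from the precision matrix.  The
signed partial correlation ``w`` is the association weight: positive values
mark preferential co-occurrence, negative values mutual exclusion.  Mutual
information over the 2x2 joint table is provided for comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .profile_io import FilterReport, ProfileMatrix, filter_by_prevalence

__all__ = [
    "AssociationResult",
    "pearson_binary",
    "mutual_information",
    "shrinkage_lambda",
    "shrink_correlation",
    "partial_correlation",
    "association_pipeline",
    "write_edge_list",
]

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-10


@dataclass
class AssociationResult:
    """Bundle of pairwise association matrices over a fixed gene order.

    All matrices are symmetric with shape (n_genes, n_genes).  ``r`` and
    ``r_star`` have unit diagonal; ``w`` has zero diagonal by convention;
    ``mi`` has the per-profile entropy on the diagonal.
    """

    gene_ids: list[str]
    r: np.ndarray = field(repr=False)
    r_star: np.ndarray = field(repr=False)
    lambda_: float
    w: np.ndarray = field(repr=False)
    mi: np.ndarray = field(repr=False)


def _check_informative(pm: ProfileMatrix) -> None:
    e = pm.presence_counts
    n = pm.n_species
    bad = np.where((e == 0) | (e == n))[0]
    if bad.size:
        raise ValueError(
            f"gene {pm.gene_ids[bad[0]]!r} is present in "
            f"{'no' if e[bad[0]] == 0 else 'all'} species; "
            "its profile has zero variance (filter with x_th >= 1 first)"
        )


def pearson_binary(pm: ProfileMatrix) -> np.ndarray:
    """Pearson correlation matrix of the 0/1 profile rows.

    Computed from the co-presence counts:
    r_ij = (N*C_ij - E_i*E_j) / sqrt(E_i*(N-E_i) * E_j*(N-E_j)),
    where C_ij is the number of species containing both genes.  This equals
    the ordinary Pearson correlation of the binary row vectors.
    """
    _check_informative(pm)
    x = pm.x.astype(np.float64)
    n = pm.n_species
    e = x.sum(axis=1)
    c = x @ x.T
    denom = np.sqrt(np.outer(e * (n - e), e * (n - e)))
    r = (n * c - np.outer(e, e)) / denom
    np.fill_diagonal(r, 1.0)
    np.clip(r, -1.0, 1.0, out=r)
    return (r + r.T) / 2.0


def mutual_information(pm: ProfileMatrix, unit: str = "nats") -> np.ndarray:
    """Mutual information of every profile pair over the 2x2 joint table.

    I_ij = sum_{a,b in {0,1}} p(a,b) * log(p(a,b) / (p(a) p(b))) with the
    0*log(0) := 0 convention.  The diagonal I_ii equals the entropy of
    profile i.

    Parameters
    ----------
    unit : {"nats", "bits"}
        Logarithm base e or 2.
    """
    if unit not in ("nats", "bits"):
        raise ValueError("unit must be 'nats' or 'bits'")
    x = pm.x.astype(np.float64)
    n = float(pm.n_species)
    e = x.sum(axis=1)
    c11 = x @ x.T
    c10 = e[:, None] - c11
    c01 = e[None, :] - c11
    c00 = n - e[:, None] - e[None, :] + c11
    mi = np.zeros((pm.n_genes, pm.n_genes))
    # cell counts paired with their (row, column) marginal counts
    for cnt, ma, mb in (
        (c11, e[:, None], e[None, :]),
        (c10, e[:, None], n - e[None, :]),
        (c01, n - e[:, None], e[None, :]),
        (c00, n - e[:, None], n - e[None, :]),
    ):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (cnt / n) * np.log(cnt * n / (ma * mb))
        mi += np.where(cnt > 0, term, 0.0)
    mi = np.maximum((mi + mi.T) / 2.0, 0.0)
    if unit == "bits":
        mi /= np.log(2.0)
    return mi


def _standardized(pm: ProfileMatrix) -> np.ndarray:
    """Rows standardized to zero mean and unit (N-1)-denominator variance."""
    _check_informative(pm)
    x = pm.x.astype(np.float64)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    return (x - mean) / sd


def shrinkage_lambda(pm: ProfileMatrix) -> float:
    """Analytic shrinkage intensity toward the identity target.

    With z_kij the product of the standardized profile entries of genes i
    and j in species k, the estimated sampling variance of each correlation
    is Var(r_ij) = N/(N-1)^3 * sum_k (z_kij - mean_k z_kij)^2, and

        lambda = clip( sum_{i != j} Var(r_ij) / sum_{i != j} r_ij^2, 0, 1 ).

    When every off-diagonal correlation is exactly zero the ratio is 0/0 and
    lambda is set to 1 (full shrinkage); this degenerate case is logged.
    """
    n = pm.n_species
    if n < 2:
        raise ValueError("at least two species are required")
    y = _standardized(pm)
    p = pm.n_genes
    s1 = y @ y.T            # sum_k z_kij
    s2 = (y**2) @ (y**2).T  # sum_k z_kij^2
    r = s1 / (n - 1)
    zbar = s1 / n
    var_hat = n / (n - 1) ** 3 * (s2 - n * zbar**2)
    off = ~np.eye(p, dtype=bool)
    denom = float((r[off] ** 2).sum())
    if denom == 0.0:
        logger.warning("all off-diagonal correlations are zero; lambda set to 1")
        return 1.0
    lam = float(var_hat[off].sum()) / denom
    return float(min(1.0, max(0.0, lam)))


def shrink_correlation(r: np.ndarray, lambda_: float) -> np.ndarray:
    """Blend ``r`` toward the identity: r*_ij = (1-lambda)*r_ij + lambda*delta_ij."""
    if not 0.0 <= lambda_ <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lambda_}")
    r = np.asarray(r, dtype=np.float64)
    r_star = (1.0 - lambda_) * r
    np.fill_diagonal(r_star, 1.0)
    return r_star


def partial_correlation(r_star: np.ndarray) -> np.ndarray:
    """Partial correlations from the precision matrix of ``r_star``.

    w_ij = -p_ij / sqrt(p_ii * p_jj) with P the inverse of ``r_star``.  The
    diagonal is reported as 0 (self-association is meaningless).
    """
    r_star = np.asarray(r_star, dtype=np.float64)
    try:
        cf = scipy.linalg.cho_factor(r_star)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "correlation matrix is not positive definite; "
            "raise the shrinkage intensity lambda"
        ) from exc
    prec = scipy.linalg.cho_solve(cf, np.eye(r_star.shape[0]))
    d = np.sqrt(np.diag(prec))
    w = -prec / np.outer(d, d)
    scale = max(1.0, float(np.abs(w).max()))
    asym = float(np.abs(w - w.T).max())
    if asym > _SYM_TOL * scale:
        raise np.linalg.LinAlgError(
            f"precision matrix asymmetric beyond tolerance ({asym:g}); "
            "raise the shrinkage intensity lambda"
        )
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    np.clip(w, -1.0, 1.0, out=w)
    return w


def association_pipeline(
    pm: ProfileMatrix,
    x_th: int = 80,
    lambda_override: float | None = None,
) -> tuple[AssociationResult, FilterReport]:
    """Run filter -> r -> lambda -> r* -> w -> I and bundle the results.

    Parameters
    ----------
    pm : ProfileMatrix
        Unfiltered profiles.
    x_th : int
        Balance threshold passed to :func:`filter_by_prevalence`.
    lambda_override : float, optional
        Bypass the analytic shrinkage intensity (sensitivity analysis).
    """
    kept, report = filter_by_prevalence(pm, x_th)
    r = pearson_binary(kept)
    lam = shrinkage_lambda(kept) if lambda_override is None else float(lambda_override)
    r_star = shrink_correlation(r, lam)
    w = partial_correlation(r_star)
    mi = mutual_information(kept)
    return AssociationResult(kept.gene_ids, r, r_star, lam, w, mi), report


def write_edge_list(result: AssociationResult, path: str | Path) -> None:
    """Write the long-format (i < j) edge table as TSV."""
    with open(path, "w") as fh:
        fh.write("gene_i\tgene_j\tr\tr_star\tw\tI\n")
        p = len(result.gene_ids)
        for i in range(p):
            for j in range(i + 1, p):
                fh.write(
                    f"{result.gene_ids[i]}\t{result.gene_ids[j]}\t"
                    f"{result.r[i, j]:.10g}\t{result.r_star[i, j]:.10g}\t"
                    f"{result.w[i, j]:.10g}\t{result.mi[i, j]:.10g}\n"
                )


def write_run_metadata(result: AssociationResult, path: str | Path, **params) -> None:
    """Record lambda and run parameters as JSON next to the edge list."""
    meta = {"lambda": result.lambda_, "n_genes": len(result.gene_ids), **params}
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
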