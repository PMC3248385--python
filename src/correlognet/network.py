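"""Maximum relatedness subnetwork (MRS), correlog groups, coupling strengths.

The MRS is a directed backbone in which every gene points to at most two
partners: the gene with the largest positive association weight (correlog
edge) and the gene with the most negative weight (anti-correlog edge).
Connected components of the undirected correlog edges are the correlog
groups; anti-correlog edges typically bridge distinct groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "MRSGraph",
    "CorrelogGroupSet",
    "CouplingStrengths",
    "build_mrs",
    "correlog_groups",
    "intergroup_anti_fraction",
    "coupling_strengths",
    "obligatory_flag",
    "check_mrs_invariants",
    "mrs_to_networkx",
    "write_mrs_edges",
    "write_groups",
]


@dataclass
class MRSGraph:
    """Directed two-category backbone.

    ``correlog_out[g] = (target, weight)`` with weight > 0;
    ``anticorrelog_out[g] = (target, weight)`` with weight < 0.
    A gene missing from a map has no out-edge of that category.
    """

    nodes: list[str]
    correlog_out: dict[str, tuple[str, float]] = field(default_factory=dict)
    anticorrelog_out: dict[str, tuple[str, float]] = field(default_factory=dict)


@dataclass
class CorrelogGroupSet:
    """Partition of the MRS nodes by undirected correlog connectivity.

    Group ids are 1-based, assigned in decreasing size then lexicographic
    order of the smallest member id.
    """

    group_of: dict[str, int]
    members: dict[int, list[str]]

    @property
    def sizes(self) -> dict[int, int]:
        return {g: len(m) for g, m in self.members.items()}

    @property
    def n_groups(self) -> int:
        return len(self.members)


@dataclass
class CouplingStrengths:
    """Per-gene summed positive (s_pos) and absolute negative (s_neg) weights."""

    gene_ids: list[str]
    s_pos: np.ndarray
    s_neg: np.ndarray


def _validate_weight_matrix(w: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    w = np.asarray(w, dtype=np.float64)
    if w.shape != (len(gene_ids), len(gene_ids)):
        raise ValueError("weight matrix shape does not match gene_ids")
    if w.size and np.abs(w - w.T).max() > 1e-10:
        raise ValueError("weight matrix must be symmetric")
    if w.size and np.abs(np.diag(w)).max() != 0.0:
        raise ValueError("weight matrix must have zero diagonal")
    return w


def build_mrs(w: np.ndarray, gene_ids: list[str]) -> MRSGraph:
    """Point each gene at its strongest positive and strongest negative partner.

    Ties at equal weight are broken by lexicographic gene id (deterministic).
    A gene with no positive (negative) partner gets no correlog
    (anti-correlog) out-edge; weights exactly zero belong to neither
    category.
    """
    w = _validate_weight_matrix(w, gene_ids)
    mrs = MRSGraph(list(gene_ids))
    order = np.argsort(np.array(gene_ids, dtype=object))  # lexicographic tie-break
    for i in range(len(gene_ids)):
        row = w[i]
        pos = row > 0
        if pos.any():
            best = row[pos].max()
            cands = [j for j in order if pos[j] and row[j] == best]
            mrs.correlog_out[gene_ids[i]] = (gene_ids[cands[0]], float(best))
        neg = row < 0
        if neg.any():
            worst = row[neg].min()
            cands = [j for j in order if neg[j] and row[j] == worst]
            mrs.anticorrelog_out[gene_ids[i]] = (gene_ids[cands[0]], float(worst))
    return mrs


def correlog_groups(mrs: MRSGraph) -> CorrelogGroupSet:
    """Connected components of the undirected projection of correlog edges."""
    g = nx.Graph()
    g.add_nodes_from(mrs.nodes)
    for src, (dst, _) in mrs.correlog_out.items():
        g.add_edge(src, dst)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    group_of: dict[str, int] = {}
    members: dict[int, list[str]] = {}
    for gid, comp in enumerate(comps, start=1):
        members[gid] = comp
        for node in comp:
            group_of[node] = gid
    return CorrelogGroupSet(group_of, members)


def intergroup_anti_fraction(
    mrs: MRSGraph, groups: CorrelogGroupSet
) -> float | None:
    """Fraction of anti-correlog edges whose endpoints lie in different groups.

    Returns None when the MRS carries no anti-correlog edges (undefined).
    """
    total = len(mrs.anticorrelog_out)
    if total == 0:
        return None
    inter = sum(
        1
        for src, (dst, _) in mrs.anticorrelog_out.items()
        if groups.group_of[src] != groups.group_of[dst]
    )
    return inter / total


def coupling_strengths(w: np.ndarray, gene_ids: list[str]) -> CouplingStrengths:
    """S_i^p = sum of positive weights around i; S_i^n = sum of |negative| weights."""
    w = _validate_weight_matrix(w, gene_ids)
    s_pos = np.where(w > 0, w, 0.0).sum(axis=1)
    s_neg = np.where(w < 0, -w, 0.0).sum(axis=1)
    return CouplingStrengths(list(gene_ids), s_pos, s_neg)


def obligatory_flag(
    w: np.ndarray, gene_ids: list[str], threshold: float = 0.045
) -> list[tuple[str, str, float, bool]]:
    """Label each unordered pair by the obligatory-association regime.

    A pair is flagged when its weight strictly exceeds ``threshold``
    (default 0.045); the regime separates strongly coupled pairs from
    conditional or transient ones.
    """
    w = _validate_weight_matrix(w, gene_ids)
    out = []
    for i in range(len(gene_ids)):
        for j in range(i + 1, len(gene_ids)):
            out.append(
                (gene_ids[i], gene_ids[j], float(w[i, j]), bool(w[i, j] > threshold))
            )
    return out


def check_mrs_invariants(mrs: MRSGraph, groups: CorrelogGroupSet | None = None) -> None:
    """Assert the structural invariants of a valid MRS.

    - out-degree per category <= 1 (by construction of the maps);
    - every correlog edge weight > 0, every anti-correlog weight < 0;
    - along the chain of correlog out-edges, weights never decrease until a
      reciprocal pair is reached;
    - every non-singleton correlog component contains a reciprocal pair;
    - groups partition the node set.
    """
    node_set = set(mrs.nodes)
    for src, (dst, wt) in mrs.correlog_out.items():
        if wt <= 0:
            raise AssertionError(f"correlog edge {src}->{dst} has weight {wt} <= 0")
        if src not in node_set or dst not in node_set:
            raise AssertionError("edge references unknown node")
        nxt = mrs.correlog_out.get(dst)
        if nxt is not None and nxt[0] != src and nxt[1] < wt:
            raise AssertionError(
                f"weight decreases along chain {src}->{dst}->{nxt[0]} "
                f"({wt} -> {nxt[1]}) without a reciprocal pair"
            )
    for src, (dst, wt) in mrs.anticorrelog_out.items():
        if wt >= 0:
            raise AssertionError(f"anti edge {src}->{dst} has weight {wt} >= 0")
    if groups is None:
        groups = correlog_groups(mrs)
    covered = [n for mem in groups.members.values() for n in mem]
    if sorted(covered) != sorted(mrs.nodes):
        raise AssertionError("groups do not partition the node set")
    for gid, mem in groups.members.items():
        if len(mem) == 1:
            continue
        has_reciprocal = any(
            mrs.correlog_out.get(mrs.correlog_out[n][0], (None,))[0] == n
            for n in mem
            if n in mrs.correlog_out
        )
        if not has_reciprocal:
            raise AssertionError(f"group {gid} has no reciprocal correlog pair")


def mrs_to_networkx(mrs: MRSGraph) -> nx.DiGraph:
    """Directed graph with ``w`` and ``category`` edge attributes (GraphML-ready)."""
    g = nx.DiGraph()
    g.add_nodes_from(mrs.nodes)
    for src, (dst, wt) in mrs.correlog_out.items():
        g.add_edge(src, dst, w=wt, category="correlog")
    for src, (dst, wt) in mrs.anticorrelog_out.items():
        # parallel category edges are rare but possible; keep the correlog one
        if not g.has_edge(src, dst):
            g.add_edge(src, dst, w=wt, category="anticorrelog")
    return g


def write_mrs_edges(mrs: MRSGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tw\tcategory\n")
        for src, (dst, wt) in sorted(mrs.correlog_out.items()):
            fh.write(f"{src}\t{dst}\t{wt:.10g}\tcorrelog\n")
        for src, (dst, wt) in sorted(mrs.anticorrelog_out.items()):
            fh.write(f"{src}\t{dst}\t{wt:.10g}\tanticorrelog\n")


def write_groups(groups: CorrelogGroupSet, path) -> None:
    sizes = groups.sizes
    with open(path, "w") as fh:
        fh.write("gene_id\tgroup_id\tgroup_size\n")
        for gid in sorted(groups.members):
            for gene in groups.members[gid]:
                fh.write(f"{gene}\t{gid}\t{sizes[gid]}\n")
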