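"""Weighted undirected gene networks.

Two sources feed the ranking stage: a precomputed association network
read from a STRING-style edge list (``protein1 protein2 combined_score``
with scores on the 0-1000 confidence scale), or a co-expression network
constructed WGCNA-style from the development expression matrix as a
soft-thresholded power of the pairwise correlation, a_ij = |c_ij|^beta.

The container is :class:`GeneNetwork`: an ordered node list plus a
symmetric sparse adjacency with weights in (0, 1].  The weighted degree
deg_i = sum_j m_ij normalizes outgoing score mass during propagation;
isolated (dangling) nodes have degree 0 and emit nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GeneNetwork",
    "load_string_network",
    "build_coexpression_network",
    "pick_soft_threshold",
    "restrict_to",
]


@dataclass
class GeneNetwork:
    """Undirected weighted graph over genes.

    Attributes
    ----------
    node_ids
        Ordered gene identifiers (pandas Index, unique).
    adjacency
        Symmetric ``N x N`` CSR matrix of edge weights in (0, 1],
        zero diagonal.
    """

    node_ids: pd.Index
    adjacency: sp.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        self.node_ids = pd.Index(self.node_ids).astype(str)
        if self.node_ids.has_duplicates:
            raise ValueError("duplicate node IDs in network")
        a = sp.csr_matrix(self.adjacency, dtype=float)
        if a.shape != (len(self.node_ids),) * 2:
            raise ValueError(
                f"adjacency shape {a.shape} does not match {len(self.node_ids)} nodes"
            )
        a.eliminate_zeros()
        if a.diagonal().any():
            a = sp.csr_matrix(a - sp.diags(a.diagonal()))
        if (abs(a - a.T) > 1e-12 * max(1.0, abs(a).max())).nnz:
            raise ValueError("adjacency must be symmetric")
        if a.nnz and (a.data <= 0).any() or a.nnz and (a.data > 1 + 1e-12).any():
            raise ValueError("edge weights must lie in (0, 1]")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def degree(self) -> np.ndarray:
        """Weighted degree deg_i = sum_j m_ij (float array, 0 for isolated)."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def edges(self) -> pd.DataFrame:
        """Upper-triangle edge table ``gene_a, gene_b, weight``."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return pd.DataFrame(
            {
                "gene_a": self.node_ids[coo.row],
                "gene_b": self.node_ids[coo.col],
                "weight": coo.data,
            }
        )

    @classmethod
    def from_edges(
        cls, node_ids, gene_a, gene_b, weight
    ) -> "GeneNetwork":
        """Build from parallel edge arrays; (i,j)/(j,i) duplicates keep the max."""
        node_ids = pd.Index(node_ids).astype(str)
        pos = {g: k for k, g in enumerate(node_ids)}
        i = np.fromiter((pos[str(g)] for g in gene_a), dtype=int, count=len(gene_a))
        j = np.fromiter((pos[str(g)] for g in gene_b), dtype=int, count=len(gene_b))
        w = np.asarray(weight, dtype=float)
        keep = i != j  # drop self-loops
        i, j, w = i[keep], j[keep], w[keep]
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        n = len(node_ids)
        # keep-max over duplicate orientations via dok accumulation
        upper: dict[tuple[int, int], float] = {}
        for a, b, ww in zip(lo, hi, w):
            key = (int(a), int(b))
            if ww > upper.get(key, 0.0):
                upper[key] = float(ww)
        if upper:
            rows, cols = zip(*upper)
            data = np.fromiter(upper.values(), dtype=float, count=len(upper))
            m = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
            adj = sp.csr_matrix(m + m.T)
        else:
            adj = sp.csr_matrix((n, n))
        return cls(node_ids, adj)

    def to_networkx(self):
        """Export to a networkx Graph (isolated nodes preserved)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for row in self.edges().itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, weight=row.weight)
        return g

    def write(self, edge_path, node_path=None) -> None:
        """Write a 3-column edge list TSV, plus a node list to keep isolates."""
        self.edges().to_csv(edge_path, sep="\t", index=False)
        if node_path is not None:
            pd.Series(self.node_ids).to_csv(
                node_path, sep="\t", index=False, header=["gene_id"]
            )

    @classmethod
    def read(cls, edge_path, node_path=None) -> "GeneNetwork":
        edges = pd.read_csv(edge_path, sep="\t", dtype={0: str, 1: str})
        if node_path is not None:
            nodes = pd.read_csv(node_path, sep="\t")["gene_id"].astype(str)
            node_ids = pd.Index(nodes)
        else:
            node_ids = pd.Index(
                pd.unique(pd.concat([edges.iloc[:, 0], edges.iloc[:, 1]]))
            )
        return cls.from_edges(
            node_ids, edges.iloc[:, 0], edges.iloc[:, 1], edges.iloc[:, 2]
        )


def load_string_network(
    path, score_cutoff: int = 400, node_list=None
) -> GeneNetwork:
    """Read a STRING-style edge list into a :class:`GeneNetwork`.

    Lines are whitespace/tab delimited ``id1 id2 combined_score`` with
    integer scores on the 0-1000 confidence scale (a header line is
    tolerated).  Edges with score >= ``score_cutoff`` are kept with
    weight ``score / 1000``; duplicate orientations keep the max score;
    self-loops are dropped.  Default cutoff 400 is the conventional
    "medium confidence" threshold.

    ``node_list`` (optional iterable of IDs) preserves genes whose only
    edges fall below the cutoff as isolated nodes; otherwise only genes
    incident to a surviving edge appear.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] != 3:
        raise ValueError(f"expected 3 columns in {path}, got {df.shape[1]}")
    scores = pd.to_numeric(df.iloc[:, 2], errors="coerce")
    if scores.isna().iloc[0] and not scores.isna().iloc[1:].any():
        df = df.iloc[1:]  # header line
        scores = scores.iloc[1:]
    if scores.isna().any():
        bad = df.iloc[:, 2][scores.isna()].iloc[0]
        raise ValueError(f"non-numeric combined_score {bad!r} in {path}")
    scores = scores.astype(float)
    if ((scores < 0) | (scores > 1000)).any():
        bad = scores[(scores < 0) | (scores > 1000)].iloc[0]
        raise ValueError(f"combined_score {bad} outside [0, 1000] in {path}")
    keep = scores >= score_cutoff
    a = df.iloc[:, 0][keep].astype(str)
    b = df.iloc[:, 1][keep].astype(str)
    w = scores[keep] / 1000.0
    if node_list is not None:
        node_ids = pd.Index(pd.Series(list(node_list)).astype(str))
    else:
        node_ids = pd.Index(pd.unique(pd.concat([a, b])))
    if len(node_ids) == 0:
        raise ValueError(f"no edges pass score cutoff {score_cutoff} in {path}")
    return GeneNetwork.from_edges(node_ids, a, b, w)


def _gene_correlations(expr: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise gene-gene Pearson correlations; returns (c, constant_mask)."""
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    c = np.atleast_2d(c)
    c[np.isnan(c)] = 0.0  # constant genes: undefined -> no edges
    np.fill_diagonal(c, 0.0)
    return np.clip(c, -1.0, 1.0), constant


def build_coexpression_network(
    expr: pd.DataFrame,
    beta: int = 6,
    edge_floor: float = 0.01,
    signed: bool = False,
    tom: bool = False,
) -> GeneNetwork:
    """Soft-thresholded co-expression adjacency over the genes of ``expr``.

    Unsigned (default): a_ij = |c_ij|^beta; signed variant uses
    ((1 + c_ij) / 2)^beta.  Entries <= ``edge_floor`` are dropped to
    sparsify the otherwise complete graph (floor 0 keeps everything).
    With ``tom=True`` the adjacency is replaced by the topological
    overlap measure before flooring.  Constant genes end up isolated
    (their correlations are undefined) with a warning.
    """
    if expr.shape[1] < 3:
        raise ValueError(f"need >= 3 samples, got {expr.shape[1]}")
    if not 0.0 <= edge_floor < 1.0:
        raise ValueError(f"edge_floor must be in [0, 1), got {edge_floor}")
    c, constant = _gene_correlations(expr)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s) left isolated in "
            "the co-expression network",
            stacklevel=2,
        )
    if signed:
        a = ((1.0 + c) / 2.0) ** beta
        a[constant, :] = 0.0
        a[:, constant] = 0.0
        np.fill_diagonal(a, 0.0)
    else:
        a = np.abs(c) ** beta
    if tom:
        a = _topological_overlap(a)
    a[a <= edge_floor] = 0.0
    np.clip(a, 0.0, 1.0, out=a)
    return GeneNetwork(pd.Index(expr.index), sp.csr_matrix(a))


def _topological_overlap(a: np.ndarray) -> np.ndarray:
    """Unsigned TOM: (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), L = A @ A."""
    k = a.sum(axis=1)
    num = a @ a + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = num / den
    t[~np.isfinite(t)] = 0.0
    np.fill_diagonal(t, 0.0)
    return t


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Sign-adjusted scale-free-topology fit R^2 of a connectivity vector.

    Bins the positive connectivities into ``n_bins`` equal-width bins,
    regresses log10(frequency) on log10(mean connectivity per occupied
    bin) and returns -sign(slope) * R^2, so heavy right tails (negative
    slope, the scale-free signature) score positive.  Returns NaN when
    fewer than 3 occupied bins exist (degenerate distribution).
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) == 0.0:
        return float("nan")
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return float("nan")
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = slope * np.asarray(xs) + intercept
    resid = np.asarray(ys) - fitted
    tss = np.sum((np.asarray(ys) - np.mean(ys)) ** 2)
    if tss == 0.0:
        return float("nan")
    r2 = 1.0 - float(np.sum(resid**2)) / float(tss)
    return float(-np.sign(slope) * r2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_betas=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12),
    r2_target: float = 0.8,
    fallback_beta: int = 6,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by the scale-free-topology criterion.

    For each candidate beta the full (un-floored) unsigned adjacency is
    formed, per-gene connectivity k_i = sum_j |c_ij|^beta computed, and
    the sign-adjusted fit R^2 of log10 frequency vs log10 binned
    connectivity evaluated.  The smallest beta reaching ``r2_target``
    wins; if none does, the beta maximizing R^2; if every fit is
    degenerate, ``fallback_beta`` with a warning.

    Returns ``(beta, table)`` where the table has one row per candidate
    with columns ``beta, r_squared, mean_connectivity``.
    """
    candidate_betas = list(candidate_betas)
    if not candidate_betas:
        raise ValueError("candidate_betas is empty")
    c, _ = _gene_correlations(expr)
    ac = np.abs(c)
    rows = []
    for beta in candidate_betas:
        a = ac**beta
        k = a.sum(axis=1)
        rows.append(
            {"beta": beta, "r_squared": scale_free_fit(k), "mean_connectivity": k.mean()}
        )
    table = pd.DataFrame(rows)
    usable = table.dropna(subset=["r_squared"])
    if usable.empty:
        warnings.warn(
            f"scale-free fit undefined for all candidates; falling back to "
            f"beta = {fallback_beta}",
            stacklevel=2,
        )
        return fallback_beta, table
    good = usable[usable["r_squared"] >= r2_target]
    if not good.empty:
        beta = int(good.sort_values("beta").iloc[0]["beta"])
    else:
        beta = int(usable.loc[usable["r_squared"].idxmax(), "beta"])
    return beta, table


def restrict_to(net: GeneNetwork, gene_ids) -> GeneNetwork:
    """Induced subgraph on ``gene_ids``, adding missing genes as isolates.

    Every requested gene exists in the result: genes present in the
    network keep their mutual edges, genes absent from it are added with
    degree zero, and network nodes outside ``gene_ids`` are dropped.
    """
    gene_ids = pd.Index(pd.Series(list(gene_ids)).astype(str))
    if gene_ids.has_duplicates:
        raise ValueError("duplicate gene IDs in restriction set")
    if len(gene_ids) == 0:
        raise ValueError("empty restriction set")
    present = gene_ids.isin(net.node_ids)
    idx = net.node_ids.get_indexer(gene_ids[present])
    n = len(gene_ids)
    sub = net.adjacency[np.ix_(idx, idx)]
    adj = sp.lil_matrix((n, n))
    where = np.flatnonzero(present)
    adj[np.ix_(where, where)] = sub
    return GeneNetwork(gene_ids, sp.csr_matrix(adj))
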