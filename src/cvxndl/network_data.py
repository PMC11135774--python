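"""Genomic binning, hypergraph construction and clique expansion.

Multiway contact data (e.g. droplet-based multiplex chromatin interaction
assays) record sets of genomic fragments captured together.  Fragments are
mapped to fixed-width genomic bins by their midpoint, each multiway contact
becomes a hyperedge over bins, and the hypergraph is collapsed to an
ordinary undirected network by clique expansion.  Downstream sampling and
learning operate on the largest connected component of that network.

Coordinates are 0-based, half-open (BED convention).  Bins are half-open
``[m*bin_size, (m+1)*bin_size)`` and a fragment belongs to the bin
containing ``floor((start + end) / 2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicBin",
    "Hypergraph",
    "Network",
    "bin_fragments",
    "build_hypergraph",
    "clique_expand",
    "largest_component",
    "read_hyperedge_tsv",
    "read_edge_list",
    "write_edge_list",
    "write_bin_table",
]


@dataclass(frozen=True)
class GenomicBin:
    """A fixed-width genomic bin acting as one network node.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based bin start; must be a multiple of ``size``.
    size : int
        Bin width in bases (default 500).
    node_id : int
        Non-negative contiguous node index within the network.
    """

    chrom: str
    start: int
    size: int
    node_id: int

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("bin size must be positive")
        if self.start % self.size != 0:
            raise ValueError("bin start must be a multiple of bin size")
        if self.node_id < 0:
            raise ValueError("node_id must be non-negative")

    @property
    def midpoint(self) -> float:
        return self.start + self.size / 2.0


@dataclass
class Hypergraph:
    """A hypergraph over binned genomic loci.

    ``hyperedges`` are frozensets of node ids in ``[0, n_nodes)``; every
    hyperedge has at least two distinct members.
    """

    n_nodes: int
    hyperedges: list[frozenset[int]]

    def __post_init__(self) -> None:
        for e in self.hyperedges:
            if len(e) < 2:
                raise ValueError("hyperedges must contain >= 2 distinct nodes")
            if min(e) < 0 or max(e) >= self.n_nodes:
                raise ValueError("hyperedge node id out of range")

    def __len__(self) -> int:
        return len(self.hyperedges)


@dataclass
class Network:
    """Undirected binary-adjacency network.

    ``adjacency`` is a symmetric CSR boolean/0-1 matrix with a zero
    diagonal; only nonzeros are stored.  ``bins`` optionally carries the
    genomic bin table (one row per node).  ``node_map`` records the mapping
    from original to current node ids after component restriction.
    """

    adjacency: sp.csr_matrix
    bins: pd.DataFrame | None = None
    node_map: dict[int, int] | None = None
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        A = sp.csr_matrix(self.adjacency)
        A.data = np.ones_like(A.data)
        A.setdiag(0)
        A.eliminate_zeros()
        if (A != A.T).nnz:
            raise ValueError("adjacency must be symmetric")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def degrees(self) -> np.ndarray:
        if getattr(self, "_degrees", None) is None:
            self._degrees = np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)
        return self._degrees

    def neighbors(self, u: int) -> np.ndarray:
        A = self.adjacency
        return A.indices[A.indptr[u] : A.indptr[u + 1]]

    def is_connected(self) -> bool:
        ncomp, _ = sp.csgraph.connected_components(self.adjacency, directed=False)
        return ncomp <= 1

    def to_networkx(self):
        import networkx as nx

        return nx.from_scipy_sparse_array(self.adjacency)


def bin_fragments(
    fragments: list[tuple[str, int, int]], bin_size: int = 500
) -> tuple[list[int], pd.DataFrame]:
    """Map genomic fragments to bin node ids via the fragment midpoint.

    Bins are half-open ``[m*bin_size, (m+1)*bin_size)`` and each fragment
    goes to the bin containing ``floor((start+end)/2)``.  Node ids are
    assigned contiguously, per chromosome in lexicographic order and in
    genomic order within a chromosome, over the bins actually observed.

    Parameters
    ----------
    fragments : list of (chrom, start, end)
        0-based half-open fragment coordinates.
    bin_size : int
        Bin width in bases.

    Returns
    -------
    node_ids : list of int
        One node id per input fragment (same order).
    bin_table : pandas.DataFrame
        Columns ``chrom, start, size, node_id``, one row per distinct bin.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    keys = []
    for i, (chrom, start, end) in enumerate(fragments):
        if start < 0:
            raise ValueError(f"fragment {i} ({chrom}:{start}-{end}): negative start")
        if end <= start:
            raise ValueError(f"fragment {i} ({chrom}:{start}-{end}): end <= start")
        mid = (start + end) // 2
        keys.append((chrom, mid // bin_size))
    distinct = sorted(set(keys))
    index = {key: j for j, key in enumerate(distinct)}
    node_ids = [index[key] for key in keys]
    bin_table = pd.DataFrame(
        {
            "chrom": [c for c, _ in distinct],
            "start": [m * bin_size for _, m in distinct],
            "size": bin_size,
            "node_id": np.arange(len(distinct)),
        }
    )
    return node_ids, bin_table


def build_hypergraph(binned_complexes: list[set[int] | list[int]]) -> Hypergraph:
    """Build a hypergraph from binned multiway complexes.

    Each complex is deduplicated (a fragment set mapping twice to one bin
    counts once); complexes left with fewer than two distinct bins are
    dropped.  The node universe is the union of observed bins, re-indexed
    contiguously in increasing original-id order.
    """
    if not binned_complexes:
        raise ValueError("no input complexes")
    edges = []
    for cx in binned_complexes:
        s = frozenset(int(v) for v in cx)
        if len(s) >= 2:
            edges.append(s)
    if not edges:
        raise ValueError("no hyperedge of size >= 2 after deduplication")
    universe = sorted(set().union(*edges))
    remap = {old: new for new, old in enumerate(universe)}
    hyperedges = [frozenset(remap[v] for v in e) for e in edges]
    return Hypergraph(n_nodes=len(universe), hyperedges=hyperedges)


def clique_expand(H: Hypergraph) -> Network:
    """Clique-expand a hypergraph into an undirected binary network.

    Edge (u, v) is present iff some hyperedge contains both u and v.  Large
    hyperedges can create spurious cliques among nodes that never co-occur
    as a group elsewhere; that distortion is inherent to the expansion.
    """
    rows, cols = [], []
    for e in H.hyperedges:
        nodes = sorted(e)
        for i, u in enumerate(nodes):
            for v in nodes[i + 1 :]:
                rows.append(u)
                cols.append(v)
    data = np.ones(len(rows), dtype=np.int8)
    A = sp.coo_matrix((data, (rows, cols)), shape=(H.n_nodes, H.n_nodes))
    A = A + A.T
    A = (A > 0).astype(np.int8).tocsr()
    return Network(adjacency=A)


def largest_component(G: Network) -> Network:
    """Restrict a network to its largest connected component.

    Nodes are re-indexed contiguously preserving order; the old->new id
    mapping is kept on the result.  The share of dropped nodes is logged.
    """
    if G.n_nodes == 0:
        raise ValueError("empty network")
    ncomp, labels = sp.csgraph.connected_components(G.adjacency, directed=False)
    if ncomp <= 1:
        return Network(
            adjacency=G.adjacency,
            bins=G.bins,
            node_map={i: i for i in range(G.n_nodes)},
            labels=G.labels,
        )
    sizes = np.bincount(labels)
    keep = np.flatnonzero(labels == sizes.argmax())
    dropped = 1.0 - len(keep) / G.n_nodes
    logger.info(
        "restricting to largest component: %d/%d nodes kept (%.1f%% dropped)",
        len(keep),
        G.n_nodes,
        100 * dropped,
    )
    A = G.adjacency[np.ix_(keep, keep)].tocsr()
    node_map = {int(old): new for new, old in enumerate(keep)}
    bins = None
    if G.bins is not None:
        bins = G.bins[G.bins["node_id"].isin(keep)].copy()
        bins["node_id"] = bins["node_id"].map(node_map)
        bins = bins.reset_index(drop=True)
    lab = G.labels[keep] if G.labels is not None else None
    return Network(adjacency=A, bins=bins, node_map=node_map, labels=lab)


# ---------------------------------------------------------------------------
# I/O


def read_hyperedge_tsv(
    path, bin_size: int = 500, max_hyperedge_size: int | None = None
) -> tuple[Hypergraph, pd.DataFrame | None]:
    """Read a hyperedge file, one multiway complex per line.

    Two dialects are auto-detected from the first non-empty line:

    * fragment lists: ``chrom:start-end;chrom:start-end;...`` — fragments
      are binned by midpoint at ``bin_size``;
    * integer node ids: comma-separated ids, pre-binned.

    Returns the hypergraph and the bin table (None for the integer
    dialect).  Complexes larger than ``max_hyperedge_size`` (in distinct
    bins) are discarded when a cap is given.
    """
    lines = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                lines.append(line)
    if not lines:
        raise ValueError(f"{path}: empty hyperedge file")
    fragment_dialect = ":" in lines[0]
    bin_table = None
    if fragment_dialect:
        frags: list[tuple[str, int, int]] = []
        complex_slices = []
        for ln, line in enumerate(lines, 1):
            start_idx = len(frags)
            for tok in line.replace("\t", ";").split(";"):
                tok = tok.strip()
                if not tok:
                    continue
                try:
                    chrom, span = tok.split(":")
                    lo, hi = span.split("-")
                    frags.append((chrom, int(lo), int(hi)))
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: cannot parse fragment {tok!r}") from exc
            complex_slices.append((start_idx, len(frags)))
        node_ids, bin_table = bin_fragments(frags, bin_size=bin_size)
        complexes = [set(node_ids[a:b]) for a, b in complex_slices]
    else:
        complexes = []
        for ln, line in enumerate(lines, 1):
            try:
                ids = {int(tok) for tok in line.replace("\t", ",").split(",") if tok.strip()}
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: cannot parse node ids") from exc
            complexes.append(ids)
    if max_hyperedge_size is not None:
        complexes = [c for c in complexes if len(c) <= max_hyperedge_size]
    H = build_hypergraph(complexes)
    return H, bin_table


def read_edge_list(path) -> Network:
    """Read an undirected 2-column TSV edge list (no header)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", names=["u", "v"])
    if df.empty:
        raise ValueError(f"{path}: empty edge list")
    n = int(max(df["u"].max(), df["v"].max())) + 1
    A = sp.coo_matrix(
        (np.ones(len(df)), (df["u"], df["v"])), shape=(n, n)
    )
    A = ((A + A.T) > 0).astype(np.int8).tocsr()
    return Network(adjacency=A)


def write_edge_list(G: Network, path) -> None:
    """Write the upper-triangle edge list as 2-column TSV."""
    coo = sp.triu(G.adjacency, k=1).tocoo()
    with open(path, "w") as fh:
        for u, v in zip(coo.row, coo.col):
            fh.write(f"{u}\t{v}\n")


def write_bin_table(bin_table: pd.DataFrame, path) -> None:
    """Write the bin table as BED: chrom, start, start+size, node_id."""
    with open(path, "w") as fh:
        for row in bin_table.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.start + row.size}\t{row.node_id}\n")
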