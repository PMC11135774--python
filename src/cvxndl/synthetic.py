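"""Synthetic benchmark networks and baseline dictionaries.

Real multiway chromatin contact data yields sparse, community-structured
networks after clique expansion.  Two generators emulate the features the
learner depends on: a stochastic block model (SBM) for end-to-end
reconstruction validation, and planted-motif networks — disjoint copies of
known small subnetworks joined by sparse linkers — for parameter-recovery
tests.  A random-dictionary baseline (convex combinations of uniformly
drawn patches, ignoring fit) provides the illustrative lower bound for
reconstruction scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .learner import Dictionary
from .network_data import Network, largest_component

__all__ = [
    "SBMSpec",
    "sbm_generate",
    "planted_motif_network",
    "difference_set_bipartite",
    "random_dictionary",
]


@dataclass(frozen=True)
class SBMSpec:
    """Stochastic block model parameters.

    Defaults give a sparse, clearly blocked graph (3 blocks of 100 nodes,
    p_in = 0.3, p_out = 0.02) in which short paths mostly stay within
    blocks.
    """

    block_sizes: tuple[int, ...] = (100, 100, 100)
    p_in: float = 0.3
    p_out: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.block_sizes or any(s <= 0 for s in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("require 0 <= p_out <= p_in <= 1")

    @property
    def n_nodes(self) -> int:
        return int(sum(self.block_sizes))


def sbm_generate(
    spec: SBMSpec, rng: np.random.Generator | None = None
) -> Network:
    """Generate an SBM network restricted to its largest component.

    Edges are independent Bernoulli draws with probability ``p_in`` within
    a block and ``p_out`` between blocks.  Node order groups blocks
    contiguously, so the adjacency exhibits the community structure
    directly; ``labels`` on the result carries block membership, and
    ``node_map`` the pre-restriction ids.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    labels = np.repeat(np.arange(len(spec.block_sizes)), spec.block_sizes)
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(labels[iu] == labels[ju], spec.p_in, spec.p_out)
    mask = rng.random(len(p)) < p
    A = sp.coo_matrix(
        (np.ones(mask.sum(), dtype=np.int8), (iu[mask], ju[mask])), shape=(n, n)
    )
    A = (A + A.T).tocsr()
    G = Network(adjacency=A, labels=labels)
    return largest_component(G)


def planted_motif_network(
    motifs: list[np.ndarray],
    copies: int | list[int],
    linker: int,
    rng: np.random.Generator,
) -> Network:
    """Disjoint motif copies joined into one connected network.

    Each motif (a small symmetric 0/1 adjacency) is instantiated on fresh
    nodes, ``copies`` times (one count for all motifs, or one per motif —
    sampling visits regions in proportion to their walk weight, so copy
    counts are the lever to balance motif types of unequal size).  A
    spanning chain of single edges joins consecutive copies (guaranteeing
    connectivity), and ``linker`` additional random inter-copy edges are
    added.  ``labels`` on the result records, per node, the index of the
    motif the node belongs to (copies are laid out contiguously in node
    order).
    """
    mats = [np.asarray(m, dtype=np.int8) for m in motifs]
    for m in mats:
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("motifs must be square adjacency matrices")
        if not np.array_equal(m, m.T) or m.diagonal().any():
            raise ValueError("motifs must be symmetric with zero diagonal")
    n_copies = (
        [copies] * len(mats) if isinstance(copies, (int, np.integer)) else list(copies)
    )
    if len(n_copies) != len(mats):
        raise ValueError("need one copy count per motif")
    # round-robin layout: consecutive blocks alternate motif types, so the
    # spanning-chain edges join unlike copies and rarely create walks that
    # stay within one motif type while crossing copies
    schedule: list[int] = []
    remaining = list(n_copies)
    while any(r > 0 for r in remaining):
        for mi in range(len(mats)):
            if remaining[mi] > 0:
                schedule.append(mi)
                remaining[mi] -= 1
    blocks = []
    labels = []
    offsets = []
    off = 0
    for mi in schedule:
        m = mats[mi]
        blocks.append(m)
        offsets.append(off)
        labels.extend([mi] * m.shape[0])
        off += m.shape[0]
    n = off
    A = sp.lil_matrix((n, n), dtype=np.int8)
    for b, o in zip(blocks, offsets):
        s = b.shape[0]
        A[o : o + s, o : o + s] = b
    # spanning chain between consecutive copies
    for i in range(len(blocks) - 1):
        u = offsets[i] + int(rng.integers(blocks[i].shape[0]))
        v = offsets[i + 1] + int(rng.integers(blocks[i + 1].shape[0]))
        A[u, v] = 1
        A[v, u] = 1
    # extra random inter-copy linkers
    added = 0
    guard = 0
    while added < linker and guard < 100 * max(linker, 1):
        guard += 1
        bi, bj = rng.integers(len(blocks), size=2)
        if bi == bj:
            continue
        u = offsets[bi] + int(rng.integers(blocks[bi].shape[0]))
        v = offsets[bj] + int(rng.integers(blocks[bj].shape[0]))
        if u != v and not A[u, v]:
            A[u, v] = 1
            A[v, u] = 1
            added += 1
    G = Network(adjacency=A.tocsr(), labels=np.asarray(labels))
    return largest_component(G)


def difference_set_bipartite(
    offsets: tuple[int, ...] = (0, 1, 3, 7, 12, 20, 30, 44),
    n_side: int = 89,
) -> np.ndarray:
    """Regular bipartite circulant graph from a planar difference set.

    Left node i connects to right nodes (i + o) mod n_side for each
    offset.  With a Sidon (B2) offset set whose pairwise differences are
    distinct mod n_side (defaults: the Mian-Chowla set mod 89, giving an
    8-regular graph) the graph has no 4-cycles (girth 6).
    Because the graph is bipartite and sparse, k-path walks induce almost
    exclusively the bare path patch — the third, "interaction-poor" motif
    type of the recovery benchmark, alongside the dense complete-bipartite
    (checkerboard patch) and clique (complete patch) types.
    """
    A = np.zeros((2 * n_side, 2 * n_side), dtype=np.int8)
    for i in range(n_side):
        for o in offsets:
            j = n_side + (i + o) % n_side
            A[i, j] = A[j, i] = 1
    return A


def random_dictionary(
    pool: np.ndarray,
    K: int,
    rng: np.random.Generator,
    min_reps: int = 10,
) -> Dictionary:
    """Baseline dictionary of uniform convex combinations of random patches.

    Each of the K elements averages ``min_reps`` patches drawn uniformly
    at random from the pool without regard to fit.  Satisfies every
    convex-interpretability invariant; used only as an illustrative lower
    bound for reconstruction quality.
    """
    pool = np.asarray(pool, dtype=np.float64)
    if pool.shape[0] < K * min_reps:
        raise ValueError(
            f"pool of {pool.shape[0]} patches too small for "
            f"K*min_reps = {K * min_reps}"
        )
    choice = rng.choice(pool.shape[0], size=K * min_reps, replace=False)
    reps, weights = [], []
    for j in range(K):
        idx = choice[j * min_reps : (j + 1) * min_reps]
        reps.append(pool[idx].T.copy())
        weights.append(np.full(min_reps, 1.0 / min_reps))
    return Dictionary(reps, weights)
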