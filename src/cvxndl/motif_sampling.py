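"""Template motifs, homomorphisms and MCMC subnetwork sampling.

A template motif ``F = ([k], A_F)`` is mapped into the input network ``G``
by homomorphisms: ordered k-tuples ``x`` of network nodes such that every
template edge lands on a network edge,

    prod_{i,j} A[x[i], x[j]] ** A_F[i,j] = 1        (0**0 = 1).

Homomorphisms need not be injective.  The induced k x k patch
``A_x[a,b] = A[x[a], x[b]]`` is the data sample fed to the dictionary
learner, flattened column-major to a d = k**2 vector.

For the default k-path template, samples are produced by a pivot Markov
chain: propose a uniformly random neighbor ``v`` of the current pivot
``x[1]``, accept with probability

    beta = min( W_{k-1}(v) / W_{k-1}(u) * deg(u) / deg(v), 1 ),

where ``W_{k-1}(u)`` counts length-(k-1) walks from ``u``, then regrow the
tail by a directed random walk of k-1 uniform neighbor steps.  The chain's
pivot marginal is proportional to ``W_{k-1}``; on regular graphs beta is
identically 1.  Backtracking walks are allowed — the homomorphism set
includes non-injective tuples, and excluding backtracking would change the
target distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_data import Network

__all__ = [
    "TemplateMotif",
    "Patch",
    "PatchPool",
    "k_path",
    "k_star",
    "enumerate_homomorphisms",
    "rejection_sample",
    "walk_weights",
    "acceptance_probability",
    "mcmc_step",
    "sample_stream",
    "stationary_homomorphism_distribution",
]

_ENUM_MAX_NODES = 30


@dataclass(frozen=True)
class TemplateMotif:
    """A k-node template network ``F = ([k], A_F)``."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=np.int8)
        if A.ndim != 2 or A.shape[0] != A.shape[1] or A.shape[0] < 2:
            raise ValueError("template adjacency must be square, k >= 2")
        if not np.array_equal(A, A.T) or A.diagonal().any():
            raise ValueError("template must be symmetric with zero diagonal")
        object.__setattr__(self, "adjacency", A)

    @property
    def k(self) -> int:
        return self.adjacency.shape[0]

    @property
    def d(self) -> int:
        return self.k * self.k

    @property
    def is_path(self) -> bool:
        return np.array_equal(self.adjacency, k_path(self.k).adjacency)


def k_path(k: int) -> TemplateMotif:
    """Path template on k nodes: edges (i, i+1) only."""
    A = np.zeros((k, k), dtype=np.int8)
    idx = np.arange(k - 1)
    A[idx, idx + 1] = 1
    A[idx + 1, idx] = 1
    return TemplateMotif(A)


def k_star(k: int) -> TemplateMotif:
    """Star template on k nodes: node 0 is the hub."""
    A = np.zeros((k, k), dtype=np.int8)
    A[0, 1:] = 1
    A[1:, 0] = 1
    return TemplateMotif(A)


@dataclass(frozen=True)
class Patch:
    """A sampled homomorphism with its induced adjacency patch."""

    nodes: tuple[int, ...]
    matrix: np.ndarray

    @property
    def flat(self) -> np.ndarray:
        """Column-major flattening to a length-k**2 vector."""
        return self.matrix.flatten(order="F").astype(np.float64)


def induced_patch(G: Network, nodes) -> Patch:
    """Build the k x k patch A_x[a,b] = A[x[a], x[b]] for a node tuple."""
    idx = np.asarray(nodes, dtype=np.int64)
    sub = G.adjacency[np.ix_(idx, idx)].toarray().astype(np.int8)
    np.fill_diagonal(sub, 0)
    return Patch(nodes=tuple(int(v) for v in idx), matrix=sub)


def is_homomorphism(G: Network, F: TemplateMotif, nodes) -> bool:
    """Check membership of a node tuple in Hom(F, G)."""
    if len(nodes) != F.k:
        return False
    A = G.adjacency
    for i in range(F.k):
        for j in range(F.k):
            if F.adjacency[i, j] and not A[nodes[i], nodes[j]]:
                return False
    return True


def enumerate_homomorphisms(
    G: Network, F: TemplateMotif
) -> list[tuple[int, ...]]:
    """Exhaustively enumerate Hom(F, G) as ordered node tuples.

    Brute-force backtracking over ordered k-tuples; guarded to small
    graphs (n <= 30) — use sampling for anything larger.
    """
    if G.n_nodes > _ENUM_MAX_NODES:
        raise ValueError(
            f"enumeration is limited to n <= {_ENUM_MAX_NODES} nodes; "
            "use MCMC or rejection sampling instead"
        )
    A = G.adjacency.toarray().astype(bool)
    k = F.k
    AF = F.adjacency
    out: list[tuple[int, ...]] = []

    def extend(partial: list[int]) -> None:
        pos = len(partial)
        if pos == k:
            out.append(tuple(partial))
            return
        for cand in range(G.n_nodes):
            ok = True
            for j in range(pos):
                if AF[pos, j] and not A[cand, partial[j]]:
                    ok = False
                    break
            if ok:
                partial.append(cand)
                extend(partial)
                partial.pop()

    extend([])
    return out


def rejection_sample(
    G: Network,
    F: TemplateMotif,
    rng: np.random.Generator,
    max_attempts: int = 100_000,
) -> tuple[int, ...]:
    """Draw one homomorphism by rejection.

    For the k-path template this is a uniform random start node followed by
    a directed random walk of k-1 uniform neighbor steps, which never
    rejects on a connected graph.  For generic motifs, uniform k-tuples are
    drawn and tested, with an attempt cap.
    """
    if F.is_path:
        start = int(rng.integers(G.n_nodes))
        return _grow_walk(G, start, F.k, rng)
    for _ in range(max_attempts):
        cand = tuple(int(v) for v in rng.integers(G.n_nodes, size=F.k))
        if is_homomorphism(G, F, cand):
            return cand
    raise RuntimeError("rejection sampling exceeded max_attempts")


def _grow_walk(G: Network, start: int, k: int, rng: np.random.Generator) -> tuple[int, ...]:
    walk = [start]
    for _ in range(k - 1):
        nbrs = G.neighbors(walk[-1])
        walk.append(int(nbrs[rng.integers(len(nbrs))]))
    return tuple(walk)


def walk_weights(G: Network, k: int) -> np.ndarray:
    """Row sums of A**(k-1): counts of length-(k-1) walks from each node.

    Computed by k-1 sparse mat-vec products on the all-ones vector — the
    full matrix power is never formed (n can be ~5e4).
    """
    w = np.ones(G.n_nodes, dtype=np.float64)
    for _ in range(k - 1):
        w = G.adjacency @ w
    return w


def acceptance_probability(
    G: Network, u: int, v: int, k: int, walk_w: np.ndarray | None = None
) -> float:
    """Pivot-move acceptance probability beta for the k-path chain.

    beta = min( W_{k-1}(v)/W_{k-1}(u) * deg(u)/deg(v), 1 ).
    """
    if not G.adjacency[u, v]:
        raise ValueError(f"nodes {u} and {v} are not adjacent")
    if walk_w is None:
        walk_w = walk_weights(G, k)
    deg = G.degrees()
    ratio = (walk_w[v] / walk_w[u]) * (deg[u] / deg[v])
    return float(min(ratio, 1.0))


def mcmc_step(
    G: Network,
    F: TemplateMotif,
    x_t: tuple[int, ...],
    rng: np.random.Generator,
    walk_w: np.ndarray | None = None,
) -> tuple[int, ...]:
    """One pivot-chain transition for the k-path template.

    Proposes v uniform from the neighborhood of the pivot x_t[1]; accepts
    with probability beta; regrows the tail by a fresh directed random walk
    either way.
    """
    if not F.is_path:
        raise ValueError("the pivot chain is defined for the k-path template")
    u = x_t[0]
    nbrs = G.neighbors(u)
    v = int(nbrs[rng.integers(len(nbrs))])
    beta = acceptance_probability(G, u, v, F.k, walk_w=walk_w)
    pivot = v if rng.uniform() < beta else u
    return _grow_walk(G, pivot, F.k, rng)


class PatchPool:
    """A pre-generated pool of sampled patches with node-tuple metadata.

    Stores flattened patches row-wise (T x d) alongside the sampled node
    tuples (T x k); sampling is performed up front and the learner streams
    from the pool.
    """

    def __init__(self, patches: np.ndarray, node_tuples: np.ndarray, k: int,
                 seed: int | None = None, burn_in: int | None = None):
        self.patches = np.asarray(patches, dtype=np.float64)
        self.node_tuples = np.asarray(node_tuples, dtype=np.int64)
        self.k = int(k)
        self.seed = seed
        self.burn_in = burn_in
        if self.patches.ndim != 2 or self.patches.shape[1] != k * k:
            raise ValueError("patches must be T x k**2")
        if self.node_tuples.shape != (self.patches.shape[0], k):
            raise ValueError("node_tuples must be T x k")

    def __len__(self) -> int:
        return self.patches.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.patches[i]

    def coverage(self, n_nodes: int) -> float:
        """Fraction of network nodes visited by at least one sample."""
        return len(np.unique(self.node_tuples)) / n_nodes

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            patches=self.patches,
            node_tuples=self.node_tuples,
            k=self.k,
            seed=-1 if self.seed is None else self.seed,
            burn_in=-1 if self.burn_in is None else self.burn_in,
        )

    @classmethod
    def load(cls, path) -> "PatchPool":
        with np.load(path) as z:
            seed = int(z["seed"])
            burn = int(z["burn_in"])
            return cls(
                z["patches"],
                z["node_tuples"],
                k=int(z["k"]),
                seed=None if seed < 0 else seed,
                burn_in=None if burn < 0 else burn,
            )


def sample_stream(
    G: Network,
    F: TemplateMotif,
    T: int,
    rng: np.random.Generator,
    burn_in: int = 1000,
) -> PatchPool:
    """Run the pivot chain and collect T patches after burn-in.

    The chain is initialized by rejection sampling and advanced with
    :func:`mcmc_step`; consecutive (correlated) samples are kept — no
    thinning, matching the online learner's tolerance for correlated
    streams.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    walk_w = walk_weights(G, F.k)
    x = rejection_sample(G, F, rng)
    for _ in range(burn_in):
        x = mcmc_step(G, F, x, rng, walk_w=walk_w)
    k = F.k
    patches = np.empty((T, k * k), dtype=np.float64)
    tuples = np.empty((T, k), dtype=np.int64)
    for t in range(T):
        x = mcmc_step(G, F, x, rng, walk_w=walk_w)
        patches[t] = induced_patch(G, x).flat
        tuples[t] = x
    return PatchPool(patches, tuples, k=k, burn_in=burn_in)


def stationary_homomorphism_distribution(
    G: Network, F: TemplateMotif
) -> dict[tuple[int, ...], float]:
    """Exact stationary distribution of the pivot chain over Hom(F, G).

    The pivot marginal is proportional to W_{k-1}(u); conditional on the
    pivot, a specific walk x has probability prod_i 1/deg(x[i]) over its
    k-1 steps.  Small-graph oracle for chain-correctness tests.
    """
    if not F.is_path:
        raise ValueError("stationary distribution derived for k-path only")
    homs = enumerate_homomorphisms(G, F)
    deg = G.degrees().astype(np.float64)
    ww = walk_weights(G, F.k)
    Z = ww.sum()
    out: dict[tuple[int, ...], float] = {}
    for x in homs:
        p = ww[x[0]] / Z
        for i in range(F.k - 1):
            p /= deg[x[i]]
        out[x] = float(p)
    return out
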