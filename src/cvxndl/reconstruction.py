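"""Network reconstruction from a learned dictionary and its evaluation.

A trained dictionary is judged by how well locally coded patches stitch
back into the input network: k-path homomorphisms are sampled by the same
pivot chain used for training, each induced patch is sparse-coded against
the dictionary, and the approximation ``D @ code`` (clipped to [0, 1]) is
accumulated onto the corresponding node pairs.  Averaging by per-pair
visit counts yields a symmetric score matrix ``W`` interpretable as edge
probabilities; ranking visited pairs by score against the true adjacency
gives the average precision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import average_precision_score

from .learner import sparse_code
from .motif_sampling import (
    induced_patch,
    k_path,
    mcmc_step,
    rejection_sample,
    walk_weights,
)
from .network_data import Network

logger = logging.getLogger(__name__)

__all__ = ["ReconstructionResult", "reconstruct", "average_precision"]


@dataclass
class ReconstructionResult:
    """Edge-score matrix from patch-wise reconstruction.

    ``W`` holds averaged approximation scores in [0, 1]; ``counts`` the
    per-pair visit counts.  Scores exist only where counts are nonzero.
    """

    W: sp.csr_matrix
    counts: sp.csr_matrix
    n_patches_used: int

    def visited_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle (row, col) indices of visited node pairs."""
        coo = sp.triu(self.counts, k=1).tocoo()
        return coo.row, coo.col

    def coverage(self, G: Network) -> float:
        """Fraction of true edges with at least one visit."""
        r, c = self.visited_pairs()
        A = G.adjacency
        hit = np.asarray(A[r, c]).ravel().sum()
        return float(hit) / max(G.n_edges, 1)

    def save(self, path) -> None:
        sp.save_npz(str(path) + ".W.npz", self.W)
        sp.save_npz(str(path) + ".counts.npz", self.counts)


def reconstruct(
    G: Network,
    D: np.ndarray,
    k: int,
    n_patches: int | None = None,
    lam: float = 1.0,
    rng: np.random.Generator | None = None,
    burn_in: int = 1000,
    homomorphisms: list[tuple[int, ...]] | None = None,
) -> ReconstructionResult:
    """Reconstruct edge scores by local patch approximation.

    For each sampled homomorphism x, the induced patch is coded against D,
    the approximation ``clip(D @ code, 0, 1)`` is accumulated onto node
    pairs ``(x[a], x[b])``, a != b, and every visited pair's count is
    incremented.  Diagonal entries of patch approximations are ignored
    (no self-edges).  Passing an explicit ``homomorphisms`` list bypasses
    sampling (used with exhaustive enumeration on small graphs).
    """
    if D.shape[0] != k * k:
        raise ValueError(
            f"dictionary dimension {D.shape[0]} does not match k**2 = {k * k}"
        )
    rng = np.random.default_rng() if rng is None else rng
    n = G.n_nodes
    F = k_path(k)
    # dense accumulators on moderate graphs; pair dicts for the general case
    dense = n <= 5000
    if dense:
        score = np.zeros((n, n))
        counts = np.zeros((n, n))
    else:
        score_d: dict[tuple[int, int], float] = {}
        count_d: dict[tuple[int, int], float] = {}

    if homomorphisms is None:
        if n_patches is None:
            n_patches = int(10 * n / k)
        if n_patches == 0:
            warnings.warn("n_patches=0: empty reconstruction")
            empty = sp.csr_matrix((n, n))
            return ReconstructionResult(W=empty, counts=empty.copy(), n_patches_used=0)
        walk_w = walk_weights(G, k)
        x = rejection_sample(G, F, rng)
        for _ in range(burn_in):
            x = mcmc_step(G, F, x, rng, walk_w=walk_w)
        tuples = []
        for _ in range(n_patches):
            x = mcmc_step(G, F, x, rng, walk_w=walk_w)
            tuples.append(x)
    else:
        tuples = list(homomorphisms)

    used = 0
    for x in tuples:
        patch = induced_patch(G, x)
        code = sparse_code(patch.flat, D, lam)
        approx = np.clip(D @ code, 0.0, 1.0).reshape(k, k, order="F")
        idx = np.asarray(x)
        for a in range(k):
            for b in range(k):
                if a == b or idx[a] == idx[b]:
                    continue
                u, v = int(idx[a]), int(idx[b])
                if dense:
                    score[u, v] += approx[a, b]
                    counts[u, v] += 1
                else:
                    key = (u, v)
                    score_d[key] = score_d.get(key, 0.0) + float(approx[a, b])
                    count_d[key] = count_d.get(key, 0.0) + 1.0
        used += 1

    if dense:
        score = 0.5 * (score + score.T)
        counts_sym = 0.5 * (counts + counts.T)
        with np.errstate(invalid="ignore", divide="ignore"):
            W = np.where(counts_sym > 0, score / np.maximum(counts_sym, 1e-300), 0.0)
        W_sp = sp.csr_matrix(W)
        counts_sp = sp.csr_matrix(counts_sym)
    else:
        rows = np.array([p[0] for p in count_d], dtype=np.int64)
        cols = np.array([p[1] for p in count_d], dtype=np.int64)
        svals = np.array([score_d[p] for p in count_d])
        cvals = np.array([count_d[p] for p in count_d])
        S = sp.coo_matrix((svals, (rows, cols)), shape=(n, n)).tocsr()
        C = sp.coo_matrix((cvals, (rows, cols)), shape=(n, n)).tocsr()
        S = 0.5 * (S + S.T)
        counts_sp = 0.5 * (C + C.T)
        W_sp = S.tocsr()
        nz = counts_sp.tocsr()
        W_sp.data = W_sp.data / nz.data
    result = ReconstructionResult(W=W_sp, counts=counts_sp, n_patches_used=used)
    logger.info(
        "reconstruction used %d patches; edge coverage %.3f",
        used,
        result.coverage(G),
    )
    return result


def average_precision(result: ReconstructionResult, G: Network) -> float:
    """Average precision of ranked edge prediction over visited pairs.

    Visited (unordered) pairs are ranked by their reconstruction score and
    compared with the true adjacency; unvisited pairs are excluded from
    the ranking.
    """
    if G.n_nodes != result.W.shape[0]:
        raise ValueError("node universe mismatch")
    r, c = result.visited_pairs()
    if len(r) == 0:
        raise ValueError("no visited pairs: nothing to evaluate")
    y_true = np.asarray(G.adjacency[r, c]).ravel().astype(int)
    y_score = np.asarray(result.W[r, c]).ravel()
    if y_true.max() == 0:
        raise ValueError("no true edges among visited pairs")
    return float(average_precision_score(y_true, y_score))


def evaluation_report(
    result: ReconstructionResult, G: Network, seed: int | None = None
) -> dict:
    """JSON-serializable evaluation summary."""
    return {
        "average_precision": average_precision(result, G),
        "edge_coverage": result.coverage(G),
        "n_patches": result.n_patches_used,
        "n_visited_pairs": int(len(result.visited_pairs()[0])),
        "seed": seed,
    }
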