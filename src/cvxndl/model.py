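"""Model/Results front end for online convex network dictionary learning.

:class:`ConvexNDL` wraps the full pipeline — pivot-chain patch sampling,
initialization, online convex dictionary updates — behind a statsmodels
style interface: build the model from a network (or input file), call
``fit()``, and receive a :class:`ConvexNDLResults` carrying the learned
dictionary, training diagnostics, per-element summaries and
reconstruction methods.  :class:`OnlineNDL` is the non-convex baseline
with the identical surface.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import learner, reconstruction
from .learner import CodingConfig, Dictionary, TrainingState
from .motif_sampling import PatchPool, k_path, sample_stream
from .network_data import (
    Network,
    clique_expand,
    largest_component,
    read_edge_list,
    read_hyperedge_tsv,
)

__all__ = ["ConvexNDL", "OnlineNDL", "ConvexNDLResults", "OnlineNDLResults"]


class _NDLBase:
    """Shared construction and sampling for the convex and baseline models."""

    def __init__(
        self,
        network: Network,
        k: int = 21,
        K: int = 25,
        lam: float = 1.0,
        n_max: int = 10,
        min_reps: int = 10,
        init_samples: int = 500,
        burn_in: int = 1000,
        max_iters: int = 1_000_000,
        tol: float = 1e-4,
        window: int = 500,
    ):
        if not network.is_connected():
            network = largest_component(network)
        self.network = network
        self.config = CodingConfig(
            lam=lam,
            K=K,
            k=k,
            n_max=n_max,
            min_reps=min_reps,
            max_iters=max_iters,
            tol=tol,
            window=window,
        )
        self.init_samples = int(init_samples)
        self.burn_in = int(burn_in)
        self.template = k_path(k)

    @classmethod
    def from_edge_list(cls, path, **kwargs) -> "_NDLBase":
        return cls(read_edge_list(path), **kwargs)

    @classmethod
    def from_hyperedge_file(
        cls, path, bin_size: int = 500, max_hyperedge_size: int | None = None, **kwargs
    ) -> "_NDLBase":
        H, bins = read_hyperedge_tsv(
            path, bin_size=bin_size, max_hyperedge_size=max_hyperedge_size
        )
        G = clique_expand(H)
        G.bins = bins
        G = largest_component(G)
        return cls(G, **kwargs)

    def sample(self, T: int, seed=None, rng=None) -> PatchPool:
        """Draw a pool of T patches with the pivot chain."""
        if rng is None:
            rng = np.random.default_rng(seed)
        pool = sample_stream(
            self.network, self.template, T, rng, burn_in=self.burn_in
        )
        pool.seed = seed
        return pool


def _split_pool(
    n: int, n_init: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random initialization subset; the rest streams in chain order."""
    perm = rng.permutation(n)
    init_idx = np.sort(perm[:n_init])
    stream_idx = np.sort(perm[n_init:])
    return init_idx, stream_idx


class ConvexNDL(_NDLBase):
    """Online convex network dictionary learning model.

    Parameters
    ----------
    network : Network
        Connected undirected input network (restricted to its largest
        component if not).
    k : int
        Path template length; samples are k x k patches (d = k**2).
    K : int
        Number of dictionary elements.
    lam : float
        L1 code penalty.
    n_max, min_reps : int
        Representative-set capacity and initialization minimum.
    init_samples : int
        Patches drawn for initialization (default 500).

    Examples
    --------
    >>> from cvxndl.synthetic import SBMSpec, sbm_generate
    >>> G = sbm_generate(SBMSpec(block_sizes=(40, 40), seed=0))
    >>> model = ConvexNDL(G, k=4, K=4, init_samples=80, min_reps=5)
    >>> res = model.fit(n_samples=300, seed=0)
    >>> res.dictionary.K
    4
    """

    def fit(
        self,
        n_samples: int | None = None,
        seed=None,
        pool: PatchPool | None = None,
        log_every: int = 100,
    ) -> "ConvexNDLResults":
        """Sample (or accept) a patch stream and run the online learner.

        When ``pool`` is given, a random subset of ``init_samples`` patches
        seeds the dictionary and the remainder forms the online stream (in
        chain order); otherwise ``init_samples + n_samples`` patches are
        drawn with the pivot chain first.
        """
        rng = np.random.default_rng(seed)
        if pool is None:
            if n_samples is None:
                raise ValueError("either n_samples or pool is required")
            pool = self.sample(self.init_samples + n_samples, rng=rng)
        if len(pool) <= self.init_samples:
            raise ValueError(
                f"pool of {len(pool)} patches leaves no online stream after "
                f"{self.init_samples} initialization samples"
            )
        init_idx, stream_idx = _split_pool(len(pool), self.init_samples, rng)
        dic = learner.initialize(
            pool.patches[init_idx],
            self.config.K,
            min_reps=self.config.min_reps,
            rng=rng,
            rep_tuples=pool.node_tuples[init_idx],
            config=self.config,
        )
        stream = zip(
            pool.patches[stream_idx],
            pool.node_tuples[stream_idx],
        )
        dic, state = learner.fit(stream, dic, self.config, log_every=log_every)
        return ConvexNDLResults(self, dic, state, seed=seed)


class OnlineNDL(_NDLBase):
    """Non-convex online NDL baseline with the same sampling and coding."""

    def fit(
        self,
        n_samples: int | None = None,
        seed=None,
        pool: PatchPool | None = None,
    ) -> "OnlineNDLResults":
        rng = np.random.default_rng(seed)
        if pool is None:
            if n_samples is None:
                raise ValueError("either n_samples or pool is required")
            pool = self.sample(self.init_samples + n_samples, rng=rng)
        init_idx, stream_idx = _split_pool(len(pool), self.init_samples, rng)
        dic0 = learner.initialize(
            pool.patches[init_idx],
            self.config.K,
            min_reps=self.config.min_reps,
            rng=rng,
        )
        D0 = dic0.D
        stream = iter(pool.patches[stream_idx])
        D, state = learner.fit_online_ndl(stream, D0, self.config)
        return OnlineNDLResults(self, D, state, seed=seed)


class _ResultsBase:
    def __init__(self, model: _NDLBase, state: TrainingState, seed=None):
        self.model = model
        self.state = state
        self.seed = seed

    @property
    def converged(self) -> bool:
        return self.state.converged

    def reconstruct(
        self,
        n_patches: int | None = None,
        lam: float | None = None,
        seed=None,
        G: Network | None = None,
    ) -> reconstruction.ReconstructionResult:
        """Reconstruct edge scores on the training (or a given) network."""
        G = self.model.network if G is None else G
        return reconstruction.reconstruct(
            G,
            self.D,
            self.model.config.k,
            n_patches=n_patches,
            lam=self.model.config.lam if lam is None else lam,
            rng=np.random.default_rng(seed),
            burn_in=self.model.burn_in,
        )

    def average_precision(
        self, n_patches: int | None = None, lam: float | None = None, seed=None
    ) -> float:
        res = self.reconstruct(n_patches=n_patches, lam=lam, seed=seed)
        return reconstruction.average_precision(res, self.model.network)


class ConvexNDLResults(_ResultsBase):
    """Fit results: learned convex dictionary plus diagnostics."""

    def __init__(self, model, dictionary: Dictionary, state, seed=None):
        super().__init__(model, state, seed=seed)
        self.dictionary = dictionary

    @property
    def D(self) -> np.ndarray:
        return self.dictionary.D

    @property
    def importance_scores(self) -> np.ndarray:
        return learner.importance_scores(self.dictionary.A_hist)

    @property
    def densities(self) -> np.ndarray:
        k = self.model.config.k
        return np.array(
            [learner.density(self.D[:, j], k) for j in range(self.dictionary.K)]
        )

    def median_adjacent_distances(self) -> np.ndarray:
        """Per-element median genomic distance of adjacent representative
        nodes (requires a bin table on the network)."""
        bins = self.model.network.bins
        if bins is None:
            raise ValueError("network carries no genomic bin table")
        return np.array(
            [
                learner.median_adjacent_distance(self.dictionary.rep_tuples[j], bins)
                for j in range(self.dictionary.K)
            ]
        )

    def summary_frame(self) -> pd.DataFrame:
        """Per-element summary ordered by importance score."""
        gamma = self.importance_scores
        df = pd.DataFrame(
            {
                "element": np.arange(self.dictionary.K),
                "importance": gamma,
                "density": self.densities,
                "n_reps": self.dictionary.n_reps(),
                "max_weight": [w.max() for w in self.dictionary.weights],
            }
        )
        bins = self.model.network.bins
        if bins is not None:
            df["d_med"] = self.median_adjacent_distances()
            df["covered_bins"] = [
                self._covered_intervals(j, bins) for j in range(self.dictionary.K)
            ]
        return df.sort_values("importance", ascending=False).reset_index(drop=True)

    def _covered_intervals(self, j: int, bins: pd.DataFrame) -> str:
        """BED-style intervals of the bins covered by element j's
        representatives, merging genomically adjacent bins."""
        by_node = bins.set_index("node_id")
        nodes = np.unique(self.dictionary.rep_tuples[j])
        rows = by_node.loc[nodes].sort_values(["chrom", "start"])
        spans = []
        cur = None
        for r in rows.itertuples():
            if cur is not None and r.chrom == cur[0] and r.start == cur[2]:
                cur = (cur[0], cur[1], r.start + r.size)
            else:
                if cur is not None:
                    spans.append(cur)
                cur = (r.chrom, r.start, r.start + r.size)
        if cur is not None:
            spans.append(cur)
        return ";".join(f"{c}:{s}-{e}" for c, s, e in spans)

    def summary(self) -> str:
        """Human-readable fit summary."""
        cfg = self.model.config
        head = [
            "Online convex network dictionary learning",
            "=" * 57,
            f"elements (K):      {cfg.K:>8d}    path length (k): {cfg.k:>8d}",
            f"lambda:            {cfg.lam:>8.3g}    capacity N_max:  {cfg.n_max:>8d}",
            f"online steps:      {self.state.t:>8d}    converged:       {str(self.converged):>8s}",
            f"surrogate loss:    {self.state.f_hat_t:>8.4f}    empirical loss:  {self.state.f_t:>8.4f}",
            "-" * 57,
        ]
        frame = self.summary_frame()
        if "covered_bins" in frame.columns:
            frame = frame.drop(columns="covered_bins")
        body = frame.to_string(index=False, float_format=lambda v: f"{v:.4f}")
        return "\n".join(head) + "\n" + body

    def save(self, path) -> None:
        self.dictionary.save(
            path,
            importance=self.importance_scores,
            densities=self.densities,
            lam=self.model.config.lam,
            k=self.model.config.k,
            seed=-1 if self.seed is None else self.seed,
        )


class OnlineNDLResults(_ResultsBase):
    """Fit results of the non-convex baseline (plain dictionary matrix)."""

    def __init__(self, model, D: np.ndarray, state, seed=None):
        super().__init__(model, state, seed=seed)
        self._D = D

    @property
    def D(self) -> np.ndarray:
        return self._D

    def summary(self) -> str:
        cfg = self.model.config
        return "\n".join(
            [
                "Online NDL baseline (non-convex)",
                f"K={cfg.K} k={cfg.k} lam={cfg.lam} steps={self.state.t} "
                f"converged={self.converged}",
            ]
        )
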