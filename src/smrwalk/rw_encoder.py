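"""Random-walk stochastic optimization and gene-network encoding.

The core primitive is a derivative-free direct-search minimizer: from the
current point it takes steps of length lambda in uniformly random
directions, accepting strict improvements, and halves lambda after N
consecutive failures until lambda falls below the control accuracy
epsilon.  The network encoder uses it to fit per-gene feature vectors X
(one row per gene, ``dim`` columns) that reconstruct the weighted
adjacency matrix, minimizing

    f(X) = sum_{i<j} (A_ij - x_i . x_j)^2 .

A random-walk-with-restart (RWR) encoder is provided as the documented
propagation-style alternative: each gene's feature vector is its
stationary restart-walk affinity to every seed gene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "RwConfig",
    "RwResult",
    "EmbeddingMatrix",
    "rw_minimize",
    "encode_network",
    "rwr_encode",
]


@dataclass
class GeneNetwork:
    """Weighted undirected gene graph with positive/unlabeled seed labels.

    Self-loops are rejected; ``seed_genes`` must all be nodes.  Node order
    is canonicalized (sorted) so downstream matrices are reproducible.
    """

    graph: nx.Graph
    seed_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed")
        missing = set(self.seed_genes) - set(self.graph.nodes)
        if missing:
            raise ValueError(f"seed genes not in network: {sorted(missing)}")
        self.seed_genes = frozenset(self.seed_genes)

    @classmethod
    def from_edges(cls, edges: Sequence[tuple[str, str, float]],
                   seed_genes: Sequence[str] = ()) -> "GeneNetwork":
        g = nx.Graph()
        for a, b, w in edges:
            if w < 0:
                raise ValueError(f"negative edge weight on ({a}, {b})")
            g.add_edge(a, b, weight=float(w))
        return cls(graph=g, seed_genes=frozenset(seed_genes))

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def adjacency(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, nodelist=self.nodes, weight="weight")

    def unlabeled(self) -> list[str]:
        return [g for g in self.nodes if g not in self.seed_genes]

    def largest_component(self) -> "GeneNetwork":
        comp = max(nx.connected_components(self.graph), key=len)
        sub = self.graph.subgraph(comp).copy()
        return GeneNetwork(graph=sub,
                           seed_genes=frozenset(self.seed_genes) & set(comp))


@dataclass(frozen=True)
class RwConfig:
    """Parameters of the random-walk minimizer.

    lambda0
        Initial walking step length.
    epsilon
        Control accuracy: the walk ends once lambda < epsilon.
    n_tries
        N, the number of consecutive failed trials before lambda is halved.
    max_evals
        Global budget of objective evaluations (truncation guard).
    dim
        Embedding dimension per gene for :func:`encode_network`.
    """

    lambda0: float = 1.0
    epsilon: float = 1e-4
    n_tries: int = 30
    max_evals: int = 50_000
    dim: int = 16
    seed: int = 0

    def __post_init__(self):
        if not (self.lambda0 > 0 and self.epsilon > 0):
            raise ValueError("lambda0 and epsilon must be positive")
        if self.epsilon >= self.lambda0:
            raise ValueError("epsilon must be smaller than lambda0")
        if self.n_tries < 1 or self.max_evals < 1 or self.dim < 1:
            raise ValueError("n_tries, max_evals and dim must be >= 1")


class RwResult(NamedTuple):
    x: np.ndarray
    fun: float
    nfev: int
    truncated: bool


def rw_minimize(f: Callable[[np.ndarray], float], x0, cfg: RwConfig) -> RwResult:
    """Minimize ``f`` by random-direction direct search.

    At step length ``lam`` (starting at ``cfg.lambda0``) a trial direction
    ``u`` is drawn uniformly from (-1, 1)^n, L2-normalized to ``u'``, and
    the candidate ``x1 = x + lam * u'`` is accepted iff ``f(x1) < f(x)``
    (strict; ties rejected), which also resets the failure counter.  After
    ``cfg.n_tries`` consecutive failures ``lam`` is halved, so after r
    failed rounds ``lam == lambda0 / 2**r`` exactly; the search ends when
    ``lam < cfg.epsilon`` or the evaluation budget runs out (the result is
    then flagged ``truncated``).  Deterministic under ``cfg.seed``.
    """
    x = np.asarray(x0, dtype=float).copy()
    fx = float(f(x))
    if not np.isfinite(fx):
        raise ValueError("objective is not finite at x0")
    rng = np.random.default_rng(cfg.seed)
    n = x.size
    nfev = 1
    lam = float(cfg.lambda0)
    truncated = False
    while lam >= cfg.epsilon and not truncated:
        k = 1
        while k <= cfg.n_tries:
            if nfev >= cfg.max_evals:
                truncated = True
                break
            u = rng.uniform(-1.0, 1.0, size=n)
            norm = np.sqrt(np.sum(u * u))
            while norm == 0.0:  # measure-zero, but resample per contract
                u = rng.uniform(-1.0, 1.0, size=n)
                norm = np.sqrt(np.sum(u * u))
            x1 = x + lam * (u / norm)
            f1 = float(f(x1))
            nfev += 1
            if f1 < fx:
                x, fx = x1, f1
                k = 1
            else:
                k += 1
        lam /= 2.0
    return RwResult(x=x, fun=fx, nfev=nfev, truncated=truncated)


@dataclass
class EmbeddingMatrix:
    """Per-gene feature vectors in row order ``gene_ids``."""

    gene_ids: list[str]
    vectors: np.ndarray
    objective_final: float

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[0] != len(self.gene_ids):
            raise ValueError("row count does not match gene_ids")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding entries")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def rows(self, gene_ids: Sequence[str]) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.gene_ids)}
        return self.vectors[[index[g] for g in gene_ids]]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.vectors, index=pd.Index(self.gene_ids, name="gene"),
                            columns=[f"f{i}" for i in range(self.dim)])

    @classmethod
    def from_frame(cls, df) -> "EmbeddingMatrix":
        return cls(gene_ids=list(df.index), vectors=df.to_numpy(float),
                   objective_final=float("nan"))


def _offdiag_objective(A: np.ndarray, dim: int) -> Callable[[np.ndarray], float]:
    n = A.shape[0]
    mask = ~np.eye(n, dtype=bool)

    def f(flat: np.ndarray) -> float:
        X = flat.reshape(n, dim)
        R = A - X @ X.T
        # each unordered pair counted once
        return float(np.sum(R[mask] ** 2) / 2.0)

    return f


def _spectral_start(A: np.ndarray, dim: int) -> np.ndarray:
    """Classical low-rank start: top-``dim`` eigenpairs of A, columns
    scaled by sqrt of the (clipped) eigenvalues."""
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(vals)[::-1][:dim]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def encode_network(net: GeneNetwork, cfg: RwConfig,
                   init: str = "spectral") -> EmbeddingMatrix:
    """Encode the gene network into per-gene features by random-walk
    minimization of the adjacency-reconstruction objective.

    ``init="spectral"`` (default) starts the walk from the truncated
    eigendecomposition of the adjacency matrix and lets the random walk
    refine it; ``init="uniform"`` starts from a small random point drawn
    uniform(-0.1, 0.1) with ``cfg.seed``.
    """
    n = net.n_nodes
    if n == 0:
        raise ValueError("empty network")
    if cfg.dim >= n:
        raise ValueError(f"dim={cfg.dim} must be < number of nodes ({n})")
    A = net.adjacency()
    if init == "spectral":
        x0 = _spectral_start(A, cfg.dim).ravel()
    elif init == "uniform":
        rng = np.random.default_rng(cfg.seed)
        x0 = rng.uniform(-0.1, 0.1, size=n * cfg.dim)
    else:
        raise ValueError(f"unknown init: {init!r}")
    res = rw_minimize(_offdiag_objective(A, cfg.dim), x0, cfg)
    if res.truncated:
        logger.info("encode_network: evaluation budget exhausted "
                    "(best objective %.6g)", res.fun)
    return EmbeddingMatrix(gene_ids=net.nodes,
                           vectors=res.x.reshape(n, cfg.dim),
                           objective_final=res.fun)


def rwr_encode(net: GeneNetwork, restart_prob: float = 0.3) -> EmbeddingMatrix:
    """Random-walk-with-restart affinity encoder.

    Feature j of gene i is the stationary probability that a walk
    restarting at seed gene j (with probability ``restart_prob`` per step)
    is at gene i.  Each seed's affinity column sums to 1 over genes
    (probability conservation) when the graph has no isolated nodes.
    """
    if not 0 < restart_prob <= 1:
        raise ValueError("restart_prob must be in (0, 1]")
    seeds = sorted(net.seed_genes)
    if not seeds:
        raise ValueError("rwr_encode requires at least one seed gene")
    nodes = net.nodes
    A = net.adjacency()
    deg = A.sum(axis=1)
    isolated = deg == 0
    if isolated.any():
        warnings.warn(f"{int(isolated.sum())} isolated node(s): affinity 0",
                      stacklevel=2)
    P = np.divide(A, np.where(isolated, 1.0, deg)[:, None],
                  where=~isolated[:, None], out=np.zeros_like(A))
    n = len(nodes)
    index = {g: i for i, g in enumerate(nodes)}
    E = np.zeros((n, len(seeds)))
    for j, s in enumerate(seeds):
        E[index[s], j] = 1.0
    M = np.eye(n) - (1.0 - restart_prob) * P.T
    F = restart_prob * np.linalg.solve(M, E)
    return EmbeddingMatrix(gene_ids=nodes, vectors=F,
                           objective_final=float("nan"))
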