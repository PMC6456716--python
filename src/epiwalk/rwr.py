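"""Random walk with restart over the heterogeneous network.

The walker propagates along the column-stochastic transition matrix W
and teleports back to the seed disease with probability r each step::

    P[s+1] = (1 - r) * W @ P[s] + r * P0

iterated until the change between successive probability vectors falls
below a tolerance.  With r in (0, 1) the map is a contraction (factor
1 - r in L1 for column-stochastic W), so the fixed point
P = r * (I - (1 - r) W)^{-1} P0 exists and is unique; ``rwr_solve``
computes it directly and serves as the exact oracle for the iteration
at test scale.  Sites are ranked by their stationary probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .hetnet import HetNet, NodeRegistry

__all__ = ["RWRConfig", "RWRResult", "rwr_iterate", "rwr_solve", "rank_sites"]


@dataclass(frozen=True)
class RWRConfig:
    """Restart probability r (walker recycling fraction), stopping
    tolerance on the iterate difference, and an iteration safety cap."""

    restart_prob: float = 0.75
    tol: float = 1e-10
    max_iter: int = 1000
    norm: str = "linf"  # or "l1"

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_prob < 1.0:
            raise ValueError("restart_prob must be in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.norm not in ("linf", "l1"):
            raise ValueError(f"unknown norm {self.norm!r}")


@dataclass
class RWRResult:
    probabilities: np.ndarray
    iterations: int
    converged: bool
    seed_id: str
    history: list[float] = field(default_factory=list, repr=False)


def _as_matrix_and_seed(net, seed):
    """Accept a HetNet with a node id, or a raw matrix with an index."""
    if isinstance(net, HetNet):
        W = net.W
        if isinstance(seed, str):
            idx = net.registry.global_index(seed)
            return W, idx, seed
        return W, int(seed), str(seed)
    W = net if sparse.issparse(net) else np.asarray(net, dtype=float)
    return W, int(seed), str(seed)


def rwr_iterate(net, seed, config: RWRConfig | None = None) -> RWRResult:
    """Iterate the restart recursion to its stationary distribution.

    ``net`` may be a :class:`HetNet` (seed given as a node id) or any
    column-(sub)stochastic matrix (seed given as an index).  Failure to
    converge within ``max_iter`` is flagged on the result, not raised.
    """
    cfg = config or RWRConfig()
    W, seed_idx, seed_id = _as_matrix_and_seed(net, seed)
    n = W.shape[0]
    p0 = np.zeros(n)
    p0[seed_idx] = 1.0
    r = cfg.restart_prob
    p = p0.copy()
    history: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        p_next = (1.0 - r) * (W @ p) + r * p0
        diff = (
            np.abs(p_next - p).max()
            if cfg.norm == "linf"
            else np.abs(p_next - p).sum()
        )
        history.append(float(diff))
        p = p_next
        if diff <= cfg.tol:
            converged = True
            break
    return RWRResult(p, iterations, converged, seed_id, history)


def rwr_solve(net, seed, r: float = 0.75) -> np.ndarray:
    """Exact fixed point by dense linear solve: P = r (I - (1-r)W)^-1 P0.

    Intended as a test-scale oracle (the system is solved densely).
    """
    W, seed_idx, _ = _as_matrix_and_seed(net, seed)
    if not 0.0 < r < 1.0:
        raise ValueError("r must be in (0, 1)")
    n = W.shape[0]
    dense = W.toarray() if sparse.issparse(W) else np.asarray(W, dtype=float)
    p0 = np.zeros(n)
    p0[seed_idx] = 1.0
    return np.linalg.solve(np.eye(n) - (1.0 - r) * dense, r * p0)


def rank_sites(
    result: RWRResult, registry: NodeRegistry
) -> list[tuple[str, float]]:
    """Site-layer probabilities, highest first; ties broken by site id."""
    probs = result.probabilities[registry.layer_slice("S")]
    pairs = list(zip(registry.sites, probs.tolist()))
    return sorted(pairs, key=lambda kv: (-kv[1], kv[0]))
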