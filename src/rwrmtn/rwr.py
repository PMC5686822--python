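"""Random walk with restart on miRNA networks.

The walker update is ``p_{t+1} = (1 - gamma) W' p_t + gamma p_0`` where
``W'`` is the transition operator obtained by normalizing each node's
outgoing edge weights to sum to one.  Because the update acts on a column
vector of node probabilities, the operator applied is the *transpose* of
the row-normalized adjacency (column-stochastic over nodes with outgoing
edges); on regular graphs the two coincide, in general they do not.

Two seed policies are provided:

* miRNA-only seeding (uniform mass over known disease miRNAs) — the
  RWRMDA policy, usable on homogeneous and heterogeneous networks alike;
* miRNA+target seeding — the RWRMTN policy, placing weight ``alpha``
  uniformly on the known disease miRNAs and ``1 - alpha`` uniformly on
  their target genes.

Iteration stops at the first step with L1 change below ``tol``
(default 1e-6); failing to converge within ``max_iter`` is an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .networks import HeterogeneousNetwork, HomogeneousNetwork, normalize_mirna

logger = logging.getLogger(__name__)

__all__ = [
    "RWRConfig",
    "SeedSet",
    "RWRResult",
    "ConvergenceError",
    "transition_matrix",
    "seed_vector_mirna",
    "seed_vector_hetero",
    "rwr",
    "rank_mirnas",
]

Network = HeterogeneousNetwork | HomogeneousNetwork


class ConvergenceError(RuntimeError):
    """Raised when the power iteration fails to reach tolerance."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        self.max_iter = max_iter
        super().__init__(
            f"no convergence after {max_iter} iterations (last L1 residual {residual:.3e})"
        )


@dataclass(frozen=True)
class RWRConfig:
    """Walk parameters.

    gamma : restart probability in [0, 1]; high gamma keeps mass near seeds.
    alpha : seed-weight split between miRNAs and their target genes, in [0, 1].
    tol   : L1 convergence threshold on successive probability vectors.
    """

    gamma: float = 0.7
    alpha: float = 0.9
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class SeedSet:
    """Seed nodes: disease miRNAs ``mirnas`` and (optionally) their targets."""

    mirnas: frozenset[str]
    genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "mirnas", frozenset(normalize_mirna(m) for m in self.mirnas))
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.mirnas and not self.genes:
            raise ValueError("empty seed set")


@dataclass
class RWRResult:
    """Steady-state of a walk: probabilities, iterations, final residual."""

    p: np.ndarray
    n_iter: int
    residual: float
    mass_deficient: bool = False


def transition_matrix(net: Network) -> sp.csr_matrix:
    """Column-stochastic transition operator of a network.

    Entry (j, i) is the probability of stepping from node i to node j:
    each node's outgoing weights are divided by their sum.  Dangling nodes
    (gene nodes of a directed bipartite network) keep an all-zero column.
    """
    A = net.adjacency
    if A.nnz == 0:
        raise ValueError("network has no edges")
    out = np.asarray(A.sum(axis=1)).ravel()
    inv = np.divide(1.0, out, out=np.zeros_like(out, dtype=float), where=out > 0)
    return (sp.diags(inv) @ A).T.tocsr()


def _present_seed_mirnas(seeds: Iterable[str], net: Network) -> list[str]:
    present, absent = [], []
    for m in sorted({normalize_mirna(s) for s in seeds}):
        idx = net._index.get(m)
        if idx is not None and (
            not isinstance(net, HeterogeneousNetwork) or idx < net.n_mirnas
        ):
            present.append(m)
        else:
            absent.append(m)
    if absent:
        logger.warning("dropped %d seed miRNAs absent from network: %s", len(absent), absent)
    return present


def seed_vector_mirna(seeds: SeedSet, net: Network) -> np.ndarray:
    """Initial vector with uniform mass 1/|S_m| on the present seed miRNAs.

    Seeds missing from the network are dropped and the remainder
    renormalized; if none remain this is an error.
    """
    present = _present_seed_mirnas(seeds.mirnas, net)
    if not present:
        raise ValueError("empty seed set: no seed miRNA present in the network")
    p0 = np.zeros(len(net.nodes))
    for m in present:
        p0[net.index(m)] = 1.0 / len(present)
    return p0


def seed_vector_hetero(
    seeds: SeedSet, alpha: float, net: HeterogeneousNetwork
) -> np.ndarray:
    """Initial vector splitting mass alpha over seed miRNAs, 1-alpha over seed genes.

    If ``seeds.genes`` is empty it is populated with the targets of the
    present seed miRNAs.  When no seed gene is present and ``alpha < 1``,
    the vector falls back to miRNA-only seeding with a warning.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    present_m = _present_seed_mirnas(seeds.mirnas, net)
    if not present_m:
        raise ValueError("empty seed set: no seed miRNA present in the network")
    genes = set(seeds.genes) or set(net.targets_of(present_m))
    gene0 = net.n_mirnas
    present_g = sorted(
        g for g in genes if (i := net._index.get(g)) is not None and i >= gene0
    )
    p0 = np.zeros(net.n_nodes)
    if not present_g:
        if alpha < 1.0:
            logger.warning("no seed genes in network; falling back to miRNA-only seeding")
        for m in present_m:
            p0[net.index(m)] = 1.0 / len(present_m)
        return p0
    for m in present_m:
        p0[net.index(m)] = alpha / len(present_m)
    for g in present_g:
        p0[net.index(g)] = (1.0 - alpha) / len(present_g)
    return p0


def rwr(T: sp.spmatrix, p0: np.ndarray, cfg: RWRConfig | None = None) -> RWRResult:
    """Iterate ``p <- (1-gamma) T p + gamma p0`` to the steady state.

    Returns the first iterate whose L1 change falls below ``cfg.tol``.
    The result is tagged ``mass_deficient`` when probability leaked into
    dangling nodes (total mass < 1), as happens on directed bipartite
    networks — the reason the miRNA+target policy needs mutual networks.
    """
    cfg = cfg or RWRConfig()
    if not np.isclose(p0.sum(), 1.0):
        raise ValueError(f"initial vector sums to {p0.sum():.6f}, expected 1")
    gamma = cfg.gamma
    p = p0.copy()
    for it in range(1, cfg.max_iter + 1):
        p_next = (1.0 - gamma) * (T @ p) + gamma * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < cfg.tol:
            deficient = p.sum() < 1.0 - 1e-9
            if deficient:
                logger.warning("steady state mass %.6f < 1 (dangling nodes)", p.sum())
            return RWRResult(p, it, residual, mass_deficient=deficient)
    raise ConvergenceError(residual, cfg.max_iter)


def rank_mirnas(
    p: np.ndarray | RWRResult,
    net: Network,
    exclude: Iterable[str] = (),
) -> list[tuple[str, float]]:
    """Rank miRNA nodes by steady-state probability, descending.

    Gene nodes and excluded ids (typically the seeds) are removed.  Ties
    break by ascending lexicographic miRNA id, for determinism.
    """
    vec = p.p if isinstance(p, RWRResult) else p
    n_m = net.n_mirnas if isinstance(net, HeterogeneousNetwork) else len(net.mirnas)
    excl = {normalize_mirna(e) for e in exclude}
    scored = [
        (m, float(vec[i]))
        for i, m in enumerate(net.nodes[:n_m])
        if m not in excl
    ]
    return sorted(scored, key=lambda t: (-t[1], t[0]))
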