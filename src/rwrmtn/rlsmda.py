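"""Regularized least-squares disease-miRNA association scoring (RLSMDA).

A semi-supervised classifier that needs no negative examples.  Given a
miRNA similarity matrix ``S_M`` (n x n), a disease-phenotype similarity
matrix ``S_D`` (m x m) and a 0/1 association matrix ``A`` (m x n), two
ridge-style classifiers are fit in the miRNA and disease spaces,

    F_M* = S_M (S_M + eta_M I)^-1 A^T        (n x m)
    F_D* = S_D (S_D + eta_D I)^-1 A          (m x n)

and blended as ``F* = w F_M*^T + (1 - w) F_D*``.  Each row of ``F*``
scores every miRNA for one disease.  Defaults eta_M = eta_D = 1, w = 0.9.

The linear systems are solved with an LU factorization rather than an
explicit inverse.  ``inverse=False`` switches to the inverse-free product
``S (S + eta I) A`` for comparison; it is not the fitted classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .networks import HomogeneousNetwork, normalize_mirna

__all__ = [
    "RLSMDAConfig",
    "rlsmda_scores",
    "similarity_from_homogeneous",
    "rank_for_disease",
]


@dataclass(frozen=True)
class RLSMDAConfig:
    """Trade-off parameters eta_M, eta_D (> 0) and space weight w in [0, 1]."""

    eta_M: float = 1.0
    eta_D: float = 1.0
    w: float = 0.9

    def __post_init__(self) -> None:
        if self.eta_M <= 0 or self.eta_D <= 0:
            raise ValueError("eta_M and eta_D must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")


def similarity_from_homogeneous(net: HomogeneousNetwork) -> pd.DataFrame:
    """Similarity matrix of the shared-target miRNA network.

    The weighted adjacency with unit diagonal; unconnected pairs are 0.
    """
    S = net.adjacency.toarray()
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=net.mirnas, columns=net.mirnas)


def _check_square_symmetric(S: pd.DataFrame, name: str) -> None:
    if S.shape[0] != S.shape[1] or list(S.index) != list(S.columns):
        raise ValueError(f"{name} must be square with matching row/column labels")
    if len(set(S.index)) != len(S.index):
        raise ValueError(f"{name} labels are not unique")
    vals = S.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T, atol=1e-8):
        raise ValueError(f"{name} is not symmetric")
    if (vals < -1e-12).any():
        raise ValueError(f"{name} has negative entries")


def rlsmda_scores(
    S_M: pd.DataFrame,
    S_D: pd.DataFrame,
    A: pd.DataFrame,
    cfg: RLSMDAConfig | None = None,
    *,
    inverse: bool = True,
) -> pd.DataFrame:
    """Blended classifier scores F* (diseases x miRNAs).

    ``A`` must carry disease row labels matching ``S_D`` and miRNA column
    labels matching ``S_M``; label mismatches are an error naming the
    offenders.
    """
    cfg = cfg or RLSMDAConfig()
    _check_square_symmetric(S_M, "S_M")
    _check_square_symmetric(S_D, "S_D")
    bad_rows = [d for d in A.index if d not in set(S_D.index)]
    bad_cols = [m for m in A.columns if m not in set(S_M.index)]
    if bad_rows or bad_cols:
        raise ValueError(
            f"association labels missing from similarity matrices: "
            f"diseases {bad_rows[:5]}, miRNAs {bad_cols[:5]}"
        )
    # align similarity matrices to A's labeling
    SM = S_M.loc[A.columns, A.columns].to_numpy(dtype=float)
    SD = S_D.loc[A.index, A.index].to_numpy(dtype=float)
    Av = A.to_numpy(dtype=float)
    if not np.isin(Av, (0.0, 1.0)).all():
        raise ValueError("association matrix entries must be 0 or 1")
    n, m = SM.shape[0], SD.shape[0]
    if inverse:
        FM = SM @ sla.solve(SM + cfg.eta_M * np.eye(n), Av.T, assume_a="sym")
        FD = SD @ sla.solve(SD + cfg.eta_D * np.eye(m), Av, assume_a="sym")
    else:
        FM = SM @ (SM + cfg.eta_M * np.eye(n)) @ Av.T
        FD = SD @ (SD + cfg.eta_D * np.eye(m)) @ Av
    F = cfg.w * FM.T + (1.0 - cfg.w) * FD
    if not np.isfinite(F).all():
        raise ValueError("non-finite scores; the regularized system may be singular")
    return pd.DataFrame(F, index=A.index, columns=A.columns)


def rank_for_disease(
    F: pd.DataFrame, disease: str, exclude: set[str] | frozenset[str] = frozenset()
) -> list[tuple[str, float]]:
    """Descending miRNA ranking for one disease row of a score matrix.

    Excluded miRNAs (the disease's known associations) are removed; ties
    break by ascending lexicographic id.
    """
    if disease not in F.index:
        raise KeyError(f"unknown disease {disease!r}")
    excl = {normalize_mirna(e) for e in exclude}
    row = F.loc[disease]
    scored = [(m, float(s)) for m, s in row.items() if m not in excl]
    return sorted(scored, key=lambda t: (-t[1], t[0]))
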