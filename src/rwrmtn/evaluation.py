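"""Cross-validation and AUC evaluation of disease-miRNA ranking methods.

The harness holds out known disease-miRNA associations (leave-one-out or
k-fold), re-ranks the held-out miRNA against every network miRNA not
known to be associated with the disease, and summarizes each method as
the mean per-disease AUC — the probability that a held-out disease miRNA
outranks a random non-associated candidate.

Three rankers share one interface (``universe`` attribute plus a
``score(disease, seed_mirnas)`` method returning a pandas Series):

* :class:`RWRMTNRanker` — random walk with restart on a mutual
  heterogeneous miRNA-target network, seeded with the disease miRNAs and
  their target genes (weight split ``alpha``);
* :class:`RWRMDARanker` — the same walk on the homogeneous shared-target
  miRNA network, seeded with disease miRNAs only;
* :class:`RLSMDARanker` — the regularized least-squares classifier, with
  the evaluated disease's association row replaced by the current seeds
  each round (zeroing the held-out association).

Ties in scores are handled with midranks for AUC (unbiased) and with the
lexicographic tie-break for displayed ranks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.stats

from .networks import (
    HeterogeneousNetwork,
    HomogeneousNetwork,
    normalize_mirna,
)
from .rlsmda import RLSMDAConfig, similarity_from_homogeneous
from .rwr import RWRConfig, SeedSet, rwr, seed_vector_hetero, seed_vector_mirna, transition_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseAssociationSet",
    "parse_associations",
    "write_associations",
    "HoldoutRecord",
    "AUCSummary",
    "RWRMTNRanker",
    "RWRMDARanker",
    "RLSMDARanker",
    "make_ranker",
    "loocv",
    "roc_auc",
    "summarize",
    "kfold",
    "parameter_sweep",
    "gamma_trend",
]


class DiseaseAssociationSet(Mapping[str, frozenset[str]]):
    """Mapping disease phenotype id -> set of associated miRNA ids."""

    def __init__(self, assoc: Mapping[str, Iterable[str]]):
        data = {
            str(d).strip(): frozenset(normalize_mirna(m) for m in ms)
            for d, ms in assoc.items()
        }
        if any(not d for d in data):
            raise ValueError("empty disease identifier")
        if any(not ms for ms in data.values()):
            raise ValueError("every disease must have at least one miRNA")
        self._data = dict(sorted(data.items()))

    def __getitem__(self, disease: str) -> frozenset[str]:
        return self._data[disease]

    def __iter__(self):
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    @property
    def n_diseases(self) -> int:
        return len(self._data)

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(itertools.chain.from_iterable(self._data.values()))

    @property
    def n_associations(self) -> int:
        return sum(len(ms) for ms in self._data.values())

    def __repr__(self) -> str:
        return (
            f"DiseaseAssociationSet({self.n_associations} associations, "
            f"{self.n_diseases} diseases, {len(self.mirnas)} miRNAs)"
        )


def parse_associations(source: str | Path | IO[str]) -> DiseaseAssociationSet:
    """Read a two-column tab-separated (disease id, miRNA id) file.

    ``#`` comment lines are skipped; numeric phenotype ids (OMIM-style)
    are kept as opaque strings.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            return parse_associations(fh)
    assoc: dict[str, set[str]] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ValueError(f"malformed association line {lineno}: {line!r}")
        assoc.setdefault(fields[0].strip(), set()).add(normalize_mirna(fields[1]))
    if not assoc:
        raise ValueError("no associations")
    return DiseaseAssociationSet(assoc)


def write_associations(assoc: DiseaseAssociationSet, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#disease\tmirna\n")
        for d in assoc:
            for m in sorted(assoc[d]):
                fh.write(f"{d}\t{m}\n")


@dataclass(frozen=True)
class HoldoutRecord:
    """One cross-validation round: the held-out miRNA and how it ranked.

    ``rank`` is the displayed 1-based rank (lexicographic tie-break);
    ``midrank`` averages over tied scores and feeds the AUC.
    """

    disease: str
    mirna: str
    rank: int
    midrank: float
    n_candidates: int

    def __post_init__(self) -> None:
        if not 1 <= self.rank <= self.n_candidates:
            raise ValueError("rank must lie in [1, n_candidates]")

    @property
    def auc(self) -> float:
        """Fraction of non-associated candidates outranked (ties 1/2)."""
        if self.n_candidates < 2:
            raise ValueError("AUC needs at least 2 candidates")
        return (self.n_candidates - self.midrank) / (self.n_candidates - 1)


@dataclass(frozen=True)
class AUCSummary:
    """Per-disease AUCs plus the unweighted grand mean for one method/setting."""

    per_disease: dict[str, float]
    method: str
    params: dict
    scheme: str

    @property
    def grand_mean(self) -> float:
        return float(np.mean(list(self.per_disease.values())))


class Ranker(Protocol):
    universe: tuple[str, ...]

    def score(self, disease: str, seed_mirnas: Sequence[str]) -> pd.Series: ...


class RWRMTNRanker:
    """Heterogeneous-network walker seeded with disease miRNAs and their targets."""

    method = "rwrmtn"

    def __init__(
        self,
        net: HeterogeneousNetwork,
        alpha: float = 0.9,
        gamma: float = 0.7,
        tol: float = 1e-6,
        max_iter: int = 1000,
    ):
        if net.mode != "mutual":
            raise ValueError(
                "the miRNA+target walk needs a mutual network: directed networks "
                "trap the walker at dangling gene nodes"
            )
        self.net = net
        self.cfg = RWRConfig(gamma=gamma, alpha=alpha, tol=tol, max_iter=max_iter)
        self._T = transition_matrix(net)
        self.universe: tuple[str, ...] = net.mirnas
        self.last_seed_genes: frozenset[str] = frozenset()

    def score(self, disease: str, seed_mirnas: Sequence[str]) -> pd.Series:
        genes = self.net.targets_of(seed_mirnas)
        self.last_seed_genes = genes
        seeds = SeedSet(frozenset(seed_mirnas), genes)
        p0 = seed_vector_hetero(seeds, self.cfg.alpha, self.net)
        res = rwr(self._T, p0, self.cfg)
        return pd.Series(res.p[: self.net.n_mirnas], index=self.net.mirnas)


class RWRMDARanker:
    """Homogeneous-network walker seeded with disease miRNAs only."""

    method = "rwrmda"

    def __init__(
        self,
        net: HomogeneousNetwork,
        gamma: float = 0.7,
        tol: float = 1e-6,
        max_iter: int = 1000,
    ):
        self.net = net
        self.cfg = RWRConfig(gamma=gamma, alpha=1.0, tol=tol, max_iter=max_iter)
        self._T = transition_matrix(net)
        self.universe: tuple[str, ...] = net.mirnas

    def score(self, disease: str, seed_mirnas: Sequence[str]) -> pd.Series:
        p0 = seed_vector_mirna(SeedSet(frozenset(seed_mirnas)), self.net)
        res = rwr(self._T, p0, self.cfg)
        return pd.Series(res.p, index=self.net.mirnas)


class RLSMDARanker:
    """Regularized least-squares scorer re-fit with the round's seed row.

    Holds the full association set; when scoring a disease, that
    disease's row of A is replaced by the indicator of the current seeds
    (so a held-out association is zeroed), all other rows keep their
    known associations.  The factorized similarity systems do not depend
    on A and are computed once.
    """

    method = "rlsmda"

    def __init__(
        self,
        homo_net: HomogeneousNetwork,
        S_D: pd.DataFrame,
        assoc: DiseaseAssociationSet,
        cfg: RLSMDAConfig | None = None,
    ):
        self.cfg = cfg or RLSMDAConfig()
        S_M = similarity_from_homogeneous(homo_net)
        self.universe: tuple[str, ...] = tuple(S_M.index)
        known_d = set(S_D.index)
        diseases = [d for d in assoc if d in known_d]
        dropped = [d for d in assoc if d not in known_d]
        if dropped:
            logger.warning(
                "dropped %d diseases absent from the phenotype similarity matrix: %s",
                len(dropped), dropped[:5],
            )
        if not diseases:
            raise ValueError("no disease shared between associations and S_D")
        self.diseases: tuple[str, ...] = tuple(diseases)
        self._d_index = {d: i for i, d in enumerate(diseases)}
        self._m_index = {m: j for j, m in enumerate(self.universe)}
        SM = S_M.to_numpy(dtype=float)
        SD = S_D.loc[diseases, diseases].to_numpy(dtype=float)
        n, m = SM.shape[0], SD.shape[0]
        # G_M = (S_M + eta I)^-1 S_M so that F_M*^T[d] = A[d] @ G_M
        self._G_M = sla.solve(SM + self.cfg.eta_M * np.eye(n), SM, assume_a="sym")
        # H_D = S_D (S_D + eta I)^-1 so that F_D*[d] = H_D[d] @ A
        self._H_D = SD @ np.linalg.inv(SD + self.cfg.eta_D * np.eye(m))
        A = np.zeros((m, n))
        for d in diseases:
            for mir in assoc[d]:
                j = self._m_index.get(mir)
                if j is not None:
                    A[self._d_index[d], j] = 1.0
        self._A = A

    def score(self, disease: str, seed_mirnas: Sequence[str]) -> pd.Series:
        if disease not in self._d_index:
            raise KeyError(f"unknown disease {disease!r}")
        i = self._d_index[disease]
        A = self._A.copy()
        A[i, :] = 0.0
        for m in seed_mirnas:
            j = self._m_index.get(normalize_mirna(m))
            if j is not None:
                A[i, j] = 1.0
        fm_row = A[i] @ self._G_M
        fd_row = self._H_D[i] @ A
        return pd.Series(self.cfg.w * fm_row + (1 - self.cfg.w) * fd_row, index=self.universe)


def make_ranker(method: str, **kwargs) -> Ranker:
    """Construct a ranker by name: 'rwrmtn', 'rwrmda' or 'rlsmda'."""
    cls = {"rwrmtn": RWRMTNRanker, "rwrmda": RWRMDARanker, "rlsmda": RLSMDARanker}
    if method not in cls:
        raise ValueError(f"unknown method {method!r}")
    return cls[method](**kwargs)


def _rank_of(scores: pd.Series, candidates: Sequence[str], positive: str) -> tuple[int, float]:
    """Displayed rank and midrank of ``positive`` among ``candidates``."""
    s = scores.loc[list(candidates)]
    pos = float(s.loc[positive])
    vals = s.to_numpy(dtype=float)
    greater = int((vals > pos).sum())
    equal = int((vals == pos).sum())  # includes the positive itself
    midrank = greater + (equal + 1) / 2.0
    # displayed rank: descending score then lexicographic id
    before = greater + sum(
        1 for c in candidates if float(s.loc[c]) == pos and c < positive
    )
    return before + 1, midrank


def loocv(
    assoc: DiseaseAssociationSet,
    ranker: Ranker,
    *,
    diseases: Iterable[str] | None = None,
) -> list[HoldoutRecord]:
    """Leave-one-out cross-validation over every eligible disease.

    Each known disease miRNA present in the ranker's miRNA universe is
    held out in turn; the remaining known miRNAs seed the method and the
    held-out miRNA is ranked against all universe miRNAs not known to be
    associated with the disease.  Diseases with fewer than two known
    miRNAs in the universe are skipped with a logged reason.
    """
    universe = set(ranker.universe)
    records: list[HoldoutRecord] = []
    for disease in sorted(diseases) if diseases is not None else list(assoc):
        known_all = assoc[disease]
        known_in = sorted(known_all & universe)
        if len(known_in) < 2:
            logger.info(
                "skipping %s: %d known miRNA(s) in the ranked universe (<2)",
                disease, len(known_in),
            )
            continue
        negatives = sorted(universe - known_all)
        for held in known_in:
            seeds = [m for m in known_in if m != held]
            scores = ranker.score(disease, seeds)
            candidates = [held] + negatives
            rank, midrank = _rank_of(scores, candidates, held)
            records.append(HoldoutRecord(disease, held, rank, midrank, len(candidates)))
    return records


def roc_auc(records: Sequence[HoldoutRecord]) -> dict[str, float]:
    """Per-disease AUC from holdout ranks.

    Equivalent to trapezoidal integration of the ROC built from every
    achieved rank threshold, and to the Mann-Whitney pair-winning
    fraction with ties counted one half.  A single record of rank r among
    c candidates gives (c - r) / (c - 1).
    """
    if not records:
        raise ValueError("no holdout records")
    by_disease: dict[str, list[HoldoutRecord]] = {}
    for r in records:
        if r.n_candidates < 2:
            raise ValueError(f"{r.disease}/{r.mirna}: fewer than 2 candidates")
        by_disease.setdefault(r.disease, []).append(r)
    return {
        d: float(np.mean([r.auc for r in rs])) for d, rs in sorted(by_disease.items())
    }


def summarize(
    records: Sequence[HoldoutRecord], method: str, params: dict, scheme: str = "loocv"
) -> AUCSummary:
    return AUCSummary(roc_auc(records), method, params, scheme)


def kfold(
    assoc: DiseaseAssociationSet,
    ranker: Ranker,
    k: int = 10,
    rng_seed: int = 0,
) -> AUCSummary:
    """Stratified per-disease k-fold cross-validation.

    Only diseases with at least ``k`` associated miRNAs in the ranker's
    universe are eligible.  Folds are drawn with a seeded shuffle; each
    fold is held out in turn with the remaining folds as seeds, and every
    held-out miRNA is ranked against the non-associated universe miRNAs.
    AUC is pooled per disease over all rounds, then averaged unweighted.
    With ``k`` equal to a disease's association count this reduces to
    leave-one-out.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(rng_seed)
    universe = set(ranker.universe)
    records: list[HoldoutRecord] = []
    eligible = 0
    for disease in assoc:
        known_all = assoc[disease]
        known_in = sorted(known_all & universe)
        if len(known_in) < k:
            continue
        eligible += 1
        order = list(known_in)
        rng.shuffle(order)
        folds = [order[i::k] for i in range(k)]
        negatives = sorted(universe - known_all)
        for fold in folds:
            seeds = [m for m in known_in if m not in set(fold)]
            scores = ranker.score(disease, seeds)
            for held in sorted(fold):
                candidates = [held] + negatives
                rank, midrank = _rank_of(scores, candidates, held)
                records.append(
                    HoldoutRecord(disease, held, rank, midrank, len(candidates))
                )
    if eligible == 0:
        raise ValueError(f"no disease has >= {k} associated miRNAs in the universe")
    method = getattr(ranker, "method", type(ranker).__name__)
    return summarize(records, method, {"k": k, "rng_seed": rng_seed}, scheme=f"{k}-fold")


def parameter_sweep(
    assoc: DiseaseAssociationSet,
    net: HeterogeneousNetwork | HomogeneousNetwork,
    method: str,
    alpha_grid: Sequence[float],
    gamma_grid: Sequence[float],
    *,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Grand-mean LOOCV AUC on a grid of (alpha, gamma).

    Returns the sweep table (columns alpha, gamma, auc) and the best
    (alpha, gamma) pair.  For the miRNA-only walker the alpha axis is
    degenerate and only the gamma grid matters.
    """
    if not len(alpha_grid) or not len(gamma_grid):
        raise ValueError("parameter grids must be non-empty")
    rows = []
    for alpha in alpha_grid:
        for gamma in gamma_grid:
            if method == "rwrmtn":
                ranker: Ranker = RWRMTNRanker(net, alpha=alpha, gamma=gamma, tol=tol, max_iter=max_iter)
            elif method == "rwrmda":
                ranker = RWRMDARanker(net, gamma=gamma, tol=tol, max_iter=max_iter)
            else:
                raise ValueError(f"sweep supports rwrmtn/rwrmda, not {method!r}")
            recs = loocv(assoc, ranker)
            auc = float(np.mean(list(roc_auc(recs).values())))
            rows.append({"alpha": alpha, "gamma": gamma, "auc": auc})
    table = pd.DataFrame(rows)
    best = table.loc[table["auc"].idxmax()]
    return table, (float(best["alpha"]), float(best["gamma"]))


def gamma_trend(gammas: Sequence[float], aucs: Sequence[float]) -> tuple[float, float]:
    """Least-squares slope of AUC against gamma with its two-sided p-value."""
    g = np.asarray(gammas, dtype=float)
    a = np.asarray(aucs, dtype=float)
    if g.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(g) == 0:
        raise ValueError("gamma values are constant")
    res = scipy.stats.linregress(g, a)
    return float(res.slope), float(res.pvalue)
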