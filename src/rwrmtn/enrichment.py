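"""Top-k candidate extraction and hypergeometric enrichment.

After ranking candidate miRNAs for a disease (seeds excluded), the top
``k`` (default 100) are compared with an independent reference
association database (HMDD-style).  Significance of the overlap is the
upper-tail hypergeometric probability of drawing at least the observed
number of reference miRNAs in ``k`` draws without replacement from the
candidate universe.

Population convention: the universe ``N`` is the number of miRNA nodes
in the network minus the disease's seed miRNAs; ``K`` counts reference
miRNAs for the disease inside that universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import hypergeom

from .evaluation import DiseaseAssociationSet, Ranker
from .networks import normalize_mirna

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "top_k", "hypergeom_upper", "enrich_disease"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap of the top-k predictions with a reference database."""

    disease: str
    k_overlap: int
    K_reference: int
    n_drawn: int
    N_universe: int
    p_value: float
    overlapping: tuple[str, ...]
    novel: tuple[str, ...]


def top_k(ranking: Sequence[tuple[str, float]] | Sequence[str], k: int) -> list[str]:
    """First min(k, len) entries of a ranking, order preserved."""
    if k < 0:
        raise ValueError("k must be non-negative")
    ids = [r[0] if isinstance(r, tuple) else r for r in ranking]
    if len(ids) < k:
        logger.warning("ranking holds only %d entries, fewer than k=%d", len(ids), k)
    return ids[:k]


def hypergeom_upper(k_overlap: int, K_reference: int, n_drawn: int, N_universe: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k_overlap).

    X counts reference successes among ``n_drawn`` draws without
    replacement from a universe of ``N_universe`` containing
    ``K_reference`` successes.
    """
    if min(k_overlap, K_reference, n_drawn, N_universe) < 0:
        raise ValueError("all arguments must be non-negative")
    if K_reference > N_universe or n_drawn > N_universe:
        raise ValueError("K and n cannot exceed the universe size N")
    if k_overlap > min(n_drawn, K_reference):
        raise ValueError("overlap cannot exceed min(n_drawn, K_reference)")
    if k_overlap == 0:
        return 1.0
    return float(hypergeom.sf(k_overlap - 1, N_universe, K_reference, n_drawn))


def enrich_disease(
    assoc: DiseaseAssociationSet,
    reference: DiseaseAssociationSet,
    ranker: Ranker,
    disease: str,
    k: int = 100,
) -> EnrichmentResult:
    """Rank novel candidates for one disease and test reference enrichment.

    Seeds are the disease's known miRNAs (the miRNA+target walker adds
    their targets internally); the top-k of the seed-excluded ranking is
    intersected with the reference miRNAs for the same disease.  Novel
    (non-reference) top-k candidates are returned alongside.
    """
    if disease not in assoc:
        raise KeyError(f"disease {disease!r} absent from the association set")
    universe = set(ranker.universe)
    known = assoc[disease]
    seeds = sorted(known & universe)
    if not seeds:
        raise ValueError(f"no known miRNA of {disease!r} is present in the network")
    scores = ranker.score(disease, seeds)
    candidates = sorted(universe - known)
    ranking = sorted(
        ((m, float(scores.loc[m])) for m in candidates), key=lambda t: (-t[1], t[0])
    )
    top = top_k(ranking, k)
    ref_mirnas = (
        {normalize_mirna(m) for m in reference[disease]} if disease in reference else set()
    )
    ref_in_universe = ref_mirnas & set(candidates)
    overlap = [m for m in top if m in ref_in_universe]
    p = hypergeom_upper(len(overlap), len(ref_in_universe), len(top), len(candidates))
    novel = tuple(m for m in top if m not in ref_mirnas)
    return EnrichmentResult(
        disease=disease,
        k_overlap=len(overlap),
        K_reference=len(ref_in_universe),
        n_drawn=len(top),
        N_universe=len(candidates),
        p_value=p,
        overlapping=tuple(overlap),
        novel=novel,
    )
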