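"""Construction of miRNA-target networks.

Two network types are built from the same miRNA-target interaction lists:

* a *heterogeneous* (bipartite) network whose nodes are miRNAs and their
  target genes, with unit-weight edges; ``mutual`` mode treats every
  miRNA-target interaction as reciprocal (symmetric adjacency), while
  ``directed`` mode points every edge miRNA -> gene, leaving gene nodes
  with out-degree zero;
* a *homogeneous* network whose nodes are miRNAs only, two miRNAs being
  connected iff they share at least one target gene, with edge weight
  ``|T_i ∩ T_j| / min(|T_i|, |T_j|)`` where ``T_x`` is the target set of
  miRNA ``x``.

Identifiers are normalized on ingestion: miRNA names are stripped and
lowercased, gene symbols stripped and uppercased, so that interaction and
association files from sources with different case conventions match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "InteractionSet",
    "HeterogeneousNetwork",
    "HomogeneousNetwork",
    "normalize_mirna",
    "normalize_gene",
    "parse_interactions",
    "build_heterogeneous",
    "build_homogeneous",
    "write_heterogeneous",
    "write_homogeneous",
]

_HEADER_TOKENS = {
    "mirna", "mirna_id", "mir_id", "mirbase", "mirbase_id",
    "gene", "gene_id", "gene_symbol", "symbol",
    "target", "target_gene", "target gene", "targets", "score",
}


def normalize_mirna(name: str) -> str:
    """Canonical form of a miRNA identifier (stripped, case-insensitive)."""
    return name.strip().lower()


def normalize_gene(symbol: str) -> str:
    """Canonical form of a gene symbol (stripped, uppercase)."""
    return symbol.strip().upper()


@dataclass(frozen=True, order=True)
class InteractionRecord:
    """One miRNA -> target-gene interaction."""

    mirna_id: str
    gene_id: str

    def __post_init__(self) -> None:
        if not self.mirna_id or not self.gene_id:
            raise ValueError("interaction identifiers must be non-empty")


class InteractionSet:
    """A deduplicated set of miRNA-target interactions.

    The raw material for both network types.  Records are unique
    ``(mirna_id, gene_id)`` pairs; the miRNA and gene identifier
    namespaces are disjoint (a node is either a miRNA or a gene).
    """

    def __init__(self, records: Iterable[InteractionRecord]):
        recs = sorted(set(records))
        if not recs:
            raise ValueError("no interactions")
        self.records: tuple[InteractionRecord, ...] = tuple(recs)
        mirnas = {r.mirna_id for r in recs}
        genes = {r.gene_id for r in recs}
        overlap = {m.casefold() for m in mirnas} & {g.casefold() for g in genes}
        if overlap:
            raise ValueError(
                f"identifiers used as both miRNA and gene: {sorted(overlap)[:5]}"
            )
        self.mirnas: tuple[str, ...] = tuple(sorted(mirnas))
        self.genes: tuple[str, ...] = tuple(sorted(genes))
        self._targets: dict[str, frozenset[str]] = {}
        by_mirna: dict[str, set[str]] = {m: set() for m in self.mirnas}
        for r in recs:
            by_mirna[r.mirna_id].add(r.gene_id)
        self._targets = {m: frozenset(g) for m, g in by_mirna.items()}

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_interactions(self) -> int:
        return len(self.records)

    def targets_of(self, mirna_id: str) -> frozenset[str]:
        """Target-gene set of one miRNA (empty if the miRNA is unknown)."""
        return self._targets.get(normalize_mirna(mirna_id), frozenset())

    def __len__(self) -> int:
        return self.n_interactions

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionSet):
            return NotImplemented
        return self.records == other.records

    def __repr__(self) -> str:
        return (
            f"InteractionSet({self.n_interactions} interactions, "
            f"{self.n_mirnas} miRNAs, {self.n_genes} genes)"
        )


def _looks_like_header(fields: list[str]) -> bool:
    # a header names its columns; data lines carry actual identifiers
    return any(f.strip().lower() in _HEADER_TOKENS for f in fields)


def parse_interactions(
    source: str | Path | IO[str],
    *,
    header: str | bool = "auto",
    score_min: float | None = None,
) -> InteractionSet:
    """Parse a tab-separated miRNA / gene interaction list.

    Lines starting with ``#`` and blank lines are skipped.  Columns beyond
    the second are ignored unless ``score_min`` is given, in which case a
    numeric third column is required and rows scoring below the threshold
    are dropped.  ``header`` may be ``True``, ``False`` or ``"auto"``
    (detect a header by keyword on the first data line).

    Raises ``ValueError`` naming the line number for malformed lines, and
    ``ValueError("no interactions")`` for an effectively empty file.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            return parse_interactions(fh, header=header, score_min=score_min)

    records: set[InteractionRecord] = set()
    n_rows = 0
    first_data_line = True
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if first_data_line:
            first_data_line = False
            if header is True or (header == "auto" and _looks_like_header(fields)):
                continue
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ValueError(f"malformed interaction line {lineno}: {line!r}")
        if score_min is not None:
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: score filtering requires a third column")
            try:
                score = float(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric score {fields[2]!r}") from exc
            if score < score_min:
                continue
        n_rows += 1
        records.add(
            InteractionRecord(normalize_mirna(fields[0]), normalize_gene(fields[1]))
        )
    if not records:
        raise ValueError("no interactions")
    iset = InteractionSet(records)
    n_dup = n_rows - iset.n_interactions
    logger.info(
        "parsed %d rows -> %d unique interactions (%d duplicates collapsed), "
        "%d miRNAs, %d genes",
        n_rows, iset.n_interactions, n_dup, iset.n_mirnas, iset.n_genes,
    )
    return iset


@dataclass
class HeterogeneousNetwork:
    """Bipartite miRNA-gene network.

    Nodes are ordered deterministically: sorted miRNAs first, then sorted
    genes.  ``adjacency`` is square over that ordering; symmetric in
    ``mutual`` mode, upper-off-diagonal (miRNA rows -> gene columns) in
    ``directed`` mode.
    """

    mirnas: tuple[str, ...]
    genes: tuple[str, ...]
    adjacency: sp.csr_matrix
    mode: str
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.mode not in ("mutual", "directed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self._index = {n: i for i, n in enumerate(self.nodes)}

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.mirnas + self.genes

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_nodes(self) -> int:
        return len(self.mirnas) + len(self.genes)

    @property
    def n_edges(self) -> int:
        nnz = self.adjacency.nnz
        return nnz // 2 if self.mode == "mutual" else nnz

    def index(self, node: str) -> int:
        return self._index[node]

    def is_mirna(self, node: str) -> bool:
        return self._index[node] < self.n_mirnas

    def targets_of(self, mirna_ids: Iterable[str]) -> frozenset[str]:
        """Union of target genes (present in the network) of the given miRNAs."""
        out: set[str] = set()
        gene0 = self.n_mirnas
        for m in mirna_ids:
            i = self._index.get(normalize_mirna(m))
            if i is None or i >= gene0:
                continue
            row = self.adjacency.getrow(i)
            out.update(self.nodes[j] for j in row.indices if j >= gene0)
        return frozenset(out)


@dataclass
class HomogeneousNetwork:
    """miRNA-only network weighted by shared-target similarity.

    Undirected, no self-loops; weights lie in (0, 1].  miRNAs sharing no
    target with any other miRNA are absent.
    """

    mirnas: tuple[str, ...]
    adjacency: sp.csr_matrix
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.mirnas)}

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.mirnas

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def index(self, node: str) -> int:
        return self._index[node]

    def weight(self, a: str, b: str) -> float:
        return float(self.adjacency[self._index[a], self._index[b]])


def build_heterogeneous(
    interactions: InteractionSet, mode: str = "mutual"
) -> HeterogeneousNetwork:
    """Build the bipartite miRNA-gene network from an interaction set."""
    if mode not in ("mutual", "directed"):
        raise ValueError(f"unknown mode {mode!r}")
    mirnas, genes = interactions.mirnas, interactions.genes
    m_idx = {m: i for i, m in enumerate(mirnas)}
    g_idx = {g: len(mirnas) + j for j, g in enumerate(genes)}
    rows = np.fromiter((m_idx[r.mirna_id] for r in interactions), dtype=np.int64)
    cols = np.fromiter((g_idx[r.gene_id] for r in interactions), dtype=np.int64)
    n = len(mirnas) + len(genes)
    data = np.ones(len(rows))
    adj = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
    if mode == "mutual":
        adj = adj + adj.T
    return HeterogeneousNetwork(mirnas, genes, adj.tocsr(), mode)


def build_homogeneous(interactions: InteractionSet) -> HomogeneousNetwork:
    """Build the shared-target miRNA similarity network.

    weight(i, j) = |T_i ∩ T_j| / min(|T_i|, |T_j|); an edge exists iff the
    two miRNAs share at least one target gene.
    """
    mirnas, genes = interactions.mirnas, interactions.genes
    m_idx = {m: i for i, m in enumerate(mirnas)}
    g_idx = {g: j for j, g in enumerate(genes)}
    rows = np.fromiter((m_idx[r.mirna_id] for r in interactions), dtype=np.int64)
    cols = np.fromiter((g_idx[r.gene_id] for r in interactions), dtype=np.int64)
    B = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(mirnas), len(genes))
    ).tocsr()
    shared = (B @ B.T).tocoo()
    t_size = np.asarray(B.sum(axis=1)).ravel()

    keep = shared.row < shared.col  # upper triangle, no self-loops
    ri, ci, ov = shared.row[keep], shared.col[keep], shared.data[keep]
    w = ov / np.minimum(t_size[ri], t_size[ci])

    connected = np.zeros(len(mirnas), dtype=bool)
    connected[ri] = True
    connected[ci] = True
    old_to_new = np.full(len(mirnas), -1, dtype=np.int64)
    kept_names = tuple(m for i, m in enumerate(mirnas) if connected[i])
    old_to_new[connected] = np.arange(len(kept_names))

    nk = len(kept_names)
    adj = sp.coo_matrix(
        (w, (old_to_new[ri], old_to_new[ci])), shape=(nk, nk)
    )
    adj = (adj + adj.T).tocsr()
    n_dropped = len(mirnas) - nk
    if n_dropped:
        logger.info("dropped %d miRNAs sharing no target with any other", n_dropped)
    return HomogeneousNetwork(kept_names, adj)


def write_heterogeneous(net: HeterogeneousNetwork, path: str | Path) -> None:
    """Write a bipartite network as a two-column miRNA\\tgene edge list."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#mirna\tgene\n")
        gene0 = net.n_mirnas
        coo = sp.triu(net.adjacency).tocoo() if net.mode == "mutual" else net.adjacency.tocoo()
        pairs = sorted(
            (net.nodes[i], net.nodes[j])
            for i, j in zip(coo.row, coo.col)
        )
        for m, g in pairs:
            fh.write(f"{m}\t{g}\n")


def write_homogeneous(net: HomogeneousNetwork, path: str | Path) -> None:
    """Write the weighted miRNA network as mirna\\tmirna\\tweight (6 sig. digits)."""
    coo = sp.triu(net.adjacency).tocoo()
    triples = sorted(
        (net.mirnas[i], net.mirnas[j], w) for i, j, w in zip(coo.row, coo.col, coo.data)
    )
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#mirna_a\tmirna_b\tweight\n")
        for a, b, w in triples:
            fh.write(f"{a}\t{b}\t{w:.6g}\n")


def parse_homogeneous(source: str | Path | IO[str]) -> HomogeneousNetwork:
    """Read a weighted miRNA-miRNA edge list written by :func:`write_homogeneous`."""
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            return parse_homogeneous(fh)
    edges: dict[tuple[str, str], float] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed weighted edge line {lineno}: {line!r}")
        a, b = normalize_mirna(fields[0]), normalize_mirna(fields[1])
        w = float(fields[2])
        if not 0 < w <= 1:
            raise ValueError(f"line {lineno}: weight {w} outside (0, 1]")
        edges[tuple(sorted((a, b)))] = w
    if not edges:
        raise ValueError("no edges")
    names = tuple(sorted({n for pair in edges for n in pair}))
    idx = {n: i for i, n in enumerate(names)}
    ri = np.array([idx[a] for a, _ in edges], dtype=np.int64)
    ci = np.array([idx[b] for _, b in edges], dtype=np.int64)
    w = np.array(list(edges.values()))
    adj = sp.coo_matrix((w, (ri, ci)), shape=(len(names), len(names)))
    return HomogeneousNetwork(names, (adj + adj.T).tocsr())
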