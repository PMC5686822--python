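"""Seeded generators of small miRNA-target fixtures with planted disease modules.

These emulate, at desk scale, the statistical structure the ranking
methods exploit: a sparse bipartite background of miRNA-target
interactions plus, per disease, a *module* of miRNAs co-wired to a
shared core of genes (the disease-module principle: miRNAs associated
with a phenotype lie close together in the network because they regulate
common genes).  Half of each module is labelled as known associations;
the hidden half is the ground truth a method should recover.

All outputs are deterministic functions of the fixture spec and its
``rng_seed``; each operation draws from its own sub-stream so adding a
generator call never perturbs earlier outputs.

Defaults are a roughly tenfold scale-down of the experimentally
validated miRNA-target network used for the real analyses (miRNA:gene
ratio ~1:4, a few targets per miRNA on average).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import DiseaseAssociationSet, write_associations
from .networks import InteractionRecord, InteractionSet

__all__ = [
    "FixtureSpec",
    "generate_interactions",
    "plant_module",
    "generate_phenotype_similarity",
    "permute_associations",
    "write_fixture",
]

_MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of a synthetic fixture.

    module_cohesion is the probability that a module miRNA is wired to
    each gene of its disease's shared core; it controls how recoverable
    the planted module is.
    """

    n_mirnas: int = 60
    n_genes: int = 240
    edge_density: float = 0.02
    n_diseases: int = 4
    module_size: int = 10
    n_core_genes: int = 12
    module_cohesion: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_genes, self.n_diseases) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 < self.edge_density <= 1.0:
            raise ValueError("edge_density must lie in (0, 1]")
        if not 0.0 < self.module_cohesion <= 1.0:
            raise ValueError(
                "module_cohesion must lie in (0, 1]; at 0 the module is "
                "indistinguishable from background"
            )
        if self.module_size > self.n_mirnas:
            raise ValueError("module_size cannot exceed n_mirnas")
        if self.module_size < 4:
            raise ValueError("module_size must be >= 4 (half known, half hidden, >= 2 each)")
        if self.n_core_genes > self.n_genes:
            raise ValueError("n_core_genes cannot exceed n_genes")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.rng_seed, spawn_key=(stream,))
        )


def _mirna_name(i: int) -> str:
    return f"mir-{i + 1:04d}"


def _gene_name(j: int) -> str:
    return f"GENE{j + 1:05d}"


def generate_interactions(spec: FixtureSpec) -> InteractionSet:
    """Background bipartite edge set: each pair kept with prob edge_density.

    Rows (miRNAs) that come out empty are redrawn so every miRNA has at
    least one target; a bounded retry count guards unusably low densities.
    """
    rng = spec._rng(0)
    mat = rng.random((spec.n_mirnas, spec.n_genes)) < spec.edge_density
    for i in range(spec.n_mirnas):
        tries = 0
        while not mat[i].any():
            tries += 1
            if tries > _MAX_RESAMPLE:
                raise ValueError(
                    f"edge_density={spec.edge_density} too low to give miRNA {i} a target"
                )
            mat[i] = rng.random(spec.n_genes) < spec.edge_density
    rows, cols = np.nonzero(mat)
    return InteractionSet(
        InteractionRecord(_mirna_name(i), _gene_name(j)) for i, j in zip(rows, cols)
    )


def plant_module(
    interactions: InteractionSet, spec: FixtureSpec
) -> tuple[InteractionSet, DiseaseAssociationSet, dict[str, frozenset[str]]]:
    """Wire one cohesive miRNA module per disease and split it known/hidden.

    For each disease, ``module_size`` miRNAs and ``n_core_genes`` core
    genes are drawn; each (module miRNA, core gene) pair is added with
    probability ``module_cohesion`` (at least one core link per module
    miRNA is enforced so the module is connected).  A random half of the
    module becomes the known associations, the rest the hidden ground
    truth.
    """
    rng = spec._rng(1)
    mirna_pool = [_mirna_name(i) for i in range(spec.n_mirnas)]
    gene_pool = [_gene_name(j) for j in range(spec.n_genes)]
    records = set(interactions.records)
    assoc: dict[str, set[str]] = {}
    truth: dict[str, frozenset[str]] = {}
    for d in range(spec.n_diseases):
        disease = f"disease-{d + 1:02d}"
        module = rng.choice(mirna_pool, size=spec.module_size, replace=False)
        core = rng.choice(gene_pool, size=spec.n_core_genes, replace=False)
        for m in module:
            wired = core[rng.random(spec.n_core_genes) < spec.module_cohesion]
            if wired.size == 0:
                wired = rng.choice(core, size=1)
            for g in wired:
                records.add(InteractionRecord(str(m), str(g)))
        shuffled = list(module)
        rng.shuffle(shuffled)
        n_known = math.ceil(spec.module_size / 2)
        assoc[disease] = {str(m) for m in shuffled[:n_known]}
        truth[disease] = frozenset(str(m) for m in shuffled[n_known:])
    return InteractionSet(records), DiseaseAssociationSet(assoc), truth


def generate_phenotype_similarity(
    n_diseases: int,
    block_structure: list[list[str]] | None = None,
    rng_seed: int = 0,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Symmetric phenotype similarity with unit diagonal, entries in [0, 1].

    Background off-diagonal similarity is i.i.d. uniform on [0, 0.3];
    pairs inside a block of ``block_structure`` are elevated to uniform
    [0.6, 0.9], emulating groups of clinically similar phenotypes.
    """
    if n_diseases < 2:
        raise ValueError("need at least 2 diseases")
    if labels is None:
        labels = [f"disease-{d + 1:02d}" for d in range(n_diseases)]
    if len(labels) != n_diseases:
        raise ValueError("labels length must match n_diseases")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=rng_seed, spawn_key=(2,))
    )
    S = rng.uniform(0.0, 0.3, size=(n_diseases, n_diseases))
    S = np.triu(S, 1)
    S = S + S.T
    idx = {lab: i for i, lab in enumerate(labels)}
    for block in block_structure or []:
        members = [idx[b] for b in block]
        for a in members:
            for b in members:
                if a < b:
                    v = rng.uniform(0.6, 0.9)
                    S[a, b] = S[b, a] = v
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=labels, columns=labels)


def permute_associations(
    assoc: DiseaseAssociationSet, mirna_pool: list[str], rng_seed: int = 0
) -> DiseaseAssociationSet:
    """Size-matched label permutation: random miRNAs replace each disease's set.

    The null baseline for planted-module recovery — association counts
    are preserved but any network structure linking a disease's miRNAs
    is destroyed.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=rng_seed, spawn_key=(3,))
    )
    pool = sorted(mirna_pool)
    return DiseaseAssociationSet(
        {
            d: {str(m) for m in rng.choice(pool, size=len(assoc[d]), replace=False)}
            for d in assoc
        }
    )


def write_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate a full fixture and write its files into ``out_dir``.

    Writes interactions.tsv, associations.tsv (known), reference.tsv
    (hidden ground truth, usable as an enrichment reference), truth.tsv
    (same content, explicit name) and phenosim.tsv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = generate_interactions(spec)
    interactions, assoc, truth = plant_module(base, spec)
    truth_set = DiseaseAssociationSet(truth)
    phenosim = generate_phenotype_similarity(
        spec.n_diseases, rng_seed=spec.rng_seed, labels=list(assoc)
    )
    paths = {
        "interactions": out / "interactions.tsv",
        "associations": out / "associations.tsv",
        "reference": out / "reference.tsv",
        "truth": out / "truth.tsv",
        "phenosim": out / "phenosim.tsv",
    }
    with open(paths["interactions"], "wt", encoding="utf-8") as fh:
        fh.write("#mirna\tgene\n")
        for r in interactions:
            fh.write(f"{r.mirna_id}\t{r.gene_id}\n")
    write_associations(assoc, paths["associations"])
    write_associations(truth_set, paths["reference"])
    write_associations(truth_set, paths["truth"])
    phenosim.to_csv(paths["phenosim"], sep="\t")
    return paths
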