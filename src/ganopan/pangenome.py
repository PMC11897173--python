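"""Pan-genome statistics over an orthogroup occupancy matrix.

A gene family's *occupancy* is the number of genomes in which it has at
least one member.  Families are binned by occupancy into the four standard
pan-genome categories — for N genomes: core (all N), softcore (N-2..N-1),
dispensable (2..N-3) and private (exactly 1).  On top of the classification
this module computes permutation-based pan/core rarefaction curves and
presence/absence pattern (Venn) counts for genome subsets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import OrthogroupTable

__all__ = [
    "CATEGORIES",
    "CategoryScheme",
    "OrthogroupMatrix",
    "FamilyClassification",
    "RarefactionResult",
    "build_matrix",
    "classify",
    "rarefy",
    "rarefy_exact",
    "shared_counts",
]

CATEGORIES = ("core", "softcore", "dispensable", "private")


@dataclass(frozen=True)
class CategoryScheme:
    """Occupancy bands mapping family occupancy to a category.

    The default scheme for N genomes is core = N, softcore = N-2..N-1,
    dispensable = 2..N-3, private = 1.  For small N the softcore and
    dispensable bands clamp to empty rather than erroring.
    """

    n_genomes: int
    core_min: int
    softcore_min: int
    dispensable_min: int = 2
    private_occupancy: int = 1

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("need at least 2 genomes")
        ok = (self.private_occupancy < self.dispensable_min
              <= self.softcore_min <= self.core_min <= self.n_genomes)
        if not ok:
            raise ValueError(f"inconsistent occupancy bands: {self}")

    @classmethod
    def default(cls, n_genomes: int) -> "CategoryScheme":
        return cls(
            n_genomes=n_genomes,
            core_min=n_genomes,
            softcore_min=max(2, n_genomes - 2),
        )

    def category(self, occupancy: int) -> str:
        if not (1 <= occupancy <= self.n_genomes):
            raise ValueError(f"occupancy {occupancy} outside [1, {self.n_genomes}]")
        if occupancy >= self.core_min:
            return "core"
        if occupancy >= self.softcore_min:
            return "softcore"
        if occupancy >= self.dispensable_min:
            return "dispensable"
        return "private"


@dataclass(frozen=True)
class OrthogroupMatrix:
    """Family x genome gene-count matrix with derived occupancy."""

    families: tuple[str, ...]
    genomes: tuple[str, ...]
    gene_count: np.ndarray        # shape (n_families, n_genomes), int, >= 0

    def __post_init__(self) -> None:
        gc = np.asarray(self.gene_count)
        if gc.shape != (len(self.families), len(self.genomes)):
            raise ValueError("gene_count shape does not match labels")
        if (gc < 0).any():
            raise ValueError("negative gene counts")
        if ((gc > 0).sum(axis=1) == 0).any():
            bad = [self.families[i] for i in np.flatnonzero((gc > 0).sum(axis=1) == 0)]
            raise ValueError(f"families with zero occupancy: {bad[:5]}")

    @property
    def presence(self) -> np.ndarray:
        return self.gene_count > 0

    @property
    def occupancy(self) -> np.ndarray:
        return self.presence.sum(axis=1)

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)


def build_matrix(tables: Sequence[OrthogroupTable]) -> OrthogroupMatrix:
    """Assemble the occupancy matrix from parsed orthogroup rows."""
    if not tables:
        raise ValueError("empty orthogroup collection")
    genomes = tuple(tables[0].members)
    for t in tables:
        if tuple(t.members) != genomes:
            raise ValueError(f"family {t.family_id}: genome set differs")
    order = sorted(range(len(tables)), key=lambda i: tables[i].family_id)
    families = tuple(tables[i].family_id for i in order)
    gc = np.zeros((len(tables), len(genomes)), dtype=int)
    for row, i in enumerate(order):
        for col, g in enumerate(genomes):
            gc[row, col] = len(tables[i].members[g])
    return OrthogroupMatrix(families, genomes, gc)


def matrix_from_occupancies(occupancies: Sequence[int], n_genomes: int,
                            prefix: str = "F") -> OrthogroupMatrix:
    """Presence matrix with given per-family occupancies (first genomes filled).

    Useful for reconstructing occupancy-band compositions when only the
    per-band tallies are known.
    """
    gc = np.zeros((len(occupancies), n_genomes), dtype=int)
    for i, occ in enumerate(occupancies):
        gc[i, :occ] = 1
    families = tuple(f"{prefix}{i:06d}" for i in range(len(occupancies)))
    genomes = tuple(f"G{j:02d}" for j in range(n_genomes))
    return OrthogroupMatrix(families, genomes, gc)


@dataclass
class FamilyClassification:
    """Per-family category labels plus category tallies.

    Singleton genes (genes assigned to no family) are tallied separately as
    private units; they do not enter the family counts or percentages.
    """

    scheme: CategoryScheme
    categories: dict[str, str]
    counts: dict[str, int]
    singleton_genes: list[str] = field(default_factory=list)

    @property
    def n_families(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        total = self.n_families
        return {c: 100.0 * self.counts[c] / total for c in CATEGORIES}

    def to_frame(self, matrix: OrthogroupMatrix) -> pd.DataFrame:
        occ = dict(zip(matrix.families, matrix.occupancy))
        return pd.DataFrame({
            "family_id": list(self.categories),
            "occupancy": [occ[f] for f in self.categories],
            "category": [self.categories[f] for f in self.categories],
        })


def classify(matrix: OrthogroupMatrix,
             scheme: CategoryScheme | None = None,
             singletons: Iterable[str] = ()) -> FamilyClassification:
    """Label every family by its occupancy band."""
    if scheme is None:
        scheme = CategoryScheme.default(matrix.n_genomes)
    if scheme.n_genomes != matrix.n_genomes:
        raise ValueError(
            f"scheme is for {scheme.n_genomes} genomes, matrix has {matrix.n_genomes}"
        )
    cats = {f: scheme.category(int(o))
            for f, o in zip(matrix.families, matrix.occupancy)}
    counts = {c: 0 for c in CATEGORIES}
    for c in cats.values():
        counts[c] += 1
    return FamilyClassification(scheme, cats, counts, list(singletons))


@dataclass
class RarefactionResult:
    """Pan/core curves over random genome orderings.

    ``pan`` and ``core`` have shape (n_permutations, N): cumulative union
    and intersection sizes as genomes are added one at a time.
    """

    genomes: tuple[str, ...]
    pan: np.ndarray
    core: np.ndarray
    seed: int | None
    exhaustive: bool = False

    @property
    def n_permutations(self) -> int:
        return self.pan.shape[0]

    @property
    def k(self) -> np.ndarray:
        return np.arange(1, self.pan.shape[1] + 1)

    def summary(self, quantiles: Sequence[float] = (0.025, 0.5, 0.975)) -> pd.DataFrame:
        rows = {"k": self.k,
                "pan_mean": self.pan.mean(axis=0),
                "core_mean": self.core.mean(axis=0)}
        for q in quantiles:
            rows[f"pan_q{q:g}"] = np.quantile(self.pan, q, axis=0)
            rows[f"core_q{q:g}"] = np.quantile(self.core, q, axis=0)
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        n_perm, n = self.pan.shape
        return pd.DataFrame({
            "permutation": np.repeat(np.arange(n_perm), n),
            "k": np.tile(np.arange(1, n + 1), n_perm),
            "pan": self.pan.ravel(),
            "core": self.core.ravel(),
        })


def _curves_for_orders(presence: np.ndarray, orders: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n_perm, n = orders.shape
    pan = np.empty((n_perm, n), dtype=int)
    core = np.empty((n_perm, n), dtype=int)
    for i, order in enumerate(orders):
        cols = presence[:, order]
        pan[i] = np.logical_or.accumulate(cols, axis=1).sum(axis=0)
        core[i] = np.logical_and.accumulate(cols, axis=1).sum(axis=0)
    return pan, core


def rarefy(matrix: OrthogroupMatrix, n_perm: int = 100,
           seed: int | None = 0) -> RarefactionResult:
    """Monte-Carlo rarefaction: sample ``n_perm`` random genome orderings.

    Within every ordering the pan curve is non-decreasing and the core
    curve non-increasing; at k = N they equal the total family count and
    the core-category count respectively.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = matrix.n_genomes
    orders = np.stack([rng.permutation(n) for _ in range(n_perm)])
    pan, core = _curves_for_orders(matrix.presence, orders)
    return RarefactionResult(matrix.genomes, pan, core, seed)


def rarefy_exact(matrix: OrthogroupMatrix) -> RarefactionResult:
    """Exhaustive rarefaction over all N! genome orderings (small N only)."""
    n = matrix.n_genomes
    if math.factorial(n) > 50_000:
        raise ValueError(f"{n}! orderings is too many for exhaustive rarefaction")
    orders = np.array(list(itertools.permutations(range(n))))
    pan, core = _curves_for_orders(matrix.presence, orders)
    return RarefactionResult(matrix.genomes, pan, core, None, exhaustive=True)


def shared_counts(matrix: OrthogroupMatrix,
                  genome_subset: Sequence[str]) -> dict[str, int]:
    """Presence/absence pattern counts over a genome subset (Venn counts).

    Patterns are strings of '0'/'1' in subset order; only families present
    in at least one subset genome are counted.
    """
    if not (2 <= len(genome_subset) <= 6):
        raise ValueError("subset size must be between 2 and 6")
    unknown = [g for g in genome_subset if g not in matrix.genomes]
    if unknown:
        raise ValueError(f"unknown genomes: {unknown}")
    idx = [matrix.genomes.index(g) for g in genome_subset]
    sub = matrix.presence[:, idx]
    sub = sub[sub.any(axis=1)]
    patterns, counts = np.unique(sub, axis=0, return_counts=True)
    return {"".join("1" if b else "0" for b in row): int(c)
            for row, c in zip(patterns, counts)}
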