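"""Multi-tool evidence filter and pathway-universe restriction.

The enrichment statistic only counts a (miRNA, gene) pair as evidence when
at least ``k`` distinct prediction tools agree on it (default 2, the
standard consensus rule for multi-tool target predictions), and only for
genes that belong to at least one pathway under analysis.  The universe
size M is the number of distinct genes across all pathways — pathway genes
never predicted as anyone's target still count in M.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .data_io import PathwayDatabase, TargetPredictionTable
from .errors import PipelineError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SupportedPairSet:
    """The evidence set: (miRNA, gene) pairs with their tool-support counts.

    ``universe_size`` (M) is None until the set has been restricted to a
    pathway database with :func:`restrict_to_universe`.
    """

    pairs: frozenset[tuple[str, str]]
    support: dict[tuple[str, str], int] = field(hash=False)
    min_tools: int = 2
    universe_size: int | None = None

    @cached_property
    def targets_by_mirna(self) -> dict[str, frozenset[str]]:
        """miRNA -> set of supported target genes; K_j = len of the value."""
        acc: dict[str, set[str]] = {}
        for mirna, gene in self.pairs:
            acc.setdefault(mirna, set()).add(gene)
        return {m: frozenset(g) for m, g in acc.items()}

    def target_count(self, mirna: str) -> int:
        """K_j, the number of supported targets of one miRNA."""
        return len(self.targets_by_mirna.get(mirna, ()))

    @cached_property
    def indicator(self):
        """(mirnas, gene_index, T, K): a cached miRNA x target-gene matrix.

        T[i, j] marks that mirnas[i] targets the j-th targeted gene; K is
        the per-miRNA row sum.  Only targeted genes get columns — pathway
        genes nobody targets contribute nothing to overlap counts.
        """
        mirnas = self.mirnas
        genes = sorted({g for _, g in self.pairs})
        gene_index = {g: i for i, g in enumerate(genes)}
        T = np.zeros((len(mirnas), len(genes)), dtype=bool)
        for mi, mirna in enumerate(mirnas):
            T[mi, [gene_index[g] for g in self.targets_by_mirna[mirna]]] = True
        return mirnas, gene_index, T, T.sum(axis=1)

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.targets_by_mirna)

    def __len__(self) -> int:
        return len(self.pairs)


def filter_min_tools(table: TargetPredictionTable, k: int = 2) -> SupportedPairSet:
    """Retain the (miRNA, gene) pairs predicted by at least ``k`` distinct tools."""
    if k < 1:
        raise ValidationError(f"min-tools threshold must be >= 1, got {k}")
    counts: dict[tuple[str, str], set[str]] = {}
    for mirna, gene, tool in table.records:
        counts.setdefault((mirna, gene), set()).add(tool)
    support = {pair: len(tools) for pair, tools in counts.items() if len(tools) >= k}
    logger.info(
        "tool-support filter (k=%d): %d of %d pairs retained", k, len(support), len(counts)
    )
    return SupportedPairSet(pairs=frozenset(support), support=support, min_tools=k)


def restrict_to_universe(pairs: SupportedPairSet, db: PathwayDatabase) -> SupportedPairSet:
    """Drop pairs whose gene is in no pathway; set M to the pathway-gene count."""
    universe = db.gene_universe
    kept = {pair: n for pair, n in pairs.support.items() if pair[1] in universe}
    if not kept:
        raise PipelineError("no overlap between predictions and pathway genes")
    logger.info(
        "universe restriction: %d of %d pairs retained, M=%d",
        len(kept), len(pairs.support), len(universe),
    )
    return SupportedPairSet(
        pairs=frozenset(kept),
        support=kept,
        min_tools=pairs.min_tools,
        universe_size=len(universe),
    )
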