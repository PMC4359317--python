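"""Randomized-pathway null: are the observed associations pathway-specific?

Every miRNA targets many genes, so *some* enrichment is expected for any
gene set.  To show that curated pathways are special, the analysis is
re-run on randomly assembled "pathways" — gene sets drawn from the pool of
pathway-member genes with sizes matching the curated collection — and the
observed q-value distribution is compared against the pooled random one
with a Welch two-sample t-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import Pathway, PathwayDatabase
from .enrichment import associate_all
from .errors import ValidationError
from .targets import SupportedPairSet

logger = logging.getLogger(__name__)

DEFAULT_N_ITERATIONS = 1000
DEFAULT_SIZE_RANGE = (4, 50)


@dataclass(frozen=True)
class NullRunResult:
    """q-values from one randomized-pathway iteration."""

    iteration: int
    q_values: tuple[float, ...]
    rng_seed: int


def random_pathway_set(
    pool,
    n_pathways: int,
    size_min: int = DEFAULT_SIZE_RANGE[0],
    size_max: int = DEFAULT_SIZE_RANGE[1],
    seed: int | np.random.SeedSequence = 0,
) -> PathwayDatabase:
    """Build ``n_pathways`` random gene sets from the pathway-gene pool.

    Sizes are uniform on [size_min, size_max]; genes are sampled uniformly
    without replacement within a set (with replacement across sets).  The
    result is fully determined by ``seed``.
    """
    pool = sorted(pool)
    if size_min < 1 or size_min > size_max:
        raise ValidationError(f"invalid size range [{size_min}, {size_max}]")
    if len(pool) < size_max:
        raise ValidationError(
            f"gene pool ({len(pool)}) smaller than the maximum pathway size ({size_max})"
        )
    rng = np.random.default_rng(seed)
    pool_arr = np.asarray(pool, dtype=object)
    width = len(str(max(n_pathways - 1, 1)))
    pathways = []
    for i in range(n_pathways):
        size = int(rng.integers(size_min, size_max + 1))
        genes = rng.choice(pool_arr, size=size, replace=False)
        pathways.append(
            Pathway(
                pathway_id=f"RAND{i:0{width}d}",
                genes=frozenset(genes.tolist()),
                source="randomized",
            )
        )
    return PathwayDatabase(pathways=tuple(pathways))


def null_distribution(
    pool,
    pairs: SupportedPairSet,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    n_pathways: int | None = None,
    size_min: int = DEFAULT_SIZE_RANGE[0],
    size_max: int = DEFAULT_SIZE_RANGE[1],
    seed: int = 0,
    tail: str = "gt",
) -> list[NullRunResult]:
    """Re-run the best-miRNA enrichment on random pathway sets.

    Per-iteration seeds are spawned from the master ``seed`` so iterations
    are reproducible independently of execution order.  ``n_pathways``
    defaults to the observed pathway count and must be supplied explicitly
    here.
    """
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    if n_pathways is None:
        raise ValidationError("n_pathways (observed pathway count) is required")
    children = np.random.SeedSequence(seed).spawn(n_iterations)
    results = []
    for it, child in enumerate(children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        db = random_pathway_set(pool, n_pathways, size_min, size_max, seed=child)
        records = associate_all(db, pairs, tail=tail)
        q = tuple(float(r.q_value) for r in records if r.has_association)
        results.append(NullRunResult(iteration=it, q_values=q, rng_seed=child_seed))
    logger.info("null model: %d iterations of %d random pathways", n_iterations, n_pathways)
    return results


def pooled_null_qvalues(results: list[NullRunResult]) -> np.ndarray:
    return np.concatenate([np.asarray(r.q_values, dtype=float) for r in results])


def compare_observed_vs_null(observed_q, null_q) -> tuple[float, float]:
    """Welch two-sample t-test between observed and random q-values.

    Returns (t statistic, two-sided p).  Degenerate zero-variance inputs
    are handled explicitly: identical constant samples give (0, 1); two
    different constants give (inf-signed t, p = 0) with a warning.
    """
    a = np.asarray(observed_q, dtype=float)
    b = np.asarray(null_q, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("both q-value samples need >= 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero-variance samples with different means; p-value degenerates to 0")
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
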