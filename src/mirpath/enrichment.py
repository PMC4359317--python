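"""Per-pathway best-miRNA hypergeometric enrichment with Storey FDR.

Every pathway is affiliated with a *single* miRNA — the one targeting the
largest number of the pathway's genes — and the association is scored with
a hypergeometric tail probability: drawing the pathway's N genes without
replacement from a universe of M genes of which K are the miRNA's targets,
what is the chance of hitting more than the observed x targets?

Tail convention.  The statistic is ``1 - sum_{i=0..x} pmf(i)``, i.e. the
strictly-greater tail P(X > x).  The more common enrichment convention
P(X >= x) is available via ``tail="geq"``; the two differ by one pmf term,
which matters for small counts.  The strict tail is the package default
because it is the convention the pipeline's published counts were scored
under.

Selecting the maximum-overlap miRNA and then testing that same overlap is
post-selection inference: the reported p-values are optimistically biased
and should be read as ranking scores, not calibrated tail probabilities.
The randomized-pathway null (``mirpath.null_model``) is the honest
calibration instrument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .data_io import Pathway, PathwayDatabase
from .errors import ValidationError
from .targets import SupportedPairSet

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))


@dataclass(frozen=True)
class AssociationRecord:
    """One pathway's best-miRNA association with its enrichment evidence.

    x: number of the miRNA's targets inside the pathway; K: the miRNA's
    total supported targets in the universe; N: pathway size; M: universe
    size.  ``q_value`` is NaN until filled jointly over a record set;
    pathways where no miRNA hits any gene carry ``mirna_id=None`` and are
    excluded from the FDR computation.
    """

    pathway_id: str
    mirna_id: str | None
    x: int
    K: int
    N: int
    M: int
    p_value: float
    q_value: float = float("nan")

    @property
    def has_association(self) -> bool:
        return self.mirna_id is not None


def hypergeom_tail(x: int, K: int, N: int, M: int, tail: str = "gt") -> float:
    """Hypergeometric tail probability of the overlap between two gene sets.

    Parameters mirror the enrichment setting: a universe of ``M`` genes of
    which ``K`` are targets, a pathway of ``N`` genes, and an observed
    overlap of ``x``.  ``tail="gt"`` returns P(X > x) (the default strict
    tail); ``tail="geq"`` returns P(X >= x).
    """
    if not (0 <= x <= N <= M and 0 <= K <= M):
        raise ValidationError(
            f"invalid hypergeometric arguments: x={x}, K={K}, N={N}, M={M}"
        )
    if tail == "gt":
        return float(hypergeom.sf(x, M, K, N))
    if tail == "geq":
        return float(hypergeom.sf(x - 1, M, K, N))
    raise ValidationError(f"unknown tail convention {tail!r}")


def best_mirna(
    pathway: Pathway, pairs: SupportedPairSet, tail: str = "gt"
) -> tuple[str | None, int]:
    """Pick the miRNA with the most targets inside the pathway.

    Ties on the count are broken by smaller tail p-value, then by
    lexicographic miRNA id, so the choice is deterministic.  Returns
    (None, 0) when no miRNA targets any pathway gene.
    """
    M = pairs.universe_size
    if M is None:
        raise ValidationError("pair set must be universe-restricted before association")
    best: tuple[int, float, str] | None = None  # (-x, p, mirna)
    for mirna, targets in pairs.targets_by_mirna.items():
        x = len(targets & pathway.genes)
        if x == 0:
            continue
        if best is not None and x < -best[0]:
            continue
        p = hypergeom_tail(x, len(targets), pathway.size, M, tail=tail)
        key = (-x, p, mirna)
        if best is None or key < best:
            best = key
    if best is None:
        return None, 0
    return best[2], -best[0]


def storey_pi0(
    p_values: np.ndarray, lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
) -> float:
    """Estimate the null proportion pi0 from the p-value distribution.

    pi0_hat(lambda) = #{p > lambda} / (m (1 - lambda)) on the grid, smoothed
    by a cubic polynomial fit and evaluated at the largest lambda, then
    clipped to (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    lam = np.asarray(lambda_grid, dtype=float)
    if lam.size == 0 or (lam < 0).any() or (lam >= 1).any():
        raise ValidationError("lambda grid must lie in [0, 1)")
    m = p.size
    raw = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if lam.size >= 4:
        coef = np.polynomial.polynomial.polyfit(lam, raw, deg=3)
        pi0 = float(np.polynomial.polynomial.polyval(lam.max(), coef))
    else:
        pi0 = float(raw[-1])
    return float(np.clip(pi0, 1e-8, 1.0))


def storey_qvalues(
    p_values,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    pi0: float | None = None,
) -> np.ndarray:
    """Storey q-values: pi0-scaled step-up FDR estimates, in input order.

    With ``pi0`` forced to 1 this reduces exactly to the
    Benjamini-Hochberg step-up adjustment.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = storey_pi0(p, lambda_grid)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1] * pi0
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def associate_all(
    db: PathwayDatabase,
    pairs: SupportedPairSet,
    tail: str = "gt",
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
) -> list[AssociationRecord]:
    """Affiliate every pathway with its best miRNA and attach p- and q-values.

    Internally vectorised: overlap counts for all (miRNA, pathway) pairs
    are computed on an indicator matrix, after which ties are resolved with
    the same rule as :func:`best_mirna`.  Pathways with no targeted gene
    are reported with ``mirna_id=None`` and excluded from the q-value
    computation.
    """
    M = pairs.universe_size
    if M is None:
        raise ValidationError("pair set must be universe-restricted before association")
    if len(db) == 0 or len(pairs) == 0:
        raise ValidationError("need a non-empty pathway database and pair set")

    # Cached miRNA x targeted-gene indicator; column gathers per pathway
    # keep the overlap counting sparse-fast and reusable across null runs.
    mirnas, gene_index, T, K = pairs.indicator

    # Pass 1: overlap counts and max-x ties per pathway.
    placeholders: list[AssociationRecord | None] = []
    cand_x, cand_K, cand_N, cand_pw, cand_mi = [], [], [], [], []
    for pi, pathway in enumerate(db):
        cols = [gene_index[g] for g in pathway.genes if g in gene_index]
        x_all = T[:, cols].sum(axis=1) if cols else np.zeros(len(mirnas), dtype=int)
        x_max = int(x_all.max()) if x_all.size else 0
        if x_max == 0:
            placeholders.append(
                AssociationRecord(
                    pathway_id=pathway.pathway_id, mirna_id=None,
                    x=0, K=0, N=pathway.size, M=M, p_value=float("nan"),
                )
            )
            continue
        placeholders.append(None)
        for mi in np.flatnonzero(x_all == x_max):
            cand_x.append(x_max)
            cand_K.append(int(K[mi]))
            cand_N.append(pathway.size)
            cand_pw.append(pi)
            cand_mi.append(int(mi))

    # Pass 2: one vectorised tail evaluation for every tie candidate.
    shift = 0 if tail == "gt" else 1
    if tail not in ("gt", "geq"):
        raise ValidationError(f"unknown tail convention {tail!r}")
    p_cand = hypergeom.sf(np.asarray(cand_x) - shift, M, np.asarray(cand_K), np.asarray(cand_N)) \
        if cand_x else np.empty(0)

    best: dict[int, tuple[float, str, int, int, int]] = {}
    for x, Ki, Ni, pi, mi, p in zip(cand_x, cand_K, cand_N, cand_pw, cand_mi, p_cand):
        key = (float(p), mirnas[mi])
        if pi not in best or key < (best[pi][0], best[pi][1]):
            best[pi] = (float(p), mirnas[mi], x, Ki, Ni)

    records: list[AssociationRecord] = []
    for pi, pathway in enumerate(db):
        if placeholders[pi] is not None:
            records.append(placeholders[pi])
            continue
        p, mirna, x, Ki, Ni = best[pi]
        records.append(
            AssociationRecord(
                pathway_id=pathway.pathway_id, mirna_id=mirna,
                x=x, K=Ki, N=Ni, M=M, p_value=p,
            )
        )

    scored = [i for i, r in enumerate(records) if r.has_association]
    if len(scored) < len(records):
        logger.info(
            "%d pathways had no targeted gene; excluded from FDR",
            len(records) - len(scored),
        )
    if scored:
        q = storey_qvalues([records[i].p_value for i in scored], lambda_grid)
        for i, qi in zip(scored, q):
            records[i] = replace(records[i], q_value=float(qi))
    return records


def associations_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Associations as a table, sorted by (q, p, pathway) with the strongest first."""
    frame = pd.DataFrame(
        [
            (r.pathway_id, r.mirna_id if r.mirna_id is not None else "",
             r.x, r.K, r.N, r.M, r.p_value, r.q_value)
            for r in records
        ],
        columns=["pathway_id", "mirna_id", "x", "K", "N", "M", "p_value", "q_value"],
    )
    return frame.sort_values(
        ["q_value", "p_value", "pathway_id"], na_position="last", kind="stable"
    ).reset_index(drop=True)


def write_associations(records: list[AssociationRecord], path) -> None:
    associations_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.6g")
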