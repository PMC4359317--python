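"""Probabilistic pathway-activity scoring from expression data.

The score follows the semantics of interaction-likelihood pathway tools:
each gene is modelled as being in an "up" or "down" expression state, a
signed interaction occurs when all its promoters are up and all its
inhibitors are down, and a pathway's activity in a sample is the mean
likelihood of its interactions.  This module is a transparent,
fully-specified surrogate for that family of methods, not a bit-level
clone of any particular tool:

* per gene, a two-component Gaussian mixture is fitted across samples by
  EM (deterministic quantile initialisation — no random restarts);
* p_up(gene, sample) is the posterior of the higher-mean component;
* interaction likelihood = prod_{promoters} p_up * prod_{inhibitors} (1 - p_up);
* pathway activity = mean over the pathway's interactions, falling back to
  the mean p_up over pathway genes when no interaction structure is known.

All scores live in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, Interaction, PathwayDatabase
from .errors import ValidationError

logger = logging.getLogger(__name__)

MIN_SAMPLES_FOR_MIXTURE = 8
_VAR_FLOOR_FRACTION = 1e-4
_EM_TOL = 1e-8
_EM_MAX_ITER = 500


@dataclass
class GeneStateProbabilities:
    """Posterior up-state probabilities per (gene, sample), plus fit metadata.

    ``p_up`` is a genes x samples DataFrame in [0, 1]; p_down = 1 - p_up by
    definition.  ``params`` holds per-gene mixture parameters (mu_down,
    mu_up, var_down, var_up, weight_up), and flags mark degenerate
    (constant) genes and non-converged EM fits.
    """

    p_up: pd.DataFrame
    params: pd.DataFrame
    degenerate: pd.Series
    converged: pd.Series
    method: str = "gmm2"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.p_up.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.p_up.columns)


@dataclass
class ActivityMatrix:
    """Pathways x samples activity scores in [0, 1] (NaN rows = unmeasurable)."""

    values: pd.DataFrame
    low_coverage: pd.Series = None
    unmeasured: pd.Series = None


def _em_two_component(V: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised EM for independent per-row 1-D two-component mixtures.

    V is genes x samples.  Returns (p_up, params (G x 5), converged (G,)).
    Initialisation: component means at the per-gene 25th/75th percentiles,
    both variances at the gene variance (shared start), weights 0.5.
    Variances are floored at 1e-4 of the gene variance.
    """
    G, S = V.shape
    mu1 = np.percentile(V, 25, axis=1)  # lower component
    mu2 = np.percentile(V, 75, axis=1)
    var = V.var(axis=1)
    floor = np.maximum(_VAR_FLOOR_FRACTION * var, 1e-300)
    var1 = var.copy()
    var2 = var.copy()
    w2 = np.full(G, 0.5)

    prev_ll = np.full(G, -np.inf)
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    for _ in range(_EM_MAX_ITER):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        v = V[idx]
        m1, m2 = mu1[idx, None], mu2[idx, None]
        s1, s2 = var1[idx, None], var2[idx, None]
        wu = w2[idx, None]
        log1 = -0.5 * (np.log(2 * np.pi * s1) + (v - m1) ** 2 / s1) + np.log1p(-wu)
        log2 = -0.5 * (np.log(2 * np.pi * s2) + (v - m2) ** 2 / s2) + np.log(wu)
        mx = np.maximum(log1, log2)
        norm = mx + np.log(np.exp(log1 - mx) + np.exp(log2 - mx))
        r2 = np.exp(log2 - norm)  # responsibility of the upper component
        ll = norm.mean(axis=1)

        n2 = r2.sum(axis=1)
        n1 = S - n2
        eps = 1e-12
        new_mu1 = (v * (1 - r2)).sum(axis=1) / np.maximum(n1, eps)
        new_mu2 = (v * r2).sum(axis=1) / np.maximum(n2, eps)
        new_var1 = ((1 - r2) * (v - new_mu1[:, None]) ** 2).sum(axis=1) / np.maximum(n1, eps)
        new_var2 = (r2 * (v - new_mu2[:, None]) ** 2).sum(axis=1) / np.maximum(n2, eps)
        fl = floor[idx]
        mu1[idx], mu2[idx] = new_mu1, new_mu2
        var1[idx] = np.maximum(new_var1, fl)
        var2[idx] = np.maximum(new_var2, fl)
        w2[idx] = np.clip(n2 / S, 1e-6, 1 - 1e-6)

        done = np.abs(ll - prev_ll[idx]) < _EM_TOL
        converged[idx[done]] = True
        prev_ll[idx] = ll
        active[idx[done]] = False

    # Posterior of the higher-mean component, for all genes at once.
    swap = mu1 > mu2
    mu1[swap], mu2[swap] = mu2[swap], mu1[swap].copy()
    var1[swap], var2[swap] = var2[swap], var1[swap].copy()
    w2[swap] = 1 - w2[swap]
    log1 = -0.5 * (np.log(2 * np.pi * var1[:, None]) + (V - mu1[:, None]) ** 2 / var1[:, None]) \
        + np.log1p(-w2[:, None])
    log2 = -0.5 * (np.log(2 * np.pi * var2[:, None]) + (V - mu2[:, None]) ** 2 / var2[:, None]) \
        + np.log(w2[:, None])
    mx = np.maximum(log1, log2)
    p_up = np.exp(log2 - mx) / (np.exp(log1 - mx) + np.exp(log2 - mx))
    params = np.column_stack([mu1, mu2, var1, var2, w2])
    return p_up, params, converged


def fit_gene_states(expr: ExpressionMatrix) -> GeneStateProbabilities:
    """Fit per-gene two-state models across samples and return p_up posteriors.

    Genes with zero variance get p_up = 0.5 everywhere and a degenerate
    flag.  With fewer than 8 samples a mixture is not identifiable in
    practice, so the fit falls back to a rank score: p_up = (rank - 0.5)/S.
    """
    V = expr.values.to_numpy(dtype=float)
    G, S = V.shape
    if S == 0 or G == 0:
        raise ValidationError("expression matrix is empty")
    gene_var = V.var(axis=1)
    degenerate = gene_var == 0.0

    cols = ["mu_down", "mu_up", "var_down", "var_up", "weight_up"]
    params = np.full((G, 5), np.nan)
    converged = np.zeros(G, dtype=bool)
    p_up = np.full((G, S), 0.5)

    if S < MIN_SAMPLES_FOR_MIXTURE:
        logger.warning(
            "only %d samples: using rank-based up-state scores instead of a mixture fit", S
        )
        ranks = V.argsort(axis=1, kind="stable").argsort(axis=1, kind="stable")
        ok = ~degenerate
        p_up[ok] = (ranks[ok] + 0.5) / S
        method = "rank"
    else:
        ok = np.flatnonzero(~degenerate)
        if ok.size:
            fitted, par, conv = _em_two_component(V[ok])
            p_up[ok] = fitted
            params[ok] = par
            converged[ok] = conv
        method = "gmm2"

    if degenerate.any():
        logger.info("%d constant genes flagged; their p_up is fixed at 0.5", int(degenerate.sum()))
    index = expr.values.index
    return GeneStateProbabilities(
        p_up=pd.DataFrame(p_up, index=index, columns=expr.values.columns),
        params=pd.DataFrame(params, index=index, columns=cols),
        degenerate=pd.Series(degenerate, index=index),
        converged=pd.Series(converged, index=index),
        method=method,
    )


def interaction_activity(
    inter: Interaction, states: GeneStateProbabilities, sample: str
) -> float:
    """Likelihood that one signed interaction occurs in one sample."""
    col = states.p_up[sample]
    missing = (inter.promoters | inter.inhibitors) - set(states.p_up.index)
    if missing:
        raise ValidationError(
            f"interaction {inter.interaction_id!r} references genes absent "
            f"from the expression data: {sorted(missing)}"
        )
    value = 1.0
    for g in inter.promoters:
        value *= float(col[g])
    for g in inter.inhibitors:
        value *= 1.0 - float(col[g])
    return value


def pathway_activity(db: PathwayDatabase, states: GeneStateProbabilities) -> ActivityMatrix:
    """Score every pathway in every sample.

    Interactions whose promoter/inhibitor genes are not all measured are
    skipped with a warning; a pathway with more than half of its
    interactions skipped is flagged low-coverage.  Pathways without any
    usable interaction fall back to the mean p_up over their measured
    genes; pathways with no measured genes at all give a NaN row and are
    flagged unmeasured.
    """
    P = states.p_up
    measured = set(P.index)
    n_samples = P.shape[1]
    rows = np.full((len(db), n_samples), np.nan)
    low_coverage = np.zeros(len(db), dtype=bool)
    unmeasured = np.zeros(len(db), dtype=bool)

    arr = P.to_numpy()
    gene_row = {g: i for i, g in enumerate(P.index)}

    for pi, pathway in enumerate(db):
        usable: list[np.ndarray] = []
        skipped = 0
        for inter in pathway.interactions:
            needed = inter.promoters | inter.inhibitors
            if not needed <= measured:
                skipped += 1
                continue
            value = np.ones(n_samples)
            for g in inter.promoters:
                value = value * arr[gene_row[g]]
            for g in inter.inhibitors:
                value = value * (1.0 - arr[gene_row[g]])
            usable.append(value)
        if skipped:
            logger.warning(
                "pathway %s: %d/%d interactions skipped (unmeasured genes)",
                pathway.pathway_id, skipped, len(pathway.interactions),
            )
            if skipped > len(pathway.interactions) / 2:
                low_coverage[pi] = True
        if usable:
            rows[pi] = np.mean(usable, axis=0)
            continue
        gene_rows = [gene_row[g] for g in pathway.genes if g in gene_row]
        if gene_rows:
            rows[pi] = arr[gene_rows].mean(axis=0)
        else:
            unmeasured[pi] = True
            logger.warning("pathway %s has no measurable genes", pathway.pathway_id)

    ids = [p.pathway_id for p in db]
    return ActivityMatrix(
        values=pd.DataFrame(rows, index=ids, columns=P.columns),
        low_coverage=pd.Series(low_coverage, index=ids),
        unmeasured=pd.Series(unmeasured, index=ids),
    )


def write_activity(act: ActivityMatrix, path) -> None:
    out = act.values.copy()
    out.index.name = "pathway_id"
    out.to_csv(path, sep="\t", float_format="%.6g")
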