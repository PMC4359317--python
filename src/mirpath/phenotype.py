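"""Clinical linkage: stratification tests, survival splits, and the
group-wise differential-correlation signature.

The central claim type here is the "broken control" pattern: a miRNA whose
expression is negatively correlated with a pathway's activity in one
clinical group (intact repression) but uncorrelated in the other (lost
regulatory link).  Correlations are computed per group (Pearson by
default, Spearman optional) and contrasted with Fisher's z test,

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)),

which makes "present in one group, absent in the other" an assertable
statistical statement rather than a visual impression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats

from .data_io import ExpressionMatrix, PhenotypeTable
from .enrichment import storey_qvalues
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StratificationResult:
    pathway_id: str
    phenotype: str
    test: str  # "t_test" | "logrank"
    statistic: float
    p_value: float
    group_summary: dict = field(hash=False, default_factory=dict)


@dataclass(frozen=True)
class GroupCorrelationResult:
    pathway_id: str
    mirna_id: str
    r_by_group: dict = field(hash=False, default_factory=dict)
    n_by_group: dict = field(hash=False, default_factory=dict)
    z: float = float("nan")
    p_value: float = float("nan")
    flags: tuple[str, ...] = ()


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero-variance groups with different means")
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def activity_group_test(
    activity_row: pd.Series,
    phenotypes: PhenotypeTable,
    group_a: str,
    group_b: str,
    phenotype_name: str = "group",
) -> StratificationResult:
    """Welch two-sample t-test of one pathway's activity between two groups."""
    a_samples = phenotypes.samples_in(group_a)
    b_samples = phenotypes.samples_in(group_b)
    a = activity_row.reindex(a_samples).dropna().to_numpy(dtype=float)
    b = activity_row.reindex(b_samples).dropna().to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 samples with activity values")
    t, p = _welch(a, b)
    return StratificationResult(
        pathway_id=str(activity_row.name),
        phenotype=phenotype_name,
        test="t_test",
        statistic=t,
        p_value=p,
        group_summary={
            group_a: {"n": int(a.size), "mean": float(a.mean())},
            group_b: {"n": int(b.size), "mean": float(b.mean())},
        },
    )


def survival_split_test(
    activity_row: pd.Series, phenotypes: PhenotypeTable, phenotype_name: str = "survival"
) -> StratificationResult:
    """Median-activity split followed by a Kaplan-Meier log-rank test."""
    if not phenotypes.has_survival:
        raise ValidationError("phenotype table carries no survival columns")
    tab = phenotypes.table[["time", "event"]].copy()
    tab["activity"] = activity_row.reindex(tab.index)
    tab = tab.dropna()
    if len(tab) < 10:
        raise ValidationError(f"need >= 10 samples with survival data, got {len(tab)}")
    if not tab["event"].astype(bool).any():
        raise ValidationError("all samples censored; log-rank test undefined")
    median = tab["activity"].median()
    high = tab["activity"] > median
    if high.sum() == 0 or (~high).sum() == 0:
        raise ValidationError("median split produced an empty half (constant activity?)")
    res = logrank_test(
        tab.loc[high, "time"], tab.loc[~high, "time"],
        event_observed_A=tab.loc[high, "event"].astype(bool),
        event_observed_B=tab.loc[~high, "event"].astype(bool),
    )
    return StratificationResult(
        pathway_id=str(activity_row.name),
        phenotype=phenotype_name,
        test="logrank",
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        group_summary={
            "high": {"n": int(high.sum()), "events": int(tab.loc[high, "event"].sum())},
            "low": {"n": int((~high).sum()), "events": int(tab.loc[~high, "event"].sum())},
            "split_at": float(median),
        },
    )


def _group_r(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValidationError(f"unknown correlation method {method!r}")


def fisher_z_contrast(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher z test for the difference between two independent correlations."""
    if min(n1, n2) < 4:
        raise ValidationError("Fisher z contrast needs >= 4 samples per group")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def group_correlation(
    mirna_row: pd.Series,
    activity_row: pd.Series,
    phenotypes: PhenotypeTable,
    groups: tuple[str, str],
    method: str = "pearson",
    mirna_id: str | None = None,
    pathway_id: str | None = None,
) -> GroupCorrelationResult:
    """Per-group miRNA-pathway correlation plus the Fisher z contrast."""
    r_by, n_by = {}, {}
    flags: list[str] = []
    for g in groups:
        samples = phenotypes.samples_in(g)
        pairs = pd.concat(
            [mirna_row.reindex(samples), activity_row.reindex(samples)], axis=1
        ).dropna()
        if len(pairs) < 4:
            raise ValidationError(f"group {g!r} has fewer than 4 usable samples")
        x, y = pairs.iloc[:, 0].to_numpy(float), pairs.iloc[:, 1].to_numpy(float)
        r = _group_r(x, y, method)
        if np.isnan(r):
            flags.append(f"zero_variance:{g}")
        r_by[g], n_by[g] = r, len(pairs)
    if any(np.isnan(r) for r in r_by.values()):
        z, p = float("nan"), float("nan")
    else:
        z, p = fisher_z_contrast(
            r_by[groups[0]], n_by[groups[0]], r_by[groups[1]], n_by[groups[1]]
        )
    return GroupCorrelationResult(
        pathway_id=pathway_id if pathway_id is not None else str(activity_row.name),
        mirna_id=mirna_id if mirna_id is not None else str(mirna_row.name),
        r_by_group=r_by,
        n_by_group=n_by,
        z=z,
        p_value=p,
        flags=tuple(flags),
    )


def gene_level_correlation(
    mirna_row: pd.Series,
    expr: ExpressionMatrix,
    target_genes,
    phenotypes: PhenotypeTable,
    groups: tuple[str, str],
    method: str = "pearson",
) -> list[GroupCorrelationResult]:
    """The per-target-gene analogue of :func:`group_correlation`.

    Genes absent from the expression matrix are skipped with a warning.
    """
    results = []
    for gene in target_genes:
        if gene not in expr.values.index:
            logger.warning("target gene %s absent from expression data; skipped", gene)
            continue
        results.append(
            group_correlation(
                mirna_row, expr.values.loc[gene], phenotypes, groups,
                method=method, pathway_id=f"gene:{gene}",
            )
        )
    return results


def scan_stratification(
    activity_values: pd.DataFrame,
    phenotypes: PhenotypeTable,
    group_a: str,
    group_b: str,
    phenotype_name: str = "group",
) -> pd.DataFrame:
    """t-test every pathway for group stratification; attach Storey q-values."""
    rows = []
    for pathway_id in activity_values.index:
        row = activity_values.loc[pathway_id]
        if row.isna().all():
            continue
        res = activity_group_test(row, phenotypes, group_a, group_b, phenotype_name)
        rows.append((res.pathway_id, res.phenotype, res.test, res.statistic, res.p_value))
    frame = pd.DataFrame(
        rows, columns=["pathway_id", "phenotype", "test", "statistic", "p_value"]
    )
    if len(frame):
        frame["q_value"] = storey_qvalues(frame["p_value"].to_numpy())
        frame = frame.sort_values(
            ["p_value", "pathway_id"], kind="stable"
        ).reset_index(drop=True)
    return frame


def correlations_to_frame(results: list[GroupCorrelationResult], groups) -> pd.DataFrame:
    g1, g2 = groups
    return pd.DataFrame(
        [
            (
                r.pathway_id, r.mirna_id,
                r.r_by_group.get(g1), r.n_by_group.get(g1),
                r.r_by_group.get(g2), r.n_by_group.get(g2),
                r.z, r.p_value, ";".join(r.flags),
            )
            for r in results
        ],
        columns=[
            "pathway_id", "mirna_id",
            f"r_{g1}", f"n_{g1}", f"r_{g2}", f"n_{g2}", "z", "p_value", "flags",
        ],
    )
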