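"""Seeded synthetic input bundles with planted, fully known ground truth.

The generator emulates the statistical structure of a multi-cohort tumour
study — multi-tool miRNA target predictions, a pathway collection of gene
sets with signed interactions, paired mRNA/miRNA expression over two
clinical groups, and survival follow-up — without any claim to biological
realism (no count noise, batch effects or real pathway topology).

Planted structure, all recoverable from ``GroundTruth``:

* every pathway receives one planted miRNA targeting a configurable
  fraction of its genes with multi-tool support, on top of a sparse
  background of random predictions calibrated so that roughly half of the
  background pairs survive the >= 2-tool filter;
* one *focal* pathway is singled out to carry the clinical signal: its
  planted miRNA targets all of its genes, group A samples have the
  pathway's genes shifted up by ``delta`` noise-SDs, and within group A
  the focal miRNA's expression is correlated (default rho = -0.6, a
  Gaussian copula-style joint draw) with its target genes' expression —
  the "intact repression in one group only" pattern;
* survival times are exponential with a group-dependent hazard.

Same seed, same bundle, byte for byte.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io
from .data_io import (
    ExpressionMatrix,
    Interaction,
    Pathway,
    PathwayDatabase,
    PhenotypeTable,
    TargetPredictionTable,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic bundle.

    ``delta`` is the group-A up-shift of focal-pathway genes in units of
    the expression noise SD; ``rho`` the planted within-group-A
    miRNA-target correlation; ``activated_fraction`` the share of focal
    targets that get +|rho| instead of -|rho| (sign-mixed regulation).
    """

    n_pathways: int = 100
    size_min: int = 4
    size_max: int = 50
    n_genes: int = 1500
    n_mirnas: int = 300
    n_tools: int = 8
    background_pair_prob: float = 0.01
    planted_fraction: float = 0.5
    plant_associations: bool = True
    focal_fraction: float = 1.0
    n_samples_per_group: int = 100
    group_labels: tuple[str, str] = ("A", "B")
    noise_sd: float = 1.0
    component_separation: float = 3.0
    delta: float = 2.0
    rho: float = -0.6
    activated_fraction: float = 0.0
    hazard_ratio: float = 3.0
    baseline_hazard: float = 1.0 / 1500.0
    censor_time: float = 3000.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.planted_fraction <= 1 and 0 < self.focal_fraction <= 1):
            raise ValidationError("planted fractions must lie in (0, 1]")
        if not (-1 < self.rho < 1):
            raise ValidationError("rho must lie in (-1, 1)")
        for name in ("n_pathways", "n_genes", "n_mirnas", "n_tools", "n_samples_per_group"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.planted_fraction * self.size_min < 1:
            raise ValidationError("planted fraction times minimum pathway size is below 1")

    @classmethod
    def null_scenario(cls, seed: int = 0, **kwargs) -> "ScenarioConfig":
        """A bundle with no planted signal of any kind (calibration runs)."""
        return cls(
            plant_associations=False, delta=0.0, rho=0.0, hazard_ratio=1.0,
            seed=seed, **kwargs,
        )


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream assertions."""

    planted_pairs: list  # (pathway_id, mirna_id, fraction)
    focal_pathway: str | None
    focal_mirna: str | None
    rho: float
    delta: float
    hazard_ratio: float
    repressed_targets: list
    activated_targets: list


@dataclass
class ScenarioBundle:
    pathways: PathwayDatabase
    predictions: TargetPredictionTable
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    phenotypes: PhenotypeTable
    ground_truth: GroundTruth
    config: ScenarioConfig


def _make_pathways(cfg: ScenarioConfig, genes: list[str], rng) -> PathwayDatabase:
    pathways = []
    for i in range(cfg.n_pathways):
        size = int(rng.integers(cfg.size_min, cfg.size_max + 1))
        members = sorted(rng.choice(genes, size=size, replace=False).tolist())
        inters = []
        for j in range(math.ceil(size / 3)):
            n_prom = int(rng.integers(1, min(3, size) + 1))
            n_inh = int(rng.integers(0, 2)) if size - n_prom >= 2 else 0
            picked = rng.choice(members, size=n_prom + n_inh + 1, replace=False).tolist()
            inters.append(
                Interaction(
                    interaction_id=f"i{j:02d}",
                    promoters=frozenset(picked[:n_prom]),
                    inhibitors=frozenset(picked[n_prom:n_prom + n_inh]),
                    outputs=frozenset(picked[n_prom + n_inh:]),
                )
            )
        pathways.append(
            Pathway(
                pathway_id=f"PW{i:03d}",
                genes=frozenset(members),
                source="synthetic",
                interactions=tuple(inters),
            )
        )
    return PathwayDatabase(pathways=tuple(pathways))


def _make_predictions(
    cfg: ScenarioConfig, genes: list[str], mirnas: list[str],
    db: PathwayDatabase, rng,
) -> tuple[TargetPredictionTable, GroundTruth]:
    tools = [f"T{t+1}" for t in range(cfg.n_tools)]
    # Per-tool hit probability beyond the first tool, calibrated so about
    # half of the background pairs carry support from >= 2 tools.
    theta = 1.0 - 0.5 ** (1.0 / max(cfg.n_tools - 1, 1))

    support: dict[tuple[str, str], int] = {}
    background = rng.random((cfg.n_mirnas, cfg.n_genes)) < cfg.background_pair_prob
    extra = rng.binomial(cfg.n_tools - 1, theta, size=background.shape)
    for mi, gi in zip(*np.nonzero(background)):
        support[(mirnas[mi], genes[gi])] = 1 + int(extra[mi, gi])

    planted_pairs: list[tuple[str, str, float]] = []
    focal_pathway = focal_mirna = None
    repressed: list[str] = []
    activated: list[str] = []
    if cfg.plant_associations:
        for i, pathway in enumerate(db):
            mirna = mirnas[i % cfg.n_mirnas]
            fraction = cfg.focal_fraction if i == 0 else cfg.planted_fraction
            members = sorted(pathway.genes)
            n_hit = max(1, math.ceil(fraction * len(members)))
            hit = sorted(rng.choice(members, size=n_hit, replace=False).tolist())
            for g in hit:
                n_tools_pair = int(rng.integers(2, cfg.n_tools + 1))
                support[(mirna, g)] = max(support.get((mirna, g), 0), n_tools_pair)
            planted_pairs.append((pathway.pathway_id, mirna, fraction))
            if i == 0:
                focal_pathway, focal_mirna = pathway.pathway_id, mirna
                n_act = int(round(cfg.activated_fraction * len(hit)))
                activated = hit[:n_act]
                repressed = hit[n_act:]

    records = []
    for (mirna, gene), count in sorted(support.items()):
        picked = rng.choice(tools, size=min(count, cfg.n_tools), replace=False)
        for tool in sorted(picked.tolist()):
            records.append((mirna, gene, tool))
    table = TargetPredictionTable.from_records(records)
    truth = GroundTruth(
        planted_pairs=planted_pairs,
        focal_pathway=focal_pathway,
        focal_mirna=focal_mirna,
        rho=cfg.rho,
        delta=cfg.delta,
        hazard_ratio=cfg.hazard_ratio,
        repressed_targets=repressed,
        activated_targets=activated,
    )
    return table, truth


def _make_expression(
    cfg: ScenarioConfig, genes: list[str], mirnas: list[str],
    db: PathwayDatabase, truth: GroundTruth, samples: list[str],
    group_of: np.ndarray, rng,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    G, S = cfg.n_genes, len(samples)
    sd = cfg.noise_sd
    in_a = group_of == 0

    baseline = rng.normal(7.0, 1.0, size=G)
    states = rng.random((G, S)) < 0.5
    V = baseline[:, None] + cfg.component_separation * states + rng.normal(0.0, sd, (G, S))

    mirna_baseline = rng.normal(5.0, 1.0, size=cfg.n_mirnas)
    W = mirna_baseline[:, None] + rng.normal(0.0, 1.0, (cfg.n_mirnas, S))

    if truth.focal_pathway is not None:
        gene_idx = {g: i for i, g in enumerate(genes)}
        mir_idx = {m: i for i, m in enumerate(mirnas)}
        focal_genes = sorted(db[truth.focal_pathway].genes)
        driver = rng.normal(0.0, 1.0, size=int(in_a.sum()))  # standardised miRNA signal
        W[mir_idx[truth.focal_mirna], in_a] = mirna_baseline[mir_idx[truth.focal_mirna]] + driver
        rho_of = {g: -abs(cfg.rho) for g in truth.repressed_targets}
        rho_of.update({g: abs(cfg.rho) for g in truth.activated_targets})
        for g in focal_genes:
            gi = gene_idx[g]
            r = rho_of.get(g, 0.0)
            resid_a = r * driver + math.sqrt(1.0 - r * r) * rng.normal(0.0, 1.0, driver.size)
            V[gi, in_a] = baseline[gi] + cfg.delta * sd + sd * resid_a
            V[gi, ~in_a] = baseline[gi] + sd * rng.normal(0.0, 1.0, int((~in_a).sum()))

    mrna = ExpressionMatrix(
        values=pd.DataFrame(V, index=genes, columns=samples), scale="log2-like"
    )
    mir = ExpressionMatrix(
        values=pd.DataFrame(W, index=mirnas, columns=samples), scale="log2-like"
    )
    return mrna, mir


def _make_phenotypes(
    cfg: ScenarioConfig, samples: list[str], group_of: np.ndarray, rng
) -> PhenotypeTable:
    rates = np.where(group_of == 0, cfg.baseline_hazard * cfg.hazard_ratio, cfg.baseline_hazard)
    raw = rng.exponential(1.0 / rates)
    event = raw <= cfg.censor_time
    time = np.minimum(raw, cfg.censor_time)
    table = pd.DataFrame(
        {
            "group": [cfg.group_labels[g] for g in group_of],
            "time": np.round(time, 6),
            "event": event,
        },
        index=pd.Index(samples, name="sample"),
    )
    return PhenotypeTable(table=table)


def generate(config: ScenarioConfig | None = None) -> ScenarioBundle:
    """Generate a complete input bundle from one master seed."""
    cfg = config if config is not None else ScenarioConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_pw, rng_pred, rng_expr, rng_surv = (np.random.default_rng(s) for s in streams)

    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    mirnas = [f"miR-{i:04d}" for i in range(cfg.n_mirnas)]
    n = cfg.n_samples_per_group
    samples = [f"S{i:03d}" for i in range(2 * n)]
    group_of = np.array([0] * n + [1] * n)

    db = _make_pathways(cfg, genes, rng_pw)
    predictions, truth = _make_predictions(cfg, genes, mirnas, db, rng_pred)
    mrna, mir = _make_expression(cfg, genes, mirnas, db, truth, samples, group_of, rng_expr)
    phen = _make_phenotypes(cfg, samples, group_of, rng_surv)
    logger.info(
        "generated bundle: %d pathways, %d prediction triples, %d+%d samples (seed=%d)",
        len(db), len(predictions), n, n, cfg.seed,
    )
    return ScenarioBundle(
        pathways=db, predictions=predictions, mrna=mrna, mirna=mir,
        phenotypes=phen, ground_truth=truth, config=cfg,
    )


BUNDLE_FILES = (
    "pathways.gmt",
    "interactions.tsv",
    "predictions.tsv",
    "mrna_expression.tsv",
    "mirna_expression.tsv",
    "phenotypes.tsv",
    "ground_truth.json",
)


def write_bundle(bundle: ScenarioBundle, directory: str | Path) -> list[Path]:
    """Write the bundle as the seven pipeline input files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data_io.write_gmt(bundle.pathways, directory / "pathways.gmt")
    data_io.write_interactions(bundle.pathways, directory / "interactions.tsv")
    data_io.write_predictions(bundle.predictions, directory / "predictions.tsv")
    data_io.write_expression(bundle.mrna, directory / "mrna_expression.tsv", "gene")
    data_io.write_expression(bundle.mirna, directory / "mirna_expression.tsv", "mirna")
    data_io.write_phenotypes(bundle.phenotypes, directory / "phenotypes.tsv")
    truth = asdict(bundle.ground_truth)
    truth["config"] = asdict(bundle.config)
    truth["config"]["group_labels"] = list(bundle.config.group_labels)
    with open(directory / "ground_truth.json", "w", encoding="utf-8") as handle:
        json.dump(truth, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return [directory / name for name in BUNDLE_FILES]


def read_bundle(directory: str | Path) -> ScenarioBundle:
    """Re-read a written bundle through the standard readers."""
    directory = Path(directory)
    db = data_io.read_gmt(directory / "pathways.gmt")
    db = data_io.read_interactions(directory / "interactions.tsv", db)
    predictions = data_io.read_predictions(directory / "predictions.tsv")
    mrna = data_io.read_expression(directory / "mrna_expression.tsv", scale="log2-like")
    mir = data_io.read_expression(directory / "mirna_expression.tsv", scale="log2-like")
    phen = data_io.read_phenotypes(directory / "phenotypes.tsv")
    with open(directory / "ground_truth.json", encoding="utf-8") as handle:
        raw = json.load(handle)
    cfg_raw = raw.pop("config")
    cfg_raw["group_labels"] = tuple(cfg_raw["group_labels"])
    truth = GroundTruth(**{k: raw[k] for k in raw})
    truth.planted_pairs = [tuple(p) for p in truth.planted_pairs]
    return ScenarioBundle(
        pathways=db, predictions=predictions, mrna=mrna, mirna=mir,
        phenotypes=phen, ground_truth=truth, config=ScenarioConfig(**cfg_raw),
    )
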