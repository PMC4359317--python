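"""Readers and writers for the tabular formats the pipeline touches.

All tabular formats are TAB-separated UTF-8 with a header row, except GMT
which follows the standard headerless convention (name, description, then
one gene per field).  Gene and miRNA identifiers are opaque, case-sensitive,
whitespace-free tokens; no symbol/alias mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

_ROLES = ("promoter", "inhibitor", "output")


def _check_token(value: str, what: str) -> str:
    s = str(value)
    if not s or s != s.strip() or any(c.isspace() for c in s):
        raise ValidationError(f"{what} must be a non-empty whitespace-free token, got {value!r}")
    return s


# ---------------------------------------------------------------------------
# Target predictions


@dataclass(frozen=True)
class TargetPredictionTable:
    """(miRNA, gene, tool) triples — the evidence base for enrichment.

    Duplicate triples are collapsed on construction; duplicate
    (miRNA, gene) pairs from *different* tools are retained, as they are
    the multi-tool evidence the downstream filter counts.
    """

    records: tuple[tuple[str, str, str], ...]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "TargetPredictionTable":
        seen: dict[tuple[str, str, str], None] = {}
        n_raw = 0
        for mirna, gene, tool in records:
            n_raw += 1
            triple = (
                _check_token(mirna, "mirna_id"),
                _check_token(gene, "gene_id"),
                _check_token(tool, "tool"),
            )
            seen.setdefault(triple, None)
        if n_raw > len(seen):
            logger.info("collapsed %d duplicate prediction triples", n_raw - len(seen))
        return cls(records=tuple(seen))

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["mirna", "gene", "tool"])


def read_predictions(path: str | Path) -> TargetPredictionTable:
    """Read a predictions TSV with header columns mirna, gene, tool."""
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty predictions file") from exc
    for col in ("mirna", "gene", "tool"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if frame.empty:
        raise FormatError(f"{path}: predictions file has no rows")
    logger.info("read %d prediction rows from %s", len(frame), path)
    return TargetPredictionTable.from_records(
        frame[["mirna", "gene", "tool"]].itertuples(index=False, name=None)
    )


def write_predictions(table: TargetPredictionTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pathways


@dataclass(frozen=True)
class Interaction:
    """One signed interaction: promoters drive it, inhibitors block it."""

    interaction_id: str
    promoters: frozenset[str]
    inhibitors: frozenset[str]
    outputs: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.promoters and not self.inhibitors:
            raise ValidationError(
                f"interaction {self.interaction_id!r} needs >=1 promoter or inhibitor"
            )


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    genes: frozenset[str]
    source: str = ""
    interactions: tuple[Interaction, ...] = ()

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"pathway {self.pathway_id!r} has an empty gene set")
        for inter in self.interactions:
            extra = (inter.promoters | inter.inhibitors | inter.outputs) - self.genes
            if extra:
                raise ValidationError(
                    f"interaction {inter.interaction_id!r} of pathway "
                    f"{self.pathway_id!r} references genes outside the pathway: {sorted(extra)}"
                )

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class PathwayDatabase:
    """Named gene sets with optional signed interactions."""

    pathways: tuple[Pathway, ...]

    def __post_init__(self):
        ids = [p.pathway_id for p in self.pathways]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate pathway ids: {dup}")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    @property
    def gene_universe(self) -> frozenset[str]:
        """Distinct genes across all pathways (the universe M counts these)."""
        out: set[str] = set()
        for p in self.pathways:
            out |= p.genes
        return frozenset(out)


def read_gmt(path: str | Path) -> PathwayDatabase:
    """Read a standard GMT file: name TAB description TAB gene ..."""
    pathways: list[Pathway] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc, *genes = fields
            name = _check_token(name, "pathway_id")
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            seen.add(name)
            genes = [_check_token(g, "gene_id") for g in genes if g]
            pathways.append(Pathway(pathway_id=name, genes=frozenset(genes), source=desc))
    if not pathways:
        raise FormatError(f"{path}: GMT file contains no pathways")
    logger.info("read %d pathways from %s", len(pathways), path)
    return PathwayDatabase(pathways=tuple(pathways))


def write_gmt(db: PathwayDatabase, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for p in db:
            handle.write("\t".join([p.pathway_id, p.source or "na", *sorted(p.genes)]) + "\n")


def read_interactions(path: str | Path, db: PathwayDatabase) -> PathwayDatabase:
    """Attach signed interactions to an existing database.

    The TSV has columns pathway_id, interaction_id, gene, role with
    role in {promoter, inhibitor, output}.  Every interaction gene must be
    a member of its pathway's gene set.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("pathway_id", "interaction_id", "gene", "role"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    bad_roles = set(frame["role"]) - set(_ROLES)
    if bad_roles:
        raise FormatError(f"{path}: unknown role token(s) {sorted(bad_roles)}")
    known = {p.pathway_id for p in db}
    bad_pw = set(frame["pathway_id"]) - known
    if bad_pw:
        raise FormatError(f"{path}: unknown pathway_id(s) {sorted(bad_pw)}")

    grouped: dict[str, list[Interaction]] = {}
    for (pw_id, int_id), sub in frame.groupby(["pathway_id", "interaction_id"], sort=True):
        roles: dict[str, set[str]] = {r: set() for r in _ROLES}
        for _, row in sub.iterrows():
            roles[row["role"]].add(row["gene"])
        grouped.setdefault(pw_id, []).append(
            Interaction(
                interaction_id=int_id,
                promoters=frozenset(roles["promoter"]),
                inhibitors=frozenset(roles["inhibitor"]),
                outputs=frozenset(roles["output"]),
            )
        )
    new_pathways = []
    for p in db:
        inters = tuple(sorted(grouped.get(p.pathway_id, []), key=lambda i: i.interaction_id))
        new_pathways.append(
            Pathway(pathway_id=p.pathway_id, genes=p.genes, source=p.source, interactions=inters)
        )
    return PathwayDatabase(pathways=tuple(new_pathways))


def write_interactions(db: PathwayDatabase, path: str | Path) -> None:
    rows = []
    for p in db:
        for inter in p.interactions:
            for role, genes in (
                ("promoter", inter.promoters),
                ("inhibitor", inter.inhibitors),
                ("output", inter.outputs),
            ):
                for g in sorted(genes):
                    rows.append((p.pathway_id, inter.interaction_id, g, role))
    pd.DataFrame(rows, columns=["pathway_id", "interaction_id", "gene", "role"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Expression matrices


@dataclass
class ExpressionMatrix:
    """Features (genes or miRNAs) x samples real-valued matrix.

    Backed by a pandas DataFrame with feature ids on the index and sample
    ids as columns; `scale` is a free-text tag describing the value scale
    (e.g. "RMA-level", "log2").
    """

    values: pd.DataFrame
    scale: str = ""

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature ids: {dup}")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite numbers")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_expression(path: str | Path, scale: str = "") -> ExpressionMatrix:
    """Read an expression TSV: first column feature id, remaining columns samples."""
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if frame.empty:
        raise FormatError(f"{path}: expression matrix has no data")
    non_numeric = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
    if non_numeric or frame.isna().any().any():
        raise FormatError(f"{path}: non-numeric or missing expression cells")
    frame.index = frame.index.astype(str)
    frame.index.name = None  # header label is presentation, not data
    frame.columns = frame.columns.astype(str)
    try:
        return ExpressionMatrix(values=frame, scale=scale)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression(expr: ExpressionMatrix, path: str | Path, feature_label: str = "feature") -> None:
    out = expr.values.copy()
    out.index.name = feature_label
    # default float repr is the shortest exact one -> lossless round trips
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Phenotypes


@dataclass
class PhenotypeTable:
    """Per-sample group labels and optional survival follow-up.

    `table` is indexed by sample id with columns: group (categorical label),
    and optionally time (non-negative days) and event (boolean).
    """

    table: pd.DataFrame

    def __post_init__(self):
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate sample ids in phenotype table")
        if "group" not in self.table.columns:
            raise ValidationError("phenotype table needs a 'group' column")
        if "time" in self.table.columns:
            if "event" not in self.table.columns:
                raise ValidationError("survival time present but event column missing")
            t = self.table["time"].to_numpy(dtype=float)
            if (t < 0).any():
                raise ValidationError("negative survival_time")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    def samples_in(self, group: str) -> list[str]:
        if group not in set(self.table["group"]):
            raise ValidationError(f"group label {group!r} absent from phenotype table")
        return list(self.table.index[self.table["group"] == group])

    @property
    def has_survival(self) -> bool:
        return "time" in self.table.columns


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    frame = pd.read_csv(
        path, sep="\t", dtype={"sample": str, "group": str}, float_precision="round_trip"
    )
    for col in ("sample", "group"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    frame = frame.set_index("sample")
    if "event" in frame.columns:
        frame["event"] = frame["event"].astype(bool)
    try:
        return PhenotypeTable(table=frame)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_phenotypes(phen: PhenotypeTable, path: str | Path) -> None:
    out = phen.table.copy()
    if "event" in out.columns:
        out["event"] = out["event"].astype(int)
    out.index.name = "sample"
    out.to_csv(path, sep="\t")
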