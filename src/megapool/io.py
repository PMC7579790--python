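"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is tab-separated text: a study manifest, per-study expression
matrices with an embedded case/control phenotype row, one-symbol-per-line
gene lists, and signed pathway edge lists.  Gene symbols are normalised to
uppercase throughout so that studies from different organisms (human, mouse,
rat) can be pooled per symbol; this is a deliberate, documented simplification
— no orthology mapping is attempted.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "FormatError",
    "DataError",
    "StudyRecord",
    "ExpressionStudy",
    "GeneSet",
    "PathwayEdge",
    "read_manifest",
    "write_manifest",
    "read_expression",
    "write_expression",
    "read_gene_set",
    "write_gene_set",
    "read_pathway_edges",
    "write_pathway_edges",
    "write_table",
]

MANIFEST_COLUMNS = [
    "study_id",
    "accession",
    "n_control",
    "n_case",
    "country",
    "study_age_years",
    "organism",
]

PHENOTYPE_ROW = "!phenotype"
PHENOTYPE_LABELS = ("case", "control")


class SchemaError(ValueError):
    """A file is missing required columns."""


class ValidationError(ValueError):
    """A file parsed but violates a content invariant."""


class FormatError(ValueError):
    """A file's structure is malformed."""


class DataError(ValueError):
    """Numeric content is unusable (non-finite values, impossible scale)."""


@dataclass(frozen=True)
class StudyRecord:
    """Metadata for one case-control expression study."""

    study_id: str
    accession: str
    n_control: int
    n_case: int
    country: str
    study_age_years: int
    organism: str

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_case < 1:
            raise ValidationError(
                f"study {self.study_id!r}: sample counts must be >= 1 "
                f"(n_control={self.n_control}, n_case={self.n_case})"
            )
        if self.study_age_years < 0:
            raise ValidationError(
                f"study {self.study_id!r}: study_age_years must be >= 0"
            )

    @property
    def n_total(self) -> int:
        return self.n_control + self.n_case


@dataclass
class ExpressionStudy:
    """A genes x samples expression matrix with case/control phenotype.

    ``scale`` is one of ``linear``, ``log2`` or ``unknown``; an unknown scale
    is resolved downstream by :func:`megapool.preprocess.ensure_log2`.
    """

    study: StudyRecord
    genes: list[str]
    samples: list[str]
    values: np.ndarray  # genes x samples
    phenotype: list[str]  # "case" / "control" per sample
    scale: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.phenotype) != len(self.samples):
            raise FormatError("phenotype length does not match sample count")
        bad = sorted(set(self.phenotype) - set(PHENOTYPE_LABELS))
        if bad:
            raise FormatError(f"unknown phenotype labels: {bad}")
        if "case" not in self.phenotype or "control" not in self.phenotype:
            raise ValidationError("need at least one case and one control sample")
        if self.scale not in ("linear", "log2", "unknown"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene symbols must be unique after collapse")

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([p == "case" for p in self.phenotype])

    @property
    def n_case(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_control(self) -> int:
        return len(self.samples) - self.n_case

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "ExpressionStudy":
        return ExpressionStudy(
            study=self.study,
            genes=list(self.genes),
            samples=list(self.samples),
            values=np.asarray(values, dtype=float),
            phenotype=list(self.phenotype),
            scale=self.scale if scale is None else scale,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass(frozen=True)
class GeneSet:
    """A named set of uppercase gene symbols."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        object.__setattr__(
            self, "genes", frozenset(normalize_symbol(g) for g in self.genes)
        )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.genes


@dataclass(frozen=True)
class PathwayEdge:
    """A signed regulator->target edge with the target's disease direction.

    ``reg_sign`` is +1 if the regulator promotes the target, -1 if it inhibits
    it; ``target_disease_sign`` is +1 for a disease-promoter target, -1 for a
    disease-inhibitor.
    """

    regulator: str
    target: str
    reg_sign: int
    target_disease_sign: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "regulator", normalize_symbol(self.regulator))
        object.__setattr__(self, "target", normalize_symbol(self.target))
        if self.reg_sign not in (1, -1) or self.target_disease_sign not in (1, -1):
            raise ValidationError(
                f"edge {self.regulator}->{self.target}: signs must be +1/-1"
            )


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol (cross-species pooling convention)."""
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# manifest


def read_manifest(path: str | Path) -> list[StudyRecord]:
    """Read a tab-separated study manifest into validated records, file order."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest {path}: missing columns {missing}")
    records: list[StudyRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        try:
            rec = StudyRecord(
                study_id=str(row["study_id"]),
                accession=str(row["accession"]),
                n_control=int(row["n_control"]),
                n_case=int(row["n_case"]),
                country=str(row["country"]),
                study_age_years=int(row["study_age_years"]),
                organism=str(row["organism"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"manifest {path}, row {i + 1}: {exc}") from exc
        if rec.study_id in seen:
            raise ValidationError(
                f"manifest {path}: duplicate study_id {rec.study_id!r}"
            )
        seen.add(rec.study_id)
        records.append(rec)
    return records


def write_manifest(records: Sequence[StudyRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "study_id": r.study_id,
                "accession": r.accession,
                "n_control": r.n_control,
                "n_case": r.n_case,
                "country": r.country,
                "study_age_years": r.study_age_years,
                "organism": r.organism,
            }
            for r in records
        ],
        columns=MANIFEST_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path: str | Path, study: StudyRecord) -> ExpressionStudy:
    """Read a gene x sample TSV with a ``!phenotype`` row.

    Layout: first column holds gene symbols, the header row holds sample IDs,
    and exactly one row labelled ``!phenotype`` gives each sample's
    case/control status.  Duplicate gene rows (multiple probes mapping to one
    symbol) are collapsed by arithmetic mean.  The scale is left ``unknown``;
    it is resolved by preprocessing.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if PHENOTYPE_ROW not in df.index:
        raise FormatError(f"{path}: missing {PHENOTYPE_ROW!r} row")
    pheno = [str(v).strip().lower() for v in df.loc[PHENOTYPE_ROW]]
    data = df.drop(index=PHENOTYPE_ROW)
    try:
        values = data.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression values: {exc}") from exc
    values.index = [normalize_symbol(g) for g in values.index]
    # probe collapse: mean over duplicate symbols, preserving first-seen order
    if values.index.has_duplicates:
        order = list(dict.fromkeys(values.index))
        values = values.groupby(level=0, sort=False).mean().loc[order]
    return ExpressionStudy(
        study=study,
        genes=list(values.index),
        samples=[str(s) for s in values.columns],
        values=values.to_numpy(),
        phenotype=pheno,
        scale="unknown",
    )


def write_expression(study: ExpressionStudy, path: str | Path) -> None:
    """Write an expression study in the same layout :func:`read_expression` reads."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(study.samples) + "\n")
        fh.write(PHENOTYPE_ROW + "\t" + "\t".join(study.phenotype) + "\n")
        for gene, row in zip(study.genes, study.values):
            fh.write(gene + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# gene lists and edge lists


def read_gene_set(path: str | Path, name: str) -> GeneSet:
    """Read a one-symbol-per-line gene list; blank lines ignored."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.append(line)
    if not symbols:
        raise ValidationError(f"gene list {path} contains no symbols")
    return GeneSet(name=name, genes=frozenset(symbols))


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted({normalize_symbol(g) for g in genes}):
            fh.write(g + "\n")


def read_pathway_edges(path: str | Path) -> list[PathwayEdge]:
    """Read a TSV edge list: regulator, target, reg_sign, target_disease_sign."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["regulator", "target", "reg_sign", "target_disease_sign"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"edge list {path}: missing columns {missing}")
    edges = []
    for i, row in df.iterrows():
        try:
            edges.append(
                PathwayEdge(
                    regulator=row["regulator"],
                    target=row["target"],
                    reg_sign=int(row["reg_sign"]),
                    target_disease_sign=int(row["target_disease_sign"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"edge list {path}, row {i + 1}: {exc}") from exc
    return edges


def write_pathway_edges(edges: Sequence[PathwayEdge], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "regulator": e.regulator,
                "target": e.target,
                "reg_sign": e.reg_sign,
                "target_disease_sign": e.target_disease_sign,
            }
            for e in edges
        ]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result tables


def config_hash(config: object) -> str:
    """Short stable hash of a configuration's repr, for output provenance."""
    return hashlib.sha1(repr(config).encode()).hexdigest()[:10]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    config: object | None = None,
    float_format: str = "%.6g",
) -> None:
    """Write a result table as TSV with a provenance comment header."""
    from . import __version__

    with open(path, "w") as fh:
        tag = f"# megapool v{__version__}"
        if config is not None:
            tag += f" config={config_hash(config)}"
        fh.write(tag + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
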