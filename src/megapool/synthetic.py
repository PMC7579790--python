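"""Synthetic multi-study case-control expression data with known ground truth.

The generator emulates the structure of a small panel of public case-control
array studies: K studies spread over a handful of countries and three sample
organisms, each contributing a gene x sample log2 expression matrix with its
own case/control sizes.  Per study i and gene g the true case-minus-control
effect is

    delta_ig = mu_g + u_ig + sum_m beta_m * x_im,   u_ig ~ N(0, tau2)

where mu_g is the gene's pooled effect, tau2 the between-study variance and
the x_im are the study's standardized moderator covariates (total sample
size, organism code, region code, study age).  Controls are drawn
N(baseline_g, sigma2_e) and cases N(baseline_g + delta_ig, sigma2_e) on the
log2 scale.  A configurable fraction of studies is emitted exponentiated
(2^value) with scale left "unknown", to exercise downstream scale inference;
genes can be dropped per study to mimic platform coverage gaps.

What this does not emulate: real array intensity distributions, probe-level
effects, within-study batch structure, or correlated genes — all values are
independent given the study effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionStudy,
    StudyRecord,
    ValidationError,
    write_expression,
    write_manifest,
)
from .moderators import MODERATOR_NAMES, categorical_codes

__all__ = ["SyntheticConfig", "generate", "fixture_table1", "write_dataset"]

_COUNTRIES = ["USA", "Germany", "Singapore", "Portugal", "United Kingdom", "Japan"]
_ORGANISMS = ["Homo sapiens", "Mus musculus", "Rattus norvegicus"]


def fixture_table1() -> list[StudyRecord]:
    """An 11-study manifest mirroring the published stroke-panel metadata.

    Six countries, three organisms, study ages 6–13 years.  The source table's
    accession/count boundaries are typographically ambiguous for some rows
    (e.g. "GSE987727/20" reads as GSE9877 with 27 controls / 20 cases, or as
    GSE98772 with 7/20); the reading used here keeps every accession at the
    conventional GEO length seen in the surrounding rows.  The per-row sums
    (98 controls / 172 cases) do not reproduce the abstract's 102/176 under
    either reading; the discrepancy is inherited from the source.
    """
    rows = [
        ("s01", "GSE21136", 6, 24, "USA", 6, "Rattus norvegicus"),
        ("s02", "GSE30655", 6, 14, "USA", 6, "Mus musculus"),
        ("s03", "GSE55260", 2, 4, "Germany", 6, "Rattus norvegicus"),
        ("s04", "GSE58294", 23, 69, "USA", 6, "Homo sapiens"),
        ("s05", "GSE28731", 4, 6, "USA", 7, "Mus musculus"),
        ("s06", "GSE46267", 1, 6, "Singapore", 7, "Rattus norvegicus"),
        ("s07", "GSE22255", 20, 20, "Portugal", 9, "Homo sapiens"),
        ("s08", "GSE9391", 3, 3, "United Kingdom", 13, "Homo sapiens"),
        ("s09", "GSE9877", 27, 20, "USA", 13, "Homo sapiens"),
        ("s10", "GSE38037", 4, 4, "USA", 7, "Rattus norvegicus"),
        ("s11", "GSE28201", 2, 2, "Japan", 8, "Mus musculus"),
    ]
    return [
        StudyRecord(
            study_id=sid,
            accession=acc,
            n_control=nc,
            n_case=ns,
            country=country,
            study_age_years=age,
            organism=org,
        )
        for sid, acc, nc, ns, country, age, org in rows
    ]


@dataclass
class SyntheticConfig:
    """Ground-truth generative parameters for a multi-study dataset.

    Defaults describe a quiet, well-powered panel: 11 studies, moderate
    within-sample noise (sigma2_e = 1.0, a typical log2-scale array variance),
    baseline log2 intensity 7, no heterogeneity, no moderator effects, no
    missingness.  ``mu`` assigns true pooled effects per gene; genes not
    listed get 0.
    """

    genes: list[str] = field(default_factory=lambda: ["G%03d" % i for i in range(20)])
    n_studies: int = 11
    mu: dict[str, float] = field(default_factory=dict)
    tau2: float = 0.0
    sigma2_e: float = 1.0
    baseline: dict[str, float] = field(default_factory=dict)
    baseline_default: float = 7.0
    moderator_betas: dict[str, float] = field(default_factory=dict)
    study_meta: list[StudyRecord] | None = None
    n_control: int = 30
    n_case: int = 30
    missing_rate: float = 0.0
    # genes listed here appear only in the given study indices (0-based),
    # overriding missing_rate for those genes
    presence: dict[str, list[int]] = field(default_factory=dict)
    linear_scale_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau2 < 0 or self.sigma2_e <= 0:
            raise ValidationError("tau2 must be >= 0 and sigma2_e > 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.linear_scale_fraction <= 1.0):
            raise ValidationError("linear_scale_fraction must be in [0, 1]")
        if not self.genes:
            raise ValidationError("need at least one gene")
        unknown = set(self.moderator_betas) - set(MODERATOR_NAMES)
        if unknown:
            raise ValidationError(f"unknown moderator names: {sorted(unknown)}")

    def resolved_meta(self, rng: np.random.Generator) -> list[StudyRecord]:
        if self.study_meta is not None:
            if len(self.study_meta) != self.n_studies:
                raise ValidationError("study_meta length must equal n_studies")
            return list(self.study_meta)
        if self.n_studies == 11 and self.n_control == 30 and self.n_case == 30:
            # the bundled panel is the natural default at K=11
            return fixture_table1()
        meta = []
        for i in range(self.n_studies):
            meta.append(
                StudyRecord(
                    study_id=f"s{i + 1:02d}",
                    accession=f"SYN{i + 1:05d}",
                    n_control=self.n_control,
                    n_case=self.n_case,
                    country=_COUNTRIES[i % len(_COUNTRIES)],
                    study_age_years=6 + i % 8,
                    organism=_ORGANISMS[i % len(_ORGANISMS)],
                )
            )
        return meta


def _standardized_covariates(meta: list[StudyRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sample_size": [float(r.n_total) for r in meta],
            "organism": categorical_codes([r.organism for r in meta]),
            "region": categorical_codes([r.country for r in meta]),
            "study_age": [float(r.study_age_years) for r in meta],
        }
    )
    for col in df.columns:
        x = df[col].to_numpy()
        sd = x.std(ddof=0)
        df[col] = (x - x.mean()) / sd if sd > 0 else 0.0
    return df


def generate(
    config: SyntheticConfig,
) -> tuple[list[StudyRecord], list[ExpressionStudy], pd.DataFrame]:
    """Draw a full multi-study dataset plus its ground-truth effect table.

    Returns the manifest, one :class:`ExpressionStudy` per study (scale left
    ``unknown`` so the pipeline must resolve it), and a truth table with one
    row per emitted (study, gene): study_id, gene, mu, delta_true.
    """
    rng = np.random.default_rng(config.seed)
    meta = config.resolved_meta(rng)
    covars = _standardized_covariates(meta)
    mod_shift = np.zeros(len(meta))
    for name, beta in config.moderator_betas.items():
        mod_shift += beta * covars[name].to_numpy()

    sigma = float(np.sqrt(config.sigma2_e))
    tau = float(np.sqrt(config.tau2))
    n_linear = int(round(config.linear_scale_fraction * len(meta)))
    linear_idx = set(rng.choice(len(meta), size=n_linear, replace=False).tolist())

    studies: list[ExpressionStudy] = []
    truth_rows = []
    for i, rec in enumerate(meta):
        present = []
        for g in config.genes:
            if g in config.presence:
                if i in config.presence[g]:
                    present.append(g)
            elif config.missing_rate == 0.0 or rng.random() >= config.missing_rate:
                present.append(g)
        n_s = rec.n_total
        values = np.empty((len(present), n_s))
        for gi, g in enumerate(present):
            mu_g = config.mu.get(g, 0.0)
            delta = mu_g + (tau * rng.standard_normal() if tau > 0 else 0.0) + mod_shift[i]
            base = config.baseline.get(g, config.baseline_default)
            ctrl = base + sigma * rng.standard_normal(rec.n_control)
            case = base + delta + sigma * rng.standard_normal(rec.n_case)
            values[gi] = np.concatenate([ctrl, case])
            truth_rows.append(
                {"study_id": rec.study_id, "gene": g, "mu": mu_g, "delta_true": delta}
            )
        phenotype = ["control"] * rec.n_control + ["case"] * rec.n_case
        samples = [f"{rec.study_id}_smp{j + 1}" for j in range(n_s)]
        if i in linear_idx:
            values = np.exp2(values)
        studies.append(
            ExpressionStudy(
                study=rec,
                genes=list(present),
                samples=samples,
                values=values,
                phenotype=phenotype,
                scale="unknown",
            )
        )
    truth = pd.DataFrame(truth_rows, columns=["study_id", "gene", "mu", "delta_true"])
    return meta, studies, truth


def write_dataset(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Generate and write manifest, per-study matrices and the truth table.

    Returns (manifest_path, expression_dir, truth_path).  Same config and
    seed produce byte-identical files.
    """
    out = Path(out_dir)
    expr_dir = out / "expression"
    expr_dir.mkdir(parents=True, exist_ok=True)
    manifest, studies, truth = generate(config)
    manifest_path = out / "manifest.tsv"
    write_manifest(manifest, manifest_path)
    for st in studies:
        write_expression(st, expr_dir / f"{st.study.study_id}.tsv")
    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.10g")
    return manifest_path, expr_dir, truth_path
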