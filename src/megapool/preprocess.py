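"""Scale resolution and per-study effect sizes.

Each study contributes, per gene, a log2 fold change (LFC = mean log2
expression in cases minus controls) together with a Welch-form sampling
variance.  Expression matrices of unknown scale are log2-resolved first:
matrices containing negative values, or whose 99th percentile is small
enough to be implausible as linear intensities, are deemed already log2;
everything else gets ``log2(x + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import DataError, ExpressionStudy

__all__ = [
    "GeneEffect",
    "ensure_log2",
    "quantile_normalize",
    "gene_effect",
    "study_effects",
    "LOG2_PERCENTILE_MAX",
    "VAR_FLOOR",
]

# 99th-percentile threshold below which an unknown-scale matrix is deemed
# already log2 (linear array intensities run into the thousands; log2 values
# rarely exceed ~20).  Config-overridable per call.
LOG2_PERCENTILE_MAX = 30.0

# floor on the LFC sampling variance so inverse-variance weights stay finite
VAR_FLOOR = 1e-8


@dataclass(frozen=True)
class GeneEffect:
    """One gene's effect size in one study."""

    study_id: str
    gene: str
    lfc: float
    var_lfc: float
    n_case: int
    n_control: int
    var_imputed: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.lfc):
            raise DataError(f"{self.study_id}/{self.gene}: non-finite LFC")
        if not (self.var_lfc > 0):
            raise DataError(f"{self.study_id}/{self.gene}: var_lfc must be > 0")


def ensure_log2(
    study: ExpressionStudy, *, percentile_max: float = LOG2_PERCENTILE_MAX
) -> ExpressionStudy:
    """Return the study on log2 scale, inferring the input scale if unknown."""
    if not np.all(np.isfinite(study.values)):
        raise DataError(f"study {study.study.study_id}: non-finite expression values")
    if study.scale == "log2":
        return study
    if study.values.size == 0:
        return study.with_values(study.values, scale="log2")
    if study.scale == "linear":
        return study.with_values(np.log2(study.values + 1.0), scale="log2")
    # unknown: infer
    if np.any(study.values < 0) or np.percentile(study.values, 99) <= percentile_max:
        return study.with_values(study.values, scale="log2")
    return study.with_values(np.log2(study.values + 1.0), scale="log2")


def quantile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Per-sample quantile normalization (columns forced to a common distribution).

    Ties are broken by row order within each column.  With fewer than two
    samples this is a no-op (a single column is its own reference) and a
    warning is emitted.
    """
    if len(study.samples) < 2:
        warnings.warn(
            f"study {study.study.study_id}: quantile normalization needs >= 2 "
            "samples; returning input unchanged",
            stacklevel=2,
        )
        return study
    x = study.values
    order = np.argsort(x, axis=0, kind="stable")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    rows = np.arange(x.shape[0])
    for j in range(x.shape[1]):
        out[order[:, j], j] = reference[rows]
    return study.with_values(out)


def _group_stats(values: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and sample variance (ddof=1; NaN when n < 2) of one group."""
    sub = values[:, mask]
    mean = sub.mean(axis=1)
    if sub.shape[1] >= 2:
        var = sub.var(axis=1, ddof=1)
    else:
        var = np.full(sub.shape[0], np.nan)
    return mean, var


def study_effects(study: ExpressionStudy, genes: list[str] | None = None) -> list[GeneEffect]:
    """Compute :class:`GeneEffect` for every (or the requested) gene in a study.

    The LFC is the case-minus-control difference of mean log2 expression; its
    variance is the Welch form ``s2_case/n_case + s2_control/n_control`` on
    sample variances.  In a study where a group has fewer than two samples the
    group variance is imputed from the study-wide median per-group sample
    variance and the effect is flagged (``var_imputed=True``).
    """
    if study.scale != "log2":
        raise DataError(
            f"study {study.study.study_id}: scale must be resolved to log2 "
            "before computing effects (call ensure_log2)"
        )
    case = study.case_mask
    ctrl = ~case
    n_case, n_ctrl = int(case.sum()), int(ctrl.sum())
    mean_case, var_case = _group_stats(study.values, case)
    mean_ctrl, var_ctrl = _group_stats(study.values, ctrl)

    imputed = False
    pool = np.concatenate(
        [var_case[np.isfinite(var_case)], var_ctrl[np.isfinite(var_ctrl)]]
    )
    if np.any(~np.isfinite(var_case)) or np.any(~np.isfinite(var_ctrl)):
        if pool.size == 0:
            raise DataError(
                f"study {study.study.study_id}: no group has >= 2 samples; "
                "cannot estimate any variance"
            )
        med = float(np.median(pool))
        var_case = np.where(np.isfinite(var_case), var_case, med)
        var_ctrl = np.where(np.isfinite(var_ctrl), var_ctrl, med)
        imputed = True

    lfc = mean_case - mean_ctrl
    var = np.maximum(var_case / n_case + var_ctrl / n_ctrl, VAR_FLOOR)

    wanted = None if genes is None else {g for g in genes}
    effects = []
    for i, g in enumerate(study.genes):
        if wanted is not None and g not in wanted:
            continue
        effects.append(
            GeneEffect(
                study_id=study.study.study_id,
                gene=g,
                lfc=float(lfc[i]),
                var_lfc=float(var[i]),
                n_case=n_case,
                n_control=n_ctrl,
                var_imputed=imputed,
            )
        )
    return effects


def gene_effect(study: ExpressionStudy, gene: str) -> GeneEffect | None:
    """Effect size for a single gene; ``None`` if the gene is absent."""
    if gene not in study.genes:
        return None
    return study_effects(study, genes=[gene])[0]
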