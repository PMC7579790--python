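"""Study-level moderator regression.

For a gene pooled across k studies, the per-study log2 fold changes are
regressed on four study-level covariates — total sample size, sample
organism, population region (country) and study age in years — by ordinary
least squares with an intercept.  The categorical covariates enter as single
alphabetically-ordered integer codes rather than dummy blocks: with a handful
of studies spread over six regions and three organisms a dummy expansion is
rank-deficient, and a single code yields the one-p-value-per-factor summary
this analysis reports.  That coding is an interpretive reconstruction and is
documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import StudyRecord, ValidationError
from .preprocess import GeneEffect

__all__ = [
    "ModeratorFit",
    "MODERATOR_NAMES",
    "categorical_codes",
    "moderator_table",
    "mlr_fit",
    "DegenerateFitError",
    "InsufficientDataError",
]

MODERATOR_NAMES = ["sample_size", "organism", "region", "study_age"]


class DegenerateFitError(ValueError):
    """The design matrix is rank-deficient beyond repair."""


class InsufficientDataError(ValueError):
    """Fewer rows than parameters; the fit is refused."""


@dataclass(frozen=True)
class ModeratorTerm:
    name: str
    coefficient: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class ModeratorFit:
    """OLS summary for one gene's study-level moderator regression."""

    gene: str
    terms: tuple[ModeratorTerm, ...]
    n_studies: int
    r_squared: float
    dropped_terms: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        for t in self.terms:
            assert t.ci_low <= t.coefficient <= t.ci_high
            assert 0.0 <= t.p_value <= 1.0

    def term(self, name: str) -> ModeratorTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": self.gene,
                    "term": t.name,
                    "coefficient": t.coefficient,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "p_value": t.p_value,
                }
                for t in self.terms
            ]
        )


def categorical_codes(values: Sequence[str]) -> np.ndarray:
    """Integer codes for a categorical covariate, alphabetical category order."""
    cats = sorted(set(values))
    lut = {c: i for i, c in enumerate(cats)}
    return np.array([lut[v] for v in values], dtype=float)


def moderator_table(
    effects: Sequence[GeneEffect],
    manifest: Sequence[StudyRecord],
    *,
    standardize: bool = False,
) -> pd.DataFrame:
    """One row per contributing study: response ``lfc`` plus the four covariates.

    With ``standardize=True`` each covariate is z-scored across the
    contributing studies (constant covariates map to zero), putting fitted
    coefficients on a per-SD scale.
    """
    by_id = {r.study_id: r for r in manifest}
    missing = [e.study_id for e in effects if e.study_id not in by_id]
    if missing:
        raise ValidationError(f"effects reference unknown study_ids: {sorted(set(missing))}")
    if not effects:
        return pd.DataFrame(columns=["study_id", "lfc", *MODERATOR_NAMES])
    recs = [by_id[e.study_id] for e in effects]
    df = pd.DataFrame(
        {
            "study_id": [e.study_id for e in effects],
            "lfc": [e.lfc for e in effects],
            "sample_size": [float(r.n_total) for r in recs],
            "organism": categorical_codes([r.organism for r in recs]),
            "region": categorical_codes([r.country for r in recs]),
            "study_age": [float(r.study_age_years) for r in recs],
        }
    )
    if standardize:
        for name in MODERATOR_NAMES:
            x = df[name].to_numpy()
            sd = x.std(ddof=0)
            df[name] = (x - x.mean()) / sd if sd > 0 else 0.0
    return df


def mlr_fit(table: pd.DataFrame, gene: str = "") -> ModeratorFit:
    """Ordinary least squares of LFC on the moderators, t-based CIs and p-values.

    Zero-variance (constant) covariates are dropped as collinear and recorded
    in ``dropped_terms``; a design that remains rank-deficient raises
    :class:`DegenerateFitError` naming the offending terms.
    """
    names = [n for n in MODERATOR_NAMES if n in table.columns]
    y = table["lfc"].to_numpy(dtype=float)

    dropped = [n for n in names if table[n].nunique() <= 1]
    kept = [n for n in names if n not in dropped]

    n_rows = len(table)
    if n_rows <= len(kept) + 1:
        raise InsufficientDataError(
            f"{n_rows} studies cannot support {len(kept)} covariates plus intercept"
        )

    X = table[kept].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify terms whose removal restores full rank
        collinear = []
        for j, name in enumerate(kept):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(name)
        raise DegenerateFitError(f"collinear moderator terms: {collinear or kept}")

    res = sm.OLS(y, design).fit()
    conf = res.conf_int(alpha=0.05)
    terms = tuple(
        ModeratorTerm(
            name=name,
            coefficient=float(res.params[j + 1]),
            ci_low=float(conf[j + 1, 0]),
            ci_high=float(conf[j + 1, 1]),
            p_value=float(res.pvalues[j + 1]),
        )
        for j, name in enumerate(kept)
    )
    return ModeratorFit(
        gene=gene,
        terms=terms,
        n_studies=n_rows,
        r_squared=float(res.rsquared),
        dropped_terms=tuple(dropped),
    )


def fit_moderators(
    gene: str,
    effects: Sequence[GeneEffect],
    manifest: Sequence[StudyRecord],
    *,
    standardize: bool = False,
) -> ModeratorFit:
    """Convenience wrapper: build the design table and fit it."""
    return mlr_fit(moderator_table(effects, manifest, standardize=standardize), gene=gene)
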