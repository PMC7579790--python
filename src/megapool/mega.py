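"""Effect-size pooling across studies (the mega-analysis core).

Per gene, study-level log2 fold changes are combined by inverse-variance
weighting.  Heterogeneity is quantified with Cochran's Q and the I² statistic
I² = 100·(Q − df)/Q, floored at 0 when Q ≤ df.  Model selection is binary:
a fixed-effect model whenever I² = 0, otherwise a random-effects model with
the DerSimonian–Laird moment estimate of the between-study variance τ².
The pooled p-value is a two-sided z (optionally t) test of estimate/SE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import GeneEffect

__all__ = [
    "MegaResult",
    "ScreenCriteria",
    "fixed_effect",
    "heterogeneity",
    "dl_tau2",
    "random_effects",
    "mega_analyze",
    "group_effects_by_gene",
    "screen",
    "percent_change",
    "results_table",
]


@dataclass(frozen=True)
class MegaResult:
    """Pooled estimate for one gene across k contributing studies."""

    gene: str
    k: int
    lfc_pooled: float
    se_pooled: float
    sd_between: float  # sample SD of the per-study LFCs
    p_value: float
    Q: float
    df: int
    ISq: float  # percent, in [0, 100]
    q_p: float
    tau2: float
    model: str  # "fixed" | "random"
    low_k: bool = False  # contributed by fewer than min_k studies

    def __post_init__(self) -> None:
        assert self.df == self.k - 1
        assert 0.0 <= self.ISq <= 100.0
        assert (self.model == "fixed") == (self.ISq == 0.0)
        assert 0.0 <= self.p_value <= 1.0

    @property
    def ci95(self) -> tuple[float, float]:
        half = 1.959963984540054 * self.se_pooled
        return (self.lfc_pooled - half, self.lfc_pooled + half)


@dataclass(frozen=True)
class ScreenCriteria:
    """Significance screen: p below ``p_max`` and |pooled LFC| above ``lfc_abs_min``."""

    p_max: float = 0.005
    lfc_abs_min: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_max < 1.0):
            raise ValueError("p_max must be in (0, 1)")
        if self.lfc_abs_min < 0:
            raise ValueError("lfc_abs_min must be >= 0")

    def passes(self, result: MegaResult) -> bool:
        return result.p_value < self.p_max and abs(result.lfc_pooled) > self.lfc_abs_min


def _arrays(effects: Sequence[GeneEffect]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([e.lfc for e in effects], dtype=float)
    v = np.array([e.var_lfc for e in effects], dtype=float)
    if np.any(v <= 0):
        raise ValueError("all effect variances must be positive")
    return y, v


def fixed_effect(effects: Sequence[GeneEffect]) -> tuple[float, float] | None:
    """Inverse-variance weighted mean: w_i = 1/v_i; returns (estimate, SE)."""
    if not effects:
        return None
    y, v = _arrays(effects)
    w = 1.0 / v
    sw = w.sum()
    return float((w * y).sum() / sw), float(math.sqrt(1.0 / sw))


def heterogeneity(
    effects: Sequence[GeneEffect], fixed_estimate: float
) -> tuple[float, int, float, float]:
    """Cochran's Q, its df = k−1, I² (percent) and the chi-square tail q_p.

    I² = 100·(Q − df)/Q when Q exceeds df, else 0: when the total dispersion
    Q is no larger than its within-study expectation df, all variance is
    attributed to sampling error.  q_p is the upper-tail chi-square(df)
    probability of Q — the probability that dispersion this large arises from
    within-study variance alone.
    """
    k = len(effects)
    if k < 2:
        return 0.0, 0, 0.0, 1.0
    y, v = _arrays(effects)
    w = 1.0 / v
    Q = float((w * (y - fixed_estimate) ** 2).sum())
    df = k - 1
    ISq = 100.0 * (Q - df) / Q if Q > df else 0.0
    q_p = float(stats.chi2.sf(Q, df))
    return Q, df, ISq, q_p


def dl_tau2(effects: Sequence[GeneEffect], Q: float, df: int) -> float:
    """DerSimonian–Laird moment estimate of the between-study variance τ².

    τ² = max(0, (Q − df) / (Σw − Σw²/Σw)) with fixed-effect weights w = 1/v.
    """
    if len(effects) < 2:
        return 0.0
    _, v = _arrays(effects)
    w = 1.0 / v
    denom = w.sum() - (w**2).sum() / w.sum()
    if denom <= 0:
        warnings.warn("degenerate DL denominator; tau2 set to 0", stacklevel=2)
        return 0.0
    return max(0.0, (Q - df) / denom)


def random_effects(
    effects: Sequence[GeneEffect], tau2: float
) -> tuple[float, float] | None:
    """Inverse-variance pooling with weights 1/(v_i + τ²)."""
    if not effects:
        return None
    y, v = _arrays(effects)
    w = 1.0 / (v + tau2)
    sw = w.sum()
    return float((w * y).sum() / sw), float(math.sqrt(1.0 / sw))


def _pooled_p(estimate: float, se: float, df: int, use_t: bool) -> float:
    z = estimate / se
    if use_t and df >= 1:
        return float(2.0 * stats.t.sf(abs(z), df))
    return float(2.0 * stats.norm.sf(abs(z)))


def pool_gene(
    gene: str,
    effects: Sequence[GeneEffect],
    *,
    min_k: int = 2,
    use_t: bool = False,
) -> MegaResult:
    """Pool one gene's study effects under the I²-selected model."""
    k = len(effects)
    if k == 0:
        raise ValueError(f"gene {gene}: no contributing studies")
    y, _ = _arrays(effects)
    est_f, se_f = fixed_effect(effects)
    Q, df, ISq, q_p = heterogeneity(effects, est_f)
    if ISq == 0.0:
        model, tau2, est, se = "fixed", 0.0, est_f, se_f
    else:
        model = "random"
        tau2 = dl_tau2(effects, Q, df)
        est, se = random_effects(effects, tau2)
    sd_between = float(np.std(y, ddof=1)) if k >= 2 else 0.0
    return MegaResult(
        gene=gene,
        k=k,
        lfc_pooled=est,
        se_pooled=se,
        sd_between=sd_between,
        p_value=_pooled_p(est, se, df, use_t),
        Q=Q,
        df=df,
        ISq=ISq,
        q_p=q_p,
        tau2=tau2,
        model=model,
        low_k=k < min_k,
    )


def group_effects_by_gene(
    effects: Iterable[GeneEffect],
) -> dict[str, list[GeneEffect]]:
    by_gene: dict[str, list[GeneEffect]] = {}
    for e in effects:
        by_gene.setdefault(e.gene, []).append(e)
    return by_gene


def mega_analyze(
    effects_by_gene: Mapping[str, Sequence[GeneEffect]],
    min_k: int = 2,
    *,
    use_t: bool = False,
) -> list[MegaResult]:
    """Pool every gene present in at least one study.

    Genes contributing fewer than ``min_k`` studies are still reported but
    flagged ``low_k`` (their heterogeneity statistics are degenerate); genes
    absent from every study simply do not appear.
    """
    if min_k < 1:
        raise ValueError("min_k must be >= 1")
    results = [
        pool_gene(gene, effs, min_k=min_k, use_t=use_t)
        for gene, effs in effects_by_gene.items()
        if effs
    ]
    results.sort(key=lambda r: (r.p_value, r.gene))
    return results


def screen(
    results: Sequence[MegaResult], crit: ScreenCriteria = ScreenCriteria()
) -> list[MegaResult]:
    """Keep results passing the significance criteria, ordered by p ascending."""
    kept = [r for r in results if crit.passes(r)]
    kept.sort(key=lambda r: (r.p_value, r.gene))
    return kept


def percent_change(lfc: float) -> float:
    """Convert a log2 fold change to a percent change: 100·(2^lfc − 1)."""
    return 100.0 * (2.0**lfc - 1.0)


def results_table(results: Sequence[MegaResult]) -> pd.DataFrame:
    """Tabulate pooled results, adding an informational Benjamini–Hochberg column.

    The screen itself operates on raw p-values; p_bh is reported for context
    only.
    """
    df = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "k": r.k,
                "lfc_pooled": r.lfc_pooled,
                "se_pooled": r.se_pooled,
                "sd_between": r.sd_between,
                "p_value": r.p_value,
                "Q": r.Q,
                "df": r.df,
                "ISq": r.ISq,
                "q_p": r.q_p,
                "tau2": r.tau2,
                "model": r.model,
                "low_k": r.low_k,
            }
            for r in results
        ]
    )
    if not df.empty:
        from statsmodels.stats.multitest import multipletests

        df["p_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
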