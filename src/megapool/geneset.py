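"""Gene-set overlap enrichment and disease-specific set derivation.

The overlap of two literature-derived gene sets is tested against a
hypergeometric null: drawing |B| genes from a universe of N of which |A| are
"successes", what is the probability of an intersection at least as large as
observed?  The universe size is a required modelling choice (default 20,000,
an approximation of the protein-coding gene count); a sweep utility reports
how the tail probability moves with N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet, ValidationError

__all__ = [
    "GeneSetOverlap",
    "DEFAULT_UNIVERSE",
    "overlap_test",
    "specific_set",
    "universe_sweep",
]

DEFAULT_UNIVERSE = 20_000


@dataclass(frozen=True)
class GeneSetOverlap:
    """Counts and enrichment p-value for the intersection of two gene sets."""

    set_a_size: int
    set_b_size: int
    overlap_size: int
    universe_size: int
    p_value: float
    specific_to_a: GeneSet  # A \ B

    def __post_init__(self) -> None:
        assert self.overlap_size <= min(self.set_a_size, self.set_b_size)
        assert len(self.specific_to_a) == self.set_a_size - self.overlap_size

    @property
    def shared_percent(self) -> float:
        """Percent of A also in B."""
        return round(100.0 * self.overlap_size / self.set_a_size, 2)

    @property
    def specific_percent(self) -> float:
        """Percent of A not in B."""
        return round(100.0 * (self.set_a_size - self.overlap_size) / self.set_a_size, 2)


def hypergeom_upper_tail(
    overlap: int, universe: int, size_a: int, size_b: int
) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, size_a, size_b)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, size_a, size_b))


def overlap_test(a: GeneSet, b: GeneSet, universe_size: int = DEFAULT_UNIVERSE) -> GeneSetOverlap:
    """Hypergeometric enrichment test of the overlap between sets ``a`` and ``b``."""
    union = a.genes | b.genes
    if universe_size < len(union):
        raise ValidationError(
            f"universe_size {universe_size} smaller than |A ∪ B| = {len(union)}"
        )
    inter = a.genes & b.genes
    diff = a.genes - b.genes
    p = hypergeom_upper_tail(len(inter), universe_size, len(a), len(b))
    specific = GeneSet(name=f"{a.name}_specific", genes=frozenset(diff)) if diff else None
    if specific is None:
        # empty difference: GeneSet forbids emptiness, represent with sentinel
        specific = _EMPTY_SET(a.name)
    return GeneSetOverlap(
        set_a_size=len(a),
        set_b_size=len(b),
        overlap_size=len(inter),
        universe_size=universe_size,
        p_value=p,
        specific_to_a=specific,
    )


class _EmptyGeneSet(GeneSet):
    """Sentinel for an empty set difference (GeneSet proper must be nonempty)."""

    def __init__(self, name: str):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", frozenset())


def _EMPTY_SET(base_name: str) -> GeneSet:
    return _EmptyGeneSet(f"{base_name}_specific")


def specific_set(a: GeneSet, b: GeneSet) -> tuple[GeneSet, float]:
    """Set difference A \\ B and the percent of A it represents (2 decimals)."""
    diff = a.genes - b.genes
    out = _EMPTY_SET(a.name) if not diff else GeneSet(f"{a.name}_specific", frozenset(diff))
    percent = round(100.0 * len(diff) / len(a), 2)
    return out, percent


def universe_sweep(
    size_a: int,
    size_b: int,
    overlap: int,
    n_min: int | None = None,
    n_max: int = 50_000,
    step: int = 100,
) -> pd.DataFrame:
    """Tail probability of the observed overlap across candidate universe sizes.

    Useful when the background universe behind a published enrichment p-value
    is unstated: the sweep shows which N are consistent with it.  p decreases
    monotonically in N (a larger universe makes the overlap more surprising).
    """
    lo = n_min if n_min is not None else size_a + size_b - overlap
    ns = np.arange(max(lo, size_a + size_b - overlap), n_max + 1, step)
    ps = [hypergeom_upper_tail(overlap, int(n), size_a, size_b) for n in ns]
    return pd.DataFrame({"universe_size": ns, "p_value": ps})
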