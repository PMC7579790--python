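"""Direction-concordance validation of a literature pathway panel.

Each edge claims a regulator either promotes (+1) or inhibits (−1) a target.
Given the regulator's own pooled expression change, the expected direction of
the target is sign(regulator LFC) × edge sign; the pooled mega-analysis result
for the target supplies the observed direction (0 when the target is not
significant at the panel threshold).  An edge is *supported* when expected and
observed directions agree, *not supported* when they disagree, and
*not evaluated* when the target is absent from all studies or shows no
significant direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io import PathwayEdge, ValidationError, normalize_symbol
from .mega import MegaResult

__all__ = [
    "EdgeVerdict",
    "evaluate_panel",
    "default_panel_edges",
    "verdicts_table",
    "DEFAULT_P_PANEL",
]

# follow-up panel significance threshold: direction is only read off targets
# whose pooled change is nominally significant
DEFAULT_P_PANEL = 0.05


@dataclass(frozen=True)
class EdgeVerdict:
    edge: PathwayEdge
    target_result: MegaResult | None
    expected_direction: int  # +1 / -1
    observed_direction: int  # +1 / -1 / 0
    status: str  # supported | not_supported | not_evaluated

    def __post_init__(self) -> None:
        assert self.expected_direction in (1, -1)
        assert self.observed_direction in (1, -1, 0)
        if self.status == "not_evaluated":
            assert self.observed_direction == 0
        else:
            assert self.status == (
                "supported"
                if self.observed_direction == self.expected_direction
                else "not_supported"
            )


def _sign(x: float) -> int:
    return 1 if x > 0 else (-1 if x < 0 else 0)


def evaluate_panel(
    edges: Sequence[PathwayEdge],
    regulator_result: MegaResult,
    results: Mapping[str, MegaResult],
    p_panel: float = DEFAULT_P_PANEL,
    lfc_noise_floor: float = 0.0,
) -> list[EdgeVerdict]:
    """Classify every edge of a regulator's panel as supported or not.

    ``results`` maps gene symbol to its pooled mega-analysis result; targets
    missing from the map were absent from every study.  A target whose pooled
    p-value is at or above ``p_panel``, or whose |LFC| does not exceed
    ``lfc_noise_floor``, has no readable direction and the edge is left
    not_evaluated.
    """
    if regulator_result.lfc_pooled == 0:
        raise ValidationError("regulator pooled LFC is zero; directions undefined")
    reg_gene = normalize_symbol(regulator_result.gene)
    reg_dir = _sign(regulator_result.lfc_pooled)
    verdicts = []
    for edge in edges:
        if edge.regulator != reg_gene:
            raise ValidationError(
                f"edge regulator {edge.regulator} does not match result gene {reg_gene}"
            )
        expected = reg_dir * edge.reg_sign
        target = results.get(edge.target)
        if target is None:
            observed = 0
        elif target.p_value < p_panel and abs(target.lfc_pooled) > lfc_noise_floor:
            observed = _sign(target.lfc_pooled)
        else:
            observed = 0
        if observed == 0:
            status = "not_evaluated"
        elif observed == expected:
            status = "supported"
        else:
            status = "not_supported"
        verdicts.append(
            EdgeVerdict(
                edge=edge,
                target_result=target,
                expected_direction=expected,
                observed_direction=observed,
                status=status,
            )
        )
    return verdicts


def default_panel_edges(regulator: str = "SP1") -> list[PathwayEdge]:
    """The bundled ten-edge stroke panel for the SP1 regulator.

    Seven promote-edges onto stroke-inhibitor targets and three inhibit-edges
    onto stroke-promoter targets.  (One source figure renders the second
    target as "L10"; it is encoded here as IL10.)
    """
    promote_inhibitors = ["PTGS2", "IL10", "IGF1", "LEP", "ENTPD1", "HSPA1A", "HIF1A"]
    inhibit_promoters = ["IL1B", "TGFB1", "ACE"]
    edges = [
        PathwayEdge(regulator, t, reg_sign=1, target_disease_sign=-1)
        for t in promote_inhibitors
    ]
    edges += [
        PathwayEdge(regulator, t, reg_sign=-1, target_disease_sign=1)
        for t in inhibit_promoters
    ]
    return edges


VERDICT_COLUMNS = [
    "regulator",
    "target",
    "reg_sign",
    "target_disease_sign",
    "expected_direction",
    "observed_direction",
    "target_lfc",
    "target_p",
    "status",
]


def verdicts_table(verdicts: Sequence[EdgeVerdict]) -> pd.DataFrame:
    if not verdicts:
        return pd.DataFrame(columns=VERDICT_COLUMNS)
    return pd.DataFrame(
        [
            {
                "regulator": v.edge.regulator,
                "target": v.edge.target,
                "reg_sign": v.edge.reg_sign,
                "target_disease_sign": v.edge.target_disease_sign,
                "expected_direction": v.expected_direction,
                "observed_direction": v.observed_direction,
                "target_lfc": v.target_result.lfc_pooled if v.target_result else float("nan"),
                "target_p": v.target_result.p_value if v.target_result else float("nan"),
                "status": v.status,
            }
            for v in verdicts
        ]
    )
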