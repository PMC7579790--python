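import numpy as np
import pytest

from megapool.io import ExpressionStudy, StudyRecord
from megapool.preprocess import GeneEffect


@pytest.fixture
def study_record():
    return StudyRecord(
        study_id="s1",
        accession="SYN00001",
        n_control=2,
        n_case=2,
        country="USA",
        study_age_years=6,
        organism="Homo sapiens",
    )


def make_study(values, phenotype, genes=None, scale="log2", record=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    record = record or StudyRecord(
        study_id="s1",
        accession="SYN00001",
        n_control=phenotype.count("control"),
        n_case=phenotype.count("case"),
        country="USA",
        study_age_years=6,
        organism="Homo sapiens",
    )
    return ExpressionStudy(
        study=record,
        genes=genes,
        samples=[f"smp{i}" for i in range(values.shape[1])],
        values=values,
        phenotype=list(phenotype),
        scale=scale,
    )


def make_effect(study_id, y, v, gene="G0", n_case=10, n_control=10):
    return GeneEffect(
        study_id=study_id,
        gene=gene,
        lfc=float(y),
        var_lfc=float(v),
        n_case=n_case,
        n_control=n_control,
    )


@pytest.fixture
def effects_factory():
    def factory(ys, vs, gene="G0"):
        return [
            make_effect(f"s{i + 1}", y, v, gene=gene)
            for i, (y, v) in enumerate(zip(ys, vs))
        ]

    return factory
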