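"""End-to-end orchestration: overlap → effects → pooling → screen → moderators → panel.

`run_pipeline` wires the stages together over files on disk and writes every
result table as TSV (with a provenance comment line), plus a run log with
per-stage row counts.  The stages are also usable individually from Python;
this module just sequences them.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .geneset import DEFAULT_UNIVERSE, overlap_test
from .io import (
    GeneSet,
    read_expression,
    read_gene_set,
    read_manifest,
    read_pathway_edges,
    write_gene_set,
    write_table,
)
from .mega import (
    MegaResult,
    ScreenCriteria,
    group_effects_by_gene,
    mega_analyze,
    results_table,
    screen,
)
from .moderators import (
    DegenerateFitError,
    InsufficientDataError,
    fit_moderators,
)
from .pathway_panel import DEFAULT_P_PANEL, evaluate_panel, verdicts_table
from .preprocess import GeneEffect, ensure_log2, quantile_normalize, study_effects

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "forest_table"]

log = logging.getLogger("megapool")

Z95 = 1.959963984540054


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and knobs for one pipeline run; round-trips through YAML."""

    manifest: str
    expression_dir: str
    out_dir: str
    gene_set_a: str | None = None  # e.g. the DVT literature list
    gene_set_b: str | None = None  # e.g. the stroke literature list
    edges: str | None = None
    regulator: str | None = None  # panel hub gene; default: top screened gene
    universe_size: int = DEFAULT_UNIVERSE
    min_k: int = 2
    p_max: float = 0.005
    lfc_abs_min: float = 1.0
    p_panel: float = DEFAULT_P_PANEL
    quantile_norm: bool = False
    use_t: bool = False
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def forest_table(
    gene: str, effects: list[GeneEffect], result: MegaResult
) -> pd.DataFrame:
    """Per-study forest rows: LFC, 95% CI under the selected model, weight %.

    Under the random model the CI half-width uses sqrt(v_i + tau2); weights
    are the selected model's inverse-variance weights normalized to 100.
    """
    tau2 = result.tau2 if result.model == "random" else 0.0
    rows = []
    wsum = sum(1.0 / (e.var_lfc + tau2) for e in effects)
    for e in effects:
        half = Z95 * (e.var_lfc + tau2) ** 0.5
        rows.append(
            {
                "study_id": e.study_id,
                "lfc": e.lfc,
                "ci_low": e.lfc - half,
                "ci_high": e.lfc + half,
                "weight_percent": 100.0 * (1.0 / (e.var_lfc + tau2)) / wsum,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["gene"] = gene
    return df


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage; returns a name → path map of the files written.

    Outputs, in order: overlap report, specific gene list, per-study effects,
    pooled mega results, screened genes, moderator fits for screened genes,
    panel verdicts, and one forest table per screened gene.  Any stage
    failure raises :class:`PipelineError` naming the stage; files written by
    earlier stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    paths: dict[str, Path] = {}

    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    log.info("megapool v%s seed=%d config=%s", __version__, config.seed, asdict(config))

    try:
        # -- stage io: manifest --------------------------------------------
        @_stage("io")
        def _load_manifest():
            manifest = read_manifest(config.manifest)
            expr_dir = Path(config.expression_dir)
            if not expr_dir.is_dir():
                raise FileNotFoundError(f"expression directory {expr_dir} not found")
            return manifest, expr_dir

        manifest, expr_dir = _load_manifest()
        counts["studies"] = len(manifest)

        # -- stage overlap --------------------------------------------------
        target_genes: GeneSet | None = None
        if config.gene_set_a and config.gene_set_b:

            @_stage("overlap")
            def _overlap():
                a = read_gene_set(config.gene_set_a, "set_a")
                b = read_gene_set(config.gene_set_b, "set_b")
                ov = overlap_test(a, b, config.universe_size)
                write_table(
                    pd.DataFrame(
                        [
                            {
                                "set_a_size": ov.set_a_size,
                                "set_b_size": ov.set_b_size,
                                "overlap_size": ov.overlap_size,
                                "universe_size": ov.universe_size,
                                "p_value": ov.p_value,
                                "specific_to_a": len(ov.specific_to_a),
                                "specific_percent": ov.specific_percent,
                            }
                        ]
                    ),
                    out / "overlap_report.tsv",
                    config=config,
                )
                write_gene_set(ov.specific_to_a.genes, out / "specific_genes.txt")
                return ov

            ov = _overlap()
            paths["overlap_report"] = out / "overlap_report.tsv"
            paths["specific_genes"] = out / "specific_genes.txt"
            counts["specific_genes"] = len(ov.specific_to_a)
            if len(ov.specific_to_a) == 0:
                log.warning("specific gene list is empty; downstream outputs will be empty")
            target_genes = ov.specific_to_a if len(ov.specific_to_a) else None
        elif config.gene_set_a:
            target_genes = read_gene_set(config.gene_set_a, "set_a")

        # -- stage effects ---------------------------------------------------
        @_stage("effects")
        def _effects():
            effects: list[GeneEffect] = []
            wanted = sorted(target_genes.genes) if target_genes else None
            if wanted is not None and config.edges:
                # the panel's follow-up pooling needs effects for edge genes too
                panel_genes = set()
                for e in read_pathway_edges(config.edges):
                    panel_genes.update((e.regulator, e.target))
                wanted = sorted(set(wanted) | panel_genes)
            for rec in manifest:
                path = expr_dir / f"{rec.study_id}.tsv"
                if not path.exists():
                    raise FileNotFoundError(f"missing expression matrix {path}")
                st = ensure_log2(read_expression(path, rec))
                if config.quantile_norm:
                    st = quantile_normalize(st)
                effects.extend(study_effects(st, genes=wanted))
            return effects

        effects = _effects()
        eff_df = pd.DataFrame(
            [
                {
                    "study_id": e.study_id,
                    "gene": e.gene,
                    "lfc": e.lfc,
                    "var_lfc": e.var_lfc,
                    "n_case": e.n_case,
                    "n_control": e.n_control,
                    "var_imputed": e.var_imputed,
                }
                for e in effects
            ],
            columns=[
                "study_id",
                "gene",
                "lfc",
                "var_lfc",
                "n_case",
                "n_control",
                "var_imputed",
            ],
        )
        write_table(eff_df, out / "study_effects.tsv", config=config)
        paths["study_effects"] = out / "study_effects.tsv"
        counts["study_effects"] = len(eff_df)

        # -- stage mega ------------------------------------------------------
        @_stage("mega")
        def _mega():
            by_gene = group_effects_by_gene(effects)
            results = mega_analyze(by_gene, min_k=config.min_k, use_t=config.use_t)
            crit = ScreenCriteria(p_max=config.p_max, lfc_abs_min=config.lfc_abs_min)
            return by_gene, results, screen(results, crit)

        by_gene, results, screened = _mega()
        write_table(results_table(results), out / "mega_results.tsv", config=config)
        write_table(results_table(screened), out / "screened_genes.tsv", config=config)
        paths["mega_results"] = out / "mega_results.tsv"
        paths["screened_genes"] = out / "screened_genes.tsv"
        counts["mega_results"] = len(results)
        counts["screened_genes"] = len(screened)

        # -- stage moderators ------------------------------------------------
        @_stage("moderators")
        def _moderators():
            frames = []
            for r in screened:
                try:
                    fit = fit_moderators(r.gene, by_gene[r.gene], manifest)
                except (DegenerateFitError, InsufficientDataError) as exc:
                    log.warning("moderators for %s skipped: %s", r.gene, exc)
                    continue
                frames.append(fit.to_frame())
            cols = ["gene", "term", "coefficient", "ci_low", "ci_high", "p_value"]
            return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=cols)

        mod_df = _moderators()
        write_table(mod_df, out / "moderator_fits.tsv", config=config)
        paths["moderator_fits"] = out / "moderator_fits.tsv"
        counts["moderator_fits"] = len(mod_df)

        # -- stage panel -----------------------------------------------------
        @_stage("panel")
        def _panel():
            if not config.edges:
                return verdicts_table([])
            edges = read_pathway_edges(config.edges)
            reg = config.regulator
            if reg is None:
                if not screened:
                    log.warning("no screened gene to act as panel regulator; panel skipped")
                    return verdicts_table([])
                reg = screened[0].gene
            res_map = {r.gene: r for r in results}
            if reg not in res_map:
                raise ValueError(f"panel regulator {reg} absent from mega results")
            verdicts = evaluate_panel(
                [e for e in edges if e.regulator == reg],
                res_map[reg],
                res_map,
                p_panel=config.p_panel,
            )
            return verdicts_table(verdicts)

        panel_df = _panel()
        write_table(panel_df, out / "panel_verdicts.tsv", config=config)
        paths["panel_verdicts"] = out / "panel_verdicts.tsv"
        counts["panel_verdicts"] = len(panel_df)

        # -- stage forest ----------------------------------------------------
        @_stage("forest")
        def _forest():
            fdir = out / "forest"
            fdir.mkdir(exist_ok=True)
            n = 0
            for r in screened:
                ft = forest_table(r.gene, by_gene[r.gene], r)
                write_table(ft, fdir / f"{r.gene}.tsv", config=config)
                n += 1
            return fdir, n

        fdir, n_forest = _forest()
        paths["forest_dir"] = fdir
        counts["forest_tables"] = n_forest

        for name, n in counts.items():
            log.info("stage count %s=%d", name, n)
        log.info("pipeline complete")
        return paths
    except PipelineError as exc:
        log.error("pipeline failed at stage %s: %s", exc.stage, exc)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
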