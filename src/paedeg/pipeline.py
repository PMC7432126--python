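"""End-to-end pipeline over the published fixture tables.

Stage order: composite index -> derivative design bookkeeping ->
environmental screening -> pathway barrier accounting -> mechanistic
consistency pairing.  Each stage emits a TSV into the configured output
directory; a failure aborts with the stage name.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import synthetic
from .composite import comprehensive_table
from .design import derivative_table
from .io import RunConfig, read_score_table, read_table, write_table
from .pathways import consistency_report, pathway_report
from .screening import ScreeningRules, property_change_rates, screen

logger = logging.getLogger("paedeg")

__all__ = ["run_pipeline"]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("composite")
def _run_composite(cfg: RunConfig, fixtures: dict) -> pd.DataFrame:
    orient = [s for s in cfg.orientations.split(",") if s] or None
    scores = read_score_table(fixtures["table1_scores"], orientations=orient)
    result = comprehensive_table(scores, floor_a=cfg.floor_a)
    report = result.to_frame()
    logger.info("composite: %d compounds, weights %s", result.m,
                ", ".join(f"{w:.4f}" for w in result.W))
    return report


@_stage("design")
def _run_design(cfg: RunConfig, fixtures: dict) -> pd.DataFrame:
    preds = read_table(fixtures["table3_derivatives"], index_col=0)
    cols = ["Z", "2PIA", "2ZYI", "3CN7"]
    return derivative_table(preds[cols], parent_id="DEP", value_columns=cols)


@_stage("screen")
def _run_screen(cfg: RunConfig, fixtures: dict,
                design: pd.DataFrame) -> pd.DataFrame:
    props = read_table(fixtures["table5_properties"], index_col=0)
    keep = ["energy_au", "gap_ev", "freq_cm1", "logLC50", "logBCF",
            "logt12", "logKOA"]
    rated = property_change_rates(props[keep], parent_id="DEP")
    rules = ScreeningRules(max_bcf=cfg.bcf_threshold,
                           max_abs_toxicity_change=cfg.toxicity_threshold,
                           min_biodeg_gain=cfg.biodeg_gain_threshold)
    verdicts = screen(rated, design["Z_rate"], rules=rules, parent_id="DEP")
    return rated.join(verdicts)


@_stage("pathways")
def _run_pathways(cfg: RunConfig, fixtures: dict,
                  design: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    steps = read_table(fixtures["table6_steps"], index_col=None)
    report = pathway_report(steps, reference="DEP")
    totals = (report.dropna(subset=["rate"])
              .drop_duplicates("compound").set_index("compound")["total_rate"])
    biodeg = design["Z_rate"].reindex(totals.index)
    consistency = consistency_report(totals, biodeg)
    return report, consistency


def run_pipeline(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage on the fixture tables; returns the report bundle."""
    out = Path(cfg.out_dir)
    fixtures = synthetic.paper_fixtures(out / "fixtures")
    logger.info("run config %s seed %d -> %s", cfg.digest(), cfg.seed, out)

    composite = _run_composite(cfg, fixtures)
    design = _run_design(cfg, fixtures)
    screening = _run_screen(cfg, fixtures, design)
    pathway, consistency = _run_pathways(cfg, fixtures, design)

    bundle = {
        "composite": composite,
        "design": design,
        "screening": screening,
        "pathways": pathway,
        "consistency": consistency,
    }
    for name, df in bundle.items():
        write_table(df, out / f"{name}.tsv", config=cfg,
                    index=name != "pathways")
    return bundle
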