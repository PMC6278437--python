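"""End-to-end orchestration: depth filter -> DMR calling (both
contrasts) -> feature annotation -> differential expression (both
contrasts) -> restoration-pattern integration, with a JSON summary
report.

The two contrasts of the design are fixed in order: induction
(OVA vs saline) and treatment (DSE vs OVA). A generic contrast list can
be supplied for other designs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import annotate, dmr, expression, integrate
from .io import (SampleSheet, read_count_matrix, read_cpg_table,
                 read_sample_sheet, write_dmr_bed, write_window_table)
from .simulate import table1_fixture

log = logging.getLogger(__name__)

#: (group_a, group_b) pairs in the design's order.
DEFAULT_CONTRASTS = (("saline", "OVA"), ("OVA", "DSE"))


@dataclass
class RunConfig:
    """Paths and stage parameters; defaults are the study thresholds
    (window 1000/step 500, depth 20, >=2 CpGs, >=10 pp, q<0.01,
    |log2 FC|>=1, p<0.05)."""

    cpg_tables: dict[str, str] = field(default_factory=dict)
    counts: str | None = None
    annotation: str | None = None
    sample_sheet: str | None = None
    outdir: str = "methrestore_out"
    window: int = 1000
    step: int = 500
    min_depth: int = 20
    min_cpgs: int = 2
    min_diff: float = 10.0
    max_q: float = 0.01
    lfc: float = 1.0
    alpha: float = 0.05
    pattern_min_fc: float = 2.0
    promoter_flank: int = 1000
    link_max_distance: int = 10_000
    max_rho: float = 0.0
    destrand: bool = False
    contrasts: Sequence[tuple[str, str]] = DEFAULT_CONTRASTS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "contrasts" in raw:
            raw["contrasts"] = [tuple(c) for c in raw["contrasts"]]
        return cls(**raw)


@dataclass
class PipelineResult:
    report: dict
    windows: dict[str, pd.DataFrame]
    dmrs: dict[str, pd.DataFrame]
    expr: dict[str, pd.DataFrame]
    integrated: pd.DataFrame


def _contrast_label(contrast: tuple[str, str]) -> str:
    return f"{contrast[1]}_vs_{contrast[0]}"


def run_analysis(tables: Mapping[str, pd.DataFrame], counts: pd.DataFrame,
                 models: Sequence[annotate.TranscriptModel],
                 sheet: SampleSheet, cfg: RunConfig) -> PipelineResult:
    """Run every stage on in-memory inputs and assemble the report."""
    contrasts = [tuple(c) for c in cfg.contrasts]
    labels = [_contrast_label(c) for c in contrasts]
    index = annotate.FeatureIndex(models, cfg.promoter_flank)

    windows: dict[str, pd.DataFrame] = {}
    dmr_tables: dict[str, pd.DataFrame] = {}
    report: dict = {"config": _config_echo(cfg), "contrasts": {}}
    for contrast, label in zip(contrasts, labels):
        try:
            res = dmr.call_dmrs(
                tables, sheet, contrast, window=cfg.window, step=cfg.step,
                min_depth=cfg.min_depth, min_cpgs=cfg.min_cpgs,
                min_diff=cfg.min_diff, max_q=cfg.max_q)
        except Exception as exc:
            raise RuntimeError(f"DMR stage failed for {label}: {exc}") \
                from exc
        called = res.dmrs.copy()
        if len(called):
            called["feature"] = [
                index.classify(c, s, e) for c, s, e in zip(
                    called["chrom"], called["start"], called["end"])]
            called["transcripts"] = [
                ",".join(t for t, _ in index.link(
                    c, s, e, cfg.link_max_distance)) or "."
                for c, s, e in zip(called["chrom"], called["start"],
                                   called["end"])]
        windows[label] = res.windows
        dmr_tables[label] = called
        n_hyper = int((called["direction"] == "hyper").sum()) \
            if len(called) else 0
        n_hypo = int((called["direction"] == "hypo").sum()) \
            if len(called) else 0
        n_bins = len(res.windows)
        pct = dmr.dmr_summary(n_hyper, n_hypo, n_bins) if n_bins else (0.0,
                                                                       0.0)
        report["contrasts"][label] = {
            "n_windows_tested": n_bins, "n_dmrs": len(called),
            "n_hyper": n_hyper, "n_hypo": n_hypo,
            "pct_hyper": pct[0], "pct_hypo": pct[1],
            "dispersion": res.dispersion,
        }

    expr_tables: dict[str, pd.DataFrame] = {}
    for contrast, label in zip(contrasts, labels):
        try:
            expr_tables[label] = expression.de_test(
                counts, sheet, contrast, lfc_threshold=cfg.lfc,
                alpha=cfg.alpha)
        except Exception as exc:
            raise RuntimeError(f"expression stage failed for {label}: "
                               f"{exc}") from exc

    label1, label2 = labels[0], labels[1]
    restoration = integrate.count_restoration_dmrs(
        windows[label1], windows[label2], min_diff=cfg.min_diff,
        max_q=cfg.max_q)
    restoration_ids = sorted(set(restoration.pop("ids_hyper_hypo"))
                             | set(restoration.pop("ids_hypo_hyper")))
    report["restoration"] = restoration

    # link restoration DMRs to transcripts, then correlate and classify
    link_rows = []
    for wid in restoration_ids:
        chrom, start, end = wid.split("$")
        for tid, gene in index.link(chrom, int(start), int(end),
                                    cfg.link_max_distance):
            link_rows.append({"dmr_id": wid, "transcript_id": tid,
                              "gene": gene})
    links = pd.DataFrame(link_rows,
                         columns=["dmr_id", "transcript_id", "gene"])

    sample_betas = dmr.window_beta_matrix(
        tables, restoration_ids, window=cfg.window, step=cfg.step) \
        if restoration_ids else None
    sample_cols = [s for s in sheet.samples if s in counts.columns]
    sample_expr = expression.normalize_counts(
        counts[sample_cols]) if restoration_ids else None

    integrated, summary = integrate.integrate(
        {integrate.CONTRAST_INDUCTION: windows[label1],
         integrate.CONTRAST_TREATMENT: windows[label2]},
        {integrate.CONTRAST_INDUCTION: expr_tables[label1],
         integrate.CONTRAST_TREATMENT: expr_tables[label2]},
        links, sample_betas, sample_expr, min_diff=cfg.min_diff,
        max_q=cfg.max_q, min_fc=cfg.pattern_min_fc, alpha=cfg.alpha,
        max_rho=cfg.max_rho)
    report["integration"] = summary
    return PipelineResult(report, windows, dmr_tables, expr_tables,
                          integrated)


def run_pipeline(cfg: RunConfig) -> dict:
    """File-based entry point: read inputs per ``cfg``, run
    :func:`run_analysis`, write per-stage outputs and report.json under
    ``cfg.outdir``, and return the report."""
    if not cfg.cpg_tables or cfg.counts is None \
            or cfg.annotation is None or cfg.sample_sheet is None:
        raise ValueError("config must provide cpg_tables, counts, "
                         "annotation and sample_sheet paths")
    sheet = read_sample_sheet(cfg.sample_sheet)
    tables = {sid: read_cpg_table(path, sid, destrand=cfg.destrand)
              for sid, path in cfg.cpg_tables.items()}
    counts = read_count_matrix(cfg.counts)
    ann_path = str(cfg.annotation)
    models = annotate.read_gtf(ann_path) \
        if ann_path.endswith((".gtf", ".gff")) \
        else annotate.read_bed12(ann_path)

    result = run_analysis(tables, counts, models, sheet, cfg)

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for label, win in result.windows.items():
        write_window_table(win, outdir / f"windows_{label}.tsv")
    for label, called in result.dmrs.items():
        write_window_table(called, outdir / f"dmrs_{label}.tsv")
        if len(called):
            write_dmr_bed(called, outdir / f"dmrs_{label}.bed")
    for label, ex in result.expr.items():
        ex.to_csv(outdir / f"expression_{label}.tsv", sep="\t")
    result.integrated.to_csv(outdir / "integrated_genes.tsv", sep="\t",
                             index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2)
    return result.report


def fixture_report(**kwargs) -> dict:
    """Classification summary of the packaged candidate table."""
    _, summary = integrate.summarize_candidate_table(table1_fixture(),
                                                     **kwargs)
    return summary


def _config_echo(cfg: RunConfig) -> dict:
    echo = asdict(cfg)
    echo["contrasts"] = [list(c) for c in cfg.contrasts]
    return echo
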