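"""Restoration-pattern classification and methylation-expression
integration.

The three-condition design yields two ordered contrasts: disease
induction (OVA vs saline) and treatment (DSE vs OVA). A *restoration
pattern* is a change induced by disease and reversed by treatment:

* methylation ``hyper_hypo`` -- hyper-methylated on induction, hypo on
  treatment (``hypo_hyper`` mirrored);
* expression ``down_up`` -- down-regulated on induction, up on
  treatment (``up_down`` mirrored).

Pattern A pairs ``hyper_hypo`` methylation with ``down_up`` expression
at a linked gene; Pattern B is the mirror image. An emitted
(DMR, transcript) pair must additionally show a negative Spearman
correlation between per-sample window methylation and per-sample
expression scaled to [0, 1], across all samples jointly.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: Ordered contrast labels used in result dictionaries.
CONTRAST_INDUCTION = "OVA_vs_saline"
CONTRAST_TREATMENT = "DSE_vs_OVA"


def classify_meth_pattern(delta1: float, q1: float, delta2: float,
                          q2: float, min_diff: float = 10.0,
                          max_q: float = 0.01) -> str:
    """Restoration pattern of a DMR across the two ordered contrasts.

    delta values are in percentage points; both contrasts must pass the
    significance threshold with opposite signs, otherwise ``none``.
    """
    sig = q1 < max_q and q2 < max_q
    if sig and delta1 >= min_diff and delta2 <= -min_diff:
        return "hyper_hypo"
    if sig and delta1 <= -min_diff and delta2 >= min_diff:
        return "hypo_hyper"
    return "none"


def classify_expr_pattern(fc1: float, p1: float, fc2: float, p2: float,
                          min_fc: float = 2.0, alpha: float = 0.05) -> str:
    """Restoration pattern of a transcript across the two contrasts.

    Fold changes are signed linear (+r / -1/r). With ``min_fc=1`` the
    rule reduces to direction + significance, the rule the published
    candidate table itself satisfies; ``min_fc=2`` matches the
    genome-wide DEG screen (|log2 FC| >= 1).
    """
    sig = p1 < alpha and p2 < alpha
    if sig and fc1 <= -min_fc and fc2 >= min_fc:
        return "down_up"
    if sig and fc1 >= min_fc and fc2 <= -min_fc:
        return "up_down"
    return "none"


def pair_pattern(meth_pattern: str, expr_pattern: str) -> str | None:
    """'A' for hyper_hypo+down_up, 'B' for hypo_hyper+up_down, else None."""
    if meth_pattern == "hyper_hypo" and expr_pattern == "down_up":
        return "A"
    if meth_pattern == "hypo_hyper" and expr_pattern == "up_down":
        return "B"
    return None


def scale_unit_interval(values: Sequence[float]) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant vector maps to all 0.5.

    The 0.5 convention avoids a divide-by-zero while leaving the ranks
    degenerate, so a downstream rank correlation is undefined and the
    pair is excluded rather than spuriously scored.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to scale")
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Spearman rank correlation with average ranks for ties.

    Returns None when either vector has zero rank variance (undefined
    correlation); callers exclude such pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    rho = stats.spearmanr(x, y).statistic
    if np.isnan(rho):
        return None
    return float(rho)


def integrate(meth_windows: Mapping[str, pd.DataFrame],
              expr_results: Mapping[str, pd.DataFrame],
              links: pd.DataFrame, sample_betas: pd.DataFrame | None = None,
              sample_expr: pd.DataFrame | None = None, *,
              min_diff: float = 10.0, max_q: float = 0.01,
              min_fc: float = 2.0, alpha: float = 0.05,
              max_rho: float = 0.0) -> tuple[pd.DataFrame, dict]:
    """Join DMRs to transcripts and emit Pattern A/B genes.

    Parameters
    ----------
    meth_windows
        Per-contrast window tables (keys :data:`CONTRAST_INDUCTION`,
        :data:`CONTRAST_TREATMENT`) indexed or indexable by ``id`` with
        ``delta_beta`` and ``q`` columns.
    expr_results
        Per-contrast DE tables indexed by transcript id with
        ``fc_signed`` and ``p``.
    links
        DataFrame with columns dmr_id, transcript_id, gene.
    sample_betas, sample_expr
        Optional per-sample window methylation (rows: dmr_id) and
        expression (rows: transcript_id) across the same sample
        columns. When provided, a pair is emitted only when the
        Spearman correlation of methylation against min-max-scaled
        expression is below ``max_rho`` (default: strictly negative).
        When absent the correlation filter is vacuous.

    Returns
    -------
    (records, summary): records unique on (dmr_id, transcript_id);
    summary counts unique DMRs, unique genes and per-pattern genes.
    """
    for key in (CONTRAST_INDUCTION, CONTRAST_TREATMENT):
        if key not in meth_windows or key not in expr_results:
            raise KeyError(f"missing contrast {key!r} in inputs")
    meth = {k: _indexed(v, "id") for k, v in meth_windows.items()}
    records = []
    seen = set()
    for row in links.itertuples(index=False):
        key = (row.dmr_id, row.transcript_id)
        if key in seen:
            continue
        seen.add(key)
        m1 = _lookup(meth[CONTRAST_INDUCTION], row.dmr_id)
        m2 = _lookup(meth[CONTRAST_TREATMENT], row.dmr_id)
        if m1 is None or m2 is None:
            continue  # window untested in one contrast
        e1 = _lookup(expr_results[CONTRAST_INDUCTION], row.transcript_id)
        e2 = _lookup(expr_results[CONTRAST_TREATMENT], row.transcript_id)
        if e1 is None or e2 is None:
            log.warning("transcript %s absent from expression results; "
                        "link to %s skipped", row.transcript_id, row.dmr_id)
            continue
        mp = classify_meth_pattern(m1["delta_beta"], m1["q"],
                                   m2["delta_beta"], m2["q"],
                                   min_diff=min_diff, max_q=max_q)
        ep = classify_expr_pattern(e1["fc_signed"], e1["p"],
                                   e2["fc_signed"], e2["p"],
                                   min_fc=min_fc, alpha=alpha)
        pattern = pair_pattern(mp, ep)
        if pattern is None:
            continue
        rho = None
        if sample_betas is not None and sample_expr is not None:
            if (row.dmr_id not in sample_betas.index
                    or row.transcript_id not in sample_expr.index):
                continue
            x = sample_betas.loc[row.dmr_id].to_numpy(dtype=float)
            y = scale_unit_interval(
                sample_expr.loc[row.transcript_id].to_numpy(dtype=float))
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3:
                continue
            rho = spearman_rho(x[ok], y[ok])
            if rho is None or rho >= max_rho:
                continue
        records.append({
            "gene": row.gene, "pattern": pattern,
            "transcript_id": row.transcript_id, "dmr_id": row.dmr_id,
            "delta_beta_1": m1["delta_beta"], "q_1": m1["q"],
            "delta_beta_2": m2["delta_beta"], "q_2": m2["q"],
            "fc_1": e1["fc_signed"], "p_1": e1["p"],
            "fc_2": e2["fc_signed"], "p_2": e2["p"], "rho": rho})
    columns = ["gene", "pattern", "transcript_id", "dmr_id",
               "delta_beta_1", "q_1", "delta_beta_2", "q_2",
               "fc_1", "p_1", "fc_2", "p_2", "rho"]
    df = pd.DataFrame(records, columns=columns)
    return df, summarize_integration(df)


def summarize_integration(records: pd.DataFrame) -> dict:
    """Unique-DMR / unique-gene / per-pattern counts of an integration
    table. A gene counts as Pattern A when any of its links is."""
    a_genes = set(records.loc[records["pattern"] == "A", "gene"])
    b_genes = set(records.loc[records["pattern"] == "B", "gene"])
    hyper = set(records.loc[records["pattern"] == "A", "dmr_id"])
    hypo = set(records.loc[records["pattern"] == "B", "dmr_id"])
    return {
        "n_dmrs_unique": int(records["dmr_id"].nunique()),
        "n_genes": int(records["gene"].nunique()),
        "n_pattern_a": len(a_genes),
        "n_pattern_b": len(b_genes),
        "n_hyper_hypo_dmrs": len(hyper),
        "n_hypo_hyper_dmrs": len(hypo),
        "total": len(hyper) + len(hypo),
    }


def restoration_summary(n_hyper_hypo: int, n_hypo_hyper: int) -> dict:
    """Totals of restoration-pattern DMRs across the two directions."""
    if n_hyper_hypo < 0 or n_hypo_hyper < 0:
        raise ValueError("counts must be non-negative")
    return {"n_hyper_hypo": int(n_hyper_hypo),
            "n_hypo_hyper": int(n_hypo_hyper),
            "total": int(n_hyper_hypo) + int(n_hypo_hyper)}


def count_restoration_dmrs(windows_induction: pd.DataFrame,
                           windows_treatment: pd.DataFrame, *,
                           min_diff: float = 10.0,
                           max_q: float = 0.01) -> dict:
    """Classify every window tested in both contrasts and count the
    hyper/hypo and hypo/hyper restoration DMRs."""
    w1 = _indexed(windows_induction, "id")
    w2 = _indexed(windows_treatment, "id")
    common = w1.index.intersection(w2.index)
    d1 = w1.loc[common, "delta_beta"].to_numpy()
    q1 = w1.loc[common, "q"].to_numpy()
    d2 = w2.loc[common, "delta_beta"].to_numpy()
    q2 = w2.loc[common, "q"].to_numpy()
    sig = (q1 < max_q) & (q2 < max_q)
    hh = sig & (d1 >= min_diff) & (d2 <= -min_diff)
    lh = sig & (d1 <= -min_diff) & (d2 >= min_diff)
    out = restoration_summary(int(hh.sum()), int(lh.sum()))
    out["ids_hyper_hypo"] = list(common[hh])
    out["ids_hypo_hyper"] = list(common[lh])
    return out


def summarize_candidate_table(table: pd.DataFrame, *,
                              min_diff: float = 10.0, max_q: float = 0.01,
                              min_fc: float = 1.0, alpha: float = 0.05
                              ) -> tuple[pd.DataFrame, dict]:
    """Re-classify a candidate table (the packaged worked example) row
    by row and roll up the pattern counts.

    The table carries per-row methylation deltas/p-values and signed
    fold changes/p-values for the two contrasts. The default expression
    rule is direction + significance (``min_fc=1``): the published
    candidates include fold changes with magnitude below 2, so the
    magnitude screen of the genome-wide DEG step does not apply here.
    Per-sample values are not part of the table, so the correlation
    filter is vacuous.
    """
    rows = []
    for row in table.itertuples(index=False):
        mp = classify_meth_pattern(row.delta_beta_1, row.meth_p_1,
                                   row.delta_beta_2, row.meth_p_2,
                                   min_diff=min_diff, max_q=max_q)
        ep = classify_expr_pattern(row.fc_1, row.expr_p_1,
                                   row.fc_2, row.expr_p_2,
                                   min_fc=min_fc, alpha=alpha)
        pattern = pair_pattern(mp, ep)
        if pattern is None:
            continue
        rows.append({"gene": row.gene, "pattern": pattern,
                     "transcript_id": row.transcript_id,
                     "dmr_id": row.dmr_id, "rho": None})
    df = pd.DataFrame(rows, columns=["gene", "pattern", "transcript_id",
                                     "dmr_id", "rho"])
    summary = {
        "n_dmrs_unique": int(df["dmr_id"].nunique()),
        "n_genes": int(df["gene"].nunique()),
        "n_pattern_a": int(df.loc[df["pattern"] == "A", "gene"].nunique()),
        "n_pattern_b": int(df.loc[df["pattern"] == "B", "gene"].nunique()),
    }
    return df, summary


def _indexed(df: pd.DataFrame, col: str) -> pd.DataFrame:
    if df.index.name == col:
        return df
    if col in df.columns:
        return df.set_index(col)
    return df


def _lookup(df: pd.DataFrame, key) -> pd.Series | None:
    try:
        row = df.loc[key]
    except KeyError:
        return None
    if isinstance(row, pd.DataFrame):
        row = row.iloc[0]
    return row
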