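"""Sliding-window differential-methylation calling.

The genome is tiled into overlapping windows (1000 bp, step 500 by
default). For each window the per-sample methylated/unmethylated read
counts of its CpGs are summed and the two groups of a contrast are
compared with a likelihood-ratio test of the binomial proportion on
group membership -- the closed form of a logistic-regression LRT with
group as the only covariate, because the logistic MLE under a single
categorical covariate is the pooled per-group proportion. The chi-square
statistic is scaled by a Pearson overdispersion factor pooled across all
tested windows of the contrast (floored at 1), which keeps the test
calibrated when counts are overdispersed relative to binomial, as
bisulfite data with biological replicates always are.

A window is reported as a DMR when it has at least ``min_cpgs`` covered
CpGs, an absolute pooled methylation difference of at least ``min_diff``
percentage points, and a Benjamini-Hochberg q-value below ``max_q``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .io import SampleSheet, dmr_name

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicWindow:
    """A genome tile in 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"window end {self.end} < start {self.start}")

    @property
    def id(self) -> str:
        return dmr_name(self.chrom, self.start, self.end)


def tile_windows(chrom_lengths: Mapping[str, int], window: int = 1000,
                 step: int = 500) -> list[GenomicWindow]:
    """Tile each chromosome with overlapping windows.

    Windows start at 1, 1+step, 1+2*step, ... and are truncated at the
    chromosome end, so every base is covered by at least one window and
    (away from the edges, with window = 2*step) by exactly two.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    out: list[GenomicWindow] = []
    for chrom, length in chrom_lengths.items():
        if length < 1:
            raise ValueError(f"chromosome {chrom!r} has length {length}")
        for start in range(1, length + 1, step):
            out.append(GenomicWindow(chrom, start, min(start + window - 1,
                                                       length)))
    return out


def align_samples(tables: Mapping[str, pd.DataFrame]
                  ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Align per-sample CpG tables on the union of (chrom, pos).

    A CpG absent from a sample contributes depth 0 there (it will simply
    fail the depth filter); no error is raised.

    Returns
    -------
    sites : DataFrame with chrom, pos for every aligned CpG.
    meth, depth : int arrays of shape (n_cpgs, n_samples), column order
        following the iteration order of ``tables``.
    """
    frames = []
    for sid, df in tables.items():
        sub = df.set_index(["chrom", "pos"])[["meth", "unmeth"]]
        if sub.index.has_duplicates:
            raise ValueError(f"sample {sid!r}: duplicate CpG positions")
        frames.append(sub)
    joined = pd.concat(frames, axis=1, keys=list(tables)).fillna(0)
    joined = joined.sort_index()
    meth = joined.xs("meth", axis=1, level=1).to_numpy(dtype=np.int64)
    unmeth = joined.xs("unmeth", axis=1, level=1).to_numpy(dtype=np.int64)
    sites = joined.index.to_frame(index=False)
    return sites, meth, meth + unmeth


def filter_cpgs(depth: np.ndarray, min_depth: int = 20,
                scope: str = "per_sample") -> np.ndarray:
    """Boolean mask of CpGs passing the read-depth filter.

    ``per_sample`` (default) keeps a CpG only when every sample of the
    contrast reaches ``min_depth``; ``group_mean`` requires the mean
    depth across the given samples to reach it.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if scope == "per_sample":
        return depth.min(axis=1) >= min_depth
    if scope == "group_mean":
        return depth.mean(axis=1) >= min_depth
    raise ValueError(f"unknown depth filter scope {scope!r}")


def _binom_ll(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    # log-likelihood up to the binomial coefficient, safe at p in {0, 1}
    return xlogy(k, p) + xlogy(n - k, 1.0 - p)


def likelihood_ratio_test(ka, na, kb, nb):
    """Pooled two-group binomial LRT.

    Parameters are pooled methylated counts (k) and depths (n) per
    group; scalars or arrays. Returns ``(G, p)`` where G is the
    likelihood-ratio statistic and p its chi-square(1 df) tail
    probability, without any overdispersion scaling.
    """
    ka, na, kb, nb = (np.asarray(x, dtype=float) for x in (ka, na, kb, nb))
    pa = np.divide(ka, na, out=np.zeros_like(ka), where=na > 0)
    pb = np.divide(kb, nb, out=np.zeros_like(kb), where=nb > 0)
    p0 = (ka + kb) / (na + nb)
    g = 2.0 * (_binom_ll(ka, na, pa) + _binom_ll(kb, nb, pb)
               - _binom_ll(ka + kb, na + nb, p0))
    g = np.maximum(g, 0.0)
    return g, stats.chi2.sf(g, df=1)


def _pearson_dispersion(meth: np.ndarray, depth: np.ndarray,
                        group_idx: Sequence[np.ndarray]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-window Pearson X^2 and residual df under the two-group model.

    ``meth``/``depth`` have shape (n_windows, n_samples). Samples with
    zero depth or a degenerate fitted proportion (0 or 1) contribute
    neither to X^2 nor to the df.
    """
    x2 = np.zeros(meth.shape[0])
    n_terms = np.zeros(meth.shape[0])
    n_groups = np.zeros(meth.shape[0])
    for cols in group_idx:
        k = meth[:, cols].astype(float)
        n = depth[:, cols].astype(float)
        ntot = n.sum(axis=1)
        phat = np.divide(k.sum(axis=1), ntot,
                         out=np.zeros(len(ntot)), where=ntot > 0)
        ok = (phat > 0) & (phat < 1)
        var = n * (phat * (1 - phat))[:, None]
        contrib = np.where((n > 0) & ok[:, None],
                           (k - n * phat[:, None]) ** 2
                           / np.where(var > 0, var, 1.0), 0.0)
        x2 += contrib.sum(axis=1)
        n_terms += ((n > 0) & ok[:, None]).sum(axis=1)
        n_groups += ok.astype(float)
    return x2, np.maximum(n_terms - n_groups, 0.0)


def _assign_windows(pos: np.ndarray, window: int, step: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """All (cpg_index, window_start) pairs covering each position."""
    n_cover = -(-window // step)  # ceil
    s0 = (pos - 1) // step * step + 1
    offsets = np.arange(n_cover) * step
    starts = s0[:, None] - offsets[None, :]
    valid = (starts >= 1) & (pos[:, None] <= starts + window - 1)
    cpg_idx = np.repeat(np.arange(len(pos)), n_cover).reshape(len(pos),
                                                              n_cover)
    return cpg_idx[valid], starts[valid]


@dataclass
class DMRCallResult:
    """All tested windows plus the significant subset for one contrast."""

    windows: pd.DataFrame
    dmrs: pd.DataFrame
    dispersion: float = 1.0
    contrast: tuple[str, str] | None = None


def call_dmrs(tables: Mapping[str, pd.DataFrame], sheet: SampleSheet,
              contrast: tuple[str, str], *, window: int = 1000,
              step: int = 500, min_depth: int = 20, min_cpgs: int = 2,
              min_diff: float = 10.0, max_q: float = 0.01,
              depth_scope: str = "per_sample",
              overdispersion: str = "pooled") -> DMRCallResult:
    """Call DMRs for one two-group contrast.

    ``contrast`` is ``(group_a, group_b)``; delta-beta is reported as
    ``100 * (beta_b - beta_a)`` in percentage points, so ``hyper`` means
    group b is more methylated than group a. BH correction runs over all
    tested windows of the contrast; the full window table (with q) is
    retained for downstream pattern analysis.
    """
    group_a, group_b = contrast
    samples_a = sheet.samples_in(group_a)
    samples_b = sheet.samples_in(group_b)
    samples = samples_a + samples_b
    missing = [s for s in samples if s not in tables]
    if missing:
        raise KeyError(f"no CpG table for sample(s) {missing}")

    sites, meth, depth = align_samples({s: tables[s] for s in samples})
    keep = filter_cpgs(depth, min_depth=min_depth, scope=depth_scope)
    sites = sites.loc[keep].reset_index(drop=True)
    meth, depth = meth[keep], depth[keep]
    empty_cols = ["id", "chrom", "start", "end", "n_cpgs", "beta_a",
                  "beta_b", "delta_beta", "p", "q", "direction"]
    if len(sites) == 0:
        log.warning("contrast %s vs %s: no CpGs pass the depth filter",
                    group_b, group_a)
        empty = pd.DataFrame(columns=empty_cols)
        return DMRCallResult(empty, empty.copy(), 1.0, contrast)

    cols_a = np.arange(len(samples_a))
    cols_b = np.arange(len(samples_a), len(samples))

    # aggregate CpG counts into overlapping windows, per chromosome
    win_frames = []
    wmeth_parts, wdepth_parts = [], []
    for chrom, idx in sites.groupby("chrom", sort=True).groups.items():
        idx = np.asarray(idx)
        pos = sites.loc[idx, "pos"].to_numpy()
        cpg_i, win_start = _assign_windows(pos, window, step)
        uniq_starts, inv = np.unique(win_start, return_inverse=True)
        n_win = len(uniq_starts)
        wm = np.zeros((n_win, len(samples)), dtype=np.int64)
        wd = np.zeros_like(wm)
        np.add.at(wm, inv, meth[idx][cpg_i])
        np.add.at(wd, inv, depth[idx][cpg_i])
        n_cpgs = np.bincount(inv, minlength=n_win)
        win_frames.append(pd.DataFrame({
            "chrom": chrom, "start": uniq_starts,
            "end": uniq_starts + window - 1, "n_cpgs": n_cpgs}))
        wmeth_parts.append(wm)
        wdepth_parts.append(wd)

    windows_df = pd.concat(win_frames, ignore_index=True)
    wmeth = np.vstack(wmeth_parts)
    wdepth = np.vstack(wdepth_parts)

    testable = windows_df["n_cpgs"].to_numpy() >= min_cpgs
    da = wdepth[:, cols_a].sum(axis=1)
    db = wdepth[:, cols_b].sum(axis=1)
    zero_depth = testable & ((da == 0) | (db == 0))
    if zero_depth.any():
        log.warning("%d window(s) skipped: zero total depth in one group",
                    int(zero_depth.sum()))
    testable &= ~zero_depth

    windows_df = windows_df.loc[testable].reset_index(drop=True)
    wmeth, wdepth = wmeth[testable], wdepth[testable]
    if len(windows_df) == 0:
        log.warning("contrast %s vs %s: no testable windows",
                    group_b, group_a)
        empty = pd.DataFrame(columns=empty_cols)
        return DMRCallResult(empty, empty.copy(), 1.0, contrast)

    ka = wmeth[:, cols_a].sum(axis=1)
    na = wdepth[:, cols_a].sum(axis=1)
    kb = wmeth[:, cols_b].sum(axis=1)
    nb = wdepth[:, cols_b].sum(axis=1)
    beta_a = ka / na
    beta_b = kb / nb

    if min(len(samples_a), len(samples_b)) == 1:
        # replicate-free groups: Fisher's exact test on the pooled table
        p = np.array([stats.fisher_exact(
            [[int(k1), int(n1 - k1)], [int(k2), int(n2 - k2)]])[1]
            for k1, n1, k2, n2 in zip(ka, na, kb, nb)])
        phi = 1.0
    else:
        g, _ = likelihood_ratio_test(ka, na, kb, nb)
        if overdispersion == "pooled":
            x2, dfree = _pearson_dispersion(wmeth, wdepth, [cols_a, cols_b])
            total_df = dfree.sum()
            phi = max(1.0, x2.sum() / total_df) if total_df > 0 else 1.0
        elif overdispersion == "none":
            phi = 1.0
        else:
            raise ValueError(f"unknown overdispersion mode "
                             f"{overdispersion!r}")
        p = stats.chi2.sf(g / phi, df=1)

    delta = 100.0 * (beta_b - beta_a)
    q = multipletests(p, method="fdr_bh")[1]
    windows_df = windows_df.assign(
        beta_a=beta_a, beta_b=beta_b, delta_beta=delta, p=p, q=q,
        direction=np.select([delta > 0, delta < 0], ["hyper", "hypo"],
                            default="none"))
    windows_df.insert(0, "id", [dmr_name(c, s, e) for c, s, e in zip(
        windows_df["chrom"], windows_df["start"], windows_df["end"])])

    is_dmr = (np.abs(delta) >= min_diff) & (q < max_q)
    dmrs = windows_df.loc[is_dmr].reset_index(drop=True)
    return DMRCallResult(windows_df, dmrs, float(phi), contrast)


def test_window(window: GenomicWindow, tables: Mapping[str, pd.DataFrame],
                groups: tuple[Sequence[str], Sequence[str]], *,
                min_cpgs: int = 2, dispersion: float | None = None
                ) -> dict | None:
    """Test a single window; returns None when it has < ``min_cpgs`` CpGs.

    ``dispersion`` fixes the overdispersion scaling factor; when None it
    is estimated from this window alone (floored at 1), which is noisy
    -- :func:`call_dmrs` pools the estimate over all windows instead.
    """
    samples_a, samples_b = groups
    if not samples_a or not samples_b:
        raise ValueError("both groups must be non-empty")
    samples = list(samples_a) + list(samples_b)
    sites, meth, depth = align_samples({s: tables[s] for s in samples})
    in_win = ((sites["chrom"] == window.chrom)
              & (sites["pos"] >= window.start)
              & (sites["pos"] <= window.end)).to_numpy()
    n_cpgs = int(in_win.sum())
    if n_cpgs < min_cpgs:
        return None
    meth, depth = meth[in_win], depth[in_win]
    cols_a = np.arange(len(samples_a))
    cols_b = np.arange(len(samples_a), len(samples))
    ka, na = meth[:, cols_a].sum(), depth[:, cols_a].sum()
    kb, nb = meth[:, cols_b].sum(), depth[:, cols_b].sum()
    if na == 0 or nb == 0:
        log.warning("window %s skipped: zero depth in one group", window.id)
        return None
    if min(len(samples_a), len(samples_b)) == 1:
        p = stats.fisher_exact([[ka, na - ka], [kb, nb - kb]])[1]
    else:
        g, _ = likelihood_ratio_test(ka, na, kb, nb)
        if dispersion is None:
            wm = meth.sum(axis=0)[None, :]
            wd = depth.sum(axis=0)[None, :]
            x2, dfree = _pearson_dispersion(wm, wd, [cols_a, cols_b])
            dispersion = (max(1.0, float(x2[0] / dfree[0]))
                          if dfree[0] > 0 else 1.0)
        p = float(stats.chi2.sf(g / dispersion, df=1))
    beta_a, beta_b = ka / na, kb / nb
    delta = 100.0 * (beta_b - beta_a)
    return {"window": window, "id": window.id, "n_cpgs": n_cpgs,
            "beta_a": beta_a, "beta_b": beta_b, "delta_beta": delta,
            "p": float(p),
            "direction": "hyper" if delta > 0 else
                         ("hypo" if delta < 0 else "none")}


def window_beta_matrix(tables: Mapping[str, pd.DataFrame],
                       window_ids: Sequence[str], *, window: int = 1000,
                       step: int = 500) -> pd.DataFrame:
    """Per-sample pooled beta for the given windows, across all samples.

    Used by the integration step, which correlates window methylation
    with expression over every sample of the study. Samples with zero
    depth in a window get NaN.
    """
    parsed = []
    for wid in window_ids:
        chrom, start, end = wid.split("$")
        parsed.append((wid, chrom, int(start), int(end)))
    sites, meth, depth = align_samples(dict(tables))
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    out = np.full((len(parsed), meth.shape[1]), np.nan)
    for i, (wid, chrom, start, end) in enumerate(parsed):
        sel = (chroms == chrom) & (pos >= start) & (pos <= end)
        if not sel.any():
            continue
        m = meth[sel].sum(axis=0).astype(float)
        d = depth[sel].sum(axis=0).astype(float)
        out[i] = np.divide(m, d, out=np.full_like(m, np.nan), where=d > 0)
    return pd.DataFrame(out, index=[p[0] for p in parsed],
                        columns=list(tables))


def dmr_summary(n_hyper: int, n_hypo: int, n_total_bins: int
                ) -> tuple[float, float]:
    """Percentages of hyper- and hypo-methylated bins among all tested bins.

    Rounded to two decimals, the precision at which such fractions are
    conventionally reported.
    """
    if n_total_bins <= 0:
        raise ZeroDivisionError("total bin count must be positive")
    if n_hyper + n_hypo > n_total_bins:
        raise ValueError("hyper + hypo DMRs exceed total bins")
    return (round(100.0 * n_hyper / n_total_bins, 2),
            round(100.0 * n_hypo / n_total_bins, 2))
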