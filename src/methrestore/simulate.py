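"""Synthetic three-group methylome + transcriptome datasets with
planted restoration-pattern genes, plus the packaged worked-example
candidate table.

The generator emulates the statistical structure of the study design:
three arms (saline n=3, OVA n=3, DSE n=4), bimodally distributed
background methylation, beta-binomial read counts at per-CpG depths
around 30, and negative-binomial transcript counts. Planted "Pattern A"
genes are hyper-methylated and down-regulated on induction and restored
by treatment; "Pattern B" genes mirror that. Methylation and expression
of a planted gene share group means, which induces the negative
methylation-expression correlation the integration step looks for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .annotate import TranscriptModel
from .io import SampleSheet


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the generator.

    Defaults follow the three-arm design (3/3/4 samples), a toy genome
    of two 2-Mb chromosomes with 10 CpGs/kb, mean read depth 30,
    beta-binomial precision 30 (moderate overdispersion), NB dispersion
    0.1, a 30-percentage-point planted methylation shift and a 4-fold
    planted expression change -- values a bulk bisulfite/RNA-seq study
    of this size would consider realistic.
    """

    n_saline: int = 3
    n_ova: int = 3
    n_dse: int = 4
    genome: tuple[tuple[str, int], ...] = (("chr1", 2_000_000),
                                           ("chr2", 2_000_000))
    n_cpg_per_kb: float = 10.0
    depth_mean: float = 30.0
    baseline_beta: float = 0.4
    planted_a: int = 20
    planted_b: int = 5
    n_null_genes: int = 500
    meth_shift: float = 30.0   # percentage points
    expr_fc: float = 4.0       # linear fold
    nb_dispersion: float = 0.1
    bb_precision: float = 30.0
    expr_mean: float = 200.0   # median of the log-normal baseline
    expr_log_sd: float = 1.0
    window: int = 1000
    step: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_beta < 1:
            raise ValueError("baseline_beta must be in (0, 1)")
        if self.meth_shift < 0:
            raise ValueError("meth_shift must be >= 0")
        for name in ("n_saline", "n_ova", "n_dse", "planted_a",
                     "planted_b", "n_null_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.n_saline, self.n_ova, self.n_dse) < 1:
            raise ValueError("every group needs at least one sample")

    @property
    def sample_ids(self) -> list[str]:
        return ([f"saline_{i + 1}" for i in range(self.n_saline)]
                + [f"OVA_{i + 1}" for i in range(self.n_ova)]
                + [f"DSE_{i + 1}" for i in range(self.n_dse)])

    def sample_sheet(self) -> SampleSheet:
        groups = {}
        for sid in self.sample_ids:
            groups[sid] = sid.rsplit("_", 1)[0]
        return SampleSheet(groups)


def _plant_windows(cfg: SimulationConfig, rng: np.random.Generator
                   ) -> pd.DataFrame:
    """Choose non-overlapping planted windows, round-robin over
    chromosomes, keeping at least one window-length gap between them."""
    n_total = cfg.planted_a + cfg.planted_b
    per_chrom: dict[str, list[int]] = {c: [] for c, _ in cfg.genome}
    rows = []
    chroms = [c for c, _ in cfg.genome]
    lengths = dict(cfg.genome)
    for i in range(n_total):
        chrom = chroms[i % len(chroms)]
        length = lengths[chrom]
        max_k = (length - cfg.window) // (2 * cfg.step) - 1
        for _ in range(1000):
            start = 1 + int(rng.integers(1, max_k)) * 2 * cfg.step
            if all(abs(start - s) >= 2 * cfg.window
                   for s in per_chrom[chrom]):
                per_chrom[chrom].append(start)
                break
        else:  # pragma: no cover - genome far larger than plant count
            raise RuntimeError("could not place planted windows")
        pattern = "A" if i < cfg.planted_a else "B"
        tag = f"{pattern.lower()}{i + 1:03d}"
        rows.append({
            "gene": f"gene_{tag}", "transcript_id": f"tx_{tag}",
            "chrom": chrom, "start": start,
            "end": start + cfg.window - 1,
            "dmr_id": f"{chrom}${start}${start + cfg.window - 1}",
            "pattern": pattern,
            "true_delta_1": (cfg.meth_shift if pattern == "A"
                             else -cfg.meth_shift),
            "true_delta_2": (-cfg.meth_shift if pattern == "A"
                             else cfg.meth_shift),
            "true_fc_1": (-cfg.expr_fc if pattern == "A" else cfg.expr_fc),
            "true_fc_2": (cfg.expr_fc if pattern == "A" else -cfg.expr_fc),
        })
    return pd.DataFrame(rows, columns=[
        "gene", "transcript_id", "chrom", "start", "end", "dmr_id",
        "pattern", "true_delta_1", "true_delta_2", "true_fc_1",
        "true_fc_2"])


def simulate_methylome(cfg: SimulationConfig
                       ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-sample CpG count tables plus the planted-truth table.

    Background per-CpG methylation is a bimodal Beta mixture centred
    near 0.1 and 0.9 (bulk methylomes are bimodal); planted windows sit
    at ``baseline_beta`` (Pattern A) or its mirror (Pattern B) so the
    shift stays inside (0, 1). Group means outside (0.02, 0.98) after
    shifting are clipped. Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = _plant_windows(cfg, rng)

    chrom_names, all_pos = [], []
    for chrom, length in cfg.genome:
        n_cpg = int(length / 1000 * cfg.n_cpg_per_kb)
        pos = np.sort(rng.choice(length, size=n_cpg, replace=False)) + 1
        chrom_names.append(np.repeat(chrom, n_cpg))
        all_pos.append(pos)
    chroms = np.concatenate(chrom_names)
    pos = np.concatenate(all_pos)
    n = len(pos)
    strand = np.where(rng.random(n) < 0.5, "+", "-")

    # background: bimodal mixture, shared across groups
    low = rng.beta(2.0, 18.0, size=n)
    high = rng.beta(18.0, 2.0, size=n)
    mu0 = np.where(rng.random(n) < 0.5, low, high)

    shift = cfg.meth_shift / 100.0
    mu = np.stack([mu0, mu0, mu0], axis=1)  # saline, OVA, DSE
    for row in truth.itertuples(index=False):
        sel = ((chroms == row.chrom) & (pos >= row.start)
               & (pos <= row.end))
        base = np.clip(rng.normal(
            cfg.baseline_beta if row.pattern == "A"
            else 1.0 - cfg.baseline_beta, 0.05, size=int(sel.sum())),
            0.05, 0.95)
        mu[sel, 0] = base
        mu[sel, 2] = base
        mu[sel, 1] = base + (shift if row.pattern == "A" else -shift)
    clipped = (mu < 0.02) | (mu > 0.98)
    if clipped.any():
        mu = np.clip(mu, 0.02, 0.98)

    group_of = {"saline": 0, "OVA": 1, "DSE": 2}
    tables: dict[str, pd.DataFrame] = {}
    prec = cfg.bb_precision
    for sid in cfg.sample_ids:
        g = group_of[sid.rsplit("_", 1)[0]]
        depth = rng.poisson(cfg.depth_mean, size=n)
        m = np.clip(mu[:, g], 1e-4, 1 - 1e-4)
        p = rng.beta(m * prec, (1.0 - m) * prec)
        meth = rng.binomial(depth, p)
        tables[sid] = pd.DataFrame({
            "chrom": chroms, "pos": pos, "strand": strand,
            "meth": meth, "unmeth": depth - meth})
    return tables, truth


def simulate_counts(cfg: SimulationConfig, truth: pd.DataFrame
                    ) -> tuple[pd.DataFrame, list[TranscriptModel]]:
    """NB count matrix plus transcript models linking planted genes'
    promoters to their planted windows.

    A fresh generator seeded with ``cfg.seed + 1`` keeps the count draw
    independent of (but reproducible alongside) the methylome draw.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    lengths = dict(cfg.genome)
    planted = truth.reset_index(drop=True)

    gene_rows = []
    models: list[TranscriptModel] = []
    occupied: dict[str, list[int]] = {c: [] for c in lengths}
    for row in planted.itertuples(index=False):
        tss = row.start + cfg.window // 2  # promoter covers the window
        exons = ((tss, min(tss + 2000, lengths[row.chrom])),)
        models.append(TranscriptModel(
            row.transcript_id, row.gene, row.chrom, "+", exons,
            (exons[0][0] + 200, exons[0][1] - 300)))
        occupied[row.chrom].append(row.start)
        gene_rows.append((row.transcript_id, row.gene, row.pattern))
    chroms = list(lengths)
    for i in range(cfg.n_null_genes):
        chrom = chroms[i % len(chroms)]
        length = lengths[chrom]
        for _ in range(1000):
            tss = int(rng.integers(5000, length - 5000))
            if all(abs(tss - s) > 3 * cfg.window
                   for s in occupied[chrom]):
                break
        tag = f"null{i + 1:04d}"
        exons = ((tss, min(tss + 2000, length)),)
        models.append(TranscriptModel(
            f"tx_{tag}", f"gene_{tag}", chrom, "+", exons,
            (exons[0][0] + 200, exons[0][1] - 300)))
        gene_rows.append((f"tx_{tag}", f"gene_{tag}", None))

    n_genes = len(gene_rows)
    base = rng.lognormal(np.log(cfg.expr_mean), cfg.expr_log_sd,
                         size=n_genes)
    mean = np.stack([base, base, base], axis=1)  # saline, OVA, DSE
    for i, (_, _, pattern) in enumerate(gene_rows):
        if pattern == "A":
            mean[i, 1] = base[i] / cfg.expr_fc
        elif pattern == "B":
            mean[i, 1] = base[i] * cfg.expr_fc

    group_of = {"saline": 0, "OVA": 1, "DSE": 2}
    phi = cfg.nb_dispersion
    data = {}
    for sid in cfg.sample_ids:
        g = group_of[sid.rsplit("_", 1)[0]]
        lam = mean[:, g]
        if phi > 0:
            lam = rng.gamma(1.0 / phi, lam * phi)
        data[sid] = rng.poisson(lam)
    counts = pd.DataFrame(data, index=pd.Index(
        [t for t, _, _ in gene_rows], name="transcript_id"))
    counts.insert(0, "gene", [g for _, g, _ in gene_rows])
    return counts, models


def simulate_dataset(cfg: SimulationConfig):
    """Convenience wrapper returning (tables, counts, models, truth,
    sample sheet) for a full pipeline run."""
    tables, truth = simulate_methylome(cfg)
    counts, models = simulate_counts(cfg, truth)
    return tables, counts, models, truth, cfg.sample_sheet()


def table1_fixture() -> pd.DataFrame:
    """The packaged worked-example candidate table.

    27 rows of (gene, published pattern, transcript, DMR position,
    per-contrast methylation delta-beta and p-value, per-contrast
    signed fold change and p-value); 25 unique DMR positions over 18
    genes. Values are as printed in the source study's candidate table.
    """
    path = resources.files("methrestore").joinpath("data/table1.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")
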