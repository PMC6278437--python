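"""Genomic-feature classification and DMR-to-transcript linking.

Each region is assigned exactly one of six feature classes --
promoter, 5' UTR, 3' UTR, CDS, intron, intergenic -- by a fixed
precedence over all transcripts it overlaps. The promoter is TSS
+/- 1000 bp by default (the usual tiling-annotation convention; the
span is configurable). Non-coding transcripts have no CDS; their
exonic intervals rank at the 3'-UTR level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

#: Highest to lowest precedence; anything unmatched is intergenic.
FEATURE_PRECEDENCE = ("promoter", "utr5", "utr3", "cds", "intron")


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exon structure, optional CDS, strand-aware TSS.

    Coordinates are 1-based inclusive. Exons must be sorted and
    non-overlapping.
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/-, got {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        prev_end = 0
        for start, end in self.exons:
            if start <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            if end < start:
                raise ValueError("exon end before start")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site respecting strand (5' end)."""
        return self.span[0] if self.strand == "+" else self.span[1]

    def promoter(self, flank: int = 1000) -> tuple[int, int]:
        return max(1, self.tss - flank), self.tss + flank

    def feature_intervals(self, promoter_flank: int = 1000
                          ) -> dict[str, list[tuple[int, int]]]:
        """1-based inclusive intervals per feature class."""
        out: dict[str, list[tuple[int, int]]] = {
            f: [] for f in FEATURE_PRECEDENCE}
        out["promoter"].append(self.promoter(promoter_flank))
        if self.cds is None:
            out["utr3"].extend(self.exons)
        else:
            cs, ce = self.cds
            for es, ee in self.exons:
                left = (es, min(ee, cs - 1)) if es < cs else None
                right = (max(es, ce + 1), ee) if ee > ce else None
                mid = (max(es, cs), min(ee, ce))
                if mid[0] <= mid[1]:
                    out["cds"].append(mid)
                upstream, downstream = ("utr5", "utr3") \
                    if self.strand == "+" else ("utr3", "utr5")
                if left and left[0] <= left[1]:
                    out[upstream].append(left)
                if right and right[0] <= right[1]:
                    out[downstream].append(right)
        for (_, prev_end), (next_start, _) in zip(self.exons,
                                                  self.exons[1:]):
            if next_start - prev_end > 1:
                out["intron"].append((prev_end + 1, next_start - 1))
        return out


class FeatureIndex:
    """Interval-tree index over transcript models for fast annotation."""

    def __init__(self, models: Iterable[TranscriptModel],
                 promoter_flank: int = 1000) -> None:
        self.models = list(models)
        self.promoter_flank = promoter_flank
        self._trees: dict[str, dict[str, IntervalTree]] = {}
        self._body: dict[str, IntervalTree] = {}
        for tm in self.models:
            trees = self._trees.setdefault(
                tm.chrom, {f: IntervalTree() for f in FEATURE_PRECEDENCE})
            for feat, ivs in tm.feature_intervals(promoter_flank).items():
                for start, end in ivs:
                    trees[feat].addi(start, end + 1)
            body = self._body.setdefault(tm.chrom, IntervalTree())
            ps, pe = tm.promoter(promoter_flank)
            s, e = tm.span
            body.addi(min(ps, s), max(pe, e) + 1, tm)

    def classify(self, chrom: str, start: int, end: int) -> str:
        trees = self._trees.get(chrom)
        if trees is None:
            return "intergenic"
        for feat in FEATURE_PRECEDENCE:
            if trees[feat].overlap(start, end + 1):
                return feat
        return "intergenic"

    def link(self, chrom: str, start: int, end: int,
             max_distance: int = 10_000) -> list[tuple[str, str]]:
        """Transcripts linked to a region.

        All transcripts whose promoter or body overlaps the region are
        returned (distance 0); otherwise the nearest-TSS transcripts
        within ``max_distance`` (ties all returned). Sorted by distance
        then transcript id.
        """
        if max_distance < 0:
            raise ValueError("max_distance must be >= 0")
        body = self._body.get(chrom)
        if body is None:
            return []
        hits = body.overlap(start, end + 1)
        if hits:
            pairs = sorted({(iv.data.transcript_id, iv.data.gene)
                            for iv in hits})
            return pairs
        best: list[tuple[str, str]] = []
        best_d = max_distance + 1
        for tm in self.models:
            if tm.chrom != chrom:
                continue
            tss = tm.tss
            d = 0 if start <= tss <= end else min(abs(tss - start),
                                                  abs(tss - end))
            if d < best_d:
                best_d = d
                best = [(tm.transcript_id, tm.gene)]
            elif d == best_d:
                best.append((tm.transcript_id, tm.gene))
        if best_d > max_distance:
            return []
        return sorted(set(best))


def classify_region(region, models, promoter_flank: int = 1000) -> str:
    """Feature class of a region (``GenomicWindow`` or (chrom,start,end))."""
    index = models if isinstance(models, FeatureIndex) \
        else FeatureIndex(models, promoter_flank)
    chrom, start, end = _region_coords(region)
    return index.classify(chrom, start, end)


def link_transcripts(region, models, max_distance: int = 10_000,
                     promoter_flank: int = 1000) -> list[tuple[str, str]]:
    """(transcript_id, gene) pairs linked to a region; see
    :meth:`FeatureIndex.link`."""
    index = models if isinstance(models, FeatureIndex) \
        else FeatureIndex(models, promoter_flank)
    chrom, start, end = _region_coords(region)
    return index.link(chrom, start, end, max_distance)


def _region_coords(region) -> tuple[str, int, int]:
    if hasattr(region, "chrom"):
        return region.chrom, region.start, region.end
    chrom, start, end = region
    return chrom, int(start), int(end)


def read_bed12(path) -> list[TranscriptModel]:
    """Read transcript models from BED12.

    The name field may be ``transcript_id|gene``; a bare name is used
    for both. thickStart == thickEnd marks a non-coding transcript.
    """
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if (not stripped or stripped.startswith("#")
                    or stripped.startswith(("track", "browser"))):
                continue
            f = stripped.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: line {lineno}: BED12 needs 12 "
                                 f"columns, got {len(f)}")
            chrom, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (chrom_start + off + 1, chrom_start + off + size)
                for off, size in zip(offsets, sizes))
            cds = None if thick_start == thick_end \
                else (thick_start + 1, thick_end)
            tid, _, gene = name.partition("|")
            models.append(TranscriptModel(tid, gene or tid, chrom, strand,
                                          exons, cds))
    return models


def write_bed12(models: Sequence[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for tm in models:
            s, e = tm.span
            # an empty thick interval (start == end) marks non-coding
            thick_start = tm.cds[0] - 1 if tm.cds else s - 1
            thick_end = tm.cds[1] if tm.cds else s - 1
            sizes = ",".join(str(ee - es + 1) for es, ee in tm.exons)
            offsets = ",".join(str(es - s) for es, _ in tm.exons)
            fh.write("\t".join(map(str, [
                tm.chrom, s - 1, e, f"{tm.transcript_id}|{tm.gene}", 0,
                tm.strand, thick_start, thick_end, "0,0,0",
                len(tm.exons), sizes, offsets])) + "\n")


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path) -> list[TranscriptModel]:
    """Read transcript models from a minimal GTF (exon and CDS features,
    gene_id/transcript_id attributes; gene_name preferred for the symbol)."""
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, feature, start, end, _, strand = f[:7]
            if feature not in ("exon", "CDS"):
                continue
            attrs = dict(_GTF_ATTR.findall(f[8]))
            tid = attrs.get("transcript_id")
            if tid is None:
                continue
            gene = attrs.get("gene_name") or attrs.get("gene_id") or tid
            meta[tid] = (gene, chrom, strand)
            target = exons if feature == "exon" else cds
            target.setdefault(tid, []).append((int(start), int(end)))
    models = []
    for tid, (gene, chrom, strand) in meta.items():
        ex = tuple(sorted(exons.get(tid, [])))
        if not ex:
            continue
        cds_iv = None
        if tid in cds:
            parts = cds[tid]
            cds_iv = (min(s for s, _ in parts), max(e for _, e in parts))
        models.append(TranscriptModel(tid, gene, chrom, strand, ex, cds_iv))
    return models
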