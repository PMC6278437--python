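"""Tabular I/O for the pipeline's standard formats.

Reads and writes per-CpG methylation count tables (Bismark
cytosine-report-like TSV), two-column sample sheets, transcript count
matrices, and DMR output as BED6 plus an extended TSV. Coordinates in
memory are 1-based inclusive throughout; only BED output uses the
standard 0-based half-open convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

CPG_COLUMNS = ("chrom", "pos", "strand", "meth", "unmeth")

#: Treatment arms of the three-condition design, in contrast order.
GROUPS = ("saline", "OVA", "DSE")


class ParseError(ValueError):
    """A malformed row in an input table (message names the line number)."""


@dataclass(frozen=True)
class SampleSheet:
    """Sample -> treatment-group assignment.

    Parameters
    ----------
    groups
        Mapping from sample id to group label (e.g. ``saline``, ``OVA``,
        ``DSE``). Sample ids are unique by construction of the mapping;
        every group must have at least one sample.
    """

    groups: dict[str, str]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("sample sheet is empty")

    @property
    def samples(self) -> list[str]:
        return list(self.groups)

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups.values():
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in(self, group: str) -> list[str]:
        out = [s for s, g in self.groups.items() if g == group]
        if not out:
            raise KeyError(f"group {group!r} not present in sample sheet")
        return out


def _looks_like_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


def read_cpg_table(path, sample_id: str | None = None,
                   destrand: bool = False) -> pd.DataFrame:
    """Read a per-CpG methylation count table.

    Expected layout: whitespace- or tab-delimited columns
    ``chrom pos strand meth unmeth`` (extra columns ignored), with or
    without a header row (detected by sniffing whether the second field
    of the first row is an integer). Lines starting with ``#`` and blank
    lines are skipped.

    Parameters
    ----------
    path
        Input file.
    sample_id
        Optional sample label stored in ``DataFrame.attrs['sample_id']``.
    destrand
        If True, merge minus-strand cytosines onto the plus-strand
        position of the CpG dyad (position - 1) and sum counts. Off by
        default: counts are used per reported cytosine.

    Returns
    -------
    DataFrame with columns chrom, pos, strand, meth, unmeth, sorted by
    (chrom, pos). Empty input yields an empty frame, not an error.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 5:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=5 columns, "
                    f"got {len(tokens)}")
            if lineno == 1 or not rows:
                # header sniff: a non-integer position field means header
                if not _looks_like_int(tokens[1]):
                    continue
            try:
                pos = int(tokens[1])
                meth = int(tokens[3])
                unmeth = int(tokens[4])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer count/position "
                    f"field: {exc}") from exc
            if meth < 0 or unmeth < 0:
                raise ParseError(
                    f"{path}: line {lineno}: negative read count "
                    f"(meth={meth}, unmeth={unmeth})")
            strand = tokens[2]
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}: line {lineno}: strand must be '+' or '-', "
                    f"got {strand!r}")
            rows.append((tokens[0], pos, strand, meth, unmeth))

    df = pd.DataFrame(rows, columns=list(CPG_COLUMNS))
    if df.empty:
        df = df.astype({"pos": int, "meth": int, "unmeth": int})
    if destrand and not df.empty:
        minus = df["strand"] == "-"
        df.loc[minus, "pos"] = df.loc[minus, "pos"] - 1
        df = (df.groupby(["chrom", "pos"], as_index=False)
                .agg(strand=("strand", lambda s: "+"),
                     meth=("meth", "sum"), unmeth=("unmeth", "sum")))
        df = df[list(CPG_COLUMNS)]
    df = df.sort_values(["chrom", "pos"], kind="mergesort",
                        ignore_index=True)
    if sample_id is not None:
        df.attrs["sample_id"] = sample_id
    return df


def write_cpg_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=list(CPG_COLUMNS))


def read_sample_sheet(path) -> SampleSheet:
    """Read a two-column (sample_id, group) TSV into a :class:`SampleSheet`."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns")
            sid, group = tokens[0], tokens[1]
            if lineno == 1 and (sid.lower(), group.lower()) == (
                    "sample_id", "group"):
                continue
            if sid in groups:
                raise ParseError(
                    f"{path}: line {lineno}: duplicate sample id {sid!r}")
            groups[sid] = group
    return SampleSheet(groups)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, group in sheet.groups.items():
            fh.write(f"{sid}\t{group}\n")


def read_count_matrix(path) -> pd.DataFrame:
    """Read a transcript count matrix TSV.

    First column is the transcript id (index); an optional ``gene``
    column carries the symbol; remaining columns are per-sample counts.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    sample_cols = [c for c in df.columns if c != "gene"]
    if (df[sample_cols] < 0).any().any():
        raise ParseError(f"{path}: negative counts in matrix")
    return df


def write_count_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="transcript_id")


def dmr_name(chrom: str, start: int, end: int) -> str:
    """1-based inclusive ``chr$start$end`` region identifier."""
    return f"{chrom}${start}${end}"


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """Write DMRs as BED6.

    The name field keeps the 1-based inclusive ``chr$start$end``
    identifier; start/end follow the BED 0-based half-open convention.
    Score is round(|delta-beta| * 10) clamped to [0, 1000].
    """
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for row in dmrs.itertuples():
            score = min(1000, int(round(abs(row.delta_beta) * 10)))
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t"
                     f"{dmr_name(row.chrom, row.start, row.end)}\t"
                     f"{score}\t.\n")


def read_dmr_bed(path) -> pd.DataFrame:
    """Read a BED6 DMR file back to 1-based inclusive coordinates."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split("\t")
            if len(tokens) < 4:
                raise ParseError(f"{path}: line {lineno}: short BED line")
            rows.append((tokens[0], int(tokens[1]) + 1, int(tokens[2]),
                         tokens[3]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_window_table(windows: pd.DataFrame, path) -> None:
    """Write the per-contrast all-windows (or DMR-only) extended TSV."""
    windows.to_csv(path, sep="\t", index=False)


def read_window_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
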