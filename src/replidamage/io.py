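"""Plain-text genomic file I/O: chrom.sizes, BED, bedGraph.

All coordinates are 0-based, half-open.  Binned tracks are written as
bedGraph with a leading ``#`` metadata line recording bin width, step and
units, so that sliding-window tracks (whose records overlap) survive a
round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReadSet",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_reads_bed",
    "write_reads_bed",
    "read_bed_intervals",
    "write_bed_intervals",
    "read_bedgraph",
    "write_bedgraph",
]


@dataclass
class ReadSet:
    """Aligned-read intervals for one sequencing sample.

    ``records`` is a list of ``(chrom, start, end, strand)`` with 0-based
    half-open coordinates, one record per mapped read (or extended
    fragment).  This is the unit consumed by the coverage module.
    """

    records: list[tuple[str, int, int, str]]
    condition_label: str = ""

    def __post_init__(self) -> None:
        for chrom, start, end, strand in self.records[:1000]:
            if start >= end:
                raise ValueError(
                    f"read on {chrom} has start {start} >= end {end}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) integer arrays, in record order."""
        out: dict[str, list[list[int]]] = {}
        for chrom, start, end, _ in self.records:
            out.setdefault(chrom, [[], []])
            out[chrom][0].append(start)
            out[chrom][1].append(end)
        return {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in out.items()
        }


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``name<TAB>length`` chromosome sizes file."""
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, length = line.split("\t")[:2]
        sizes[name] = int(length)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_reads_bed(path: str | Path, condition_label: str = "") -> ReadSet:
    """Read aligned reads from BED3+ (strand taken from column 6 if present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    strands = df[5] if df.shape[1] >= 6 else pd.Series(["+"] * len(df))
    records = [
        (str(c), int(s), int(e), str(st))
        for c, s, e, st in zip(df[0], df[1], df[2], strands)
    ]
    label = condition_label or Path(path).stem
    return ReadSet(records=records, condition_label=label)


def write_reads_bed(reads: ReadSet, path: str | Path) -> None:
    """Write a ReadSet as BED6 (name ``.``, score 0)."""
    with open(path, "w") as fh:
        for chrom, start, end, strand in reads.records:
            fh.write(f"{chrom}\t{start}\t{end}\t.\t0\t{strand}\n")


def read_bed_intervals(
    path: str | Path,
) -> list[tuple[str, int, int, str]]:
    """Read BED intervals as ``(chrom, start, end, name)`` tuples.

    The name column (4th) is returned verbatim, or ``"."`` when absent;
    used for timing-domain classes (early/late) and gene spans.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = df[3] if df.shape[1] >= 4 else pd.Series(["."] * len(df))
    return [
        (str(c), int(s), int(e), str(n))
        for c, s, e, n in zip(df[0], df[1], df[2], names)
    ]


def write_bed_intervals(
    intervals: Iterable[Sequence],
    path: str | Path,
) -> None:
    """Write ``(chrom, start, end[, name[, score[, strand]]])`` rows as BED."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_bedgraph(
    path: str | Path,
    chroms: Sequence[str],
    starts: Sequence[int],
    ends: Sequence[int],
    values: Sequence[float],
    *,
    bin_width: int | None = None,
    step: int | None = None,
    units: str | None = None,
) -> None:
    """Write a bedGraph; bin metadata goes into a leading ``#`` line."""
    with open(path, "w") as fh:
        if bin_width is not None:
            fh.write(
                f"# replidamage bedgraph bin_width={bin_width} "
                f"step={step} units={units}\n"
            )
        for c, s, e, v in zip(chroms, starts, ends, values):
            fh.write(f"{c}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph into a DataFrame (chrom, start, end, value).

    Any ``# replidamage bedgraph`` metadata line is parsed into
    ``df.attrs`` (keys ``bin_width``, ``step``, ``units``).
    """
    attrs: dict = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# replidamage bedgraph"):
        for token in first.split()[3:]:
            key, _, val = token.partition("=")
            attrs[key] = val if key == "units" else int(val)
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    df.attrs.update(attrs)
    return df
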