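"""Shared tabular containers: samples and the per-variant count table."""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd

CONDITIONS = ("DMSO", "cisplatin", "olaparib")
REPLICATES = (1, 2)

#: Row id for unedited reference reads.
WT_ROW = "WT"
#: Prefix for per-(size, offset) indel pseudo-keys, e.g. ``indel:-1@0``.
INDEL_PREFIX = "indel:"


class Sample(NamedTuple):
    day: int          # 3 or 14
    condition: str    # "pre" at day 3; DMSO/cisplatin/olaparib at day 14
    replicate: int

    @property
    def name(self) -> str:
        return f"d{self.day}_{self.condition}_r{self.replicate}"


def sample_name(day: int, condition: str, replicate: int) -> str:
    return Sample(day, condition, replicate).name


def parse_sample(name: str) -> Sample:
    day, cond, rep = name.split("_")
    return Sample(int(day[1:]), cond, int(rep[1:]))


def all_samples() -> list[Sample]:
    """The standard 8-sample layout: day-3 pre-selection plus three day-14 arms."""
    out = [Sample(3, "pre", r) for r in REPLICATES]
    out += [Sample(14, c, r) for c in CONDITIONS for r in REPLICATES]
    return out


def indel_row(size: int, offset: int) -> str:
    return f"{INDEL_PREFIX}{size:+d}@{offset:+d}"


def parse_indel_row(row: str) -> tuple[int, int]:
    size, offset = row[len(INDEL_PREFIX):].split("@")
    return int(size), int(offset)


def is_variant_row(row: str) -> bool:
    return row.startswith("c.")


@dataclass
class CountTable:
    """Integer read counts by variant (rows) and sample (columns).

    Rows are HGVS ``c.`` keys for HDR-gated library variants (including the
    marker-only ``c.=`` allele), plus the ``WT`` pseudo-row and per-(size,
    offset) ``indel:`` pseudo-rows.  ``totals`` holds the per-sample number
    of aligned reads, which may exceed the column sums because reads
    rejected during classification still count toward the library depth.
    """

    counts: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.fillna(0).astype(int)
        self.totals = self.totals.astype(int).reindex(self.counts.columns)
        if (self.counts < 0).any().any():
            raise ValueError("negative counts")
        short = self.totals < self.counts.sum(axis=0)
        # Totals must cover at least the classified reads.
        if short.any():
            raise ValueError(
                f"totals below classified-read sums for {list(self.totals.index[short])}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def variant_rows(self) -> list[str]:
        return [r for r in self.counts.index if is_variant_row(r)]

    def indel_rows(self) -> list[str]:
        return [r for r in self.counts.index if r.startswith(INDEL_PREFIX)]

    # -- IO -----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        df = self.counts.copy()
        df.loc["__total__"] = self.totals
        df.index.name = "variant"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "__total__" not in df.index:
            raise ValueError("count TSV lacks the __total__ row")
        totals = df.loc["__total__"]
        counts = df.drop(index="__total__")
        return cls(counts, totals)

    def to_string(self) -> str:
        buf = io.StringIO()
        self.to_tsv(buf)
        return buf.getvalue()


def concat_counts(tables: Iterable[CountTable]) -> CountTable:
    """Column-wise concatenation of per-sample count tables."""
    tables = list(tables)
    counts = pd.concat([t.counts for t in tables], axis=1).fillna(0)
    totals = pd.concat([t.totals for t in tables])
    return CountTable(counts, totals)
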