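"""Insertion-site reading, deduplication, and per-gene orientation counts.

The counted unit throughout the pipeline is the *unique* gene-trap insertion:
a distinct (chromosome, position, cassette strand) triple within one sample
library. An insertion whose cassette strand equals the host gene's strand is
a *sense* (disruptive) integration; the opposite orientation is *antisense*
(largely neutral). The per-gene, per-sample sense/antisense counts are the
sufficient statistic for every downstream test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import STRANDS, RegionIndex

__all__ = [
    "Insertion",
    "InsertionParseError",
    "GeneCountTable",
    "read_insertions",
    "write_insertions",
    "deduplicate",
    "assign_and_count",
]

logger = logging.getLogger(__name__)


class InsertionParseError(ValueError):
    """Malformed insertion-site input."""


@dataclass(frozen=True, order=True)
class Insertion:
    """A gene-trap integration site: 0-based position and cassette strand."""

    chrom: str
    pos: int
    strand: str
    sample: str

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"insertion position must be >= 0, got {self.pos}")
        if self.strand not in STRANDS:
            raise ValueError(f"insertion strand must be '+' or '-', got {self.strand!r}")


def read_insertions(path: str | Path, sample: str | None = None) -> list[Insertion]:
    """Read a BED-like insertion file: chrom, pos, pos+1, strand[, sample].

    The sample label defaults to the file stem when the file carries no fifth
    column and no ``sample`` override is given.
    """
    path = Path(path)
    default_sample = sample if sample is not None else path.stem
    out: list[Insertion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise InsertionParseError(
                    f"{path}:{lineno}: expected >= 4 tab-separated columns"
                )
            chrom, pos_s, _end, strand = fields[:4]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise InsertionParseError(
                    f"{path}:{lineno}: non-integer position {pos_s!r}"
                ) from exc
            if strand not in STRANDS:
                raise InsertionParseError(
                    f"{path}:{lineno}: bad strand {strand!r}"
                )
            smp = fields[4] if len(fields) > 4 and sample is None else default_sample
            out.append(Insertion(chrom, pos, strand, smp))
    return out


def write_insertions(insertions: Iterable[Insertion], path: str | Path) -> None:
    """Write insertions in the same BED-like dialect ``read_insertions`` reads."""
    with open(path, "w") as fh:
        for ins in insertions:
            fh.write(f"{ins.chrom}\t{ins.pos}\t{ins.pos + 1}\t{ins.strand}\t{ins.sample}\n")


def deduplicate(insertions: Sequence[Insertion]) -> list[Insertion]:
    """Collapse to unique (chrom, pos, strand, sample) in deterministic order."""
    return sorted(set(insertions))


@dataclass
class GeneCountTable:
    """Per-gene, per-sample unique sense/antisense insertion counts.

    ``counts``: DataFrame with columns gene_id, sample, sense, antisense.
    ``totals``: DataFrame indexed by sample with columns total_sense,
    total_antisense, total_unassigned; the totals satisfy
    sum_genes(sense + antisense) + total_unassigned == unique insertions
    per sample.
    """

    counts: pd.DataFrame
    totals: pd.DataFrame

    def __post_init__(self):
        self.counts = self.counts.reset_index(drop=True)
        for col in ("sense", "antisense"):
            if (self.counts[col] < 0).any():
                raise ValueError(f"negative {col} count")
        self.counts = self.counts.sort_values(["sample", "gene_id"]).reset_index(
            drop=True
        )

    @property
    def samples(self) -> list[str]:
        return list(self.totals.index)

    def sample_counts(self, sample: str) -> pd.DataFrame:
        """Counts for one sample, indexed by gene_id."""
        sub = self.counts[self.counts["sample"] == sample]
        return sub.set_index("gene_id")[["sense", "antisense"]]

    def pooled(self, samples: Sequence[str] | None = None, label: str = "pooled") -> "GeneCountTable":
        """Sum counts over the given samples (default: all) into one sample."""
        if samples is None:
            samples = self.samples
        sub = self.counts[self.counts["sample"].isin(samples)]
        agg = (
            sub.groupby("gene_id", as_index=False)[["sense", "antisense"]]
            .sum()
            .assign(sample=label)
        )
        tot = self.totals.loc[list(samples)].sum()
        totals = pd.DataFrame([tot], index=pd.Index([label], name="sample"))
        return GeneCountTable(agg[["gene_id", "sample", "sense", "antisense"]], totals)

    def to_tsv(self, path: str | Path) -> None:
        """TSV export with per-sample totals in a commented header block."""
        with open(path, "w") as fh:
            for sample, row in self.totals.iterrows():
                fh.write(
                    f"# totals\t{sample}\t{int(row['total_sense'])}"
                    f"\t{int(row['total_antisense'])}\t{int(row['total_unassigned'])}\n"
                )
            self.counts.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneCountTable":
        """Read a table written by :meth:`to_tsv` or a pre-tabulated
        gene/sample/sense/antisense TSV (totals then derived from the body)."""
        totals_rows = {}
        with open(path) as fh:
            body_start = 0
            for line in fh:
                if line.startswith("# totals\t"):
                    _, sample, ts, ta, tu = line.rstrip("\n").split("\t")
                    totals_rows[sample] = {
                        "total_sense": int(ts),
                        "total_antisense": int(ta),
                        "total_unassigned": int(tu),
                    }
                    body_start += 1
                else:
                    break
        counts = pd.read_csv(path, sep="\t", skiprows=body_start)
        required = {"gene_id", "sample", "sense", "antisense"}
        if not required.issubset(counts.columns):
            raise InsertionParseError(
                f"count table must have columns {sorted(required)}"
            )
        if not totals_rows:
            agg = counts.groupby("sample")[["sense", "antisense"]].sum()
            totals = agg.rename(
                columns={"sense": "total_sense", "antisense": "total_antisense"}
            )
            totals["total_unassigned"] = 0
        else:
            totals = pd.DataFrame.from_dict(totals_rows, orient="index")
            totals.index.name = "sample"
        return cls(counts[["gene_id", "sample", "sense", "antisense"]], totals)


def assign_and_count(
    insertions: Sequence[Insertion], index: RegionIndex
) -> GeneCountTable:
    """Assign unique insertions to indexed gene regions and tabulate counts.

    An insertion whose position falls in a region increments that gene's sense
    count when the cassette strand equals the gene strand, antisense
    otherwise. Insertions outside every region (including on chromosomes
    absent from the index) count as unassigned.
    """
    unassigned: dict[str, int] = {}
    known_chroms = index.chroms
    missing_logged: set[str] = set()

    df = pd.DataFrame(
        {
            "chrom": [i.chrom for i in insertions],
            "pos": np.array([i.pos for i in insertions], dtype=np.int64),
            "strand": [i.strand for i in insertions],
            "sample": [i.sample for i in insertions],
        }
    )
    # uniqueness at the (chrom, pos, strand, sample) level, as for deduplicate()
    df = df.drop_duplicates().reset_index(drop=True)
    if df.empty:
        counts = pd.DataFrame(columns=["gene_id", "sample", "sense", "antisense"])
        totals = pd.DataFrame(
            columns=["total_sense", "total_antisense", "total_unassigned"]
        )
        totals.index.name = "sample"
        return GeneCountTable(counts, totals)

    for sample in sorted(df["sample"].unique()):
        unassigned.setdefault(sample, 0)

    parts = []
    for chrom, sub in df.groupby("chrom", sort=True):
        if chrom not in known_chroms and chrom not in missing_logged:
            logger.warning("chromosome %s absent from region index", chrom)
            missing_logged.add(chrom)
        gene, gstrand = index.assign(chrom, sub["pos"].to_numpy())
        sub = sub.assign(gene_id=gene, gene_strand=gstrand)
        parts.append(sub)
    assigned = pd.concat(parts, ignore_index=True)
    miss = assigned["gene_id"].isna()
    for sample, n in assigned.loc[miss, "sample"].value_counts().items():
        unassigned[sample] += int(n)
    hit = assigned[~miss].copy()
    hit["orient"] = np.where(hit["strand"] == hit["gene_strand"], "sense", "antisense")
    tab = (
        hit.groupby(["gene_id", "sample", "orient"], sort=True)
        .size()
        .unstack("orient", fill_value=0)
        .reset_index()
    )
    for col in ("sense", "antisense"):
        if col not in tab.columns:
            tab[col] = 0
    counts = tab[["gene_id", "sample", "sense", "antisense"]]

    totals = (
        counts.groupby("sample")[["sense", "antisense"]]
        .sum()
        .rename(columns={"sense": "total_sense", "antisense": "total_antisense"})
    )
    totals = totals.reindex(sorted(unassigned), fill_value=0)
    totals["total_unassigned"] = pd.Series(unassigned)
    totals.index.name = "sample"
    return GeneCountTable(counts, totals.astype(int))
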