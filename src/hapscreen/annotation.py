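"""Gene annotation parsing and the non-overlapping region index.

Gene-trap insertions are assigned to protein-coding gene bodies. To make each
assignment unambiguous, overlapping annotation is resolved into a set of
non-overlapping regions before any counting: under the default policy, every
base covered by two or more genes is removed from the index entirely, so each
indexed base maps to exactly one gene.

Coordinates are 0-based half-open (BED convention) everywhere. The gene body
is the union of the transcript spans, introns included, because gene-trap
integrations are predominantly intronic; an exon-only mode is available for
the BED12 and refFlat readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeneModel",
    "RegionIndex",
    "AnnotationError",
    "read_annotation",
    "build_region_index",
    "locate",
    "write_index_bed",
]

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """A gene as a strand-annotated set of genomic intervals.

    intervals are 0-based half-open, sorted, non-empty and pairwise
    non-overlapping within the gene.
    """

    gene_id: str
    chrom: str
    strand: str
    intervals: tuple[tuple[int, int], ...]
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise AnnotationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        ivs = tuple((int(s), int(e)) for s, e in self.intervals)
        if not ivs:
            raise AnnotationError(f"gene {self.gene_id}: no intervals")
        prev_end = -1
        for s, e in ivs:
            if s < 0 or e <= s:
                raise AnnotationError(
                    f"gene {self.gene_id}: invalid interval [{s}, {e})"
                )
            if s < prev_end:
                raise AnnotationError(
                    f"gene {self.gene_id}: intervals unsorted or overlapping"
                )
            prev_end = e
        object.__setattr__(self, "intervals", ivs)

    @property
    def span(self) -> tuple[int, int]:
        return self.intervals[0][0], self.intervals[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)


def _parse_bed12(fields: list[str], lineno: int, exons_only: bool) -> GeneModel:
    if len(fields) < 6:
        raise AnnotationError(f"line {lineno}: BED record needs >= 6 columns")
    chrom, start, end, name = fields[0], fields[1], fields[2], fields[3]
    strand = fields[5]
    if strand not in STRANDS:
        raise AnnotationError(f"line {lineno}: unknown strand {strand!r}")
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: non-integer coordinate") from exc
    if exons_only:
        if len(fields) < 12:
            raise AnnotationError(
                f"line {lineno}: exon mode requires a full 12-column BED record"
            )
        try:
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise AnnotationError(f"line {lineno}: malformed block columns") from exc
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise AnnotationError(f"line {lineno}: block count mismatch")
        intervals = tuple(
            (start_i + off, start_i + off + size) for off, size in zip(starts, sizes)
        )
    else:
        intervals = ((start_i, end_i),)
    # A 13th column, when present, carries the biotype.
    biotype = fields[12] if len(fields) > 12 else "protein_coding"
    return GeneModel(name, chrom, strand, intervals, biotype)


def _parse_refflat(fields: list[str], lineno: int, exons_only: bool) -> GeneModel:
    # geneName name chrom strand txStart txEnd cdsStart cdsEnd exonCount
    # exonStarts exonEnds
    if len(fields) < 11:
        raise AnnotationError(f"line {lineno}: refFlat record needs 11 columns")
    gene, chrom, strand = fields[0], fields[2], fields[3]
    if strand not in STRANDS:
        raise AnnotationError(f"line {lineno}: unknown strand {strand!r}")
    try:
        tx_start, tx_end = int(fields[4]), int(fields[5])
        if exons_only:
            starts = [int(x) for x in fields[9].rstrip(",").split(",")]
            ends = [int(x) for x in fields[10].rstrip(",").split(",")]
            intervals = tuple(zip(starts, ends))
        else:
            intervals = ((tx_start, tx_end),)
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: non-integer coordinate") from exc
    biotype = fields[11] if len(fields) > 11 else "protein_coding"
    return GeneModel(gene, chrom, strand, intervals, biotype)


def read_annotation(
    path: str | Path, format: str = "bed12", exons_only: bool = False
) -> list[GeneModel]:
    """Read gene models from a BED12 or refFlat annotation file.

    Non-protein-coding biotypes (an optional trailing column) are retained but
    flagged via ``GeneModel.biotype``; ``build_region_index`` excludes them.
    With ``exons_only`` the gene body is the exon blocks instead of the whole
    transcript span.
    """
    if format not in ("bed12", "refflat"):
        raise ValueError(f"unknown annotation format {format!r}")
    parser = _parse_bed12 if format == "bed12" else _parse_refflat
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            genes.append(parser(line.split("\t"), lineno, exons_only))
    return genes


def _merge_gene_records(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Union intervals of records sharing a gene_id; error on conflicts."""
    by_id: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_id.setdefault(g.gene_id, []).append(g)
    merged = []
    for gene_id, records in by_id.items():
        chroms = {g.chrom for g in records}
        strands = {g.strand for g in records}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"duplicate gene_id {gene_id!r} with conflicting coordinates"
            )
        ivs = sorted(iv for g in records for iv in g.intervals)
        out: list[list[int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged.append(
            GeneModel(
                gene_id,
                records[0].chrom,
                records[0].strand,
                tuple((s, e) for s, e in out),
                records[0].biotype,
            )
        )
    return merged


@dataclass
class RegionIndex:
    """Non-overlapping genomic regions, each mapping to exactly one gene.

    ``regions`` holds (chrom, start, end, gene_id, strand) tuples. Lookup is
    binary search over per-chromosome sorted arrays. Under the default build
    policy no two regions overlap anywhere; under the same-strand policy
    regions of opposite strands may overlap, and a strand-less lookup at such
    a base reports ambiguity as ``None``.
    """

    regions: list[tuple[str, int, int, str, str]]
    _by_strand: dict[
        tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]
    ] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.regions = sorted(self.regions)
        grouped: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
        for chrom, s, e, gid, strand in self.regions:
            grouped.setdefault((chrom, strand), []).append((s, e, gid))
        for key, rows in grouped.items():
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            gids = np.array([r[2] for r in rows], dtype=object)
            # Within one (chrom, strand) the regions never overlap, so binary
            # search against starts identifies the unique candidate.
            if np.any(starts[1:] < ends[:-1]):
                raise AnnotationError(
                    f"overlapping regions on {key[0]} strand {key[1]}"
                )
            self._by_strand[key] = (starts, ends, gids)

    @property
    def chroms(self) -> set[str]:
        return {chrom for chrom, _ in self._by_strand}

    def total_bases(self) -> int:
        return sum(e - s for _, s, e, _, _ in self.regions)

    def locate(
        self, chrom: str, pos: int, strand: str | None = None
    ) -> tuple[str, str] | None:
        """Return (gene_id, gene_strand) for the region containing pos, or None.

        Positions covered by regions on both strands (possible only under the
        same-strand build policy) are ambiguous: None is returned unless a
        ``strand`` hint selects the gene on that strand.
        """
        if pos < 0:
            raise ValueError("position must be >= 0")
        hits = []
        for st in STRANDS:
            entry = self._by_strand.get((chrom, st))
            if entry is None:
                continue
            starts, ends, gids = entry
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i >= 0 and pos < ends[i]:
                hits.append((str(gids[i]), st))
        if strand is not None:
            hits = [h for h in hits if h[1] == strand]
        if len(hits) == 1:
            return hits[0]
        return None

    def assign(
        self, chrom: str, positions: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised lookup: per-position gene_id (object, None=miss) and strand."""
        positions = np.asarray(positions, dtype=np.int64)
        gene_out = np.full(positions.shape, None, dtype=object)
        strand_out = np.full(positions.shape, None, dtype=object)
        n_hits = np.zeros(positions.shape, dtype=np.int64)
        for st in STRANDS:
            entry = self._by_strand.get((chrom, st))
            if entry is None:
                continue
            starts, ends, gids = entry
            idx = np.searchsorted(starts, positions, side="right") - 1
            safe = np.clip(idx, 0, None)
            ok = (idx >= 0) & (positions < ends[safe])
            n_hits += ok
            gene_out[ok] = gids[idx[ok]]
            strand_out[ok] = st
        missed = n_hits != 1
        gene_out[missed & (n_hits > 1)] = None
        strand_out[missed] = None
        gene_out[n_hits == 0] = None
        return gene_out, strand_out


def build_region_index(
    genes: Sequence[GeneModel],
    policy: str = "exclude_all",
    protein_coding_only: bool = True,
) -> RegionIndex:
    """Resolve gene models into the non-overlapping assignment index.

    policy 'exclude_all' (default): any base covered by >= 2 genes, whatever
    their strands, is excluded from every gene. policy 'same_strand': the
    exclusion is computed per strand, so genes overlapping only a gene on the
    opposite strand keep their shared bases (lookups without a strand hint
    treat doubly-covered bases as unassigned).
    """
    if policy not in ("exclude_all", "same_strand"):
        raise ValueError(f"unknown overlap policy {policy!r}")
    if protein_coding_only:
        genes = [g for g in genes if g.biotype == "protein_coding"]
    merged = _merge_gene_records(genes)

    regions: list[tuple[str, int, int, str, str]] = []
    chroms = sorted({g.chrom for g in merged})
    for chrom in chroms:
        chrom_genes = [g for g in merged if g.chrom == chrom]
        if policy == "exclude_all":
            groups = [chrom_genes]
        else:
            groups = [
                [g for g in chrom_genes if g.strand == st] for st in STRANDS
            ]
        for group in groups:
            regions.extend(_single_coverage_regions(chrom, group))
    return RegionIndex(regions)


def _single_coverage_regions(
    chrom: str, genes: list[GeneModel]
) -> list[tuple[str, int, int, str, str]]:
    """Sweep-line: maximal segments covered by exactly one gene of the group."""
    events: list[tuple[int, int, int]] = []  # (pos, delta, gene_idx)
    for i, g in enumerate(genes):
        for s, e in g.intervals:
            events.append((s, 1, i))
            events.append((e, -1, i))
    if not events:
        return []
    events.sort()
    out: list[tuple[str, int, int, str, str]] = []
    active: dict[int, int] = {}
    prev_pos = events[0][0]
    j = 0
    while j < len(events):
        pos = events[j][0]
        if pos > prev_pos and len(active) == 1:
            (gi,) = active
            g = genes[gi]
            out.append((chrom, prev_pos, pos, g.gene_id, g.strand))
        while j < len(events) and events[j][0] == pos:
            _, delta, gi = events[j]
            active[gi] = active.get(gi, 0) + delta
            if active[gi] == 0:
                del active[gi]
            j += 1
        prev_pos = pos
    # Merge adjacent segments of the same gene split by events that did not
    # change single-coverage status.
    merged: list[tuple[str, int, int, str, str]] = []
    for r in out:
        if merged and merged[-1][2] == r[1] and merged[-1][3] == r[3]:
            prev = merged.pop()
            r = (prev[0], prev[1], r[2], prev[3], prev[4])
        merged.append(r)
    return merged


def locate(
    index: RegionIndex, chrom: str, pos: int, strand: str | None = None
) -> tuple[str, str] | None:
    """Functional wrapper around :meth:`RegionIndex.locate`."""
    return index.locate(chrom, pos, strand)


def write_index_bed(index: RegionIndex, path: str | Path) -> None:
    """Write the resolved regions as BED6 (name=gene_id) for audit."""
    with open(path, "w") as fh:
        for chrom, s, e, gid, strand in index.regions:
            fh.write(f"{chrom}\t{s}\t{e}\t{gid}\t0\t{strand}\n")


def index_to_gene_models(index: RegionIndex) -> list[GeneModel]:
    """Reconstruct per-gene models from an index's own regions."""
    by_gene: dict[str, list[tuple[str, int, int, str]]] = {}
    for chrom, s, e, gid, strand in index.regions:
        by_gene.setdefault(gid, []).append((chrom, s, e, strand))
    models = []
    for gid, rows in by_gene.items():
        rows.sort()
        models.append(
            GeneModel(
                gid,
                rows[0][0],
                rows[0][3],
                tuple((s, e) for _, s, e, _ in rows),
            )
        )
    return models
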