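"""Synthetic gene-trap screen generator.

Generates annotations and insertion libraries with the statistical structure
the analyses assume, so the whole pipeline can be exercised and calibrated at
desk scale:

* one synthetic chromosome of non-overlapping gene bodies whose lengths are
  log-normal (human gene bodies are roughly log-normal with a median in the
  tens of kilobases);
* insertion positions uniform over the genome, so per-gene insertion counts
  are proportional to gene length (no hotspot model);
* cassette orientation: inside a gene, sense with probability
  ``orientation_p`` (default 0.5, the null of the orientation test);
  intergenic insertions get +/- with probability 1/2;
* configurable per-gene effects: a *regulator* biases which sorted bin a
  disruptive carrier cell enters in a FACS screen (odds multiplied by
  ``sort_bias``); a *fitness* gene thins its sense insertions to survival
  probability ``sense_survival``; a *conditional_fitness* gene does so only
  in a matching genotype (synthetic lethality).

Everything is deterministic given the config seed. Sub-streams are derived
as ``default_rng([seed, stage, ...])`` with stage 0 = annotation, 1 =
fitness screen (plus replicate index and a CRC32 of the genotype label),
2 = FACS screen.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotation import GeneModel
from .insertions import Insertion

__all__ = [
    "EffectSpec",
    "SimulationConfig",
    "simulate_annotation",
    "simulate_fitness_screen",
    "simulate_facs_screen",
]

CHROM = "chrS"

_STAGE_ANNOTATION = 0
_STAGE_FITNESS = 1
_STAGE_FACS = 2


@dataclass(frozen=True)
class EffectSpec:
    """Per-gene effect: 'regulator', 'fitness' or 'conditional_fitness'."""

    kind: str
    sort_bias: float = 1.0
    sense_survival: float = 1.0
    genotype: str | None = None

    def __post_init__(self):
        if self.kind not in ("regulator", "fitness", "conditional_fitness"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.sort_bias <= 0:
            raise ValueError("sort_bias must be positive")
        if not 0.0 <= self.sense_survival <= 1.0:
            raise ValueError("sense_survival must lie in [0, 1]")
        if self.kind == "conditional_fitness" and self.genotype is None:
            raise ValueError("conditional_fitness requires a genotype")


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic screen.

    ``library_size`` is the expected number of unique insertions per output
    sample (per fitness replicate; per retained FACS bin). Gene lengths are
    log-normal in bp; defaults give a ~20 kb median over 2,000 genes with
    half the genome intergenic.
    """

    seed: int
    n_genes: int = 2000
    length_log_mean: float = float(np.log(20_000.0))
    length_log_sigma: float = 0.75
    min_gene_length: int = 200
    intergenic_fraction: float = 0.5
    library_size: int = 200_000
    orientation_p: float = 0.5
    effects: Mapping[str, EffectSpec] = field(default_factory=dict)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory (no silent nondeterminism)")
        if not 0.0 <= self.orientation_p <= 1.0:
            raise ValueError("orientation_p must lie in [0, 1]")
        if not 0.0 <= self.intergenic_fraction < 1.0:
            raise ValueError("intergenic_fraction must lie in [0, 1)")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        self.effects = {
            gid: (e if isinstance(e, EffectSpec) else EffectSpec(**e))
            for gid, e in dict(self.effects).items()
        }


def simulate_annotation(
    config: SimulationConfig, overlap_pairs: int = 0
) -> tuple[list[GeneModel], int]:
    """Place ``n_genes`` non-overlapping genes on one synthetic chromosome.

    Returns (gene models, genome length). With ``overlap_pairs`` > 0, that
    many extra genes are injected, each nested inside one of the first base
    genes, producing exactly that many overlapping pairs (for exercising the
    overlap-resolution machinery; the screen simulators ignore them).
    """
    rng = np.random.default_rng([config.seed, _STAGE_ANNOTATION])
    if config.n_genes == 0:
        return [], 1000
    lengths = rng.lognormal(
        config.length_log_mean, config.length_log_sigma, config.n_genes
    )
    lengths = np.maximum(lengths.astype(np.int64), config.min_gene_length)
    total_genic = int(lengths.sum())
    genome_length = int(np.ceil(total_genic / (1.0 - config.intergenic_fraction)))
    intergenic_total = genome_length - total_genic
    gaps = rng.multinomial(
        intergenic_total, np.full(config.n_genes + 1, 1.0 / (config.n_genes + 1))
    )
    strands = rng.choice(["+", "-"], size=config.n_genes)

    genes: list[GeneModel] = []
    cursor = 0
    width = max(4, len(str(config.n_genes)))
    for i in range(config.n_genes):
        cursor += int(gaps[i])
        start = cursor
        end = start + int(lengths[i])
        genes.append(
            GeneModel(f"G{i + 1:0{width}d}", CHROM, str(strands[i]), ((start, end),))
        )
        cursor = end

    if overlap_pairs:
        hosts = [g for g in genes if g.length >= 16][:overlap_pairs]
        if len(hosts) < overlap_pairs:
            raise ValueError("not enough genes long enough to host overlaps")
        for j, host in enumerate(hosts):
            s, e = host.span
            quarter = (e - s) // 4
            genes.append(
                GeneModel(
                    f"OVL{j + 1:04d}",
                    CHROM,
                    "+" if host.strand == "-" else "-",
                    ((s + quarter, e - quarter),),
                )
            )
    return genes, genome_length


def _gene_arrays(genes: Sequence[GeneModel]):
    """Sorted start/end/strand/id arrays for base (non-overlapping) genes."""
    base = sorted(
        (g for g in genes if not g.gene_id.startswith("OVL")),
        key=lambda g: g.span[0],
    )
    starts = np.array([g.span[0] for g in base], dtype=np.int64)
    ends = np.array([g.span[1] for g in base], dtype=np.int64)
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError("simulator requires non-overlapping base genes")
    plus = np.array([g.strand == "+" for g in base])
    ids = np.array([g.gene_id for g in base], dtype=object)
    return starts, ends, plus, ids


def _draw_insertions(
    rng: np.random.Generator,
    n_draws: int,
    genome_length: int,
    starts: np.ndarray,
    ends: np.ndarray,
    gene_plus: np.ndarray,
    orientation_p: float,
):
    """Positions, host-gene index (-1 intergenic) and cassette-strand-is-plus."""
    pos = rng.integers(0, genome_length, size=n_draws)
    u_orient = rng.random(n_draws)
    idx = np.searchsorted(starts, pos, side="right") - 1
    safe = np.clip(idx, 0, None)
    in_gene = (idx >= 0) & (pos < ends[safe])
    idx = np.where(in_gene, idx, -1)
    sense = u_orient < orientation_p  # matches host strand, meaningful in-gene
    cassette_plus = np.where(
        in_gene, gene_plus[safe] == sense, u_orient < 0.5
    )
    return pos, idx, in_gene, sense, cassette_plus


def _unique_insertions(
    pos: np.ndarray, cassette_plus: np.ndarray, sample: str
) -> list[Insertion]:
    key = pos * 2 + cassette_plus.astype(np.int64)
    uniq = np.unique(key)
    out_pos = uniq // 2
    out_plus = (uniq % 2).astype(bool)
    return [
        Insertion(CHROM, int(p), "+" if pl else "-", sample)
        for p, pl in zip(out_pos, out_plus)
    ]


def simulate_fitness_screen(
    config: SimulationConfig,
    genotype: str = "WT",
    n_replicates: int = 2,
    annotation: tuple[list[GeneModel], int] | None = None,
) -> list[list[Insertion]]:
    """Simulate passaged insertion libraries, one list per replicate.

    Fitness and genotype-matched conditional-fitness genes retain each sense
    insertion with probability ``sense_survival``; everything else is
    neutral. Sample labels are ``{genotype}_r{i}``.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    genes, genome_length = (
        annotation if annotation is not None else simulate_annotation(config)
    )
    starts, ends, plus, ids = _gene_arrays(genes)
    survival = np.ones(len(ids))
    for gi, gid in enumerate(ids):
        eff = config.effects.get(gid)
        if eff is None:
            continue
        if eff.kind == "fitness" or (
            eff.kind == "conditional_fitness" and eff.genotype == genotype
        ):
            survival[gi] = eff.sense_survival

    replicates = []
    tag = zlib.crc32(genotype.encode())
    for rep in range(n_replicates):
        rng = np.random.default_rng([config.seed, _STAGE_FITNESS, rep, tag])
        pos, idx, in_gene, sense, cassette_plus = _draw_insertions(
            rng,
            config.library_size,
            genome_length,
            starts,
            ends,
            plus,
            config.orientation_p,
        )
        u_surv = rng.random(config.library_size)
        p_keep = np.ones(config.library_size)
        mask = in_gene & sense
        p_keep[mask] = survival[idx[mask]]
        keep = u_surv < p_keep
        replicates.append(
            _unique_insertions(
                pos[keep], cassette_plus[keep], f"{genotype}_r{rep + 1}"
            )
        )
    return replicates


def simulate_facs_screen(
    config: SimulationConfig,
    annotation: tuple[list[GeneModel], int] | None = None,
    sort_fraction: float = 0.05,
) -> tuple[list[Insertion], list[Insertion]]:
    """Simulate a FACS enrichment screen; returns (high bin, low bin).

    Each simulated cell carries one insertion. Baseline cells enter the high
    and low bins with probability ``sort_fraction`` each (5% tails by
    default). A cell carrying a disruptive (sense, in-gene) insertion in a
    regulator gene with sort_bias b keeps the same total retention
    probability but splits high:low with odds b, so the downstream MI
    estimates b. The number of cells is library_size / sort_fraction, giving
    ~library_size unique insertions per bin.
    """
    if not 0.0 < sort_fraction <= 0.5:
        raise ValueError("sort_fraction must lie in (0, 0.5]")
    genes, genome_length = (
        annotation if annotation is not None else simulate_annotation(config)
    )
    starts, ends, plus, ids = _gene_arrays(genes)
    bias = np.ones(len(ids))
    for gi, gid in enumerate(ids):
        eff = config.effects.get(gid)
        if eff is not None and eff.kind == "regulator":
            bias[gi] = min(eff.sort_bias, 1e9)

    n_cells = int(round(config.library_size / sort_fraction))
    rng = np.random.default_rng([config.seed, _STAGE_FACS])
    pos, idx, in_gene, sense, cassette_plus = _draw_insertions(
        rng, n_cells, genome_length, starts, ends, plus, config.orientation_p
    )
    b = np.ones(n_cells)
    disruptive = in_gene & sense
    b[disruptive] = bias[idx[disruptive]]
    p_high = 2.0 * sort_fraction * b / (1.0 + b)
    p_low = 2.0 * sort_fraction / (1.0 + b)
    u = rng.random(n_cells)
    high = u < p_high
    low = (~high) & (u < p_high + p_low)
    return (
        _unique_insertions(pos[high], cassette_plus[high], "high"),
        _unique_insertions(pos[low], cassette_plus[low], "low"),
    )
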