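"""Calibration and spike-in recovery experiments on synthetic screens.

These functions wire the generator to the analysis stages to measure the
pipeline's operating characteristics: false-positive calibration under a
null screen (no gene effects) and sensitivity/specificity for spiked-in
regulator, fitness and synthetic-lethal effects. They are used by the test
suite and the reproduction script; problem sizes default to the desk-scale
study conditions (2,000 genes, 2x10^5 unique insertions per sample).
"""

from __future__ import annotations

import numpy as np

from .annotation import build_region_index
from .facs import analyze_facs
from .fitness import analyze_orientation, replicate_consensus
from .insertions import assign_and_count
from .simulate import (
    EffectSpec,
    SimulationConfig,
    simulate_annotation,
    simulate_facs_screen,
    simulate_fitness_screen,
)
from .synlethal import call_hits, compare_to_controls

__all__ = [
    "run_facs_null",
    "run_fitness_null",
    "regulator_recovery",
    "synthetic_lethal_recovery",
]


def _seed_for(base: int, i: int) -> int:
    # distinct per-iteration seeds derived from one base seed, kept < 2^31
    return (base * 100_003 + i) % (2**31 - 1)


def run_facs_null(
    seed: int,
    n_seeds: int = 20,
    n_genes: int = 2000,
    library_size: int = 200_000,
    alpha: float = 0.05,
) -> dict:
    """Fraction of genes called significant in effect-free FACS screens.

    Simulates ``n_seeds`` independent null screens and averages the
    per-screen fraction of non-ns regulator calls at ``alpha``.
    """
    fractions = []
    for i in range(n_seeds):
        cfg = SimulationConfig(
            seed=_seed_for(seed, i), n_genes=n_genes, library_size=library_size
        )
        ann = simulate_annotation(cfg)
        high, low = simulate_facs_screen(cfg, annotation=ann)
        index = build_region_index(ann[0])
        counts = assign_and_count(high + low, index)
        res = analyze_facs(counts, "high", "low", alpha=alpha)
        fractions.append(float((res["reg_class"] != "ns").mean()))
    return {
        "mean_significant_fraction": float(np.mean(fractions)),
        "n_genes": n_genes,
        "n_seeds": n_seeds,
    }


def run_fitness_null(
    seed: int,
    n_seeds: int = 20,
    n_genes: int = 2000,
    library_size: int = 200_000,
    n_replicates: int = 2,
    alpha: float = 0.05,
) -> dict:
    """Fraction of genes called significant in effect-free fitness screens."""
    fractions = []
    for i in range(n_seeds):
        cfg = SimulationConfig(
            seed=_seed_for(seed, i), n_genes=n_genes, library_size=library_size
        )
        ann = simulate_annotation(cfg)
        reps = simulate_fitness_screen(
            cfg, genotype="WT", n_replicates=n_replicates, annotation=ann
        )
        index = build_region_index(ann[0])
        counts = assign_and_count([ins for r in reps for ins in r], index)
        cons = replicate_consensus(analyze_orientation(counts), alpha=alpha)
        fractions.append(float(cons["significant"].mean()))
    return {
        "mean_significant_fraction": float(np.mean(fractions)),
        "n_genes": n_genes,
        "n_seeds": n_seeds,
    }


def _spike_genes(genes, min_length: int, n_spikes: int, skip: int = 0) -> list[str]:
    eligible = [g.gene_id for g in genes if g.length >= min_length]
    if len(eligible) < skip + n_spikes:
        raise ValueError(
            f"only {len(eligible)} genes >= {min_length} bp; "
            f"need {skip + n_spikes}"
        )
    return eligible[skip : skip + n_spikes]


def regulator_recovery(
    seed: int,
    n_genes: int = 2000,
    library_size: int = 200_000,
    n_spikes: int = 20,
    sort_bias: float = 8.0,
    min_gene_length: int = 20_000,
    alpha: float = 0.05,
) -> dict:
    """Spike-in recovery of FACS regulators.

    Spikes ``n_spikes`` negative regulators (sort_bias) and ``n_spikes``
    positive regulators (1/sort_bias) into genes long enough to expect >= 30
    disruptive insertions across the two sorted bins, then measures the
    fraction recovered with the correct direction, the number recovered with
    the wrong direction, and the false-call rate among neutral genes.
    """
    base_cfg = SimulationConfig(seed=seed, n_genes=n_genes, library_size=library_size)
    genes, genome_length = simulate_annotation(base_cfg)
    negatives = _spike_genes(genes, min_gene_length, n_spikes)
    positives = _spike_genes(genes, min_gene_length, n_spikes, skip=n_spikes)
    effects = {g: EffectSpec("regulator", sort_bias=sort_bias) for g in negatives}
    effects.update(
        {g: EffectSpec("regulator", sort_bias=1.0 / sort_bias) for g in positives}
    )
    cfg = SimulationConfig(
        seed=seed, n_genes=n_genes, library_size=library_size, effects=effects
    )
    high, low = simulate_facs_screen(cfg, annotation=(genes, genome_length))
    index = build_region_index(genes)
    counts = assign_and_count(high + low, index)
    res = analyze_facs(counts, "high", "low", alpha=alpha).set_index("gene_id")

    neg_classes = res.loc[negatives, "reg_class"]
    pos_classes = res.loc[positives, "reg_class"]
    neutral = res.drop(index=negatives + positives)
    return {
        "negative_sensitivity": float((neg_classes == "negative").mean()),
        "positive_sensitivity": float((pos_classes == "positive").mean()),
        "direction_errors": int(
            (neg_classes == "positive").sum() + (pos_classes == "negative").sum()
        ),
        "neutral_call_rate": float((neutral["reg_class"] != "ns").mean()),
        "n_spikes_per_class": n_spikes,
        "n_genes": n_genes,
    }


def synthetic_lethal_recovery(
    seed: int,
    n_genes: int = 2000,
    library_size: int = 200_000,
    n_spikes: int = 20,
    sense_survival: float = 0.1,
    min_gene_length: int = 50_000,
    n_query_replicates: int = 2,
    n_controls: int = 4,
    alpha: float = 0.05,
    p_thresh: float = 0.05,
    or_thresh: float = 0.8,
) -> dict:
    """Spike-in recovery of genotype-conditional (synthetic-lethal) effects.

    Spiked genes carry sense-insertion survival ``sense_survival`` in the
    query genotype and are fully neutral in the wild-type controls. Spikes
    go into genes long enough to expect >= 50 insertions per replicate.
    """
    base_cfg = SimulationConfig(seed=seed, n_genes=n_genes, library_size=library_size)
    genes, genome_length = simulate_annotation(base_cfg)
    spiked = _spike_genes(genes, min_gene_length, n_spikes)
    effects = {
        g: EffectSpec(
            "conditional_fitness", sense_survival=sense_survival, genotype="KO"
        )
        for g in spiked
    }
    cfg = SimulationConfig(
        seed=seed, n_genes=n_genes, library_size=library_size, effects=effects
    )
    ann = (genes, genome_length)
    query_reps = simulate_fitness_screen(
        cfg, genotype="KO", n_replicates=n_query_replicates, annotation=ann
    )
    control_reps = simulate_fitness_screen(
        cfg, genotype="WT", n_replicates=n_controls, annotation=ann
    )
    index = build_region_index(genes)
    query_counts = assign_and_count(
        [ins for r in query_reps for ins in r], index
    )
    control_counts = [assign_and_count(r, index) for r in control_reps]

    consensus = replicate_consensus(
        analyze_orientation(query_counts), alpha=alpha
    )
    comparisons = compare_to_controls(query_counts, control_counts)
    hits = call_hits(
        consensus, comparisons, p_thresh=p_thresh, or_thresh=or_thresh
    ).set_index("gene_id")

    spiked_in_table = [g for g in spiked if g in hits.index]
    neutral = hits.drop(index=spiked_in_table)
    return {
        "sensitivity": float(hits.loc[spiked_in_table, "hit"].mean())
        if spiked_in_table
        else 0.0,
        "neutral_hit_rate": float(neutral["hit"].mean()),
        "n_spikes": n_spikes,
        "n_genes": n_genes,
    }
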