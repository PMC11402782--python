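"""Fitness screen analysis: sense-ratio orientation bias with replicate consensus.

In a haploid fitness screen, cells carrying a disruptive (sense) insertion in
a gene required for growth are depleted during passaging, while antisense
insertions in the same gene are largely neutral. The per-gene *sense ratio*
sense / (sense + antisense) therefore drops below its null value for fitness
genes. Each replicate is tested with an exact two-sided binomial test against
the null sense fraction p0 (default 0.5) and BH-adjusted within the
replicate; a gene is called significant for a genotype only if its *least
significant* adjusted p across replicates clears alpha and every replicate
deviates in the same direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .insertions import GeneCountTable
from .stats import binomial_two_sided, fdr_adjust

__all__ = [
    "sense_ratio",
    "binomial_orientation_test",
    "analyze_orientation",
    "replicate_consensus",
    "fitness_fishtail_table",
]


def sense_ratio(sense: int, antisense: int) -> float:
    """sense / (sense + antisense); undefined (ValueError) when both are 0."""
    n = sense + antisense
    if n <= 0:
        raise ValueError("sense ratio undefined for a gene with no insertions")
    return sense / n


def binomial_orientation_test(sense: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p for the observed sense count."""
    return binomial_two_sided(sense, n, p0)


def analyze_orientation(
    counts: GeneCountTable,
    samples: list[str] | None = None,
    p0: float = 0.5,
    estimate_p0: bool = False,
) -> pd.DataFrame:
    """Per-replicate orientation-bias test for every gene with insertions.

    Returns a DataFrame with columns gene_id, replicate_id, sense, antisense,
    n, sense_ratio, p, q (BH within replicate) and p0. With ``estimate_p0``
    the null sense fraction is the replicate's library-wide sense fraction
    (absorbing any cassette orientation bias) instead of the supplied ``p0``.
    Genes with zero insertions in a replicate do not appear for it.
    """
    if samples is None:
        samples = counts.samples
    frames = []
    for rep in samples:
        sub = counts.sample_counts(rep).copy()
        sub = sub[(sub["sense"] + sub["antisense"]) > 0]
        if sub.empty:
            continue
        n = (sub["sense"] + sub["antisense"]).to_numpy(dtype=np.int64)
        sense = sub["sense"].to_numpy(dtype=np.int64)
        if estimate_p0:
            tot = counts.totals.loc[rep]
            denom = tot["total_sense"] + tot["total_antisense"]
            rep_p0 = float(tot["total_sense"] / denom) if denom > 0 else p0
        else:
            rep_p0 = p0
        p = np.array([binomial_two_sided(s, k, rep_p0) for s, k in zip(sense, n)])
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": sub.index,
                    "replicate_id": rep,
                    "sense": sense,
                    "antisense": sub["antisense"].to_numpy(dtype=np.int64),
                    "n": n,
                    "sense_ratio": sense / n,
                    "p": p,
                    "q": fdr_adjust(p),
                    "p0": rep_p0,
                }
            )
        )
    if not frames:
        raise ValueError("no replicate contains any insertions")
    return pd.concat(frames, ignore_index=True)


def replicate_consensus(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Across-replicate consensus: the least significant replicate decides.

    For each gene present in *all* replicates, consensus_q is the maximum
    (least significant) within-replicate BH-adjusted p. A gene is significant
    iff consensus_q < alpha and every replicate's sense ratio lies on the
    same side of its null fraction p0. Direction is 'sense_depleted' when the
    ratios sit below p0, 'sense_enriched' above, and None without agreement.
    """
    reps = sorted(records["replicate_id"].unique())
    if not reps:
        raise ValueError("consensus requires at least one replicate")
    rows = []
    for gene_id, sub in records.groupby("gene_id", sort=True):
        present = len(sub) == len(reps)
        consensus_q = float(sub["q"].max())
        below = (sub["sense_ratio"] < sub["p0"]).all()
        above = (sub["sense_ratio"] > sub["p0"]).all()
        if below:
            direction = "sense_depleted"
        elif above:
            direction = "sense_enriched"
        else:
            direction = None
        significant = bool(
            present and direction is not None and consensus_q < alpha
        )
        rows.append(
            {
                "gene_id": gene_id,
                "n_replicates": len(sub),
                "consensus_q": consensus_q,
                "direction": direction,
                "significant": significant,
                "mean_sense_ratio": float(sub["sense_ratio"].mean()),
                "total_n": int(sub["n"].sum()),
            }
        )
    return pd.DataFrame(rows)


def fitness_fishtail_table(records: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table per gene/replicate: x = log10 n, y = sense ratio."""
    df = records[records["n"] > 0].copy()
    df["x_log10_n"] = np.log10(df["n"].astype(float))
    return df[
        ["gene_id", "replicate_id", "x_log10_n", "sense_ratio", "q"]
    ].reset_index(drop=True)
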