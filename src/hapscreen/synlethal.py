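"""Synthetic-lethality calling: genotype-selective depletion versus controls.

A gene is synthetic lethal with a query genotype when its disruption is
tolerated in wild-type cells but depleted in the mutant background. The test
pools the query genotype's sense/antisense counts and compares them with
wild-type control datasets in a 2x2 Fisher exact test

    [[sense_query, antisense_query], [sense_control, antisense_control]]

whose sample odds ratio falls below 1 when disruptive insertions are
selectively lost in the query. Hits require the conjunction of (i) a
significant within-genotype orientation bias (replicate consensus, sense
depleted), (ii) Fisher p below the threshold (used raw, no FDR — the FDR
correction applies to the within-genotype binomial step only), and (iii) an
odds ratio below the threshold. The effect size reported for ranking is
delta_sr = sense_ratio(control) - sense_ratio(query), positive for
synthetic-lethal genes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .insertions import GeneCountTable
from .stats import fisher_exact_two_sided, odds_ratio

__all__ = [
    "pool_controls",
    "fisher_vs_control",
    "compare_to_controls",
    "call_hits",
    "rank_table",
]


def pool_controls(controls: Sequence[GeneCountTable]) -> GeneCountTable:
    """Element-wise per-gene sum of sense/antisense counts across controls.

    Genes missing from one control contribute 0 there. Raises on an empty
    list.
    """
    if not controls:
        raise ValueError("at least one control dataset is required")
    counts = pd.concat([c.counts for c in controls], ignore_index=True)
    agg = (
        counts.groupby("gene_id", as_index=False)[["sense", "antisense"]]
        .sum()
        .assign(sample="control_pooled")
    )
    totals = pd.DataFrame(
        [pd.concat([c.totals for c in controls]).sum()],
        index=pd.Index(["control_pooled"], name="sample"),
    ).astype(int)
    return GeneCountTable(agg[["gene_id", "sample", "sense", "antisense"]], totals)


def fisher_vs_control(
    sense_ko: int, anti_ko: int, sense_ctrl: int, anti_ctrl: int
) -> tuple[float, float]:
    """Two-sided Fisher p and sample odds ratio, query versus control.

    odds_ratio = (sense_ko * anti_ctrl) / (anti_ko * sense_ctrl), reported as
    +inf when the denominator is 0 (nan if the numerator is too).
    """
    if min(sense_ko, anti_ko, sense_ctrl, anti_ctrl) < 0:
        raise ValueError("counts must be non-negative")
    if sense_ko + anti_ko + sense_ctrl + anti_ctrl == 0:
        raise ValueError("comparison undefined for an all-zero table")
    p = fisher_exact_two_sided(sense_ko, anti_ko, sense_ctrl, anti_ctrl)
    return p, odds_ratio(sense_ko, anti_ko, sense_ctrl, anti_ctrl)


def compare_to_controls(
    query: GeneCountTable,
    controls: Sequence[GeneCountTable],
    mode: str = "pooled",
) -> pd.DataFrame:
    """Per-gene Fisher comparison of the query genotype against controls.

    The query's replicates are pooled into one sense/antisense pair per gene.
    ``mode='pooled'`` (default) also pools the control datasets before a
    single Fisher test; ``mode='per_control'`` runs the test against every
    control separately and reports the least significant p and the odds
    ratio closest to 1 (a hit must then clear the thresholds against every
    control). Genes with no insertions anywhere are omitted.
    """
    if mode not in ("pooled", "per_control"):
        raise ValueError(f"unknown control mode {mode!r}")
    q = query.pooled(label="query").counts.set_index("gene_id")[["sense", "antisense"]]
    ctrl_tables = (
        [pool_controls(controls)] if mode == "pooled" else [c.pooled(label="ctrl") for c in controls]
    )
    ctrl_frames = [
        t.counts.set_index("gene_id")[["sense", "antisense"]] for t in ctrl_tables
    ]
    genes = sorted(set(q.index).union(*[set(f.index) for f in ctrl_frames]))
    q = q.reindex(genes, fill_value=0)

    rows = []
    for gene in genes:
        s_ko = int(q.at[gene, "sense"])
        a_ko = int(q.at[gene, "antisense"])
        ps, ors, s_cs, a_cs = [], [], [], []
        for frame in ctrl_frames:
            s_c = int(frame["sense"].get(gene, 0))
            a_c = int(frame["antisense"].get(gene, 0))
            if s_ko + a_ko + s_c + a_c == 0:
                continue
            p, orat = fisher_vs_control(s_ko, a_ko, s_c, a_c)
            ps.append(p)
            ors.append(orat)
            s_cs.append(s_c)
            a_cs.append(a_c)
        if not ps:
            continue
        # per_control: weakest evidence governs the hit decision
        i_p = int(np.argmax(ps))
        finite = [abs(np.log(o)) if 0 < o < np.inf else np.inf for o in ors]
        i_or = int(np.argmin(finite)) if any(f < np.inf for f in finite) else int(np.argmax(ors))
        sense_ctrl = sum(s_cs)
        anti_ctrl = sum(a_cs)
        n_ko = s_ko + a_ko
        n_ctrl = sense_ctrl + anti_ctrl
        sr_ko = s_ko / n_ko if n_ko else np.nan
        sr_ctrl = sense_ctrl / n_ctrl if n_ctrl else np.nan
        rows.append(
            {
                "gene_id": gene,
                "sense_ko": s_ko,
                "anti_ko": a_ko,
                "sense_ctrl": sense_ctrl,
                "anti_ctrl": anti_ctrl,
                "sr_ko": sr_ko,
                "sr_ctrl": sr_ctrl,
                "delta_sr": sr_ctrl - sr_ko,
                "p_fisher": ps[i_p],
                "odds_ratio": ors[i_or],
            }
        )
    return pd.DataFrame(rows)


def call_hits(
    orientation: pd.DataFrame,
    comparisons: pd.DataFrame,
    p_thresh: float = 0.05,
    or_thresh: float = 0.8,
) -> pd.DataFrame:
    """Flag hits: consensus sense depletion AND p_fisher < p AND OR < threshold.

    ``orientation`` is the replicate-consensus table of the query genotype;
    ``comparisons`` the output of :func:`compare_to_controls`. Returns the
    comparison table with a boolean ``hit`` column, sorted by delta_sr
    descending (ties: p_fisher ascending, then gene_id).
    """
    cons = orientation.set_index("gene_id")
    df = comparisons.copy()
    sig = df["gene_id"].map(
        lambda g: bool(
            g in cons.index
            and cons.at[g, "significant"]
            and cons.at[g, "direction"] == "sense_depleted"
        )
    )
    df["hit"] = sig & (df["p_fisher"] < p_thresh) & (df["odds_ratio"] < or_thresh)
    return df.sort_values(
        ["delta_sr", "p_fisher", "gene_id"], ascending=[False, True, True]
    ).reset_index(drop=True)


def rank_table(hits: pd.DataFrame) -> pd.DataFrame:
    """Rank plot table for called hits: rank, gene, delta_sr, p_fisher."""
    df = hits[hits["hit"]].copy()
    df = df.sort_values(
        ["delta_sr", "p_fisher", "gene_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df[["rank", "gene_id", "delta_sr", "p_fisher", "odds_ratio"]]
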