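"""FACS-sorted enrichment screen analysis: mutational index and hit calling.

In a FACS-based enrichment screen, mutagenised cells are sorted into the
highest and lowest tails of a reporter signal and the gene-trap insertions in
each tail are sequenced. For each gene the *mutational index* (MI) compares
the gene's unique sense-insertion frequency, normalised to the total sense
insertions of each sorted population:

    MI = ((c_high + pc) / T_high) / ((c_low + pc) / T_low)

Genes whose disruption raises the readout accumulate insertions in the high
bin (MI > 1, a "negative regulator" of the readout's removal — labelled
negative here following the screen convention that disruption *increases*
signal); genes whose disruption lowers the readout have MI < 1 (positive
regulators). Significance comes from a two-sided Fisher exact test on the
gene-versus-rest 2x2 table of sense counts, BH-adjusted across genes. The
pseudocount ``pc`` (default 1) only makes log2 MI finite for display; the
Fisher test always uses raw counts.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .insertions import GeneCountTable
from .stats import fdr_adjust, fisher_exact_two_sided

__all__ = [
    "mutational_index",
    "fisher_enrichment_test",
    "analyze_facs",
    "classify_regulators",
    "comparative_filter",
    "fishtail_table",
]

REG_CLASSES = ("positive", "negative", "ns")


def mutational_index(
    c_high: int, T_high: int, c_low: int, T_low: int, pseudocount: float = 1.0
) -> float:
    """Ratio of normalised sense-insertion frequencies, high over low."""
    if T_high <= 0 or T_low <= 0:
        raise ValueError("population sense totals must be positive")
    if not (0 <= c_high <= T_high and 0 <= c_low <= T_low):
        raise ValueError("gene counts must satisfy 0 <= c <= T")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    return ((c_high + pseudocount) / T_high) / ((c_low + pseudocount) / T_low)


def fisher_enrichment_test(c_high: int, T_high: int, c_low: int, T_low: int) -> float:
    """Two-sided Fisher p for the gene-vs-rest table of sense counts.

    Table: [[c_high, T_high - c_high], [c_low, T_low - c_low]].
    """
    if c_high > T_high or c_low > T_low:
        raise ValueError("gene count exceeds population total")
    return fisher_exact_two_sided(c_high, T_high - c_high, c_low, T_low - c_low)


def analyze_facs(
    counts: GeneCountTable,
    high: str,
    low: str,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    min_combined: int = 1,
) -> pd.DataFrame:
    """Per-gene enrichment analysis between the high and low sorted samples.

    Returns a DataFrame with one row per gene observed in either population:
    c_high, c_low, T_high, T_low, mi, p, q, combined_insertions, reg_class.
    Only sense insertions enter the statistics.
    """
    hi = counts.sample_counts(high)["sense"]
    lo = counts.sample_counts(low)["sense"]
    genes = sorted(set(hi.index) | set(lo.index))
    c_high = hi.reindex(genes, fill_value=0).to_numpy(dtype=np.int64)
    c_low = lo.reindex(genes, fill_value=0).to_numpy(dtype=np.int64)
    T_high = int(counts.totals.loc[high, "total_sense"])
    T_low = int(counts.totals.loc[low, "total_sense"])
    if T_high <= 0 or T_low <= 0:
        raise ValueError("each sorted population needs at least one sense insertion")

    mi = ((c_high + pseudocount) / T_high) / ((c_low + pseudocount) / T_low)
    p = np.array(
        [
            fisher_enrichment_test(ch, T_high, cl, T_low)
            for ch, cl in zip(c_high, c_low)
        ]
    )
    q = fdr_adjust(p)
    df = pd.DataFrame(
        {
            "gene_id": genes,
            "c_high": c_high,
            "c_low": c_low,
            "T_high": T_high,
            "T_low": T_low,
            "mi": mi,
            "p": p,
            "q": q,
            "combined_insertions": c_high + c_low,
        }
    )
    return classify_regulators(df, alpha=alpha, min_combined=min_combined)


def classify_regulators(
    records: pd.DataFrame, alpha: float = 0.05, min_combined: int = 1
) -> pd.DataFrame:
    """Set reg_class from adjusted significance and MI direction.

    negative: q <= alpha and MI > 1 (enriched in the high bin);
    positive: q <= alpha and MI < 1; everything else ns. Genes with fewer
    than ``min_combined`` combined insertions are forced to ns.
    """
    df = records.copy()
    sig = df["q"] <= alpha
    df["reg_class"] = "ns"
    df.loc[sig & (df["mi"] > 1), "reg_class"] = "negative"
    df.loc[sig & (df["mi"] < 1), "reg_class"] = "positive"
    df.loc[df["combined_insertions"] < min_combined, "reg_class"] = "ns"
    return df


def comparative_filter(
    treatment: pd.DataFrame,
    mock: pd.DataFrame,
    keep: Sequence[str] = (),
) -> pd.DataFrame:
    """Remove from the treatment hit list genes significant in both screens.

    A gene classified non-ns in both the treatment and the mock screen is set
    to ns in the returned treatment table, unless its gene_id appears in
    ``keep`` (e.g. the antigen target itself). This isolates regulators
    specific to the treatment condition.
    """
    keep = set(keep)
    missing = keep - set(treatment["gene_id"])
    if missing:
        warnings.warn(
            f"keep genes absent from treatment screen: {sorted(missing)}",
            stacklevel=2,
        )
    mock_sig = set(mock.loc[mock["reg_class"] != "ns", "gene_id"])
    df = treatment.copy()
    drop = (
        df["gene_id"].isin(mock_sig)
        & (df["reg_class"] != "ns")
        & ~df["gene_id"].isin(keep)
    )
    df.loc[drop, "reg_class"] = "ns"
    return df


def fishtail_table(records: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: x = log10 combined insertions, y = log2 MI, class.

    Genes with zero combined insertions have no finite x and are dropped.
    """
    df = records[records["combined_insertions"] > 0].copy()
    df["x_log10_combined"] = np.log10(df["combined_insertions"].astype(float))
    df["y_log2_mi"] = np.log2(df["mi"].astype(float))
    return df[["gene_id", "x_log10_combined", "y_log2_mi", "reg_class"]].reset_index(
        drop=True
    )
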