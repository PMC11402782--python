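"""Exact tests and multiple-testing correction used throughout the pipeline.

All screen statistics reduce to two-sided exact tests on small count
configurations:

* a Fisher exact test on a 2x2 table (enrichment between sorted populations,
  or sense/antisense counts in a query genotype versus pooled controls), and
* an exact binomial test on the sense orientation of insertions within a gene.

Both use the "point-probability" definition of the two-sided p-value: the sum
of the probabilities of all outcomes whose null point probability does not
exceed that of the observed outcome. Floating-point ties are resolved with a
small relative tolerance (`TIE_RTOL`), so that outcomes whose probability is
equal to the observed one up to rounding are included in the tail sum. This
only matters on knife-edge tables.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TIE_RTOL",
    "fisher_exact_two_sided",
    "odds_ratio",
    "binomial_two_sided",
    "fdr_adjust",
]

#: Relative tolerance for comparing point probabilities when summing the
#: two-sided tail (handles floating-point ties on symmetric tables).
TIE_RTOL = 1e-7


def _log_binom_coef(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _two_sided_from_logpmf(logpmf: np.ndarray, observed_idx: int) -> float:
    """Sum pmf over outcomes no more probable than the observed one."""
    sel = logpmf <= logpmf[observed_idx] + np.log1p(TIE_RTOL)
    p = float(np.exp(logpmf[sel]).sum())
    return min(p, 1.0)


def _check_count(value: int, name: str) -> int:
    v = int(value)
    if v != value or v < 0:
        raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
    return v


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [c, d]].

    The null distribution is hypergeometric with the table margins fixed; the
    p-value sums the probabilities of all margin-consistent tables whose point
    probability is <= that of the observed table (with relative tie tolerance
    ``TIE_RTOL``).

    Raises
    ------
    ValueError
        If any cell is negative or all four cells are zero.
    """
    a = _check_count(a, "a")
    b = _check_count(b, "b")
    c = _check_count(c, "c")
    d = _check_count(d, "d")
    total = a + b + c + d
    if total == 0:
        raise ValueError("Fisher test undefined for an all-zero table")
    n_row1 = a + b
    n_col1 = a + c
    k_min = max(0, n_row1 - (total - n_col1))
    k_max = min(n_row1, n_col1)
    support = np.arange(k_min, k_max + 1)
    logpmf = (
        _log_binom_coef(n_col1, support)
        + _log_binom_coef(total - n_col1, n_row1 - support)
        - _log_binom_coef(total, n_row1)
    )
    return _two_sided_from_logpmf(logpmf, a - k_min)


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample cross-product ratio (a*d)/(b*c) for the table [[a, b], [c, d]].

    Returns ``inf`` when b*c == 0 and a*d > 0, and ``nan`` when both products
    are zero (the ratio carries no information).
    """
    num = a * d
    den = b * c
    if den == 0:
        return float("nan") if num == 0 else float("inf")
    return num / den


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value for ``k`` successes out of ``n``.

    Sums Binomial(n, p0) point probabilities over all outcomes whose
    probability is <= that of the observed count (relative tie tolerance
    ``TIE_RTOL``).

    Raises
    ------
    ValueError
        If ``n`` < 1, ``k`` outside [0, n], or ``p0`` outside (0, 1).
    """
    k = _check_count(k, "k")
    n = _check_count(n, "n")
    if n < 1:
        raise ValueError("binomial test requires n >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0!r}")
    support = np.arange(n + 1)
    logpmf = (
        _log_binom_coef(n, support)
        + support * np.log(p0)
        + (n - support) * np.log1p(-p0)
    )
    return _two_sided_from_logpmf(logpmf, k)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1.

    Order-preserving: q[i] corresponds to pvalues[i]. Raises ``ValueError``
    if any input p lies outside [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
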