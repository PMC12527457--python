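"""Two-tailed Fisher exact testing and Benjamini–Hochberg adjustment.

The two-sided p-value uses the point-probability ("minimum likelihood")
rule: with row/column margins fixed, sum the hypergeometric probabilities
of every table whose point probability does not exceed that of the observed
table. A small relative guard (1 + 1e-7) absorbs floating-point ties, the
same convention mainstream statistics libraries use.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .models import EnrichmentResult, FilterConfig

__all__ = [
    "fisher_exact_two_tailed",
    "fisher_exact_two_tailed_all",
    "bh_adjust",
    "variant_enrichment",
]

_TIE_GUARD = 1.0 + 1e-7


def _validate_table(a: int, b: int, c: int, d: int) -> None:
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError(f"table entries must be nonnegative integers, got {x}")
    if a + b + c + d == 0:
        raise ValueError("all-zero contingency table")


def fisher_exact_two_tailed(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table ``[[a, b], [c, d]]``."""
    (a, b), (c, d) = table
    _validate_table(a, b, c, d)
    n = a + b + c + d
    r1 = a + b  # row-1 margin
    c1 = a + c  # column-1 margin
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * _TIE_GUARD].sum())
    return min(p, 1.0)


def fisher_exact_two_tailed_all(n: int, r1: int, c1: int) -> np.ndarray:
    """Two-sided p-values for every table with margins (r1, n-r1; c1, n-c1).

    Returns an array aligned with the support ``a = max(0, r1+c1-n) ..
    min(r1, c1)``. Sharing one pmf evaluation across the whole margin class
    makes exhaustive verification cheap.
    """
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    cum = np.cumsum(sorted_pmf)
    # for each observed a, include every table whose pmf <= pmf[a] * guard
    idx = np.searchsorted(sorted_pmf, pmf * _TIE_GUARD, side="right") - 1
    return np.minimum(cum[idx], 1.0)


def bh_adjust(p_values: Iterable[float]) -> List[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = list(p_values)
    if not p:
        return []
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(arr, method="fdr_bh")
    return [float(q) for q in adjusted]


def variant_enrichment(
    tests: Sequence[tuple],
    cfg: FilterConfig,
) -> List[EnrichmentResult]:
    """Batch cohort-vs-population enrichment.

    ``tests`` holds (variant_key, cohort_ac, cohort_an, pop_ac, pop_an)
    tuples. Each builds the allele-count table
    [[cohort_ac, cohort_an - cohort_ac], [pop_ac, pop_an - pop_ac]];
    adjustment is batch-wise over all variants of the run, and a variant is
    significant when its adjusted p falls below
    ``cfg.enrichment_alpha_adjusted``.
    """
    raws = []
    for key, cac, can, pac, pan in tests:
        if can <= 0 or pan <= 0:
            raise ValueError(f"allele numbers must be positive for {key}")
        if cac > can or pac > pan:
            raise ValueError(f"allele count exceeds allele number for {key}")
        raws.append(
            fisher_exact_two_tailed([[cac, can - cac], [pac, pan - pac]])
        )
    adjusted = bh_adjust(raws)
    results = []
    for (key, cac, can, pac, pan), p_raw, p_adj in zip(tests, raws, adjusted):
        results.append(
            EnrichmentResult(
                variant_key=key,
                cohort_ac=cac,
                cohort_an=can,
                pop_ac=pac,
                pop_an=pan,
                p_raw=p_raw,
                p_adjusted=p_adj,
                significant=p_adj < cfg.enrichment_alpha_adjusted,
            )
        )
    return results
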