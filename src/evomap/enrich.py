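"""Enrichment and association statistics.

The ion-binding pocket test asks: given that ``n`` of the 74 Sprinzl sites
show elevated substitution rates, what is the probability that ``k`` of them
fall within the ``K`` sites of the extended ion-binding pocket between the
D- and T-arms (Sprinzl coordinates 15-20, 59, 60)?  The point probability is
the hypergeometric mass C(K,k) C(N-K, n-k) / C(N,n), evaluated with exact
integer binomials.

Contingency chi-square association (e.g. chromosomal location versus pocket
substitutions) uses the Pearson statistic without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Sequence

import numpy as np
from scipy.stats import chi2_contingency

#: Extended ion-binding pocket between the D- and T-arms.
ION_POCKET_SITES = ("15", "16", "17", "18", "19", "20", "59", "60")


@dataclass(frozen=True)
class EnrichmentInput:
    """Overlap of a top-site set with a pocket-site set among N total sites."""

    N: int = 74
    pocket_sites: tuple[str, ...] = ION_POCKET_SITES
    top_sites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.pocket_sites)) != len(self.pocket_sites):
            raise ValueError("pocket sites must be unique")
        if len(set(self.top_sites)) != len(self.top_sites):
            raise ValueError("top sites must be unique")
        if self.K > self.N or self.n > self.N:
            raise ValueError("site sets cannot exceed the total site count")

    @property
    def K(self) -> int:
        return len(self.pocket_sites)

    @property
    def n(self) -> int:
        return len(self.top_sites)

    @property
    def k(self) -> int:
        return len(set(self.pocket_sites) & set(self.top_sites))


def hypergeometric_point(N: int, K: int, n: int, k: int) -> float:
    """Exact hypergeometric point probability C(K,k) C(N-K,n-k) / C(N,n)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or n - k > N - K:
        raise ValueError(
            f"invalid hypergeometric parameters N={N}, K={K}, n={n}, k={k}")
    frac = Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))
    return float(frac)


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail probability P(overlap >= k)."""
    return float(sum(
        Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
        for j in range(k, min(K, n) + 1)
        if n - j <= N - K
    ))


def pocket_enrichment(e: EnrichmentInput, tail: bool = False) -> float:
    """Pocket-overlap probability for an :class:`EnrichmentInput`."""
    f = hypergeometric_tail if tail else hypergeometric_point
    return f(e.N, e.K, e.n, e.k)


@dataclass(frozen=True)
class ContingencyTable:
    cells: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.cells)
        if arr.ndim != 2:
            raise ValueError("contingency table must be two-dimensional")
        if (arr < 0).any():
            raise ValueError("cells must be nonnegative")

    @property
    def N(self) -> int:
        return int(np.asarray(self.cells).sum())


def chi_square(table: ContingencyTable | Sequence[Sequence[int]]
               ) -> dict[str, float]:
    """Pearson chi-square of independence, no continuity correction.

    Returns statistic, degrees of freedom (r-1)(c-1), and p-value.
    """
    cells = table.cells if isinstance(table, ContingencyTable) else table
    arr = np.asarray(cells, dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column marginal")
    stat, p, dof, _ = chi2_contingency(arr, correction=False)
    return {"statistic": float(stat), "df": int(dof), "p": float(p)}
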