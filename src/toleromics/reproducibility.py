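"""Cross-experiment reproducibility of gene-class membership.

Two independent experiments each yield a gene set of a given class (say, the
NT genes).  Under random coincidence the expected intersection of sets of
sizes n1 and n2 drawn from N analysed genes is n12 = n1*n2/N (rounded to the
nearest integer, ties away from zero).  When the observed intersection n3
exceeds n12, the expected and observed proportions are compared by a Pearson
chi-square test on a 2x2 table; p < 0.05 marks the class as reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class OverlapResult:
    n1: int
    n2: int
    n3: int
    N: int
    p12: float  # random-coincidence probability
    n12: int  # expected number of coincidences
    chi2: float
    p_value: float
    significant: bool


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def expected_overlap(n1: int, n2: int, N: int) -> tuple[float, int]:
    """Random-coincidence probability p12 = n1*n2/N**2 and count n12."""
    if N <= 0:
        raise ValueError("N must be positive")
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ValueError(f"class sizes must lie in [0, N]; got n1={n1}, n2={n2}, N={N}")
    p12 = n1 * n2 / N**2
    n12 = _round_half_up(n1 * n2 / N)
    return p12, n12


def chi2_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square (1 df) on the table [[a, b], [c, d]].

    Degenerate tables (a zero row or column margin) return (0.0, 1.0).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def overlap_significance(
    n1: int, n2: int, n3: int, N: int, yates: bool = False
) -> OverlapResult:
    """Assess whether an observed class intersection exceeds chance.

    The test compares proportions n12/N (expected) and n3/N (observed) and is
    performed only when n3 > n12; otherwise the result records
    significant=False with p_value 1.0.
    """
    if n3 > min(n1, n2):
        raise ValueError(
            f"intersection n3={n3} exceeds a class size (n1={n1}, n2={n2})"
        )
    if n3 < 0:
        raise ValueError("n3 must be non-negative")
    p12, n12 = expected_overlap(n1, n2, N)
    if n3 <= n12:
        return OverlapResult(n1, n2, n3, N, p12, n12, 0.0, 1.0, False)
    chi2, p = chi2_2x2(n12, N - n12, n3, N - n3, yates=yates)
    return OverlapResult(n1, n2, n3, N, p12, n12, chi2, p, p < 0.05)


def compare_classifications(
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    classes: tuple[str, ...] = ("T", "NT", "SE", "NH"),
    yates: bool = False,
) -> pd.DataFrame:
    """Per-class overlap statistics between two classification tables.

    The gene universe N is the intersection of the two tables' gene sets;
    class membership is read from the ``overall`` column for T/NT and from
    ``subcategory`` for SE/NH.
    """
    from .classification import class_members

    universe = set(table1.index) & set(table2.index)
    if not universe:
        raise ValueError("classification tables share no genes")
    N = len(universe)
    rows = []
    for cls in classes:
        s1 = class_members(table1, cls) & universe
        s2 = class_members(table2, cls) & universe
        res = overlap_significance(len(s1), len(s2), len(s1 & s2), N, yates=yates)
        rows.append(
            {
                "gene_class": cls,
                "n1": res.n1,
                "n2": res.n2,
                "n3": res.n3,
                "N": res.N,
                "p12": res.p12,
                "n12": res.n12,
                "chi2": res.chi2,
                "p_value": res.p_value,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows).set_index("gene_class")
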